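"""Labelled expression-matrix containers and TSV/CSV round-trip I/O.

The central container is :class:`ExpressionMatrix`: an ``n`` conditions x
``d`` genes matrix of strictly positive abundances, with a ``scale`` flag
recording whether the values are absolute amounts, relative (closed)
abundances, or of unknown provenance.  Log-ratio transformed data live in
:class:`TransformedMatrix`, which carries the reference it was built with
(:class:`ReferenceSpec`) so downstream results are always attributable to a
specific reference choice.

On disk the format is a plain TSV/CSV table: one header row of gene
identifiers, one leading column of condition identifiers, floating-point
cells.  Writing uses 17 significant digits so a read/write round trip is
lossless to (at least) 15 significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataDomainError, ParameterError, ShapeError

Scale = Literal["absolute", "relative", "unknown"]

_CONDITION_COL = "condition"


def _check_labels(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        seen, dup = set(), None
        for x in labels:
            if x in seen:
                dup = x
                break
            seen.add(x)
        raise ParameterError(f"duplicate {what} label: {dup!r}")
    return labels


@dataclass
class ExpressionMatrix:
    """Conditions x genes matrix of positive expression values.

    Parameters
    ----------
    values
        ``(n, d)`` array of finite, nonnegative reals.  Zeros are tolerated
        in the container (so that raw counts can be loaded) but every
        log-ratio operation refuses them; apply :func:`~propcoda.transforms.pseudocount`
        first.
    condition_ids, gene_ids
        Unique row and column labels.
    scale
        ``"absolute"`` (original mRNA amounts), ``"relative"`` (row-closed
        or otherwise only ratio-informative), or ``"unknown"``.
    meta
        Free-form provenance (pseudocount applied, true log *s* of a
        simulation, ...).  Never interpreted by the statistics.
    """

    values: np.ndarray
    condition_ids: list[str]
    gene_ids: list[str]
    scale: Scale = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(f"values must be 2-D, got shape {self.values.shape}")
        n, d = self.values.shape
        if n < 3:
            raise ShapeError(f"need at least 3 conditions (rows), got {n}")
        if d < 1:
            raise ShapeError("need at least one gene (column)")
        self.condition_ids = _check_labels(self.condition_ids, "condition")
        self.gene_ids = _check_labels(self.gene_ids, "gene")
        if len(self.condition_ids) != n:
            raise ShapeError(
                f"{len(self.condition_ids)} condition labels for {n} rows"
            )
        if len(self.gene_ids) != d:
            raise ShapeError(f"{len(self.gene_ids)} gene labels for {d} columns")
        if not np.all(np.isfinite(self.values)):
            raise DataDomainError("non-finite entries in expression matrix")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise DataDomainError(
                f"negative entry at condition {self.condition_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        if self.scale not in ("absolute", "relative", "unknown"):
            raise ParameterError(f"unknown scale flag {self.scale!r}")

    # -- basic introspection -------------------------------------------------

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def has_zeros(self) -> bool:
        return bool(np.any(self.values == 0.0))

    def require_positive(self) -> None:
        """Raise :class:`DataDomainError` naming the first offending entry
        if any value is not strictly positive."""
        if self.has_zeros:
            i, j = np.argwhere(self.values == 0.0)[0]
            raise DataDomainError(
                f"zero entry at condition {self.condition_ids[i]!r}, gene "
                f"{self.gene_ids[j]!r}; apply a pseudocount before log-ratio "
                "transforms"
            )

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not found") from None

    def column(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene_id)]

    def log(self) -> np.ndarray:
        """Natural log of the values (requires strictly positive entries)."""
        self.require_positive()
        return np.log(self.values)

    # -- conversion ----------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.condition_ids, columns=self.gene_ids
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, scale: Scale = "unknown", **meta
    ) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            condition_ids=[str(i) for i in df.index],
            gene_ids=[str(c) for c in df.columns],
            scale=scale,
            meta=dict(meta),
        )


@dataclass
class ReferenceSpec:
    """Specification of the log-ratio reference.

    ``kind`` is one of ``"gene"`` (additive log-ratio with a named gene),
    ``"geometric_mean"`` (centred log-ratio), or ``"supplied_normalizer"``
    (an explicit per-condition positive factor, the normalization-as-
    backtransform view).
    """

    kind: Literal["gene", "geometric_mean", "supplied_normalizer"]
    gene_id: str | None = None
    normalizer: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind == "gene" and self.gene_id is None:
            raise ParameterError("kind='gene' requires gene_id")
        if self.kind == "supplied_normalizer":
            if self.normalizer is None:
                raise ParameterError(
                    "kind='supplied_normalizer' requires a normalizer vector"
                )
            self.normalizer = np.asarray(self.normalizer, dtype=float)
            if np.any(~np.isfinite(self.normalizer)) or np.any(
                self.normalizer <= 0
            ):
                raise DataDomainError("normalizer must be strictly positive")


@dataclass
class TransformedMatrix:
    """Log-ratio transformed data with its reference specification."""

    values: np.ndarray
    condition_ids: list[str]
    gene_ids: list[str]
    reference: ReferenceSpec
    parent_gene_ids: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError("values must be 2-D")
        if self.values.shape != (len(self.condition_ids), len(self.gene_ids)):
            raise ShapeError("labels do not match matrix shape")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not found") from None

    def column(self, gene_id: str) -> np.ndarray:
        return self.values[:, self.gene_index(gene_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.condition_ids, columns=self.gene_ids
        )


# -- file I/O ----------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path, scale: Scale = "unknown") -> ExpressionMatrix:
    """Read a conditions x genes table (TSV by default, CSV for ``.csv``).

    First column: condition identifiers; header row: gene identifiers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return ExpressionMatrix.from_dataframe(df, scale=scale, source=str(path))


def write_matrix(m: ExpressionMatrix | TransformedMatrix, path: str | Path) -> None:
    """Write a matrix in the same dialect :func:`read_matrix` reads.

    Cells are printed with 17 significant digits, so the round trip is
    lossless at double precision.
    """
    path = Path(path)
    df = m.to_dataframe()
    df.index.name = _CONDITION_COL
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")
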