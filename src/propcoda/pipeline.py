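"""End-to-end analysis surface: model object, all-pairs tables, confusion.

The user-facing entry point is :class:`ProportionalityModel`, a
statsmodels-style model object: construct it from an
:class:`~propcoda.data.ExpressionMatrix` (or DataFrame) together with the
preprocessing choices (pseudocount, transform, reference), call
:meth:`~ProportionalityModel.fit` and get a
:class:`ProportionalityResults` holding the all-pairs statistics table,
the threshold/selection logic, a ``summary()`` and the comparison
machinery against a second (e.g. absolute-data) run.

All-pairs statistics are computed from the gene-gene covariance matrix in
one vectorized pass, so a few thousand genes (millions of pairs) are
practical on one CPU.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, TransformedMatrix
from .exceptions import ParameterError, ShapeError, UndefinedStatisticError
from . import transforms as _tf

__all__ = [
    "ProportionalityModel",
    "ProportionalityResults",
    "ConfusionSummary",
    "all_pairs_stats",
    "threshold_pairs",
    "compare_predictions",
    "full_specificity_cutoff",
    "select_reference_min_cv",
    "slope_diagnostic",
]

log = logging.getLogger(__name__)

_PAIR_COLUMNS = ["gene_i", "gene_j", "vlr", "rho", "phi", "beta", "r"]


def _logged_values(m) -> tuple[np.ndarray, list[str]]:
    if isinstance(m, TransformedMatrix):
        return m.values, list(m.gene_ids)
    if isinstance(m, ExpressionMatrix):
        return m.log(), list(m.gene_ids)
    raise ParameterError(f"unsupported matrix type {type(m).__name__}")


def all_pairs_stats(m) -> pd.DataFrame:
    """Per-pair statistics for every gene pair i < j.

    Accepts a :class:`TransformedMatrix` (already on the log-ratio scale)
    or an :class:`ExpressionMatrix` (logged internally).  Returns a tidy
    table with columns ``gene_i, gene_j, vlr, rho, phi, beta, r`` where
    ``phi`` is oriented with the *row* gene i in the denominator
    (``phi = vlr / var_i``; the transposed orientation is ``phi * beta**2
    / ...`` - recompute by swapping i and j, or use ``vlr / var_j``).
    Genes with zero variance are excluded and listed in
    ``df.attrs["degenerate_genes"]``.
    """
    logs, gene_ids = _logged_values(m)
    if logs.shape[1] < 2:
        raise ShapeError("need at least 2 genes")
    if logs.shape[0] < 3:
        raise ShapeError("need at least 3 conditions")
    v = logs.var(axis=0, ddof=1)
    keep = v > 0
    degenerate = [g for g, k in zip(gene_ids, keep) if not k]
    if degenerate:
        log.warning(
            "excluding %d zero-variance genes: %s",
            len(degenerate),
            degenerate[:10],
        )
    logs = logs[:, keep]
    gene_ids = [g for g, k in zip(gene_ids, keep) if k]
    if len(gene_ids) < 2:
        raise UndefinedStatisticError(
            "fewer than 2 genes with positive variance"
        )
    v = v[keep]
    cov = np.cov(logs, rowvar=False, ddof=1)
    iu, ju = np.triu_indices(len(gene_ids), k=1)
    c = cov[iu, ju]
    vi, vj = v[iu], v[ju]
    vlr = vi + vj - 2.0 * c
    rho = 2.0 * c / (vi + vj)
    np.clip(rho, -1.0, 1.0, out=rho)
    df = pd.DataFrame(
        {
            "gene_i": np.asarray(gene_ids, dtype=object)[iu],
            "gene_j": np.asarray(gene_ids, dtype=object)[ju],
            "vlr": vlr,
            "rho": rho,
            "phi": vlr / vi,
            "beta": np.sqrt(vj / vi),
            "r": c / np.sqrt(vi * vj),
        }
    )
    df.attrs["degenerate_genes"] = degenerate
    return df


def _pair_key(df: pd.DataFrame) -> pd.Series:
    """Order-free pair key so tables align regardless of column order."""
    a = df["gene_i"].astype(str)
    b = df["gene_j"].astype(str)
    return np.where(a <= b, a + "\t" + b, b + "\t" + a)


def threshold_pairs(table: pd.DataFrame, K: float, statistic: str = "rho") -> set:
    """Select pairs called proportional at cut-off K (inclusive).

    ``rho``: keep pairs with ``rho >= K``; ``phi``: keep ``phi <= K``
    (small phi means proportional).
    """
    if statistic == "rho":
        if not -1.0 < K < 1.0:
            raise ParameterError(f"rho cut-off must lie in (-1, 1), got {K!r}")
        kept = table[table["rho"] >= K]
    elif statistic == "phi":
        if not K > 0:
            raise ParameterError(f"phi cut-off must be positive, got {K!r}")
        kept = table[table["phi"] <= K]
    else:
        raise ParameterError(f"unknown statistic {statistic!r}")
    return {
        tuple(sorted(p)) for p in zip(kept["gene_i"], kept["gene_j"])
    }


@dataclass
class ConfusionSummary:
    """Absolute-vs-relative confusion counts and derived rates.

    ``ppv = TP/(TP+FP)`` and ``sensitivity = TP/(TP+FN)`` are ``None``
    when their denominators are empty (not coerced to 0).
    ``full_specificity_cutoff`` is the exclusive bound on the relative
    statistic above which no false positives remain.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    cutoff_abs: float
    cutoff_rel: float
    full_specificity_cutoff: float | None = None

    @property
    def n_pairs(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    def to_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
            "PPV": self.ppv,
            "sensitivity": self.sensitivity,
            "cutoff_abs": self.cutoff_abs,
            "cutoff_rel": self.cutoff_rel,
            "full_specificity_cutoff": self.full_specificity_cutoff,
        }


def _aligned(abs_table: pd.DataFrame, rel_table: pd.DataFrame) -> pd.DataFrame:
    a = abs_table.assign(_key=_pair_key(abs_table)).set_index("_key")
    r = rel_table.assign(_key=_pair_key(rel_table)).set_index("_key")
    if len(a) != len(r) or not a.index.sort_values().equals(
        r.index.sort_values()
    ):
        raise ShapeError(
            "absolute and relative tables cover different pair universes"
        )
    return a.join(r[["rho", "phi"]], rsuffix="_rel")


def compare_predictions(
    abs_table: pd.DataFrame,
    rel_table: pd.DataFrame,
    K_abs: float,
    K_rel: float,
    statistic: str = "rho",
) -> ConfusionSummary:
    """Confusion summary of relative-data calls against absolute-data calls.

    Pairs are aligned by sorted gene-id keys; a mismatch in the pair
    universe raises.  TP = called on both, FP = relative only,
    FN = absolute only, TN = neither (inclusive thresholds; for phi the
    call is ``<= K``).
    """
    j = _aligned(abs_table, rel_table)
    if statistic == "rho":
        on_abs = j["rho"] >= K_abs
        on_rel = j["rho_rel"] >= K_rel
    elif statistic == "phi":
        on_abs = j["phi"] <= K_abs
        on_rel = j["phi_rel"] <= K_rel
    else:
        raise ParameterError(f"unknown statistic {statistic!r}")
    tp = int((on_abs & on_rel).sum())
    fp = int((~on_abs & on_rel).sum())
    fn = int((on_abs & ~on_rel).sum())
    tn = int((~on_abs & ~on_rel).sum())
    return ConfusionSummary(
        tp=tp, fp=fp, tn=tn, fn=fn, cutoff_abs=K_abs, cutoff_rel=K_rel
    )


def full_specificity_cutoff(
    abs_table: pd.DataFrame,
    rel_table: pd.DataFrame,
    K_abs: float,
    statistic: str = "rho",
) -> float:
    """Exclusive cut-off on the relative statistic removing all FPs.

    For rho: the maximum relative-data rho over false-positive pairs; any
    cut-off strictly above it yields zero FP (for phi, the minimum over
    FPs, and cut-offs strictly below work).  With no FPs at ``K_abs`` the
    value ``K_abs`` itself is returned.
    """
    j = _aligned(abs_table, rel_table)
    if statistic == "rho":
        fp = j[(j["rho"] < K_abs) & (j["rho_rel"] >= K_abs)]
        if fp.empty:
            return float(K_abs)
        return float(fp["rho_rel"].max())
    elif statistic == "phi":
        fp = j[(j["phi"] > K_abs) & (j["phi_rel"] <= K_abs)]
        if fp.empty:
            return float(K_abs)
        return float(fp["phi_rel"].min())
    raise ParameterError(f"unknown statistic {statistic!r}")


def select_reference_min_cv(
    m: ExpressionMatrix, top: int = 10
) -> tuple[str, pd.DataFrame]:
    """Pick the alr reference gene by minimum coefficient of variation.

    The CV (sd/mean of the *unlogged* expression across conditions) is
    meaningful on absolute-scale data; calling this on relative data is
    allowed but logged as a caveat, since closure distorts per-gene
    variation.  Ties are broken by lexicographic gene id (logged).

    Returns the chosen gene and a report of the ``top`` candidates with
    their CVs and per-condition expression, for the manual inspection of
    condition bias that no formula replaces: a gene can have a low CV yet
    be systematically high or low in one condition.
    """
    if m.scale != "absolute":
        log.warning(
            "selecting a reference by CV on %s-scale data; CVs on closed "
            "data reflect the closure, not absolute stability",
            m.scale,
        )
    mean = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=1)
    cv = sd / mean
    order = np.lexsort((np.asarray(m.gene_ids, dtype=object), cv))
    best = m.gene_ids[order[0]]
    if len(order) > 1 and math.isclose(
        cv[order[0]], cv[order[1]], rel_tol=0.0, abs_tol=0.0
    ):
        log.warning("CV tie at %.6g broken lexicographically -> %r",
                    cv[order[0]], best)
    idx = order[: min(top, len(order))]
    report = pd.DataFrame(
        {
            "gene": [m.gene_ids[i] for i in idx],
            "cv": cv[idx],
            "mean": mean[idx],
            "sd": sd[idx],
        }
    )
    per_cond = pd.DataFrame(
        m.values[:, idx].T,
        index=report["gene"],
        columns=m.condition_ids,
    )
    report = report.set_index("gene").join(per_cond)
    return best, report.reset_index()


def slope_diagnostic(a_i, a_j) -> tuple[float, float]:
    """Through-origin slope and log-scale intercept diagnostic for a pair.

    On the unlogged scale the slope of gene j against gene i is estimated
    by ``sqrt(var(exp(a_j)) / var(exp(a_i)))`` (a line through the origin,
    matching a beta = 1 fit of the logs); on the logged scale the beta = 1
    intercept is ``mean(a_j - a_i)``.  ``slope(i, j) * slope(j, i) = 1``.
    """
    a_i = np.asarray(a_i, dtype=float)
    a_j = np.asarray(a_j, dtype=float)
    if a_i.shape != a_j.shape or a_i.ndim != 1:
        raise ShapeError("a_i, a_j must be 1-D of equal length")
    e_i, e_j = np.exp(a_i), np.exp(a_j)
    if not (np.all(np.isfinite(e_i)) and np.all(np.isfinite(e_j))):
        raise UndefinedStatisticError("exponentials overflow; rescale inputs")
    v_i = np.var(e_i, ddof=1)
    if v_i == 0.0:
        raise UndefinedStatisticError("var(exp(a_i)) is zero")
    slope = float(np.sqrt(np.var(e_j, ddof=1) / v_i))
    intercept = float(np.mean(a_j - a_i))
    return slope, intercept


# -- model / results objects -------------------------------------------------


class ProportionalityModel:
    """Proportionality analysis of one expression matrix.

    Parameters
    ----------
    data
        Expression matrix (conditions x genes, positive values).
    transform
        ``"alr"``, ``"clr"`` or ``"none"`` (``"none"`` analyses plain logs,
        appropriate for absolute-scale data).
    reference
        Gene id for alr, or ``"auto"`` to select by minimum CV.
    pseudocount
        Optional constant added before logging; required if zeros are
        present (no silent default).

    Examples
    --------
    >>> model = ProportionalityModel(matrix, transform="alr", reference="auto")
    >>> res = model.fit(cutoff=0.98)
    >>> res.proportional_pairs()           # doctest: +SKIP
    """

    def __init__(
        self,
        data: ExpressionMatrix,
        transform: str = "clr",
        reference: str | None = None,
        pseudocount: float | None = None,
    ) -> None:
        if transform not in ("alr", "clr", "none"):
            raise ParameterError(f"unknown transform {transform!r}")
        if transform == "alr" and reference is None:
            raise ParameterError("alr requires a reference gene or 'auto'")
        self.data = data
        self.transform = transform
        self.reference = reference
        self.pseudocount = pseudocount

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, scale: str = "unknown", **kwargs
    ) -> "ProportionalityModel":
        return cls(ExpressionMatrix.from_dataframe(df, scale=scale), **kwargs)

    def fit(self, cutoff: float = 0.98, statistic: str = "rho") -> "ProportionalityResults":
        """Run the transform and the all-pairs computation."""
        m = self.data
        if self.pseudocount is not None:
            m = _tf.pseudocount(m, self.pseudocount)
        m.require_positive()

        reference_report = None
        reference_used = None
        if self.transform == "alr":
            ref = self.reference
            if ref == "auto":
                ref, reference_report = select_reference_min_cv(m)
            reference_used = ref
            transformed = _tf.alr(m, ref)
        elif self.transform == "clr":
            transformed = _tf.clr(m)
        else:
            transformed = None

        table = all_pairs_stats(transformed if transformed is not None else m)
        return ProportionalityResults(
            model=self,
            pairs=table,
            transformed=transformed,
            cutoff=cutoff,
            statistic=statistic,
            reference_used=reference_used,
            reference_report=reference_report,
        )


class ProportionalityResults:
    """Fitted all-pairs proportionality table plus selection/comparison.

    Attributes
    ----------
    pairs : pandas.DataFrame
        Tidy per-pair statistics (``gene_i, gene_j, vlr, rho, phi, beta, r``).
    transformed : TransformedMatrix or None
        The log-ratio data the statistics were computed on (None when the
        model ran on plain logs).
    """

    def __init__(
        self,
        model: ProportionalityModel,
        pairs: pd.DataFrame,
        transformed: TransformedMatrix | None,
        cutoff: float,
        statistic: str,
        reference_used: str | None,
        reference_report: pd.DataFrame | None,
    ) -> None:
        self.model = model
        self.pairs = pairs
        self.transformed = transformed
        self.cutoff = cutoff
        self.statistic = statistic
        self.reference_used = reference_used
        self.reference_report = reference_report

    def proportional_pairs(self, cutoff: float | None = None) -> set:
        """Pairs called proportional at the given (or fitted) cut-off."""
        K = self.cutoff if cutoff is None else cutoff
        return threshold_pairs(self.pairs, K, self.statistic)

    def compare(
        self,
        other: "ProportionalityResults",
        cutoff_abs: float | None = None,
        cutoff_rel: float | None = None,
    ) -> ConfusionSummary:
        """Confusion of *this* run (relative) against ``other`` (absolute).

        Also fills in the full-specificity cut-off adjustment.
        """
        K_abs = other.cutoff if cutoff_abs is None else cutoff_abs
        K_rel = self.cutoff if cutoff_rel is None else cutoff_rel
        cs = compare_predictions(
            other.pairs, self.pairs, K_abs, K_rel, self.statistic
        )
        cs.full_specificity_cutoff = full_specificity_cutoff(
            other.pairs, self.pairs, K_abs, self.statistic
        )
        return cs

    def partial_wrt(self, k: str) -> pd.DataFrame:
        """Partial proportionality of all pairs given gene ``k`` (requires
        a transformed matrix)."""
        from .partial_prop import partial_rho_matrix

        if self.transformed is None:
            raise ParameterError(
                "partial coefficients need the transformed matrix; fit with "
                "transform='alr' or 'clr'"
            )
        return partial_rho_matrix(self.transformed, k)

    def summary(self, top: int = 10) -> str:
        """Human-readable run summary."""
        p = self.pairs
        called = self.proportional_pairs()
        lines = [
            "Proportionality analysis",
            "=" * 24,
            f"conditions:    {self.model.data.n_conditions}",
            f"genes:         {self.model.data.n_genes}"
            + (
                f" ({len(p.attrs.get('degenerate_genes', []))} degenerate "
                "excluded)"
                if p.attrs.get("degenerate_genes")
                else ""
            ),
            f"scale flag:    {self.model.data.scale}",
            f"transform:     {self.model.transform}"
            + (
                f" (reference: {self.reference_used})"
                if self.reference_used
                else ""
            ),
            f"statistic:     {self.statistic} "
            f"({'>=' if self.statistic == 'rho' else '<='} {self.cutoff})",
            f"pairs:         {len(p)}",
            f"called:        {len(called)}",
            "",
            f"top {top} pairs by |rho|:",
        ]
        show = p.reindex(
            p["rho"].abs().sort_values(ascending=False).index
        ).head(top)
        lines.append(
            show.to_string(
                index=False, float_format=lambda x: f"{x: .4f}"
            )
        )
        return "\n".join(lines)

    # -- plotting helpers (optional; imported lazily) ------------------------

    def plot_scatter(self, other: "ProportionalityResults", ax=None):
        """Scatter of this run's statistic against ``other``'s, with the
        fitted cut-offs marked (diagnostic for absolute-vs-relative runs)."""
        import matplotlib.pyplot as plt

        j = _aligned(other.pairs, self.pairs)
        if ax is None:
            _, ax = plt.subplots()
        col = self.statistic
        ax.scatter(j[col], j[f"{col}_rel"], s=2, alpha=0.3, color="grey")
        ax.axvline(other.cutoff, color="red", lw=0.8)
        ax.axhline(self.cutoff, color="red", lw=0.8)
        ax.set_xlabel(f"{col} (reference run)")
        ax.set_ylabel(f"{col} (this run)")
        return ax

    def plot_hist(self, column: str = "rho", bins: int = 50, ax=None):
        """Histogram of a pair-statistic column."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.pairs[column].dropna(), bins=bins, color="grey")
        ax.set_xlabel(column)
        ax.set_ylabel("pairs")
        return ax
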