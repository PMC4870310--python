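"""Compositional preprocessing: closure, pseudocounts, alr/clr transforms.

Relative expression data only carry ratio information: each condition (row)
can be divided by an arbitrary positive factor without changing anything
measurable.  The log-ratio transforms remove this ambiguity by expressing
every gene against a reference:

* :func:`alr` - additive log-ratio, ``log(x_j / x_ref)`` against one named
  reference gene, which is "sacrificed" (output has ``d - 1`` columns);
* :func:`clr` - centred log-ratio, ``log(x_j / g(x))`` against the
  per-condition geometric mean ``g(x)`` (output keeps ``d`` columns, rows
  sum to zero);
* :func:`backtransform_check` - the normalization-as-backtransform view:
  subtract the log of a supplied per-condition normalizer, e.g. the true
  total mRNA factor ``s`` times an unchanged gene.

Log-ratio variances between retained genes are exactly unchanged by any of
these (the reference cancels), which is the formal reason proportionality
is computable on relative data at all.  Individual variances, by contrast,
depend on the reference - that dependence is quantified in
:mod:`propcoda.reference_theory`.

Zeros are never patched silently: transforms refuse them and the caller
must apply :func:`pseudocount` explicitly (recorded in ``meta``).
"""

from __future__ import annotations

import numpy as np

from .data import ExpressionMatrix, ReferenceSpec, TransformedMatrix
from .exceptions import ParameterError, ShapeError

__all__ = ["closure", "pseudocount", "alr", "clr", "backtransform_check"]


def closure(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each row by its sum so rows become compositions summing to 1.

    Within-row ratios (hence every log-ratio statistic) are preserved
    exactly; the result is flagged ``scale="relative"``.
    """
    m.require_positive()
    vals = m.values / m.values.sum(axis=1, keepdims=True)
    return ExpressionMatrix(
        values=vals,
        condition_ids=list(m.condition_ids),
        gene_ids=list(m.gene_ids),
        scale="relative",
        meta={**m.meta, "closed": True},
    )


def pseudocount(m: ExpressionMatrix, c: float) -> ExpressionMatrix:
    """Add a constant ``c > 0`` to every entry (recorded in ``meta``).

    There is no default value: the choice of pseudocount is a data-analytic
    decision the caller must make and own.
    """
    if not (c > 0):
        raise ParameterError(f"pseudocount must be > 0, got {c!r}")
    return ExpressionMatrix(
        values=m.values + c,
        condition_ids=list(m.condition_ids),
        gene_ids=list(m.gene_ids),
        scale=m.scale,
        meta={**m.meta, "pseudocount": float(c)},
    )


def alr(m: ExpressionMatrix, ref: str) -> TransformedMatrix:
    """Additive log-ratio transform with gene ``ref`` as the reference.

    Column ``j`` of the output is ``log(x_j / x_ref)`` row-wise, for every
    gene except the reference itself; original gene ordering is kept.  If
    the reference is (on the absolute scale) unchanged across conditions,
    this recovers the absolute-data proportionality structure exactly.
    """
    m.require_positive()
    k = m.gene_index(ref)  # raises KeyError if absent
    logs = np.log(m.values)
    out = np.delete(logs - logs[:, [k]], k, axis=1)
    gene_ids = [g for g in m.gene_ids if g != ref]
    return TransformedMatrix(
        values=out,
        condition_ids=list(m.condition_ids),
        gene_ids=gene_ids,
        reference=ReferenceSpec(kind="gene", gene_id=ref),
        parent_gene_ids=list(m.gene_ids),
        meta=dict(m.meta),
    )


def clr(m: ExpressionMatrix) -> TransformedMatrix:
    """Centred log-ratio transform (geometric-mean reference).

    The geometric mean is computed as the exponential-free mean of logs for
    numerical stability; output rows sum to zero.  Note clr is
    sub-compositionally incoherent: transforming a subset of genes is not
    the same as subsetting the transformed matrix, because the reference
    itself changes with the gene set.
    """
    m.require_positive()
    logs = np.log(m.values)
    out = logs - logs.mean(axis=1, keepdims=True)
    return TransformedMatrix(
        values=out,
        condition_ids=list(m.condition_ids),
        gene_ids=list(m.gene_ids),
        reference=ReferenceSpec(kind="geometric_mean"),
        parent_gene_ids=list(m.gene_ids),
        meta=dict(m.meta),
    )


def backtransform_check(
    relative: ExpressionMatrix, normalizer
) -> TransformedMatrix:
    """Supplied-normalizer log-ratio: ``log(x) - log(normalizer)`` per row.

    With the true per-condition factor (total mRNA amount ``s`` times the
    closure constant) this recovers the logged absolute data up to an
    additive per-gene constant - i.e. normalization is itself a log-ratio
    transformation.  With an all-ones normalizer it is a plain log.
    """
    normalizer = np.asarray(normalizer, dtype=float)
    if normalizer.shape != (relative.n_conditions,):
        raise ShapeError(
            f"normalizer length {normalizer.shape} does not match "
            f"{relative.n_conditions} conditions"
        )
    relative.require_positive()
    spec = ReferenceSpec(kind="supplied_normalizer", normalizer=normalizer)
    out = np.log(relative.values) - np.log(spec.normalizer)[:, None]
    return TransformedMatrix(
        values=out,
        condition_ids=list(relative.condition_ids),
        gene_ids=list(relative.gene_ids),
        reference=spec,
        parent_gene_ids=list(relative.gene_ids),
        meta=dict(relative.meta),
    )
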