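"""Partial proportionality of a gene pair with respect to a third gene.

Partial correlation removes, from the correlation of two variables, the
part mediated by a third.  The same construction applies to the
proportionality coefficient: regress ``y_i`` and ``y_j`` (logged,
transformed expression) on ``y_k`` by least squares (with intercept), and
evaluate rho on the residuals.  The result has three equivalent closed
forms in terms of pairwise moments:

(i)   ``1 - vlr*(1 - corr(y_i - y_j, y_k)^2) /
      (var_i*(1 - r_ik^2) + var_j*(1 - r_jk^2))``

(ii)  ``2*(r - r_ik*r_jk) / ((1 - r_jk^2)*beta + (1 - r_ik^2)/beta)``

(iii) ``(1 - beta_tilde^2/G) / (1 + beta_tilde^2/G)`` with
      ``G = (1 - corr(y_i + y_j, y_k)^2) / (1 - corr(y_i - y_j, y_k)^2)``

where ``beta``, ``beta_tilde``, ``r`` are as in :mod:`propcoda.comp_core`.
Geometrically: partialling on a direction perpendicular to the pair leaves
rho unchanged; partialling on the pair's log ratio (``y_k`` parallel to
``y_i - y_j``) gives partial proportionality +1; on the pair sum, partial
reciprocality -1; on either member alone, 0.

:func:`partial_rho` computes all three forms and checks their mutual
agreement; :func:`partial_rho_residuals` is the brute-force regression
route kept as an independent oracle.  Partialling is restricted to a
single third gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import comp_core
from .data import TransformedMatrix
from .exceptions import (
    DegenerateResidualError,
    ShapeError,
    UndefinedStatisticError,
)

__all__ = [
    "PartialStats",
    "partial_rho",
    "partial_rho_residuals",
    "partial_rho_matrix",
]

log = logging.getLogger(__name__)

#: residual variance below this fraction of the input variance counts as
#: degenerate (the covariate absorbs the gene entirely)
RESIDUAL_TOL = 1e-14

#: mutual-agreement guard between the three closed forms
_FORM_AGREE_TOL = 1e-6


@dataclass
class PartialStats:
    """Partial proportionality of a pair (i, j) given covariate k.

    Carries the pairwise correlations entering the closed forms and the
    variance-ratio factor ``G``; ``rho_partial`` is the common value of the
    three forms.
    """

    rho_partial: float
    r: float
    r_ik: float
    r_jk: float
    beta: float
    beta_tilde: float
    G: float
    forms: tuple[float, float, float]


def _moments(y_i, y_j, y_k):
    y_i = np.asarray(y_i, dtype=float)
    y_j = np.asarray(y_j, dtype=float)
    y_k = np.asarray(y_k, dtype=float)
    if not (y_i.shape == y_j.shape == y_k.shape) or y_i.ndim != 1:
        raise ShapeError("y_i, y_j, y_k must be 1-D of equal length")
    if y_i.size < 4:
        raise ShapeError(
            f"partialling needs length >= 4, got {y_i.size}"
        )
    cov = np.cov(np.vstack([y_i, y_j, y_k]), ddof=1)
    v_i, v_j, v_k = np.diag(cov)
    if v_i <= 0 or v_j <= 0:
        raise UndefinedStatisticError("pair variances must be positive")
    if v_k <= 0:
        raise DegenerateResidualError("covariate y_k has zero variance")
    return y_i, y_j, y_k, cov


def partial_rho(y_i, y_j, y_k) -> PartialStats:
    """Partial proportionality coefficient of (y_i, y_j) given y_k.

    Evaluates the three closed forms from pairwise moments, verifies they
    agree, and returns form (ii) as the canonical value.

    Raises
    ------
    DegenerateResidualError
        If y_k has zero variance, or is so collinear with *both* members
        that the residual pair is degenerate.
    """
    y_i, y_j, y_k, cov = _moments(y_i, y_j, y_k)
    v_i, v_j, v_k = np.diag(cov)
    r = cov[0, 1] / np.sqrt(v_i * v_j)
    r_ik = cov[0, 2] / np.sqrt(v_i * v_k)
    r_jk = cov[1, 2] / np.sqrt(v_j * v_k)
    beta = np.sqrt(v_j / v_i)

    res_i = v_i * (1.0 - r_ik**2)  # residual variances
    res_j = v_j * (1.0 - r_jk**2)
    if res_i < RESIDUAL_TOL * v_i and res_j < RESIDUAL_TOL * v_j:
        raise DegenerateResidualError(
            "y_k is collinear with both members of the pair; "
            "residual pair is degenerate"
        )

    v_diff = v_i + v_j - 2.0 * cov[0, 1]
    v_sum = v_i + v_j + 2.0 * cov[0, 1]
    c_diff_k = cov[0, 2] - cov[1, 2]
    c_sum_k = cov[0, 2] + cov[1, 2]
    # squared correlations of the rotated pair with the covariate
    q_diff = c_diff_k**2 / (v_diff * v_k) if v_diff > 0 else 0.0
    q_sum = c_sum_k**2 / (v_sum * v_k) if v_sum > 0 else 0.0

    denom_i = res_i + res_j
    form1 = 1.0 - v_diff * (1.0 - q_diff) / denom_i

    form2 = (
        2.0
        * (r - r_ik * r_jk)
        / ((1.0 - r_jk**2) * beta + (1.0 - r_ik**2) / beta)
    )

    beta_tilde = np.sqrt(v_diff / v_sum) if v_sum > 0 else np.inf
    one_minus_qd = 1.0 - q_diff
    G = (1.0 - q_sum) / one_minus_qd if one_minus_qd > 0 else np.inf
    if np.isinf(G):
        form3 = 1.0  # covariate parallel to the log ratio
    elif np.isinf(beta_tilde) or G == 0.0:
        form3 = -1.0  # covariate parallel to the pair sum
    else:
        t = beta_tilde**2 / G
        form3 = (1.0 - t) / (1.0 + t)

    forms = (float(form1), float(form2), float(form3))
    spread = max(forms) - min(forms)
    if spread > _FORM_AGREE_TOL * max(1.0, *map(abs, forms)):
        raise UndefinedStatisticError(
            f"closed forms disagree ({forms}); input too close to a "
            "degenerate configuration"
        )
    return PartialStats(
        rho_partial=forms[1],
        r=float(r),
        r_ik=float(r_ik),
        r_jk=float(r_jk),
        beta=float(beta),
        beta_tilde=float(beta_tilde),
        G=float(G),
        forms=forms,
    )


def partial_rho_residuals(y_i, y_j, y_k) -> float:
    """Brute-force route: rho of the least-squares residuals.

    Fits ``y_i ~ 1 + y_k`` and ``y_j ~ 1 + y_k`` and returns
    ``rho(residual_i, residual_j)`` via :func:`propcoda.comp_core.rho`.
    Kept deliberately independent of :func:`partial_rho` as its oracle.
    """
    y_i, y_j, y_k, cov = _moments(y_i, y_j, y_k)
    X = np.column_stack([np.ones_like(y_k), y_k])
    res_i = y_i - X @ np.linalg.lstsq(X, y_i, rcond=None)[0]
    res_j = y_j - X @ np.linalg.lstsq(X, y_j, rcond=None)[0]
    v_i, v_j = cov[0, 0], cov[1, 1]
    if (
        np.var(res_i, ddof=1) < RESIDUAL_TOL * v_i
        and np.var(res_j, ddof=1) < RESIDUAL_TOL * v_j
    ):
        raise DegenerateResidualError("both residuals are degenerate")
    return comp_core.rho(res_i, res_j)


def partial_rho_matrix(transformed: TransformedMatrix, k: str) -> pd.DataFrame:
    """Partial proportionality of every gene pair given covariate gene k.

    Returns a tidy table with columns ``gene_i, gene_j, k, rho_partial, r,
    r_ik, r_jk`` over all pairs i < j excluding k.  Pairs that are
    degenerate given k are skipped with a warning and listed in
    ``df.attrs["skipped"]``.
    """
    y_k = transformed.column(k)
    genes = [g for g in transformed.gene_ids if g != k]
    if len(genes) < 2:
        raise ShapeError("need at least 2 genes besides k")
    rows, skipped = [], []
    for a in range(len(genes)):
        for b in range(a + 1, len(genes)):
            gi, gj = genes[a], genes[b]
            try:
                st = partial_rho(
                    transformed.column(gi), transformed.column(gj), y_k
                )
            except (DegenerateResidualError, UndefinedStatisticError) as exc:
                log.warning("skipping pair (%s, %s) wrt %s: %s", gi, gj, k, exc)
                skipped.append((gi, gj))
                continue
            rows.append(
                {
                    "gene_i": gi,
                    "gene_j": gj,
                    "k": k,
                    "rho_partial": st.rho_partial,
                    "r": st.r,
                    "r_ik": st.r_ik,
                    "r_jk": st.r_jk,
                }
            )
    df = pd.DataFrame(
        rows, columns=["gene_i", "gene_j", "k", "rho_partial", "r", "r_ik", "r_jk"]
    )
    df.attrs["skipped"] = skipped
    return df
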