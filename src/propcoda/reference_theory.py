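"""Closed-form theory of reference-induced distortion of proportionality.

Write ``A_i = log(s * X_i)`` for the logged absolute abundances and
``Y_i = log(X_i / X_d) = A_i - A_d`` for the additive log-ratio transform
of the relative data with reference gene ``d``.  How far can
``rho(Y_i, Y_j)`` stray from the absolute-data coefficient
``rho(A_i, A_j)``?  The answer is exact and remarkably compact.  With the
scaled reference size

    varphi = sqrt(var(2*A_d) / (var(A_i) + var(A_j)))
           = sqrt(4 * var_ref / (var_i + var_j))

and the distortion scalar

    F = varphi**2 - 2*sqrt(1 + rho_abs) * corr(A_i + A_j, A_d) * varphi

the exact relation is

    rho(Y_i, Y_j) - rho(A_i, A_j) = (1 - rho_abs) / (1 + 2/F).

Everything else in this module is bookkeeping around that relation: the
small-``varphi`` series for an approximately unchanged reference, the
worst-case cut-off adjustment bounds in terms of the variance ratio
``C = (var_i + var_j) / (2 * var_ref) = 1/(2*varphi**2)``, the condition
under which the reference inflates rho (it does for negative correlation
with the pair sum, and for var_ref exceeding four times the pair's group
variance), the TP/FP/TN/FN regime classification at a cut-off ``K`` via
``K_tilde = 2*(K - rho_abs)/(1 - K)``, and the sufficient reference
variance ``8*var(eps)/(1 - K)`` above which pairs of unchanged genes
(individual variances at most ``var(eps)``) are spuriously called
proportional.

The relation has an isolated pole at ``F = -2`` (where the transformed
pair degenerates); evaluation there raises :class:`PoleError` rather than
propagating infinities, and sweep utilities mask it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import ParameterError, PoleError

__all__ = [
    "ReferenceTheoryInput",
    "PairClassification",
    "varphi_from_C",
    "f_of_reference",
    "f_value",
    "rho_relative_exact",
    "rho_relative_expansion",
    "first_order_coefficient",
    "worst_case_rho_bound",
    "worst_case_f_bound",
    "reference_increases_rho",
    "k_tilde",
    "classify_pair",
    "unchanged_fp_threshold",
    "is_admissible",
    "rho_relative_from_cov",
    "sweep_reference",
]

#: the cut-off the worked bounds are quoted at; generalized forms take
#: rho_abs as a parameter.
RHO_WORKED = 0.98

#: rounded integer divisor of the first-order cut-off adjustment at
#: rho_abs = 0.98 (the exact coefficient is 1/35.53...; see
#: :func:`first_order_coefficient`).
ROUNDED_DIVISOR = 35


@dataclass
class ReferenceTheoryInput:
    """Scalar inputs of the reference-distortion formulas for one pair.

    ``rho_abs``: proportionality coefficient of the pair on logged absolute
    data; ``var_i``, ``var_j``: its individual variances; ``var_ref``:
    variance of the logged reference (``var(A_d)``, or ``var(eps)`` for an
    approximately unchanged reference); ``corr_ref``: correlation of the
    reference with the pair sum ``A_i + A_j``; optional cut-off ``K``.
    """

    rho_abs: float
    var_i: float
    var_j: float
    var_ref: float
    corr_ref: float
    K: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho_abs <= 1.0:
            raise ParameterError(f"rho_abs out of [-1, 1]: {self.rho_abs!r}")
        if not -1.0 <= self.corr_ref <= 1.0:
            raise ParameterError(f"corr_ref out of [-1, 1]: {self.corr_ref!r}")
        if self.var_i <= 0 or self.var_j <= 0:
            raise ParameterError("pair variances must be positive")
        if self.var_ref < 0:
            raise ParameterError("var_ref must be nonnegative")
        if self.K is not None and not 0.0 < self.K < 1.0:
            raise ParameterError(f"K must lie in (0, 1): {self.K!r}")

    @property
    def varphi(self) -> float:
        """Scaled reference size ``sqrt(4*var_ref / (var_i + var_j))``."""
        return math.sqrt(4.0 * self.var_ref / (self.var_i + self.var_j))

    @property
    def C(self) -> float:
        """Variance ratio ``(var_i + var_j) / (2*var_ref) = 1/(2*varphi^2)``."""
        if self.var_ref == 0.0:
            return math.inf
        return (self.var_i + self.var_j) / (2.0 * self.var_ref)


def varphi_from_C(C: float) -> float:
    """Convert the variance ratio ``C`` to ``varphi = 1/sqrt(2C)``."""
    if not C > 0:
        raise ParameterError(f"C must be positive, got {C!r}")
    return 1.0 / math.sqrt(2.0 * C)


def f_value(rho_abs: float, varphi: float, corr_ref: float) -> float:
    """The distortion scalar ``F = varphi^2 - 2*sqrt(1+rho_abs)*corr_ref*varphi``."""
    return varphi**2 - 2.0 * math.sqrt(1.0 + rho_abs) * corr_ref * varphi


def f_of_reference(inp: ReferenceTheoryInput) -> float:
    """Evaluate ``F`` from a :class:`ReferenceTheoryInput`."""
    return f_value(inp.rho_abs, inp.varphi, inp.corr_ref)


def rho_relative_exact(rho_abs: float, F: float) -> float:
    """Exact relative-data coefficient ``rho_abs + (1-rho_abs)/(1+2/F)``.

    ``F = 0`` (unchanged reference) returns ``rho_abs`` unchanged.  The raw
    value is returned unclamped so theory checks can see overshoot; report
    layers clamp to [-1, 1] themselves.

    Raises
    ------
    PoleError
        At ``F = -2``, where the relation is discontinuous.
    """
    if F == 0.0:
        return float(rho_abs)
    if F == -2.0:
        raise PoleError("rho_relative_exact has a pole at F = -2")
    return float(rho_abs + (1.0 - rho_abs) / (1.0 + 2.0 / F))


def rho_relative_expansion(
    rho_abs: float,
    corr_eps: float,
    varphi_eps: float,
    order: Literal[1, 2] = 2,
) -> float:
    """Series for rho on relative data with an approximately unchanged reference.

    Expansion in the scaled reference size ``varphi_eps`` (NOT in the raw
    error variance), valid for small ``varphi_eps`` i.e. large ``C``::

        rho_rel = rho_abs
                  - corr_eps * sqrt((1-rho_abs^2)(1-rho_abs)) * varphi_eps
                  - (1-rho_abs) * (corr_eps^2 (1+rho_abs) - 1/2) * varphi_eps^2
                  + O(varphi_eps^3)

    ``order=1`` keeps the linear term only; ``order=2`` adds the quadratic
    one.  The omitted remainder is cubic, which the test suite verifies
    empirically against :func:`rho_relative_exact`.
    """
    if order not in (1, 2):
        raise ParameterError(f"order must be 1 or 2, got {order!r}")
    if not -1.0 <= corr_eps <= 1.0:
        raise ParameterError(f"corr_eps out of [-1, 1]: {corr_eps!r}")
    if varphi_eps < 0:
        raise ParameterError("varphi_eps must be nonnegative")
    out = rho_abs - corr_eps * math.sqrt(
        (1.0 - rho_abs**2) * (1.0 - rho_abs)
    ) * varphi_eps
    if order == 2:
        out -= (
            (1.0 - rho_abs)
            * (corr_eps**2 * (1.0 + rho_abs) - 0.5)
            * varphi_eps**2
        )
    return float(out)


def first_order_coefficient(rho_abs: float = RHO_WORKED) -> float:
    """Worst-case linear coefficient ``sqrt((1-rho_abs^2)(1-rho_abs))``.

    The maximal first-order increase of rho over all reference directions
    is this coefficient times ``varphi``.  At ``rho_abs = 0.98`` it equals
    1/35.53..., conventionally rounded to 1/35 in the worked bounds.
    """
    return math.sqrt((1.0 - rho_abs**2) * (1.0 - rho_abs))


def worst_case_rho_bound(
    C: float, rho_abs: float = RHO_WORKED, exact_coefficient: bool = False
) -> float:
    """First-order worst-case cut-off adjustment: ``rho_abs + 1/(35*sqrt(2C))``.

    Upper bound on the relative-data coefficient of any pair with absolute
    coefficient just below ``rho_abs``, whose average variance is ``C``
    times the variance of the (approximately unchanged) reference.  The
    default uses the rounded divisor 35 (exactly as conventionally quoted
    at ``rho_abs = 0.98``); ``exact_coefficient=True`` substitutes the
    unrounded ``first_order_coefficient``.
    """
    if not C > 0:
        raise ParameterError(f"C must be positive, got {C!r}")
    if exact_coefficient or rho_abs != RHO_WORKED:
        coef = first_order_coefficient(rho_abs)
    else:
        coef = 1.0 / ROUNDED_DIVISOR
    return float(rho_abs + coef / math.sqrt(2.0 * C))


def worst_case_f_bound(C: float) -> float:
    """Upper bound ``1/(2C) + 2/sqrt(C)`` on the distortion scalar F.

    Valid for ``rho_abs`` up to 0.98 (it rounds ``sqrt(2*(1+rho_abs))`` up
    to 2*sqrt(2)/sqrt(2) = 2); the exact maximum of F over
    ``corr_ref in [-1, 1]`` is attained at ``corr_ref = -1`` and never
    exceeds this bound.
    """
    if not C > 0:
        raise ParameterError(f"C must be positive, got {C!r}")
    return float(1.0 / (2.0 * C) + 2.0 / math.sqrt(C))


def reference_increases_rho(
    corr_ref: float, var_ref: float, var_sum_pair: float
) -> bool:
    """Does this reference inflate rho on the relative data?

    True iff ``corr(A_i+A_j, A_d) <= sqrt(var_ref / var(A_i+A_j))``
    (boundary counted as an increase).  In particular any nonpositive
    correlation with the pair sum inflates rho, as does a reference whose
    variance exceeds the pair's group variance ``var((A_i+A_j)/2)`` by a
    factor of four.
    """
    if not var_sum_pair > 0:
        raise ParameterError("var_sum_pair must be positive")
    if var_ref < 0:
        raise ParameterError("var_ref must be nonnegative")
    return corr_ref <= math.sqrt(var_ref / var_sum_pair)


def k_tilde(K: float, rho_abs: float) -> float:
    """Regime threshold ``K_tilde = 2*(K - rho_abs) / (1 - K)`` on F."""
    if K >= 1.0:
        raise ParameterError(f"K must be < 1, got {K!r}")
    return 2.0 * (K - rho_abs) / (1.0 - K)


@dataclass
class PairClassification:
    """Outcome of the regime classification of one pair at cut-off K.

    ``label`` follows the absolute-vs-relative confusion convention:
    TP = proportional on both scales, FP = only on relative data,
    TN = on neither, FN = only on absolute data.
    """

    label: Literal["TP", "FP", "TN", "FN"]
    F: float
    K_tilde: float


def classify_pair(F: float, K: float, rho_abs: float) -> PairClassification:
    """Classify a pair as TP/FP/TN/FN from its distortion scalar F.

    The rule is a direct reading of the exact relation: the pair is called
    proportional on relative data iff ``F >= K_tilde``, and on absolute
    data iff ``K_tilde <= 0`` (i.e. ``rho_abs >= K``).
    """
    kt = k_tilde(K, rho_abs)
    if F >= kt:
        label = "TP" if kt <= 0 else "FP"
    else:
        label = "FN" if kt <= 0 else "TN"
    return PairClassification(label=label, F=F, K_tilde=kt)


def unchanged_fp_threshold(var_eps: float, K: float) -> float:
    """Reference variance above which unchanged-gene pairs turn spurious.

    ``8*var_eps / (1 - K)`` suffices: any pair of unchanged genes
    (individual variances at most ``var_eps``) with absolute coefficient
    below the cut-off ``K`` is called proportional on the relative data
    once ``var(A_d)`` reaches this threshold, regardless of the direction
    of the reference.  Sufficiency only - the constant 8 is not claimed to
    be minimal.
    """
    if not var_eps > 0:
        raise ParameterError(f"var_eps must be positive, got {var_eps!r}")
    if not 0.0 < K < 1.0:
        raise ParameterError(f"K must lie in (0, 1), got {K!r}")
    return 8.0 * var_eps / (1.0 - K)


# -- realizability and cross-check helpers -----------------------------------


def implied_covariance(inp: ReferenceTheoryInput) -> np.ndarray:
    """3x3 covariance of ``(A_i, A_j, A_d)`` implied by the scalar inputs.

    The covariance of the reference with the pair sum is fixed by
    ``corr_ref``; it is split evenly between the two genes (the formulas
    only depend on the sum, so any split gives the same F and rho).
    """
    v_i, v_j = inp.var_i, inp.var_j
    c_ij = inp.rho_abs * (v_i + v_j) / 2.0
    var_sum = v_i + v_j + 2.0 * c_ij
    c_sum_d = inp.corr_ref * math.sqrt(max(var_sum, 0.0) * inp.var_ref)
    c_id = c_jd = c_sum_d / 2.0
    return np.array(
        [
            [v_i, c_ij, c_id],
            [c_ij, v_j, c_jd],
            [c_id, c_jd, inp.var_ref],
        ]
    )


def is_admissible(inp: ReferenceTheoryInput, tol: float = 1e-10) -> bool:
    """Is the implied 3x3 covariance of ``(A_i, A_j, A_d)`` realizable (PSD)?

    The closed-form results implicitly require a realizable joint
    configuration; sweeps should skip inadmissible grid points.
    """
    w = np.linalg.eigvalsh(implied_covariance(inp))
    return bool(w.min() >= -tol * max(w.max(), 1.0))


def rho_relative_from_cov(cov: np.ndarray) -> float:
    """Population rho of ``(A_i - A_d, A_j - A_d)`` from a 3x3 covariance.

    Independent route to the exact relation: used as a cross-check that
    :func:`rho_relative_exact` matches direct propagation of the
    covariance through the transform.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (3, 3):
        raise ParameterError("cov must be 3x3")
    vi, vj, vd = cov[0, 0], cov[1, 1], cov[2, 2]
    var_yi = vi + vd - 2.0 * cov[0, 2]
    var_yj = vj + vd - 2.0 * cov[1, 2]
    cov_y = cov[0, 1] - cov[0, 2] - cov[1, 2] + vd
    return float(2.0 * cov_y / (var_yi + var_yj))


def sweep_reference(
    C_grid,
    corr_grid,
    rho_abs: float,
    K: float,
    pole_margin: float = 1e-9,
) -> pd.DataFrame:
    """Tidy sweep of the distortion theory over a (C, corr_ref) grid.

    Returns a DataFrame with columns ``C, corr_ref, rho_abs, F, rho_rel,
    label`` (one row per grid point), suitable for regime maps of the
    relative-data coefficient as a function of the reference.  Grid points
    within ``pole_margin`` of the ``F = -2`` pole are masked (``rho_rel``
    NaN, label ``"pole"``).
    """
    rows = []
    for C in C_grid:
        varphi = varphi_from_C(float(C))
        for corr in corr_grid:
            F = f_value(rho_abs, varphi, float(corr))
            if abs(F + 2.0) <= pole_margin:
                rho_rel, label = float("nan"), "pole"
            else:
                rho_rel = rho_relative_exact(rho_abs, F)
                label = classify_pair(F, K, rho_abs).label
            rows.append(
                {
                    "C": float(C),
                    "corr_ref": float(corr),
                    "rho_abs": float(rho_abs),
                    "F": F,
                    "rho_rel": rho_rel,
                    "label": label,
                }
            )
    return pd.DataFrame(rows)
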