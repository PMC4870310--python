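"""Core proportionality statistics on logged expression vectors.

Two genes *i*, *j* with strictly positive abundances are *proportional*
across conditions when ``x_i ~ m * x_j`` for some constant ``m > 0``, which
is exactly the statement that the variance of ``log(x_i / x_j)`` vanishes.
This module implements that log-ratio variance (``vlr``) and the two
statistics that put it on an interpretable scale:

``phi(a_i, a_j) = vlr / var(a_i) = 1 + beta**2 - 2*beta*r``
    an asymmetric scaling by the variance of the first argument, and

``rho(a_i, a_j) = 2*cov(a_i, a_j) / (var(a_i) + var(a_j))``
    the symmetric proportionality coefficient, a concordance-type
    correlation lying in [-1, 1] with rho = 1 for proportional and
    rho = -1 for reciprocal pairs.

Here ``a_i``, ``a_j`` are *logged* abundances, ``beta = sqrt(var(a_j) /
var(a_i))`` is the (absolute value of the) standardized-major-axis slope of
the log-log scatter and ``r`` the Pearson correlation of the logs.  All
variances are sample variances with denominator ``n - 1``, and all logs are
natural; any log base cancels in ``rho`` and ``phi`` but not in the raw
``vlr``.

The identity suite connecting these quantities (``rho = 1 - vlr/(var_i +
var_j) = 2r/(beta + 1/beta) = (1 - beta_tilde**2)/(1 + beta_tilde**2)``,
with ``beta_tilde = sqrt(var(a_i - a_j)/var(a_i + a_j))``) is exposed
through :func:`pair_stats` and checked by the test suite at 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataDomainError, ShapeError, UndefinedStatisticError

#: numeric overshoot beyond [-1, 1] tolerated and clamped in `rho`
CLAMP_TOL = 1e-12


def _as_vector(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ShapeError(f"{name} must be 1-D, got shape {x.shape}")
    if x.size < 3:
        raise ShapeError(f"{name} needs length >= 3, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise DataDomainError(f"non-finite entry in {name}")
    return x


def _pair(a_i, a_j) -> tuple[np.ndarray, np.ndarray]:
    a_i = _as_vector(a_i, "a_i")
    a_j = _as_vector(a_j, "a_j")
    if a_i.size != a_j.size:
        raise ShapeError(f"length mismatch: {a_i.size} vs {a_j.size}")
    return a_i, a_j


def _require_positive(x: np.ndarray, name: str) -> None:
    bad = np.where(x <= 0)[0]
    if bad.size:
        raise DataDomainError(
            f"nonpositive entry in {name} at index {bad[0]} "
            f"(value {x[bad[0]]!r}); logs require strictly positive data"
        )


def vlr(x_i, x_j) -> float:
    """Log-ratio variance of two positive abundance vectors.

    Sample variance (denominator ``n - 1``) of ``log(x_i / x_j)`` using the
    natural log.  Symmetric, zero iff the pair is perfectly proportional,
    and invariant both to rescaling either gene by a positive constant and
    to any per-condition common factor (so closure of the parent matrix
    does not change it).
    """
    x_i, x_j = _pair(x_i, x_j)
    _require_positive(x_i, "x_i")
    _require_positive(x_j, "x_j")
    return float(np.var(np.log(x_i) - np.log(x_j), ddof=1))


def rho(a_i, a_j) -> float:
    """Proportionality coefficient of two *logged* abundance vectors.

    ``2*cov/(var_i + var_j)``; 1 for proportional pairs, -1 for reciprocal
    ones.  Values overshooting [-1, 1] by at most ``CLAMP_TOL`` (floating-
    point noise) are clamped.

    Raises
    ------
    UndefinedStatisticError
        If both arguments have zero variance.
    """
    a_i, a_j = _pair(a_i, a_j)
    v_i = np.var(a_i, ddof=1)
    v_j = np.var(a_j, ddof=1)
    if v_i + v_j == 0.0:
        raise UndefinedStatisticError(
            "rho undefined: both vectors have zero variance"
        )
    c = np.cov(a_i, a_j, ddof=1)[0, 1]
    val = 2.0 * c / (v_i + v_j)
    if val > 1.0:
        if val > 1.0 + CLAMP_TOL:
            raise UndefinedStatisticError(f"rho = {val!r} outside [-1, 1]")
        val = 1.0
    elif val < -1.0:
        if val < -1.0 - CLAMP_TOL:
            raise UndefinedStatisticError(f"rho = {val!r} outside [-1, 1]")
        val = -1.0
    return float(val)


def phi(a_i, a_j) -> float:
    """The phi statistic ``var(a_i - a_j) / var(a_i)`` on logged vectors.

    Not symmetric: the denominator is the variance of the *first* argument.
    Equals ``1 + beta**2 - 2*beta*r``, and ``phi = (1 - rho)*(1 + beta**2)``.
    """
    a_i, a_j = _pair(a_i, a_j)
    v_i = np.var(a_i, ddof=1)
    if v_i == 0.0:
        raise UndefinedStatisticError(
            "phi undefined: first argument has zero variance"
        )
    return float(np.var(a_i - a_j, ddof=1) / v_i)


@dataclass
class PairStats:
    """All per-pair statistics for one (logged) gene pair.

    ``beta`` is the positive root ``sqrt(var_j / var_i)`` (sign information
    lives in ``r``); ``beta_tilde = sqrt(var(a_i - a_j)/var(a_i + a_j))``
    is the analogous slope of the rotated (sum/difference) pair and is
    reported as ``inf`` when ``var(a_i + a_j) = 0`` (exact reciprocality,
    ``rho = -1``).
    """

    i: int
    j: int
    vlr: float
    rho: float
    phi: float
    beta: float
    r: float
    beta_tilde: float


def pair_stats(a_i, a_j, i: int = 0, j: int = 1) -> PairStats:
    """Compute the full :class:`PairStats` record for two logged vectors.

    Raises
    ------
    UndefinedStatisticError
        If either vector has zero variance (degenerate pair); the only
        tolerated degeneracy is ``var(a_i + a_j) = 0``, reported as
        ``beta_tilde = inf`` with ``rho = -1``.
    """
    a_i, a_j = _pair(a_i, a_j)
    v_i = float(np.var(a_i, ddof=1))
    v_j = float(np.var(a_j, ddof=1))
    if v_i == 0.0 or v_j == 0.0:
        raise UndefinedStatisticError(
            "pair statistics undefined: an argument has zero variance"
        )
    c = float(np.cov(a_i, a_j, ddof=1)[0, 1])
    v_diff = float(np.var(a_i - a_j, ddof=1))
    v_sum = float(np.var(a_i + a_j, ddof=1))
    beta = float(np.sqrt(v_j / v_i))
    r = float(c / np.sqrt(v_i * v_j))
    if v_sum == 0.0:
        beta_tilde = float("inf")
        rho_val = -1.0
    else:
        beta_tilde = float(np.sqrt(v_diff / v_sum))
        rho_val = rho(a_i, a_j)
    return PairStats(
        i=i,
        j=j,
        vlr=v_diff,
        rho=rho_val,
        phi=v_diff / v_i,
        beta=beta,
        r=r,
        beta_tilde=beta_tilde,
    )
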