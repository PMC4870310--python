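"""Reference-distortion theory: exact relation, expansions, bounds, regimes."""

import math

import numpy as np
import pytest

from propcoda import (
    classify_pair,
    f_of_reference,
    f_value,
    first_order_coefficient,
    k_tilde,
    reference_increases_rho,
    rho,
    rho_relative_exact,
    rho_relative_expansion,
    sweep_reference,
    unchanged_fp_threshold,
    varphi_from_C,
    worst_case_f_bound,
    worst_case_rho_bound,
)
from propcoda.exceptions import ParameterError, PoleError
from propcoda.reference_theory import (
    ReferenceTheoryInput,
    implied_covariance,
    is_admissible,
    rho_relative_from_cov,
)


class TestFStatistic:
    def test_zero_variance_reference_gives_zero(self):
        inp = ReferenceTheoryInput(0.9, 1.0, 1.0, var_ref=0.0, corr_ref=0.5)
        assert f_of_reference(inp) == 0.0

    def test_worked_value_positive_correlation(self):
        # rho=0.98, C=1/5 -> varphi=sqrt(2.5); F = 2.5 - 2 sqrt(1.98) sqrt(2.5)
        varphi = varphi_from_C(0.2)
        F = f_value(0.98, varphi, +1.0)
        assert F == pytest.approx(2.5 - 2 * math.sqrt(1.98 * 2.5), rel=1e-12)
        assert F == pytest.approx(-1.9497, abs=1e-4)

    def test_worked_value_negative_correlation(self):
        F = f_value(0.98, varphi_from_C(0.2), -1.0)
        assert F == pytest.approx(6.9497, abs=1e-4)
        assert F <= 7.0


class TestExactRelation:
    def test_unchanged_reference_is_identity(self):
        assert rho_relative_exact(0.73, 0.0) == 0.73

    def test_worked_lower_reach(self):
        F = f_value(0.98, varphi_from_C(0.2), +1.0)
        val = rho_relative_exact(0.98, F)
        assert round(val, 1) == 0.2

    def test_worked_upper_bound(self):
        val = rho_relative_exact(0.98, 7.0)
        assert val == pytest.approx(0.98 + 0.02 / (1 + 2 / 7), rel=1e-12)
        assert val <= 0.996

    def test_pole_raises(self):
        with pytest.raises(PoleError):
            rho_relative_exact(0.9, -2.0)

    def test_matches_covariance_propagation(self, rng):
        """Independent route: propagate a random admissible covariance
        through Y = A - A_ref and compare population rho."""
        for _ in range(200):
            inp = ReferenceTheoryInput(
                rho_abs=rng.uniform(-0.9, 0.99),
                var_i=rng.uniform(0.1, 3.0),
                var_j=rng.uniform(0.1, 3.0),
                var_ref=rng.uniform(0.0, 3.0),
                corr_ref=rng.uniform(-0.95, 0.95),
            )
            if not is_admissible(inp):
                continue
            F = f_of_reference(inp)
            if abs(F + 2) < 1e-3:
                continue
            want = rho_relative_from_cov(implied_covariance(inp))
            assert rho_relative_exact(inp.rho_abs, F) == pytest.approx(
                want, abs=1e-10
            )

    def test_empirical_convergence_on_simulated_alr(self, rng):
        """Simulated alr data at n = 10^4 matches the exact relation to 0.02
        across a 5 x 5 (C, corr_ref) grid."""
        rho_abs = 0.98
        for C in [0.2, 0.5, 1.0, 2.0, 5.0]:
            for corr in [-0.9, -0.45, 0.0, 0.45, 0.9]:
                inp = ReferenceTheoryInput(
                    rho_abs, 1.0, 1.0, var_ref=1.0 / C, corr_ref=corr
                )
                assert is_admissible(inp)
                cov = implied_covariance(inp)
                L = np.linalg.cholesky(cov + 1e-12 * np.eye(3))
                A = rng.standard_normal((10_000, 3)) @ L.T
                emp = rho(A[:, 0] - A[:, 2], A[:, 1] - A[:, 2])
                pred = rho_relative_exact(rho_abs, f_of_reference(inp))
                assert emp == pytest.approx(pred, abs=0.02)

    def test_lower_reach_attained_near_predicted_C(self):
        """The minimum of rho_rel over C at corr_ref=+1 sits near
        C = 1/(2(1+rho)) where the distortion reaches -(1+rho)."""
        rho_abs = 0.98
        Cs = np.linspace(0.05, 2.0, 2000)
        vals = [
            rho_relative_exact(rho_abs, f_value(rho_abs, varphi_from_C(c), 1.0))
            for c in Cs
        ]
        c_pred = 1 / (2 * (1 + rho_abs))
        c_star = Cs[int(np.argmin(vals))]
        assert c_star == pytest.approx(c_pred, abs=0.01)
        # at the predicted extremum the distortion is exactly -(1+rho)
        at_pred = rho_relative_exact(
            rho_abs, f_value(rho_abs, varphi_from_C(c_pred), 1.0)
        )
        assert at_pred == pytest.approx(rho_abs - (1 + rho_abs), abs=1e-10)
        assert min(vals) == pytest.approx(at_pred, abs=1e-3)


class TestExpansion:
    def test_zero_varphi_returns_rho_abs(self):
        assert rho_relative_expansion(0.9, -1.0, 0.0) == 0.9

    def test_order1_error_is_quadratic(self):
        rho_abs, corr = 0.98, -1.0
        errs = []
        for ph in [0.1, 0.05, 0.025]:
            exact = rho_relative_exact(rho_abs, f_value(rho_abs, ph, corr))
            errs.append(
                abs(rho_relative_expansion(rho_abs, corr, ph, order=1) - exact)
            )
        # quadratic remainder: halving varphi shrinks the error ~4x
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.35)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.35)

    @pytest.mark.parametrize(
        "rho_abs,corr", [(0.5, -0.5), (0.8, -0.6), (0.5, 0.6)]
    )
    def test_order2_error_is_cubic(self, rho_abs, corr):
        phis = np.array([0.1 / 2**k for k in range(6)])
        errs = [
            abs(
                rho_relative_expansion(rho_abs, corr, p, order=2)
                - rho_relative_exact(rho_abs, f_value(rho_abs, p, corr))
            )
            for p in phis
        ]
        slope = np.polyfit(np.log(phis), np.log(errs), 1)[0]
        assert slope == pytest.approx(3.0, abs=0.3)

    def test_worst_case_coefficient_value(self):
        coef = first_order_coefficient(0.98)
        assert coef == pytest.approx(math.sqrt((1 - 0.98**2) * 0.02), rel=1e-12)
        # the conventional rounded divisor vs the exact one
        assert 1 / coef == pytest.approx(35.53, abs=0.01)
        assert math.floor(1 / coef) == 35

    def test_unsupported_order(self):
        with pytest.raises(ParameterError):
            rho_relative_expansion(0.9, 0.0, 0.1, order=3)


class TestBounds:
    def test_cutoff_bound_at_C5(self):
        assert worst_case_rho_bound(5.0) == pytest.approx(0.98904, abs=1e-5)
        assert worst_case_rho_bound(5.0) <= 0.99

    def test_cutoff_bound_limit_and_monotonicity(self):
        Cs = np.logspace(-2, 4, 50)
        vals = [worst_case_rho_bound(c) for c in Cs]
        assert np.all(np.diff(vals) < 0)
        assert worst_case_rho_bound(1e12) == pytest.approx(0.98, abs=1e-5)

    def test_f_bound_worked_values(self):
        assert worst_case_f_bound(0.2) == pytest.approx(6.9721, abs=1e-4)
        assert worst_case_f_bound(0.2) <= 7.0
        assert worst_case_f_bound(1.0) == pytest.approx(2.5, rel=1e-12)

    def test_f_bound_dominates_exact_max(self):
        """Exact max of F over corr (at corr = -1, rho = 0.98) never exceeds
        the bound across a wide C grid."""
        for C in np.logspace(-2, 2, 60):
            exact = f_value(0.98, varphi_from_C(C), -1.0)
            assert exact <= worst_case_f_bound(C) + 1e-12

    def test_invalid_C(self):
        with pytest.raises(ParameterError):
            worst_case_rho_bound(0.0)
        with pytest.raises(ParameterError):
            worst_case_f_bound(-1.0)


class TestIncreaseCondition:
    def test_negative_correlation_always_increases(self):
        assert reference_increases_rho(-0.5, 0.3, 2.0)

    def test_boundary_counts_as_increase(self):
        assert reference_increases_rho(math.sqrt(0.25 / 1.0), 0.25, 1.0)

    def test_small_reference_positive_correlation_decreases(self):
        assert not reference_increases_rho(1.0, 1e-6, 2.0)

    def test_agrees_with_sign_of_exact_distortion(self, rng):
        for _ in range(300):
            inp = ReferenceTheoryInput(
                rho_abs=rng.uniform(-0.9, 0.95),
                var_i=rng.uniform(0.1, 2.0),
                var_j=rng.uniform(0.1, 2.0),
                var_ref=rng.uniform(1e-4, 2.0),
                corr_ref=rng.uniform(-0.99, 0.99),
            )
            if not is_admissible(inp):
                continue
            var_sum = (1 + inp.rho_abs) * (inp.var_i + inp.var_j)
            F = f_of_reference(inp)
            if abs(F) < 1e-9 or abs(F + 2) < 1e-6:
                continue
            delta = rho_relative_exact(inp.rho_abs, F) - inp.rho_abs
            assert reference_increases_rho(
                inp.corr_ref, inp.var_ref, var_sum
            ) == (delta >= -1e-12)


class TestRegimes:
    def test_k_tilde_worked_values(self):
        assert k_tilde(0.975, 0.98) == pytest.approx(-0.4, rel=1e-12)
        assert k_tilde(0.985, 0.98) == pytest.approx(2 / 3, rel=1e-9)
        assert k_tilde(0.9, 0.9) == 0.0

    def test_k_tilde_rejects_K_ge_1(self):
        with pytest.raises(ParameterError):
            k_tilde(1.0, 0.9)

    def test_classification_worked_cases(self):
        assert classify_pair(7.0, 0.975, 0.98).label == "TP"
        assert classify_pair(7.0, 0.985, 0.98).label == "FP"
        assert classify_pair(0.0, 0.985, 0.98).label == "TN"

    def test_classification_agrees_with_direct_thresholding(self, rng):
        for _ in range(500):
            rho_abs = rng.uniform(-0.5, 0.999)
            K = rng.uniform(0.3, 0.999)
            # realizable F range is [-(1+rho), inf)
            F = rng.uniform(-(1 + rho_abs) * 0.999, 10.0)
            if abs(F + 2) < 1e-6:
                continue
            lab = classify_pair(F, K, rho_abs).label
            on_abs = rho_abs >= K
            on_rel = rho_relative_exact(rho_abs, F) >= K - 1e-12
            want = {
                (True, True): "TP",
                (False, True): "FP",
                (False, False): "TN",
                (True, False): "FN",
            }[(on_abs, on_rel)]
            assert lab == want

    def test_unchanged_threshold_plugin_values(self):
        assert unchanged_fp_threshold(1.0, 0.5) == pytest.approx(16.0)
        assert unchanged_fp_threshold(1.0, 0.9) == pytest.approx(80.0)
        Ks = np.linspace(0.1, 0.99, 30)
        vals = [unchanged_fp_threshold(1.0, k) for k in Ks]
        assert np.all(np.diff(vals) > 0)

    def test_unchanged_threshold_sufficiency_grid(self):
        """At var_ref = 8 var_eps/(1-K), every admissible unchanged pair
        with rho_abs < K is called proportional on the relative data."""
        var_eps = 1.0
        for K in [0.5, 0.8, 0.9, 0.98]:
            thr = unchanged_fp_threshold(var_eps, K)
            worst = 1.0
            for vi in [0.2, 0.5, 1.0]:
                for vj in [0.2, 0.5, 1.0]:
                    for r_ in np.linspace(-0.95, K - 1e-6, 9):
                        for corr in np.linspace(-1.0, 1.0, 11):
                            inp = ReferenceTheoryInput(
                                r_, vi, vj, var_ref=thr, corr_ref=corr
                            )
                            if not is_admissible(inp):
                                continue
                            worst = min(
                                worst,
                                rho_relative_exact(r_, f_of_reference(inp)),
                            )
            assert worst >= K

    def test_fp_regime_absent_for_small_reference(self):
        """Far below the threshold the same grid contains non-spurious
        configurations (the FP regime is not universal)."""
        K = 0.9
        inp = ReferenceTheoryInput(
            0.0, 1.0, 1.0, var_ref=1e-4, corr_ref=0.0
        )
        assert rho_relative_exact(0.0, f_of_reference(inp)) < K


class TestSweep:
    def test_tidy_output_and_pole_masking(self):
        df = sweep_reference(
            C_grid=[0.2, 1.0, 5.0],
            corr_grid=[-1.0, 0.0, 1.0],
            rho_abs=0.98,
            K=0.975,
        )
        assert list(df.columns) == [
            "C",
            "corr_ref",
            "rho_abs",
            "F",
            "rho_rel",
            "label",
        ]
        assert len(df) == 9
        assert set(df["label"]) <= {"TP", "FP", "TN", "FN", "pole"}
        # all rows here are away from the pole
        assert df["rho_rel"].notna().all()
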