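"""Unit and property tests of the core probability model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom, multinomial

from dualscreen import (
    ModelParams,
    ScreeningCounts,
    cell_probs,
    derived_quantities,
    joint_accuracy,
    log_likelihood,
    ppv_and_correlations,
    sequential_accuracy,
    stage_one_cell_probs,
    stage_two_cell_probs,
)
from conftest import random_valid_params

# scenario "2.1"-style truth with rho_D+ = 0.5, rho_D- = 0.4
SC21 = dict(pi=0.4, se1=0.9, sp1=0.95, se2=0.95, sp2=0.90,
            cov_dp=0.0326917, cov_dn=0.0261534)


class TestScreeningCounts:
    def test_totals_and_accessors(self):
        c = ScreeningCounts(x11=39, x10=91, x01=237, x00=5360,
                            a11=29, a10=338, a0=5360)
        assert c.n == 5727
        assert c.n_positive == 367
        assert c.stage_one().sum() == c.n
        assert c.stage_two().sum() == c.n

    @pytest.mark.parametrize(
        "kwargs, fragment",
        [
            (dict(x11=1, x10=0, x01=0, x00=5, a11=2, a10=0, a0=5),
             "joint-positive"),
            (dict(x11=1, x10=0, x01=0, x00=5, a11=1, a10=0, a0=4),
             "a0 must equal x00"),
            (dict(x11=-1, x10=0, x01=0, x00=5, a11=-1, a10=0, a0=5),
             "nonnegative"),
        ],
    )
    def test_invariant_violations_named(self, kwargs, fragment):
        with pytest.raises(ValueError, match=fragment):
            ScreeningCounts(**kwargs)

    def test_json_and_csv_round_trip(self, tmp_path):
        c = ScreeningCounts(x11=3, x10=2, x01=1, x00=10, a11=4, a10=2, a0=10)
        jpath = tmp_path / "counts.json"
        c.to_json(jpath)
        assert ScreeningCounts.from_json(str(jpath)) == c
        cpath = tmp_path / "counts.csv"
        c.to_csv(cpath)
        assert ScreeningCounts.from_csv(str(cpath)) == c

    def test_declared_n_mismatch_rejected(self):
        d = dict(x11=3, x10=2, x01=1, x00=10, a11=4, a10=2, a0=10, n=99)
        with pytest.raises(ValueError, match="n=99"):
            ScreeningCounts.from_dict(d)


class TestModelParams:
    def test_covariance_bound_enforced(self):
        with pytest.raises(ValueError, match="cov_dp"):
            ModelParams(pi=0.1, se1=0.9, se2=0.9, sp1=0.9, sp2=0.9,
                        cov_dp=0.2)
        with pytest.raises(ValueError, match="cov_dn"):
            ModelParams(pi=0.1, se1=0.9, se2=0.9, sp1=0.8, sp2=0.9,
                        cov_dn=0.3)

    def test_probability_range_enforced(self):
        with pytest.raises(ValueError, match="pi"):
            ModelParams(pi=1.2, se1=0.9, se2=0.9, sp1=0.9, sp2=0.9)


class TestCellProbs:
    def test_perfect_tests(self):
        p = ModelParams(pi=0.3, se1=1, se2=1, sp1=1, sp2=1)
        px = stage_one_cell_probs(p)
        np.testing.assert_allclose(px, [0.3, 0.0, 0.0, 0.7])
        pa = stage_two_cell_probs(p)
        np.testing.assert_allclose(pa, [0.3, 0.0, 0.7])

    def test_dependent_example_hand_arithmetic(self):
        # expected cells from the four formulas, spelled out term by term
        p, q = 0.4, 0.6
        cdp, cdn = SC21["cov_dp"], SC21["cov_dn"]
        exp = [
            p * (0.9 * 0.95 + cdp) + q * (0.05 * 0.10 + cdn),
            p * (0.9 * 0.05 - cdp) + q * (0.05 * 0.90 - cdn),
            p * (0.1 * 0.95 - cdp) + q * (0.95 * 0.10 - cdn),
            p * (0.1 * 0.05 + cdp) + q * (0.95 * 0.90 + cdn),
        ]
        px = stage_one_cell_probs(ModelParams(**SC21))
        np.testing.assert_allclose(px, exp, rtol=0, atol=1e-15)

    def test_stage_two_hand_arithmetic(self):
        # pi = 0.0065 with joint accuracies fixed via the covariances
        params = ModelParams(pi=0.0065, se1=0.81, se2=0.0, sp1=0.9405,
                             sp2=1.0, cov_dp=0.0, cov_dn=0.0)
        # se_je = 0.81, sp_je = 0.9405 by construction
        pa = stage_two_cell_probs(params)
        np.testing.assert_allclose(
            pa,
            [0.0065 * 0.81, 0.9935 * 0.0595, 1 - 0.0065 * 0.81 - 0.9935 * 0.0595],
            atol=1e-12,
        )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_normalization_and_shared_negative_mass(self, seed):
        params = random_valid_params(np.random.default_rng(seed))
        cp = cell_probs(params)
        assert abs(cp.stage_one().sum() - 1) < 1e-12
        assert abs(cp.stage_two().sum() - 1) < 1e-12
        assert (cp.stage_one() >= -1e-15).all()
        # the unverified mass is exactly the double-negative mass
        assert abs(cp.pa0 - cp.px00) < 1e-12


class TestJointAccuracy:
    def test_independence_formula(self):
        p = ModelParams(pi=0.2, se1=0.5, se2=0.5, sp1=0.8, sp2=0.8)
        se_je, sp_je = joint_accuracy(p)
        assert se_je == pytest.approx(0.75)
        assert sp_je == pytest.approx(0.64)

    def test_dependent_hand_arithmetic(self):
        se_je, sp_je = joint_accuracy(ModelParams(**SC21))
        assert se_je == pytest.approx(0.9623083, abs=1e-7)
        assert sp_je == pytest.approx(0.8811534, abs=1e-7)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_adds_sensitivity_loses_specificity(self, seed):
        p = random_valid_params(np.random.default_rng(seed))
        se_je, sp_je = joint_accuracy(p)
        assert se_je >= max(p.se1, p.se2) - 1e-12
        assert sp_je <= min(p.sp1, p.sp2) + 1e-12
        assert -1e-12 <= se_je <= 1 + 1e-12
        assert -1e-12 <= sp_je <= 1 + 1e-12

    def test_sequential_accuracy(self):
        assert sequential_accuracy(0.8, 0.9, 1, 1) == pytest.approx((0.8, 1.0))
        assert sequential_accuracy(0.8, 0.9, 0.9, 0.8) == pytest.approx((0.72, 0.98))
        # perfect gold standard passes the joint sensitivity through
        for x in (0.0, 0.31, 1.0):
            assert sequential_accuracy(x, 0.5)[0] == pytest.approx(x)
        with pytest.raises(ValueError, match="se_gs"):
            sequential_accuracy(0.8, 0.9, 1.5, 1)


class TestPPVAndCorrelations:
    def test_zero_covariance_zero_correlation(self):
        p = ModelParams(pi=0.1, se1=0.7, se2=0.8, sp1=0.9, sp2=0.85)
        ppv, rdp, rdn = ppv_and_correlations(p)
        assert rdp == 0.0 and rdn == 0.0
        se_je, sp_je = joint_accuracy(p)
        assert ppv == pytest.approx(
            0.1 * se_je / (0.1 * se_je + 0.9 * (1 - sp_je)))

    def test_round_trip_with_known_correlations(self):
        ppv, rdp, rdn = ppv_and_correlations(ModelParams(**SC21))
        assert rdp == pytest.approx(0.5, abs=1e-5)
        assert rdn == pytest.approx(0.4, abs=1e-5)

    def test_boundary_accuracy_gives_nan_not_exception(self):
        p = ModelParams(pi=0.1, se1=1.0, se2=0.8, sp1=0.9, sp2=0.85)
        _, rdp, _ = ppv_and_correlations(p)
        assert math.isnan(rdp)

    def test_derived_quantities_consistent(self):
        p = ModelParams(**SC21)
        d = derived_quantities(p)
        assert d.se_je == pytest.approx(p.se1 + p.se2 - d.se11)
        assert d.sp_je == pytest.approx(d.sp22)
        assert d.se_jb == pytest.approx(d.se_je)  # perfect gold standard
        assert d.sp_jb == pytest.approx(1.0)


class TestLogLikelihood:
    def _oracle(self, counts, params):
        """Independent evaluation: scipy multinomial log-masses."""
        cp = cell_probs(params)
        return (
            multinomial.logpmf(counts.stage_one(), counts.n, cp.stage_one())
            + multinomial.logpmf(counts.stage_two(), counts.n, cp.stage_two())
        )

    def test_single_cell_probability_one(self):
        c = ScreeningCounts(x11=0, x10=0, x01=0, x00=9, a11=0, a10=0, a0=9)
        p = ModelParams(pi=0.0, se1=1, se2=1, sp1=1, sp2=1)
        # all mass in the double-negative cell: log 1 = 0 (constants retained)
        assert log_likelihood(c, p) == pytest.approx(0.0)

    def test_zero_probability_with_positive_count(self):
        c = ScreeningCounts(x11=1, x10=0, x01=0, x00=9, a11=1, a10=0, a0=9)
        p = ModelParams(pi=0.0, se1=1, se2=1, sp1=1, sp2=1)
        assert log_likelihood(c, p) == -math.inf

    def test_matches_independent_multinomial_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            params = random_valid_params(rng)
            gen = random_valid_params(rng)
            from dualscreen import simulate_counts
            counts = simulate_counts(gen, n=int(rng.integers(5, 500)), seed=rng)
            got = log_likelihood(counts, params)
            want = self._oracle(counts, params)
            if math.isinf(want):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(want, abs=1e-9)

    def test_independence_nested_model_identity(self):
        c = ScreeningCounts(x11=5, x10=3, x01=2, x00=90, a11=6, a10=4, a0=90)
        base = dict(pi=0.1, se1=0.7, se2=0.8, sp1=0.9, sp2=0.85)
        dep = ModelParams(cov_dp=0.0, cov_dn=0.0, **base)
        indep = ModelParams(**base)
        assert log_likelihood(c, dep) == log_likelihood(c, indep)

    def test_factorized_mode_oracle(self):
        c = ScreeningCounts(x11=5, x10=3, x01=2, x00=90, a11=6, a10=4, a0=90)
        p = ModelParams(pi=0.1, se1=0.7, se2=0.8, sp1=0.9, sp2=0.85,
                        cov_dp=0.01, cov_dn=0.02)
        cp = cell_probs(p)
        want = multinomial.logpmf(c.stage_one(), c.n, cp.stage_one()) + \
            binom.logpmf(c.a11, c.n_positive, cp.pa11 / (cp.pa11 + cp.pa10))
        assert log_likelihood(c, p, factorized=True) == pytest.approx(want, abs=1e-9)

    def test_constant_terms_can_be_dropped(self):
        c = ScreeningCounts(x11=5, x10=3, x01=2, x00=90, a11=6, a10=4, a0=90)
        p = ModelParams(pi=0.1, se1=0.7, se2=0.8, sp1=0.9, sp2=0.85)
        full = log_likelihood(c, p)
        kernel = log_likelihood(c, p, include_constant=False)
        # the dropped terms depend only on the counts, not the parameters
        p2 = ModelParams(pi=0.2, se1=0.6, se2=0.9, sp1=0.8, sp2=0.95)
        assert (full - kernel) == pytest.approx(
            log_likelihood(c, p2) - log_likelihood(c, p2, include_constant=False),
            abs=1e-9,
        )
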