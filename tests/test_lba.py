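"""LBA densities, likelihood ridge, simulation, transforms, rescaling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from cogscale import lba

# modest random parameter boxes keeping both-negative-drift mass negligible
param_sets = st.builds(
    lba.LBAParams,
    A=st.floats(0.1, 0.8),
    B=st.floats(0.9, 2.0),
    v1=st.floats(2.0, 4.0),
    v2=st.floats(0.8, 2.0),
    s1=st.floats(0.5, 1.5),
    s2=st.floats(0.5, 1.5),
    t0=st.floats(0.05, 0.4),
)


class TestSingleAccumulator:
    def test_cdf_vanishes_at_zero(self):
        assert lba.lba_cdf_one(0.0, 0.5, 1.0, 2.0, 1.0) == 0.0
        assert lba.lba_cdf_one(1e-9, 0.5, 1.0, 2.0, 1.0) < 1e-6

    def test_zero_start_range_reduces_to_drift_threshold_crossing(self):
        # start at 0, threshold 1: finished by t=1 iff drift >= 1
        assert lba.lba_cdf_one(1.0, 0.0, 1.0, 1.0, 0.2) == pytest.approx(0.5, abs=1e-12)
        assert lba.lba_cdf_one(2.0, 0.0, 1.0, 1.0, 0.2) == pytest.approx(
            norm.cdf((1.0 - 0.5) / 0.2), abs=1e-9
        )

    def test_pdf_zero_for_nonpositive_time(self):
        assert lba.lba_pdf_one(0.0, 0.5, 1.0, 2.0, 1.0) == 0.0
        assert lba.lba_pdf_one(-1.0, 0.5, 1.0, 2.0, 1.0) == 0.0

    @given(param_sets, st.floats(0.1, 3.0), st.sampled_from([0.25, 2.0, 7.5]))
    def test_pdf_scale_invariance(self, p, t, k):
        base = lba.lba_pdf_one(t, p.A, p.B, p.v1, p.s1)
        scaled = lba.lba_pdf_one(t, k * p.A, k * p.B, k * p.v1, k * p.s1)
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize("A, b, v, s", [(0.5, 1.0, 3.0, 1.0), (0.2, 1.5, 1.5, 0.7),
                                            (0.0, 1.0, 2.0, 0.5)])
    def test_cdf_matches_integrated_pdf(self, A, b, v, s):
        for t in (0.2, 0.5, 1.0, 2.0):
            integral, _ = quad(lambda u: lba.lba_pdf_one(u, A, b, v, s), 0, t, limit=200)
            assert lba.lba_cdf_one(t, A, b, v, s) == pytest.approx(integral, abs=1e-5)

    @pytest.mark.parametrize("t", [0.25, 0.6, 1.2])
    def test_pdf_matches_cdf_central_difference(self, t):
        A, b, v, s = 0.5, 1.0, 3.0, 1.0
        h = 1e-5
        deriv = (lba.lba_cdf_one(t + h, A, b, v, s) - lba.lba_cdf_one(t - h, A, b, v, s)) / (2 * h)
        assert lba.lba_pdf_one(t, A, b, v, s) == pytest.approx(deriv, abs=1e-4)

    def test_invalid_domain_rejected(self):
        with pytest.raises(ValueError):
            lba.lba_cdf_one(1.0, 2.0, 1.0, 1.0, 1.0)  # A > b
        with pytest.raises(ValueError):
            lba.lba_pdf_one(1.0, 0.5, 1.0, 1.0, 0.0)  # s = 0


class TestDefectiveDensity:
    def test_zero_at_and_before_nondecision_time(self, reference_lba_params):
        p = reference_lba_params
        assert lba.defective_pdf(p.t0, p, winner=1) == 0.0
        assert lba.defective_pdf(0.5 * p.t0, p, winner=2) == 0.0

    def test_total_probability_sums_to_one(self, reference_lba_params):
        p = reference_lba_params
        total = lba.response_probability(p, 1) + lba.response_probability(p, 2)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_hopeless_loser_reduces_to_marginal(self):
        p = lba.LBAParams(A=0.3, B=1.0, v1=3.0, v2=1e-6, s1=0.5, s2=1e-6, t0=0.1)
        # the loser essentially never finishes: defective ~ winner's marginal
        t = np.array([0.3, 0.5, 0.9])
        defective = lba.defective_pdf(t, p, winner=1)
        marginal = lba.lba_pdf_one(t - p.t0, p.A, p.B, p.v1, p.s1)
        assert defective == pytest.approx(marginal, rel=0.01)


class TestNegLogLikelihood:
    def test_scaling_ridge(self, lba_trials_1000, reference_lba_params):
        base = lba.neg_log_likelihood(lba_trials_1000, reference_lba_params)
        for k in (0.5, 2.0, 10.0):
            scaled = lba.neg_log_likelihood(lba_trials_1000, reference_lba_params.scaled(k))
            assert scaled == pytest.approx(base, abs=1e-9)

    def test_floor_for_impossible_trial(self, reference_lba_params):
        trials = lba.LBATrialSet(rt=np.array([0.1]), choice=np.array([1]))  # rt < t0
        nll = lba.neg_log_likelihood(trials, reference_lba_params)
        assert nll == pytest.approx(-math.log(lba.DENSITY_FLOOR), abs=1e-9)

    def test_matches_direct_summation_reference(self, rng, reference_lba_params):
        # independent re-implementation: plain scipy.stats.norm, trial-by-trial
        p = reference_lba_params
        rt = rng.uniform(p.t0 + 0.05, 1.5, size=100)
        choice = rng.integers(1, 3, size=100)
        trials = lba.LBATrialSet(rt=rt, choice=choice)

        def cdf(t, v, s):
            z1 = (p.B - p.A - t * v) / (t * s)
            z2 = (p.B - t * v) / (t * s)
            val = (1 + (p.B - p.A - t * v) / p.A * norm.cdf(z1)
                   - (p.B - t * v) / p.A * norm.cdf(z2)
                   + t * s / p.A * norm.pdf(z1) - t * s / p.A * norm.pdf(z2))
            return min(max(val, 0.0), 1.0)

        def pdf(t, v, s):
            z1 = (p.B - p.A - t * v) / (t * s)
            z2 = (p.B - t * v) / (t * s)
            return max((-v * norm.cdf(z1) + s * norm.pdf(z1)
                        + v * norm.cdf(z2) - s * norm.pdf(z2)) / p.A, 0.0)

        p_none = norm.cdf(-p.v1 / p.s1) * norm.cdf(-p.v2 / p.s2)
        total = 0.0
        for t, c in zip(rt, choice):
            u = t - p.t0
            vw, sw = (p.v1, p.s1) if c == 1 else (p.v2, p.s2)
            vl, sl = (p.v2, p.s2) if c == 1 else (p.v1, p.s1)
            dens = pdf(u, vw, sw) * (1 - cdf(u, vl, sl))
            if p_none > lba.RENORM_THRESHOLD:
                dens /= 1 - p_none
            total -= math.log(max(dens, lba.DENSITY_FLOOR))
        assert lba.neg_log_likelihood(trials, p) == pytest.approx(total, abs=1e-9)


class TestTransforms:
    @given(param_sets)
    def test_roundtrip_identity(self, p):
        min_rt = p.t0 + 0.1
        x = lba.transform_params(p, min_rt)
        q = lba.untransform_params(x, min_rt)
        for name in ("A", "B", "v1", "v2", "s1", "s2", "t0"):
            assert getattr(q, name) == pytest.approx(getattr(p, name), rel=1e-12, abs=1e-12)

    def test_t0_logistic_midpoint_and_limit(self):
        min_rt = 0.4
        x = lba.transform_params(lba.LBAParams(0.2, 1.0, 2.0, 1.0, 1.0, 1.0, 0.2), min_rt)
        assert x[-1] == pytest.approx(0.0, abs=1e-12)  # t0 = min_rt/2 maps to 0
        far_out = x.copy()
        far_out[-1] = 40.0
        assert lba.untransform_params(far_out, min_rt).t0 == pytest.approx(min_rt, abs=1e-9)

    def test_domain_errors(self):
        p = lba.LBAParams(0.0, 1.0, 2.0, 1.0, 1.0, 1.0, 0.2)
        with pytest.raises(ValueError):
            lba.transform_params(p, 0.4)  # A = 0 is outside the log domain
        with pytest.raises(ValueError):
            lba.transform_params(lba.LBAParams(0.2, 1.0, 2.0, 1.0, 1.0, 1.0, 0.5), 0.4)


class TestSimulate:
    def test_deterministic_under_seed(self, reference_lba_params):
        a = lba.simulate_lba(reference_lba_params, 200, seed=4)
        b = lba.simulate_lba(reference_lba_params, 200, seed=4)
        assert np.array_equal(a.rt, b.rt) and np.array_equal(a.choice, b.choice)

    def test_deterministic_limit(self):
        p = lba.LBAParams(A=0.0, B=1.0, v1=2.0, v2=1.0, s1=1e-8, s2=1e-8, t0=0.15)
        trials = lba.simulate_lba(p, 500, seed=1)
        assert np.all(trials.choice == 1)
        assert trials.rt == pytest.approx(np.full(500, 1.0 / 2.0 + 0.15), abs=1e-5)

    def test_simulation_matches_analytic_cdf(self, reference_lba_params):
        p = reference_lba_params
        trials = lba.simulate_lba(p, 10_000, seed=99)
        ks = max(_ks_distance(trials, p, w) for w in (1, 2))
        assert ks < 0.02


def _ks_distance(trials: lba.LBATrialSet, params: lba.LBAParams, winner: int) -> float:
    """KS distance between simulated RTs for one response and the analytic
    conditional CDF (cumulative-trapezoid integration of the defective density)."""
    rts = np.sort(trials.rt[trials.choice == winner])
    upper = max(rts.max() * 1.5, params.t0 + 5.0)
    grid = np.linspace(params.t0, upper, 6000)
    dens = lba.defective_pdf(grid, params, winner)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
    total = lba.response_probability(params, winner)
    analytic = np.interp(rts, grid, cdf) / total
    ecdf = np.arange(1, rts.size + 1) / rts.size
    return float(np.max(np.abs(ecdf - analytic)))


class TestFit:
    def test_fit_reaches_truth_level_likelihood(self, lba_trials_1000, reference_lba_params):
        fit = lba.fit_lba(lba_trials_1000, n_restarts=8, seed=5, constraint="s1")
        assert fit.converged
        truth_nll = lba.neg_log_likelihood(lba_trials_1000, reference_lba_params)
        assert fit.neg_log_lik <= truth_nll + 1e-6
        assert fit.params.s1 == 1.0

    def test_unconstrained_fits_agree_on_ratios(self, lba_trials_1000):
        f1 = lba.fit_lba(lba_trials_1000, n_restarts=8, seed=1, constraint="none")
        f2 = lba.fit_lba(lba_trials_1000, n_restarts=8, seed=2, constraint="none")
        assert abs(f1.neg_log_lik - f2.neg_log_lik) < 0.1
        r1 = np.array([f1.params.B, f1.params.v1, f1.params.v2, f1.params.s2]) / f1.params.s1
        r2 = np.array([f2.params.B, f2.params.v1, f2.params.v2, f2.params.s2]) / f2.params.s1
        assert r1 == pytest.approx(r2, rel=0.05)

    def test_ridge_invariance_of_objective(self, lba_trials_1000):
        f = lba.fit_lba(lba_trials_1000, n_restarts=6, seed=3, constraint="none")
        doubled = f.params.scaled(2.0)
        assert lba.neg_log_likelihood(lba_trials_1000, doubled) == pytest.approx(
            f.neg_log_lik, abs=1e-9
        )


class TestRescale:
    @pytest.fixture
    def params(self):
        return lba.LBAParams(A=1.0, B=2.0, v1=3.0, v2=1.0, s1=1.0, s2=0.5, t0=0.2)

    def test_v_sum_division(self, params):
        out = lba.rescale_params(params, "v_sum")
        p = out.params
        assert (p.A, p.B) == (0.25, 0.5)
        assert (p.v1, p.v2) == (0.75, 0.25)
        assert (p.s1, p.s2) == (0.25, 0.125)
        assert p.t0 == 0.2  # untouched
        assert p.v1 + p.v2 == 1.0  # exact

    def test_threshold_division_relabels_drifts_as_frequency(self, params):
        out = lba.rescale_params(params, "B")
        assert out.params.B == 1.0
        assert out.unit_labels["v1"] == "1/s"
        assert out.unit_labels["v2"] == "1/s"

    def test_likelihood_preserved(self, params, rng):
        trials = lba.simulate_lba(params, 300, seed=8)
        base = lba.neg_log_likelihood(trials, params)
        for by in lba.RESCALE_CHOICES:
            rescaled = lba.rescale_params(params, by).params
            assert lba.neg_log_likelihood(trials, rescaled) == pytest.approx(base, abs=1e-9)

    def test_small_denominator_flag(self):
        p = lba.LBAParams(A=0.001, B=0.01, v1=0.03, v2=0.01, s1=0.01, s2=0.01, t0=0.2)
        assert lba.rescale_params(p, "B").small_denominator


def test_params_validation():
    with pytest.raises(ValueError):
        lba.LBAParams(A=1.0, B=0.5, v1=1.0, v2=1.0, s1=1.0, s2=1.0, t0=0.1)  # B < A
    with pytest.raises(ValueError):
        lba.LBAParams(A=0.5, B=1.0, v1=1.0, v2=1.0, s1=0.0, s2=1.0, t0=0.1)
    with pytest.raises(ValueError):
        lba.LBAParams(A=0.5, B=1.0, v1=1.0, v2=1.0, s1=1.0, s2=1.0, t0=-0.1)
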