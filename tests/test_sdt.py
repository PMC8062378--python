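"""Signal detection theory: estimation, constraints, rescaling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from cogscale import sdt

rates_interior = st.tuples(
    st.floats(0.01, 0.99), st.floats(0.01, 0.99)
).map(lambda hf: sdt.RatePair(*hf))


class TestRatesFromCounts:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((84, 16, 16, 84), (0.84, 0.16)),
            ((100, 0, 0, 100), (199 / 200, 1 / 200)),  # half-count edge rule
            ((0, 50, 25, 25), (1 / 100, 0.5)),
        ],
    )
    def test_half_count(self, counts, expected):
        rates = sdt.rates_from_counts(sdt.DetectionCounts(*counts))
        assert (rates.hr, rates.far) == pytest.approx(expected, abs=1e-12)

    def test_error_policy_raises_on_degenerate_rate(self):
        with pytest.raises(sdt.DegenerateRateError):
            sdt.rates_from_counts(sdt.DetectionCounts(100, 0, 10, 90), edge_policy="error")

    def test_counts_validation(self):
        with pytest.raises(ValueError):
            sdt.DetectionCounts(0, 0, 5, 5)  # no signal trials
        with pytest.raises(ValueError):
            sdt.DetectionCounts(-1, 5, 5, 5)


class TestForwardModel:
    def test_symmetric_zero_case(self):
        rates = sdt.forward_rates(sdt.SDTParams(0.0, 0.0, 1.0))
        assert (rates.hr, rates.far) == (0.5, 0.5)

    def test_cutoff_anchor_example(self):
        # d'=1, cutoff 0.5, sigma 0.5: hit z = +1, false-alarm z = -1
        rates = sdt.forward_rates(sdt.SDTParams(1.0, 0.5, 0.5))
        assert rates.hr == pytest.approx(norm.cdf(1.0), abs=1e-9)
        assert rates.far == pytest.approx(norm.cdf(-1.0), abs=1e-9)

    @given(st.floats(0.05, 3.0), st.floats(-1.5, 1.5), st.floats(0.2, 3.0),
           st.floats(0.1, 10.0))
    def test_scale_invariance(self, d, c, s, k):
        base = sdt.forward_rates(sdt.SDTParams(d, c, s))
        scaled = sdt.forward_rates(sdt.SDTParams(d * k, c * k, s * k))
        assert scaled.hr == pytest.approx(base.hr, abs=1e-12)
        assert scaled.far == pytest.approx(base.far, abs=1e-12)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            sdt.SDTParams(1.0, 0.0, 0.0)


class TestEstimateStandard:
    def test_symmetric_rates_give_exact_z_units(self):
        est = sdt.estimate_standard(sdt.RatePair(norm.cdf(1.0), norm.cdf(-1.0)))
        assert est.d_prime == pytest.approx(2.0, abs=1e-9)
        assert est.criterion == pytest.approx(0.0, abs=1e-9)
        assert est.sigma == 1.0
        # same criterion under the negated sign convention, by symmetry
        neg = sdt.estimate_standard(sdt.RatePair(norm.cdf(1.0), norm.cdf(-1.0)), "negated")
        assert neg.criterion == pytest.approx(0.0, abs=1e-9)

    def test_chance_rates_give_zero(self):
        est = sdt.estimate_standard(sdt.RatePair(0.5, 0.5))
        assert est.d_prime == 0.0 and est.criterion == 0.0

    def test_frozen_quantile_values(self):
        # high-precision normal-quantile oracle, frozen
        est = sdt.estimate_standard(sdt.RatePair(0.9, 0.3))
        assert est.d_prime == pytest.approx(1.8059520782526413, abs=1e-9)
        assert est.criterion == pytest.approx(-0.3785755264182797, abs=1e-9)

    def test_degenerate_rates_rejected(self):
        with pytest.raises(sdt.DegenerateRateError):
            sdt.estimate_standard(sdt.RatePair(1.0, 0.2))

    @given(rates_interior)
    def test_roundtrip_through_forward_model(self, rates):
        for convention in ("standard", "negated"):
            est = sdt.estimate_standard(rates, convention)
            back = sdt.forward_rates(est)
            assert back.hr == pytest.approx(rates.hr, abs=1e-9)
            assert back.far == pytest.approx(rates.far, abs=1e-9)

    def test_unit_labels_name_the_sigma_ratio(self):
        est = sdt.estimate_standard(sdt.RatePair(0.8, 0.4))
        assert est.unit_labels["criterion"] == "c/s"
        assert est.unit_labels["d_prime"] == "d'/s"


class TestRefitUnderConstraint:
    def test_sigma_constraint_matches_standard_estimator(self):
        rates = sdt.RatePair(0.77, 0.21)
        refit = sdt.refit_under_constraint(rates, sdt.ConstraintSpec("sigma", 1.0))
        est = sdt.estimate_standard(rates)
        assert refit.d_prime == pytest.approx(est.d_prime, abs=1e-12)
        assert refit.criterion == pytest.approx(est.criterion, abs=1e-12)

    def test_d_prime_constraint_recovers_generating_cutoff(self):
        # rates generated by (d'=1, cutoff=0.5, sigma=0.5)
        rates = sdt.forward_rates(sdt.SDTParams(1.0, 0.5, 0.5))
        refit = sdt.refit_under_constraint(rates, sdt.ConstraintSpec("d_prime", 1.0))
        assert refit.d_prime == 1.0
        assert refit.sigma == pytest.approx(0.5, rel=1e-8)
        assert refit.cutoff == pytest.approx(0.5, abs=1e-8)
        back = sdt.forward_rates(refit)
        assert back.hr == pytest.approx(rates.hr, abs=1e-9)
        assert back.far == pytest.approx(rates.far, abs=1e-9)

    @pytest.mark.parametrize(
        "rates, constraint",
        [
            ((0.6, 0.7), sdt.ConstraintSpec("criterion", 1.0)),  # implied criterion < 0
            ((0.3, 0.6), sdt.ConstraintSpec("d_prime", 1.0)),  # hr < far implies d' < 0
        ],
    )
    def test_infeasible_constraints_raise(self, rates, constraint):
        with pytest.raises(sdt.InfeasibleConstraintError):
            sdt.refit_under_constraint(sdt.RatePair(*rates), constraint)

    @given(rates_interior)
    def test_agrees_with_analytic_rescaling(self, rates):
        est = sdt.estimate_standard(rates)
        for constraint in (sdt.ConstraintSpec("d_prime", 1.0), sdt.ConstraintSpec("criterion", 1.0)):
            try:
                refit = sdt.refit_under_constraint(rates, constraint)
            except sdt.InfeasibleConstraintError:
                continue
            rescaled = sdt.rescale_estimate(est, constraint)
            for name in sdt.PARAM_NAMES:
                assert getattr(refit, name) == pytest.approx(
                    getattr(rescaled, name), rel=1e-6, abs=1e-6
                )


class TestRescaleEstimate:
    @pytest.fixture
    def est(self):
        return sdt.SDTEstimate(2.0, 0.5, 1.0, sdt.ConstraintSpec("sigma", 1.0),
                               unit_labels=sdt.unit_labels_for("sigma"))

    def test_divide_by_d_prime(self, est):
        out = sdt.rescale_estimate(est, sdt.ConstraintSpec("d_prime", 1.0))
        assert (out.d_prime, out.criterion, out.sigma) == (1.0, 0.25, 0.5)
        assert out.unit_labels["criterion"] == "c/d'"
        assert out.unit_labels["sigma"] == "s/d'"

    def test_divide_by_criterion(self, est):
        out = sdt.rescale_estimate(est, sdt.ConstraintSpec("criterion", 1.0))
        assert (out.d_prime, out.criterion, out.sigma) == (4.0, 1.0, 2.0)
        assert out.unit_labels["d_prime"] == "d'/c"

    def test_roundtrip_is_identity(self, est):
        there = sdt.rescale_estimate(est, sdt.ConstraintSpec("d_prime", 1.0))
        back = sdt.rescale_estimate(there, sdt.ConstraintSpec("sigma", 1.0))
        for name in sdt.PARAM_NAMES:
            assert getattr(back, name) == pytest.approx(getattr(est, name), abs=1e-12)

    @given(rates_interior, st.sampled_from(["sigma", "d_prime", "criterion"]),
           st.sampled_from(["sigma", "d_prime", "criterion"]))
    def test_ratio_invariance_across_constraints(self, rates, which_a, which_b):
        est = sdt.estimate_standard(rates)
        outs = []
        for which in (which_a, which_b):
            try:
                outs.append(sdt.rescale_estimate(est, sdt.ConstraintSpec(which, 1.0)))
            except ZeroDivisionError:
                return
        a, b = outs
        assert a.criterion / a.sigma == pytest.approx(b.criterion / b.sigma, abs=1e-8)
        assert a.d_prime / a.sigma == pytest.approx(b.d_prime / b.sigma, abs=1e-8)

    def test_small_denominator_flag(self, est):
        tiny = sdt.SDTEstimate(2.0, 0.01, 1.0, sdt.ConstraintSpec("sigma", 1.0))
        out = sdt.rescale_estimate(tiny, sdt.ConstraintSpec("criterion", 1.0))
        assert out.small_denominator
        assert not sdt.rescale_estimate(est, sdt.ConstraintSpec("criterion", 1.0)).small_denominator

    def test_zero_denominator_raises(self):
        zero = sdt.SDTEstimate(2.0, 0.0, 1.0, sdt.ConstraintSpec("sigma", 1.0))
        with pytest.raises(ZeroDivisionError):
            sdt.rescale_estimate(zero, sdt.ConstraintSpec("criterion", 1.0))

    def test_constrained_field_pinned_exactly(self, est):
        out = sdt.rescale_estimate(est, sdt.ConstraintSpec("d_prime", 1.0))
        assert out.d_prime == 1.0  # bit-exact


def test_estimate_invariant_rejects_mismatched_constraint():
    with pytest.raises(ValueError):
        sdt.SDTEstimate(2.0, 0.5, 1.5, sdt.ConstraintSpec("sigma", 1.0))


def test_constraint_spec_rejects_zero():
    with pytest.raises(ValueError):
        sdt.ConstraintSpec("sigma", 0.0)
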