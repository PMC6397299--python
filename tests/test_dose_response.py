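from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from debrisdose.dose_response import (
    assign_intervals,
    dose_for_probability,
    fit_fractional_logistic,
    logistic,
    logit,
    monte_carlo_fit,
    predict_curve,
    solve_from_anchors,
)
from debrisdose.records import Cohort
from debrisdose.simulate import default_config, generate_cohort, null_dose_config

from _oracles import grid_refine_logistic
from conftest import make_bird


def fixture_40_birds():
    """Fixed 40-bird design with binary outcomes (no separation)."""
    rng = np.random.default_rng(2024)
    counts = rng.integers(0, 13, size=40).astype(float)
    weights = rng.uniform(100, 900, size=40)
    p = logistic(-1.0 + 0.25 * counts - 0.001 * weights)
    y = (rng.random(40) < p).astype(float)
    return counts, weights, y


class TestAssignIntervals:
    @pytest.mark.parametrize(
        "cod,variant,expected",
        [
            ("KND", "trust_KD", (0.0, 0.0)),
            ("Ind", "trust_KD", (0.0, 1.0)),
            ("KD", "trust_KD", (1.0, 1.0)),
            ("KND", "distrust_KD", (0.0, 0.0)),
            ("Ind", "distrust_KD", (0.0, 1.0)),
            ("KD", "distrust_KD", (0.0, 1.0)),
        ],
    )
    def test_interval_assignment(self, cod, variant, expected):
        bird = make_bird("x", cod=cod, n_items=2)
        iv = assign_intervals(Cohort([bird]), variant)[0]
        assert (iv.lower, iv.upper) == expected

    def test_unknown_variant_rejected(self, tiny_cohort):
        with pytest.raises(ValueError, match="variant"):
            assign_intervals(tiny_cohort, "maybe_KD")


class TestFractionalLogistic:
    def test_constant_half_response_gives_zero_coefficients(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 10, 50).astype(float)
        weights = rng.uniform(-1, 1, 50)
        counts = counts - counts.mean()
        y = np.full(50, 0.5)
        fit = fit_fractional_logistic(counts, weights, y)
        assert fit.converged
        assert fit.b0 == pytest.approx(0.0, abs=1e-8)
        assert fit.b1 == pytest.approx(0.0, abs=1e-8)
        assert fit.b2 == pytest.approx(0.0, abs=1e-8)

    def test_agrees_with_grid_refinement_oracle(self):
        counts, weights, y = fixture_40_birds()
        fit = fit_fractional_logistic(counts, weights, y)
        assert fit.converged
        (b0, b1, b2), ll = grid_refine_logistic(counts, weights, y)
        assert fit.b0 == pytest.approx(b0, abs=1e-4)
        assert fit.b1 == pytest.approx(b1, abs=1e-4)
        assert fit.b2 == pytest.approx(b2, abs=1e-4)
        assert fit.log_likelihood >= ll - 1e-8

    def test_parameter_recovery_n5000(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(4, 5000).astype(float)
        weights = rng.uniform(100, 900, 5000)
        y = (rng.random(5000) < logistic(-2.0 + 0.2 * counts)).astype(float)
        fit = fit_fractional_logistic(counts, weights, y)
        assert fit.converged
        assert abs(fit.b0 - (-2.0)) < 3 * fit.se_b0
        assert abs(fit.b1 - 0.2) < 3 * fit.se_b1
        assert abs(fit.b2 - 0.0) < 3 * fit.se_b2

    def test_all_zero_responses_flagged_not_converged(self):
        counts, weights, _ = fixture_40_birds()
        fit = fit_fractional_logistic(counts, weights, np.zeros(40))
        assert not fit.converged

    def test_complete_separation_flagged(self):
        counts = np.arange(20.0)
        weights = np.full(20, 500.0)
        y = (counts >= 10).astype(float)
        fit = fit_fractional_logistic(counts, weights, y)
        assert not fit.converged

    def test_fractional_responses_accepted(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 10, 100).astype(float)
        weights = rng.uniform(100, 900, 100)
        y = rng.random(100)
        fit = fit_fractional_logistic(counts, weights, y)
        assert fit.converged and np.isfinite(fit.log_likelihood)


class TestMonteCarlo:
    def test_no_indeterminate_birds_leaves_no_randomness(self):
        # overlapping load ranges so the binary outcomes are not separable
        birds = [make_bird(f"k{i}", cod="KND", n_items=i % 9) for i in range(30)] + [
            make_bird(f"d{i}", cod="KD", n_items=2 + i % 7) for i in range(10)
        ]
        mc = monte_carlo_fit(Cohort(birds), "trust_KD", n_reps=20, seed=1)
        b1s = [f.b1 for f in mc.fits]
        assert len(set(b1s)) == 1  # every replicate is bit-identical

    def test_seed_reproducibility_bitwise(self):
        cohort, _ = generate_cohort(default_config(n_birds=400, seed=8))
        a = monte_carlo_fit(cohort, "trust_KD", n_reps=40, seed=5)
        b = monte_carlo_fit(cohort, "trust_KD", n_reps=40, seed=5)
        assert [f.b1 for f in a.fits] == [f.b1 for f in b.fits]
        assert a.median_b1 == b.median_b1

    def test_seed_stability_within_monte_carlo_error(self):
        cohort, _ = generate_cohort(default_config(n_birds=1000, seed=8))
        runs = [monte_carlo_fit(cohort, "trust_KD", n_reps=150, seed=s) for s in (1, 2)]
        ses = []
        for mc in runs:
            b1 = np.array([f.b1 for f in mc.converged_fits])
            ses.append(1.2533 * b1.std() / math.sqrt(len(b1)))  # SE of a median
        diff = abs(runs[0].median_b1 - runs[1].median_b1)
        assert diff < 3 * math.hypot(*ses)

    def test_positive_dose_response_recovers_sign(self):
        cohort, _ = generate_cohort(default_config(n_birds=2000, seed=13))
        mc = monte_carlo_fit(cohort, "trust_KD", n_reps=200, seed=0)
        b1 = np.array([f.b1 for f in mc.converged_fits])
        assert np.mean(b1 > 0) >= 0.95
        assert mc.frac_slope_significant >= 0.95

    def test_null_slope_recovered_near_zero(self):
        cohort, _ = generate_cohort(null_dose_config(n_birds=2000, seed=14))
        mc = monte_carlo_fit(cohort, "trust_KD", n_reps=200, seed=0)
        b1 = np.array([f.b1 for f in mc.converged_fits])
        se_med = 1.2533 * b1.std() / math.sqrt(len(b1))
        # allow generator sampling error on top of the MC resolution error
        assert abs(mc.median_b1) < max(4 * se_med, 0.02)

    def test_all_fixed_identical_outcomes_not_identifiable(self):
        birds = [make_bird(f"k{i}", cod="KND", n_items=i % 3) for i in range(20)]
        with pytest.raises(ValueError, match="identifiable"):
            monte_carlo_fit(Cohort(birds), "trust_KD", n_reps=5, seed=0)


class TestCurves:
    def test_anchor_coefficients_predict_half_at_nine_items(self):
        birds = [make_bird(f"k{i}", cod="KND", n_items=i % 9) for i in range(30)] + [
            make_bird(f"d{i}", cod="KD", n_items=2 + i % 7) for i in range(10)
        ]
        mc = monte_carlo_fit(Cohort(birds), "trust_KD", n_reps=1, seed=0)
        # overwrite with the published-anchor coefficients: single-rep curve
        mc.fits[0].b0, mc.fits[0].b1, mc.fits[0].b2 = -1.5317, 0.1702, 0.0
        mc.median_b0, mc.median_b1, mc.median_b2 = -1.5317, 0.1702, 0.0
        curve = predict_curve(mc, reference_weight=500.0, n_grid=np.arange(0, 20))
        assert curve.p_median[9] == pytest.approx(0.5, abs=5e-4)

    def test_envelope_orders_and_monotone(self):
        cohort, _ = generate_cohort(default_config(n_birds=800, seed=15))
        mc = monte_carlo_fit(cohort, "trust_KD", n_reps=60, seed=3)
        curve = predict_curve(mc)
        assert np.all(curve.p_min <= curve.p_median + 1e-12)
        assert np.all(curve.p_median <= curve.p_max + 1e-12)
        if all(f.b1 > 0 for f in mc.converged_fits):
            assert np.all(np.diff(curve.p_median) > 0)

    def test_trust_envelope_nested_in_distrust_envelope(self):
        # KD birds carry high loads, so trusting their labels pins the upper
        # tail and narrows the envelope relative to the distrust variant
        widths = {}
        cohort, _ = generate_cohort(default_config(n_birds=1500, seed=16))
        for variant in ("trust_KD", "distrust_KD"):
            mc = monte_carlo_fit(cohort, variant, n_reps=100, seed=4)
            curve = predict_curve(mc, reference_weight=500.0)
            widths[variant] = np.trapezoid(curve.p_max - curve.p_min, curve.n_grid)
        assert widths["trust_KD"] < widths["distrust_KD"]


class TestInversionAndAnchors:
    def test_anchor_solve_matches_published_anchors(self):
        b0, b1 = solve_from_anchors((1, 0.204), (9, 0.5))
        assert b1 == pytest.approx(0.17018, abs=1e-5)
        assert b0 == pytest.approx(-1.53166, abs=1e-5)

    def test_flat_anchors_give_zero_slope(self):
        b0, b1 = solve_from_anchors((0, 0.5), (1, 0.5))
        assert b0 == 0.0 and b1 == 0.0

    def test_equal_loads_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            solve_from_anchors((3, 0.2), (3, 0.4))

    def test_published_curve_saturates_by_93_items(self):
        b0, b1 = solve_from_anchors((1, 0.204), (9, 0.5))
        p93 = float(logistic(b0 + b1 * 93))
        assert round(100 * p93) == 100

    def test_dose_for_half_probability_is_nine_items(self):
        n = dose_for_probability((-1.5317, 0.1702, 0.0), 500.0, 0.5)
        assert n == pytest.approx(9.0, abs=0.05)

    def test_near_certain_mortality_around_ninety_items(self):
        n = dose_for_probability((-1.5317, 0.1702, 0.0), 500.0, 0.999999)
        assert n == pytest.approx(90.2, abs=0.05)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            dose_for_probability((0.1, 0.0, 0.0), 500.0, 0.5)

    @given(
        b0=st.floats(-4, 4),
        b1=st.floats(0.01, 1.0),
        b2=st.floats(-0.01, 0.01),
        n=st.floats(0, 50),
    )
    def test_inversion_round_trip(self, b0, b1, b2, n):
        w = 400.0
        p = float(logistic(b0 + b1 * n + b2 * w))
        if 1e-9 < p < 1 - 1e-9:
            back = dose_for_probability((b0, b1, b2), w, p)
            assert back == pytest.approx(n, abs=1e-6)
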