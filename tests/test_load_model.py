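from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from debrisdose.load_model import (
    THETA_MAX,
    aic_table,
    anova_posthoc,
    check_overdispersion,
    cod_ordering_test,
    cohort_frame,
    fit_nb_glm,
)
from debrisdose.records import Cohort
from debrisdose.simulate import default_config, generate_cohort, null_dose_config

from _oracles import grid_refine_nb_intercept, nb_intercept_loglik
from conftest import make_bird


def cohort_with_counts(counts, cod="KND"):
    return Cohort([make_bird(f"b{i}", cod=cod, n_items=int(k)) for i, k in enumerate(counts)])


def nb_sample(rng, mu, theta, n):
    return rng.negative_binomial(theta, theta / (theta + mu), size=n)


class TestNbGlm:
    def test_intercept_only_equidispersed_hits_poisson_limit(self):
        fit = fit_nb_glm(cohort_with_counts([2, 2, 2, 2]), ())
        assert fit.coefficients["Intercept"] == pytest.approx(math.log(2.0), abs=1e-6)
        assert fit.theta >= 1e5  # no overdispersion: theta runs to its cap
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * fit.n_params)

    def test_intercept_only_matches_grid_search_oracle(self):
        rng = np.random.default_rng(12)
        y = nb_sample(rng, mu=3.0, theta=1.2, n=50)
        fit = fit_nb_glm(cohort_with_counts(y), ())
        (b0_star, lt_star), ll_star = grid_refine_nb_intercept(y)
        assert fit.log_likelihood == pytest.approx(ll_star, abs=1e-3)
        assert fit.coefficients["Intercept"] == pytest.approx(b0_star, abs=1e-3)

    def test_parameter_recovery_at_n5000(self):
        rng = np.random.default_rng(99)
        y = nb_sample(rng, mu=math.exp(1.0), theta=1.5, n=5000)
        fit = fit_nb_glm(cohort_with_counts(y), ())
        b0, se = fit.coefficients["Intercept"], fit.standard_errors["Intercept"]
        assert abs(b0 - 1.0) < 3 * se
        # theta within 3 profile-likelihood SEs (numeric curvature)
        lt = math.log(fit.theta)
        h = 1e-3
        ll = lambda t: nb_intercept_loglik(np.array([b0]), np.array([t]), y)[0]
        curv = (ll(lt + h) - 2 * ll(lt) + ll(lt - h)) / h**2
        se_lt = 1.0 / math.sqrt(-curv)
        assert abs(lt - math.log(1.5)) < 3 * se_lt

    def test_loglik_local_optimum(self):
        rng = np.random.default_rng(4)
        y = nb_sample(rng, mu=2.0, theta=0.8, n=200)
        fit = fit_nb_glm(cohort_with_counts(y), ())
        b0 = fit.coefficients["Intercept"]
        lt = math.log(fit.theta)
        for db, dlt in [(0.05, 0), (-0.05, 0), (0, 0.1), (0, -0.1), (0.03, 0.05)]:
            perturbed = nb_intercept_loglik(np.array([b0 + db]), np.array([lt + dlt]), y)[0]
            assert fit.log_likelihood >= perturbed - 1e-9

    def test_poisson_limit_of_nb_loglik(self):
        y = np.array([0, 1, 2, 3, 1, 0, 2, 4])
        mu = y.mean()
        ll_pois = np.sum(stats.poisson.logpmf(y, mu))
        ll_nb = nb_intercept_loglik(np.array([math.log(mu)]), np.array([math.log(1e7)]), y)[0]
        assert ll_nb == pytest.approx(ll_pois, abs=1e-4)

    def test_rank_deficiency_reported_with_aliased_terms(self):
        # family is constant + species single level, but two cod levels make
        # species==family aliasing when species mirrors cod exactly
        birds = [
            make_bird("a", cod="KND", species="S1"),
            make_bird("b", cod="Ind", species="S2", n_items=1),
            make_bird("c", cod="KND", species="S1", n_items=2),
            make_bird("d", cod="Ind", species="S2", n_items=3),
        ]
        with pytest.raises(ValueError, match="aliased"):
            fit_nb_glm(Cohort(birds), ("cod", "species"))


class TestAdequacy:
    def test_null_rejection_rate_is_near_nominal(self):
        rng = np.random.default_rng(21)
        rejections = 0
        reps = 200
        for _ in range(reps):
            y = nb_sample(rng, mu=2.5, theta=1.5, n=300)
            fit = fit_nb_glm(cohort_with_counts(y), ())
            rep = check_overdispersion(fit, cohort_with_counts(y))
            rejections += rep.p_value < 0.05
        assert 0.01 <= rejections / reps <= 0.12

    def test_poisson_rejected_on_overdispersed_data(self):
        rng = np.random.default_rng(22)
        reject = 0
        reps = 40
        for _ in range(reps):
            y = nb_sample(rng, mu=2.5, theta=0.3, n=300)
            fit = fit_nb_glm(cohort_with_counts(y), ())
            rep = check_overdispersion(fit, cohort_with_counts(y))
            reject += rep.poisson_p_value < 0.05
        assert reject / reps >= 0.95


class TestAicTable:
    def test_identical_formulas_tie(self):
        cohort, _ = generate_cohort(default_config(n_birds=300, seed=31))
        t1 = fit_nb_glm(cohort, ("cod",))
        t2 = fit_nb_glm(cohort, ("cod",))
        assert t1.aic == pytest.approx(t2.aic, abs=1e-8)

    def test_sorted_ascending_with_zero_delta_best(self):
        cohort, _ = generate_cohort(default_config(n_birds=400, seed=32))
        table = aic_table(cohort, [("cod",), ("cod", "species"), ()])
        aics = [a for _, a in table.rows]
        assert aics == sorted(aics)
        assert table.deltas[table.best_label] == 0.0

    def test_species_effect_is_selected_when_generated(self):
        wins = 0
        reps = 50
        for rep in range(reps):
            cohort, _ = generate_cohort(default_config(n_birds=1200, seed=4000 + rep))
            table = aic_table(cohort, [("species",), ()])
            wins += table.best_label == "species"
        assert wins / reps >= 0.90

    def test_parsimony_when_no_effects_generated(self):
        close = 0
        reps = 50
        for rep in range(reps):
            cohort, _ = generate_cohort(
                null_dose_config(n_birds=500, seed=5000 + rep)
            )
            table = aic_table(cohort, [("species",), ("species_weight",), ()])
            close += table.deltas["null"] <= 2.0
        assert close / reps > 0.5


class TestCodOrdering:
    def test_forced_ordering_all_contrasts_positive(self):
        birds = (
            [make_bird(f"k{i}", cod="KND", n_items=1) for i in range(20)]
            + [make_bird(f"i{i}", cod="Ind", n_items=5) for i in range(20)]
            + [make_bird(f"d{i}", cod="KD", n_items=10) for i in range(20)]
        )
        fit = fit_nb_glm(Cohort(birds), ("cod",))
        res = cod_ordering_test(fit)
        assert res.ordering_satisfied
        assert all(est > 0 for est, _, _ in res.contrasts.values())

    def test_requires_cod_term(self):
        cohort, _ = generate_cohort(default_config(n_birds=200, seed=33))
        fit = fit_nb_glm(cohort, ())
        with pytest.raises(ValueError, match="cod"):
            cod_ordering_test(fit)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        birds = (
            [make_bird(f"k{i}", cod="KND", n_items=5) for i in range(3)]
            + [make_bird(f"i{i}", cod="Ind", n_items=5) for i in range(3)]
            + [make_bird(f"d{i}", cod="KD", n_items=5) for i in range(3)]
        )
        res = anova_posthoc(Cohort(birds), "count")
        assert res.f_statistic == 0.0 and res.p_value == 1.0

    def test_textbook_oracle(self):
        # one-way ANOVA of {1,2,3},{4,5,6},{7,8,9}: SSB=54 (df 2), SSW=6 (df 6)
        # => F = 27, p = 0.00100 (hand computation, confirmed by f_oneway)
        birds = (
            [make_bird(f"k{i}", cod="KND", n_items=k) for i, k in enumerate([1, 2, 3])]
            + [make_bird(f"i{i}", cod="Ind", n_items=k) for i, k in enumerate([4, 5, 6])]
            + [make_bird(f"d{i}", cod="KD", n_items=k) for i, k in enumerate([7, 8, 9])]
        )
        res = anova_posthoc(Cohort(birds), "count")
        assert res.f_statistic == pytest.approx(27.0, rel=1e-10)
        assert res.p_value == pytest.approx(0.001, rel=1e-3)

    def test_direction_on_default_synthetic_cohort(self, default_cohort):
        cohort, _ = default_cohort
        res = anova_posthoc(cohort, "count")
        assert res.group_means["KD"] > res.group_means["KND"]
        assert res.p_value < 0.05

    def test_missing_group_pair_not_estimable(self):
        birds = [make_bird(f"k{i}", cod="KND", n_items=i) for i in range(5)] + [
            make_bird(f"i{i}", cod="Ind", n_items=i + 1) for i in range(5)
        ]
        res = anova_posthoc(Cohort(birds), "count")
        assert math.isnan(res.pairwise_p["Ind-KD"])
        assert not math.isnan(res.pairwise_p["KND-Ind"])
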