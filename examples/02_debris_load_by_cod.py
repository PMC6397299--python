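"""Does ingested-debris load order as KND < Ind < KD?

Fits negative binomial count regressions (log link, variance mu + mu^2/theta)
to the per-bird debris counts, ranks candidate covariate sets by AIC, and
tests the pairwise cause-of-death contrasts on the log scale.  A one-way
ANOVA on the raw loads gives the simpler group comparison.
"""

from debrisdose import (
    anova_posthoc,
    check_overdispersion,
    cod_ordering_test,
    default_config,
    fit_nb_glm,
    generate_cohort,
)
from debrisdose.load_model import aic_table

cohort, _ = generate_cohort(default_config(seed=2))

table = aic_table(cohort, [("cod", "species"), ("cod", "species_weight"), ("cod",), ()])
print(table.to_frame().to_string(index=False))

fit = fit_nb_glm(cohort, ("cod",))
print(f"\ndispersion theta = {fit.theta:.3f} (strong overdispersion)")
adequacy = check_overdispersion(fit)
print(f"NB adequacy: Pearson X2/df = {adequacy.pearson_chi2/adequacy.df_resid:.2f} "
      f"(p = {adequacy.p_value:.2f}); Poisson contrast p = {adequacy.poisson_p_value:.1e}")

order = cod_ordering_test(fit)
for name, (est, se, p) in order.contrasts.items():
    print(f"contrast {name:8s}: {est:+.3f} (SE {se:.3f}, p {p:.2e})")
print(f"KND < Ind < KD ordering satisfied: {order.ordering_satisfied}")

anova = anova_posthoc(cohort, "count")
print(f"\nANOVA on counts: F = {anova.f_statistic:.1f}, p = {anova.p_value:.2e}")
print(
    "\nPositive contrasts mean birds that died of debris ingestion carried\n"
    "systematically larger debris loads than indeterminate or known-other birds."
)
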