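# debrisdose

Quantitative analysis linking marine-debris ingestion to seabird mortality.

Wild seabirds — Procellariiformes above all — ingest floating plastic,
balloons, rope and other anthropogenic debris. Necropsy cohorts of
beach-washed, by-caught and veterinary-casualty birds are the only practical
source of dose-response information: each bird carries a measured
ingested-debris load and a cause-of-death call which is often only partially
informative. `debrisdose` packages the statistical machinery for this
setting, for ecotoxicologists and seabird ecologists working with necropsy
data:

1. **Debris-load modelling.** Per-bird debris counts are strongly
   overdispersed, so loads across the three cause-of-death (COD) categories
   — KND (known, non-debris), Ind (indeterminate), KD (known debris-caused)
   — are compared with a negative binomial GLM: `log mu = X beta`, variance
   `mu + mu^2/theta`, candidate covariate sets (COD, species, age, family,
   mean species weight) ranked by `AIC = -2 log L + 2k`. Pairwise Wald
   contrasts on the COD coefficients test the expected ordering
   `KND < Ind < KD`; a one-way ANOVA with Welch post-hoc t-tests gives the
   per-metric (count / mass / volume) group comparison.
2. **Interval-outcome dose-response.** Each bird's probability of having
   died from debris is interval-valued: `[0,0]` for KND, `[1,1]` for KD,
   `[0,1]` for Ind (a second variant distrusts the KD attribution and widens
   KD to `[0,1]`). A Monte Carlo procedure draws Uniform(0,1) responses for
   the `[0,1]` birds and maximises the binomial-form likelihood of
   `logit P(death) = b0 + b1 * n_items + b2 * weight`
   (valid for fractional responses) in each of 1,000 replicates, summarised
   by median coefficients, the fraction of replicates with a significant
   slope, and a pointwise min/median/max dose-response envelope.
3. **Per-item lethality.** Deaths attributed to each debris type divided by
   items of that type ingested, expressed as risk ratios against hard
   plastic, including the soft-versus-hard aggregate contrast.
4. **Synthetic cohorts.** A generator with known ground truth (NB counts,
   logistic lifetime mortality, Bernoulli label masking) emulating the shape
   of a real 1733-bird cohort, so every stage is testable end to end without
   field data.

## Worked example

```python
from debrisdose import default_config, generate_cohort, monte_carlo_fit, predict_curve

cohort, truth = generate_cohort(default_config(seed=3))
mc = monte_carlo_fit(cohort, variant="trust_KD", n_reps=500, seed=0)
curve = predict_curve(mc)
print(f"median slope = {mc.median_b1:.4f} per item "
      f"(significant in {mc.frac_slope_significant:.0%} of {mc.n_converged} reps)")
for n in (1, 9, 20):
    print(f"P(death | {n:2d} items) = {curve.p_median[n]:.3f} "
          f"[{curve.p_min[n]:.3f}, {curve.p_max[n]:.3f}]")
```

prints

```
median slope = 0.2075 per item (significant in 100% of 500 reps)
P(death |  1 items) = 0.226 [0.212, 0.238]
P(death |  9 items) = 0.606 [0.556, 0.679]
P(death | 20 items) = 0.938 [0.904, 0.969]
```

i.e. on this synthetic cohort a single ingested item already carries a ~23%
lifetime chance of a debris-caused death, the odds rising by `exp(0.21)` per
additional item, with the bracketed envelope spanning the Monte Carlo
replicates. The scripts in `examples/` walk through each capability
(cohort simulation and summaries, the NB load model and AIC table, the
dose-response variants, per-item lethality ratios) and print a line of
interpretation with each result.

A thin CLI mirrors the library:

```sh
debris-dose simulate --out cohort.csv --seed 1
debris-dose run-all --out-dir report --reps 1000 --seed 1
```

`run-all` writes a diffable bundle of CSV/JSON artifacts (AIC table, COD
contrasts, per-replicate coefficients, dose curves, risk table), each
stamped with the config hash and seed that regenerate it exactly.

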