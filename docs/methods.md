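# Methods

This note documents the statistical models implemented in `debrisdose`, the
synthetic data-generating process used to validate them, and the numerical
and design choices that were genuinely open.

## Setting and data model

The unit of observation is a necropsied seabird: species and family codes,
age class, mean adult body mass of its species (grams), a list of ingested
debris items (type; mass in mg and volume in mm^3, either possibly
unrecorded), and a cause-of-death (COD) call in three grades —

* **KND**: a clearly identifiable non-debris cause (by-catch, trauma,
  disease);
* **Ind**: indeterminate — debris present and/or no cause could be
  confirmed;
* **KD**: debris-caused (gut blockage, obstruction or perforation
  attributed to an item), always accompanied by the lethal item's type.

Ind birds judged very likely to have died of debris (obstruction suspected
but unconfirmed, e.g. because of decomposition) carry a
`probable_debris_death` flag and a lethal-item attribution; they stay Ind
for the dose-response model but count as "probable" deaths in the per-item
risk tables.

Volumes of rigid items are derived from mass and an average material
density (0.95 g/cm^3 hard plastics, 0.91 balloons, 7.7 fishing hooks);
`mg / (g/cm^3) = mm^3`, so the derivation is a plain division. Soft and
compressible materials are not density-derivable and must carry a measured
displacement volume. Items with unrecorded mass/volume are kept in all
count-based analyses and simply excluded from mass/volume summaries.

## Debris-load model

Counts of ingested items are modelled as negative binomial (NB2): log link,
`Var(Y) = mu + mu^2 / theta`. The dispersion is estimated by profile
likelihood: for each candidate `alpha = 1/theta` the coefficients are
fitted by IRLS (a GLM with fixed-alpha NB family, whose log-likelihood is
the exact NB likelihood), and the profile is maximised by bounded Brent
search on `log alpha` over `[log 1e-7, log 1e3]`. `theta` is capped at
1e7, which is numerically the Poisson limit; equidispersed data run to the
cap. Standard errors and the coefficient covariance are conditional on the
fitted `theta` (the convention of the classic NB-GLM implementations);
AIC counts `theta` as one parameter, `AIC = -2 log L + 2(p + 1)`.

Candidate covariate sets (the default list spans COD, species, age, family
and mean species weight in eleven combinations) are all fitted on identical
rows — birds of unknown age are dropped up front only if any candidate
includes the age term — and ranked by AIC. Because mean species weight is
a species-level covariate, a model containing both the species factor and
species weight is exactly rank deficient; such members are excluded from
the table with a warning rather than silently pivoted, and a direct
`fit_nb_glm` call on an aliased design raises, naming the aliased columns.

The ordering hypothesis — debris load lowest in KND, intermediate in Ind,
highest in KD — is tested by Wald contrasts `Ind-KND`, `KD-Ind`, `KD-KND`
on the log-count scale with KND as the reference level; `ordering_satisfied`
means all three point estimates are positive. Model adequacy is checked by
the Pearson chi-square of the NB fit against its residual degrees of
freedom, with the analogous Poisson statistic reported for contrast.

The per-metric group comparison is a one-way ANOVA on the raw per-bird
load (count, summed mass, or summed volume) across the three COD groups,
computed from explicit sums of squares so that degenerate inputs behave
sensibly (identical groups give F = 0, p = 1, where the usual routine
returns NaN). Post-hoc pairwise comparisons use Welch's unequal-variance
t-test with Holm adjustment over the three pairs; both choices are
deliberately conservative, and a log-scale analysis is available by
transforming the loads before building the cohort frame. A pair involving
a group with fewer than two birds is reported as not estimable (NaN).

## Interval-outcome Monte Carlo dose-response

Each bird's probability of having died from debris ingestion is known only
to an interval: `[0,0]` (KND), `[1,1]` (KD), `[0,1]` (Ind). The
`distrust_KD` variant treats the KD attribution as unreliable and assigns
`[0,1]` to KD birds as well.

One Monte Carlo replicate draws an independent Uniform(0,1) response for
every `[0,1]` bird (fixed-interval birds keep their endpoint) and maximises
the binomial-form log-likelihood

    sum_i  y_i log p_i + (1 - y_i) log(1 - p_i),
    p_i = logistic(b0 + b1 * n_items_i + b2 * weight_i),

which is a proper objective for fractional `y`. The draw was specified
only as "a value in the interval"; the continuous-uniform reading is the
default, and a Bernoulli(1/2) mode is provided for sensitivity analysis.
Species weight enters linearly in grams as a gut-volume proxy; species
itself is excluded because a necropsy cohort will generally not contain all
three COD grades within every species. The fit is Newton-Raphson on
internally standardised covariates (step damping at near-separation;
gradient tolerance 1e-10; 60 iterations), with standard errors from the
observed information mapped back to the raw scale. Complete separation, a
response vector stuck at one extreme, or a coefficient exceeding 30 on the
standardised scale is flagged `converged=False`; a zero-variance covariate
(single-species cohort) is dropped and reported with a zero coefficient.

Replicates (default 1,000, seeded, bit-reproducible) are summarised by
coordinate-wise median coefficients over converged fits, the fraction of
converged replicates whose slope is Wald-significant at the 5% level, and a
dose-response curve at a reference body mass (default: the cohort mean)
whose envelope is the pointwise minimum/maximum of the per-replicate
curves — curve-wise extremes, not coefficient-wise extremes, since the
latter need not bound probabilities pointwise. More than 20% non-converged
replicates triggers a warning; medians are taken over the converged subset.
The logistic is inverted analytically for the load at a target mortality
(`n = (logit(p) - b0 - b2 w)/b1`), and a two-point exact solve through
anchor pairs `(n, p)` supports consistency checks of published curves.

## Per-item lethality

For each debris type: items ingested across the cohort, deaths attributed
(KD plus probable, by the recorded lethal item; confirmed-only counts are
reported alongside), the per-item death rate, and the rate ratio against a
reference type (hard plastic by default — dominant by count, least lethal
per item). The soft-item aggregate {soft plastic, balloon, rubber/foam,
rope} versus hard plastic is predefined; rope belongs in the soft group
because rope obstructions count among the soft-item deaths. Raw ratios are
canonical; integer rounding is presentation only. No uncertainty is
attached to the ratios — they are descriptive arithmetic on small death
counts.

## Synthetic cohort generator

The generator produces dead, necropsied birds with known ground truth:

* species drawn from a configurable table (six synthetic species spanning
  45 g storm-petrel to 3 kg albatross scale, Procellariiform-style family
  codes) by relative abundance;
* debris count `k ~ NB(mu, theta)` with
  `log mu = a0 + species effect`; defaults `a0 = log 1.5 - 0.055`,
  `theta = 0.17` give ~32% of birds ingesting, a mean count of ~1.5 and a
  maximum per-bird load around 40 in a 1733-bird cohort;
* item types i.i.d. from a mix dominated by hard plastic (92% of typed
  items); masses log-normal (median ~40 mg, sigma = 1 log-unit; ~1%
  unrecorded); volumes derived from density where derivable, otherwise
  from an assumed material density standing in for a displacement
  measurement;
* true debris death with probability
  `logistic(c0 + c1 k + c2 w)` — defaults anchored so that one ingested
  item carries a 20.4% lifetime mortality at the cohort mean weight and
  50% is reached at nine items (`c1 = 0.1702` per item,
  `c2 = -0.0005` per gram: heavier birds, larger guts, lower risk);
  otherwise an identifiable other cause (probability 0.8) or an
  unexplainable death;
* label masking: a debris death with recovered items is labelled KD with
  probability 0.8, else Ind with the probable flag and a lethal item drawn
  from the bird's items weighted by per-type lethality (balloons most
  lethal); a debris death with **zero** recovered items cannot be
  attributed by necropsy and is labelled through the other-cause channel
  (KND with probability 0.8, else Ind); other-cause deaths are labelled
  KND with probability 0.8, else Ind; unexplained deaths are always Ind.

The death mechanism is a lifetime (cross-sectional) probability — no time
dimension, gut turnover or age structure is simulated, and the recorded
load stands in for the bird's typical load. A consequence worth stating
plainly: under the default anchoring the logistic assigns ~18% mortality
even at zero recorded load (debris passed before death), and roughly a
quarter of generated deaths are debris-caused — far more than the
confirmed-KD fraction of a real cohort, which is consistent with necropsy
confirmation being conservative. The generator therefore emulates the
*mechanism* the analysis assumes, not the precise label frequencies of any
field dataset; default label shares come out near KND 59% / Ind 32% /
KD 9%.

Two default choices deserve their rationale:

* **Masking rates at 0.8.** The uniform-draw Monte Carlo estimator has two
  opposing systematic errors: Ind responses are pulled toward 1/2
  (attenuating the slope), while the unattributable zero-load debris deaths
  labelled KND depress the response at `k = 0` below the generating curve
  (inflating it). At detection rates of 0.8 (and other-cause rate 0.8)
  these cancel almost exactly, which makes slope-recovery checks
  meaningful; raising detection toward 1 reintroduces net inflation of
  several tens of percent. This is a property of the estimator, not a
  tuning of the truth.
* **KD labels require recovered items.** A structural consequence is that
  when many birds carry zero load, the KD group is load-enriched even under
  a null (zero-slope) generator — a real confounder that field data share.
  Type-I checks of the COD contrast therefore use the near-universal-
  ingestion null configuration (`null_dose_config`: `a0 = log 8`,
  `theta = 10`, `c1 = 0`), where this selection effect is negligible.

What passing tests on synthetic cohorts do **not** show about real data:
the generator has no spatial or seasonal structure, no age-dependent
ingestion, no debris turnover kinetics, independent Bernoulli masking
(real indeterminacy clusters by carcass condition), and a log-normal item
mass convenience assumption.

## Numerical choices and problem sizes

Statistical property tests run at sizes chosen for adequate power:
slope recovery over 20 generator replicates of n = 2000 with 200 Monte
Carlo replicates each; COD-ordering power over 50 replicates of n = 2000;
the null rejection rate of the KD-KND contrast over 200 replicates (a rate
estimate at 50 replicates has a binomial SE wider than the band being
checked); AIC selection consistency at n = 1200, where the generated
species effects are reliably detected. Oracle cross-checks (grid-refinement
maximisers of the NB and fractional-logistic likelihoods, written
independently of the fitting code) agree with the implementations to 1e-3
in log-likelihood and 1e-4 in coefficients on fixed small designs.

Degenerate-input conventions: empty cohorts summarise to zeros; ANOVA on
identical groups returns F = 0, p = 1; a Monte Carlo run with no free
intervals is deterministic; a reference debris type with no items or no
attributed deaths makes the risk table unavailable rather than silently
infinite. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configurations reproduce every
artifact bit-for-bit.

## Known limitations

The dose-response estimates inherit the biases of the uniform-draw interval
resolution discussed above; the package reports median coefficients and
envelopes but no frequentist confidence intervals for the dose curve; risk
ratios carry no uncertainty; and the NB fit's standard errors do not
propagate dispersion uncertainty. Population-level mortality projection is
out of scope.
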