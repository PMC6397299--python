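"""Debris-load modelling: NB GLM, overdispersion check, AIC ranking, COD tests.

The central question is whether ingested-debris load orders across
cause-of-death categories as KND < Ind < KD.  Counts are modelled with a
negative binomial GLM (log link, variance ``mu + mu^2/theta``) because the
loads are strongly overdispersed; candidate covariate sets are ranked by
AIC; and the COD coefficients (KND reference) are compared pairwise with
Wald contrasts.  A one-way ANOVA with Welch post-hoc t-tests provides the
simpler per-metric group comparison.

The dispersion ``theta`` is estimated by profiling: for each candidate
``alpha = 1/theta`` the regression coefficients are fitted by IRLS
(statsmodels GLM with a fixed-alpha negative binomial family, whose
log-likelihood is the exact NB likelihood), and ``alpha`` is maximised over
a bounded log-scale grid by Brent search.  ``theta`` is capped at 1e7 to
represent the Poisson limit.  Standard errors are conditional on the fitted
``theta``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .records import Cohort

__all__ = [
    "NBFit",
    "AdequacyReport",
    "AicTable",
    "CodOrderResult",
    "AnovaResult",
    "THETA_MAX",
    "TABLE1_MODEL_SET",
    "cohort_frame",
    "fit_nb_glm",
    "check_overdispersion",
    "aic_table",
    "cod_ordering_test",
    "anova_posthoc",
]

logger = logging.getLogger(__name__)

THETA_MAX = 1.0e7  # Poisson limit for the dispersion

VALID_TERMS = ("cod", "species", "age", "family", "species_weight")

#: The 11 candidate covariate sets ranked in the published AIC table.
TABLE1_MODEL_SET: tuple[tuple[str, ...], ...] = (
    ("cod", "species", "species_weight"),
    ("cod", "species"),
    ("cod", "age", "species"),
    ("cod", "age", "family", "species_weight"),
    ("cod", "age", "family"),
    ("cod", "family", "species_weight"),
    ("cod", "family"),
    ("cod", "species_weight"),
    ("cod", "age"),
    ("cod",),
    (),
)


def model_label(terms: Sequence[str]) -> str:
    return " + ".join(terms) if terms else "null"


@dataclass
class NBFit:
    """A fitted negative binomial count regression (log link)."""

    label: str
    terms: tuple[str, ...]
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    cov: np.ndarray  # covariance of beta, conditional on theta
    theta: float
    log_likelihood: float
    n_params: int  # counts theta
    aic: float
    converged: bool
    n_obs: int
    fitted_mu: np.ndarray
    response: np.ndarray  # the counts the model was fitted to
    exog: np.ndarray  # the design matrix rows used

    @property
    def param_names(self) -> list[str]:
        return list(self.coefficients)


@dataclass
class AdequacyReport:
    """Pearson chi-square adequacy of the NB fit, with a Poisson contrast."""

    pearson_chi2: float
    df_resid: int
    p_value: float
    poisson_pearson_chi2: float
    poisson_p_value: float

    @property
    def adequate(self) -> bool:
        return self.p_value >= 0.05


@dataclass
class AicTable:
    """Models ranked by ascending AIC with deltas to the best model."""

    rows: list[tuple[str, float]]  # (label, aic), ascending
    deltas: dict[str, float]
    fits: dict[str, NBFit]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [r[0] for r in self.rows],
                "aic": [r[1] for r in self.rows],
                "delta_aic": [self.deltas[r[0]] for r in self.rows],
            }
        )

    @property
    def best_label(self) -> str:
        return self.rows[0][0]


@dataclass
class CodOrderResult:
    """Pairwise COD contrasts on the log-count scale (KND reference)."""

    contrasts: dict[str, tuple[float, float, float]]  # name -> (est, se, p)
    ordering_satisfied: bool


@dataclass
class AnovaResult:
    metric: str
    f_statistic: float
    p_value: float
    pairwise_p: dict[str, float]  # Holm-adjusted Welch t-tests; NaN if not estimable
    group_means: dict[str, float]


# ---------------------------------------------------------------------------


def cohort_frame(cohort: Cohort) -> pd.DataFrame:
    """Per-bird analysis frame: count response plus candidate covariates."""
    return pd.DataFrame(
        {
            "bird_id": [b.bird_id for b in cohort],
            "count": [b.n_items for b in cohort],
            "cod": [b.cod for b in cohort],
            "species": [b.species for b in cohort],
            "family": [b.family for b in cohort],
            "age": [b.age_class for b in cohort],
            "species_weight": [b.species_weight for b in cohort],
            "mass": [b.total_mass() for b in cohort],
            "volume": [b.total_volume() for b in cohort],
        }
    )


def _design_matrix(df: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Treatment-coded design matrix; COD reference level is KND."""
    cols = {"Intercept": np.ones(len(df))}
    for term in terms:
        if term == "species_weight":
            cols["species_weight"] = df["species_weight"].to_numpy(float)
            continue
        if term not in ("cod", "species", "family", "age"):
            raise ValueError(f"unknown model term {term!r}; valid terms: {VALID_TERMS}")
        values = df[term].astype(str)
        levels = sorted(values.unique())
        if term == "cod":
            # KND is the reference so COD coefficients read directly as the
            # KND < Ind < KD ordering
            levels = [l for l in ("KND", "Ind", "KD") if l in levels]
        ref = levels[0]
        for level in levels[1:]:
            cols[f"{term}[{level}]"] = (values == level).to_numpy(float)
    X = pd.DataFrame(cols, index=df.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns by greedy rank inspection
        aliased = []
        keep: list[str] = []
        for c in X.columns:
            trial = keep + [c]
            if np.linalg.matrix_rank(X[trial].to_numpy()) < len(trial):
                aliased.append(c)
            else:
                keep.append(c)
        raise ValueError(f"design matrix is rank deficient; aliased terms: {aliased}")
    return X


def _rows_for_model_set(df: pd.DataFrame, model_set: Sequence[Sequence[str]]) -> pd.DataFrame:
    """Drop rows with unusable covariates for any model in the set."""
    used = {t for terms in model_set for t in terms}
    if "age" in used:
        df = df[df["age"] != "unknown"]
    return df.reset_index(drop=True)


def _nb_fit_given_alpha(y: np.ndarray, X: np.ndarray, alpha: float):
    fam = sm.families.NegativeBinomial(alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(y, X, family=fam).fit(maxiter=200)


def fit_nb_glm(cohort_or_frame, terms: Sequence[str] = ("cod",)) -> NBFit:
    """Fit the NB count regression by profile likelihood over the dispersion.

    ``terms`` is a subset of ``cod, species, age, family, species_weight``;
    the response is the per-bird debris item count.  Rows with unknown age
    are dropped only when the model includes the age term.
    """
    df = cohort_or_frame if isinstance(cohort_or_frame, pd.DataFrame) else cohort_frame(cohort_or_frame)
    terms = tuple(terms)
    if "age" in terms:
        df = df[df["age"] != "unknown"].reset_index(drop=True)
    X = _design_matrix(df, terms)
    y = df["count"].to_numpy(float)
    Xv = X.to_numpy(float)

    log_alpha_lo, log_alpha_hi = np.log(1.0 / THETA_MAX), np.log(1.0e3)

    def neg_profile_llf(log_alpha: float) -> float:
        res = _nb_fit_given_alpha(y, Xv, float(np.exp(log_alpha)))
        return -res.llf

    opt = optimize.minimize_scalar(
        neg_profile_llf,
        bounds=(log_alpha_lo, log_alpha_hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    alpha = float(np.exp(opt.x))
    res = _nb_fit_given_alpha(y, Xv, alpha)
    theta = min(1.0 / alpha, THETA_MAX)

    k = X.shape[1] + 1  # + theta
    llf = float(res.llf)
    names = list(X.columns)
    return NBFit(
        label=model_label(terms),
        terms=terms,
        coefficients=dict(zip(names, map(float, res.params))),
        standard_errors=dict(zip(names, map(float, res.bse))),
        cov=np.asarray(res.cov_params()),
        theta=theta,
        log_likelihood=llf,
        n_params=k,
        aic=-2.0 * llf + 2.0 * k,
        converged=bool(getattr(res, "converged", True) and opt.success),
        n_obs=len(y),
        fitted_mu=np.asarray(res.fittedvalues, dtype=float),
        response=y,
        exog=Xv,
    )


def check_overdispersion(fit: NBFit, cohort_or_frame=None) -> AdequacyReport:
    """Pearson chi-square adequacy of the NB variance, vs a Poisson contrast.

    Uses the rows the model was actually fitted on (stored on the fit), so
    it is valid even when the fit dropped rows (e.g. unknown-age birds).
    """
    y = fit.response
    mu = fit.fitted_mu
    var_nb = mu + mu**2 / fit.theta
    chi2 = float(np.sum((y - mu) ** 2 / var_nb))
    df_resid = len(y) - (fit.n_params - 1)
    p = float(stats.chi2.sf(chi2, df_resid))

    X = fit.exog
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    mu_p = np.asarray(pois.fittedvalues)
    chi2_p = float(np.sum((y - mu_p) ** 2 / mu_p))
    p_p = float(stats.chi2.sf(chi2_p, df_resid))
    return AdequacyReport(chi2, df_resid, p, chi2_p, p_p)


def aic_table(
    cohort: Cohort,
    model_set: Sequence[Sequence[str]] = TABLE1_MODEL_SET,
) -> AicTable:
    """Rank candidate covariate sets by AIC, all fitted on identical rows."""
    df = _rows_for_model_set(cohort_frame(cohort), model_set)
    fits: dict[str, NBFit] = {}
    for terms in model_set:
        label = model_label(terms)
        try:
            fit = fit_nb_glm(df, terms)
        except ValueError as err:
            # e.g. species_weight aliased with the species factor when weight
            # is a species-level covariate
            logger.warning("model %r not estimable (%s); excluded from AIC table", label, err)
            continue
        if not fit.converged:
            logger.warning("model %r did not converge; excluded from AIC table", label)
            continue
        fits[label] = fit
    if not fits:
        raise RuntimeError("no model in the set converged")
    rows = sorted(((lbl, f.aic) for lbl, f in fits.items()), key=lambda r: (r[1], r[0]))
    best = rows[0][1]
    deltas = {lbl: aic - best for lbl, aic in rows}
    return AicTable(rows=rows, deltas=deltas, fits=fits)


def cod_ordering_test(fit: NBFit) -> CodOrderResult:
    """Wald contrasts Ind-KND, KD-Ind, KD-KND on the log-count scale."""
    names = fit.param_names
    try:
        i_ind = names.index("cod[Ind]")
        i_kd = names.index("cod[KD]")
    except ValueError:
        raise ValueError(
            "fit does not include the cod term with both Ind and KD levels"
        ) from None
    beta = np.array([fit.coefficients[n] for n in names])
    cov = fit.cov

    def contrast(vec: np.ndarray) -> tuple[float, float, float]:
        est = float(vec @ beta)
        se = float(np.sqrt(vec @ cov @ vec))
        p = float(2.0 * stats.norm.sf(abs(est) / se)) if se > 0 else float("nan")
        return est, se, p

    k = len(names)
    v_ind = np.zeros(k)
    v_ind[i_ind] = 1.0
    v_kd = np.zeros(k)
    v_kd[i_kd] = 1.0
    contrasts = {
        "Ind-KND": contrast(v_ind),
        "KD-Ind": contrast(v_kd - v_ind),
        "KD-KND": contrast(v_kd),
    }
    ordering = all(c[0] > 0 for c in contrasts.values())
    return CodOrderResult(contrasts=contrasts, ordering_satisfied=ordering)


_METRIC_COL = {"count": "count", "mass": "mass", "volume": "volume"}


def anova_posthoc(cohort: Cohort, metric: str = "count") -> AnovaResult:
    """One-way ANOVA of per-bird load across COD groups with Welch post-hocs.

    Pairwise p-values are Holm-adjusted across the three COD pairs; a pair
    with a group of fewer than two birds is reported as NaN (not estimable).
    Loads are analysed on the raw scale.
    """
    if metric not in _METRIC_COL:
        raise ValueError(f"metric must be one of {sorted(_METRIC_COL)}")
    df = cohort_frame(cohort)
    groups = {c: df.loc[df["cod"] == c, _METRIC_COL[metric]].to_numpy(float) for c in ("KND", "Ind", "KD")}
    usable = {c: g for c, g in groups.items() if len(g) >= 2}
    if len(usable) < 2:
        raise ValueError("ANOVA needs at least two COD groups with >= 2 birds")

    # explicit sums of squares so that identical groups give F=0, p=1
    # (scipy.f_oneway returns NaN there)
    allv = np.concatenate(list(usable.values()))
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in usable.values())
    ssw = sum(((g - g.mean()) ** 2).sum() for g in usable.values())
    df_b = len(usable) - 1
    df_w = len(allv) - len(usable)
    if ssb <= 0:
        f_stat, p = 0.0, 1.0
    elif ssw <= 0 or df_w <= 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))

    pairs = [("KND", "Ind"), ("Ind", "KD"), ("KND", "KD")]
    raw: list[float] = []
    estimable: list[str] = []
    pairwise: dict[str, float] = {}
    for a, b in pairs:
        name = f"{a}-{b}"
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            pairwise[name] = float("nan")
            continue
        if np.var(groups[a]) == 0 and np.var(groups[b]) == 0:
            pw = 1.0 if groups[a].mean() == groups[b].mean() else 0.0
        else:
            pw = float(stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue)
        raw.append(pw)
        estimable.append(name)
    if raw:
        adj = multipletests(raw, method="holm")[1]
        pairwise.update(dict(zip(estimable, map(float, adj))))
    means = {c: (float(g.mean()) if len(g) else float("nan")) for c, g in groups.items()}
    return AnovaResult(
        metric=metric,
        f_statistic=float(f_stat),
        p_value=float(p),
        pairwise_p=pairwise,
        group_means=means,
    )
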