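"""Monte Carlo interval-outcome logistic dose-response model.

Each necropsied bird's probability of having died from debris ingestion is
known only to an interval: [0, 0] for known non-debris deaths (KND),
[1, 1] for confirmed debris deaths (KD), and [0, 1] for indeterminate
deaths (Ind).  A second model variant distrusts the KD attribution and
widens KD birds to [0, 1] as well.

The interval outcomes are resolved by Monte Carlo: in each replicate every
[0, 1] bird receives an independent Uniform(0, 1) draw as its response
(a Bernoulli(1/2) draw mode is available for sensitivity analysis) and a
logistic regression of the response on the number of ingested items and the
species mean body mass is fitted by maximising the binomial-form
log-likelihood

    sum_i  y_i log p_i + (1 - y_i) log(1 - p_i),
    p_i = logistic(b0 + b1 * n_items_i + b2 * weight_i),

which is well defined for fractional responses.  Replicates are summarised
by coordinate-wise median coefficients, the fraction of replicates with a
slope significant at the 5% level, and pointwise min/median/max predicted
dose-response curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .records import Cohort

__all__ = [
    "IntervalOutcome",
    "LogisticFit",
    "MonteCarloDoseFit",
    "DoseCurve",
    "assign_intervals",
    "fit_fractional_logistic",
    "monte_carlo_fit",
    "predict_curve",
    "dose_for_probability",
    "solve_from_anchors",
    "logit",
    "logistic",
]

VARIANTS = ("trust_KD", "distrust_KD")


def logit(p: float) -> float:
    if not 0.0 < p < 1.0:
        raise ValueError(f"logit requires p in (0, 1), got {p}")
    return math.log(p / (1.0 - p))


def logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class IntervalOutcome:
    """Per-bird [lower, upper] interval for the debris-death probability."""

    bird_id: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError(
                f"invalid interval [{self.lower}, {self.upper}] for bird {self.bird_id}"
            )

    @property
    def fixed(self) -> bool:
        return self.lower == self.upper


@dataclass
class LogisticFit:
    """One logistic fit: intercept, per-item slope, per-gram weight coefficient."""

    b0: float
    b1: float
    b2: float
    se_b0: float
    se_b1: float
    se_b2: float
    log_likelihood: float
    converged: bool

    @property
    def slope_p_value(self) -> float:
        if not self.converged or self.se_b1 <= 0:
            return float("nan")
        return float(2.0 * stats.norm.sf(abs(self.b1) / self.se_b1))


@dataclass
class MonteCarloDoseFit:
    """Monte Carlo summary over repeated interval resolutions."""

    variant: str
    n_reps: int
    seed: int
    draw: str  # "uniform" or "bernoulli"
    fits: list[LogisticFit]
    median_b0: float
    median_b1: float
    median_b2: float
    frac_slope_significant: float
    n_converged: int
    mean_species_weight: float  # cohort bird-weighted mean, grams

    @property
    def converged_fits(self) -> list[LogisticFit]:
        return [f for f in self.fits if f.converged]


@dataclass
class DoseCurve:
    """Median dose-response curve with a pointwise min/max envelope."""

    reference_weight: float
    n_grid: np.ndarray
    p_median: np.ndarray
    p_min: np.ndarray
    p_max: np.ndarray


def assign_intervals(cohort: Cohort, variant: str = "trust_KD") -> list[IntervalOutcome]:
    """Interval outcomes per COD: KND [0,0]; Ind [0,1]; KD [1,1] or [0,1].

    Under ``distrust_KD`` the KD attribution is assumed unreliable and KD
    birds receive [0, 1] like indeterminate birds.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    out = []
    for b in cohort:
        if b.cod == "KND":
            lo, hi = 0.0, 0.0
        elif b.cod == "Ind":
            lo, hi = 0.0, 1.0
        else:  # KD
            lo, hi = (1.0, 1.0) if variant == "trust_KD" else (0.0, 1.0)
        out.append(IntervalOutcome(b.bird_id, lo, hi))
    return out


# ---------------------------------------------------------------------------
# fractional-response logistic fit (Newton-Raphson with internal scaling)

_MAX_ITER = 60
_GRAD_TOL = 1e-10
_SEP_BOUND = 30.0  # |scaled coefficient| beyond this signals separation


def fit_fractional_logistic(
    counts: Sequence[float],
    weights: Sequence[float],
    y: Sequence[float],
) -> LogisticFit:
    """Maximum likelihood logistic fit accepting fractional responses in [0, 1].

    Newton-Raphson on internally standardised covariates; standard errors
    come from the observed information at the optimum (equal to the expected
    information for the binomial-form likelihood), mapped back to the raw
    covariate scale.  Complete separation or a response vector stuck at one
    extreme is reported as ``converged=False``.
    """
    n_arr = np.asarray(counts, dtype=float)
    w_arr = np.asarray(weights, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if n_arr.shape != y_arr.shape or w_arr.shape != y_arr.shape:
        raise ValueError("counts, weights and y must have equal length")
    if len(y_arr) < 3:
        raise ValueError("need at least 3 birds to fit the logistic model")
    if np.any((y_arr < 0) | (y_arr > 1)):
        raise ValueError("responses must lie in [0, 1]")
    # a response vector stuck at one extreme has its likelihood supremum at
    # an infinite intercept: flag rather than chase it
    degenerate = bool(np.all(y_arr == 0.0) or np.all(y_arr == 1.0))

    # standardise covariates for Newton stability; map coefficients back after.
    # A zero-variance covariate (e.g. a single-species cohort's weight) is
    # dropped from the optimisation and reported with a zero coefficient.
    m = np.array([n_arr.mean(), w_arr.mean()])
    s = np.array([n_arr.std(), w_arr.std()])
    active = np.concatenate([[True], s > 0])
    s_safe = np.where(s > 0, s, 1.0)
    X_full = np.column_stack(
        [np.ones_like(y_arr), (n_arr - m[0]) / s_safe[0], (w_arr - m[1]) / s_safe[1]]
    )
    X = X_full[:, active]

    beta = np.zeros(X.shape[1])
    ok = True
    for _ in range(_MAX_ITER):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y_arr - p)
        W = p * (1.0 - p)
        H = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            ok = False
            break
        # dampen huge steps (near-separation)
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        if np.max(np.abs(grad)) < _GRAD_TOL:
            break
    else:
        ok = ok and np.max(np.abs(X.T @ (y_arr - 1.0 / (1.0 + np.exp(-X @ beta))))) < 1e-6

    if degenerate or np.max(np.abs(beta)) > _SEP_BOUND or not np.all(np.isfinite(beta)):
        ok = False

    eta = X @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1.0 - 1e-12)
    llf = float(np.sum(y_arr * np.log(p) + (1.0 - y_arr) * np.log(1.0 - p)))

    beta_full = np.zeros(3)
    beta_full[active] = beta
    cov_raw = np.full((3, 3), np.nan)
    if ok:
        W = p * (1.0 - p)
        H = X.T @ (X * W[:, None])
        try:
            cov_scaled = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            ok = False
            cov_scaled = None
        if cov_scaled is not None:
            cov_full = np.zeros((3, 3))
            cov_full[np.ix_(active, active)] = cov_scaled
            # linear map from scaled to raw coefficients
            A = np.array(
                [
                    [1.0, -m[0] / s_safe[0], -m[1] / s_safe[1]],
                    [0.0, 1.0 / s_safe[0], 0.0],
                    [0.0, 0.0, 1.0 / s_safe[1]],
                ]
            )
            cov_raw = A @ cov_full @ A.T
            if np.any(np.diag(cov_raw)[active] <= 0):
                ok = False

    b_raw = np.array(
        [
            beta_full[0] - beta_full[1] * m[0] / s_safe[0] - beta_full[2] * m[1] / s_safe[1],
            beta_full[1] / s_safe[0],
            beta_full[2] / s_safe[1],
        ]
    )
    se = np.sqrt(np.abs(np.diag(cov_raw)))
    se[~active] = np.nan
    return LogisticFit(
        b0=float(b_raw[0]),
        b1=float(b_raw[1]),
        b2=float(b_raw[2]),
        se_b0=float(se[0]),
        se_b1=float(se[1]),
        se_b2=float(se[2]),
        log_likelihood=llf,
        converged=bool(ok),
    )


def monte_carlo_fit(
    cohort: Cohort,
    variant: str = "trust_KD",
    n_reps: int = 1000,
    seed: int = 0,
    draw: str = "uniform",
) -> MonteCarloDoseFit:
    """Repeatedly resolve interval outcomes at random and refit the logistic.

    ``draw="uniform"`` gives each [0, 1] bird an independent Uniform(0, 1)
    response (the default, matching a continuous value drawn in the
    interval); ``draw="bernoulli"`` draws 0/1 with probability 1/2 instead.
    The same seed reproduces the result bit-for-bit.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if draw not in ("uniform", "bernoulli"):
        raise ValueError("draw must be 'uniform' or 'bernoulli'")
    intervals = assign_intervals(cohort, variant)
    lower = np.array([iv.lower for iv in intervals])
    free = np.array([not iv.fixed for iv in intervals])
    if not free.any() and len(set(lower)) < 2:
        raise ValueError(
            "outcomes are all fixed at a single value; the model is not identifiable"
        )
    counts = np.array([b.n_items for b in cohort], dtype=float)
    weights = np.array([b.species_weight for b in cohort], dtype=float)

    rng = np.random.default_rng(seed)
    fits: list[LogisticFit] = []
    for _ in range(n_reps):
        y = lower.copy()
        if free.any():
            if draw == "uniform":
                y[free] = rng.random(int(free.sum()))
            else:
                y[free] = (rng.random(int(free.sum())) < 0.5).astype(float)
        fits.append(fit_fractional_logistic(counts, weights, y))

    conv = [f for f in fits if f.converged]
    if not conv:
        raise RuntimeError("no Monte Carlo replicate converged")
    frac_bad = 1.0 - len(conv) / len(fits)
    if frac_bad > 0.20:
        warnings.warn(
            f"{frac_bad:.0%} of Monte Carlo replicates failed to converge",
            RuntimeWarning,
            stacklevel=2,
        )
    b0s = np.array([f.b0 for f in conv])
    b1s = np.array([f.b1 for f in conv])
    b2s = np.array([f.b2 for f in conv])
    pvals = np.array([f.slope_p_value for f in conv])
    return MonteCarloDoseFit(
        variant=variant,
        n_reps=n_reps,
        seed=seed,
        draw=draw,
        fits=fits,
        median_b0=float(np.median(b0s)),
        median_b1=float(np.median(b1s)),
        median_b2=float(np.median(b2s)),
        frac_slope_significant=float(np.mean(pvals < 0.05)),
        n_converged=len(conv),
        mean_species_weight=float(weights.mean()),
    )


def predict_curve(
    mcfit: MonteCarloDoseFit,
    reference_weight: Optional[float] = None,
    n_grid: Optional[Sequence[float]] = None,
) -> DoseCurve:
    """Median curve and pointwise min/max envelope at a reference body mass.

    The reference mass defaults to the cohort's bird-weighted mean species
    weight recorded on the fit.
    """
    if reference_weight is None:
        reference_weight = mcfit.mean_species_weight
    grid = np.asarray(n_grid if n_grid is not None else np.arange(0, 101), dtype=float)
    conv = mcfit.converged_fits
    if not conv:
        raise ValueError("no converged replicate to predict from")
    med = logistic(
        mcfit.median_b0 + mcfit.median_b1 * grid + mcfit.median_b2 * reference_weight
    )
    curves = np.vstack(
        [logistic(f.b0 + f.b1 * grid + f.b2 * reference_weight) for f in conv]
    )
    p_min = np.minimum(curves.min(axis=0), med)
    p_max = np.maximum(curves.max(axis=0), med)
    return DoseCurve(
        reference_weight=float(reference_weight),
        n_grid=grid,
        p_median=med,
        p_min=p_min,
        p_max=p_max,
    )


def dose_for_probability(
    coefficients: tuple[float, float, float],
    reference_weight: float,
    p: float,
) -> float:
    """Invert the logistic: the load at which death probability reaches ``p``."""
    b0, b1, b2 = coefficients
    if b1 == 0:
        raise ValueError("slope b1 is zero; dose for a target probability is undefined")
    if not 0.0 < p < 1.0:
        raise ValueError(f"target probability must be in (0, 1), got {p}")
    return (logit(p) - b0 - b2 * reference_weight) / b1


def solve_from_anchors(
    anchor1: tuple[float, float], anchor2: tuple[float, float]
) -> tuple[float, float]:
    """Exact two-point solve of ``logit(P) = b0 + b1 * n`` (fixed weight term).

    Used to check the internal consistency of printed dose-probability
    anchor pairs.
    """
    n1, p1 = anchor1
    n2, p2 = anchor2
    if n1 == n2:
        raise ValueError("anchor loads must differ")
    l1, l2 = logit(p1), logit(p2)
    b1 = (l2 - l1) / (n2 - n1)
    b0 = l1 - b1 * n1
    return b0, b1
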