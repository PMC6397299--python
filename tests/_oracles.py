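"""Independent brute-force oracles used to cross-check the fitted models.

These deliberately avoid the package's own optimisation paths: both are
plain iterative grid-refinement maximisers of the likelihood written from
the density formulas.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def fractional_logistic_loglik(
    b0: np.ndarray, b1: np.ndarray, b2: np.ndarray,
    counts: np.ndarray, weights: np.ndarray, y: np.ndarray,
) -> np.ndarray:
    """Binomial-form log-likelihood for fractional responses, broadcastable."""
    eta = (
        np.asarray(b0)[..., None]
        + np.asarray(b1)[..., None] * counts
        + np.asarray(b2)[..., None] * weights
    )
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    return np.sum(y * np.log(p) + (1 - y) * np.log(1 - p), axis=-1)


def grid_refine_logistic(
    counts, weights, y, rounds: int = 12, pts: int = 21,
    b0_range=(-10.0, 10.0), b1_range=(-2.0, 2.0), b2_range=(-0.05, 0.05),
):
    """Maximise the fractional logistic likelihood by iterative grid zooming."""
    counts = np.asarray(counts, float)
    weights = np.asarray(weights, float)
    y = np.asarray(y, float)
    lo = np.array([b0_range[0], b1_range[0], b2_range[0]])
    hi = np.array([b0_range[1], b1_range[1], b2_range[1]])
    best = None
    for _ in range(rounds):
        g0 = np.linspace(lo[0], hi[0], pts)
        g1 = np.linspace(lo[1], hi[1], pts)
        g2 = np.linspace(lo[2], hi[2], pts)
        B0, B1, B2 = np.meshgrid(g0, g1, g2, indexing="ij")
        ll = fractional_logistic_loglik(
            B0.ravel(), B1.ravel(), B2.ravel(), counts, weights, y
        )
        k = int(np.argmax(ll))
        best = np.array([B0.ravel()[k], B1.ravel()[k], B2.ravel()[k]])
        span = (hi - lo) / (pts - 1)
        lo = best - 2 * span
        hi = best + 2 * span
    return best, fractional_logistic_loglik(
        best[0:1], best[1:2], best[2:3], counts, weights, y
    )[0]


def nb_intercept_loglik(b0: np.ndarray, log_theta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """NB2 log-likelihood of an intercept-only log-link model, broadcastable."""
    mu = np.exp(np.asarray(b0))[..., None]
    theta = np.exp(np.asarray(log_theta))[..., None]
    return np.sum(stats.nbinom.logpmf(y, theta, theta / (theta + mu)), axis=-1)


def grid_refine_nb_intercept(
    y, rounds: int = 12, pts: int = 41,
    b0_range=(-5.0, 5.0), log_theta_range=(-5.0, 8.0),
):
    """Maximise the intercept-only NB likelihood over (b0, log theta)."""
    y = np.asarray(y, float)
    lo = np.array([b0_range[0], log_theta_range[0]])
    hi = np.array([b0_range[1], log_theta_range[1]])
    best = None
    for _ in range(rounds):
        g0 = np.linspace(lo[0], hi[0], pts)
        g1 = np.linspace(lo[1], hi[1], pts)
        B0, LT = np.meshgrid(g0, g1, indexing="ij")
        ll = nb_intercept_loglik(B0.ravel(), LT.ravel(), y)
        k = int(np.argmax(ll))
        best = np.array([B0.ravel()[k], LT.ravel()[k]])
        span = (hi - lo) / (pts - 1)
        lo = best - 2 * span
        hi = best + 2 * span
    return best, nb_intercept_loglik(best[0:1], best[1:2], y)[0]
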