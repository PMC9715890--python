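"""Beta-binomial model for positive-node counts among node-positive patients.

The number of positive nodes ``m`` found when ``e`` nodes are examined is
modelled as binomial with a patient-specific involvement probability drawn
from a Beta(alpha, beta) distribution, i.e. the beta-binomial distribution

    P(m | e) = C(e, m) * B(alpha + m, beta + e - m) / B(alpha, beta)

where B is the beta function.  The beta mixing captures between-patient
heterogeneity (overdispersion) in the fraction of involved nodes that a plain
binomial cannot.  Shape parameters are estimated per T stage by maximum
likelihood on node-positive (pN+) patients only; patients whose examined
nodes were all positive (m = e) carry no information about the negative-node
fraction and are excluded from the fit (but still counted as true positives
downstream).

All probability computations are done in log space via ``scipy.special`` so
they are stable for large node counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, digamma, gammaln

from .errors import FitError

__all__ = [
    "BetaBinomParams",
    "FitResult",
    "pmf",
    "logpmf",
    "log_likelihood",
    "exclude_all_positive",
    "fit_mle",
    "grid_search_mle",
]

# log-shape box used both as optimizer bounds and grid-oracle extent
_LOG_SHAPE_LO = math.log(1e-4)
_LOG_SHAPE_HI = math.log(1e4)
_LL_SENTINEL = -1e300  # finite stand-in for -inf so optimizers never see nan


@dataclass(frozen=True)
class BetaBinomParams:
    """Shape pair (alpha, beta) of the beta mixing distribution."""

    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0) or not (
            math.isfinite(self.alpha) and math.isfinite(self.beta)
        ):
            raise ValueError(
                f"shape parameters must be positive finite, got "
                f"alpha={self.alpha}, beta={self.beta}"
            )

    @property
    def mean_fraction(self) -> float:
        """Expected fraction of involved nodes, alpha / (alpha + beta)."""
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a per-stratum maximum-likelihood fit."""

    params: BetaBinomParams
    log_likelihood: float
    converged: bool
    n_used: int
    n_excluded_all_positive: int
    t_stage: int | None = None


def _validate_counts(m, e):
    m = np.asarray(m)
    e = np.asarray(e)
    if np.any(m < 0) or np.any(e < 0):
        raise ValueError("counts must be non-negative")
    if np.any(m > e):
        raise ValueError("nodes positive m cannot exceed nodes examined e")
    return m, e


def logpmf(m, e, params: BetaBinomParams):
    """Log beta-binomial probability, vectorized over ``m`` and ``e``.

    ``e = 0`` is only valid with ``m = 0`` and returns log(1) = 0: with no
    nodes examined the only possible observation is zero positives.
    """
    m, e = _validate_counts(m, e)
    a, b = params.alpha, params.beta
    out = (
        gammaln(e + 1)
        - gammaln(m + 1)
        - gammaln(e - m + 1)
        + betaln(a + m, b + e - m)
        - betaln(a, b)
    )
    return out


def pmf(m, e, params: BetaBinomParams):
    """Beta-binomial probability mass C(e,m) B(a+m, b+e-m) / B(a,b)."""
    return np.exp(logpmf(m, e, params))


def _as_pairs(observations) -> np.ndarray:
    arr = np.asarray(observations, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("observations must be a sequence of (m, e) pairs")
    return arr


def log_likelihood(observations, params: BetaBinomParams) -> float:
    """Sum of log pmf over (m, e) pairs; -inf-safe.

    The fitting set contains only node-positive patients, so every pair must
    satisfy 1 <= m <= e.
    """
    arr = _as_pairs(observations)
    if arr.shape[0] == 0:
        raise ValueError("log-likelihood of an empty observation set is undefined")
    if np.any(arr[:, 0] < 1):
        raise ValueError("fitting pairs must have m >= 1 (pN+ patients only)")
    ll = float(np.sum(logpmf(arr[:, 0], arr[:, 1], params)))
    if not math.isfinite(ll):
        return _LL_SENTINEL
    return ll


def exclude_all_positive(observations):
    """Drop pairs with m = e (zero negative nodes) before fitting.

    Such patients would always have had more positives had more nodes been
    examined; they contribute nothing to estimating the negative-node
    fraction.  They remain counted as true positives in the downstream
    false-negative tallies.  Returns ``(kept, n_excluded)``.
    """
    arr = _as_pairs(observations) if len(observations) else np.empty((0, 2))
    if arr.shape[0] == 0:
        return [], 0
    keep = arr[:, 0] < arr[:, 1]
    kept = [(int(m), int(e)) for m, e in arr[keep]]
    return kept, int((~keep).sum())


def _moment_init(arr: np.ndarray) -> tuple[float, float]:
    # method of moments on the m/e fractions; clipped, with uniform fallback
    frac = arr[:, 0] / arr[:, 1]
    mu = float(np.mean(frac))
    v = float(np.var(frac))
    if 0 < v < mu * (1 - mu):
        common = mu * (1 - mu) / v - 1
        a, b = mu * common, (1 - mu) * common
    else:
        a, b = 1.0, 1.0
    return float(np.clip(a, 0.01, 100.0)), float(np.clip(b, 0.01, 100.0))


def _negll_factory(arr: np.ndarray, truncated: bool):
    m, e = arr[:, 0], arr[:, 1]
    n = len(m)
    # constant in (alpha, beta); kept so the reported loglik is the true value
    const = float(np.sum(gammaln(e + 1) - gammaln(m + 1) - gammaln(e - m + 1)))

    def negll(x):
        a, b = math.exp(x[0]), math.exp(x[1])
        ll = const + float(np.sum(betaln(a + m, b + e - m)) - n * betaln(a, b))
        if truncated:
            # condition on m >= 1: subtract sum log(1 - P(0 | e))
            log_p0 = betaln(a, b + e) - betaln(a, b)
            ll -= float(np.sum(np.log1p(-np.exp(log_p0))))
        if not math.isfinite(ll):
            return -_LL_SENTINEL
        return -ll

    def negll_grad(x):
        # analytic gradient in (log alpha, log beta) via digamma
        a, b = math.exp(x[0]), math.exp(x[1])
        psi_abe = digamma(a + b + e)
        psi_ab = digamma(a + b)
        da = float(np.sum(digamma(a + m) - psi_abe)) - n * (digamma(a) - psi_ab)
        db = float(np.sum(digamma(b + e - m) - psi_abe)) - n * (
            digamma(b) - psi_ab
        )
        if truncated:
            log_p0 = betaln(a, b + e) - betaln(a, b)
            w = np.exp(log_p0 - np.log1p(-np.exp(log_p0)))  # P0 / (1 - P0)
            da += float(np.sum(w * (psi_ab - psi_abe)))
            db += float(np.sum(w * (digamma(b + e) - psi_abe - digamma(b) + psi_ab)))
        g = -np.array([da * a, db * b])
        if not np.all(np.isfinite(g)):
            g = np.zeros(2)
        return negll(x), g

    return negll, negll_grad


def fit_mle(
    observations, t_stage: int | None = None, truncated: bool = True
) -> FitResult:
    """Maximum-likelihood shape estimates for one stratum's pN+ pairs.

    The fitting set consists of observed node-positive patients, i.e. a
    sample conditioned on m >= 1.  By default the matching zero-truncated
    likelihood ``pmf(m | e) / (1 - pmf(0 | e))`` is maximized, which is
    consistent for (alpha, beta) under that sampling; ``truncated=False``
    maximizes the plain unconditional likelihood instead (the simpler
    objective used by earlier staging-score work; it overstates nodal
    involvement because zero draws are never observed).

    All-positive pairs (m = e) are excluded first and counted.  Optimization
    runs in (log alpha, log beta) space from a method-of-moments start,
    bounded to log-shape in [log 1e-4, log 1e4].  ``log_likelihood`` in the
    result is the maximized objective.

    Raises :class:`FitError` when fewer than two informative pairs remain.
    Non-convergence is reported via ``converged=False``, never silently.
    """
    kept, n_excluded = exclude_all_positive(observations)
    if len(kept) < 2:
        raise FitError(
            f"only {len(kept)} informative pN+ pairs after excluding m = e; "
            "need at least 2 — consider pooling strata"
        )
    arr = _as_pairs(kept)
    if np.any(arr[:, 0] < 1):
        raise ValueError("fitting pairs must have m >= 1 (pN+ patients only)")

    a0, b0 = _moment_init(arr)
    negll, negll_grad = _negll_factory(arr, truncated)
    x0 = [math.log(a0), math.log(b0)]
    bounds = [(_LOG_SHAPE_LO, _LOG_SHAPE_HI)] * 2
    res = minimize(
        negll_grad,
        x0=x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-12, "gtol": 1e-9, "maxiter": 500},
    )
    if not res.success:
        # derivative-free fallback for awkward likelihood surfaces
        res = minimize(
            negll,
            x0=res.x,
            method="Nelder-Mead",
            bounds=bounds,
            options={"fatol": 1e-8, "xatol": 1e-8, "maxiter": 2000, "maxfev": 4000},
        )
    params = BetaBinomParams(math.exp(res.x[0]), math.exp(res.x[1]))
    return FitResult(
        params=params,
        log_likelihood=-float(res.fun),
        converged=bool(res.success),
        n_used=len(kept),
        n_excluded_all_positive=n_excluded,
        t_stage=t_stage,
    )


def grid_search_mle(
    observations,
    n_grid: int = 200,
    lo: float = 0.01,
    hi: float = 100.0,
    truncated: bool = True,
) -> tuple[BetaBinomParams, float]:
    """Brute-force likelihood maximization over a log-spaced shape grid.

    Deliberately simple and exhaustive: evaluates the (same) objective as
    :func:`fit_mle` at every (alpha, beta) on an ``n_grid`` x ``n_grid``
    log-spaced grid over [lo, hi]^2 and returns the argmax with its
    log-likelihood.  Serves as an independent check on the optimizer.
    """
    kept, _ = exclude_all_positive(observations)
    arr = _as_pairs(kept)
    if arr.shape[0] == 0:
        raise FitError("no informative pairs for grid search")
    m, e = arr[:, 0], arr[:, 1]
    const = float(np.sum(gammaln(e + 1) - gammaln(m + 1) - gammaln(e - m + 1)))
    shapes = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    best_ll, best = -np.inf, (1.0, 1.0)
    n = len(m)
    for a in shapes:  # chunk over alpha to bound memory at n_grid * n floats
        bl = betaln(a + m[None, :], shapes[:, None] + e[None, :] - m[None, :])
        ll_rows = bl.sum(axis=1) - n * betaln(a, shapes)
        if truncated:
            log_p0 = betaln(a, shapes[:, None] + e[None, :]) - betaln(a, shapes)[:, None]
            ll_rows = ll_rows - np.log1p(-np.exp(log_p0)).sum(axis=1)
        j = int(np.argmax(ll_rows))
        if ll_rows[j] > best_ll:
            best_ll = float(ll_rows[j])
            best = (float(a), float(shapes[j]))
    return BetaBinomParams(*best), best_ll + const
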