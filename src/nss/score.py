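"""Nodal staging score: false-negative correction and staging adequacy.

Given per-T-stage beta-binomial shapes (alpha, beta) fitted on pN+ patients,
this module chains four quantities:

1. ``P(FN | e)`` — the probability that a truly node-positive patient shows
   zero positive nodes among ``e`` examined:
   ``P(FN | e) = B(alpha, beta + e) / B(alpha, beta)``.
2. ``FN_e`` — the expected number of false-negative pN0 patients at each
   observed ``e``:  ``min(P(FN) * TP_e / (1 - P(FN)), N_e)``, capped because
   no more pN0 patients can be reclassified than exist.
3. The adjusted LNM rate — prevalence after reclassifying the estimated
   false negatives:  ``(sum FN + sum TP) / (sum N + sum TP)``.
4. The nodal staging score — the posterior probability that a pN0 call is
   correct, by Bayes' rule with the adjusted rate as prior:
   ``NSS(e) = (1 - rate) / ((1 - rate) + rate * P(FN | e))``.

``adequate_lne`` inverts the NSS curve: the smallest number of examined
nodes at which the score exceeds a target (90% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln

from .betabinom import BetaBinomParams, FitResult
from .cohort import StratifiedCohort
from .errors import ConfigurationError, UndefinedRateError

__all__ = [
    "AdjustedRate",
    "AdequacyResult",
    "prob_false_negative",
    "estimate_false_negatives",
    "adjusted_rate",
    "nodal_staging_score",
    "adequate_lne",
    "build_nss_table",
    "stratum_adjusted_rate",
]


@dataclass(frozen=True)
class AdjustedRate:
    """Raw and false-negative-corrected LNM rate for one stratum."""

    t_stage: int | None
    raw_rate: float
    adjusted_rate: float

    @property
    def increase(self) -> float:
        return self.adjusted_rate - self.raw_rate


@dataclass(frozen=True)
class AdequacyResult:
    """Smallest examined-node count reaching the staging-score target.

    ``attainable`` is False when the target is not reached by ``e_max``;
    ``nss_attained`` then holds the score at ``e_max``.
    """

    e_required: int
    nss_attained: float
    attainable: bool
    threshold: float


def prob_false_negative(e, params: BetaBinomParams):
    """P(zero positive nodes among e examined | truly node-positive).

    Equals the beta-binomial pmf at m = 0: B(alpha, beta+e) / B(alpha, beta).
    Strictly decreasing in e; equals 1 at e = 0 (no examination, no
    information).  Vectorized over ``e``.
    """
    e_arr = np.asarray(e)
    if np.any(e_arr < 0):
        raise ValueError("nodes examined must be non-negative")
    a, b = params.alpha, params.beta
    out = np.exp(betaln(a, b + e_arr) - betaln(a, b))
    return out if out.ndim else float(out)


def estimate_false_negatives(p_fn: float, tp_e: int, n_e: int) -> float:
    """Expected false-negative pN0 count at one examined-node value.

    Scales the true-positive tally by the odds of missing,
    ``p_fn / (1 - p_fn)``, and caps at the available pN0 count ``n_e``.
    At ``p_fn = 1`` the cap is the limit: every pN0 patient at that ``e``
    is potentially false-negative.
    """
    if not (0 <= p_fn <= 1):
        raise ValueError("p_fn must be a probability")
    if tp_e < 0 or n_e < 0:
        raise ValueError("tallies must be non-negative")
    if p_fn >= 1.0:
        return float(n_e)
    return float(min(p_fn * tp_e / (1.0 - p_fn), n_e))


def adjusted_rate(
    fn_by_e: dict[int, float],
    tp_by_e: dict[int, int],
    n_by_e: dict[int, int],
    t_stage: int | None = None,
) -> AdjustedRate:
    """Corrected LNM rate after reclassifying estimated false negatives.

    raw      = sum TP / (sum N + sum TP)
    adjusted = (sum FN + sum TP) / (sum N + sum TP)

    The denominator is unchanged because every reclassified false negative
    moves from the pN0 numerator to the positive one; hence adjusted >= raw.
    """
    es = set(fn_by_e) | set(tp_by_e) | set(n_by_e)
    fn_sum = sum(fn_by_e.get(e, 0.0) for e in es)
    tp_sum = sum(tp_by_e.get(e, 0) for e in es)
    n_sum = sum(n_by_e.get(e, 0) for e in es)
    total = n_sum + tp_sum
    if total == 0:
        raise UndefinedRateError(f"empty stratum {t_stage!r}")
    for e in es:
        if fn_by_e.get(e, 0.0) > n_by_e.get(e, 0) + 1e-9:
            raise ValueError(f"fn estimate exceeds pN0 count at e={e}")
    return AdjustedRate(
        t_stage=t_stage,
        raw_rate=tp_sum / total,
        adjusted_rate=(fn_sum + tp_sum) / total,
    )


def nodal_staging_score(e, rate: float, params: BetaBinomParams):
    """Probability that a pN0 diagnosis at ``e`` examined nodes is correct.

    Bayes' rule with prior prevalence ``rate``:
    NSS = (1 - rate) / ((1 - rate) + rate * P(FN | e)).
    Strictly increasing in ``e``; equals ``1 - rate`` at e = 0 and tends to
    1 as P(FN) vanishes.  Vectorized over ``e``.
    """
    if not (0 < rate < 1):
        raise ValueError("rate must lie strictly inside (0, 1)")
    p_fn = prob_false_negative(e, params)
    out = (1.0 - rate) / ((1.0 - rate) + rate * np.asarray(p_fn))
    return out if np.ndim(out) else float(out)


def adequate_lne(
    rate: float,
    params: BetaBinomParams,
    threshold: float = 0.90,
    e_max: int = 200,
    strict: bool = True,
) -> AdequacyResult:
    """Smallest examined-node count whose staging score exceeds ``threshold``.

    ``strict=True`` requires NSS > threshold (the adequacy convention used
    throughout this package); set False for >=.  If even zero examined nodes
    already satisfy the target (prior 1 - rate above it), returns 0 with a
    warning.  If the target is not reached by ``e_max``, returns an
    unattainable result carrying the score at ``e_max``.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    prior = nodal_staging_score(0, rate, params)
    op = np.greater if strict else np.greater_equal
    if op(prior, threshold):
        warnings.warn(
            f"prior probability of true pN0 ({prior:.3f}) already exceeds the "
            f"threshold {threshold}; no nodal examination needed",
            stacklevel=2,
        )
        return AdequacyResult(0, float(prior), True, threshold)
    es = np.arange(0, e_max + 1)
    scores = nodal_staging_score(es, rate, params)
    hits = np.flatnonzero(op(scores, threshold))
    if hits.size == 0:
        return AdequacyResult(e_max, float(scores[-1]), False, threshold)
    e_req = int(es[hits[0]])
    return AdequacyResult(e_req, float(scores[hits[0]]), True, threshold)


def stratum_adjusted_rate(
    cohort: StratifiedCohort, t_stage: int, params: BetaBinomParams
) -> AdjustedRate:
    """Adjusted LNM rate of one stratum from its tallies and fitted shapes."""
    tp_by_e, n_by_e = cohort.tallies(t_stage)
    es = sorted(set(tp_by_e) | set(n_by_e))
    fn_by_e = {
        e: estimate_false_negatives(
            float(prob_false_negative(e, params)),
            tp_by_e.get(e, 0),
            n_by_e.get(e, 0),
        )
        for e in es
    }
    return adjusted_rate(fn_by_e, tp_by_e, n_by_e, t_stage)


def build_nss_table(
    cohort: StratifiedCohort,
    fits: dict[int, FitResult | BetaBinomParams],
    e_max: int | None = None,
) -> pd.DataFrame:
    """Per (T stage, e) table of P(FN), false-negative estimate and NSS.

    The grid runs over integers 1..max observed e in each stratum (or
    ``e_max`` if given); tallies are zero at unobserved e, where the
    false-negative estimate is definitionally zero but P(FN) and NSS remain
    defined.  Columns: t_stage, e, p_fn, fn_est, tp, n, nss.
    """
    rows = []
    for t in cohort.t_stages:
        if t not in fits:
            raise ConfigurationError(f"no fitted parameters for stratum T{t}")
        fit = fits[t]
        params = fit.params if isinstance(fit, FitResult) else fit
        tp_by_e, n_by_e = cohort.tallies(t)
        top = e_max if e_max is not None else max([*tp_by_e, *n_by_e])
        es = np.arange(1, top + 1)
        p_fn = prob_false_negative(es, params)
        fn_by_e = {
            int(e): estimate_false_negatives(
                float(p), tp_by_e.get(int(e), 0), n_by_e.get(int(e), 0)
            )
            for e, p in zip(es, p_fn)
        }
        adj = adjusted_rate(fn_by_e, tp_by_e, n_by_e, t)
        nss = nodal_staging_score(es, adj.adjusted_rate, params)
        for e, p, s in zip(es, p_fn, nss):
            rows.append(
                {
                    "t_stage": t,
                    "e": int(e),
                    "p_fn": float(p),
                    "fn_est": fn_by_e[int(e)],
                    "tp": tp_by_e.get(int(e), 0),
                    "n": n_by_e.get(int(e), 0),
                    "nss": float(s),
                }
            )
    return pd.DataFrame(rows)
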