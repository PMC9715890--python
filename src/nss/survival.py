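"""Model-free validation of the staging score by survival separation.

The staging score is built only from nodal counts, never from follow-up, so
follow-up provides an independent check: among observed pN0 patients, a
higher score means a smaller chance of occult nodal disease and should
therefore predict better disease-specific survival.  This module scores pN0
patients, groups them by score quartile, and compares the groups with
Kaplan-Meier curves and a log-rank test (via :mod:`lifelines`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .betabinom import BetaBinomParams, FitResult
from .errors import ConfigurationError
from .score import nodal_staging_score

__all__ = [
    "KMCurve",
    "assign_nss",
    "quartile_groups",
    "km_estimate",
    "log_rank",
    "survival_by_nss_quartile",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate for one group."""

    times: np.ndarray  # ascending
    survival: np.ndarray  # step-function values, starts at 1
    at_risk: np.ndarray
    label: str

    def at(self, t: float) -> float:
        """Survival probability at time ``t`` (right-continuous step)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _params_of(fit) -> BetaBinomParams:
    return fit.params if isinstance(fit, FitResult) else fit


def assign_nss(
    pn0: pd.DataFrame,
    fits: dict[int, FitResult | BetaBinomParams],
    rates: dict[int, float],
) -> pd.DataFrame:
    """Score observed pN0 patients: NSS(e_i) with their stratum's rate.

    ``rates`` maps t_stage to the adjusted LNM rate used as the Bayes prior.
    Rejects any node-positive row — the score is only defined for pN0 calls.
    Returns the input frame with an ``nss`` column appended.
    """
    if (pn0["nodes_positive"] >= 1).any():
        raise ValueError("assign_nss expects pN0 patients only")
    missing = [t for t in pn0["t_stage"].unique() if t not in fits or t not in rates]
    if missing:
        raise ConfigurationError(f"no fit/rate for strata {sorted(missing)}")
    out = pn0.copy()
    scores = np.empty(len(out))
    for t, sub in out.groupby("t_stage"):
        s = nodal_staging_score(
            sub["nodes_examined"].to_numpy(), rates[t], _params_of(fits[t])
        )
        scores[out["t_stage"].to_numpy() == t] = s
    out["nss"] = scores
    return out


def quartile_groups(scores) -> np.ndarray:
    """Assign 1..4 by sample quartile, ties going to the lower group.

    The score takes one value per examined-node count within a stratum, so
    ties are common; values exactly at a quartile cut are placed in the
    lower group deterministically.  With fewer than four distinct values,
    fewer groups result (warned).
    """
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(scores)) < 4:
        warnings.warn(
            "fewer than 4 distinct scores; quartile grouping collapses",
            stacklevel=2,
        )
    cuts = np.quantile(scores, [0.25, 0.5, 0.75])
    return np.searchsorted(cuts, scores, side="left") + 1


def km_estimate(times, events, label: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label or None)
    tl = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    at_risk = kmf.event_table["at_risk"].reindex(tl).to_numpy(dtype=float)
    return KMCurve(times=tl, survival=surv, at_risk=at_risk, label=label)


def log_rank(times, events, groups) -> tuple[float, float]:
    """Multi-group log-rank test; returns (chi-square statistic, p-value)."""
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("log-rank is undefined with no events in any group")
    res = multivariate_logrank_test(
        np.asarray(times, dtype=float), np.asarray(groups), events
    )
    return float(res.test_statistic), float(res.p_value)


def survival_by_nss_quartile(
    pn0_scored: pd.DataFrame,
    horizon_months: float = 60.0,
) -> dict:
    """Quartile-group KM curves, horizon survival, and the log-rank test.

    Expects the output of :func:`assign_nss` (needs columns nss,
    survival_months, event).  Returns a dict with per-group curves,
    survival at ``horizon_months`` (5 years by default), group sizes, and
    the log-rank statistic and p-value.
    """
    groups = quartile_groups(pn0_scored["nss"].to_numpy())
    times = pn0_scored["survival_months"].to_numpy(dtype=float)
    events = pn0_scored["event"].to_numpy(dtype=int)
    curves, horizon, sizes = {}, {}, {}
    for g in np.unique(groups):
        mask = groups == g
        curve = km_estimate(times[mask], events[mask], label=f"Q{g}")
        curves[int(g)] = curve
        horizon[int(g)] = curve.at(horizon_months)
        sizes[int(g)] = int(mask.sum())
    stat, p = log_rank(times, events, groups)
    return {
        "curves": curves,
        "survival_at_horizon": horizon,
        "group_sizes": sizes,
        "logrank_statistic": stat,
        "logrank_p": p,
        "horizon_months": horizon_months,
    }
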