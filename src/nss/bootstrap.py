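"""Bootstrap confidence intervals for shapes and LNM rates.

Patients are resampled with replacement within each T stratum — pN0 and pN+
jointly, preserving the stratum size — and the whole estimation chain
(shape fit, false-negative estimates, adjusted rate) is rerun on every
replicate.  Intervals are percentile bounds, so they are auditable from the
replicate draws alone.  A master seed spawns one independent substream per
replicate, making results reproducible and independent of evaluation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .betabinom import fit_mle
from .cohort import StratifiedCohort
from .errors import FitError, NSSError
from .score import (
    estimate_false_negatives,
    prob_false_negative,
    stratum_adjusted_rate,
)

__all__ = ["BootstrapResult", "bootstrap_statistics"]

_STATS = ("alpha", "beta", "raw_rate", "adjusted_rate", "increase")


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile interval for one statistic in one stratum."""

    statistic: str
    t_stage: int
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    n_failed: int


def _replicate_stats(m: np.ndarray, e: np.ndarray, t: int) -> dict[str, float]:
    """All tracked statistics from one stratum's (m, e) arrays."""
    pos = m >= 1
    pairs = np.column_stack([m[pos], e[pos]])
    fit = fit_mle(pairs, t_stage=t)
    params = fit.params
    # tallies by examined-node count
    raw = float(pos.mean())
    es, idx = np.unique(e, return_inverse=True)
    tp = np.bincount(idx[pos], minlength=len(es))
    n0 = np.bincount(idx[~pos], minlength=len(es))
    p_fn = prob_false_negative(es, params)
    fn = sum(
        estimate_false_negatives(float(p), int(tp_i), int(n_i))
        for p, tp_i, n_i in zip(p_fn, tp, n0)
    )
    adj = (fn + tp.sum()) / len(m)
    return {
        "alpha": params.alpha,
        "beta": params.beta,
        "raw_rate": raw,
        "adjusted_rate": float(adj),
        "increase": float(adj) - raw,
    }


def bootstrap_statistics(
    cohort: StratifiedCohort,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    max_failed_fraction: float = 0.10,
) -> list[BootstrapResult]:
    """Percentile bootstrap for alpha, beta, raw/adjusted rate and increase.

    Replicates whose shape fit cannot run or does not converge are dropped
    and counted; more than ``max_failed_fraction`` failures aborts, since
    the surviving intervals would be selection-biased.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    lo_q = 100 * (1 - level) / 2
    hi_q = 100 - lo_q
    streams = np.random.SeedSequence(seed).spawn(n_boot)
    results: list[BootstrapResult] = []
    for t in cohort.t_stages:
        sub = cohort.stratum(t)
        m_all = sub["nodes_positive"].to_numpy()
        e_all = sub["nodes_examined"].to_numpy()
        n = len(sub)

        fit = fit_mle(
            np.column_stack([m_all[m_all >= 1], e_all[m_all >= 1]]), t_stage=t
        )
        adj = stratum_adjusted_rate(cohort, t, fit.params)
        point = {
            "alpha": fit.params.alpha,
            "beta": fit.params.beta,
            "raw_rate": adj.raw_rate,
            "adjusted_rate": adj.adjusted_rate,
            "increase": adj.increase,
        }

        draws: dict[str, list[float]] = {s: [] for s in _STATS}
        n_failed = 0
        for ss in streams:
            rng = np.random.default_rng(ss)
            idx = rng.integers(0, n, size=n)
            try:
                rep = _replicate_stats(m_all[idx], e_all[idx], t)
            except (FitError, NSSError, ValueError):
                n_failed += 1
                continue
            for s in _STATS:
                draws[s].append(rep[s])
        if n_failed > max_failed_fraction * n_boot:
            raise FitError(
                f"stratum T{t}: {n_failed}/{n_boot} bootstrap replicates failed"
            )
        for s in _STATS:
            arr = np.asarray(draws[s])
            lo, hi = np.percentile(arr, [lo_q, hi_q])
            if not (lo <= point[s] <= hi):
                warnings.warn(
                    f"T{t} {s}: point estimate {point[s]:.4g} outside the "
                    f"percentile interval [{lo:.4g}, {hi:.4g}] — expected "
                    "occasionally for skewed statistics",
                    stacklevel=2,
                )
            results.append(
                BootstrapResult(
                    statistic=s,
                    t_stage=t,
                    point=float(point[s]),
                    ci_low=float(lo),
                    ci_high=float(hi),
                    n_boot=n_boot,
                    seed=seed,
                    n_failed=n_failed,
                )
            )
    return results
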