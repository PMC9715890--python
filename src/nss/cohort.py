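"""Reading, validating and stratifying patient-level cohort tables.

A cohort is a patient-per-row table with the six core columns below plus any
pass-through annotation columns (sex, grade, site, ...).  Records are
stratified by primary-tumor depth (T stage 1-4) and partitioned within each
stratum into pN0 (no positive node among those examined) and pN+ (at least
one positive node).

Core columns
------------
patient_id        opaque identifier
t_stage           integer 1..4
nodes_examined    lymph nodes harvested and assessed (>= 1)
nodes_positive    positive nodes found (0 <= positive <= examined)
survival_months   follow-up time, non-negative
event             1 = death from disease, 0 = censored
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortValidationError, ConfigurationError, UndefinedRateError

__all__ = [
    "CORE_COLUMNS",
    "PatientRecord",
    "StratifiedCohort",
    "read_cohort",
    "write_cohort",
    "cohort_from_frame",
    "apply_exclusions",
    "raw_lnm_rate",
]

logger = logging.getLogger(__name__)

CORE_COLUMNS = [
    "patient_id",
    "t_stage",
    "nodes_examined",
    "nodes_positive",
    "survival_months",
    "event",
]

T_STAGES = (1, 2, 3, 4)


@dataclass(frozen=True)
class PatientRecord:
    """One resected, pathologically staged patient."""

    patient_id: str
    t_stage: int
    nodes_examined: int
    nodes_positive: int
    survival_months: float
    event: int
    annotations: dict = field(default_factory=dict)

    @property
    def is_node_positive(self) -> bool:
        return self.nodes_positive >= 1


def _row_diagnostics(df: pd.DataFrame) -> list[tuple[int, str]]:
    bad = []
    for idx, row in df.iterrows():
        if row["t_stage"] not in T_STAGES:
            bad.append((idx, f"t_stage {row['t_stage']} not in 1..4"))
        if row["nodes_examined"] < 1:
            bad.append((idx, "nodes_examined must be >= 1 (unstaged patient)"))
        if not (0 <= row["nodes_positive"] <= row["nodes_examined"]):
            bad.append(
                (
                    idx,
                    f"nodes_positive={row['nodes_positive']} outside "
                    f"[0, nodes_examined={row['nodes_examined']}]",
                )
            )
        if row["survival_months"] < 0:
            bad.append((idx, "survival_months must be non-negative"))
        if row["event"] not in (0, 1):
            bad.append((idx, f"event {row['event']} not binary"))
    return bad


class StratifiedCohort:
    """Validated cohort stratified by T stage with pN0 / pN+ partitions.

    Thin wrapper around a :class:`pandas.DataFrame`; all columns beyond the
    core six are carried through untouched.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing required columns: {missing}")
        df = df.copy().reset_index(drop=True)
        for col in ("t_stage", "nodes_examined", "nodes_positive", "event"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
        df["survival_months"] = pd.to_numeric(df["survival_months"], errors="raise")
        bad = _row_diagnostics(df)
        if bad:
            detail = "; ".join(f"row {i}: {msg}" for i, msg in bad[:10])
            raise CohortValidationError(
                f"{len(bad)} invalid rows (first shown): {detail}", rows=bad
            )
        self._df = df

    # -- basic access -----------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df.copy()

    def __len__(self) -> int:
        return len(self._df)

    @property
    def t_stages(self) -> list[int]:
        """T stages present, ascending."""
        return sorted(self._df["t_stage"].unique().tolist())

    def stratum(self, t_stage: int) -> pd.DataFrame:
        return self._df[self._df["t_stage"] == t_stage].copy()

    def pn0(self, t_stage: int | None = None) -> pd.DataFrame:
        """Patients with no positive node found (observed pN0)."""
        df = self._df if t_stage is None else self.stratum(t_stage)
        return df[df["nodes_positive"] == 0].copy()

    def pn_plus(self, t_stage: int | None = None) -> pd.DataFrame:
        """Patients with at least one positive node (pN+)."""
        df = self._df if t_stage is None else self.stratum(t_stage)
        return df[df["nodes_positive"] >= 1].copy()

    # -- derived tallies ---------------------------------------------------
    def positive_pairs(self, t_stage: int) -> list[tuple[int, int]]:
        """(m, e) pairs of pN+ patients in a stratum — the fitting set."""
        sub = self.pn_plus(t_stage)
        return list(zip(sub["nodes_positive"].tolist(), sub["nodes_examined"].tolist()))

    def tallies(self, t_stage: int) -> tuple[dict[int, int], dict[int, int]]:
        """Per examined-node count ``e``: (TP_e, N_e).

        TP_e counts pN+ patients with e nodes examined (including those with
        every examined node positive); N_e counts pN0 patients at e.
        """
        sub = self.stratum(t_stage)
        pos = sub["nodes_positive"] >= 1
        tp = sub.loc[pos, "nodes_examined"].value_counts().to_dict()
        n = sub.loc[~pos, "nodes_examined"].value_counts().to_dict()
        return ({int(k): int(v) for k, v in tp.items()},
                {int(k): int(v) for k, v in n.items()})

    def records(self):
        """Iterate rows as :class:`PatientRecord` objects."""
        extra = [c for c in self._df.columns if c not in CORE_COLUMNS]
        for _, row in self._df.iterrows():
            yield PatientRecord(
                patient_id=str(row["patient_id"]),
                t_stage=int(row["t_stage"]),
                nodes_examined=int(row["nodes_examined"]),
                nodes_positive=int(row["nodes_positive"]),
                survival_months=float(row["survival_months"]),
                event=int(row["event"]),
                annotations={c: row[c] for c in extra},
            )

    def summary(self) -> dict:
        """Strata sizes and pN0/pN+ splits, JSON-friendly."""
        out = {}
        for t in self.t_stages:
            out[f"T{t}"] = {
                "n": int(len(self.stratum(t))),
                "pn0": int(len(self.pn0(t))),
                "pn_plus": int(len(self.pn_plus(t))),
            }
        out["total"] = int(len(self))
        return out


def read_cohort(path, column_map: dict[str, str] | None = None) -> StratifiedCohort:
    """Read a patient CSV, rename columns via ``column_map``, validate.

    ``column_map`` maps required names to the file's actual header names,
    e.g. ``{"nodes_examined": "Regional nodes examined"}`` for registry-style
    exports.  Unmapped extra columns pass through as annotations.
    """
    df = pd.read_csv(path)
    if column_map:
        rename = {src: dst for dst, src in column_map.items()}
        missing = [src for src in rename if src not in df.columns]
        if missing:
            raise ConfigurationError(
                f"column_map refers to columns absent from {path}: {missing}"
            )
        df = df.rename(columns=rename)
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path} lacks required columns {missing}")
    return StratifiedCohort(df)


def write_cohort(cohort: StratifiedCohort, path) -> None:
    """Write the cohort back to CSV (round-trips exactly through read)."""
    cohort.df.to_csv(path, index=False)


def cohort_from_frame(df: pd.DataFrame) -> StratifiedCohort:
    """Validate an in-memory table (e.g. a simulated cohort)."""
    return StratifiedCohort(df)


def apply_exclusions(
    cohort: StratifiedCohort, min_followup_months: float = 1.0
) -> StratifiedCohort:
    """Drop patients with follow-up shorter than ``min_followup_months``.

    Very short follow-up carries no survival information and typically
    reflects perioperative death or registry artefacts.
    """
    if min_followup_months < 0:
        raise ValueError("min_followup_months must be >= 0")
    df = cohort.df
    keep = df["survival_months"] >= min_followup_months
    n_removed = int((~keep).sum())
    logger.info(
        "follow-up exclusion (< %s months): removed %d of %d records",
        min_followup_months, n_removed, len(df),
    )
    if keep.sum() == 0:
        logger.warning("all records excluded by follow-up filter")
    return StratifiedCohort(df[keep])


def raw_lnm_rate(cohort: StratifiedCohort, t_stage: int | str = "all") -> float:
    """Observed lymph-node-metastasis rate: #pN+ / #patients.

    ``t_stage="all"`` pools every stratum.  This is the uncorrected rate;
    false-negative pN0 patients deflate it (see :mod:`nss.score`).
    """
    df = cohort.df if t_stage == "all" else cohort.stratum(int(t_stage))
    if len(df) == 0:
        raise UndefinedRateError(f"no patients in stratum {t_stage!r}")
    return float(np.mean(df["nodes_positive"] >= 1))
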