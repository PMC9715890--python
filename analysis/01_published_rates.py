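#!/usr/bin/env python
"""Raw lymph-node-metastasis rates from published stratum counts.

The raw LNM rate per T stage depends only on the per-stage pN0/pN+ counts,
which are public.  This script encodes those counts for the two source
populations (a registry extract and an institutional series of resected
esophageal squamous cell carcinoma), validates them through the cohort
layer, and tabulates the rates.
"""

from pathlib import Path

import pandas as pd

from nss import cohort_from_stage_counts, raw_lnm_rate

SEER_COUNTS = {1: (171, 39), 2: (169, 69), 3: (340, 211), 4: (125, 146)}
INSTITUTION_COUNTS = {1: (116, 34), 2: (171, 117), 3: (260, 255), 4: (196, 255)}

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for label, counts in (("seer", SEER_COUNTS), ("institution", INSTITUTION_COUNTS)):
        cohort = cohort_from_stage_counts(counts)
        for t in (1, 2, 3, 4):
            rows.append(
                {
                    "database": label,
                    "t_stage": t,
                    "n": len(cohort.stratum(t)),
                    "n_pn_plus": len(cohort.pn_plus(t)),
                    "raw_lnm_rate": round(raw_lnm_rate(cohort, t), 3),
                }
            )
        rows.append(
            {
                "database": label,
                "t_stage": "all",
                "n": len(cohort),
                "n_pn_plus": len(cohort.pn_plus()),
                "raw_lnm_rate": round(raw_lnm_rate(cohort, "all"), 3),
            }
        )
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "raw_lnm_rates.csv", index=False)
    print(table.to_string(index=False))
    print(
        "\nRates rise monotonically with T stage in both populations; the "
        "institutional series shows higher rates at every stage, consistent "
        "with its more extensive nodal harvests detecting more disease."
    )


if __name__ == "__main__":
    main()
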