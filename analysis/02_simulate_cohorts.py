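#!/usr/bin/env python
"""Generate the two synthetic study cohorts used by the downstream steps.

Each preset reproduces its source population's stratum sizes, examined-node
distribution and observed LNM rates, with known latent truth (which patients
actually harbor nodal disease) so that every later estimate can be checked
against the generative parameters.
"""

from pathlib import Path

from nss import make_fixture_tables, read_cohort, raw_lnm_rate

OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"
SEED = 20240917


def main() -> None:
    for preset in ("seer-like", "institution-like"):
        paths = make_fixture_tables(preset, OUT, seed=SEED)
        cohort = read_cohort(paths["cohort"])
        sizes = {t: len(cohort.stratum(t)) for t in cohort.t_stages}
        print(f"{preset}: n={len(cohort)} strata={sizes}")
        print(
            "  observed LNM rates:",
            {t: round(raw_lnm_rate(cohort, t), 3) for t in cohort.t_stages},
        )
        print(f"  wrote {paths['cohort'].name}, {paths['truth'].name}")


if __name__ == "__main__":
    main()
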