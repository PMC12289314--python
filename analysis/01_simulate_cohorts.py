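#!/usr/bin/env python
"""Simulate two desk-scale synthetic EHR sites.

Site 1 mirrors the KUMC cohort's outcome prevalences (AKI 11.90%, 1-year
mortality 12.62%) and site 2 the MCW cohort's (9.30% / 15.51%), each with
mixed medication / procedure / lab features, sub-1% sparse columns, lab
missingness straddling 30%, and injected outliers. Feature and sample
counts are reduced from the full cohorts (579/654 features, 13,752/9,568
patients) to a size every later stage can rerun in minutes.

Writes the cohorts under scratch/cohorts/ (regenerable from the recorded
specs) and a summary table to results/cohort_summary.csv.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from patsim.cohort import KUMC_STATS, MCW_STATS, CohortSpec, cohort_summary, generate_cohort  # noqa: E402
from patsim.config import derive_seed  # noqa: E402

SEED = 2026

SITES = {
    "site1_kumc_like": dict(
        n_patients=1600, n_medications=60, n_procedures=60, n_labs=12,
        prevalence_aki=KUMC_STATS["aki"] / KUMC_STATS["n"],
        prevalence_mortality=KUMC_STATS["mortality"] / KUMC_STATS["n"]),
    "site2_mcw_like": dict(
        n_patients=1200, n_medications=66, n_procedures=62, n_labs=12,
        prevalence_aki=MCW_STATS["aki"] / MCW_STATS["n"],
        prevalence_mortality=MCW_STATS["mortality"] / MCW_STATS["n"]),
}


def main() -> None:
    rows = []
    for site, kw in SITES.items():
        spec = CohortSpec(seed=derive_seed(SEED, site), **kw)
        table = generate_cohort(spec)
        table.write(ROOT / "scratch" / "cohorts" / site)
        s = cohort_summary(table)
        rows.append({"site": site,
                     **{k: v for k, v in s.items()
                        if not k.startswith("column_")}})
        print(f"{site}: n={s['n']}, m={s['n_features']} "
              f"({s['n_medications']}/{s['n_procedures']}/{s['n_labs']} "
              f"meds/procs/labs), AKI {s['aki_rate_pct']}%, "
              f"mortality {s['mortality_rate_pct']}%")

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "cohort_summary.csv", index=False)
    print(f"\nwrote {out / 'cohort_summary.csv'}; cohorts under scratch/cohorts/")


if __name__ == "__main__":
    main()
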