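#!/usr/bin/env python
"""Relative solvent accessibility of cysteine sites, by oxidation state.

Computes Shrake-Rupley relative SASA (probe 1.4 A, 960 points/atom) over the
exposure cohort, in which reduced sites were generated buried and oxidized
sites exposed, and summarizes the distributions per state.
"""

from pathlib import Path

import pandas as pd

from oxcys.accessibility import summarize_by_state
from oxcys.survey import run_survey, sasa_by_state

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "scratch" / "cohort_exposure"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    result = run_survey(COHORT, COHORT / "manifest.tsv")
    records = sasa_by_state(result)

    per_site = pd.DataFrame([{
        "site_id": r.site_id, "state": r.state,
        "absolute_sasa": round(r.absolute_sasa, 2),
        "reference_sasa": round(r.reference_sasa, 2),
        "relative_sasa": round(min(max(r.relative_sasa, 0.0), 1.0), 4),
    } for r in records])
    per_site.to_csv(RESULTS / "sasa_per_site.tsv", sep="\t", index=False)

    summary = summarize_by_state(records)
    keep = ["state", "n", "mean", "median", "q25", "q75"]
    summary[keep].round(4).to_csv(RESULTS / "sasa_by_state.tsv", sep="\t",
                                  index=False)
    print(summary[keep].round(3).to_string(index=False))
    print(f"wrote {RESULTS / 'sasa_by_state.tsv'}")


if __name__ == "__main__":
    main()
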