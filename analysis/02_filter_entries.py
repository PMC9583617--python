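#!/usr/bin/env python
"""Apply the survey quality filters (resolution < 2.5 A, R-free < 0.30).

Demonstrates the strict-inequality behaviour on a boundary set and filters
the enrichment-cohort manifest produced by 01_simulate_cohorts.py.
"""

from pathlib import Path

import pandas as pd

from oxcys.dataset import EntryMeta, filter_entries, query_entries

ROOT = Path(__file__).resolve().parents[1]
MANIFEST = ROOT / "scratch" / "cohort_enrichment" / "manifest.tsv"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    boundary = [
        EntryMeta("AT_BOTH_CUTS", resolution=2.49, r_free=0.29),
        EntryMeta("RES_AT_CUT", resolution=2.50, r_free=0.29),
        EntryMeta("RFREE_ABOVE", resolution=2.49, r_free=0.31),
        EntryMeta("NO_RFREE", resolution=1.80, r_free=None),
    ]
    kept, report = filter_entries(boundary)
    print(f"boundary set: kept {[e.entry_id for e in kept]}")
    print(report.to_string(index=False))

    entries = query_entries(("CYS", "CSO", "CSD", "OCS"), manifest=MANIFEST)
    cohort_kept, cohort_report = filter_entries(entries)
    print(f"cohort: {len(cohort_kept)} of {len(entries)} entries pass the filters")

    out = RESULTS / "filter_report.tsv"
    pd.concat([report, cohort_report]).to_csv(out, sep="\t", index=False)
    kept_out = RESULTS / "entries_kept.tsv"
    pd.DataFrame({
        "entry_id": [e.entry_id for e in cohort_kept],
        "resolution": [e.resolution for e in cohort_kept],
        "r_free": [e.r_free for e in cohort_kept],
    }).to_csv(kept_out, sep="\t", index=False)
    print(f"wrote {out} and {kept_out}")


if __name__ == "__main__":
    main()
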