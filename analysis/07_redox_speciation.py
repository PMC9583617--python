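#!/usr/bin/env python
"""Redox and protonation speciation curves for thiol couples.

Tabulates the Nernst oxidized fraction across ambient potentials for the
glutathione (-240 mV), ERp57 (-167 mV) and thioredoxin (-270 mV) couples,
and the Henderson-Hasselbalch titration of the cysteine thiol (pKa 8.5) and
a mid-range sulfenic acid (pKa 6.5).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from oxcys.redox import (
    E0_ERP57,
    E0_GLUTATHIONE,
    E0_THIOREDOXIN,
    RedoxCouple,
    Titratable,
    decade_millivolts,
    deprotonated_fraction,
    nernst_ratio,
)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

COUPLES = {
    "glutathione": E0_GLUTATHIONE,
    "ERp57_C57-C60": E0_ERP57,
    "thioredoxin_C32-C35": E0_THIOREDOXIN,
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    potentials = np.arange(-400.0, -99.0, 10.0)
    rows = []
    for name, e0 in COUPLES.items():
        couple = RedoxCouple(e0, n_electrons=2)
        for e in potentials:
            ratio = nernst_ratio(couple, e)
            rows.append({
                "couple": name, "E0_mv": e0, "potential_mv": e,
                "fraction_oxidized": ratio / (1 + ratio),
            })
    redox_table = pd.DataFrame(rows)
    redox_table.to_csv(RESULTS / "redox_speciation.tsv", sep="\t", index=False,
                       float_format="%.6g")

    phs = np.arange(4.0, 12.01, 0.25)
    rows = []
    for name, pka in (("cysteine_thiol", 8.5), ("sulfenic_acid", 6.5)):
        t = Titratable(pka)
        for ph in phs:
            rows.append({"group": name, "pka": pka, "ph": ph,
                         "deprotonated_fraction": deprotonated_fraction(t, ph)})
    hh_table = pd.DataFrame(rows)
    hh_table.to_csv(RESULTS / "titration.tsv", sep="\t", index=False,
                    float_format="%.6g")

    print(f"one ratio decade per {decade_millivolts(1):.2f} mV "
          "(n=1, 298.15 K)")
    for name, e0 in COUPLES.items():
        couple = RedoxCouple(e0, n_electrons=2)
        ratio = nernst_ratio(couple, -300.0)
        print(f"  {name}: at -300 mV, fraction oxidized = "
              f"{ratio / (1 + ratio):.4g}")
    print(f"wrote {RESULTS / 'redox_speciation.tsv'} and "
          f"{RESULTS / 'titration.tsv'}")


if __name__ == "__main__":
    main()
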