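# oxcys — a structural survey of cysteine oxidation states

Cysteine thiols are progressively oxidized to sulfenic (`CSO`, –SOH),
sulfinic (`CSD`, –SO₂H) and sulfonic (`OCS`, –SO₃H) acids, chemically minor
modifications with outsized biophysical consequences. `oxcys` is a pipeline
for surveying these states in crystal structures: it reads PDB/mmCIF files,
builds the first biological assembly from the deposited BIOMT operators,
classifies every cysteine-family residue by oxidation state (excluding
disulfide-bonded CYX), and then characterizes each site by

* **microenvironment** — all residues with a heavy atom within 3.6 Å of the
  sulfur (SG), pooled per state into normalized neighbor-category
  frequencies and compared against background amino-acid abundance;
* **hydrogen bonding** — heavy-atom donor/acceptor classification of side
  chain and backbone partners of SG and of the sulfur-bonded oxygens;
* **solvent accessibility** — Shrake–Rupley relative SASA (probe 1.4 Å,
  960 points/atom), normalized by the isolated residue so 0 = buried,
  1 = fully exposed;
* **the Thr/Arg/Gly sulfonate motif** — a hydrogen-bond network in which all
  three sulfonate oxygens accept a bond, with Thr OG1, Arg NE/NH1/NH2 or a
  Gly backbone amide among the donors;
* **annotation overlap** — mapping of entries to protein accessions,
  subcellular-location keyword tallies, and exact set overlap against
  proteomics accession lists;
* **redox speciation** — the Nernst ratio `[ox]/[red] = exp(nF(E′−E₀)/RT)`
  and its protonation analogue, the Henderson–Hasselbalch fraction
  `1/(1+10^(pKa−pH))`, with literature constants (glutathione −240 mV;
  cysteine pKa ≈ 8.5).

A synthetic-structure generator (`oxcys.synthetic`) builds single-site
fixtures with neighbor atoms at controlled distances, burial shells, BIOMT
multimers, disulfide pairs, and whole cohorts with programmed neighbor
enrichment, so every stage is testable offline against known ground truth.

## Worked example

Generate a cohort in which a histidine contact is placed around oxidized
sites three times more often than around reduced ones, then recover that
enrichment from the structures alone:

```python
from oxcys.synthetic import CohortSpec, make_cohort
from oxcys.survey import run_survey

spec = CohortSpec(
    n_sites={"CYS": 200, "CSO": 200, "CSD": 200, "OCS": 200},
    enrichment={("CSO", "HIS"): 0.6, ("CSD", "HIS"): 0.6,
                ("OCS", "HIS"): 0.6, ("CYS", "HIS"): 0.2},
    random_seed=7,
)
out = make_cohort(spec, "scratch/cohort")
result = run_survey("scratch/cohort", out["manifest"])
for state in ("CSO", "CSD", "OCS"):
    ratio = (result.profiles[state].frequencies["HIS"]
             / result.profiles["CYS"].frequencies["HIS"])
    print(state, round(ratio, 2))
```

prints

```
CSO 3.37
CSD 3.42
OCS 3.55
```

i.e. the measured His frequency around each oxidized state is ~3× its
frequency around reduced cysteines, recovering the programmed enrichment
(the exact values carry binomial sampling noise from the 200-site draws).

The numbered drivers under `analysis/` run the full survey narrative on
synthetic cohorts — generation, quality filtering (resolution < 2.5 Å,
R-free < 0.30, strict), environment profiles, SASA by state, the motif
scan, annotation overlap (173 of 349 → 49.5%) and redox speciation — and
write their tables under `results/`. Run them in order:

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_filter_entries.py
# ... through 07_redox_speciation.py
```

A thin CLI mirrors the library (`oxcys filter`, `oxcys env`, `oxcys sasa`,
`oxcys motif`, `oxcys overlap`, `oxcys redox`, `oxcys simulate`); run
`oxcys --help` for usage.

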