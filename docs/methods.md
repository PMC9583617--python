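# Methods

## Scope and model of the data

`oxcys` analyzes cysteine-family residues — CYS (thiol/thiolate), CSO
(sulfenic acid, one sulfur-bonded oxygen), CSD (sulfinic, two), OCS
(sulfonic, three) — in X-ray crystal structures. The unit of analysis is the
**first biological assembly**: the asymmetric unit's chains transformed by
the first-listed set of deposited rotation/translation operators (REMARK 350
BIOMT in PDB files, `_pdbx_struct_assembly_gen`/`_pdbx_struct_oper_list` in
mmCIF). "First" means the lowest assembly identifier in file order; when a
file carries no operators the asymmetric unit is used and a warning logged.
Sites are identified **per assembly copy** — a homodimer contributes each
cysteine twice — because the two copies can have different environments at
an interface. Hydrogens are ignored throughout (rarely present in X-ray
data); when an atom has alternate locations, the highest-occupancy conformer
is kept, ties broken alphabetically, so downstream geometry always sees a
single conformer.

Disulfides are the union of deposited SSBOND/`_struct_conn` records and
geometric SG–SG pairs at ≤ 2.3 Å (covalent S–S ≈ 2.05 Å, with margin for
coordinate error). Cysteines in a disulfide are relabeled CYX and excluded
from all environment statistics.

Sulfur-bonded oxygens are attached by naming convention (CSO → OD; CSD →
OD1/OD2; OCS → OD1/OD2/OD3) with a fallback that accepts any side-chain
oxygen within 1.8 Å of SG, because component dictionaries varied across
deposition eras. A site whose resolved oxygen count still disagrees with its
state is flagged malformed, reported, and excluded from profiles and motif
counts rather than silently dropped.

## Entry selection

Entries are selected from a TSV manifest (entry id, resolution, R-free,
method, release date, components, accessions); a remote search service would
populate the same schema, and keeping the interface file-based makes every
stage runnable offline and deterministic. Quality filters are **strict**
inequalities: resolution < 2.5 Å and R-free < 0.30. Entries missing either
value (e.g. non-crystallographic methods without R-free) are excluded and
tallied in a rejection report; the filters presume crystallographic
metadata, and exempting such entries would mix incomparable data.

## Microenvironment profiles

For each site, the neighborhood is every residue with a heavy atom within
**3.6 Å of SG** (k-d tree search; an exhaustive all-pairs scan serves as the
test oracle). One record per neighboring residue keeps the nearest atom and
its distance; the site's own residue is excluded; waters are category HOH;
ligands and unknown residues are "other"; oxidized cysteines encountered as
neighbors fold into the Cys category.

Per-state frequencies are **pooled fractions**: neighbors of category c
divided by all neighbor residues of that state. Pooling weights sites by
their neighbor counts; the mean neighbor count per site is reported
alongside so a per-site average can be reconstructed. Enrichment divides a
frequency by the background abundance of that amino acid. The shipped
default background is uniform (0.05 per amino acid), a deliberately neutral
testing default — real analyses should supply measured PDB abundances as a
20-row TSV; enrichment *ratios between states* are independent of the shared
background, which is why the cohort tests are phrased as ratios.

Hydrogen bonds use a heavy-atom distance criterion only — donor/acceptor
capability from a fixed per-residue atom table (His counted as both), within
3.6 Å of SG or, for oxidized states, of any sulfur-bonded oxygen. No angle
term is applied since donors' hydrogens are not observed; 3.6 Å matches the
neighborhood radius and is configurable. Partners of an outer sulfonate
oxygen can lie beyond the SG ball, so the hydrogen-bond scan covers the
whole assembly, not just the SG neighborhood. Proline backbone N is never a
donor; waters are skipped (no directionality information).

Side-chain conformation: chi1 = dihedral(N, CA, CB, SG), binned m = [−120,
0), p = [0, 120), t = the rest — the standard gauche−/gauche+/trans
partition. Sites missing any of the four atoms yield flagged records that
summaries exclude.

## Relative solvent accessibility

SASA uses Shrake–Rupley sphere-point sampling: each atom carries a
deterministic golden-spiral point set on its probe-expanded sphere (probe
1.4 Å; radii C 1.70, N 1.55, O 1.52, S 1.80 Å; 960 points/atom by default);
a point is accessible when outside every other expanded sphere. A lone atom
therefore scores exactly 4π(r+p)², and doubling the point count changes
results by well under 1% on test fixtures. The implementation is vectorized
numpy with k-d tree occluder pruning; an independent implementation
(biotite's) is used as a cross-check in the test suite, never as the
computation.

Relative SASA divides the residue's in-assembly area by the area of the
same residue **computed in isolation with its own coordinates**. This makes
a free-standing residue score exactly 1.0 by construction and sidesteps the
choice of a reference conformer; values slightly above 1 can occur for
unusually extended conformations and are clipped to [0, 1] on export (the
clip is logged). Waters and non-cysteine hetero ligands are excluded from
the occluding set by default — crystallographic waters would artifactually
bury sites — and this is configurable and logged. Distributions are
summarized per state with mean, median, quartiles and fixed 0.05-wide
histogram bins on [0, 1].

## The Thr/Arg/Gly sulfonate motif

The recurring hydrogen-bond network around sulfonic acids is
operationalized as: **all three sulfonate oxygens accept at least one
hydrogen bond, and at least one donor belongs to {Thr OG1, Arg NE/NH1/NH2,
Gly backbone N}**. The disjunctive class rule ("some combination" rather
than all three types at once) matches the observed family examples;
non-glycine backbone amides count toward oxygen coverage but not toward the
class requirement. Both the cutoff and the class set are parameters, so
sensitivity analyses are one call away. Note that the three oxygens sit
~2.4 Å apart, so a single well-placed donor can legitimately cover two
oxygens; coverage counts distinct oxygens, not distinct donors.

## Annotation overlap

ID mapping and keyword annotation are flat-file tables (two-column TSV;
accession + semicolon-joined keywords), keeping the module fully offline.
Accession version suffixes (".2") are stripped and isoform suffixes ("-2")
collapsed before comparison, since proteomics supplements mix conventions.
Unmapped entries are counted and reported, never silently dropped. Overlap
is exact set intersection; the percentage is taken on the left set and
**truncated** (not rounded) at one decimal, matching how the survey-scale
tables print (173 of 349 = 49.57% prints as 49.5%); an empty left set
reports the percentage as undefined rather than 0.

## Redox and protonation speciation

The Nernst ratio is `[ox]/[red] = exp(nF(E′−E₀)/RT)` with F = 96485.332
C/mol, R = 8.31446 J/(mol·K), T defaulting to 298.15 K, and all potentials
in millivolts (the field's convention). Its inverse is closed-form; the
exponent is capped at ±700 with a warning so extreme potentials saturate
instead of overflowing. At 298.15 K a one-electron couple shifts one decade
per (RT ln10)/F ≈ 59.16 mV. The protonation analogue is the
Henderson–Hasselbalch fraction `1/(1+10^(pKa−pH))`. Shipped named constants
are literature values, not validated measurements: glutathione E₀ ≈ −240
mV, ERp57 Cys57–Cys60 −167 mV, thioredoxin Cys32–Cys35 −270 mV, cysteine
thiol pKa ≈ 8.5, sulfenic acid pKa ≈ 6–7 (sulfinic/sulfonic < 2). Coupled
proton-electron equilibria (disulfide formation releases two protons as
well as two electrons) are deliberately not modeled; the two equations are
treated as independent speciation axes.

## Synthetic fixtures: what they emulate, and what they do not

The generator builds single-site fixtures from idealized internal geometry
(standard bond lengths/angles, sites constructed at a requested chi1;
sulfonate oxygens ~tetrahedral about SG at 1.45 Å). Requested neighbor
distances are met to ±0.01 Å by construction (the only loss is the PDB
format's 3-decimal coordinates); placements below 1.0 Å separation are
refused as unsatisfiable. Neighbor residues are reduced to their contact
atom plus one outward support atom; decoy alanines sit > 10 Å away to keep
files protein-like; burial is a spherical shell of carbons (radius 6 Å, up
to 400 atoms) whose spherical-cap coverage fraction tunes exposure. Cohorts
draw per-site enrichment Bernoulli variables and per-site seeds from one
generator (PCG64), so a fixed seed yields byte-identical directories; a
JSON sidecar per file and a cohort ground-truth table record everything a
test needs to score downstream stages.

These fixtures emulate *contact geometry*, *burial*, *multimerization* and
*cohort-level enrichment statistics*. They do not emulate realistic protein
packing, secondary structure, crystallographic noise, alternate
conformations, or correlated neighbor identities — so passing cohort tests
demonstrates that the measurement machinery recovers programmed signals,
not that real proteins show those signals.

### Study-condition defaults

The enrichment cohort runs 200 sites per state (seed 7) with a His contact
placed at probability 0.6 around oxidized sites and 0.2 around reduced
ones — a 3× placement enrichment mirroring the survey-scale His
observation. Each site also carries a six-residue baseline contact shell
(Ala, Leu, Ser, Thr, Val, Gly), a realistic first-shell residue count at
3.6 Å; with pooled fractions the expected measured frequency ratio is
(0.6/6.6)/(0.2/6.2) ≈ 2.8, inside the ±20% recovery band around 3 that the
cohort test asserts. The exposure cohort (20 sites/state, seed 11) buries
reduced sites under a 90%-coverage shell and leaves oxidized sites largely
exposed, reproducing the qualitative exposure ordering. These sizes keep
the full suite and the acceptance script within a few seconds on one CPU
while leaving binomial sampling error well inside the asserted bands.

## Numerical choices and degenerate inputs

* Rotation operators must be orthonormal (checked to 1e-4; rigid transforms
  preserve intra-copy distances to < 1e-6 Å in tests).
* Missing header metadata stays `None` — never defaulted to 0 — and
  missing-value entries fail the quality filter with a counted reason.
* Zero sites for a state produce an empty profile (no NaNs); an empty OCS
  list produces an empty motif table; an empty left set an undefined
  percentage.
* Neighbor-search results are returned sorted by residue key, and all
  cohort tables are sorted, so identical inputs give identical outputs.
* The profile background must sum to 1 ± 1e-6 over the 20 amino acids;
  profile frequencies sum to 1 ± 1e-9 by construction (asserted over
  randomized cohorts).

## Known limitations

* The hydrogen-bond criterion is distance-only; without hydrogens it cannot
  distinguish donor from acceptor geometry for ambiguous pairs (His is
  simply counted as both).
* The remote PDB query is not bundled; the manifest interface is the
  supported entry point.
* Relative SASA references the isolated residue's own conformation, so
  values are not directly comparable with tools that use a standard
  tripeptide reference, though the [0, 1] interpretation is the same.
* NMR multi-model entries and crystal-symmetry expansion beyond the listed
  assembly operators are out of scope.
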