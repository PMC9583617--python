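"""Synthetic structure fixtures with known ground truth.

Generates small PDB files containing a single cysteine-family site built from
idealized internal geometry (standard bond lengths and angles), with neighbor
atoms placed at controlled distances from the sulfur or from a named
sulfonate oxygen, optional burial shells that control solvent accessibility,
optional BIOMT assembly operators, disulfide partners, and cohorts with a
programmed enrichment of chosen neighbor residue types around oxidized
sites. Every requested inter-atomic distance is met by construction, a JSON
sidecar records the ground truth, and a fixed seed yields byte-identical
output, so every pipeline stage can be scored offline.

These fixtures are deliberately not physically realistic whole proteins:
decoy residues are alanines, neighbor residues are reduced to their contact
atom plus a support atom, and no energy model is applied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import place_atom, sphere_points
from .structure_io import (
    AssemblyOperatorSet,
    AtomRecord,
    StructureModel,
    write_structure,
)

logger = logging.getLogger(__name__)

PLACEMENT_TOL = 0.01  # Å, guaranteed accuracy of requested distances
MIN_SEPARATION = 1.5  # Å, placement clash threshold (error below 1.0 per contract)

#: representative contact atom per residue type, used by cohort enrichment
REPRESENTATIVE_ATOM = {
    "ALA": "CB", "ARG": "NH1", "ASN": "ND2", "ASP": "OD1", "CYS": "SG",
    "GLN": "NE2", "GLU": "OE1", "GLY": "N", "HIS": "ND1", "ILE": "CD1",
    "LEU": "CD1", "LYS": "NZ", "MET": "SD", "PHE": "CZ", "PRO": "CG",
    "SER": "OG", "THR": "OG1", "TRP": "NE1", "TYR": "OH", "VAL": "CG1",
}

_ELEMENT_FROM_NAME = {"N": "N", "O": "O", "S": "S"}

_N_OXYGENS = {"CYS": 0, "CSO": 1, "CSD": 2, "OCS": 3}

#: default first-shell filler around every site: a realistic mixed
#: polar/apolar contact shell of six residues
DEFAULT_BASELINE_NEIGHBORS = (
    ("ALA", "CB"), ("LEU", "CD1"), ("SER", "OG"),
    ("THR", "OG1"), ("VAL", "CG1"), ("GLY", "N"),
)


class GenerationError(ValueError):
    """Raised when a requested placement is geometrically unsatisfiable."""


@dataclass
class NeighborPlacement:
    """One neighbor atom at a controlled distance from an anchor atom."""

    residue_type: str
    atom_name: str
    distance: float
    anchor: str = "SG"  # "SG" or a sulfonate oxygen name (OD/OD1/OD2/OD3)

    def __post_init__(self) -> None:
        if self.distance <= 1.0:
            raise GenerationError(
                f"target distance {self.distance} Å is below the 1.0 Å clash limit"
            )


@dataclass
class SyntheticSpec:
    """Recipe for one single-site fixture."""

    state: str = "CYS"
    neighbors: list[NeighborPlacement] = field(default_factory=list)
    burial: tuple[float, int] | None = None  # (shell radius Å, atom count)
    burial_fraction: float = 1.0  # spherical-cap coverage of the shell, [0,1]
    assembly_operators: list[tuple[np.ndarray, np.ndarray]] | None = None
    disulfide_partner: bool = False
    chi1: float = -65.0  # degrees; the common gauche-minus conformer
    random_seed: int = 0
    entry_id: str = "SYN1"
    resolution: float = 1.80
    r_free: float = 0.22

    def __post_init__(self) -> None:
        if self.state not in _N_OXYGENS:
            raise GenerationError(f"unknown oxidation state {self.state!r}")
        if not (0.0 <= self.burial_fraction <= 1.0):
            raise GenerationError("burial_fraction must lie in [0, 1]")


@dataclass
class CohortSpec:
    """Recipe for a multi-site cohort with programmed neighbor enrichment."""

    n_sites: dict[str, int]
    enrichment: dict[tuple[str, str], float] = field(default_factory=dict)
    exposure: dict[str, float] = field(default_factory=dict)  # state -> burial fraction
    baseline_neighbors: tuple[tuple[str, str], ...] = DEFAULT_BASELINE_NEIGHBORS
    burial_shell: tuple[float, int] = (6.0, 400)
    random_seed: int = 0

    def __post_init__(self) -> None:
        for state, n in self.n_sites.items():
            if state not in _N_OXYGENS:
                raise GenerationError(f"unknown oxidation state {state!r}")
            if n < 0:
                raise GenerationError("site counts must be non-negative")
        for (state, rtype), p in self.enrichment.items():
            if not (0.0 <= p <= 1.0):
                raise GenerationError(
                    f"enrichment probability for ({state}, {rtype}) outside [0, 1]"
                )
            if rtype not in REPRESENTATIVE_ATOM:
                raise GenerationError(f"no representative atom for {rtype!r}")


# ---------------------------------------------------------------------------
# residue construction


def _build_site_residue(state: str, chi1: float) -> dict[str, np.ndarray]:
    """Idealized cysteine-family residue centred on CA at the origin."""
    ca = np.zeros(3)
    n = np.array([1.458, 0.0, 0.0])
    c = 1.525 * np.array([np.cos(np.radians(-111.0)), np.sin(np.radians(-111.0)), 0.0])
    o = place_atom(n, ca, c, 1.231, 120.5, 180.0)
    cb = place_atom(c, n, ca, 1.530, 110.4, -122.6)
    sg = place_atom(n, ca, cb, 1.810, 114.0, chi1)
    atoms = {"N": n, "CA": ca, "C": c, "O": o, "CB": cb, "SG": sg}
    n_ox = _N_OXYGENS[state]
    names = {1: ("OD",), 2: ("OD1", "OD2"), 3: ("OD1", "OD2", "OD3")}.get(n_ox, ())
    for k, name in enumerate(names):
        atoms[name] = place_atom(ca, cb, sg, 1.450, 104.5, 180.0 - 120.0 * k)
    return atoms


def _decoy_alanine(offset: np.ndarray) -> dict[str, np.ndarray]:
    ca = offset
    n = offset + np.array([1.458, 0.0, 0.0])
    c = offset + 1.525 * np.array(
        [np.cos(np.radians(-111.0)), np.sin(np.radians(-111.0)), 0.0])
    o = place_atom(n, ca, c, 1.231, 120.5, 180.0)
    cb = place_atom(c, n, ca, 1.530, 110.4, -122.6)
    return {"N": n, "CA": ca, "C": c, "O": o, "CB": cb}


def _element_of(atom_name: str) -> str:
    return _ELEMENT_FROM_NAME.get(atom_name[0], "C")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _place_neighbor_atom(
    anchor: np.ndarray,
    distance: float,
    existing: list[np.ndarray],
    rng: np.random.Generator,
    away_from: np.ndarray | None = None,
    max_tries: int = 500,
) -> np.ndarray:
    """Place a point at exactly ``distance`` from ``anchor``, clash-free."""
    for _ in range(max_tries):
        direction = _random_unit(rng)
        if away_from is not None and np.dot(direction, away_from) < 0.1:
            continue
        pos = anchor + distance * direction
        if all(np.linalg.norm(pos - q) >= MIN_SEPARATION for q in existing):
            return pos
    raise GenerationError(
        f"could not place an atom {distance:.2f} Å from the anchor without a clash"
    )


# ---------------------------------------------------------------------------
# fixture generation


def build_site_model(spec: SyntheticSpec) -> tuple[StructureModel, dict]:
    """Construct the in-memory model and ground-truth record for one fixture."""
    rng = np.random.default_rng(spec.random_seed)
    atoms: list[AtomRecord] = []
    serial = 0

    def add(name: str, resname: str, resnum: int, xyz: np.ndarray,
            element: str | None = None, hetero: bool = False) -> None:
        nonlocal serial
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, atom_name=name, element=element or _element_of(name),
            residue_name=resname, chain_id="A", residue_number=resnum,
            coordinates=np.round(xyz, 3), occupancy=1.0, b_factor=15.0,
            is_hetero=hetero,
        ))

    # decoy alanines keep the file protein-like, far from the site
    for i in range(3):
        offset = np.array([18.0 + 6.0 * i, 14.0, 9.0])
        for name, xyz in _decoy_alanine(offset).items():
            add(name, "ALA", i + 1, xyz)

    site_atoms = _build_site_residue(spec.state, spec.chi1)
    site_resnum = 10
    # oxidized cysteines are hetero components in deposited structures
    hetero = spec.state != "CYS"
    for name in ("N", "CA", "C", "O", "CB", "SG", "OD", "OD1", "OD2", "OD3"):
        if name in site_atoms:
            add(name, spec.state, site_resnum, site_atoms[name], hetero=hetero)
    sg = site_atoms["SG"]

    occupied = [a.coordinates for a in atoms]
    truth_neighbors = []
    resnum = 20
    for nb in spec.neighbors:
        if nb.anchor not in site_atoms:
            raise GenerationError(
                f"anchor {nb.anchor!r} not present in a {spec.state} residue"
            )
        anchor = site_atoms[nb.anchor]
        away = None
        if nb.anchor != "SG":
            away = (anchor - sg) / np.linalg.norm(anchor - sg)
        pos = _place_neighbor_atom(anchor, nb.distance, occupied, rng, away)
        pos = np.round(pos, 3)
        add(nb.atom_name, nb.residue_type, resnum, pos)
        occupied.append(pos)
        # support atom so the residue has a backbone anchor, placed outward
        outward = (pos - anchor) / np.linalg.norm(pos - anchor)
        support_name = "CA" if nb.atom_name != "CA" else "CB"
        support = np.round(pos + 2.4 * outward, 3)
        add(support_name, nb.residue_type, resnum, support)
        occupied.append(support)
        truth_neighbors.append({
            "residue_type": nb.residue_type,
            "atom_name": nb.atom_name,
            "anchor": nb.anchor,
            "target_distance": nb.distance,
            "realized_distance": float(np.linalg.norm(pos - anchor)),
            "residue_number": resnum,
        })
        resnum += 1

    if spec.disulfide_partner:
        if spec.state != "CYS":
            raise GenerationError("disulfide partners apply to CYS sites only")
        direction = _random_unit(rng)
        sg2 = np.round(sg + 2.05 * direction, 3)
        cb2 = np.round(sg2 + 1.81 * direction, 3)
        ca2 = np.round(cb2 + 1.53 * direction, 3)
        n2 = np.round(ca2 + 1.46 * np.array([0.0, 0.0, 1.0]), 3)
        partner_resnum = 11
        for name, xyz in (("N", n2), ("CA", ca2), ("CB", cb2), ("SG", sg2)):
            add(name, "CYS", partner_resnum, xyz)

    shell_count = 0
    if spec.burial is not None:
        radius, count = spec.burial
        if radius <= 1.0:
            raise GenerationError("burial shell radius must exceed 1 Å")
        center = np.mean([site_atoms[n] for n in site_atoms], axis=0)
        cap_limit = 1.0 - 2.0 * spec.burial_fraction  # keep u_z >= limit
        shell_resnum = 100
        for u in sphere_points(count):
            if u[2] < cap_limit:
                continue
            pos = np.round(center + radius * u, 3)
            if any(np.linalg.norm(pos - q) < 1.2 for q in occupied):
                continue
            add("C1", "UNK", shell_resnum, pos, element="C")
            shell_resnum += 1
            shell_count += 1

    if spec.assembly_operators is not None:
        rots = np.array([r for r, _ in spec.assembly_operators], float)
        trans = np.array([t for _, t in spec.assembly_operators], float)
    else:
        rots = np.eye(3)[None, :, :]
        trans = np.zeros((1, 3))
    assemblies = [AssemblyOperatorSet(assembly_id="1", chains=(),
                                      rotations=rots, translations=trans)]

    ssbonds = []
    if spec.disulfide_partner:
        ssbonds.append((("A", site_resnum, ""), ("A", 11, "")))

    model = StructureModel(
        entry_id=spec.entry_id,
        atoms=atoms,
        resolution=spec.resolution,
        r_free=spec.r_free,
        assemblies=assemblies,
        ssbond_pairs=ssbonds,
    )
    model.validate()

    truth = {
        "entry_id": spec.entry_id,
        "state": spec.state,
        "random_seed": spec.random_seed,
        "rng": "numpy.random.default_rng(PCG64)",
        "site": {"chain": "A", "residue_number": site_resnum},
        "chi1": spec.chi1,
        "neighbors": truth_neighbors,
        "burial": None if spec.burial is None else {
            "radius": spec.burial[0],
            "requested_atoms": spec.burial[1],
            "placed_atoms": shell_count,
            "fraction": spec.burial_fraction,
        },
        "disulfide_partner": spec.disulfide_partner,
        "operator_count": len(rots),
    }
    return model, truth


def make_site_fixture(spec: SyntheticSpec, out: str | Path) -> tuple[Path, Path]:
    """Write one fixture PDB plus its JSON ground-truth sidecar.

    ``out`` may be a directory (files named after the entry id) or a ``.pdb``
    path. Returns (structure path, sidecar path).
    """
    model, truth = build_site_model(spec)
    out = Path(out)
    if out.suffix.lower() == ".pdb":
        pdb_path = out
        out.parent.mkdir(parents=True, exist_ok=True)
    else:
        out.mkdir(parents=True, exist_ok=True)
        pdb_path = out / f"{spec.entry_id}.pdb"
    write_structure(model, pdb_path, dialect="pdb")
    sidecar = pdb_path.with_suffix(".json")
    sidecar.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return pdb_path, sidecar


def make_cohort(spec: CohortSpec, out_dir: str | Path) -> dict:
    """Generate a cohort of single-site fixtures with programmed enrichment.

    Writes one PDB + sidecar per site, a ``manifest.tsv`` consumable by the
    dataset module, and a ``ground_truth.tsv``. Deterministic: a fixed seed
    yields byte-identical output. Returns a summary dict with file paths and
    the realized per-state enriched-neighbor frequencies.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.random_seed)

    manifest_rows = ["entry_id\tresolution\tr_free\tmethod\trelease_date\tcomponents\tuniprot"]
    truth_rows = ["entry_id\tstate\tenriched_types\tburial_fraction"]
    realized: dict[tuple[str, str], list[int]] = {}
    paths: list[Path] = []

    for state in sorted(spec.n_sites):
        for i in range(spec.n_sites[state]):
            entry_id = f"{state}{i:04d}"
            neighbors = [
                NeighborPlacement(rtype, aname, float(rng.uniform(3.1, 3.5)))
                for rtype, aname in spec.baseline_neighbors
            ]
            enriched_types = []
            for (st, rtype), p in sorted(spec.enrichment.items()):
                if st != state:
                    continue
                hit = int(rng.random() < p)
                realized.setdefault((st, rtype), []).append(hit)
                if hit:
                    neighbors.append(NeighborPlacement(
                        rtype, REPRESENTATIVE_ATOM[rtype],
                        float(rng.uniform(3.2, 3.5)),
                    ))
                    enriched_types.append(rtype)
            burial_fraction = spec.exposure.get(state, 0.0)
            site_spec = SyntheticSpec(
                state=state,
                neighbors=neighbors,
                burial=spec.burial_shell if burial_fraction > 0 else None,
                burial_fraction=burial_fraction,
                random_seed=int(rng.integers(0, 2**31 - 1)),
                entry_id=entry_id,
            )
            pdb_path, _ = make_site_fixture(site_spec, out_dir)
            paths.append(pdb_path)
            manifest_rows.append(
                f"{entry_id}\t1.80\t0.22\tX-RAY DIFFRACTION\t2019-06-01\t{state}\t"
            )
            truth_rows.append(
                f"{entry_id}\t{state}\t{';'.join(enriched_types)}\t{burial_fraction}"
            )

    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(manifest_rows) + "\n")
    truth_table = out_dir / "ground_truth.tsv"
    truth_table.write_text("\n".join(truth_rows) + "\n")

    return {
        "manifest": manifest,
        "ground_truth": truth_table,
        "structures": paths,
        "realized_frequency": {
            f"{st}:{rt}": (float(np.mean(hits)) if hits else 0.0)
            for (st, rt), hits in sorted(realized.items())
        },
    }
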