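"""Microenvironment profiling around cysteine sulfur atoms.

The survey characterizes each cysteine site by the residues whose heavy atoms
fall within 3.6 Å of the sulfur (SG), pooled per oxidation state into
normalized neighbor-category frequencies that are compared against the
background amino-acid abundance of folded proteins. Hydrogen-bond partners are
classified from heavy-atom donor/acceptor geometry only (X-ray structures
rarely resolve hydrogens), and side-chain conformation is summarized by the
chi1 rotamer class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .dataset import CysSite
from .geometry import dihedral
from .structure_io import BioAssembly

logger = logging.getLogger(__name__)

#: neighborhood radius around the sulfur atom, Å
NEIGHBOR_CUTOFF = 3.6

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: oxidized cysteines seen as *neighbors* fold into the CYS category
_NEIGHBOR_ALIASES = {"CSO": "CYS", "CSD": "CYS", "OCS": "CYS", "MSE": "MET"}

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")

#: side-chain hydrogen-bond capability table (heavy atoms only)
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "TRP": ("NE1",), "HIS": ("ND1", "NE2"), "ASN": ("ND2",), "GLN": ("NE2",),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"),
}
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",),
}

#: chi1 rotamer partition (degrees): minus / plus / trans gauche convention
ROTAMER_BINS = {"m": (-120.0, 0.0), "p": (0.0, 120.0)}


def neighbor_category(residue_name: str) -> str:
    """Map a residue name to a profile category (20 AAs, HOH, or 'other')."""
    name = _NEIGHBOR_ALIASES.get(residue_name, residue_name)
    if name in AMINO_ACIDS:
        return name
    if name == "HOH":
        return "HOH"
    return "other"


# residue key within an assembly: (copy, chain, resnum, icode, resname)
AssemblyResidueKey = tuple[int, str, int, str, str]


@dataclass
class NeighborRecord:
    """Nearest-atom contact between a cysteine site and one neighboring residue."""

    site_id: str
    state: str
    neighbor_category: str
    neighbor_residue: AssemblyResidueKey
    nearest_atom_name: str
    min_distance: float


@dataclass
class EnvironmentProfile:
    """Pooled neighbor-category frequencies for one oxidation state."""

    state: str
    frequencies: dict[str, float]
    mean_neighbor_count: float
    n_sites: int
    background: dict[str, float] = field(default_factory=dict)
    enrichment: dict[str, float] = field(default_factory=dict)


@dataclass
class HBondContact:
    site_id: str
    state: str
    partner_residue: AssemblyResidueKey
    partner_atom_name: str
    partner_role: str  # sidechain_donor | sidechain_acceptor | backbone_amide_donor | backbone_carbonyl_acceptor
    site_atom_name: str  # SG or one of the sulfur-bonded oxygens
    distance: float


@dataclass
class RotamerRecord:
    site_id: str
    state: str
    chi1: float
    rotamer_class: str | None
    valid: bool = True


class StructuralError(ValueError):
    """Raised when a site lacks the atoms an operation needs."""


# ---------------------------------------------------------------------------
# neighbor extraction


def find_neighbors(
    assembly: BioAssembly,
    site: CysSite,
    cutoff: float = NEIGHBOR_CUTOFF,
) -> list[NeighborRecord]:
    """All residues with a heavy atom within ``cutoff`` Å of the site's sulfur.

    One record per distinct neighboring residue carrying the nearest atom and
    its distance; the site's own residue is excluded, waters are reported
    under category ``HOH``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sg = site.sg_coordinates
    if sg is None or not np.all(np.isfinite(sg)):
        raise StructuralError(
            f"{site.site_id}: sulfur coordinates missing for neighbor search"
        )

    coords = assembly.coordinates
    if len(coords) == 0:
        return []
    tree = cKDTree(coords)
    idx = tree.query_ball_point(sg, cutoff)

    own = (site.copy_index, *site.residue_id)
    best: dict[AssemblyResidueKey, tuple[float, str]] = {}
    for i in idx:
        atom = assembly.atoms[i]
        copy = assembly.copy_index[i]
        if (copy, *atom.residue_id) == own:
            continue
        key = (copy, atom.chain_id, atom.residue_number,
               atom.insertion_code, atom.residue_name)
        d = float(np.linalg.norm(atom.coordinates - sg))
        if key not in best or d < best[key][0]:
            best[key] = (d, atom.atom_name)

    return [
        NeighborRecord(
            site_id=site.site_id,
            state=site.state,
            neighbor_category=neighbor_category(key[4]),
            neighbor_residue=key,
            nearest_atom_name=atom_name,
            min_distance=d,
        )
        for key, (d, atom_name) in sorted(best.items(), key=lambda kv: kv[0])
    ]


# ---------------------------------------------------------------------------
# profiles


def uniform_background() -> dict[str, float]:
    """Flat 0.05 amino-acid background (shipped default for testing).

    The survey's background is the average amino-acid abundance of proteins in
    the PDB; supply measured abundances via ``background`` for real analyses.
    """
    return {aa: 0.05 for aa in AMINO_ACIDS}


def compute_profile(
    state: str,
    records: list[NeighborRecord],
    n_sites: int,
    background: dict[str, float] | None = None,
) -> EnvironmentProfile:
    """Pooled neighbor-category frequencies for one oxidation state.

    ``frequencies[c]`` is the fraction of all neighbor residues (pooled over
    sites) that belong to category ``c``; ``mean_neighbor_count`` is neighbor
    residues per site; ``enrichment[aa]`` is frequency/background for the 20
    amino-acid categories wherever the background is positive.
    """
    background = dict(background) if background is not None else uniform_background()
    total_bg = sum(background.get(aa, 0.0) for aa in AMINO_ACIDS)
    if abs(total_bg - 1.0) > 1e-6:
        raise ValueError(
            f"background frequencies sum to {total_bg:.8f}, expected 1 over the 20 amino acids"
        )
    if n_sites < 0:
        raise ValueError("n_sites must be non-negative")

    if n_sites == 0 or not records:
        return EnvironmentProfile(
            state=state,
            frequencies={},
            mean_neighbor_count=0.0,
            n_sites=n_sites,
            background=background,
        )

    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.neighbor_category] = counts.get(rec.neighbor_category, 0) + 1
    total = sum(counts.values())
    frequencies = {cat: n / total for cat, n in sorted(counts.items())}
    enrichment = {
        aa: frequencies[aa] / background[aa]
        for aa in AMINO_ACIDS
        if aa in frequencies and background.get(aa, 0.0) > 0
    }
    return EnvironmentProfile(
        state=state,
        frequencies=frequencies,
        mean_neighbor_count=total / n_sites,
        n_sites=n_sites,
        background=background,
        enrichment=enrichment,
    )


# ---------------------------------------------------------------------------
# hydrogen-bond partner classification


def _polar_roles(residue_name: str, atom_name: str) -> list[str]:
    roles: list[str] = []
    if atom_name == "N" and residue_name != "PRO":
        roles.append("backbone_amide_donor")
    if atom_name in ("O", "OXT"):
        roles.append("backbone_carbonyl_acceptor")
    name = _NEIGHBOR_ALIASES.get(residue_name, residue_name)
    if atom_name in SIDECHAIN_DONORS.get(name, ()):
        roles.append("sidechain_donor")
    if atom_name in SIDECHAIN_ACCEPTORS.get(name, ()):
        roles.append("sidechain_acceptor")
    return roles


def classify_hbond_partners(
    records: list[NeighborRecord],
    assembly: BioAssembly,
    site: CysSite,
    hbond_cutoff: float = NEIGHBOR_CUTOFF,
) -> list[HBondContact]:
    """Hydrogen-bond donor/acceptor partners of a cysteine site.

    A partner atom qualifies when it has donor or acceptor capability and lies
    within ``hbond_cutoff`` Å (heavy-atom distance; no angle term) of the
    site's SG or, for oxidized states, of any sulfur-bonded oxygen — partners
    of an outer sulfonate oxygen can therefore lie beyond the SG neighborhood
    that ``records`` covers, so the whole assembly is scanned. One contact is
    emitted per (partner atom, role), at the shortest qualifying distance.
    Waters are skipped (no directionality information).
    """
    target_atoms: list[tuple[str, np.ndarray]] = [("SG", site.sg_coordinates)]
    target_atoms += [(name, xyz) for name, xyz in site.oxygen_atoms]

    own = (site.copy_index, *site.residue_id)
    contacts: list[HBondContact] = []
    for copy, atom in zip(assembly.copy_index, assembly.atoms):
        key = (copy, atom.chain_id, atom.residue_number,
               atom.insertion_code, atom.residue_name)
        if (copy, *atom.residue_id) == own or atom.residue_name == "HOH":
            continue
        roles = _polar_roles(atom.residue_name, atom.atom_name)
        if not roles:
            continue
        dists = [(float(np.linalg.norm(atom.coordinates - xyz)), tname)
                 for tname, xyz in target_atoms]
        d, tname = min(dists)
        if d > hbond_cutoff:
            continue
        for role in roles:
            contacts.append(HBondContact(
                site_id=site.site_id,
                state=site.state,
                partner_residue=key,
                partner_atom_name=atom.atom_name,
                partner_role=role,
                site_atom_name=tname,
                distance=d,
            ))
    contacts.sort(key=lambda c: (c.partner_residue, c.partner_atom_name, c.partner_role))
    return contacts


# ---------------------------------------------------------------------------
# chi1 rotamers


def rotamer_class(chi1: float) -> str:
    """m/p/t class from chi1 in degrees: m=[-120,0), p=[0,120), t otherwise."""
    for cls, (lo, hi) in ROTAMER_BINS.items():
        if lo <= chi1 < hi:
            return cls
    return "t"


def chi1_rotamer(assembly: BioAssembly, site: CysSite) -> RotamerRecord:
    """chi1 = dihedral(N, CA, CB, SG) of the site's residue, with its class.

    A site whose residue lacks any of the four atoms yields a flagged record
    (``valid=False``) that summaries must exclude.
    """
    atoms: dict[str, np.ndarray] = {}
    for copy, atom in zip(assembly.copy_index, assembly.atoms):
        if copy == site.copy_index and atom.residue_id == site.residue_id:
            atoms[atom.atom_name] = atom.coordinates
    needed = ("N", "CA", "CB", "SG")
    if any(n not in atoms for n in needed):
        missing = [n for n in needed if n not in atoms]
        logger.warning("%s: chi1 undefined, missing %s", site.site_id, missing)
        return RotamerRecord(site_id=site.site_id, state=site.state,
                             chi1=float("nan"), rotamer_class=None, valid=False)
    chi1 = dihedral(*(atoms[n] for n in needed))
    return RotamerRecord(site_id=site.site_id, state=site.state,
                         chi1=chi1, rotamer_class=rotamer_class(chi1))
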