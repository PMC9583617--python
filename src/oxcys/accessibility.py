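"""Relative solvent accessible surface area of cysteine sites.

Shrake–Rupley-style sphere-point sampling: each atom is dressed with a probe-
expanded sphere (radius r_atom + r_probe) carrying a deterministic golden-
spiral point set; a point is accessible when it lies outside every other
probe-expanded sphere. Relative SASA divides the residue's accessible area in
the assembly by that of the same residue computed in isolation with its own
coordinates, so 0 means fully buried and 1 fully exposed; a self-reference is
exactly 1 by construction.

Waters and non-cysteine hetero ligands are excluded from the occluding set by
default — crystallographic waters would artifactually bury sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .dataset import CysSite
from .geometry import sphere_points
from .microenvironment import AMINO_ACIDS
from .structure_io import BioAssembly, CYS_FAMILY

logger = logging.getLogger(__name__)

PROBE_RADIUS = 1.4  # Å, water probe
N_POINTS = 960  # sphere points per atom

#: van der Waals radii, Å (configurable)
ATOM_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_RADIUS = 1.70

#: relative SASA may exceed 1 slightly when the in-assembly conformation is
#: more extended than the reference; clipped on export beyond this tolerance
REL_SASA_EPS = 0.05

HISTOGRAM_EDGES = np.round(np.arange(0.0, 1.0001, 0.05), 10)


@dataclass
class RelSASARecord:
    site_id: str
    state: str
    absolute_sasa: float
    reference_sasa: float
    relative_sasa: float


def atom_radius(element: str) -> float:
    return ATOM_RADII.get(element.upper(), DEFAULT_RADIUS)


def sasa_per_atom(
    coords: np.ndarray,
    radii: np.ndarray,
    subset: np.ndarray | None = None,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
) -> np.ndarray:
    """Accessible surface area (Å²) of ``subset`` atoms against all atoms.

    ``coords`` is (n, 3); ``radii`` the matching van der Waals radii. With
    ``subset=None`` every atom's area is returned.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_points < 100:
        raise ValueError("n_points must be at least 100 for usable accuracy")
    coords = np.asarray(coords, float).reshape(-1, 3)
    radii = np.asarray(radii, float).ravel()
    if len(radii) != len(coords):
        raise ValueError("coords and radii length mismatch")
    if subset is None:
        subset = np.arange(len(coords))
    subset = np.asarray(subset, int)

    unit = sphere_points(n_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    max_r = expanded.max() if len(expanded) else 0.0

    areas = np.zeros(len(subset))
    for out_i, i in enumerate(subset):
        r_i = expanded[i]
        pts = coords[i] + r_i * unit
        # candidate occluders: anything whose expanded sphere can reach ours
        cand = [j for j in tree.query_ball_point(coords[i], r_i + max_r) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in cand:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        areas[out_i] = 4.0 * np.pi * r_i ** 2 * accessible.mean()
    return areas


def _occluder_mask(assembly: BioAssembly, site: CysSite,
                   include_hetero: bool = False) -> np.ndarray:
    """Atoms that occlude: protein heavy atoms (cysteine-family hetero residues
    included), minus waters and — unless requested — other hetero ligands."""
    mask = np.ones(len(assembly.atoms), dtype=bool)
    for i, atom in enumerate(assembly.atoms):
        if atom.residue_name == "HOH":
            mask[i] = False
        elif atom.is_hetero and not include_hetero:
            mask[i] = atom.residue_name in CYS_FAMILY or atom.residue_name in AMINO_ACIDS
    return mask


def _site_atom_indices(assembly: BioAssembly, site: CysSite) -> list[int]:
    return [
        i for i, (copy, atom) in enumerate(zip(assembly.copy_index, assembly.atoms))
        if copy == site.copy_index and atom.residue_id == site.residue_id
    ]


def absolute_sasa(
    assembly: BioAssembly,
    site: CysSite,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
    include_hetero: bool = False,
) -> float:
    """Accessible area (Å²) of the site's residue within the assembly."""
    own = _site_atom_indices(assembly, site)
    if not own:
        raise ValueError(f"{site.site_id}: residue not found in assembly")
    mask = _occluder_mask(assembly, site, include_hetero)
    mask[own] = True
    idx = np.flatnonzero(mask)
    coords = assembly.coordinates[idx]
    radii = np.array([atom_radius(assembly.atoms[i].element) for i in idx])
    pos = {orig: new for new, orig in enumerate(idx)}
    subset = np.array([pos[i] for i in own])
    return float(sasa_per_atom(coords, radii, subset, probe_radius, n_points).sum())


def reference_sasa(
    assembly: BioAssembly,
    site: CysSite,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
) -> float:
    """Fully exposed reference: the residue computed in isolation."""
    own = _site_atom_indices(assembly, site)
    if not own:
        raise ValueError(f"{site.site_id}: residue not found in assembly")
    coords = assembly.coordinates[own]
    radii = np.array([atom_radius(assembly.atoms[i].element) for i in own])
    return float(sasa_per_atom(coords, radii, None, probe_radius, n_points).sum())


def relative_sasa(
    assembly: BioAssembly,
    site: CysSite,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
    include_hetero: bool = False,
) -> RelSASARecord:
    """Relative SASA of one site (absolute / isolated-residue reference)."""
    abs_area = absolute_sasa(assembly, site, probe_radius, n_points, include_hetero)
    ref_area = reference_sasa(assembly, site, probe_radius, n_points)
    if ref_area <= 0:
        raise ValueError(f"{site.site_id}: non-positive reference area")
    rel = abs_area / ref_area
    if rel > 1.0 + REL_SASA_EPS:
        logger.warning("%s: relative SASA %.3f exceeds 1+eps", site.site_id, rel)
    return RelSASARecord(
        site_id=site.site_id,
        state=site.state,
        absolute_sasa=abs_area,
        reference_sasa=ref_area,
        relative_sasa=rel,
    )


def summarize_by_state(records: list[RelSASARecord]) -> pd.DataFrame:
    """Per-state distribution summary of relative SASA.

    Columns: n, mean, median, q25, q75 and fixed 0.05-wide histogram bins over
    [0, 1] (values clipped into [0, 1] for binning; the clip is logged).
    """
    if not records:
        raise ValueError("no records to summarize")
    rows = []
    by_state: dict[str, list[float]] = {}
    for r in records:
        by_state.setdefault(r.state, []).append(r.relative_sasa)
    for state, values in sorted(by_state.items()):
        v = np.asarray(values)
        clipped = np.clip(v, 0.0, 1.0)
        n_clip = int(np.sum(clipped != v))
        if n_clip:
            logger.info("state %s: %d relative SASA values clipped into [0,1]", state, n_clip)
        hist, _ = np.histogram(clipped, bins=HISTOGRAM_EDGES)
        row = {
            "state": state,
            "n": len(v),
            "mean": float(v.mean()),
            "median": float(np.median(v)),
            "q25": float(np.percentile(v, 25)),
            "q75": float(np.percentile(v, 75)),
        }
        for k, count in enumerate(hist):
            row[f"bin_{HISTOGRAM_EDGES[k]:.2f}"] = int(count)
        rows.append(row)
    return pd.DataFrame(rows)
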