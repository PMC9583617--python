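"""Thr/Arg/Gly hydrogen-bond motif around sulfonic acid (OCS) sites.

Sulfonylated cysteines are frequently stabilized by a network in which all
three sulfonate oxygens accept hydrogen bonds, with threonine side chains,
arginine side chains and glycine backbone amides as the recurring donors
(peroxiredoxins, LuxS, lectin and TdcF families). The motif is operationalized
as: every oxygen carries at least one donor contact AND at least one donor
belongs to {Thr OG1, Arg NE/NH1/NH2, Gly backbone N}. Non-glycine backbone
amides count toward oxygen coverage but not toward the class requirement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CysSite
from .microenvironment import (
    NEIGHBOR_CUTOFF,
    HBondContact,
    SIDECHAIN_DONORS,
)
from .structure_io import BioAssembly

logger = logging.getLogger(__name__)

#: donor classes that satisfy the motif requirement
MOTIF_CLASSES = frozenset({"Thr_sidechain", "Arg_sidechain", "Gly_backbone"})


class MotifError(ValueError):
    pass


@dataclass
class MotifHit:
    """Hydrogen-bond coverage of one sulfonate site."""

    site_id: str
    contacts: list[HBondContact] = field(default_factory=list)
    partner_classes_present: frozenset[str] = frozenset()
    oxygens_covered: int = 0
    is_motif: bool = False
    malformed: bool = False


def _donor_class(residue_name: str, atom_name: str) -> str | None:
    if atom_name == "N":
        if residue_name == "PRO":
            return None  # proline nitrogen has no amide hydrogen
        return "Gly_backbone" if residue_name == "GLY" else "other_backbone"
    if residue_name == "THR" and atom_name == "OG1":
        return "Thr_sidechain"
    if residue_name == "ARG" and atom_name in ("NE", "NH1", "NH2"):
        return "Arg_sidechain"
    if atom_name in SIDECHAIN_DONORS.get(residue_name, ()):
        return "other_sidechain"
    return None


def detect_motif(
    assembly: BioAssembly,
    site: CysSite,
    hbond_cutoff: float = NEIGHBOR_CUTOFF,
) -> MotifHit:
    """Classify the hydrogen-bond network around one OCS site.

    Contacts are donor atoms within ``hbond_cutoff`` Å of any of the three
    sulfonate oxygens. A site whose oxygen set is not fully resolved is
    flagged malformed and never scores as a motif.
    """
    if site.state != "OCS":
        raise MotifError(f"{site.site_id}: motif detection applies to OCS sites, "
                         f"got {site.state}")
    if site.malformed or len(site.oxygen_atoms) != 3:
        logger.warning("%s: malformed sulfonate oxygen set (%d oxygens)",
                       site.site_id, len(site.oxygen_atoms))
        return MotifHit(site_id=site.site_id, malformed=True)

    contacts: list[HBondContact] = []
    covered: set[str] = set()
    classes: set[str] = set()
    for copy, atom in zip(assembly.copy_index, assembly.atoms):
        if copy == site.copy_index and atom.residue_id == site.residue_id:
            continue
        if atom.residue_name == "HOH":
            continue
        cls = _donor_class(atom.residue_name, atom.atom_name)
        if cls is None:
            continue
        for ox_name, ox_xyz in site.oxygen_atoms:
            d = float(np.linalg.norm(atom.coordinates - ox_xyz))
            if d <= hbond_cutoff:
                covered.add(ox_name)
                classes.add(cls)
                role = ("backbone_amide_donor"
                        if cls in ("Gly_backbone", "other_backbone")
                        else "sidechain_donor")
                contacts.append(HBondContact(
                    site_id=site.site_id,
                    state=site.state,
                    partner_residue=(copy, atom.chain_id, atom.residue_number,
                                     atom.insertion_code, atom.residue_name),
                    partner_atom_name=atom.atom_name,
                    partner_role=role,
                    site_atom_name=ox_name,
                    distance=d,
                ))

    contacts.sort(key=lambda c: (c.site_atom_name, c.distance))
    is_motif = len(covered) == 3 and bool(classes & MOTIF_CLASSES)
    return MotifHit(
        site_id=site.site_id,
        contacts=contacts,
        partner_classes_present=frozenset(classes),
        oxygens_covered=len(covered),
        is_motif=is_motif,
    )


def scan_cohort(
    assemblies: list[BioAssembly],
    sites: list[CysSite],
    hbond_cutoff: float = NEIGHBOR_CUTOFF,
    family_labels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Motif table over a cohort of OCS sites.

    One row per site with hit fields; malformed sites are reported but carry
    ``is_motif=False`` and are excluded from aggregate counts. Optional
    ``family_labels`` (entry_id → tag) annotate rows for per-family tallies.
    """
    by_entry = {a.entry_id: a for a in assemblies}
    rows = []
    for site in sites:
        if site.state != "OCS":
            continue
        assembly = by_entry.get(site.entry_id)
        if assembly is None:
            logger.warning("%s: no assembly provided for entry %s",
                           site.site_id, site.entry_id)
            continue
        hit = detect_motif(assembly, site, hbond_cutoff)
        rows.append({
            "site_id": site.site_id,
            "entry_id": site.entry_id,
            "family": (family_labels or {}).get(site.entry_id, ""),
            "oxygens_covered": hit.oxygens_covered,
            "n_contacts": len(hit.contacts),
            "partner_classes": ";".join(sorted(hit.partner_classes_present)),
            "is_motif": hit.is_motif,
            "malformed": hit.malformed,
        })
    columns = ["site_id", "entry_id", "family", "oxygens_covered", "n_contacts",
               "partner_classes", "is_motif", "malformed"]
    return pd.DataFrame(rows, columns=columns)
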