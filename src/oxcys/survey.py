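"""End-to-end survey orchestration over a directory of structures.

Chains the pipeline stages — manifest query, quality filters, assembly
construction, disulfide detection, site classification, neighbor profiling,
hydrogen-bond classification, rotamers and relative SASA — so analysis
drivers and tests run one call instead of re-wiring the stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .accessibility import RelSASARecord, relative_sasa
from .dataset import (
    CysSite,
    classify_cysteines,
    filter_entries,
    query_entries,
)
from .microenvironment import (
    NEIGHBOR_CUTOFF,
    EnvironmentProfile,
    HBondContact,
    NeighborRecord,
    RotamerRecord,
    chi1_rotamer,
    classify_hbond_partners,
    compute_profile,
    find_neighbors,
)
from .structure_io import BioAssembly, build_first_assembly, detect_disulfides, read_structure

logger = logging.getLogger(__name__)

ALL_STATES = ("CYS", "CSO", "CSD", "OCS")


@dataclass
class SurveyResult:
    """Pooled per-state survey outputs for one cohort."""

    sites: list[CysSite] = field(default_factory=list)
    neighbor_records: dict[str, list[NeighborRecord]] = field(default_factory=dict)
    n_sites: dict[str, int] = field(default_factory=dict)
    profiles: dict[str, EnvironmentProfile] = field(default_factory=dict)
    hbond_contacts: list[HBondContact] = field(default_factory=list)
    rotamers: list[RotamerRecord] = field(default_factory=list)
    assemblies: dict[str, BioAssembly] = field(default_factory=dict)

    def profile_frame(self) -> pd.DataFrame:
        rows = []
        for state, prof in sorted(self.profiles.items()):
            for cat, freq in sorted(prof.frequencies.items()):
                rows.append({
                    "state": state, "category": cat, "frequency": freq,
                    "enrichment": prof.enrichment.get(cat),
                    "n_sites": prof.n_sites,
                    "mean_neighbor_count": prof.mean_neighbor_count,
                })
        return pd.DataFrame(rows)


def run_survey(
    structure_dir: str | Path,
    manifest: str | Path,
    components: tuple[str, ...] = ALL_STATES,
    cutoff: float = NEIGHBOR_CUTOFF,
    background: dict[str, float] | None = None,
    max_resolution: float = 2.5,
    max_rfree: float = 0.30,
    with_hbonds: bool = False,
    with_rotamers: bool = False,
) -> SurveyResult:
    """Run the site survey over every retained entry in ``structure_dir``.

    Disulfide-bonded (CYX) and malformed sites are classified and reported in
    ``sites`` but excluded from profiles, matching the survey's exclusion
    rule.
    """
    structure_dir = Path(structure_dir)
    entries = query_entries(component_ids=components, manifest=manifest)
    kept, rejections = filter_entries(entries, max_resolution, max_rfree)
    if len(rejections):
        logger.info("%d entries rejected by quality filters", len(rejections))

    result = SurveyResult(
        neighbor_records={s: [] for s in ALL_STATES},
        n_sites={s: 0 for s in ALL_STATES},
    )
    for entry in kept:
        path = structure_dir / f"{entry.entry_id}.pdb"
        if not path.exists():
            path = structure_dir / f"{entry.entry_id}.cif"
        if not path.exists():
            logger.warning("no structure file for entry %s; skipped", entry.entry_id)
            continue
        model = read_structure(path)
        assembly = build_first_assembly(model)
        result.assemblies[entry.entry_id] = assembly
        disulfides = detect_disulfides(model)
        for site in classify_cysteines(assembly, disulfides):
            result.sites.append(site)
            if site.state == "CYX" or site.malformed:
                continue
            records = find_neighbors(assembly, site, cutoff)
            result.neighbor_records[site.state].extend(records)
            result.n_sites[site.state] += 1
            if with_hbonds:
                result.hbond_contacts.extend(
                    classify_hbond_partners(records, assembly, site, cutoff))
            if with_rotamers:
                result.rotamers.append(chi1_rotamer(assembly, site))

    for state in ALL_STATES:
        result.profiles[state] = compute_profile(
            state, result.neighbor_records[state], result.n_sites[state], background)
    return result


def enrichment_ratio(
    result: SurveyResult,
    category: str,
    state: str,
    reference_state: str = "CYS",
) -> float:
    """Neighbor-frequency ratio of ``category`` between two states.

    With a shared background this equals the ratio of background-normalized
    enrichments; the survey's headline His observation is this quantity for
    the oxidized states against CYS.
    """
    num = result.profiles[state].frequencies.get(category, 0.0)
    den = result.profiles[reference_state].frequencies.get(category, 0.0)
    if den == 0.0:
        raise ZeroDivisionError(
            f"category {category} absent around {reference_state} sites")
    return num / den


def sasa_by_state(
    result: SurveyResult,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> list[RelSASARecord]:
    """Relative SASA for every profiled site of the survey."""
    records = []
    for site in result.sites:
        if site.state == "CYX" or site.malformed:
            continue
        assembly = result.assemblies.get(site.entry_id)
        if assembly is None:
            continue
        records.append(relative_sasa(assembly, site, probe_radius, n_points))
    return records
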