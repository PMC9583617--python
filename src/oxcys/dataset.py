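"""Survey dataset assembly: entry selection, quality filtering, site classification.

The survey keeps crystal structures that contain at least one oxidized
cysteine component (CSO, CSD or OCS), pass resolution < 2.5 Å and
R-free < 0.30 (strict inequalities), and classifies every cysteine-family
residue in the first biological assembly by oxidation state:

====== ============================ =========================
 code   chemistry                    sulfur-bonded oxygens
====== ============================ =========================
 CYS    thiol/thiolate               0
 CSO    sulfenic acid (-SOH)         1
 CSD    sulfinic acid (-SO2H)        2
 OCS    sulfonic acid (-SO3H)        3
 CYX    disulfide-bonded cysteine    0 (excluded from profiles)
====== ============================ =========================

Entry metadata comes from a TSV manifest so the whole pipeline runs offline;
a remote query against the wwPDB search API would populate the same schema.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import BioAssembly, ResidueId

logger = logging.getLogger(__name__)

OXIDIZED_STATES = ("CSO", "CSD", "OCS")

#: expected sulfur-bonded oxygen names per oxidation state; deposition-era
#: variations are handled by the distance fallback in `classify_cysteines`
OXYGEN_NAMES = {
    "CYS": (),
    "CSO": ("OD",),
    "CSD": ("OD1", "OD2"),
    "OCS": ("OD1", "OD2", "OD3"),
}

#: fallback: any O-element atom of the residue within this distance of SG
SG_OXYGEN_BOND_CUTOFF = 1.8

MANIFEST_COLUMNS = ["entry_id", "resolution", "r_free", "method",
                    "release_date", "components", "uniprot"]


@dataclass
class EntryMeta:
    """Metadata for one structure entry, as used by the survey filters."""

    entry_id: str
    resolution: float | None = None
    r_free: float | None = None
    experimental_method: str = ""
    release_date: dt.date | None = None
    components_present: frozenset[str] = frozenset()
    uniprot_accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.resolution is not None and not self.resolution > 0:
            raise ValueError(f"{self.entry_id}: resolution must be positive")
        if self.r_free is not None and not (0 < self.r_free < 1):
            raise ValueError(f"{self.entry_id}: r_free must lie in (0, 1)")


@dataclass
class CysSite:
    """One cysteine-family residue in a biological assembly."""

    entry_id: str
    chain_id: str
    residue_number: int
    insertion_code: str
    state: str  # CYS | CSO | CSD | OCS | CYX
    sg_coordinates: np.ndarray
    oxygen_atoms: list[tuple[str, np.ndarray]] = field(default_factory=list)
    copy_index: int = 0
    malformed: bool = False

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def site_id(self) -> str:
        icode = self.insertion_code or ""
        return f"{self.entry_id}/{self.copy_index}/{self.chain_id}{self.residue_number}{icode}"


# ---------------------------------------------------------------------------
# manifest handling


def read_manifest(path: str | Path) -> tuple[list[EntryMeta], list[tuple[int, str]]]:
    """Parse a manifest TSV into entries plus row-level error reports.

    Malformed rows are skipped and reported as (row number, reason); they are
    never silently dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("entry_id",) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest lacks required column(s) {missing}")

    entries: list[EntryMeta] = []
    errors: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based, after header
        try:
            entries.append(_entry_from_row(row))
        except (ValueError, KeyError) as exc:
            logger.warning("manifest row %d skipped: %s", rownum, exc)
            errors.append((rownum, str(exc)))
    return entries, errors


def _parse_optional_float(value: str, name: str) -> float | None:
    value = value.strip()
    if value in ("", "NA", "nan", "."):
        return None
    try:
        return float(value)
    except ValueError:
        raise ValueError(f"non-numeric {name}: {value!r}")


def _entry_from_row(row: pd.Series) -> EntryMeta:
    entry_id = str(row["entry_id"]).strip()
    if not entry_id:
        raise ValueError("empty entry_id")
    release = None
    raw_date = str(row.get("release_date", "")).strip()
    if raw_date:
        try:
            release = dt.date.fromisoformat(raw_date)
        except ValueError:
            raise ValueError(f"bad release_date {raw_date!r} (expected ISO yyyy-mm-dd)")
    components = frozenset(
        c.strip().upper() for c in str(row.get("components", "")).split(";") if c.strip()
    )
    uniprot = tuple(
        u.strip() for u in str(row.get("uniprot", "")).split(";") if u.strip()
    )
    return EntryMeta(
        entry_id=entry_id,
        resolution=_parse_optional_float(str(row.get("resolution", "")), "resolution"),
        r_free=_parse_optional_float(str(row.get("r_free", "")), "r_free"),
        experimental_method=str(row.get("method", "")).strip(),
        release_date=release,
        components_present=components,
        uniprot_accessions=uniprot,
    )


def query_entries(
    component_ids: set[str] | tuple[str, ...] = OXIDIZED_STATES,
    date_cutoff: dt.date | None = None,
    manifest: str | Path | None = None,
) -> list[EntryMeta]:
    """Select entries containing at least one listed chemical component.

    Runs against a local manifest file; entries released after ``date_cutoff``
    are excluded and duplicate entry identifiers are collapsed to the first
    occurrence, so the result is deterministic given a fixed manifest.
    """
    if manifest is None:
        raise ValueError(
            "remote PDB queries are not bundled; provide a manifest file "
            "(TSV with columns entry_id, resolution, r_free, method, "
            "release_date, components, uniprot)"
        )
    wanted = {c.upper() for c in component_ids}
    entries, _ = read_manifest(manifest)
    seen: set[str] = set()
    out: list[EntryMeta] = []
    for e in entries:
        if e.entry_id in seen:
            logger.info("duplicate manifest entry %s ignored", e.entry_id)
            continue
        if not (e.components_present & wanted):
            continue
        if date_cutoff is not None and (
            e.release_date is None or e.release_date > date_cutoff
        ):
            continue
        seen.add(e.entry_id)
        out.append(e)
    return out


def filter_entries(
    entries: list[EntryMeta],
    max_resolution: float = 2.5,
    max_rfree: float = 0.30,
) -> tuple[list[EntryMeta], pd.DataFrame]:
    """Apply the survey quality filters (strict ``<`` on both cutoffs).

    Entries missing either value are excluded and tallied in the rejection
    report (non-crystallographic methods lack R-free and are therefore
    excluded rather than exempted).

    Returns (kept entries in input order, rejection report with columns
    ``entry_id`` and ``reason``).
    """
    if max_resolution <= 0 or max_rfree <= 0:
        raise ValueError("filter thresholds must be positive")
    kept: list[EntryMeta] = []
    rejected: list[dict] = []
    for e in entries:
        if e.resolution is None:
            rejected.append({"entry_id": e.entry_id, "reason": "missing_resolution"})
        elif e.r_free is None:
            rejected.append({"entry_id": e.entry_id, "reason": "missing_rfree"})
        elif not e.resolution < max_resolution:
            rejected.append({"entry_id": e.entry_id, "reason": "resolution"})
        elif not e.r_free < max_rfree:
            rejected.append({"entry_id": e.entry_id, "reason": "rfree"})
        else:
            kept.append(e)
    report = pd.DataFrame(rejected, columns=["entry_id", "reason"])
    return kept, report


# ---------------------------------------------------------------------------
# site classification


def classify_cysteines(
    assembly: BioAssembly,
    disulfides: list[tuple[ResidueId, ResidueId]] | None = None,
) -> list[CysSite]:
    """One :class:`CysSite` per cysteine-family residue, per assembly copy.

    CYS residues appearing in a disulfide pair are relabeled CYX (they are
    excluded from environment profiling downstream). Sulfur-bonded oxygens are
    attached by naming convention with a distance fallback; an oxidized site
    whose resolved oxygen count still disagrees with its state is flagged
    malformed and excluded from profiles by the callers.
    """
    in_disulfide: set[ResidueId] = set()
    for p1, p2 in disulfides or []:
        in_disulfide.add(p1)
        in_disulfide.add(p2)

    sites: list[CysSite] = []
    for (copy, chain, resnum, icode, resname), idxs in assembly.iter_residues():
        if resname not in OXYGEN_NAMES:
            continue
        atoms = [assembly.atoms[i] for i in idxs]
        sg = next((a for a in atoms if a.atom_name == "SG"), None)
        if sg is None:
            logger.warning("%s %s%s: cysteine without SG atom skipped",
                           assembly.entry_id, chain, resnum)
            continue

        expected = OXYGEN_NAMES[resname]
        oxygens = [(a.atom_name, a.coordinates) for a in atoms
                   if a.atom_name in expected]
        if len(oxygens) != len(expected):
            oxygens = [
                (a.atom_name, a.coordinates) for a in atoms
                if a.element == "O" and a.atom_name not in ("O", "OXT")
                and np.linalg.norm(a.coordinates - sg.coordinates) <= SG_OXYGEN_BOND_CUTOFF
            ]
        malformed = len(oxygens) != len(expected)
        state = resname
        if resname == "CYS" and (chain, resnum, icode) in in_disulfide:
            state = "CYX"
            oxygens = []
            malformed = False
        if malformed:
            logger.warning(
                "%s %s%s: %s with %d sulfur-bonded oxygens (expected %d); flagged",
                assembly.entry_id, chain, resnum, resname, len(oxygens), len(expected),
            )
        sites.append(CysSite(
            entry_id=assembly.entry_id,
            chain_id=chain,
            residue_number=resnum,
            insertion_code=icode,
            state=state,
            sg_coordinates=sg.coordinates,
            oxygen_atoms=oxygens,
            copy_index=copy,
            malformed=malformed,
        ))
    return sites


def state_counts(sites: list[CysSite]) -> dict[str, int]:
    """Per-state site tally (malformed sites counted under their state)."""
    counts: dict[str, int] = {}
    for s in sites:
        counts[s.state] = counts.get(s.state, 0) + 1
    return counts
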