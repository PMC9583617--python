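"""Protein-accession mapping, keyword tallies and proteomics-overlap statistics.

Structure entries are linked to protein (UniProt-style) accessions through a
flat two-column mapping table, subcellular-location keywords are tallied from
an annotation table, and set overlaps against proteomics accession lists are
reported as exact intersections with a half-up percentage of the left set —
all offline, so the module is fully testable without ID-mapping services.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from pathlib import Path

logger = logging.getLogger(__name__)


@dataclass
class AccessionMap:
    entries: dict[str, list[str]]
    unmapped: list[str]

    @property
    def accessions(self) -> set[str]:
        return {acc for accs in self.entries.values() for acc in accs}


@dataclass
class OverlapResult:
    n_left: int
    n_right: int
    n_intersection: int
    percent_of_left: float | None  # None marks "undefined" (empty left set)

    def __post_init__(self) -> None:
        if self.n_intersection > min(self.n_left, self.n_right):
            raise ValueError("intersection larger than one of the sets")


_VERSION_SUFFIX = re.compile(r"\.\d+$")
_ISOFORM_SUFFIX = re.compile(r"-\d+$")


def normalize_accession(accession: str) -> str:
    """Canonicalize an accession: strip version (".2") and isoform ("-2") suffixes."""
    acc = accession.strip()
    acc = _VERSION_SUFFIX.sub("", acc)
    acc = _ISOFORM_SUFFIX.sub("", acc)
    return acc


def map_ids(entry_ids: list[str], mapping_table: str | Path) -> AccessionMap:
    """Map entry identifiers to accessions via a two-column TSV.

    Entries absent from the table are reported in ``unmapped`` (and logged),
    never silently dropped. A chimeric entry mapping to several accessions
    retains all of them. Malformed rows are skipped with a row-level log entry.
    """
    table: dict[str, list[str]] = {}
    with open(mapping_table) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                logger.warning("%s:%d: malformed mapping row skipped: %r",
                               mapping_table, lineno, line)
                continue
            entry = parts[0].strip()
            acc = normalize_accession(parts[1])
            table.setdefault(entry, [])
            if acc not in table[entry]:
                table[entry].append(acc)

    entries: dict[str, list[str]] = {}
    unmapped: list[str] = []
    for eid in entry_ids:
        if eid in table:
            entries[eid] = list(table[eid])
        else:
            unmapped.append(eid)
    if unmapped:
        logger.info("%d of %d entries unmapped", len(unmapped), len(entry_ids))
    return AccessionMap(entries=entries, unmapped=unmapped)


def read_accession_list(path: str | Path) -> set[str]:
    """One accession per line; comments (#) and blanks ignored; normalized."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(normalize_accession(line))
    return out


def read_annotation_table(path: str | Path) -> dict[str, set[str]]:
    """Accession → keyword set from a TSV (accession, semicolon-joined keywords)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not parts[0].strip():
                logger.warning("%s:%d: malformed annotation row skipped", path, lineno)
                continue
            acc = normalize_accession(parts[0])
            kws = set()
            if len(parts) > 1:
                kws = {k.strip() for k in parts[1].split(";") if k.strip()}
            out.setdefault(acc, set()).update(kws)
    return out


def tally_keywords(
    accessions: set[str],
    annotation_table: str | Path | dict[str, set[str]],
    keyword_list: list[str],
) -> dict[str, int]:
    """Count accessions annotated with each keyword.

    The result also carries two bookkeeping totals: ``_any`` (accessions with
    at least one listed keyword) and ``_none`` (accessions with none). An
    accession with several keywords counts once per keyword and once in
    ``_any``.
    """
    if not keyword_list:
        raise ValueError("keyword list must be non-empty")
    annot = (annotation_table if isinstance(annotation_table, dict)
             else read_annotation_table(annotation_table))
    normalized = {normalize_accession(a) for a in accessions}
    counts = {kw: 0 for kw in keyword_list}
    n_any = 0
    for acc in sorted(normalized):
        kws = annot.get(acc, set())
        hit = False
        for kw in keyword_list:
            if kw in kws:
                counts[kw] += 1
                hit = True
        n_any += hit
    counts["_any"] = n_any
    counts["_none"] = len(normalized) - n_any
    return counts


def round_half_up(value: float, decimals: int = 1) -> float:
    """Half-up decimal rounding helper."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def truncate_percent(value: float, decimals: int = 1) -> float:
    """Truncate a percentage toward zero at ``decimals`` places.

    Survey tables print percentages truncated, not rounded: 173 of 349 is
    49.57% and prints as 49.5%.
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_DOWN))


def overlap_stats(left: set[str], right: set[str],
                  normalize: bool = True) -> OverlapResult:
    """Exact set intersection with the percentage taken on the left set.

    An empty left set yields ``percent_of_left=None`` (undefined), not 0.
    """
    if normalize:
        left = {normalize_accession(a) for a in left}
        right = {normalize_accession(a) for a in right}
    inter = left & right
    percent = None
    if left:
        percent = truncate_percent(100.0 * len(inter) / len(left), 1)
    return OverlapResult(
        n_left=len(left),
        n_right=len(right),
        n_intersection=len(inter),
        percent_of_left=percent,
    )
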