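"""Reading, writing and biological-assembly construction for protein structures.

Supports the PDB and mmCIF dialects. Coordinates are in Å; author residue
numbering is preserved. Hydrogens are dropped on read (most X-ray structures
lack them). When one atom carries several alternate locations, the
highest-occupancy conformer is kept (ties broken alphabetically by altloc) so
that downstream geometry sees a single conformer.

The biological assembly is built by applying the first-listed assembly's
rotation/translation operators (REMARK 350 BIOMT in the PDB dialect,
``_pdbx_struct_oper_list`` in mmCIF) to their target chains.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: residue names of the cysteine oxidation series handled throughout the package
CYS_FAMILY = ("CYS", "CSO", "CSD", "OCS")

#: covalent S-S bond is ~2.05 Å; margin for coordinate error
DISULFIDE_SG_CUTOFF = 2.3

_ORTHO_TOL = 1e-6


class FormatError(ValueError):
    """Raised when a structure file cannot be parsed under the named dialect."""


class ValidationError(ValueError):
    """Raised when parsed content violates a structural invariant."""


# residue identifier: (chain_id, residue_number, insertion_code)
ResidueId = tuple[str, int, str]


@dataclass
class AtomRecord:
    """One heavy atom of a structure, with author numbering."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    coordinates: np.ndarray
    insertion_code: str = ""
    altloc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,) or not np.all(np.isfinite(self.coordinates)):
            raise ValidationError(
                f"atom {self.serial} {self.atom_name}: coordinates must be a finite 3-vector"
            )
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValidationError(
                f"atom {self.serial} {self.atom_name}: occupancy {self.occupancy} outside [0, 1]"
            )
        if not self.residue_name:
            raise ValidationError(f"atom {self.serial}: empty residue name")

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class AssemblyOperatorSet:
    """One generator of a biological assembly: operators applied to target chains."""

    assembly_id: str
    chains: tuple[str, ...]  # empty tuple means "all chains"
    rotations: np.ndarray  # (n_ops, 3, 3)
    translations: np.ndarray  # (n_ops, 3)

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float).reshape(-1, 3, 3)
        self.translations = np.asarray(self.translations, dtype=float).reshape(-1, 3)
        for rot in self.rotations:
            if abs(abs(np.linalg.det(rot)) - 1.0) > 1e-4:
                raise ValidationError(
                    f"assembly {self.assembly_id}: rotation determinant "
                    f"{np.linalg.det(rot):.6f} is not ±1"
                )
            if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-4):
                raise ValidationError(
                    f"assembly {self.assembly_id}: rotation matrix is not orthonormal"
                )


@dataclass
class StructureModel:
    """Parsed asymmetric unit plus the header metadata the survey pipeline uses.

    ``resolution`` and ``r_free`` are ``None`` when absent from the file; they
    are never defaulted to 0.
    """

    entry_id: str
    atoms: list[AtomRecord] = field(default_factory=list)
    resolution: float | None = None
    r_free: float | None = None
    assemblies: list[AssemblyOperatorSet] = field(default_factory=list)
    ssbond_pairs: list[tuple[ResidueId, ResidueId]] = field(default_factory=list)

    def validate(self) -> None:
        seen: set[tuple] = set()
        for atom in self.atoms:
            key = (atom.chain_id, atom.residue_number, atom.insertion_code,
                   atom.atom_name, atom.altloc)
            if key in seen:
                raise ValidationError(f"{self.entry_id}: duplicate atom {key}")
            seen.add(key)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms], dtype=float).reshape(-1, 3)


@dataclass
class BioAssembly:
    """Atoms of the first biological assembly, tagged with their copy index."""

    entry_id: str
    atoms: list[AtomRecord]
    copy_index: list[int]
    operator_count: int
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def coordinates(self) -> np.ndarray:
        if self._coords is None:
            self._coords = np.array(
                [a.coordinates for a in self.atoms], dtype=float
            ).reshape(-1, 3)
        return self._coords

    def residue_keys(self) -> list[tuple[int, str, int, str, str]]:
        """Per-atom (copy, chain, resnum, icode, resname) keys."""
        return [
            (c, a.chain_id, a.residue_number, a.insertion_code, a.residue_name)
            for c, a in zip(self.copy_index, self.atoms)
        ]

    def iter_residues(self) -> Iterable[tuple[tuple[int, str, int, str, str], list[int]]]:
        """Yield (residue key, atom indices) preserving file order."""
        groups: dict[tuple, list[int]] = {}
        order: list[tuple] = []
        for i, key in enumerate(self.residue_keys()):
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(i)
        for key in order:
            yield key, groups[key]


# ---------------------------------------------------------------------------
# reading


def _dedupe_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom: highest occupancy, ties alphabetical."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (atom.chain_id, atom.residue_number, atom.insertion_code, atom.atom_name)
        prev = best.get(key)
        if prev is None:
            best[key] = atom
            order.append(key)
        elif (atom.occupancy, _altloc_rank(atom.altloc)) > (
            prev.occupancy, _altloc_rank(prev.altloc)
        ):
            best[key] = atom
    return [best[k] for k in order]


def _altloc_rank(altloc: str) -> float:
    # later in the alphabet ranks lower; blank altloc outranks everything
    return 0.0 if not altloc else -ord(altloc)


_RFREE_RE = re.compile(r"FREE R VALUE\s*(?:\(NO CUTOFF\))?\s*:\s*([0-9.]+)")


def _read_pdb(path: Path) -> StructureModel:
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: not parseable as PDB: {exc}") from exc

    if len(st) == 0:
        raise FormatError(f"{path}: no models found")

    atoms: list[AtomRecord] = []
    serial = 0
    for chain in st[0]:
        for res in chain:
            for at in res:
                if at.element.name == "H" or at.element.name == "D":
                    continue
                serial += 1
                atoms.append(AtomRecord(
                    serial=serial,
                    atom_name=at.name,
                    element=at.element.name,
                    residue_name=res.name,
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    altloc=(at.altloc or "").strip(" \x00"),
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    coordinates=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    b_factor=at.b_iso,
                    is_hetero=(res.het_flag == "H"),
                ))

    resolution = st.resolution if st.resolution > 0 else None
    r_free = None
    for line in st.raw_remarks:
        if line.startswith("REMARK   3"):
            m = _RFREE_RE.search(line)
            if m:
                r_free = float(m.group(1))
                break

    assemblies = []
    for asm in st.assemblies:
        for gen in asm.generators:
            rots, trans = [], []
            for op in gen.operators:
                rots.append(np.array(op.transform.mat.tolist()))
                trans.append(np.array(op.transform.vec.tolist()))
            if rots:
                assemblies.append(AssemblyOperatorSet(
                    assembly_id=asm.name,
                    chains=tuple(gen.chains),
                    rotations=np.array(rots),
                    translations=np.array(trans),
                ))

    ssbonds = []
    for conn in st.connections:
        if conn.type == gemmi.ConnectionType.Disulf:
            p1 = (conn.partner1.chain_name, conn.partner1.res_id.seqid.num,
                  (conn.partner1.res_id.seqid.icode or "").strip())
            p2 = (conn.partner2.chain_name, conn.partner2.res_id.seqid.num,
                  (conn.partner2.res_id.seqid.icode or "").strip())
            ssbonds.append((p1, p2))

    entry_id = st.name if st.name and st.name not in ("", "XXXX") else path.stem
    model = StructureModel(
        entry_id=entry_id,
        atoms=_dedupe_altlocs(atoms),
        resolution=resolution,
        r_free=r_free,
        assemblies=assemblies,
        ssbond_pairs=ssbonds,
    )
    model.validate()
    return model


def _cif_float(block: "gemmi.cif.Block", tag: str) -> float | None:
    val = block.find_value(tag)
    if val is None or val in (".", "?"):
        return None
    try:
        return float(val)
    except ValueError:
        raise FormatError(f"mmCIF field {tag}: non-numeric value {val!r}")


def _read_mmcif(path: Path) -> StructureModel:
    try:
        doc = gemmi.cif.read(str(path))
        block = doc[0]
    except (RuntimeError, ValueError, IndexError) as exc:
        raise FormatError(f"{path}: not parseable as mmCIF: {exc}") from exc

    entry_id = block.find_value("_entry.id") or block.name or path.stem

    site = block.find("_atom_site.", [
        "group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
        "label_comp_id", "auth_asym_id", "auth_seq_id", "?pdbx_PDB_ins_code",
        "Cartn_x", "Cartn_y", "Cartn_z", "occupancy", "B_iso_or_equiv",
    ])
    if len(site) == 0:
        raise FormatError(f"{path}: no _atom_site loop found")

    def clean(v: str) -> str:
        v = gemmi.cif.as_string(v)
        return "" if v in (".", "?") else v

    atoms: list[AtomRecord] = []
    for row in site:
        element = clean(row[2]).upper()
        if element in ("H", "D"):
            continue
        try:
            atoms.append(AtomRecord(
                serial=int(row[1]),
                atom_name=clean(row[3]),
                element=element,
                residue_name=clean(row[5]),
                chain_id=clean(row[6]),
                residue_number=int(row[7]),
                insertion_code=clean(row[8]) if row.has(8) else "",
                altloc=clean(row[4]),
                occupancy=float(row[12]),
                coordinates=np.array([float(row[9]), float(row[10]), float(row[11])]),
                b_factor=float(row[13]),
                is_hetero=(clean(row[0]) == "HETATM"),
            ))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: bad _atom_site row ({exc})") from exc

    resolution = _cif_float(block, "_refine.ls_d_res_high")
    r_free = _cif_float(block, "_refine.ls_R_factor_R_free")

    opers: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    oper_tags = ["id"]
    for i in (1, 2, 3):
        oper_tags += [f"matrix[{i}][1]", f"matrix[{i}][2]", f"matrix[{i}][3]", f"vector[{i}]"]
    tab = block.find("_pdbx_struct_oper_list.", oper_tags)
    for row in tab:
        vals = [float(row[j]) for j in range(1, 13)]
        rot = np.array([vals[0:3], vals[4:7], vals[8:11]])
        vec = np.array([vals[3], vals[7], vals[11]])
        opers[gemmi.cif.as_string(row[0])] = (rot, vec)

    assemblies: list[AssemblyOperatorSet] = []
    gen_tab = block.find("_pdbx_struct_assembly_gen.",
                         ["assembly_id", "oper_expression", "asym_id_list"])
    for row in gen_tab:
        asm_id = gemmi.cif.as_string(row[0])
        expr = gemmi.cif.as_string(row[1])
        chains = tuple(c for c in gemmi.cif.as_string(row[2]).split(",") if c)
        op_ids = [t for t in re.split(r"[,()]", expr) if t.strip()]
        expanded: list[str] = []
        for tok in op_ids:
            tok = tok.strip()
            if "-" in tok and all(p.strip().isdigit() for p in tok.split("-", 1)):
                lo, hi = (int(p) for p in tok.split("-", 1))
                expanded.extend(str(k) for k in range(lo, hi + 1))
            else:
                expanded.append(tok)
        rots, trans = [], []
        for oid in expanded:
            if oid not in opers:
                raise FormatError(f"{path}: assembly {asm_id} references unknown operator {oid}")
            rots.append(opers[oid][0])
            trans.append(opers[oid][1])
        if rots:
            assemblies.append(AssemblyOperatorSet(
                assembly_id=asm_id, chains=chains,
                rotations=np.array(rots), translations=np.array(trans),
            ))

    ssbonds = []
    conn_tab = block.find("_struct_conn.", [
        "conn_type_id", "ptnr1_auth_asym_id", "ptnr1_auth_seq_id",
        "?pdbx_ptnr1_PDB_ins_code", "ptnr2_auth_asym_id", "ptnr2_auth_seq_id",
        "?pdbx_ptnr2_PDB_ins_code",
    ])
    for row in conn_tab:
        if gemmi.cif.as_string(row[0]).lower() != "disulf":
            continue
        ic1 = clean(row[3]) if row.has(3) else ""
        ic2 = clean(row[6]) if row.has(6) else ""
        ssbonds.append((
            (clean(row[1]), int(row[2]), ic1),
            (clean(row[4]), int(row[5]), ic2),
        ))

    model = StructureModel(
        entry_id=entry_id,
        atoms=_dedupe_altlocs(atoms),
        resolution=resolution,
        r_free=r_free,
        assemblies=assemblies,
        ssbond_pairs=ssbonds,
    )
    model.validate()
    return model


def read_structure(path: str | Path, dialect: str | None = None) -> StructureModel:
    """Read a structure file into a :class:`StructureModel`.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"pdb"`` or ``"mmcif"``. Guessed from the file suffix when omitted
        (``.cif`` → mmCIF, anything else → PDB).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if dialect == "pdb":
        return _read_pdb(path)
    if dialect == "mmcif":
        return _read_mmcif(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'pdb' or 'mmcif'")


# ---------------------------------------------------------------------------
# writing


def _pdb_atom_line(a: AtomRecord) -> str:
    record = "HETATM" if a.is_hetero else "ATOM"
    name = a.atom_name
    # standard PDB alignment: 1-3 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    x, y, z = a.coordinates
    return (
        f"{record:<6s}{a.serial % 100000:>5d} {name_field}{a.altloc or ' ':1s}"
        f"{a.residue_name:>3s} {a.chain_id[:1]:1s}{a.residue_number:>4d}"
        f"{a.insertion_code or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
        f"          {a.element:>2s}"
    )


def _write_pdb(model: StructureModel, path: Path) -> None:
    lines: list[str] = []
    if model.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {model.resolution:.2f} ANGSTROMS.")
    if model.r_free is not None:
        lines.append("REMARK   3 REFINEMENT.")
        lines.append(f"REMARK   3   FREE R VALUE                     : {model.r_free:.3f}")
    for asm in model.assemblies:
        lines.append(f"REMARK 350 BIOMOLECULE: {asm.assembly_id}")
        chains = ", ".join(asm.chains) if asm.chains else ", ".join(
            sorted({a.chain_id for a in model.atoms}))
        lines.append(f"REMARK 350 APPLY THE FOLLOWING TO CHAINS: {chains}")
        for k, (rot, vec) in enumerate(zip(asm.rotations, asm.translations), start=1):
            for i in range(3):
                lines.append(
                    f"REMARK 350   BIOMT{i + 1} {k:>3d}"
                    f"{rot[i, 0]:10.6f}{rot[i, 1]:10.6f}{rot[i, 2]:10.6f}"
                    f"{vec[i]:15.5f}"
                )
    for n, (p1, p2) in enumerate(model.ssbond_pairs, start=1):
        lines.append(
            f"SSBOND{n:>4d} CYS {p1[0][:1]:1s} {p1[1]:>4d}{p1[2] or ' ':1s}"
            f"   CYS {p2[0][:1]:1s} {p2[1]:>4d}{p2[2] or ' ':1s}"
        )
    lines.extend(_pdb_atom_line(a) for a in model.atoms)
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _write_mmcif(model: StructureModel, path: Path) -> None:
    out: list[str] = [f"data_{model.entry_id}", f"_entry.id {model.entry_id}"]
    if model.resolution is not None:
        out.append(f"_refine.ls_d_res_high {model.resolution:.2f}")
    if model.r_free is not None:
        out.append(f"_refine.ls_R_factor_R_free {model.r_free:.3f}")
    if model.assemblies:
        out.append("loop_\n_pdbx_struct_assembly.id")
        for aid in dict.fromkeys(a.assembly_id for a in model.assemblies):
            out.append(str(aid))
        out.append("loop_")
        out.append("_pdbx_struct_assembly_gen.assembly_id")
        out.append("_pdbx_struct_assembly_gen.oper_expression")
        out.append("_pdbx_struct_assembly_gen.asym_id_list")
        oper_rows: list[str] = []
        next_op = 1
        for asm in model.assemblies:
            ids = list(range(next_op, next_op + len(asm.rotations)))
            next_op += len(asm.rotations)
            chains = ",".join(asm.chains) if asm.chains else ",".join(
                sorted({a.chain_id for a in model.atoms}))
            out.append(f"{asm.assembly_id} '{','.join(map(str, ids))}' {chains}")
            for oid, rot, vec in zip(ids, asm.rotations, asm.translations):
                vals = []
                for i in range(3):
                    vals += [f"{rot[i, j]:.6f}" for j in range(3)] + [f"{vec[i]:.5f}"]
                oper_rows.append(f"{oid} " + " ".join(vals))
        out.append("loop_\n_pdbx_struct_oper_list.id")
        for i in (1, 2, 3):
            for j in (1, 2, 3):
                out.append(f"_pdbx_struct_oper_list.matrix[{i}][{j}]")
            out.append(f"_pdbx_struct_oper_list.vector[{i}]")
        out.extend(oper_rows)
    if model.ssbond_pairs:
        out.append("loop_")
        for tag in ("id", "conn_type_id", "ptnr1_auth_asym_id", "ptnr1_auth_seq_id",
                    "pdbx_ptnr1_PDB_ins_code", "ptnr2_auth_asym_id", "ptnr2_auth_seq_id",
                    "pdbx_ptnr2_PDB_ins_code"):
            out.append(f"_struct_conn.{tag}")
        for n, (p1, p2) in enumerate(model.ssbond_pairs, start=1):
            out.append(
                f"disulf{n} disulf {p1[0]} {p1[1]} {p1[2] or '?'} "
                f"{p2[0]} {p2[1]} {p2[2] or '?'}"
            )
    out.append("loop_")
    for tag in ("group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
                "label_comp_id", "auth_asym_id", "auth_seq_id", "pdbx_PDB_ins_code",
                "Cartn_x", "Cartn_y", "Cartn_z", "occupancy", "B_iso_or_equiv"):
        out.append(f"_atom_site.{tag}")
    for a in model.atoms:
        x, y, z = a.coordinates
        out.append(
            f"{'HETATM' if a.is_hetero else 'ATOM'} {a.serial} {a.element} "
            f"{a.atom_name} {a.altloc or '.'} {a.residue_name} {a.chain_id} "
            f"{a.residue_number} {a.insertion_code or '?'} "
            f"{x:.3f} {y:.3f} {z:.3f} {a.occupancy:.2f} {a.b_factor:.2f}"
        )
    path.write_text("\n".join(out) + "\n")


def write_structure(model: StructureModel, path: str | Path,
                    dialect: str | None = None) -> Path:
    """Write ``model`` as a single-model PDB or mmCIF file."""
    path = Path(path)
    if dialect is None:
        dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if dialect == "pdb":
        _write_pdb(model, path)
    elif dialect == "mmcif":
        _write_mmcif(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'pdb' or 'mmcif'")
    return path


# ---------------------------------------------------------------------------
# assembly construction and disulfide detection


def build_first_assembly(model: StructureModel) -> BioAssembly:
    """Apply the first-listed assembly's operators to their target chains.

    "First" means the first assembly identifier in file order. A model with no
    operator block yields the asymmetric unit (operator count 1) with a logged
    warning.
    """
    if not model.assemblies:
        logger.warning("%s: no assembly operators; using asymmetric unit", model.entry_id)
        return BioAssembly(
            entry_id=model.entry_id,
            atoms=[_copy_atom(a, a.coordinates) for a in model.atoms],
            copy_index=[0] * len(model.atoms),
            operator_count=1,
        )

    first_id = model.assemblies[0].assembly_id
    generators = [a for a in model.assemblies if a.assembly_id == first_id]

    atoms: list[AtomRecord] = []
    copy_index: list[int] = []
    copy = 0
    n_ops = 0
    for gen in generators:
        targets = [a for a in model.atoms
                   if not gen.chains or a.chain_id in gen.chains]
        for rot, vec in zip(gen.rotations, gen.translations):
            for a in targets:
                atoms.append(_copy_atom(a, rot @ a.coordinates + vec))
            copy_index.extend([copy] * len(targets))
            copy += 1
            n_ops += 1
    return BioAssembly(
        entry_id=model.entry_id,
        atoms=atoms,
        copy_index=copy_index,
        operator_count=n_ops,
    )


def _copy_atom(a: AtomRecord, coords: np.ndarray) -> AtomRecord:
    return AtomRecord(
        serial=a.serial, atom_name=a.atom_name, element=a.element,
        residue_name=a.residue_name, chain_id=a.chain_id,
        residue_number=a.residue_number, coordinates=np.asarray(coords, float).copy(),
        insertion_code=a.insertion_code, altloc=a.altloc,
        occupancy=a.occupancy, b_factor=a.b_factor, is_hetero=a.is_hetero,
    )


def detect_disulfides(
    model: StructureModel,
    sg_cutoff: float = DISULFIDE_SG_CUTOFF,
) -> list[tuple[ResidueId, ResidueId]]:
    """Disulfide pairs: union of SSBOND records and geometric SG–SG contacts.

    Two cysteine-family SG atoms within ``sg_cutoff`` Å are treated as bonded
    even without an SSBOND record (covalent S–S is ~2.05 Å).
    """
    pairs: dict[frozenset, tuple[ResidueId, ResidueId]] = {}
    for p1, p2 in model.ssbond_pairs:
        pairs[frozenset((p1, p2))] = (p1, p2)

    sg = [(a.residue_id, a.coordinates) for a in model.atoms
          if a.atom_name == "SG" and a.residue_name in CYS_FAMILY]
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            if sg[i][0] == sg[j][0]:
                continue
            if np.linalg.norm(sg[i][1] - sg[j][1]) <= sg_cutoff:
                pairs.setdefault(frozenset((sg[i][0], sg[j][0])), (sg[i][0], sg[j][0]))
    return list(pairs.values())
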