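"""Structure reading/writing, assembly construction and disulfide detection."""

import logging

import numpy as np
import pytest

from oxcys.structure_io import (
    AssemblyOperatorSet,
    AtomRecord,
    StructureModel,
    ValidationError,
    build_first_assembly,
    detect_disulfides,
    read_structure,
    write_structure,
)

from conftest import FIVE_ATOM_COORDS, FIVE_ATOM_PDB


def test_read_pdb_captures_atoms_and_header(five_atom_pdb):
    model = read_structure(five_atom_pdb)
    assert len(model.atoms) == 5
    np.testing.assert_allclose(model.coordinates, FIVE_ATOM_COORDS, atol=1e-6)
    assert model.resolution == pytest.approx(1.80)
    assert model.r_free == pytest.approx(0.220)
    assert model.atoms[4].is_hetero and model.atoms[4].residue_name == "HOH"
    assert not model.atoms[0].is_hetero


def test_missing_metadata_stays_absent(tmp_path):
    path = tmp_path / "bare.pdb"
    path.write_text(
        "ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00 10.00"
        "           N\nEND\n"
    )
    model = read_structure(path)
    assert model.resolution is None
    assert model.r_free is None


@pytest.mark.parametrize("dialect", ["pdb", "mmcif"])
def test_write_read_round_trip(five_atom_pdb, tmp_path, dialect):
    model = read_structure(five_atom_pdb)
    suffix = ".pdb" if dialect == "pdb" else ".cif"
    out = tmp_path / f"rt{suffix}"
    write_structure(model, out, dialect)
    again = read_structure(out, dialect)
    np.testing.assert_allclose(model.coordinates, again.coordinates, atol=1e-3)
    assert again.resolution == model.resolution
    assert again.r_free == model.r_free
    for a, b in zip(model.atoms, again.atoms):
        assert (a.atom_name, a.residue_name, a.chain_id, a.residue_number,
                a.is_hetero) == (b.atom_name, b.residue_name, b.chain_id,
                                 b.residue_number, b.is_hetero)


def test_dialect_equivalence(five_atom_pdb, tmp_path):
    """The same content expressed as PDB and as mmCIF parses identically."""
    model = read_structure(five_atom_pdb)
    cif = tmp_path / "same.cif"
    write_structure(model, cif, "mmcif")
    other = read_structure(cif, "mmcif")
    np.testing.assert_allclose(model.coordinates, other.coordinates, atol=1e-6)
    assert [a.atom_name for a in model.atoms] == [a.atom_name for a in other.atoms]
    assert [a.element for a in model.atoms] == [a.element for a in other.atoms]
    assert (model.resolution, model.r_free) == (other.resolution, other.r_free)


def test_altloc_keeps_highest_occupancy(tmp_path):
    path = tmp_path / "alt.pdb"
    path.write_text(
        "ATOM      1  SG ACYS A   1       0.000   0.000   0.000  0.60 10.00"
        "           S\n"
        "ATOM      2  SG BCYS A   1       1.000   0.000   0.000  0.40 10.00"
        "           S\nEND\n"
    )
    model = read_structure(path)
    assert len(model.atoms) == 1
    assert model.atoms[0].altloc == "A"
    assert model.atoms[0].occupancy == pytest.approx(0.6)


def test_altloc_tie_breaks_alphabetically(tmp_path):
    path = tmp_path / "tie.pdb"
    path.write_text(
        "ATOM      1  SG BCYS A   1       1.000   0.000   0.000  0.50 10.00"
        "           S\n"
        "ATOM      2  SG ACYS A   1       0.000   0.000   0.000  0.50 10.00"
        "           S\nEND\n"
    )
    model = read_structure(path)
    assert len(model.atoms) == 1
    assert model.atoms[0].altloc == "A"


def test_unknown_dialect_and_missing_file(five_atom_pdb, tmp_path):
    with pytest.raises(ValueError, match="dialect"):
        read_structure(five_atom_pdb, dialect="xyz")
    with pytest.raises(FileNotFoundError):
        read_structure(tmp_path / "absent.pdb")


def _tiny_model(assemblies=None):
    coords = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [1.5, 1.5, 0.0]])
    atoms = [
        AtomRecord(serial=i + 1, atom_name=n, element=n[0], residue_name="GLY",
                   chain_id="A", residue_number=1, coordinates=c)
        for i, (n, c) in enumerate(zip(("N", "CA", "C"), coords))
    ]
    return StructureModel(entry_id="TINY", atoms=atoms, assemblies=assemblies or [])


def test_identity_operator_preserves_coordinates():
    model = _tiny_model([AssemblyOperatorSet("1", (), np.eye(3)[None], np.zeros((1, 3)))])
    asm = build_first_assembly(model)
    assert asm.operator_count == 1
    np.testing.assert_allclose(asm.coordinates, model.coordinates, atol=1e-12)


def test_two_operator_assembly_matches_hand_applied_matrices():
    rot = np.array([[-1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, 1.0]])
    vec = np.array([10.0, 0.0, 0.0])
    ops = AssemblyOperatorSet("1", ("A",),
                              np.stack([np.eye(3), rot]),
                              np.stack([np.zeros(3), vec]))
    model = _tiny_model([ops])
    asm = build_first_assembly(model)
    assert len(asm.atoms) == 6
    assert asm.operator_count == 2
    expected = np.vstack([model.coordinates,
                          (rot @ model.coordinates.T).T + vec])
    np.testing.assert_allclose(asm.coordinates, expected, atol=1e-6)
    assert asm.copy_index == [0, 0, 0, 1, 1, 1]


def test_no_operator_block_falls_back_to_asymmetric_unit(caplog):
    model = _tiny_model()
    with caplog.at_level(logging.WARNING):
        asm = build_first_assembly(model)
    assert asm.operator_count == 1
    np.testing.assert_allclose(asm.coordinates, model.coordinates)
    assert any("asymmetric unit" in r.message for r in caplog.records)


def test_rigid_transform_preserves_intra_copy_distances():
    theta = np.radians(73.0)
    rot = np.array([
        [np.cos(theta), -np.sin(theta), 0.0],
        [np.sin(theta), np.cos(theta), 0.0],
        [0.0, 0.0, 1.0],
    ])
    ops = AssemblyOperatorSet("1", (), np.stack([np.eye(3), rot]),
                              np.stack([np.zeros(3), np.array([3.0, -2.0, 7.0])]))
    model = _tiny_model([ops])
    asm = build_first_assembly(model)
    ref = model.coordinates
    ref_d = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
    for copy in (0, 1):
        idx = [i for i, c in enumerate(asm.copy_index) if c == copy]
        pts = asm.coordinates[idx]
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.testing.assert_allclose(d, ref_d, atol=1e-6)


def test_non_orthonormal_rotation_rejected():
    with pytest.raises(ValidationError, match="orthonormal|determinant"):
        AssemblyOperatorSet("1", (), 2.0 * np.eye(3)[None], np.zeros((1, 3)))


def _two_cys_model(sg_distance, with_ssbond=False):
    atoms = []
    for i, x in enumerate((0.0, sg_distance)):
        atoms.append(AtomRecord(
            serial=2 * i + 1, atom_name="CB", element="C", residue_name="CYS",
            chain_id="A", residue_number=i + 1,
            coordinates=np.array([x, 1.8, 0.0])))
        atoms.append(AtomRecord(
            serial=2 * i + 2, atom_name="SG", element="S", residue_name="CYS",
            chain_id="A", residue_number=i + 1,
            coordinates=np.array([x, 0.0, 0.0])))
    ssbonds = [(("A", 1, ""), ("A", 2, ""))] if with_ssbond else []
    return StructureModel(entry_id="SS", atoms=atoms, ssbond_pairs=ssbonds)


def test_ssbond_record_reported():
    model = _two_cys_model(3.5, with_ssbond=True)
    assert detect_disulfides(model) == [(("A", 1, ""), ("A", 2, ""))]


def test_geometric_disulfide_at_bond_distance():
    model = _two_cys_model(2.05)
    pairs = detect_disulfides(model)
    assert {frozenset(p) for p in pairs} == {frozenset(((("A", 1, "")), ("A", 2, "")))}


def test_no_disulfide_beyond_cutoff():
    assert detect_disulfides(_two_cys_model(3.50)) == []


def test_duplicate_atoms_rejected():
    a = AtomRecord(serial=1, atom_name="CA", element="C", residue_name="GLY",
                   chain_id="A", residue_number=1, coordinates=np.zeros(3))
    b = AtomRecord(serial=2, atom_name="CA", element="C", residue_name="GLY",
                   chain_id="A", residue_number=1, coordinates=np.ones(3))
    model = StructureModel(entry_id="DUP", atoms=[a, b])
    with pytest.raises(ValidationError, match="duplicate"):
        model.validate()


def test_unparseable_file_names_format(tmp_path):
    bad = tmp_path / "bad.cif"
    bad.write_text("loop_\n_atom_site.id\n")  # loop without values
    from oxcys.structure_io import FormatError
    with pytest.raises(FormatError):
        read_structure(bad, "mmcif")
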