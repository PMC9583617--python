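"""Neighbor extraction, profiles, hydrogen-bond partners and chi1 rotamers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxcys.dataset import CysSite, classify_cysteines
from oxcys.microenvironment import (
    AMINO_ACIDS,
    StructuralError,
    chi1_rotamer,
    classify_hbond_partners,
    compute_profile,
    find_neighbors,
    neighbor_category,
    rotamer_class,
    uniform_background,
)
from oxcys.structure_io import AtomRecord, BioAssembly, build_first_assembly, read_structure
from oxcys.synthetic import NeighborPlacement, SyntheticSpec, make_site_fixture


# ---------------------------------------------------------------------------
# helpers


def brute_force_neighbors(assembly, site, cutoff):
    """Independent O(n^2) oracle: per-residue minimum distance scan."""
    best = {}
    own = (site.copy_index, *site.residue_id)
    for copy, atom in zip(assembly.copy_index, assembly.atoms):
        key = (copy, atom.chain_id, atom.residue_number,
               atom.insertion_code, atom.residue_name)
        if (copy, *atom.residue_id) == own:
            continue
        d = float(np.sqrt(np.sum((atom.coordinates - site.sg_coordinates) ** 2)))
        if d <= cutoff and (key not in best or d < best[key]):
            best[key] = d
    return best


def random_assembly(seed, n_atoms=500, box=25.0):
    """A random point cloud grouped into residues, with one CYS site."""
    rng = np.random.default_rng(seed)
    atoms = [AtomRecord(serial=1, atom_name="SG", element="S", residue_name="CYS",
                        chain_id="A", residue_number=1,
                        coordinates=rng.uniform(5, box - 5, 3))]
    resnames = list(AMINO_ACIDS) + ["HOH", "LIG"]
    for i in range(n_atoms - 1):
        resnum = 2 + i // 3
        atoms.append(AtomRecord(
            serial=i + 2,
            atom_name=f"X{i % 3}",
            element="C",
            residue_name=resnames[int(rng.integers(len(resnames)))] if i % 3 == 0
            else None or resnames[int(rng.integers(len(resnames)))],
            chain_id="A",
            residue_number=resnum,
            coordinates=rng.uniform(0, box, 3),
        ))
    # make residue names consistent within each residue
    by_res = {}
    for a in atoms:
        by_res.setdefault(a.residue_number, a.residue_name)
        a.residue_name = by_res[a.residue_number]
    assembly = BioAssembly(entry_id=f"R{seed}", atoms=atoms,
                           copy_index=[0] * len(atoms), operator_count=1)
    site = CysSite(entry_id=f"R{seed}", chain_id="A", residue_number=1,
                   insertion_code="", state="CYS",
                   sg_coordinates=atoms[0].coordinates)
    return assembly, site


# ---------------------------------------------------------------------------
# find_neighbors


def _single_site(tmp_path, spec):
    pdb, _ = make_site_fixture(spec, tmp_path)
    model = read_structure(pdb)
    asm = build_first_assembly(model)
    site = [s for s in classify_cysteines(asm, []) if s.state == spec.state][0]
    return asm, site


def test_his_at_cutoff_boundary_included(tmp_path):
    asm, site = _single_site(tmp_path, SyntheticSpec(
        state="CYS", neighbors=[NeighborPlacement("HIS", "ND1", 3.50)],
        random_seed=1, entry_id="N1"))
    records = find_neighbors(asm, site, cutoff=3.6)
    his = [r for r in records if r.neighbor_category == "HIS"]
    assert len(his) == 1
    assert his[0].min_distance == pytest.approx(3.50, abs=0.01)
    assert his[0].nearest_atom_name == "ND1"


def test_neighbor_beyond_cutoff_excluded(tmp_path):
    asm, site = _single_site(tmp_path, SyntheticSpec(
        state="CYS", neighbors=[NeighborPlacement("HIS", "ND1", 3.70)],
        random_seed=1, entry_id="N2"))
    assert not [r for r in find_neighbors(asm, site, cutoff=3.6)
                if r.neighbor_category == "HIS"]


@pytest.mark.parametrize("seed", range(10))
def test_matches_brute_force_scan(seed):
    assembly, site = random_assembly(seed)
    records = find_neighbors(assembly, site, cutoff=3.6)
    oracle = brute_force_neighbors(assembly, site, cutoff=3.6)
    assert {r.neighbor_residue: pytest.approx(r.min_distance) for r in records} == oracle


def test_own_residue_excluded(tmp_path):
    asm, site = _single_site(tmp_path, SyntheticSpec(
        state="OCS", random_seed=2, entry_id="N3"))
    own = (site.copy_index, *site.residue_id)
    assert all(r.neighbor_residue != own for r in find_neighbors(asm, site))


def test_cutoff_monotonicity():
    assembly, site = random_assembly(42)
    keys = {}
    for cutoff in (2.0, 3.0, 3.6, 5.0, 8.0):
        keys[cutoff] = {r.neighbor_residue for r in
                        find_neighbors(assembly, site, cutoff)}
    assert keys[2.0] <= keys[3.0] <= keys[3.6] <= keys[5.0] <= keys[8.0]


def test_missing_sulfur_raises():
    assembly, site = random_assembly(0)
    site.sg_coordinates = np.array([np.nan, 0.0, 0.0])
    with pytest.raises(StructuralError):
        find_neighbors(assembly, site)


def test_oxidized_neighbors_fold_into_cys_category():
    assert neighbor_category("CSO") == "CYS"
    assert neighbor_category("OCS") == "CYS"
    assert neighbor_category("HOH") == "HOH"
    assert neighbor_category("NAG") == "other"


# ---------------------------------------------------------------------------
# profiles


def _records(cats):
    from oxcys.microenvironment import NeighborRecord
    return [NeighborRecord(site_id=f"s{i}", state="CYS", neighbor_category=c,
                           neighbor_residue=(0, "A", i + 10, "", c),
                           nearest_atom_name="X", min_distance=3.0)
            for i, c in enumerate(cats)]


def test_profile_single_category():
    prof = compute_profile("CSO", _records(["HIS"] * 4), n_sites=4)
    assert prof.frequencies == {"HIS": 1.0}


def test_profile_hand_counted_example():
    prof = compute_profile("CSO", _records(["HIS", "HIS", "HIS", "THR"]), n_sites=2)
    assert prof.frequencies == pytest.approx({"HIS": 0.75, "THR": 0.25})
    assert prof.mean_neighbor_count == pytest.approx(2.0)


def test_enrichment_against_uniform_background():
    prof = compute_profile(
        "CSO", _records(["HIS"] * 3 + ["ALA"] * 17), n_sites=5)
    assert prof.frequencies["HIS"] == pytest.approx(0.15)
    assert prof.enrichment["HIS"] == pytest.approx(3.0)


def test_zero_sites_profile_is_empty_not_nan():
    prof = compute_profile("CSD", [], n_sites=0)
    assert prof.n_sites == 0
    assert prof.frequencies == {}
    assert prof.mean_neighbor_count == 0.0


def test_background_must_sum_to_one():
    bad = {aa: 0.04 for aa in AMINO_ACIDS}
    with pytest.raises(ValueError, match="background"):
        compute_profile("CYS", _records(["HIS"]), 1, background=bad)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.sampled_from(list(AMINO_ACIDS) + ["HOH", "other"]),
                min_size=1, max_size=60),
       st.integers(min_value=1, max_value=20))
def test_profile_frequencies_always_normalized(cats, n_sites):
    prof = compute_profile("CYS", _records(cats), n_sites)
    assert abs(sum(prof.frequencies.values()) - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# hydrogen-bond partners


def test_thr_hydroxyl_near_sulfenic_oxygen_is_sidechain_donor(tmp_path):
    asm, site = _single_site(tmp_path, SyntheticSpec(
        state="CSO", neighbors=[NeighborPlacement("THR", "OG1", 3.0, anchor="OD")],
        random_seed=3, entry_id="H1"))
    records = find_neighbors(asm, site)
    contacts = classify_hbond_partners(records, asm, site)
    roles = {(c.partner_residue[4], c.partner_role) for c in contacts}
    assert ("THR", "sidechain_donor") in roles


def test_gly_amide_near_sulfonate_oxygen_is_backbone_donor(tmp_path):
    asm, site = _single_site(tmp_path, SyntheticSpec(
        state="OCS", neighbors=[NeighborPlacement("GLY", "N", 3.0, anchor="OD2")],
        random_seed=3, entry_id="H2"))
    contacts = classify_hbond_partners(find_neighbors(asm, site), asm, site)
    assert any(c.partner_role == "backbone_amide_donor"
               and c.partner_residue[4] == "GLY" for c in contacts)


def test_nonpolar_atom_never_classified(tmp_path):
    asm, site = _single_site(tmp_path, SyntheticSpec(
        state="CYS", neighbors=[NeighborPlacement("LEU", "CD1", 3.0)],
        random_seed=3, entry_id="H3"))
    contacts = classify_hbond_partners(find_neighbors(asm, site), asm, site)
    assert not [c for c in contacts if c.partner_residue[4] == "LEU"]


def test_histidine_counts_as_donor_and_acceptor(tmp_path):
    asm, site = _single_site(tmp_path, SyntheticSpec(
        state="CYS", neighbors=[NeighborPlacement("HIS", "ND1", 3.2)],
        random_seed=3, entry_id="H4"))
    contacts = classify_hbond_partners(find_neighbors(asm, site), asm, site)
    his_roles = {c.partner_role for c in contacts if c.partner_residue[4] == "HIS"}
    assert his_roles == {"sidechain_donor", "sidechain_acceptor"}


# ---------------------------------------------------------------------------
# chi1 rotamers


@pytest.mark.parametrize("chi1,cls", [(180.0, "t"), (-60.0, "m"), (60.0, "p")])
def test_chi1_recovered_from_constructed_dihedral(chi1, cls):
    """Coordinates built from internal coordinates give back the set dihedral."""
    from oxcys.geometry import place_atom

    n = np.array([1.458, 0.0, 0.0])
    ca = np.zeros(3)
    cb = place_atom(np.array([0.0, -1.0, 0.5]), n, ca, 1.53, 110.4, -122.6)
    sg = place_atom(n, ca, cb, 1.81, 114.0, chi1)
    atoms = [
        AtomRecord(serial=i + 1, atom_name=name, element=name[0],
                   residue_name="CYS", chain_id="A", residue_number=1,
                   coordinates=xyz)
        for i, (name, xyz) in enumerate(
            (("N", n), ("CA", ca), ("CB", cb), ("SG", sg)))
    ]
    asm = BioAssembly(entry_id="CHI", atoms=atoms, copy_index=[0] * 4,
                      operator_count=1)
    site = CysSite(entry_id="CHI", chain_id="A", residue_number=1,
                   insertion_code="", state="CYS", sg_coordinates=sg)
    record = chi1_rotamer(asm, site)
    assert record.valid
    assert record.chi1 == pytest.approx(chi1, abs=0.01)
    assert record.rotamer_class == cls


@pytest.mark.parametrize("chi1,cls", [
    (-120.0, "m"), (-0.0, "p"), (119.99, "p"), (120.0, "t"),
    (180.0, "t"), (-179.9, "t"), (-120.01, "t"),
])
def test_rotamer_bin_edges(chi1, cls):
    assert rotamer_class(chi1) == cls


def test_missing_backbone_atom_flags_record(tmp_path):
    spec = SyntheticSpec(state="CYS", random_seed=5, entry_id="C5")
    pdb, _ = make_site_fixture(spec, tmp_path)
    lines = [l for l in pdb.read_text().splitlines()
             if not (" CB  CYS A  10" in l)]
    pdb.write_text("\n".join(lines) + "\n")
    model = read_structure(pdb)
    asm = build_first_assembly(model)
    site = [s for s in classify_cysteines(asm, []) if s.state == "CYS"][0]
    record = chi1_rotamer(asm, site)
    assert not record.valid
    assert record.rotamer_class is None
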