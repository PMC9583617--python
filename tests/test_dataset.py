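"""Entry selection, quality filtering and oxidation-state classification."""

import datetime as dt
import json

import numpy as np
import pytest

from oxcys.dataset import (
    EntryMeta,
    classify_cysteines,
    filter_entries,
    query_entries,
    read_manifest,
    state_counts,
)
from oxcys.structure_io import build_first_assembly, detect_disulfides, read_structure
from oxcys.synthetic import NeighborPlacement, SyntheticSpec, make_site_fixture


def _write_manifest(path, rows):
    header = "entry_id\tresolution\tr_free\tmethod\trelease_date\tcomponents\tuniprot"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


@pytest.fixture
def manifest(tmp_path):
    return _write_manifest(tmp_path / "manifest.tsv", [
        "1AAA\t1.9\t0.22\tX-RAY DIFFRACTION\t2015-05-01\tCSO\tP11111",
        "1BBB\t2.1\t0.25\tX-RAY DIFFRACTION\t2018-01-20\tCYS\tP22222",
        "1CCC\t2.4\t0.28\tX-RAY DIFFRACTION\t2020-07-07\tCSO;CSD\tP33333",
        "1DDD\t1.5\t0.19\tX-RAY DIFFRACTION\t2022-01-01\tOCS\t",
    ])


class TestQueryEntries:
    def test_component_selection(self, manifest):
        got = query_entries({"CSO"}, manifest=manifest)
        assert [e.entry_id for e in got] == ["1AAA", "1CCC"]

    def test_release_date_cutoff_is_inclusive_boundary(self, manifest):
        got = query_entries({"CSO", "OCS"}, date_cutoff=dt.date(2020, 7, 7),
                            manifest=manifest)
        assert [e.entry_id for e in got] == ["1AAA", "1CCC"]

    def test_duplicate_entries_collapse(self, tmp_path):
        m = _write_manifest(tmp_path / "dup.tsv", [
            "1AAA\t1.9\t0.22\tX-RAY\t2015-05-01\tCSO\t",
            "1AAA\t1.9\t0.22\tX-RAY\t2015-05-01\tCSO\t",
        ])
        assert len(query_entries({"CSO"}, manifest=m)) == 1

    def test_malformed_row_reported_not_fatal(self, tmp_path):
        m = _write_manifest(tmp_path / "bad.tsv", [
            "1AAA\t1.9\t0.22\tX-RAY\t2015-05-01\tCSO\t",
            "1BAD\tnot-a-number\t0.22\tX-RAY\t2015-05-01\tCSO\t",
        ])
        entries, errors = read_manifest(m)
        assert [e.entry_id for e in entries] == ["1AAA"]
        assert len(errors) == 1 and "resolution" in errors[0][1]


class TestFilterEntries:
    def test_strict_boundaries(self):
        entries = [
            EntryMeta("KEEP", resolution=2.49, r_free=0.29),
            EntryMeta("RES", resolution=2.50, r_free=0.29),
            EntryMeta("RFREE", resolution=2.49, r_free=0.31),
        ]
        kept, report = filter_entries(entries, 2.5, 0.30)
        assert [e.entry_id for e in kept] == ["KEEP"]
        assert set(report["entry_id"]) == {"RES", "RFREE"}

    def test_empty_input(self):
        kept, report = filter_entries([], 2.5, 0.30)
        assert kept == [] and len(report) == 0

    def test_missing_values_excluded_with_reason(self):
        entries = [EntryMeta("NORF", resolution=2.0, r_free=None),
                   EntryMeta("NORES", resolution=None, r_free=0.2)]
        kept, report = filter_entries(entries)
        assert kept == []
        reasons = dict(zip(report["entry_id"], report["reason"]))
        assert reasons == {"NORF": "missing_rfree", "NORES": "missing_resolution"}

    def test_idempotent_and_order_preserving(self):
        entries = [EntryMeta(f"E{i}", resolution=1.0 + 0.1 * i, r_free=0.2)
                   for i in range(10)]
        once, _ = filter_entries(entries)
        twice, _ = filter_entries(once)
        assert [e.entry_id for e in once] == [e.entry_id for e in twice]
        assert [e.entry_id for e in once] == [e.entry_id for e in entries
                                              if e.resolution < 2.5]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_entries([], max_resolution=0.0)


def _assembly_from_spec(spec, tmp_path):
    pdb, _ = make_site_fixture(spec, tmp_path)
    model = read_structure(pdb)
    return model, build_first_assembly(model)


class TestClassifyCysteines:
    @pytest.mark.parametrize("state,n_oxygens", [
        ("CYS", 0), ("CSO", 1), ("CSD", 2), ("OCS", 3),
    ])
    def test_oxygen_counts_per_state(self, tmp_path, state, n_oxygens):
        model, asm = _assembly_from_spec(
            SyntheticSpec(state=state, random_seed=1, entry_id="X1"), tmp_path)
        sites = [s for s in classify_cysteines(asm, []) if s.state == state]
        assert len(sites) == 1
        assert len(sites[0].oxygen_atoms) == n_oxygens
        assert not sites[0].malformed

    def test_disulfide_pair_relabelled_cyx(self, tmp_path):
        model, asm = _assembly_from_spec(
            SyntheticSpec(state="CYS", disulfide_partner=True, random_seed=2,
                          entry_id="X2"), tmp_path)
        sites = classify_cysteines(asm, detect_disulfides(model))
        assert sorted(s.state for s in sites) == ["CYX", "CYX"]
        assert all(not s.oxygen_atoms for s in sites)

    def test_oxygen_distance_fallback_for_nonstandard_names(self, tmp_path):
        """A sulfenic oxygen deposited under a legacy name is still attached."""
        spec = SyntheticSpec(state="CSO", random_seed=4, entry_id="X3")
        pdb, _ = make_site_fixture(spec, tmp_path)
        text = pdb.read_text().replace(" OD  CSO", " OE  CSO")
        pdb.write_text(text)
        model = read_structure(pdb)
        asm = build_first_assembly(model)
        sites = [s for s in classify_cysteines(asm, []) if s.state == "CSO"]
        assert len(sites) == 1 and not sites[0].malformed
        assert sites[0].oxygen_atoms[0][0] == "OE"

    def test_wrong_oxygen_count_flags_malformed(self, tmp_path):
        spec = SyntheticSpec(state="OCS", random_seed=5, entry_id="X4")
        pdb, _ = make_site_fixture(spec, tmp_path)
        lines = [l for l in pdb.read_text().splitlines()
                 if " OD3 OCS" not in l]
        pdb.write_text("\n".join(lines) + "\n")
        model = read_structure(pdb)
        sites = [s for s in classify_cysteines(build_first_assembly(model), [])
                 if s.state == "OCS"]
        assert len(sites) == 1 and sites[0].malformed

    def test_counting_conservation(self, small_cohort):
        """Summed per-state counts equal the number of cysteine-family residues."""
        total_sites = 0
        total_residues = 0
        for path in small_cohort["structures"]:
            model = read_structure(path)
            asm = build_first_assembly(model)
            sites = classify_cysteines(asm, detect_disulfides(model))
            total_sites += sum(state_counts(sites).values())
            total_residues += len([
                key for key, _ in asm.iter_residues()
                if key[4] in ("CYS", "CSO", "CSD", "OCS")
            ])
        assert total_sites == total_residues > 0

    def test_label_recovery_on_synthetic_cohort(self, small_cohort):
        """Ground-truth oxidation states are recovered for every site."""
        recovered = {}
        for path in small_cohort["structures"]:
            truth = json.loads(path.with_suffix(".json").read_text())
            model = read_structure(path)
            sites = classify_cysteines(build_first_assembly(model),
                                       detect_disulfides(model))
            main = [s for s in sites if s.residue_number
                    == truth["site"]["residue_number"]]
            assert len(main) == 1
            recovered[truth["entry_id"]] = (main[0].state == truth["state"])
        assert all(recovered.values())
        assert len(recovered) == 40

    def test_assembly_copies_counted_separately(self, tmp_path):
        rot = np.array([[-1.0, 0, 0], [0, -1.0, 0], [0, 0, 1.0]])
        spec = SyntheticSpec(
            state="CSD",
            assembly_operators=[(np.eye(3), np.zeros(3)),
                                (rot, np.array([25.0, 0.0, 0.0]))],
            random_seed=6, entry_id="X5")
        model, asm = _assembly_from_spec(spec, tmp_path)
        sites = [s for s in classify_cysteines(asm, []) if s.state == "CSD"]
        assert len(sites) == 2
        assert sorted(s.copy_index for s in sites) == [0, 1]
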