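"""Shared fixtures: hand-written structure files and synthetic cohorts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from oxcys.structure_io import build_first_assembly, read_structure
from oxcys.synthetic import CohortSpec, make_cohort

# five atoms with easily checked coordinates, plus header metadata
FIVE_ATOM_PDB = """\
REMARK   2 RESOLUTION.    1.80 ANGSTROMS.
REMARK   3 REFINEMENT.
REMARK   3   FREE R VALUE                     : 0.220
ATOM      1  N   CYS A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  CYS A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  CB  CYS A   1       2.009   1.427   0.000  1.00 10.00           C
ATOM      4  SG  CYS A   1       1.250   2.500   1.300  1.00 10.00           S
HETATM    5  O   HOH A 101       5.000   5.000   5.000  1.00 20.00           O
END
"""

FIVE_ATOM_COORDS = np.array([
    [0.000, 0.000, 0.000],
    [1.458, 0.000, 0.000],
    [2.009, 1.427, 0.000],
    [1.250, 2.500, 1.300],
    [5.000, 5.000, 5.000],
])


@pytest.fixture
def five_atom_pdb(tmp_path: Path) -> Path:
    path = tmp_path / "five.pdb"
    path.write_text(FIVE_ATOM_PDB)
    return path


def _load_assembly(path: Path):
    model = read_structure(path)
    return model, build_first_assembly(model)


@pytest.fixture(scope="session")
def enrichment_cohort(tmp_path_factory: pytest.TempPathFactory) -> dict:
    """The histidine-enrichment study cohort: 200 sites per state, seed 7.

    Oxidized sites receive a His neighbor with probability 0.6, reduced (CYS)
    sites with probability 0.2, a 3x programmed enrichment.
    """
    out_dir = tmp_path_factory.mktemp("cohort_enrichment")
    spec = CohortSpec(
        n_sites={"CYS": 200, "CSO": 200, "CSD": 200, "OCS": 200},
        enrichment={
            ("CSO", "HIS"): 0.6, ("CSD", "HIS"): 0.6, ("OCS", "HIS"): 0.6,
            ("CYS", "HIS"): 0.2,
        },
        random_seed=7,
    )
    summary = make_cohort(spec, out_dir)
    return {"dir": out_dir, **summary}


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory: pytest.TempPathFactory) -> dict:
    """A 10-site-per-state cohort for label-recovery and plumbing tests."""
    out_dir = tmp_path_factory.mktemp("cohort_small")
    spec = CohortSpec(
        n_sites={"CYS": 10, "CSO": 10, "CSD": 10, "OCS": 10},
        random_seed=3,
    )
    summary = make_cohort(spec, out_dir)
    return {"dir": out_dir, **summary}
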