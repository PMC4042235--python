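"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

import gridqsar as g
from gridqsar.chem import molecule_from_smiles

TSC_SMILES = "NC(=S)N/N=C/c1ccccc1"  # benzaldehyde thiosemicarbazone
# congener with 2 donors, 2 aromatic rings and an aliphatic linker, so a
# five-site donor/donor/hydrophobe/ring/ring geometry exists
DDHRR_SMILES = "NC(=S)N/N=C/c1ccc(CCc2ccccc2)cc1"


def random_rigid_motion(seed: int) -> tuple[np.ndarray, np.ndarray]:
    """A seeded proper rotation and translation."""
    rng = np.random.default_rng(seed)
    Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q, rng.uniform(-5.0, 5.0, 3)


def rigid_copy(mol, seed: int, new_id: str):
    R, t = random_rigid_motion(seed)
    out = mol.with_coords(mol.coords @ R.T + t)
    out.id = new_id
    return out


@pytest.fixture(scope="session")
def tsc_molecule():
    return molecule_from_smiles(TSC_SMILES, "tsc")


@pytest.fixture(scope="session")
def ddhrr_molecule():
    return molecule_from_smiles(DDHRR_SMILES, "act_0")


@pytest.fixture(scope="session")
def ddhrr_actives(ddhrr_molecule):
    """Three actives sharing an identical five-site feature geometry
    (rigid copies of one conformer)."""
    return [ddhrr_molecule,
            rigid_copy(ddhrr_molecule, 11, "act_1"),
            rigid_copy(ddhrr_molecule, 22, "act_2")]


@pytest.fixture(scope="session")
def series28():
    """The default synthetic congeneric series: 28 compounds, noiseless
    planted four-descriptor activity model."""
    return g.generate_congeneric_series(n=28, seed=42)


@pytest.fixture(scope="session")
def filtered28(series28):
    return g.filter_invariant_columns(series28.matrix, 0.1)
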