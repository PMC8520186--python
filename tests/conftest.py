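"""Shared fixtures: hand-built molecules, tiny synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from posescore import LigandMol, SyntheticSpec, planted_signal_dataset
from posescore.structio import ProteinAtom, ProteinStructure


def embed_smiles(smiles: str, seed: int = 11) -> LigandMol:
    """Heavy-atom LigandMol with ETKDG 3D coordinates."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    assert AllChem.EmbedMolecule(mol, randomSeed=seed) == 0
    return LigandMol.from_rdkit(Chem.RemoveHs(mol))


def hexagon_benzene(rotate_deg: float = 0.0) -> LigandMol:
    """Benzene with an ideal planar hexagon conformer (radius 1.39 A)."""
    base = embed_smiles("c1ccccc1")
    ang = np.deg2rad(np.arange(6) * 60.0 + rotate_deg)
    coords = np.stack([1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)], axis=1)
    return base.with_coords(coords)


def single_atom_protein(element: str = "C", xyz=(0.0, 0.0, 0.0),
                        res_name: str = "ALA", atom_name: str = "CB") -> ProteinStructure:
    atom = ProteinAtom(element, tuple(xyz), res_name, 1, "A", atom_name)
    return ProteinStructure(atoms=[atom], chains={"A": "A"})


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 small synthetic complexes shared across tests."""
    spec = SyntheticSpec(n_complexes=12, poses_per_complex=10, seed=42)
    return planted_signal_dataset(spec)


@pytest.fixture(scope="session")
def medium_dataset():
    """40 complexes for model-recovery sanity checks."""
    spec = SyntheticSpec(n_complexes=40, poses_per_complex=12, seed=7)
    return planted_signal_dataset(spec)
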