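"""Featurizers against brute-force oracles and invariance properties."""

import numpy as np
import pytest
from rdkit import Chem
from scipy.spatial.transform import Rotation

from posescore import (assemble_features, build_schema,
                       derive_ligand_type_vocabulary,
                       derive_protein_type_vocabulary, ecif_atom_type,
                       ecif_featurize, elem_featurize, ligand_control_featurize,
                       load_ligand_types, load_protein_types, protein_atom_type,
                       rank_feature, vina_terms, make_complex, SyntheticSpec)
from posescore.features import VDW_RADII, VINA_TERM_NAMES
from posescore.structio import (LIGAND_ELEMENTS, PROTEIN_ELEMENTS, LigandMol,
                                Pose, ProteinAtom, ProteinStructure)
from conftest import embed_smiles, single_atom_protein


def methane() -> LigandMol:
    mol = Chem.AddHs(Chem.MolFromSmiles("C"))
    from rdkit.Chem import AllChem
    AllChem.EmbedMolecule(mol, randomSeed=4)
    return LigandMol.from_rdkit(Chem.RemoveHs(mol))


# ---------------------------------------------------------------------------
# vocabularies and typing
# ---------------------------------------------------------------------------

def test_ecif_atom_type_examples():
    assert ecif_atom_type(methane(), 0) == "C;4;0;4;0;0"
    benzene = embed_smiles("c1ccccc1")
    assert ecif_atom_type(benzene, 0) == "C;4;2;1;1;1"
    # backbone carbonyl carbon, from the alanine template
    assert protein_atom_type("ALA", "C") == "C;4;3;0;0;0"
    assert protein_atom_type("ALA", "ZZZ") is None


def test_out_of_alphabet_atom_excluded():
    mol = embed_smiles("CC[Si](C)(C)C")
    idx = mol.elements.index("Si")
    assert ecif_atom_type(mol, idx) is None


def test_protein_vocabulary_has_22_types_and_matches_package_data():
    derived = derive_protein_type_vocabulary()
    assert len(derived) == 22
    assert derived == set(load_protein_types())


def test_partial_template_set_gives_subset():
    gly_only = derive_protein_type_vocabulary(["GLY"])
    full = derive_protein_type_vocabulary()
    assert gly_only < full
    assert derive_protein_type_vocabulary(["GLY", "GLY", "ALA", "ALA"]) == \
           derive_protein_type_vocabulary(["GLY", "ALA"])


def test_ligand_vocabulary_has_71_types_and_matches_package_data():
    derived = derive_ligand_type_vocabulary()
    assert len(derived) == 71
    assert derived == load_ligand_types()


def test_schema_block_lengths():
    assert len(build_schema(["elem"])) == 36
    assert len(build_schema(["ecif"])) == 22 * 71 == 1562
    assert len(build_schema(["vina"])) == 5
    assert len(build_schema(["ecif", "vina", "rank"])) == 1568
    with pytest.raises(ValueError):
        build_schema([])
    with pytest.raises(ValueError):
        build_schema(["nope"])


# ---------------------------------------------------------------------------
# ELEM
# ---------------------------------------------------------------------------

def test_elem_single_pair():
    receptor = single_atom_protein("C")
    lig = methane().with_coords(np.array([[3.0, 0.0, 0.0]]))
    vec = elem_featurize(receptor, lig)
    names = build_schema(["elem"]).names
    nonzero = {names[i]: v for i, v in enumerate(vec) if v}
    assert nonzero == {"ELEM::C-C": 1.0}


def test_elem_cutoff_inclusive_and_beyond():
    receptor = single_atom_protein("C")
    at_cut = methane().with_coords(np.array([[6.0, 0.0, 0.0]]))
    beyond = methane().with_coords(np.array([[6.5, 0.0, 0.0]]))
    assert elem_featurize(receptor, at_cut).sum() == 1.0    # <= 6.0 counts
    assert elem_featurize(receptor, beyond).sum() == 0.0


def _brute_elem(receptor, mol, cutoff=6.0):
    counts = {}
    for pa in receptor.atoms:
        for la, lxyz in zip(mol.atoms, mol.coords):
            if pa.element in PROTEIN_ELEMENTS and la.element in LIGAND_ELEMENTS:
                d = np.linalg.norm(np.array(pa.xyz) - lxyz)
                if d <= cutoff:
                    counts[(pa.element, la.element)] = counts.get((pa.element, la.element), 0) + 1
    vec = np.zeros(36)
    for k, (p, l) in enumerate([(p, l) for p in PROTEIN_ELEMENTS for l in LIGAND_ELEMENTS]):
        vec[k] = counts.get((p, l), 0)
    return vec


def _brute_ecif(receptor, mol, cutoff=6.0):
    p_types = load_protein_types()
    l_types = load_ligand_types()
    counts = np.zeros((22, 71))
    for pa in receptor.atoms:
        pk = protein_atom_type(pa.res_name, pa.atom_name)
        if pk not in p_types:
            continue
        for j, lxyz in enumerate(mol.coords):
            lk = ecif_atom_type(mol, j)
            if lk not in l_types:
                continue
            if np.linalg.norm(np.array(pa.xyz) - lxyz) <= cutoff:
                counts[p_types.index(pk), l_types.index(lk)] += 1
    return counts.ravel()


def _brute_vina(receptor, mol):
    from posescore.features import _protein_lookup
    lookup = _protein_lookup()
    nbr = mol.neighbors()
    terms = np.zeros(5)
    for pa in receptor.atoms:
        info = lookup.get((pa.res_name, pa.atom_name))
        for j, la in enumerate(mol.atoms):
            r = float(np.linalg.norm(np.array(pa.xyz) - mol.coords[j]))
            if r > 8.0:
                continue
            d = r - VDW_RADII[pa.element] - VDW_RADII[la.element]
            terms[0] += np.exp(-((d / 0.5) ** 2))
            terms[1] += np.exp(-(((d - 3.0) / 2.0) ** 2))
            if d < 0:
                terms[2] += d * d
            p_hydro = info.hydrophobic if info else False
            l_hydro = la.element == "C" and not any(
                mol.atoms[k].element in "NOS" for k in nbr[j])
            if p_hydro and l_hydro:
                terms[3] += 1.0 if d <= 0.5 else (0.0 if d >= 1.5 else (1.5 - d))
            p_don = info.donor if info else pa.element in ("N", "O")
            p_acc = info.acceptor if info else pa.element in ("N", "O")
            l_don = la.element in ("N", "O") and la.n_h > 0
            l_acc = la.element in ("N", "O")
            if (p_don and l_acc) or (p_acc and l_don):
                terms[4] += 1.0 if d <= -0.7 else (0.0 if d >= 0 else -d / 0.7)
    return terms


@pytest.mark.parametrize("seed", range(8))
def test_pair_count_features_match_brute_force(seed):
    ps = make_complex(SyntheticSpec(n_complexes=1, poses_per_complex=3, seed=seed), 0)
    for pose in ps.poses[:2]:
        assert np.array_equal(elem_featurize(ps.receptor, pose.mol),
                              _brute_elem(ps.receptor, pose.mol))
        assert np.array_equal(ecif_featurize(ps.receptor, pose.mol),
                              _brute_ecif(ps.receptor, pose.mol))
        assert vina_terms(ps.receptor, pose.mol) == pytest.approx(
            _brute_vina(ps.receptor, pose.mol), abs=1e-9)


# ---------------------------------------------------------------------------
# Vina functional forms
# ---------------------------------------------------------------------------

def test_vina_terms_at_surface_contact():
    # C-C pair at exactly r = R_C + R_C: d = 0
    receptor = single_atom_protein("C", res_name="ALA", atom_name="CB")
    lig = methane().with_coords(np.array([[2 * VDW_RADII["C"], 0.0, 0.0]]))
    g1, g2, rep, hyd, hb = vina_terms(receptor, lig)
    assert g1 == pytest.approx(1.0, abs=1e-12)
    assert rep == 0.0
    assert g2 == pytest.approx(np.exp(-(3.0 / 2.0) ** 2), abs=1e-12)
    assert hyd == pytest.approx(1.0)     # CB(Ala) and CH4 are both hydrophobic
    assert hb == 0.0


def test_vina_terms_zero_beyond_cutoff():
    receptor = single_atom_protein("C")
    lig = methane().with_coords(np.array([[8.5, 0.0, 0.0]]))
    assert np.all(vina_terms(receptor, lig) == 0.0)


def test_hbond_pair_requires_donor_acceptor():
    # Ser OG (donor+acceptor) against a carbonyl O at contact distance
    receptor = single_atom_protein("O", res_name="SER", atom_name="OG")
    aceto = embed_smiles("CC(C)=O")
    o_idx = aceto.elements.index("O")
    coords = aceto.coords - aceto.coords[o_idx] + np.array([3.0, 0.0, 0.0])
    shifted = aceto.with_coords(coords)
    hb = vina_terms(receptor, shifted)[4]
    assert hb > 0.0


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------

def _permute_ligand(mol: LigandMol, rng) -> LigandMol:
    perm = rng.permutation(len(mol))
    inv = np.argsort(perm)
    from posescore.structio import Bond
    atoms = [mol.atoms[p] for p in perm]
    bonds = [Bond(int(inv[b.i]), int(inv[b.j]), b.order, b.aromatic) for b in mol.bonds]
    return LigandMol(atoms=atoms, bonds=bonds)


def test_atom_order_permutation_invariance():
    rng = np.random.default_rng(0)
    ps = make_complex(SyntheticSpec(seed=9), 0)
    mol = ps.poses[0].mol
    shuffled_l = _permute_ligand(mol, rng)
    p_perm = rng.permutation(len(ps.receptor))
    shuffled_r = ProteinStructure(atoms=[ps.receptor.atoms[i] for i in p_perm],
                                  chains=ps.receptor.chains)
    for fn in (elem_featurize, ecif_featurize, vina_terms):
        assert fn(shuffled_r, shuffled_l) == pytest.approx(
            fn(ps.receptor, mol), abs=1e-9)


def test_joint_rigid_motion_invariance():
    ps = make_complex(SyntheticSpec(seed=2), 0)
    mol = ps.poses[0].mol
    rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    shift = np.array([5.0, -3.0, 2.0])
    moved_l = mol.with_coords(mol.coords @ rot.T + shift)
    moved_atoms = [ProteinAtom(a.element, tuple(np.array(a.xyz) @ rot.T + shift),
                               a.res_name, a.res_seq, a.chain_id, a.atom_name)
                   for a in ps.receptor.atoms]
    moved_r = ProteinStructure(atoms=moved_atoms, chains=ps.receptor.chains)
    for fn in (elem_featurize, ecif_featurize, vina_terms):
        assert fn(moved_r, moved_l) == pytest.approx(fn(ps.receptor, mol), abs=1e-9)


def test_count_monotonicity_in_cutoff():
    ps = make_complex(SyntheticSpec(seed=13), 0)
    mol = ps.poses[0].mol
    for fn in (elem_featurize, ecif_featurize):
        c4 = fn(ps.receptor, mol, cutoff=4.0)
        c6 = fn(ps.receptor, mol, cutoff=6.0)
        c8 = fn(ps.receptor, mol, cutoff=8.0)
        assert np.all(c4 <= c6) and np.all(c6 <= c8)


# ---------------------------------------------------------------------------
# rank + ligand control
# ---------------------------------------------------------------------------

def test_rank_feature_values_and_missing():
    mol = methane()
    assert rank_feature(Pose(mol=mol, dock_rank=1))[0] == 1.0
    assert rank_feature(Pose(mol=mol, dock_rank=17))[0] == 17.0
    assert np.isnan(rank_feature(Pose(mol=mol, is_crystal=True))[0])


def test_ligand_control_receptor_blind_and_conformation_sensitive():
    stretched = embed_smiles("CCCC", seed=1)
    coords = stretched.coords.copy()
    compact = stretched.with_coords(coords * np.array([0.6, 1.0, 1.0]))
    assert not np.allclose(ligand_control_featurize(stretched),
                           ligand_control_featurize(compact))
    # single atom: histogram all zero
    vec = ligand_control_featurize(methane())
    assert vec[len(LIGAND_ELEMENTS):-1].sum() == 0.0
    # receptor never enters the computation (signature takes only the ligand)
    same = ligand_control_featurize(stretched)
    assert np.allclose(same, ligand_control_featurize(stretched))


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def test_assemble_lengths_and_rank_policy(tiny_dataset):
    ps = tiny_dataset[0]
    table = assemble_features(ps, ["ecif", "vina", "rank"])
    feature_cols = [c for c in table.columns if "::" in c]
    assert len(feature_cols) == 1568
    assert len(table) == len(ps.poses)
    table36 = assemble_features(ps, ["elem"])
    assert sum("::" in c for c in table36.columns) == 36
    with pytest.raises(ValueError):
        assemble_features(ps, [])


def test_assemble_rank_requires_ranked_poses():
    from posescore.structio import PoseSet
    ps0 = make_complex(SyntheticSpec(seed=1, poses_per_complex=4), 0)
    crystal_only = PoseSet(ps0.complex_id, ps0.receptor_id, ps0.receptor,
                           ps0.reference,
                           [Pose(mol=ps0.reference, is_crystal=True)])
    with pytest.raises(ValueError, match="rank-free"):
        assemble_features(crystal_only, ["elem", "rank"])


def test_count_features_are_nonnegative_integers(tiny_dataset):
    ps = tiny_dataset[1]
    for pose in ps.poses[:2]:
        for fn in (elem_featurize, ecif_featurize):
            vec = fn(ps.receptor, pose.mol)
            assert np.all(vec >= 0)
            assert np.array_equal(vec, np.round(vec))
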