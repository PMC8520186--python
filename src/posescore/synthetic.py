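"""Desk-scale synthetic complexes with a planted contact-count signal.

The generator emulates the geometry of a docking campaign without any
physics: a pocket is a hemispherical shell of amino-acid residue fragments
(with template-derived local geometry, so every atom carries a valid
residue/atom name and hence a valid connectivity type), the reference
ligand sits at the pocket mouth, and poses are rigid perturbations of the
reference whose RMSD spectrum is controlled exactly.  Near-native poses
(RMSD < 2 A) remain in contact with the pocket while decoys are displaced
away from it, so interaction features (contact counts, energy terms) carry
label signal while receptor-blind ligand descriptors do not -- the planted
structure that model-recovery experiments test for.

Docking ranks are assigned by noisy RMSD ordering: informative but
imperfect, as with a real docking program's scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.transform import Rotation

from ._residues import AA_TEMPLATES, template_mol, residue_atoms
from .rmsd import symmetry_rmsd
from .structio import (LigandMol, Pose, PoseSet, ProteinAtom, ProteinStructure,
                       THREE_TO_ONE, write_ligand_sdf)

__all__ = [
    "SyntheticSpec", "LIGAND_LIBRARY",
    "make_ligand", "make_pocket", "make_pose_ensemble",
    "make_complex", "planted_signal_dataset", "write_synthetic_inputs",
    "SHELL_CENTROID_RADII", "SHELL_BOUNDS",
]

#: built-in ligand library spanning the 9-element ligand alphabet
LIGAND_LIBRARY: dict[str, str] = {
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "phenol": "Oc1ccccc1",
    "aniline": "Nc1ccccc1",
    "pyridine": "c1ccncc1",
    "butane": "CCCC",
    "isobutanol": "CC(C)CO",
    "acetamide": "CC(N)=O",
    "ethanethiol": "CCS",
    "thiophene": "c1ccsc1",
    "methyl_phosphate": "COP(O)(O)=O",
    "fluorobenzene": "Fc1ccccc1",
    "chlorobenzene": "Clc1ccccc1",
    "bromoethane": "CCBr",
    "iodobenzene": "Ic1ccccc1",
    "glycerol": "OCC(O)CO",
    "acetic_acid": "CC(O)=O",
    "dimethylamine": "CNC",
}

#: residue centroids are placed at these radii from the pocket origin (A)
SHELL_CENTROID_RADII = (6.0, 8.0)
#: all pocket atoms are guaranteed inside these radial bounds (A)
SHELL_BOUNDS = (1.5, 14.0)


@dataclass
class SyntheticSpec:
    """Full description of a synthetic study; outputs are a pure function
    of the spec (including its seed)."""

    n_complexes: int = 200
    poses_per_complex: int = 20
    positive_fraction: float = 0.48     # near-native share of docked poses
    near_rmsd_range: tuple[float, float] = (0.3, 1.8)
    decoy_rmsd_range: tuple[float, float] = (2.6, 8.0)
    rank_noise: float = 1.5             # A of noise in the rank-assigning score
    include_crystal: bool = False
    rmsd_cutoff: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.poses_per_complex > 20:
            raise ValueError("at most 20 poses per complex")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _embed(mol: Chem.Mol, seed: int) -> Chem.Mol:
    mol = Chem.AddHs(mol)
    for attempt in range(5):
        if AllChem.EmbedMolecule(mol, randomSeed=seed + attempt) == 0:
            break
    else:  # pragma: no cover - library molecules embed reliably
        raise RuntimeError("3D embedding failed")
    return Chem.RemoveHs(mol)


def make_ligand(name: str, seed: int = 0) -> LigandMol:
    """Embed a library ligand in 3D, centered at the origin."""
    smiles = LIGAND_LIBRARY[name]
    mol = _embed(Chem.MolFromSmiles(smiles), seed)
    lig = LigandMol.from_rdkit(mol, name=name)
    return lig.with_coords(lig.coords - lig.coords.mean(axis=0))


_RESIDUE_GEOMETRY: dict[str, tuple[list[str], list[str], np.ndarray]] = {}


def _residue_geometry(resname: str) -> tuple[list[str], list[str], np.ndarray]:
    """(atom names, elements, centered template coordinates) per residue."""
    if resname not in _RESIDUE_GEOMETRY:
        mol = _embed(Chem.Mol(template_mol(resname)), seed=7)
        pairs = residue_atoms(resname)
        conf = mol.GetConformer()
        names = [n for n, _ in pairs]
        idxs = [a.GetIdx() for _, a in pairs]
        elements = [a.GetSymbol() for _, a in pairs]
        coords = np.array([[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z] for i in idxs])
        coords -= coords.mean(axis=0)
        _RESIDUE_GEOMETRY[resname] = (names, elements, coords)
    return _RESIDUE_GEOMETRY[resname]


def make_pocket(seed: int = 0, n_atoms_range: tuple[int, int] = (30, 80)
                ) -> ProteinStructure:
    """Residue fragments on a hemispherical shell around the origin.

    Atoms keep their template residue/atom names, so every atom maps to the
    22-type protein vocabulary; centroids sit at SHELL_CENTROID_RADII and
    all atoms are guaranteed inside SHELL_BOUNDS.
    """
    rng = np.random.default_rng(seed)
    target = int(rng.integers(n_atoms_range[0], n_atoms_range[1] + 1))
    resnames = sorted(AA_TEMPLATES)
    atoms: list[ProteinAtom] = []
    sequence = []
    res_seq = 0
    while len(atoms) < target:
        resname = resnames[rng.integers(0, len(resnames))]
        names, elements, coords = _residue_geometry(resname)
        if len(atoms) + len(names) > n_atoms_range[1]:
            if len(atoms) >= n_atoms_range[0]:
                break
            continue  # redraw a smaller residue
        res_seq += 1
        rot = Rotation.random(random_state=rng).as_matrix()
        # hemisphere direction (z >= 0.15 keeps the shell one-sided)
        while True:
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            if v[2] >= 0.15:
                break
        radius = rng.uniform(*SHELL_CENTROID_RADII)
        placed = coords @ rot.T + v * radius
        norms = np.linalg.norm(placed, axis=1)
        if norms.max() > SHELL_BOUNDS[1] or norms.min() < SHELL_BOUNDS[0]:
            res_seq -= 1
            continue  # re-draw orientation; keeps the bound guarantee exact
        for name, el, xyz in zip(names, elements, placed):
            atoms.append(ProteinAtom(el, tuple(xyz), resname, res_seq, "A", name))
        sequence.append(THREE_TO_ONE[resname])
        if len(atoms) >= n_atoms_range[1]:
            break
    return ProteinStructure(atoms=atoms, chains={"A": "".join(sequence)})


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perturbed_pose(reference: LigandMol, target_rmsd: float, away: np.ndarray,
                    rng: np.random.Generator) -> LigandMol:
    """Rigid rotation + jitter + exact-residual translation to hit a target
    RMSD (identity-mapping); near-native poses drift randomly, decoys along
    ``away`` (out of the pocket)."""
    ref = reference.coords
    center = ref.mean(axis=0)
    if target_rmsd <= 0:
        return reference.with_coords(ref.copy())
    angle = min(0.15 * target_rmsd, 0.5)
    axis = _unit(rng.normal(size=3))
    rot = Rotation.from_rotvec(angle * axis).as_matrix()
    # constant jitter: internal distortion must not correlate with the label,
    # otherwise the receptor-blind control features would carry planted signal
    jitter = rng.normal(scale=0.05, size=ref.shape)
    coords = (ref - center) @ rot.T + center + jitter
    r0 = float(np.sqrt(np.mean(np.sum((coords - ref) ** 2, axis=1))))
    if r0 < target_rmsd:
        if target_rmsd < 2.0:
            direction = _unit(rng.normal(size=3))
        else:
            direction = _unit(away + 0.3 * rng.normal(size=3))
        # rotation about the centroid leaves the mean displacement ~0, so the
        # translation magnitude adds in quadrature
        coords = coords + direction * np.sqrt(target_rmsd ** 2 - r0 ** 2)
    return reference.with_coords(coords)


def make_pose_ensemble(reference: LigandMol, spec: SyntheticSpec,
                       rng: np.random.Generator | None = None,
                       pocket_center: np.ndarray | None = None,
                       rmsd_targets: Sequence[float] | None = None) -> list[Pose]:
    """Docked poses with a controlled RMSD spectrum and noisy-rank order.

    The returned list is in dock-rank order (rank = noisy RMSD ordering).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if pocket_center is None:
        pocket_center = np.array([0.0, 0.0, 7.0])
    away = _unit(reference.coords.mean(axis=0) - pocket_center)
    if rmsd_targets is None:
        n = spec.poses_per_complex
        n_pos = int(round(spec.positive_fraction * n))
        targets = np.concatenate([
            rng.uniform(*spec.near_rmsd_range, size=n_pos),
            rng.uniform(*spec.decoy_rmsd_range, size=n - n_pos)])
        rng.shuffle(targets)
    else:
        targets = np.asarray(rmsd_targets, dtype=float)
    mols = [_perturbed_pose(reference, t, away, rng) for t in targets]
    rmsds = np.array([symmetry_rmsd(m, reference) for m in mols])
    noisy = rmsds + rng.normal(scale=spec.rank_noise, size=len(mols))
    order = np.argsort(noisy, kind="stable")
    return [Pose(mol=mols[i], dock_rank=rank, source="synthetic")
            for rank, i in enumerate(order, start=1)]


def make_complex(spec: SyntheticSpec, index: int) -> PoseSet:
    """One synthetic complex: pocket + reference ligand + pose ensemble."""
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(index,))
    seeds = ss.generate_state(3)
    rng = np.random.default_rng(seeds[2])
    lig_names = sorted(LIGAND_LIBRARY)
    name = lig_names[index % len(lig_names)]
    pocket = make_pocket(seed=int(seeds[0]))
    reference = make_ligand(name, seed=int(seeds[1]) % (2 ** 31 - 1))
    # reference at the pocket mouth, slightly inside the hemisphere
    reference = reference.translated([0.0, 0.0, 2.5])
    pocket_center = pocket.coords.mean(axis=0)
    poses = make_pose_ensemble(reference, spec, rng=rng, pocket_center=pocket_center)
    if spec.include_crystal:
        poses = poses + [Pose(mol=reference, is_crystal=True, source="crystal")]
    return PoseSet(complex_id=f"cplx{index:04d}", receptor_id=f"rec{index:04d}",
                   receptor=pocket, reference=reference, poses=poses, mode="redock")


def planted_signal_dataset(spec: SyntheticSpec) -> list[PoseSet]:
    """The full synthetic study: ``spec.n_complexes`` independent complexes."""
    return [make_complex(spec, i) for i in range(spec.n_complexes)]


# ---------------------------------------------------------------------------
# file export (the `simulate` CLI subcommand)
# ---------------------------------------------------------------------------

def _write_pdb(structure: ProteinStructure, path: Path) -> None:
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
        lines.append(
            f"ATOM  {i:5d} {name:<4s} {a.res_name:<3s} {a.chain_id}{a.res_seq:4d}    "
            f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def write_synthetic_inputs(spec: SyntheticSpec, outdir: str | Path) -> Path:
    """Emit PDB/SDF inputs + metadata CSV matching the I/O contract.

    Returns the metadata CSV path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(spec.n_complexes):
        ps = make_complex(spec, i)
        rec = outdir / f"{ps.complex_id}_receptor.pdb"
        ref = outdir / f"{ps.complex_id}_reference.sdf"
        lig = outdir / f"{ps.complex_id}_poses.sdf"
        _write_pdb(ps.receptor, rec)
        write_ligand_sdf([ps.reference], ref)
        write_ligand_sdf([p.mol for p in ps.docked_poses], lig)
        rows.append({"complex_id": ps.complex_id, "receptor_id": ps.receptor_id,
                     "ligand_file": lig.name, "reference_file": ref.name,
                     "receptor_file": rec.name, "program": "synthetic",
                     "mode": ps.mode})
    meta = outdir / "metadata.csv"
    pd.DataFrame(rows).to_csv(meta, index=False)
    return meta
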