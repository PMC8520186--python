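"""Structure I/O: receptors, ligand poses, and docking pose sets.

Receptors are read from PDB files (heavy ATOM records only), ligands from
SDF/MOL2 files with explicit bond blocks.  A :class:`PoseSet` bundles one
docking campaign: the receptor, the crystal reference ligand (in the same
coordinate frame), and the ranked docked poses.  Coordinates are assumed to
already share a common frame; no superposition is ever performed.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "FormatError",
    "EmptyStructureError",
    "ProteinAtom",
    "ProteinStructure",
    "LigandAtom",
    "Bond",
    "LigandMol",
    "Pose",
    "PoseSet",
    "read_protein",
    "read_ligand",
    "write_ligand_sdf",
    "assemble_pose_set",
    "read_metadata",
    "METADATA_COLUMNS",
]


class FormatError(ValueError):
    """A structure file could not be interpreted."""


class EmptyStructureError(ValueError):
    """A parsed structure contained no usable atoms."""


#: canonical three-letter -> one-letter amino-acid codes
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: ligand-side element alphabet used throughout the package
LIGAND_ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")
#: protein-side element alphabet
PROTEIN_ELEMENTS = ("C", "N", "O", "S")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinAtom:
    element: str
    xyz: tuple[float, float, float]
    res_name: str
    res_seq: int
    chain_id: str
    atom_name: str


@dataclass
class ProteinStructure:
    """Heavy-atom protein structure with per-chain one-letter sequences."""

    atoms: list[ProteinAtom]
    chains: dict[str, str]

    def __post_init__(self) -> None:
        coords = self.coords
        if len(self.atoms) and not np.all(np.isfinite(coords)):
            raise FormatError("non-finite coordinates in protein structure")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class LigandAtom:
    element: str
    xyz: tuple[float, float, float]
    aromatic: bool
    in_ring: bool
    n_h: int          # attached hydrogens (implicit-valence completion)
    valence: int      # total valence incl. attached hydrogens


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: float      # kekulized order (1, 2, 3)
    aromatic: bool


@dataclass
class LigandMol:
    """Heavy-atom small molecule with an explicit bond graph.

    Instances are normally built from an RDKit molecule so that attached-H
    counts and valences follow the toolkit's implicit-valence model.
    """

    atoms: list[LigandAtom]
    bonds: list[Bond]
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise FormatError(f"bond index out of range: ({b.i}, {b.j})")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise FormatError(f"duplicate bond: {key}")
            seen.add(key)

    # -- basic views --------------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def formula(self) -> Counter:
        return Counter(self.elements)

    def neighbors(self) -> list[list[int]]:
        nbr: list[list[int]] = [[] for _ in self.atoms]
        for b in self.bonds:
            nbr[b.i].append(b.j)
            nbr[b.j].append(b.i)
        return nbr

    def __len__(self) -> int:
        return len(self.atoms)

    # -- conversions --------------------------------------------------------
    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, conf_id: int = -1, name: str = "") -> "LigandMol":
        mol = Chem.RemoveHs(mol, sanitize=False)
        if mol.GetNumConformers() == 0:
            raise FormatError("molecule has no coordinates")
        conf = mol.GetConformer(conf_id)
        kek = Chem.Mol(mol)
        try:
            Chem.Kekulize(kek, clearAromaticFlags=False)
        except Chem.KekulizeException:
            kek = mol
        atoms = []
        for a in mol.GetAtoms():
            p = conf.GetAtomPosition(a.GetIdx())
            atoms.append(LigandAtom(
                element=a.GetSymbol(),
                xyz=(p.x, p.y, p.z),
                aromatic=a.GetIsAromatic(),
                in_ring=a.IsInRing(),
                n_h=a.GetTotalNumHs(),
                valence=a.GetTotalValence(),
            ))
        bonds = []
        for b in mol.GetBonds():
            order = kek.GetBondBetweenAtoms(b.GetBeginAtomIdx(), b.GetEndAtomIdx()).GetBondTypeAsDouble()
            bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                              order=float(order), aromatic=b.GetIsAromatic()))
        return cls(atoms=atoms, bonds=bonds, name=name or (mol.GetProp("_Name") if mol.HasProp("_Name") else ""))

    def to_rdkit(self) -> Chem.Mol:
        rw = Chem.RWMol()
        for a in self.atoms:
            at = Chem.Atom(a.element)
            at.SetNoImplicit(True)
            at.SetNumExplicitHs(a.n_h)
            rw.AddAtom(at)
        order_map = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE, 3.0: Chem.BondType.TRIPLE}
        for b in self.bonds:
            rw.AddBond(b.i, b.j, order_map.get(b.order, Chem.BondType.SINGLE))
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol, catchErrors=True)
        except Exception:  # pragma: no cover - best effort
            pass
        conf = Chem.Conformer(len(self.atoms))
        for i, a in enumerate(self.atoms):
            conf.SetAtomPosition(i, a.xyz)
        mol.AddConformer(conf, assignId=True)
        if self.name:
            mol.SetProp("_Name", self.name)
        return mol

    def translated(self, shift: Sequence[float]) -> "LigandMol":
        shift = np.asarray(shift, dtype=float)
        atoms = [LigandAtom(a.element, tuple(np.asarray(a.xyz) + shift), a.aromatic,
                            a.in_ring, a.n_h, a.valence) for a in self.atoms]
        return LigandMol(atoms=atoms, bonds=list(self.bonds), name=self.name)

    def with_coords(self, coords: np.ndarray) -> "LigandMol":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [LigandAtom(a.element, tuple(coords[i]), a.aromatic, a.in_ring, a.n_h, a.valence)
                 for i, a in enumerate(self.atoms)]
        return LigandMol(atoms=atoms, bonds=list(self.bonds), name=self.name)

    def is_connected(self) -> bool:
        if len(self.atoms) <= 1:
            return True
        nbr = self.neighbors()
        seen = {0}
        stack = [0]
        while stack:
            for j in nbr[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == len(self.atoms)


NO_RANK = 0  # sentinel dock_rank for crystal poses


@dataclass
class Pose:
    mol: LigandMol
    dock_rank: int = NO_RANK   # 1-based docking-program rank; NO_RANK for crystal poses
    source: str = ""
    is_crystal: bool = False

    def __post_init__(self) -> None:
        if self.is_crystal:
            self.dock_rank = NO_RANK
        elif self.dock_rank < 1:
            raise ValueError("docked poses need a positive dock_rank")


@dataclass
class PoseSet:
    """One docking campaign: receptor, crystal reference, ranked poses."""

    complex_id: str
    receptor_id: str
    receptor: ProteinStructure
    reference: LigandMol
    poses: list[Pose]
    mode: str = "redock"           # redock | crossdock

    def __post_init__(self) -> None:
        if self.mode not in ("redock", "crossdock"):
            raise ValueError(f"unknown mode: {self.mode!r}")
        ranks = [p.dock_rank for p in self.poses if not p.is_crystal]
        if len(ranks) != len(set(ranks)):
            raise ValueError("duplicate dock_rank within a docking run")

    @property
    def docked_poses(self) -> list[Pose]:
        return [p for p in self.poses if not p.is_crystal]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_protein(path: str | Path) -> ProteinStructure:
    """Parse the heavy atoms of a PDB file's ATOM records.

    HETATM records, waters, and hydrogens are dropped.  For alternate
    locations the first-listed conformer is kept.  Nonstandard residues map
    to ``X`` in the chain sequences.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    atoms: list[ProteinAtom] = []
    chain_res: dict[str, list[tuple[int, str]]] = {}
    seen_altloc: set[tuple[str, int, str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("ATOM"):
                continue
            try:
                atom_name = line[12:16].strip()
                altloc = line[16]
                res_name = line[17:20].strip()
                chain_id = line[21].strip() or "A"
                res_seq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                element = line[76:78].strip() if len(line) >= 78 else ""
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path.name}: unparsable ATOM record at line {lineno}") from exc
            if not element:
                element = _element_from_atom_name(atom_name)
            element = element.capitalize()
            if element in ("H", "D"):
                continue
            if res_name == "HOH":
                continue
            key = (chain_id, res_seq, res_name, atom_name)
            if altloc != " ":
                if key in seen_altloc:
                    continue  # keep the first-listed altloc only
                seen_altloc.add(key)
            atoms.append(ProteinAtom(element, (x, y, z), res_name, res_seq, chain_id, atom_name))
            chain_res.setdefault(chain_id, [])
            if not chain_res[chain_id] or chain_res[chain_id][-1][0] != res_seq:
                if (res_seq, res_name) not in [(s, n) for s, n in chain_res[chain_id]]:
                    chain_res[chain_id].append((res_seq, res_name))
    if not atoms:
        raise EmptyStructureError(f"{path.name}: no protein heavy atoms found")
    chains = {
        cid: "".join(THREE_TO_ONE.get(name, "X") for _, name in residues)
        for cid, residues in chain_res.items()
    }
    return ProteinStructure(atoms=atoms, chains=chains)


def _element_from_atom_name(atom_name: str) -> str:
    name = atom_name.strip()
    if name[:2].capitalize() in ("Cl", "Br", "Fe", "Zn", "Mg", "Mn", "Na", "Ca"):
        return name[:2]
    return name[0]


def read_ligand(path: str | Path) -> list[LigandMol]:
    """Read every record of an SDF (V2000) or MOL2 file, in file order.

    Record order defines pose order downstream.  Records without a bond
    block are rejected (connectivity-typed features require bonds); valence
    problems produce a warning and a best-effort parse.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".sdf", ".sd", ".mol"):
        rd_mols = _read_sdf(path)
    elif suffix == ".mol2":
        rd_mols = _read_mol2(path)
    else:
        raise FormatError(f"unsupported ligand format: {path.name}")
    if not rd_mols:
        raise EmptyStructureError(f"{path.name}: no ligand records parsed")
    out = []
    for idx, mol in enumerate(rd_mols):
        if mol.GetNumAtoms() > 1 and mol.GetNumBonds() == 0:
            raise FormatError(f"{path.name}: record {idx + 1} has no bond block")
        out.append(LigandMol.from_rdkit(mol, name=f"{path.stem}:{idx + 1}"))
    return out


def _partial_sanitize(mol: Chem.Mol) -> Chem.Mol:
    flags = (Chem.SanitizeFlags.SANITIZE_SYMMRINGS
             | Chem.SanitizeFlags.SANITIZE_SETAROMATICITY
             | Chem.SanitizeFlags.SANITIZE_ADJUSTHS)
    Chem.SanitizeMol(mol, flags, catchErrors=True)
    return mol


def _read_sdf(path: Path) -> list[Chem.Mol]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    mols = []
    for mol in supplier:
        if mol is None:
            raise FormatError(f"{path.name}: unreadable SDF record")
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            warnings.warn(f"{path.name}: valence/sanitization problem; best-effort parse")
            _partial_sanitize(mol)
        mols.append(Chem.RemoveHs(mol, sanitize=False))
    return mols


def _read_mol2(path: Path) -> list[Chem.Mol]:
    text = path.read_text()
    blocks = ["@<TRIPOS>MOLECULE" + b for b in text.split("@<TRIPOS>MOLECULE")[1:]]
    if not blocks:
        raise FormatError(f"{path.name}: no @<TRIPOS>MOLECULE record")
    mols = []
    for idx, block in enumerate(blocks):
        mol = Chem.MolFromMol2Block(block, sanitize=True, removeHs=True)
        if mol is None:
            mol = Chem.MolFromMol2Block(block, sanitize=False, removeHs=False)
            if mol is None:
                raise FormatError(f"{path.name}: unreadable MOL2 record {idx + 1}")
            warnings.warn(f"{path.name}: valence/sanitization problem; best-effort parse")
            _partial_sanitize(mol)
            mol = Chem.RemoveHs(mol, sanitize=False)
        mols.append(mol)
    return mols


def write_ligand_sdf(mols: Iterable[LigandMol], path: str | Path) -> None:
    """Write molecules to an SDF (V2000) file, one record per molecule."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for m in mols:
        writer.write(m.to_rdkit())
    writer.close()


# ---------------------------------------------------------------------------
# pose-set assembly
# ---------------------------------------------------------------------------

def assemble_pose_set(
    receptor: ProteinStructure,
    reference: LigandMol,
    pose_mols: Sequence[LigandMol],
    complex_id: str,
    receptor_id: str = "",
    program: str = "",
    mode: str = "redock",
    include_crystal: bool = False,
    native_flags: Sequence[bool] | None = None,
    max_poses: int = 20,
) -> PoseSet:
    """Bundle docked poses with their receptor and crystal reference.

    ``dock_rank`` is the 1-based position in the docking output.  The
    crystal pose is appended only when ``include_crystal`` is set and the
    mode is ``redock``; in ``crossdock`` mode any pose flagged as native
    (``native_flags``) is rejected, since such cross-native poses are
    geometric transplants rather than docking results.
    """
    if not pose_mols:
        raise EmptyStructureError(f"{complex_id}: empty pose set")
    if native_flags is not None and len(native_flags) != len(pose_mols):
        raise ValueError("native_flags length mismatch")
    ref_formula = reference.formula()
    poses: list[Pose] = []
    rank = 0
    for idx, mol in enumerate(pose_mols):
        if mol.formula() != ref_formula:
            raise FormatError(
                f"{complex_id}: pose {idx + 1} heavy-atom formula "
                f"{dict(mol.formula())} != reference {dict(ref_formula)}")
        is_native = bool(native_flags[idx]) if native_flags is not None else False
        if is_native:
            if mode == "crossdock":
                warnings.warn(f"{complex_id}: cross-native pose {idx + 1} rejected")
                continue
            poses.append(Pose(mol=mol, is_crystal=True, source=program))
            continue
        rank += 1
        poses.append(Pose(mol=mol, dock_rank=rank, source=program))
    n_docked = sum(not p.is_crystal for p in poses)
    if n_docked == 0:
        raise EmptyStructureError(f"{complex_id}: no docked poses after filtering")
    if n_docked > max_poses:
        raise ValueError(f"{complex_id}: {n_docked} docked poses exceed max_poses={max_poses}")
    if include_crystal and mode == "redock" and not any(p.is_crystal for p in poses):
        poses.append(Pose(mol=reference, is_crystal=True, source="crystal"))
    return PoseSet(complex_id=complex_id, receptor_id=receptor_id or complex_id,
                   receptor=receptor, reference=reference, poses=poses, mode=mode)


METADATA_COLUMNS = ["complex_id", "receptor_id", "ligand_file",
                    "reference_file", "receptor_file", "program", "mode"]


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-complex metadata table (CSV)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata table missing columns: {missing}")
    return df


def load_pose_sets(metadata: pd.DataFrame, root: str | Path = ".",
                   include_crystal: bool = False, max_poses: int = 20) -> list[PoseSet]:
    """Materialize pose sets from a metadata table of file paths."""
    root = Path(root)
    sets = []
    for _, row in metadata.iterrows():
        receptor = read_protein(root / row["receptor_file"])
        reference = read_ligand(root / row["reference_file"])[0]
        pose_mols = read_ligand(root / row["ligand_file"])
        sets.append(assemble_pose_set(
            receptor, reference, pose_mols,
            complex_id=row["complex_id"], receptor_id=row["receptor_id"],
            program=row.get("program", ""), mode=row.get("mode", "redock"),
            include_crystal=include_crystal, max_poses=max_poses))
    return sets
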