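"""Per-pose feature vectors for pose rescoring.

Five feature families are implemented:

* ``elem`` -- 36 element-pair contact counts (4 protein x 9 ligand elements
  within a 6.0 A cutoff), the classic distance-count descriptor.
* ``ecif`` -- 1562 connectivity-typed atom-pair contact counts.  Each atom
  is typed by ``element;valence;heavy-neighbors;attached-H;aromatic;ring``;
  22 protein types (derivable from amino-acid templates) x 71 ligand types.
* ``vina`` -- the five empirical energy terms (two attractive Gaussians,
  quadratic steric repulsion, hydrophobic contact, hydrogen bond) evaluated
  on the surface distance d = r - (R_i + R_j) with an 8 A pair cutoff.
* ``rank`` -- the 1-based docking-program rank of the pose (NaN for crystal
  poses or pooled multi-program sets where ranks are unobtainable).
* ``ligand_control`` -- a receptor-blind conformational descriptor (element
  counts, intramolecular distance histogram, radius of gyration) used as a
  negative control: a model trained on it alone cannot encode interactions.

Distance-cutoff comparisons are inclusive (d <= cutoff).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.spatial.distance import cdist, pdist

from ._residues import AA_TEMPLATES, VARIANT_TEMPLATES, residue_atoms
from .rmsd import DEFAULT_RMSD_CUTOFF, LabeledPose, label_pose_set
from .structio import (LIGAND_ELEMENTS, PROTEIN_ELEMENTS, LigandMol, Pose,
                       PoseSet, ProteinStructure, NO_RANK)

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSchema", "FeatureVector", "FAMILIES",
    "ecif_atom_type", "protein_atom_type",
    "derive_protein_type_vocabulary", "derive_ligand_type_vocabulary",
    "load_protein_types", "load_ligand_types",
    "elem_featurize", "ecif_featurize", "vina_terms", "rank_feature",
    "ligand_control_featurize", "build_schema", "featurize_pose",
    "assemble_features", "assemble_dataset",
    "DEFAULT_CONTACT_CUTOFF", "VINA_PAIR_CUTOFF",
]

DEFAULT_CONTACT_CUTOFF = 6.0   # A, inclusive, for ELEM/ECIF pair counts
VINA_PAIR_CUTOFF = 8.0         # A, center-center, for the energy terms

FAMILIES = ("elem", "ecif", "vina", "rank", "ligand_control")


# ---------------------------------------------------------------------------
# ECIF atom typing
# ---------------------------------------------------------------------------

def _rdkit_atom_key(atom: Chem.Atom) -> str:
    return ";".join([
        atom.GetSymbol(),
        str(atom.GetTotalValence()),
        str(atom.GetDegree()),
        str(atom.GetTotalNumHs()),
        str(int(atom.GetIsAromatic())),
        str(int(atom.IsInRing())),
    ])


def ecif_atom_type(mol: LigandMol, idx: int) -> str | None:
    """Connectivity type key of a ligand heavy atom.

    Returns None (atom excluded from typed counts) when the element is
    outside the 9-element ligand alphabet.
    """
    atom = mol.atoms[idx]
    if atom.element not in LIGAND_ELEMENTS:
        return None
    heavy_deg = sum(1 for b in mol.bonds if idx in (b.i, b.j))
    return ";".join([atom.element, str(atom.valence), str(heavy_deg),
                     str(atom.n_h), str(int(atom.aromatic)), str(int(atom.in_ring))])


def derive_protein_type_vocabulary(
        templates: Iterable[str] | None = None) -> set[str]:
    """Distinct ECIF keys over {C,N,O,S} in the amino-acid templates.

    With the default template set (20 canonical residues in peptide context
    plus the standard alternative protonation forms) this yields exactly 22
    types.
    """
    if templates is None:
        templates = list(AA_TEMPLATES) + list(VARIANT_TEMPLATES)
    types: set[str] = set()
    for resname in templates:
        for _, atom in residue_atoms(resname):
            if atom.GetSymbol() in PROTEIN_ELEMENTS:
                types.add(_rdkit_atom_key(atom))
    return types


#: hand-written corpus of drug-like fragments spanning the ligand alphabet;
#: the shipped 71-type ligand vocabulary is the set of distinct ECIF keys
#: occurring in it (a stand-in for the reference ligand corpus, which is
#: external data).
LIGAND_TYPE_CORPUS = """\
CC CCC CC(C)C CC(C)(C)C CC1(C)CCCC1 C1CCCCC1 C1CCCC1 C1CC2CCC1CC2
c1ccccc1 Cc1ccccc1 c1ccncc1 c1ccc2ccccc2c1 c1ccc2[nH]ccc2c1 c1cn[nH]c1 c1csc(N)n1
c1ccoc1 c1ccsc1 c1cc[nH+]cc1 [O-][n+]1ccccc1 o1cccc1C=O
C=C C=CC=C C#C CC#C CC=C C1=CCCCC1 CC(=C)C C C1CCC#CCCC1
CCO CC(C)O OCCO CC=O C(=O)O CC(C)=O O=C1CCCCC1 O=C1CCCN1 O=C1CCCO1
CC(=O)O CC(=O)OC CC(=O)NC CC(=O)N(C)C OC(=O)C(=O)O
CCN CCNC CCN(C)C C1CCNCC1 CN1CCCC1 CC(N)=N NC(N)=N CC=NC CC=NO CCN=[N+]=[N-]
CC#N CCC#N N#Cc1ccccc1 CNC(=O)c1ccccc1 CC(=O)c1ccccc1 C=O
Oc1ccccc1 Nc1ccccc1 COc1ccccc1 CN(C)c1ccccc1 [O-][N+](=O)c1ccccc1 C[N+](C)(C)C
CC[NH3+] CC[NH2+]C C1CC[NH2+]CC1 CC(=[NH2+])N CC=[NH+]C C[NH+]1CCCCC1
C[N+]1(C)CCCC1 C1CCC=[N+]1C
CS CSC CS(C)=O CS(C)(=O)=O NS(=O)(=O)c1ccccc1 CSSC C1CCSC1 O=S1(=O)CCCN1
O=S1CCCC1 [S-]CC CC(=S)N C[S+](C)C
OP(O)(O)=O COP(=O)(OC)OC CP(C)(C)=O CP(C)C C1COP(=O)(O1)O CCOP(=O)(OCC)OCC
C1CCPC1 C[P+](C)(C)C C1CCP(C)C1 CP
FC(F)(F)c1ccccc1 Fc1ccccc1 FCC ClCC Clc1ccccc1 ClC(Cl)Cl BrCC Brc1ccccc1 ICC Ic1ccccc1
OCC1OC(O)C(O)C(O)C1O NC1CCCCC1 c1ccc(cc1)C2CCNCC2 CN1CCOCC1 CN1CCNCC1
O=c1cc[nH]c(=O)[nH]1 c1cnc2[nH]cnc2n1 Nc1ncnc2[nH]cnc12 Cn1cnc2c1c(=O)n(C)c(=O)n2C
CC1=CC(=O)CC(C)(C)C1 CC(=CCO)C C1COCCO1 C1CCOC1 CCSCC CC(Br)C CC(Cl)C(=O)O
CNC(=O)NC COC(=O)c1ccccc1 CCOC(=O)C O=Cc1ccccc1 OC=O
""".split()


def derive_ligand_type_vocabulary(corpus: Sequence[str] = LIGAND_TYPE_CORPUS) -> list[str]:
    """Sorted distinct ECIF keys over the ligand alphabet in a SMILES corpus."""
    types: set[str] = set()
    for smi in corpus:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - corpus is static
            raise ValueError(f"bad corpus SMILES: {smi}")
        for atom in mol.GetAtoms():
            if atom.GetSymbol() in LIGAND_ELEMENTS:
                types.add(_rdkit_atom_key(atom))
    return sorted(types)


def _load_vocab_file(name: str) -> list[str]:
    try:
        text = resources.files("posescore.data").joinpath(name).read_text()
    except FileNotFoundError as exc:  # pragma: no cover
        raise RuntimeError(f"vocabulary file missing: {name}") from exc
    return [line.strip() for line in text.splitlines() if line.strip()]


_PROTEIN_TYPES: list[str] | None = None
_LIGAND_TYPES: list[str] | None = None


def load_protein_types() -> list[str]:
    global _PROTEIN_TYPES
    if _PROTEIN_TYPES is None:
        _PROTEIN_TYPES = _load_vocab_file("protein_atom_types.txt")
    return _PROTEIN_TYPES


def load_ligand_types() -> list[str]:
    global _LIGAND_TYPES
    if _LIGAND_TYPES is None:
        _LIGAND_TYPES = _load_vocab_file("ligand_atom_types.txt")
    return _LIGAND_TYPES


# ---------------------------------------------------------------------------
# protein-side per-atom annotation (from residue templates)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _ProteinAtomInfo:
    key: str
    hydrophobic: bool   # carbon with no N/O/S neighbor
    donor: bool         # N/O carrying at least one hydrogen
    acceptor: bool      # any N/O


_PROTEIN_LOOKUP: dict[tuple[str, str], _ProteinAtomInfo] | None = None


def _protein_lookup() -> dict[tuple[str, str], _ProteinAtomInfo]:
    global _PROTEIN_LOOKUP
    if _PROTEIN_LOOKUP is not None:
        return _PROTEIN_LOOKUP
    table: dict[tuple[str, str], _ProteinAtomInfo] = {}
    for resname in AA_TEMPLATES:
        for name, atom in residue_atoms(resname):
            el = atom.GetSymbol()
            nbr_els = {n.GetSymbol() for n in atom.GetNeighbors()}
            info = _ProteinAtomInfo(
                key=_rdkit_atom_key(atom),
                hydrophobic=(el == "C" and not nbr_els & {"N", "O", "S"}),
                donor=(el in ("N", "O") and atom.GetTotalNumHs() > 0),
                acceptor=el in ("N", "O"),
            )
            table[(resname, name)] = info
    _PROTEIN_LOOKUP = table
    return table


def protein_atom_type(res_name: str, atom_name: str) -> str | None:
    """ECIF key of a protein heavy atom, from its residue template."""
    info = _protein_lookup().get((res_name, atom_name))
    return info.key if info is not None else None


# ---------------------------------------------------------------------------
# featurizers
# ---------------------------------------------------------------------------

def elem_featurize(receptor: ProteinStructure, pose_mol: LigandMol,
                   cutoff: float = DEFAULT_CONTACT_CUTOFF) -> np.ndarray:
    """36 element-pair contact counts within ``cutoff`` (inclusive)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    counts = np.zeros((len(PROTEIN_ELEMENTS), len(LIGAND_ELEMENTS)))
    if len(receptor) and len(pose_mol):
        p_el = np.array(receptor.elements)
        l_el = np.array(pose_mol.elements)
        dist = cdist(receptor.coords, pose_mol.coords)
        within = dist <= cutoff
        for i, pe in enumerate(PROTEIN_ELEMENTS):
            pm = p_el == pe
            if not pm.any():
                continue
            for j, le in enumerate(LIGAND_ELEMENTS):
                lm = l_el == le
                if lm.any():
                    counts[i, j] = within[np.ix_(pm, lm)].sum()
    return counts.ravel()


def ecif_featurize(receptor: ProteinStructure, pose_mol: LigandMol,
                   cutoff: float = DEFAULT_CONTACT_CUTOFF) -> np.ndarray:
    """1562 connectivity-typed pair counts within ``cutoff`` (inclusive).

    Atoms whose type is outside the shipped vocabularies are ignored; the
    ignored tallies are logged at DEBUG level.
    """
    p_types = load_protein_types()
    l_types = load_ligand_types()
    p_index = {t: i for i, t in enumerate(p_types)}
    l_index = {t: i for i, t in enumerate(l_types)}

    p_ids, p_rows = [], []
    skipped_p = 0
    for i, atom in enumerate(receptor.atoms):
        key = protein_atom_type(atom.res_name, atom.atom_name)
        idx = p_index.get(key) if key is not None else None
        if idx is None:
            skipped_p += 1
            continue
        p_ids.append(idx)
        p_rows.append(i)
    l_ids, l_cols = [], []
    skipped_l = 0
    for j in range(len(pose_mol)):
        key = ecif_atom_type(pose_mol, j)
        idx = l_index.get(key) if key is not None else None
        if idx is None:
            skipped_l += 1
            continue
        l_ids.append(idx)
        l_cols.append(j)
    if skipped_p or skipped_l:
        logger.debug("ecif: ignored %d protein / %d ligand atoms outside vocabularies",
                     skipped_p, skipped_l)
    counts = np.zeros((len(p_types), len(l_types)))
    if p_rows and l_cols:
        dist = cdist(receptor.coords[p_rows], pose_mol.coords[l_cols])
        pi, lj = np.nonzero(dist <= cutoff)
        np.add.at(counts, (np.array(p_ids)[pi], np.array(l_ids)[lj]), 1)
    return counts.ravel()


#: van der Waals radii (A) used for the surface distance d = r - Ri - Rj
VDW_RADII = {"C": 1.9, "N": 1.8, "O": 1.7, "S": 2.0, "P": 2.1,
             "F": 1.5, "Cl": 1.8, "Br": 2.0, "I": 2.2}
_DEFAULT_RADIUS = 1.8

VINA_TERM_NAMES = ("gauss1", "gauss2", "repulsion", "hydrophobic", "hbond")


def _radius(element: str) -> float:
    r = VDW_RADII.get(element)
    if r is None:
        logger.warning("unknown element %r: using generic vdW radius %.1f A",
                       element, _DEFAULT_RADIUS)
        return _DEFAULT_RADIUS
    return r


def vina_terms(receptor: ProteinStructure, pose_mol: LigandMol) -> np.ndarray:
    """The five empirical energy terms summed over pairs within 8 A.

    On the surface distance d: gauss1 = exp(-(d/0.5)^2);
    gauss2 = exp(-((d-3)/2)^2); repulsion = d^2 for d < 0;
    hydrophobic = ramp 1->0 over d in [0.5, 1.5] for hydrophobic-carbon
    pairs; hbond = ramp 1->0 over d in [-0.7, 0] for donor--acceptor pairs.
    """
    lookup = _protein_lookup()
    n_p, n_l = len(receptor), len(pose_mol)
    if n_p == 0 or n_l == 0:
        return np.zeros(5)

    p_rad = np.array([_radius(a.element) for a in receptor.atoms])
    p_info = [lookup.get((a.res_name, a.atom_name)) for a in receptor.atoms]
    p_hydro = np.array([i.hydrophobic if i else False for i in p_info])
    p_don = np.array([(i.donor if i else a.element in ("N", "O"))
                      for i, a in zip(p_info, receptor.atoms)])
    p_acc = np.array([(i.acceptor if i else a.element in ("N", "O"))
                      for i, a in zip(p_info, receptor.atoms)])

    nbr = pose_mol.neighbors()
    l_rad = np.array([_radius(a.element) for a in pose_mol.atoms])
    l_hydro = np.array([
        a.element == "C" and not any(pose_mol.atoms[k].element in ("N", "O", "S")
                                     for k in nbr[i])
        for i, a in enumerate(pose_mol.atoms)])
    l_don = np.array([a.element in ("N", "O") and a.n_h > 0 for a in pose_mol.atoms])
    l_acc = np.array([a.element in ("N", "O") for a in pose_mol.atoms])

    r = cdist(receptor.coords, pose_mol.coords)
    within = r <= VINA_PAIR_CUTOFF
    d = r - (p_rad[:, None] + l_rad[None, :])

    gauss1 = np.where(within, np.exp(-((d / 0.5) ** 2)), 0.0).sum()
    gauss2 = np.where(within, np.exp(-(((d - 3.0) / 2.0) ** 2)), 0.0).sum()
    repulsion = np.where(within & (d < 0), d ** 2, 0.0).sum()

    hydro_pair = within & p_hydro[:, None] & l_hydro[None, :]
    ramp = np.clip((1.5 - d) / 1.0, 0.0, 1.0)
    hydrophobic = np.where(hydro_pair, ramp, 0.0).sum()

    hb_pair = within & ((p_don[:, None] & l_acc[None, :]) | (p_acc[:, None] & l_don[None, :]))
    hb_ramp = np.clip(-d / 0.7, 0.0, 1.0)
    hbond = np.where(hb_pair, hb_ramp, 0.0).sum()

    return np.array([gauss1, gauss2, repulsion, hydrophobic, hbond])


def rank_feature(pose: Pose) -> np.ndarray:
    """Docking rank as a feature; NaN when the pose carries no rank."""
    if pose.is_crystal or pose.dock_rank == NO_RANK:
        return np.array([np.nan])
    return np.array([float(pose.dock_rank)])


_LC_BIN_EDGES = np.arange(0.0, 8.5, 0.5)   # 16 intramolecular distance bins


def ligand_control_featurize(pose_mol: LigandMol) -> np.ndarray:
    """Receptor-blind ligand descriptor: element counts, intramolecular
    distance histogram, radius of gyration.  Conformation-sensitive but by
    construction independent of the receptor."""
    counts = np.array([pose_mol.elements.count(el) for el in LIGAND_ELEMENTS], dtype=float)
    coords = pose_mol.coords
    if len(pose_mol) >= 2:
        dists = pdist(coords)
        hist, _ = np.histogram(dists, bins=_LC_BIN_EDGES)
        rgyr = float(np.sqrt(np.mean(np.sum((coords - coords.mean(axis=0)) ** 2, axis=1))))
    else:
        hist = np.zeros(len(_LC_BIN_EDGES) - 1)
        rgyr = 0.0
    return np.concatenate([counts, hist.astype(float), [rgyr]])


# ---------------------------------------------------------------------------
# schema + assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSchema:
    names: tuple[str, ...]
    families: tuple[str, ...]       # family tag per feature, parallel to names
    version: str = "1"

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class FeatureVector:
    schema: FeatureSchema
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != len(self.schema):
            raise ValueError("feature vector length does not match schema")


def _family_names(family: str) -> list[str]:
    if family == "elem":
        return [f"ELEM::{p}-{l}" for p in PROTEIN_ELEMENTS for l in LIGAND_ELEMENTS]
    if family == "ecif":
        return [f"ECIF::{p}-{l}" for p in load_protein_types() for l in load_ligand_types()]
    if family == "vina":
        return [f"VINA::{t}" for t in VINA_TERM_NAMES]
    if family == "rank":
        return ["RANK::dock_rank"]
    if family == "ligand_control":
        names = [f"LC::count_{el}" for el in LIGAND_ELEMENTS]
        names += [f"LC::dist_{_LC_BIN_EDGES[i]:.1f}_{_LC_BIN_EDGES[i+1]:.1f}"
                  for i in range(len(_LC_BIN_EDGES) - 1)]
        names += ["LC::rgyr"]
        return names
    raise ValueError(f"unknown feature family: {family!r}")


def build_schema(families: Sequence[str]) -> FeatureSchema:
    """Concatenated feature schema for an ordered subset of families."""
    if not families:
        raise ValueError("empty feature family set")
    unknown = [f for f in families if f not in FAMILIES]
    if unknown:
        raise ValueError(f"unknown feature families: {unknown}")
    ordered = [f for f in FAMILIES if f in families]
    names: list[str] = []
    tags: list[str] = []
    for fam in ordered:
        fam_names = _family_names(fam)
        names.extend(fam_names)
        tags.extend([fam] * len(fam_names))
    return FeatureSchema(names=tuple(names), families=tuple(tags))


def featurize_pose(pose_set: PoseSet, pose: Pose, families: Sequence[str],
                   cutoff: float = DEFAULT_CONTACT_CUTOFF) -> np.ndarray:
    """Concatenated feature vector for one pose, in schema order."""
    ordered = [f for f in FAMILIES if f in families]
    blocks = []
    for fam in ordered:
        if fam == "elem":
            blocks.append(elem_featurize(pose_set.receptor, pose.mol, cutoff))
        elif fam == "ecif":
            blocks.append(ecif_featurize(pose_set.receptor, pose.mol, cutoff))
        elif fam == "vina":
            blocks.append(vina_terms(pose_set.receptor, pose.mol))
        elif fam == "rank":
            blocks.append(rank_feature(pose))
        elif fam == "ligand_control":
            blocks.append(ligand_control_featurize(pose.mol))
    return np.concatenate(blocks)


ID_COLUMNS = ["complex_id", "pose_id", "is_crystal", "dock_rank", "rmsd", "label"]


def assemble_features(pose_set: PoseSet, families: Sequence[str],
                      labeled: Sequence[LabeledPose] | None = None,
                      cutoff: float = DEFAULT_CONTACT_CUTOFF,
                      rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF) -> pd.DataFrame:
    """One row per pose: identifiers, RMSD, label, and feature columns.

    Requesting the ``rank`` family for a set in which no docked pose carries
    a rank raises, pointing at the rank-free model instead (ranks cannot be
    reconstructed for pooled multi-program pose sets).
    """
    schema = build_schema(families)
    if "rank" in families and not any(
            p.dock_rank != NO_RANK for p in pose_set.docked_poses):
        raise ValueError(
            f"{pose_set.complex_id}: 'rank' family requested but no pose has a "
            "docking rank; train a rank-free model for this set")
    if labeled is None:
        labeled = label_pose_set(pose_set, cutoff=rmsd_cutoff)
    rows = []
    for idx, lp in enumerate(labeled):
        vec = featurize_pose(pose_set, lp.pose, families, cutoff)
        rows.append({
            "complex_id": pose_set.complex_id,
            "pose_id": f"{pose_set.complex_id}:{idx + 1}",
            "is_crystal": lp.pose.is_crystal,
            "dock_rank": lp.pose.dock_rank if lp.pose.dock_rank != NO_RANK else pd.NA,
            "rmsd": lp.rmsd,
            "label": int(lp.label),
            **dict(zip(schema.names, vec)),
        })
    return pd.DataFrame(rows)


def assemble_dataset(pose_sets: Iterable[PoseSet], families: Sequence[str],
                     cutoff: float = DEFAULT_CONTACT_CUTOFF,
                     rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF) -> pd.DataFrame:
    """Concatenate per-set feature tables into one dataset table."""
    tables = [assemble_features(ps, families, cutoff=cutoff, rmsd_cutoff=rmsd_cutoff)
              for ps in pose_sets]
    if not tables:
        raise ValueError("no pose sets supplied")
    return pd.concat(tables, ignore_index=True)


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a dataset table."""
    return [c for c in table.columns if c not in ID_COLUMNS]
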