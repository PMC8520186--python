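"""Target-level train/test partitioning.

All schemes assign whole complexes (never individual poses) to partitions:
a random 4:1 split repeated ten times, the refined-core style hold-out, and
a threefold clustered cross-validation (CCV) in which complexes that are
similar -- by protein sequence or by ligand structure -- are forced into
the same fold.

Two complexes are *linked* (must share a fold) when their protein sequence
similarity is >= 0.5, or when it is >= 0.3 while their ligand Tanimoto
similarity is >= 0.9.  Folds are the connected components of this linkage
graph packed greedily largest-first, which guarantees that no cross-fold
pair violates the thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from rdkit import Chem
from rdkit import DataStructs

from .structio import LigandMol

__all__ = [
    "SimilarityMatrix", "SplitPlan",
    "ligand_similarity", "sequence_similarity", "similarity_matrix",
    "random_split", "refined_core_split", "clustered_cv_split",
    "PROTEIN_SIM_THRESHOLD", "PROTEIN_SIM_THRESHOLD_LOW", "LIGAND_SIM_THRESHOLD",
]

PROTEIN_SIM_THRESHOLD = 0.5      # proteins at/above this are linked
PROTEIN_SIM_THRESHOLD_LOW = 0.3  # ... or above this when the ligands are similar
LIGAND_SIM_THRESHOLD = 0.9       # ligand Tanimoto triggering the low protein threshold


# ---------------------------------------------------------------------------
# pairwise similarities
# ---------------------------------------------------------------------------

def ligand_similarity(mol_a: LigandMol | Chem.Mol, mol_b: LigandMol | Chem.Mol) -> float:
    """Tanimoto similarity of hashed path-based topological fingerprints."""
    ra = mol_a.to_rdkit() if isinstance(mol_a, LigandMol) else mol_a
    rb = mol_b.to_rdkit() if isinstance(mol_b, LigandMol) else mol_b
    if ra.GetNumAtoms() == 0 or rb.GetNumAtoms() == 0:
        raise ValueError("empty molecule")
    fa = Chem.RDKFingerprint(ra)
    fb = Chem.RDKFingerprint(rb)
    return float(DataStructs.TanimotoSimilarity(fa, fb))


_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    # global alignment scoring matches only (match=1, no mismatch/gap
    # penalties), so the optimal score equals the longest common subsequence
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1
        a.mismatch_score = 0
        a.open_gap_score = 0
        a.extend_gap_score = 0
        _ALIGNER = a
    return _ALIGNER


def sequence_similarity(seq_a: str, seq_b: str) -> float:
    """Match-count global alignment score normalized by max sequence length."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    score = _aligner().score(seq_a, seq_b)
    return float(score) / max(len(seq_a), len(seq_b))


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise protein/ligand similarities over complex ids."""

    ids: list[str]
    protein_sim: np.ndarray
    ligand_sim: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        for mat in (self.protein_sim, self.ligand_sim):
            if mat.shape != (n, n):
                raise ValueError("similarity matrix shape mismatch")
            if not np.allclose(mat, mat.T):
                raise ValueError("similarity matrix not symmetric")
            if not np.allclose(np.diag(mat), 1.0):
                raise ValueError("similarity matrix diagonal must be 1")

    def to_frames(self):
        import pandas as pd
        return (pd.DataFrame(self.protein_sim, index=self.ids, columns=self.ids),
                pd.DataFrame(self.ligand_sim, index=self.ids, columns=self.ids))


def similarity_matrix(ids: Sequence[str], sequences: Sequence[str],
                      ligands: Sequence[LigandMol]) -> SimilarityMatrix:
    """Compute the full pairwise similarity matrix for a set of complexes."""
    n = len(ids)
    if not (n == len(sequences) == len(ligands)):
        raise ValueError("ids, sequences and ligands must align")
    psim = np.eye(n)
    lsim = np.eye(n)
    fps = [Chem.RDKFingerprint(m.to_rdkit()) for m in ligands]
    for i in range(n):
        for j in range(i + 1, n):
            psim[i, j] = psim[j, i] = sequence_similarity(sequences[i], sequences[j])
            lsim[i, j] = lsim[j, i] = float(DataStructs.TanimotoSimilarity(fps[i], fps[j]))
    return SimilarityMatrix(ids=list(ids), protein_sim=psim, ligand_sim=lsim)


# ---------------------------------------------------------------------------
# split plans
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Assignment of every complex to exactly one fold."""

    assignment: dict[str, str]       # complex_id -> fold label
    scheme: str                      # random | refined_core | ccv
    seed: int | None = None

    def fold(self, label: str) -> list[str]:
        return [cid for cid, f in self.assignment.items() if f == label]

    @property
    def fold_labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"scheme": self.scheme, "seed": self.seed,
                              "assignment": self.assignment}, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "SplitPlan":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        obj = json.loads(text)
        return cls(assignment=obj["assignment"], scheme=obj["scheme"], seed=obj.get("seed"))


def random_split(ids: Sequence[str], ratio: float = 0.2, repeats: int = 10,
                 seed: int = 0) -> list[SplitPlan]:
    """Repeated random train/test splits at the target level.

    ``ratio`` is the test fraction (default 1/5, the 4:1 split); the test
    size is round(n * ratio) with banker's rounding as implemented by
    ``round``.  Reproducible under ``seed``; repeat k uses seed + k.
    """
    ids = list(ids)
    if len(ids) < 5:
        raise ValueError("need at least 5 complexes for a 4:1 split")
    n_test = int(round(len(ids) * ratio))
    plans = []
    for k in range(repeats):
        rng = np.random.default_rng(seed + k)
        order = rng.permutation(len(ids))
        test = {ids[i] for i in order[:n_test]}
        assignment = {cid: ("test" if cid in test else "train") for cid in ids}
        plans.append(SplitPlan(assignment=assignment, scheme="random", seed=seed + k))
    return plans


def refined_core_split(ids: Sequence[str], core_ids: Sequence[str]) -> SplitPlan:
    """Hold out a designated core subset as the test set."""
    ids = list(ids)
    core = set(core_ids)
    unknown = core - set(ids)
    if unknown:
        raise ValueError(f"core ids not in dataset: {sorted(unknown)}")
    if core == set(ids):
        raise ValueError("core set equals the full dataset; empty training set")
    assignment = {cid: ("test" if cid in core else "train") for cid in ids}
    return SplitPlan(assignment=assignment, scheme="refined_core")


def linkage_predicate(protein_sim: float, ligand_sim: float,
                      protein_threshold: float = PROTEIN_SIM_THRESHOLD,
                      protein_threshold_low: float = PROTEIN_SIM_THRESHOLD_LOW,
                      ligand_threshold: float = LIGAND_SIM_THRESHOLD) -> bool:
    """True when two complexes are too similar to straddle folds."""
    return (protein_sim >= protein_threshold
            or (protein_sim >= protein_threshold_low and ligand_sim >= ligand_threshold))


def clustered_cv_split(sim: SimilarityMatrix, k: int = 3,
                       protein_threshold: float = PROTEIN_SIM_THRESHOLD,
                       protein_threshold_low: float = PROTEIN_SIM_THRESHOLD_LOW,
                       ligand_threshold: float = LIGAND_SIM_THRESHOLD) -> SplitPlan:
    """Clustered k-fold assignment respecting the similarity constraints.

    Connected components of the linkage graph are packed greedily (largest
    component first, ties by smallest member id) into the currently
    smallest fold, so no linked pair can end up in different folds.
    """
    import networkx as nx
    import warnings

    n = len(sim.ids)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if linkage_predicate(sim.protein_sim[i, j], sim.ligand_sim[i, j],
                                 protein_threshold, protein_threshold_low,
                                 ligand_threshold):
                g.add_edge(i, j)
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), sim.ids[c[0]]))
    if components and len(components[0]) > n / k:
        warnings.warn(
            f"largest linked component has {len(components[0])} of {n} complexes "
            f"(> n/k); fold balance will be degraded")
    sizes = [0] * k
    assignment: dict[str, str] = {}
    for comp in components:
        fold = int(np.argmin(sizes))
        sizes[fold] += len(comp)
        for i in comp:
            assignment[sim.ids[i]] = f"fold{fold}"
    return SplitPlan(assignment=assignment, scheme="ccv")
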