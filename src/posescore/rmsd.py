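"""Symmetry-corrected heavy-atom RMSD and near-native labeling.

The RMSD between a docked pose and the crystal reference is minimized over
all graph automorphisms of the element-colored heavy-atom bond graph (bond
orders are deliberately ignored, so the result is robust to dialect-
dependent bond-order perception).  No superposition is applied: docked and
crystal poses already share the receptor frame.  Poses with RMSD strictly
below the cutoff (2.0 A by default) are labeled near-native.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.algorithms.isomorphism import GraphMatcher, categorical_node_match
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .structio import LigandMol, Pose, PoseSet

__all__ = [
    "GraphMismatchError",
    "LabeledPose",
    "symmetry_rmsd",
    "label_pose",
    "label_pose_set",
    "DEFAULT_RMSD_CUTOFF",
    "AUTOMORPHISM_CAP",
]

DEFAULT_RMSD_CUTOFF = 2.0  # Angstrom; strictly-below is near-native
AUTOMORPHISM_CAP = 10_000  # mappings enumerated before the Hungarian fallback


class GraphMismatchError(ValueError):
    """Pose and reference bond graphs are not isomorphic."""


def _to_graph(mol: LigandMol) -> nx.Graph:
    g = nx.Graph()
    for i, atom in enumerate(mol.atoms):
        g.add_node(i, element=atom.element)
    for b in mol.bonds:
        g.add_edge(b.i, b.j)
    return g


def symmetry_rmsd(pose_mol: LigandMol, reference: LigandMol,
                  cap: int = AUTOMORPHISM_CAP) -> float:
    """Minimum in-place heavy-atom RMSD over graph-isomorphic atom mappings.

    Pose and reference must share the heavy-atom formula and have isomorphic
    bond graphs (element-colored).  When the number of isomorphic mappings
    exceeds ``cap``, a per-element Hungarian assignment on the distance
    matrix is used instead (a lower-bound heuristic) with a warning.
    """
    if pose_mol.formula() != reference.formula():
        raise GraphMismatchError("heavy-atom formula mismatch")
    gp, gr = _to_graph(pose_mol), _to_graph(reference)
    matcher = GraphMatcher(gr, gp, node_match=categorical_node_match("element", None))
    if not matcher.is_isomorphic():
        raise GraphMismatchError("pose and reference bond graphs are not isomorphic")

    xyz_p = pose_mol.coords
    xyz_r = reference.coords
    n = len(reference)
    best = np.inf
    count = 0
    for mapping in GraphMatcher(gr, gp, node_match=categorical_node_match("element", None)).isomorphisms_iter():
        count += 1
        if count > cap:
            warnings.warn(
                f"more than {cap} graph mappings; falling back to per-element "
                "Hungarian assignment (lower-bound heuristic)")
            return _hungarian_rmsd(pose_mol, reference)
        perm = np.empty(n, dtype=int)
        for r_idx, p_idx in mapping.items():
            perm[r_idx] = p_idx
        sq = np.sum((xyz_r - xyz_p[perm]) ** 2)
        if sq < best:
            best = sq
    return float(np.sqrt(best / n))


def _hungarian_rmsd(pose_mol: LigandMol, reference: LigandMol) -> float:
    """Element-wise optimal assignment RMSD (ignores connectivity)."""
    xyz_p = pose_mol.coords
    xyz_r = reference.coords
    elems_p = np.array(pose_mol.elements)
    elems_r = np.array(reference.elements)
    total_sq = 0.0
    for el in np.unique(elems_r):
        rp = xyz_p[elems_p == el]
        rr = xyz_r[elems_r == el]
        d2 = cdist(rr, rp, metric="sqeuclidean")
        rows, cols = linear_sum_assignment(d2)
        total_sq += d2[rows, cols].sum()
    return float(np.sqrt(total_sq / len(reference)))


def label_pose(rmsd: float, cutoff: float = DEFAULT_RMSD_CUTOFF) -> bool:
    """Near-native label: True iff ``rmsd < cutoff`` (strict inequality)."""
    if rmsd < 0 or not np.isfinite(rmsd):
        raise ValueError(f"invalid RMSD: {rmsd}")
    return rmsd < cutoff


@dataclass
class LabeledPose:
    pose: Pose
    rmsd: float
    label: bool


def label_pose_set(pose_set: PoseSet, cutoff: float = DEFAULT_RMSD_CUTOFF,
                   cap: int = AUTOMORPHISM_CAP) -> list[LabeledPose]:
    """Compute symmetry-corrected RMSDs and labels for every pose in a set.

    Crystal poses get RMSD 0.0 by definition.
    """
    out = []
    for idx, pose in enumerate(pose_set.poses):
        if pose.is_crystal:
            rmsd = 0.0
        else:
            try:
                rmsd = symmetry_rmsd(pose.mol, pose_set.reference, cap=cap)
            except GraphMismatchError as exc:
                raise GraphMismatchError(f"{pose_set.complex_id}: pose {idx + 1}: {exc}") from exc
        out.append(LabeledPose(pose=pose, rmsd=rmsd, label=label_pose(rmsd, cutoff)))
    return out
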