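"""Docking-power evaluation of scored pose sets.

Metrics follow the CASF-style docking-power protocol: pooled (inter-target)
and per-complex averaged (intra-target) AUROC and Spearman rank
correlation, top-k success rates SR_k with their ceiling, binding-funnel
analysis over nested RMSD windows, an ensemble-docking pooling strategy,
complex-level bootstrap uncertainty, and paired Wilcoxon signed-rank
comparisons between methods.

Score orientation: higher = more likely near-native (classifier
probability of the positive class).  Spearman values are reported as
Rs = -spearman(score, RMSD), so a good method scores positive; the funnel
analysis reports the magnitude of the per-complex correlation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .rmsd import DEFAULT_RMSD_CUTOFF

__all__ = [
    "ScoredPoseSet", "IntraResult", "EvalReport",
    "inter_metrics", "intra_metrics", "success_rate", "ceiling",
    "funnel_analysis", "ensemble_pool", "bootstrap", "compare_methods",
    "per_complex_success", "evaluate_sets", "sets_from_table",
    "DEFAULT_FUNNEL_WINDOWS",
]

DEFAULT_FUNNEL_WINDOWS = tuple((0.0, float(w)) for w in range(2, 11))


@dataclass
class ScoredPoseSet:
    """Scores, RMSDs, and labels for one docking campaign's poses."""

    complex_id: str
    scores: np.ndarray
    rmsds: np.ndarray
    labels: np.ndarray                    # bool; near-native
    dock_ranks: np.ndarray | None = None  # 0/NaN = missing
    is_crystal: np.ndarray | None = None
    ligand_id: str = ""                   # for ensemble pooling

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.rmsds = np.asarray(self.rmsds, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        n = len(self.scores)
        if not (len(self.rmsds) == len(self.labels) == n):
            raise ValueError("scores/rmsds/labels length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError(f"{self.complex_id}: non-finite scores")
        if self.dock_ranks is None:
            self.dock_ranks = np.zeros(n)
        else:
            self.dock_ranks = np.asarray(self.dock_ranks, dtype=float)
        if self.is_crystal is None:
            self.is_crystal = np.zeros(n, dtype=bool)
        else:
            self.is_crystal = np.asarray(self.is_crystal, dtype=bool)
        if not self.ligand_id:
            self.ligand_id = self.complex_id

    def __len__(self) -> int:
        return len(self.scores)

    def without_crystal(self) -> "ScoredPoseSet":
        keep = ~self.is_crystal
        return ScoredPoseSet(self.complex_id, self.scores[keep], self.rmsds[keep],
                             self.labels[keep], self.dock_ranks[keep],
                             self.is_crystal[keep], self.ligand_id)

    def top_k_order(self) -> np.ndarray:
        """Pose indices by score desc, then dock rank asc, then pose order."""
        n = len(self)
        ranks = np.where((self.dock_ranks > 0) & np.isfinite(self.dock_ranks),
                         self.dock_ranks, np.inf)
        return np.lexsort((np.arange(n), ranks, -self.scores))


def sets_from_table(table: pd.DataFrame,
                    cutoff: float = DEFAULT_RMSD_CUTOFF) -> list[ScoredPoseSet]:
    """Build scored sets from a table with columns complex_id, score, rmsd
    and optionally dock_rank, is_crystal, ligand_id."""
    required = {"complex_id", "score", "rmsd"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"scored-pose table missing columns: {sorted(missing)}")
    out = []
    for cid, grp in table.groupby("complex_id", sort=True):
        ranks = grp["dock_rank"].to_numpy(dtype=float) if "dock_rank" in grp else None
        xtal = grp["is_crystal"].to_numpy(dtype=bool) if "is_crystal" in grp else None
        lig = str(grp["ligand_id"].iloc[0]) if "ligand_id" in grp else ""
        rmsds = grp["rmsd"].to_numpy(dtype=float)
        out.append(ScoredPoseSet(str(cid), grp["score"].to_numpy(dtype=float),
                                 rmsds, rmsds < cutoff, ranks, xtal, lig))
    return out


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------

def _pool(all_sets: Sequence[ScoredPoseSet]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    scores = np.concatenate([s.scores for s in all_sets])
    rmsds = np.concatenate([s.rmsds for s in all_sets])
    labels = np.concatenate([s.labels for s in all_sets])
    return scores, rmsds, labels


def inter_metrics(all_sets: Sequence[ScoredPoseSet]) -> tuple[float, float]:
    """Pooled AUROC and pooled Rs = -spearman(score, RMSD)."""
    scores, rmsds, labels = _pool(all_sets)
    if len(scores) < 2:
        raise ValueError("need at least 2 pooled poses")
    if labels.all() or not labels.any():
        raise ValueError("pooled poses contain a single class; AUROC undefined")
    auroc = float(roc_auc_score(labels, scores))
    if len(np.unique(scores)) < 2 or len(np.unique(rmsds)) < 2:
        rs = 0.0   # correlation undefined on constant input
    else:
        rs = -float(stats.spearmanr(scores, rmsds).statistic)
    return auroc, rs


@dataclass
class IntraResult:
    auroc: float
    rs: float
    n_auroc: int        # complexes contributing to the AUROC average
    n_rs: int
    skipped_auroc: int  # complexes skipped (single class / too few poses)
    skipped_rs: int


def intra_metrics(all_sets: Sequence[ScoredPoseSet]) -> IntraResult:
    """Per-complex AUROC/Rs averaged over evaluable complexes.

    Complexes where a statistic is undefined (fewer than two poses, a
    single label class, or zero rank variance) are skipped and counted.
    """
    aurocs, rss = [], []
    skipped_a = skipped_r = 0
    for s in all_sets:
        if len(s) >= 2 and s.labels.any() and not s.labels.all():
            aurocs.append(float(roc_auc_score(s.labels, s.scores)))
        else:
            skipped_a += 1
        if len(s) >= 2 and len(np.unique(s.rmsds)) > 1 and len(np.unique(s.scores)) > 1:
            rss.append(-float(stats.spearmanr(s.scores, s.rmsds).statistic))
        else:
            skipped_r += 1
    if not aurocs and not rss:
        raise ValueError("no evaluable complex for intra-target metrics")
    return IntraResult(
        auroc=float(np.mean(aurocs)) if aurocs else float("nan"),
        rs=float(np.mean(rss)) if rss else float("nan"),
        n_auroc=len(aurocs), n_rs=len(rss),
        skipped_auroc=skipped_a, skipped_rs=skipped_r)


# ---------------------------------------------------------------------------
# success rates
# ---------------------------------------------------------------------------

def per_complex_success(s: ScoredPoseSet, k: int,
                        cutoff: float = DEFAULT_RMSD_CUTOFF) -> bool:
    """Whether any of the k top-scored poses has RMSD < cutoff."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(s) == 0:
        raise ValueError(f"{s.complex_id}: empty scored set")
    top = s.top_k_order()[:k]
    return bool((s.rmsds[top] < cutoff).any())


def success_rate(all_sets: Sequence[ScoredPoseSet], k: int,
                 cutoff: float = DEFAULT_RMSD_CUTOFF) -> float:
    """SR_k: fraction of complexes solved within the top k scored poses."""
    if not all_sets:
        raise ValueError("no scored sets")
    return float(np.mean([per_complex_success(s, k, cutoff) for s in all_sets]))


def ceiling(all_sets: Sequence[ScoredPoseSet],
            cutoff: float = DEFAULT_RMSD_CUTOFF) -> float:
    """Upper bound of any SR_k: fraction of complexes holding at least one
    near-native pose."""
    if not all_sets:
        raise ValueError("no scored sets")
    return float(np.mean([bool((s.rmsds < cutoff).any()) for s in all_sets]))


# ---------------------------------------------------------------------------
# binding-funnel analysis
# ---------------------------------------------------------------------------

def funnel_analysis(all_sets: Sequence[ScoredPoseSet],
                    windows: Sequence[tuple[float, float]] = DEFAULT_FUNNEL_WINDOWS,
                    min_poses: int = 3) -> dict[tuple[float, float], float]:
    """Mean per-complex |spearman(score, RMSD)| within nested RMSD windows.

    A complex contributes to a window only when at least ``min_poses`` of
    its poses fall inside it with both score and RMSD variation; windows
    with no evaluable complex map to NaN.
    """
    out: dict[tuple[float, float], float] = {}
    for lo, hi in windows:
        vals = []
        for s in all_sets:
            inside = (s.rmsds >= lo) & (s.rmsds <= hi)
            if inside.sum() < min_poses:
                continue
            r, sc = s.rmsds[inside], s.scores[inside]
            if len(np.unique(r)) < 2 or len(np.unique(sc)) < 2:
                continue
            vals.append(abs(float(stats.spearmanr(sc, r).statistic)))
        out[(lo, hi)] = float(np.mean(vals)) if vals else float("nan")
    return out


# ---------------------------------------------------------------------------
# ensemble pooling
# ---------------------------------------------------------------------------

def ensemble_pool(all_sets: Sequence[ScoredPoseSet]) -> list[ScoredPoseSet]:
    """Pool every ligand's poses across receptors into one set per ligand.

    Each pose keeps the RMSD computed against its own receptor's reference,
    so downstream success is judged on the selected pose's own RMSD.
    """
    by_ligand: dict[str, list[ScoredPoseSet]] = {}
    for s in all_sets:
        by_ligand.setdefault(s.ligand_id, []).append(s)
    pooled = []
    for lig, group in sorted(by_ligand.items()):
        pooled.append(ScoredPoseSet(
            complex_id=lig,
            scores=np.concatenate([s.scores for s in group]),
            rmsds=np.concatenate([s.rmsds for s in group]),
            labels=np.concatenate([s.labels for s in group]),
            dock_ranks=np.concatenate([s.dock_ranks for s in group]),
            is_crystal=np.concatenate([s.is_crystal for s in group]),
            ligand_id=lig))
    return pooled


# ---------------------------------------------------------------------------
# uncertainty and paired comparison
# ---------------------------------------------------------------------------

def bootstrap(statistic: Callable[[Sequence[ScoredPoseSet]], float],
              all_sets: Sequence[ScoredPoseSet], n_boot: int = 1000,
              seed: int = 0) -> tuple[float, float]:
    """Bootstrap a statistic by resampling complexes with replacement."""
    if len(all_sets) < 2:
        raise ValueError("need at least 2 complexes to bootstrap")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    n = len(all_sets)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        vals[b] = statistic([all_sets[i] for i in idx])
    return float(vals.mean()), float(vals.std())


def compare_methods(values_a: Sequence[float], values_b: Sequence[float]
                    ) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired per-complex values.

    All-zero differences yield (0.0, 1.0) by convention; very small
    samples trigger an underpowered-test warning but still report the
    exact p-value.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired value vectors must have equal length")
    diffs = a - b
    if np.all(diffs == 0):
        return 0.0, 1.0
    if len(a) < 6:
        warnings.warn(f"only {len(a)} pairs: Wilcoxon test is underpowered")
    res = stats.wilcoxon(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    metrics: dict[str, dict]
    skipped: dict[str, int] = field(default_factory=dict)
    comparisons: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"metrics": self.metrics, "skipped": self.skipped,
                              "comparisons": self.comparisons}, indent=2,
                             sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def evaluate_sets(all_sets: Sequence[ScoredPoseSet],
                  ks: Sequence[int] = (1, 3),
                  cutoff: float = DEFAULT_RMSD_CUTOFF,
                  n_boot: int = 1000, seed: int = 0,
                  exclude_crystal: bool = True,
                  funnel: bool = True) -> EvalReport:
    """Compute the full docking-power report with bootstrap uncertainty.

    Crystal poses are excluded from the test-time sets by default, so the
    success rates reflect only the docking program's own poses.
    """
    sets = [s.without_crystal() for s in all_sets] if exclude_crystal else list(all_sets)
    sets = [s for s in sets if len(s) > 0]
    if not sets:
        raise ValueError("no poses left to evaluate")
    metrics: dict[str, dict] = {}

    def record(name: str, stat: Callable[[Sequence[ScoredPoseSet]], float]) -> None:
        value = stat(sets)
        entry = {"value": value, "n_boot": 0}
        if n_boot > 0 and len(sets) >= 2:
            mean, sd = bootstrap(stat, sets, n_boot=n_boot, seed=seed)
            entry.update({"boot_mean": mean, "boot_sd": sd, "n_boot": n_boot})
        metrics[name] = entry

    record("inter_auroc", lambda ss: inter_metrics(ss)[0])
    record("inter_rs", lambda ss: inter_metrics(ss)[1])
    record("intra_auroc", lambda ss: intra_metrics(ss).auroc)
    record("intra_rs", lambda ss: intra_metrics(ss).rs)
    for k in ks:
        record(f"sr{k}", lambda ss, k=k: success_rate(ss, k, cutoff))
    record("ceiling", lambda ss: ceiling(ss, cutoff))

    intra = intra_metrics(sets)
    skipped = {"intra_auroc": intra.skipped_auroc, "intra_rs": intra.skipped_rs}
    report = EvalReport(metrics=metrics, skipped=skipped)
    if funnel:
        fw = funnel_analysis(sets)
        report.metrics["funnel"] = {
            "value": {f"0-{int(hi)}": v for (lo, hi), v in fw.items()}, "n_boot": 0}
    return report
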