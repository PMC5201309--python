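"""Docking post-analysis: common-scaffold RMSD, pose clustering, and
virtual-screening enrichment metrics.

Poses are compared in the shared receptor frame — no superposition before
RMSD unless explicitly requested — because docked poses of a common scaffold
already live in one coordinate system. Clustering is complete-linkage
agglomeration cut at an RMSD threshold (default 2.5 Å), which bounds the
within-cluster scaffold spread. Ranked active/decoy lists are summarized by
the enrichment factor EF@x% = (tp/selected)/(TA/N) and the ROC curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

log = logging.getLogger(__name__)

__all__ = [
    "PoseSet",
    "EnrichmentResult",
    "scaffold_rmsd",
    "pose_rmsd_matrix",
    "cluster_poses",
    "enrichment_factor",
    "roc_curve",
]


@dataclass
class PoseSet:
    """All scaffold-atom poses of one ligand, with their docking scores."""

    ligand_id: str
    poses: np.ndarray   # (n_poses, n_scaffold_atoms, 3)
    scores: np.ndarray  # (n_poses,)

    def __post_init__(self):
        self.poses = np.asarray(self.poses, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.poses.ndim != 3 or self.poses.shape[2] != 3:
            raise ValueError("poses must have shape (n_poses, n_atoms, 3)")
        if len(self.scores) != len(self.poses):
            raise ValueError("one score per pose required")


@dataclass
class EnrichmentResult:
    fraction: float  # %
    tp: int
    fp: int
    TA: int
    N: int
    ef: float
    auc: float | None = None

    def __post_init__(self):
        if self.tp > self.TA:
            raise ValueError("true positives cannot exceed total actives")
        if self.ef < 0:
            raise ValueError("EF cannot be negative")


def _kabsch_align(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Optimal rotation of b onto a (both centered); returns moved b."""
    ac, bc = a - a.mean(axis=0), b - b.mean(axis=0)
    H = bc.T @ ac
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    return bc @ R + a.mean(axis=0)


def scaffold_rmsd(a: np.ndarray, b: np.ndarray, *, superpose: bool = False) -> float:
    """RMSD over matched scaffold atoms, √(mean ‖a_i − b_i‖²), in Å.

    Atom ordering must agree; by default no superposition is performed (the
    receptor frame is shared). ``superpose`` enables Kabsch fitting for
    frame-free comparisons.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ or are not (n, 3): {a.shape} vs {b.shape}")
    if superpose:
        b = _kabsch_align(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def pose_rmsd_matrix(pose_sets: list[PoseSet]) -> tuple[np.ndarray, list[str]]:
    """Stack every pose of every ligand and return the full pairwise RMSD
    matrix plus the ligand id of each row."""
    all_poses = np.concatenate([ps.poses for ps in pose_sets])
    ligand_of = [ps.ligand_id for ps in pose_sets for _ in range(len(ps.poses))]
    n = len(all_poses)
    diffs = all_poses[:, None, :, :] - all_poses[None, :, :, :]
    D = np.sqrt(np.mean(np.sum(diffs**2, axis=3), axis=2))
    D[np.arange(n), np.arange(n)] = 0.0
    return D, ligand_of


def cluster_poses(
    rmsd_matrix: np.ndarray,
    cutoff: float = 2.5,
    ligand_ids: list[str] | None = None,
    method: str = "complete",
) -> tuple[np.ndarray, dict[int, set[str]]]:
    """Agglomerative clustering of poses, merging while linkage < cutoff.

    Returns (cluster label per pose, per-cluster set of distinct ligand ids —
    the "12/12 ligands in one cluster" style coverage report). Labels are
    renumbered 0..k−1 by decreasing cluster size (ties by first occurrence).
    """
    D = np.asarray(rmsd_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("rmsd_matrix must be square")
    if np.isnan(D).any():
        raise ValueError("NaN in RMSD matrix")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("RMSD matrix must be symmetric")
    n = D.shape[0]
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        Z = linkage(squareform(D, checks=False), method=method)
        raw = fcluster(Z, t=cutoff, criterion="distance")
        order: dict[int, int] = {}
        sizes = {lab: int((raw == lab).sum()) for lab in np.unique(raw)}
        for lab in sorted(sizes, key=lambda l: (-sizes[l], np.flatnonzero(raw == l)[0])):
            order[lab] = len(order)
        labels = np.array([order[l] for l in raw])
    coverage: dict[int, set[str]] = {}
    if ligand_ids is not None:
        if len(ligand_ids) != n:
            raise ValueError("one ligand id per pose required")
        for lab, lig in zip(labels, ligand_ids):
            coverage.setdefault(int(lab), set()).add(lig)
    return labels, coverage


def enrichment_factor(
    scores: np.ndarray, labels: np.ndarray, fraction: float
) -> EnrichmentResult:
    """EF at the top ``fraction`` % of the score-ranked list.

    EF = (tp/(tp+fp)) / (TA/N); ranking is by descending score with ties
    broken by stable input order (logged when present).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    N = len(scores)
    if len(labels) != N:
        raise ValueError("scores and labels length mismatch")
    TA = int(labels.sum())
    if TA == 0:
        raise ValueError("at least one active required")
    if not 0 < fraction <= 100:
        raise ValueError(f"fraction must be in (0, 100], got {fraction}")
    n_sel = int(round(fraction * N / 100.0))
    if n_sel == 0:
        raise ValueError(f"fraction {fraction}% of {N} compounds selects nothing")
    order = np.argsort(-scores, kind="stable")
    if len(np.unique(scores)) < N:
        log.debug("tied scores present; ties broken by stable input order")
    sel = order[:n_sel]
    tp = int(labels[sel].sum())
    fp = n_sel - tp
    ef = (tp / n_sel) / (TA / N)
    return EnrichmentResult(fraction=fraction, tp=tp, fp=fp, TA=TA, N=N, ef=ef)


def roc_curve(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by threshold sweep; AUC by trapezoid (equals the Mann–Whitney
    U statistic scaled by n₁·n₀)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present for a ROC curve")
    fpr, tpr, _ = _sk_roc_curve(labels.astype(int), scores)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))
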