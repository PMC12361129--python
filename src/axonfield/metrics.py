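"""Skeleton-matching evaluation and the Aggregated Jaccard Index.

A predicted skeleton point counts as matched when it lies strictly within
``thre`` voxels (Euclidean, default 3) of some ground-truth point, and vice
versa; recall, precision and F1 follow.  For topology, each connected
skeleton's radius-3 expanded region forms one instance, and the AJI
aggregates matched-pair intersections over unions plus all unmatched
instance sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io import SkeletonTree
from .labels import expand_region

__all__ = [
    "MatchConfig",
    "EvalReport",
    "match_indicator",
    "skeleton_scores",
    "instances_from_skeletons",
    "aji",
    "evaluate_skeletons",
]


@dataclass
class MatchConfig:
    """Matching threshold and instance-region parameters (voxel units)."""

    thre: float = 3.0
    squared_norm: bool = False  # compare squared distances against thre instead
    region_radius: float = 3.0

    def __post_init__(self) -> None:
        if self.thre <= 0:
            raise ValueError("thre must be positive")


@dataclass
class EvalReport:
    recall: float
    precision: float
    f1: float
    n_g: int
    n_p: int
    aji: float | None = None
    matched_pairs: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "n_g": self.n_g,
            "n_p": self.n_p,
            "aji": self.aji,
            "matched_pairs": [list(p) for p in self.matched_pairs],
        }


def _min_dists(points: np.ndarray, reference: np.ndarray) -> np.ndarray:
    d, _ = cKDTree(reference).query(points)
    return d


def match_indicator(p: np.ndarray, G: np.ndarray, thre: float = 3.0,
                    squared_norm: bool = False) -> int:
    """1 iff the nearest point of ``G`` is strictly closer than ``thre``."""
    G = np.asarray(G, dtype=float)
    if G.size == 0:
        raise ValueError("reference point set is empty")
    d = float(np.min(np.linalg.norm(G - np.asarray(p, dtype=float), axis=1)))
    if squared_norm:
        d = d * d
    return int(d < thre)


def _f1(recall: float, precision: float) -> float:
    s = recall + precision
    if not np.isfinite(s) or s <= 0:
        return np.nan if not np.isfinite(s) else 0.0
    return 2.0 * recall * precision / s


def skeleton_scores(P: np.ndarray, G: np.ndarray,
                    cfg: MatchConfig | None = None) -> tuple[float, float, float]:
    """Recall, precision and F1 between point sets.

    Recall is the fraction of ground-truth points within ``thre`` of a
    predicted point; precision the converse.  Both sets empty is perfect by
    convention (nothing to find, nothing found); an empty reference side
    makes the corresponding score undefined (NaN, with a warning).
    """
    cfg = cfg or MatchConfig()
    P = np.asarray(P, dtype=float).reshape(-1, 3) if np.size(P) else np.empty((0, 3))
    G = np.asarray(G, dtype=float).reshape(-1, 3) if np.size(G) else np.empty((0, 3))
    if len(P) == 0 and len(G) == 0:
        return 1.0, 1.0, 1.0

    thre = cfg.thre

    def frac_matched(query: np.ndarray, ref: np.ndarray) -> float:
        if len(query) == 0:
            return np.nan
        if len(ref) == 0:
            return 0.0
        d = _min_dists(query, ref)
        if cfg.squared_norm:
            d = d * d
        return float(np.mean(d < thre))

    recall = frac_matched(G, P)
    precision = frac_matched(P, G)
    if np.isnan(recall) or np.isnan(precision):
        warnings.warn("one point set is empty; the corresponding score is undefined")
    return recall, precision, _f1(recall, precision)


def instances_from_skeletons(trees: Sequence[SkeletonTree],
                             shape: tuple[int, int, int],
                             region_radius: float = 3.0) -> np.ndarray:
    """Label each tree's expanded region with a distinct instance id.

    Voxels claimed by several trees go to the nearer skeleton (ties to the
    lower tree id).  Returns an integer array with ids contiguous from 1 and
    0 for background.
    """
    labels = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf, dtype=np.float64)
    next_label = 0
    for tree in sorted(trees, key=lambda t: t.tree_id):
        pos = tree.positions()
        if pos.shape[0] == 0:
            continue
        next_label += 1
        mask = expand_region([tree], shape, region_radius)
        vz, vy, vx = np.nonzero(mask)
        if vz.size == 0:
            continue
        pts = np.stack([vx, vy, vz], axis=1).astype(float)
        d = _min_dists(pts, pos)
        closer = d < best[vz, vy, vx]  # strict: ties keep the earlier (lower) id
        labels[vz[closer], vy[closer], vx[closer]] = next_label
        best[vz[closer], vy[closer], vx[closer]] = d[closer]
    # compact ids: a tree fully claimed by a nearer neighbor must not leave a gap
    present = np.unique(labels)
    present = present[present > 0]
    if present.size and (present[-1] != present.size):
        remap = np.zeros(int(present[-1]) + 1, dtype=np.int32)
        remap[present] = np.arange(1, present.size + 1, dtype=np.int32)
        labels = remap[labels]
    return labels


def _instance_sizes(labels: np.ndarray) -> dict[int, int]:
    ids, counts = np.unique(labels, return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts) if i > 0}


def aji(G_map: np.ndarray, P_map: np.ndarray,
        return_pairs: bool = False):
    """Aggregated Jaccard Index between two instance maps.

    Greedy over ground-truth instances in ascending id: each is paired with
    the unused predicted instance of largest Jaccard index (ties to the
    lowest predicted id); zero-overlap instances stay unmatched.  The score
    sums matched intersections over matched unions plus the sizes of every
    unmatched instance on either side.
    """
    G_map = np.asarray(G_map)
    P_map = np.asarray(P_map)
    if G_map.shape != P_map.shape:
        raise ValueError(f"shape mismatch: {G_map.shape} vs {P_map.shape}")

    g_sizes = _instance_sizes(G_map)
    p_sizes = _instance_sizes(P_map)
    if not g_sizes and not p_sizes:
        return (1.0, []) if return_pairs else 1.0

    both = (G_map > 0) & (P_map > 0)
    overlaps: dict[int, dict[int, int]] = {}
    if both.any():
        gids = G_map[both].ravel()
        pids = P_map[both].ravel()
        pair_ids, counts = np.unique(np.stack([gids, pids]), axis=1, return_counts=True)
        for (gi, pj), c in zip(pair_ids.T, counts):
            overlaps.setdefault(int(gi), {})[int(pj)] = int(c)

    used_p: set[int] = set()
    matched: list[tuple[int, int]] = []
    inter_sum = 0
    union_sum = 0
    for gi in sorted(g_sizes):
        cands = overlaps.get(gi, {})
        best_j, best_jac = None, 0.0
        for pj in sorted(cands):
            if pj in used_p:
                continue
            inter = cands[pj]
            union = g_sizes[gi] + p_sizes[pj] - inter
            jac = inter / union
            if jac > best_jac:
                best_j, best_jac = pj, jac
        if best_j is not None:
            used_p.add(best_j)
            matched.append((gi, best_j))
            inter = cands[best_j]
            inter_sum += inter
            union_sum += g_sizes[gi] + p_sizes[best_j] - inter

    unmatched_g = sum(g_sizes[gi] for gi in g_sizes if gi not in {m[0] for m in matched})
    unmatched_p = sum(p_sizes[pj] for pj in p_sizes if pj not in used_p)
    denom = union_sum + unmatched_g + unmatched_p
    score = inter_sum / denom if denom > 0 else 1.0
    return (score, matched) if return_pairs else score


def evaluate_skeletons(pred_trees: Sequence[SkeletonTree],
                       truth_trees: Sequence[SkeletonTree],
                       shape: tuple[int, int, int],
                       cfg: MatchConfig | None = None,
                       resample: bool = True) -> EvalReport:
    """Full report comparing predicted against ground-truth skeletons.

    Point sets are the (by default resampled, ≤1-voxel-spaced) node positions
    of each side; instance maps come from per-tree region expansion.
    """
    from .labels import resample_skeleton

    cfg = cfg or MatchConfig()
    if resample:
        pred_trees = [resample_skeleton(t) for t in pred_trees]
        truth_trees = [resample_skeleton(t) for t in truth_trees]
    P = np.concatenate([t.positions() for t in pred_trees], axis=0) if pred_trees else np.empty((0, 3))
    G = np.concatenate([t.positions() for t in truth_trees], axis=0) if truth_trees else np.empty((0, 3))
    recall, precision, f1 = skeleton_scores(P, G, cfg)
    g_map = instances_from_skeletons(truth_trees, shape, cfg.region_radius)
    p_map = instances_from_skeletons(pred_trees, shape, cfg.region_radius)
    score, pairs = aji(g_map, p_map, return_pairs=True)
    return EvalReport(recall=recall, precision=precision, f1=f1,
                      n_g=int(len(G)), n_p=int(len(P)), aji=score, matched_pairs=pairs)
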