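"""Distance-field supervision labels from axonal skeletons.

The label-generation protocol has three stages:

1. **Resampling** — interpolate skeleton nodes so adjacent points are at most
   ``max_spacing`` (default 1) voxel apart.
2. **Region expansion** — the union of open balls of ``expand_radius``
   (default 3) voxels centred on every skeleton point:
   ``S_reg = {v : min_i ||v - s_i|| < r}``.
3. **Distance field** — inside the expanded region each voxel gets
   ``exp(-dist_perp / (2 sigma^2))`` where ``dist_perp`` is the perpendicular
   distance from the voxel to the local centerline direction at its nearest
   skeleton point.  The field is 1 on the centerline and decays outward;
   it is 0 outside the expanded region.

By default the exponent is linear in the distance (not the conventional
squared form); ``LabelConfig.squared_exponent`` switches to a true Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io import SkeletonNode, SkeletonTree

__all__ = [
    "LabelConfig",
    "resample_skeleton",
    "expand_region",
    "perpendicular_distance",
    "make_distance_field",
]


@dataclass
class LabelConfig:
    """Parameters of the label-generation protocol (all in voxel units)."""

    max_spacing: float = 1.0
    expand_radius: float = 3.0
    sigma: float = 2.0
    strict_less: bool = True  # "< radius" as printed; False uses "<="
    squared_exponent: bool = False  # exp(-d^2/(2 sigma^2)) instead of exp(-d/(2 sigma^2))

    def __post_init__(self) -> None:
        if self.max_spacing <= 0 or self.expand_radius <= 0 or self.sigma <= 0:
            raise ValueError("max_spacing, expand_radius and sigma must be positive")


def resample_skeleton(tree: SkeletonTree, max_spacing: float = 1.0) -> SkeletonTree:
    """Insert nodes so every parent-child edge is at most ``max_spacing`` long.

    Original nodes are kept at their exact positions; inserted nodes are
    evenly spaced on the straight segment between the original endpoints.
    Node ids are renumbered consecutively in the output.
    """
    if max_spacing <= 0:
        raise ValueError("max_spacing must be positive")
    if not tree.nodes:
        return SkeletonTree(nodes=[], tree_id=tree.tree_id)

    by_id = tree.node_by_id()
    out_nodes: list[SkeletonNode] = []
    new_id_of: dict[int, int] = {}
    next_id = 1

    def emit(structure_type: int, pos: np.ndarray, radius: float, parent_new: int) -> int:
        nonlocal next_id
        out_nodes.append(
            SkeletonNode(
                id=next_id,
                structure_type=structure_type,
                position=np.array(pos, dtype=float),
                radius=radius,
                parent_id=parent_new,
            )
        )
        next_id += 1
        return next_id - 1

    for node in tree.nodes:
        if node.parent_id == -1:
            new_id_of[node.id] = emit(node.structure_type, node.position, node.radius, -1)
            continue
        parent = by_id[node.parent_id]
        start, end = parent.position, node.position
        length = float(np.linalg.norm(end - start))
        n_seg = max(1, int(np.ceil(length / max_spacing - 1e-12)))
        prev = new_id_of[parent.id]
        for k in range(1, n_seg):
            pos = start + (end - start) * (k / n_seg)
            prev = emit(node.structure_type, pos, node.radius, prev)
        new_id_of[node.id] = emit(node.structure_type, node.position, node.radius, prev)

    return SkeletonTree(nodes=out_nodes, tree_id=tree.tree_id)


def expand_region(
    trees: Sequence[SkeletonTree],
    shape: tuple[int, int, int],
    radius: float = 3.0,
    strict_less: bool = True,
) -> np.ndarray:
    """Union of radius-``radius`` balls around all skeleton points.

    ``shape`` is in array order ``(nz, ny, nx)``; the returned boolean mask is
    indexed ``[z, y, x]``.  A voxel ``v`` (integer lattice point) is inside
    iff ``min_i ||v - s_i|| < radius`` (strict inequality by default).
    Balls are clipped at the grid boundary.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    nz, ny, nx = shape
    mask = np.zeros(shape, dtype=bool)
    r = float(radius)
    for tree in trees:
        for pos in tree.positions():
            x, y, z = pos
            zlo, zhi = max(0, int(np.ceil(z - r))), min(nz - 1, int(np.floor(z + r)))
            ylo, yhi = max(0, int(np.ceil(y - r))), min(ny - 1, int(np.floor(y + r)))
            xlo, xhi = max(0, int(np.ceil(x - r))), min(nx - 1, int(np.floor(x + r)))
            if zlo > zhi or ylo > yhi or xlo > xhi:
                continue
            zz, yy, xx = np.meshgrid(
                np.arange(zlo, zhi + 1), np.arange(ylo, yhi + 1), np.arange(xlo, xhi + 1),
                indexing="ij",
            )
            d2 = (xx - x) ** 2 + (yy - y) ** 2 + (zz - z) ** 2
            inside = d2 < r * r if strict_less else d2 <= r * r
            mask[zlo : zhi + 1, ylo : yhi + 1, xlo : xhi + 1] |= inside
    return mask


def _node_directions(tree: SkeletonTree) -> tuple[np.ndarray, dict[int, list[np.ndarray]]]:
    """Unit local direction per node (by index in ``tree.nodes``).

    The primary direction points toward the node's first child; a leaf reuses
    its incoming (parent) direction.  Branch points additionally carry the
    directions toward their other children so the caller can take the
    minimizing segment.  An isolated node gets a zero direction (callers fall
    back to plain Euclidean distance).
    """
    idx_of = {n.id: i for i, n in enumerate(tree.nodes)}
    children = tree.children_of()
    by_id = tree.node_by_id()
    dirs = np.zeros((len(tree.nodes), 3))
    extras: dict[int, list[np.ndarray]] = {}

    def unit(v: np.ndarray) -> np.ndarray:
        n = np.linalg.norm(v)
        return v / n if n > 0 else np.zeros(3)

    for i, node in enumerate(tree.nodes):
        kids = sorted(children[node.id])  # lowest id first: deterministic primary
        cand = [unit(by_id[k].position - node.position) for k in kids]
        cand = [c for c in cand if np.any(c)]
        if not cand:
            if node.parent_id != -1:
                dirs[i] = unit(node.position - by_id[node.parent_id].position)
            continue
        dirs[i] = cand[0]
        if len(cand) > 1:
            extras[i] = cand[1:]
    return dirs, extras


def _perp_distances(points: np.ndarray, tree: SkeletonTree, kdtree: cKDTree | None = None) -> np.ndarray:
    """Perpendicular centerline distance for each query point (vectorized)."""
    pos = tree.positions()
    if pos.shape[0] == 0:
        raise ValueError("tree has no nodes")
    if kdtree is None:
        kdtree = cKDTree(pos)
    _, nearest = kdtree.query(points)
    dirs, extras = _node_directions(tree)

    diff = points - pos[nearest]  # (m, 3)
    u = dirs[nearest]
    has_dir = np.any(u != 0, axis=1)
    # |diff x u| is the perpendicular component when u is a unit vector
    d = np.where(has_dir, np.linalg.norm(np.cross(diff, u), axis=1), np.linalg.norm(diff, axis=1))
    if extras:
        for i, alt_dirs in extras.items():
            sel = nearest == i
            if not np.any(sel):
                continue
            for alt in alt_dirs:
                d[sel] = np.minimum(d[sel], np.linalg.norm(np.cross(diff[sel], alt), axis=1))
    return d


def perpendicular_distance(p: np.ndarray, tree: SkeletonTree) -> float:
    """Perpendicular distance from point ``p`` to the skeleton centerline.

    Finds the nearest skeleton point ``s`` and returns the norm of the
    component of ``p - s`` perpendicular to the local skeleton direction at
    ``s`` (equivalently ``||p-s|| sin(angle)``).  A single-node skeleton has
    no direction and the plain Euclidean distance is returned; at branch
    points the segment giving the smaller distance wins.
    """
    p = np.asarray(p, dtype=float)
    return float(_perp_distances(p[None, :], tree)[0])


def make_distance_field(
    trees: Sequence[SkeletonTree],
    shape: tuple[int, int, int],
    config: LabelConfig | None = None,
) -> np.ndarray:
    """Distance-field label for a set of (resampled) skeletons.

    Per tree, every voxel of that tree's expanded region gets
    ``exp(-d/(2 sigma^2))`` with ``d`` its perpendicular centerline distance;
    overlapping trees combine by voxel-wise maximum.  Returns a float32 array
    in ``[0, 1]``, zero outside all expanded regions.
    """
    cfg = config or LabelConfig()
    field = np.zeros(shape, dtype=np.float32)
    denom = 2.0 * cfg.sigma**2
    for tree in trees:
        if not tree.nodes:
            continue
        mask = expand_region([tree], shape, cfg.expand_radius, cfg.strict_less)
        vz, vy, vx = np.nonzero(mask)
        if vz.size == 0:
            continue
        pts = np.stack([vx, vy, vz], axis=1).astype(float)  # (x, y, z) order
        d = _perp_distances(pts, tree)
        if cfg.squared_exponent:
            vals = np.exp(-(d**2) / denom)
        else:
            vals = np.exp(-d / denom)
        field[vz, vy, vx] = np.maximum(field[vz, vy, vx], vals.astype(np.float32))
    return field
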