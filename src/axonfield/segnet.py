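"""Training, inference, enhancement, and foreground/skeleton extraction.

The network regresses a distance field from a raw volume.  Training uses a
four-term region-weighted L1 loss: a global term over all voxels plus terms
restricted to where the label exceeds 3/255 (any foreground), where the
label exceeds 103/255 (near-centerline), and where the *input image* exceeds
103/255 (bright structures, axonal or not).  Each term is normalized by its
own region size, so sparse foreground voxels carry far more weight than the
empty background — the property that lets the network pick up very weak
axonal segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree

from .io import SkeletonNode, SkeletonTree, Volume
from .unet import NetConfig, UNet3D

__all__ = [
    "TrainConfig",
    "region_weighted_l1",
    "train",
    "predict",
    "enhance",
    "extract_foreground",
    "skeletonize",
]


@dataclass
class TrainConfig:
    """Optimization protocol (Adam, batch size 1, lr 2e-4 by default)."""

    learning_rate: float = 2e-4
    batch_size: int = 1
    epochs: int = 10
    seed: int = 0
    reg1_thresh: float = 3.0 / 255.0
    reg2_thresh: float = 103.0 / 255.0
    split_fractions: tuple[float, float, float] = (0.79, 0.10, 0.11)
    patch_size: int | None = None  # train on random cubic crops of this size
    crops_per_volume: int = 4  # only used when patch_size is set

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.reg1_thresh < 1 and 0 < self.reg2_thresh < 1):
            raise ValueError("region thresholds must lie in (0, 1)")


def _loss_terms(y_p: np.ndarray, y_g: np.ndarray, x: np.ndarray,
                reg1_thresh: float, reg2_thresh: float) -> tuple[float, np.ndarray]:
    """Loss value and per-voxel weight map (d loss / d |y_p - y_g|)."""
    diff = y_p - y_g
    absdiff = np.abs(diff)
    weight = np.full(y_p.shape, 1.0 / y_p.size, dtype=np.float64)
    total = float(absdiff.sum()) / y_p.size
    for mask in (y_g > reg1_thresh, y_g > reg2_thresh, x > reg2_thresh):
        n = int(mask.sum())
        if n:
            total += float(absdiff[mask].sum()) / n
            weight[mask] += 1.0 / n
    return total, weight


def region_weighted_l1(y_p: np.ndarray, y_g: np.ndarray, x: np.ndarray,
                       reg1_thresh: float = 3.0 / 255.0,
                       reg2_thresh: float = 103.0 / 255.0) -> float:
    """Four-term region-weighted L1 loss.

    ``mean|d|`` over all voxels, plus ``mean|d|`` over {y_g > reg1_thresh},
    {y_g > reg2_thresh} and {x > reg2_thresh}.  An empty region contributes 0.
    """
    y_p, y_g, x = (np.asarray(a) for a in (y_p, y_g, x))
    if not (y_p.shape == y_g.shape == x.shape):
        raise ValueError(f"shape mismatch: {y_p.shape}, {y_g.shape}, {x.shape}")
    return _loss_terms(y_p, y_g, x, reg1_thresh, reg2_thresh)[0]


def _loss_and_grad(y_p, y_g, x, cfg: TrainConfig) -> tuple[float, np.ndarray]:
    total, weight = _loss_terms(y_p, y_g, x, cfg.reg1_thresh, cfg.reg2_thresh)
    grad = (weight * np.sign(y_p - y_g)).astype(np.float32)
    return total, grad


def _as_array(vol) -> np.ndarray:
    return vol.data if isinstance(vol, Volume) else np.asarray(vol, dtype=np.float32)


def _random_crop(rng: np.random.Generator, arrs: list[np.ndarray], size: int,
                 focus: np.ndarray | None) -> list[np.ndarray]:
    """Cubic crop, biased toward label foreground when any exists."""
    shape = arrs[0].shape
    if any(s < size for s in shape):
        return arrs
    if focus is not None and focus.size and rng.random() < 0.7:
        center = focus[rng.integers(focus.shape[0])]
        lo = [int(np.clip(c - size // 2, 0, s - size)) for c, s in zip(center, shape)]
    else:
        lo = [int(rng.integers(0, s - size + 1)) for s in shape]
    sl = tuple(slice(l, l + size) for l in lo)
    return [a[sl] for a in arrs]


def train(pairs, net: NetConfig | None = None, cfg: TrainConfig | None = None,
          model: UNet3D | None = None, callback=None):
    """Train the U-Net on ``(Volume, distance-field)`` pairs.

    Splits the pairs into train/validation by ``cfg.split_fractions``
    (renormalized over the first two entries; callers hold out their own test
    set), runs Adam with the region-weighted L1 loss, and keeps the
    best-validation checkpoint.  Returns ``(model, history)`` where history
    maps ``"train_loss"``/``"val_loss"`` to per-epoch lists.

    One seed controls the split, weight initialization, crop sampling, and
    data order.
    """
    cfg = cfg or TrainConfig()
    pairs = list(pairs)
    if not pairs:
        raise ValueError("training requires at least one (volume, label) pair")
    rng = np.random.default_rng(cfg.seed)
    if model is None:
        model = UNet3D(net or NetConfig(), seed=cfg.seed)

    n = len(pairs)
    order = rng.permutation(n)
    f_train, f_val, _ = cfg.split_fractions
    n_val = int(round(n * f_val / (f_train + f_val))) if n >= 2 else 0
    val_idx = order[:n_val]
    train_idx = order[n_val:]
    if len(train_idx) == 0:
        train_idx, val_idx = val_idx, train_idx

    data = [(_as_array(v), np.asarray(y, dtype=np.float32)) for v, y in pairs]
    # foreground voxel lists for crop biasing
    focus = [np.argwhere(y > cfg.reg1_thresh) for _, y in data]

    opt = model.make_optimizer(lr=cfg.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = model.state_dict()
    best_state = {k: v.copy() for k, v in best_state.items()}

    for epoch in range(cfg.epochs):
        losses = []
        for i in rng.permutation(train_idx):
            x, y = data[i]
            if cfg.patch_size and all(s >= cfg.patch_size for s in x.shape):
                for _ in range(cfg.crops_per_volume):
                    xc, yc = _random_crop(rng, [x, y], cfg.patch_size, focus[i])
                    losses.append(_train_step(model, opt, xc, yc, cfg))
            else:
                losses.append(_train_step(model, opt, x, y, cfg))
        train_loss = float(np.mean(losses))

        if len(val_idx):
            val_losses = []
            for i in val_idx:
                x, y = data[i]
                y_p = model.forward(x)
                val_losses.append(region_weighted_l1(y_p, y, x, cfg.reg1_thresh, cfg.reg2_thresh))
            val_loss = float(np.mean(val_losses))
        else:
            val_loss = train_loss

        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if val_loss <= best_val:
            best_val = val_loss
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        if callback is not None:
            callback(epoch, train_loss, val_loss)

    model.load_state_dict(best_state)
    return model, history


def _train_step(model: UNet3D, opt, x: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> float:
    y_p = model.forward(x)
    loss, grad = _loss_and_grad(y_p, y, x, cfg)
    opt.zero_grad()
    model.backward(grad)
    opt.step()
    return loss


def predict(model: UNet3D, vol, tile: int = 64, margin: int = 8) -> np.ndarray:
    """Full-volume inference, tiled with overlap when the volume exceeds ``tile``.

    Tiles of ``tile`` voxels per axis are run with a ``margin``-voxel overlap;
    only each tile's interior is written back, which suppresses convolution
    boundary effects.  Output values are clamped to [0, 1] and the shape
    equals the input shape.
    """
    x = _as_array(vol)
    shape = x.shape
    if all(s <= tile for s in shape):
        return model.forward(x)
    out = np.zeros(shape, dtype=np.float32)
    step = tile - 2 * margin
    if step <= 0:
        raise ValueError("tile must exceed twice the margin")
    starts = [list(range(0, max(s - 2 * margin, 1), step)) for s in shape]
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                lo = [z0, y0, x0]
                hi = [min(l + tile, s) for l, s in zip(lo, shape)]
                lo = [max(h - tile, 0) for h in hi]  # full-size tiles at the far edge
                block = x[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                pred = model.forward(block)
                ilo = [l + (margin if l > 0 else 0) for l in lo]
                ihi = [h - (margin if h < s else 0) for h, s in zip(hi, shape)]
                src = tuple(
                    slice(il - l, ih - l) for il, ih, l in zip(ilo, ihi, lo)
                )
                dst = tuple(slice(il, ih) for il, ih in zip(ilo, ihi))
                out[dst] = pred[src]
    return np.clip(out, 0.0, 1.0)


def enhance(vol: Volume, pred: np.ndarray) -> Volume:
    """Overlay the x255-scaled prediction onto the raw image.

    On the raw 8-bit scale: ``clip(raw + 255 * pred, 0, dtype_max)``.  With a
    zero prediction the volume is returned unchanged.
    """
    pred = np.asarray(pred, dtype=np.float32)
    if pred.shape != vol.shape:
        raise ValueError(f"shape mismatch: volume {vol.shape} vs prediction {pred.shape}")
    mx = vol.source_dtype_max
    raw = np.clip(vol.raw() + 255.0 * pred, 0, mx)
    return Volume(data=raw / mx, source_dtype_max=mx)


def extract_foreground(pred: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Voxel coordinates (x, y, z) where the field strictly exceeds ``threshold``."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    vz, vy, vx = np.nonzero(np.asarray(pred) > threshold)
    return np.stack([vx, vy, vz], axis=1).astype(float)


def skeletonize(points: np.ndarray, edge_cutoff: float = 2.0,
                prune_length: float = 4.0) -> list[SkeletonTree]:
    """Fallback point-set skeletonizer: Euclidean MST plus spur pruning.

    Connects points whose separation is below ``edge_cutoff`` (longer edges
    split the result into separate trees), takes the minimum spanning tree of
    each component, and prunes side branches shorter than ``prune_length``
    voxels that hang off junction nodes.  Any external skeletonizer honoring
    the SWC tree contract can replace this.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        return []
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array")
    n = points.shape[0]
    if n == 1:
        return [SkeletonTree(nodes=[SkeletonNode(1, 2, points[0], 1.0, -1)], tree_id=1)]

    tree_index = cKDTree(points)
    pairs = tree_index.query_pairs(edge_cutoff, output_type="ndarray")
    if pairs.size:
        dists = np.linalg.norm(points[pairs[:, 0]] - points[pairs[:, 1]], axis=1)
        # strictly positive weights so the sparse MST keeps coincident points connected
        graph = coo_matrix((np.maximum(dists, 1e-9), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        graph = coo_matrix((n, n))
    mst = minimum_spanning_tree(graph).tocoo()

    adj: dict[int, dict[int, float]] = {i: {} for i in range(n)}
    for i, j, w in zip(mst.row, mst.col, mst.data):
        adj[int(i)][int(j)] = float(w)
        adj[int(j)][int(i)] = float(w)

    _prune_spurs(adj, prune_length)

    # split into connected components and emit SWC-style trees
    trees: list[SkeletonTree] = []
    tree_id = 0
    visited: set[int] = set()
    for start in sorted(adj.keys()):
        if start in visited:
            continue
        # BFS from a degree<=1 node of this component if one exists
        comp_nodes = _component_of(adj, start)
        visited |= comp_nodes
        root = min((v for v in comp_nodes if len(adj[v]) <= 1), default=min(comp_nodes))
        tree_id += 1
        trees.append(_emit_tree(adj, points, root, comp_nodes, tree_id))
    return trees


def _component_of(adj: dict[int, dict[int, float]], start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for u in adj[v]:
            if u not in seen:
                seen.add(u)
                stack.append(u)
    return seen


def _prune_spurs(adj: dict[int, dict[int, float]], prune_length: float) -> None:
    """Remove leaf chains shorter than ``prune_length`` that end at junctions.

    A component with no junction (a pure path, or an isolated point) is left
    untouched, so the main skeleton is never consumed.
    """
    changed = True
    while changed:
        changed = False
        for leaf in [v for v, nb in adj.items() if len(nb) == 1]:
            if leaf not in adj or len(adj[leaf]) != 1:
                continue  # pruned or rewired by an earlier chain this sweep
            prev, v = leaf, next(iter(adj[leaf]))
            chain = [leaf]
            length = adj[leaf][v]
            while len(adj[v]) == 2 and length < prune_length:
                nxt = next(u for u in adj[v] if u != prev)
                chain.append(v)
                length += adj[v][nxt]
                prev, v = v, nxt
            if len(adj[v]) >= 3 and length < prune_length:
                for c in chain:
                    for u in list(adj[c]):
                        del adj[u][c]
                    del adj[c]
                changed = True


def _emit_tree(adj, points, root: int, comp_nodes: set[int], tree_id: int) -> SkeletonTree:
    nodes: list[SkeletonNode] = []
    next_id = 1
    id_of: dict[int, int] = {}
    stack = [(root, -1)]
    seen = {root}
    while stack:
        v, parent_new = stack.pop()
        id_of[v] = next_id
        nodes.append(SkeletonNode(next_id, 2, points[v], 1.0, parent_new))
        my_id = next_id
        next_id += 1
        for u in sorted(adj[v], reverse=True):
            if u not in seen:
                seen.add(u)
                stack.append((u, my_id))
    return SkeletonTree(nodes=nodes, tree_id=tree_id)
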