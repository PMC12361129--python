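"""Reading and writing of SWC skeletons and 3D image volumes.

Conventions fixed here for the whole toolkit:

* SWC coordinates are zero-based voxel units with voxel centers at integer
  coordinates.  A node position ``(x, y, z)`` addresses the array element
  ``data[z, y, x]`` — i.e. volumes are stored z-major, matching the page
  order of a multi-page TIFF stack.
* Volume intensities are normalized to ``[0, 1]`` by the dtype maximum of the
  source file (255 for 8-bit, 65535 for 16-bit), recorded in
  :attr:`Volume.source_dtype_max`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

__all__ = [
    "SkeletonNode",
    "SkeletonTree",
    "Volume",
    "SwcParseError",
    "SwcStructureError",
    "read_swc",
    "write_swc",
    "read_volume",
    "write_volume",
]


class SwcParseError(ValueError):
    """A line of an SWC file could not be parsed."""


class SwcStructureError(ValueError):
    """An SWC file references a parent id that does not exist."""


@dataclass
class SkeletonNode:
    """One point of an axonal skeleton (one SWC row).

    ``position`` is the SWC ``(x, y, z)`` triple in voxel units.  ``radius``
    and ``structure_type`` are carried through but not interpreted.
    """

    id: int
    structure_type: int
    position: np.ndarray  # (x, y, z) float
    radius: float
    parent_id: int  # -1 for roots

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"node {self.id}: position must be a finite 3-vector")


@dataclass
class SkeletonTree:
    """One connected axonal skeleton: an ordered node list with parent links."""

    nodes: list[SkeletonNode] = field(default_factory=list)
    tree_id: int = 1

    def __len__(self) -> int:
        return len(self.nodes)

    def positions(self) -> np.ndarray:
        """Node positions as an ``(n, 3)`` array of SWC ``(x, y, z)`` coords."""
        if not self.nodes:
            return np.empty((0, 3), dtype=float)
        return np.stack([n.position for n in self.nodes])

    def node_by_id(self) -> dict[int, SkeletonNode]:
        return {n.id: n for n in self.nodes}

    def children_of(self) -> dict[int, list[int]]:
        """Map node id -> ids of its children, in insertion order."""
        out: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1:
                out[n.parent_id].append(n.id)
        return out


@dataclass
class Volume:
    """A 3D scalar image with intensities normalized to [0, 1].

    ``data`` is indexed ``[z, y, x]``; ``shape`` therefore reads
    ``(nz, ny, nx)``.  ``source_dtype_max`` remembers the raw integer scale so
    round-trips and raw-scale arithmetic (e.g. the x255 enhancement overlay)
    are exact.
    """

    data: np.ndarray
    source_dtype_max: int = 255

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3-dimensional")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 1):
            raise ValueError("Volume intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def raw(self) -> np.ndarray:
        """Intensities on the original integer scale (float array)."""
        return self.data * float(self.source_dtype_max)


def _parse_swc_rows(path: Path) -> list[tuple[int, int, float, float, float, float, int]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) < 7:
                raise SwcParseError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                rows.append(
                    (
                        int(parts[0]),
                        int(parts[1]),
                        float(parts[2]),
                        float(parts[3]),
                        float(parts[4]),
                        float(parts[5]),
                        int(parts[6]),
                    )
                )
            except ValueError as exc:
                raise SwcParseError(f"{path}:{lineno}: {exc}") from exc
    return rows


def read_swc(path: str | Path) -> list[SkeletonTree]:
    """Read an SWC file and split it into root-connected components.

    Returns one :class:`SkeletonTree` per root (parent −1), with nodes in
    file order within each tree and ``tree_id`` numbered from 1 in order of
    first appearance.

    Raises
    ------
    SwcParseError
        on a malformed line (names the line number).
    SwcStructureError
        when a parent id references a node that is not in the file.
    """
    path = Path(path)
    rows = _parse_swc_rows(path)
    ids = {r[0] for r in rows}
    for r in rows:
        if r[6] != -1 and r[6] not in ids:
            raise SwcStructureError(f"{path}: node {r[0]} references missing parent {r[6]}")

    # union-find over parent links to split connected components
    parent_of = {r[0]: r[6] for r in rows}

    def root_of(i: int) -> int:
        seen = set()
        while parent_of[i] != -1:
            if i in seen:  # cycle guard
                raise SwcStructureError(f"{path}: cycle involving node {i}")
            seen.add(i)
            i = parent_of[i]
        return i

    trees: dict[int, SkeletonTree] = {}
    next_tree = 1
    for r in rows:
        root = root_of(r[0])
        if root not in trees:
            trees[root] = SkeletonTree(nodes=[], tree_id=next_tree)
            next_tree += 1
        trees[root].nodes.append(
            SkeletonNode(
                id=r[0],
                structure_type=r[1],
                position=np.array(r[2:5], dtype=float),
                radius=r[5],
                parent_id=r[6],
            )
        )
    return list(trees.values())


def write_swc(trees: Iterable[SkeletonTree], path: str | Path) -> None:
    """Write trees as a standard 7-column SWC file.

    Node ids are renumbered consecutively across the file; each tree's root
    gets parent −1.  Coordinates are written with 4 decimal places, the
    precision at which round-trips are lossless.
    """
    path = Path(path)
    lines = ["# id type x y z radius parent"]
    next_id = 1
    for tree in trees:
        remap: dict[int, int] = {}
        for node in tree.nodes:
            remap[node.id] = next_id
            parent = -1 if node.parent_id == -1 else remap[node.parent_id]
            x, y, z = node.position
            lines.append(
                f"{next_id} {node.structure_type} {x:.4f} {y:.4f} {z:.4f} "
                f"{node.radius:.4f} {parent}"
            )
            next_id += 1
    path.write_text("\n".join(lines) + "\n")


_SUPPORTED_DTYPES = {np.dtype(np.uint8): 255, np.dtype(np.uint16): 65535}


def read_volume(path: str | Path) -> Volume:
    """Read a multi-page TIFF stack into a normalized :class:`Volume`.

    Pages are stacked along z, so the array is indexed ``[z, y, x]``.  Only
    unsigned 8- and 16-bit integer stacks are accepted; values are divided by
    the dtype maximum.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.dtype not in _SUPPORTED_DTYPES:
        raise ValueError(f"{path}: unsupported dtype {arr.dtype}; expected uint8 or uint16")
    divisor = _SUPPORTED_DTYPES[arr.dtype]
    return Volume(data=arr.astype(np.float32) / divisor, source_dtype_max=divisor)


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a :class:`Volume` as a TIFF stack on its original integer scale."""
    mx = vol.source_dtype_max
    dtype = np.uint8 if mx <= 255 else np.uint16
    raw = np.clip(np.rint(vol.data * mx), 0, mx).astype(dtype)
    tifffile.imwrite(str(path), raw, photometric="minisblack")


def trees_points(trees: Sequence[SkeletonTree]) -> np.ndarray:
    """Concatenate node positions of several trees into an ``(n, 3)`` array."""
    parts = [t.positions() for t in trees if len(t)]
    if not parts:
        return np.empty((0, 3), dtype=float)
    return np.concatenate(parts, axis=0)
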