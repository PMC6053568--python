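"""Fractal habitat arrays and their nested multi-scale groupings.

The habitat is a recursively nested triangular ("fractal") arrangement of
host-plant patches: three patches at the vertices of an equilateral triangle
form a cluster, three clusters form a larger triangle, and so on.  A complete
array with ``L`` levels holds ``3**L`` patches and supports aggregation of
population counts at group sizes 1, 3, 9, ..., 3**L.  The design gives a
systematic, simultaneous increase in between-patch distance and total area
with spatial scale, which is what makes multi-scale interaction analysis on a
single layout meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "SpatialLayout",
    "DEFAULT_SPACINGS",
    "build_fractal_layout",
    "scale_partition",
    "partition_matrix",
    "layout_to_csv",
    "layout_from_csv",
]

#: Default inter-cluster (centroid-to-centroid) distances per level, in metres.
#: Placeholder values increasing threefold per level; the physical array's
#: exact spacings are not encoded here and should be supplied when known.
DEFAULT_SPACINGS = (0.5, 1.5, 4.5, 13.5)


@dataclass(frozen=True)
class SpatialLayout:
    """A set of patches with coordinates, distances and a nested hierarchy.

    Attributes
    ----------
    coords : ndarray, shape (N, 2)
        Planar patch positions in metres.
    dist : ndarray, shape (N, N)
        Pairwise Euclidean distances in metres.
    groups : ndarray, shape (levels + 1, N)
        ``groups[l][i]`` is the level-``l`` group index of patch ``i``.
        Level-0 is the identity partition; each level-(l+1) group is the
        union of exactly three level-l groups.
    spacings : tuple of float
        Per-level inter-cluster distances used to build the layout
        (empty for imported layouts of unknown provenance).
    """

    coords: np.ndarray
    dist: np.ndarray
    groups: np.ndarray
    spacings: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        _validate_groups(self.groups)
        n = self.coords.shape[0]
        if self.dist.shape != (n, n) or self.groups.shape[1] != n:
            raise ValueError("coords, dist and groups disagree on patch count")

    @property
    def n_patches(self) -> int:
        return self.coords.shape[0]

    @property
    def patch_ids(self) -> np.ndarray:
        return np.arange(self.n_patches)

    @property
    def levels(self) -> int:
        return self.groups.shape[0] - 1

    @property
    def scales(self) -> tuple[int, ...]:
        """Group sizes available for aggregation (1, 3, 9, ...)."""
        return tuple(3**l for l in range(self.levels + 1))

    def group_index(self, level: int) -> np.ndarray:
        """Level-``level`` group label for every patch."""
        if not 0 <= level <= self.levels:
            raise ValueError(f"level {level} outside 0..{self.levels}")
        return self.groups[level].copy()


def _validate_groups(groups: np.ndarray) -> None:
    n = groups.shape[1]
    if not np.array_equal(groups[0], np.arange(n)):
        raise ValueError("level-0 grouping must be the identity partition")
    for lev in range(groups.shape[0]):
        labels, counts = np.unique(groups[lev], return_counts=True)
        if not np.all(counts == 3**lev):
            raise ValueError(f"level-{lev} groups must all have size {3 ** lev}")
        if lev > 0:
            # each level-l group must contain exactly 3 distinct level-(l-1) groups
            for g in labels:
                sub = np.unique(groups[lev - 1][groups[lev] == g])
                if sub.size != 3:
                    raise ValueError(
                        f"level-{lev} group {g} is not a union of 3 level-{lev - 1} groups"
                    )


def build_fractal_layout(
    levels: int, spacings: tuple[float, ...] | None = None
) -> SpatialLayout:
    """Build a complete fractal array with ``3**levels`` patches.

    Each level-``l`` cluster consists of three level-(l-1) clusters placed at
    the vertices of an equilateral triangle whose centroid-to-centroid side
    length is ``spacings[l-1]``.  Patch indices follow the hierarchy path
    (lexicographic), so the level-``l`` group of patch ``i`` is ``i // 3**l``.

    Parameters
    ----------
    levels : int
        Number of nesting levels (``levels=4`` gives the 81-patch array with
        groupings of size 1, 3, 9, 27 and 81).
    spacings : sequence of float, optional
        Inter-cluster distance per level, metres, length ``levels``.
        Defaults extend :data:`DEFAULT_SPACINGS` threefold per level.
    """
    if levels < 0:
        raise ValueError("levels must be non-negative")
    if spacings is None:
        spacings = tuple(
            DEFAULT_SPACINGS[l] if l < len(DEFAULT_SPACINGS) else DEFAULT_SPACINGS[-1] * 3 ** (l - 3)
            for l in range(levels)
        )
    spacings = tuple(float(s) for s in spacings)
    if len(spacings) != levels:
        raise ValueError(f"expected {levels} spacings, got {len(spacings)}")
    if any(s <= 0 for s in spacings):
        raise ValueError("spacings must be strictly positive")

    pts = np.zeros((1, 2))
    # vertex directions of an equilateral triangle, centroid at the origin
    angles = np.deg2rad([90.0, 210.0, 330.0])
    unit = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    for d in spacings:
        offsets = (d / np.sqrt(3.0)) * unit  # circumradius = side / sqrt(3)
        pts = np.concatenate([pts + off for off in offsets])

    n = pts.shape[0]
    idx = np.arange(n)
    groups = np.stack([idx // 3**l for l in range(levels + 1)])
    dist = cdist(pts, pts)
    return SpatialLayout(coords=pts, dist=dist, groups=groups, spacings=spacings)


def _scale_to_level(layout: SpatialLayout, scale: int) -> int:
    lev = int(round(np.log(scale) / np.log(3))) if scale > 0 else -1
    if scale <= 0 or 3**lev != scale:
        raise ValueError(f"scale {scale} is not a power of 3")
    if lev > layout.levels:
        raise ValueError(f"scale {scale} exceeds layout size {layout.n_patches}")
    return lev


def scale_partition(layout: SpatialLayout, scale: int) -> np.ndarray:
    """Patch -> group mapping at the given group size (1, 3, 9, ...).

    Every group contains exactly ``scale`` patches; groups at successive
    scales are nested.
    """
    return layout.group_index(_scale_to_level(layout, scale))


def partition_matrix(layout: SpatialLayout, scale: int) -> np.ndarray:
    """One-hot membership matrix ``M`` of shape (N, G): ``counts @ M`` sums
    patch counts into group counts."""
    part = scale_partition(layout, scale)
    n_groups = layout.n_patches // scale
    m = np.zeros((layout.n_patches, n_groups), dtype=np.int64)
    m[np.arange(layout.n_patches), part] = 1
    return m


def layout_to_csv(layout: SpatialLayout, path) -> None:
    """Write the layout as tabular text: patch_id, x, y, group_level1..L."""
    data = {"patch_id": layout.patch_ids, "x": layout.coords[:, 0], "y": layout.coords[:, 1]}
    for lev in range(1, layout.levels + 1):
        data[f"group_level{lev}"] = layout.groups[lev]
    pd.DataFrame(data).to_csv(path, index=False)


def layout_from_csv(path) -> SpatialLayout:
    """Read a layout written by :func:`layout_to_csv`.

    The hierarchy is taken from the ``group_level*`` columns and re-validated;
    distances are recomputed from the coordinates.
    """
    df = pd.read_csv(path).sort_values("patch_id").reset_index(drop=True)
    required = {"patch_id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"layout file must have columns {sorted(required)}")
    n = len(df)
    if not np.array_equal(df["patch_id"].to_numpy(), np.arange(n)):
        raise ValueError("patch_id must be 0..N-1")
    levels = 0
    while f"group_level{levels + 1}" in df.columns:
        levels += 1
    coords = df[["x", "y"]].to_numpy(dtype=float)
    groups = np.stack(
        [np.arange(n)]
        + [df[f"group_level{lev}"].to_numpy(dtype=np.int64) for lev in range(1, levels + 1)]
    )
    return SpatialLayout(coords=coords, dist=cdist(coords, coords), groups=groups)
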