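"""Template rendering styles: glass, surface, filled, cloudy.

Each style converts a brain volume into renderable geometry — a triangle
mesh (surface, via marching cubes) or a semi-transparent point cloud
(glass: supervoxel-boundary voxels; cloudy: surface-adjacent voxels;
filled: every mask voxel).  Geometry is expressed in world millimetres.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from skimage import measure, segmentation

from .volume_io import BrainVolume, downsample, voxel_to_world

DEFAULT_ALPHAS = {"surface": 1.0, "glass": 0.01, "cloudy": 0.05, "filled": 0.2}
STYLES = ("glass", "surface", "filled", "cloudy")
ISO_LEVEL = 0.5  # iso-level on the binarized mask


@dataclass
class Mesh:
    """Triangle mesh in world mm."""

    vertices: np.ndarray  # (V, 3)
    faces: np.ndarray     # (F, 3) vertex indices
    alpha: float = 1.0
    color: str = "lightgray"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValueError("face indices out of range")

    def surface_area(self) -> float:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum()

    def n_components(self) -> int:
        """Connected components over the face-edge graph."""
        v = len(self.vertices)
        if v == 0:
            return 0
        rows = np.concatenate([self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]])
        cols = np.concatenate([self.faces[:, 1], self.faces[:, 2], self.faces[:, 0]])
        adj = sparse.coo_matrix((np.ones_like(rows), (rows, cols)), shape=(v, v))
        n, _ = csgraph.connected_components(adj, directed=False)
        return int(n)

    def euler_characteristic(self) -> int:
        edges = np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                                self.faces[:, [2, 0]]])
        edges = np.unique(np.sort(edges, axis=1), axis=0)
        return len(self.vertices) - len(edges) + len(self.faces)


@dataclass
class PointCloud:
    """Scatter geometry in world mm with uniform per-point alpha/size."""

    points: np.ndarray  # (N, 3)
    alpha: float = 1.0
    size: float = 5.0
    color: str = "lightgray"
    values: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.points.size and not np.isfinite(self.points).all():
            raise ValueError("point coordinates must be finite")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.points)


def binarize(v: BrainVolume, level: float = 0.0) -> np.ndarray:
    """Boolean mask ``grid > level``."""
    return np.asarray(v.grid) > level


def _require_nonempty(mask: np.ndarray) -> None:
    if not mask.any():
        raise ValueError("volume is empty after binarization; nothing to render")


def extract_surface(mask: np.ndarray, affine: np.ndarray,
                    alpha: float = 1.0, color: str = "lightgray") -> Mesh:
    """Marching-cubes isosurface of a binary mask at level 0.5, in world mm.

    The mask is zero-padded by one voxel so masks touching the grid edge
    still close into a watertight surface.
    """
    mask = np.asarray(mask)
    _require_nonempty(mask)
    padded = np.pad(mask.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=ISO_LEVEL)
    verts -= 1.0  # undo padding offset, back to source index space
    return Mesh(vertices=voxel_to_world(verts, affine), faces=faces,
                alpha=alpha, color=color)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with >= 1 background 6-neighbor (grid edge counts as
    background)."""
    padded = np.pad(mask, 1)
    interior = np.ones_like(mask, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            sl = [slice(1, -1)] * 3
            sl[axis] = slice(2, None) if shift == 1 else slice(None, -2)
            interior &= padded[tuple(sl)]
    return mask & ~interior


def cloudy_geometry(v: BrainVolume, alpha: Optional[float] = None,
                    color: str = "lightgray") -> PointCloud:
    """Semi-transparent cloud of the mask's surface-adjacent voxels."""
    mask = binarize(v)
    _require_nonempty(mask)
    idx = np.argwhere(_surface_voxels(mask))
    return PointCloud(points=voxel_to_world(idx.astype(float), v.affine),
                      alpha=DEFAULT_ALPHAS["cloudy"] if alpha is None else alpha,
                      color=color)


def glass_geometry(v: BrainVolume, n_segments: int = 500, compactness: float = 0.05,
                   alpha: Optional[float] = None, color: str = "lightgray",
                   intensity_tol: float = 0.1) -> PointCloud:
    """Sparse low-alpha cloud on intensity borders, via supervoxels.

    The intensity-normalized volume is partitioned into ``n_segments``
    compact supervoxels (SLIC) inside the mask.  A border voxel is a mask
    voxel 6-adjacent to background, or to a supervoxel whose mean
    intensity differs by more than ``intensity_tol`` of the normalized
    range — so a uniform solid yields only its outer shell while nested
    intensity regions also expose their internal boundary.
    """
    mask = binarize(v)
    _require_nonempty(mask)
    grid = np.asarray(v.grid, dtype=float)
    rng = grid.max() - grid.min()
    norm = (grid - grid.min()) / rng if rng > 0 else np.zeros_like(grid)
    segments = segmentation.slic(norm, n_segments=n_segments, compactness=compactness,
                                 mask=mask, channel_axis=None, start_label=1)
    n_labels = int(segments.max())
    means = np.zeros(n_labels + 1)
    if n_labels:
        counts = np.bincount(segments.ravel(), minlength=n_labels + 1)
        sums = np.bincount(segments.ravel(), weights=norm.ravel(), minlength=n_labels + 1)
        nonzero = counts > 0
        means[nonzero] = sums[nonzero] / counts[nonzero]

    border = np.zeros_like(mask)
    padded_seg = np.pad(segments, 1)
    padded_mask = np.pad(mask, 1)
    core = (slice(1, -1),) * 3
    for axis in range(3):
        for shift in (1, -1):
            sl = [slice(1, -1)] * 3
            sl[axis] = slice(2, None) if shift == 1 else slice(None, -2)
            nb_seg = padded_seg[tuple(sl)]
            nb_mask = padded_mask[tuple(sl)]
            differs = mask & (~nb_mask | (
                (nb_seg != segments) & (np.abs(means[nb_seg] - means[segments]) > intensity_tol)))
            border |= differs
    idx = np.argwhere(border)
    return PointCloud(points=voxel_to_world(idx.astype(float), v.affine),
                      alpha=DEFAULT_ALPHAS["glass"] if alpha is None else alpha,
                      size=2.0, color=color)


def filled_geometry(v: BrainVolume, voxelsize: Optional[float] = None,
                    alpha: Optional[float] = None, color: str = "lightgray") -> PointCloud:
    """One point per mask voxel at its world-mm center.

    ``voxelsize`` (mm) optionally downsamples first — the documented
    performance lever for this memory-hungry style.
    """
    if voxelsize is not None:
        v = downsample(v, voxelsize)
    mask = binarize(v)
    _require_nonempty(mask)
    idx = np.argwhere(mask)
    return PointCloud(points=voxel_to_world(idx.astype(float), v.affine),
                      alpha=DEFAULT_ALPHAS["filled"] if alpha is None else alpha,
                      color=color)


def style_dispatch(style: str, v: Optional[BrainVolume],
                   options: Optional[dict] = None):
    """Route a template style name to its geometry builder.

    Returns a Mesh, a PointCloud, or None for style 'none'.
    """
    options = options or {}
    if style in (None, "none"):
        return None
    if style not in STYLES:
        raise ValueError(f"unknown template style {style!r}; choose one of "
                         f"{list(STYLES)} (or 'none')")
    if v is None:
        raise ValueError(f"template style {style!r} requires a template volume")
    alpha = options.get("alpha")
    color = options.get("color", "lightgray")
    if style == "surface":
        return extract_surface(binarize(v), v.affine,
                               alpha=DEFAULT_ALPHAS["surface"] if alpha is None else alpha,
                               color=color)
    if style == "glass":
        return glass_geometry(v, n_segments=options.get("glass_segments", 500),
                              compactness=options.get("glass_compactness", 0.05),
                              alpha=alpha, color=color)
    if style == "cloudy":
        return cloudy_geometry(v, alpha=alpha, color=color)
    return filled_geometry(v, voxelsize=options.get("voxelsize"),
                           alpha=alpha, color=color)
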