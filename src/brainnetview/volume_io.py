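"""Volumetric images: loading, affine geometry, centroids, resampling.

A :class:`BrainVolume` is a 3D intensity grid plus the 4x4 affine mapping
voxel indices to world millimetres (RAS orientation: x grows to the
subject's right).  A :class:`Parcellation` is the integer-labeled special
case in which each nonzero label defines one network node; node locations
are the labels' world-space centroids.

Template images are resolved through a pluggable fetcher interface: a
local-directory resolver mirroring the standard template-repository
naming scheme is provided, and any object with the same ``query`` method
(e.g. a remote-repository adapter) can be injected in its place.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Protocol

import nibabel as nib
import numpy as np

from .data_model import NodeTable, EdgeTable, empty_edge_table

import pandas as pd

logger = logging.getLogger("brainnetview")


@dataclass
class BrainVolume:
    """3D intensity grid + voxel-to-world (mm) affine."""

    grid: np.ndarray
    affine: np.ndarray
    space_name: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError(f"volume grid must be 3D with all dims >= 1, got {self.grid.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge lengths (mm) of one voxel along each axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) world-mm corners of the grid's bounding box."""
        ni, nj, nk = self.grid.shape
        corners = np.array([[i, j, k] for i in (0, ni - 1)
                            for j in (0, nj - 1) for k in (0, nk - 1)], dtype=float)
        world = voxel_to_world(corners, self.affine)
        return world.min(axis=0), world.max(axis=0)


@dataclass
class Parcellation(BrainVolume):
    """Integer-labeled volume; 0 is background, each label one node."""

    def __post_init__(self) -> None:
        super().__post_init__()
        grid = np.asarray(self.grid)
        if not np.issubdtype(grid.dtype, np.integer):
            rounded = np.rint(grid)
            if np.abs(grid - rounded).max() > 1e-6:
                raise ValueError("parcellation grid values must be integers")
            grid = rounded.astype(np.int64)
        if grid.min() < 0:
            raise ValueError("parcellation labels must be non-negative")
        self.grid = grid

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the grid."""
        u = np.unique(self.grid)
        return u[u > 0]


def as_parcellation(v: BrainVolume) -> Parcellation:
    if isinstance(v, Parcellation):
        return v
    return Parcellation(grid=v.grid, affine=v.affine,
                        space_name=v.space_name, metadata=dict(v.metadata))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def from_nibabel(img: nib.spatialimages.SpatialImage,
                 space_name: Optional[str] = None) -> BrainVolume:
    """Wrap a nibabel image, reorienting to RAS and squeezing singleton dims."""
    img = nib.as_closest_canonical(img)
    grid = np.asanyarray(img.dataobj)
    if grid.ndim > 3:
        squeezed = np.squeeze(grid)
        if squeezed.ndim > 3:
            raise ValueError(f"volume has {grid.ndim} non-singleton dimensions; expected 3")
        grid = squeezed
    if grid.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {grid.ndim}D with shape {grid.shape}")
    return BrainVolume(grid=grid, affine=np.asarray(img.affine), space_name=space_name)


def load_volume(path: str | Path) -> BrainVolume:
    """Load a 3D NIfTI volume (optionally gzip-compressed) as RAS."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    return from_nibabel(nib.load(str(path)), space_name=path.stem.split(".")[0])


def save_volume(v: BrainVolume, path: str | Path) -> Path:
    path = Path(path)
    grid = v.grid
    if np.issubdtype(grid.dtype, np.integer):
        grid = grid.astype(np.int32)
    nib.save(nib.Nifti1Image(grid, v.affine), str(path))
    return path


# ---------------------------------------------------------------------------
# Affine geometry
# ---------------------------------------------------------------------------

def voxel_to_world(indices: Any, affine: np.ndarray) -> np.ndarray:
    """Map voxel indices through the affine to world mm.

    Accepts one (i, j, k) triple or an (N, 3) array; order preserved.
    """
    idx = np.atleast_2d(np.asarray(indices, dtype=float))
    out = idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    return out[0] if np.asarray(indices).ndim == 1 else out


def world_to_voxel(coords: Any, affine: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(np.asarray(affine))
    pts = np.atleast_2d(np.asarray(coords, dtype=float))
    out = pts @ inv[:3, :3].T + inv[:3, 3]
    return out[0] if np.asarray(coords).ndim == 1 else out


# ---------------------------------------------------------------------------
# Centroids
# ---------------------------------------------------------------------------

def compute_centroids(p: Parcellation) -> NodeTable:
    """One node per label, at the label's voxel-mean mapped to world mm.

    Rows are in ascending label order; the integer label is kept in a
    ``label`` metadata column.  Centroids are computed in continuous index
    space (no rounding) and then pushed through the affine.
    """
    labels = p.labels
    if labels.size == 0:
        raise ValueError("parcellation contains no nonzero labels")
    from scipy import ndimage
    centers = ndimage.center_of_mass(np.ones_like(p.grid, dtype=float),
                                     labels=p.grid, index=labels)
    world = voxel_to_world(np.asarray(centers, dtype=float), p.affine)
    df = pd.DataFrame({
        "node_id": np.arange(labels.size),
        "x": world[:, 0], "y": world[:, 1], "z": world[:, 2],
        "label": labels.astype(int),
    })
    return NodeTable(df)


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def _block_mode(blocks: np.ndarray) -> np.ndarray:
    """Per-row modal value, background (0) excluded unless all-background."""
    out = np.zeros(blocks.shape[0], dtype=blocks.dtype)
    for r in range(blocks.shape[0]):
        row = blocks[r]
        nz = row[row != 0]
        if nz.size == 0:
            continue
        vals, counts = np.unique(nz, return_counts=True)
        out[r] = vals[np.argmax(counts)]
    return out


def downsample(v: BrainVolume, voxelsize: float) -> BrainVolume:
    """Resample to a coarser isotropic voxel size (mm), preserving extent.

    Intensity volumes aggregate by block mean; integer-labeled volumes by
    block mode with background excluded from the vote.  Upsampling is not
    supported.  The output affine keeps each new voxel center at the mean
    world position of the source block it covers.
    """
    native = v.voxel_size
    if voxelsize < native.min() - 1e-9:
        raise ValueError(f"voxelsize {voxelsize} mm is finer than the native "
                         f"voxel size {native.min():g} mm; upsampling is unsupported")
    factor = max(1, int(round(voxelsize / native.min())))
    if factor == 1:
        return v

    is_labels = isinstance(v, Parcellation)
    grid = v.grid
    pad = [(0, (-s) % factor) for s in grid.shape]
    grid = np.pad(grid, pad, mode="constant")
    ns = tuple(s // factor for s in grid.shape)
    blocks = grid.reshape(ns[0], factor, ns[1], factor, ns[2], factor)
    blocks = blocks.transpose(0, 2, 4, 1, 3, 5).reshape(-1, factor ** 3)
    if is_labels:
        new_grid = _block_mode(blocks).reshape(ns)
    else:
        new_grid = blocks.astype(float).mean(axis=1).reshape(ns)

    new_affine = v.affine.copy()
    new_affine[:3, :3] = v.affine[:3, :3] * factor
    # new voxel (0,0,0) covers source indices 0..factor-1 along each axis
    shift = np.full(3, (factor - 1) / 2.0)
    new_affine[:3, 3] = voxel_to_world(shift, v.affine)
    cls = Parcellation if is_labels else BrainVolume
    return cls(grid=new_grid, affine=new_affine, space_name=v.space_name,
               metadata=dict(v.metadata))


# ---------------------------------------------------------------------------
# Hemisphere restriction
# ---------------------------------------------------------------------------

def _world_x(v: BrainVolume) -> np.ndarray:
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in v.grid.shape), indexing="ij")
    a = v.affine
    return a[0, 0] * ii + a[0, 1] * jj + a[0, 2] * kk + a[0, 3]


def hemisphere_restrict_volume(v: BrainVolume, side: str) -> BrainVolume:
    """Zero voxels strictly on the other side of the midline (world x = 0).

    Midline voxels belong to both hemispheres.  RAS: 'R' keeps x >= 0.
    """
    if side not in ("L", "R"):
        raise ValueError(f"hemisphere must be 'L' or 'R', got {side!r}")
    x = _world_x(v)
    keep = x <= 0 if side == "L" else x >= 0
    grid = np.where(keep, v.grid, 0)
    cls = Parcellation if isinstance(v, Parcellation) else BrainVolume
    return cls(grid=grid, affine=v.affine, space_name=v.space_name,
               metadata=dict(v.metadata))


def hemisphere_restrict_network(nodes: NodeTable, edges: Optional[EdgeTable],
                                side: str) -> tuple[NodeTable, Optional[EdgeTable]]:
    """Drop nodes on the other side of x = 0 and any edge that lost an
    endpoint — only connections within the hemisphere remain."""
    if side not in ("L", "R"):
        raise ValueError(f"hemisphere must be 'L' or 'R', got {side!r}")
    x = nodes.data["x"].to_numpy(dtype=float)
    keep = x <= 0 if side == "L" else x >= 0
    kept_ids = set(nodes.data.loc[keep, "node_id"].tolist())
    new_nodes = NodeTable(nodes.data.loc[keep].reset_index(drop=True))
    if edges is None:
        return new_nodes, None
    mask = edges.data.apply(lambda r: r["i"] in kept_ids and r["j"] in kept_ids, axis=1) \
        if edges.n else pd.Series(dtype=bool)
    new_edges = EdgeTable(edges.data.loc[mask].reset_index(drop=True)) if edges.n \
        else empty_edge_table()
    return new_nodes, new_edges


def hemisphere_restrict(obj: Any, side: str, edges: Optional[EdgeTable] = None):
    """Dispatch to the volume or node/edge form of hemisphere restriction."""
    if isinstance(obj, BrainVolume):
        return hemisphere_restrict_volume(obj, side)
    if isinstance(obj, NodeTable):
        return hemisphere_restrict_network(obj, edges, side)
    raise TypeError(f"cannot hemisphere-restrict a {type(obj).__name__}")


# ---------------------------------------------------------------------------
# Template resolution
# ---------------------------------------------------------------------------

class Fetcher(Protocol):
    """Resolver for standard-space images by entity key/values."""

    def query(self, space: str, **filters: Any) -> Optional[Path]: ...


class LocalTemplateResolver:
    """Offline fetcher reading a directory tree in the standard
    template-repository layout: ``root/tpl-<space>/tpl-<space>[_key-value...]_<suffix>.nii[.gz]``.
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)

    def query(self, space: str, **filters: Any) -> Optional[Path]:
        space_dir = self.root / f"tpl-{space}"
        if not space_dir.is_dir():
            return None
        suffix = filters.pop("suffix", None)
        if "resolution" in filters:  # 'resolution' keyword maps to the res- entity
            filters["res"] = filters.pop("resolution")
        for path in sorted(space_dir.glob("*.nii*")):
            name = path.name
            for ext in (".nii.gz", ".nii"):
                if name.endswith(ext):
                    name = name[: -len(ext)]
            parts = name.split("_")
            file_suffix = parts[-1]
            entities = dict(p.split("-", 1) for p in parts[:-1] if "-" in p)
            if suffix is not None and file_suffix != suffix:
                continue
            if all(str(entities.get(k)) == str(v) for k, v in filters.items()):
                return path
        return None


def select_template_image(identifier: Any, fetcher: Optional[Fetcher] = None) -> BrainVolume:
    """Resolve the template argument into a loaded volume.

    Paths and in-memory volumes pass straight through.  A bare space-name
    string is resolved through ``fetcher``: a segmented T1w anatomical
    image is preferred; if absent, the binary brain mask is the fallback.
    The chosen variant is recorded in the volume's metadata.
    """
    if isinstance(identifier, BrainVolume):
        return identifier
    if hasattr(identifier, "get_fdata") and hasattr(identifier, "affine"):
        return from_nibabel(identifier)
    if isinstance(identifier, Path) or (
            isinstance(identifier, str) and identifier.endswith((".nii", ".nii.gz"))):
        return load_volume(identifier)
    if isinstance(identifier, str):
        if fetcher is None:
            raise ValueError(
                f"template {identifier!r} looks like a space name; resolving it "
                "requires a fetcher (e.g. LocalTemplateResolver)")
        queried = []
        for variant, filters in (("T1w", {"suffix": "T1w"}),
                                 ("mask", {"suffix": "mask"})):
            queried.append(filters)
            path = fetcher.query(identifier, **filters)
            if path is not None:
                vol = load_volume(path)
                vol.space_name = identifier
                vol.metadata["template_variant"] = variant
                if variant == "mask":
                    logger.info("template %s: no segmented T1w image found; "
                                "falling back to the binary brain mask", identifier)
                return vol
        raise ValueError(f"template space {identifier!r} could not be resolved; "
                         f"queried: {queried}")
    raise TypeError(f"unsupported template identifier of type {type(identifier).__name__}")


def fetch_atlas(spec: dict, fetcher: Fetcher) -> Parcellation:
    """Resolve an atlas-descriptor mapping (atlas/desc/resolution/...) to a
    labeled parcellation volume via the fetcher."""
    spec = dict(spec)
    if not all(isinstance(k, str) for k in spec):
        raise ValueError("atlas descriptor keys must be strings")
    space = spec.pop("template", None) or spec.pop("space", None)
    if space is None:
        raise ValueError("atlas descriptor needs a 'template' (space name) entry")
    res = spec.get("resolution")
    if res is not None and (not isinstance(res, int) or res <= 0):
        raise ValueError(f"atlas resolution must be a positive integer, got {res!r}")
    spec.setdefault("suffix", "dseg")
    path = fetcher.query(space, **spec)
    if path is None:
        raise ValueError(f"no atlas matches {spec} in space {space!r}")
    return as_parcellation(load_volume(path))
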