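"""Seeded synthetic inputs: ellipsoid templates, Voronoi parcellations,
community-structured networks, and highlight matrices.

Every input form the engine accepts can be generated here offline, so no
anatomical download is ever required.  The template is a smooth ellipsoid
"brain" (intensity 1 inside, soft falloff at the border) on a RAS grid
whose world origin sits at the ellipsoid center; parcels are the Voronoi
cells of seed points inside the mask; networks have planted community
structure with separate within/between edge probabilities.

All operations are pure functions of (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .data_model import EdgeTable, NodeTable, empty_edge_table
from .volume_io import BrainVolume, Parcellation, save_volume


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic generators."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_mm: float = 2.0
    semi_axes: tuple[float, float, float] = (24.0, 28.0, 20.0)  # voxels
    falloff: float = 0.1          # border softness, fraction of the radius
    n_labels: int = 20
    n_nodes: int = 30
    n_communities: int = 3
    p_within: float = 0.5
    p_between: float = 0.05
    seed: int = 42

    def __post_init__(self) -> None:
        for p in (self.p_within, self.p_between):
            if not 0.0 <= p <= 1.0:
                raise ValueError("edge probabilities must lie in [0, 1]")
        for n in (self.n_labels, self.n_nodes, self.n_communities):
            if n < 1:
                raise ValueError("counts must be positive")


def _ras_affine(cfg: FixtureConfig) -> np.ndarray:
    affine = np.diag([cfg.voxel_mm] * 3 + [1.0])
    center = (np.asarray(cfg.shape) - 1) / 2.0
    affine[:3, 3] = -center * cfg.voxel_mm
    return affine


def _ellipsoid_radius(cfg: FixtureConfig) -> np.ndarray:
    """Normalized ellipsoid radius r (r <= 1 inside) at each voxel."""
    center = (np.asarray(cfg.shape) - 1) / 2.0
    axes = np.asarray(cfg.semi_axes, dtype=float)
    grids = np.meshgrid(*(np.arange(s, dtype=float) for s in cfg.shape), indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return np.sqrt(r2)


def make_template(cfg: FixtureConfig = FixtureConfig()) -> BrainVolume:
    """Smooth ellipsoidal brain phantom with intensity 1 inside and a
    linear falloff of width ``cfg.falloff`` at the border."""
    axes = np.asarray(cfg.semi_axes, dtype=float)
    if np.any(axes * (1 + cfg.falloff / 2) > (np.asarray(cfg.shape) - 1) / 2.0 + 0.5):
        raise ValueError(f"semi-axes {tuple(axes)} (with falloff) exceed the "
                         f"grid {cfg.shape}")
    r = _ellipsoid_radius(cfg)
    if cfg.falloff <= 0:
        grid = (r <= 1.0).astype(float)
    else:
        # linear ramp centered on r=1 so the half-intensity surface is the
        # nominal ellipsoid itself
        grid = np.clip((1.0 + cfg.falloff / 2 - r) / cfg.falloff, 0.0, 1.0)
    return BrainVolume(grid=grid, affine=_ras_affine(cfg), space_name="synthetic-ellipsoid")


def make_parcellation(template: BrainVolume, n_labels: int,
                      seed: int = 42) -> Parcellation:
    """Voronoi parcellation: ``n_labels`` seed voxels drawn uniformly in
    the mask; every mask voxel takes the label of its nearest seed."""
    mask = template.grid > 0.5
    voxels = np.argwhere(mask)
    if n_labels > len(voxels):
        raise ValueError(f"n_labels={n_labels} exceeds mask size {len(voxels)}")
    rng = np.random.default_rng(seed)
    seeds = voxels[rng.choice(len(voxels), size=n_labels, replace=False)]
    _, nearest = cKDTree(seeds).query(voxels)
    grid = np.zeros(template.grid.shape, dtype=np.int32)
    grid[tuple(voxels.T)] = nearest + 1
    return Parcellation(grid=grid, affine=template.affine,
                        space_name=template.space_name)


def _sample_in_ellipsoid(cfg: FixtureConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """World-mm points rejection-sampled uniformly inside the ellipsoid."""
    axes_mm = np.asarray(cfg.semi_axes) * cfg.voxel_mm
    pts = np.empty((0, 3))
    while len(pts) < n:
        cand = rng.uniform(-1, 1, size=(4 * n, 3))
        cand = cand[np.sum(cand ** 2, axis=1) <= 1.0]
        pts = np.vstack([pts, cand * axes_mm])
    return pts[:n]


def make_network(n_nodes: int | None = None,
                 cfg: FixtureConfig = FixtureConfig()) -> tuple[NodeTable, EdgeTable]:
    """Community-structured random network inside the template ellipsoid.

    Nodes carry a 'community' label (round-robin 1..n_communities) and two
    continuous measures ('measure1', 'measure2'); an edge between nodes of
    the same community appears with probability ``p_within``, otherwise
    ``p_between``; weights are uniform on (0, 1].
    """
    n = cfg.n_nodes if n_nodes is None else n_nodes
    if n < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    coords = _sample_in_ellipsoid(cfg, n, rng)
    community = (np.arange(n) % cfg.n_communities) + 1
    nodes = NodeTable(pd.DataFrame({
        "node_id": np.arange(n),
        "x": coords[:, 0], "y": coords[:, 1], "z": coords[:, 2],
        "community": community,
        "measure1": rng.uniform(0, 1, size=n),
        "measure2": rng.normal(0, 1, size=n),
    }))
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            p = cfg.p_within if community[i] == community[j] else cfg.p_between
            if rng.random() < p:
                rows.append((i, j, 1.0 - rng.random()))  # uniform on (0, 1]
    edges = EdgeTable(pd.DataFrame(rows, columns=["i", "j", "weight"])) if rows \
        else empty_edge_table()
    return nodes, edges


def make_highlight_matrix(edges: EdgeTable, n_select: int,
                          seed: int = 42) -> np.ndarray:
    """Symmetric binary matrix marking ``n_select`` existing edges —
    shaped like the significant-cluster mask of a network-based-statistics
    run, for the highlight_edges keyword."""
    if n_select > edges.n:
        raise ValueError(f"cannot select {n_select} of {edges.n} edges")
    pairs = edges.pairs
    n_nodes = int(pairs.max()) + 1 if len(pairs) else 1
    m = np.zeros((n_nodes, n_nodes), dtype=int)
    if n_select:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(edges.n, size=n_select, replace=False)
        for i, j in pairs[chosen]:
            m[i, j] = m[j, i] = 1
    return m


# ---------------------------------------------------------------------------
# File-format writers (fixtures in the same formats the engine reads)
# ---------------------------------------------------------------------------

def write_fixture_set(outdir: str | Path,
                      cfg: FixtureConfig = FixtureConfig()) -> dict[str, Path]:
    """Write a complete on-disk fixture set: template + parcellation NIfTIs,
    node/edge TSVs, and an adjacency-matrix text file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    template = make_template(cfg)
    parc = make_parcellation(template, cfg.n_labels, seed=cfg.seed)
    nodes, edges = make_network(cfg=cfg)
    paths = {
        "template": outdir / "template.nii.gz",
        "parcellation": outdir / "parcellation.nii.gz",
        "nodes": outdir / "nodes.tsv",
        "edges": outdir / "edges.tsv",
        "adjacency": outdir / "adjacency.txt",
    }
    save_volume(template, paths["template"])
    save_volume(parc, paths["parcellation"])
    nodes.data.to_csv(paths["nodes"], sep="\t", index=False)
    edges.data.to_csv(paths["edges"], sep="\t", index=False)
    from .data_model import edgelist_to_adjacency
    np.savetxt(paths["adjacency"], edgelist_to_adjacency(edges, nodes.n))
    return paths
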