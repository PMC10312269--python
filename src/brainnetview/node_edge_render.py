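"""Node and edge geometry, declarative aesthetics, highlighting, legends.

The high-level interface maps metadata columns of the node/edge tables
onto visual channels: a column name given as ``node_color`` or
``node_size`` resolves to one color/size per node, with the legend built
automatically.  Integer-valued columns with few distinct values (e.g.
community labels) are treated categorically; everything else numeric is
continuous.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence, Union

import numpy as np
import pandas as pd
from matplotlib import colormaps
from matplotlib.colors import Normalize, to_hex

from .data_model import EdgeTable, NodeTable
from .template_styles import Mesh, extract_surface
from .volume_io import Parcellation

CATEGORICAL_MAX_LEVELS = 12
DEFAULT_DIM_ALPHA = 0.15
_CATEGORICAL_PALETTE = "tab10"


# ---------------------------------------------------------------------------
# Aesthetic mappings
# ---------------------------------------------------------------------------

@dataclass
class AestheticMapping:
    """A resolved column -> visual-channel mapping plus its legend block."""

    source_column: str
    kind: str                       # 'categorical' | 'continuous' | 'constant'
    channel: str                    # 'color' | 'size'
    values: np.ndarray              # one resolved value per element
    legend_entries: list[tuple[str, Any]] = field(default_factory=list)


def _is_categorical(values: pd.Series) -> bool:
    if not pd.api.types.is_numeric_dtype(values):
        return True
    arr = values.to_numpy()
    if np.allclose(arr, np.round(arr)):
        return len(np.unique(arr)) <= CATEGORICAL_MAX_LEVELS
    return False


def map_color(values: Sequence, cmap: str = "viridis",
              categorical: Optional[bool] = None,
              column: str = "value") -> AestheticMapping:
    """Resolve a data column to one color per element.

    Categorical columns (non-numeric, or integer-valued with at most
    ``CATEGORICAL_MAX_LEVELS`` distinct values) get one distinct palette
    color per category; continuous columns map linearly onto ``cmap``
    between the observed min and max.
    """
    s = pd.Series(values)
    if len(s) == 0:
        raise ValueError("cannot map colors for an empty column")
    if categorical is None:
        categorical = _is_categorical(s)
    if categorical:
        try:
            cats = sorted(pd.unique(s))
        except TypeError as err:
            raise ValueError(f"column {column!r} mixes un-orderable types: {err}") from err
        palette = colormaps[_CATEGORICAL_PALETTE]
        lut = {c: to_hex(palette(k % palette.N)) for k, c in enumerate(cats)}
        resolved = np.array([lut[v] for v in s])
        legend = [(str(c), lut[c]) for c in cats]
        kind = "categorical" if len(cats) > 1 else "constant"
        return AestheticMapping(column, kind, "color", resolved, legend)
    arr = pd.to_numeric(s, errors="raise").to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError(f"column {column!r} contains non-finite values")
    vmin, vmax = arr.min(), arr.max()
    norm = Normalize(vmin=vmin, vmax=vmax if vmax > vmin else vmin + 1.0)
    cm = colormaps[cmap]
    resolved = np.array([to_hex(cm(norm(v))) for v in arr])
    legend = [(f"{q:g}", to_hex(cm(norm(q))))
              for q in (vmin, (vmin + vmax) / 2, vmax)]
    return AestheticMapping(column, "continuous", "color", resolved, legend)


def map_size(values: Sequence, bounds: tuple[float, float] = (10.0, 50.0),
             column: str = "value") -> AestheticMapping:
    """Affine map of the observed value range onto ``bounds``.

    Constant columns map to the midpoint; the legend carries the
    min/mid/max representative sizes.
    """
    s = pd.to_numeric(pd.Series(values), errors="coerce")
    if s.isna().any():
        raise ValueError(f"size column {column!r} must be numeric")
    arr = s.to_numpy(dtype=float)
    if len(arr) == 0:
        raise ValueError("cannot map sizes for an empty column")
    if not np.isfinite(arr).all():
        raise ValueError(f"size column {column!r} contains non-finite values")
    lo, hi = bounds
    vmin, vmax = arr.min(), arr.max()
    if vmax == vmin:
        sizes = np.full_like(arr, (lo + hi) / 2.0)
    else:
        sizes = lo + (arr - vmin) * (hi - lo) / (vmax - vmin)
    legend = [(f"{v:g}", float(sz)) for v, sz in
              [(vmin, sizes.min()), ((vmin + vmax) / 2, (sizes.min() + sizes.max()) / 2),
               (vmax, sizes.max())]]
    return AestheticMapping(column, "constant" if vmax == vmin else "continuous",
                            "size", sizes, legend)


# ---------------------------------------------------------------------------
# Highlighting
# ---------------------------------------------------------------------------

@dataclass
class HighlightSpec:
    """What to emphasize: a boolean column name, an explicit id list, or —
    for edges — a binary N x N selection matrix (e.g. significant-cluster
    output of network-based statistics)."""

    selector: Union[str, Sequence[int], np.ndarray]
    dim_alpha: float = DEFAULT_DIM_ALPHA

    def __post_init__(self) -> None:
        if not 0.0 <= self.dim_alpha <= 1.0:
            raise ValueError("dim_alpha must lie in [0, 1]")


@dataclass
class HighlightResult:
    selected: np.ndarray   # boolean per element
    alphas: np.ndarray     # per-element alpha
    n_selected: int


def _resolve_selector(elements: Union[NodeTable, EdgeTable],
                      spec: HighlightSpec) -> np.ndarray:
    sel = spec.selector
    n = elements.n
    if isinstance(sel, str):
        if sel not in elements.data.columns:
            raise ValueError(f"highlight column {sel!r} not found; available: "
                             f"{list(elements.data.columns)}")
        return elements.data[sel].astype(bool).to_numpy()
    arr = np.asarray(sel)
    if arr.ndim == 2:
        if not isinstance(elements, EdgeTable):
            raise ValueError("a matrix selector applies to edges only")
        pairs = elements.pairs
        n_nodes = int(pairs.max()) + 1 if len(pairs) else 0
        if arr.shape[0] != arr.shape[1] or (n_nodes and arr.shape[0] < n_nodes):
            raise ValueError(f"highlight matrix shape {arr.shape} does not cover "
                             f"node ids up to {n_nodes - 1}")
        return np.array([bool(arr[i, j]) or bool(arr[j, i]) for i, j in pairs])
    if arr.dtype == bool:
        if len(arr) != n:
            raise ValueError(f"boolean selector length {len(arr)} != {n} elements")
        return arr
    mask = np.zeros(n, dtype=bool)
    if isinstance(elements, NodeTable):
        ids = elements.data["node_id"].to_numpy()
        mask = np.isin(ids, arr)
    else:
        mask[np.asarray(arr, dtype=int)] = True
    return mask


def apply_highlight(elements: Union[NodeTable, EdgeTable],
                    spec: HighlightSpec,
                    base_alpha: float = 1.0) -> HighlightResult:
    """Emphasize selected elements; everything else is dimmed to
    ``spec.dim_alpha``.  Geometry is untouched — only alpha changes."""
    selected = _resolve_selector(elements, spec)
    alphas = np.where(selected, base_alpha, min(spec.dim_alpha, base_alpha))
    return HighlightResult(selected=selected, alphas=alphas,
                           n_selected=int(selected.sum()))


# ---------------------------------------------------------------------------
# Node geometry
# ---------------------------------------------------------------------------

NODE_STYLES = ("circles", "spheres", "parcels")
SPHERE_RESOLUTION = 20


def sphere_radius(size: float) -> float:
    """Marker size (area-like units) -> sphere radius in mm."""
    return float(np.sqrt(max(size, 0.0)) / 2.0)


def _unit_sphere(resolution: int = SPHERE_RESOLUTION) -> tuple[np.ndarray, np.ndarray]:
    u = np.linspace(0, 2 * np.pi, resolution)
    t = np.linspace(0, np.pi, resolution)
    uu, tt = np.meshgrid(u, t)
    verts = np.column_stack([(np.sin(tt) * np.cos(uu)).ravel(),
                             (np.sin(tt) * np.sin(uu)).ravel(),
                             np.cos(tt).ravel()])
    faces = []
    for r in range(resolution - 1):
        for c in range(resolution - 1):
            a = r * resolution + c
            faces.append([a, a + 1, a + resolution])
            faces.append([a + 1, a + resolution + 1, a + resolution])
    return verts, np.asarray(faces)


@dataclass
class MarkerSet:
    """Billboard circle markers: positions + per-node size/color/alpha."""

    positions: np.ndarray
    sizes: np.ndarray
    colors: np.ndarray
    alphas: np.ndarray


def node_geometry(nodes: NodeTable, style: str,
                  sizes: Optional[np.ndarray] = None,
                  colors: Optional[np.ndarray] = None,
                  alphas: Optional[np.ndarray] = None,
                  parcellation: Optional[Parcellation] = None,
                  default_color: str = "steelblue",
                  default_size: float = 20.0):
    """Build renderable node geometry for the chosen style.

    circles -> a MarkerSet; spheres -> one tessellated Mesh per node with
    radius monotonic in size; parcels -> one isosurface Mesh per label of
    the retained parcellation (which is therefore required).
    """
    if style not in NODE_STYLES:
        raise ValueError(f"unknown node style {style!r}; choose one of {set(NODE_STYLES)}")
    n = nodes.n
    sizes = np.full(n, default_size, dtype=float) if sizes is None else np.asarray(sizes, dtype=float)
    colors = np.full(n, default_color, dtype=object) if colors is None else np.asarray(colors, dtype=object)
    alphas = np.ones(n) if alphas is None else np.asarray(alphas, dtype=float)

    if style == "circles":
        return MarkerSet(positions=nodes.coordinates, sizes=sizes,
                         colors=colors, alphas=alphas)
    if style == "spheres":
        base_v, base_f = _unit_sphere()
        meshes = []
        for k, center in enumerate(nodes.coordinates):
            r = sphere_radius(sizes[k])
            meshes.append(Mesh(vertices=center + r * base_v, faces=base_f,
                               alpha=float(alphas[k]), color=colors[k]))
        return meshes
    # parcels
    if parcellation is None:
        raise ValueError("node style 'parcels' requires the nodes to be "
                         "specified as a labeled volume (parcellation)")
    if "label" in nodes.data.columns:
        labels = nodes.data["label"].to_numpy(dtype=int)
    else:
        labels = parcellation.labels
    meshes = []
    for k, label in enumerate(labels):
        mask = parcellation.grid == label
        meshes.append(extract_surface(mask, parcellation.affine,
                                      alpha=float(alphas[k % len(alphas)]),
                                      color=colors[k % len(colors)]))
    return meshes


# ---------------------------------------------------------------------------
# Edge geometry
# ---------------------------------------------------------------------------

@dataclass
class SegmentSet:
    """3D line segments between node centroids, one per surviving edge."""

    starts: np.ndarray      # (E, 3)
    ends: np.ndarray        # (E, 3)
    widths: np.ndarray      # (E,)
    edge_index: np.ndarray  # row index into the source EdgeTable
    colors: np.ndarray
    alphas: np.ndarray

    @property
    def n(self) -> int:
        return len(self.starts)


def edge_segments(nodes: NodeTable, edges: EdgeTable,
                  weight_scaling: Optional[tuple[str, tuple[float, float]]] = None,
                  threshold: Optional[float] = None,
                  threshold_absolute: bool = False,
                  color: str = "dimgray",
                  alphas: Optional[np.ndarray] = None) -> SegmentSet:
    """Straight lines between node centroids.

    Thresholding (keep weight >= threshold; optionally on |weight|)
    happens before width scaling, so widths span the surviving weights.
    """
    coords = {int(nid): xyz for nid, xyz in
              zip(nodes.data["node_id"], nodes.coordinates)}
    df = edges.data
    idx = np.arange(len(df))
    if threshold is not None and len(df):
        w = df["weight"].to_numpy(dtype=float)
        keep = (np.abs(w) if threshold_absolute else w) >= threshold
        df, idx = df.loc[keep], idx[keep]
    missing = [nid for nid in pd.unique(df[["i", "j"]].to_numpy().ravel())
               if int(nid) not in coords] if len(df) else []
    if missing:
        raise ValueError(f"edges reference unknown node ids {missing}")
    starts = np.array([coords[int(i)] for i in df["i"]]).reshape(-1, 3)
    ends = np.array([coords[int(j)] for j in df["j"]]).reshape(-1, 3)
    if weight_scaling is not None and len(df):
        wcol, bounds = weight_scaling
        widths = map_size(df[wcol], bounds=bounds, column=wcol).values
    else:
        widths = np.full(len(df), 1.5)
    a = np.ones(len(df)) if alphas is None else np.asarray(alphas)[idx]
    return SegmentSet(starts=starts, ends=ends, widths=widths,
                      edge_index=idx,
                      colors=np.full(len(df), color, dtype=object),
                      alphas=a)


# ---------------------------------------------------------------------------
# Legends
# ---------------------------------------------------------------------------

def build_legend(mappings: Sequence[AestheticMapping]) -> Optional[list[dict]]:
    """One legend block per mapping, in declaration order.

    Categorical color blocks enumerate every category; size blocks carry
    min/mid/max representative entries.  No mappings -> no legend.
    """
    blocks = []
    for m in mappings:
        if not m.legend_entries:
            continue
        blocks.append({"title": m.source_column, "channel": m.channel,
                       "kind": m.kind, "entries": list(m.legend_entries)})
    return blocks or None
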