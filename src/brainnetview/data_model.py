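"""Canonical domain types and input normalization.

The engine composes three independently specified components — a template
volume, a node set, and an edge set.  This module owns the tabular side:
node and edge tables in all their accepted forms (coordinate tables,
integer-labeled parcellations, atlas descriptors, adjacency matrices,
edge lists, node-attributed graphs) and the ``<component>_<option>``
keyword-routing convention used by the high-level interface.

Nodes are world-millimetre points with open-ended metadata columns; edges
are undirected weighted pairs referencing dense 0-based node ids.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("brainnetview")

COORD_COLUMNS = ("x", "y", "z")
SYMMETRY_TOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class NodeTable:
    """Per-node records: dense 0-based ``node_id``, world-mm ``x,y,z``,
    plus arbitrary metadata columns (community labels, centrality, ...)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("node_id", *COORD_COLUMNS):
            if col not in df.columns:
                raise ValueError(f"NodeTable requires column {col!r}; has {list(df.columns)}")
        coords = df[list(COORD_COLUMNS)].to_numpy()
        if coords.size and not np.isfinite(coords.astype(float)).all():
            raise ValueError("node coordinates must be finite numerics")
        ids = df["node_id"].to_numpy()
        if len(ids) != len(set(ids)):
            raise ValueError("node_id values must be unique")
        self.data = df.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def coordinates(self) -> np.ndarray:
        """(N, 3) world-mm coordinates."""
        return self.data[list(COORD_COLUMNS)].to_numpy(dtype=float)

    @property
    def metadata_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("node_id", *COORD_COLUMNS)]

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"no node column {name!r}; available: {list(self.data.columns)}")
        return self.data[name]


@dataclass
class EdgeTable:
    """Per-edge records: node ids ``i`` < ``j``, ``weight`` (default 1.0),
    plus arbitrary metadata columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("i", "j"):
            if col not in df.columns:
                raise ValueError(f"EdgeTable requires column {col!r}; has {list(df.columns)}")
        if "weight" not in df.columns:
            df = df.assign(weight=1.0)
        self.data = df.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def pairs(self) -> np.ndarray:
        return self.data[["i", "j"]].to_numpy(dtype=int)

    @property
    def weights(self) -> np.ndarray:
        return self.data["weight"].to_numpy(dtype=float)

    @property
    def metadata_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("i", "j", "weight")]


def empty_edge_table() -> EdgeTable:
    return EdgeTable(pd.DataFrame({"i": pd.Series(dtype=int),
                                   "j": pd.Series(dtype=int),
                                   "weight": pd.Series(dtype=float)}))


# ---------------------------------------------------------------------------
# Option routing: the <component>_<option> convention
# ---------------------------------------------------------------------------

TEMPLATE_DEFAULTS: dict[str, Any] = {
    "style": "glass",
    "alpha": None,          # style-specific default chosen at render time
    "voxelsize": None,      # mm; downsampling lever for the filled style
    "color": "lightgray",
    "hemisphere": None,     # 'L' | 'R'
    "glass_segments": 500,
    "glass_compactness": 0.05,
}

NODE_DEFAULTS: dict[str, Any] = {
    "style": "circles",     # circles | spheres | parcels
    "color": "steelblue",   # constant color or a metadata column name
    "size": 20.0,           # constant size or a metadata column name
    "size_bounds": (10.0, 50.0),
    "alpha": 1.0,
    "cmap": "viridis",
    "columnnames": None,    # alternative (x, y, z) column names
    "df": None,             # extra metadata table (the nodes_df keyword)
    "highlight": None,
}

EDGE_DEFAULTS: dict[str, Any] = {
    "color": "dimgray",
    "alpha": 1.0,
    "weights": "weight",    # weight column name
    "width_bounds": (0.5, 3.0),
    "widthscale": True,     # scale line width by weight
    "threshold": None,
    "threshold_absolute": False,
    "columnnames": None,    # alternative (i, j) column names
    "df": None,             # extra metadata table (the edges_df keyword)
    "highlight": None,
}

FIGURE_DEFAULTS: dict[str, Any] = {
    "view": "L",
    "frames": None,
    "savename": None,
    "panel_size": 4.0,      # inches per panel
    "background": "white",
    "seed": 42,
    "dim_alpha": 0.15,      # de-emphasis alpha used by highlighting
}

_COMPONENT_DEFAULTS = {
    "template": TEMPLATE_DEFAULTS,
    "node": NODE_DEFAULTS,
    "edge": EDGE_DEFAULTS,
    "fig": FIGURE_DEFAULTS,
}

# Figure-level options are unprefixed, matching the call convention
# (view=..., frames=..., savename=...).
_FIGURE_PLAIN = set(FIGURE_DEFAULTS)

_ALIASES: dict[str, tuple[str, str]] = {
    "nodes_df": ("node", "df"),
    "edges_df": ("edge", "df"),
    "highlight_edges": ("edge", "highlight"),
    "highlight_nodes": ("node", "highlight"),
    "hemisphere": ("template", "hemisphere"),
}


def known_option_names() -> list[str]:
    """Every accepted keyword, in canonical form."""
    names: list[str] = []
    for comp in ("template", "node", "edge"):
        names.extend(f"{comp}_{opt}" for opt in _COMPONENT_DEFAULTS[comp])
    names.extend(sorted(_FIGURE_PLAIN))
    names.extend(_ALIASES)
    return names


def _levenshtein(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _nearest_option(name: str, max_dist: int = 3) -> Optional[str]:
    best, best_d = None, max_dist + 1
    for cand in known_option_names():
        d = _levenshtein(name, cand)
        if d < best_d:
            best, best_d = cand, d
    return best if best_d <= max_dist else None


@dataclass
class StyleOptions:
    """Resolved per-component option maps (complete: all defaults filled)."""

    template: dict[str, Any] = field(default_factory=dict)
    node: dict[str, Any] = field(default_factory=dict)
    edge: dict[str, Any] = field(default_factory=dict)
    figure: dict[str, Any] = field(default_factory=dict)

    def to_flat(self) -> dict[str, Any]:
        """Re-express as the flat keyword map that produced this object."""
        flat: dict[str, Any] = {}
        for comp in ("template", "node", "edge"):
            for opt, val in getattr(self, comp).items():
                flat[f"{comp}_{opt}"] = val
        flat.update(self.figure)
        return flat

    def copy(self) -> "StyleOptions":
        return replace(self, template=dict(self.template), node=dict(self.node),
                       edge=dict(self.edge), figure=dict(self.figure))


def resolve_options(raw: Mapping[str, Any] | StyleOptions) -> StyleOptions:
    """Route ``<component>_<option>`` keywords into per-component maps.

    Unknown names are rejected: with the nearest known option (edit
    distance <= 3) when one exists, otherwise naming the valid component
    prefixes.  Idempotent: resolving an already-resolved set is a no-op.
    """
    if isinstance(raw, StyleOptions):
        raw = raw.to_flat()
    maps = {comp: dict(defaults) for comp, defaults in _COMPONENT_DEFAULTS.items()}
    for name, value in raw.items():
        if not isinstance(name, str):
            raise TypeError(f"option names must be strings, got {name!r}")
        if name in _ALIASES:
            comp, opt = _ALIASES[name]
            maps[comp][opt] = value
            continue
        if name in _FIGURE_PLAIN:
            maps["fig"][name] = value
            continue
        comp, _, opt = name.partition("_")
        if comp in ("template", "node", "edge") and opt in _COMPONENT_DEFAULTS[comp]:
            maps[comp][opt] = value
            continue
        suggestion = _nearest_option(name)
        if suggestion is not None:
            raise ValueError(f"unknown option {name!r}; did you mean {suggestion!r}?")
        if comp not in ("template", "node", "edge"):
            raise ValueError(
                f"unknown option {name!r}: component prefix {comp!r} is not one of "
                "'template', 'node', 'edge' (figure options view/frames/savename/"
                "seed/panel_size/background/dim_alpha are unprefixed)")
        raise ValueError(
            f"unknown option {opt!r} for component {comp!r}; known options: "
            f"{sorted(_COMPONENT_DEFAULTS[comp])}")
    return StyleOptions(template=maps["template"], node=maps["node"],
                        edge=maps["edge"], figure=maps["fig"])


# ---------------------------------------------------------------------------
# Edge parsing
# ---------------------------------------------------------------------------

def adjacency_to_edgelist(matrix: np.ndarray) -> EdgeTable:
    """Convert a symmetric N x N adjacency matrix to an undirected edge list.

    One record per unordered pair (i < j) with a nonzero value; the
    diagonal is ignored.  Asymmetry beyond 1e-9 is an error.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"adjacency matrix must be square, got shape {m.shape}")
    asym = np.abs(m - m.T).max() if m.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ValueError(
            f"adjacency matrix is asymmetric: max |m[i,j]-m[j,i]| = {asym:g} "
            f"(tolerance {SYMMETRY_TOL:g}); undirected edges require symmetry")
    iu, ju = np.triu_indices(m.shape[0], k=1)
    vals = m[iu, ju]
    keep = vals != 0
    return EdgeTable(pd.DataFrame({"i": iu[keep].astype(int),
                                   "j": ju[keep].astype(int),
                                   "weight": vals[keep]}))


def edgelist_to_adjacency(edges: EdgeTable, n_nodes: int) -> np.ndarray:
    """Inverse of :func:`adjacency_to_edgelist` (zero diagonal, symmetric)."""
    m = np.zeros((n_nodes, n_nodes))
    for i, j, w in zip(edges.data["i"], edges.data["j"], edges.data["weight"]):
        m[int(i), int(j)] = w
        m[int(j), int(i)] = w
    return m


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def parse_edges(source: Any, columnnames: Optional[Sequence[str]] = None,
                weights_column: Optional[str] = None,
                n_nodes: Optional[int] = None) -> EdgeTable:
    """Normalize any accepted edge form into a canonical :class:`EdgeTable`.

    ``source`` may be an N x N array (adjacency matrix), a DataFrame /
    delimited-file path (edge list with columns 'i','j' or the pair named
    by ``columnnames``), or an existing EdgeTable.  Self-loops are dropped
    with a warning; duplicate unordered pairs collapse to their first
    occurrence; node references are validated against ``n_nodes``.
    """
    if isinstance(source, EdgeTable):
        df = source.data.copy()
    elif isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix.lower() in (".tsv", ".csv"):
            df = _read_table(path)
        else:  # whitespace-delimited matrix text
            return parse_edges(np.loadtxt(path), n_nodes=n_nodes)
    elif isinstance(source, np.ndarray):
        table = adjacency_to_edgelist(source)
        if n_nodes is not None and source.shape[0] != n_nodes:
            raise ValueError(
                f"adjacency matrix is {source.shape[0]}x{source.shape[1]} but "
                f"{n_nodes} nodes were supplied")
        return table
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        raise TypeError(f"unsupported edge source of type {type(source).__name__}")

    if columnnames is not None:
        ci, cj = columnnames
        missing = [c for c in (ci, cj) if c not in df.columns]
        if missing:
            raise ValueError(f"edge columns {missing} not found; available: {list(df.columns)}")
        df = df.rename(columns={ci: "i", cj: "j"})
    for col in ("i", "j"):
        if col not in df.columns:
            raise ValueError(f"edge table lacks column {col!r}; available: {list(df.columns)} "
                             "(use edge_columnnames to remap)")
    if weights_column is not None and weights_column != "weight":
        if weights_column not in df.columns:
            raise ValueError(f"edge weight column {weights_column!r} not found; "
                             f"available: {list(df.columns)}")
        df = df.rename(columns={weights_column: "weight"})
    if "weight" not in df.columns:
        df["weight"] = 1.0

    # normalize to i < j, drop self-loops and duplicate unordered pairs
    ii = df["i"].to_numpy()
    jj = df["j"].to_numpy()
    loops = ii == jj
    if loops.any():
        logger.warning("dropping %d self-loop edge(s)", int(loops.sum()))
        df = df.loc[~loops]
        ii, jj = df["i"].to_numpy(), df["j"].to_numpy()
    lo, hi = np.minimum(ii, jj), np.maximum(ii, jj)
    df = df.assign(i=lo.astype(int), j=hi.astype(int))
    df = df.drop_duplicates(subset=["i", "j"], keep="first")
    df = df.sort_values(["i", "j"], kind="stable").reset_index(drop=True)

    if n_nodes is not None and len(df):
        bad = (df["i"].to_numpy() < 0) | (df["j"].to_numpy() >= n_nodes)
        if bad.any():
            rows = df.index[bad].tolist()
            raise ValueError(f"edge rows {rows} reference node ids outside 0..{n_nodes - 1}")
    return EdgeTable(df)


# ---------------------------------------------------------------------------
# Node parsing
# ---------------------------------------------------------------------------

def _canonical_node_frame(df: pd.DataFrame,
                          columnnames: Optional[Sequence[str]]) -> pd.DataFrame:
    df = df.copy()
    if columnnames is not None:
        if len(columnnames) != 3:
            raise ValueError("node_columnnames must name exactly three columns (x, y, z)")
        missing = [c for c in columnnames if c not in df.columns]
        if missing:
            raise ValueError(f"node columns {missing} not found; available: {list(df.columns)}")
        df = df.rename(columns=dict(zip(columnnames, COORD_COLUMNS)))
    missing = [c for c in COORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"node table lacks coordinate columns {missing}; "
                         f"available: {list(df.columns)} (use node_columnnames to remap)")
    for c in COORD_COLUMNS:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"node coordinate column {c!r} contains non-numeric values")
        df[c] = vals.astype(float)
    if "node_id" not in df.columns:
        df.insert(0, "node_id", np.arange(len(df)))
    return df


def parse_nodes(source: Any, columnnames: Optional[Sequence[str]] = None,
                metadata: Optional[pd.DataFrame] = None,
                fetcher: Any = None) -> tuple[NodeTable, Optional[Any]]:
    """Normalize any accepted node form into ``(NodeTable, Parcellation | None)``.

    Accepted forms: a coordinate DataFrame (columns x/y/z or the triple in
    ``columnnames``), a delimited-file path, an integer-labeled volume
    (path to a NIfTI file, a nibabel image, or a Parcellation), or an
    atlas-descriptor mapping resolved through ``fetcher``.  Parcellation
    sources yield one node per label at its centroid and the parcellation
    itself is retained for the 'parcels' node style.
    """
    from . import volume_io  # deferred: avoids import cycle

    parcellation = None
    if isinstance(source, volume_io.Parcellation):
        parcellation = source
    elif isinstance(source, volume_io.BrainVolume):
        parcellation = volume_io.as_parcellation(source)
    elif isinstance(source, Mapping):  # atlas descriptor
        if fetcher is None:
            raise ValueError("an atlas-descriptor node source requires a fetcher")
        parcellation = volume_io.fetch_atlas(dict(source), fetcher)
    elif isinstance(source, (str, Path)) and str(source).endswith((".nii", ".nii.gz")):
        parcellation = volume_io.as_parcellation(volume_io.load_volume(source))
    elif hasattr(source, "get_fdata") and hasattr(source, "affine"):  # nibabel image
        parcellation = volume_io.as_parcellation(volume_io.from_nibabel(source))

    if parcellation is not None:
        nodes = volume_io.compute_centroids(parcellation)
    else:
        if isinstance(source, (str, Path)):
            df = _read_table(Path(source))
        elif isinstance(source, pd.DataFrame):
            df = source
        elif isinstance(source, NodeTable):
            df = source.data
        else:
            raise TypeError(f"unsupported node source of type {type(source).__name__}")
        nodes = NodeTable(_canonical_node_frame(df, columnnames))

    if metadata is not None:
        nodes = merge_node_metadata(nodes, metadata)
    return nodes, parcellation


def merge_node_metadata(nodes: NodeTable, extra: pd.DataFrame) -> NodeTable:
    """Append metadata columns row-wise (the ``nodes_df`` keyword).

    When nodes came from a parcellation their rows are already in ascending
    integer-label order, so row k of ``extra`` attaches to the k-th label.
    """
    if len(extra) != nodes.n:
        raise ValueError(f"metadata has {len(extra)} rows but there are {nodes.n} nodes")
    collisions = [c for c in extra.columns if c in COORD_COLUMNS]
    if collisions:
        raise ValueError(f"metadata columns {collisions} collide with coordinate columns")
    merged = pd.concat([nodes.data.reset_index(drop=True),
                        extra.reset_index(drop=True)], axis=1)
    merged = merged.loc[:, ~merged.columns.duplicated(keep="last")]
    return NodeTable(merged)


# ---------------------------------------------------------------------------
# Graph ingestion
# ---------------------------------------------------------------------------

def ingest_graph(graph: Any,
                 columnnames: Optional[Sequence[str]] = None) -> tuple[NodeTable, EdgeTable]:
    """Split a node-attributed undirected graph into (NodeTable, EdgeTable).

    Every graph node must carry x/y/z attributes (or the names given in
    ``columnnames``).  Node identifiers are remapped to dense 0-based ids;
    the original identifier is preserved in a ``name`` column.  All other
    node/edge attributes become metadata columns usable for aesthetics.
    """
    coord_names = tuple(columnnames) if columnnames is not None else COORD_COLUMNS
    node_ids = list(graph.nodes)
    rows = []
    for nid in node_ids:
        attrs = dict(graph.nodes[nid])
        for cn in coord_names:
            if cn not in attrs:
                raise ValueError(f"graph node {nid!r} is missing coordinate attribute {cn!r}")
        row = {"name": nid}
        row.update({canon: attrs.pop(cn) for canon, cn in zip(COORD_COLUMNS, coord_names)})
        row.update(attrs)
        rows.append(row)
    if rows:
        ndf = pd.DataFrame(rows)
        ndf.insert(0, "node_id", np.arange(len(ndf)))
    else:
        ndf = pd.DataFrame({"node_id": pd.Series(dtype=int), "name": [],
                            "x": pd.Series(dtype=float), "y": pd.Series(dtype=float),
                            "z": pd.Series(dtype=float)})
    nodes = NodeTable(ndf)

    index = {nid: k for k, nid in enumerate(node_ids)}
    erows = []
    for u, v, attrs in graph.edges(data=True):
        row = {"i": index[u], "j": index[v]}
        row.update(attrs)
        erows.append(row)
    edges = parse_edges(pd.DataFrame(erows), n_nodes=len(node_ids)) if erows \
        else empty_edge_table()
    return nodes, edges
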