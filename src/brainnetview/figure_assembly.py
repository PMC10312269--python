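"""The high-level entry point: compose template, nodes, and edges into a
multi-panel 3D figure.

``plot`` resolves the declarative keyword options, normalizes the three
component inputs, builds each panel's geometry, lays the panels out on
the requested view grid (anatomical cameras plus an optional 2D spring-
layout panel), auto-generates legends from the active aesthetic
mappings, and optionally writes the figure to PNG or SVG.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import matplotlib
matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.lines import Line2D
from matplotlib.figure import Figure

from . import views as views_mod
from .data_model import (EdgeTable, NodeTable, StyleOptions, ingest_graph,
                         parse_edges, parse_nodes, resolve_options)
from .node_edge_render import (AestheticMapping, HighlightSpec, MarkerSet,
                               apply_highlight, build_legend, edge_segments,
                               map_color, map_size, node_geometry)
from .template_styles import Mesh, PointCloud, style_dispatch
from .volume_io import (BrainVolume, Parcellation, hemisphere_restrict_network,
                        hemisphere_restrict_volume, select_template_image)

logger = logging.getLogger("brainnetview")

# stable hashed ids in SVG output so seeded re-runs are byte-identical
matplotlib.rcParams["svg.hashsalt"] = "brainnetview"


@dataclass
class FigureResult:
    """Figure handle, per-panel axes, legend blocks, and a provenance
    record of every resolved option and input summary."""

    figure: Figure
    panels: list
    legend: Optional[list] = None
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Panel rendering helpers
# ---------------------------------------------------------------------------

def _draw_geometry(ax, geom, background: str) -> None:
    if geom is None:
        return
    if isinstance(geom, Mesh):
        ax.plot_trisurf(geom.vertices[:, 0], geom.vertices[:, 1], geom.vertices[:, 2],
                        triangles=geom.faces, color=geom.color, alpha=geom.alpha,
                        linewidth=0, antialiased=False, shade=True)
    elif isinstance(geom, PointCloud):
        ax.scatter(geom.points[:, 0], geom.points[:, 1], geom.points[:, 2],
                   s=geom.size, c=geom.color, alpha=geom.alpha, linewidths=0,
                   depthshade=False)


def _draw_markers(ax, markers: MarkerSet) -> None:
    ax.scatter(markers.positions[:, 0], markers.positions[:, 1],
               markers.positions[:, 2], s=markers.sizes,
               c=list(markers.colors), alpha=None, edgecolors="none",
               depthshade=False)
    # per-marker alpha applied via collection when non-uniform
    if len(set(markers.alphas.tolist())) > 1:
        coll = ax.collections[-1]
        rgba = coll.get_facecolor()
        if len(rgba) == len(markers.alphas):
            rgba[:, 3] = markers.alphas
            coll.set_facecolor(rgba)


def _draw_segments(ax, segs) -> None:
    for k in range(segs.n):
        p0, p1 = segs.starts[k], segs.ends[k]
        ax.plot([p0[0], p1[0]], [p0[1], p1[1]], [p0[2], p1[2]],
                color=segs.colors[k], linewidth=segs.widths[k],
                alpha=float(segs.alphas[k]))


def _style_3d_axes(ax, extent: Optional[tuple[np.ndarray, np.ndarray]],
                   angle: views_mod.CameraAngle, background: str) -> None:
    ax.set_axis_off()
    ax.set_facecolor(background)
    if extent is not None:
        lo, hi = extent
        span = np.maximum(hi - lo, 1e-6)
        ax.set_xlim(lo[0], hi[0])
        ax.set_ylim(lo[1], hi[1])
        ax.set_zlim(lo[2], hi[2])
        ax.set_box_aspect(span)
    ax.view_init(elev=angle.elevation, azim=angle.azimuth)


def _data_extent(template_geom, nodes: Optional[NodeTable],
                 template: Optional[BrainVolume]):
    pts = []
    if template is not None:
        lo, hi = template.world_bounds()
        pts.append(np.vstack([lo, hi]))
    elif isinstance(template_geom, Mesh):
        pts.append(template_geom.vertices)
    elif isinstance(template_geom, PointCloud):
        pts.append(template_geom.points)
    if nodes is not None and nodes.n:
        pts.append(nodes.coordinates)
    if not pts:
        return None
    allpts = np.vstack(pts)
    lo, hi = allpts.min(axis=0), allpts.max(axis=0)
    pad = 0.02 * np.maximum(hi - lo, 1.0)
    return lo - pad, hi + pad


# ---------------------------------------------------------------------------
# The entry point
# ---------------------------------------------------------------------------

def plot(template: Any = None, nodes: Any = None, edges: Any = None,
         network: Any = None, fetcher: Any = None, **options: Any) -> FigureResult:
    """Compose a multi-panel 3D brain-network figure.

    All three components are optional (a template alone, or nodes alone,
    are valid figures), but edges require nodes, and ``network`` (a
    node-attributed graph carrying x/y/z) is mutually exclusive with
    nodes/edges.  Keyword options follow the ``<component>_<option>``
    convention; see :func:`brainnetview.data_model.resolve_options`.
    """
    opts = resolve_options(options)

    if network is not None:
        if nodes is not None or edges is not None:
            raise ValueError("the 'network' argument is mutually exclusive with "
                             "'nodes' and 'edges'")
        nodes, edges = ingest_graph(network, columnnames=opts.node["columnnames"])
    if edges is not None and nodes is None:
        raise ValueError("if edges are specified, the 'nodes' argument must be specified")
    if template is None and nodes is None:
        raise ValueError("nothing to draw: specify a template, nodes, or a network")

    # --- resolve inputs -----------------------------------------------------
    template_vol: Optional[BrainVolume] = None
    if template is not None:
        template_vol = select_template_image(template, fetcher=fetcher)
        logger.info("template: %s (%s)", template_vol.space_name,
                    template_vol.metadata.get("template_variant", "local"))

    node_table: Optional[NodeTable] = None
    parcellation: Optional[Parcellation] = None
    if nodes is not None:
        if isinstance(nodes, NodeTable) and isinstance(edges, EdgeTable):
            node_table = nodes
            if opts.node["df"] is not None:
                from .data_model import merge_node_metadata
                node_table = merge_node_metadata(node_table, opts.node["df"])
        else:
            node_table, parcellation = parse_nodes(
                nodes, columnnames=opts.node["columnnames"],
                metadata=opts.node["df"], fetcher=fetcher)
        logger.info("nodes: %d", node_table.n)

    edge_table: Optional[EdgeTable] = None
    if edges is not None:
        edge_table = parse_edges(edges, columnnames=opts.edge["columnnames"],
                                 weights_column=(opts.edge["weights"]
                                                 if opts.edge["weights"] != "weight" else None),
                                 n_nodes=node_table.n)
        if opts.edge["df"] is not None:
            extra = opts.edge["df"]
            if len(extra) != edge_table.n:
                raise ValueError(f"edges_df has {len(extra)} rows but there are "
                                 f"{edge_table.n} edges")
            import pandas as pd
            merged = pd.concat([edge_table.data.reset_index(drop=True),
                                extra.reset_index(drop=True)], axis=1)
            edge_table = EdgeTable(merged.loc[:, ~merged.columns.duplicated(keep="last")])
        logger.info("edges: %d", edge_table.n)

    # --- hemisphere restriction --------------------------------------------
    hemisphere = opts.template["hemisphere"]
    if hemisphere is not None:
        if template_vol is not None:
            template_vol = hemisphere_restrict_volume(template_vol, hemisphere)
        if node_table is not None:
            node_table, edge_table = hemisphere_restrict_network(
                node_table, edge_table, hemisphere)

    # --- aesthetics ---------------------------------------------------------
    mappings: list[AestheticMapping] = []
    node_colors = node_sizes = None
    if node_table is not None and node_table.n:
        color_opt = opts.node["color"]
        if isinstance(color_opt, str) and color_opt in node_table.data.columns:
            m = map_color(node_table.column(color_opt), cmap=opts.node["cmap"],
                          column=color_opt)
            node_colors = m.values
            mappings.append(m)
        size_opt = opts.node["size"]
        if isinstance(size_opt, str):
            m = map_size(node_table.column(size_opt),
                         bounds=tuple(opts.node["size_bounds"]), column=size_opt)
            node_sizes = m.values
            mappings.append(m)
        elif size_opt is not None:
            node_sizes = np.full(node_table.n, float(size_opt))

    node_alphas = None
    if node_table is not None and opts.node["highlight"] is not None:
        hl = apply_highlight(node_table,
                             HighlightSpec(opts.node["highlight"],
                                           dim_alpha=opts.figure["dim_alpha"]),
                             base_alpha=float(opts.node["alpha"]))
        node_alphas = hl.alphas
        logger.info("highlighted nodes: %d / %d", hl.n_selected, node_table.n)
    elif node_table is not None:
        node_alphas = np.full(node_table.n, float(opts.node["alpha"]))

    edge_alphas = None
    if edge_table is not None and opts.edge["highlight"] is not None:
        hl = apply_highlight(edge_table,
                             HighlightSpec(opts.edge["highlight"],
                                           dim_alpha=opts.figure["dim_alpha"]),
                             base_alpha=float(opts.edge["alpha"]))
        edge_alphas = hl.alphas
        logger.info("highlighted edges: %d / %d", hl.n_selected, edge_table.n)
    elif edge_table is not None:
        edge_alphas = np.full(edge_table.n, float(opts.edge["alpha"]))

    # --- geometry -----------------------------------------------------------
    template_geom = style_dispatch(opts.template["style"], template_vol,
                                   opts.template) if template_vol is not None else None

    node_geom = None
    if node_table is not None and node_table.n:
        node_geom = node_geometry(
            node_table, opts.node["style"], sizes=node_sizes, colors=node_colors,
            alphas=node_alphas, parcellation=parcellation,
            default_color=opts.node["color"]
            if not isinstance(opts.node["color"], str)
            or node_table is None or opts.node["color"] not in node_table.data.columns
            else "steelblue")

    segs = None
    if edge_table is not None and node_table is not None and edge_table.n:
        scaling = ("weight", tuple(opts.edge["width_bounds"])) \
            if opts.edge["widthscale"] else None
        segs = edge_segments(node_table, edge_table, weight_scaling=scaling,
                             threshold=opts.edge["threshold"],
                             threshold_absolute=bool(opts.edge["threshold_absolute"]),
                             color=opts.edge["color"], alphas=edge_alphas)

    # --- panels -------------------------------------------------------------
    spec = views_mod.parse_view(opts.figure["view"], frames=opts.figure["frames"])
    panel_in = float(opts.figure["panel_size"])
    background = opts.figure["background"]
    fig = plt.figure(figsize=(spec.n_cols * panel_in, spec.n_rows * panel_in),
                     facecolor=background)
    extent = _data_extent(template_geom, node_table, template_vol)

    spring_pos = None
    panels = []
    for r, row in enumerate(spec.rows):
        for c, panel in enumerate(row):
            idx = r * spec.n_cols + c + 1
            if panel == views_mod.SPRING_MARKER:
                ax = fig.add_subplot(spec.n_rows, spec.n_cols, idx)
                if node_table is None:
                    raise ValueError("a spring-layout panel requires nodes")
                if spring_pos is None:
                    spring_pos = views_mod.spring_layout(
                        node_table, edge_table, seed=int(opts.figure["seed"]))
                _draw_spring_panel(ax, node_table, edge_table, spring_pos,
                                   node_colors, node_sizes, node_alphas,
                                   edge_alphas, opts, background)
            else:
                ax = fig.add_subplot(spec.n_rows, spec.n_cols, idx, projection="3d")
                _draw_geometry(ax, template_geom, background)
                if isinstance(node_geom, MarkerSet):
                    _draw_markers(ax, node_geom)
                elif isinstance(node_geom, list):
                    for mesh in node_geom:
                        _draw_geometry(ax, mesh, background)
                if segs is not None:
                    _draw_segments(ax, segs)
                _style_3d_axes(ax, extent, panel, background)
            panels.append(ax)

    legend = build_legend(mappings)
    if legend:
        _attach_legend(fig, legend)

    provenance = {
        "options": _serializable(opts),
        "template": None if template_vol is None else {
            "space": template_vol.space_name,
            "variant": template_vol.metadata.get("template_variant", "local"),
            "shape": list(template_vol.grid.shape)},
        "n_nodes": 0 if node_table is None else node_table.n,
        "n_edges": 0 if edge_table is None else edge_table.n,
        "n_panels": spec.total_panels,
        "seed": int(opts.figure["seed"]),
    }
    result = FigureResult(figure=fig, panels=panels, legend=legend,
                          provenance=provenance)
    if opts.figure["savename"]:
        save_figure(result, opts.figure["savename"])
    return result


def _draw_spring_panel(ax, nodes: NodeTable, edges: Optional[EdgeTable],
                       pos: np.ndarray, colors, sizes, alphas, edge_alphas,
                       opts: StyleOptions, background: str) -> None:
    """2D force-layout companion panel with the 3D panels' aesthetics."""
    id_to_row = {int(nid): k for k, nid in enumerate(nodes.data["node_id"])}
    if edges is not None:
        for k, (i, j) in enumerate(edges.pairs):
            a, b = pos[id_to_row[int(i)]], pos[id_to_row[int(j)]]
            ax.plot([a[0], b[0]], [a[1], b[1]], color=opts.edge["color"],
                    alpha=float(edge_alphas[k]) if edge_alphas is not None else 1.0,
                    linewidth=1.0, zorder=1)
    c = list(colors) if colors is not None else opts.node["color"]
    if isinstance(c, str) and c in nodes.data.columns:
        c = "steelblue"
    s = sizes if sizes is not None else float(opts.node["size"]) \
        if not isinstance(opts.node["size"], str) else 20.0
    ax.scatter(pos[:, 0], pos[:, 1], c=c, s=s, zorder=2,
               alpha=None if alphas is None else None, edgecolors="none")
    ax.set_aspect("equal")
    ax.set_axis_off()
    ax.set_facecolor(background)


def _attach_legend(fig: Figure, legend_blocks: list[dict]) -> None:
    handles, labels = [], []
    for block in legend_blocks:
        for label, value in block["entries"]:
            if block["channel"] == "color":
                handles.append(Line2D([], [], marker="o", linestyle="",
                                      markerfacecolor=value, markeredgecolor="none",
                                      markersize=8))
            else:  # size
                handles.append(Line2D([], [], marker="o", linestyle="",
                                      markerfacecolor="gray", markeredgecolor="none",
                                      markersize=max(2.0, np.sqrt(float(value)))))
            labels.append(f"{block['title']}: {label}")
    fig.legend(handles, labels, loc="lower center", ncol=min(len(labels), 6),
               frameon=False, fontsize=8)


def _serializable(opts: StyleOptions) -> dict:
    def conv(v):
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, np.ndarray):
            return v.tolist()
        if hasattr(v, "to_dict"):
            return "<table>"
        if isinstance(v, (list, tuple)):
            return [conv(x) for x in v]
        if isinstance(v, (str, int, float, bool)) or v is None:
            return v
        return repr(v)
    return {comp: {k: conv(v) for k, v in getattr(opts, comp).items()}
            for comp in ("template", "node", "edge", "figure")}


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def save_figure(result: FigureResult, path: str | Path) -> Path:
    """Write the figure to PNG or SVG (``.png`` appended when the path has
    no extension).  SVG output omits the creation date so identical
    seeded calls produce byte-identical files."""
    path = Path(path)
    if path.suffix == "":
        path = path.with_suffix(".png")
    if path.suffix.lower() not in (".png", ".svg"):
        raise ValueError(f"unsupported figure format {path.suffix!r}; "
                         "supported formats are .png and .svg")
    kwargs: dict[str, Any] = {"facecolor": result.figure.get_facecolor()}
    if path.suffix.lower() == ".svg":
        kwargs["metadata"] = {"Date": None}
    result.figure.savefig(path, **kwargs)
    return path
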