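# brainnetview

Multi-panel 3D figures of brain networks, for network-neuroscience
researchers who need publication-quality connectome visualizations
without hand-placing every element.

A brain-network figure composes three independently specified
components:

- **template** — an anatomical reference volume (a 3D NIfTI image with
  its voxel→world affine) that establishes the coordinate space and is
  rendered as a translucent backdrop;
- **nodes** — brain regions, given either as a table of world-mm
  coordinates `x, y, z` (plus any metadata columns), as an
  integer-labeled parcellation volume whose label centroids become the
  node positions, or as an atlas descriptor resolved through a
  pluggable template-repository fetcher;
- **edges** — weighted undirected connectivity, given as an N×N
  adjacency matrix or an edge list with columns `i, j` and optional
  `weight`; straight lines are drawn between node centroids.

A single entry point, `brainnetview.plot`, resolves all of this
declaratively. Keyword options follow the `<component>_<option>`
convention (`template_alpha`, `node_style`, `edge_threshold`, ...), and
aesthetics are column-driven: passing `node_color="community"` colors
nodes by that metadata column (categorically for integer labels,
continuously otherwise), `node_size="measure"` scales marker sizes by an
affine map of the column onto a size range, and legends are generated
automatically. Views are anatomical letters (`L`, `R`, `A`, `P`, `S`,
`I`), letter strings and lists of strings for panel grids, `preset-N`
shorthands, rotation sequences between two views via `frames`, explicit
`(azimuth, elevation)` tuples, and a lowercase `s` for a force-directed
(Fruchterman–Reingold) spring-layout companion panel that reuses the 3D
panels' colors, sizes, and highlighting. Binary N×N selection matrices
(e.g. the significant-cluster output of network-based statistics) can be
passed as `highlight_edges` to emphasize a subnetwork while dimming the
rest.

Templates render in four styles: `glass` (supervoxel-boundary point
cloud at very low alpha), `surface` (marching-cubes mesh), `filled`
(every mask voxel, with `template_voxelsize` as a downsampling
performance lever), and `cloudy` (surface-adjacent voxels). Nodes render
as `circles`, `spheres`, or `parcels` (one mesh per parcellation label).

## Worked example

```python
import brainnetview as bnv

cfg = bnv.FixtureConfig(seed=1)            # 64^3 grid, 2 mm, 30 nodes
template = bnv.make_template(cfg)          # ellipsoid brain phantom
nodes, edges = bnv.make_network(cfg=cfg)   # community-structured network
print("nodes:", nodes.n, "edges:", edges.n)

res = bnv.plot(template=template, nodes=nodes, edges=edges,
               template_style="glass", node_color="community",
               node_size="measure1", view="LSR", seed=1,
               savename="example.png")
print("panels:", len(res.panels))
print("legend blocks:", [b["title"] for b in res.legend])
```

prints

```
nodes: 30 edges: 69
panels: 3
legend blocks: ['community', 'measure1']
```

`nodes: 30 edges: 69` is the synthetic network's size (30 regions, 69
surviving undirected edges at the default community edge
probabilities). `panels: 3` confirms that the view string `LSR`
produced one subplot per letter — left, superior, and right anatomical
cameras. The two legend blocks are auto-generated from the two
column-driven aesthetics: one swatch per community and min/mid/max
reference sizes for the continuous measure. `res.figure` is the
Matplotlib figure and `res.panels` the list of per-subplot axes, so any
low-level Matplotlib customization remains available;
`res.provenance` records every resolved option, input summary, and seed.

There is also a small CLI over the same machinery:

```sh
brainnetview --nodes nodes.tsv --edges edges.tsv --view LSR --savename out.png
```

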