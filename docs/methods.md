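# Methods

This note documents the models, conventions, and numerical choices
behind brainnetview, in the order data flows through the engine.

## Coordinate model

All geometry lives in world millimetres. A volume is a 3D grid plus a
4×4 affine mapping homogeneous voxel indices to world coordinates;
voxel indices are 0-based and centroids are computed in continuous
index space (no rounding) before being pushed through the affine.
Volumes are reoriented to RAS on load (`nibabel.as_closest_canonical`),
so x increases toward the subject's right everywhere downstream. This
fixed orientation is what makes the anatomical view letters and the
hemisphere logic well defined. Hemisphere restriction zeroes voxels /
drops nodes strictly on the other side of the midplane x = 0; anything
exactly at x = 0 belongs to **both** hemispheres — a deterministic
convention that avoids silently losing midline structures. Edges with a
dropped endpoint are removed, so only connections within the requested
hemisphere remain.

## Input normalization

Node ids are dense 0-based integers internally; external identifiers
(graph node names, parcellation labels) are preserved as metadata
columns (`name`, `label`). Edges are undirected: adjacency matrices
must be symmetric to 1e-9 (the maximum deviation is reported on
failure), the diagonal is ignored, self-loops are dropped with a
warning (a zero-length line cannot be rendered), and unordered pairs
are deduplicated keeping the first occurrence and stored as i < j.
Converting a matrix to an edge list and back reproduces the matrix
exactly.

Extra metadata supplied via `nodes_df` attaches by row order; when the
nodes came from a parcellation, the rows are already in ascending
integer-label order, so row k attaches to the k-th smallest label. An
id-keyed merge would be preferable when an id column exists, but
row-order-onto-ascending-labels is the only convention that is
reproducible for a bare metadata table; it is stated here because it is
an assumption, not a discovery about the inputs.

Unknown keyword options are rejected with the nearest known option
(Levenshtein distance ≤ 3) as a suggestion, falling back to naming the
valid component prefixes — catching errors like `nodes_alpha` for
`node_alpha` at the interface rather than silently ignoring them.

## Template styles

All styles binarize the volume at intensity > 0 first.

- **surface**: marching cubes at iso-level 0.5 on the mask (the mask
  midpoint; fixed so results are deterministic). The mask is
  zero-padded by one voxel so regions touching the grid edge still
  close into a watertight mesh; a convex solid yields a single
  component with Euler characteristic 2.
- **glass**: the intensity-normalized volume is partitioned into
  compact supervoxels (SLIC, default 500 segments, compactness 0.05,
  both overridable via `template_glass_segments` /
  `template_glass_compactness`). A border voxel is a mask voxel
  6-adjacent to background or to a supervoxel whose mean intensity
  differs by more than 0.1 of the normalized range. A uniform solid
  therefore contributes only its outer shell, while nested intensity
  regions (gray/white-matter-like contrast) also expose internal
  borders — which is the visual point of the style.
- **cloudy**: mask voxels with at least one background 6-neighbor
  (grid edges count as background). 6-connectivity is the cheapest
  deterministic border definition and makes counts exactly testable
  (a 3×3×3 solid cube has 26 surface voxels).
- **filled**: one point per mask voxel at its world center. The
  `template_voxelsize` option downsamples first: block-mean for
  intensities, block-mode for labels (background excluded from the vote
  unless the block is all background, since averaging labels would
  invent spurious ones). The output affine keeps each coarse voxel
  center at the mean world position of its source block, preserving
  world extent to within one output voxel. Upsampling is refused.

Default alphas — surface 1.0, glass 0.01, cloudy 0.05, filled 0.2 —
are aesthetic constants; transparency is inherently a taste parameter
and these values merely make the defaults legible.

## Aesthetics

A color column is treated categorically when it is non-numeric or
integer-valued with ≤ 12 distinct values (the size of the default
qualitative palette), and continuously otherwise; the rule is
overridable per call. Community labels like `[1, 1, 2]` therefore get
one distinct color per community, while a continuous centrality measure
maps linearly onto the colormap between its observed min and max.

Sizes are an affine map of `[min(values), max(values)]` onto the size
bounds (default 10–50 marker units); a constant column maps to the
midpoint. Sphere-style nodes use radius √s/2 mm for marker size s
(the square-root mirrors the area-like convention of scatter marker
sizes); sphere tessellation is a fixed 20×20 parametric grid.

Edge thresholding keeps `weight ≥ threshold` on the raw signed weight
by default, with `edge_threshold_absolute=True` switching to
`|weight|`; thresholding happens **before** width scaling, so line
widths span the surviving weights. Highlighting never moves geometry:
selected elements keep their alpha, unselected ones are dimmed to
`dim_alpha` (default 0.15). Edge selectors may be a boolean column, an
index list, or a symmetric binary matrix of node pairs — the shape in
which network-based statistics reports significant clusters.

## Views

The six anatomical letters map to fixed (azimuth, elevation) pairs
under RAS: L (180, 0), R (0, 0), A (90, 0), P (−90, 0), S (−90, 90),
I (−90, −90). The literature names these views but no degree
convention; these values are this package's documented, test-locked
choice. Presets are fixed grids: preset-3 = `LSR`, preset-4 = `LPRA`,
preset-6 = `['LRA','PSI']`, preset-9 adds an oblique row at azimuths
(45, −45, 135) with elevation 30. Rotation sequences interpolate
azimuth along the shorter arc with exact 180° ties broken toward
decreasing azimuth (again: any deterministic rule works; this one is
stated so frames are reproducible), endpoints included exactly.

The spring-layout panel is a networkx Fruchterman–Reingold embedding,
seeded (default 42, surfaced as the `seed` option) so repeated calls
are identical; it is rendered as a square 2D panel occupying one grid
cell and reuses the node colors/sizes and highlight alphas computed for
the 3D panels.

## Figure assembly and export

No default template is drawn: the user must identify the template they
used, because silently assuming a standard space invites mismatched
node/template coordinate systems. Option precedence in the CLI is
flags > config file > built-in defaults. PNG and SVG are the output
formats; SVG is written without a creation date and with a fixed hash
salt, so identically seeded calls are byte-identical — useful both for
reproducibility audits and for testing. The returned result carries
the figure, the per-panel axes, the legend blocks, and a serializable
provenance record (resolved options, template variant, element counts,
seed).

## Synthetic study conditions

The fixture module emulates the shapes of real inputs, not their
content: a 64×64×64 ellipsoid "brain" at 2 mm voxels (semi-axes
24×28×20 voxels, linear intensity falloff of width 0.1·r centered on
the nominal surface so the half-intensity shell is the analytic
ellipsoid), Voronoi parcellations of uniformly drawn seed voxels, and
community-structured random networks (default 30 nodes, 3 round-robin
communities, within/between edge probabilities 0.5/0.05, weights
uniform on (0, 1], plus `community`/`measure1`/`measure2` metadata
columns). These sizes keep surface extraction sub-second while leaving
every geometric property (shell counts, centroid oracles, hemisphere
splits) exactly checkable. What passing tests on these fixtures does
**not** show: behavior on real anatomy (folded cortical surfaces,
anisotropic voxels, oblique affines beyond axis permutations), very
large parcellations, or statistically realistic connectome topology —
the generator plants community structure only.

Tests and the acceptance script use smaller conditions (32³ or smaller
grids, 4–12 nodes/labels) where the check is property-based rather
than condition-dependent; the defaults above are used where the
generated data itself is the subject.

## Known limitations

Surface file formats (GIFTI/CIFTI) are not supported — the engine
renders NIfTI volumes only. No interactive rotation: the design target
is static multi-panel figures. Edges are straight undirected lines;
directed semantics, curved bundles, and sign-specific edge coloring are
out of scope. The remote template-repository adapter is an injected
interface; the shipped resolver reads a local directory tree in the
standard naming scheme.
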