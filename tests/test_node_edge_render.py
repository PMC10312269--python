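"""Aesthetic mappings, node/edge geometry, highlighting, legends."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainnetview import (HighlightSpec, apply_highlight, build_legend,
                          edge_segments, map_color, map_size, node_geometry,
                          parse_edges)
from brainnetview.data_model import NodeTable
from brainnetview.node_edge_render import MarkerSet, sphere_radius
from brainnetview.template_styles import Mesh


@pytest.fixture
def three_nodes():
    return NodeTable(pd.DataFrame({"node_id": [0, 1, 2],
                                   "x": [0.0, 10.0, -10.0],
                                   "y": [0.0, 0.0, 5.0],
                                   "z": [0.0, 5.0, 0.0],
                                   "community": [1, 1, 2]}))


class TestMapColor:
    def test_community_column_yields_two_colors_first_two_shared(self):
        m = map_color([1, 1, 2], column="community")
        assert m.kind == "categorical"
        assert m.values[0] == m.values[1] != m.values[2]
        assert len(set(m.values)) == 2

    def test_constant_column_single_legend_entry(self):
        m = map_color([5, 5, 5])
        assert len(set(m.values)) == 1
        assert len(m.legend_entries) == 1

    def test_continuous_colors_follow_value_rank(self):
        m = map_color([0.5, 0.2, 0.8])
        assert m.kind == "continuous"
        # viridis luminance increases with value: check rank via colormap position
        from matplotlib.colors import to_rgb
        lum = [sum(to_rgb(c)) for c in m.values]
        assert lum[1] < lum[0] < lum[2]

    def test_string_categories(self):
        m = map_color(["a", "b", "a"], column="group")
        assert m.values[0] == m.values[2] != m.values[1]

    def test_legend_enumerates_every_category(self):
        m = map_color([3, 1, 2, 1], column="community")
        assert [lab for lab, _ in m.legend_entries] == ["1", "2", "3"]

    def test_many_distinct_integers_treated_continuous(self):
        m = map_color(list(range(30)))
        assert m.kind == "continuous"

    def test_mixed_uncoercible_types_rejected(self):
        with pytest.raises(ValueError, match="mixes"):
            map_color([1, "a", 2.5])


class TestMapSize:
    def test_affine_interpolation_example(self):
        # affine map of [0.2, 0.8] onto [10, 50]: midpoint 0.5 -> 30
        m = map_size([0.5, 0.2, 0.8], bounds=(10, 50))
        np.testing.assert_allclose(m.values, [30.0, 10.0, 50.0])

    def test_constant_column_maps_to_midpoint(self):
        m = map_size([4, 4, 4], bounds=(10, 50))
        np.testing.assert_allclose(m.values, 30.0)

    def test_two_values_hit_endpoints(self):
        m = map_size([1.0, 3.0], bounds=(5, 9))
        np.testing.assert_allclose(m.values, [5.0, 9.0])

    def test_non_numeric_rejected(self):
        with pytest.raises(ValueError, match="numeric"):
            map_size(["a", "b"])

    def test_legend_has_min_mid_max(self):
        m = map_size([0.0, 1.0, 2.0], bounds=(10, 50))
        assert [v for _, v in m.legend_entries] == [10.0, 30.0, 50.0]

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20, unique=True))
    def test_affinity_invariant(self, values):
        a, b, c = sorted(values)[:3]
        if c - a < 1e-6:
            return
        m = map_size([a, b, c] + values[3:], bounds=(2, 12))
        sa, sb, sc = m.values[:3]
        np.testing.assert_allclose((sb - sa) / (sc - sa), (b - a) / (c - a),
                                   atol=1e-9)

    def test_order_independent(self):
        vals = [3.0, 1.0, 2.0, 5.0]
        m = map_size(vals, bounds=(0, 10))
        perm = [1, 3, 0, 2]
        m2 = map_size([vals[i] for i in perm], bounds=(0, 10))
        np.testing.assert_allclose(m2.values, m.values[perm])


class TestHighlight:
    def _edges(self, n_nodes=5, rows=None):
        rows = rows or [(0, 1), (0, 2), (1, 2), (2, 3), (3, 4)]
        return parse_edges(pd.DataFrame(rows, columns=["i", "j"]), n_nodes=n_nodes)

    def test_matrix_selector_counts_pairs(self):
        edges = self._edges()
        m = np.zeros((5, 5))
        m[0, 1] = m[1, 0] = 1
        m[2, 3] = m[3, 2] = 1
        res = apply_highlight(edges, HighlightSpec(m))
        assert res.n_selected == 2
        assert (res.alphas == 1.0).sum() == 2
        assert np.all(res.alphas[~res.selected] == 0.15)

    def test_all_true_changes_nothing_but_reports_count(self):
        edges = self._edges()
        res = apply_highlight(edges, HighlightSpec(np.ones(edges.n, dtype=bool)))
        assert res.n_selected == edges.n
        assert np.all(res.alphas == 1.0)

    def test_all_false_dims_everything(self):
        edges = self._edges()
        res = apply_highlight(edges, HighlightSpec(np.zeros(edges.n, dtype=bool),
                                                   dim_alpha=0.2))
        assert res.n_selected == 0
        assert np.all(res.alphas == 0.2)

    def test_column_selector(self, three_nodes):
        nodes = NodeTable(three_nodes.data.assign(sig=[True, False, True]))
        res = apply_highlight(nodes, HighlightSpec("sig"))
        assert res.n_selected == 2

    def test_missing_column_rejected(self, three_nodes):
        with pytest.raises(ValueError, match="'nope'"):
            apply_highlight(three_nodes, HighlightSpec("nope"))

    def test_bad_matrix_shape_rejected(self):
        edges = self._edges()
        with pytest.raises(ValueError, match="shape"):
            apply_highlight(edges, HighlightSpec(np.zeros((2, 2))))

    def test_id_list_selector_on_nodes(self, three_nodes):
        res = apply_highlight(three_nodes, HighlightSpec([0, 2]))
        assert list(res.selected) == [True, False, True]


class TestNodeGeometry:
    def test_circles_markers_at_coordinates(self, three_nodes):
        geom = node_geometry(three_nodes, "circles")
        assert isinstance(geom, MarkerSet)
        np.testing.assert_allclose(geom.positions, three_nodes.coordinates)

    def test_sphere_vertices_within_radius_and_monotonic(self, three_nodes):
        one = NodeTable(three_nodes.data.iloc[:1])
        for s in (10.0, 40.0):
            mesh = node_geometry(one, "spheres", sizes=np.array([s]))[0]
            center = one.coordinates[0]
            d = np.linalg.norm(mesh.vertices - center, axis=1)
            assert d.max() <= sphere_radius(s) * (1 + 1e-9)
        assert sphere_radius(40.0) > sphere_radius(10.0)

    def test_parcels_two_labels_two_disjoint_meshes(self, parcellation, three_nodes):
        from brainnetview import compute_centroids
        nodes = compute_centroids(parcellation)
        meshes = node_geometry(nodes, "parcels", parcellation=parcellation)
        assert len(meshes) == len(parcellation.labels)
        assert all(isinstance(m, Mesh) and len(m.faces) for m in meshes)

    def test_parcels_without_parcellation_rejected(self, three_nodes):
        with pytest.raises(ValueError, match="parcellation"):
            node_geometry(three_nodes, "parcels")

    def test_unknown_style_rejected(self, three_nodes):
        with pytest.raises(ValueError, match="circles"):
            node_geometry(three_nodes, "hexagons")


class TestEdgeSegments:
    def test_single_edge_endpoints(self, three_nodes):
        edges = parse_edges(pd.DataFrame({"i": [0], "j": [1]}), n_nodes=3)
        segs = edge_segments(three_nodes, edges)
        np.testing.assert_allclose(segs.starts[0], [0, 0, 0])
        np.testing.assert_allclose(segs.ends[0], [10, 0, 5])

    def test_threshold_removes_light_edges(self, three_nodes):
        edges = parse_edges(pd.DataFrame({"i": [0, 0, 1], "j": [1, 2, 2],
                                          "weight": [1.0, 2.0, 3.0]}), n_nodes=3)
        segs = edge_segments(three_nodes, edges, threshold=2.0)
        assert segs.n == 2

    def test_absolute_threshold_keeps_strong_negative(self, three_nodes):
        edges = parse_edges(pd.DataFrame({"i": [0, 0], "j": [1, 2],
                                          "weight": [-3.0, 1.0]}), n_nodes=3)
        signed = edge_segments(three_nodes, edges, threshold=2.0)
        absolute = edge_segments(three_nodes, edges, threshold=2.0,
                                 threshold_absolute=True)
        assert signed.n == 0 and absolute.n == 1

    def test_equal_weights_equal_widths(self, three_nodes):
        edges = parse_edges(pd.DataFrame({"i": [0, 0], "j": [1, 2],
                                          "weight": [2.0, 2.0]}), n_nodes=3)
        segs = edge_segments(three_nodes, edges,
                             weight_scaling=("weight", (1.0, 4.0)))
        assert segs.widths[0] == segs.widths[1]

    def test_segment_count_always_matches_surviving_rows(self, node_table,
                                                         edge_table):
        for thr in (None, 0.25, 0.5, 0.9):
            segs = edge_segments(node_table, edge_table, threshold=thr)
            expect = edge_table.n if thr is None else \
                int((edge_table.weights >= thr).sum())
            assert segs.n == expect

    def test_highlight_preserves_geometry(self, three_nodes):
        edges = parse_edges(pd.DataFrame({"i": [0, 0], "j": [1, 2]}), n_nodes=3)
        plain = edge_segments(three_nodes, edges)
        hl = apply_highlight(edges, HighlightSpec(np.array([True, False])))
        dimmed = edge_segments(three_nodes, edges, alphas=hl.alphas)
        np.testing.assert_array_equal(plain.starts, dimmed.starts)
        np.testing.assert_array_equal(plain.ends, dimmed.ends)
        assert dimmed.alphas[1] < dimmed.alphas[0]


class TestLegend:
    def test_two_category_block(self):
        m = map_color([1, 1, 2], column="community")
        legend = build_legend([m])
        assert len(legend) == 1
        assert len(legend[0]["entries"]) == 2
        assert legend[0]["title"] == "community"

    def test_no_mappings_no_legend(self):
        assert build_legend([]) is None

    def test_blocks_in_declaration_order(self):
        mc = map_color([1, 2], column="community")
        ms = map_size([0.1, 0.9], column="participation")
        legend = build_legend([mc, ms])
        assert [b["title"] for b in legend] == ["community", "participation"]
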