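"""Volumetric I/O, affine geometry, centroids, resampling, hemispheres."""
import nibabel as nib
import numpy as np
import pytest

from brainnetview import (BrainVolume, Parcellation, compute_centroids,
                          downsample, hemisphere_restrict, load_volume,
                          make_parcellation, make_template, parse_edges,
                          save_volume, select_template_image, voxel_to_world)
from brainnetview.data_model import NodeTable, parse_nodes
from brainnetview.synthetic_fixtures import FixtureConfig
from brainnetview.volume_io import (LocalTemplateResolver,
                                    hemisphere_restrict_network, world_to_voxel)
from conftest import brute_force_centroids

import pandas as pd


class TestLoadVolume:
    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = BrainVolume(grid=rng.random((10, 10, 10)),
                          affine=np.diag([2.0, 2.0, 2.0, 1.0]))
        path = save_volume(vol, tmp_path / "v.nii")
        loaded = load_volume(path)
        np.testing.assert_allclose(loaded.grid, vol.grid, atol=1e-6)
        np.testing.assert_allclose(loaded.affine, vol.affine, atol=1e-6)

    def test_gzip_matches_uncompressed(self, tmp_path):
        rng = np.random.default_rng(1)
        vol = BrainVolume(grid=rng.random((6, 7, 8)), affine=np.eye(4))
        p1 = save_volume(vol, tmp_path / "v.nii")
        p2 = save_volume(vol, tmp_path / "v.nii.gz")
        np.testing.assert_array_equal(load_volume(p1).grid, load_volume(p2).grid)

    def test_singleton_fourth_dimension_squeezed(self, tmp_path):
        img = nib.Nifti1Image(np.ones((4, 4, 4, 1), dtype=np.float32), np.eye(4))
        nib.save(img, tmp_path / "v4.nii")
        assert load_volume(tmp_path / "v4.nii").grid.shape == (4, 4, 4)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_volume(tmp_path / "absent.nii")

    def test_2d_image_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.ones((5, 5), dtype=np.float32), np.eye(4))
        nib.save(img, tmp_path / "flat.nii")
        with pytest.raises(ValueError, match="3D"):
            load_volume(tmp_path / "flat.nii")


class TestVoxelToWorld:
    def test_identity_affine(self):
        np.testing.assert_array_equal(voxel_to_world((0, 0, 0), np.eye(4)),
                                      [0.0, 0.0, 0.0])

    def test_scale_and_translation(self):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-10, -10, -10]
        np.testing.assert_allclose(voxel_to_world((1, 2, 3), affine), [-8, -6, -4])

    def test_batch_preserves_order(self):
        affine = np.diag([3.0, 1.0, 1.0, 1.0])
        idx = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        out = voxel_to_world(idx, affine)
        assert out.shape == (3, 3)
        np.testing.assert_allclose(out[:, 0], [0, 3, 6])

    def test_inverse_composes_to_identity(self):
        rng = np.random.default_rng(5)
        affine = np.eye(4)
        affine[:3, :3] = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        affine[:3, 3] = rng.normal(size=3)
        pts = rng.random((50, 3)) * 20
        np.testing.assert_allclose(world_to_voxel(voxel_to_world(pts, affine), affine),
                                   pts, atol=1e-9)


class TestCentroids:
    def test_two_voxel_label_identity_affine(self):
        grid = np.zeros((3, 3, 3), dtype=int)
        grid[0, 0, 0] = grid[2, 0, 0] = 1
        nodes = compute_centroids(Parcellation(grid=grid, affine=np.eye(4)))
        np.testing.assert_allclose(nodes.coordinates, [[1.0, 0.0, 0.0]])

    def test_scaled_affine_scales_centroid(self):
        grid = np.zeros((3, 3, 3), dtype=int)
        grid[0, 0, 0] = grid[2, 0, 0] = 1
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        nodes = compute_centroids(Parcellation(grid=grid, affine=affine))
        np.testing.assert_allclose(nodes.coordinates, [[2.0, 0.0, 0.0]])

    def test_rows_ordered_by_label(self):
        grid = np.zeros((4, 4, 4), dtype=int)
        grid[0, 0, 0] = 7
        grid[3, 3, 3] = 2
        nodes = compute_centroids(Parcellation(grid=grid, affine=np.eye(4)))
        assert list(nodes.data["label"]) == [2, 7]

    def test_empty_parcellation_rejected(self):
        with pytest.raises(ValueError, match="no nonzero"):
            compute_centroids(Parcellation(grid=np.zeros((3, 3, 3), dtype=int),
                                           affine=np.eye(4)))

    def test_matches_brute_force_oracle_on_random_parcellations(self):
        cfg = FixtureConfig(shape=(24, 24, 24), semi_axes=(9, 10, 8), n_labels=5)
        template = make_template(cfg)
        for seed in range(10):
            parc = make_parcellation(template, 5, seed=seed)
            nodes = compute_centroids(parc)
            oracle = brute_force_centroids(parc)
            assert list(nodes.data["label"]) == [lab for lab, _ in oracle]
            got = nodes.coordinates
            want = np.array([w for _, w in oracle])
            np.testing.assert_allclose(got, want, atol=1e-9)


class TestDownsample:
    def test_native_voxelsize_is_identity(self):
        vol = BrainVolume(grid=np.ones((4, 4, 4)), affine=np.eye(4))
        out = downsample(vol, 1.0)
        np.testing.assert_array_equal(out.grid, vol.grid)

    def test_constant_volume_stays_constant(self):
        vol = BrainVolume(grid=np.full((8, 8, 8), 3.5), affine=np.eye(4))
        out = downsample(vol, 2.0)
        assert out.grid.shape == (4, 4, 4)
        np.testing.assert_allclose(out.grid, 3.5)

    def test_block_means_match_brute_force(self):
        rng = np.random.default_rng(2)
        grid = rng.random((4, 4, 4))
        vol = BrainVolume(grid=grid, affine=np.eye(4))
        out = downsample(vol, 2.0)
        expected = np.zeros((2, 2, 2))
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    expected[i, j, k] = grid[2*i:2*i+2, 2*j:2*j+2, 2*k:2*k+2].mean()
        np.testing.assert_allclose(out.grid, expected, atol=1e-12)

    def test_global_mean_conserved_for_exact_multiples(self):
        rng = np.random.default_rng(3)
        grid = rng.random((8, 8, 8))
        out = downsample(BrainVolume(grid=grid, affine=np.eye(4)), 2.0)
        assert abs(out.grid.mean() - grid.mean()) < 1e-6

    def test_world_extent_preserved(self):
        vol = BrainVolume(grid=np.ones((8, 8, 8)), affine=np.diag([1.0, 1, 1, 1]))
        out = downsample(vol, 2.0)
        lo0, hi0 = vol.world_bounds()
        lo1, hi1 = out.world_bounds()
        # within one output voxel
        assert np.all(np.abs(lo1 - lo0) <= 2.0) and np.all(np.abs(hi1 - hi0) <= 2.0)

    def test_upsampling_rejected(self):
        vol = BrainVolume(grid=np.ones((4, 4, 4)), affine=np.diag([2.0, 2, 2, 1]))
        with pytest.raises(ValueError, match="upsampling"):
            downsample(vol, 1.0)

    def test_labels_use_modal_aggregation_excluding_background(self):
        grid = np.zeros((4, 4, 4), dtype=int)
        grid[0, 0, 0] = 3          # one labeled voxel in an otherwise empty block
        grid[2:4, 2:4, 2:4] = 2    # a solid block of label 2
        parc = Parcellation(grid=grid, affine=np.eye(4))
        out = downsample(parc, 2.0)
        assert isinstance(out, Parcellation)
        assert out.grid[0, 0, 0] == 3   # background excluded from the vote
        assert out.grid[1, 1, 1] == 2


class TestHemisphere:
    def test_crossing_edge_removed(self):
        nodes = NodeTable(pd.DataFrame({"node_id": [0, 1],
                                        "x": [-10.0, 10.0],
                                        "y": [0.0, 0.0], "z": [0.0, 0.0]}))
        edges = parse_edges(pd.DataFrame({"i": [0], "j": [1]}), n_nodes=2)
        left_nodes, left_edges = hemisphere_restrict_network(nodes, edges, "L")
        assert left_nodes.n == 1 and left_edges.n == 0

    def test_noop_when_all_on_requested_side(self):
        nodes = NodeTable(pd.DataFrame({"node_id": [0, 1],
                                        "x": [-5.0, -1.0],
                                        "y": [0.0, 0.0], "z": [0.0, 0.0]}))
        edges = parse_edges(pd.DataFrame({"i": [0], "j": [1]}), n_nodes=2)
        out_nodes, out_edges = hemisphere_restrict_network(nodes, edges, "L")
        assert out_nodes.n == 2 and out_edges.n == 1

    def test_midline_nodes_belong_to_both_sides(self):
        nodes = NodeTable(pd.DataFrame({"node_id": [0, 1, 2],
                                        "x": [-3.0, 0.0, 3.0],
                                        "y": [0.0] * 3, "z": [0.0] * 3}))
        left, _ = hemisphere_restrict_network(nodes, None, "L")
        right, _ = hemisphere_restrict_network(nodes, None, "R")
        assert set(left.data["node_id"]) == {0, 1}
        assert set(right.data["node_id"]) == {1, 2}

    def test_union_recovers_all_nodes(self, node_table):
        left, _ = hemisphere_restrict_network(node_table, None, "L")
        right, _ = hemisphere_restrict_network(node_table, None, "R")
        assert set(left.data["node_id"]) | set(right.data["node_id"]) == \
            set(node_table.data["node_id"])

    def test_volume_midline_voxel_retained_both_sides(self):
        affine = np.eye(4)
        affine[0, 3] = -1.0  # voxel i=1 sits exactly at world x=0
        grid = np.ones((3, 3, 3))
        left = hemisphere_restrict(BrainVolume(grid=grid, affine=affine), "L")
        right = hemisphere_restrict(BrainVolume(grid=grid, affine=affine), "R")
        assert left.grid[1].all() and right.grid[1].all()
        assert not left.grid[2].any() and not right.grid[0].any()

    def test_invalid_side(self, node_table):
        with pytest.raises(ValueError, match="'L' or 'R'"):
            hemisphere_restrict_network(node_table, None, "X")


def _write_template_tree(root, space, variants):
    d = root / f"tpl-{space}"
    d.mkdir(parents=True)
    for suffix in variants:
        img = nib.Nifti1Image(np.ones((4, 4, 4), dtype=np.float32), np.eye(4))
        nib.save(img, d / f"tpl-{space}_res-1_{suffix}.nii.gz")


class TestSelectTemplate:
    def test_local_path_passthrough(self, tmp_path, template):
        path = save_volume(template, tmp_path / "t.nii.gz")
        vol = select_template_image(str(path))
        np.testing.assert_allclose(vol.grid, template.grid, atol=1e-6)

    def test_in_memory_volume_passthrough(self, template):
        assert select_template_image(template) is template

    def test_prefers_segmented_anatomical_image(self, tmp_path):
        _write_template_tree(tmp_path, "TestSpace", ["T1w", "mask"])
        vol = select_template_image("TestSpace",
                                    fetcher=LocalTemplateResolver(tmp_path))
        assert vol.metadata["template_variant"] == "T1w"

    def test_falls_back_to_mask_and_records_it(self, tmp_path):
        _write_template_tree(tmp_path, "MaskOnly", ["mask"])
        vol = select_template_image("MaskOnly",
                                    fetcher=LocalTemplateResolver(tmp_path))
        assert vol.metadata["template_variant"] == "mask"

    def test_unresolvable_name_lists_queries(self, tmp_path):
        with pytest.raises(ValueError, match="T1w"):
            select_template_image("Nowhere", fetcher=LocalTemplateResolver(tmp_path))

    def test_name_without_fetcher_rejected(self):
        with pytest.raises(ValueError, match="fetcher"):
            select_template_image("SomeSpace")


class TestAtlasSpec:
    def test_atlas_descriptor_resolves_parcellation(self, tmp_path, parcellation):
        d = tmp_path / "tpl-Synth"
        d.mkdir()
        save_volume(parcellation, d / "tpl-Synth_atlas-Voronoi_res-1_dseg.nii.gz")
        nodes, parc = parse_nodes({"template": "Synth", "atlas": "Voronoi",
                                   "resolution": 1},
                                  fetcher=LocalTemplateResolver(tmp_path))
        assert parc is not None
        assert nodes.n == len(parcellation.labels)

    def test_atlas_without_fetcher_rejected(self):
        with pytest.raises(ValueError, match="fetcher"):
            parse_nodes({"template": "Synth", "atlas": "A"})

    def test_bad_resolution_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="resolution"):
            parse_nodes({"template": "Synth", "atlas": "A", "resolution": -1},
                        fetcher=LocalTemplateResolver(tmp_path))
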