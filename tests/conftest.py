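import matplotlib

matplotlib.use("Agg", force=True)

import numpy as np
import pandas as pd
import pytest

from brainnetview import (FixtureConfig, make_network, make_parcellation,
                          make_template)


@pytest.fixture(scope="session")
def small_cfg():
    """Small synthetic study conditions used by most tests (fast)."""
    return FixtureConfig(shape=(32, 32, 32), voxel_mm=2.0,
                         semi_axes=(12.0, 14.0, 10.0),
                         n_labels=6, n_nodes=12, n_communities=3,
                         p_within=0.6, p_between=0.1, seed=7)


@pytest.fixture(scope="session")
def template(small_cfg):
    return make_template(small_cfg)


@pytest.fixture(scope="session")
def parcellation(template, small_cfg):
    return make_parcellation(template, small_cfg.n_labels, seed=small_cfg.seed)


@pytest.fixture(scope="session")
def network(small_cfg):
    return make_network(cfg=small_cfg)


@pytest.fixture
def node_table(network):
    return network[0]


@pytest.fixture
def edge_table(network):
    return network[1]


@pytest.fixture
def coord_frame():
    return pd.DataFrame({"x": [-10.0, 10.0, 0.0],
                         "y": [0.0, 5.0, -5.0],
                         "z": [2.0, -2.0, 0.0]})


def brute_force_centroids(parc):
    """Independent centroid oracle: per-label voxel mean through the affine."""
    out = []
    for label in np.unique(parc.grid):
        if label == 0:
            continue
        idx = np.argwhere(parc.grid == label).astype(float)
        mean = idx.mean(axis=0)
        world = parc.affine[:3, :3] @ mean + parc.affine[:3, 3]
        out.append((int(label), world))
    return out
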