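import numpy as np
import pandas as pd
import pytest

from aromafuse import synthetic
from aromafuse.fusion import fuse
from aromafuse.preprocessing import autoscale


@pytest.fixture(scope="session")
def default_specs():
    return synthetic.paper_default_classes()


@pytest.fixture(scope="session")
def dataset(default_specs):
    """One paper-default synthetic dataset (480 rows, seed 1)."""
    return synthetic.generate_dataset(default_specs, seed=1)


@pytest.fixture(scope="session")
def scaled_blocks(dataset):
    """Autoscaled e-nose and acoustic blocks plus labels."""
    chans = [c for c in dataset.columns if c.startswith("ch")]
    enose, _ = autoscale(dataset[chans], block="enose")
    acoustic, _ = autoscale(dataset[["FI", "AFI"]], block="acoustic")
    return enose, acoustic, dataset["class"].to_numpy()


@pytest.fixture(scope="session")
def fused_matrix(scaled_blocks):
    enose, acoustic, y = scaled_blocks
    return fuse(enose, acoustic), y


def make_blobs(centroids, n_per, sd, seed):
    """Tiny Gaussian-cluster generator used as oracle input."""
    rng = np.random.default_rng(seed)
    centroids = np.asarray(centroids, dtype=float)
    X = np.vstack([c + rng.normal(0, sd, (n_per, centroids.shape[1]))
                   for c in centroids])
    y = np.repeat(np.arange(1, len(centroids) + 1), n_per)
    return X, y
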