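import numpy as np
import pytest

import chemclust as cc


def make_fps(bit_rows, ids=None, radius=2):
    """FingerprintSet from a list of 0/1 rows."""
    bits = np.asarray(bit_rows, dtype=np.uint8)
    if ids is None:
        ids = [f"m{i}" for i in range(bits.shape[0])]
    return cc.FingerprintSet(ids=ids, bits=bits, radius=radius)


def condensed_from_sim(sim, ids=None):
    """CondensedDistanceMatrix with distances 1 - sim for a given similarity matrix."""
    from scipy.spatial.distance import squareform

    sim = np.asarray(sim, dtype=np.float64)
    n = sim.shape[0]
    if ids is None:
        ids = [f"m{i}" for i in range(n)]
    return cc.CondensedDistanceMatrix(values=squareform(1.0 - sim, checks=False), n=n, ids=ids)


@pytest.fixture(scope="session")
def planted_fps():
    """Clean 4-cluster planted set (no outliers), low noise, seed 0."""
    spec = cc.SyntheticSpec(eps_off=0.1, eps_on=0.005, n_outliers=0, seed=0)
    return cc.generate_planted_fingerprints(spec)


@pytest.fixture(scope="session")
def planted_embedding(planted_fps):
    """UMAP embedding of the planted set (shared across tests: embedding is slow)."""
    cfg = cc.UmapConfig(n_neighbors=15, min_dist=0.1, n_clusters=4, seed=42)
    return cc.umap_embed(planted_fps, cfg)
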