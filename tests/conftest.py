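import numpy as np
import pytest

from lazytox.features import EUCLIDEAN, TANIMOTO, FeatureMatrix
from lazytox.lll import Neighbor, NeighborSet
from lazytox.synthetic import SyntheticSpec, generate_descriptor_world, toy_smiles_set


@pytest.fixture(scope="session")
def toy_set():
    return toy_smiles_set()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_descriptor_world():
    spec = SyntheticSpec(
        n_clusters=3, compounds_per_cluster=15, feature_dim=6,
        within_cluster_spread=0.02, noise_sigma=0.05, seed=7,
    )
    return generate_descriptor_world(spec)


def make_neighbor_set(distances, activities, metric="ECFP4", kind=TANIMOTO, query_id="q"):
    neighbors = [
        Neighbor(id=f"n{i:02d}", index=i, distance=float(d),
                 similarity=max(0.0, 1.0 - float(d)), activity=float(a))
        for i, (d, a) in enumerate(zip(distances, activities))
    ]
    return NeighborSet(query_id=query_id, metric_name=metric, kind=kind, neighbors=neighbors)


def random_feature_matrix(rng, n=20, width=8, kind=EUCLIDEAN, metric="DES"):
    if kind == EUCLIDEAN:
        vecs = rng.random((n, width))
    else:
        vecs = (rng.random((n, width)) < 0.4).astype(np.uint8)
    return FeatureMatrix(metric_name=metric, kind=kind,
                         ids=[f"r{i:03d}" for i in range(n)], vectors=vecs)
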