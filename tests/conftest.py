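import numpy as np
import pytest

from stratanet import LayeredNetwork, generate, preset


@pytest.fixture(scope="session")
def esc_net_manifest():
    """One draw of the 4-layer, 3-time-point study-shaped network."""
    return generate(preset("esc_core", seed=7))


@pytest.fixture()
def esc_net(esc_net_manifest):
    return esc_net_manifest[0]


@pytest.fixture()
def esc_manifest(esc_net_manifest):
    return esc_net_manifest[1]


@pytest.fixture()
def tiny_net():
    """Two-layer, two-entity, three-time-point network with one missing value."""
    return LayeredNetwork(
        layers=["lay1", "lay2"],
        entities=["a", "b"],
        time_points=["t1", "t2", "t3"],
        values={
            ("lay1", "a"): np.array([0.0, 1.0, 5.0]),
            ("lay1", "b"): np.array([2.0, np.nan, 4.0]),
            ("lay2", "a"): np.array([-1.0, 0.0, 1.0]),
        },
        intra_edges={("lay1", "a", "b")},
        inter_edges={(("lay1", "a"), ("lay2", "a"))},
    ).validate()


def random_network(rng: np.random.Generator, n_layers=2, n_entities=5, n_t=4,
                   missing_prob=0.1):
    layers = [f"L{i}" for i in range(n_layers)]
    entities = [f"e{i}" for i in range(n_entities)]
    values = {}
    for lay in layers:
        for e in entities:
            v = rng.normal(size=n_t)
            mask = rng.random(n_t) < missing_prob
            v[mask] = np.nan
            if np.isnan(v).all():
                v[0] = rng.normal()
            values[(lay, e)] = v
    intra = set()
    for lay in layers:
        for i in range(n_entities):
            for j in range(i + 1, n_entities):
                if rng.random() < 0.3:
                    intra.add((lay, entities[i], entities[j]))
    return LayeredNetwork(layers, entities, [f"t{i}" for i in range(n_t)],
                          values, intra).validate()
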