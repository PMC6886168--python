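import numpy as np
import pytest

from essnet import (AlignedDataset, EssentialityModel, ExpressionMatrix,
                    PPINetwork, SkipGramConfig, SyntheticSpec, WalkConfig,
                    align, LabelSet, generate_dataset)

# Desk-scale embedding configuration used by the end-to-end tests: the
# walk corpus is shortened relative to the node2vec reference defaults so
# the whole suite runs at laptop scale; embedding quality on the 1000-node
# fixture is indistinguishable between the two.
DESK_WALK = WalkConfig(walk_length=40, walks_per_node=10, seed=0)
DESK_SG = SkipGramConfig(window=5, epochs=3, seed=0)


def make_network(edges, extra_nodes=()):
    return PPINetwork.from_edges(edges, extra_nodes=extra_nodes)


@pytest.fixture
def triangle():
    return make_network([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def star4():
    # center "c" with three leaves
    return make_network([("c", "l1"), ("c", "l2"), ("c", "l3")])


@pytest.fixture
def path3():
    return make_network([("A", "B"), ("B", "C")])


@pytest.fixture
def k4():
    nodes = ["A", "B", "C", "D"]
    return make_network([(u, v) for i, u in enumerate(nodes)
                         for v in nodes[i + 1:]])


def constant_expression(nodes, value=0.0):
    return ExpressionMatrix(rows={v: np.full(36, value) for v in nodes})


def identical_varying_expression(nodes):
    profile = np.sin(np.linspace(0, 4 * np.pi, 36))
    return ExpressionMatrix(rows={v: profile.copy() for v in nodes})


def toy_dataset(network, essential, expr=None):
    expr = expr or ExpressionMatrix(
        rows={v: np.arange(36, dtype=float) + sum(ord(c) for c in v) % 7
              for v in network.nodes})
    return align(network, expr, LabelSet(essential_ids=frozenset(essential)))


@pytest.fixture(scope="session")
def default_dataset() -> AlignedDataset:
    return generate_dataset(SyntheticSpec())


@pytest.fixture(scope="session")
def default_model(default_dataset) -> EssentialityModel:
    model = EssentialityModel(default_dataset, walk_cfg=DESK_WALK,
                              sg_cfg=DESK_SG)
    model.embed()
    return model


@pytest.fixture(scope="session")
def pipeline_fits(default_model):
    """Held-out results for 3 seeds x {balanced, raw, DC-feature}."""
    out = {}
    for seed in (0, 1, 2):
        out[("balanced", seed)] = default_model.fit(seed=seed)
        out[("raw", seed)] = default_model.fit(seed=seed, strategy="raw")
        out[("dc", seed)] = default_model.fit(seed=seed, features="DC")
    return out


@pytest.fixture(scope="session")
def small_dataset() -> AlignedDataset:
    return generate_dataset(SyntheticSpec(n_nodes=150, attach_m=3, seed=7))
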