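import numpy as np
import pytest

from fallnet.bayesnet import (
    BayesNet,
    CPT,
    NodeSpec,
    SchemaError,
    bundled_schema_path,
    forward_sample,
    load_schema,
)
from fallnet import synthetic

from conftest import random_binary_net


def test_nodespec_rejects_duplicate_states():
    with pytest.raises(SchemaError):
        NodeSpec("a", ("x", "x"))


def test_nodespec_rejects_self_parent():
    with pytest.raises(SchemaError):
        NodeSpec("a", ("x", "y"), parents=("a",))


def test_cycle_detection_names_the_cycle():
    nodes = [
        NodeSpec("a", ("x", "y"), ("b",)),
        NodeSpec("b", ("x", "y"), ("a",)),
    ]
    with pytest.raises(SchemaError, match="cycle"):
        BayesNet(nodes)


def test_unknown_parent_rejected():
    with pytest.raises(SchemaError):
        BayesNet([NodeSpec("a", ("x", "y"), ("ghost",))])


def test_topological_order_respects_arcs_and_declaration():
    nodes = [
        NodeSpec("b", ("x", "y")),
        NodeSpec("a", ("x", "y")),
        NodeSpec("c", ("x", "y"), ("a", "b")),
    ]
    order = BayesNet(nodes).topological_order()
    assert order.index("c") > order.index("a")
    assert order.index("c") > order.index("b")
    # ties broken by declaration order
    assert order[:2] == ["b", "a"]


def test_cpt_rows_must_sum_to_one():
    net = BayesNet([NodeSpec("a", ("x", "y"))])
    with pytest.raises(ValueError):
        net.set_cpt("a", np.array([[0.5, 0.4]]))


def test_cpt_shape_checked_against_parents():
    nodes = [NodeSpec("a", ("x", "y")), NodeSpec("b", ("x", "y", "z"), ("a",))]
    net = BayesNet(nodes)
    with pytest.raises(ValueError):
        net.set_cpt("b", np.full((3, 3), 1 / 3))  # needs 2 rows, not 3


def test_row_index_is_lexicographic_over_parent_states():
    nodes = [
        NodeSpec("a", ("a0", "a1")),
        NodeSpec("b", ("b0", "b1", "b2")),
        NodeSpec("c", ("c0", "c1"), ("a", "b")),
    ]
    net = BayesNet(nodes)
    # oracle: numpy C-order raveling over parent cardinalities
    for ia in range(2):
        for ib in range(3):
            expected = np.ravel_multi_index((ia, ib), (2, 3))
            assert net.row_index("c", (ia, ib)) == expected


def test_json_round_trip_is_lossless(planted_chain):
    restored = BayesNet.from_json(planted_chain.to_json())
    assert restored.node_names() == planted_chain.node_names()
    for name in planted_chain.nodes:
        assert restored.nodes[name] == planted_chain.nodes[name]
        np.testing.assert_array_equal(
            restored.cpts[name].table, planted_chain.cpts[name].table
        )


def test_json_file_round_trip(tmp_path, planted_chain):
    path = tmp_path / "net.json"
    planted_chain.to_json(path)
    restored = BayesNet.from_json(path)
    assert restored.to_json() == planted_chain.to_json()


def test_summary_counts_nodes_and_arcs(planted_chain):
    s = planted_chain.summary()
    assert s["n_nodes"] == 4
    assert s["n_arcs"] == 3


@pytest.mark.parametrize("style", ["development", "validation"])
def test_bundled_schema_matches_generator_truth_structure(style):
    maker = (
        synthetic.development_config
        if style == "development"
        else synthetic.validation_config
    )
    truth = synthetic.ground_truth_network(maker(n_admissions=1))
    schema = load_schema(bundled_schema_path(style))
    assert schema.node_names() == truth.node_names()
    assert sorted(schema.arcs()) == sorted(truth.arcs())
    for name in truth.nodes:
        assert schema.nodes[name].states == truth.nodes[name].states


def test_load_schema_merges_toplevel_arcs():
    raw = {
        "nodes": [
            {"name": "a", "states": ["x", "y"]},
            {"name": "b", "states": ["x", "y"]},
        ],
        "arcs": [["a", "b"]],
    }
    net = load_schema(raw)
    assert net.nodes["b"].parents == ("a",)


def test_forward_sample_recovers_root_marginal():
    net = BayesNet([NodeSpec("a", ("x", "y", "z"))])
    net.set_cpt("a", np.array([[0.2, 0.5, 0.3]]))
    rng = np.random.default_rng(3)
    draws = forward_sample(net, 200_000, rng)["a"]
    freq = np.bincount(draws, minlength=3) / len(draws)
    np.testing.assert_allclose(freq, [0.2, 0.5, 0.3], atol=0.01)


def test_forward_sample_respects_conditional_rows():
    rng = np.random.default_rng(4)
    net = random_binary_net(rng, 4)
    draws = forward_sample(net, 400_000, rng)
    # check the last node's conditional frequencies against its CPT
    name = "n3"
    spec = net.nodes[name]
    if not spec.parents:  # random DAG may leave n3 parentless
        freq = np.bincount(draws[name], minlength=2) / len(draws[name])
        np.testing.assert_allclose(freq, net.cpts[name].table[0], atol=0.01)
        return
    cards = net.parent_cards(name)
    rows = np.ravel_multi_index(tuple(draws[p] for p in spec.parents), cards)
    for r in range(net.n_parent_configs(name)):
        mask = rows == r
        if mask.sum() < 5000:
            continue
        freq = np.bincount(draws[name][mask], minlength=2) / mask.sum()
        np.testing.assert_allclose(freq, net.cpts[name].table[r], atol=0.02)


def test_encode_rejects_unknown_state(planted_chain):
    from fallnet.bayesnet import DataError

    with pytest.raises(DataError):
        planted_chain.encode({"v0": "maybe"})


def test_cpt_validate_accepts_exact_rows():
    CPT(node="a", table=np.array([[0.25, 0.75]])).validate()
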