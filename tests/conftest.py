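import numpy as np
import pytest

from fallnet.bayesnet import BayesNet, NodeSpec


def random_binary_net(rng, n_nodes, max_parents=3, p_range=(0.05, 0.95)):
    """Random DAG over binary nodes with random CPTs (test helper)."""
    nodes = []
    for i in range(n_nodes):
        k = int(rng.integers(0, min(i, max_parents) + 1))
        parents = ()
        if k:
            parents = tuple(
                f"n{j}" for j in sorted(rng.choice(i, size=k, replace=False))
            )
        nodes.append(NodeSpec(f"n{i}", ("s0", "s1"), parents))
    net = BayesNet(nodes)
    for s in nodes:
        rows = net.n_parent_configs(s.name)
        p = rng.uniform(*p_range, size=rows)
        net.set_cpt(s.name, np.column_stack([1 - p, p]))
    return net


def random_evidence(rng, net, exclude, p_observe=0.4):
    ev = {}
    for name, spec in net.nodes.items():
        if name in exclude:
            continue
        if rng.random() < p_observe:
            ev[name] = spec.states[int(rng.integers(spec.n_states))]
    return ev


@pytest.fixture(scope="session")
def planted_chain():
    """v0 -> v1 -> v2 -> fall chain with fixed random CPTs (seeded)."""
    rng = np.random.default_rng(20240915)
    nodes = [
        NodeSpec("v0", ("no", "yes")),
        NodeSpec("v1", ("no", "yes"), ("v0",)),
        NodeSpec("v2", ("no", "yes"), ("v1",)),
        NodeSpec("fall", ("no", "yes"), ("v2",), subgroup="outcome"),
    ]
    net = BayesNet(nodes)
    for s in nodes:
        rows = net.n_parent_configs(s.name)
        p = rng.uniform(0.2, 0.8, size=rows)
        net.set_cpt(s.name, np.column_stack([1 - p, p]))
    return net


@pytest.fixture(scope="session")
def small_cohort():
    import fallnet as fn

    return fn.sample_cohort(fn.development_config(n_admissions=600, seed=11))


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    from fallnet.windowing import build_all_windows

    return build_all_windows(small_cohort)
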