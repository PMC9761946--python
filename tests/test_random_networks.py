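import itertools

import networkx as nx
import numpy as np
import pytest

from bnmiss import (
    DirichletSpec,
    ParameterisedNetwork,
    DirectedNetwork,
    forward_sample,
    generate_random_dag,
    sample_cpts,
)


def test_two_node_dag_has_at_most_one_edge():
    for seed in range(20):
        net = generate_random_dag(2, max_in_degree=3, n_levels=3, seed=seed)
        assert len(net.edges) in (0, 1)
        assert all(len(net.levels[n]) == 3 for n in net.nodes)


def test_in_degree_bound_holds_across_seeds():
    for seed in range(100):
        net = generate_random_dag(20, max_in_degree=3, seed=seed)
        assert max(len(net.parents(n)) for n in net.nodes) <= 3


def test_generated_structure_is_acyclic_and_deterministic():
    for seed in range(30):
        a = generate_random_dag(5, seed=seed)
        b = generate_random_dag(5, seed=seed)
        assert a.edges == b.edges
        assert nx.is_directed_acyclic_graph(a.to_networkx())


def test_rejects_degenerate_sizes():
    with pytest.raises(ValueError):
        generate_random_dag(1, seed=0)
    with pytest.raises(ValueError):
        generate_random_dag(3, max_in_degree=0, seed=0)


def test_connected_option_yields_connected_skeleton():
    for seed in range(10):
        net = generate_random_dag(6, seed=seed, connected=True)
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        g.add_edges_from(tuple(e) for e in net.edges)
        assert nx.is_connected(g)


def test_dirichlet_root_mean_matches_symmetric_prior():
    # symmetric Dirichlet(alpha=5, k=3): mean 1/3, var = (1/3)(2/3)/(15+1)
    net = generate_random_dag(2, seed=0)
    draws = np.array(
        [
            sample_cpts(net, DirichletSpec(0.5, 5.0), seed=s).cpts[net.nodes[0]][0]
            for s in range(1000)
        ]
    )
    assert not net.parents(net.nodes[0])
    var = (1 / 3) * (2 / 3) / 16
    se = np.sqrt(var / 1000)
    assert np.abs(draws.mean(axis=0) - 1 / 3).max() < 3 * se


def test_child_rows_more_dispersed_than_root_rows():
    levels = {n: ["0", "1", "2"] for n in "AB"}
    net = DirectedNetwork("AB", {("A", "B")}, levels)
    root_cells, child_cells = [], []
    for s in range(300):
        bn = sample_cpts(net, DirichletSpec(0.5, 5.0), seed=s)
        root_cells.append(bn.cpts["A"].ravel())
        child_cells.append(bn.cpts["B"].ravel())
    assert np.var(np.concatenate(child_cells)) > np.var(np.concatenate(root_cells))


def test_cpt_rows_are_distributions():
    for seed in range(10):
        net = generate_random_dag(6, seed=seed)
        bn = sample_cpts(net, seed=seed)
        for node, cpt in bn.cpts.items():
            assert np.allclose(cpt.sum(axis=1), 1.0, atol=1e-12)
            assert (cpt >= 0).all()


def test_forward_sample_degenerate_cpt():
    levels = {"A": ["0", "1", "2"]}
    net = DirectedNetwork(["A"], set(), levels)
    bn = ParameterisedNetwork(net, {"A": np.array([[1.0, 0.0, 0.0]])})
    t = forward_sample(bn, 50, seed=1)
    assert (t.codes == 0).all()


def test_forward_sample_shape_and_completeness():
    net = generate_random_dag(4, seed=3)
    bn = sample_cpts(net, seed=3)
    t = forward_sample(bn, 1000, seed=3)
    assert t.shape == (1000, 4) and t.is_complete


def test_two_node_chain_matches_enumerated_joint():
    levels = {n: ["0", "1", "2"] for n in "AB"}
    net = DirectedNetwork("AB", {("A", "B")}, levels)
    bn = sample_cpts(net, DirichletSpec(0.5, 5.0), seed=11)
    n = 10_000
    t = forward_sample(bn, n, seed=12)
    # exact joint by direct CPT product over all (a, b) cells
    pa = bn.cpts["A"][0]
    exact = pa[:, None] * bn.cpts["B"]
    emp = np.zeros((3, 3))
    for a, b in t.codes:
        emp[a, b] += 1 / n
    se = np.sqrt(exact * (1 - exact) / n)
    assert (np.abs(emp - exact) <= 4 * se + 1e-12).all()


def test_forward_sample_marginals_converge_to_enumeration():
    # exact marginals by brute-force enumeration of all joint configurations
    net = generate_random_dag(5, seed=21, connected=True)
    bn = sample_cpts(net, seed=22)
    names = list(net.nodes)
    col = {n: j for j, n in enumerate(names)}
    k = [len(net.levels[n]) for n in names]
    exact = {n: np.zeros(len(net.levels[n])) for n in names}
    for combo in itertools.product(*[range(x) for x in k]):
        p = 1.0
        for n in names:
            parents = net.parents(n)
            if parents:
                cfg = bn.parent_config_index(
                    n, np.array([[combo[col[q]] for q in parents]])
                )[0]
            else:
                cfg = 0
            p *= bn.cpts[n][cfg, combo[col[n]]]
        for n in names:
            exact[n][combo[col[n]]] += p
    n_rows = 20_000
    t = forward_sample(bn, n_rows, seed=23)
    for j, n in enumerate(names):
        emp = np.bincount(t.codes[:, j], minlength=k[j]) / n_rows
        se = np.sqrt(exact[n] * (1 - exact[n]) / n_rows)
        assert (np.abs(emp - exact[n]) <= 4 * se + 1e-12).all()
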