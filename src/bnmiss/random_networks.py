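"""Random discrete Bayesian networks and ancestral sampling.

Networks are generated by drawing a uniformly random topological order and
then, for each node, a uniformly random in-degree (bounded by the cap) with
parents chosen uniformly without replacement among its predecessors.  This
satisfies the benchmark's structural requirements (acyclic, in-degree cap,
shared level sets) while staying simple and exactly reproducible; the
generator name is recorded so a different sampler over DAGs can be swapped in.

Conditional probability tables are drawn row-wise from symmetric Dirichlet
distributions, with a small concentration for nodes with parents (skewed,
strongly informative rows) and a larger one for root nodes (near-uniform
marginals).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import DirectedNetwork, ParameterisedNetwork
from .table import CategoricalTable

__all__ = [
    "DirichletSpec",
    "generate_random_dag",
    "sample_cpts",
    "forward_sample",
]

GENERATOR_NAME = "uniform-order-bounded-indegree"


@dataclass(frozen=True)
class DirichletSpec:
    """Symmetric Dirichlet concentrations for CPT rows.

    ``alpha_with_parents`` applies to nodes with at least one parent (default
    0.5: skewed conditional rows, hence strong parent-child dependence);
    ``alpha_root`` to parentless nodes (default 5: near-uniform marginals).
    """

    alpha_with_parents: float = 0.5
    alpha_root: float = 5.0

    def __post_init__(self) -> None:
        if self.alpha_with_parents <= 0 or self.alpha_root <= 0:
            raise ValueError("Dirichlet concentrations must be positive")


def _node_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"X{i:0{width}d}" for i in range(1, n + 1)]


def generate_random_dag(
    n_nodes: int,
    max_in_degree: int = 3,
    n_levels: int = 3,
    seed: int | None = None,
    connected: bool = False,
    max_tries: int = 1000,
) -> DirectedNetwork:
    """Draw a random DAG with bounded in-degree and shared level sets.

    Parameters
    ----------
    n_nodes : int
        Number of variables (at least 2).
    max_in_degree : int
        Upper bound on the number of parents of any node.
    n_levels : int
        Every node gets the same ``n_levels`` category labels.
    seed : int
        Fixed seed gives a byte-identical network.
    connected : bool
        If True, redraw until the skeleton is a connected graph (rejection
        sampling, up to ``max_tries``).
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if max_in_degree < 1:
        raise ValueError("max_in_degree must be >= 1")
    rng = np.random.default_rng(seed)
    names = _node_names(n_nodes)
    labels = [str(i) for i in range(n_levels)]
    for _ in range(max_tries):
        order = rng.permutation(n_nodes)
        edges = set()
        for pos in range(1, n_nodes):
            child = names[order[pos]]
            cap = min(max_in_degree, pos)
            k = int(rng.integers(0, cap + 1))
            if k:
                picks = rng.choice(pos, size=k, replace=False)
                edges.update((names[order[p]], child) for p in picks)
        net = DirectedNetwork(names, edges, {n: labels for n in names})
        if not connected:
            return net
        g = nx.Graph()
        g.add_nodes_from(names)
        g.add_edges_from(tuple(e) for e in edges)
        if nx.is_connected(g):
            return net
    raise RuntimeError("failed to draw a connected DAG within max_tries")


def sample_cpts(
    structure: DirectedNetwork,
    spec: DirichletSpec = DirichletSpec(),
    seed: int | None = None,
) -> ParameterisedNetwork:
    """Fill every CPT row with a symmetric-Dirichlet draw."""
    rng = np.random.default_rng(seed)
    cpts = {}
    for node in structure.nodes:
        parents = structure.parents(node)
        r = len(structure.levels[node])
        q = int(np.prod([len(structure.levels[p]) for p in parents])) if parents else 1
        alpha = spec.alpha_with_parents if parents else spec.alpha_root
        # gamma draws normalised row-wise == symmetric Dirichlet
        g = rng.gamma(alpha, size=(q, r))
        # guard against all-zero rows at tiny alpha
        g = np.where(g.sum(axis=1, keepdims=True) == 0, 1.0, g)
        cpts[node] = g / g.sum(axis=1, keepdims=True)
    return ParameterisedNetwork(structure, cpts)


def forward_sample(
    bn: ParameterisedNetwork, n_rows: int, seed: int | None = None
) -> CategoricalTable:
    """Ancestral sampling: draw each node given its (already drawn) parents."""
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    structure = bn.structure
    names = list(structure.nodes)
    col_of = {n: j for j, n in enumerate(names)}
    codes = np.zeros((n_rows, len(names)), dtype=np.int64)
    for node in structure.topological_order():
        parents = structure.parents(node)
        cpt = bn.cpts[node]
        if parents:
            pcols = codes[:, [col_of[p] for p in parents]]
            cfg = bn.parent_config_index(node, pcols)
        else:
            cfg = np.zeros(n_rows, dtype=np.int64)
        cum = np.cumsum(cpt, axis=1)
        u = rng.random(n_rows)
        codes[:, col_of[node]] = (u[:, None] > cum[cfg]).sum(axis=1)
    # numerical safety: clip into the level range
    r = np.array([len(structure.levels[n]) for n in names])
    codes = np.minimum(codes, r - 1)
    return CategoricalTable(
        names, {n: list(structure.levels[n]) for n in names}, codes
    )
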