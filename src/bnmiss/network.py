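"""Directed networks over categorical variables, CPDAGs and skeletons.

A :class:`DirectedNetwork` is the object that structure learning produces and
that evaluation compares.  A :class:`ParameterisedNetwork` adds conditional
probability tables and is the sampling distribution of the synthetic-data
generator.  :func:`to_cpdag` maps a DAG (or partially directed graph) to the
completed partially directed acyclic graph representing its Markov
equivalence class; :func:`skeleton` drops orientations altogether.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

__all__ = [
    "DirectedNetwork",
    "PDAG",
    "ParameterisedNetwork",
    "to_cpdag",
    "skeleton",
]


@dataclass(frozen=True)
class DirectedNetwork:
    """A DAG over named categorical variables.

    ``edges`` are (parent, child) pairs; ``levels`` maps each node to its
    ordered category labels.  Construction validates acyclicity, declared
    endpoints and absence of self-loops.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    levels: dict[str, list[str]]

    def __init__(self, nodes, edges, levels):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(
            self, "edges", frozenset((str(a), str(b)) for a, b in edges)
        )
        object.__setattr__(
            self, "levels", {n: list(levels[n]) for n in self.nodes}
        )
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node names")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("edge relation is cyclic")

    # -- structure queries ---------------------------------------------------
    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of ``node`` in node-list order (deterministic)."""
        ps = {a for a, b in self.edges if b == node}
        return tuple(n for n in self.nodes if n in ps)

    def children(self, node: str) -> tuple[str, ...]:
        cs = {b for a, b in self.edges if a == node}
        return tuple(n for n in self.nodes if n in cs)

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def skeleton_edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.edges)

    # -- serialisation --------------------------------------------------------
    def to_adjacency_json(self) -> str:
        payload = {
            "nodes": list(self.nodes),
            "levels": {n: self.levels[n] for n in self.nodes},
            "parents": {n: list(self.parents(n)) for n in self.nodes},
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_adjacency_json(cls, text: str) -> "DirectedNetwork":
        payload = json.loads(text)
        edges = {
            (p, child)
            for child, parents in payload["parents"].items()
            for p in parents
        }
        return cls(payload["nodes"], edges, payload["levels"])

    def to_modelstring(self) -> str:
        """R-ecosystem text form, e.g. ``[A][B|A][C|A:B]``."""
        parts = []
        for n in self.nodes:
            ps = self.parents(n)
            parts.append(f"[{n}|{':'.join(ps)}]" if ps else f"[{n}]")
        return "".join(parts)

    @classmethod
    def from_modelstring(
        cls, text: str, levels: dict[str, list[str]]
    ) -> "DirectedNetwork":
        nodes, edges = [], set()
        for chunk in text.strip("[]").split("]["):
            if "|" in chunk:
                child, ps = chunk.split("|", 1)
                nodes.append(child)
                edges.update((p, child) for p in ps.split(":"))
            else:
                nodes.append(chunk)
        return cls(nodes, edges, levels)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


@dataclass(frozen=True)
class PDAG:
    """Partially directed acyclic graph: directed plus undirected edges."""

    nodes: tuple[str, ...]
    directed: frozenset[tuple[str, str]]
    undirected: frozenset[frozenset[str]]

    def __init__(self, nodes, directed, undirected):
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "directed", frozenset(tuple(e) for e in directed))
        object.__setattr__(
            self, "undirected", frozenset(frozenset(e) for e in undirected)
        )

    def skeleton_edges(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.directed) | self.undirected

    def has_link(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.skeleton_edges()

    def consistent_extension(self) -> DirectedNetwork | None:
        """Orient all undirected edges into a DAG with the same v-structures.

        Dor & Tarsi's algorithm: repeatedly find a node x whose outgoing
        directed edges are none and whose undirected neighbours are adjacent
        to all of x's neighbours; orient x's undirected edges into x.
        Returns ``None`` when no consistent extension exists.
        """
        nodes = list(self.nodes)
        directed = set(self.directed)
        undirected = {tuple(sorted(e)) for e in self.undirected}
        oriented = set(directed)
        remaining = set(nodes)

        def nbrs(x, und, dirs):
            out = set()
            for a, b in dirs:
                if a == x:
                    out.add(b)
                if b == x:
                    out.add(a)
            for a, b in und:
                if a == x:
                    out.add(b)
                if b == x:
                    out.add(a)
            return out

        while remaining:
            progress = False
            for x in sorted(remaining):
                has_out = any(a == x for a, b in directed)
                if has_out:
                    continue
                und_nb = {b if a == x else a for a, b in undirected if x in (a, b)}
                all_nb = nbrs(x, undirected, directed)
                ok = all(
                    (y in nbrs(z, undirected, directed)) or y == z
                    for y in und_nb
                    for z in all_nb
                    if z != y
                )
                if not ok:
                    continue
                for y in und_nb:
                    oriented.add((y, x))
                directed = {
                    (a, b) for a, b in directed if x not in (a, b)
                }
                undirected = {e for e in undirected if x not in e}
                remaining.discard(x)
                progress = True
                break
            if not progress:
                return None
        levels = {n: ["0", "1"] for n in nodes}
        return DirectedNetwork(nodes, oriented, levels)


@dataclass
class ParameterisedNetwork:
    """A DAG plus conditional probability tables.

    ``cpts[node]`` is an array of shape ``(q, r)`` where ``q`` is the number of
    joint parent configurations (1 for root nodes) and ``r`` the node's level
    count.  Parent configurations are indexed in row-major (C) order over the
    parents as returned by :meth:`DirectedNetwork.parents`.
    """

    structure: DirectedNetwork
    cpts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node in self.structure.nodes:
            cpt = np.asarray(self.cpts[node], dtype=float)
            parents = self.structure.parents(node)
            q = int(
                np.prod([len(self.structure.levels[p]) for p in parents])
            ) if parents else 1
            r = len(self.structure.levels[node])
            if cpt.shape != (q, r):
                raise ValueError(
                    f"CPT of {node!r} has shape {cpt.shape}, expected {(q, r)}"
                )
            if (cpt < 0).any() or np.abs(cpt.sum(axis=1) - 1.0).max() > 1e-12:
                raise ValueError(f"CPT rows of {node!r} are not distributions")
            self.cpts[node] = cpt

    def parent_config_index(
        self, node: str, parent_codes: np.ndarray
    ) -> np.ndarray:
        """Row index into the CPT for each row of parent codes."""
        parents = self.structure.parents(node)
        if not parents:
            return np.zeros(parent_codes.shape[0], dtype=np.int64)
        dims = [len(self.structure.levels[p]) for p in parents]
        return np.ravel_multi_index(tuple(parent_codes.T), dims)


# ---------------------------------------------------------------------------
# CPDAG machinery
# ---------------------------------------------------------------------------


def _dag_to_cpdag(net: DirectedNetwork) -> PDAG:
    """CPDAG of a DAG: keep v-structure edges directed, close under Meek rules."""
    adj = {frozenset(e) for e in net.edges}
    directed: set[tuple[str, str]] = set()
    # v-structures a -> c <- b with a, b non-adjacent are compelled
    for c in net.nodes:
        ps = net.parents(c)
        for a, b in combinations(ps, 2):
            if frozenset((a, b)) not in adj:
                directed.add((a, c))
                directed.add((b, c))
    compelled_pairs = {frozenset(d) for d in directed}
    undirected = {e for e in adj if e not in compelled_pairs}
    directed, undirected = _apply_meek_rules(net.nodes, directed, undirected)
    return PDAG(net.nodes, directed, undirected)


def _apply_meek_rules(nodes, directed, undirected):
    """Close orientation under Meek rules R1-R3 (no background knowledge)."""
    directed = set(directed)
    undirected = {frozenset(e) for e in undirected}

    def adjacent(a, b):
        return (
            (a, b) in directed or (b, a) in directed
            or frozenset((a, b)) in undirected
        )

    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=sorted):
            a, b = sorted(e)
            for x, y in ((a, b), (b, a)):
                # R1: z -> x, x - y, z and y non-adjacent  =>  x -> y
                if any(
                    (z, x) in directed and not adjacent(z, y) and z != y
                    for z in nodes
                ):
                    directed.add((x, y))
                    undirected.discard(e)
                    changed = True
                    break
                # R2: x -> z -> y and x - y  =>  x -> y
                if any(
                    (x, z) in directed and (z, y) in directed for z in nodes
                ):
                    directed.add((x, y))
                    undirected.discard(e)
                    changed = True
                    break
                # R3: x - z1, x - z2, z1 -> y, z2 -> y, z1,z2 non-adjacent
                zs = [
                    z
                    for z in nodes
                    if frozenset((x, z)) in undirected and (z, y) in directed
                ]
                if any(
                    not adjacent(z1, z2)
                    for z1, z2 in combinations(zs, 2)
                ):
                    directed.add((x, y))
                    undirected.discard(e)
                    changed = True
                    break
            if changed:
                break
    return frozenset(directed), frozenset(undirected)


def to_cpdag(net: DirectedNetwork | PDAG) -> PDAG:
    """Completed partially directed acyclic graph of ``net``.

    For a DAG this is the canonical representative of its Markov equivalence
    class (compelled edges directed, reversible edges undirected).  A PDAG is
    first extended to a consistent DAG, so the map is idempotent.
    """
    if isinstance(net, PDAG):
        ext = net.consistent_extension()
        if ext is None:
            raise ValueError("PDAG admits no consistent extension")
        return _dag_to_cpdag(ext)
    return _dag_to_cpdag(net)


def skeleton(net: DirectedNetwork | PDAG) -> frozenset[frozenset[str]]:
    """Undirected edge set: orientations (and compelled status) discarded."""
    return net.skeleton_edges()
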