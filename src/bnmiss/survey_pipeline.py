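"""Survey analysis stage: repeated-seed structural EM, arc-strength consensus
and community detection.

Because hard-assignment structural EM with stochastic E-step draws varies
from run to run, the pipeline learns many networks under distinct derived
seeds, converts each to its CPDAG, and scores every variable pair by the
fraction of runs whose CPDAG contains the link in any orientation (its *arc
strength*).  Arc strengths on survey-like data tend to be strongly bimodal —
links are either in nearly every run or nearly none — so the consensus
threshold is detected from the gap between the two modes.  The retained
skeleton is then partitioned by Girvan-Newman edge-betweenness divisive
clustering, cutting the dendrogram at maximum modularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple

import networkx as nx
import numpy as np

from .learners import StructuralEMLearner
from .network import PDAG, to_cpdag
from .table import CategoricalTable

__all__ = [
    "ConsensusNetwork",
    "CommunityPartition",
    "BimodalThreshold",
    "repeated_sem",
    "consensus",
    "detect_bimodal_threshold",
    "communities",
    "partition_agreement",
]

logger = logging.getLogger(__name__)


@dataclass
class ConsensusNetwork:
    """Averaged network over repeated runs.

    ``strengths`` maps each unordered variable pair to the fraction of runs
    whose CPDAG contains the link; ``retained`` holds the pairs at or above
    ``threshold``.
    """

    nodes: tuple[str, ...]
    strengths: dict[frozenset, float]
    threshold: float
    retained: frozenset = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.retained is None:
            self.retained = frozenset(
                pair for pair, s in self.strengths.items() if s >= self.threshold
            )

    def skeleton_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for pair in self.retained:
            a, b = sorted(pair)
            g.add_edge(a, b, strength=self.strengths[pair])
        return g

    def write_graphml(self, path) -> None:
        g = self.skeleton_graph()
        nx.write_graphml(g, path)


@dataclass
class CommunityPartition:
    """Node -> community id map with the modularity trace of the divisive
    dendrogram (one value per candidate partition, coarsest first)."""

    assignment: dict[str, int]
    modularity_trace: list[float]

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))


class BimodalThreshold(NamedTuple):
    value: float
    is_bimodal: bool
    gap: float


def repeated_sem(
    data: CategoricalTable,
    n_repeats: int,
    base_seed: int | None = None,
    max_em_iterations: int = 5,
    **sem_params,
) -> list[PDAG]:
    """Learn ``n_repeats`` structures by seeded structural EM, as CPDAGs.

    Each repeat gets a distinct seed derived from ``base_seed``; the E-step
    draws imputations stochastically so repeats genuinely differ on
    incomplete data.  Individual run failures are logged and excluded.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(n_repeats) % (2**31)
    cpdags: list[PDAG] = []
    failures = 0
    for k in range(n_repeats):
        try:
            learner = StructuralEMLearner(
                max_em_iterations=max_em_iterations,
                e_step_method="draw",
                random_state=int(seeds[k]),
                **sem_params,
            ).fit(data)
            cpdags.append(to_cpdag(learner.network_))
        except Exception:  # pragma: no cover - defensive
            failures += 1
            logger.exception("structural EM repeat %d failed; excluded", k)
    if failures:
        logger.warning("%d of %d repeats failed", failures, n_repeats)
    if not cpdags:
        raise RuntimeError("all repeats failed")
    return cpdags


def consensus(networks: list[PDAG], threshold: float) -> ConsensusNetwork:
    """Arc-strength consensus: retain links present in >= threshold of runs.

    A link counts as present when the CPDAG contains it in any orientation
    (directed either way or undirected): the consensus is presented as a
    skeleton of statistical associations, not causal claims.
    """
    if not networks:
        raise ValueError("need at least one network")
    nodes = networks[0].nodes
    for net in networks[1:]:
        if set(net.nodes) != set(nodes):
            raise ValueError("networks share no common node set")
    strengths: dict[frozenset, float] = {}
    m = len(networks)
    for a, b in combinations(sorted(nodes), 2):
        pair = frozenset((a, b))
        count = sum(net.has_link(a, b) for net in networks)
        if count:
            strengths[pair] = count / m
    return ConsensusNetwork(tuple(nodes), strengths, threshold)


def detect_bimodal_threshold(
    strengths, min_gap: float = 0.5, default: float = 0.87
) -> BimodalThreshold:
    """Threshold between the two modes of an arc-strength distribution.

    Strengths are sorted and split at the largest gap; if that gap is at
    least ``min_gap`` the minimum of the upper cluster is returned.  With no
    qualifying gap, a single cluster lying entirely in the upper half counts
    as the upper mode (its minimum is returned); otherwise the distribution
    is flagged non-bimodal and the configured ``default`` is returned.
    """
    values = np.sort(np.asarray(list(strengths), dtype=float))
    if values.size == 0:
        raise ValueError("empty strengths")
    if values.size == 1:
        return BimodalThreshold(float(values[0]), True, 0.0)
    gaps = np.diff(values)
    k = int(np.argmax(gaps))
    if gaps[k] >= min_gap:
        return BimodalThreshold(float(values[k + 1]), True, float(gaps[k]))
    if values[0] >= 0.5:  # single tight cluster in the upper mode
        return BimodalThreshold(float(values[0]), True, float(gaps.max()))
    logger.warning(
        "arc-strength distribution not bimodal (max gap %.3f); using default %.2f",
        gaps.max(),
        default,
    )
    return BimodalThreshold(float(default), False, float(gaps.max()))


def communities(graph: nx.Graph) -> CommunityPartition:
    """Girvan-Newman divisive clustering cut at maximum modularity.

    Isolated nodes end up as singleton communities.  The modularity trace
    covers the initial (connected-components) partition and every division
    produced by removing the highest-betweenness edges.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    base = [set(c) for c in nx.connected_components(graph)]
    partitions = [base]
    if graph.number_of_edges() > 0:
        partitions += [
            [set(c) for c in part] for part in nx.community.girvan_newman(graph)
        ]
    trace = [nx.community.modularity(graph, p) if graph.number_of_edges() else 0.0
             for p in partitions]
    best = partitions[int(np.argmax(trace))]
    assignment = {
        node: cid
        for cid, comm in enumerate(sorted(best, key=lambda c: sorted(c)[0]))
        for node in sorted(comm)
    }
    return CommunityPartition(assignment, trace)


def partition_agreement(
    partition: dict[str, int],
    reference: dict[str, int],
    n_permutations: int = 1000,
    seed: int | None = None,
) -> dict:
    """Adjusted Rand agreement with a label-permutation null.

    Returns the observed adjusted Rand index, the null's 95th percentile,
    and the permutation p-value.
    """
    from sklearn.metrics import adjusted_rand_score

    nodes = sorted(reference)
    a = [partition[n] for n in nodes]
    b = [reference[n] for n in nodes]
    observed = adjusted_rand_score(a, b)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    arr = np.array(a)
    for i in range(n_permutations):
        null[i] = adjusted_rand_score(rng.permutation(arr), b)
    return {
        "ari": float(observed),
        "null_95": float(np.percentile(null, 95)),
        "p_value": float((1 + (null >= observed).sum()) / (1 + n_permutations)),
    }
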