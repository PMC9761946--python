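"""Tabu search over DAG structures with decomposable scores.

Greedy hill climbing over single-edge additions, deletions and reversals that
preserve acyclicity, extended with a tabu list of the last ``tabu_tenure``
*structures* visited: a move whose resulting edge set is in the list is
forbidden (unless it would beat the best score seen — the usual aspiration
criterion), which makes the walk self-avoiding within the window, and the
search may take up to ``max_non_improving`` consecutive worsening steps past
a local optimum.  The best-scoring structure visited is returned.  Move
enumeration and tie-breaking are lexicographic by (operation, parent, child),
so the search is deterministic.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .network import DirectedNetwork
from .scores import ScoreConfig, _family_counts, _family_score_from_counts
from .table import CategoricalTable

try:  # sklearn estimator surface
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    BaseEstimator = object

__all__ = ["SearchConfig", "TabuStructureLearner", "tabu_search"]


@dataclass(frozen=True)
class SearchConfig:
    """Tabu search control parameters (all positive)."""

    tabu_tenure: int = 10
    max_non_improving: int = 10
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if min(self.tabu_tenure, self.max_non_improving, self.max_iterations) < 1:
            raise ValueError("all search parameters must be positive")


class _ScoreCache:
    """Family scores memoized by (node index, sorted parent tuple)."""

    def __init__(self, X: np.ndarray, r: np.ndarray, cfg: ScoreConfig):
        self.X = X
        self.r = r
        self.cfg = cfg
        self.n = X.shape[0]
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def __call__(self, i: int, parents: frozenset[int]) -> float:
        key = (i, tuple(sorted(parents)))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        counts, q_total = _family_counts(self.X, self.r, i, key[1])
        val = _family_score_from_counts(counts, q_total, self.n, self.cfg)
        self._cache[key] = val
        return val


def _has_path(children: list[set[int]], src: int, dst: int) -> bool:
    """Iterative DFS: is dst reachable from src along directed edges?"""
    if src == dst:
        return True
    stack = [src]
    seen = {src}
    while stack:
        u = stack.pop()
        for v in children[u]:
            if v == dst:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


def _tabu_core(
    X: np.ndarray,
    r: np.ndarray,
    score_cfg: ScoreConfig,
    search_cfg: SearchConfig,
    start_parents: list[frozenset[int]] | None = None,
) -> tuple[list[frozenset[int]], float]:
    p = X.shape[1]
    score = _ScoreCache(X, r, score_cfg)
    parents = (
        [frozenset(ps) for ps in start_parents]
        if start_parents is not None
        else [frozenset() for _ in range(p)]
    )
    children: list[set[int]] = [set() for _ in range(p)]
    for v in range(p):
        for u in parents[v]:
            children[u].add(v)
    fam = [score(i, parents[i]) for i in range(p)]
    total = float(sum(fam))
    cur_key: frozenset[tuple[int, int]] = frozenset(
        (u, v) for v in range(p) for u in parents[v]
    )
    best_parents = list(parents)
    best_total = total
    # structure-based tabu: a FIFO window of recently visited edge sets;
    # moves that would recreate one are forbidden unless they beat the best
    tabu = deque([cur_key], maxlen=search_cfg.tabu_tenure)
    tabu_set = {cur_key}
    non_improving = 0
    eps = 1e-10

    for _it in range(search_cfg.max_iterations):
        best_move = None
        best_move_total = -np.inf
        # moves in lexicographic order: add, delete, reverse; ties keep the first
        for op in ("add", "delete", "reverse"):
            for u in range(p):
                for v in range(p):
                    if u == v:
                        continue
                    if op == "add":
                        if u in parents[v] or _has_path(children, v, u):
                            continue
                        new_key = cur_key | {(u, v)}
                        new_total = total - fam[v] + score(v, parents[v] | {u})
                    elif op == "delete":
                        if u not in parents[v]:
                            continue
                        new_key = cur_key - {(u, v)}
                        new_total = total - fam[v] + score(v, parents[v] - {u})
                    else:  # reverse u -> v into v -> u
                        if u not in parents[v]:
                            continue
                        children[u].discard(v)
                        cyclic = _has_path(children, u, v)
                        children[u].add(v)
                        if cyclic:
                            continue
                        new_key = (cur_key - {(u, v)}) | {(v, u)}
                        new_total = (
                            total
                            - fam[v]
                            - fam[u]
                            + score(v, parents[v] - {u})
                            + score(u, parents[u] | {v})
                        )
                    if new_key in tabu_set and new_total <= best_total + eps:
                        continue  # tabu, and aspiration does not apply
                    if new_total > best_move_total + eps:
                        best_move = (op, u, v, new_key)
                        best_move_total = new_total
        if best_move is None:
            break
        op, u, v, cur_key = best_move
        if op == "add":
            parents[v] = parents[v] | {u}
            children[u].add(v)
            fam[v] = score(v, parents[v])
        elif op == "delete":
            parents[v] = parents[v] - {u}
            children[u].discard(v)
            fam[v] = score(v, parents[v])
        else:
            parents[v] = parents[v] - {u}
            parents[u] = parents[u] | {v}
            children[u].discard(v)
            children[v].add(u)
            fam[v] = score(v, parents[v])
            fam[u] = score(u, parents[u])
        if len(tabu) == tabu.maxlen:
            tabu_set.discard(tabu[0])
        tabu.append(cur_key)
        tabu_set.add(cur_key)
        total = best_move_total
        if total > best_total + eps:
            best_total = total
            best_parents = list(parents)
            non_improving = 0
        else:
            non_improving += 1
            if non_improving >= search_cfg.max_non_improving:
                break
    return best_parents, best_total


class TabuStructureLearner(BaseEstimator):
    """Score-and-search structure learner for complete categorical data.

    Parameters
    ----------
    score : {"bde", "bds", "bic"}
        Network score (default BDe with imaginary sample size 1).
    iss : float
        Imaginary sample size for BDe/BDs.
    bic_penalty : float or None
        BIC penalty coefficient; None selects ``0.5 * log(n_rows)``.
    tabu_tenure, max_non_improving, max_iterations : int
        Tabu search controls.
    random_state : int, optional
        Accepted for API symmetry; the search itself is deterministic.
    start : DirectedNetwork, optional
        Structure the search starts from (default: the empty graph).

    Attributes
    ----------
    network_ : DirectedNetwork
        Best-scoring structure found.
    score_ : float
        Its total network score.
    """

    def __init__(
        self,
        score: str = "bde",
        iss: float = 1.0,
        bic_penalty: float | None = None,
        tabu_tenure: int = 10,
        max_non_improving: int = 10,
        max_iterations: int = 10_000,
        random_state: int | None = None,
        start: DirectedNetwork | None = None,
    ):
        self.score = score
        self.iss = iss
        self.bic_penalty = bic_penalty
        self.tabu_tenure = tabu_tenure
        self.max_non_improving = max_non_improving
        self.max_iterations = max_iterations
        self.random_state = random_state
        self.start = start

    def _configs(self) -> tuple[ScoreConfig, SearchConfig]:
        return (
            ScoreConfig(self.score, self.iss, self.bic_penalty),
            SearchConfig(
                self.tabu_tenure, self.max_non_improving, self.max_iterations
            ),
        )

    def fit(self, X: CategoricalTable, y=None) -> "TabuStructureLearner":
        if not isinstance(X, CategoricalTable):
            X = CategoricalTable.from_frame(X)
        if not X.is_complete:
            raise ValueError(
                "tabu search requires complete data; impute or drop rows first"
            )
        if X.n_rows < 1 or X.n_cols < 2:
            raise ValueError("need at least 1 row and 2 variables")
        score_cfg, search_cfg = self._configs()
        start_parents = None
        if self.start is not None:
            idx = {c: j for j, c in enumerate(X.columns)}
            start_parents = [frozenset() for _ in X.columns]
            for u, v in self.start.edges:
                start_parents[idx[v]] = start_parents[idx[v]] | {idx[u]}
        parents, total = _tabu_core(
            X.codes, X.level_counts, score_cfg, search_cfg, start_parents
        )
        names = X.columns
        edges = {
            (names[u], names[v])
            for v, ps in enumerate(parents)
            for u in ps
        }
        self.network_ = DirectedNetwork(
            names, edges, {c: list(X.levels[c]) for c in names}
        )
        self.score_ = total
        return self


def tabu_search(
    data: CategoricalTable,
    score_cfg: ScoreConfig = ScoreConfig(),
    search_cfg: SearchConfig = SearchConfig(),
    seed: int | None = None,
    start: DirectedNetwork | None = None,
) -> DirectedNetwork:
    """Functional form of :class:`TabuStructureLearner`."""
    learner = TabuStructureLearner(
        score=score_cfg.score_name,
        iss=score_cfg.imaginary_sample_size,
        bic_penalty=score_cfg.bic_penalty_coefficient,
        tabu_tenure=search_cfg.tabu_tenure,
        max_non_improving=search_cfg.max_non_improving,
        max_iterations=search_cfg.max_iterations,
        random_state=seed,
        start=start,
    )
    return learner.fit(data).network_
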