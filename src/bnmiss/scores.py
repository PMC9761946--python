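"""Decomposable network scores for discrete data: BDe, BDs and BIC.

All three scores factor over families (a node plus its parent set), so a
network's score is the sum of its family scores and local search only ever
re-scores the families a move touches.

BDe (BDeu) places a uniform Dirichlet prior split by the imaginary sample
size ``iss``: each of the ``q_i * r_i`` cells of node i's CPT receives
hyperparameter ``iss / (q_i * r_i)``.  BDs replaces ``q_i`` with the number of
parent configurations actually observed in the data, which keeps the prior
mass from being diluted over unobserved configurations in sparse tables.
BIC is the multinomial log-likelihood minus ``penalty * free_parameters``,
with the conventional penalty ``0.5 * log(n)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .network import DirectedNetwork
from .table import CategoricalTable

__all__ = ["ScoreConfig", "FamilyCountTable", "family_score", "network_score"]

SCORE_NAMES = ("bde", "bds", "bic")


@dataclass(frozen=True)
class ScoreConfig:
    """Which score to use and its hyperparameters.

    ``imaginary_sample_size`` is the BDe/BDs equivalent prior sample size
    (default 1).  ``bic_penalty_coefficient`` multiplies the number of free
    parameters; ``None`` means the conventional ``0.5 * log(n_rows)``.
    """

    score_name: str = "bde"
    imaginary_sample_size: float = 1.0
    bic_penalty_coefficient: float | None = None

    def __post_init__(self) -> None:
        if self.score_name not in SCORE_NAMES:
            raise ValueError(f"score_name must be one of {SCORE_NAMES}")
        if self.imaginary_sample_size <= 0:
            raise ValueError("imaginary_sample_size must be positive")
        if (
            self.bic_penalty_coefficient is not None
            and self.bic_penalty_coefficient <= 0
        ):
            raise ValueError("bic_penalty_coefficient must be positive")


@dataclass
class FamilyCountTable:
    """Sufficient statistics of one family on complete data.

    ``counts[j, k]`` is the number of rows with parent configuration ``j``
    (among configurations observed in the data) and child level ``k``;
    ``margins[j]`` the row sums; ``q_total`` the number of possible parent
    configurations (product of parent level counts).
    """

    node: str
    parents: tuple[str, ...]
    counts: np.ndarray
    margins: np.ndarray
    q_total: int

    def __post_init__(self) -> None:
        if not np.array_equal(self.counts.sum(axis=1), self.margins):
            raise ValueError("margins do not match counts")


def _family_counts(
    X: np.ndarray, r: np.ndarray, i: int, parents: tuple[int, ...]
) -> tuple[np.ndarray, int]:
    """Counts (q_observed, r_i) over observed parent configurations only.

    Unobserved configurations contribute nothing to any of the three scores
    (their Gamma terms cancel and their likelihood terms are empty), so they
    are never materialised.
    """
    r_i = int(r[i])
    if not parents:
        counts = np.bincount(X[:, i], minlength=r_i)[None, :]
        return counts.astype(np.int64), 1
    dims = r[list(parents)]
    q_total = int(np.prod(dims.astype(np.float64)))
    j_codes = np.ravel_multi_index(tuple(X[:, list(parents)].T), dims)
    _, inv = np.unique(j_codes, return_inverse=True)
    q_obs = int(inv.max()) + 1
    counts = np.bincount(inv * r_i + X[:, i], minlength=q_obs * r_i)
    return counts.reshape(q_obs, r_i).astype(np.int64), q_total


def _family_score_from_counts(
    counts: np.ndarray, q_total: int, n_rows: int, cfg: ScoreConfig
) -> float:
    r_i = counts.shape[1]
    margins = counts.sum(axis=1)
    if cfg.score_name in ("bde", "bds"):
        q_eff = q_total if cfg.score_name == "bde" else counts.shape[0]
        a_ij = cfg.imaginary_sample_size / q_eff
        a_ijk = a_ij / r_i
        score = float(
            np.sum(gammaln(a_ij) - gammaln(a_ij + margins))
            + np.sum(gammaln(a_ijk + counts) - gammaln(a_ijk))
        )
        return score
    # BIC: multinomial log-likelihood minus penalty * free parameters
    nz = counts > 0
    ll = float(
        np.sum(counts[nz] * np.log(counts[nz] / margins[:, None].repeat(r_i, 1)[nz]))
    )
    penalty = (
        cfg.bic_penalty_coefficient
        if cfg.bic_penalty_coefficient is not None
        else 0.5 * np.log(n_rows)
    )
    n_params = q_total * (r_i - 1)
    return ll - penalty * n_params


def family_score(
    node: str,
    parents: tuple[str, ...] | list[str],
    data: CategoricalTable,
    cfg: ScoreConfig = ScoreConfig(),
) -> float:
    """Score of one family (node given its candidate parent set)."""
    if node in parents:
        raise ValueError("a node cannot be its own parent")
    if data.n_rows == 0:
        raise ValueError("empty data")
    if not data.is_complete:
        raise ValueError("scoring requires complete data; impute or drop first")
    col = {c: j for j, c in enumerate(data.columns)}
    X = data.codes
    r = data.level_counts
    counts, q_total = _family_counts(
        X, r, col[node], tuple(col[p] for p in parents)
    )
    return _family_score_from_counts(counts, q_total, data.n_rows, cfg)


def family_count_table(
    node: str,
    parents: tuple[str, ...] | list[str],
    data: CategoricalTable,
) -> FamilyCountTable:
    """Materialised sufficient statistics of a family."""
    col = {c: j for j, c in enumerate(data.columns)}
    counts, q_total = _family_counts(
        data.codes, data.level_counts, col[node], tuple(col[p] for p in parents)
    )
    return FamilyCountTable(
        node, tuple(parents), counts, counts.sum(axis=1), q_total
    )


def network_score(
    net: DirectedNetwork, data: CategoricalTable, cfg: ScoreConfig = ScoreConfig()
) -> float:
    """Decomposable total: the sum of family scores over all nodes."""
    return sum(family_score(n, net.parents(n), data, cfg) for n in net.nodes)
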