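"""Learning Bayesian network structure from incomplete categorical data.

Three strategies are provided:

* :class:`CompleteCaseLearner` — listwise deletion, then tabu search.
* :class:`MICELearner` — chained-equation imputation (one completed dataset,
  polytomous logistic conditional models), then tabu search.
* :class:`StructuralEMLearner` — hard-assignment structural EM: alternate
  imputing each missing cell from its parents under the current network
  (E-step) with tabu search plus maximum-likelihood parameter refitting on
  the completed table (M-step).

All three share the same downstream score-and-search machinery, so any
difference in recovered structure is attributable to the missing-data
handling alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .network import DirectedNetwork, ParameterisedNetwork
from .scores import ScoreConfig, network_score
from .search import SearchConfig, TabuStructureLearner, tabu_search
from .table import CategoricalTable

__all__ = [
    "MiceConfig",
    "SemConfig",
    "LearnOutput",
    "NoCompleteCasesError",
    "CompleteCaseLearner",
    "MiceImputer",
    "MICELearner",
    "StructuralEMLearner",
    "learn_complete_cases",
    "mice_impute",
    "learn_with_mice",
    "structural_em",
    "impute_from_parents",
    "fit_mle",
]


class NoCompleteCasesError(RuntimeError):
    """Raised when listwise deletion leaves zero rows."""


@dataclass(frozen=True)
class MiceConfig:
    """Chained-equation imputation controls.

    ``n_cycles`` full passes over the variables (default 5);
    the conditional model is polytomous (multinomial) logistic regression;
    ``n_completed_datasets`` completed tables can be drawn, but structure
    learning consumes a single one.
    """

    n_cycles: int = 5
    predictor_model: str = "polytomous-logistic"
    n_completed_datasets: int = 1

    def __post_init__(self) -> None:
        if self.n_cycles < 1 or self.n_completed_datasets < 1:
            raise ValueError("n_cycles and n_completed_datasets must be >= 1")


@dataclass(frozen=True)
class SemConfig:
    """Structural EM controls: at most ``max_em_iterations`` E/M alternations
    (default 5), imputing from parents in the E-step."""

    max_em_iterations: int = 5
    impute_method: str = "parents"
    score_cfg: ScoreConfig = field(default_factory=ScoreConfig)
    search_cfg: SearchConfig = field(default_factory=SearchConfig)

    def __post_init__(self) -> None:
        if self.max_em_iterations < 1:
            raise ValueError("max_em_iterations must be >= 1")


@dataclass
class LearnOutput:
    """Learned structure plus (for imputing methods) the completed table."""

    network: DirectedNetwork
    completed_table: CategoricalTable | None = None
    diagnostics: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Parameter fitting and parent-based imputation
# ---------------------------------------------------------------------------


def fit_mle(
    structure: DirectedNetwork, table: CategoricalTable
) -> ParameterisedNetwork:
    """Maximum-likelihood CPTs from a complete table.

    Parent configurations never observed get a uniform conditional (they carry
    no likelihood and only matter if later asked to impute such a row).
    """
    if not table.is_complete:
        raise ValueError("MLE fitting requires a complete table")
    col = {c: j for j, c in enumerate(table.columns)}
    X = table.codes
    r = table.level_counts
    cpts = {}
    for node in structure.nodes:
        parents = structure.parents(node)
        r_i = int(r[col[node]])
        if parents:
            dims = r[[col[p] for p in parents]]
            q = int(np.prod(dims))
            j_codes = np.ravel_multi_index(
                tuple(X[:, [col[p] for p in parents]].T), dims
            )
            counts = np.bincount(
                j_codes * r_i + X[:, col[node]], minlength=q * r_i
            ).reshape(q, r_i).astype(float)
        else:
            counts = np.bincount(X[:, col[node]], minlength=r_i)[None, :].astype(
                float
            )
        tot = counts.sum(axis=1, keepdims=True)
        uniform = np.full_like(counts, 1.0 / r_i)
        cpts[node] = np.where(tot > 0, counts / np.where(tot == 0, 1, tot), uniform)
    return ParameterisedNetwork(structure, cpts)


def available_case_parameters(table: CategoricalTable) -> ParameterisedNetwork:
    """Empty-structure network with per-variable available-case marginals."""
    empty = DirectedNetwork(
        table.columns, set(), {c: list(table.levels[c]) for c in table.columns}
    )
    obs = table.observed_codes()
    cpts = {}
    for j, node in enumerate(table.columns):
        r_i = len(table.levels[node])
        vals = obs[:, j]
        vals = vals[vals >= 0]
        if vals.size == 0:
            raise ValueError(
                f"variable {node!r} has no observed values; cannot estimate it"
            )
        counts = np.bincount(vals, minlength=r_i).astype(float)
        cpts[node] = (counts / counts.sum())[None, :]
    return ParameterisedNetwork(empty, cpts)


def impute_from_parents(
    table: CategoricalTable,
    bn: ParameterisedNetwork,
    seed: int | None = None,
    method: str = "mode",
) -> CategoricalTable:
    """Fill each missing cell from its parents' values in the same row.

    Nodes are visited in topological order so that a missing parent is filled
    before its children are imputed; parentless nodes use their marginal.
    ``method="mode"`` (default) takes the most probable level, ties breaking
    to the lowest level index (argmax convention) — fully deterministic, and
    ``seed`` is then accepted only for API symmetry.  ``method="draw"``
    samples each cell from its conditional distribution instead, which is the
    stochastic variant used when averaging repeated runs.
    """
    if method not in ("mode", "draw"):
        raise ValueError("method must be 'mode' or 'draw'")
    rng = np.random.default_rng(seed) if method == "draw" else None
    structure = bn.structure
    col = {c: j for j, c in enumerate(table.columns)}
    codes = table.observed_codes()
    for node in structure.topological_order():
        j = col[node]
        missing = codes[:, j] < 0
        if not missing.any():
            continue
        parents = structure.parents(node)
        cpt = bn.cpts[node]
        if parents:
            pcols = codes[np.ix_(missing, [col[p] for p in parents])]
            cfg = bn.parent_config_index(node, pcols)
        else:
            cfg = np.zeros(int(missing.sum()), dtype=np.int64)
        if method == "mode":
            codes[missing, j] = np.argmax(cpt[cfg], axis=1)
        else:
            rows = cpt[cfg]
            cum = np.cumsum(rows, axis=1)
            u = rng.random(rows.shape[0])
            codes[missing, j] = np.minimum(
                (u[:, None] > cum).sum(axis=1), rows.shape[1] - 1
            )
    return table.filled(codes)


# ---------------------------------------------------------------------------
# Complete-case learning
# ---------------------------------------------------------------------------


class CompleteCaseLearner(BaseEstimator):
    """Listwise deletion followed by tabu search.

    Raises :class:`NoCompleteCasesError` when no fully observed row remains,
    so batch runners can record a missing result rather than crash.
    """

    def __init__(
        self,
        score: str = "bde",
        iss: float = 1.0,
        bic_penalty: float | None = None,
        tabu_tenure: int = 10,
        max_non_improving: int = 10,
        max_iterations: int = 10_000,
    ):
        self.score = score
        self.iss = iss
        self.bic_penalty = bic_penalty
        self.tabu_tenure = tabu_tenure
        self.max_non_improving = max_non_improving
        self.max_iterations = max_iterations

    def fit(self, X: CategoricalTable, y=None) -> "CompleteCaseLearner":
        if not isinstance(X, CategoricalTable):
            X = CategoricalTable.from_frame(X)
        cc = X.complete_cases()
        self.n_complete_rows_ = cc.n_rows
        if cc.n_rows == 0:
            raise NoCompleteCasesError("no complete cases to learn from")
        inner = TabuStructureLearner(
            score=self.score,
            iss=self.iss,
            bic_penalty=self.bic_penalty,
            tabu_tenure=self.tabu_tenure,
            max_non_improving=self.max_non_improving,
            max_iterations=self.max_iterations,
        ).fit(cc)
        self.network_ = inner.network_
        self.score_ = inner.score_
        return self


def learn_complete_cases(
    data: CategoricalTable,
    score_cfg: ScoreConfig = ScoreConfig(),
    search_cfg: SearchConfig = SearchConfig(),
) -> LearnOutput:
    learner = CompleteCaseLearner(
        score=score_cfg.score_name,
        iss=score_cfg.imaginary_sample_size,
        bic_penalty=score_cfg.bic_penalty_coefficient,
        tabu_tenure=search_cfg.tabu_tenure,
        max_non_improving=search_cfg.max_non_improving,
        max_iterations=search_cfg.max_iterations,
    ).fit(data)
    return LearnOutput(
        learner.network_,
        None,
        [{"n_complete_rows": learner.n_complete_rows_}],
    )


# ---------------------------------------------------------------------------
# MICE
# ---------------------------------------------------------------------------


class MiceImputer(BaseEstimator, TransformerMixin):
    """Chained-equation imputation with polytomous logistic models.

    Missing cells are first initialised by sampling from each variable's
    observed empirical distribution.  Then for ``n_cycles`` passes, in column
    order, each variable's imputed cells are re-drawn from a multinomial
    logistic regression of that variable on one-hot encodings of all other
    (currently completed) variables, fitted on the rows where the variable is
    observed.  Ridge regularisation stabilises separation; degenerate fits
    (a single observed level, solver failure) fall back to drawing from the
    observed marginal for that cycle and are logged in ``log_``.
    """

    def __init__(
        self,
        n_cycles: int = 5,
        ridge_c: float = 1.0,
        max_solver_iter: int = 150,
        random_state: int | None = None,
    ):
        self.n_cycles = n_cycles
        self.ridge_c = ridge_c
        self.max_solver_iter = max_solver_iter
        self.random_state = random_state

    def fit(self, X: CategoricalTable, y=None) -> "MiceImputer":
        return self

    def transform(self, X: CategoricalTable) -> CategoricalTable:
        if not isinstance(X, CategoricalTable):
            X = CategoricalTable.from_frame(X)
        self.log_: list[dict] = []
        if X.is_complete:
            return X.copy()
        rng = np.random.default_rng(self.random_state)
        n, p = X.shape
        r = X.level_counts
        obs_codes = X.observed_codes()
        missing = X.mask.copy()
        codes = obs_codes.copy()

        # initialisation: draw from each variable's observed marginal
        for j in range(p):
            mj = missing[:, j]
            if not mj.any():
                continue
            observed = obs_codes[~mj, j]
            if observed.size == 0:
                raise ValueError(
                    f"variable {X.columns[j]!r} has no observed values"
                )
            probs = np.bincount(observed, minlength=r[j]).astype(float)
            probs /= probs.sum()
            codes[mj, j] = rng.choice(r[j], size=int(mj.sum()), p=probs)

        onehot_width = int(r.sum())
        offsets = np.concatenate([[0], np.cumsum(r)[:-1]])

        def onehot_excluding(j: int) -> np.ndarray:
            Z = np.zeros((n, onehot_width), dtype=float)
            Z[np.arange(n)[:, None], offsets[None, :] + codes] = 1.0
            keep = np.ones(onehot_width, dtype=bool)
            keep[offsets[j] : offsets[j] + r[j]] = False
            return Z[:, keep]

        for cycle in range(self.n_cycles):
            for j in range(p):
                mj = missing[:, j]
                if not mj.any():
                    continue
                y_obs = obs_codes[~mj, j]
                classes = np.unique(y_obs)
                if classes.size < 2:
                    codes[mj, j] = classes[0]
                    self.log_.append(
                        {"cycle": cycle, "var": X.columns[j], "fallback": "single-level"}
                    )
                    continue
                Z = onehot_excluding(j)
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", ConvergenceWarning)
                        model = LogisticRegression(
                            C=self.ridge_c,
                            max_iter=self.max_solver_iter,
                            solver="lbfgs",
                        ).fit(Z[~mj], y_obs)
                    proba = model.predict_proba(Z[mj])
                except Exception as exc:  # degenerate fit: marginal fallback
                    self.log_.append(
                        {
                            "cycle": cycle,
                            "var": X.columns[j],
                            "fallback": f"fit-error: {exc}",
                        }
                    )
                    probs = np.bincount(y_obs, minlength=r[j]).astype(float)
                    probs /= probs.sum()
                    codes[mj, j] = rng.choice(r[j], size=int(mj.sum()), p=probs)
                    continue
                # draw imputations from the fitted category probabilities
                cum = np.cumsum(proba, axis=1)
                u = rng.random(proba.shape[0])
                draw = (u[:, None] > cum).sum(axis=1)
                draw = np.minimum(draw, proba.shape[1] - 1)
                codes[mj, j] = model.classes_[draw]
        return X.filled(codes)


def mice_impute(
    data: CategoricalTable, cfg: MiceConfig = MiceConfig(), seed: int | None = None
) -> CategoricalTable:
    """Functional form of :class:`MiceImputer` (one completed dataset)."""
    return MiceImputer(n_cycles=cfg.n_cycles, random_state=seed).fit_transform(data)


class MICELearner(BaseEstimator):
    """Chained-equation imputation followed by tabu search."""

    def __init__(
        self,
        n_cycles: int = 5,
        score: str = "bde",
        iss: float = 1.0,
        bic_penalty: float | None = None,
        tabu_tenure: int = 10,
        max_non_improving: int = 10,
        max_iterations: int = 10_000,
        random_state: int | None = None,
    ):
        self.n_cycles = n_cycles
        self.score = score
        self.iss = iss
        self.bic_penalty = bic_penalty
        self.tabu_tenure = tabu_tenure
        self.max_non_improving = max_non_improving
        self.max_iterations = max_iterations
        self.random_state = random_state

    def fit(self, X: CategoricalTable, y=None) -> "MICELearner":
        if not isinstance(X, CategoricalTable):
            X = CategoricalTable.from_frame(X)
        imputer = MiceImputer(
            n_cycles=self.n_cycles, random_state=self.random_state
        )
        completed = imputer.fit_transform(X)
        inner = TabuStructureLearner(
            score=self.score,
            iss=self.iss,
            bic_penalty=self.bic_penalty,
            tabu_tenure=self.tabu_tenure,
            max_non_improving=self.max_non_improving,
            max_iterations=self.max_iterations,
        ).fit(completed)
        self.network_ = inner.network_
        self.score_ = inner.score_
        self.completed_table_ = completed
        self.imputer_log_ = imputer.log_
        return self


def learn_with_mice(
    data: CategoricalTable,
    mice_cfg: MiceConfig = MiceConfig(),
    score_cfg: ScoreConfig = ScoreConfig(),
    search_cfg: SearchConfig = SearchConfig(),
    seed: int | None = None,
) -> LearnOutput:
    learner = MICELearner(
        n_cycles=mice_cfg.n_cycles,
        score=score_cfg.score_name,
        iss=score_cfg.imaginary_sample_size,
        bic_penalty=score_cfg.bic_penalty_coefficient,
        tabu_tenure=search_cfg.tabu_tenure,
        max_non_improving=search_cfg.max_non_improving,
        max_iterations=search_cfg.max_iterations,
        random_state=seed,
    ).fit(data)
    return LearnOutput(
        learner.network_, learner.completed_table_, learner.imputer_log_
    )


# ---------------------------------------------------------------------------
# Structural EM (hard assignment)
# ---------------------------------------------------------------------------


class StructuralEMLearner(BaseEstimator):
    """Hard-assignment structural EM.

    Starts from an empty network with available-case marginal parameters;
    each iteration imputes every missing cell from its parents under the
    current network (E-step), then re-learns structure by tabu search —
    warm-started from the previous iteration's structure — and refits
    parameters by maximum likelihood on the completed table (M-step).
    Stops when the structure is unchanged between iterations or after
    ``max_em_iterations``.  The per-iteration network score on the iteration's
    own completed data is recorded in ``diagnostics_``; a decrease is logged
    as a warning flag (hard assignment does not guarantee monotonicity).

    Attributes
    ----------
    network_ : DirectedNetwork
    completed_table_ : CategoricalTable
        Completion from the final E-step (agrees with all observed cells).
    diagnostics_ : list of dict
    """

    def __init__(
        self,
        max_em_iterations: int = 5,
        e_step_method: str = "mode",
        score: str = "bde",
        iss: float = 1.0,
        bic_penalty: float | None = None,
        tabu_tenure: int = 10,
        max_non_improving: int = 10,
        max_iterations: int = 10_000,
        random_state: int | None = None,
    ):
        self.max_em_iterations = max_em_iterations
        self.e_step_method = e_step_method
        self.score = score
        self.iss = iss
        self.bic_penalty = bic_penalty
        self.tabu_tenure = tabu_tenure
        self.max_non_improving = max_non_improving
        self.max_iterations = max_iterations
        self.random_state = random_state

    def fit(self, X: CategoricalTable, y=None) -> "StructuralEMLearner":
        if not isinstance(X, CategoricalTable):
            X = CategoricalTable.from_frame(X)
        score_cfg = ScoreConfig(self.score, self.iss, self.bic_penalty)
        search_cfg = SearchConfig(
            self.tabu_tenure, self.max_non_improving, self.max_iterations
        )
        self.diagnostics_ = []
        if X.is_complete:
            net = tabu_search(X, score_cfg, search_cfg)
            self.network_ = net
            self.completed_table_ = X.copy()
            self.diagnostics_.append({"iteration": 0, "vacuous_e_step": True})
            return self

        current = available_case_parameters(X)  # empty net, marginal params
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            self.max_em_iterations
        ) % (2**31)
        prev_edges = None
        prev_score = None
        completed = None
        net = current.structure
        start = None
        for it in range(self.max_em_iterations):
            completed = impute_from_parents(  # E-step
                X, current, seed=int(seeds[it]), method=self.e_step_method
            )
            # M-step: search warm-started from the previous structure so
            # structural progress accumulates across EM iterations
            net = tabu_search(completed, score_cfg, search_cfg, start=start)
            start = net
            current = fit_mle(net, completed)
            sc = network_score(net, completed, score_cfg)
            entry = {"iteration": it, "score": sc, "n_edges": len(net.edges)}
            if prev_score is not None and sc < prev_score:
                entry["score_decreased"] = True
            self.diagnostics_.append(entry)
            prev_score = sc
            if prev_edges is not None and net.edges == prev_edges:
                entry["converged"] = True
                break
            prev_edges = net.edges
        self.network_ = net
        self.completed_table_ = completed
        return self


def structural_em(
    data: CategoricalTable,
    cfg: SemConfig = SemConfig(),
    seed: int | None = None,
) -> LearnOutput:
    learner = StructuralEMLearner(
        max_em_iterations=cfg.max_em_iterations,
        score=cfg.score_cfg.score_name,
        iss=cfg.score_cfg.imaginary_sample_size,
        bic_penalty=cfg.score_cfg.bic_penalty_coefficient,
        tabu_tenure=cfg.search_cfg.tabu_tenure,
        max_non_improving=cfg.search_cfg.max_non_improving,
        max_iterations=cfg.search_cfg.max_iterations,
        random_state=seed,
    ).fit(data)
    return LearnOutput(
        learner.network_, learner.completed_table_, learner.diagnostics_
    )
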