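"""Multivariate amputation: planting MCAR / MAR / MNAR missingness.

Complete tables are made incomplete by (1) assigning each row to a missing
pattern according to a relative frequency vector, then (2) deciding within
each pattern subset which rows become incomplete.  Under MCAR that decision
is a fair coin with the target proportion; under MAR and MNAR the probability
is a logistic function of a standardized weighted-sum score computed from the
row's values — other variables' values for MAR, the to-be-missing variable's
own value for MNAR — with the logistic offset solved by bisection so the
expected incomplete-row fraction matches the target proportion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .table import CategoricalTable

__all__ = [
    "MissingnessSpec",
    "Amputer",
    "ampute",
    "weighted_sum_scores",
    "score_to_probability",
]

MECHANISMS = ("MCAR", "MAR", "MNAR")


@dataclass
class MissingnessSpec:
    """Mechanism, target proportion and the pattern/frequency/weight matrices.

    Defaults mirror the one-variable-per-pattern convention: the number of
    patterns equals the number of variables, pattern ``i`` hides exactly
    variable ``i``, every pattern is equally likely, MAR weights put 1 on all
    variables except the missing one, and MNAR weights put 1 on the missing
    variable itself.
    """

    mechanism: str = "MCAR"
    proportion: float = 0.3
    patterns: np.ndarray | None = None
    freq: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("proportion must be in [0, 1]")

    def resolve(self, n_vars: int) -> "MissingnessSpec":
        """Fill in default pattern/freq/weight matrices for ``n_vars``."""
        patterns = (
            np.eye(n_vars, dtype=int)
            if self.patterns is None
            else np.asarray(self.patterns, dtype=int)
        )
        if patterns.ndim != 2 or patterns.shape[1] != n_vars:
            raise ValueError("patterns must be (n_patterns, n_vars)")
        if (patterns.sum(axis=1) < 1).any():
            raise ValueError("every pattern must hide at least one variable")
        n_pat = patterns.shape[0]
        freq = (
            np.full(n_pat, 1.0 / n_pat)
            if self.freq is None
            else np.asarray(self.freq, dtype=float)
        )
        if abs(freq.sum() - 1.0) > 1e-12 or (freq < 0).any():
            raise ValueError("freq must be a probability vector")
        if self.weights is not None:
            weights = np.asarray(self.weights, dtype=float)
        elif self.mechanism == "MAR":
            weights = 1.0 - patterns.astype(float)
        elif self.mechanism == "MNAR":
            weights = patterns.astype(float)
        else:
            weights = np.zeros_like(patterns, dtype=float)
        return MissingnessSpec(
            self.mechanism, self.proportion, patterns, freq, weights
        )

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {"mechanism": self.mechanism, "proportion": self.proportion}
        for key in ("patterns", "freq", "weights"):
            v = getattr(self, key)
            if v is not None:
                d[key] = np.asarray(v).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MissingnessSpec":
        return cls(
            mechanism=d["mechanism"],
            proportion=float(d["proportion"]),
            patterns=np.asarray(d["patterns"]) if "patterns" in d else None,
            freq=np.asarray(d["freq"]) if "freq" in d else None,
            weights=np.asarray(d["weights"]) if "weights" in d else None,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "MissingnessSpec":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "MissingnessSpec":
        return cls.from_dict(json.loads(text))


def weighted_sum_scores(
    table: CategoricalTable | np.ndarray, weights_row: np.ndarray
) -> np.ndarray:
    """Per-row weighted sum of standardized integer level codes.

    Categories are encoded 0..k-1 in declared level order; each column is
    standardized to zero mean and unit variance (a zero-variance column's
    z-scores are defined as 0, removing it from the score).
    """
    codes = (
        table.codes.astype(float)
        if isinstance(table, CategoricalTable)
        else np.asarray(table, dtype=float)
    )
    if isinstance(table, CategoricalTable) and not table.is_complete:
        raise ValueError("weighted-sum scores require a complete table")
    w = np.asarray(weights_row, dtype=float)
    mu = codes.mean(axis=0)
    sd = codes.std(axis=0)
    z = np.where(sd > 0, (codes - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    return z @ w


def score_to_probability(
    scores: np.ndarray,
    target_proportion: float,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> np.ndarray:
    """Monotone logistic map from scores to missingness probabilities.

    ``p_r = expit(shift + z(score_r))`` with the shift solved by bisection so
    that ``mean(p) == target_proportion`` within ``tol``.  Higher scores get
    higher probabilities ("RIGHT"-type allocation).
    """
    from scipy.special import expit

    if not 0.0 <= target_proportion <= 1.0:
        raise ValueError("target_proportion must be in [0, 1]")
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n == 0:
        return np.zeros(0)
    if target_proportion in (0.0, 1.0):
        return np.full(n, target_proportion)
    sd = scores.std()
    if sd == 0:
        return np.full(n, target_proportion)
    z = (scores - scores.mean()) / sd
    lo, hi = -40.0, 40.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        m = expit(mid + z).mean()
        if abs(m - target_proportion) <= tol:
            return expit(mid + z)
        if m < target_proportion:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(
        "bisection failed to hit the target proportion: "
        f"target={target_proportion}, reached={expit(0.5 * (lo + hi) + z).mean():.6g}"
    )


class Amputer(BaseEstimator, TransformerMixin):
    """Transformer that plants missing values in a complete table.

    Parameters
    ----------
    mechanism : {"MCAR", "MAR", "MNAR"}
    proportion : float
        Target fraction of incomplete rows.
    patterns, freq, weights : array-like, optional
        Explicit pattern matrix, pattern frequency vector and weight matrix;
        defaults per :class:`MissingnessSpec`.
    random_state : int, optional
    """

    def __init__(
        self,
        mechanism: str = "MCAR",
        proportion: float = 0.3,
        patterns=None,
        freq=None,
        weights=None,
        random_state: int | None = None,
    ):
        self.mechanism = mechanism
        self.proportion = proportion
        self.patterns = patterns
        self.freq = freq
        self.weights = weights
        self.random_state = random_state

    def fit(self, X: CategoricalTable, y=None) -> "Amputer":
        spec = MissingnessSpec(
            self.mechanism, self.proportion, self.patterns, self.freq, self.weights
        )
        self.spec_ = spec.resolve(X.n_cols)
        return self

    def transform(self, X: CategoricalTable) -> CategoricalTable:
        if not hasattr(self, "spec_"):
            self.fit(X)
        if not X.is_complete:
            raise ValueError("amputation requires a complete table")
        spec = self.spec_
        rng = np.random.default_rng(self.random_state)
        n, p = X.shape
        n_pat = spec.patterns.shape[0]
        assignment = rng.choice(n_pat, size=n, p=spec.freq)
        mask = np.zeros((n, p), dtype=bool)
        for k in range(n_pat):
            rows = np.flatnonzero(assignment == k)
            if rows.size == 0:
                continue
            if spec.mechanism == "MCAR":
                probs = np.full(rows.size, spec.proportion)
            else:
                scores = weighted_sum_scores(
                    X.codes[rows].astype(float), spec.weights[k]
                )
                probs = score_to_probability(scores, spec.proportion)
            hit = rng.random(rows.size) < probs
            mask[np.ix_(rows[hit], np.flatnonzero(spec.patterns[k]))] = True
        return X.with_mask(mask)


def ampute(
    table: CategoricalTable, spec: MissingnessSpec, seed: int | None = None
) -> CategoricalTable:
    """Functional form of :class:`Amputer` driven by a :class:`MissingnessSpec`."""
    amp = Amputer(
        mechanism=spec.mechanism,
        proportion=spec.proportion,
        patterns=spec.patterns,
        freq=spec.freq,
        weights=spec.weights,
        random_state=seed,
    )
    return amp.fit(table).transform(table)
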