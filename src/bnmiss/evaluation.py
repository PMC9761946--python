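"""Structure-recovery and imputation-accuracy metrics, plus the statistical
aggregation layer of the benchmark.

Learned and reference networks are compared as *skeletons* (all links taken
undirected), which avoids penalising orientation differences between members
of the same Markov equivalence class:

    precision = TP / (TP + FP)        recall = TP / (TP + FN)

where TP counts links shared with the reference skeleton, FP links invented
by the learner, FN links of the reference the learner missed.  Imputation
accuracy is the Hamming distance between a completed table and the
pre-amputation ground truth over the masked cells.

The aggregation layer groups replicate results into cells (variable-count
group x missing proportion x sample size x mechanism), runs one-way ANOVA
across the three methods per cell, Bonferroni-corrects p-values within each
(metric, sample size, mechanism) panel, and follows significant cells with
Tukey HSD pairwise comparisons; Hamming distances are compared by t-tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import DirectedNetwork, PDAG, skeleton
from .table import CategoricalTable

__all__ = [
    "ComparisonResult",
    "ScenarioResult",
    "VARIABLE_GROUPS",
    "variable_group",
    "compare_skeletons",
    "hamming_distance",
    "aggregate_and_test",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Edge-set confusion counts on skeletons and derived precision/recall.

    ``precision`` is NaN when the learned skeleton is empty (TP + FP == 0);
    ``recall`` is NaN when the reference skeleton is empty.
    """

    true_positive: int
    false_positive: int
    false_negative: int

    @property
    def precision(self) -> float:
        denom = self.true_positive + self.false_positive
        return self.true_positive / denom if denom else math.nan

    @property
    def recall(self) -> float:
        denom = self.true_positive + self.false_negative
        return self.true_positive / denom if denom else math.nan


@dataclass
class ScenarioResult:
    """One method's outcome on one replicate of one scenario."""

    n_vars: int
    proportion: float
    mechanism: str
    n_rows: int
    method: str
    replicate: int
    seed: int
    comparison: ComparisonResult | None
    hamming: int | None = None

    def to_record(self) -> dict:
        c = self.comparison
        return {
            "n_vars": self.n_vars,
            "proportion": self.proportion,
            "mechanism": self.mechanism,
            "n_rows": self.n_rows,
            "method": self.method,
            "replicate": self.replicate,
            "seed": self.seed,
            "tp": c.true_positive if c else np.nan,
            "fp": c.false_positive if c else np.nan,
            "fn": c.false_negative if c else np.nan,
            "precision": c.precision if c else np.nan,
            "recall": c.recall if c else np.nan,
            "hamming": np.nan if self.hamming is None else self.hamming,
        }


#: six variable-count groups partitioning 2..20
VARIABLE_GROUPS: list[tuple[str, int, int]] = [
    ("2-5", 2, 5),
    ("6-8", 6, 8),
    ("9-11", 9, 11),
    ("12-14", 12, 14),
    ("15-17", 15, 17),
    ("18-20", 18, 20),
]


def variable_group(n_vars: int) -> str:
    for label, lo, hi in VARIABLE_GROUPS:
        if lo <= n_vars <= hi:
            return label
    raise ValueError(f"n_vars={n_vars} outside the grouped range 2..20")


def compare_skeletons(
    learned: DirectedNetwork | PDAG, reference: DirectedNetwork | PDAG
) -> ComparisonResult:
    """Confusion counts between two networks' undirected skeletons."""
    if set(learned.nodes) != set(reference.nodes):
        raise ValueError("learned and reference networks have different nodes")
    ls, rs = skeleton(learned), skeleton(reference)
    return ComparisonResult(
        true_positive=len(ls & rs),
        false_positive=len(ls - rs),
        false_negative=len(rs - ls),
    )


def hamming_distance(
    imputed: CategoricalTable,
    original: CategoricalTable,
    mask: np.ndarray | None = None,
) -> int:
    """Number of masked cells whose imputed value differs from the truth.

    ``mask`` defaults to the original table's missingness mask.  Observed
    cells contribute nothing because completions must agree there.
    """
    if imputed.shape != original.shape:
        raise ValueError("shape mismatch")
    if not imputed.is_complete:
        raise ValueError("imputed table still has missing cells")
    mask = original.mask if mask is None else np.asarray(mask, dtype=bool)
    truth = original.ground_truth_codes()
    return int((imputed.codes[mask] != truth[mask]).sum())


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def aggregate_and_test(
    results: pd.DataFrame | list,
    alpha: float = 0.05,
) -> dict:
    """Summarise replicate results and test method differences.

    Parameters
    ----------
    results : DataFrame or list of ScenarioResult
        Tidy records with columns n_vars, proportion, mechanism, n_rows,
        method, precision, recall and optionally hamming.
    alpha : float
        Significance level applied to Bonferroni-corrected ANOVA p-values.

    Returns
    -------
    dict with keys
        ``cell_stats`` — per-cell per-method mean/SE of precision and recall;
        ``anova`` — per-cell per-metric F statistic, raw and corrected p;
        ``tukey`` — pairwise Tukey HSD rows for significant cells;
        ``hamming_tests`` — per-cell t-tests comparing methods' Hamming
        distances;
        ``excluded`` — counts of undefined (NaN) metric values excluded.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame([r.to_record() for r in results])
    df = results.copy()
    df["var_group"] = df["n_vars"].map(variable_group)
    cell_keys = ["var_group", "proportion", "n_rows", "mechanism"]

    stats_rows, anova_rows, tukey_rows = [], [], []
    excluded = {"precision": 0, "recall": 0}

    for metric in ("precision", "recall"):
        # Bonferroni families: cells within one (metric, n_rows, mechanism) panel
        panel_sizes: dict[tuple, int] = {}
        cells = list(df.groupby(cell_keys, sort=True))
        for key, sub in cells:
            panel = (metric, key[2], key[3])
            vals = sub[metric].dropna()
            methods = sub.loc[sub[metric].notna(), "method"].nunique()
            if methods >= 2 and len(vals) > methods:
                panel_sizes[panel] = panel_sizes.get(panel, 0) + 1
        for key, sub in cells:
            excluded[metric] += int(sub[metric].isna().sum())
            groups = [
                g[metric].dropna().to_numpy()
                for _, g in sub.groupby("method", sort=True)
            ]
            for method, g in sub.groupby("method", sort=True):
                vals = g[metric].dropna()
                stats_rows.append(
                    dict(
                        zip(cell_keys, key),
                        metric=metric,
                        method=method,
                        mean=vals.mean() if len(vals) else np.nan,
                        se=vals.sem() if len(vals) > 1 else np.nan,
                        n=len(vals),
                    )
                )
            groups = [g for g in groups if len(g) > 0]
            if len(groups) < 2 or sum(len(g) for g in groups) <= len(groups):
                continue
            if np.ptp(np.concatenate(groups)) == 0:
                # identical values everywhere: no between-group variance
                f_stat, p_raw = 0.0, 1.0
            else:
                with np.errstate(invalid="ignore", divide="ignore"):
                    f_stat, p_raw = stats.f_oneway(*groups)
                if np.isnan(f_stat):
                    f_stat, p_raw = 0.0, 1.0
            panel = (metric, key[2], key[3])
            m = panel_sizes.get(panel, 1)
            p_adj = _bonferroni(float(p_raw), m)
            anova_rows.append(
                dict(
                    zip(cell_keys, key),
                    metric=metric,
                    f_stat=float(f_stat),
                    p_raw=float(p_raw),
                    p_bonferroni=p_adj,
                    n_cells_in_family=m,
                )
            )
            if p_adj < alpha and f_stat > 0:
                tukey_rows.extend(
                    _tukey(sub, metric, key, cell_keys, alpha)
                )

    hamming_rows = _hamming_tests(df, cell_keys)
    return {
        "cell_stats": pd.DataFrame(stats_rows),
        "anova": pd.DataFrame(anova_rows),
        "tukey": pd.DataFrame(tukey_rows),
        "hamming_tests": pd.DataFrame(hamming_rows),
        "excluded": excluded,
    }


def _tukey(sub: pd.DataFrame, metric: str, key, cell_keys, alpha: float):
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    ok = sub[metric].notna()
    res = pairwise_tukeyhsd(
        sub.loc[ok, metric].to_numpy(), sub.loc[ok, "method"].to_numpy(), alpha=alpha
    )
    rows = []
    table = res.summary().data[1:]
    for g1, g2, meandiff, p_adj, lower, upper, reject in table:
        rows.append(
            dict(
                zip(cell_keys, key),
                metric=metric,
                group1=g1,
                group2=g2,
                meandiff=float(meandiff),
                p_adj=float(p_adj),
                reject=bool(reject),
            )
        )
    return rows


def _hamming_tests(df: pd.DataFrame, cell_keys):
    rows = []
    ham = df[df["hamming"].notna()]
    if ham.empty:
        return rows
    for key, sub in ham.groupby(cell_keys, sort=True):
        methods = sorted(sub["method"].unique())
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                a = sub.loc[sub["method"] == methods[i], "hamming"].to_numpy()
                b = sub.loc[sub["method"] == methods[j], "hamming"].to_numpy()
                if len(a) < 2 or len(b) < 2:
                    continue
                t_stat, p = stats.ttest_ind(a, b)
                rows.append(
                    dict(
                        zip(cell_keys, key),
                        method_a=methods[i],
                        method_b=methods[j],
                        mean_a=float(a.mean()),
                        mean_b=float(b.mean()),
                        t_stat=float(t_stat),
                        p_value=float(p),
                    )
                )
    return rows
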