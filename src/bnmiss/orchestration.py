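"""Factorial benchmark runner.

A :class:`ScenarioGrid` spans variable counts, missing proportions,
mechanisms and sample sizes; each scenario is replicated with pre-derived
seeds so results are independent of execution order.  One replicate runs the
full pipeline — random network, CPT sampling, forward sampling, amputation —
and then hands the *same* incomplete table to all three learners
(complete-case, MICE, structural EM) so the comparison isolates the
missing-data handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .amputation import MissingnessSpec, ampute
from .evaluation import ComparisonResult, ScenarioResult, compare_skeletons, hamming_distance
from .learners import (
    MiceConfig,
    NoCompleteCasesError,
    SemConfig,
    learn_complete_cases,
    learn_with_mice,
    structural_em,
)
from .random_networks import DirichletSpec, forward_sample, generate_random_dag, sample_cpts
from .scores import ScoreConfig
from .search import SearchConfig

__all__ = [
    "Scenario",
    "ScenarioGrid",
    "enumerate_scenarios",
    "replicate_seed",
    "run_replicate",
    "run_grid",
]

logger = logging.getLogger(__name__)

METHODS = ("none", "mice", "sem")


class Scenario(NamedTuple):
    n_vars: int
    proportion: float
    mechanism: str
    n_rows: int


@dataclass(frozen=True)
class ScenarioGrid:
    """Cartesian benchmark grid with per-replicate derived seeds.

    Defaults span 2-20 variables, missing proportions 0.1-0.6 in steps of
    0.1, all three mechanisms, sample sizes 1000/5000/10000 and 100
    replicates: 1026 scenarios, 102,600 datasets.
    """

    n_vars: tuple[int, ...] = tuple(range(2, 21))
    proportions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)
    mechanisms: tuple[str, ...] = ("MCAR", "MAR", "MNAR")
    n_rows: tuple[int, ...] = (1000, 5000, 10000)
    replicates: int = 100
    master_seed: int = 0
    max_in_degree: int = 3
    n_levels: int = 3
    dirichlet: DirichletSpec = field(default_factory=DirichletSpec)

    @property
    def scenario_count(self) -> int:
        return (
            len(self.n_vars)
            * len(self.proportions)
            * len(self.mechanisms)
            * len(self.n_rows)
        )

    @property
    def dataset_count(self) -> int:
        return self.scenario_count * self.replicates

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioGrid":
        d = yaml.safe_load(text)
        kwargs = {}
        for key in ("n_vars", "proportions", "mechanisms", "n_rows"):
            if key in d:
                kwargs[key] = tuple(d[key])
        for key in ("replicates", "master_seed", "max_in_degree", "n_levels"):
            if key in d:
                kwargs[key] = int(d[key])
        if "dirichlet" in d:
            kwargs["dirichlet"] = DirichletSpec(**d["dirichlet"])
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "n_vars": list(self.n_vars),
                "proportions": list(self.proportions),
                "mechanisms": list(self.mechanisms),
                "n_rows": list(self.n_rows),
                "replicates": self.replicates,
                "master_seed": self.master_seed,
                "max_in_degree": self.max_in_degree,
                "n_levels": self.n_levels,
                "dirichlet": {
                    "alpha_with_parents": self.dirichlet.alpha_with_parents,
                    "alpha_root": self.dirichlet.alpha_root,
                },
            }
        )


def enumerate_scenarios(grid: ScenarioGrid) -> list[Scenario]:
    """Deterministic Cartesian product of the grid dimensions."""
    return [
        Scenario(v, p, m, n)
        for v, p, m, n in product(
            grid.n_vars, grid.proportions, grid.mechanisms, grid.n_rows
        )
    ]


def replicate_seed(master_seed: int, scenario: Scenario, replicate: int) -> int:
    """Deterministic per-replicate seed, independent of execution order."""
    key = (
        master_seed,
        scenario.n_vars,
        int(round(scenario.proportion * 1000)),
        ("MCAR", "MAR", "MNAR").index(scenario.mechanism),
        scenario.n_rows,
        replicate,
    )
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


def run_replicate(
    scenario: Scenario,
    replicate: int,
    master_seed: int = 0,
    max_in_degree: int = 3,
    n_levels: int = 3,
    dirichlet: DirichletSpec = DirichletSpec(),
    score_cfg: ScoreConfig = ScoreConfig(),
    search_cfg: SearchConfig = SearchConfig(),
    mice_cfg: MiceConfig = MiceConfig(),
    sem_max_iterations: int = 5,
    with_hamming: bool = True,
) -> list[ScenarioResult]:
    """Generate -> sample -> ampute -> learn with all three methods -> compare.

    All methods see the byte-identical amputed table.  A per-method failure
    (for instance no complete cases at high missingness) is recorded as a
    missing result; the batch continues.
    """
    base = replicate_seed(master_seed, scenario, replicate)
    sub = np.random.SeedSequence(base).generate_state(8) % (2**31)
    structure = generate_random_dag(
        scenario.n_vars, max_in_degree, n_levels, seed=int(sub[0])
    )
    bn = sample_cpts(structure, dirichlet, seed=int(sub[1]))
    complete = forward_sample(bn, scenario.n_rows, seed=int(sub[2]))
    spec = MissingnessSpec(scenario.mechanism, scenario.proportion)
    incomplete = ampute(complete, spec, seed=int(sub[3]))

    results: list[ScenarioResult] = []

    def record(method: str, comparison, hamming=None):
        results.append(
            ScenarioResult(
                scenario.n_vars,
                scenario.proportion,
                scenario.mechanism,
                scenario.n_rows,
                method,
                replicate,
                base,
                comparison,
                hamming,
            )
        )

    try:
        out = learn_complete_cases(incomplete, score_cfg, search_cfg)
        record("none", compare_skeletons(out.network, structure))
    except NoCompleteCasesError:
        logger.warning("replicate %s/%d: no complete cases", scenario, replicate)
        record("none", None)

    try:
        out = learn_with_mice(
            incomplete, mice_cfg, score_cfg, search_cfg, seed=int(sub[4])
        )
        ham = (
            hamming_distance(out.completed_table, incomplete)
            if with_hamming
            else None
        )
        record("mice", compare_skeletons(out.network, structure), ham)
    except Exception:
        logger.exception("replicate %s/%d: MICE failed", scenario, replicate)
        record("mice", None)

    try:
        cfg = SemConfig(
            max_em_iterations=sem_max_iterations,
            score_cfg=score_cfg,
            search_cfg=search_cfg,
        )
        out = structural_em(incomplete, cfg, seed=int(sub[5]))
        ham = (
            hamming_distance(out.completed_table, incomplete)
            if with_hamming
            else None
        )
        record("sem", compare_skeletons(out.network, structure), ham)
    except Exception:
        logger.exception("replicate %s/%d: SEM failed", scenario, replicate)
        record("sem", None)

    return results


def run_grid(grid: ScenarioGrid, with_hamming: bool = False) -> pd.DataFrame:
    """Run every replicate of every scenario; returns tidy results.

    One row per (scenario, replicate, method); failed method runs appear with
    NaN metrics so collation stays accountable.
    """
    records = []
    for scenario in enumerate_scenarios(grid):
        for rep in range(grid.replicates):
            for res in run_replicate(
                scenario,
                rep,
                master_seed=grid.master_seed,
                max_in_degree=grid.max_in_degree,
                n_levels=grid.n_levels,
                dirichlet=grid.dirichlet,
                with_hamming=with_hamming,
            ):
                records.append(res.to_record())
    return pd.DataFrame(records)
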