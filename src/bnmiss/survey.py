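"""Synthetic ageing-cohort survey fixture.

Emulates the shape of a linked biomedical/social survey on older adults:
29 categorical variables with 2-4 levels, grouped into five thematically
planted blocks (cardiometabolic conditions, diabetes/metabolic markers,
musculoskeletal/memory, cognition/respiratory/behaviour, socioeconomic),
densely linked within a block and sparsely between blocks so that community
detection has a recoverable ground truth.  Missingness is uneven and planted
under MAR: most variables lose well under 5% of values, two lose about 10%,
and household income about 33%, leaving roughly 40-55% of rows fully
complete.

The generator parameters are fixture choices made to reproduce these summary
characteristics of real linked survey data; they are not estimates from any
dataset.
"""

from __future__ import annotations

import numpy as np

from .amputation import MissingnessSpec, ampute
from .network import DirectedNetwork
from .random_networks import DirichletSpec, forward_sample, sample_cpts
from .table import CategoricalTable

__all__ = ["SURVEY_BLOCKS", "generate_survey_fixture", "planted_block_labels"]

#: planted community blocks: 29 variables, 2-4 levels each
SURVEY_BLOCKS: dict[str, list[str]] = {
    "cardiovascular": [
        "heart_disease", "stroke", "high_bp", "bp_treatment",
        "total_cholesterol", "heart_treatment",
    ],
    "metabolic": [
        "diabetes", "hba1c", "diabetes_treatment", "bmi_class",
        "hdl_cholesterol", "crp_level",
    ],
    "musculoskeletal": [
        "arthritis", "memory_decline", "pain", "mobility_limits", "falls",
    ],
    "cognition_behaviour": [
        "cognitive_impairment", "cancer", "lung_disease", "smoking",
        "race", "drinking",
    ],
    "socioeconomic": [
        "education", "gender", "cohabitation", "hhincome", "exercise",
        "individual_income",
    ],
}

#: per-variable level counts (2-4), fixture design
_LEVEL_COUNTS: dict[str, int] = {
    "heart_disease": 2, "stroke": 2, "high_bp": 2, "bp_treatment": 2,
    "total_cholesterol": 3, "heart_treatment": 2,
    "diabetes": 2, "hba1c": 3, "diabetes_treatment": 2, "bmi_class": 4,
    "hdl_cholesterol": 3, "crp_level": 3,
    "arthritis": 2, "memory_decline": 3, "pain": 2, "mobility_limits": 3,
    "falls": 2,
    "cognitive_impairment": 3, "cancer": 2, "lung_disease": 2, "smoking": 3,
    "race": 4, "drinking": 3,
    "education": 4, "gender": 2, "cohabitation": 2, "hhincome": 4,
    "exercise": 3, "individual_income": 4,
}

#: uneven MAR missingness targets: one high (~33%), two moderate (~10%),
#: the rest low (<5%); chosen so 40-55% of rows stay fully complete
_MISSINGNESS_TARGETS: dict[str, float] = {
    "hhincome": 0.33,
    "individual_income": 0.10,
    "hba1c": 0.10,
}
_LOW_MISSINGNESS = 0.008


def _planted_structure() -> DirectedNetwork:
    """Dense within-block chains with skip edges; single sparse bridges
    between consecutive blocks.  In-degree stays at most 3."""
    nodes = [v for block in SURVEY_BLOCKS.values() for v in block]
    edges: set[tuple[str, str]] = set()
    blocks = list(SURVEY_BLOCKS.values())
    for block in blocks:
        for i in range(len(block) - 1):
            edges.add((block[i], block[i + 1]))
        for i in range(len(block) - 2):
            edges.add((block[i], block[i + 2]))
    for b in range(len(blocks) - 1):
        # one bridge: last variable of one block feeds the first of the next
        edges.add((blocks[b][-1], blocks[b + 1][0]))
    levels = {v: [str(i) for i in range(_LEVEL_COUNTS[v])] for v in nodes}
    return DirectedNetwork(nodes, edges, levels)


def planted_block_labels() -> dict[str, int]:
    """Ground-truth community id per variable (for agreement checks)."""
    return {
        v: b
        for b, block in enumerate(SURVEY_BLOCKS.values())
        for v in block
    }


def generate_survey_fixture(
    n_rows: int = 5726, seed: int | None = None
) -> CategoricalTable:
    """Sample the planted survey network and plant uneven MAR missingness.

    Returns a table whose masked cells retain their ground-truth values, so
    imputation accuracy remains measurable.
    """
    if n_rows < 100:
        raise ValueError("n_rows must be >= 100")
    ss = np.random.SeedSequence(seed)
    cpt_seed, sample_seed, *amp_seeds = [
        int(s) for s in ss.generate_state(2 + len(_LEVEL_COUNTS)) % (2**31)
    ]
    structure = _planted_structure()
    bn = sample_cpts(structure, DirichletSpec(0.5, 5.0), seed=cpt_seed)
    complete = forward_sample(bn, n_rows, seed=sample_seed)

    # per-variable MAR amputation (single pattern hiding that variable);
    # masks are then combined, giving multi-variable missing patterns overall
    n_vars = complete.n_cols
    mask = np.zeros(complete.shape, dtype=bool)
    for k, name in enumerate(complete.columns):
        target = _MISSINGNESS_TARGETS.get(name, _LOW_MISSINGNESS)
        pattern = np.zeros((1, n_vars), dtype=int)
        pattern[0, k] = 1
        spec = MissingnessSpec(
            mechanism="MAR", proportion=target, patterns=pattern, freq=np.ones(1)
        )
        amputed = ampute(complete, spec, seed=amp_seeds[k])
        mask |= amputed.mask
    return complete.with_mask(mask)
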