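import numpy as np
import pytest

from bnmiss import (
    CategoricalTable,
    DirectedNetwork,
    MissingnessSpec,
    NoCompleteCasesError,
    ParameterisedNetwork,
    ampute,
    compare_skeletons,
    forward_sample,
    generate_random_dag,
    impute_from_parents,
    learn_complete_cases,
    learn_with_mice,
    mice_impute,
    sample_cpts,
    structural_em,
    tabu_search,
)
from bnmiss.learners import CompleteCaseLearner, MiceImputer, StructuralEMLearner

from conftest import make_table


def incomplete_dataset(n_vars=5, n_rows=1000, proportion=0.3, mech="MCAR", seed=0):
    net = generate_random_dag(n_vars, seed=seed)
    bn = sample_cpts(net, seed=seed + 1)
    complete = forward_sample(bn, n_rows, seed=seed + 2)
    return net, ampute(complete, MissingnessSpec(mech, proportion), seed=seed + 3)


# -- complete-case learning --------------------------------------------------


def test_complete_input_equals_direct_tabu():
    net = generate_random_dag(4, seed=2)
    data = forward_sample(sample_cpts(net, seed=2), 500, seed=2)
    direct = tabu_search(data)
    assert learn_complete_cases(data).network.edges == direct.edges
    assert structural_em(data).network.edges == direct.edges
    assert learn_with_mice(data, seed=0).network.edges == direct.edges


def test_listwise_deletion_row_count():
    mask = np.zeros((10, 3), dtype=bool)
    mask[[0, 3, 5, 7], [0, 1, 2, 0]] = True
    t = make_table(np.random.default_rng(0).integers(0, 2, (10, 3)), mask=mask)
    learner = CompleteCaseLearner().fit(t)
    assert learner.n_complete_rows_ == 6


def test_zero_complete_rows_raises_specific_error():
    mask = np.ones((5, 2), dtype=bool)
    mask[:, 1] = False
    mask[0, 1] = True
    mask[0, 0] = True
    t = make_table(np.zeros((5, 2), dtype=int), n_levels=[2, 2], mask=np.ones((5, 2), bool))
    with pytest.raises(NoCompleteCasesError):
        learn_complete_cases(t)


# -- parent-based imputation ---------------------------------------------------


def test_impute_mode_given_observed_parents():
    levels = {"P": ["0", "1", "2"], "C": ["0", "1", "2"]}
    structure = DirectedNetwork(["P", "C"], {("P", "C")}, levels)
    cpt = np.array([[0.1, 0.7, 0.2], [0.2, 0.2, 0.6], [1 / 3, 1 / 3, 1 / 3]])
    bn = ParameterisedNetwork(structure, {"P": np.array([[0.5, 0.3, 0.2]]), "C": cpt})
    mask = np.array([[False, True]])
    t = make_table([[0, 0]], names=["P", "C"], n_levels=[3, 3], mask=mask)
    out = impute_from_parents(t, bn)
    assert out.codes[0, 1] == 1  # argmax of (0.1, 0.7, 0.2)


def test_impute_ties_break_to_lowest_level():
    levels = {"A": ["0", "1"]}
    structure = DirectedNetwork(["A"], set(), levels)
    bn = ParameterisedNetwork(structure, {"A": np.array([[0.5, 0.5]])})
    t = make_table([[0]], names=["A"], n_levels=[2], mask=np.array([[True]]))
    assert impute_from_parents(t, bn).codes[0, 0] == 0


def test_fully_missing_row_imputed_in_topological_order():
    levels = {"A": ["0", "1"], "B": ["0", "1"]}
    structure = DirectedNetwork(["A", "B"], {("A", "B")}, levels)
    # A's marginal mode is 1; B given A=1 has mode 0
    bn = ParameterisedNetwork(
        structure,
        {"A": np.array([[0.2, 0.8]]), "B": np.array([[0.1, 0.9], [0.9, 0.1]])},
    )
    t = make_table([[0, 0]], names=["A", "B"], n_levels=[2, 2], mask=np.ones((1, 2), bool))
    out = impute_from_parents(t, bn)
    assert out.codes[0, 0] == 1 and out.codes[0, 1] == 0


def test_impute_draw_variant_is_seeded_and_respects_observations():
    _, data = incomplete_dataset(seed=11)
    from bnmiss.learners import available_case_parameters

    bn = available_case_parameters(data)
    a = impute_from_parents(data, bn, seed=5, method="draw")
    b = impute_from_parents(data, bn, seed=5, method="draw")
    c = impute_from_parents(data, bn, seed=6, method="draw")
    assert (a.codes == b.codes).all()
    assert (a.codes != c.codes).any()
    obs = ~data.mask
    assert (a.codes[obs] == data.codes[obs]).all()


# -- MICE ----------------------------------------------------------------------


def test_mice_noop_on_complete_table():
    net = generate_random_dag(3, seed=3)
    data = forward_sample(sample_cpts(net, seed=3), 200, seed=3)
    out = mice_impute(data, seed=1)
    assert (out.codes == data.codes).all() and out.is_complete


def test_mice_never_alters_observed_cells():
    _, data = incomplete_dataset(seed=21, proportion=0.4)
    out = mice_impute(data, seed=2)
    obs = ~data.mask
    assert out.is_complete
    assert (out.codes[obs] == data.codes[obs]).all()


def test_mice_recovers_deterministic_dependence():
    rng = np.random.default_rng(7)
    a = rng.integers(0, 2, size=1000)
    codes = np.column_stack([a, a])  # perfectly correlated binaries
    mask = np.zeros((1000, 2), dtype=bool)
    mask[rng.random(1000) < 0.3, 1] = True
    t = make_table(codes, n_levels=[2, 2], mask=mask)
    out = mice_impute(t, seed=3)
    hidden = mask[:, 1]
    acc = (out.codes[hidden, 1] == codes[hidden, 1]).mean()
    assert acc >= 0.9


def test_mice_single_level_fallback_logged():
    codes = np.zeros((50, 2), dtype=int)
    codes[:, 0] = np.arange(50) % 2
    mask = np.zeros((50, 2), dtype=bool)
    mask[:5, 1] = True
    t = make_table(codes, n_levels=[2, 2], mask=mask)
    imputer = MiceImputer(random_state=0)
    out = imputer.fit_transform(t)
    assert out.is_complete and (out.codes[:5, 1] == 0).all()
    assert any(e["fallback"] == "single-level" for e in imputer.log_)


# -- structural EM ---------------------------------------------------------------


def test_sem_completed_table_respects_observations():
    _, data = incomplete_dataset(seed=31)
    out = structural_em(data, seed=1)
    obs = ~data.mask
    assert out.completed_table.is_complete
    assert (out.completed_table.codes[obs] == data.codes[obs]).all()


def test_sem_stops_when_structure_stable():
    _, data = incomplete_dataset(seed=41)
    out = structural_em(data, seed=2)
    assert len(out.diagnostics) <= 5
    if len(out.diagnostics) < 5:
        assert out.diagnostics[-1].get("converged")


def test_sem_unobserved_variable_fails_with_diagnostic():
    mask = np.zeros((20, 2), dtype=bool)
    mask[:, 1] = True
    t = make_table(np.zeros((20, 2), dtype=int), n_levels=[2, 2], mask=mask)
    with pytest.raises(ValueError, match="no observed values"):
        structural_em(t)


def test_sem_recall_usually_at_least_complete_case():
    wins = 0
    n_seeds = 20
    for s in range(n_seeds):
        net, data = incomplete_dataset(n_vars=5, proportion=0.3, seed=1000 + s)
        cc_recall = compare_skeletons(
            learn_complete_cases(data).network, net
        ).recall
        sem_recall = compare_skeletons(structural_em(data).network, net).recall
        if sem_recall >= cc_recall:
            wins += 1
    assert wins >= n_seeds * 0.6


def test_all_learners_agree_at_negligible_missingness():
    net = generate_random_dag(6, seed=51)
    bn = sample_cpts(net, seed=52)
    complete = forward_sample(bn, 5000, seed=53)
    data = ampute(complete, MissingnessSpec("MCAR", 0.01), seed=54)
    from bnmiss import skeleton

    cc = skeleton(learn_complete_cases(data).network)
    sem = skeleton(structural_em(data, seed=1).network)
    mice = skeleton(learn_with_mice(data, seed=2).network)
    assert cc == sem == mice
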