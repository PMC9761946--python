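import math

import numpy as np
import pandas as pd
import pytest

from bnmiss import (
    ComparisonResult,
    DirectedNetwork,
    VARIABLE_GROUPS,
    aggregate_and_test,
    compare_skeletons,
    hamming_distance,
    variable_group,
)

from conftest import make_table


def net(names, edges):
    return DirectedNetwork(names, edges, {n: ["0", "1"] for n in names})


def test_identical_networks_score_perfectly():
    a = net("ABC", {("A", "B"), ("B", "C")})
    r = compare_skeletons(a, a)
    assert (r.true_positive, r.false_positive, r.false_negative) == (2, 0, 0)
    assert r.precision == 1.0 and r.recall == 1.0


def test_empty_learned_network_has_undefined_precision():
    learned = net("ABCDEF", set())
    reference = net(
        "ABCDEF",
        {("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("E", "F")},
    )
    r = compare_skeletons(learned, reference)
    assert r.true_positive == 0 and r.false_negative == 5
    assert r.recall == 0.0 and math.isnan(r.precision)


def test_confusion_counts_are_set_arithmetic():
    learned = net("ABCD", {("A", "B"), ("C", "D")})
    reference = net("ABCD", {("A", "B"), ("B", "C")})
    r = compare_skeletons(learned, reference)
    assert (r.true_positive, r.false_positive, r.false_negative) == (1, 1, 1)
    assert r.precision == 0.5 and r.recall == 0.5


def test_direction_is_ignored():
    assert compare_skeletons(net("AB", {("A", "B")}), net("AB", {("B", "A")})).recall == 1.0


def test_node_set_mismatch_rejected():
    with pytest.raises(ValueError):
        compare_skeletons(net("AB", set()), net("AC", set()))


def test_reference_edge_count_identity():
    reference = net("ABCD", {("A", "B"), ("B", "C"), ("C", "D")})
    learned = net("ABCD", {("A", "B"), ("A", "C")})
    r = compare_skeletons(learned, reference)
    assert r.true_positive + r.false_negative == 3


def test_hamming_distance_counts_wrong_imputations():
    mask = np.array([[False, True], [True, False], [False, True], [False, False]])
    original = make_table([[0, 1], [1, 0], [0, 0], [1, 1]], mask=mask)
    perfect = original.filled(original.ground_truth_codes())
    assert hamming_distance(perfect, original) == 0
    wrong = original.ground_truth_codes()
    wrong[mask] = 1 - wrong[mask]
    assert hamming_distance(original.filled(wrong), original) == 3
    one_off = original.ground_truth_codes()
    one_off[0, 1] = 1 - one_off[0, 1]
    assert hamming_distance(original.filled(one_off), original) == 1


def test_hamming_shape_mismatch_rejected():
    a = make_table([[0, 1]])
    b = make_table([[0, 1], [1, 0]])
    with pytest.raises(ValueError):
        hamming_distance(a, b)


def test_variable_groups_partition_2_to_20():
    seen = [variable_group(v) for v in range(2, 21)]
    assert set(seen) == {label for label, _, _ in VARIABLE_GROUPS}
    # contiguity: each n_vars maps to exactly one group
    for v in range(2, 21):
        assert sum(lo <= v <= hi for _, lo, hi in VARIABLE_GROUPS) == 1


def _records(method, recalls, precisions=None, n_vars=10, hamming=None):
    precisions = precisions if precisions is not None else recalls
    return [
        {
            "n_vars": n_vars,
            "proportion": 0.3,
            "mechanism": "MCAR",
            "n_rows": 1000,
            "method": method,
            "replicate": i,
            "precision": p,
            "recall": r,
            "hamming": np.nan if hamming is None else hamming[i],
        }
        for i, (r, p) in enumerate(zip(recalls, precisions))
    ]


def test_identical_methods_yield_flat_anova_and_no_tukey():
    vals = [0.5] * 30
    df = pd.DataFrame(
        _records("none", vals) + _records("mice", vals) + _records("sem", vals)
    )
    report = aggregate_and_test(df)
    anova = report["anova"]
    assert (anova["f_stat"] == 0).all() and (anova["p_bonferroni"] == 1).all()
    assert report["tukey"].empty


def test_planted_difference_flagged_by_anova_and_tukey():
    rng = np.random.default_rng(0)
    noise = lambda: rng.normal(0, 0.01, 100)
    df = pd.DataFrame(
        _records("sem", np.clip(0.9 + noise(), 0, 1))
        + _records("mice", np.clip(0.5 + noise(), 0, 1))
        + _records("none", np.clip(0.5 + noise(), 0, 1))
    )
    report = aggregate_and_test(df)
    assert (report["anova"]["p_bonferroni"] < 0.05).all()
    tk = report["tukey"]
    flagged = {
        frozenset((row.group1, row.group2))
        for row in tk.itertuples()
        if row.reject
    }
    assert frozenset(("sem", "mice")) in flagged
    assert frozenset(("sem", "none")) in flagged
    assert frozenset(("mice", "none")) not in flagged


def test_bonferroni_multiplies_by_cells_in_panel():
    rng = np.random.default_rng(1)
    frames = []
    for n_vars in (5, 10, 15):  # three cells in the same (metric, n, mech) panel
        for method, mu in (("sem", 0.8), ("mice", 0.75), ("none", 0.5)):
            frames.extend(
                _records(method, np.clip(mu + rng.normal(0, 0.05, 20), 0, 1), n_vars=n_vars)
            )
    report = aggregate_and_test(pd.DataFrame(frames))
    anova = report["anova"]
    assert (anova["n_cells_in_family"] == 3).all()
    expected = np.minimum(1.0, anova["p_raw"] * 3)
    assert np.allclose(anova["p_bonferroni"], expected)


def test_undefined_precision_excluded_with_counts():
    recalls = [0.5] * 10
    recs = _records("none", recalls)
    for r in recs[:4]:
        r["precision"] = np.nan
    df = pd.DataFrame(recs + _records("sem", [0.7] * 10))
    report = aggregate_and_test(df)
    assert report["excluded"]["precision"] == 4
    stats = report["cell_stats"]
    none_prec = stats[(stats.method == "none") & (stats.metric == "precision")]
    assert int(none_prec["n"].iloc[0]) == 6


def test_hamming_t_test_detects_ordering():
    rng = np.random.default_rng(2)
    sem_h = rng.normal(80, 5, 30).round().astype(int)
    mice_h = rng.normal(120, 5, 30).round().astype(int)
    df = pd.DataFrame(
        _records("sem", [0.8] * 30, hamming=sem_h)
        + _records("mice", [0.7] * 30, hamming=mice_h)
    )
    tests = aggregate_and_test(df)["hamming_tests"]
    assert len(tests) == 1
    row = tests.iloc[0]
    means = {row.method_a: row.mean_a, row.method_b: row.mean_b}
    assert means["sem"] < means["mice"] and row.p_value < 1e-6
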