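import numpy as np
import pytest
from scipy import stats

from bnmiss import (
    MissingnessSpec,
    ampute,
    forward_sample,
    generate_random_dag,
    sample_cpts,
    score_to_probability,
    weighted_sum_scores,
)

from conftest import make_table


def complete_table(n_vars=5, n_rows=10_000, seed=0):
    net = generate_random_dag(n_vars, seed=seed)
    return forward_sample(sample_cpts(net, seed=seed + 1), n_rows, seed=seed + 2)


def test_proportion_zero_is_noop():
    t = complete_table(n_rows=500)
    out = ampute(t, MissingnessSpec("MCAR", 0.0), seed=1)
    assert out.mask.sum() == 0
    assert (out.codes == t.codes).all()


def test_invalid_inputs_rejected():
    t = complete_table(n_rows=100)
    with pytest.raises(ValueError):
        MissingnessSpec("MCAR", 1.5)
    already = ampute(t, MissingnessSpec("MCAR", 0.3), seed=1)
    with pytest.raises(ValueError):
        ampute(already, MissingnessSpec("MCAR", 0.3), seed=2)


@pytest.mark.parametrize("mechanism", ["MCAR", "MAR", "MNAR"])
def test_realized_proportion_within_binomial_error(mechanism):
    t = complete_table()
    out = ampute(t, MissingnessSpec(mechanism, 0.3), seed=7)
    frac = 1 - out.n_complete_rows / out.n_rows
    se = np.sqrt(0.3 * 0.7 / out.n_rows)
    assert abs(frac - 0.3) <= 4 * se


def test_mcar_splits_missingness_evenly_across_variables():
    t = complete_table(n_vars=5)
    out = ampute(t, MissingnessSpec("MCAR", 0.3), seed=3)
    per_var = out.mask.mean(axis=0)
    # uniform pattern frequency: each variable misses ~0.30 / 5 of its cells
    assert np.abs(per_var - 0.06).max() < 0.02


def test_observed_values_never_altered():
    t = complete_table(n_rows=2000)
    out = ampute(t, MissingnessSpec("MNAR", 0.4), seed=9)
    obs = ~out.mask
    assert (out.codes[obs] == t.codes[obs]).all()
    # ground truth retained under the mask for evaluation
    assert (out.ground_truth_codes() == t.codes).all()


def test_mcar_independent_mnar_dependent_on_value():
    """Missingness vs underlying value: chi-square flat under MCAR, not MNAR."""
    n_seeds = 30
    mcar_sig = mnar_sig = 0
    t = complete_table(n_vars=4, n_rows=8000, seed=5)
    j = 0
    for s in range(n_seeds):
        for mech, bucket in (("MCAR", "mcar"), ("MNAR", "mnar")):
            out = ampute(t, MissingnessSpec(mech, 0.3), seed=1000 + s)
            tbl = np.zeros((2, len(t.levels[t.columns[j]])))
            for miss in (0, 1):
                rows = out.mask[:, j] == bool(miss)
                tbl[miss] = np.bincount(
                    t.codes[rows, j], minlength=tbl.shape[1]
                )
            keep = tbl.sum(axis=0) > 0
            p = stats.chi2_contingency(tbl[:, keep])[1]
            if p < 0.01:
                if mech == "MCAR":
                    mcar_sig += 1
                else:
                    mnar_sig += 1
    assert mcar_sig <= 0.05 * n_seeds + 1
    assert mnar_sig > n_seeds / 2


def test_mar_missingness_driven_by_other_columns():
    # under MAR, rows with missing var j have systematically different
    # weighted-sum scores (computed from the other columns) than complete rows
    t = complete_table(n_vars=4, n_rows=8000, seed=6)
    pattern = np.zeros((1, 4), dtype=int)
    pattern[0, 0] = 1
    spec = MissingnessSpec("MAR", 0.3, patterns=pattern, freq=np.ones(1))
    out = ampute(t, spec, seed=4)
    w = np.array([0.0, 1.0, 1.0, 1.0])
    scores = weighted_sum_scores(t, w)
    assert scores[out.mask[:, 0]].mean() > scores[~out.mask[:, 0]].mean() + 0.1


def test_weighted_sum_scores_linearity_and_projection(toy_table):
    assert (weighted_sum_scores(toy_table, np.zeros(2)) == 0).all()
    z = weighted_sum_scores(toy_table, np.array([0.0, 1.0]))
    col = toy_table.codes[:, 1].astype(float)
    expected = (col - col.mean()) / col.std()
    assert np.allclose(z, expected)


def test_weighted_sum_scores_match_manual_arithmetic(toy_table):
    # codes: col0 = (0,1,2), col1 = (1,0,1); standardize, then sum
    got = weighted_sum_scores(toy_table, np.array([1.0, 1.0]))
    z0 = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2 / 3)
    z1 = np.array([1 / 3, -2 / 3, 1 / 3]) / np.sqrt(2 / 9)
    assert np.allclose(got, z0 + z1)


def test_zero_variance_column_excluded_from_score():
    t = make_table([[0, 1], [0, 0], [0, 1]], n_levels=[1, 2])
    got = weighted_sum_scores(t, np.array([5.0, 0.0]))
    assert (got == 0).all()


def test_score_to_probability_contracts():
    rng = np.random.default_rng(0)
    # equal scores: every probability equals the target
    assert np.allclose(score_to_probability(np.ones(10), 0.25), 0.25)
    # mean hits the target within bisection tolerance; order preserved
    for _ in range(5):
        scores = rng.normal(size=200)
        p = score_to_probability(scores, 0.3)
        assert abs(p.mean() - 0.3) <= 1e-6
        order = np.argsort(scores)
        assert (np.diff(p[order]) >= -1e-12).all()
    # boundary targets
    assert (score_to_probability(rng.normal(size=50), 0.0) == 0).all()
    assert (score_to_probability(rng.normal(size=50), 1.0) == 1).all()


def test_spec_yaml_json_roundtrip():
    spec = MissingnessSpec("MAR", 0.2).resolve(3)
    for text, parse in (
        (spec.to_yaml(), MissingnessSpec.from_yaml),
        (spec.to_json(), MissingnessSpec.from_json),
    ):
        back = parse(text)
        assert back.mechanism == "MAR" and back.proportion == 0.2
        assert np.array_equal(back.patterns, spec.patterns)
        assert np.allclose(back.weights, spec.weights)
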