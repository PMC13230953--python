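"""Inference layer: mixed ANOVA against a brute-force cell-means oracle,
t tests, JZS Bayes factors against an independent implementation, and
Raftery evidence labels."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dualmem import jzs_bf_t, mixed_anova_2x2, raftery_label, t_tests
from dualmem.exceptions import StatsError


def _frame(groups, a, b):
    return pd.DataFrame(
        {
            "participant_id": [f"s{i:03d}" for i in range(len(groups))],
            "group": groups,
            "a": np.asarray(a, float),
            "b": np.asarray(b, float),
        }
    )


def _brute_force_mixed_anova(df):
    """Cell-means sums-of-squares decomposition for one within-pair x one
    between factor, balanced groups; the textbook mixed-design partition."""
    y = df.melt(
        id_vars=["participant_id", "group"], value_vars=["a", "b"],
        var_name="m", value_name="y",
    )
    grand = y["y"].mean()
    subj = y.groupby("participant_id")["y"].mean()
    grp_of = df.set_index("participant_id")["group"]
    grp = y.groupby("group")["y"].mean()
    meas = y.groupby("m")["y"].mean()
    cell = y.groupby(["group", "m"])["y"].mean()
    n_subj = df.groupby("group").size()
    N = len(df)

    ss_between = 2 * sum(n_subj[g] * (grp[g] - grand) ** 2 for g in grp.index)
    ss_subj = 2 * sum((subj[s] - grp[grp_of[s]]) ** 2 for s in subj.index)
    ss_within = N * sum((meas[m] - grand) ** 2 for m in meas.index)
    ss_inter = sum(
        n_subj[g] * (cell[(g, m)] - grp[g] - meas[m] + grand) ** 2
        for g, m in cell.index
    )
    ss_err = sum(
        (r["y"] - cell[(grp_of[r["participant_id"]], r["m"])]
         - subj[r["participant_id"]] + grp[grp_of[r["participant_id"]]]) ** 2
        for _, r in y.iterrows()
    )
    df_subj, df_err = N - 2, N - 2
    return {
        "between": (ss_between / 1) / (ss_subj / df_subj),
        "within": (ss_within / 1) / (ss_err / df_err),
        "interaction": (ss_inter / 1) / (ss_err / df_err),
    }


def test_mixed_anova_matches_cell_means_oracle():
    rng = np.random.default_rng(8)
    df = _frame(["low"] * 3 + ["high"] * 3, rng.normal(size=6), rng.normal(size=6))
    res = mixed_anova_2x2(df, within=("a", "b"))
    oracle = _brute_force_mixed_anova(df)
    for effect in ("between", "within", "interaction"):
        assert res[effect].statistic == pytest.approx(oracle[effect], rel=1e-6)
        assert 0 <= res[effect].p_value <= 1
        assert 0 <= res[effect].effect_size <= 1


def test_mixed_anova_null_effects():
    rng = np.random.default_rng(9)
    a = rng.normal(size=8)
    # identical within measures: within and interaction effects vanish
    df = _frame(["low"] * 4 + ["high"] * 4, a, a.copy())
    res = mixed_anova_2x2(df, within=("a", "b"))
    for effect in ("within", "interaction"):
        assert res[effect].statistic == 0.0
        assert res[effect].p_value == 1.0

    # mirrored groups: between effect vanishes
    vals_a, vals_b = rng.normal(size=4), rng.normal(size=4)
    df2 = _frame(
        ["low"] * 4 + ["high"] * 4,
        np.concatenate([vals_a, vals_a]),
        np.concatenate([vals_b, vals_b]),
    )
    assert abs(mixed_anova_2x2(df2, within=("a", "b"))["between"].statistic) < 1e-10


def test_mixed_anova_input_validation(study_summaries):
    with pytest.raises(StatsError):
        mixed_anova_2x2(study_summaries, within=("pc_r", "nope"))
    one_group = study_summaries[study_summaries["group"] == "high"]
    with pytest.raises(StatsError):
        mixed_anova_2x2(one_group, within=("pc_r", "pc_t"))


def test_mixed_anova_on_study_cohort(study_summaries):
    """Data Type x Relatedness: the correlated high group departs from the
    model while the independent low group does not, driving an interaction."""
    res = mixed_anova_2x2(study_summaries, within=("pc_t", "pc_t_pred"))
    assert res["interaction"].df == (1.0, float(len(study_summaries) - 2))
    dev = study_summaries["pc_t"] - study_summaries["pc_t_pred"]
    by_group = dev.groupby(study_summaries["group"]).mean()
    assert by_group["high"] < by_group["low"]
    assert res["interaction"].statistic > 0


def test_paired_t_equals_one_sample_on_differences():
    rng = np.random.default_rng(10)
    a, b = rng.normal(size=20), rng.normal(size=20)
    res = t_tests(a, b, paired=True)
    t1, p1 = sps.ttest_1samp(a - b, 0.0)
    assert res.statistic == pytest.approx(float(t1), abs=1e-12)
    assert res.p_value == pytest.approx(float(p1), abs=1e-12)
    assert res.df == 19


def test_unpaired_t_matches_scipy():
    rng = np.random.default_rng(11)
    a, b = rng.normal(size=12), rng.normal(0.5, 1, size=15)
    res = t_tests(a, b)
    t, p = sps.ttest_ind(a, b)
    assert res.statistic == pytest.approx(float(t))
    assert res.df == 25


def test_identical_paired_samples_give_null_limit():
    a = np.array([0.2, 0.4, 0.6, 0.8])
    res = t_tests(a, a.copy(), paired=True)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_zero_variance_with_difference_raises():
    with pytest.raises(StatsError):
        t_tests([0, 0, 0, 0], [1, 1, 1, 1])
    with pytest.raises(StatsError):
        t_tests([0, 0, 0, 0], [1, 1, 1, 1], paired=True)


def test_t_test_length_contracts():
    with pytest.raises(StatsError):
        t_tests([1.0], [2.0], paired=True)
    with pytest.raises(StatsError):
        t_tests([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)


@pytest.mark.parametrize("t", [0.5, 1.42, 2.5, 4.74])
@pytest.mark.parametrize("n", [(20, None), (113, None), (118, 113)])
def test_jzs_matches_independent_implementation(t, n):
    """Cross-check the 1-D quadrature against pingouin's JZS routine."""
    import pingouin as pg

    n1, n2 = n
    mine = jzs_bf_t(t, n1, n2)
    ref = float(pg.bayesfactor_ttest(t, n1, n2, paired=(n2 is None), r=0.707))
    assert mine == pytest.approx(ref, rel=1e-6)


def test_jzs_reciprocal_and_null_direction():
    bf = jzs_bf_t(0.0, 50)
    assert bf < 1.0
    assert bf * (1.0 / bf) == pytest.approx(1.0)


def test_jzs_monotone_in_abs_t():
    ts = [0.0, 0.5, 1.0, 2.0, 3.0, 5.0]
    bfs = [jzs_bf_t(t, 40) for t in ts]
    assert all(x < y for x, y in zip(bfs, bfs[1:]))
    assert jzs_bf_t(-2.0, 40) == pytest.approx(jzs_bf_t(2.0, 40), rel=1e-9)


def test_jzs_rejects_bad_input():
    with pytest.raises(ValueError):
        jzs_bf_t(np.inf, 20)
    with pytest.raises(ValueError):
        jzs_bf_t(1.0, 1)


@pytest.mark.parametrize(
    "bf, label",
    [
        (1.0, "weak"),
        (2.99, "weak"),
        (3.0, "positive"),
        (6.86, "positive"),
        (19.99, "positive"),
        (20.0, "strong"),
        (149.9, "strong"),
        (150.0, "very strong"),
        (204.9, "very strong"),
        (2411.0, "very strong"),
    ],
)
def test_raftery_bins(bf, label):
    assert raftery_label(bf) == label


def test_raftery_rejects_sub_unit_bf():
    with pytest.raises(ValueError, match="invert"):
        raftery_label(0.5)
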