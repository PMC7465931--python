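"""Mixed ANOVA decomposition, rank tests and post hoc tables, each checked
against independent oracles (design-matrix least squares, pingouin,
brute-force enumeration)."""

import numpy as np
import pandas as pd
import pytest

from rettnet import (FeatureTable, MixedAnova, mann_whitney, mixed_anova,
                     posthoc_pairs, wilcoxon_signed_rank)
from rettnet.exceptions import (DegenerateInputError, UnbalancedDesignError,
                                UndefinedTestError)
from rettnet.montage import PAIR_LABELS


# --------------------------------------------------------------------------
# brute-force oracle: sequential design-matrix least squares

def anova_ss_oracle(y, groups):
    """Sum-of-squares decomposition via residual differences of nested
    least-squares fits (intercept -> +group -> +subject -> +time ->
    +group:time), independent of the closed-form implementation."""
    n, t = y.shape
    obs = y.ravel()
    subj = np.repeat(np.arange(n), t)
    time = np.tile(np.arange(t), n)
    grp = np.repeat(pd.factorize(groups)[0], t)

    def dummies(codes):
        return np.eye(codes.max() + 1)[codes]

    def rss(x):
        beta, *_ = np.linalg.lstsq(x, obs, rcond=None)
        return float(((obs - x @ beta) ** 2).sum())

    one = np.ones((obs.size, 1))
    m_g = np.hstack([one, dummies(grp)])
    m_s = np.hstack([one, dummies(subj)])
    m_st = np.hstack([m_s, dummies(time)])
    inter = dummies(grp)[:, :, None] * dummies(time)[:, None, :]
    m_full = np.hstack([m_st, inter.reshape(obs.size, -1)])
    rss0, rss_g, rss_s, rss_st, rss_f = (rss(one), rss(m_g), rss(m_s),
                                         rss(m_st), rss(m_full))
    return {"group": rss0 - rss_g, "subject(group)": rss_g - rss_s,
            "time": rss_s - rss_st, "group:time": rss_st - rss_f,
            "time:subject(group)": rss_f}


@pytest.mark.parametrize("sizes", [(3, 3), (5, 4), (4, 3, 3)])
def test_anova_matches_design_matrix_oracle(sizes):
    rng = np.random.default_rng(sum(sizes))
    n = sum(sizes)
    groups = np.repeat([f"g{i}" for i in range(len(sizes))], sizes)
    for _ in range(5):
        y = rng.normal(size=(n, 2))
        res = mixed_anova(y, groups)
        oracle = anova_ss_oracle(y, groups)
        for term, ss in oracle.items():
            assert res.table.loc[term, "sum_sq"] == pytest.approx(
                ss, abs=1e-8), term


def test_anova_total_ss_partition():
    rng = np.random.default_rng(5)
    y = rng.normal(size=(12, 3))
    groups = np.repeat(["a", "b"], 6)
    res = mixed_anova(y, groups)
    assert res.table["sum_sq"].sum() == pytest.approx(
        ((y - y.mean()) ** 2).sum(), abs=1e-8)


def test_anova_matches_pingouin():
    """Independent cross-check against pingouin's mixed_anova."""
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(8)
    y = rng.normal(size=(9, 2))
    groups = np.array(["a"] * 5 + ["b"] * 4)
    res = mixed_anova(y, groups)
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(9), 2),
        "time": np.tile(["t1", "t2"], 9),
        "group": np.repeat(groups, 2),
        "y": y.ravel()})
    ref = pg.mixed_anova(long, dv="y", within="time", between="group",
                         subject="subject").set_index("Source")
    assert res.f_group == pytest.approx(ref.loc["group", "F"], rel=1e-9)
    assert res.f_time == pytest.approx(ref.loc["time", "F"], rel=1e-9)
    assert res.f_interaction == pytest.approx(
        ref.loc["Interaction", "F"], rel=1e-9)
    assert res.p_interaction == pytest.approx(
        ref.loc["Interaction", "p_unc"], rel=1e-9)


def test_anova_constant_data_gives_null_result():
    y = np.full((8, 2), 3.5)
    res = mixed_anova(y, np.repeat(["a", "b"], 4))
    assert res.f_group == 0.0 and res.p_group == 1.0
    assert res.f_time == 0.0 and res.p_time == 1.0
    assert res.f_interaction == 0.0 and res.p_interaction == 1.0


def test_anova_pure_group_contrast():
    """Group-coded constants with no time variation load the group term
    only."""
    y = np.repeat(np.repeat([1.0, 2.0], 4)[:, None], 2, axis=1)
    y += np.tile([0.0, 0.0], (8, 1))
    res = mixed_anova(y + np.random.default_rng(0).normal(scale=1e-9,
                                                          size=y.shape),
                      np.repeat(["a", "b"], 4))
    assert res.table.loc["group", "sum_sq"] == pytest.approx(4.0, rel=1e-4)
    assert res.table.loc["time", "sum_sq"] == pytest.approx(0.0, abs=1e-12)
    assert res.table.loc["group:time", "sum_sq"] == pytest.approx(
        0.0, abs=1e-12)


def test_anova_missing_timepoint_raises():
    y = np.random.default_rng(0).normal(size=(6, 2))
    y[2, 1] = np.nan
    with pytest.raises(UnbalancedDesignError):
        mixed_anova(y, np.repeat(["a", "b"], 3))


def test_anova_from_long_round_trip():
    rng = np.random.default_rng(9)
    y = rng.normal(size=(6, 2))
    groups = np.repeat(["a", "b"], 3)
    long = pd.DataFrame({
        "subject": np.repeat([f"s{i}" for i in range(6)], 2),
        "time": np.tile(["baseline", "month12"], 6),
        "group": np.repeat(groups, 2),
        "y": y.ravel()})
    res_long = MixedAnova.from_long(long, dv="y", subject="subject",
                                    within="time", between="group").fit()
    res_wide = mixed_anova(y, groups)
    assert np.allclose(res_long.table["sum_sq"], res_wide.table["sum_sq"])


def test_interaction_p_uniform_under_null():
    """Under a true null the interaction p-value is Uniform[0,1]
    (moderate-scale version of the calibration check)."""
    from scipy import stats as sps
    rng = np.random.default_rng(10)
    groups = np.repeat(["a", "b"], 6)
    ps = [mixed_anova(rng.normal(size=(12, 2)), groups).p_interaction
          for _ in range(400)]
    assert sps.kstest(ps, "uniform").statistic < 0.08


# --------------------------------------------------------------------------
# rank tests

def test_mann_whitney_identical_samples():
    u, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert u == 4.5  # n1*n2/2 with midranks
    assert p == 1.0


def test_mann_whitney_separated_exact():
    """Complete separation at n1=n2=4: exactly 2 of the 70 arrangements
    are as extreme."""
    u, p = mann_whitney([1, 2, 3, 4], [5, 6, 7, 8], mode="exact")
    assert u == 0.0
    assert p == pytest.approx(2 / 70)


def test_mann_whitney_exact_matches_enumeration():
    """Exact p agrees with brute-force enumeration of all rank splits."""
    from itertools import combinations
    rng = np.random.default_rng(11)
    x, y = rng.normal(size=4), rng.normal(0.8, 1, size=4)
    u_obs, p = mann_whitney(x, y, mode="exact")
    pooled = np.concatenate([x, y])
    ranks = pooled.argsort().argsort() + 1
    n1 = len(x)
    u_null = []
    for idx in combinations(range(8), n1):
        r1 = ranks[list(idx)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2
        u_null.append(u1)
    u_null = np.array(u_null)
    mu = n1 * 4 / 2
    p_enum = np.mean(np.abs(u_null - mu) >= abs(u_obs - mu) - 1e-12)
    assert p == pytest.approx(p_enum, abs=1e-12)


def test_mann_whitney_exact_close_to_normal_at_nine_per_group():
    rng = np.random.default_rng(12)
    for _ in range(100):
        x, y = rng.normal(size=9), rng.normal(0.4, 1, size=9)
        _, pe = mann_whitney(x, y, mode="exact")
        _, pn = mann_whitney(x, y, mode="normal")
        assert abs(pe - pn) < 0.02


def test_wilcoxon_constant_shift_is_extreme():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    w, p = wilcoxon_signed_rank(x + 3.0, x)
    assert w == 0.0
    assert p == pytest.approx(2 / 2 ** 6)  # smallest attainable for n=6


def test_wilcoxon_balanced_signs_near_one():
    x = np.zeros(6)
    y = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
    _, p = wilcoxon_signed_rank(x, y)
    assert p > 0.8


def test_wilcoxon_exact_matches_sign_enumeration():
    """Exact p agrees with enumeration of all 2^6 sign patterns."""
    from itertools import product
    d = np.array([0.8, -1.6, 2.3, 3.1, -0.4, 5.2])
    w_obs, p = wilcoxon_signed_rank(d, np.zeros(6), mode="exact")
    ranks = np.abs(d).argsort().argsort() + 1.0
    w_null = []
    for signs in product([0, 1], repeat=6):
        s = np.array(signs)
        w_plus = ranks[s == 1].sum()
        w_null.append(min(w_plus, ranks.sum() - w_plus))
    p_enum = np.mean(np.array(w_null) <= w_obs + 1e-12)
    assert p == pytest.approx(p_enum, abs=1e-12)


def test_wilcoxon_all_zero_differences_undefined():
    with pytest.raises(UndefinedTestError):
        wilcoxon_signed_rank(np.ones(5), np.ones(5))


# --------------------------------------------------------------------------
# post hoc tables

def _feature_frame(rng, n, group, timepoint="baseline", start=0):
    df = pd.DataFrame(rng.uniform(0.2, 0.6, size=(n, 28)),
                      columns=PAIR_LABELS)
    df.insert(0, "subject_id", [f"S{start + i}" for i in range(n)])
    df.insert(1, "group", group)
    df.insert(2, "timepoint", timepoint)
    return df


def test_posthoc_has_28_rows_and_consistent_flags():
    rng = np.random.default_rng(13)
    df = pd.concat([_feature_frame(rng, 8, "a"),
                    _feature_frame(rng, 8, "b", start=8)])
    ph = posthoc_pairs(FeatureTable(df), between=("a", "b"),
                       timepoint="baseline")
    assert len(ph.table) == 28
    assert (ph.table["significant"] == (ph.table["p"] < 0.05)).all()
    assert (ph.table["p_bonferroni"] >= ph.table["p"]).all()
    assert (ph.table["p_bonferroni"] <= 1.0).all()


def test_posthoc_identical_groups_flags_nothing():
    rng = np.random.default_rng(14)
    base = _feature_frame(rng, 6, "a")
    copy = base.copy()
    copy["group"] = "b"
    copy["subject_id"] = [f"T{i}" for i in range(6)]
    ph = posthoc_pairs(FeatureTable(pd.concat([base, copy])),
                       between=("a", "b"), timepoint="baseline")
    assert not ph.table["significant"].any()


def test_posthoc_within_group_uses_wilcoxon():
    rng = np.random.default_rng(15)
    t1 = _feature_frame(rng, 7, "treated", "baseline")
    t2 = _feature_frame(rng, 7, "treated", "month12")
    t2["O1-O2"] = t1["O1-O2"].to_numpy() + 0.2  # systematic shift
    ph = posthoc_pairs(FeatureTable(pd.concat([t1, t2])),
                       within_group="treated",
                       timepoints=("baseline", "month12"))
    assert ph.test == "Wilcoxon signed-rank"
    row = ph.table.set_index("pair").loc["O1-O2"]
    assert row["p"] < 0.05
    assert row["median_diff"] == pytest.approx(-0.2)


def test_posthoc_degenerate_cell_raises():
    rng = np.random.default_rng(16)
    df = pd.concat([_feature_frame(rng, 1, "a"),
                    _feature_frame(rng, 5, "b", start=1)])
    with pytest.raises(DegenerateInputError):
        posthoc_pairs(FeatureTable(df), between=("a", "b"),
                      timepoint="baseline")
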