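"""Statistical battery: hand-computable oracles, cross-checks against
independent library implementations, and structural invariances."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from gustaquant.stats import (
    chi_square,
    dunn_test,
    holm_sidak_adjust,
    kruskal_wallis,
    paired_t,
    two_way_anova,
)

THREE_GROUPS = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]


# --------------------------------------------------------------------------
# Kruskal-Wallis


def test_h_on_worked_three_group_example():
    res = kruskal_wallis(THREE_GROUPS)
    assert res.statistic == pytest.approx(7.2, abs=1e-9)
    assert res.df == 2


def test_h_zero_when_all_identical():
    res = kruskal_wallis([[5, 5], [5, 5, 5], [5]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_h_invariant_under_monotone_transform():
    rng = np.random.default_rng(1)
    groups = [rng.normal(m, 1, 8) for m in (0, 0.5, 1.0)]
    h1 = kruskal_wallis(groups).statistic
    h2 = kruskal_wallis([np.exp(g) for g in groups]).statistic
    assert h1 == pytest.approx(h2, abs=1e-12)


def test_h_matches_scipy_with_ties():
    rng = np.random.default_rng(2)
    groups = [rng.integers(0, 5, 12) for _ in range(4)]
    mine = kruskal_wallis(groups)
    ref = sps.kruskal(*groups)
    assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_empty_group_rejected():
    with pytest.raises(ValueError, match="empty"):
        kruskal_wallis([[1, 2], []])


# --------------------------------------------------------------------------
# Dunn


def test_dunn_extreme_pair_closed_form():
    res = dunn_test(THREE_GROUPS)
    z = res.posthoc.query("group_i == 0 and group_j == 2")["z"].iloc[0]
    assert z == pytest.approx(-6 / np.sqrt(5), abs=1e-9)


def test_dunn_identical_groups_all_null():
    res = dunn_test([[3, 3, 3], [3, 3, 3]])
    assert (res.posthoc["z"] == 0).all()
    assert (res.posthoc["p_raw"] == 1.0).all()


def test_dunn_holm_adjustment_monotone():
    rng = np.random.default_rng(3)
    groups = [rng.normal(m, 1, 10) for m in (0, 0.3, 0.9, 1.4)]
    res = dunn_test(groups, adjust="holm")
    assert (res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-15).all()
    assert (res.posthoc["p_adj"] <= 1.0).all()


def test_dunn_z_squares_to_h_for_two_groups():
    rng = np.random.default_rng(4)
    groups = [rng.integers(0, 8, 9), rng.integers(0, 8, 7)]  # with ties
    res = dunn_test(groups)
    h = kruskal_wallis(groups).statistic
    z = res.posthoc["z"].iloc[0]
    assert z**2 == pytest.approx(h, abs=1e-9)


# --------------------------------------------------------------------------
# two-way ANOVA


def test_anova_zero_noise_equal_means_gives_zero_f():
    values = [3.0] * 12
    a = ["x", "y"] * 6
    b = ["u"] * 6 + ["v"] * 6
    res = two_way_anova(values, a, b)
    table = res.extra["anova_table"]
    assert (table.loc[table["effect"] != "residual", "F"] == 0).all()


def test_anova_2x2_hand_decomposition():
    """Balanced 2x2 with n=3, zero noise: SS terms by direct arithmetic."""
    means = {("a1", "b1"): 1.0, ("a1", "b2"): 2.0,
             ("a2", "b1"): 4.0, ("a2", "b2"): 7.0}
    rows = [(v, a, b) for (a, b), v in means.items() for _ in range(3)]
    values, fa, fb = zip(*rows)
    res = two_way_anova(values, fa, fb)
    table = res.extra["anova_table"].set_index("effect")
    # grand mean 3.5; A means 1.5/5.5 (dev 2), B means 2.5/4.5 (dev 1),
    # interaction deviation 0.5 per cell; 6 obs per level, 3 per cell
    assert table.loc["a", "ss"] == pytest.approx(6 * 2 * 2.0**2, abs=1e-9)
    assert table.loc["b", "ss"] == pytest.approx(6 * 2 * 1.0**2, abs=1e-9)
    assert table.loc["a:b", "ss"] == pytest.approx(12 * 0.5**2, abs=1e-9)
    assert table.loc["residual", "ss"] == pytest.approx(0.0, abs=1e-9)


def test_anova_type2_matches_statsmodels_on_unbalanced_data():
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(5)
    rows = []
    for a, b, n in [("a1", "b1", 4), ("a1", "b2", 7), ("a2", "b1", 5),
                    ("a2", "b2", 3), ("a1", "b3", 6), ("a2", "b3", 4)]:
        for _ in range(n):
            rows.append({"a": a, "b": b,
                         "y": rng.normal((a == "a1") * 0.8 + (b == "b2") * 0.5)})
    df = pd.DataFrame(rows)
    res = two_way_anova(df["y"], df["a"], df["b"])
    ref = sm.stats.anova_lm(smf.ols("y ~ C(a) * C(b)", data=df).fit(), typ=2)
    table = res.extra["anova_table"].set_index("effect")
    assert table.loc["a", "ss"] == pytest.approx(ref.loc["C(a)", "sum_sq"])
    assert table.loc["b", "ss"] == pytest.approx(ref.loc["C(b)", "sum_sq"])
    assert table.loc["a:b", "ss"] == pytest.approx(ref.loc["C(a):C(b)", "sum_sq"])
    assert table.loc["a", "F"] == pytest.approx(ref.loc["C(a)", "F"])


def test_mixed_design_matches_pingouin():
    import pingouin as pg

    rng = np.random.default_rng(6)
    rows = []
    for s in range(10):
        geno = "WT" if s < 5 else "KO"
        for stim in ("NH4Cl", "sucrose", "NaCl"):
            rows.append({"subject": f"s{s}", "geno": geno, "stim": stim,
                         "y": rng.normal((geno == "WT") * 0.6)})
    df = pd.DataFrame(rows)
    res = two_way_anova(df["y"], df["geno"], df["stim"],
                       repeated_on=df["subject"])
    table = res.extra["anova_table"].set_index("effect")
    ref = pg.mixed_anova(data=df, dv="y", within="stim",
                         subject="subject", between="geno")
    ref = ref.set_index("Source")
    assert table.loc["a", "F"] == pytest.approx(ref.loc["geno", "F"])
    assert table.loc["b", "F"] == pytest.approx(ref.loc["stim", "F"])
    assert table.loc["a:b", "F"] == pytest.approx(ref.loc["Interaction", "F"])
    assert res.extra["sphericity_assumed"]


def test_fully_within_design_matches_pingouin():
    import pingouin as pg

    rng = np.random.default_rng(7)
    rows = []
    for s in range(7):
        for a in ("low", "high"):
            for b in ("x", "y", "z"):
                rows.append({"s": f"s{s}", "a": a, "b": b,
                             "y": rng.normal((a == "high") * 0.4)})
    df = pd.DataFrame(rows)
    res = two_way_anova(df["y"], df["a"], df["b"], repeated_on=df["s"])
    table = res.extra["anova_table"].set_index("effect")
    ref = pg.rm_anova(data=df, dv="y", within=["a", "b"], subject="s")
    ref = ref.set_index("Source")
    assert table.loc["a", "F"] == pytest.approx(ref.loc["a", "F"])
    assert table.loc["b", "F"] == pytest.approx(ref.loc["b", "F"])
    assert table.loc["a:b", "F"] == pytest.approx(ref.loc["a * b", "F"])


def test_anova_empty_cell_rejected():
    with pytest.raises(ValueError, match="cell"):
        two_way_anova([1, 2, 3], ["a1", "a1", "a2"], ["b1", "b2", "b1"])


def test_holm_sidak_posthoc_adjusted_monotone():
    rng = np.random.default_rng(8)
    values = rng.normal(0, 1, 24) + np.repeat([0, 0.5, 1.2, 0.1], 6)
    a = np.repeat(["g1", "g2"], 12)
    b = np.tile(np.repeat(["b1", "b2"], 6), 1)
    res = two_way_anova(values, a, np.resize(b, 24))
    ph = res.posthoc
    assert (ph["p_adj"] >= ph["p_raw"] - 1e-15).all()
    direct = holm_sidak_adjust(ph["p_raw"].to_numpy())
    np.testing.assert_allclose(ph["p_adj"], direct)


# --------------------------------------------------------------------------
# chi-square


def test_chi_square_2x2_closed_form():
    res = chi_square([[10, 20], [20, 10]])
    assert res.statistic == pytest.approx(20 / 3, abs=1e-9)
    assert res.df == 1


def test_chi_square_proportional_rows_zero():
    res = chi_square([[10, 20, 30], [20, 40, 60]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_chi_square_transpose_invariant():
    table = [[12, 7, 9], [3, 14, 8]]
    assert chi_square(table).statistic == pytest.approx(
        chi_square(np.transpose(table)).statistic, abs=1e-12
    )


def test_chi_square_matches_scipy():
    table = [[15, 25, 10], [30, 5, 15]]
    res = chi_square(table)
    ref = sps.chi2_contingency(table, correction=False)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
    np.testing.assert_allclose(res.extra["expected"], ref.expected_freq)


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        chi_square([[0, 0], [5, 5]])


# --------------------------------------------------------------------------
# paired t


def test_paired_t_hand_example():
    res = paired_t([2, 3, 4], [1, 1, 1])  # differences {1, 2, 3}
    assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-9)
    assert res.df == 2


def test_paired_t_identical_inputs():
    res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_paired_t_antisymmetric():
    x = [2.0, 4.0, 5.0, 9.0]
    y = [1.0, 5.0, 3.0, 6.0]
    assert paired_t(x, y).statistic == pytest.approx(
        -paired_t(y, x).statistic, abs=1e-12
    )


def test_paired_t_matches_scipy():
    rng = np.random.default_rng(9)
    x, y = rng.normal(0, 1, 15), rng.normal(0.2, 1, 15)
    res = paired_t(x, y)
    ref = sps.ttest_rel(x, y)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_paired_t_constant_nonzero_difference_rejected():
    with pytest.raises(ValueError, match="zero variance"):
        paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])


def test_paired_t_single_pair_rejected():
    with pytest.raises(ValueError, match="2 pairs"):
        paired_t([1.0], [2.0])
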