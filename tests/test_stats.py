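"""Baseline-statistics tests, including the reproduction of published
2x2 chi-square statistics and brute-force oracles for the exact and
rank tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lnmfusion.cohort import SyntheticParams, generate_cohort
from lnmfusion.stats import (ContingencyTable2x2, baseline_table,
                             fisher_exact, ks_normality, mann_whitney_z,
                             pearson_chi_square, pooled_t_test)

# Published baseline-table 2x2 counts (rows = category level, columns =
# LN+ / LN-) with their printed uncorrected Pearson chi-square values.
REFERENCE_TABLES = [
    ("scc_ag", [[5, 70], [11, 41]], 5.853),
    ("clinical_stage", [[3, 110], [13, 1]], 92.045),
    ("differentiation_grade", [[10, 71], [6, 40]], 0.013),
    ("lymphovascular_invasion", [[8, 81], [8, 30]], 3.520),
    ("perineural_invasion", [[14, 102], [2, 9]], 0.341),
]


@pytest.mark.parametrize("name,table,expected",
                         REFERENCE_TABLES, ids=[t[0] for t in REFERENCE_TABLES])
def test_chi_square_reproduces_published_statistics(name, table, expected):
    res = pearson_chi_square(table)
    assert res.statistic == pytest.approx(expected, abs=5e-4)
    assert res.df == 1
    assert 0 <= res.p_value <= 1


def test_chi_square_zero_for_equal_proportions():
    assert pearson_chi_square([[10, 10], [10, 10]]).statistic == 0.0


def test_chi_square_permutation_invariance():
    base = pearson_chi_square([[5, 70], [11, 41]]).statistic
    assert pearson_chi_square([[11, 41], [5, 70]]).statistic == \
        pytest.approx(base)
    assert pearson_chi_square([[70, 5], [41, 11]]).statistic == \
        pytest.approx(base)


def test_chi_square_degenerate_marginal_rejected():
    with pytest.raises(ValueError):
        pearson_chi_square([[0, 0], [5, 7]])
    with pytest.raises(ValueError):
        pearson_chi_square(ContingencyTable2x2(0, 5, 0, 7))


# ------------------------------------------------------------------- Fisher

def fisher_oracle_two_sided(a, b, c, d):
    """Hypergeometric enumeration: sum P(table) over all tables with the
    same marginals whose probability <= the observed one."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                / math.comb(n, row1))
    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


@pytest.mark.parametrize("table", [(1, 9, 9, 1), (2, 8, 5, 5), (0, 10, 6, 4)])
def test_fisher_matches_enumeration_oracle(table):
    res = fisher_exact([[table[0], table[1]], [table[2], table[3]]])
    assert res.p_value == pytest.approx(fisher_oracle_two_sided(*table),
                                        rel=1e-9)


def test_fisher_symmetric_table_p_one():
    assert fisher_exact([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)


def test_fisher_and_chi_square_agree_on_large_tables():
    rng = np.random.default_rng(8)
    for _ in range(20):
        t = rng.integers(20, 200, size=(2, 2))
        p_chi = pearson_chi_square(t).p_value
        p_f = fisher_exact(t).p_value
        assert (p_chi < 0.05) == (p_f < 0.05) or \
            abs(p_chi - p_f) < 0.04      # near-threshold tables may straddle


# ------------------------------------------------------------------- t-test

def test_t_identical_groups_zero():
    res = pooled_t_test([1.0, 2, 3, 4], [1.0, 2, 3, 4])
    assert res.statistic == pytest.approx(0.0)
    assert res.df == 6


def test_t_from_published_summary_statistics():
    """Platelet row: means/SDs rounded to one decimal give |t| near the
    published 0.040 (exact agreement is not expected from rounded
    inputs)."""
    res = pooled_t_test(244.3, 48.3, 16, 245.0, 65.5, 111)
    assert abs(res.statistic) == pytest.approx(0.041, abs=0.01)
    assert res.df == 125


def test_t_matches_textbook_formula(rng):
    s1 = rng.normal(size=12)
    s2 = rng.normal(loc=0.4, size=17)
    res = pooled_t_test(s1, s2)
    n1, n2 = len(s1), len(s2)
    sp2 = ((n1 - 1) * s1.var(ddof=1) + (n2 - 1) * s2.var(ddof=1)) / (n1 + n2 - 2)
    t = (s1.mean() - s2.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    assert res.statistic == pytest.approx(t, abs=1e-10)


def test_t_degenerate_samples_rejected():
    with pytest.raises(ValueError):
        pooled_t_test([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        pooled_t_test(1.0, 1.0, 1, 2.0, 1.0, 10)


# ------------------------------------------------------------- Mann-Whitney

def mann_whitney_u_oracle(s1, s2):
    wins = 0.0
    for x in s1:
        for y in s2:
            wins += 1.0 if x > y else (0.5 if x == y else 0.0)
    return wins


def test_mwu_identical_samples():
    res = mann_whitney_z([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    assert abs(res.statistic) < 0.2
    assert res.p_value > 0.8


def test_mwu_complete_separation_extreme_u():
    res = mann_whitney_z([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
    assert res.extra["U"] == 0.0
    res2 = mann_whitney_z([10, 11, 12, 13, 14], [1, 2, 3, 4, 5])
    assert res2.extra["U"] == 25.0
    assert res2.statistic == pytest.approx(-res.statistic)


@settings(derandomize=True, max_examples=60)
@given(st.integers(0, 2 ** 31 - 1))
def test_mwu_matches_pairwise_oracle_and_u_identity(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = int(rng.integers(2, 13)), int(rng.integers(2, 13))
    s1 = np.round(rng.normal(size=n1), 1)    # rounding induces ties
    s2 = np.round(rng.normal(size=n2), 1)
    res = mann_whitney_z(s1, s2)
    assert res.extra["U"] == pytest.approx(mann_whitney_u_oracle(s1, s2))
    assert res.extra["U"] + res.extra["U_prime"] == pytest.approx(n1 * n2)
    # cross-check against the library implementation of U
    u_sp = sps.mannwhitneyu(s1, s2, alternative="two-sided").statistic
    assert res.extra["U"] == pytest.approx(u_sp)
    # two-sided p is symmetric under swapping the samples
    swapped = mann_whitney_z(s2, s1)
    assert res.p_value == pytest.approx(swapped.p_value, abs=1e-12)
    assert 0 <= res.p_value <= 1


def test_mwu_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney_z([], [1.0])


# ---------------------------------------------------------------- normality

def test_ks_accepts_normal_rejects_skewed():
    accept = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        if ks_normality(rng.normal(size=500)).p_value > 0.05:
            accept += 1
    assert accept >= 19
    reject = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        if ks_normality(rng.exponential(size=200)).p_value < 0.05:
            reject += 1
    assert reject >= 19


def test_ks_degenerate_inputs():
    with pytest.raises(ValueError):
        ks_normality([1.0, 2.0])
    with pytest.raises(ValueError, match="constant"):
        ks_normality([3.0] * 50)


# ------------------------------------------------------------ baseline table

def test_baseline_table_counts_percentages_and_routing():
    cohort = generate_cohort(SyntheticParams(seed=13, n_patients=127,
                                             n_positive=16, image_size=8,
                                             effect_clin=2.0))
    table = baseline_table(cohort.clinical_frame())
    header = table.iloc[0]
    assert header["group_pos"] == "n=16" and header["group_neg"] == "n=111"
    flag_rows = table[table.variable == "scc_ag_elevated"]
    assert len(flag_rows) == 1
    assert "%" in flag_rows.iloc[0]["group_pos"]
    routed = table[table.variable.isin(["age", "sii"])]
    assert routed["test"].str.match(r"[tz] = ").all()


def test_baseline_table_elevated_proportion_formatting():
    """11 of 16 positive patients elevated formats as 68.8%."""
    import pandas as pd
    rng = np.random.default_rng(0)
    n_pos, n_neg = 16, 111
    scc_pos = np.where(np.arange(n_pos) < 11, 5.0, 1.0)    # 11 elevated
    scc_neg = np.where(np.arange(n_neg) < 41, 5.0, 1.0)    # 41 elevated
    df = pd.DataFrame({
        "label": [1] * n_pos + [0] * n_neg,
        "scc_ag": np.concatenate([scc_pos, scc_neg]),
        "age": rng.normal(55, 10, n_pos + n_neg),
    })
    table = baseline_table(df, continuous=("age",),
                           categorical=("scc_ag_elevated",))
    row = table[table.variable == "scc_ag_elevated"].iloc[0]
    assert row["group_pos"] == "11 (68.8%)"
    assert row["statistic"] == pytest.approx(5.853, abs=5e-4)


def test_baseline_table_null_pvalues_roughly_uniform():
    """With no group differences the per-seed p-values are not
    systematically small."""
    ps = []
    for seed in range(25):
        cohort = generate_cohort(SyntheticParams(
            seed=seed, n_patients=120, n_positive=40, image_size=8,
            effect_clin=0.0))
        table = baseline_table(cohort.clinical_frame(),
                               continuous=("platelets",), categorical=())
        ps.append(float(table[table.variable == "platelets"]
                        .p_value.iloc[0]))
    ps = np.array(ps)
    assert sps.kstest(ps, "uniform").pvalue > 0.01
    assert (ps < 0.05).mean() < 0.25


def test_baseline_table_missing_variable_skipped():
    import pandas as pd
    df = pd.DataFrame({"label": [0, 1] * 10,
                       "age": np.random.default_rng(0).normal(50, 5, 20)})
    table = baseline_table(df, continuous=("age", "ghost"), categorical=())
    row = table[table.variable == "ghost"].iloc[0]
    assert row["test"] == "missing-variable"
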