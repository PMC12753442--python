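"""Baseline-characteristics statistics for the clinical table.

Normality-gated summaries (mean +/- SD with a pooled two-sample t-test
vs median (P25, P75) with a Mann-Whitney U test), Pearson chi-square on
2x2 contingency tables *without* continuity correction (the convention
that reproduces published baseline tables of this kind), Fisher's exact
test, and a baseline-table generator.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clinical import MarkerThresholds, derived_indices

__all__ = [
    "ContingencyTable2x2", "TestResult",
    "pearson_chi_square", "fisher_exact", "pooled_t_test",
    "mann_whitney_z", "ks_normality", "baseline_table",
]


@dataclasses.dataclass(frozen=True)
class ContingencyTable2x2:
    """Observed counts; rows = category level, columns = group (e.g.
    LN+ / LN-)."""

    a: int
    b: int
    c: int
    d: int

    def to_array(self) -> np.ndarray:
        arr = np.array([[self.a, self.b], [self.c, self.d]], dtype=float)
        if (arr < 0).any():
            raise ValueError("contingency counts must be non-negative")
        if arr.sum() == 0:
            raise ValueError("contingency table is empty")
        return arr


@dataclasses.dataclass
class TestResult:
    method: str
    statistic: float
    symbol: str          # "x2", "t", "z", "D", or "OR"
    p_value: float
    df: float | None = None
    extra: dict = dataclasses.field(default_factory=dict)


def _as_table(table) -> np.ndarray:
    if isinstance(table, ContingencyTable2x2):
        return table.to_array()
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any() or arr.sum() == 0:
        raise ValueError("invalid contingency table")
    return arr


def pearson_chi_square(table) -> TestResult:
    """Pearson chi-square on a 2x2 table, no continuity correction,
    df = 1."""
    arr = _as_table(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a zero marginal makes the "
                         "chi-square undefined")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return TestResult(method="pearson-chi-square", statistic=float(stat),
                      symbol="x2", p_value=float(p), df=float(df))


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test by hypergeometric enumeration."""
    arr = _as_table(table).astype(int)
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return TestResult(method="fisher-exact", statistic=float(odds),
                      symbol="OR", p_value=float(p))


def pooled_t_test(*args) -> TestResult:
    """Independent two-sample t-test with pooled variance.

    Either ``pooled_t_test(sample1, sample2)`` with raw arrays, or
    ``pooled_t_test(mean1, sd1, n1, mean2, sd2, n2)`` with summary
    statistics; df = n1 + n2 - 2.
    """
    if len(args) == 2:
        s1 = np.asarray(args[0], dtype=float)
        s2 = np.asarray(args[1], dtype=float)
        if len(s1) < 2 or len(s2) < 2:
            raise ValueError("each sample needs at least 2 observations")
        t, p = sps.ttest_ind(s1, s2, equal_var=True)
        df = len(s1) + len(s2) - 2
    elif len(args) == 6:
        mean1, sd1, n1, mean2, sd2, n2 = args
        if n1 < 2 or n2 < 2:
            raise ValueError("each group needs n >= 2")
        if sd1 < 0 or sd2 < 0:
            raise ValueError("standard deviations must be >= 0")
        t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                        equal_var=True)
        df = n1 + n2 - 2
    else:
        raise TypeError("pass two samples or six summary statistics")
    return TestResult(method="pooled-t", statistic=float(t), symbol="t",
                      p_value=float(p), df=float(df))


def mann_whitney_z(sample1, sample2) -> TestResult:
    """Mann-Whitney U with a normal z approximation.

    Conventions (documented constants): U is the statistic of the first
    sample; the variance is tie-corrected; a 0.5 continuity correction
    is applied toward the null mean; z is signed by U - n1*n2/2 so a
    first sample with smaller ranks gives negative z; p is two-sided.
    """
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if len(s1) == 0 or len(s2) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(s1), len(s2)
    combined = np.concatenate([s1, s2])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
                if n > 1 else 0.0)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        diff = u1 - mu
        cc = 0.5 * np.sign(diff)
        z = (diff - cc) / np.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(method="mann-whitney", statistic=float(z), symbol="z",
                      p_value=float(min(p, 1.0)),
                      extra={"U": float(u1), "U_prime": float(n1 * n2 - u1)})


def ks_normality(sample) -> TestResult:
    """One-sample Kolmogorov-Smirnov statistic against a normal with the
    sample's own mean and SD (the common baseline-table screening
    dialect); used to route continuous summaries.  A constant sample
    has no defined normal fit and raises."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 5:
        raise ValueError("normality screening needs n >= 5")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality test undefined")
    stat, p = sps.kstest(x, "norm", args=(x.mean(), sd))
    return TestResult(method="ks-normality", statistic=float(stat),
                      symbol="D", p_value=float(p))


# ----------------------------------------------------------- baseline table

def _summary_continuous(x: np.ndarray, normal: bool) -> str:
    if normal:
        return f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return f"{q50:.1f} ({q25:.1f},{q75:.1f})"


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    try:
        return ks_normality(x).p_value > alpha
    except ValueError:
        return False


DEFAULT_CONTINUOUS = ("age", "platelets", "albumin",
                      "nlr", "plr", "sii", "pni")
DEFAULT_CATEGORICAL = ("scc_ag_elevated", "ca125_elevated",
                       "ca19_9_elevated", "advanced_stage")


def baseline_table(frame: pd.DataFrame, group_col: str = "label",
                   continuous: tuple[str, ...] = DEFAULT_CONTINUOUS,
                   categorical: tuple[str, ...] = DEFAULT_CATEGORICAL,
                   alpha: float = 0.05,
                   categorical_test: str = "chi2") -> pd.DataFrame:
    """Baseline-characteristics rows comparing the two label groups.

    Expects the raw clinical columns; derives NLR/PLR/SII/PNI, the
    marker elevation flags and an advanced-stage (FIGO III-IV) flag when
    absent.  Continuous variables are routed by the K-S screen in both
    groups: normal -> mean +/- SD and pooled t; otherwise median
    (P25, P75) and Mann-Whitney.  Categorical variables get within-group
    counts (%) and a chi-square (or Fisher) test.  Missing variables are
    skipped with a ``skipped`` marker row.
    """
    df = frame.copy()
    if group_col not in df.columns:
        raise ValueError(f"group column {group_col!r} not found")
    if not set(np.unique(df[group_col])) <= {0, 1}:
        raise ValueError("grouping must be binary 0/1")
    needed_idx = {"nlr", "plr", "sii", "pni"}
    if needed_idx - set(df.columns) and {"neutrophils", "lymphocytes",
                                         "platelets",
                                         "albumin"} <= set(df.columns):
        idx = df.apply(lambda r: derived_indices(r.to_dict()), axis=1,
                       result_type="expand")
        for col in needed_idx - set(df.columns):
            df[col] = idx[col]
    marker_flags = {"scc_ag_elevated": "scc_ag", "ca125_elevated": "ca125",
                    "ca19_9_elevated": "ca19_9"}
    thresholds = MarkerThresholds()
    for flag, marker in marker_flags.items():
        if flag not in df.columns and marker in df.columns:
            # inclusive lower bound: >= threshold counts as elevated
            df[flag] = (df[marker].astype(float)
                        >= getattr(thresholds, marker)).astype(int)
    if "advanced_stage" not in df.columns and "figo_stage" in df.columns:
        df["advanced_stage"] = (df["figo_stage"] >= 3).astype(int)

    g1 = df[df[group_col] == 1]     # LN+
    g0 = df[df[group_col] == 0]     # LN-
    rows = [{"variable": "n", "group_pos": f"n={len(g1)}",
             "group_neg": f"n={len(g0)}", "p_value": np.nan,
             "test": "", "statistic": np.nan}]
    for var in continuous:
        if var not in df.columns:
            rows.append({"variable": var, "group_pos": "skipped",
                         "group_neg": "skipped", "p_value": np.nan,
                         "test": "missing-variable", "statistic": np.nan})
            continue
        x1 = g1[var].to_numpy(float)
        x0 = g0[var].to_numpy(float)
        normal = _is_normal(x1, alpha) and _is_normal(x0, alpha)
        if normal:
            res = pooled_t_test(x1, x0)
        else:
            res = mann_whitney_z(x1, x0)
        rows.append({"variable": var,
                     "group_pos": _summary_continuous(x1, normal),
                     "group_neg": _summary_continuous(x0, normal),
                     "p_value": res.p_value,
                     "test": f"{res.symbol} = {res.statistic:.3f}",
                     "statistic": res.statistic})
    for var in categorical:
        if var not in df.columns:
            rows.append({"variable": var, "group_pos": "skipped",
                         "group_neg": "skipped", "p_value": np.nan,
                         "test": "missing-variable", "statistic": np.nan})
            continue
        v1 = g1[var].astype(int)
        v0 = g0[var].astype(int)
        table = np.array([[(v1 == 0).sum(), (v0 == 0).sum()],
                          [(v1 == 1).sum(), (v0 == 1).sum()]])
        try:
            res = (fisher_exact(table) if categorical_test == "fisher"
                   else pearson_chi_square(table))
            p, label = res.p_value, f"{res.symbol} = {res.statistic:.3f}"
            stat = res.statistic
        except ValueError as exc:
            p, label, stat = np.nan, f"degenerate ({exc})", np.nan
        pct1 = 100.0 * (v1 == 1).mean() if len(v1) else np.nan
        pct0 = 100.0 * (v0 == 1).mean() if len(v0) else np.nan
        rows.append({"variable": var,
                     "group_pos": f"{(v1 == 1).sum()} ({pct1:.1f}%)",
                     "group_neg": f"{(v0 == 1).sum()} ({pct0:.1f}%)",
                     "p_value": p, "test": label, "statistic": stat})
    return pd.DataFrame(rows)
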