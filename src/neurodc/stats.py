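"""Demographics-table statistics: normality screening and group tests.

Continuous variables are screened for normality with a one-sample
Kolmogorov-Smirnov test against a Normal with the sample's own mean/SD
(optionally Lilliefors-corrected); normal-looking variables are compared
with a pooled two-sample t-test (Welch optional), the rest with a
Mann-Whitney U test.  Dichotomous variables use a Yates-corrected
chi-square.  The t-test also runs directly from printed per-group
summaries (n, mean, SD), so a published demographics table can be
checked without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .reference import GroupSummary

__all__ = [
    "ContingencyTable2x2",
    "ks_normality",
    "route_by_normality",
    "ttest_from_summary",
    "mannwhitney",
    "chi2_yates",
    "demographics_table",
]

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts: rows = group (MCI, nMCI), columns = category."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def ks_normality(sample: np.ndarray, lilliefors_correction: bool = False):
    """One-sample KS test against N(sample mean, sample SD).

    The default uses the plain KS distribution even though the Normal's
    parameters are estimated from the same sample (anti-conservative in
    principle; this mirrors common statistics-package behaviour).  Set
    ``lilliefors_correction=True`` for the corrected reference
    distribution.
    """
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 5:
        raise ValueError("need at least 5 observations")
    sd = sample.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: normality is undefined")
    if lilliefors_correction:
        stat, p = lilliefors(sample, dist="norm")
        return float(stat), float(p)
    stat, p = sps.kstest(sample, "norm", args=(sample.mean(), sd))
    return float(stat), float(p)


def route_by_normality(p_normality: float) -> str:
    """Choose the group-comparison test from the KS p-value."""
    return "t-test" if p_normality > NORMALITY_ALPHA else "mann-whitney"


def ttest_from_summary(
    g1: GroupSummary, g2: GroupSummary, variant: str = "pooled"
) -> tuple[float, float, float]:
    """Two-sample t-test from per-group (n, mean, SD) summaries.

    ``pooled`` uses the Student pooled-variance statistic with
    df = n1 + n2 - 2; ``welch`` drops the equal-variance assumption.
    Returns (t, df, two-sided p).
    """
    equal_var = {"pooled": True, "welch": False}[variant]
    res = sps.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=equal_var
    )
    if equal_var:
        df = g1.n + g2.n - 2
    else:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def mannwhitney(sample1: np.ndarray, sample2: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact null distribution for small tie-free samples; otherwise the
    normal approximation with tie correction.
    """
    sample1 = np.asarray(sample1, dtype=float)
    sample2 = np.asarray(sample2, dtype=float)
    pooled = np.concatenate([sample1, sample2])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(len(sample1), len(sample2)) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(sample1, sample2, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi2_yates(table: ContingencyTable2x2) -> tuple[float, float]:
    """Yates continuity-corrected chi-square on a 2x2 table, df = 1.

    The correction is capped so the statistic stays >= 0.  Zero row or
    column margins make the test undefined and raise.
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square is undefined")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=True)
    return float(stat), float(p)


def chi2_uncorrected(table: ContingencyTable2x2) -> tuple[float, float]:
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square is undefined")
    stat, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    odds, p = sps.fisher_exact(table.as_array())
    return float(odds), float(p)


def demographics_table(
    participants: pd.DataFrame,
    variables: list[str],
    group_col: str = "group",
    ttest_variant: str = "pooled",
    lilliefors_correction: bool = False,
) -> pd.DataFrame:
    """Per-variable group comparison in the published-table layout.

    For each requested continuous variable: mean +/- SD per group, the
    KS normality screen on each group, the routed test (pooled t if both
    groups look normal, Mann-Whitney otherwise) and its p-value.
    """
    missing = [v for v in variables if v not in participants.columns]
    if missing:
        raise ValueError(f"missing participant columns: {missing}")
    if group_col not in participants.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = sorted(participants[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    g1 = participants[participants[group_col] == groups[0]]
    g2 = participants[participants[group_col] == groups[1]]

    rows = []
    for var in variables:
        x1 = g1[var].to_numpy(dtype=float)
        x2 = g2[var].to_numpy(dtype=float)
        if np.array_equal(np.sort(x1), np.sort(x2)):
            # identical distributions by construction: nothing to test
            rows.append(
                {
                    "variable": var,
                    "group1": f"{x1.mean():.2f} ± {x1.std(ddof=1):.2f}",
                    "group2": f"{x2.mean():.2f} ± {x2.std(ddof=1):.2f}",
                    "test": "none (identical groups)",
                    "p": 1.0,
                }
            )
            continue
        _, p_norm1 = ks_normality(x1, lilliefors_correction)
        _, p_norm2 = ks_normality(x2, lilliefors_correction)
        branch = route_by_normality(min(p_norm1, p_norm2))
        if branch == "t-test":
            s1 = GroupSummary(len(x1), float(x1.mean()), float(x1.std(ddof=1)))
            s2 = GroupSummary(len(x2), float(x2.mean()), float(x2.std(ddof=1)))
            _, _, p = ttest_from_summary(s1, s2, variant=ttest_variant)
            test_name = f"{ttest_variant} t-test"
        else:
            _, p = mannwhitney(x1, x2)
            test_name = "mann-whitney"
        rows.append(
            {
                "variable": var,
                "group1": f"{x1.mean():.2f} ± {x1.std(ddof=1):.2f}",
                "group2": f"{x2.mean():.2f} ± {x2.std(ddof=1):.2f}",
                "test": test_name,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows)


def demographics_markdown(table: pd.DataFrame) -> str:
    lines = ["| Variable | Group 1 | Group 2 | Test | p |", "|---|---|---|---|---|"]
    for _, row in table.iterrows():
        lines.append(
            f"| {row['variable']} | {row['group1']} | {row['group2']} "
            f"| {row['test']} | {row['p']:.3g} |"
        )
    return "\n".join(lines) + "\n"
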