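"""Normality-gated two-group comparisons for cohort covariates and markers.

Continuous variables are tested with the pooled-variance Student t-test when
both groups pass a Kolmogorov–Smirnov normality check (Lilliefors null, since
location and scale are estimated from the sample), and with the two-sided
Mann–Whitney U test otherwise. Categorical variables use Pearson's chi-square
without continuity correction. All tests are two-sided at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

ALPHA = 0.05

#: Monte-Carlo draws for the Lilliefors null distribution of the KS distance.
LILLIEFORS_DRAWS = 10_000
_LILLIEFORS_SEED = 987_654_321  # fixed internal stream: the null table is a constant


@dataclass
class NormalityFlag:
    variable: str
    group: str
    statistic: float  # KS distance D
    p: float
    normal: bool


@dataclass
class TestResult:
    variable: str
    test: str  # STUDENT_T | MANN_WHITNEY | CHI_SQUARE
    statistic: float
    df: float | None
    p: float
    group_summaries: dict = field(default_factory=dict)
    direction: str | None = None  # for markers: higher in PFS / CONTROL / tie


def _ks_distance(x: np.ndarray) -> float:
    """KS distance between the empirical CDF and the normal fitted by
    sample mean / sample SD (ddof=1)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(cdf - (i - 1) / n, i / n - cdf)))


@lru_cache(maxsize=64)
def _lilliefors_null(n: int, draws: int = LILLIEFORS_DRAWS) -> np.ndarray:
    """Sorted null distribution of the KS distance with estimated parameters."""
    rng = np.random.default_rng([_LILLIEFORS_SEED, n])
    sims = rng.standard_normal((draws, n))
    sims.sort(axis=1)
    means = sims.mean(axis=1, keepdims=True)
    sds = sims.std(axis=1, ddof=1, keepdims=True)
    z = (sims - means) / sds
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    d = np.maximum(cdf - (i - 1) / n, i / n - cdf).max(axis=1)
    d.sort()
    return d


def ks_normality(values, variable: str = "", group: str = "") -> NormalityFlag:
    """Kolmogorov–Smirnov normality check with the Lilliefors-corrected null.

    The null distribution of D (location/scale estimated) is tabulated once
    per sample size by seeded Monte Carlo; p is the upper-tail proportion.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 4:
        raise ValueError("normality check needs n >= 4")
    if x.std(ddof=1) == 0:
        raise ValueError("zero variance sample")
    d = _ks_distance(x)
    null = _lilliefors_null(len(x))
    # (1 + #{D_null >= d}) / (B + 1): valid Monte-Carlo p-value
    p = (1 + len(null) - np.searchsorted(null, d, side="left")) / (len(null) + 1)
    return NormalityFlag(variable=variable, group=group, statistic=d, p=float(p), normal=p >= ALPHA)


def t_from_summary(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float, variable: str = ""
) -> TestResult:
    """Pooled-variance two-sided Student t-test from printed summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("negative SD")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return TestResult(variable, "STUDENT_T", 0.0, float(n1 + n2 - 2), 1.0,
                              {"group1": (mean1, sd1), "group2": (mean2, sd2)})
        raise ValueError("both SDs zero with different means")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return TestResult(
        variable=variable,
        test="STUDENT_T",
        statistic=float(t),
        df=float(n1 + n2 - 2),
        p=float(p),
        group_summaries={"group1": (mean1, sd1), "group2": (mean2, sd2)},
    )


def compare_groups_continuous(x1, x2, variable: str = "", force_test: str | None = None) -> TestResult:
    """Two-group comparison with the normality gate.

    Student t (pooled variance) if both samples pass :func:`ks_normality`
    (or when forced); otherwise two-sided Mann–Whitney U — exact when
    n1+n2 <= 20 with no ties, tie-corrected normal approximation otherwise.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs n >= 2")

    if force_test is None:
        try:
            normal = ks_normality(x1).normal and ks_normality(x2).normal
        except ValueError:  # constant or tiny sample: fall back to the rank test
            normal = False
        test = "STUDENT_T" if normal else "MANN_WHITNEY"
    else:
        test = force_test

    if test == "STUDENT_T":
        if np.array_equal(x1, x2):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(x1, x2, equal_var=True)
        return TestResult(
            variable, "STUDENT_T", float(t), float(len(x1) + len(x2) - 2), float(p),
            {"group1": (x1.mean(), x1.std(ddof=1)), "group2": (x2.mean(), x2.std(ddof=1))},
        )
    if test == "MANN_WHITNEY":
        pooled = np.concatenate([x1, x2])
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
        u, p = stats.mannwhitneyu(x1, x2, alternative="two-sided", method=method)
        q = lambda v: (np.median(v), *np.percentile(v, [25, 75]))
        return TestResult(
            variable, "MANN_WHITNEY", float(u), None, float(p),
            {"group1": q(x1), "group2": q(x2)},
        )
    raise ValueError(f"unknown test {force_test!r}")


def compare_groups_categorical(table, variable: str = "") -> TestResult:
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("negative counts")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    total = obs.sum()
    summaries = {
        "counts": obs.astype(int).tolist(),
        "percent": (100 * obs / obs.sum(axis=1, keepdims=True)).tolist(),
    }
    return TestResult(variable, "CHI_SQUARE", float(chi2), float(dof), float(p), summaries)


def _fmt_mean_sd(x: np.ndarray) -> str:
    return f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"


def _fmt_median_iqr(x: np.ndarray) -> str:
    q1, q3 = np.percentile(x, [25, 75])
    return f"{np.median(x):.1f} ({q1:.1f}–{q3:.1f})"


def summarize_cohort(table: CohortTable) -> pd.DataFrame:
    """Study-population summary: one row per covariate with per-group
    summaries (mean±SD when normal in both groups, else median (IQR);
    counts (%) for sex) and the two-group test p-value."""
    g1 = table.group_mask("PFS")
    g2 = table.group_mask("CONTROL")
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("both groups must be present with n >= 2")

    rows = []
    continuous = ["age", "bmi", "sppb", "alm", "alm_bmi", "n_diseases", "n_medications"]
    for var in continuous:
        x1 = np.asarray(getattr(table, var), dtype=float)[g1]
        x2 = np.asarray(getattr(table, var), dtype=float)[g2]
        res = compare_groups_continuous(x1, x2, variable=var)
        if res.test == "STUDENT_T":
            s1, s2 = _fmt_mean_sd(x1), _fmt_mean_sd(x2)
        else:
            s1, s2 = _fmt_median_iqr(x1), _fmt_median_iqr(x2)
        rows.append((var, s1, s2, res.test, res.p))

    f1 = int(np.sum(table.sex[g1] == "F"))
    f2 = int(np.sum(table.sex[g2] == "F"))
    n1, n2 = int(g1.sum()), int(g2.sum())
    counts = [[f1, n1 - f1], [f2, n2 - f2]]
    try:
        res = compare_groups_categorical(counts, variable="sex_female")
        p_sex = res.p
    except ValueError:
        p_sex = np.nan
    rows.insert(
        1,
        (
            "sex_female",
            f"{f1} ({100 * f1 / n1:.1f})",
            f"{f2} ({100 * f2 / n2:.1f})",
            "CHI_SQUARE",
            p_sex,
        ),
    )
    return pd.DataFrame(rows, columns=["variable", "PFS", "CONTROL", "test", "p"])


def compare_markers(table: CohortTable) -> list[TestResult]:
    """Per-marker two-group comparison with direction and box-plot summaries."""
    g1 = table.group_mask("PFS")
    g2 = table.group_mask("CONTROL")
    out = []
    for j, name in enumerate(table.marker_names):
        x1 = table.markers[g1, j]
        x2 = table.markers[g2, j]
        res = compare_groups_continuous(x1, x2, variable=name)
        dmed = np.median(x1) - np.median(x2)
        if np.array_equal(np.sort(x1), np.sort(x2)):
            res.direction = "tie"
        else:
            res.direction = "higher in PFS" if dmed > 0 else ("higher in CONTROL" if dmed < 0 else "tie")
        box = lambda v: {
            "median": float(np.median(v)),
            "q1": float(np.percentile(v, 25)),
            "q3": float(np.percentile(v, 75)),
            "min": float(v.min()),
            "max": float(v.max()),
        }
        res.group_summaries = {"PFS": box(x1), "CONTROL": box(x2)}
        out.append(res)
    return out
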