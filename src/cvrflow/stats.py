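"""Group-comparison battery for CVR study tables.

One-way, two-way (age x sex) and mixed (group x repeated condition) ANOVA,
Holm-Šidák step-down multiple-comparison adjustment, paired/unpaired
two-tailed t-tests, and the Brown-Forsythe equal-variance test.  One-way and
mixed ANOVA use the classical sums-of-squares formulas directly (they are
exercised thousands of times in calibration runs and need to be cheap); the
two-way ANOVA delegates to statsmodels OLS with Type-III sums of squares and
sum-to-zero contrasts, which also covers mildly unbalanced layouts.

The unpaired t-test pools variances by default so that the one-way ANOVA
F = t^2 identity holds exactly; Welch's correction is available by flag.
No sphericity correction is applied in the mixed ANOVA (documented
limitation; the repeated factor here has three levels measured under one
protocol).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "one_way_anova",
    "two_way_anova",
    "mixed_anova",
    "holm_sidak",
    "t_tests",
    "brown_forsythe",
]


@dataclass
class TestResult:
    comparison: str
    statistic: float
    df: tuple[float, ...]
    p: float
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p must lie in [0, 1]")
        if any(d <= 0 for d in self.df):
            raise ValueError("degrees of freedom must be positive")


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in out):
        raise ValueError("each group needs n >= 2")
    return out


def one_way_anova(groups, comparison: str = "one_way") -> TestResult:
    """Classical one-way fixed-effects ANOVA.

    F = MS_between / MS_within with df (k-1, N-k); p from the F distribution.
    Zero within-group variance with equal means leaves F undefined and is
    reported as an error.
    """
    gs = _as_groups(groups)
    k = len(gs)
    ns = np.array([len(g) for g in gs])
    N = int(ns.sum())
    means = np.array([g.mean() for g in gs])
    grand = np.concatenate(gs).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(gs, means)))
    df1, df2 = k - 1, N - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            raise ValueError("undefined F: all values identical")
        f = np.inf
        p = 0.0
    else:
        f = (ss_between / df1) / (ss_within / df2)
        p = float(sps.f.sf(f, df1, df2))
    return TestResult(comparison=comparison, statistic=float(f),
                      df=(df1, df2), p=p)


def two_way_anova(
    table: pd.DataFrame,
    factors: tuple[str, str] = ("group", "sex"),
    value: str = "value",
) -> list[TestResult]:
    """Two-factor ANOVA with interaction (Type-III SS, sum contrasts).

    ``table`` holds one row per subject with the two factor columns and the
    response.  All four cells must be non-empty.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fa, fb = factors
    counts = table.groupby([fa, fb], observed=True).size()
    la = table[fa].nunique()
    lb = table[fb].nunique()
    if len(counts) < la * lb or (counts < 1).any():
        raise ValueError("every factor-level cell must be non-empty")
    df = table.rename(columns={fa: "_A", fb: "_B", value: "_y"})
    model = smf.ols("_y ~ C(_A, Sum) * C(_B, Sum)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=3)
    name_map = {
        "C(_A, Sum)": fa,
        "C(_B, Sum)": fb,
        "C(_A, Sum):C(_B, Sum)": f"{fa}:{fb}",
    }
    out = []
    df_resid = float(aov.loc["Residual", "df"])
    for row, label in name_map.items():
        out.append(
            TestResult(
                comparison=label,
                statistic=float(aov.loc[row, "F"]),
                df=(float(aov.loc[row, "df"]), df_resid),
                p=float(aov.loc[row, "PR(>F)"]),
            )
        )
    return out


def mixed_anova(
    table: pd.DataFrame,
    between: str = "group",
    within: str = "condition",
    subject: str = "subject",
    value: str = "value",
) -> list[TestResult]:
    """Two-way repeated-measures (split-plot) ANOVA, subject as repeated unit.

    Between-subject factor tested against subjects-within-groups; the
    within-subject factor and the interaction against the subject x condition
    residual.  Every subject must appear under every condition.  No
    sphericity correction is applied.
    """
    piv = table.pivot_table(
        index=[subject, between], columns=within, values=value, observed=True
    )
    if piv.isna().any().any():
        bad = piv[piv.isna().any(axis=1)].index[0][0]
        raise ValueError(f"subject {bad!r} is missing one or more conditions")
    data = piv.to_numpy()  # (N subjects, c conditions)
    groups = piv.index.get_level_values(between).to_numpy()
    levels = pd.unique(groups)
    N, c = data.shape
    G = len(levels)
    if G < 2:
        raise ValueError("need >= 2 between-subject groups")

    grand = data.mean()
    subj_means = data.mean(axis=1)
    cond_means = data.mean(axis=0)
    ss_subjects = c * float(((subj_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())

    ng = np.array([(groups == g).sum() for g in levels])
    group_means = np.array([subj_means[groups == g].mean() for g in levels])
    ss_group = c * float((ng * (group_means - grand) ** 2).sum())
    ss_subj_within = ss_subjects - ss_group  # between-subject error

    ss_cond = N * float(((cond_means - grand) ** 2).sum())
    # group x condition cell means
    ss_cells = 0.0
    for gi, g in enumerate(levels):
        cell = data[groups == g].mean(axis=0)
        ss_cells += ng[gi] * float(
            ((cell - group_means[gi] - cond_means + grand) ** 2).sum()
        )
    ss_inter = ss_cells
    ss_within = ss_total - ss_subjects
    ss_error = ss_within - ss_cond - ss_inter

    df_group = G - 1
    df_subj = N - G
    df_cond = c - 1
    df_inter = (G - 1) * (c - 1)
    df_error = (N - G) * (c - 1)

    def _res(label, ss, df1, ss_err, df2):
        if ss_err <= 0:
            raise ValueError(f"zero error variance for {label}")
        f = (ss / df1) / (ss_err / df2)
        return TestResult(
            comparison=label, statistic=float(f), df=(df1, df2),
            p=float(sps.f.sf(f, df1, df2)),
        )

    return [
        _res(between, ss_group, df_group, ss_subj_within, df_subj),
        _res(within, ss_cond, df_cond, ss_error, df_error),
        _res(f"{between}:{within}", ss_inter, df_inter, ss_error, df_error),
    ]


def holm_sidak(pvalues, alpha: float = 0.05) -> pd.DataFrame:
    """Holm-Šidák step-down adjustment.

    Sorting the m p-values ascending, step k gets adjusted
    p = 1 - (1 - p)^(m - k + 1); rejection proceeds while adjusted p < alpha
    and stops at the first failure.  Adjusted values are made monotone
    non-decreasing by a running maximum.  Returns a DataFrame in the original
    input order with columns p, p_adjusted, reject.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    reject_sorted = np.zeros(m, dtype=bool)
    for k in range(m):
        if adj_sorted[k] < alpha:
            reject_sorted[k] = True
        else:
            break
    adjusted = np.empty(m)
    reject = np.empty(m, dtype=bool)
    adjusted[order] = adj_sorted
    reject[order] = reject_sorted
    return pd.DataFrame({"p": p, "p_adjusted": adjusted, "reject": reject})


def t_tests(
    a,
    b,
    paired: bool = False,
    welch: bool = False,
    comparison: str | None = None,
) -> TestResult:
    """Two-tailed t-test, paired or unpaired (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal lengths")
        if len(a) < 2:
            raise ValueError("need n >= 2 pairs")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            raise ValueError("zero-variance differences; paired t undefined")
        res = sps.ttest_rel(a, b)
        df = (float(len(a) - 1),)
        label = comparison or "paired_t"
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each sample needs n >= 2")
        res = sps.ttest_ind(a, b, equal_var=not welch)
        df = (float(res.df),)
        label = comparison or ("welch_t" if welch else "unpaired_t")
    return TestResult(
        comparison=label, statistic=float(res.statistic), df=df,
        p=float(res.pvalue),
    )


def brown_forsythe(groups, comparison: str = "brown_forsythe") -> TestResult:
    """Brown-Forsythe equal-variance test: one-way ANOVA on absolute
    deviations from the group medians."""
    gs = _as_groups(groups)
    stat, p = sps.levene(*gs, center="median")
    k = len(gs)
    N = sum(len(g) for g in gs)
    return TestResult(
        comparison=comparison, statistic=float(stat), df=(k - 1, N - k),
        p=float(p),
    )
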