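"""Four-group polygenic-score comparisons.

Individuals with both an insomnia classification (ISI total > 8) and a
sleep-duration label are assigned to one of four quadrants:

1. short sleep + insomnia
2. short sleep + no insomnia
3. normal/long sleep + insomnia
4. normal/long sleep + no insomnia

Polygenic scores (one per twin pair, carried by twin 1; three p-value
thresholds) are compared across quadrants by one-way ANOVA, by an
age/sex-adjusted ANCOVA, and by a pooled-variance t-test of quadrant 1
against quadrant 3.  Tukey HSD post-hoc comparisons are attached when
the ANOVA is significant; no multiple-testing correction is applied when
every omnibus test is non-significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scales import classify_insomnia, classify_sleep_duration, SHORT
from .synthetic_cohort import PGS_COLUMNS

__all__ = [
    "assign_quadrant",
    "one_way_anova",
    "ancova_adjusted",
    "two_sample_t",
    "tukey_posthoc",
    "PgsTestReport",
    "pgs_quadrant_report",
    "pgs_table",
]

QUADRANT_LABELS = {
    1: "short sleep + insomnia",
    2: "short sleep + no insomnia",
    3: "normal/long sleep + insomnia",
    4: "normal/long sleep + no insomnia",
}


def assign_quadrant(isi_total: float, sleep_label: str) -> int | None:
    """Quadrant 1-4 from the insomnia cut-off and the sleep label.

    Returns ``None`` when either input is missing (callers count the
    exclusion).
    """
    if sleep_label is None or isi_total is None or not np.isfinite(isi_total):
        return None
    insomnia = classify_insomnia(isi_total)
    short = sleep_label == SHORT
    if short:
        return 1 if insomnia else 2
    return 3 if insomnia else 4


def _group_arrays(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = []
    for lab in pd.unique(labels):
        v = values[labels == lab]
        v = v[np.isfinite(v)]
        if v.size:
            groups.append(v)
    return groups


def one_way_anova(values, labels) -> tuple[float, float]:
    """Classical between/within F test with (k-1, n-k) df."""
    groups = _group_arrays(values, labels)
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n = sum(g.size for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within <= 0:
        if ss_between <= 0:
            raise ValueError("all values identical; F undefined")
        return float("inf"), 0.0
    f = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = float(stats.f.sf(f, k - 1, n - k))
    return float(f), p


def ancova_adjusted(values, labels, covariates) -> tuple[float, float]:
    """Covariate-adjusted group test: residualize, then F with reduced df.

    The values are residualized on the covariates by pooled OLS
    (intercept included), the between/within sums of squares are formed
    on the residuals, and the denominator df is reduced by the number of
    covariates: F has (k-1, n-k-p) df.  This is a residualized-ANOVA
    approximation to the general-linear-model ANCOVA.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    ok = np.isfinite(values) & np.isfinite(X).all(axis=1)
    values, labels, X = values[ok], labels[ok], X[ok]

    design = np.column_stack([np.ones(len(values)), X])
    # drop constant covariate columns (they duplicate the intercept)
    keep = [0] + [j for j in range(1, design.shape[1])
                  if np.ptp(design[:, j]) > 0]
    design = design[:, keep]
    p_cov = design.shape[1] - 1
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ beta

    groups = _group_arrays(resid, labels)
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n = sum(g.size for g in groups)
    k = len(groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df2 = n - k - p_cov
    if df2 < 1:
        raise ValueError("not enough residual degrees of freedom")
    if ss_within <= 0:
        raise ValueError("zero residual variance; F undefined")
    f = (ss_between / (k - 1)) / (ss_within / df2)
    return float(f), float(stats.f.sf(f, k - 1, df2))


def two_sample_t(group1, group2) -> tuple[float, float]:
    """Two-sided Student (pooled-variance) t-test."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    n1, n2 = a.size, b.size
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) \
        / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance; t undefined")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), n1 + n2 - 2))
    return float(t), p


def tukey_posthoc(values, labels) -> pd.DataFrame:
    """All-pairs Tukey HSD comparisons (used after a significant ANOVA)."""
    labels = np.asarray(labels)
    uniq = list(pd.unique(labels))
    groups = [np.asarray(values, dtype=float)[labels == lab] for lab in uniq]
    groups = [g[np.isfinite(g)] for g in groups]
    res = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            rows.append({"group_a": uniq[i], "group_b": uniq[j],
                         "diff": float(np.mean(groups[i]) - np.mean(groups[j])),
                         "p": float(res.pvalue[i, j])})
    return pd.DataFrame(rows)


@dataclass
class PgsTestReport:
    """Per-threshold descriptive and inferential summary."""

    threshold: str
    n_by_quadrant: dict[int, int]
    mean_by_quadrant: dict[int, float]
    sd_by_quadrant: dict[int, float]
    anova_f: float
    anova_p: float
    ancova_f: float
    ancova_p: float
    t_1_vs_3: float
    p_1_vs_3: float
    n_excluded: int
    empty_quadrants: tuple[int, ...] = ()
    posthoc: pd.DataFrame | None = field(default=None, repr=False)
    multiple_testing_note: str = ""


def pgs_quadrant_report(cohort: pd.DataFrame,
                        pgs_cols: tuple[str, ...] = PGS_COLUMNS,
                        alpha: float = 0.05) -> list[PgsTestReport]:
    """Table-4-style report: one entry per polygenic-score threshold.

    The polygenic score belongs to twin 1 of each pair, so the analysis
    set is one individual per pair, classified by twin 1's own ISI total
    and sleep duration.
    """
    isi = cohort["isi1"].to_numpy(dtype=float)
    hours = cohort["hours1"].to_numpy(dtype=float)
    labels = np.array([classify_sleep_duration(h) if np.isfinite(h) else None
                       for h in hours], dtype=object)
    quad = np.array([assign_quadrant(t, lab) if lab is not None else None
                     for t, lab in zip(isi, labels)], dtype=object)
    age = cohort["age"].to_numpy(dtype=float)
    female = (cohort["sex1"].astype(str) == "F").to_numpy(dtype=float)

    reports = []
    for col in pgs_cols:
        pgs = cohort[col].to_numpy(dtype=float)
        ok = np.array([q is not None for q in quad]) & np.isfinite(pgs)
        q = quad[ok].astype(int)
        v = pgs[ok]
        n_excluded = int(len(cohort) - ok.sum())
        means, sds, ns = {}, {}, {}
        empty = []
        for g in (1, 2, 3, 4):
            vals = v[q == g]
            ns[g] = int(vals.size)
            if vals.size:
                means[g] = float(vals.mean())
                sds[g] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
            else:
                means[g] = sds[g] = float("nan")
                empty.append(g)
        f, p = one_way_anova(v, q)
        fa, pa = ancova_adjusted(v, q, np.column_stack([age[ok], female[ok]]))
        t, pt = two_sample_t(v[q == 1], v[q == 3])
        all_p = [p, pa, pt]
        posthoc = tukey_posthoc(v, q) if p < alpha else None
        note = ("no multiple-testing correction applied: no test reached "
                f"the {alpha} significance level"
                if all(x > alpha for x in all_p) else "")
        reports.append(PgsTestReport(
            threshold=col, n_by_quadrant=ns, mean_by_quadrant=means,
            sd_by_quadrant=sds, anova_f=f, anova_p=p, ancova_f=fa,
            ancova_p=pa, t_1_vs_3=t, p_1_vs_3=pt, n_excluded=n_excluded,
            empty_quadrants=tuple(empty), posthoc=posthoc,
            multiple_testing_note=note))
    return reports


def pgs_table(reports: list[PgsTestReport]) -> pd.DataFrame:
    """Flatten quadrant means/SDs and test results into a tidy frame."""
    rows = []
    for rep in reports:
        for g in (1, 2, 3, 4):
            rows.append({
                "threshold": rep.threshold, "quadrant": g,
                "label": QUADRANT_LABELS[g], "n": rep.n_by_quadrant[g],
                "mean_pgs": rep.mean_by_quadrant[g],
                "sd_pgs": rep.sd_by_quadrant[g],
                "anova_f": rep.anova_f, "anova_p": rep.anova_p,
                "ancova_f": rep.ancova_f, "ancova_p": rep.ancova_p,
                "t_1_vs_3": rep.t_1_vs_3, "p_1_vs_3": rep.p_1_vs_3,
            })
    return pd.DataFrame(rows)
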