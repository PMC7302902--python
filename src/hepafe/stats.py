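"""Agreement and discrimination statistics for multi-method LIC studies.

Covers the analysis battery of a two-rater, patient/control method-comparison
study: Shapiro-Wilk-gated group comparison (Student's t vs Mann-Whitney),
Yates-corrected chi-square for 2×2 tables, Spearman correlation, the paired
mean-difference t-test, two-way intraclass correlation (absolute agreement,
single measures) with its F-based confidence interval, and ROC analysis with
DeLong variance for AUC confidence intervals and paired AUC comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "Contingency2x2",
    "ROCResult",
    "ICCResult",
    "validate_rating_table",
    "rating_matrix",
    "icc_two_way",
    "mean_difference_test",
    "roc_auc",
    "compare_auc_paired",
    "chi_square_2x2",
    "spearman_rho",
    "group_compare",
]

RATING_COLUMNS = ("subject_id", "group", "method", "rater", "repeat", "estimate")


def validate_rating_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy rating-table contract: required columns, unique reads."""
    missing = [c for c in RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"rating table is missing columns {missing}")
    dup = df.duplicated(subset=["subject_id", "method", "rater", "repeat"])
    if dup.any():
        raise ValueError("duplicate (subject, method, rater, repeat) reads")
    return df


def rating_matrix(
    df: pd.DataFrame, method: str, by: str = "rater", repeat: int | None = 1
) -> np.ndarray:
    """Pivot one method's reads to a complete subjects × raters/repeats matrix.

    ``by='rater'`` compares the raters (fixing ``repeat``); ``by='repeat'``
    compares rater 1's repeated reads.  Missing cells raise — agreement
    statistics here do not impute.
    """
    sel = df[df["method"] == method]
    if by == "rater":
        sel = sel[sel["repeat"] == repeat] if repeat is not None else sel
        wide = sel.pivot(index="subject_id", columns="rater", values="estimate")
    elif by == "repeat":
        sel = sel[sel["rater"] == 1]
        wide = sel.pivot(index="subject_id", columns="repeat", values="estimate")
    else:
        raise ValueError("by must be 'rater' or 'repeat'")
    if wide.isna().any().any():
        raise ValueError("incomplete two-way layout: missing cells")
    return wide.to_numpy(dtype=float)


# --------------------------------------------------------------------------
# intraclass correlation


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    ms_rows: float
    ms_cols: float
    ms_err: float
    n_subjects: int
    n_raters: int
    definition: str


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    n, k = x.shape
    grand = x.mean()
    rows = x.mean(axis=1)
    cols = x.mean(axis=0)
    msr = k * np.sum((rows - grand) ** 2) / (n - 1)
    msc = n * np.sum((cols - grand) ** 2) / (k - 1)
    resid = x - rows[:, None] - cols[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_two_way(
    table: np.ndarray | pd.DataFrame,
    definition: str = "A-1",
    alpha: float = 0.05,
) -> ICCResult:
    """Two-way single-measures intraclass correlation with 95% CI.

    ``table`` is a complete subjects × raters matrix (n ≥ 2 rows, k ≥ 2
    columns; NaN cells raise).  The default definition ``A-1`` is the
    two-way random-effects, absolute-agreement, single-measures coefficient

        ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E)),

    with the standard F-based confidence interval (Satterthwaite degrees of
    freedom).  ``C-1`` (consistency) is exposed as an alternative.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a complete n>=2 subjects x k>=2 raters matrix")
    if np.isnan(x).any():
        raise ValueError("missing cells in rating matrix")
    n, k = x.shape
    msr, msc, mse = _mean_squares(x)

    if definition == "C-1":
        denom = msr + (k - 1) * mse
        icc = (msr - mse) / denom if denom > 0 else 1.0
        fstat = msr / mse if mse > 0 else np.inf
        fl = fstat / sps.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        fu = fstat * sps.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
        return ICCResult(float(icc), ci, msr, msc, mse, n, k, definition)
    if definition != "A-1":
        raise ValueError(f"unknown ICC definition {definition!r}")

    if mse == 0 and msc == 0:
        # identical raters: perfect absolute agreement
        return ICCResult(1.0, (1.0, 1.0), msr, msc, mse, n, k, definition)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        ci = (1.0, 1.0)
    else:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
        ci = (float(lower), float(upper))
    return ICCResult(float(icc), ci, msr, msc, mse, n, k, definition)


# --------------------------------------------------------------------------
# paired mean difference


def mean_difference_test(a, b, alpha: float = 0.05) -> tuple[float, tuple[float, float], float]:
    """Mean of paired differences with t-based 95% CI and two-sided p.

    Tests whether the mean difference between two paired read series equals
    zero.  Zero-variance differences follow the convention p = 1 when all
    differences are zero and p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired samples of equal length >= 3")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    n = d.size
    if sd == 0:
        return mean, (mean, mean), (1.0 if mean == 0 else 0.0)
    se = sd / np.sqrt(n)
    tcrit = sps.t.ppf(1 - alpha / 2, n - 1)
    t = mean / se
    p = 2 * sps.t.sf(abs(t), n - 1)
    return mean, (mean - tcrit * se, mean + tcrit * se), float(p)


# --------------------------------------------------------------------------
# ROC / AUC with DeLong variance


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    return y


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_structural(scores: np.ndarray, y: np.ndarray):
    """DeLong placement components for one score vector.

    Returns (auc, v_pos, v_neg): the per-positive and per-negative placement
    values whose variances/covariances give the AUC variance estimate.
    """
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v_pos = (all_r[:m] - pos_r) / n  # P(score_neg < score_pos | this pos)
    v_neg = 1.0 - (all_r[m:] - neg_r) / m
    return float(auc), v_pos, v_neg


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance estimate."""
    y = _check_labels(labels)
    auc, v_pos, v_neg = _delong_structural(np.asarray(scores, dtype=float), y)
    m, n = v_pos.size, v_neg.size
    var = np.var(v_pos, ddof=1) / m + np.var(v_neg, ddof=1) / n
    return auc, float(var)


def roc_auc(scores, labels, alpha: float = 0.05) -> ROCResult:
    """Empirical ROC curve, trapezoid AUC, and DeLong 95% CI.

    The trapezoid AUC over the empirical curve equals the tie-corrected
    Mann-Whitney statistic U/(n_pos·n_neg).  The CI is the Wald interval with
    DeLong's variance, clipped to [0, 1].
    """
    y = _check_labels(labels)
    s = np.asarray(scores, dtype=float)
    fpr, tpr, thr = _sk_roc_curve(y, s)
    auc_trap = float(np.trapezoid(tpr, fpr))
    auc, var = delong_auc_variance(s, y)
    se = np.sqrt(var)
    z = sps.norm.ppf(1 - alpha / 2)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    # trapezoid and Mann-Whitney forms agree; keep the trapezoid value
    assert abs(auc_trap - auc) < 1e-10
    return ROCResult(auc_trap, ci, int(y.sum()), int((1 - y).sum()), fpr, tpr, thr)


def compare_auc_paired(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong's paired test for the difference of two correlated AUCs.

    Both score vectors must rate the same subjects.  Returns
    (auc_a − auc_b, two-sided p).  Identical score vectors give p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    y = _check_labels(labels)
    auc_a, vp_a, vn_a = _delong_structural(a, y)
    auc_b, vp_b, vn_b = _delong_structural(b, y)
    m, n = vp_a.size, vn_a.size
    cov_pos = np.cov(vp_a, vp_b, ddof=1)
    cov_neg = np.cov(vn_a, vn_b, ddof=1)
    var = (
        cov_pos[0, 0] / m + cov_pos[1, 1] / m - 2 * cov_pos[0, 1] / m
        + cov_neg[0, 0] / n + cov_neg[1, 1] / n - 2 * cov_neg[0, 1] / n
    )
    diff = auc_a - auc_b
    if var <= 0:
        return diff, 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return float(diff), float(2 * sps.norm.sf(abs(z)))


# --------------------------------------------------------------------------
# classical tests


@dataclass(frozen=True)
class Contingency2x2:
    """2×2 contingency table with non-negative integer cells."""

    cells: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("a", "b")
    col_labels: tuple[str, str] = ("x", "y")

    def __post_init__(self) -> None:
        arr = np.asarray(self.cells)
        if arr.shape != (2, 2) or np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("cells must be a 2x2 array of non-negative integers")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.cells)


def chi_square_2x2(
    table: Contingency2x2 | np.ndarray, correction: bool = True
) -> tuple[float, float]:
    """Chi-square test of independence on a 2×2 table.

    Yates' continuity correction is applied by default, as is conventional
    for 2×2 tables at these sample sizes.  Returns (statistic, p).
    """
    arr = table.array if isinstance(table, Contingency2x2) else np.asarray(table)
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    res = sps.chi2_contingency(arr, correction=correction)
    return float(res[0]), float(res[1])


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired vectors of length >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass(frozen=True)
class GroupComparison:
    test: str  # "t" | "mann-whitney"
    statistic: float
    p: float
    shapiro_p: tuple[float, float]


def group_compare(values, groups, alpha_normality: float = 0.05) -> GroupComparison:
    """Two-group comparison gated by Shapiro-Wilk normality tests.

    Each group is tested for normality at ``alpha_normality``; if both pass,
    Student's t-test for independent samples runs, otherwise the
    Mann-Whitney-Wilcoxon test.  The result records which pathway ran.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError("need exactly two groups")
    g1 = values[groups == levels[0]]
    g2 = values[groups == levels[1]]
    if g1.size < 3 or g2.size < 3:
        raise ValueError("each group needs at least 3 observations")
    p1 = float(sps.shapiro(g1).pvalue)
    p2 = float(sps.shapiro(g2).pvalue)
    if p1 > alpha_normality and p2 > alpha_normality:
        res = sps.ttest_ind(g1, g2, equal_var=True)
        return GroupComparison("t", float(res.statistic), float(res.pvalue), (p1, p2))
    res = sps.mannwhitneyu(g1, g2, alternative="two-sided")
    return GroupComparison("mann-whitney", float(res.statistic), float(res.pvalue), (p1, p2))
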