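"""Agreement, error and diagnostic-accuracy statistics.

Squared-error tables, Spearman rank correlation, Bland-Altman agreement with
fixed/proportional bias tests, Friedman omnibus with Holm-adjusted posthoc
p-values, paired/unpaired rank tests, ROC/AUC with the DeLong comparison of
correlated AUCs, and LLN-based screening confusion rates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BlandAltmanResult",
    "RocResult",
    "DeLongResult",
    "squared_error_table",
    "spearman",
    "bland_altman",
    "friedman",
    "holm_adjust",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "roc_auc",
    "delong_test",
    "screening_confusion",
    "screening_score",
    "partial_correlation_matrix",
]


# ---------------------------------------------------------------- errors


def squared_error_table(measured, estimates: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-observation squared error per method, with mean/median summary
    rows accessible via ``df.attrs['mean']`` / ``df.attrs['median']``."""
    measured = np.asarray(measured, dtype=float)
    cols = {}
    for name, est in estimates.items():
        est = np.asarray(est, dtype=float)
        if est.shape != measured.shape:
            raise ValueError(f"length mismatch for method {name!r}")
        cols[name] = (est - measured) ** 2
    df = pd.DataFrame(cols)
    df.attrs["mean"] = df.mean().to_dict()
    df.attrs["median"] = df.median().to_dict()
    return df


# ----------------------------------------------------------- correlation


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with its p-value; exact
    permutation p for n <= 8, t-approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant vector")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 8:
        observed = abs(rho)
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r = float(np.corrcoef(rx[list(perm)], ry)[0, 1])
            total += 1
            if abs(r) >= observed - 1e-12:
                count += 1
        return rho, count / total
    t = rho * np.sqrt((n - 2) / max(1 - rho**2, np.finfo(float).tiny))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


def partial_correlation_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Pairwise partial correlations controlling for all remaining columns
    (inverse-correlation-matrix method). Utility for variable screening."""
    corr = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    prec = np.linalg.pinv(corr)
    d = np.sqrt(np.diag(prec))
    pcorr = -prec / np.outer(d, d)
    np.fill_diagonal(pcorr, 1.0)
    return pd.DataFrame(pcorr, index=df.columns, columns=df.columns)


# ---------------------------------------------------------- Bland-Altman


@dataclass(frozen=True)
class BlandAltmanResult:
    """Difference statistics for measured - estimated, with limits of
    agreement at mean +/- ``sd_multiplier`` * SD (default 2, not 1.96)."""

    mean_diff: float
    sd_diff: float
    limits: tuple[float, float]
    fixed_bias_t: float | None
    fixed_bias_p: float | None
    proportional_bias_r: float | None
    proportional_bias_p: float | None
    sd_multiplier: float = 2.0
    orientation: str = "measured - estimated"


def bland_altman(measured, estimated, sd_multiplier: float = 2.0) -> BlandAltmanResult:
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if measured.size != estimated.size or measured.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    diffs = measured - estimated
    means = (measured + estimated) / 2.0
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    limits = (mean_diff - sd_multiplier * sd_diff, mean_diff + sd_multiplier * sd_diff)
    if sd_diff > 0:
        t_stat, t_p = stats.ttest_1samp(diffs, 0.0)
        t_stat, t_p = float(t_stat), float(t_p)
    else:
        t_stat = t_p = None  # zero-variance differences: t undefined
    if np.ptp(diffs) > 0 and np.ptp(means) > 0:
        r, r_p = stats.pearsonr(diffs, means)
        r, r_p = float(r), float(r_p)
    else:
        r = r_p = None
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        limits=limits,
        fixed_bias_t=t_stat,
        fixed_bias_p=t_p,
        proportional_bias_r=r,
        proportional_bias_p=r_p,
        sd_multiplier=sd_multiplier,
    )


# ------------------------------------------------------- omnibus/posthoc


def friedman(matrix) -> tuple[float, float]:
    """Friedman rank test on an (n subjects x k methods) matrix; midrank
    ties with tie correction; chi-square p on k-1 df."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need an (n >= 2) x (k) matrix")
    n, k = matrix.shape
    if k < 3:
        raise ValueError("Friedman requires k >= 3 methods; use a paired test")
    if np.all(np.ptp(matrix, axis=1) == 0):
        return 0.0, 1.0  # every row fully tied: no evidence of differences
    stat, p = stats.friedmanchisquare(*matrix.T)
    return float(stat), float(p)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        running_max = max(running_max, (m - rank) * p[idx])
        adjusted[idx] = min(running_max, 1.0)
    return adjusted


def wilcoxon_signed_rank(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Paired signed-rank test; zero differences dropped; exact p for
    n <= 12 non-zero pairs, normal approximation with corrections above."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("signed-rank requires paired equal-length vectors")
    d = x - y
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all pairs tied: signed-rank undefined")
    mode = "exact" if nz.size <= 12 else "approx"
    res = stats.wilcoxon(
        x, y, zero_method="wilcox", correction=(mode == "approx"), method=mode,
        alternative=alternative,
    )
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float]:
    """Unpaired rank-sum test; exact for small tie-free samples, normal
    approximation with tie/continuity correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    small = x.size <= 8 and y.size <= 8
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if small and not ties else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ------------------------------------------------------------- screening


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    positive_definition: str = "measured VC < LLN"
    score_definition: str = "LLN - estimated VC (higher = more abnormal)"


def screening_score(estimates, lln_values) -> np.ndarray:
    """Continuous abnormality score: LLN - estimate. Thresholding at 0
    reproduces the decision rule 'estimate < LLN'."""
    return np.asarray(lln_values, dtype=float) - np.asarray(estimates, dtype=float)


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    # Midrank placement values; AUC is their mean (Mann-Whitney with ties 1/2)
    m, n = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)
    pos_ranks = ranks[:m]
    neg_ranks = ranks[m:]
    v10 = (pos_ranks - stats.rankdata(pos)) / n  # per-positive placements
    v01 = 1.0 - (neg_ranks - stats.rankdata(neg)) / m  # per-negative
    auc = float(v10.mean())
    return v10, v01, auc


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC; AUC via midrank placements, equal to brute-force
    pair counting with ties scored 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    pos, neg = scores[labels], scores[~labels]
    _, _, auc = _placements(pos, neg)
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p: float
    variance: float
    degenerate: bool = False


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong comparison of two correlated AUCs on the same subjects.

    Uses the placement-value (structural component) covariance estimate;
    a zero-variance difference is reported as degenerate with p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not (scores_a.size == scores_b.size == labels.size):
        raise ValueError("paired scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    pos = labels
    m, n = int(pos.sum()), int((~pos).sum())
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    aucs = np.empty(2)
    for k, s in enumerate((scores_a, scores_b)):
        v10[k], v01[k], aucs[k] = _placements(s[pos], s[~pos])
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = float(aucs[0] - aucs[1])
    if var_diff <= 0:
        return DeLongResult(
            auc_a=float(aucs[0]), auc_b=float(aucs[1]), z=0.0, p=1.0,
            variance=max(var_diff, 0.0), degenerate=True,
        )
    z = diff / np.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z)))
    return DeLongResult(
        auc_a=float(aucs[0]), auc_b=float(aucs[1]), z=float(z), p=p, variance=var_diff
    )


def screening_confusion(estimates, measured, lln_values) -> dict[str, float]:
    """Confusion rates for the rule predicted-positive <=> estimate < LLN,
    against true-positive <=> measured < LLN. TPR + FNR = 1 exactly."""
    estimates = np.asarray(estimates, dtype=float)
    measured = np.asarray(measured, dtype=float)
    lln_values = np.asarray(lln_values, dtype=float)
    if not (estimates.size == measured.size == lln_values.size):
        raise ValueError("length mismatch")
    truth = measured < lln_values
    pred = estimates < lln_values
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    if n_pos == 0:
        raise ValueError("no positive-class subjects (measured VC < LLN)")
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    tpr = tp / n_pos
    fpr = fp / n_neg if n_neg else float("nan")
    return {
        "TPR": tpr,
        "FNR": 1.0 - tpr,
        "FPR": fpr,
        "TNR": 1.0 - fpr if n_neg else float("nan"),
    }
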