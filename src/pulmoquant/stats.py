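"""Cohort-level statistics: normality screening, two-group comparisons,
correlation with mPAP, and ROC analysis with an optimal cutoff.

The comparison layer mirrors a classic two-arm diagnostic study: unpaired
t-tests at alpha = 0.05 per metric (Welch by default, Student pooled
variance available), Shapiro-Wilk normality checks, Pearson correlation
against invasive mPAP, and a ROC curve for the most discriminative metric
with the cutoff maximizing Youden's J (sensitivity + specificity - 1;
ties break toward the higher specificity). No multiple-testing correction
is applied, which is flagged in the rendered report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

POSITIVE_GROUP = "PH"  # higher score => PH by convention


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    df: Optional[float] = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class GroupSummary:
    """mean +/- SD per group for one metric, with its two-group test."""

    metric: str
    n: dict[str, int]
    mean: dict[str, float]
    sd: dict[str, float]
    test: TestResult
    significant: bool


@dataclass
class ROCResult:
    fpr: np.ndarray  # 1 - specificity, nondecreasing
    tpr: np.ndarray  # sensitivity, nondecreasing
    thresholds: np.ndarray
    auc: float
    optimal_cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    criterion: str = "youden"


def _as_clean_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def shapiro_wilk(values: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000, non-constant)."""
    arr = _as_clean_array(values, "sample")
    if arr.size < 3 or arr.size > 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(arr) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(arr)
    return TestResult(statistic=float(w), p_value=float(p), test_name="shapiro-wilk")


def unpaired_t_test(a: Sequence[float], b: Sequence[float],
                    variant: str = "welch") -> TestResult:
    """Two-sided unpaired t-test; ``welch`` (default) or ``student``."""
    if variant not in ("welch", "student"):
        raise ValueError("variant must be 'welch' or 'student'")
    xa = _as_clean_array(a, "a")
    xb = _as_clean_array(b, "b")
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(xa) == 0 and np.ptp(xb) == 0:
        raise ValueError("t-test undefined: both groups have zero variance")
    res = sps.ttest_ind(xa, xb, equal_var=(variant == "student"))
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=float(res.df), test_name=f"t-{variant}")


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with a two-sided p-value via the t transform."""
    xa = _as_clean_array(x, "x")
    ya = _as_clean_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must be paired")
    if xa.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    r, p = sps.pearsonr(xa, ya)
    return TestResult(statistic=float(r), p_value=float(p), test_name="pearson")


def roc_analysis(scores: Sequence[float], labels: Sequence,
                 positive=POSITIVE_GROUP, criterion: str = "youden") -> ROCResult:
    """ROC curve over all distinct thresholds, trapezoidal AUC, and the
    optimal cutoff.

    The positive direction is higher score => positive class. ``youden``
    (default) maximizes J = sensitivity + specificity - 1; ``accuracy``
    maximizes classification accuracy. Ties break toward the higher
    specificity. A subject is called positive when score >= cutoff.
    """
    if criterion not in ("youden", "accuracy"):
        raise ValueError("criterion must be 'youden' or 'accuracy'")
    s = _as_clean_array(scores, "scores")
    y = np.asarray([lab == positive for lab in labels], dtype=bool)
    if y.all() or not y.any():
        raise ValueError("ROC analysis needs both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if criterion == "youden":
        objective = tpr - fpr
    else:
        objective = (tpr * n_pos + (1.0 - fpr) * n_neg) / (n_pos + n_neg)
    best = objective.max()
    tied = np.nonzero(np.isclose(objective, best))[0]
    idx = tied[np.argmin(fpr[tied])]  # highest specificity among ties
    cutoff = float(thr[idx])
    if not np.isfinite(cutoff):  # sklearn's sentinel above the top score
        cutoff = float(s.max()) + 1.0
    return ROCResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
                     optimal_cutoff=cutoff,
                     sensitivity_at_cutoff=float(tpr[idx]),
                     specificity_at_cutoff=float(1.0 - fpr[idx]),
                     criterion=criterion)


def summarize_cohort(table: pd.DataFrame, metrics: Sequence[str],
                     group_col: str = "group", alpha: float = 0.05,
                     variant: str = "welch") -> list[GroupSummary]:
    """Per-metric group means +/- SD and two-group tests.

    Missing values (e.g. undefined ratios) are excluded pairwise, with the
    per-group n reported after exclusion; each group must retain n >= 2.
    """
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    out: list[GroupSummary] = []
    for metric in metrics:
        sub = table[[group_col, metric]].dropna()
        samples = {g: sub.loc[sub[group_col] == g, metric].to_numpy(dtype=float)
                   for g in groups}
        for g, arr in samples.items():
            if arr.size < 2:
                raise ValueError(f"group {g!r} has n < 2 for metric {metric!r}")
        test = unpaired_t_test(samples[groups[0]], samples[groups[1]], variant=variant)
        test.alpha = alpha
        out.append(GroupSummary(
            metric=metric,
            n={g: int(v.size) for g, v in samples.items()},
            mean={g: float(v.mean()) for g, v in samples.items()},
            sd={g: float(v.std(ddof=1)) for g, v in samples.items()},
            test=test,
            significant=test.significant,
        ))
    return out


def render_summary_table(summaries: Sequence[GroupSummary]) -> str:
    """Markdown table of group summaries (mean +/- SD, p, flag)."""
    if not summaries:
        return ""
    groups = list(summaries[0].mean.keys())
    header = "| metric | " + " | ".join(f"{g} (mean ± SD, n)" for g in groups) + " | p | sig |"
    rule = "|" + "---|" * (len(groups) + 3)
    lines = [header, rule]
    for s in summaries:
        cells = [f"{s.mean[g]:.4g} ± {s.sd[g]:.4g} (n={s.n[g]})" for g in groups]
        lines.append("| " + s.metric + " | " + " | ".join(cells)
                     + f" | {s.test.p_value:.4g} | {'*' if s.significant else ''} |")
    lines.append("")
    lines.append("No multiple-testing correction applied.")
    return "\n".join(lines)
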