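"""Diagnostic performance metrics with exact binomial confidence intervals.

Sensitivity, specificity and accuracy are simple binomial proportions, so
their 95% intervals are the exact Clopper-Pearson intervals (the
convention of clinical diagnostic-test calculators).  AUC is the
Mann-Whitney statistic with ties counted 1/2, with a DeLong variance for
its confidence interval.  The combined-diagnostic-panel (CDP) rule calls a
sample positive if any of the three conventional serum markers (CEA,
CA19-9, CA72-4) exceeds its clinical cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RocCurve",
    "clopper_pearson",
    "confusion_metrics",
    "metrics_from_counts",
    "roc_auc",
    "cdp_classify",
    "CDP_CUTOFFS",
    "round3",
]

#: Conventional clinical positivity cutoffs (CEA ng/mL, CA19-9 U/mL,
#: CA72-4 U/mL); overridable wherever they are consumed.
CDP_CUTOFFS = {"cea": 5.0, "ca199": 37.0, "ca724": 6.9}


def round3(x: float) -> float:
    """Half-up rounding to 3 decimals, as printed in clinical tables."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"),
                                                  rounding=ROUND_HALF_UP))


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval for x successes of n."""
    if n == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(x, n, alpha=1 - level, method="beta")
    lo = 0.0 if np.isnan(lo) else float(lo)
    hi = 1.0 if np.isnan(hi) else float(hi)
    return lo, hi


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Point estimates with exact 95% CIs, as a clinical table row."""

    counts: ConfusionCounts
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    auc: float | None = None
    auc_ci: tuple[float, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        def fmt(v, ci):
            if v is None or np.isnan(v):
                return "NA"
            return f"{round3(v):.3f} ({round3(ci[0]):.3f}-{round3(ci[1]):.3f})"

        row = {
            "Accuracy (95%CI)": fmt(self.accuracy, self.accuracy_ci),
            "Sensitivity (95%CI)": fmt(self.sensitivity, self.sensitivity_ci),
            "Specificity (95%CI)": fmt(self.specificity, self.specificity_ci),
        }
        if self.auc is not None:
            row["AUC (95%CI)"] = fmt(self.auc, self.auc_ci)
        return pd.DataFrame([row])


def metrics_from_counts(counts: ConfusionCounts) -> MetricsReport:
    """Metrics + exact CIs from raw confusion counts."""
    npos = counts.tp + counts.fn
    nneg = counts.tn + counts.fp
    sens = counts.tp / npos if npos else float("nan")
    spec = counts.tn / nneg if nneg else float("nan")
    acc = (counts.tp + counts.tn) / counts.n if counts.n else float("nan")
    return MetricsReport(
        counts,
        acc, clopper_pearson(counts.tp + counts.tn, counts.n),
        sens, clopper_pearson(counts.tp, npos) if npos else (np.nan, np.nan),
        spec, clopper_pearson(counts.tn, nneg) if nneg else (np.nan, np.nan),
    )


def confusion_metrics(
    scores, truth, threshold: float = 0.5, with_auc: bool = True
) -> MetricsReport:
    """Evaluate scores (or hard labels) against binary truth.

    *truth* is boolean-like with True = positive class.  A sample is called
    positive iff its score is strictly greater than *threshold*; passing
    already-binary labels with the default threshold leaves them unchanged.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth).astype(bool)
    if s.shape != t.shape:
        raise ValueError("scores and truth differ in length")
    pred = s > threshold
    counts = ConfusionCounts(
        tp=int((pred & t).sum()),
        fp=int((pred & ~t).sum()),
        tn=int((~pred & ~t).sum()),
        fn=int((~pred & t).sum()),
    )
    report = metrics_from_counts(counts)
    if with_auc and t.any() and (~t).any() and len(np.unique(s)) > 1:
        roc = roc_auc(s, t)
        report.auc = roc.auc
        report.auc_ci = roc.auc_ci
    return report


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    auc_se: float


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores, truth, level: float = 0.95) -> RocCurve:
    """ROC curve and AUC with a DeLong confidence interval.

    AUC is the normalized Mann-Whitney U with ties counted 1/2.  The CI is
    DeLong's, from the structural-component variance of the placement
    values, truncated to [0, 1].  Constant scores give AUC 0.5 with a
    degenerate curve.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth).astype(bool)
    if not t.any() or not (~t).any():
        raise ValueError("both classes must be present")
    pos, neg = s[t], s[~t]
    m, n = len(pos), len(neg)

    # placement values (DeLong structural components)
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n          # per positive sample
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # per negative sample
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = stats.norm.ppf(0.5 + level / 2)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))

    # curve by threshold sweep over unique scores (descending)
    thr = np.concatenate([[np.inf], np.unique(s)[::-1]])
    tpr = np.array([(pos > c).mean() if np.isfinite(c) else 0.0 for c in thr])
    fpr = np.array([(neg > c).mean() if np.isfinite(c) else 0.0 for c in thr])
    return RocCurve(fpr, tpr, thr, auc, ci, se)


def cdp_classify(
    cea, ca199, ca724, cutoffs: dict[str, float] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Combined-diagnostic-panel rule: positive if ANY marker exceeds cutoff.

    Missing marker values are ignored; a sample with all three missing is
    excluded from evaluation.  Exceeding means strictly greater than the
    cutoff.

    Returns ``(prediction, evaluable)`` boolean arrays; ``prediction`` is
    False where not evaluable.
    """
    cutoffs = dict(CDP_CUTOFFS, **(cutoffs or {}))
    arrays = {
        "cea": np.asarray(cea, dtype=float),
        "ca199": np.asarray(ca199, dtype=float),
        "ca724": np.asarray(ca724, dtype=float),
    }
    n = len(arrays["cea"])
    positive = np.zeros(n, dtype=bool)
    available = np.zeros(n, dtype=bool)
    for name, arr in arrays.items():
        ok = ~np.isnan(arr)
        available |= ok
        positive |= ok & (arr > cutoffs[name])
    return positive & available, available
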