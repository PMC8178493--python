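"""ROC diagnostics for a scalar marker against stage dichotomies.

The empirical ROC is built over the distinct observed scores; the area
under it, by trapezoidal integration, equals the concordant-pair fraction
with half credit for ties (the Mann-Whitney statistic).  The optimal
cutoff maximizes Youden's J = sensitivity + specificity - 1 and is
reported as the midpoint between the adjacent distinct scores; J-ties
break toward the higher-specificity cutoff.  The AUC confidence interval
uses the Hanley-McNeil variance with a normal approximation (a DeLong
variance is available by flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RocResult", "roc", "stage_rocs"]


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci95: tuple[float, float]
    cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    n_positive: int
    n_negative: int
    positive_label: str = "positive"
    negative_label: str = "negative"

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )

    def summary(self) -> dict:
        return {
            "auc": self.auc,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "cutoff": self.cutoff,
            "sensitivity": self.sens_at_cutoff,
            "specificity": self.spec_at_cutoff,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "positive": self.positive_label,
            "negative": self.negative_label,
        }


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _delong_se(scores: np.ndarray, labels: np.ndarray, auc: float) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # placement values
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / len(neg) for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / len(pos) for q in neg])
    var = np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg)
    return float(np.sqrt(max(var, 0.0)))


def roc(scores, labels, ci: str = "hanley-mcneil") -> RocResult:
    """Empirical ROC of ``scores`` against binary ``labels`` (1 = positive).

    Higher scores must indicate the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC analysis")

    distinct = np.unique(scores)
    # candidate thresholds: below the minimum, the midpoints, above the max.
    mids = (distinct[:-1] + distinct[1:]) / 2.0 if len(distinct) > 1 else np.array([])
    thresholds = np.concatenate(([distinct[0] - 1.0], mids, [distinct[-1] + 1.0]))
    # classify positive when score > threshold is equivalent to >= next score
    sens = np.array([np.mean(scores[labels == 1] > t) for t in thresholds])
    spec = np.array([np.mean(scores[labels == 0] <= t) for t in thresholds])

    # AUC by trapezoid over the (FPR, TPR) curve; thresholds ascend, so both
    # fpr and sens descend — reverse to integrate left to right.
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))

    youden = sens + spec - 1.0
    # J-ties break toward higher specificity
    best = max(range(len(thresholds)), key=lambda i: (round(youden[i], 12), spec[i]))
    se = (
        _delong_se(scores, labels, auc)
        if ci == "delong"
        else _hanley_mcneil_se(auc, n_pos, n_neg)
    )
    lo, hi = auc - 1.959963984540054 * se, auc + 1.959963984540054 * se
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        ci95=(max(lo, 0.0), min(hi, 1.0)),
        cutoff=float(thresholds[best]),
        sens_at_cutoff=float(sens[best]),
        spec_at_cutoff=float(spec[best]),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def stage_rocs(
    feature_table: pd.DataFrame, marker: str = "FCR", ci: str = "hanley-mcneil"
) -> dict[str, RocResult]:
    """ROC of a marker for the two stage dichotomies on pre-operative data.

    Dichotomy 1: T0-2 vs T3-4 (advanced disease); dichotomy 2: T0 vs T1-4
    (healthy controls vs any tumour).  ``feature_table`` needs ``t_class``,
    ``timepoint`` and the marker column.
    """
    pre = feature_table[feature_table["timepoint"] == "pre"]
    pre = pre[np.isfinite(pre[marker])]
    if len(pre) == 0:
        raise ValueError("no pre-operative sessions with a finite marker value")
    t = pre["t_class"].to_numpy(dtype=int)
    out: dict[str, RocResult] = {}
    for name, pos_mask, pos_label, neg_label in [
        ("T0-2_vs_T3-4", t >= 3, "T3-4", "T0-2"),
        ("T0_vs_T1-4", t >= 1, "T1-4", "T0"),
    ]:
        if pos_mask.all() or not pos_mask.any():
            raise ValueError(f"dichotomy {name}: one side is empty")
        res = roc(pre[marker].to_numpy(dtype=float), pos_mask.astype(int), ci=ci)
        res.positive_label = pos_label
        res.negative_label = neg_label
        out[name] = res
    return out
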