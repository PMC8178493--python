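"""Marker screening with per-syllable, per-gender linear SVMs.

For each (gender, syllable) pair a soft-margin linear SVM is trained on the
15 z-scored acoustic metrics against the binary articulation outcome
(1 = correct).  Because the kernel is linear and the features are
standardized, the fitted weight vector — the per-predictor "LPCs" in the
clinical sense, not to be confused with DSP linear predictive coding —
directly ranks the metrics by influence, and its sign gives the direction:
a metric whose increase raises the probability of misarticulation gets a
negative weight.  The 15 x 12 weight matrices per gender feed the dominance
ranking and the cross-gender dimorphism t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .metrics import FEATURE_NAMES

__all__ = [
    "SvmModel",
    "LpcMatrix",
    "train_syllable_model",
    "evaluate_model",
    "lpc_matrix",
    "rank_predictors",
    "compare_lpc_across_gender",
]


@dataclass
class SvmModel:
    """A trained per-syllable linear SVM with its scaler and CV metrics."""

    gender: str
    syllable_id: str
    weights: np.ndarray          # length 15, standardized scale
    bias: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    cv_metrics: dict = field(default_factory=dict)
    n_support: int = 0
    n_train: int = 0
    seed: int = 0

    def decision_function(self, X) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.feature_means) / self.feature_sds
        return Z @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


def _binary_metrics(y_true, y_pred, scores=None) -> dict:
    """Accuracy, AUC, sensitivity, specificity, PPV, NPV (positive class = 1).

    Ratios with zero denominators are reported as NaN (missing), never 0.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    out = {
        "accuracy": (tp + tn) / len(y_true),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }
    if scores is not None and len(np.unique(y_true)) == 2:
        from .diagnostics import roc  # pair-counting AUC, shared convention

        out["auc"] = roc(np.asarray(scores, float), y_true).auc
    else:
        out["auc"] = float("nan")
    return out


def train_syllable_model(
    features: pd.DataFrame,
    labels,
    gender: str = "",
    syllable_id: str = "",
    folds: int = 10,
    box_constraint: float = 1.0,
    seed: int = 0,
) -> SvmModel:
    """Fit the linear SVM for one (gender, syllable) dataset.

    Features are z-scored with stored parameters; CV metrics come from a
    stratified ``folds``-fold split with a fixed seed.  Orientation is fixed
    so that the positive decision side is label 1 (correct articulation).
    """
    X = np.asarray(features[list(FEATURE_NAMES)] if isinstance(features, pd.DataFrame) else features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {X.shape[1]}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"degenerate syllable {syllable_id!r}: single-class labels")
    if counts.min() < 2:
        raise ValueError(f"degenerate syllable {syllable_id!r}: a class has < 2 rows")

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    n_folds = min(folds, int(counts.min()))
    if n_folds < folds:
        import logging

        logging.getLogger(__name__).warning(
            "%s/%s: folds reduced %d -> %d (smallest class)", gender, syllable_id, folds, n_folds
        )

    clf = SVC(kernel="linear", C=box_constraint)
    # out-of-fold predictions for the CV metrics
    oof_pred = np.empty_like(y)
    oof_score = np.empty(len(y), dtype=float)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(Z, y):
        fold_clf = SVC(kernel="linear", C=box_constraint)
        fold_clf.fit(Z[tr], y[tr])
        oof_pred[te] = fold_clf.predict(Z[te])
        oof_score[te] = fold_clf.decision_function(Z[te])
    cv_metrics = _binary_metrics(y, oof_pred, oof_score)

    clf.fit(Z, y)
    # sklearn orients coef_ so positive decision values map to classes_[1];
    # our positive class is label 1, which sorts last in {0, 1}.
    w = clf.coef_.ravel().astype(float)
    b = float(clf.intercept_[0])
    return SvmModel(
        gender=gender,
        syllable_id=syllable_id,
        weights=w,
        bias=b,
        feature_means=mu,
        feature_sds=sd,
        cv_metrics=cv_metrics,
        n_support=int(clf.n_support_.sum()),
        n_train=len(y),
        seed=seed,
    )


def evaluate_model(model: SvmModel, features: pd.DataFrame, labels) -> dict:
    """Apply a trained model (stored scaler + decision rule) to a test set."""
    if isinstance(features, pd.DataFrame):
        missing = set(FEATURE_NAMES) - set(features.columns)
        if missing:
            raise ValueError(f"test features lack columns: {sorted(missing)}")
        X = features[list(FEATURE_NAMES)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    scores = model.decision_function(X)
    preds = (scores >= 0).astype(int)
    if len(np.unique(y)) == 2:
        return _binary_metrics(y, preds, scores)
    out = _binary_metrics(y, preds)
    return out


@dataclass
class LpcMatrix:
    """Per-gender 15 x 12 matrix of SVM predictor weights."""

    gender: str
    matrix: pd.DataFrame  # rows = FEATURE_NAMES, columns = syllable ids

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(FEATURE_NAMES), 12):
            raise ValueError(f"LPC matrix must be 15 x 12, got {self.matrix.shape}")


def lpc_matrix(models: dict[str, SvmModel], gender: str, syllable_order) -> LpcMatrix:
    """Assemble the weight matrix in canonical feature/syllable order."""
    gaps = [s for s in syllable_order if s not in models]
    if gaps:
        raise ValueError(f"missing syllable model(s): {gaps}")
    mat = pd.DataFrame(
        {s: models[s].weights for s in syllable_order}, index=list(FEATURE_NAMES)
    )
    return LpcMatrix(gender=gender, matrix=mat)


def rank_predictors(*matrices: LpcMatrix) -> pd.DataFrame:
    """Rank the 15 metrics by mean |weight| across syllables (and genders).

    Returns a frame sorted by rank with the dominance statistic, the count
    of negative/positive weights per feature, and a ``degenerate`` flag for
    an all-zero input.  Ties break by canonical feature order.
    """
    stacked = pd.concat([m.matrix for m in matrices], axis=1)
    mean_abs = stacked.abs().mean(axis=1)
    order = np.arange(len(FEATURE_NAMES))
    ranked = pd.DataFrame(
        {
            "feature": list(FEATURE_NAMES),
            "mean_abs_weight": mean_abs.to_numpy(),
            "n_negative": (stacked < 0).sum(axis=1).to_numpy(),
            "n_positive": (stacked > 0).sum(axis=1).to_numpy(),
            "n_models": stacked.shape[1],
            "canonical_order": order,
        }
    )
    ranked = ranked.sort_values(
        ["mean_abs_weight", "canonical_order"], ascending=[False, True]
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    ranked.attrs["degenerate"] = bool(np.allclose(stacked.to_numpy(), 0.0))
    ranked.attrs["dominant"] = str(ranked.iloc[0]["feature"])
    return ranked


def compare_lpc_across_gender(male: LpcMatrix, female: LpcMatrix) -> pd.DataFrame:
    """Two-tailed two-sample t-test per feature over the 12 syllable weights.

    Zero-variance-in-both-genders features are reported as missing.  An
    uncorrected p is the primary column; a Holm-adjusted column is attached.
    """
    if male.matrix.shape != female.matrix.shape:
        raise ValueError("LPC matrices must have matching shapes")
    rows = []
    for feat in FEATURE_NAMES:
        a = male.matrix.loc[feat].to_numpy(dtype=float)
        b = female.matrix.loc[feat].to_numpy(dtype=float)
        if np.var(a) == 0 and np.var(b) == 0:
            if np.allclose(a.mean(), b.mean()):
                # identical constants: no dimorphism by construction
                t, p = 0.0, 1.0
            else:
                t, p = float("nan"), float("nan")
        else:
            t, p = stats.ttest_ind(a, b)
        rows.append(
            {
                "feature": feat,
                "t": float(t),
                "df": len(a) + len(b) - 2,
                "p": float(p),
                "mean_male": a.mean(),
                "mean_female": b.mean(),
            }
        )
    table = pd.DataFrame(rows)
    finite = table["p"].notna()
    adj = np.full(len(table), np.nan)
    if finite.any():
        adj[finite.to_numpy()] = multipletests(table.loc[finite, "p"], method="holm")[1]
    table["p_holm"] = adj
    return table
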