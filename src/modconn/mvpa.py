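"""Multivariate pattern analysis and brain-behavior correlation.

Subjects are classified from their modulewise coordinates and/or behavior
scores with a linear maximum-margin classifier (SVM, C = 1). Accuracy comes
from stratified fourfold cross-validation — train on 75% of subjects, test
on the held-out 25%, pool the predictions — with feature standardization
fitted inside each training fold. Feature weights and the per-subject
dimensional classification score (signed distance to the separating
hyperplane, read as confidence of group membership) come from a full-data
refit. A separate screen correlates each block coordinate with each behavior
measure across all subjects and flags large effects (|r| >= 0.5 by default).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


@dataclass
class MvpaResult:
    """Cross-validated classification outcome for one feature set."""

    feature_set: str
    cv_accuracy: float
    predicted: pd.Series            # held-out predicted group per subject
    dimensional_scores: pd.Series   # signed hyperplane distance, full refit
    weights: pd.Series              # per-feature weight, full refit
    folds: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "feature_set": self.feature_set,
            "cv_accuracy": self.cv_accuracy,
            "seed": self.seed,
            "predicted": {k: int(v) for k, v in self.predicted.items()},
            "dimensional_scores": {k: float(v)
                                   for k, v in self.dimensional_scores.items()},
            "weights": {k: float(v) for k, v in self.weights.items()},
            "folds": self.folds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def fit_classifier_cv(features: pd.DataFrame, labels: pd.Series,
                      n_folds: int = 4, seed: int = 0, C: float = 1.0,
                      kernel: str = "linear",
                      feature_set: str = "connectivity",
                      heldout_scores: bool = False) -> MvpaResult:
    """Linear SVM with stratified k-fold cross-validation.

    Features are z-scored with means/SDs estimated on each training fold and
    applied to its test fold; accuracy pools the held-out predictions.
    Dimensional scores and weights come from a full-data refit by default
    (``heldout_scores=True`` reports fold-wise held-out scores instead).
    Positive score means the higher group label.
    """
    X = features.to_numpy(dtype=float)
    y = labels.reindex(features.index)
    if y.isna().any():
        raise ValueError("every subject needs a group label")
    y = y.to_numpy()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("need exactly 2 classes")
    if np.isnan(X).any():
        raise ValueError("missing feature values")
    min_class = min((y == c).sum() for c in classes)
    if min_class < n_folds:
        raise ValueError(f"need at least {n_folds} subjects per group for "
                         f"{n_folds}-fold stratified CV")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=y.dtype)
    heldout = np.empty(len(y), dtype=float)
    folds = {}
    for k, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("single-class training fold")
        scaler = StandardScaler().fit(X[tr])
        clf = SVC(kernel=kernel, C=C).fit(scaler.transform(X[tr]), y[tr])
        Xte = scaler.transform(X[te])
        pred[te] = clf.predict(Xte)
        heldout[te] = clf.decision_function(Xte)
        for i in te:
            folds[str(features.index[i])] = k
    accuracy = float((pred == y).mean())

    scaler = StandardScaler().fit(X)
    full = SVC(kernel=kernel, C=C).fit(scaler.transform(X), y)
    if kernel == "linear":
        weights = pd.Series(full.coef_.ravel(), index=features.columns)
    else:
        weights = pd.Series(np.nan, index=features.columns)
    scores = heldout if heldout_scores else full.decision_function(
        scaler.transform(X))
    return MvpaResult(
        feature_set=feature_set,
        cv_accuracy=accuracy,
        predicted=pd.Series(pred, index=features.index),
        dimensional_scores=pd.Series(scores, index=features.index),
        weights=weights,
        folds=folds,
        seed=seed,
    )


def classifier_weights(result: MvpaResult, top_k: int | None = None) -> pd.Series:
    """Features ranked by absolute weight; signed weights returned."""
    if result.weights.isna().any():
        raise ValueError("feature weights undefined for a nonlinear kernel")
    ranked = result.weights.reindex(
        result.weights.abs().sort_values(ascending=False).index)
    return ranked if top_k is None else ranked.iloc[:top_k]


def correlate_dimensional_scores(scores_a: pd.Series,
                                 scores_b: pd.Series) -> tuple[float, float]:
    """Pearson r (with two-sided p) between two per-subject score sets."""
    b = scores_b.reindex(scores_a.index)
    if b.isna().any():
        raise ValueError("score sets cover different subjects")
    if len(scores_a) < 3:
        raise ValueError("need at least 3 subjects")
    if scores_a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance score set")
    r, p = stats.pearsonr(scores_a.to_numpy(), b.to_numpy())
    return float(r), float(p)


def behavior_block_correlations(coordinates: pd.DataFrame,
                                behavior: pd.DataFrame,
                                r_threshold: float = 0.5) -> pd.DataFrame:
    """Correlate every block coordinate with every behavior measure.

    Correlations pool all subjects (both groups). Rows with missing behavior
    are excluded pairwise (logged). Returns columns ``block``, ``measure``,
    ``r``, ``p_uncorrected``, ``selected`` (|r| >= r_threshold).
    """
    behavior = behavior.reindex(coordinates.index)
    rows = []
    for measure in behavior.columns:
        b = behavior[measure]
        ok = b.notna()
        if not ok.all():
            logger.info("measure %r: excluding %d subjects with missing "
                        "values", measure, int((~ok).sum()))
        if ok.sum() < 3:
            raise ValueError(f"measure {measure!r}: fewer than 3 subjects")
        if b[ok].std() == 0:
            raise ValueError(f"behavior measure {measure!r} is constant")
        for block in coordinates.columns:
            c = coordinates.loc[ok, block]
            r, p = stats.pearsonr(c.to_numpy(), b[ok].to_numpy())
            rows.append({"block": block, "measure": measure, "r": float(r),
                         "p_uncorrected": float(p),
                         "selected": bool(abs(r) >= r_threshold)})
    return pd.DataFrame(rows)
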