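"""Class-weighted logistic model of post-surgical seizure freedom.

Three localization features — abnormality coverage, DRS(MEG), DRS(iEEG) —
enter a logistic regression of 1-year seizure freedom (ILAE 1 vs ILAE 2+).
Because outcome groups are imbalanced, each class is weighted by the other
class's prevalence (w_1 = n_2/N, w_2 = n_1/N), which gives both groups equal
total weight in the likelihood. Features are not standardized: all three
live on [0, 1] and have natural interpretations.

The fitted model is rendered as a nomogram: each feature accrues points in
proportion to its coefficient times its observed range, the most influential
feature spanning 0-100 points; a subject's point total is an increasing
affine transform of the linear predictor, so classifying by a point
threshold is identical to thresholding the predicted probability at 0.5.

Robustness is assessed by leave-one-out refitting, and group differences by
one-tailed tests (one-sample t against chance 0.5; Mann-Whitney U between
outcome groups, whose normalized statistic is the ROC AUC effect size).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .metrics import FEATURE_COLUMNS, SubjectFeatures, rank_auc

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedLogisticOutcome",
    "fit_weighted_logistic",
    "Nomogram",
    "build_nomogram",
    "LooResult",
    "loo_auc",
    "GroupStatResult",
    "one_sample_t_greater",
    "mann_whitney_auc_greater",
    "features_frame",
]

#: Ridge strength used only as a fallback under (quasi-)separation.
SEPARATION_RIDGE = 1e-6
#: |coefficient| beyond which an unpenalized fit is treated as diverging.
_DIVERGENCE_NORM = 30.0


def _equalizing_weights(y: np.ndarray) -> dict[int, float]:
    """Per-class weights w_c = n_other/N so both classes carry equal mass."""
    n = y.size
    n1 = int(y.sum())
    return {0: n1 / n, 1: (n - n1) / n}


class WeightedLogisticOutcome(ClassifierMixin, BaseEstimator):
    """Class-weighted logistic regression fitted by Newton's method.

    Maximizes the class-weighted log-likelihood without input
    standardization. If the unpenalized fit diverges (complete or quasi-
    separation), the fit restarts with a tiny ridge penalty
    (``ridge_fallback``) and records this in ``fit_meta_``.

    Parameters
    ----------
    class_weight : "equalize" or dict
        "equalize" sets w_c = n_other/N; a dict maps class label (0/1) to
        weight directly.
    tol : float
        Newton convergence tolerance on the max absolute step.
    ridge_fallback : float
        L2 strength (on slopes, not the intercept) used when separation is
        detected.

    Attributes
    ----------
    coef_ : ndarray (1, n_features)
    intercept_ : ndarray (1,)
    classes_ : ndarray
    class_weight_ : dict
    fit_meta_ : dict with keys converged, separation_fallback, penalty, n_iter
    """

    def __init__(self, class_weight="equalize", tol: float = 1e-10,
                 max_iter: int = 200, ridge_fallback: float = SEPARATION_RIDGE):
        self.class_weight = class_weight
        self.tol = tol
        self.max_iter = max_iter
        self.ridge_fallback = ridge_fallback

    def _newton(self, X: np.ndarray, y: np.ndarray, w: np.ndarray,
                ridge: float) -> tuple[np.ndarray, bool, int]:
        n, p = X.shape
        Xd = np.column_stack([np.ones(n), X])
        beta = np.zeros(p + 1)
        pen = np.zeros(p + 1)
        pen[1:] = ridge  # intercept unpenalized
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = Xd @ beta
            prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
            grad = Xd.T @ (w * (y - prob)) - pen * beta
            wt = w * prob * (1.0 - prob)
            hess = (Xd * wt[:, None]).T @ Xd + np.diag(pen)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                return beta, False, it
            # damped update for numerical safety far from the optimum
            if np.abs(step).max() > 10.0:
                step *= 10.0 / np.abs(step).max()
            beta = beta + step
            if np.abs(step).max() < self.tol:
                converged = True
                break
            if ridge == 0 and np.abs(beta).max() > 1e6:
                return beta, False, it
        return beta, converged, it

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("need exactly two outcome classes")
        yb = (y == self.classes_[1]).astype(float)
        if self.class_weight == "equalize":
            cw = _equalizing_weights(yb)
        else:
            cw = dict(self.class_weight)
        w = np.where(yb == 1, cw[1], cw[0]).astype(float)
        beta, converged, n_iter = self._newton(X, yb, w, ridge=0.0)
        fallback = (not converged) or np.abs(beta).max() > _DIVERGENCE_NORM
        penalty = 0.0
        if fallback:
            logger.warning("separation detected; refitting with ridge %.1e",
                           self.ridge_fallback)
            penalty = self.ridge_fallback
            beta, converged, n_iter = self._newton(X, yb, w, ridge=penalty)
        if not np.isfinite(beta).all():
            raise RuntimeError("logistic fit produced non-finite parameters")
        self.intercept_ = beta[:1].copy()
        self.coef_ = beta[1:].reshape(1, -1)
        self.class_weight_ = cw
        self.n_features_in_ = X.shape[1]
        self.fit_meta_ = {
            "converged": bool(converged),
            "separation_fallback": bool(fallback),
            "penalty": penalty,
            "n_iter": int(n_iter),
        }
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_.ravel() + self.intercept_[0]

    def predict_proba(self, X):
        eta = np.clip(self.decision_function(X), -500, 500)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def features_frame(features: Iterable[SubjectFeatures] | pd.DataFrame) -> pd.DataFrame:
    """Normalize a feature collection to a DataFrame indexed by subject."""
    if isinstance(features, pd.DataFrame):
        df = features.copy()
        if "subject_id" in df.columns:
            df = df.set_index("subject_id")
    else:
        rows = list(features)
        df = pd.DataFrame(
            {c: [getattr(r, c) for r in rows] for c in (*FEATURE_COLUMNS, "ilae")},
            index=pd.Index([r.subject_id for r in rows], name="subject_id"),
        )
    missing = [c for c in (*FEATURE_COLUMNS, "ilae") if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    for col in FEATURE_COLUMNS:
        bad = df.index[~np.isfinite(df[col].astype(float))]
        if len(bad):
            raise ValueError(f"missing/non-finite {col} for subject {bad[0]}")
    return df


def _xy(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = df[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = (df["ilae"].to_numpy() == 1).astype(int)
    return X, y


def fit_weighted_logistic(
    features: Iterable[SubjectFeatures] | pd.DataFrame,
) -> WeightedLogisticOutcome:
    """Fit the three-feature class-weighted outcome model on a cohort."""
    df = features_frame(features)
    X, y = _xy(df)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least two subjects per outcome class")
    return WeightedLogisticOutcome().fit(X, y)


@dataclass
class Nomogram:
    """Point rendering of a fitted logistic model.

    Each feature i maps its value x to
    ``points_i(x) = 100 * (beta_i * x - min_range(beta_i * x)) / D`` with
    ``D = max_j |beta_j| * range_j``, so the most influential feature spans
    exactly [0, 100] and every contribution is nonnegative. Total points are
    an increasing affine transform of the linear predictor; crossing
    ``threshold_points`` is equivalent to predicted probability > 0.5.
    """

    feature_names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    ranges: np.ndarray  # (n_features, 2) observed min/max
    scale: float  # points per unit of linear predictor
    offsets: np.ndarray  # min over range of beta_i * x, per feature
    threshold_points: float

    def points(self, X: np.ndarray) -> np.ndarray:
        """Per-feature points for rows of feature values."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.scale * (X * self.coefficients - self.offsets)

    def total_points(self, X: np.ndarray) -> np.ndarray:
        return self.points(X).sum(axis=1)

    def predict_seizure_free(self, X: np.ndarray) -> np.ndarray:
        return self.total_points(X) > self.threshold_points

    def breakpoint_table(self, n_points: int = 11) -> pd.DataFrame:
        """Long table (feature, value, points) sampling each feature's range."""
        rows = []
        for i, name in enumerate(self.feature_names):
            lo, hi = self.ranges[i]
            vals = np.linspace(lo, hi, n_points)
            pts = self.scale * (vals * self.coefficients[i] - self.offsets[i])
            rows.append(pd.DataFrame({"feature": name, "value": vals,
                                      "points": pts}))
        return pd.concat(rows, ignore_index=True)


def build_nomogram(model: WeightedLogisticOutcome,
                   features: Iterable[SubjectFeatures] | pd.DataFrame) -> Nomogram:
    """Derive the point mappings of a fitted model over the observed cohort."""
    check_is_fitted(model, "coef_")
    df = features_frame(features)
    X = df[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    beta = model.coef_.ravel()
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = np.abs(beta) * (hi - lo)
    if np.all(span <= 0):
        raise ValueError("every feature has zero range; nomogram undefined")
    denom = span.max()
    scale = 100.0 / denom
    offsets = np.minimum(beta * lo, beta * hi)
    threshold = scale * (-model.intercept_[0] - offsets.sum())
    return Nomogram(
        feature_names=tuple(FEATURE_COLUMNS),
        coefficients=beta.copy(),
        intercept=float(model.intercept_[0]),
        ranges=np.column_stack([lo, hi]),
        scale=float(scale),
        offsets=offsets,
        threshold_points=float(threshold),
    )


@dataclass
class LooResult:
    """Summary of leave-one-out validation AUCs."""

    mean: float
    min: float
    max: float
    n_folds: int
    n_skipped: int
    mode: str
    fold_aucs: list[float] = field(default_factory=list)


def loo_auc(features: Iterable[SubjectFeatures] | pd.DataFrame,
            heldout: bool = False) -> LooResult:
    """Leave-one-out validation of the weighted logistic model.

    For each subject, the model is refitted on the remaining n-1 subjects
    (class weights recomputed) and an AUC recorded. By default the AUC is
    computed from the refitted model's scores on those n-1 training
    subjects; with ``heldout=True`` the left-out subjects' scores are
    accumulated and a single held-out AUC is computed at the end.
    """
    df = features_frame(features)
    X, y = _xy(df)
    fold_aucs: list[float] = []
    held_scores, held_labels = [], []
    skipped = 0
    for i in range(len(df)):
        mask = np.ones(len(df), dtype=bool)
        mask[i] = False
        ytr = y[mask]
        if ytr.min() == ytr.max():
            warnings.warn(f"LOO fold {df.index[i]}: training set lost a class; "
                          "fold skipped", stacklevel=2)
            skipped += 1
            continue
        m = WeightedLogisticOutcome().fit(X[mask], ytr)
        scores = m.decision_function(X[mask])
        if heldout:
            held_scores.append(float(m.decision_function(X[i:i + 1])[0]))
            held_labels.append(int(y[i]))
        else:
            fold_aucs.append(rank_auc(scores[ytr == 1], scores[ytr == 0]))
    if heldout:
        hs = np.asarray(held_scores)
        hl = np.asarray(held_labels)
        auc = rank_auc(hs[hl == 1], hs[hl == 0])
        fold_aucs = [auc]
    if not fold_aucs:
        raise ValueError("no valid leave-one-out folds")
    return LooResult(
        mean=float(np.mean(fold_aucs)),
        min=float(np.min(fold_aucs)),
        max=float(np.max(fold_aucs)),
        n_folds=len(fold_aucs) if not heldout else len(held_scores),
        n_skipped=skipped,
        mode="heldout" if heldout else "train",
        fold_aucs=[float(a) for a in fold_aucs],
    )


@dataclass(frozen=True)
class GroupStatResult:
    """A one-tailed test result with its AUC effect size where defined."""

    statistic: float
    auc_effect_size: float
    one_tailed_p: float
    n_per_group: tuple[int, ...]


def one_sample_t_greater(values: Sequence[float],
                         mu0: float = 0.5) -> GroupStatResult:
    """One-tailed one-sample t-test of mean(values) > mu0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if np.isclose(v.std(ddof=1), 0.0):
        raise ValueError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(v, mu0, alternative="greater")
    return GroupStatResult(
        statistic=float(res.statistic),
        auc_effect_size=float("nan"),
        one_tailed_p=float(res.pvalue),
        n_per_group=(int(v.size),),
    )


def mann_whitney_auc_greater(group_a: Sequence[float],
                             group_b: Sequence[float]) -> GroupStatResult:
    """One-tailed Mann-Whitney U test of group_a > group_b.

    The normalized statistic U/(n_a * n_b) is the ROC AUC effect size. The
    p-value uses exact enumeration for small tie-free samples
    (n_a * n_b <= 400) and the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    auc = rank_auc(a, b)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return GroupStatResult(
        statistic=float(res.statistic),
        auc_effect_size=float(auc),
        one_tailed_p=float(res.pvalue),
        n_per_group=(int(a.size), int(b.size)),
    )
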