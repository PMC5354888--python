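"""Diagonal pooled-covariance Gaussian discriminant classification.

With thousands of selected signature regions and only hundreds of
training samples, a full pooled covariance matrix is singular, so the
discriminant uses a diagonal pooled covariance: per-class feature means,
a single pooled within-class variance per feature (floored at a small
epsilon so constant features stay finite), and class priors. The
discriminant score of sample x for class c is

    log pi_c - 1/2 * sum_j [ (x_j - mu_cj)^2 / s_j^2 + log s_j^2 ]

and the prediction is the argmax over classes (ties broken by class
label order and flagged). A full pooled-covariance (classic LDA) mode
is available when the feature count is below the sample count.

On a single feature and two classes the decision boundary reduces to
the textbook LDA threshold, which the test suite checks in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .core import ValidationError
from .signatures import CnvSignatureSelector

__all__ = [
    "DiagonalDiscriminant",
    "ClassificationReport",
    "cross_validate_origin",
    "resubstitution_report",
]


class DiagonalDiscriminant(ClassifierMixin, BaseEstimator):
    """Gaussian discriminant with diagonal pooled within-class covariance.

    Parameters
    ----------
    priors : "empirical", "uniform" or array-like, default "empirical"
        Class prior probabilities; empirical uses training frequencies.
    var_floor : float, default 1e-6
        Lower bound on every pooled per-feature variance.
    covariance : {"diagonal", "full"}, default "diagonal"
        Full pooled covariance (classic LDA) is only permitted when the
        number of features is below the number of samples.

    Attributes
    ----------
    classes_ : (n_classes,) array of labels in sorted order.
    means_ : (n_classes, n_features) per-class feature means.
    variances_ : (n_features,) pooled, floored variances (diagonal mode).
    log_priors_ : (n_classes,) log prior per class.
    """

    def __init__(self, priors="empirical", var_floor: float = 1e-6,
                 covariance: str = "diagonal"):
        self.priors = priors
        self.var_floor = var_floor
        self.covariance = covariance

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if self.var_floor <= 0:
            raise ValidationError("var_floor must be positive")
        if self.covariance not in ("diagonal", "full"):
            raise ValidationError("covariance must be 'diagonal' or 'full'")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValidationError("need at least two classes to train")
        if (counts < 2).any():
            small = classes[counts < 2]
            raise ValidationError(f"classes with fewer than two samples: {list(small)}")
        n, k = X.shape
        if self.covariance == "full" and k >= n:
            raise ValidationError(
                f"full covariance requires features < samples ({k} >= {n}); "
                "use the diagonal mode"
            )
        self.classes_ = classes
        self.n_features_in_ = k
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in classes])
        centered = X - self.means_[np.searchsorted(classes, y)]
        dof = n - len(classes)
        if self.covariance == "diagonal":
            pooled = (centered**2).sum(axis=0) / max(dof, 1)
            self.variances_ = np.maximum(pooled, self.var_floor)
        else:
            cov = centered.T @ centered / max(dof, 1)
            cov[np.diag_indices_from(cov)] = np.maximum(
                np.diag(cov), self.var_floor
            )
            self.covariance_ = cov
            self._precision_ = np.linalg.pinv(cov)
        if isinstance(self.priors, str) and self.priors == "empirical":
            priors = counts / n
        elif isinstance(self.priors, str) and self.priors == "uniform":
            priors = np.full(len(classes), 1.0 / len(classes))
        else:
            priors = np.asarray(self.priors, dtype=float)
            if priors.shape != classes.shape or not np.isclose(priors.sum(), 1.0):
                raise ValidationError("priors must match classes and sum to 1")
        self.log_priors_ = np.log(priors)
        return self

    def decision_function(self, X) -> np.ndarray:
        """Per-class discriminant scores, shape (n_samples, n_classes)."""
        check_is_fitted(self, "means_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        scores = np.empty((X.shape[0], len(self.classes_)))
        if self.covariance == "diagonal":
            log_det = np.log(self.variances_).sum()
            for j, mu in enumerate(self.means_):
                maha = ((X - mu) ** 2 / self.variances_).sum(axis=1)
                scores[:, j] = self.log_priors_[j] - 0.5 * (maha + log_det)
        else:
            for j, mu in enumerate(self.means_):
                diff = X - mu
                maha = np.einsum("ij,jk,ik->i", diff, self._precision_, diff)
                scores[:, j] = self.log_priors_[j] - 0.5 * maha
        return scores

    def predict(self, X) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def predict_verbose(self, X, rtol: float = 1e-12):
        """Predictions plus scores and a per-sample tie flag.

        A sample is flagged when its top two class scores agree to
        within relative tolerance; the tie resolves to the earlier
        class label, matching :meth:`predict`.
        """
        scores = self.decision_function(X)
        order = np.argsort(scores, axis=1)
        top, second = scores[np.arange(len(scores)), order[:, -1]], scores[
            np.arange(len(scores)), order[:, -2]
        ]
        scale = np.maximum(np.abs(top), 1.0)
        ties = np.abs(top - second) <= rtol * scale
        return self.classes_[np.argmax(scores, axis=1)], scores, ties


@dataclass
class ClassificationReport:
    """Confusion matrix and per-class accuracy under a named protocol."""

    protocol: str
    confusion: pd.DataFrame  # rows: true class, columns: predicted
    per_class_accuracy: dict[str, float]
    overall_accuracy: float
    n_selected_per_fold: list[int]

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "confusion": {
                str(r): {str(c): int(v) for c, v in row.items()}
                for r, row in self.confusion.iterrows()
            },
            "per_class_accuracy": self.per_class_accuracy,
            "overall_accuracy": self.overall_accuracy,
            "n_selected_per_fold": self.n_selected_per_fold,
        }


def _report(y_true, y_pred, protocol, n_selected) -> ClassificationReport:
    classes = np.unique(y_true)
    confusion = pd.DataFrame(
        0, index=classes, columns=classes, dtype=int
    )
    for t, p in zip(y_true, y_pred):
        confusion.loc[t, p] += 1
    per_class = {
        str(c): float(confusion.loc[c, c] / confusion.loc[c].sum()) for c in classes
    }
    overall = float((np.asarray(y_true) == np.asarray(y_pred)).mean())
    return ClassificationReport(
        protocol=protocol,
        confusion=confusion,
        per_class_accuracy=per_class,
        overall_accuracy=overall,
        n_selected_per_fold=list(n_selected),
    )


def make_origin_pipeline(
    alpha: float = 1e-12, method: str = "logistic", priors="empirical",
    var_floor: float = 1e-6,
) -> Pipeline:
    """Signature selection followed by the diagonal discriminant."""
    return Pipeline(
        [
            ("signatures", CnvSignatureSelector(alpha=alpha, method=method)),
            ("discriminant", DiagonalDiscriminant(priors=priors, var_floor=var_floor)),
        ]
    )


def cross_validate_origin(
    X,
    y,
    alpha: float = 1e-12,
    n_splits: int = 5,
    seed: int = 0,
    method: str = "logistic",
    priors="empirical",
) -> ClassificationReport:
    """Stratified k-fold accuracy with signature selection re-run per fold.

    Selection inside each training fold prevents information leaking
    from held-out samples into the feature set. Classes must each hold
    at least ``n_splits`` samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_splits < 2:
        raise ValidationError("need at least two folds")
    _, counts = np.unique(y, return_counts=True)
    if (counts < n_splits).any():
        raise ValidationError(
            f"every class needs >= {n_splits} samples for stratified CV"
        )
    splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    y_pred = np.empty(len(y), dtype=y.dtype)
    n_selected = []
    for train, test in splitter.split(X, y):
        selector = CnvSignatureSelector(alpha=alpha, method=method).fit(
            X[train], y[train]
        )
        mask = selector._get_support_mask()
        if not mask.any():
            raise ValidationError(
                "no signature region passed the cutoff in a training fold; "
                "refusing to train"
            )
        n_selected.append(int(mask.sum()))
        model = DiagonalDiscriminant(priors=priors).fit(X[train][:, mask], y[train])
        y_pred[test] = model.predict(X[test][:, mask])
    return _report(y, y_pred, f"stratified {n_splits}-fold CV", n_selected)


def resubstitution_report(
    X, y, alpha: float = 1e-12, method: str = "logistic", priors="empirical"
) -> ClassificationReport:
    """Accuracy on the training data itself (select + train + score once)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    selector = CnvSignatureSelector(alpha=alpha, method=method).fit(X, y)
    mask = selector._get_support_mask()
    if not mask.any():
        raise ValidationError(
            "no signature region passed the cutoff; refusing to train"
        )
    model = DiagonalDiscriminant(priors=priors).fit(X[:, mask], y)
    return _report(y, model.predict(X[:, mask]), "resubstitution", [int(mask.sum())])
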