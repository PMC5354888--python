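"""Per-region association screening and cancer-type CNV signature selection.

Each aligned region is screened for association between its copy-number
value and the cancer-type label: for every class a one-vs-rest binomial
logistic regression of class membership on the region value is fitted,
and the region's p-value is the minimum over classes of the
likelihood-ratio test against the intercept-only model (per-class
p-values and effect directions are kept alongside). Regions with
p < alpha (strict; default alpha = 1e-12) form the signature set.

Because a genome-wide screen fits tens of thousands of single-covariate
logistic models, the scan is implemented as a Newton/IRLS iteration
vectorized across all regions simultaneously (each model has only an
intercept and a slope, so the per-region Hessian is a closed-form 2x2
solve). A tiny ridge (1e-8) on the Hessian diagonal and a cap on the
linear predictor keep the iteration finite under perfect separation;
separated and degenerate (constant-value) regions are flagged. A
per-region one-way ANOVA F-test is available as an alternative scorer.

The selector is a scikit-learn transformer (``fit`` / ``transform`` /
``get_support``) so it composes with pipelines and cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .core import ValidationError

__all__ = [
    "logistic_lrt_scan",
    "score_region_association",
    "CnvSignatureSelector",
    "SignatureSet",
    "select_signatures",
]

_ETA_CAP = 30.0
_RIDGE = 1e-8
_SEPARATION_DEVIANCE = 1e-6


def logistic_lrt_scan(
    X: np.ndarray, y01: np.ndarray, max_iter: int = 60, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Likelihood-ratio p-values for single-covariate logistic fits, one per column.

    Parameters
    ----------
    X : (n_samples, n_features) array
        One covariate per column.
    y01 : (n_samples,) array of 0/1
        Binary outcome shared by all fits.

    Returns
    -------
    pvalues : (n_features,) array
        Chi-square(1) LRT p-values against the intercept-only model.
        Degenerate (constant) columns get p = 1.
    slopes : (n_features,) array
        Fitted slope per column (0 for degenerate columns).
    flags : (n_features,) array of str
        ``""``, ``"degenerate"`` or ``"separation"``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y01, dtype=float)
    n, k = X.shape
    if y.shape != (n,):
        raise ValidationError("outcome length does not match X rows")
    if not np.isfinite(X).all():
        raise ValidationError("region values must be finite")
    pbar = y.mean()
    if pbar in (0.0, 1.0):
        raise ValidationError("outcome is constant; association is undefined")

    degenerate = np.ptp(X, axis=0) == 0.0
    ll_null = n * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))

    Xw = X[:, ~degenerate]
    m = Xw.shape[1]
    pvalues = np.ones(k)
    slopes = np.zeros(k)
    flags = np.array([""] * k, dtype=object)
    flags[degenerate] = "degenerate"
    if m:
        b0 = np.full(m, special.logit(pbar))
        b1 = np.zeros(m)
        yc = y[:, None]
        for _ in range(max_iter):
            eta = np.clip(b0[None, :] + Xw * b1[None, :], -_ETA_CAP, _ETA_CAP)
            mu = special.expit(eta)
            w = mu * (1.0 - mu)
            resid = yc - mu
            g0 = resid.sum(axis=0)
            g1 = (resid * Xw).sum(axis=0)
            h00 = w.sum(axis=0) + _RIDGE
            h01 = (w * Xw).sum(axis=0)
            h11 = (w * Xw * Xw).sum(axis=0) + _RIDGE
            det = h00 * h11 - h01 * h01
            d0 = (h11 * g0 - h01 * g1) / det
            d1 = (h00 * g1 - h01 * g0) / det
            b0 += d0
            b1 += d1
            if max(np.abs(d0).max(initial=0.0), np.abs(d1).max(initial=0.0)) < tol:
                break
        eta = np.clip(b0[None, :] + Xw * b1[None, :], -_ETA_CAP, _ETA_CAP)
        mu = np.clip(special.expit(eta), 1e-15, 1 - 1e-15)
        ll_full = (yc * np.log(mu) + (1 - yc) * np.log(1 - mu)).sum(axis=0)
        lrt = np.clip(2.0 * (ll_full - ll_null), 0.0, None)
        p = stats.chi2.sf(lrt, df=1)
        pvalues[~degenerate] = np.clip(p, np.finfo(float).tiny, 1.0)
        slopes[~degenerate] = b1
        separated = -2.0 * ll_full < _SEPARATION_DEVIANCE
        idx = np.flatnonzero(~degenerate)
        flags[idx[separated]] = "separation"
    return pvalues, slopes, flags


def anova_scan(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way ANOVA F-test p-value per column (alternative scorer)."""
    groups = [X[labels == c] for c in np.unique(labels)]
    with np.errstate(invalid="ignore", divide="ignore"):
        result = stats.f_oneway(*groups, axis=0)
    p = np.asarray(result.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0  # constant columns
    return p


@dataclass
class SignatureSet:
    """Regions passing the association cutoff, with per-region statistics."""

    selected: np.ndarray  # indices into the region set
    pvalues: np.ndarray  # min-over-classes p-value, all regions
    class_pvalues: dict[str, np.ndarray]
    class_effects: dict[str, np.ndarray]  # logistic slope per class
    flags: np.ndarray
    alpha: float

    def __len__(self) -> int:
        return len(self.selected)


def score_region_association(
    values: np.ndarray, labels: np.ndarray, method: str = "logistic"
) -> tuple[np.ndarray, dict[str, np.ndarray], dict[str, np.ndarray], np.ndarray]:
    """Screen every region (column of *values*) against the class labels.

    Returns (min-over-classes p-values, per-class p-values, per-class
    effects, per-region flags). Requires at least two classes with at
    least two samples each.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and len(labels) != 1:
        values = values.T
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("need at least two classes")
    if (counts < 2).any():
        small = classes[counts < 2]
        raise ValidationError(f"classes with fewer than two samples: {list(small)}")
    if method == "anova":
        p = anova_scan(values, labels)
        empty = np.zeros(values.shape[1])
        flags = np.where(np.ptp(values, axis=0) == 0, "degenerate", "").astype(object)
        return p, {c: p for c in classes}, {c: empty for c in classes}, flags
    if method != "logistic":
        raise ValidationError(f"unknown scoring method {method!r}")
    class_p: dict[str, np.ndarray] = {}
    class_eff: dict[str, np.ndarray] = {}
    flags = None
    for c in classes:
        p, slope, fl = logistic_lrt_scan(values, (labels == c).astype(float))
        class_p[str(c)] = p
        class_eff[str(c)] = slope
        flags = fl if flags is None else np.where(flags == "", fl, flags)
    min_p = np.min(np.stack(list(class_p.values())), axis=0)
    return min_p, class_p, class_eff, flags


class CnvSignatureSelector(SelectorMixin, BaseEstimator):
    """Select cancer-type-associated regions by per-region association p-value.

    Parameters
    ----------
    alpha : float, default 1e-12
        Strict selection cutoff: a region is kept iff its min-over-classes
        p-value is < alpha.
    method : {"logistic", "anova"}, default "logistic"
        Per-region scorer; one-vs-rest binomial LRT or one-way F-test.

    Attributes
    ----------
    pvalues_ : (n_features,) array of min-over-classes p-values.
    class_pvalues_, class_effects_ : per-class arrays keyed by label.
    flags_ : per-region "", "degenerate" or "separation".
    n_features_in_ : int
    """

    def __init__(self, alpha: float = 1e-12, method: str = "logistic"):
        self.alpha = alpha
        self.method = method

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=4)
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        self.n_features_in_ = X.shape[1]
        (
            self.pvalues_,
            self.class_pvalues_,
            self.class_effects_,
            self.flags_,
        ) = score_region_association(X, y, method=self.method)
        self.classes_ = np.unique(y)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "pvalues_")
        return self.pvalues_ < self.alpha

    def _more_tags(self):  # pragma: no cover - sklearn plumbing
        return {"requires_y": True}


def select_signatures(matrix, alpha: float = 1e-12, method: str = "logistic") -> SignatureSet:
    """Screen a labelled :class:`~clonorigin.regions.RegionMatrix` for signatures.

    Deterministic given its inputs; an empty selection is returned with
    a warning flag (downstream training refuses to proceed on it).
    """
    X = matrix.feature_matrix()
    y = matrix.label_array()
    selector = CnvSignatureSelector(alpha=alpha, method=method).fit(X, y)
    selected = np.flatnonzero(selector._get_support_mask())
    return SignatureSet(
        selected=selected,
        pvalues=selector.pvalues_,
        class_pvalues=selector.class_pvalues_,
        class_effects=selector.class_effects_,
        flags=selector.flags_,
        alpha=alpha,
    )
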