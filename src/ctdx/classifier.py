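"""Multimodal logistic classifier of durable clinical benefit.

The model is a plain binary logistic regression over up to three features —
log10 normalized bTMB, log10 ΔctDNA, and the 0/1 first-RECIST-responder
coding — fitted by iteratively reweighted least squares with step halving
(deviance never increases across iterations).  The operating threshold is
chosen on the training ROC by Youden's J = sensitivity + specificity − 1,
ties broken toward higher specificity then higher threshold.  External
validation freezes transforms, coefficients and threshold; nothing is
re-estimated.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .config import FeatureSpec
from .errors import ValidationError
from . import survival as sv

__all__ = [
    "FittedModel",
    "RocCurve",
    "OperatingPoint",
    "CvReport",
    "ScoreStrata",
    "build_features",
    "fit_logistic",
    "train_model",
    "predict_scores",
    "roc_auc",
    "youden_point",
    "confusion_stats",
    "repeated_cv",
    "external_validate",
    "stratify_by_score",
]

logger = logging.getLogger(__name__)

_RESPONDER_RECIST = {"CR", "PR"}
_NONRESPONDER_RECIST = {"SD", "PD"}
_CONTINUOUS = ("normalized_btmb", "delta_ctdna")


def build_features(
    metrics: pd.DataFrame,
    labels,
    spec: FeatureSpec | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the design matrix and 0/1 label vector.

    ``labels`` holds DCB/NDB/indeterminate per row of ``metrics``;
    indeterminate rows, and rows with a missing value in a used feature
    (e.g. RECIST ``NA`` for the 3-feature model), are dropped with a log
    line.  Continuous ratio features get ``log10(max(x, floor))``.
    """
    spec = spec or FeatureSpec()
    lab = pd.Series(np.asarray(labels, dtype=object), index=metrics.index)
    keep = lab.isin([sv.DCB, sv.NDB])
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("build_features: dropping %d indeterminate-label rows", n_drop)

    cols = {}
    for f in spec.features:
        if f == "recist_responder":
            if "recist_responder" in metrics.columns:
                col = metrics["recist_responder"].astype(float)
            elif "recist_first" in metrics.columns:
                r = metrics["recist_first"].astype(object)
                col = pd.Series(
                    np.where(r.isin(_RESPONDER_RECIST), 1.0,
                             np.where(r.isin(_NONRESPONDER_RECIST), 0.0, np.nan)),
                    index=metrics.index,
                )
            else:
                raise ValidationError("no recist_responder or recist_first column")
        else:
            if f not in metrics.columns:
                raise ValidationError(f"missing feature column {f!r}")
            col = metrics[f].astype(float)
            if f in _CONTINUOUS and spec.transform == "log10_floor":
                col = np.log10(np.maximum(col, spec.floor))
        cols[f] = col
    X = pd.DataFrame(cols, index=metrics.index)

    complete = ~X.isna().any(axis=1)
    n_missing = int((keep & ~complete).sum())
    if n_missing:
        logger.info("build_features: dropping %d rows with missing feature values", n_missing)
    keep = keep & complete
    X = X.loc[keep]
    y = (lab.loc[keep] == sv.DCB).to_numpy(dtype=int)
    return X, y


@dataclass
class RocCurve:
    """ROC by descending threshold sweep; positives are score > threshold."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray      # +inf, midpoints of sorted unique scores, -inf
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    youden_j: float


@dataclass
class FittedModel:
    """Logistic coefficients plus everything needed to apply the model
    verbatim to new data."""

    feature_names: list[str]
    coef: np.ndarray             # [intercept, per-feature...]
    spec: FeatureSpec
    converged: bool
    n_iter: int
    deviance: float
    mean_: np.ndarray | None = None   # training standardization stats
    scale_: np.ndarray | None = None
    roc: RocCurve | None = None
    operating_point: OperatingPoint | None = None
    ridge: float = 0.0

    def to_json(self) -> str:
        d = {
            "feature_names": self.feature_names,
            "coef": [float(c) for c in self.coef],
            "spec": {
                "features": list(self.spec.features),
                "transform": self.spec.transform,
                "floor": self.spec.floor,
                "standardize": self.spec.standardize,
            },
            "converged": self.converged,
            "n_iter": self.n_iter,
            "deviance": self.deviance,
            "ridge": self.ridge,
            "mean": None if self.mean_ is None else [float(v) for v in self.mean_],
            "scale": None if self.scale_ is None else [float(v) for v in self.scale_],
            "threshold": None if self.operating_point is None else self.operating_point.threshold,
            "auc": None if self.roc is None else self.roc.auc,
        }
        return json.dumps(d, indent=2, sort_keys=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _deviance(y, p, eps=1e-12) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_logistic(
    X,
    y,
    ridge: float = 0.0,
    spec: FeatureSpec | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FittedModel:
    """Maximum-likelihood logistic regression by IRLS with step halving.

    ``ridge`` adds an L2 penalty (not on the intercept).  Coefficients
    diverging without the deviance settling — the complete-separation
    signature — trigger an automatic refit with a small ridge (1e-6) and a
    warning, keeping small-cohort fits finite.
    """
    Xdf = pd.DataFrame(X)
    names = [str(c) for c in Xdf.columns]
    Xm = Xdf.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("labels must be 0/1")
    if np.unique(y).size < 2:
        raise ValidationError("both classes must be present")
    n, p = Xm.shape
    if n <= p + 1:
        raise ValidationError(f"need n > n_features + 1 (n={n}, features={p})")

    spec = spec or FeatureSpec(features=tuple(
        f for f in names if f in ("normalized_btmb", "delta_ctdna", "recist_responder")
    ) or ("delta_ctdna",))

    mean_ = scale_ = None
    if spec.standardize:
        mean_ = Xm.mean(axis=0)
        scale_ = Xm.std(axis=0, ddof=0)
        scale_[scale_ == 0] = 1.0
        Xm = (Xm - mean_) / scale_

    A = np.hstack([np.ones((n, 1)), Xm])
    pen = np.full(p + 1, ridge)
    pen[0] = 0.0

    beta = np.zeros(p + 1)
    dev = _deviance(y, _sigmoid(A @ beta)) + ridge * float(beta[1:] @ beta[1:])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = _sigmoid(A @ beta)
        W = mu * (1 - mu)
        grad = A.T @ (y - mu) - pen * beta
        H = (A * W[:, None]).T @ A + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving keeps the penalized deviance non-increasing
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            cdev = _deviance(y, _sigmoid(A @ cand)) + ridge * float(cand[1:] @ cand[1:])
            if cdev <= dev + 1e-12:
                break
            alpha *= 0.5
        beta, dev = cand, cdev
        if np.max(np.abs(grad)) < tol:
            converged = True
            break

    if ridge == 0.0 and np.max(np.abs(beta)) > 30.0:
        warnings.warn(
            "possible complete separation in logistic fit; refitting with ridge=1e-6",
            RuntimeWarning,
        )
        m = fit_logistic(Xdf, y, ridge=1e-6, spec=spec, tol=tol, max_iter=max_iter)
        return m

    return FittedModel(
        feature_names=names,
        coef=beta,
        spec=spec,
        converged=converged,
        n_iter=it,
        deviance=_deviance(y, _sigmoid(A @ beta)),
        mean_=mean_,
        scale_=scale_,
        ridge=ridge,
    )


def predict_scores(model: FittedModel, X) -> np.ndarray:
    """Predicted DCB probabilities under a fitted model."""
    Xdf = pd.DataFrame(X)
    missing = [c for c in model.feature_names if c not in Xdf.columns]
    if missing:
        raise ValidationError(f"feature mismatch: missing {missing}")
    Xm = Xdf[model.feature_names].to_numpy(dtype=float)
    if model.mean_ is not None:
        Xm = (Xm - model.mean_) / model.scale_
    A = np.hstack([np.ones((Xm.shape[0], 1)), Xm])
    return _sigmoid(A @ model.coef)


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve and trapezoid AUC (tied scores contribute 1/2).

    Thresholds are +inf, the midpoints between consecutive sorted unique
    scores, and -inf, so each point is realizable by the strict
    score-above-threshold rule.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs both classes present")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[np.inf], mids[::-1], [-np.inf]])
    fpr = np.empty(thresholds.size)
    tpr = np.empty(thresholds.size)
    for i, th in enumerate(thresholds):
        pred = s > th
        tpr[i] = (pred & (y == 1)).sum() / n_pos
        fpr[i] = (pred & (y == 0)).sum() / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
                    n_pos=n_pos, n_neg=n_neg)


def youden_point(roc: RocCurve) -> OperatingPoint:
    """Operating point maximizing Youden's J over the ROC thresholds.

    Ties go to the higher specificity (lower FPR), then the higher
    threshold.
    """
    j = roc.tpr - roc.fpr
    # lexicographic: max J, then min fpr, then max threshold
    order = sorted(
        range(j.size),
        key=lambda i: (-j[i], roc.fpr[i], -roc.thresholds[i]),
    )
    i = order[0]
    n = roc.n_pos + roc.n_neg
    tp = roc.tpr[i] * roc.n_pos
    tn = (1 - roc.fpr[i]) * roc.n_neg
    return OperatingPoint(
        threshold=float(roc.thresholds[i]),
        sensitivity=float(roc.tpr[i]),
        specificity=float(1 - roc.fpr[i]),
        accuracy=float((tp + tn) / n),
        youden_j=float(j[i]),
    )


def confusion_stats(scores, labels, threshold: float) -> dict:
    """Sensitivity, specificity, accuracy and the raw confusion counts at a
    threshold (positive = score strictly above)."""
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = s > threshold
    tp = int((pred & (y == 1)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    return {
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": (tp + tn) / y.size,
    }


def train_model(X, y, spec: FeatureSpec | None = None, ridge: float = 0.0) -> FittedModel:
    """Fit the logistic model and attach its training ROC and Youden
    operating point."""
    model = fit_logistic(X, y, ridge=ridge, spec=spec)
    scores = predict_scores(model, X)
    model.roc = roc_auc(scores, y)
    model.operating_point = youden_point(model.roc)
    return model


@dataclass
class CvReport:
    """AUCs from repeated stratified k-fold cross-validation."""

    aucs: np.ndarray            # shape (repeats, k)
    mean: float
    sd: float
    k: int
    repeats: int
    seed: int


def repeated_cv(X, y, k: int = 5, repeats: int = 20, seed: int = 0,
                spec: FeatureSpec | None = None) -> CvReport:
    """Repeated stratified k-fold CV of the logistic model, scored by
    held-out AUC.  Fold assignment is stratified by class and fully
    determined by ``seed``."""
    Xdf = pd.DataFrame(X).reset_index(drop=True)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValidationError(f"each class needs >= k={k} members, got {counts.tolist()}")
    rng = np.random.SeedSequence(seed)
    fold_seeds = rng.generate_state(repeats)
    aucs = np.empty((repeats, k))
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(fold_seeds[r] % (2**31)))
        for f, (tr, te) in enumerate(skf.split(Xdf, y)):
            m = fit_logistic(Xdf.iloc[tr], y[tr], spec=spec)
            s = predict_scores(m, Xdf.iloc[te])
            aucs[r, f] = roc_auc(s, y[te]).auc
    return CvReport(aucs=aucs, mean=float(aucs.mean()), sd=float(aucs.std(ddof=1)),
                    k=k, repeats=repeats, seed=seed)


def external_validate(model: FittedModel, X_ext, y_ext) -> tuple[OperatingPoint, RocCurve]:
    """Apply a frozen model (transforms, coefficients, threshold) to an
    external cohort; nothing is re-estimated."""
    if model.operating_point is None:
        raise ValidationError("model has no training operating point; use train_model")
    scores = predict_scores(model, X_ext)
    roc = roc_auc(scores, y_ext)
    cs = confusion_stats(scores, y_ext, model.operating_point.threshold)
    op = OperatingPoint(
        threshold=model.operating_point.threshold,
        sensitivity=cs["sensitivity"],
        specificity=cs["specificity"],
        accuracy=cs["accuracy"],
        youden_j=cs["sensitivity"] + cs["specificity"] - 1.0,
    )
    return op, roc


@dataclass
class ScoreStrata:
    """Survival contrast between high- and low-score patients."""

    km_high: sv.KMCurve
    km_low: sv.KMCurve
    logrank: sv.LogRankResult
    cox: sv.CoxResult
    n_high: int
    n_low: int

    @property
    def hazard_ratio(self) -> float:
        return float(self.cox.hr[0])


def stratify_by_score(scores, threshold: float, time, event) -> ScoreStrata:
    """Split patients at the model threshold and contrast their survival:
    both KM curves, the log-rank test and the high-vs-low Cox HR."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    high = s > threshold
    if high.all() or (~high).all():
        raise ValidationError("threshold leaves an empty stratum")
    km_high = sv.km_fit(t[high], e[high])
    km_low = sv.km_fit(t[~high], e[~high])
    lr = sv.logrank_test(t, e, high.astype(int))
    cox = sv.cox_fit(t, e, pd.DataFrame({"high_score": high.astype(float)}))
    return ScoreStrata(km_high=km_high, km_low=km_low, logrank=lr, cox=cox,
                       n_high=int(high.sum()), n_low=int((~high).sum()))
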