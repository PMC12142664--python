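"""Binomial linear classifier, data splitting and performance accounting.

The classifier is a penalized logistic regression (elastic net by default,
with the penalty strength chosen by internal cross-validation on the
training data only). Evaluation follows the clinical-classifier
conventions: stratified 70/30 train/test split with per-class floor
rounding, leave-one-out cross-validation with the feature transform refit
inside every fold (no leakage), and confusion-matrix accuracy /
sensitivity / specificity plus the rank-formulation AUROC.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
import sklearn.metrics as skm

from .cohortsim import ROLE_STUDY, FeatureTable
from .preprocess import TransformState, apply_transform, fit_transform

POSITIVE = "shock"


# ---------------------------------------------------------------------------
# model containers

@dataclass
class PenaltySpec:
    """Regularization of the binomial fit.

    kind: 'elastic_net', 'l1', 'l2' or 'none'. When ``C`` is None the
    inverse strength is chosen by ``cv``-fold internal cross-validation over
    ``Cs`` on the training data.
    """

    kind: str = "elastic_net"
    l1_ratio: float = 0.5
    C: float | None = 1.0
    Cs: tuple[float, ...] = tuple(np.logspace(-2, 2, 9))
    cv: int = 3
    seed: int = 0
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if self.kind not in ("elastic_net", "l1", "l2", "none"):
            raise ValueError(f"unknown penalty kind {self.kind!r}")
        if not 0 <= self.l1_ratio <= 1:
            raise ValueError("l1_ratio must lie in [0, 1]")


@dataclass
class FittedModel:
    """Intercept + coefficients on the model (standardized-input) scale."""

    intercept: float
    coefficients: np.ndarray
    feature_ids: list[str]
    transform: TransformState | None = None
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.feature_ids):
            raise ValueError("coefficient/feature length mismatch")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class PerformanceReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    auroc: float = float("nan")
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    scores: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": round(100 * self.accuracy, 1),
            "sensitivity": round(100 * self.sensitivity, 1),
            "specificity": round(100 * self.specificity, 1),
            "auroc": None if np.isnan(self.auroc) else round(self.auroc, 3),
        }


# ---------------------------------------------------------------------------
# splitting

def stratified_split(samples: pd.DataFrame, train_frac: float, seed: int):
    """Per-class floor-rounded train/test partition of the study samples.

    Each class contributes floor(train_frac * n_class) training samples;
    the remainder go to test. 124 samples (32 shock / 92 nonshock) at 0.7
    give the canonical 86-train / 38-test split.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    study = samples[samples["role"] == ROLE_STUDY] if "role" in samples.columns else samples
    labels = study["label"]
    classes = labels.dropna().unique()
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for cls in sorted(classes):
        ids = np.array(sorted(labels.index[labels == cls]))
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        n_train = int(np.floor(train_frac * len(ids)))
        perm = rng.permutation(len(ids))
        train_ids += list(ids[perm[:n_train]])
        test_ids += list(ids[perm[n_train:]])
    return sorted(train_ids), sorted(test_ids)


# ---------------------------------------------------------------------------
# fitting and scoring

def _labels_to_binary(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "OUS":
        return (y == POSITIVE).astype(int)
    uniq = np.unique(y)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError(f"labels must be binary or shock/nonshock, got {uniq}")
    return y.astype(int)


def fit_glm(X: pd.DataFrame | np.ndarray, y, penalty: PenaltySpec | None = None) -> FittedModel:
    """Penalized maximum-likelihood fit of the binomial linear model."""
    penalty = penalty or PenaltySpec()
    feature_ids = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    Xv = np.asarray(X, dtype=float)
    yv = _labels_to_binary(y)
    if not np.isfinite(Xv).all():
        raise ValueError("model matrix contains non-finite values")
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present")
    if penalty.kind != "none" and penalty.C is None:
        penalty = _choose_C(Xv, yv, penalty)
    est = _make_estimator(penalty)
    est.fit(Xv, yv)
    coef = est.coef_.ravel().astype(float)
    icpt = float(np.asarray(est.intercept_).ravel()[0])
    if penalty.kind == "none":
        p = np.clip(est.predict_proba(Xv)[:, 1], 1e-300, 1 - 1e-16)
        loss = -np.mean(yv * np.log(p) + (1 - yv) * np.log(1 - p))
        if loss < 1e-4 and np.max(np.abs(coef), initial=0.0) > 10:
            raise ValueError(
                "perfect separation: unpenalized coefficients diverge; enable a penalty"
            )
    return FittedModel(icpt, coef, feature_ids)


def _make_estimator(penalty: PenaltySpec):
    common = dict(max_iter=penalty.max_iter, tol=1e-8)
    if penalty.kind == "none":
        return LogisticRegression(C=np.inf, solver="lbfgs", **common)
    if penalty.kind == "elastic_net":
        # saga's duality gap closes slowly; 1e-4 is ample for stable
        # coefficients at these problem sizes
        return LogisticRegression(solver="saga", l1_ratio=penalty.l1_ratio,
                                  C=penalty.C, random_state=penalty.seed,
                                  max_iter=penalty.max_iter, tol=1e-4)
    return LogisticRegression(solver="liblinear", C=penalty.C,
                              l1_ratio=1 if penalty.kind == "l1" else 0,
                              random_state=penalty.seed, **common)


def _choose_C(Xv: np.ndarray, yv: np.ndarray, penalty: PenaltySpec) -> PenaltySpec:
    """Pick the inverse penalty strength by stratified K-fold log-loss on the
    training data only; ties favor the stronger penalty."""
    n_splits = min(penalty.cv, int(np.bincount(yv).min()))
    if n_splits < 2:
        raise ValueError("too few samples per class for internal CV")
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=penalty.seed)
    folds = list(cv.split(Xv, yv))
    losses = []
    for C in penalty.Cs:
        cand = dataclasses.replace(penalty, C=float(C))
        loss = 0.0
        for tr, te in folds:
            est = _make_estimator(cand)
            est.fit(Xv[tr], yv[tr])
            p = np.clip(est.predict_proba(Xv[te])[:, 1], 1e-12, 1 - 1e-12)
            loss += -np.mean(yv[te] * np.log(p) + (1 - yv[te]) * np.log(1 - p))
        losses.append(loss / len(folds))
    best = int(np.argmin(losses))  # first on ties: strongest penalty when Cs ascend
    return dataclasses.replace(penalty, C=float(penalty.Cs[best]))


def predict_scores(model: FittedModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Posterior shock probabilities: inverse-logit of the linear predictor."""
    if isinstance(X, pd.DataFrame):
        missing = [f for f in model.feature_ids if f not in X.columns]
        extra = [f for f in X.columns if f not in model.feature_ids]
        if missing or extra:
            raise ValueError(f"feature mismatch; missing={missing[:5]}, extra={extra[:5]}")
        Xv = X[model.feature_ids].to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.shape[1] != len(model.feature_ids):
            raise ValueError("column count does not match model features")
    eta = model.intercept + Xv @ model.coefficients
    return 1.0 / (1.0 + np.exp(-eta))


# ---------------------------------------------------------------------------
# performance accounting

def confusion_metrics(tp: int, fp: int, tn: int, fn: int):
    """(accuracy, sensitivity, specificity) as proportions in [0, 1]."""
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    return accuracy, sensitivity, specificity


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties = 1/2).

    Mann-Whitney rank formulation; exactly the trapezoidal area under the
    empirical ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = _labels_to_binary(labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(scores, labels) -> list[tuple[float, float]]:
    """(fpr, tpr) points from (0,0) to (1,1), both coordinates non-decreasing."""
    y = _labels_to_binary(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = skm.roc_curve(y, np.asarray(scores, dtype=float), drop_intermediate=False)
    pts = list(zip(fpr.tolist(), tpr.tolist()))
    if pts[0] != (0.0, 0.0):
        pts.insert(0, (0.0, 0.0))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts


def report_from_scores(scores, labels, threshold: float = 0.5) -> PerformanceReport:
    s = np.asarray(scores, dtype=float)
    y = _labels_to_binary(labels)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    acc, sens, spec = confusion_metrics(tp, fp, tn, fn)
    both = len(np.unique(y)) == 2
    return PerformanceReport(
        tp, fp, tn, fn, acc, sens, spec,
        auroc=auroc(s, y) if both else float("nan"),
        roc_points=roc_curve(s, y) if both else [],
        scores=s,
    )


def evaluate(model: FittedModel, X, y) -> PerformanceReport:
    """Score the model on (X, y) and assemble the confusion/ROC report."""
    return report_from_scores(predict_scores(model, X), y, model.threshold)


# ---------------------------------------------------------------------------
# leave-one-out cross-validation

def loocv_evaluate(
    X: pd.DataFrame,
    y,
    penalty: PenaltySpec | None = None,
    refit_transform: bool = False,
    threshold: float = 0.5,
) -> PerformanceReport:
    """LOOCV: refit on n-1 samples, score the held-out one; report on the
    n held-out scores.

    With ``refit_transform=True`` ``X`` is an untransformed intensity table
    and the log10/autoscale transform is relearned inside every fold, so no
    statistic of the held-out sample leaks into its own prediction.
    """
    penalty = penalty or PenaltySpec(kind="l2", C=1.0)
    yv = _labels_to_binary(y)
    n = len(yv)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present")
    inten = X.intensities if isinstance(X, FeatureTable) else X
    scores = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        try:
            if refit_transform:
                state = fit_transform(inten.iloc[tr])
                Xtr = apply_transform(state, inten.iloc[tr])
                Xte = apply_transform(state, inten.iloc[[i]])
            else:
                Xtr, Xte = inten.iloc[tr], inten.iloc[[i]]
            model = fit_glm(Xtr, yv[tr], penalty)
            scores[i] = predict_scores(model, Xte)[0]
        except Exception as exc:  # noqa: BLE001 - annotate the failing fold
            raise RuntimeError(f"LOOCV refit failed on fold {i} ({inten.index[i]})") from exc
    return report_from_scores(scores, yv, threshold)
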