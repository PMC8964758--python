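"""SMOTE oversampling, the RBF-kernel soft-margin classifier, and
leave-one-out evaluation.

The classifier contract is a soft-margin SVM with the radial basis function
kernel K(x, x') = exp(−γ‖x−x'‖²), trained on z-scored features, with the
HCC (case) side of the boundary positive by convention. Beyond prediction
it exposes the signed distance to the decision boundary in the reproducing
kernel Hilbert space (RKHS),

    d(x) = f(x) / ‖w‖_H ,   ‖w‖_H² = Σ_ij α_i α_j y_i y_j K(x_i, x_j),

which is the ordinal severity statistic used by the staging analysis.

Class imbalance inside the control group (few healthy volunteers, many
cirrhotics) is handled with SMOTE: synthetic minority points interpolated
uniformly between a minority sample and one of its k nearest minority
neighbors. During leave-one-out CV, SMOTE and standardization are both
refit inside each training fold so the held-out sample never leaks into
either.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVC

from ._rng import substream

__all__ = [
    "ClassifierConfig",
    "CVMetrics",
    "BreathSVC",
    "smote_oversample",
    "fit_classifier",
    "loo_evaluate",
    "signed_distance",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """Kernel-classifier and SMOTE settings.

    γ ("scale" = 1/(n_features · Var[X]), sklearn's convention) and C default
    to single-setting use without nested tuning; ``smote_k`` follows the
    original SMOTE formulation's five neighbors.
    """

    gamma: float | str = "scale"
    C: float = 1.0
    standardize: bool = True
    smote_k: int = 5
    smote_target: str = "balance_control_subgroups"
    seed: int = 0

    def validate(self) -> None:
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")


@dataclass(frozen=True)
class CVMetrics:
    """Pooled confusion counts with derived fractions (positive = HCC).

    ``mean_margin`` is the mean held-out signed decision margin y·f(x)
    (positive when correct), recorded by LOO evaluation. It is a tie-break
    quantity for subset ranking: on strongly separable panels many subsets
    tie at accuracy 1, and the margin still orders them by how confidently
    they separate.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    mean_margin: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def smote_oversample(
    minority: np.ndarray,
    target: int,
    k: int = 5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Synthesize ``target − n`` minority points by k-NN interpolation.

    Each synthetic point is x_i + λ (x_nn − x_i) with λ ~ Uniform(0, 1) and
    x_nn one of the k nearest minority neighbors of a randomly chosen base
    point x_i (Euclidean distance in the coordinates given — pass
    standardized features). Returns an empty array when target ≤ n.
    """
    minority = np.asarray(minority, dtype=float)
    n = len(minority)
    if n < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    if k > n - 1:
        raise ValueError(f"k={k} exceeds available neighbors (n-1={n - 1})")
    n_new = target - n
    if n_new <= 0:
        return np.empty((0, minority.shape[1]))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    d2 = np.sum((minority[:, None, :] - minority[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.argsort(d2, axis=1, kind="stable")[:, :k]

    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    lam = rng.random(n_new)
    neighbors = minority[nn_idx[base, pick]]
    return minority[base] + lam[:, None] * (neighbors - minority[base])


class BreathSVC(BaseEstimator, ClassifierMixin):
    """RBF-kernel soft-margin SVM with z-score standardization and RKHS
    boundary distances.

    Parameters
    ----------
    gamma, C : kernel bandwidth and soft-margin cost (sklearn conventions).
    standardize : z-score features using means/SDs of the fit data only.
    positive_label : the label treated as the positive (HCC) class; its side
        of the boundary has positive decision values. A decision value of
        exactly 0 is classified as the negative (control) class.

    Fitted attributes (trailing underscore) expose the dual form — support
    vectors in standardized coordinates, dual coefficients α_i·y_i, bias,
    and the RKHS norm ‖w‖_H — sufficient to re-evaluate decision values
    independently.
    """

    def __init__(self, gamma="scale", C: float = 1.0, standardize: bool = True,
                 positive_label=1):
        self.gamma = gamma
        self.C = C
        self.standardize = standardize
        self.positive_label = positive_label

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        pos = y == self.positive_label
        if pos.all() or (~pos).all():
            raise ValueError("fit requires at least one sample of each class")
        y01 = pos.astype(int)
        self.classes_ = np.unique(y)

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        Xs = (X - self.mean_) / self.scale_

        svc = SVC(kernel="rbf", gamma=self.gamma, C=self.C)
        svc.fit(Xs, y01)  # classes_ [0, 1] -> decision positive on class 1 (HCC)
        self._svc = svc
        self.support_vectors_ = svc.support_vectors_
        self.dual_coef_ = svc.dual_coef_[0]
        self.intercept_ = float(svc.intercept_[0])
        if self.gamma == "scale":
            xv = Xs.var()
            self.gamma_ = 1.0 / (X.shape[1] * xv) if xv > 0 else 1.0
        elif self.gamma == "auto":
            self.gamma_ = 1.0 / X.shape[1]
        else:
            self.gamma_ = float(self.gamma)
        K = rbf_kernel(self.support_vectors_, self.support_vectors_, gamma=self.gamma_)
        self.rkhs_norm_ = float(np.sqrt(max(self.dual_coef_ @ K @ self.dual_coef_, 0.0)))
        return self

    def decision_function(self, X) -> np.ndarray:
        """f(x) = Σ α_i y_i K(x_i, x) + b on standardized coordinates."""
        Xs = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        return self._svc.decision_function(Xs)

    def predict(self, X) -> np.ndarray:
        """Positive label where f(x) > 0; ties (f = 0) go to the control side."""
        f = self.decision_function(X)
        neg = [c for c in self.classes_ if c != self.positive_label]
        negative_label = neg[0] if neg else self.positive_label
        out = np.where(f > 0, self.positive_label, negative_label)
        return out

    def signed_distance(self, X) -> np.ndarray:
        """RKHS-normalized boundary distance f(x)/‖w‖_H (positive = HCC side)."""
        if self.rkhs_norm_ <= 0:
            raise ValueError("degenerate model: RKHS norm is zero")
        return self.decision_function(X) / self.rkhs_norm_

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "gamma": self.gamma_,
            "C": self.C,
            "intercept": self.intercept_,
            "dual_coef": self.dual_coef_.tolist(),
            "support_vectors": self.support_vectors_.tolist(),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "rkhs_norm": self.rkhs_norm_,
            "classes": np.asarray(self.classes_).tolist(),
            "positive_label": self.positive_label,
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def decision_from_json(doc: str | dict, X) -> np.ndarray:
        """Re-evaluate decision values from a serialized dual form."""
        if isinstance(doc, str):
            doc = json.loads(doc)
        Xs = (np.asarray(X, dtype=float) - np.asarray(doc["mean"])) / np.asarray(doc["scale"])
        K = rbf_kernel(Xs, np.asarray(doc["support_vectors"]), gamma=doc["gamma"])
        return K @ np.asarray(doc["dual_coef"]) + doc["intercept"]


def fit_classifier(X, y, config: ClassifierConfig = ClassifierConfig(),
                   positive_label="hcc") -> BreathSVC:
    """Fit a :class:`BreathSVC` from a :class:`ClassifierConfig`."""
    config.validate()
    clf = BreathSVC(gamma=config.gamma, C=config.C, standardize=config.standardize,
                    positive_label=positive_label)
    return clf.fit(X, y)


def signed_distance(model: BreathSVC, X) -> np.ndarray:
    return model.signed_distance(X)


def _fold_smote(Xs_train, pos_train, subgroups, k, rng):
    """Balance the minority control subgroup up to the majority subgroup
    count inside one (already standardized) training fold."""
    if subgroups is None:
        return Xs_train, pos_train
    ctrl_mask = ~pos_train
    labels, counts = np.unique(subgroups[ctrl_mask], return_counts=True)
    if len(labels) < 2 or counts.min() == counts.max():
        return Xs_train, pos_train
    minority = labels[np.argmin(counts)]
    target = int(counts.max())
    pts = Xs_train[ctrl_mask & (subgroups == minority)]
    if len(pts) < 2:
        return Xs_train, pos_train
    k_eff = min(k, len(pts) - 1)
    synth = smote_oversample(pts, target, k=k_eff, seed=rng)
    if len(synth) == 0:
        return Xs_train, pos_train
    return np.vstack([Xs_train, synth]), np.concatenate([pos_train, np.zeros(len(synth), bool)])


def loo_evaluate(
    X,
    y,
    config: ClassifierConfig = ClassifierConfig(),
    positive_label="hcc",
    smote_subgroups=None,
) -> CVMetrics:
    """Leave-one-out CV pooled into a single confusion table.

    For each sample: hold it out; standardize on the remaining samples;
    apply SMOTE within the designated control subgroups (``smote_subgroups``
    is a per-sample subgroup label array, typically healthy/cirrhosis for
    controls); fit; predict the held-out sample. Positive class = HCC.
    """
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos = y == positive_label if not np.issubdtype(y.dtype, np.bool_) else y
    n = len(X)
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValueError("LOO evaluation needs n >= 2 per class")
    subgroups = None if smote_subgroups is None else np.asarray(smote_subgroups)

    rng = substream(config.seed, "loo-smote")
    tp = tn = fp = fn = 0
    margins = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        X_tr, pos_tr = X[tr], pos[tr]
        if config.standardize:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)
        else:
            mu, sd = 0.0, 1.0
        Xs_tr = (X_tr - mu) / sd
        sub_tr = None if subgroups is None else subgroups[tr]
        Xs_aug, pos_aug = _fold_smote(Xs_tr, pos_tr, sub_tr, config.smote_k, rng)
        svc = SVC(kernel="rbf", gamma=config.gamma, C=config.C)
        svc.fit(Xs_aug, pos_aug.astype(int))
        f = svc.decision_function(((X[i] - mu) / sd).reshape(1, -1))[0]
        pred_pos = f > 0
        margins[i] = f if pos[i] else -f
        if pos[i]:
            tp += pred_pos
            fn += not pred_pos
        else:
            fp += pred_pos
            tn += not pred_pos
    return CVMetrics(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn),
                     mean_margin=float(margins.mean()))
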