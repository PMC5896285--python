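"""Pairwise classification protocol: LDA and RBF-SVM under repeated random
subsampling, with accuracy / sensitivity / specificity / ROC / AUC metrics.

The protocol mirrors the evaluation design the band-peak features were built
for: each class contributes 200 epochs; per repetition, 50 epochs per class
are drawn (without replacement) for training and 50 test epochs are drawn
from the pooled disjoint remainder; 100 repetitions give the reported mean
accuracy and its standard deviation.  Features are z-scored with the
training split's statistics only, so there is no leakage.

The SVM is off-the-shelf (scikit-learn); the two-class LDA is the ten-line
closed form, written out so its ridge regularization, equal-priors bias and
zero-score tie-break are exactly the documented contract.  The protocol,
score conventions and the rank-based ROC/AUC are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from sklearn.svm import SVC

__all__ = [
    "KernelSpec",
    "ProtocolSpec",
    "EvaluationResult",
    "RocCurve",
    "fit_predict_lda",
    "fit_predict_svm",
    "roc_auc",
    "evaluate_pairwise",
    "CLASSIFIERS",
]

CLASSIFIERS = ("lda", "svm_rbf")


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian RBF kernel k(x, x') = exp(-||x - x'||^2 / (2 sigma^2)).

    ``sigma=None`` selects the median pairwise training-distance heuristic, a
    parameter-free default that adapts to feature scale.  ``C`` is the
    soft-margin penalty.
    """

    sigma: float | None = None
    C: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma is not None and not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError("sigma must be finite and positive (or None for heuristic)")
        if not self.C > 0:
            raise ValueError("C must be positive")

    def resolve_sigma(self, X_train: np.ndarray) -> float:
        if self.sigma is not None:
            return self.sigma
        d = pdist(X_train)
        med = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
        return med if med > 0 else 1.0


@dataclass(frozen=True)
class ProtocolSpec:
    """Repeated random subsampling protocol parameters."""

    n_train_per_class: int = 50
    n_test_draw: int = 50
    n_repetitions: int = 100
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train_per_class < 1 or self.n_test_draw < 1:
            raise ValueError("train/test counts must be >= 1")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass
class EvaluationResult:
    """Accuracy distribution and derived metrics for one (pair, channel, clf)."""

    task_pair: tuple[str, str]
    channel_name: str
    classifier_id: str
    accuracies: np.ndarray            # per-repetition accuracy, percent
    sensitivity: float                # percent; positive class = task_pair[0]
    specificity: float                # percent
    auc: float
    confusion: dict = field(default_factory=dict)  # total TP/TN/FP/FN over reps

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def _predict_from_scores(scores: np.ndarray, classes: np.ndarray) -> np.ndarray:
    # score > 0 -> higher-index class; ties (score == 0) go to the lower one
    return np.where(scores > 0, classes[1], classes[0])


def fit_predict_lda(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear discriminant analysis: predicted labels plus decision scores.

    Closed-form two-class LDA with equal priors (the protocol always trains
    on balanced splits): score(x) = w.x + b with w = S^-1 (mu1 - mu0) and
    b = -w.(mu0 + mu1)/2, where S is the pooled within-class covariance
    regularized by a ridge of 1e-6 * trace(S)/dim (an absolute 1e-12 floor
    when the scatter is exactly zero), so a singular scatter can never crash
    the protocol.  Positive score means the higher-index class; a zero score
    breaks toward the lower one.
    """
    classes = np.unique(y_train)
    if len(classes) != 2:
        raise ValueError(f"binary classifier needs exactly 2 classes, got {len(classes)}")
    X0 = X_train[y_train == classes[0]]
    X1 = X_train[y_train == classes[1]]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("LDA needs >= 2 training samples per class")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    C0 = (X0 - mu0).T @ (X0 - mu0)
    C1 = (X1 - mu1).T @ (X1 - mu1)
    S = (C0 + C1) / (len(X0) + len(X1) - 2)
    d = S.shape[0]
    tr = np.trace(S)
    ridge = 1e-6 * tr / d if tr > 0 else 1e-12
    w = np.linalg.solve(S + ridge * np.eye(d), mu1 - mu0)
    scores = X_test @ w - 0.5 * w @ (mu0 + mu1)
    return _predict_from_scores(scores, classes), scores


def fit_predict_svm(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    kernel: KernelSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Soft-margin SVM with Gaussian RBF kernel; labels plus decision values.

    The decision value is sum_i alpha_i y_i k(x_i, x) + b whose sign is the
    predicted class; the continuous value feeds the ROC analysis.
    """
    kernel = kernel or KernelSpec()
    classes = np.unique(y_train)
    if len(classes) != 2:
        raise ValueError(f"binary classifier needs exactly 2 classes, got {len(classes)}")
    sigma = kernel.resolve_sigma(X_train)
    clf = SVC(C=kernel.C, kernel="rbf", gamma=1.0 / (2.0 * sigma**2))
    clf.fit(X_train, y_train)
    scores = clf.decision_function(X_test)
    return _predict_from_scores(scores, classes), scores


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve and AUC from continuous scores and binary labels.

    ``labels`` is boolean-like with True/1 = positive.  The curve sweeps all
    distinct score thresholds; the AUC is the rank-average Mann-Whitney
    statistic, identical to the trapezoidal area under the tie-grouped curve
    and to the probability that a random positive outscores a random
    negative (ties count one half).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = labels[order]
    tp = np.cumsum(sorted_pos)
    fp = np.cumsum(~sorted_pos)
    # keep only the last point of each tied-score run
    keep = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tp[keep] / n_pos]
    fpr = np.r_[0.0, fp[keep] / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[keep]]
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=float(auc))


def standardize(X_train: np.ndarray, *others: np.ndarray):
    """Z-score using the training split's mean/sd (sd of 0 maps to 1)."""
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return tuple((X - mu) / sd for X in (X_train, *others))


def _fit_predict(classifier_id, X_train, y_train, X_test, kernel):
    if classifier_id == "lda":
        return fit_predict_lda(X_train, y_train, X_test)
    if classifier_id == "svm_rbf":
        return fit_predict_svm(X_train, y_train, X_test, kernel)
    raise ValueError(f"unknown classifier_id {classifier_id!r}; expected {CLASSIFIERS}")


def evaluate_pairwise(
    features_pos: np.ndarray,
    features_neg: np.ndarray,
    task_pair: tuple[str, str],
    classifier_id: str = "svm_rbf",
    protocol: ProtocolSpec | None = None,
    kernel: KernelSpec | None = None,
    channel_name: str = "",
) -> EvaluationResult:
    """Run the repeated-subsampling protocol on one channel's feature sets.

    ``features_pos``/``features_neg`` are (n_epochs, dim) arrays for the two
    tasks; the first task of the pair is the positive class for sensitivity
    and specificity.  Each repetition independently redraws both the training
    epochs (per class, without replacement) and the test epochs (from the
    pooled remainder, without replacement).  Fully reproducible from
    ``protocol.rng_seed``.
    """
    protocol = protocol or ProtocolSpec()
    Xp = np.asarray(features_pos, dtype=np.float64)
    Xn = np.asarray(features_neg, dtype=np.float64)
    if Xp.ndim != 2 or Xn.ndim != 2 or Xp.shape[1] != Xn.shape[1]:
        raise ValueError("feature sets must be 2-D with matching dimensions")
    n_tr = protocol.n_train_per_class
    for name, X in (("positive", Xp), ("negative", Xn)):
        if len(X) < n_tr + 1:
            raise ValueError(
                f"protocol needs >= {n_tr + 1} epochs per class; {name} class "
                f"({task_pair[0] if name == 'positive' else task_pair[1]}) has {len(X)}"
            )
    rng = np.random.default_rng(protocol.rng_seed)
    accuracies = np.empty(protocol.n_repetitions)
    aucs = np.empty(protocol.n_repetitions)
    tp = tn = fp = fn = 0
    for rep in range(protocol.n_repetitions):
        perm_p = rng.permutation(len(Xp))
        perm_n = rng.permutation(len(Xn))
        X_train = np.vstack([Xp[perm_p[:n_tr]], Xn[perm_n[:n_tr]]])
        y_train = np.r_[np.ones(n_tr, dtype=int), np.zeros(n_tr, dtype=int)]
        pool_X = np.vstack([Xp[perm_p[n_tr:]], Xn[perm_n[n_tr:]]])
        pool_y = np.r_[
            np.ones(len(Xp) - n_tr, dtype=int), np.zeros(len(Xn) - n_tr, dtype=int)
        ]
        take = rng.choice(len(pool_X), size=min(protocol.n_test_draw, len(pool_X)),
                          replace=False)
        X_test, y_test = pool_X[take], pool_y[take]
        X_train_z, X_test_z = standardize(X_train, X_test)
        y_pred, scores = _fit_predict(classifier_id, X_train_z, y_train, X_test_z, kernel)
        accuracies[rep] = 100.0 * np.mean(y_pred == y_test)
        tp += int(np.sum((y_pred == 1) & (y_test == 1)))
        tn += int(np.sum((y_pred == 0) & (y_test == 0)))
        fp += int(np.sum((y_pred == 1) & (y_test == 0)))
        fn += int(np.sum((y_pred == 0) & (y_test == 1)))
        if 0 < y_test.sum() < len(y_test):
            aucs[rep] = roc_auc(scores, y_test).auc
        else:  # single-class draw: AUC undefined for this repetition
            aucs[rep] = np.nan
    sensitivity = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    specificity = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return EvaluationResult(
        task_pair=task_pair,
        channel_name=channel_name,
        classifier_id=classifier_id,
        accuracies=accuracies,
        sensitivity=sensitivity,
        specificity=specificity,
        auc=float(np.nanmean(aucs)),
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    )
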