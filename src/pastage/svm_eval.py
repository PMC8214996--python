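"""Multi-class SVM staging and repeated hold-out evaluation.

Features are standardized (center/scale learned from the training rows) and
fed to a one-vs-one support vector machine with an RBF, polynomial or linear
kernel.  Each binary subproblem scores a sample by the signed distance

    f(x) = sum_j alpha_j y_j G(x, x_j) + b

over its support vectors x_j; the class collecting the most pairwise votes
wins, with vote ties broken by summed scores.  Fitting is delegated to
scikit-learn's ``SVC``; :func:`decision_score` re-evaluates the formula
directly from the fitted dual coefficients so hand-set models can be scored
through the identical code path.

Evaluation follows the study protocol: stratified 80/20 hold-out repeated
10 times with distinct split seeds, reporting per-class sensitivity,
one-vs-rest specificity, and overall accuracy from the confusion matrix.
The default ``"rowwise"`` split policy splits rows independently, so rescaled
copies of one original trace may land on both sides — exactly what happens
when augmentation precedes the split.  The ``"grouped"`` policy keeps all
rows sharing an ``origin_id`` on one side and is the leakage-free variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import linear_kernel, polynomial_kernel, rbf_kernel
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .wpd import FEATURE_META_COLUMNS

KERNELS = ("rbf", "polynomial", "linear")
_SKLEARN_KERNEL = {"rbf": "rbf", "polynomial": "poly", "linear": "linear"}


@dataclass(frozen=True)
class SVMHyperparameters:
    """Kernel hyperparameters: penalty C; RBF width gamma (``"scale"`` =
    1/(n_features * feature variance)); polynomial degree and offset."""

    C: float = 1.0
    gamma: float | str = "scale"
    degree: int = 3
    coef0: float = 1.0


def split_features_labels(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) arrays from a feature matrix with metadata columns."""
    cols = [c for c in table.columns if c not in FEATURE_META_COLUMNS]
    return table[cols].to_numpy(dtype=float), table["label"].to_numpy()


def stratified_split(
    matrix: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    policy: str = "rowwise",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a feature matrix into train/test parts, stratified by class.

    ``policy="rowwise"`` assigns rows independently; ``policy="grouped"``
    assigns whole origin families (an original plus its rescaled copies)
    to one side, stratifying over families within each class.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if policy not in ("rowwise", "grouped"):
        raise ValueError("policy must be 'rowwise' or 'grouped'")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    labels = matrix["label"].to_numpy()
    for cls in pd.unique(labels):
        pos = np.flatnonzero(labels == cls)
        if pos.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 rows")
        if policy == "rowwise":
            perm = rng.permutation(pos)
            n_train = int(round(train_fraction * pos.size))
            n_train = min(max(n_train, 1), pos.size - 1)
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
        else:
            origins = pd.unique(matrix["origin_id"].to_numpy()[pos])
            if origins.size < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 origin families")
            perm = rng.permutation(origins)
            n_train = int(round(train_fraction * origins.size))
            n_train = min(max(n_train, 1), origins.size - 1)
            chosen = set(perm[:n_train])
            in_train = np.array(
                [o in chosen for o in matrix["origin_id"].to_numpy()[pos]]
            )
            train_idx.append(pos[in_train])
            test_idx.append(pos[~in_train])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return matrix.iloc[tr].reset_index(drop=True), matrix.iloc[te].reset_index(drop=True)


@dataclass
class SVMModel:
    """A fitted standardize-then-SVC pipeline for one kernel."""

    kernel: str
    hyperparameters: SVMHyperparameters
    scaler: StandardScaler
    svc: SVC
    feature_names: list[str]

    @property
    def classes(self) -> np.ndarray:
        return self.svc.classes_

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.feature_names):
            raise ValueError("feature dimension mismatch")
        return self.scaler.transform(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(self._transform(X))

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        X, _ = split_features_labels(table)
        return self.predict(X)


def train_svm(
    train: pd.DataFrame,
    kernel: str = "rbf",
    hyperparameters: SVMHyperparameters | None = None,
) -> SVMModel:
    """Fit a one-vs-one multi-class SVM on a training feature matrix."""
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}")
    hp = hyperparameters or SVMHyperparameters()
    X, y = split_features_labels(train)
    if not np.all(np.isfinite(X)):
        raise ValueError("training features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    scaler = StandardScaler().fit(X)
    svc = SVC(
        kernel=_SKLEARN_KERNEL[kernel],
        C=hp.C,
        gamma=hp.gamma,
        degree=hp.degree,
        coef0=hp.coef0,
        decision_function_shape="ovo",
    )
    svc.fit(scaler.transform(X), y)
    cols = [c for c in train.columns if c not in FEATURE_META_COLUMNS]
    return SVMModel(kernel=kernel, hyperparameters=hp, scaler=scaler, svc=svc, feature_names=cols)


# -- decision function -----------------------------------------------------


def binary_decision_score(
    x: np.ndarray,
    support_vectors: np.ndarray,
    alpha_y: np.ndarray,
    bias: float,
    kernel: str = "linear",
    gamma: float = 1.0,
    degree: int = 3,
    coef0: float = 1.0,
) -> float:
    """Evaluate f(x) = sum_j alpha_j y_j G(x, x_j) + b for one binary SVM.

    ``alpha_y`` holds the signed products alpha_j * y_j.  This is the
    primitive used both for hand-set models and for re-scoring fitted
    one-vs-one subproblems.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    sv = np.atleast_2d(np.asarray(support_vectors, dtype=float))
    if x.shape[1] != sv.shape[1]:
        raise ValueError("feature dimension mismatch")
    if kernel == "linear":
        K = linear_kernel(x, sv)
    elif kernel == "rbf":
        K = rbf_kernel(x, sv, gamma=gamma)
    elif kernel == "polynomial":
        K = polynomial_kernel(x, sv, gamma=gamma, degree=degree, coef0=coef0)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return float((K @ np.asarray(alpha_y, dtype=float))[0] + bias)


def _effective_gamma(model: SVMModel) -> float:
    return float(model.svc._gamma)


def decision_score(model: SVMModel, x: np.ndarray) -> dict[tuple[str, str], float]:
    """Signed one-vs-one scores of a single sample, one per class pair.

    Each entry ``(a, b) -> f(x)`` is evaluated from the fitted dual
    coefficients with :func:`binary_decision_score`; positive favors class
    ``a``.  Matches ``SVC.decision_function`` on the standardized sample.
    """
    xs = model._transform(x)[0]
    svc = model.svc
    classes = list(svc.classes_)
    starts = np.concatenate([[0], np.cumsum(svc.n_support_)])
    scores: dict[tuple[str, str], float] = {}
    p = 0
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            sv_i = slice(starts[i], starts[i + 1])
            sv_j = slice(starts[j], starts[j + 1])
            sv = np.vstack([svc.support_vectors_[sv_i], svc.support_vectors_[sv_j]])
            alpha_y = np.concatenate(
                [svc.dual_coef_[j - 1, sv_i], svc.dual_coef_[i, sv_j]]
            )
            scores[(classes[i], classes[j])] = binary_decision_score(
                xs,
                sv,
                alpha_y,
                float(svc.intercept_[p]),
                kernel=model.kernel,
                gamma=_effective_gamma(model),
                degree=model.hyperparameters.degree,
                coef0=model.hyperparameters.coef0,
            )
            p += 1
    return scores


# -- evaluation ------------------------------------------------------------


@dataclass
class EvaluationReport:
    """Confusion matrix and derived metrics of one hold-out evaluation.

    Percentages throughout; confusion-matrix rows are true classes.
    Sensitivity of a class absent from the test set is NaN and the class is
    listed in ``undefined_sensitivity`` rather than silently dropped.
    """

    kernel: str
    split_seed: int
    classes: tuple[str, ...]
    confusion: np.ndarray
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    accuracy: float
    undefined_sensitivity: tuple[str, ...] = ()

    @property
    def n_test(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "kernel": self.kernel,
            "split_seed": self.split_seed,
            "classes": list(self.classes),
            "confusion": self.confusion.tolist(),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "undefined_sensitivity": list(self.undefined_sensitivity),
        }


def metrics_from_confusion(
    confusion: np.ndarray, classes: tuple[str, ...]
) -> tuple[dict[str, float], dict[str, float], float]:
    """Per-class sensitivity/specificity (%) and overall accuracy (%) from a
    confusion matrix with rows = true classes."""
    cm = np.asarray(confusion, dtype=float)
    if cm.shape != (len(classes), len(classes)):
        raise ValueError("confusion matrix shape mismatch")
    total = cm.sum()
    sens: dict[str, float] = {}
    spec: dict[str, float] = {}
    for c, cls in enumerate(classes):
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = total - tp - fn - fp
        sens[cls] = float(tp / (tp + fn) * 100) if tp + fn > 0 else float("nan")
        spec[cls] = float(tn / (tn + fp) * 100) if tn + fp > 0 else float("nan")
    accuracy = float(np.trace(cm) / total * 100)
    return sens, spec, accuracy


def evaluate(model: SVMModel, test: pd.DataFrame, split_seed: int = 0) -> EvaluationReport:
    """Score a test partition and derive the study's performance metrics."""
    if len(test) == 0:
        raise ValueError("empty test partition")
    X, y_true = split_features_labels(test)
    y_pred = model.predict(X)
    classes = tuple(model.classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    sens, spec, acc = metrics_from_confusion(cm, classes)
    undefined = tuple(c for c in classes if cm[index[c]].sum() == 0)
    return EvaluationReport(
        kernel=model.kernel,
        split_seed=split_seed,
        classes=classes,
        confusion=cm,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        undefined_sensitivity=undefined,
    )


# -- repeated hold-out -----------------------------------------------------

_SPLIT_STREAM = 3


def split_seed_for_repeat(master_seed: int, repeat: int) -> int:
    """Per-repeat split seed fanned out from the master seed (< 2**31)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_SPLIT_STREAM, repeat))
    return int(ss.generate_state(1)[0] >> 1)


@dataclass
class RepeatedHoldoutResult:
    """All per-repeat reports plus the best model per kernel."""

    reports: dict[str, list[EvaluationReport]]
    best_models: dict[str, SVMModel]
    best_reports: dict[str, EvaluationReport]

    @property
    def n_reports(self) -> int:
        return sum(len(v) for v in self.reports.values())

    def summary_frame(self) -> pd.DataFrame:
        """Long-format summary mirroring the study's metric table."""
        rows = []
        for kernel, report in self.best_reports.items():
            for cls in report.classes:
                rows.append(
                    {
                        "class": cls,
                        "kernel": kernel,
                        "specificity_pct": report.specificity[cls],
                        "sensitivity_pct": report.sensitivity[cls],
                        "accuracy_pct": report.accuracy,
                    }
                )
        return pd.DataFrame(rows)


def repeated_holdout(
    matrix: pd.DataFrame,
    kernels: tuple[str, ...] = KERNELS,
    n_repeats: int = 10,
    master_seed: int = 0,
    train_fraction: float = 0.8,
    policy: str = "rowwise",
    hyperparameters: SVMHyperparameters | None = None,
    seeds: list[int] | None = None,
) -> RepeatedHoldoutResult:
    """Repeat split/train/evaluate for every kernel and keep the best model.

    The same per-repeat split seed is used for all kernels, so kernel
    comparisons are paired.  "Best" is the highest test accuracy, ties
    resolved toward the earlier repeat.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if seeds is None:
        seeds = [split_seed_for_repeat(master_seed, r) for r in range(n_repeats)]
    if len(seeds) != n_repeats:
        raise ValueError("need one seed per repeat")
    reports: dict[str, list[EvaluationReport]] = {k: [] for k in kernels}
    best_models: dict[str, SVMModel] = {}
    best_reports: dict[str, EvaluationReport] = {}
    for kernel in kernels:
        for seed in seeds:
            train, test = stratified_split(matrix, train_fraction, seed, policy)
            model = train_svm(train, kernel, hyperparameters)
            report = evaluate(model, test, split_seed=seed)
            reports[kernel].append(report)
            if kernel not in best_reports or report.accuracy > best_reports[kernel].accuracy:
                best_reports[kernel] = report
                best_models[kernel] = model
    return RepeatedHoldoutResult(reports=reports, best_models=best_models, best_reports=best_reports)
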