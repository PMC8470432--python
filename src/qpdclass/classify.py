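"""Classifier benchmark under signal-wise stratified cross-validation.

Segments cut from one acquisition are strongly correlated, so the unit of
cross-validation is the acquisition signal, never the segment: each outer
fold holds out exactly one signal per class (all of its segments) for
testing, and hyper-parameters are tuned by an inner signal-wise CV on the
training signals only.  Four classifier families are benchmarked — random
forest, RBF-kernel SVM, k-nearest neighbours and a one-hidden-layer MLP —
in two channel modes: all three QPD channels (6 features) or the SUM
channel alone (2 features).  Per family the report carries mean/best/worst
fold accuracy and a confusion matrix accumulated over folds and
row-normalised at the end.

Scale-sensitive families (SVM, KNN, MLP) see z-scored features, with the
scaler fitted on the training fold; random forests use raw features.  PCA
is fitted on the training fold's spectra only (configurable to a single
global fit), so no test information leaks into the representation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Any, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import (
    ChannelMode,
    PCAModel,
    SpectrumSet,
    fit_channel_pca,
    project_features,
)
from .trap_sim import InvalidParameterError

__all__ = [
    "CVSplit",
    "ClassifierSpec",
    "FoldResult",
    "FamilyReport",
    "ClassificationReport",
    "ModeComparison",
    "FAMILIES",
    "default_classifier_specs",
    "make_signalwise_folds",
    "build_estimator",
    "train_eval_fold",
    "run_benchmark",
    "run_benchmark_frame",
    "compare_channel_modes",
]

FAMILIES = ("random_forest", "svm", "knn", "mlp")


class FoldDesignError(ValueError):
    """The dataset does not admit the requested signal-wise fold design."""


@dataclass(frozen=True)
class CVSplit:
    """Signal-wise folds: (train signal_ids, test signal_ids) pairs."""

    folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    n_folds: int


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with its hyper-parameter search grid."""

    family: str
    grid: Mapping[str, Sequence[Any]]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidParameterError(
                f"family must be one of {FAMILIES}, got {self.family!r}"
            )

    def grid_points(self) -> list[dict[str, Any]]:
        """Deterministic enumeration of the grid (keys sorted)."""
        keys = sorted(self.grid)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.grid[k] for k in keys))
        ]


@dataclass(frozen=True)
class FoldResult:
    fold_index: int
    accuracy: float
    confusion_counts: np.ndarray  # rows true class, cols predicted
    chosen_params: dict[str, Any]
    n_test: int


@dataclass(frozen=True)
class FamilyReport:
    family: str
    fold_results: tuple[FoldResult, ...]
    confusion_normalized: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.fold_results]))

    @property
    def best_accuracy(self) -> float:
        return float(np.max([r.accuracy for r in self.fold_results]))

    @property
    def worst_accuracy(self) -> float:
        return float(np.min([r.accuracy for r in self.fold_results]))


@dataclass(frozen=True)
class ClassificationReport:
    families: dict[str, FamilyReport]
    class_labels: tuple[str, ...]
    channel_mode: ChannelMode
    n_folds: int

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family": name,
                "mean": rep.mean_accuracy,
                "best": rep.best_accuracy,
                "worst": rep.worst_accuracy,
            }
            for name, rep in self.families.items()
        ]
        return pd.DataFrame(rows).set_index("family")


@dataclass(frozen=True)
class ModeComparison:
    all_channels: ClassificationReport
    sum_only: ClassificationReport
    accuracy_delta: dict[str, float]  # 3-channel mean minus SUM-only mean


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------


def make_signalwise_folds(
    meta: pd.DataFrame, n_folds: int = 6, seed: int = 0
) -> CVSplit:
    """Build stratified signal-wise folds.

    ``meta`` needs columns ``signal_id`` and ``label``; every class must
    contribute exactly ``n_folds`` distinct signals.  Under a seeded
    per-class permutation, fold f's test set takes the f-th signal of every
    class; all remaining signals train.
    """
    sigs = meta[["signal_id", "label"]].drop_duplicates().sort_values("signal_id")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    per_class: dict[str, np.ndarray] = {}
    for label in sorted(sigs["label"].unique()):
        ids = sigs.loc[sigs["label"] == label, "signal_id"].to_numpy()
        if ids.size != n_folds:
            raise FoldDesignError(
                f"class {label!r} has {ids.size} signals, need exactly {n_folds}"
            )
        per_class[label] = rng.permutation(ids)
    all_ids = set(sigs["signal_id"])
    folds = []
    for f in range(n_folds):
        test = tuple(sorted(int(per_class[c][f]) for c in per_class))
        train = tuple(sorted(all_ids - set(test)))
        folds.append((train, test))
    split = CVSplit(folds=tuple(folds), n_folds=n_folds)
    _assert_fold_integrity(split, all_ids)
    return split


def _assert_fold_integrity(split: CVSplit, all_ids: set[int]) -> None:
    """No signal on both sides of a fold; test folds partition the signals."""
    seen_test: set[int] = set()
    for train, test in split.folds:
        if set(train) & set(test):
            raise FoldDesignError("signal appears in both train and test of a fold")
        if seen_test & set(test):
            raise FoldDesignError("signal appears in two test folds")
        seen_test.update(test)
    if seen_test != all_ids:
        raise FoldDesignError("union of test folds does not cover all signals")


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def default_classifier_specs(seed: int = 0) -> list[ClassifierSpec]:
    """Small standard grids for the four families."""
    return [
        ClassifierSpec(
            "random_forest",
            {"n_estimators": [100, 300], "max_depth": [None, 10]},
            seed,
        ),
        ClassifierSpec(
            "svm",
            {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.01, 0.1]},
            seed,
        ),
        ClassifierSpec("knn", {"n_neighbors": [1, 3, 5, 9]}, seed),
        ClassifierSpec("mlp", {"hidden_units": [16, 64]}, seed),
    ]


def build_estimator(family: str, params: Mapping[str, Any], seed: int = 0):
    """Instantiate one configured estimator (with z-scoring where needed)."""
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 100),
            max_depth=params.get("max_depth"),
            random_state=seed,
        )
    if family == "svm":
        clf = SVC(kernel="rbf", C=params.get("C", 1.0), gamma=params.get("gamma", "scale"))
    elif family == "knn":
        # prediction ties resolve to the first label in sorted order
        clf = KNeighborsClassifier(
            n_neighbors=params.get("n_neighbors", 5), metric="euclidean"
        )
    elif family == "mlp":
        # stop on a training-loss plateau rather than a held-out validation
        # split: the split would be tiny and not signal-aware
        clf = MLPClassifier(
            hidden_layer_sizes=(params.get("hidden_units", 16),),
            early_stopping=False,
            n_iter_no_change=20,
            max_iter=500,
            random_state=seed,
        )
    else:
        raise InvalidParameterError(f"unknown family {family!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


# ---------------------------------------------------------------------------
# Fold training / evaluation
# ---------------------------------------------------------------------------


def _confusion(y_true, y_pred, labels: Sequence[str]) -> np.ndarray:
    idx = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[idx[t], idx[p]] += 1
    return mat


def _tune(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    spec: ClassifierSpec,
    inner_folds: int,
    seed: int,
) -> dict[str, Any]:
    """Grid search by inner signal-wise CV; returns the best grid point.

    The inner fold count is capped by the number of training signals per
    class.  Ties break toward the earlier grid point, so the search is
    deterministic.
    """
    grid = spec.grid_points()
    if len(grid) == 1:
        return grid[0]
    meta = pd.DataFrame({"signal_id": groups, "label": y})
    counts = meta.drop_duplicates().groupby("label").size()
    k = int(min(inner_folds, counts.min()))
    if k < 2:
        return grid[0]
    split = make_signalwise_folds(meta, n_folds=k, seed=seed)
    best_params, best_acc = None, -np.inf
    for params in grid:
        accs = []
        try:
            for train_ids, test_ids in split.folds:
                tr = np.isin(groups, train_ids)
                te = np.isin(groups, test_ids)
                est = build_estimator(spec.family, params, seed=spec.seed)
                est.fit(X[tr], y[tr])
                accs.append(float(np.mean(est.predict(X[te]) == y[te])))
        except ValueError:
            continue  # infeasible at this fold size (e.g. k > n_samples)
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_acc, best_params = acc, params
    return best_params if best_params is not None else grid[0]


def train_eval_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    groups_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    spec: ClassifierSpec,
    class_labels: Sequence[str],
    fold_index: int = 0,
    inner_folds: int = 5,
    tune_seed: int = 0,
) -> FoldResult:
    """Tune on the training fold, refit, evaluate once on the test fold."""
    missing = set(class_labels) - set(y_train)
    if missing:
        raise FoldDesignError(f"training fold lacks classes: {sorted(missing)}")
    params = _tune(X_train, y_train, groups_train, spec, inner_folds, tune_seed)
    est = build_estimator(spec.family, params, seed=spec.seed)
    est.fit(X_train, y_train)
    y_pred = est.predict(X_test)
    acc = float(np.mean(y_pred == y_test))
    return FoldResult(
        fold_index=fold_index,
        accuracy=acc,
        confusion_counts=_confusion(y_test, y_pred, class_labels),
        chosen_params=dict(params),
        n_test=len(y_test),
    )


# ---------------------------------------------------------------------------
# Benchmark driver
# ---------------------------------------------------------------------------


def _project_matrix(
    spectra: Sequence[SpectrumSet], model: PCAModel, channel_mode: ChannelMode
) -> np.ndarray:
    return np.vstack(
        [project_features(s, model, channel_mode).values for s in spectra]
    )


def run_benchmark(
    spectra: Sequence[SpectrumSet],
    specs: Sequence[ClassifierSpec],
    channel_mode: ChannelMode = "all",
    seed: int = 0,
    n_folds: int = 6,
    pca_scope: Literal["train_only", "global"] = "train_only",
    n_components: int = 2,
    inner_folds: int = 5,
) -> ClassificationReport:
    """Run the full signal-wise CV benchmark for every classifier family.

    Per outer fold: fit PCA on the training signals' spectra (or once
    globally), project both sides, tune and evaluate every family on the
    same split.  Confusion counts accumulate over folds and are
    row-normalised at the end.  Fully deterministic given (spectra, seed).
    """
    meta = pd.DataFrame(
        {
            "signal_id": [s.parent_signal_id for s in spectra],
            "label": [s.label for s in spectra],
        }
    )
    class_labels = tuple(sorted(meta["label"].unique()))
    split = make_signalwise_folds(meta, n_folds=n_folds, seed=seed)
    global_model = (
        fit_channel_pca(spectra, n_components) if pca_scope == "global" else None
    )

    per_family: dict[str, list[FoldResult]] = {s.family: [] for s in specs}
    groups = meta["signal_id"].to_numpy()
    labels = meta["label"].to_numpy()
    for fold_index, (train_ids, test_ids) in enumerate(split.folds):
        tr = np.isin(groups, train_ids)
        te = np.isin(groups, test_ids)
        train_spectra = [s for s, m in zip(spectra, tr) if m]
        test_spectra = [s for s, m in zip(spectra, te) if m]
        model = global_model or fit_channel_pca(train_spectra, n_components)
        X_train = _project_matrix(train_spectra, model, channel_mode)
        X_test = _project_matrix(test_spectra, model, channel_mode)
        for spec in specs:
            per_family[spec.family].append(
                train_eval_fold(
                    X_train,
                    labels[tr],
                    groups[tr],
                    X_test,
                    labels[te],
                    spec,
                    class_labels,
                    fold_index=fold_index,
                    inner_folds=inner_folds,
                    tune_seed=seed + fold_index,
                )
            )

    families = {}
    for name, results in per_family.items():
        counts = np.sum([r.confusion_counts for r in results], axis=0)
        row_sums = counts.sum(axis=1, keepdims=True)
        families[name] = FamilyReport(
            family=name,
            fold_results=tuple(results),
            confusion_normalized=counts / np.where(row_sums == 0, 1, row_sums),
        )
    return ClassificationReport(
        families=families,
        class_labels=class_labels,
        channel_mode=channel_mode,
        n_folds=n_folds,
    )


def run_benchmark_frame(
    features: pd.DataFrame,
    specs: Sequence[ClassifierSpec],
    channel_mode: ChannelMode = "all",
    seed: int = 0,
    n_folds: int = 6,
    inner_folds: int = 5,
) -> ClassificationReport:
    """Benchmark a pre-projected feature table (columns signal_id,
    segment_index, label, f1..fk).

    Because the features were projected with a single PCA model, this path
    corresponds to the ``global`` PCA scope; the spectra-based
    :func:`run_benchmark` refits PCA per fold.  In ``sum_only`` mode the
    last two feature columns (the SUM-channel scores) are used.
    """
    feat_cols = [c for c in features.columns if c.startswith("f")]
    if channel_mode == "sum_only" and len(feat_cols) > 2:
        feat_cols = feat_cols[-2:]
    X = features[feat_cols].to_numpy()
    labels = features["label"].to_numpy()
    groups = features["signal_id"].to_numpy()
    class_labels = tuple(sorted(np.unique(labels)))
    split = make_signalwise_folds(features, n_folds=n_folds, seed=seed)
    per_family: dict[str, list[FoldResult]] = {s.family: [] for s in specs}
    for fold_index, (train_ids, test_ids) in enumerate(split.folds):
        tr = np.isin(groups, train_ids)
        te = np.isin(groups, test_ids)
        for spec in specs:
            per_family[spec.family].append(
                train_eval_fold(
                    X[tr], labels[tr], groups[tr], X[te], labels[te],
                    spec, class_labels, fold_index=fold_index,
                    inner_folds=inner_folds, tune_seed=seed + fold_index,
                )
            )
    families = {}
    for name, results in per_family.items():
        counts = np.sum([r.confusion_counts for r in results], axis=0)
        row_sums = counts.sum(axis=1, keepdims=True)
        families[name] = FamilyReport(
            family=name,
            fold_results=tuple(results),
            confusion_normalized=counts / np.where(row_sums == 0, 1, row_sums),
        )
    return ClassificationReport(
        families=families,
        class_labels=class_labels,
        channel_mode=channel_mode,
        n_folds=n_folds,
    )


def compare_channel_modes(
    spectra: Sequence[SpectrumSet],
    specs: Sequence[ClassifierSpec],
    seed: int = 0,
    n_folds: int = 6,
    pca_scope: Literal["train_only", "global"] = "train_only",
    inner_folds: int = 5,
) -> ModeComparison:
    """Paired 3-channel vs SUM-only benchmark on identical CV splits."""
    rep_all = run_benchmark(
        spectra, specs, "all", seed, n_folds, pca_scope, inner_folds=inner_folds
    )
    rep_sum = run_benchmark(
        spectra, specs, "sum_only", seed, n_folds, pca_scope, inner_folds=inner_folds
    )
    delta = {
        fam: rep_all.families[fam].mean_accuracy - rep_sum.families[fam].mean_accuracy
        for fam in rep_all.families
    }
    return ModeComparison(all_channels=rep_all, sum_only=rep_sum, accuracy_delta=delta)
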