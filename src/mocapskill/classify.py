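"""Experience-level discrimination under nested repeated k-fold CV.

Three classifiers — an RBF-kernel SVM, SVM on PCA-reduced features
(PCA-SVM) and a gradient-boosting decision tree (GBDT, LightGBM) — are
evaluated with stratified nested cross-validation: the inner folds run a
grid search over hyperparameters on the outer-training portion only, the
winner is refit on the full outer-training portion and scored on the held
out outer fold, and the whole scheme is repeated with fresh partitions.
Robust-z normalization and (for PCA-SVM) the PCA rotation are fit on
training rows only, inside every fold.  The per-repetition accuracy is the
pooled proportion correct over all outer test folds.

Accuracy distributions of the three models are compared with Friedman's
test and pairwise Wilcoxon signed-rank tests over the paired repetitions.
Note the statistical caveat: repeated-CV accuracies are not independent
blocks, so these p-values mirror the study procedure rather than a
calibrated inference.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

from .io import FeatureMatrix, RunConfig
from .stats import NIQR_FACTOR, WilcoxonResult, friedman_test, wilcoxon_signed_rank

CLASSIFIER_KINDS = ("svm", "pca_svm", "gbdt")


class RobustZScaler(BaseEstimator, TransformerMixin):
    """Median/NIQR columnwise scaler; degenerate (IQR = 0) columns map to 0."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        q25, q50, q75 = np.percentile(X, [25, 50, 75], axis=0)
        self.median_ = q50
        self.niqr_ = NIQR_FACTOR * (q75 - q25)
        self.n_fit_rows_ = X.shape[0]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = np.zeros_like(X)
        ok = self.niqr_ > 0
        out[:, ok] = (X[:, ok] - self.median_[ok]) / self.niqr_[ok]
        return out


@dataclass
class ClassifierSpec:
    """Classifier kind plus its hyperparameter grid (dict of named lists).

    Grid points are enumerated in declared order (itertools.product over the
    insertion-ordered lists); grid-search ties break to the first point.
    """

    kind: str
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("hyperparameter grid must be nonempty")

    def grid_points(self) -> list[dict]:
        keys = list(self.grid)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.grid[k] for k in keys))
        ]

    def build(self, params: dict, seed: int) -> Pipeline:
        if self.kind == "svm":
            model = SVC(kernel="rbf", C=params["C"], gamma=params["gamma"])
            return Pipeline([("scale", RobustZScaler()), ("svm", model)])
        if self.kind == "pca_svm":
            model = SVC(kernel="rbf", C=params["C"], gamma=params["gamma"])
            return Pipeline(
                [
                    ("scale", RobustZScaler()),
                    ("pca", PCA(n_components=params["retained_variance"],
                                svd_solver="full")),
                    ("svm", model),
                ]
            )
        # min_child_samples/min_data_in_bin relaxed for cohort-sized (tens
        # of trials) training sets; lightgbm's defaults assume thousands
        model = LGBMClassifier(
            learning_rate=params["learning_rate"],
            n_estimators=params["n_estimators"],
            num_leaves=params["num_leaves"],
            min_child_samples=5,
            min_data_in_bin=1,
            n_jobs=1,
            random_state=seed,
            verbosity=-1,
        )
        return Pipeline([("scale", RobustZScaler()), ("gbdt", model)])

    @classmethod
    def from_config(cls, kind: str, config: RunConfig) -> "ClassifierSpec":
        grids = {
            "svm": config.svm_grid,
            "pca_svm": config.pca_svm_grid,
            "gbdt": config.gbdt_grid,
        }
        return cls(kind=kind, grid=grids[kind])


@dataclass
class CVResult:
    """Per-repetition pooled accuracies of one classifier."""

    kind: str
    scheme: str
    accuracies: np.ndarray
    seeds: np.ndarray

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def median(self) -> float:
        return float(np.median(self.accuracies))

    @property
    def iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.accuracies, [25, 75])
        return float(lo), float(hi)


def _grid_seed(base: int, rep: int) -> int:
    return int((base + rep) % (2**31 - 1))


def nested_repeated_cv(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    spec: ClassifierSpec,
    outer_k: int = 10,
    inner_k: int = 10,
    repetitions: int = 100,
    base_seed: int = 0,
    scheme: str = "unspecified",
    audit: list | None = None,
) -> CVResult:
    """Stratified nested repeated k-fold CV with inner grid search.

    Repetition ``r`` uses seed ``base_seed + r`` for both fold layers, so
    distinct classifiers run on identical partitions when given the same
    base seed.  ``audit``, if a list, receives one record per outer fold
    with the train/test indices, the inner splits and the rows used to fit
    the winning pipeline — consumed by the leakage checks.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < outer_k:
        raise ValueError(
            f"smallest class has {counts.min()} members; need >= outer_k={outer_k}"
        )
    grid_points = spec.grid_points()
    accuracies = np.empty(repetitions)
    seeds = np.empty(repetitions, dtype=int)
    # lightgbm's sklearn wrapper warns about feature names on plain arrays
    warnings.filterwarnings(
        "ignore", message="X does not have valid feature names", category=UserWarning
    )
    for rep in range(repetitions):
        seed = _grid_seed(base_seed, rep)
        seeds[rep] = seed
        outer = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed)
        n_correct = 0
        for fold_idx, (train_idx, test_idx) in enumerate(outer.split(X, y)):
            X_train, y_train = X[train_idx], y[train_idx]
            inner_seed = _grid_seed(seed * 131 + fold_idx, 0)
            inner = StratifiedKFold(
                n_splits=inner_k, shuffle=True, random_state=inner_seed
            )
            inner_splits = list(inner.split(X_train, y_train))
            best_score, best_params = -np.inf, None
            for params in grid_points:
                correct = 0
                total = 0
                for in_train, in_val in inner_splits:
                    model = spec.build(params, seed=inner_seed)
                    model.fit(X_train[in_train], y_train[in_train])
                    pred = model.predict(X_train[in_val])
                    correct += int(np.sum(pred == y_train[in_val]))
                    total += in_val.size
                score = correct / total
                if score > best_score:  # strict: ties keep the earlier point
                    best_score, best_params = score, params
            final = spec.build(best_params, seed=inner_seed)
            final.fit(X_train, y_train)
            pred = final.predict(X[test_idx])
            n_correct += int(np.sum(pred == y[test_idx]))
            if audit is not None:
                audit.append(
                    {
                        "rep": rep,
                        "fold": fold_idx,
                        "train_idx": np.array(train_idx),
                        "test_idx": np.array(test_idx),
                        "inner_splits": [
                            (train_idx[a], train_idx[b]) for a, b in inner_splits
                        ],
                        "scaler_fit_rows": int(final.named_steps["scale"].n_fit_rows_),
                        "best_params": dict(best_params),
                    }
                )
        accuracies[rep] = n_correct / y.size
    return CVResult(kind=spec.kind, scheme=scheme, accuracies=accuracies, seeds=seeds)


def run_discrimination(
    features: FeatureMatrix,
    scheme: str,
    config: RunConfig,
    audit: list | None = None,
) -> dict[str, CVResult]:
    """Nested repeated CV of all three classifiers on paired fold sequences.

    ``scheme`` is ``three_group`` (expert/intermediate/novice) or
    ``two_group`` (expert vs non-expert).  Trials with any missing metric
    are listwise-deleted first.
    """
    if scheme not in ("three_group", "two_group"):
        raise ValueError("scheme must be 'three_group' or 'two_group'")
    clean = features.dropna_rows()
    X = clean.values.to_numpy(dtype=float)
    y = (clean.labels3 if scheme == "three_group" else clean.labels2).to_numpy()
    results = {}
    for kind in CLASSIFIER_KINDS:
        spec = ClassifierSpec.from_config(kind, config)
        results[kind] = nested_repeated_cv(
            X,
            y,
            spec,
            outer_k=config.outer_k,
            inner_k=config.inner_k,
            repetitions=config.repetitions,
            base_seed=config.base_seed,
            scheme=scheme,
            audit=audit,
        )
    return results


@dataclass
class ModelComparisonResult:
    """Friedman + pairwise Wilcoxon comparison of the three accuracy vectors."""

    friedman_statistic: float
    friedman_p: float
    pairwise: dict[tuple[str, str], WilcoxonResult]
    summary: pd.DataFrame  # per model: median, q25, q75

    def to_table(self) -> pd.DataFrame:
        """Accuracy-comparison layout: median (IQR) per model plus p-values."""
        row = {
            f"{kind}": f"{self.summary.loc[kind, 'median']:.4f} "
            f"({self.summary.loc[kind, 'q25']:.4f}-{self.summary.loc[kind, 'q75']:.4f})"
            for kind in self.summary.index
        }
        row["friedman_p"] = f"{self.friedman_p:.4g}"
        for (a, b), res in self.pairwise.items():
            row[f"{a}_vs_{b}_p"] = f"{res.p:.4g}"
        return pd.DataFrame([row])


def compare_models(results: dict[str, CVResult]) -> ModelComparisonResult:
    """Compare paired per-repetition accuracies of the three classifiers."""
    kinds = list(results)
    lengths = {len(results[k].accuracies) for k in kinds}
    if len(lengths) != 1:
        raise ValueError("repetition counts differ between classifiers")
    for k in kinds[1:]:
        if not np.array_equal(results[k].seeds, results[kinds[0]].seeds):
            raise ValueError("classifiers were not run on paired seeds")
    matrix = np.column_stack([results[k].accuracies for k in kinds])
    stat, p = friedman_test(matrix)
    pairwise = {
        (a, b): wilcoxon_signed_rank(results[a].accuracies, results[b].accuracies)
        for a, b in itertools.combinations(kinds, 2)
    }
    summary = pd.DataFrame(
        {
            "median": [results[k].median for k in kinds],
            "q25": [results[k].iqr[0] for k in kinds],
            "q75": [results[k].iqr[1] for k in kinds],
        },
        index=kinds,
    )
    return ModelComparisonResult(
        friedman_statistic=stat, friedman_p=p, pairwise=pairwise, summary=summary
    )
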