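"""Multi-feature discriminability: combinations x classifiers x resampling.

Seventeen descriptor subsets (the 11 singles plus the thigh-, shoulder-,
hip-, length- and angle-related groups and the full set) are evaluated
with six off-the-shelf classifier families — AdaBoost on CART stumps, a
CART decision tree, k-nearest neighbours, a random forest, an RBF-kernel
SVM and gradient-boosted trees (XGBoost) — under three resampling
strategies (10x10-fold stratified CV, and stratified 8:2 / 6:4 holdouts
repeated 100 times; each yields 100 train/test pairs).  On every training
set the classifier's hyperparameters are tuned by exhaustive grid search
with stratified 5-fold cross-validation on accuracy; the tuned model's
accuracy, sensitivity, specificity and AUC on the held-out test set are
averaged over the 100 pairs.  Feature sets are finally compared by their
rank on each index, averaged across the six families (lower = better).

Features are standardised (train-set mean/SD) inside every fit: the RBF
grid (gamma 50-500) and kNN operate on distances and are meaningless on
raw descriptor scales that span three orders of magnitude; tree ensembles
are unaffected.

Tuning an ensemble grid does not refit one model per ``n_estimators``
value: boosting is sequential and forests draw tree seeds sequentially,
so a single maximum-size fit per (other-params, fold) evaluates every
``n_estimators`` prefix exactly (verified against direct refits).

All randomness flows from one master seed: stream k of a computation is
seeded from ``numpy.random.SeedSequence([master, *k])``, so any single
(strategy, combination, classifier) cell reproduces independently of
which other cells run.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import (
    RepeatedStratifiedKFold,
    StratifiedKFold,
    StratifiedShuffleSplit,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .cutoff import rank_auc
from .features import DESCRIPTORS, LABEL_COLUMN
from .skeleton import ADHD

__all__ = [
    "COMBINATIONS",
    "CLASSIFIERS",
    "STRATEGIES",
    "ResamplingStrategy",
    "ClassifierSpec",
    "FittedModel",
    "derive_seed",
    "make_splits",
    "tune_and_fit",
    "evaluate_combination",
    "run_analysis",
    "averaged_ranking",
]

INDEX_NAMES = ("accuracy", "sensitivity", "specificity", "auc")

# ---------------------------------------------------------------------------
# feature combinations

_SINGLES = {d: (d,) for d in DESCRIPTORS}
COMBINATIONS: dict[str, tuple[str, ...]] = {
    **_SINGLES,
    "thigh_related": ("var_l_9_10", "var_th_9_10"),
    "shoulder_related": ("var_l_1_2", "var_l_1_5", "var_th_1_2", "var_th_1_5"),
    "hip_related": ("var_l_8_9", "var_l_8_12", "var_th_8_9", "var_th_8_12"),
    "length_related": ("var_l_1_2", "var_l_1_5", "var_l_8_9", "var_l_8_12", "var_l_9_10"),
    "angle_related": (
        "var_th_1_2",
        "var_th_1_5",
        "var_th_8_9",
        "var_th_8_12",
        "var_th_9_10",
        "var_th_8_1",
    ),
    "all": DESCRIPTORS,
}
assert len(COMBINATIONS) == 17

# ---------------------------------------------------------------------------
# seeding

def derive_seed(master: int, *key: int) -> int:
    """Deterministic child seed for the stream identified by ``key``."""
    ss = np.random.SeedSequence([int(master), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# classifier specifications

@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with its immutable tuning grid.

    ``param_names``/``param_values`` define the grid in its documented
    order (full cartesian product, last parameter varying fastest), which
    is also the tie-break order during tuning.  ``ensemble_param`` names
    the boosting/forest size parameter whose grid values are evaluated as
    prefixes of one maximum-size fit.
    """

    name: str
    param_names: tuple[str, ...]
    param_values: tuple[tuple, ...]
    builder: Callable[..., object]
    ensemble_param: str | None = None
    seeded: bool = True

    @property
    def grid(self) -> list[dict]:
        return [
            dict(zip(self.param_names, combo))
            for combo in itertools.product(*self.param_values)
        ]

    def group_index(self, grid_index: int) -> int:
        """Index of the grid point's non-ensemble parameter combination."""
        if self.ensemble_param is None:
            return grid_index
        n_sizes = len(self.param_values[self.param_names.index(self.ensemble_param)])
        # the ensemble parameter is always listed last, varying fastest
        return grid_index // n_sizes

    def build(self, params: Mapping, n_features: int, random_state: int | None):
        return self.builder(params, n_features, random_state)


def _build_adaboost(params, n_features, rs):
    return AdaBoostClassifier(n_estimators=params["n_estimators"], random_state=rs)


def _build_tree(params, n_features, rs):
    return DecisionTreeClassifier(max_depth=params["max_depth"], random_state=rs)


def _build_knn(params, n_features, rs):
    return KNeighborsClassifier(n_neighbors=params["n_neighbors"])


def _build_forest(params, n_features, rs):
    # a grid max_features larger than the subset's width clamps to it
    return RandomForestClassifier(
        n_estimators=params["n_estimators"],
        max_depth=params["max_depth"],
        max_features=min(params["max_features"], n_features),
        random_state=rs,
        n_jobs=1,
    )


def _build_svm(params, n_features, rs):
    return SVC(kernel="rbf", gamma=params["gamma"], C=params["C"])


def _build_xgboost(params, n_features, rs):
    return XGBClassifier(
        learning_rate=params["learning_rate"],
        max_depth=params["max_depth"],
        n_estimators=params["n_estimators"],
        n_jobs=1,
        random_state=rs,
        eval_metric="logloss",
        verbosity=0,
    )


CLASSIFIERS: dict[str, ClassifierSpec] = {
    "adaboost": ClassifierSpec(
        "adaboost", ("n_estimators",), ((1, 5, 10, 20, 30, 50),),
        _build_adaboost, ensemble_param="n_estimators",
    ),
    "decision_tree": ClassifierSpec(
        "decision_tree", ("max_depth",), ((1, 2, 3, 5, 7),), _build_tree,
    ),
    "knn": ClassifierSpec(
        "knn", ("n_neighbors",), ((1, 2, 3),), _build_knn, seeded=False,
    ),
    "random_forest": ClassifierSpec(
        "random_forest",
        ("max_features", "max_depth", "n_estimators"),
        ((1, 2, 3), (1, 2, 3, 5, 7), (1, 5, 10, 20, 30, 50)),
        _build_forest,
        ensemble_param="n_estimators",
    ),
    "svm": ClassifierSpec(
        "svm", ("gamma", "C"), ((50, 100, 300, 500), (0.001, 0.01, 0.1, 1)),
        _build_svm, seeded=False,
    ),
    "xgboost": ClassifierSpec(
        "xgboost",
        ("learning_rate", "max_depth", "n_estimators"),
        ((0.1, 0.2, 0.3), (1, 2, 3, 5, 7), (1, 5, 10, 20, 30, 50)),
        _build_xgboost,
        ensemble_param="n_estimators",
    ),
}

# ---------------------------------------------------------------------------
# resampling strategies

@dataclass(frozen=True)
class ResamplingStrategy:
    """A scheme producing stratified train/test pairs.

    The three standard schemes each yield 100 pairs; :meth:`with_pairs`
    derives a reduced-replication variant (same kind, same seeds) for
    smaller studies.
    """

    name: str
    kind: str  # "repeated_kfold" | "holdout"
    n_folds: int = 10
    n_repeats: int = 10
    test_fraction: float | None = None
    n_splits: int = 100

    @property
    def n_pairs(self) -> int:
        if self.kind == "repeated_kfold":
            return self.n_folds * self.n_repeats
        return self.n_splits

    def with_pairs(self, n_pairs: int) -> "ResamplingStrategy":
        if self.kind == "repeated_kfold":
            if n_pairs % self.n_folds:
                raise ValueError(f"n_pairs must be a multiple of {self.n_folds}")
            return replace(self, n_repeats=n_pairs // self.n_folds)
        return replace(self, n_splits=n_pairs)


STRATEGY_ORDER = ("cv10x10", "holdout82", "holdout64")
STRATEGIES: dict[str, ResamplingStrategy] = {
    "cv10x10": ResamplingStrategy("cv10x10", "repeated_kfold", n_folds=10, n_repeats=10),
    "holdout82": ResamplingStrategy("holdout82", "holdout", test_fraction=0.2),
    "holdout64": ResamplingStrategy("holdout64", "holdout", test_fraction=0.4),
}


def make_splits(
    labels: np.ndarray | Sequence, strategy: ResamplingStrategy, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Materialise the strategy's stratified train/test index pairs."""
    y = _encode(labels)
    if strategy.kind == "repeated_kfold":
        splitter = RepeatedStratifiedKFold(
            n_splits=strategy.n_folds, n_repeats=strategy.n_repeats, random_state=seed
        )
    elif strategy.kind == "holdout":
        splitter = StratifiedShuffleSplit(
            n_splits=strategy.n_splits,
            test_size=strategy.test_fraction,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown resampling kind {strategy.kind!r}")
    return [(tr, te) for tr, te in splitter.split(np.zeros(len(y)), y)]


def _encode(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels.astype(int)
    if np.issubdtype(labels.dtype, np.integer):
        return labels
    return (labels == ADHD).astype(int)


# ---------------------------------------------------------------------------
# tuning

@dataclass
class FittedModel:
    """A tuned, refitted classifier with its standardisation statistics."""

    spec: ClassifierSpec
    params: dict
    cv_accuracy: float
    center: np.ndarray
    scale: np.ndarray
    estimator: object
    grid_scores: np.ndarray = field(repr=False, default=None)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(self._transform(X))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Continuous score for ROC analysis, higher = more ADHD-like.

        Probability of the positive class where the family provides one,
        the SVM margin otherwise; families without any continuous output
        would fall back to 0/1 predictions.
        """
        Xs = self._transform(X)
        est = self.estimator
        if hasattr(est, "predict_proba"):
            proba = est.predict_proba(Xs)
            pos = int(np.flatnonzero(est.classes_ == 1)[0])
            return proba[:, pos]
        if hasattr(est, "decision_function"):
            return est.decision_function(Xs)
        return est.predict(Xs).astype(float)


def _prefix_accuracies(
    spec: ClassifierSpec, est, X_val: np.ndarray, y_val: np.ndarray, sizes: Sequence[int]
) -> list[float]:
    """Validation accuracy of each ``n_estimators`` prefix of one fit."""
    if spec.name == "adaboost":
        stages = [p for p in est.staged_predict(X_val)]
        return [float(np.mean(stages[min(n, len(stages)) - 1] == y_val)) for n in sizes]
    if spec.name == "random_forest":
        tree_probas = np.stack([t.predict_proba(X_val) for t in est.estimators_])
        cum = np.cumsum(tree_probas, axis=0)
        out = []
        for n in sizes:
            pred = est.classes_[np.argmax(cum[n - 1] / n, axis=1)]
            out.append(float(np.mean(pred == y_val)))
        return out
    if spec.name == "xgboost":
        out = []
        for n in sizes:
            proba = est.predict_proba(X_val, iteration_range=(0, n))
            pred = est.classes_[np.argmax(proba, axis=1)]
            out.append(float(np.mean(pred == y_val)))
        return out
    raise ValueError(f"{spec.name} has no ensemble prefix structure")


def grid_cv_scores(
    spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, seed: int, n_folds: int = 5
) -> np.ndarray:
    """Mean stratified CV accuracy of every grid point, in grid order.

    ``X`` must already be standardised.  Estimator seeds depend only on
    (tuning seed, parameter group, fold), so a naive point-by-point refit
    reproduces these scores exactly.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    folds = list(
        StratifiedKFold(n_folds, shuffle=True, random_state=seed % (2**31)).split(X, y)
    )
    grid = spec.grid
    scores = np.zeros(len(grid))
    if spec.ensemble_param is None:
        for gi, params in enumerate(grid):
            accs = []
            for f, (tr, va) in enumerate(folds):
                rs = derive_seed(seed, gi, f) if spec.seeded else None
                est = spec.build(params, X.shape[1], rs)
                est.fit(X[tr], y[tr])
                accs.append(np.mean(est.predict(X[va]) == y[va]))
            scores[gi] = float(np.mean(accs))
        return scores

    sizes = spec.param_values[spec.param_names.index(spec.ensemble_param)]
    n_groups = len(grid) // len(sizes)
    for group in range(n_groups):
        members = list(range(group * len(sizes), (group + 1) * len(sizes)))
        base_params = {
            k: v for k, v in grid[members[0]].items() if k != spec.ensemble_param
        }
        acc = np.zeros(len(sizes))
        for f, (tr, va) in enumerate(folds):
            rs = derive_seed(seed, group, f) if spec.seeded else None
            est = spec.build(
                {**base_params, spec.ensemble_param: max(sizes)}, X.shape[1], rs
            )
            est.fit(X[tr], y[tr])
            acc += _prefix_accuracies(spec, est, X[va], y[va], sizes)
        scores[members] = acc / len(folds)
    return scores


def tune_and_fit(
    spec: ClassifierSpec, X: np.ndarray, y: np.ndarray, seed: int
) -> FittedModel:
    """Grid-search 5-fold CV tuning, then refit on the whole training set.

    Selection is by mean CV accuracy; ties break to the earliest grid
    point in documented grid order.
    """
    X = np.asarray(X, dtype=float)
    y = _encode(y)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    Xs = (X - center) / scale

    scores = grid_cv_scores(spec, Xs, y, seed)
    best = int(np.argmax(scores))
    params = dict(spec.grid[best])
    refit_seed = derive_seed(seed, spec.group_index(best), 5) if spec.seeded else None
    est = spec.build(params, X.shape[1], refit_seed)
    est.fit(Xs, y)
    if spec.name == "random_forest":
        params["max_features"] = min(params["max_features"], X.shape[1])
    return FittedModel(spec, params, float(scores[best]), center, scale, est, scores)


# ---------------------------------------------------------------------------
# evaluation

def _test_indices(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray) -> dict:
    pos = y_true == 1
    n1 = int(pos.sum())
    n0 = y_true.size - n1
    tp = int(((y_pred == 1) & pos).sum())
    tn = int(((y_pred == 0) & ~pos).sum())
    return {
        "accuracy": (tp + tn) / y_true.size,
        "sensitivity": tp / n1 if n1 else np.nan,
        "specificity": tn / n0 if n0 else np.nan,
        "auc": rank_auc(scores, pos) if (n1 and n0) else np.nan,
    }


def evaluate_combination(
    dataset: pd.DataFrame,
    combination: str | Sequence[str],
    classifier: str | ClassifierSpec,
    strategy: str | ResamplingStrategy,
    seed: int = 0,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> dict:
    """Mean test indices of one (combination, classifier, strategy) cell.

    ``seed`` is the master seed; split and tuning streams derive from it
    through the documented stream-splitting scheme, so the cell reproduces
    identically inside or outside :func:`run_analysis`.
    """
    combo_name, columns = _resolve_combination(combination)
    spec = CLASSIFIERS[classifier] if isinstance(classifier, str) else classifier
    strat = STRATEGIES[strategy] if isinstance(strategy, str) else strategy

    X = dataset[list(columns)].to_numpy(dtype=float)
    y = _encode(dataset[LABEL_COLUMN].to_numpy())
    strat_idx = STRATEGY_ORDER.index(strat.name)
    if splits is None:
        splits = make_splits(y, strat, derive_seed(seed, 0, strat_idx))

    combo_idx = list(COMBINATIONS).index(combo_name) if combo_name in COMBINATIONS else -1
    clf_idx = list(CLASSIFIERS).index(spec.name)
    cell_seed = derive_seed(seed, 1, strat_idx, combo_idx, clf_idx)

    rows = []
    for s, (tr, te) in enumerate(splits):
        model = tune_and_fit(spec, X[tr], y[tr], derive_seed(cell_seed, s))
        rows.append(
            _test_indices(y[te], model.predict(X[te]), model.decision_scores(X[te]))
        )
    per_split = pd.DataFrame(rows)
    result = {
        "combination": combo_name,
        "classifier": spec.name,
        "strategy": strat.name,
        "n_reps": len(splits),
    }
    result.update({k: float(per_split[k].mean()) for k in INDEX_NAMES})
    return result


def _resolve_combination(combination) -> tuple[str, tuple[str, ...]]:
    if isinstance(combination, str):
        return combination, COMBINATIONS[combination]
    cols = tuple(combination)
    return "+".join(cols), cols


def run_analysis(
    dataset: pd.DataFrame,
    strategies: Iterable[str | ResamplingStrategy] = STRATEGY_ORDER,
    combinations: Iterable[str] | None = None,
    classifiers: Iterable[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy results table over combinations x classifiers x strategies."""
    combinations = list(combinations or COMBINATIONS)
    classifiers = list(classifiers or CLASSIFIERS)
    rows = []
    for strategy in strategies:
        strat = STRATEGIES[strategy] if isinstance(strategy, str) else strategy
        strat_idx = STRATEGY_ORDER.index(strat.name)
        y = _encode(dataset[LABEL_COLUMN].to_numpy())
        splits = make_splits(y, strat, derive_seed(seed, 0, strat_idx))
        for combo in combinations:
            for clf in classifiers:
                rows.append(
                    evaluate_combination(
                        dataset, combo, clf, strat, seed=seed, splits=splits
                    )
                )
    return pd.DataFrame(rows)


def averaged_ranking(results: pd.DataFrame, strategy: str | None = None) -> pd.DataFrame:
    """Average each combination's per-classifier rank on every index.

    Within each classifier and index, the combinations are ranked
    descending by mean index value (ties share the average rank); ranks
    are then averaged across classifiers.  Lower is better.
    """
    df = results
    if strategy is not None:
        df = df[df["strategy"] == strategy]
    if df["strategy"].nunique() != 1:
        raise ValueError("ranking mixes strategies; pass strategy=...")
    out = {}
    for index in INDEX_NAMES:
        wide = df.pivot(index="combination", columns="classifier", values=index)
        ranks = wide.rank(ascending=False, method="average")
        out[f"{index}_avg_rank"] = ranks.mean(axis=1)
    table = pd.DataFrame(out)
    order = [c for c in COMBINATIONS if c in table.index]
    return table.loc[order]
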