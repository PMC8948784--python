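"""Leakage-safe supervised comparison of two transition groups.

Within each cross-validation fold (or once, on the training half of a 70/30
hold-out) the features are ranked by a two-sided Wilcoxon rank-sum test on
the *training rows only*, the 100 best are kept, and SVM and Random-Forest
classifiers are fitted on those columns to emit held-out class probabilities.
Ranking inside the fold is what keeps the univariate selection from leaking
test information — with thousands of candidate cells and a few dozen samples,
selecting on the full data inflates apparent accuracy dramatically (the test
suite asserts this with a deliberately leaky variant).

Fold assignment is stratified (minority transition groups can be as small as
7-8 samples), keyed by sample id rather than row order, and can be grouped by
patient so that a patient contributing several pairs never straddles a fold
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.metrics import roc_auc_score
from sklearn.base import BaseEstimator
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

from .preprocess import FeatureLocation, FeatureMatrix

__all__ = [
    "ModelConfig",
    "FoldResult",
    "PredictionSet",
    "rank_sum_pvalues",
    "rank_features_wilcoxon",
    "select_top_k",
    "WilcoxonTopK",
    "fit_classifier",
    "run_cv",
    "run_holdout",
    "modal_selected_features",
]

CLASSIFIERS = ("svm", "rf")

# exact null distribution is used when both groups are at most this large
# (and the column has no ties); beyond that the tie-corrected normal
# approximation is accurate and much cheaper
_EXACT_MAX_GROUP = 25


@lru_cache(maxsize=64)
def _exact_u_cdf(n1: int, n0: int) -> np.ndarray:
    """CDF of the Mann-Whitney U statistic under the null, by counting DP.

    ``N[m][n](u) = N[m][n-1](u) + N[m-1][n](u-n)`` — counts of rank
    assignments of ``m`` cases among ``m+n`` samples yielding statistic u.
    Counts stay below 2**53 for the group sizes used here, so float64 DP is
    exact.
    """
    u_max = n1 * n0
    f = np.zeros((n0 + 1, u_max + 1))
    f[:, 0] = 1.0  # m = 0
    for _m in range(1, n1 + 1):
        g = np.zeros_like(f)
        g[0, 0] = 1.0
        for n in range(1, n0 + 1):
            g[n] = g[n - 1]
            g[n, n:] += f[n, : u_max + 1 - n]
        f = g
    counts = f[n0]
    return np.cumsum(counts) / counts.sum()


def _tie_sums(X_sorted: np.ndarray) -> np.ndarray:
    """Per-column sum of t^3 - t over tied runs, vectorised."""
    n, p = X_sorted.shape
    cols = np.ascontiguousarray(X_sorted.T)
    new_run = np.ones((p, n), dtype=bool)
    new_run[:, 1:] = cols[:, 1:] != cols[:, :-1]
    starts = np.flatnonzero(new_run.ravel())
    lengths = np.diff(np.append(starts, p * n)).astype(float)
    col_of_run = starts // n
    return np.bincount(col_of_run, weights=lengths**3 - lengths, minlength=p)


def rank_sum_pvalues(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value for every column of ``X``.

    Exact p-values (from the enumerated U null distribution) for tie-free
    columns when both groups have <= 25 samples; tie-corrected,
    continuity-corrected normal approximation otherwise.  Constant columns
    get p = 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("need exactly two classes in y")
    mask1 = y == classes[1]
    n1 = int(mask1.sum())
    n0 = int((~mask1).sum())
    if min(n0, n1) < 2:
        raise ValueError("need at least 2 samples per class")
    n = n0 + n1

    ranks = stats.rankdata(X, axis=0)
    r1 = ranks[mask1].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0

    X_sorted = np.sort(X, axis=0)
    tie_sum = _tie_sums(X_sorted)
    has_ties = tie_sum > 0

    pvals = np.ones(X.shape[1])

    exact_cols = ~has_ties if max(n0, n1) <= _EXACT_MAX_GROUP else np.zeros(X.shape[1], bool)
    if exact_cols.any():
        cdf = _exact_u_cdf(n1, n0)
        u = np.rint(u1[exact_cols]).astype(int)
        lower = cdf[u]
        upper = np.where(u > 0, 1.0 - cdf[np.maximum(u - 1, 0)], 1.0)
        pvals[exact_cols] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))

    approx_cols = ~exact_cols
    if approx_cols.any():
        ts = tie_sum[approx_cols]
        var = n1 * n0 / 12.0 * ((n + 1) - ts / (n * (n - 1)))
        sd = np.sqrt(np.maximum(var, 0.0))
        dev = np.abs(u1[approx_cols] - n1 * n0 / 2.0)
        z = np.zeros_like(dev)
        ok = sd > 0
        z[ok] = np.maximum(dev[ok] - 0.5, 0.0) / sd[ok]  # continuity correction
        p = special.erfc(z / np.sqrt(2.0))
        p[~ok] = 1.0  # constant column: no discrimination
        pvals[approx_cols] = np.minimum(p, 1.0)
    return pvals


def rank_features_wilcoxon(X, y) -> list[tuple[int, float]]:
    """Rank features by rank-sum p-value, ascending.

    Ties on p are broken by the absolute group-mean difference, descending
    (volcano-plot logic: significance first, effect size second), then by
    feature index.  The effect-size tie-break matters in practice: strongly
    separated cohorts push many cells onto the test's discrete p-value floor,
    and among those the rank statistic carries no ordering information at
    all, whereas the mean difference still points at the peak cores.
    """
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pvals = rank_sum_pvalues(X, y)
    classes = np.unique(y)
    absdiff = np.abs(
        X[y == classes[1]].mean(axis=0) - X[y == classes[0]].mean(axis=0)
    )
    order = np.lexsort((np.arange(pvals.size), -absdiff, pvals))
    return [(int(i), float(pvals[i])) for i in order]


def select_top_k(ranked: list[tuple[int, float]], k: int) -> list[int]:
    """First ``k`` feature indices of a ranked list."""
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds the {len(ranked)} available features")
    if k < 1:
        raise ValueError("k must be positive")
    return [idx for idx, _ in ranked[:k]]


class WilcoxonTopK(SelectorMixin, BaseEstimator):
    """Sklearn feature selector keeping the ``k`` best rank-sum features.

    Inside an sklearn :class:`~sklearn.pipeline.Pipeline` this makes the
    univariate selection automatically fold-local under cross-validation.

    Attributes
    ----------
    pvalues_ : ndarray
        Two-sided rank-sum p-value per input feature.
    ranking_ : list of (feature_index, p_value)
        Features sorted ascending by p, ties broken by index.
    selected_ : list of int
        The ``k`` retained feature indices.
    """

    def __init__(self, k: int = 100):
        self.k = k

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.n_features_in_ = X.shape[1]
        self.pvalues_ = rank_sum_pvalues(X, y)
        self.ranking_ = [
            (int(i), float(self.pvalues_[i]))
            for i in np.lexsort((np.arange(self.pvalues_.size), self.pvalues_))
        ]
        self.selected_ = select_top_k(self.ranking_, self.k)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "selected_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask


@dataclass
class ModelConfig:
    """Modelling configuration with the study defaults.

    ``n_features`` top rank-sum features per fold (default 100), 10-fold
    stratified CV by default, or a stratified 70/30 hold-out (``mode``
    "holdout").  ``group_folds_by_patient`` keeps all of one patient's samples
    in a single fold when patient groups are supplied.
    """

    n_features: int = 100
    n_folds: int = 10
    mode: str = "cv"
    holdout_train_fraction: float = 0.70
    classifiers: tuple[str, ...] = ("svm", "rf")
    seed: int = 0
    group_folds_by_patient: bool = True
    svm_params: dict = field(default_factory=dict)
    rf_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("cv", "holdout"):
            raise ValueError("mode must be 'cv' or 'holdout'")
        if not 0.0 < self.holdout_train_fraction < 1.0:
            raise ValueError("holdout_train_fraction must be in (0, 1)")
        if self.n_features < 1 or self.n_folds < 2:
            raise ValueError("n_features must be >= 1 and n_folds >= 2")
        unknown = set(self.classifiers) - set(CLASSIFIERS)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")


@dataclass
class FoldResult:
    """Per-fold provenance: the selected features and held-out probabilities."""

    fold_index: int
    selected: list[tuple[FeatureLocation, float]]
    test_sample_ids: list[str]
    probabilities: dict[str, np.ndarray]

    @property
    def selected_indices(self) -> list[int]:
        return [loc.feature_index for loc, _ in self.selected]


@dataclass
class PredictionSet:
    """Held-out class-1 probabilities for every evaluated sample."""

    sample_ids: list[str]
    y_true: np.ndarray
    probabilities: dict[str, np.ndarray]
    fold: np.ndarray
    mode: str
    config: ModelConfig

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids, "true_label": self.y_true})
        for clf in self.config.classifiers:
            if clf in self.probabilities:
                df[f"prob_{clf}"] = self.probabilities[clf]
        df["fold"] = self.fold
        return df


def fit_classifier(kind: str, X: np.ndarray, y: np.ndarray, seed: int = 0, **params):
    """Fit a probability-emitting classifier on already-selected features.

    ``svm``: RBF-kernel SVC behind a StandardScaler (training-fold statistics),
    probabilities via the library's internal cross-validated sigmoid
    calibration.  ``rf``: 500-tree Random Forest, probabilities as vote
    fractions.  Hyperparameters beyond these documented defaults pass through.
    """
    X, y = check_X_y(X, y)
    if np.unique(y).size < 2:
        raise ValueError("training labels are constant; need both classes")
    if kind == "svm":
        svm_kwargs = {"kernel": "rbf", "C": 1.0, "gamma": "scale", **params}
        counts = np.bincount(y.astype(int))
        cal_cv = int(min(5, counts[counts > 0].min()))  # sigmoid CV limited by minority class
        if cal_cv < 2:
            raise ValueError("need at least 2 samples per class to calibrate SVM probabilities")
        model = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svc",
                    CalibratedClassifierCV(
                        SVC(random_state=seed, **svm_kwargs),
                        method="sigmoid",
                        cv=cal_cv,
                        ensemble=False,
                    ),
                ),
            ]
        )
    elif kind == "rf":
        rf_kwargs = {"n_estimators": 500, **params}
        model = RandomForestClassifier(random_state=seed, **rf_kwargs)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    return model.fit(X, y)


def _prob_class1(model, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(check_array(X))
    classes = model.classes_ if hasattr(model, "classes_") else model[-1].classes_
    col = int(np.flatnonzero(classes == 1)[0])
    return proba[:, col]


def _classifier_params(config: ModelConfig, kind: str) -> dict:
    return config.svm_params if kind == "svm" else config.rf_params


def _sorted_view(features: FeatureMatrix, labels, groups):
    sample_ids = np.asarray(features.sample_ids)
    if sample_ids.size != np.unique(sample_ids).size:
        raise ValueError("sample ids must be unique")
    order = np.argsort(sample_ids, kind="stable")
    X = features.values[order]
    y = np.asarray(labels)[order]
    ids = sample_ids[order]
    g = None if groups is None else np.asarray(groups)[order]
    return X, y, ids, g


def run_cv(
    features: FeatureMatrix,
    labels: np.ndarray,
    config: ModelConfig,
    groups: np.ndarray | None = None,
    leak_selection: bool = False,
) -> tuple[PredictionSet, list[FoldResult]]:
    """Stratified k-fold CV with fold-local feature selection.

    Fold assignment is keyed by sample id (rows are sorted by id before
    splitting), so the output is invariant to input row order.  ``groups``
    (e.g. patient ids, aligned with rows) activates grouped stratified folds
    when ``config.group_folds_by_patient`` is set.

    ``leak_selection`` is a diagnostic switch that ranks features on the full
    data before splitting — deliberate information leakage, kept only so the
    test suite can demonstrate that fold-local selection matters.  Never use
    it for reported results.
    """
    X, y, ids, g = _sorted_view(features, labels, groups)
    n = len(ids)
    if config.n_folds > n:
        raise ValueError(f"n_folds={config.n_folds} exceeds n_samples={n}")
    if np.unique(y).size != 2:
        raise ValueError("labels must contain exactly two classes")

    if g is not None and config.group_folds_by_patient:
        splitter = StratifiedGroupKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
        splits = splitter.split(X, y, groups=g)
    else:
        splitter = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
        splits = splitter.split(X, y)

    global_ranked = rank_features_wilcoxon(X, y) if leak_selection else None

    probs = {clf: np.full(n, np.nan) for clf in config.classifiers}
    fold_assign = np.full(n, -1, dtype=int)
    fold_results: list[FoldResult] = []
    for fold_index, (train, test) in enumerate(splits):
        if np.unique(y[train]).size < 2:
            raise ValueError(
                f"fold {fold_index} has single-class training data; use fewer folds"
            )
        ranked = global_ranked if leak_selection else rank_features_wilcoxon(X[train], y[train])
        selected = select_top_k(ranked, config.n_features)
        pmap = dict(ranked)
        fold_probs: dict[str, np.ndarray] = {}
        for kind in config.classifiers:
            model = fit_classifier(
                kind, X[np.ix_(train, selected)], y[train], seed=config.seed,
                **_classifier_params(config, kind),
            )
            p = _prob_class1(model, X[np.ix_(test, selected)])
            probs[kind][test] = p
            fold_probs[kind] = p
        fold_assign[test] = fold_index
        fold_results.append(
            FoldResult(
                fold_index=fold_index,
                selected=[(features.locations[i], pmap[i]) for i in selected],
                test_sample_ids=[str(s) for s in ids[test]],
                probabilities=fold_probs,
            )
        )
    if (fold_assign < 0).any():
        raise RuntimeError("fold test sets do not cover every sample")
    pred = PredictionSet(
        sample_ids=[str(s) for s in ids],
        y_true=y,
        probabilities=probs,
        fold=fold_assign,
        mode="cv",
        config=config,
    )
    return pred, fold_results


def run_holdout(
    features: FeatureMatrix,
    labels: np.ndarray,
    config: ModelConfig,
) -> tuple[PredictionSet, FoldResult]:
    """Single stratified train/test split (default 70/30).

    Feature ranking and model fitting use the training partition only;
    probabilities are emitted for the test partition.
    """
    X, y, ids, _ = _sorted_view(features, labels, None)
    if np.unique(y).size != 2:
        raise ValueError("labels must contain exactly two classes")
    idx = np.arange(len(ids))
    train, test = train_test_split(
        idx,
        train_size=config.holdout_train_fraction,
        stratify=y,
        random_state=config.seed,
        shuffle=True,
    )
    for part, name in ((train, "training"), (test, "test")):
        if np.unique(y[part]).size < 2:
            raise ValueError(f"{name} partition lost a class; adjust the split")
    ranked = rank_features_wilcoxon(X[train], y[train])
    selected = select_top_k(ranked, config.n_features)
    pmap = dict(ranked)
    probs: dict[str, np.ndarray] = {}
    for kind in config.classifiers:
        model = fit_classifier(
            kind, X[np.ix_(train, selected)], y[train], seed=config.seed,
            **_classifier_params(config, kind),
        )
        probs[kind] = _prob_class1(model, X[np.ix_(test, selected)])
    test_order = np.sort(test)
    # re-map probabilities to the sorted test rows for a stable output order
    remap = {t: i for i, t in enumerate(test)}
    probs = {k: v[[remap[t] for t in test_order]] for k, v in probs.items()}
    fold_result = FoldResult(
        fold_index=0,
        selected=[(features.locations[i], pmap[i]) for i in selected],
        test_sample_ids=[str(s) for s in ids[test_order]],
        probabilities=probs,
    )
    pred = PredictionSet(
        sample_ids=[str(s) for s in ids[test_order]],
        y_true=y[test_order],
        probabilities=probs,
        fold=np.zeros(len(test_order), dtype=int),
        mode="holdout",
        config=config,
    )
    return pred, fold_result


def pipeline_permutation_pvalue(
    features: FeatureMatrix,
    labels: np.ndarray,
    config: ModelConfig,
    classifier: str = "svm",
    groups: np.ndarray | None = None,
    n_permutations: int = 199,
    early_stop_hits: int = 3,
    seed: int | None = None,
) -> float:
    """Calibrated significance for a cross-validated comparison.

    Rank tests applied directly to pooled out-of-fold probabilities are
    anticonservative: fold models share training samples, which correlates
    scores across folds and inflates the null variance of the pooled AUC.
    The only reference distribution that honours the full procedure is to
    permute the labels and re-run the entire pipeline (fold assignment,
    feature selection, fitting), comparing |AUC - 1/2| against the permuted
    values.

    Permutations are drawn sequentially and stopped early once
    ``early_stop_hits`` permuted statistics reach the observed one
    (Besag-Clifford), so clearly non-significant comparisons cost only a
    handful of pipeline re-runs.  The returned p-value is ``hits / trials``
    when stopped early, else ``(hits + 1) / (n_permutations + 1)``.
    """
    y = np.asarray(labels)
    cfg = replace(config, classifiers=(classifier,))

    def pooled_stat(lab: np.ndarray) -> float:
        pred, _ = run_cv(features, lab, cfg, groups=groups)
        return abs(roc_auc_score(pred.y_true, pred.probabilities[classifier]) - 0.5)

    observed = pooled_stat(y)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    hits = 0
    for trial in range(1, n_permutations + 1):
        if pooled_stat(rng.permutation(y)) >= observed - 1e-12:
            hits += 1
            if hits >= early_stop_hits and trial < n_permutations:
                return hits / trial
    return (hits + 1) / (n_permutations + 1)


def modal_selected_features(fold_results: list[FoldResult], k: int) -> list[int]:
    """The ``k`` features selected most often across folds (ties by index)."""
    counts: dict[int, int] = {}
    for fr in fold_results:
        for idx in fr.selected_indices:
            counts[idx] = counts.get(idx, 0) + 1
    ordered = sorted(counts, key=lambda i: (-counts[i], i))
    return ordered[:k]
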