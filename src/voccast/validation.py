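"""Self-validation experiments: recovery, null calibration, leakage sentinels.

Because the clinical cohort behind this pipeline is not publicly available,
the package validates itself on synthetic studies whose ground truth is
known.  The experiments here define the package's standard study conditions:

* **recovery** — can the full pipeline find planted group differences?
  Desk-scale spectra (200 x 150), 5 planted effect peaks amplified 3-fold in
  one group, 40 samples per group.
* **null** — does everything stay quiet when there is nothing to find?
  Reduced 50 x 40 spectra with group sizes (41, 8) mirroring the
  remission-to-remission vs remission-to-exacerbation comparison, and no
  planted effect.
* **leakage sentinel** — the same null data run once correctly (fold-local
  feature selection) and once deliberately leakily (selection on all rows);
  the gap between the two is what the fold-local guard buys.

All functions are deterministic given their seed arguments.
"""

from __future__ import annotations

import numpy as np

from .evaluate import compute_auc
from .model import (
    ModelConfig,
    modal_selected_features,
    pipeline_permutation_pvalue,
    run_cv,
)
from .preprocess import FeatureMatrix, build_feature_matrix
from .simulate import (
    CohortDesign,
    default_background_regions,
    default_crop_window,
    default_design,
    simulate_cohort,
)

__all__ = [
    "recovery_design",
    "null_design",
    "prepare_features",
    "recovery_experiment",
    "null_experiment",
    "leakage_experiment",
]


def recovery_design(seed: int) -> CohortDesign:
    """Standard planted-effect recovery conditions."""
    return default_design(
        seed=seed,
        matrix_shape=(200, 150),
        n_per_group=(40, 40),
        n_shared=60,
        n_effect=5,
        effect_multiplier=3.0,
    )


def null_design(seed: int) -> CohortDesign:
    """Standard no-effect conditions at the study's imbalanced group sizes."""
    return default_design(
        seed=seed,
        matrix_shape=(50, 40),
        n_per_group=(41, 8),
        n_shared=15,
        n_effect=2,
        effect_multiplier=1.0,
    )


def prepare_features(design: CohortDesign):
    """Simulate a cohort and reduce it to features with the default windows."""
    spectra, labels, truth = simulate_cohort(design)
    features = build_feature_matrix(
        spectra, default_crop_window(design), default_background_regions(design)
    )
    return features, labels, truth


def _oof_auc(features: FeatureMatrix, labels, config: ModelConfig, **kw) -> float:
    pred, _ = run_cv(features, labels, config, **kw)
    clf = config.classifiers[0]
    return compute_auc(pred.probabilities[clf], pred.y_true)


def recovery_experiment(seeds: list[int]) -> dict:
    """Out-of-fold SVM AUC and feature recovery across planted-effect cohorts.

    Feature recovery is the fraction of the 100 modally-selected features
    (most frequently chosen across folds) lying inside the planted peaks'
    2-sigma ground-truth footprint.
    """
    aucs, fractions = [], []
    for seed in seeds:
        features, labels, truth = prepare_features(recovery_design(seed))
        config = ModelConfig(seed=seed, classifiers=("svm",))
        pred, folds = run_cv(features, labels, config)
        aucs.append(compute_auc(pred.probabilities["svm"], pred.y_true))
        truth_cells = {(t.retention_index, t.drift_index) for t in truth}
        modal = modal_selected_features(folds, config.n_features)
        hits = sum(
            (features.locations[i].retention_index, features.locations[i].drift_index)
            in truth_cells
            for i in modal
        )
        fractions.append(hits / len(modal))
    return {
        "aucs": aucs,
        "median_auc": float(np.median(aucs)),
        "recovery_fractions": fractions,
        "median_recovery_fraction": float(np.median(fractions)),
    }


def null_experiment(
    auc_seeds: list[int],
    pvalue_seeds: list[int],
    n_permutations: int = 199,
) -> dict:
    """Null AUC level and permutation-test type-I error on no-effect cohorts.

    Each seed draws an independent null cohort; ``auc_seeds`` feed the pooled
    out-of-fold AUC average, ``pvalue_seeds`` the fraction of significant
    full-pipeline permutation p-values at alpha = 0.05.
    """
    aucs = []
    for seed in auc_seeds:
        features, labels, _ = prepare_features(null_design(seed))
        aucs.append(_oof_auc(features, labels, ModelConfig(seed=seed, classifiers=("svm",))))
    pvalues = []
    for seed in pvalue_seeds:
        features, labels, _ = prepare_features(null_design(seed))
        pvalues.append(
            pipeline_permutation_pvalue(
                features,
                labels,
                ModelConfig(seed=seed, classifiers=("svm",)),
                classifier="svm",
                n_permutations=n_permutations,
                seed=seed + 7919,
            )
        )
    return {
        "aucs": aucs,
        "mean_auc": float(np.mean(aucs)),
        "pvalues": pvalues,
        "type_i_error": float(np.mean(np.asarray(pvalues) < 0.05)),
    }


def leakage_experiment(seeds: list[int]) -> dict:
    """Fold-local vs whole-data feature selection on identical null cohorts."""
    correct, leaky = [], []
    for seed in seeds:
        features, labels, _ = prepare_features(null_design(seed))
        config = ModelConfig(seed=seed, classifiers=("svm",))
        correct.append(_oof_auc(features, labels, config))
        leaky.append(_oof_auc(features, labels, config, leak_selection=True))
    return {
        "correct_aucs": correct,
        "leaky_aucs": leaky,
        "mean_correct_auc": float(np.mean(correct)),
        "mean_leaky_auc": float(np.mean(leaky)),
    }
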