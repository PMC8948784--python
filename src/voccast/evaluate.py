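"""ROC-based evaluation of held-out probabilities.

Produces, per comparison and classifier: AUC with a DeLong 95% confidence
interval, the optimum cut-off by Youden's J with its sensitivity /
specificity / PPV / NPV, and a two-sided Mann-Whitney significance p-value
on the probabilities.  All statistics are rank-based, so the report is
invariant under strictly monotone transforms of the probabilities (the
cut-off itself is re-expressed on the transformed scale).

Conventions fixed for reproducibility: cases are class 1; a sample is
predicted positive when its probability is >= the cut-off; candidate cut-offs
are the observed probability values; cut-off ties are broken by higher
sensitivity, then lower cut-off.  PPV/NPV are NaN when no sample falls on the
corresponding side of the cut-off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .model import PredictionSet

__all__ = [
    "ROCResult",
    "compute_auc",
    "auc_ci",
    "optimal_cutoff",
    "comparison_pvalue",
    "roc_points",
    "evaluate_predictions",
    "build_report",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = [
    "comparison",
    "classifier",
    "mode",
    "auc",
    "ci_low",
    "ci_high",
    "cutoff",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "p_value",
    "n_cases",
    "n_controls",
]


def _validate(probabilities, labels):
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probabilities and labels must be 1-D and aligned")
    if not np.all(np.isfinite(p)):
        raise ValueError("probabilities must be finite")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes 0 and 1")
    return p, y


def compute_auc(probabilities, labels) -> float:
    """AUC = fraction of (case, control) pairs correctly ordered, ties 1/2."""
    p, y = _validate(probabilities, labels)
    return float(roc_auc_score(y, p))


def auc_ci(probabilities, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong variance-based confidence interval for the AUC, clipped to [0, 1].

    With degenerate placement variance (e.g. all probabilities equal, or
    perfect separation at small n) the interval collapses to the point
    estimate with a warning.
    """
    p, y = _validate(probabilities, labels)
    cases = p[y == 1]
    controls = p[y == 0]
    m, n = cases.size, controls.size
    # placement values: mean Heaviside score of each case against all controls
    diff = cases[:, None] - controls[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)  # per-case placements
    v01 = psi.mean(axis=0)  # per-control placements
    auc = float(psi.mean())
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    if var <= 0:
        warnings.warn("degenerate DeLong variance; interval collapses to the estimate")
        return auc, auc
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def optimal_cutoff(probabilities, labels) -> tuple[float, float, float, float, float]:
    """Cut-off maximizing Youden's J over the observed probability values.

    Returns ``(cutoff, sensitivity, specificity, ppv, npv)`` from the implied
    confusion matrix (predicted positive = probability >= cutoff).  Ties on J
    break toward higher sensitivity, then lower cut-off.
    """
    p, y = _validate(probabilities, labels)
    n_cases = int(y.sum())
    n_controls = y.size - n_cases
    best = None
    for cut in np.unique(p):
        pred = p >= cut
        tp = int(np.sum(pred & (y == 1)))
        fp = int(np.sum(pred & (y == 0)))
        fn = n_cases - tp
        tn = n_controls - fp
        sens = tp / n_cases
        spec = tn / n_controls
        j = sens + spec - 1.0
        key = (j, sens, -cut)
        if best is None or key > best[0]:
            ppv = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
            npv = tn / (tn + fn) if (tn + fn) > 0 else float("nan")
            best = (key, (float(cut), sens, spec, ppv, npv))
    return best[1]


def comparison_pvalue(
    probabilities,
    labels,
    method: str = "mannwhitney",
    n_permutations: int = 2000,
    rng: np.random.Generator | None = None,
) -> float:
    """Significance of the case/control probability separation.

    Default is a two-sided Mann-Whitney U test on the held-out probabilities
    (exact where scipy can be, i.e. small tie-free samples).  ``method=
    "permutation"`` instead permutes labels and compares AUCs, for users who
    prefer a resampling reference distribution.
    """
    p, y = _validate(probabilities, labels)
    if method == "mannwhitney":
        res = stats.mannwhitneyu(p[y == 1], p[y == 0], alternative="two-sided", method="auto")
        return float(res.pvalue)
    if method == "permutation":
        rng = rng if rng is not None else np.random.default_rng(0)
        observed = abs(compute_auc(p, y) - 0.5)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(y)
            if np.unique(perm).size < 2:  # cannot happen: permutation preserves counts
                continue
            if abs(compute_auc(p, perm) - 0.5) >= observed - 1e-12:
                hits += 1
        return float((hits + 1) / (n_permutations + 1))
    raise ValueError(f"unknown method {method!r}")


def roc_points(probabilities, labels) -> pd.DataFrame:
    """ROC curve as (fpr, tpr, threshold) rows, for plotting/export."""
    p, y = _validate(probabilities, labels)
    fpr, tpr, thr = roc_curve(y, p)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass(frozen=True)
class ROCResult:
    """One report row: a (comparison, classifier, mode) evaluation."""

    comparison: str
    classifier: str
    mode: str
    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    p_value: float
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.auc <= self.ci_high):
            raise ValueError("confidence interval must contain the AUC estimate")


def evaluate_predictions(
    predictions: PredictionSet,
    comparison: str,
    pvalue_method: str = "mannwhitney",
) -> list[ROCResult]:
    """Evaluate every classifier in a prediction set against the true labels."""
    y = predictions.y_true
    results = []
    for clf, probs in predictions.probabilities.items():
        cutoff, sens, spec, ppv, npv = optimal_cutoff(probs, y)
        lo, hi = auc_ci(probs, y)
        results.append(
            ROCResult(
                comparison=comparison,
                classifier=clf,
                mode=predictions.mode,
                auc=compute_auc(probs, y),
                ci_low=lo,
                ci_high=hi,
                cutoff=cutoff,
                sensitivity=sens,
                specificity=spec,
                ppv=ppv,
                npv=npv,
                p_value=comparison_pvalue(probs, y, method=pvalue_method),
                n_cases=int(y.sum()),
                n_controls=int((y == 0).sum()),
            )
        )
    return results


def build_report(results: list[ROCResult]) -> pd.DataFrame:
    """Assemble results into the per-comparison, per-classifier report table."""
    if not results:
        return pd.DataFrame(columns=REPORT_COLUMNS)
    return pd.DataFrame([asdict(r) for r in results], columns=REPORT_COLUMNS)
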