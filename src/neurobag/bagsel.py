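"""Feature-bagging classification scores with permutation statistics.

The selection statistic works as follows.  Small random subsets ("bags") of
component features are drawn without replacement within a bag; for each bag
a linear classifier separates the two groups under cross-validation,
yielding a distribution of accuracies over bags.  A feature's
*classification score* is the probability of belonging to the bags in the
top quartile of that distribution (threshold percentile configurable).
Statistical significance is assessed by permuting group labels (group sizes
preserved), rerunning the entire bagging procedure per permutation with
fresh bags, pooling all permuted scores into one feature-independent null
distribution, and FDR-correcting the resulting per-feature p-values.  A
global count test asks whether the number of significant features exceeds
what the permutations produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import _kernels
from .components import FeatureMatrix

__all__ = [
    "BagConfig",
    "BagResult",
    "ScoreResult",
    "SelectionResult",
    "run_feature_bagging",
    "classification_scores",
    "permutation_null",
    "score_significance",
    "permutation_significant_counts",
    "global_significance",
    "run_selection",
]

logger = logging.getLogger(__name__)

CLASSIFIERS = ("linear-svm", "lda", "nearest-centroid", "stump", "hinge-svm")
CV_SCHEMES = ("loo", "5fold", "10fold")


@dataclass(frozen=True)
class BagConfig:
    """Configuration of the bagging statistic.

    ``n_draw`` defaults to a desk-scale 2e5 (the study-scale value is 2e7);
    ``bag_size`` and the 75-percentile accuracy threshold follow the study
    design.  The default classifier is a least-squares SVM (max-margin
    linear classifier with fixed unit ridge regularization) whose
    leave-one-out predictions are computed in closed form.
    """

    bag_size: int = 10
    n_draw: int = 200_000
    threshold_percentile: float = 75.0
    cv: str = "loo"
    classifier: str = "linear-svm"
    ridge: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.bag_size < 1:
            raise ValueError("bag_size must be >= 1")
        if not 0 < self.threshold_percentile < 100:
            raise ValueError("threshold percentile must lie in (0, 100)")
        if self.cv not in CV_SCHEMES:
            raise ValueError(f"cv must be one of {CV_SCHEMES}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")


@dataclass
class BagResult:
    """Accuracies and feature memberships of one bagging run."""

    accuracies: np.ndarray  # (n_draw,)
    bags: np.ndarray  # (n_draw, bag_size) feature indices
    n_features: int
    config: BagConfig


@dataclass
class ScoreResult:
    """Per-feature classification scores after thresholding the accuracy
    distribution."""

    scores: np.ndarray  # (n_features,) in [0, 1]
    threshold_value: float
    n_selected: int
    n_draw: int
    membership_total: np.ndarray
    membership_selected: np.ndarray

    @property
    def selected_fraction(self) -> float:
        return self.n_selected / self.n_draw


@dataclass
class SelectionResult:
    """Permutation-based selection of significant features."""

    scores: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    perm_counts: np.ndarray
    global_p: float
    feature_index: Optional[pd.DataFrame] = None

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_frame(self) -> pd.DataFrame:
        out = (
            self.feature_index.copy()
            if self.feature_index is not None
            else pd.DataFrame(index=np.arange(len(self.scores)))
        )
        out["score"] = self.scores
        out["p"] = self.p
        out["q"] = self.q
        out["significant"] = self.significant
        return out


def _standardize(x: np.ndarray) -> np.ndarray:
    """Label-free per-feature standardization over the supplied subjects."""
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mean) / sd


def _fold_ids(n: int, y: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Stratified fold assignment (balanced label counts per fold)."""
    ids = np.empty(n, dtype=np.int64)
    for lab in (1.0, -1.0):
        idx = np.nonzero(y == lab)[0]
        perm = rng.permutation(idx)
        ids[perm] = np.arange(len(perm)) % n_folds
    return ids


def _hinge_svm_loo(x: np.ndarray, y: np.ndarray, bags: np.ndarray) -> np.ndarray:
    """Slow exact hinge-loss linear SVM path (scikit-learn), for cross-checks."""
    from sklearn.svm import LinearSVC

    n = x.shape[0]
    acc = np.empty(bags.shape[0])
    for b, bag in enumerate(bags):
        xb = x[:, bag]
        correct = 0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            clf = LinearSVC(C=1.0, loss="squared_hinge", max_iter=10_000)
            clf.fit(xb[mask], y[mask])
            if clf.predict(xb[i : i + 1])[0] == y[i]:
                correct += 1
        acc[b] = correct / n
    return acc


def run_feature_bagging(
    features: FeatureMatrix | np.ndarray,
    labels: Optional[np.ndarray] = None,
    config: BagConfig = BagConfig(),
    seed: Optional[int] = None,
) -> BagResult:
    """Draw bags and record cross-validated accuracy per bag.

    Deterministic given the seed (``config.seed`` unless overridden).
    Features are standardized once over the supplied subjects (label-free).
    """
    if isinstance(features, FeatureMatrix):
        x = features.values()
        y = features.y()
    else:
        x = np.asarray(features, dtype=np.float64)
        y = np.asarray(labels, dtype=np.float64)
    n, n_feat = x.shape
    if np.sum(y > 0) < 3 or np.sum(y < 0) < 3:
        raise ValueError("each group needs >= 3 subjects")
    cfg = config if seed is None else replace(config, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    xs = _standardize(x)
    bags = _kernels.draw_bags(rng, cfg.n_draw, n_feat, cfg.bag_size)

    if cfg.cv == "loo":
        if cfg.classifier == "linear-svm":
            if _kernels.NUMBA_AVAILABLE:
                acc = _kernels.lssvm_loo_accuracy(xs, y, bags, cfg.ridge)
            else:
                acc = _kernels.lssvm_loo_accuracy_np(xs, y, bags, cfg.ridge)
        elif cfg.classifier == "nearest-centroid":
            if _kernels.NUMBA_AVAILABLE:
                acc = _kernels.centroid_loo_accuracy(xs, y, bags)
            else:
                acc = _kernels.centroid_loo_accuracy_np(xs, y, bags)
        elif cfg.classifier == "lda":
            acc = _kernels.dlda_loo_accuracy_np(xs, y, bags)
        elif cfg.classifier == "stump":
            acc = _kernels.stump_loo_accuracy_np(xs, y, bags)
        else:  # hinge-svm
            acc = _hinge_svm_loo(xs, y, bags)
    else:
        n_folds = 5 if cfg.cv == "5fold" else 10
        folds = _fold_ids(n, y, n_folds, rng)
        if cfg.classifier != "linear-svm":
            raise NotImplementedError("k-fold CV is implemented for linear-svm")
        acc = _kernels.lssvm_kfold_accuracy_np(xs, y, bags, cfg.ridge, folds)
    return BagResult(accuracies=acc, bags=bags, n_features=n_feat, config=cfg)


def classification_scores(
    bag_result: BagResult, percentile: Optional[float] = None
) -> ScoreResult:
    """Probability of each feature to belong to the top-accuracy bags.

    Bags at or above the requested percentile of the accuracy distribution
    (inclusive; ties at the threshold are selected) count as selected;
    ``score_f`` = selected bags containing f / selected bags.  The scores
    sum to the bag size exactly.
    """
    if bag_result.accuracies.shape[0] < 100:
        raise ValueError("need >= 100 bags for a stable threshold")
    pct = bag_result.config.threshold_percentile if percentile is None else percentile
    acc = bag_result.accuracies
    threshold = float(np.percentile(acc, pct))
    selected = acc >= threshold
    n_sel = int(selected.sum())
    if np.ptp(acc) == 0:
        logger.warning(
            "all %d bag accuracies tied at %.3f; every bag selected",
            len(acc),
            acc[0],
        )
    total = np.bincount(
        bag_result.bags.ravel(), minlength=bag_result.n_features
    ).astype(np.float64)
    sel_counts = np.bincount(
        bag_result.bags[selected].ravel(), minlength=bag_result.n_features
    ).astype(np.float64)
    scores = sel_counts / n_sel
    assert np.isclose(scores.sum(), bag_result.config.bag_size)
    return ScoreResult(
        scores=scores,
        threshold_value=threshold,
        n_selected=n_sel,
        n_draw=len(acc),
        membership_total=total,
        membership_selected=sel_counts,
    )


def permutation_null(
    features: FeatureMatrix | np.ndarray,
    labels: Optional[np.ndarray] = None,
    config: BagConfig = BagConfig(),
    n_perm: int = 200,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Classification scores under group-label permutations.

    Subjects are randomly reassigned to groups (sizes preserved) and the
    full bagging procedure is rerun with fresh bag draws per permutation.
    Returns an (n_perm, n_features) score matrix; its flattened values form
    the pooled, feature-independent null distribution.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100 for usable p-value resolution")
    if isinstance(features, FeatureMatrix):
        x = features.values()
        y = features.y()
    else:
        x = np.asarray(features, dtype=np.float64)
        y = np.asarray(labels, dtype=np.float64)
    base_seed = config.seed if seed is None else seed
    children = np.random.SeedSequence((base_seed, 0x9E3779B9)).spawn(n_perm)
    null_scores = np.empty((n_perm, x.shape[1]))
    for j, child in enumerate(children):
        rng = np.random.default_rng(child)
        y_perm = rng.permutation(y)
        child_seed = int(rng.integers(0, 2**31 - 1))
        bag_res = run_feature_bagging(x, y_perm, config, seed=child_seed)
        null_scores[j] = classification_scores(bag_res).scores
    return null_scores


def _pooled_pvalues(scores: np.ndarray, sorted_null: np.ndarray) -> np.ndarray:
    """Add-one permutation p-values against the pooled null (p is never 0)."""
    n_pool = sorted_null.shape[0]
    n_ge = n_pool - np.searchsorted(sorted_null, scores, side="left")
    return (1.0 + n_ge) / (1.0 + n_pool)


def score_significance(
    observed_scores: np.ndarray,
    null_scores: np.ndarray,
    q: float = 0.05,
    feature_index: Optional[pd.DataFrame] = None,
) -> SelectionResult:
    """Per-feature p against the pooled null, BH-FDR, and the global count
    test against the per-permutation significant-feature counts."""
    null_matrix = np.atleast_2d(null_scores)
    pooled = np.sort(null_matrix.ravel())
    p = _pooled_pvalues(np.asarray(observed_scores), pooled)
    qvals = multipletests(p, method="fdr_bh")[1]
    significant = qvals < q
    perm_counts = permutation_significant_counts(null_matrix, q)
    global_p = global_significance(int(significant.sum()), perm_counts)
    return SelectionResult(
        scores=np.asarray(observed_scores),
        p=p,
        q=qvals,
        significant=significant,
        perm_counts=perm_counts,
        global_p=global_p,
        feature_index=feature_index,
    )


def permutation_significant_counts(null_scores: np.ndarray, q: float = 0.05):
    """Number of FDR-significant features each permutation would report when
    tested against the same pooled null distribution."""
    pooled = np.sort(null_scores.ravel())
    counts = np.empty(null_scores.shape[0], dtype=np.int64)
    for j in range(null_scores.shape[0]):
        p = _pooled_pvalues(null_scores[j], pooled)
        counts[j] = int(np.sum(multipletests(p, method="fdr_bh")[1] < q))
    return counts


def global_significance(observed_count: int, perm_counts: np.ndarray) -> float:
    """p = (1 + #{permutation count >= observed}) / (1 + n_perm)."""
    perm_counts = np.asarray(perm_counts)
    return float(
        (1.0 + np.sum(perm_counts >= observed_count)) / (1.0 + len(perm_counts))
    )


def run_selection(
    features: FeatureMatrix,
    config: BagConfig = BagConfig(),
    n_perm: int = 200,
    q: float = 0.05,
    seed: Optional[int] = None,
) -> tuple[SelectionResult, ScoreResult]:
    """Observed scores + permutation statistics in one call."""
    bag_res = run_feature_bagging(features, config=config, seed=seed)
    observed = classification_scores(bag_res)
    null_scores = permutation_null(
        features, config=config, n_perm=n_perm, seed=bag_res.config.seed
    )
    selection = score_significance(
        observed.scores, null_scores, q=q, feature_index=features.feature_index
    )
    return selection, observed
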