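"""Classification confidence, severity correlation, and unbiased accuracy.

*Confidence* of subject i is the difference of squared Mahalanobis
distances of its feature vector to the control and patient group
distributions (leave-self-out mean and covariance)::

    D_i_g = (f_i - mu_g) C_g^{-1} (f_i - mu_g)'
    confidence_i = D_i_control - D_i_patient

so a positive value marks a subject as patient-like.  The squared form is
used throughout (no square root).

*Unbiased accuracy* comes from a second-level leave-one-out loop: for every
held-out subject the entire feature-selection stage is refit on the
remaining subjects, a linear classifier is trained on the selected
features, and the held-out subject's signed distance to the decision
boundary is recorded in units of the in-sample distance standard
deviation.  Gaussians fit separately to the patient and control distance
distributions yield sensitivity (patient mass above zero), specificity
(control mass below zero) and their group-size weighted accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bagsel import BagConfig, classification_scores, run_feature_bagging
from .components import FeatureMatrix

__all__ = [
    "ConfidenceScores",
    "AccuracyEstimate",
    "mahalanobis_confidence",
    "severity_correlation",
    "gaussian_accuracy",
    "nested_loo_accuracy",
]

logger = logging.getLogger(__name__)


@dataclass
class ConfidenceScores:
    """Per-subject squared-Mahalanobis distances and their difference."""

    subject_ids: np.ndarray
    labels: np.ndarray  # +1 patient, -1 control
    d_control: np.ndarray
    d_patient: np.ndarray
    feature_ids: list

    @property
    def confidence(self) -> np.ndarray:
        return self.d_control - self.d_patient

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "label": self.labels,
                "d_control": self.d_control,
                "d_patient": self.d_patient,
                "confidence": self.confidence,
            }
        )


@dataclass
class AccuracyEstimate:
    """Gaussian-integral accuracy estimate from signed boundary distances."""

    distances: np.ndarray  # signed, SD-normalized; positive = classified patient
    labels: np.ndarray
    mean_patient: float
    sd_patient: float
    mean_control: float
    sd_control: float
    sensitivity: float
    specificity: float
    accuracy: float
    n_patients: int
    n_controls: int

    @property
    def n_all(self) -> int:
        return self.n_patients + self.n_controls


def _group_stats(x: np.ndarray, covariance: str, shrinkage: float):
    """Mean and covariance of group member rows.

    ``covariance="sample"`` uses the plain sample covariance (the classical
    distance formula exactly), falling back to diagonal loading toward the
    average variance when the matrix is singular or ill-conditioned;
    ``covariance="lw"`` always applies Ledoit-Wolf shrinkage (preferable
    when the feature dimension is not far below the group size).
    """
    mu = x.mean(axis=0)
    n, d = x.shape
    if n < 2:
        raise ValueError("group too small for covariance estimation")
    if covariance == "lw":
        from sklearn.covariance import LedoitWolf

        return mu, LedoitWolf().fit(x).covariance_, True
    c = np.cov(x, rowvar=False, ddof=1).reshape(d, d)
    needs_shrink = n <= d + 1 or np.linalg.cond(c) > 1e8
    if needs_shrink:
        target = np.trace(c) / d
        c = (1.0 - shrinkage) * c + shrinkage * target * np.eye(d)
    return mu, c, needs_shrink


def mahalanobis_confidence(
    features: FeatureMatrix,
    feature_mask: Optional[np.ndarray] = None,
    covariance: str = "sample",
    shrinkage: float = 0.1,
) -> ConfidenceScores:
    """Squared Mahalanobis distance of every subject to both group
    distributions, excluding the subject from its own group's mean and
    covariance.

    ``feature_mask`` restricts the feature set (typically the significant
    components).  With the default sample covariance, diagonal-loading
    shrinkage toward the average variance is applied and logged whenever a
    group covariance is singular or ill-conditioned (subset dimension close
    to group size); ``covariance="lw"`` switches to Ledoit-Wolf shrinkage
    throughout.
    """
    if covariance not in ("sample", "lw"):
        raise ValueError("covariance must be 'sample' or 'lw'")
    fm = features if feature_mask is None else features.restrict(feature_mask)
    x = fm.values()
    y = fm.y()
    n, d = x.shape
    if d == 0:
        raise ValueError("empty feature subset")
    d_pat = np.empty(n)
    d_con = np.empty(n)
    shrunk_any = False
    for i in range(n):
        for group_label, out in ((1.0, d_pat), (-1.0, d_con)):
            members = (y == group_label) & (np.arange(n) != i)
            mu, c, shrunk = _group_stats(x[members], covariance, shrinkage)
            shrunk_any |= shrunk
            diff = x[i] - mu
            out[i] = float(diff @ np.linalg.solve(c, diff))
    if shrunk_any and covariance == "sample":
        logger.warning(
            "mahalanobis_confidence: covariance shrinkage (gamma=%.2f) applied "
            "(feature dimension %d vs group sizes %d/%d)",
            shrinkage,
            d,
            int(np.sum(y > 0)),
            int(np.sum(y < 0)),
        )
    return ConfidenceScores(
        subject_ids=fm.scores.index.to_numpy(),
        labels=y.astype(int),
        d_control=d_con,
        d_patient=d_pat,
        feature_ids=list(fm.scores.columns),
    )


def severity_correlation(
    confidence: ConfidenceScores,
    severity: pd.DataFrame,
    min_patients: int = 5,
) -> pd.DataFrame:
    """Product-moment correlation of patient confidence with severity scores.

    ``severity`` is indexed by subject id with one column per clinical
    score; missing values are dropped pairwise; BH correction runs across
    the scores tested.
    """
    conf = pd.Series(confidence.confidence, index=confidence.subject_ids)
    patients = conf[confidence.labels > 0]
    rows = []
    for col in severity.columns:
        joined = pd.concat([patients, severity[col]], axis=1, join="inner").dropna()
        n = len(joined)
        if n < min_patients:
            rows.append((col, n, np.nan, np.nan))
            continue
        a, b = joined.iloc[:, 0], joined.iloc[:, 1]
        if a.std() == 0 or b.std() == 0:
            logger.warning("severity_correlation: zero variance for %s", col)
            rows.append((col, n, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(a, b)
        rows.append((col, n, r, p))
    out = pd.DataFrame(rows, columns=["score", "n", "r", "p"])
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    return out


def gaussian_accuracy(distances: np.ndarray, labels: np.ndarray) -> AccuracyEstimate:
    """Fit per-group Gaussians to signed distances and integrate.

    sensitivity = patient Gaussian mass above 0, specificity = control mass
    below 0, accuracy = (n_pat * sensitivity + n_con * specificity) / n_all.
    A zero-SD group degenerates to a step function (mass 0, 1/2 or 1).
    """
    d = np.asarray(distances, dtype=np.float64)
    y = np.asarray(labels)
    pat = d[y > 0]
    con = d[y < 0]
    if len(pat) < 2 or len(con) < 2:
        raise ValueError("each group needs >= 2 subjects")

    def upper_mass(mean, sd):
        if sd == 0:
            logger.warning("gaussian_accuracy: zero-SD group treated as step")
            return 1.0 if mean > 0 else (0.5 if mean == 0 else 0.0)
        return float(stats.norm.sf(0.0, loc=mean, scale=sd))

    mu_p, sd_p = float(pat.mean()), float(pat.std(ddof=1))
    mu_c, sd_c = float(con.mean()), float(con.std(ddof=1))
    sens = upper_mass(mu_p, sd_p)
    spec = 1.0 - upper_mass(mu_c, sd_c)
    n_p, n_c = len(pat), len(con)
    acc = (n_p * sens + n_c * spec) / (n_p + n_c)
    return AccuracyEstimate(
        distances=d,
        labels=y,
        mean_patient=mu_p,
        sd_patient=sd_p,
        mean_control=mu_c,
        sd_control=sd_c,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        n_patients=n_p,
        n_controls=n_c,
    )


def _boundary_distances(x: np.ndarray, y: np.ndarray, lam: float):
    """Fit the linear classifier and return signed boundary distances."""
    from ._kernels import lssvm_fit

    w, b = lssvm_fit(x, y, lam)
    norm = np.linalg.norm(w)
    if norm == 0:
        return np.zeros(x.shape[0]), w, b
    return (x @ w + b) / norm, w, b


def nested_loo_accuracy(
    features: FeatureMatrix,
    config: BagConfig = BagConfig(),
    feature_mask: Optional[np.ndarray] = None,
    selection: str = "top",
    q: float = 0.05,
    n_perm: int = 200,
    seed: Optional[int] = None,
) -> AccuracyEstimate:
    """Second-level leave-one-out estimate of classification accuracy.

    For each held-out subject the bagging selection is rerun on the
    remaining subjects only (features standardized on those subjects), a
    least-squares SVM is trained on the selected features, and the held-out
    subject's signed distance to the decision boundary is divided by the
    standard deviation of the in-sample subjects' distances (both groups
    pooled, ddof=1).  The reference-cohort component basis is fixed
    throughout, so no study subject ever influences the feature space.

    ``selection="top"`` (default) keeps the ``bag_size`` features with the
    highest classification scores per fold; ``selection="fdr"`` runs the
    full permutation test per fold and keeps the FDR-significant features,
    falling back to the top-``bag_size`` set when none survive.
    """
    if selection not in ("top", "fdr"):
        raise ValueError("selection must be 'top' or 'fdr'")
    fm = features if feature_mask is None else features.restrict(feature_mask)
    x = fm.values()
    y = fm.y()
    n = x.shape[0]
    base_seed = config.seed if seed is None else seed
    fold_seeds = np.random.SeedSequence((base_seed, 0x5DEECE66)).spawn(n)
    dists = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        x_tr, y_tr = x[mask], y[mask]
        fold_seed = int(np.random.default_rng(fold_seeds[i]).integers(0, 2**31 - 1))
        bag_res = run_feature_bagging(x_tr, y_tr, config, seed=fold_seed)
        scores = classification_scores(bag_res).scores
        if selection == "fdr":
            from .bagsel import permutation_null, score_significance

            null = permutation_null(x_tr, y_tr, config, n_perm=n_perm, seed=fold_seed)
            sel = score_significance(scores, null, q=q).significant
            if not sel.any():
                logger.info(
                    "nested fold %d: no significant features; falling back to "
                    "top-%d scored features",
                    i,
                    config.bag_size,
                )
                sel = np.zeros_like(sel)
                sel[np.argsort(scores)[::-1][: config.bag_size]] = True
        else:
            sel = np.zeros(len(scores), dtype=bool)
            sel[np.argsort(scores)[::-1][: config.bag_size]] = True
        # standardize on training subjects only; apply to the held-out subject
        mean = x_tr[:, sel].mean(axis=0)
        sd = x_tr[:, sel].std(axis=0)
        sd[sd == 0] = 1.0
        xt = (x_tr[:, sel] - mean) / sd
        xi = (x[i, sel] - mean) / sd
        d_tr, w, b = _boundary_distances(xt, y_tr, config.ridge)
        sd_d = np.std(d_tr, ddof=1)
        if sd_d == 0:
            dists[i] = 0.0
            continue
        norm = np.linalg.norm(w)
        d_i = (xi @ w + b) / norm if norm > 0 else 0.0
        dists[i] = d_i / sd_d
    return gaussian_accuracy(dists, y)
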