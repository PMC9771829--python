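"""Reference-cohort PCA of coupling space and study-cohort projection.

For every (coupling mode, frequency) pair a principal-component basis is fit
on the z-scored coupling profiles of an independent reference cohort.  Study
subjects' profiles are projected onto the leading ``k`` (default 30)
eigenvectors; the component scores across all modes and frequencies form the
feature matrix consumed by the bagging classifier.  Additional helpers align
component signs so that positive loadings mean coupling increased in
patients, and summarize significant components per canonical frequency band
after normalizing each loading vector by its absolute 98th percentile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ComponentBasis",
    "FeatureMatrix",
    "BandSummary",
    "BANDS",
    "fit_component_basis",
    "project_profiles",
    "assemble_features",
    "align_component_signs",
    "band_average_components",
    "split_average_components",
]

logger = logging.getLogger(__name__)

#: Canonical band definitions (Hz, inclusive edges).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (2.8, 3.4),
    "theta": (4.0, 6.7),
    "alpha": (8.0, 13.0),
    "beta": (16.0, 27.0),
    "low_gamma": (32.0, 54.0),
    "high_gamma": (64.0, 128.0),
}

_BAND_TOL = 1e-3  # relative tolerance when matching grid frequencies to bands


@dataclass
class ComponentBasis:
    """PCA basis for one (mode, frequency): loadings, variances, mean profile."""

    mode: str
    frequency: float
    eigenvectors: np.ndarray  # (n_connections, k), orthonormal columns
    eigenvalues: np.ndarray  # (k,), nonincreasing, ddof=1 variances
    mean_profile: np.ndarray  # (n_connections,)
    n_reference: int

    @property
    def k(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def n_connections(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass
class FeatureMatrix:
    """Component scores (subjects x features) with a (mode, frequency, rank)
    column index and per-subject group labels (+1 patient, -1 control)."""

    scores: pd.DataFrame
    labels: pd.Series

    def __post_init__(self):
        if not self.scores.index.equals(self.labels.index):
            raise ValueError("scores and labels must share the subject index")

    @property
    def n_features(self) -> int:
        return self.scores.shape[1]

    @property
    def feature_index(self) -> pd.DataFrame:
        idx = self.scores.columns.to_frame(index=False)
        idx.columns = ["mode", "frequency", "rank"]
        return idx

    def values(self) -> np.ndarray:
        return self.scores.to_numpy()

    def y(self) -> np.ndarray:
        return self.labels.to_numpy().astype(np.float64)

    def restrict(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(scores=self.scores.loc[:, mask], labels=self.labels)

    def mode_mask(self, mode: str) -> np.ndarray:
        return np.asarray(self.scores.columns.get_level_values("mode") == mode)

    def frequency_mask(self, lo: float = 0.0, hi: float = np.inf) -> np.ndarray:
        f = self.scores.columns.get_level_values("frequency").to_numpy(float)
        return (f >= lo) & (f <= hi)


@dataclass
class BandSummary:
    """Signed mean loading over significant components in one band and mode."""

    band: str
    mode: str
    lo: float
    hi: float
    loading: np.ndarray | None
    components: list[tuple[str, float, int]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return self.loading is None


def fit_component_basis(
    reference_profiles: np.ndarray,
    mode: str,
    frequency: float,
    k: int = 30,
) -> ComponentBasis:
    """Fit the PCA basis on (reference subjects x connections) profiles.

    The cross-subject mean profile is removed; principal axes come from the
    singular decomposition of the centered matrix (computed on the small,
    subject-side dimension).  Eigenvalues are the component score variances
    across reference subjects (ddof = 1).  If the matrix rank is below
    ``k``, the available rank is retained with a warning.
    """
    ref = np.asarray(reference_profiles, dtype=np.float64)
    n_ref, n_c = ref.shape
    if n_ref < k + 1:
        raise ValueError(f"need >= k + 1 = {k + 1} reference subjects, got {n_ref}")
    mean_profile = ref.mean(axis=0)
    centered = ref - mean_profile
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = s.max(initial=0.0) * max(n_ref, n_c) * np.finfo(np.float64).eps
    rank = int(np.sum(s > tol))
    if rank < k:
        warnings.warn(
            f"reference matrix rank {rank} < requested {k} components at "
            f"{frequency:g} Hz ({mode}); retaining {rank}",
            stacklevel=2,
        )
        k = rank
    eigenvectors = vt[:k].T
    eigenvalues = s[:k] ** 2 / (n_ref - 1)
    return ComponentBasis(
        mode=mode,
        frequency=frequency,
        eigenvectors=eigenvectors,
        eigenvalues=eigenvalues,
        mean_profile=mean_profile,
        n_reference=n_ref,
    )


def project_profiles(
    profiles: np.ndarray,
    basis: ComponentBasis,
    center: bool = True,
) -> np.ndarray:
    """Project (subjects x connections) z-scored profiles onto the basis.

    By default the reference mean profile is subtracted first (standard PCA
    projection); ``center=False`` reproduces a plain eigenvector product.
    """
    prof = np.asarray(profiles, dtype=np.float64)
    if prof.shape[1] != basis.n_connections:
        raise ValueError(
            f"profile connection count {prof.shape[1]} != basis "
            f"{basis.n_connections}"
        )
    if center:
        prof = prof - basis.mean_profile
    return prof @ basis.eigenvectors


def assemble_features(
    score_blocks: dict[tuple[str, float], np.ndarray],
    subject_ids: np.ndarray,
    labels: np.ndarray,
) -> FeatureMatrix:
    """Stack per-(mode, frequency) score blocks into one feature table.

    Columns are ordered mode-major, then frequency, then component rank; the
    column MultiIndex is a bijection onto (mode, frequency, rank).
    """
    cols = []
    mats = []
    for (mode, f) in sorted(score_blocks, key=lambda mf: (mf[0], mf[1])):
        block = score_blocks[(mode, f)]
        for r in range(block.shape[1]):
            cols.append((mode, float(f), r))
        mats.append(block)
    columns = pd.MultiIndex.from_tuples(cols, names=["mode", "frequency", "rank"])
    scores = pd.DataFrame(np.hstack(mats), index=subject_ids, columns=columns)
    return FeatureMatrix(
        scores=scores, labels=pd.Series(labels, index=subject_ids, name="label")
    )


def align_component_signs(
    features: FeatureMatrix,
    bases: dict[tuple[str, float], ComponentBasis],
) -> tuple[FeatureMatrix, dict[tuple[str, float], ComponentBasis]]:
    """Flip components whose patient mean score is below the control mean.

    Afterwards every component satisfies patient mean >= control mean, so a
    positive loading reads as coupling increased in patients.  Idempotent.
    """
    y = features.y()
    if not (np.any(y > 0) and np.any(y < 0)):
        raise ValueError("both groups must be present to align signs")
    x = features.values()
    pat_mean = x[y > 0].mean(axis=0)
    con_mean = x[y < 0].mean(axis=0)
    flip = pat_mean < con_mean
    scores = features.scores.copy()
    scores.loc[:, flip] = -scores.loc[:, flip]
    new_bases = {}
    for key, basis in bases.items():
        mode, f = key
        col_mask = np.array(
            [(m == mode and np.isclose(fr, f)) for (m, fr, _) in features.scores.columns]
        )
        flips_here = flip[col_mask]
        vecs = basis.eigenvectors.copy()
        vecs[:, flips_here[: vecs.shape[1]]] *= -1.0
        new_bases[key] = replace(basis, eigenvectors=vecs)
    return FeatureMatrix(scores=scores, labels=features.labels), new_bases


def _normalize_loading(vec: np.ndarray) -> np.ndarray:
    """Divide by the absolute 98th percentile (linear-interpolation convention)."""
    p98 = np.percentile(np.abs(vec), 98)
    if p98 <= 0:
        return vec.copy()
    return vec / p98


def band_average_components(
    bases: dict[tuple[str, float], ComponentBasis],
    significant: list[tuple[str, float, int]],
    bands: dict[str, tuple[float, float]] | None = None,
) -> list[BandSummary]:
    """Average normalized sign-aligned loadings of significant components per
    band and mode.  Empty bands are flagged, not errors."""
    if bands is None:
        bands = BANDS
    if not significant:
        raise ValueError("significant component set is empty")
    modes = sorted({mode for (mode, _, _) in significant})
    out = []
    for band, (lo, hi) in bands.items():
        for mode in modes:
            members = [
                (m, f, r)
                for (m, f, r) in significant
                if m == mode and lo * (1 - _BAND_TOL) <= f <= hi * (1 + _BAND_TOL)
            ]
            if not members:
                out.append(BandSummary(band, mode, lo, hi, None))
                continue
            acc = [
                _normalize_loading(bases[(m, f)].eigenvectors[:, r])
                for (m, f, r) in members
            ]
            out.append(
                BandSummary(band, mode, lo, hi, np.mean(acc, axis=0), members)
            )
    return out


def split_average_components(
    bases: dict[tuple[str, float], ComponentBasis],
    significant: list[tuple[str, float, int]],
    split_hz: float = 35.0,
) -> list[BandSummary]:
    """Mean absolute normalized loadings below/above the split frequency,
    per mode (high-frequency coupling largely reflects residual muscle
    activity, hence the split)."""
    modes = sorted({mode for (mode, _, _) in significant})
    out = []
    for name, lo, hi in (("low", 0.0, split_hz), ("high", split_hz, np.inf)):
        for mode in modes:
            members = [
                (m, f, r) for (m, f, r) in significant if m == mode and lo < f <= hi
            ]
            if not members:
                out.append(BandSummary(name, mode, lo, hi, None))
                continue
            acc = [
                np.abs(_normalize_loading(bases[(m, f)].eigenvectors[:, r]))
                for (m, f, r) in members
            ]
            out.append(BandSummary(name, mode, lo, hi, np.mean(acc, axis=0), members))
    return out
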