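"""Volume-conduction-insensitive coupling metrics and coupling profiles.

Two coupling modes are computed from complex wavelet coefficients:

* **amplitude** — product-moment correlation of log-power envelopes after
  per-time-point pairwise orthogonalization, which removes the component of
  one signal that is in phase with the other and therefore cannot be
  distinguished from instantaneous (zero-lag) field spread.
* **phase** — the weighted phase-lag index (wPLI), the magnitude of the mean
  imaginary cross-spectrum normalized by the mean magnitude of its imaginary
  part; blind to zero-lag coupling by construction.

A subject's symmetric all-to-all coupling matrix at one frequency is
flattened to its upper triangle ("coupling profile"), the pipeline's atomic
measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectral import SpectralFrame

__all__ = [
    "MODES",
    "CouplingMatrix",
    "CouplingProfile",
    "orthogonalized_amplitude_correlation",
    "weighted_phase_lag_index",
    "vectorize_profile",
    "profile_to_matrix",
    "zscore_profile",
    "zscore_vector",
    "n_connections",
]

logger = logging.getLogger(__name__)

MODES = ("amplitude", "phase")

# relative floor for squared orthogonalized envelopes before the log
# transform: residuals below 1e-10 of a channel's RMS amplitude are
# numerically indistinguishable from zero (collinear signals), so they clamp
# to a constant that the zero-variance guard maps to 0
_REL_AMP_FLOOR = 1e-10
_LOG_FLOOR = 1e-300

_MIN_STEPS = 20


@dataclass
class CouplingMatrix:
    """Symmetric source-by-source coupling values; the diagonal is undefined
    (NaN)."""

    mode: str
    frequency: float
    values: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class CouplingProfile:
    """Upper triangle (i < j, row-major) of a coupling matrix as a vector."""

    mode: str
    frequency: float
    vector: np.ndarray
    n_sources: int
    connection_index: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        expected = n_connections(self.n_sources)
        if self.vector.shape != (expected,):
            raise ValueError(
                f"profile length {self.vector.shape} != n(n-1)/2 = {expected}"
            )
        if self.connection_index is None:
            iu = np.triu_indices(self.n_sources, k=1)
            self.connection_index = np.column_stack(iu)


def n_connections(n_sources: int) -> int:
    """Number of unique (unordered, off-diagonal) connections."""
    return n_sources * (n_sources - 1) // 2


def _check_steps(frame: SpectralFrame) -> np.ndarray:
    coeffs = np.asarray(frame.coefficients)
    if coeffs.shape[1] < _MIN_STEPS:
        raise ValueError(
            f"need >= {_MIN_STEPS} valid time steps, got {coeffs.shape[1]}"
        )
    return coeffs


def orthogonalized_amplitude_correlation(frame: SpectralFrame) -> CouplingMatrix:
    """Correlation of log-power envelopes of pairwise-orthogonalized signals.

    For each ordered pair (X -> Y), the component of Y's complex coefficient
    orthogonal to X's instantaneous phase is retained, its log squared
    magnitude is correlated with X's log power, and the two directed values
    are averaged into a symmetric coupling estimate.  Degenerate pairs with a
    zero-variance orthogonalized envelope (collinear signals) are set to 0
    and logged.
    """
    coeffs = _check_steps(frame)
    n, n_t = coeffs.shape
    amp = np.abs(coeffs)
    safe_amp = np.where(amp > 0, amp, 1.0)
    log_power = np.log(np.maximum(amp**2, _LOG_FLOOR))
    lp_c = log_power - log_power.mean(axis=1, keepdims=True)
    lp_sd = lp_c.std(axis=1)

    directed = np.zeros((n, n))
    n_degenerate = 0
    for i in range(n):
        unit_phase = coeffs[i] / safe_amp[i]
        # imag part of Y expressed in X's phase frame = component of Y
        # orthogonal to X's phase
        ortho = np.imag(coeffs * np.conj(unit_phase)[None, :])
        power_floor = np.maximum(
            (_REL_AMP_FLOOR**2) * (amp**2).mean(axis=1, keepdims=True), _LOG_FLOOR
        )
        log_q = np.log(np.maximum(ortho**2, power_floor))
        lq_c = log_q - log_q.mean(axis=1, keepdims=True)
        lq_sd = lq_c.std(axis=1)
        denom = lq_sd * lp_sd[i] * n_t
        valid = denom > 0
        cov = lq_c @ lp_c[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(valid, cov / np.where(valid, denom, 1.0), 0.0)
        n_degenerate += int(np.sum(~valid)) - 1  # the self pair is always flagged
        directed[:, i] = r  # column i holds corr(log|Y_perp_i|^2, log|X_i|^2)
    if n_degenerate > 0:
        logger.warning(
            "amplitude coupling at %.3f Hz: %d degenerate directed pair(s) set to 0",
            frame.frequency,
            n_degenerate,
        )
    sym = 0.5 * (directed + directed.T)
    np.fill_diagonal(sym, np.nan)
    return CouplingMatrix(mode="amplitude", frequency=frame.frequency, values=sym)


def weighted_phase_lag_index(frame: SpectralFrame) -> CouplingMatrix:
    """wPLI: |mean Im S| / mean |Im S| with S the cross-spectrum per step.

    Pairs whose imaginary cross-spectrum vanishes identically (e.g. channels
    that are real mixtures of a single source) are set to 0 by the
    degeneracy guard.
    """
    coeffs = _check_steps(frame)
    im_s = np.imag(np.einsum("it,jt->ijt", coeffs, np.conj(coeffs)))
    num = np.abs(im_s.mean(axis=2))
    den = np.abs(im_s).mean(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(w, np.nan)
    return CouplingMatrix(mode="phase", frequency=frame.frequency, values=w)


def vectorize_profile(matrix: CouplingMatrix, atol: float = 1e-10) -> CouplingProfile:
    """Flatten the upper triangle (i < j, row-major) into a coupling profile."""
    v = matrix.values
    off_diag = ~np.eye(v.shape[0], dtype=bool)
    if not np.allclose(v[off_diag], v.T[off_diag], atol=atol, equal_nan=True):
        raise ValueError("coupling matrix is not symmetric within tolerance")
    iu = np.triu_indices(v.shape[0], k=1)
    return CouplingProfile(
        mode=matrix.mode,
        frequency=matrix.frequency,
        vector=np.ascontiguousarray(v[iu]),
        n_sources=v.shape[0],
        connection_index=np.column_stack(iu),
    )


def profile_to_matrix(profile: CouplingProfile) -> CouplingMatrix:
    """Rebuild the symmetric matrix (NaN diagonal) from a profile."""
    n = profile.n_sources
    out = np.full((n, n), np.nan)
    i, j = profile.connection_index.T
    out[i, j] = profile.vector
    out[j, i] = profile.vector
    return CouplingMatrix(mode=profile.mode, frequency=profile.frequency, values=out)


def zscore_profile(profile: CouplingProfile) -> CouplingProfile:
    """Z-score across connections within the subject (population-SD convention)."""
    z = zscore_vector(profile.vector)
    return CouplingProfile(
        mode=profile.mode,
        frequency=profile.frequency,
        vector=z,
        n_sources=profile.n_sources,
        connection_index=profile.connection_index,
    )


def zscore_vector(vector: np.ndarray) -> np.ndarray:
    """Population-SD z-scoring of a 1-D (or row-wise 2-D) profile array."""
    v = np.asarray(vector, dtype=np.float64)
    mean = v.mean(axis=-1, keepdims=True)
    sd = v.std(axis=-1, keepdims=True)  # ddof=0
    if np.any(sd <= 0):
        raise ValueError("constant coupling profile: zero standard deviation")
    return (v - mean) / sd
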