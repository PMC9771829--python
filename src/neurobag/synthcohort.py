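"""Synthetic study and reference cohorts with controllable coupling structure.

Two generation levels are provided:

* :func:`generate_timeseries_cohort` — band-limited oscillatory source
  signals.  Per carrier frequency, each source is an amplitude-modulated
  sinusoid with a stochastic log-normal envelope and Ornstein–Uhlenbeck
  phase jitter.  Envelope correlations are imposed through a Gaussian copula
  on the log-envelopes; phase coupling through a shared phase-jitter process
  with a configurable nonzero lag (wPLI is blind to zero-lag coupling).
  Instantaneous linear mixing (:func:`apply_mixing`) serves as a
  volume-conduction surrogate that both coupling metrics must reject.

* :func:`generate_profile_cohort` — coupling profiles drawn directly from a
  low-rank generative model (mean profile + orthonormal component loadings
  with a decaying variance spectrum + isotropic noise), with patient-group
  means shifted along planted components by an effect size expressed in
  units of the reference cohort's component-score standard deviation.  This
  fast path exercises every stage downstream of spectral estimation.

Severity scores for synthetic patients are noisy monotone functions of each
patient's realized planted-component deviation, so correlation analyses have
a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .coupling import MODES, n_connections

__all__ = [
    "PlantedEffect",
    "SimulationConfig",
    "SyntheticCohort",
    "generate_timeseries_cohort",
    "apply_mixing",
    "generate_profile_cohort",
    "save_cohort",
]

#: Desk-scale carrier grid: octave steps from 2^1.5 Hz, one carrier per
#: canonical band (delta, theta, alpha, beta, low gamma, high gamma).
DEFAULT_CARRIERS = tuple(2.0**1.5 * 2.0**k for k in range(6))

GROUP_PATIENT = "patient"
GROUP_CONTROL = "control"
GROUP_REFERENCE = "reference"


@dataclass(frozen=True)
class PlantedEffect:
    """A group difference planted along one generative coupling component.

    ``effect_size`` is expressed in units of the reference cohort's
    component-score standard deviation.  For profile cohorts ``rank``
    addresses a generative component; for time-series cohorts a
    ``loading`` vector over connections modulates the envelope-correlation
    (amplitude mode) or phase-lag (phase mode) matrix instead.
    """

    mode: str
    frequency: float
    effect_size: float
    rank: Optional[int] = None
    loading: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if (self.rank is None) == (self.loading is None):
            raise ValueError("exactly one of rank or loading must be given")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohorts (time-series and profile paths).

    Defaults follow the study geometry scaled to desk size: a 17 + 17
    two-group study cohort, a 95-subject reference cohort, 30 sources
    (435 connections), six carrier frequencies, and 60 s of signal at
    250 Hz.
    """

    n_sources: int = 30
    n_patients: int = 17
    n_controls: int = 17
    n_reference: int = 95
    sampling_rate: float = 250.0
    duration: float = 60.0
    carrier_frequencies: tuple[float, ...] = DEFAULT_CARRIERS
    #: per-frequency symmetric matrix in [-1, 1] with unit diagonal (Gaussian
    #: copula correlation of log-envelopes); None = identity
    envelope_correlation: Optional[dict[float, np.ndarray]] = None
    #: per-frequency antisymmetric-by-convention phase-lag matrix (radians);
    #: a nonzero entry (i, j) couples the pair with that lag; None = uncoupled
    phase_lag: Optional[dict[float, np.ndarray]] = None
    mixing_matrix: Optional[np.ndarray] = None
    planted_effects: tuple[PlantedEffect, ...] = ()
    noise_sd: float = 0.1
    seed: int = 0

    # time-series texture
    envelope_log_sd: float = 0.5
    envelope_tau_cycles: float = 5.0
    #: OU jitter (rad) of coupled sources around their shared phase walk
    phase_jitter_sd: float = 0.3
    phase_tau_cycles: float = 5.0
    #: free-running phase diffusion, rad per sqrt(cycle); every phase process
    #: is a random walk so that uncoupled sources decohere (~10 cycles at the
    #: default) instead of staying spuriously locked at one carrier
    phase_drift: float = 2.0
    default_phase_lag: float = np.pi / 4

    # profile-cohort generative model
    n_generative: int = 30
    eigen_decay: float = 0.75
    component_scale: float = 0.3
    mean_scale: float = 1.0
    profile_noise_sd: float = 0.1

    def validate(self) -> None:
        if self.n_sources < 3:
            raise ValueError("n_sources must be >= 3")
        for grp, n in (("patients", self.n_patients), ("controls", self.n_controls)):
            if n < 2:
                raise ValueError(f"need >= 2 {grp}")
        if self.n_reference < 3:
            raise ValueError("need >= 3 reference subjects")
        f_low = min(self.carrier_frequencies)
        # ~100 wavelet steps at the lowest carrier (step = sigma_t / 2)
        from .spectral import temporal_sd

        n_steps = self.duration / (temporal_sd(f_low) / 2.0)
        if n_steps < 100:
            raise ValueError(
                f"duration x sampling_rate too short: {n_steps:.0f} wavelet steps "
                f"at {f_low:g} Hz (need >= 100)"
            )
        if self.envelope_correlation is not None:
            for f, mat in self.envelope_correlation.items():
                _check_correlation_matrix(mat, self.n_sources, f)

    def n_study(self) -> int:
        return self.n_patients + self.n_controls


def _check_correlation_matrix(mat: np.ndarray, n: int, f: float) -> None:
    mat = np.asarray(mat)
    if mat.shape != (n, n):
        raise ValueError(f"envelope correlation at {f:g} Hz has shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError(f"envelope correlation at {f:g} Hz is not symmetric")
    if not np.allclose(np.diag(mat), 1.0, atol=1e-12):
        raise ValueError(f"envelope correlation at {f:g} Hz lacks unit diagonal")
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals.min() < -1e-10:
        raise ValueError(
            f"envelope correlation at {f:g} Hz is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3e})"
        )


@dataclass
class SyntheticCohort:
    """A generated cohort: manifest plus recordings or coupling profiles.

    ``recordings`` maps subject id to a (sources x samples) array;
    ``profiles`` maps (mode, frequency) to a (subjects x connections) array
    whose rows align with the manifest.  Exactly one of the two is set.
    """

    manifest: pd.DataFrame
    config: SimulationConfig
    recordings: Optional[dict[str, np.ndarray]] = None
    profiles: Optional[dict[tuple[str, float], np.ndarray]] = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.recordings is None) == (self.profiles is None):
            raise ValueError("exactly one of recordings or profiles must be set")
        n = len(self.manifest)
        if self.recordings is not None:
            missing = set(self.manifest["subject_id"]) - set(self.recordings)
            if missing:
                raise ValueError(f"manifest entries without recordings: {missing}")
        else:
            for key, arr in self.profiles.items():
                if arr.shape[0] != n:
                    raise ValueError(f"profile block {key} has {arr.shape[0]} rows != {n}")

    def subjects(self, group: str | None = None) -> pd.DataFrame:
        if group is None:
            return self.manifest
        return self.manifest[self.manifest["group"] == group]

    def labels(self) -> pd.Series:
        """+1 for patients, -1 for controls (study subjects only)."""
        study = self.manifest[self.manifest["group"] != GROUP_REFERENCE]
        return pd.Series(
            np.where(study["group"] == GROUP_PATIENT, 1, -1),
            index=study["subject_id"].to_numpy(),
            name="label",
        )


def _build_manifest(config: SimulationConfig, rng: np.random.Generator,
                    severity_signal: Optional[np.ndarray] = None) -> pd.DataFrame:
    rows = []
    for i in range(config.n_patients):
        rows.append((f"pat{i:03d}", GROUP_PATIENT))
    for i in range(config.n_controls):
        rows.append((f"con{i:03d}", GROUP_CONTROL))
    for i in range(config.n_reference):
        rows.append((f"ref{i:03d}", GROUP_REFERENCE))
    df = pd.DataFrame(rows, columns=["subject_id", "group"])
    df["sampling_rate"] = config.sampling_rate
    df["path"] = ""
    edss = np.full(len(df), np.nan)
    msfc = np.full(len(df), np.nan)
    n_p = config.n_patients
    if severity_signal is None:
        signal = np.zeros(n_p)
    else:
        sd = severity_signal.std()
        signal = severity_signal / sd if sd > 0 else np.zeros(n_p)
    # severity = standardized planted deviation + unit noise (SNR ~ 1),
    # mapped to an EDSS-like (0-7, higher worse) and an MSFC-like scale
    # (already mirrored so that higher = more severe)
    edss[:n_p] = np.clip(1.5 + 0.8 * (signal + rng.standard_normal(n_p)), 0.0, 7.0)
    msfc[:n_p] = 1.8 + 0.8 * (signal + rng.standard_normal(n_p))
    df["edss_like"] = edss
    df["msfc_like"] = msfc
    return df


# ---------------------------------------------------------------------------
# time-series path
# ---------------------------------------------------------------------------


def _ou_process(rng: np.random.Generator, shape: tuple[int, int], rho: float,
                sd: float) -> np.ndarray:
    """Stationary AR(1) (discretized Ornstein-Uhlenbeck) rows with SD ``sd``."""
    n, t = shape
    innov = rng.standard_normal((n, t)) * np.sqrt(1.0 - rho**2)
    innov[:, 0] = rng.standard_normal(n)  # stationary start
    out = lfilter([1.0], [1.0, -rho], innov, axis=1)
    return sd * out


def _phase_groups(lag: np.ndarray) -> tuple[list[list[int]], np.ndarray]:
    """Connected components of the phase-coupling graph and per-source offsets.

    Offsets are assigned by breadth-first traversal using the pairwise lags
    (offset_j = offset_i + lag[i, j]); inconsistent cycles keep the first
    visited value.
    """
    n = lag.shape[0]
    coupled = np.abs(lag) > 0
    offsets = np.zeros(n)
    seen = np.zeros(n, dtype=bool)
    groups: list[list[int]] = []
    for start in range(n):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = [start]
        while queue:
            i = queue.pop()
            for j in np.nonzero(coupled[i])[0]:
                if not seen[j]:
                    seen[j] = True
                    offsets[j] = offsets[i] + lag[i, j]
                    comp.append(j)
                    queue.append(j)
        groups.append(comp)
    return groups, offsets


def _group_matrices(config: SimulationConfig, f: float, group: str):
    n = config.n_sources
    env = np.eye(n)
    if config.envelope_correlation and f in config.envelope_correlation:
        env = np.asarray(config.envelope_correlation[f], dtype=np.float64).copy()
    lag = np.zeros((n, n))
    if config.phase_lag and f in config.phase_lag:
        lag = np.asarray(config.phase_lag[f], dtype=np.float64).copy()
    if group == GROUP_PATIENT:
        iu = np.triu_indices(n, k=1)
        for effect in config.planted_effects:
            if effect.loading is None or not np.isclose(effect.frequency, f):
                continue
            delta = np.zeros((n, n))
            delta[iu] = effect.effect_size * np.asarray(effect.loading)
            delta = delta + delta.T
            if effect.mode == "amplitude":
                env = np.clip(env + delta, -1.0, 1.0)
                np.fill_diagonal(env, 1.0)
            else:
                mask = (lag == 0) & (delta != 0)
                lag = lag + np.where(mask, np.sign(delta) * config.default_phase_lag, 0.0)
    if group == GROUP_PATIENT and config.envelope_correlation and f in (
        config.envelope_correlation
    ):
        _check_correlation_matrix(env, n, f)
    return env, lag


def _synthesize_subject(config: SimulationConfig, rng: np.random.Generator,
                        group: str) -> np.ndarray:
    n = config.n_sources
    n_samp = int(round(config.duration * config.sampling_rate))
    dt = 1.0 / config.sampling_rate
    t = np.arange(n_samp) * dt
    x = np.zeros((n, n_samp))
    for f in config.carrier_frequencies:
        env_corr, lag = _group_matrices(config, f, group)
        try:
            chol = np.linalg.cholesky(env_corr + 1e-12 * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"envelope correlation at {f:g} Hz is not positive semi-definite"
            ) from exc
        rho_env = np.exp(-dt / (config.envelope_tau_cycles / f))
        z = _ou_process(rng, (n, n_samp), rho_env, 1.0)
        z = chol @ z
        env = np.exp(config.envelope_log_sd * z - 0.5 * config.envelope_log_sd**2)

        rho_ph = np.exp(-dt / (config.phase_tau_cycles / f))
        drift_step = config.phase_drift * np.sqrt(f * dt)
        groups, offsets = _phase_groups(lag)
        phase = np.empty((n, n_samp))
        base = 2.0 * np.pi * f * t

        def phase_walk():
            return rng.uniform(0, 2 * np.pi) + np.cumsum(
                drift_step * rng.standard_normal(n_samp)
            )

        for comp in groups:
            if len(comp) == 1:
                phase[comp[0]] = base + phase_walk()
            else:
                shared = phase_walk()
                for k in comp:
                    jitter = _ou_process(
                        rng, (1, n_samp), rho_ph, config.phase_jitter_sd
                    )[0]
                    phase[k] = base + shared + offsets[k] + jitter
        x += env * np.cos(phase)
    x += config.noise_sd * rng.standard_normal((n, n_samp))
    return x


def generate_timeseries_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate raw oscillatory recordings for study and reference cohorts.

    Deterministic given ``config.seed``.  Patient-group coupling matrices are
    modulated by loading-vector planted effects; rank-addressed effects are
    only meaningful for the profile path and raise here.
    """
    config.validate()
    for effect in config.planted_effects:
        if effect.loading is None:
            raise ValueError(
                "time-series cohorts require loading-vector planted effects; "
                f"got rank-addressed effect {effect!r}"
            )
        if effect.loading.shape != (n_connections(config.n_sources),):
            raise ValueError("planted loading length != n(n-1)/2")
    seq = np.random.SeedSequence(config.seed)
    s_manifest, subj_seq = seq.spawn(2)
    manifest = _build_manifest(config, np.random.default_rng(s_manifest))
    recordings: dict[str, np.ndarray] = {}
    child_seeds = subj_seq.spawn(len(manifest))
    for (_, row), child in zip(manifest.iterrows(), child_seeds):
        rng = np.random.default_rng(child)
        recordings[row["subject_id"]] = _synthesize_subject(config, rng, row["group"])
    ground_truth = {"planted_effects": list(config.planted_effects)}
    return SyntheticCohort(
        manifest=manifest,
        config=config,
        recordings=recordings,
        ground_truth=ground_truth,
    )


def apply_mixing(cohort: SyntheticCohort, mixing: np.ndarray) -> SyntheticCohort:
    """Apply an instantaneous (zero-lag) linear mixing matrix to every sample.

    The mixing must be square, real and full rank; it surrogates volume
    conduction / field spread.
    """
    if cohort.recordings is None:
        raise ValueError("apply_mixing requires a time-series cohort")
    m = np.asarray(mixing, dtype=np.float64)
    n = cohort.config.n_sources
    if m.shape != (n, n):
        raise ValueError(f"mixing shape {m.shape} != ({n}, {n})")
    if np.linalg.matrix_rank(m) < n:
        raise ValueError("mixing matrix is rank deficient")
    mixed = {sid: m @ arr for sid, arr in cohort.recordings.items()}
    gt = dict(cohort.ground_truth)
    gt["mixing_matrix"] = m
    return SyntheticCohort(
        manifest=cohort.manifest.copy(),
        config=cohort.config,
        recordings=mixed,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# profile path
# ---------------------------------------------------------------------------


def generate_profile_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw coupling profiles directly from a low-rank generative model.

    Per (mode, frequency): profile = mean + Q @ (scale * sqrt(lambda) * s)
    + isotropic noise, with Q an orthonormal loading basis, lambda a
    geometric variance spectrum and s standard normal subject scores.
    Patients are shifted along planted components by
    ``effect_size * SD_ref`` where ``SD_ref`` is the reference cohort's
    component-score standard deviation implied by the generative model.
    """
    config.validate()
    m = config.n_generative
    for effect in config.planted_effects:
        if effect.rank is None:
            raise ValueError("profile cohorts require rank-addressed planted effects")
        if not 0 <= effect.rank < m:
            raise ValueError(
                f"planted rank {effect.rank} outside generative components [0, {m})"
            )
        if not any(np.isclose(effect.frequency, f) for f in config.carrier_frequencies):
            raise ValueError(f"planted frequency {effect.frequency} not on the grid")

    seq = np.random.SeedSequence(config.seed)
    s_basis, s_scores, s_manifest = seq.spawn(3)
    rng_basis = np.random.default_rng(s_basis)
    rng_scores = np.random.default_rng(s_scores)

    n_c = n_connections(config.n_sources)
    if m > n_c:
        raise ValueError("n_generative exceeds connection count")
    n_total = config.n_study() + config.n_reference
    n_p = config.n_patients
    lam = config.eigen_decay ** np.arange(m)
    comp_sd = config.component_scale * np.sqrt(lam)
    sd_ref = np.sqrt(comp_sd**2 + config.profile_noise_sd**2)

    profiles: dict[tuple[str, float], np.ndarray] = {}
    bases: dict[tuple[str, float], np.ndarray] = {}
    severity_signal = np.zeros(n_p)
    for mode in MODES:
        for f in config.carrier_frequencies:
            q, _ = np.linalg.qr(rng_basis.standard_normal((n_c, m)))
            mu = config.mean_scale * rng_basis.standard_normal(n_c)
            scores = rng_scores.standard_normal((n_total, m))
            noise = config.profile_noise_sd * rng_scores.standard_normal((n_total, n_c))
            block = mu[None, :] + (scores * comp_sd[None, :]) @ q.T + noise
            for effect in config.planted_effects:
                if effect.mode != mode or not np.isclose(effect.frequency, f):
                    continue
                shift = effect.effect_size * sd_ref[effect.rank]
                block[:n_p] += shift * q[:, effect.rank][None, :]
                severity_signal += (
                    scores[:n_p, effect.rank] * comp_sd[effect.rank] + shift
                ) / sd_ref[effect.rank]
            profiles[(mode, f)] = block
            bases[(mode, f)] = q
    manifest = _build_manifest(
        config,
        np.random.default_rng(s_manifest),
        severity_signal if config.planted_effects else None,
    )
    ground_truth = {
        "planted_effects": list(config.planted_effects),
        "component_sd_reference": sd_ref,
        "generative_bases": bases,
        "eigenvalues": comp_sd**2,
    }
    return SyntheticCohort(
        manifest=manifest,
        config=config,
        profiles=profiles,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> pd.DataFrame:
    """Write manifest (CSV), recordings/profiles (.npy + JSON sidecars).

    Returns the manifest with populated ``path`` column.
    """
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    if cohort.recordings is not None:
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for idx, row in manifest.iterrows():
            sid = row["subject_id"]
            path = rec_dir / f"{sid}.npy"
            np.save(path, cohort.recordings[sid])
            sidecar = {
                "subject_id": sid,
                "sampling_rate": cohort.config.sampling_rate,
                "source_labels": [f"src{k:03d}" for k in range(cohort.config.n_sources)],
            }
            (rec_dir / f"{sid}.json").write_text(json.dumps(sidecar, indent=1))
            manifest.loc[idx, "path"] = str(path)
    else:
        prof_dir = out / "profiles"
        prof_dir.mkdir(exist_ok=True)
        for (mode, f), block in cohort.profiles.items():
            np.save(prof_dir / f"{mode}_{f:.4f}Hz.npy", block)
        manifest["path"] = str(prof_dir)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
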