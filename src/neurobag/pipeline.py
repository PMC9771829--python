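"""Pipeline orchestration: simulate -> spectra -> couple -> univariate ->
reduce -> select -> confidence -> accuracy.

Each stage persists its outputs under the run directory so later stages can
be rerun in isolation; a run record (config hash, stage wall times,
warnings) is emitted for every run.  Seeds propagate from one master seed
to every stochastic stage by counter-based derivation, so reruns with the
same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bagsel import BagConfig, classification_scores, run_feature_bagging, run_selection
from .components import (
    BANDS,
    FeatureMatrix,
    assemble_features,
    fit_component_basis,
    project_profiles,
)
from .confacc import (
    gaussian_accuracy,
    mahalanobis_confidence,
    nested_loo_accuracy,
    severity_correlation,
)
from .connstats import connectionwise_tests, sign_asymmetry_test
from .coupling import (
    MODES,
    orthogonalized_amplitude_correlation,
    vectorize_profile,
    weighted_phase_lag_index,
    zscore_vector,
)
from .spectral import morlet_transform
from .synthcohort import (
    GROUP_REFERENCE,
    SimulationConfig,
    SyntheticCohort,
    generate_profile_cohort,
    generate_timeseries_cohort,
    save_cohort,
)

__all__ = ["PipelineConfig", "RunRecord", "run_pipeline", "cohort_to_features"]

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "couple",
    "univariate",
    "reduce",
    "select",
    "confidence",
    "accuracy",
)


@dataclass
class PipelineConfig:
    """Top-level configuration tying all stage configs together."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    bag: BagConfig = field(default_factory=BagConfig)
    simulate_profiles: bool = True  # False: raw time series + spectral stages
    n_components: int = 30
    n_perm: int = 200
    fdr_q: float = 0.05
    univariate_alpha: float = 0.05
    sign_test_df: int = 40
    split_hz: float = 35.0
    project_centered: bool = True
    out_dir: str = "neurobag_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # one master seed drives every stochastic stage
        self.simulation = replace(self.simulation, seed=self.seed)
        self.bag = replace(self.bag, seed=self.seed + 1)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["simulation"]["carrier_frequencies"] = [
            float(f) for f in self.simulation.carrier_frequencies
        ]
        for key in ("envelope_correlation", "phase_lag", "mixing_matrix",
                    "planted_effects"):
            if out["simulation"].get(key):
                out["simulation"][key] = "<array>"
        return out

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunRecord:
    """Provenance of one pipeline run."""

    config_hash: str
    version: str
    stage_seconds: dict[str, float]
    warnings: list[str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)


def _profiles_from_recordings(cohort: SyntheticCohort) -> dict:
    """Wavelet transform + both coupling metrics, per subject and frequency."""
    config = cohort.config
    n_subj = len(cohort.manifest)
    blocks: dict[tuple[str, float], list[np.ndarray]] = {
        (mode, f): [] for mode in MODES for f in config.carrier_frequencies
    }
    for _, row in cohort.manifest.iterrows():
        signal = cohort.recordings[row["subject_id"]]
        for f in config.carrier_frequencies:
            frame = morlet_transform(signal, config.sampling_rate, f)
            for mode, metric in (
                ("amplitude", orthogonalized_amplitude_correlation),
                ("phase", weighted_phase_lag_index),
            ):
                profile = vectorize_profile(metric(frame))
                blocks[(mode, f)].append(profile.vector)
    return {key: np.vstack(vecs) for key, vecs in blocks.items()}


def cohort_to_features(
    cohort: SyntheticCohort,
    profiles: Optional[dict] = None,
    k: int = 30,
    centered: bool = True,
) -> tuple[FeatureMatrix, dict]:
    """Z-score profiles, fit PCA bases on the reference rows, project the
    study rows; returns the feature matrix and the fitted bases."""
    if profiles is None:
        profiles = (
            cohort.profiles
            if cohort.profiles is not None
            else _profiles_from_recordings(cohort)
        )
    groups = cohort.manifest["group"].to_numpy()
    is_ref = groups == GROUP_REFERENCE
    labels = cohort.labels()
    bases = {}
    score_blocks = {}
    for key, block in profiles.items():
        mode, f = key
        z = zscore_vector(block)
        bases[key] = fit_component_basis(z[is_ref], mode, f, k=k)
        score_blocks[key] = project_profiles(z[~is_ref], bases[key], center=centered)
    features = assemble_features(
        score_blocks,
        cohort.manifest.loc[~is_ref, "subject_id"].to_numpy(),
        labels.to_numpy(),
    )
    return features, bases


def run_pipeline(config: PipelineConfig) -> RunRecord:
    """Execute the configured stages in order, persisting artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    record_times: dict[str, float] = {}
    warnings_log: list[str] = []
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    cohort: Optional[SyntheticCohort] = None
    profiles = None
    features: Optional[FeatureMatrix] = None
    selection = None

    def timed(stage):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                record_times[stage] = round(time.perf_counter() - self.t0, 3)

        return _Timer()

    if "simulate" in config.stages:
        with timed("simulate"):
            gen = (
                generate_profile_cohort
                if config.simulate_profiles
                else generate_timeseries_cohort
            )
            cohort = gen(config.simulation)
            save_cohort(cohort, out)
    if cohort is None:
        raise RuntimeError("pipeline requires the simulate stage (or a cohort)")

    if "couple" in config.stages or cohort.profiles is None:
        with timed("couple"):
            profiles = (
                cohort.profiles
                if cohort.profiles is not None
                else _profiles_from_recordings(cohort)
            )
    else:
        profiles = cohort.profiles

    study_mask = (cohort.manifest["group"] != GROUP_REFERENCE).to_numpy()
    y = cohort.labels().to_numpy()

    if "univariate" in config.stages:
        with timed("univariate"):
            results = []
            for (mode, f), block in sorted(profiles.items()):
                study = block[study_mask]
                results.append(
                    connectionwise_tests(
                        study[y > 0], study[y < 0], mode, f,
                        alpha=config.univariate_alpha,
                    )
                )
            asym = sign_asymmetry_test(
                results, alpha=config.univariate_alpha, df=config.sign_test_df
            )
            asym.to_csv(out / "univariate_asymmetry.tsv", sep="\t", index=False)

    if "reduce" in config.stages:
        with timed("reduce"):
            features, bases = cohort_to_features(
                cohort, profiles, k=config.n_components,
                centered=config.project_centered,
            )
            flat = features.scores.copy()
            flat.columns = [f"{m}_{f:g}Hz_c{r}" for (m, f, r) in flat.columns]
            flat.to_csv(out / "features.tsv", sep="\t")
            features.feature_index.to_csv(out / "feature_index.csv", index=False)
            basis_dir = out / "basis"
            basis_dir.mkdir(exist_ok=True)
            for (mode, f), basis in bases.items():
                np.savez(
                    basis_dir / f"{mode}_{f:.4f}Hz.npz",
                    eigenvectors=basis.eigenvectors,
                    eigenvalues=basis.eigenvalues,
                    mean_profile=basis.mean_profile,
                )
    if features is None and (
        {"select", "confidence", "accuracy"} & set(config.stages)
    ):
        raise RuntimeError("select/confidence/accuracy stages require reduce")

    if "select" in config.stages:
        with timed("select"):
            selection, observed = run_selection(
                features, config.bag, n_perm=config.n_perm, q=config.fdr_q
            )
            frame = selection.to_frame()
            frame.to_csv(out / "selection.tsv", sep="\t", index=False)
            (out / "selection.json").write_text(
                json.dumps(
                    {
                        "n_significant": selection.n_significant,
                        "global_p": selection.global_p,
                        "threshold_value": observed.threshold_value,
                        "selected_fraction": observed.selected_fraction,
                        "config_hash": config.config_hash(),
                    },
                    indent=1,
                )
            )

    if "confidence" in config.stages:
        with timed("confidence"):
            if selection is not None and selection.significant.any():
                mask = selection.significant
            else:
                warnings_log.append(
                    "confidence: no significant features; using top bag_size scores"
                )
                bag_res = run_feature_bagging(features, config=config.bag)
                scores = classification_scores(bag_res).scores
                mask = np.zeros(features.n_features, dtype=bool)
                mask[np.argsort(scores)[::-1][: config.bag.bag_size]] = True
            conf = mahalanobis_confidence(features, feature_mask=mask)
            conf.to_frame().to_csv(out / "confidence.tsv", sep="\t", index=False)
            severity = cohort.manifest.set_index("subject_id")[
                ["edss_like", "msfc_like"]
            ]
            corr = severity_correlation(conf, severity)
            corr.to_csv(out / "severity_correlation.tsv", sep="\t", index=False)

    if "accuracy" in config.stages:
        with timed("accuracy"):
            estimate = nested_loo_accuracy(features, config.bag)
            pd.DataFrame(
                {
                    "subject_id": features.scores.index,
                    "label": estimate.labels,
                    "distance": estimate.distances,
                }
            ).to_csv(out / "distances.tsv", sep="\t", index=False)
            (out / "accuracy.json").write_text(
                json.dumps(
                    {
                        "sensitivity": estimate.sensitivity,
                        "specificity": estimate.specificity,
                        "accuracy": estimate.accuracy,
                        "n_patients": estimate.n_patients,
                        "n_controls": estimate.n_controls,
                        "config_hash": config.config_hash(),
                    },
                    indent=1,
                )
            )

    record = RunRecord(
        config_hash=config.config_hash(),
        version=__version__,
        stage_seconds=record_times,
        warnings=warnings_log,
    )
    (out / "run_record.json").write_text(record.to_json())
    return record
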