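import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from neurobag.bagsel import BagConfig, classification_scores, run_feature_bagging
from neurobag.coupling import (
    n_connections,
    orthogonalized_amplitude_correlation,
    weighted_phase_lag_index,
)
from neurobag.pipeline import cohort_to_features
from neurobag.spectral import morlet_transform
from neurobag.synthcohort import (
    PlantedEffect,
    SimulationConfig,
    apply_mixing,
    generate_profile_cohort,
    generate_timeseries_cohort,
)

F0 = 2.0**1.5
RATE = 250.0


def _small_ts_config(**kw):
    base = dict(
        n_sources=4,
        n_patients=2,
        n_controls=2,
        n_reference=3,
        duration=60.0,
        carrier_frequencies=(16.0,),
        seed=7,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestTimeseriesCohort:
    def test_deterministic_given_seed(self):
        a = generate_timeseries_cohort(_small_ts_config())
        b = generate_timeseries_cohort(_small_ts_config())
        for sid in a.recordings:
            np.testing.assert_array_equal(a.recordings[sid], b.recordings[sid])
        assert a.manifest.equals(b.manifest)

    def test_independent_sources_have_near_zero_coupling(self):
        cohort = generate_timeseries_cohort(_small_ts_config(n_sources=5))
        frame = morlet_transform(cohort.recordings["pat000"], RATE, 16.0)
        iu = np.triu_indices(5, 1)
        aec = orthogonalized_amplitude_correlation(frame).values[iu]
        assert abs(aec.mean()) < 3.0 / np.sqrt(frame.n_steps) * 3

    def test_planted_envelope_correlation_matches_monte_carlo_oracle(self):
        """Planted 0.6 log-envelope correlation at 16 Hz: one subject's
        measured orthogonalized AEC falls within +/-0.1 of the mean over 50
        independent realizations."""
        env = np.eye(4)
        env[0, 1] = env[1, 0] = 0.6
        values = []
        for seed in range(50):
            cohort = generate_timeseries_cohort(
                _small_ts_config(
                    n_patients=2, n_controls=2, n_reference=3,
                    envelope_correlation={16.0: env}, seed=1000 + seed,
                )
            )
            frame = morlet_transform(cohort.recordings["pat000"], RATE, 16.0)
            values.append(
                orthogonalized_amplitude_correlation(frame).values[0, 1]
            )
        oracle = np.mean(values)
        assert oracle > 0.05  # the plant is detectable at all
        assert abs(values[0] - oracle) < 0.1

    def test_planted_phase_lag_yields_high_wpli(self):
        lag = np.zeros((4, 4))
        lag[2, 3], lag[3, 2] = np.pi / 4, -np.pi / 4
        cohort = generate_timeseries_cohort(
            _small_ts_config(phase_lag={16.0: lag})
        )
        frame = morlet_transform(cohort.recordings["con000"], RATE, 16.0)
        w = weighted_phase_lag_index(frame).values
        assert w[2, 3] > 0.8
        assert w[0, 1] < 0.4

    def test_infeasible_correlation_matrix_rejected(self):
        env = np.array([[1, 0.9, 0], [0.9, 1, 0.9], [0, 0.9, 1.0]])
        cfg = _small_ts_config(n_sources=3, envelope_correlation={16.0: env})
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_timeseries_cohort(cfg)


class TestMixing:
    def test_identity_mixing_leaves_cohort_unchanged(self):
        cohort = generate_timeseries_cohort(_small_ts_config(duration=20.0))
        mixed = apply_mixing(cohort, np.eye(4))
        for sid in cohort.recordings:
            np.testing.assert_array_equal(cohort.recordings[sid], mixed.recordings[sid])

    def test_dimension_mismatch_and_rank_deficiency_rejected(self):
        cohort = generate_timeseries_cohort(_small_ts_config(duration=20.0))
        with pytest.raises(ValueError, match="shape"):
            apply_mixing(cohort, np.eye(3))
        bad = np.eye(4)
        bad[3] = bad[0]
        with pytest.raises(ValueError, match="rank"):
            apply_mixing(cohort, bad)

    def test_orthogonal_mixing_of_uncoupled_cohort_rejected_by_both_metrics(self):
        """Random orthogonal mixing (a volume-conduction surrogate) must not
        create coupling: the mixed 95th percentile over pairs stays below the
        unmixed cohort's null 97.5th percentile."""
        cfg = _small_ts_config(n_sources=8, n_patients=2, n_controls=2,
                               n_reference=3, duration=90.0, seed=5)
        cohort = generate_timeseries_cohort(cfg)
        q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((8, 8)))
        mixed = apply_mixing(cohort, q)
        iu = np.triu_indices(8, 1)
        pools = {"wpli": ([], []), "aec": ([], [])}
        for sid in cohort.recordings:
            for coh, slot in ((cohort, 0), (mixed, 1)):
                frame = morlet_transform(coh.recordings[sid], RATE, 16.0)
                pools["wpli"][slot].append(weighted_phase_lag_index(frame).values[iu])
                pools["aec"][slot].append(
                    np.abs(orthogonalized_amplitude_correlation(frame).values[iu])
                )
        for metric, (unmixed, mixed_vals) in pools.items():
            null_975 = np.percentile(np.concatenate(unmixed), 97.5)
            mixed_95 = np.percentile(np.concatenate(mixed_vals), 95)
            assert mixed_95 < null_975, metric


class TestProfileCohort:
    def test_deterministic_given_seed(self):
        a = generate_profile_cohort(SimulationConfig(seed=4))
        b = generate_profile_cohort(SimulationConfig(seed=4))
        for key in a.profiles:
            np.testing.assert_array_equal(a.profiles[key], b.profiles[key])

    def test_null_cohort_feature_tstats_follow_student_null(self):
        """With effect size 0, feature-wise two-sample t statistics follow
        the Student null (KS p > 0.01 across features)."""
        cohort = generate_profile_cohort(SimulationConfig(seed=29))
        features, _ = cohort_to_features(cohort)
        x, y = features.values(), features.y()
        tvals = stats.ttest_ind(x[y > 0], x[y < 0], axis=0).statistic
        ks = stats.kstest(tvals, "t", args=(len(y) - 2,))
        assert ks.pvalue > 0.01

    def test_effect_two_separates_groups_with_high_auc(self):
        """A 2-SD shift on one component yields empirical AUC > 0.9 for the
        planted component's score at n = 17 + 17 (a 2-SD shift implies a
        population AUC of Phi(sqrt(2)) ~ 0.92; averaged over a small seed
        bank to tame the +/-0.05 sampling spread of the empirical AUC)."""
        y = np.array([1] * 17 + [-1] * 17)
        aucs = []
        for seed in (31, 32, 33, 34, 35):
            cohort = generate_profile_cohort(
                SimulationConfig(
                    seed=seed,
                    planted_effects=(PlantedEffect("amplitude", F0 * 4, 2.0, rank=0),),
                )
            )
            q = cohort.ground_truth["generative_bases"][("amplitude", F0 * 4)][:, 0]
            scores = cohort.profiles[("amplitude", F0 * 4)][:34] @ q
            auc = roc_auc_score(y > 0, scores)
            aucs.append(max(auc, 1 - auc))
        assert np.mean(aucs) > 0.9

    def test_both_planted_modes_reach_top_scores_downstream(self):
        """Two planted components (one per mode) surface at the top of the
        classification-score ranking.  Each planted component is identified
        with the estimated principal component whose loadings best align
        with the generative loading vector (PCA estimation noise spreads a
        planted effect across neighboring components, so nominal rank
        correspondence is not guaranteed)."""
        top5_hits = 0
        top10_hits = 0
        cfg_bag = BagConfig(n_draw=20_000)
        for seed in range(20):
            cohort = generate_profile_cohort(
                SimulationConfig(
                    seed=300 + seed,
                    planted_effects=(
                        PlantedEffect("amplitude", F0 * 4, 2.0, rank=0),
                        PlantedEffect("phase", F0 * 2, 2.0, rank=1),
                    ),
                )
            )
            features, bases = cohort_to_features(cohort)
            bag_res = run_feature_bagging(features, config=cfg_bag, seed=seed)
            scores = classification_scores(bag_res).scores
            cols = list(features.scores.columns)
            matched = set()
            for eff in cohort.ground_truth["planted_effects"]:
                q = cohort.ground_truth["generative_bases"][
                    (eff.mode, eff.frequency)
                ][:, eff.rank]
                basis = bases[(eff.mode, eff.frequency)]
                r_best = int(np.argmax(np.abs(q @ basis.eigenvectors)))
                matched.add(cols.index((eff.mode, eff.frequency, r_best)))
            order = np.argsort(scores)[::-1]
            top5_hits += matched <= set(order[:5])
            top10_hits += matched <= set(order[:10])
        assert top10_hits >= 18
        assert top5_hits >= 14

    def test_classification_score_monotone_in_effect_size(self):
        """The planted component's mean classification score never decreases
        as the effect size grows over {0, 0.5, 1, 2} (fixed seed bank)."""
        seeds = (0, 1, 2)
        cfg_bag = BagConfig(n_draw=5000)
        means = []
        for effect in (0.0, 0.5, 1.0, 2.0):
            vals = []
            for seed in seeds:
                planted = (
                    (PlantedEffect("amplitude", F0 * 4, effect, rank=0),)
                    if effect > 0
                    else ()
                )
                cohort = generate_profile_cohort(
                    SimulationConfig(seed=400 + seed, planted_effects=planted)
                )
                features, _ = cohort_to_features(cohort)
                bag_res = run_feature_bagging(features, config=cfg_bag, seed=seed)
                scores = classification_scores(bag_res).scores
                col = list(features.scores.columns).index(("amplitude", F0 * 4, 0))
                vals.append(scores[col])
            means.append(np.mean(vals))
        assert all(b >= a - 1e-9 for a, b in zip(means, means[1:]))

    def test_severity_scores_only_for_patients(self):
        cohort = generate_profile_cohort(SimulationConfig(seed=5))
        man = cohort.manifest
        assert man.loc[man.group == "patient", "edss_like"].notna().all()
        assert man.loc[man.group != "patient", "edss_like"].isna().all()

    def test_planted_rank_out_of_range_rejected(self):
        cfg = SimulationConfig(
            planted_effects=(PlantedEffect("amplitude", F0, 1.0, rank=99),)
        )
        with pytest.raises(ValueError, match="rank"):
            generate_profile_cohort(cfg)
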