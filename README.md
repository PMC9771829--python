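# neurobag

Multistage classification of brain-wide, frequency-resolved phase- and
amplitude-coupling.

## The problem

Resting-state electrophysiology (MEG/EEG source estimates) yields, per
subject, an all-to-all coupling matrix for every carrier frequency and
coupling mode — at 457 cortical sources and 23 frequencies that is
~4.8 million coupling values per subject. Detecting group differences
(e.g. patients vs. controls) connection-by-connection fails: after
correcting for 10⁵ comparisons per frequency nothing survives, even when
real, distributed differences exist. `neurobag` implements a multistage
pipeline for exactly this regime — small cohorts (tens of subjects),
enormous feature spaces — aimed at researchers analyzing source-level
coupling who need statistically calibrated group discrimination, feature
attribution, and an unbiased accuracy estimate.

## The method

1. **Coupling profiles.** Morlet wavelets (bandwidth 0.5 octaves = 1
   spectral SD, quarter-octave grid) give complex coefficients; two
   volume-conduction-insensitive metrics are computed per source pair:
   orthogonalized amplitude-envelope correlation (amplitude coupling) and
   the weighted phase-lag index
   `wPLI = |⟨Im S⟩| / ⟨|Im S|⟩`, `S = X·conj(Y)` (phase coupling).
   Each symmetric matrix's upper triangle, z-scored within subject, is a
   *coupling profile*.
2. **Coupling components.** PCA bases fit per (mode, frequency) on an
   independent reference cohort (n = 95); study profiles are projected
   onto the top 30 components → 690 features per mode, 1380 total
   (>3000-fold reduction).
3. **Feature bagging.** Random 10-feature bags are classified
   (least-squares SVM, leave-one-out CV); a feature's *classification
   score* is its probability of appearing in the top quartile of bags by
   accuracy.
4. **Permutation selection.** Group labels are permuted (n = 1000 at
   study scale), the full bagging stage reruns per permutation, and all
   permuted scores pool into one null distribution; per-feature p-values
   are BH-FDR corrected and a global count test assesses overall
   classifiability.
5. **Confidence & accuracy.** Per-subject confidence
   `D_Mah,con − D_Mah,pat` (squared Mahalanobis distances, leave-self-out
   moments) correlates with clinical severity; a second-level
   leave-one-out loop refits the whole selection per held-out subject and
   Gaussian fits to the signed boundary distances give sensitivity,
   specificity and accuracy = `(n_pat·sens + n_con·spec)/n_all`.

A synthetic-cohort generator (`neurobag.synthcohort`) stands in for the
study's recordings: band-limited oscillators with copula-controlled
envelope correlations, lagged phase coupling, zero-lag mixing as a
volume-conduction surrogate, and profile-level cohorts with planted
low-rank group effects in reference-SD units. See `docs/methods.md` for
models, assumptions and limitations.

## Worked example

Run the complete pipeline on a small synthetic cohort (8 patients + 8
controls, 40 reference subjects, one planted amplitude component at
effect size 2.5):

```python
from neurobag.bagsel import BagConfig
from neurobag.pipeline import PipelineConfig, run_pipeline
from neurobag.synthcohort import PlantedEffect, SimulationConfig

f0 = 2.0 ** 1.5  # delta carrier; grid is f0 * 2**k
config = PipelineConfig(
    simulation=SimulationConfig(
        n_sources=10, n_patients=8, n_controls=8, n_reference=40,
        planted_effects=(PlantedEffect("amplitude", f0 * 4, 2.5, rank=0),),
    ),
    bag=BagConfig(n_draw=2000),
    n_components=10, n_perm=100,
    out_dir="example_run", seed=42,
)
run_pipeline(config)
```

which writes, among other tables, `example_run/selection.json`

```json
{"n_significant": 1, "global_p": 0.0495, "threshold_value": 0.6875,
 "selected_fraction": 0.266}
```

— one coupling component survives FDR against the pooled permutation
null (the planted one), and no label permutation produced as many
significant components (p = 1/(100+1) ≈ 0.0495, the permutation floor) —
and `example_run/accuracy.json`

```json
{"sensitivity": 0.688, "specificity": 0.742, "accuracy": 0.715}
```

— the nested leave-one-out estimate: a new subject from this cohort
would be classified correctly ~72% of the time (chance 50%).
`example_run/severity_correlation.tsv` shows the planted
severity relation recovered from classification confidence
(EDSS-like score: r = 0.89, q = 0.006 at n = 8).

The same stages are exposed as shell subcommands
(`neurobag all --config cfg.yaml --seed 42 --out run/`, plus `simulate`,
`couple`, `univariate`, `reduce`, `select`, `confidence`, `accuracy`).

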