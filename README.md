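# neurosync

Intersubject neural synchrony and emotion-rating analysis for fNIRS cohorts.

`neurosync` implements the statistical toolchain of a naturalistic-viewing
study design in which two groups of participants watch emotionally charged
videos while prefrontal activity is recorded with functional near-infrared
spectroscopy (fNIRS), and rate their discrete emotions on 0–100 scales.  The
package covers:

- **Synthetic data generation** — a shared-response model for multi-subject
  time courses with controllable intersubject correlation, behavior-coupled
  synchrony structure (Anna Karenina or nearest-neighbor), forward simulation
  of raw two-wavelength optical intensities, and a two-part generative model
  for zero-inflated emotion ratings.
- **Preprocessing** — channel quality control (spectral quartile coefficient
  of dispersion and saturation-run rules), condition-wise trimming, band-pass
  filtering, PCA motion correction, the modified Beer–Lambert law, and
  z-scored total-hemoglobin extraction.
- **Intersubject correlation (ISC)** — pairwise and leave-one-out ISC, a
  two-sample (within-group vs. between-group) statistic with subject-wise
  permutation inference, and a one-sample circular-shift test.
- **Intersubject representational similarity analysis (IS-RSA)** — Anna
  Karenina ("high scorers are alike, low scorers differ idiosyncratically")
  and nearest-neighbor ("similar scores, similar brains") similarity
  structures, Spearman second-order correlation, subject-wise permutation and
  Mantel tests, and paired model comparison across channels.
- **Emotion models** — logarithmic rating transforms, a two-part
  zero-inflated Gaussian mixed model (logistic mixed submodel for extreme
  responding + Gaussian mixed submodel for graded responses), a plain linear
  mixed model for fear, latent-scale intraclass correlations, and
  marginal/conditional R² by variance partitioning.
- **I/O and CLI** — plain-text cohort and raw-intensity formats, YAML run
  configurations, a deterministic end-to-end pipeline driver, and a
  `neurosync` command-line interface.

## Worked example

```python
import numpy as np
import neurosync as ns
from neurosync.synth import RatingsGenSpec

# 1. simulate a cohort whose synchrony follows the AnnaK structure
rng = np.random.default_rng(0)
scores = rng.uniform(0, 100, 30)
base = ns.SharedResponseSpec(
    n_subjects=30, n_timepoints=300, shared_weights=0.2,
    noise_sd=1.0, n_channels=5, seed=0,
)
cohort, scores = ns.simulate_coupled_cohort(
    ns.BehaviorCouplingSpec(
        scores=scores, structure="annak", coupling_strength=1.0, base=base
    )
)

# 2. which similarity structure fits the neural data better?
fit_annak = ns.isrsa_per_channel(cohort, scores, model="annak")
fit_nn = ns.isrsa_per_channel(cohort, scores, model="nn")
comparison = ns.compare_similarity_models(
    fit_annak["r"].to_numpy(), fit_nn["r"].to_numpy()
)
print(f"mean IS-RSA r  AnnaK: {fit_annak['r'].mean():.3f}   NN: {fit_nn['r'].mean():.3f}")
print(f"paired t = {comparison.t_statistic:.2f}, p = {comparison.p_value:.2e}")

# 3. permutation test of one channel's brain-behavior association
behav = ns.annak_similarity_matrix(scores)
neural = ns.pairwise_isc(cohort, channel=0)
res = ns.swp_isrsa_test(neural, behav, n_perm=5000, seed=0)
print(f"channel 0: rho = {res.statistic:.3f}, p = {res.p_value:.4f}")

# 4. two-part zero-inflated model of simulated anger ratings
ratings = ns.simulate_ratings(RatingsGenSpec(seed=0))
fit = ns.fit_two_part_zig(ratings, emotion="anger")
i = fit.logistic.terms.index("time_x_group")
print(f"logistic time x group OR = {fit.logistic.odds_ratio[i]:.3f} "
      f"[{fit.logistic.or_ci_low[i]:.3f}, {fit.logistic.or_ci_high[i]:.3f}]")
print(f"logistic ICC = {fit.logistic.icc:.3f}   "
      f"Gaussian ICC = {fit.gaussian.icc:.3f}")
print(f"R2 marginal = {fit.r2_marginal:.3f}   conditional = {fit.r2_conditional:.3f}")
```

Output:

```
mean IS-RSA r  AnnaK: 0.895   NN: 0.398
paired t = 32.47, p = 5.36e-06
channel 0: rho = 0.902, p = 0.0002
logistic time x group OR = 0.141 [0.071, 0.279]
logistic ICC = 0.460   Gaussian ICC = 0.449
R2 marginal = 0.030   conditional = 0.466
```

The cohort was generated with Anna Karenina coupling, and the AnnaK metric
correctly fits it far better than the nearest-neighbor metric.  The odds
ratio below 1 on the time × group interaction means the trained group became
much more likely to respond at the rating extreme after training — the
pattern the two-part model is designed to capture.

## Command line

```bash
neurosync simulate --n-subjects 16 --structure annak --seed 0 --out cohort/
neurosync isrsa --cohort cohort/manifest.json --ratings cohort/scores.csv \
    --model annak --n-perm 5000 --out isrsa.csv
neurosync run --seed 0 --out results/      # full deterministic pipeline
```

All outputs are plain text (TSV/CSV/JSON/YAML) and carry the seeds that
produced them; rerunning with the same configuration yields byte-identical
files.

## Documentation

See [docs/methods.md](docs/methods.md) for the statistical models, generator
parameterizations, numerical choices, and known limitations.
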