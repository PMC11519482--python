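# emospec

Self-learning synthetic-emotion spectra from reinforcement-learning
experience.

An RL agent continuously observes two "crucial values": the instantaneous
**reward** r_t and the critic's **state-value** v_t (its expectation of
future reward). The hypothesis this package operationalizes is that
emotions correspond to distinct temporal patterns in such values, judged
against the agent's own *homeostatic* references (the historical mean and
sd of each value). `emospec` learns those patterns unsupervised and names
them:

1. **trajectory** — record per-step (r_t, v_t) series, slice them into
   W-step windows (default W = 20), and z-score them against homeostatic
   norms fitted on the training experience only.
2. **encoder** — a 1D-convolutional autoencoder (two strided conv layers,
   32 and 16 filters, kernel 5, stride 2, 'same' padding, relu; dense
   projection to a d = 5 latent) compresses each normalized window into a
   latent emotional state Ψ_t ∈ R^d. The encoder half has exactly 3,333
   trainable parameters. Implemented directly on numpy (analytic
   gradients, Adam, early stopping), so training is fully deterministic
   per seed.
3. **spectrum** — a full-covariance Gaussian mixture over the latents is
   the *emotional spectrum*: components are learned emotions, posterior
   responsibilities give step-wise emotion probabilities, and candidate
   component counts are compared by BIC. Attributions are stabilized by a
   trailing 5-step moving average with hysteresis (switch on smoothed
   p ≥ 0.9, or after 10 consecutive raw-argmax steps).
4. **love** — LOVE ("Latest Observed Values Encoding") mappings: a grid
   of idealized W-step templates in σ units (levels 0/±1σ and linear
   ramps), each combination carrying an emotion term — e.g.
   (average reward, increased expectation) → *excitement*;
   (average, decreased-to-average) → *anger*; (average,
   decreased-to-negative) → *fear*. The 2:5×6 mapping has 30 profiles.
   Cluster prototypes (per-step means of member windows) are matched to
   the nearest template to name each learned emotion, and term chains are
   checked by a sequence-coherence test.
5. **padval** — validation statistics for human attribution studies on
   the pleasure–arousal–dominance (PAD) model: ICC(2,k) reliability,
   Hotelling T² pairwise distinguishability, three mapping methods
   against literature PAD norms, and the cross-source "semantic collage".
6. **synth** — planted-profile corpora, scripted landing episodes, and
   random-effects survey fixtures, so the whole stack is testable with
   known ground truth and no RL training.

## Worked example

Run the full offline-learning pipeline on the default synthetic corpus
(2,000 windows, 8 planted emotion classes, noise sd 0.5σ):

```sh
$ emospec run --out run/ --seed 7
encoder parameters: 3333
selected K: 8
BIC: K=2: 37619.4, K=3: 36294.6, K=4: 35089.6, K=5: 34660.1, K=6: 34637.2, K=7: 34591.1, K=8: 34476.7, K=9: 34607.3, K=10: 34733.3
raw-scale RMSE: reward: 2.507, state_value: 9.521
clusters:
  0: optimism (13.2%)
  1: distress (13.2%)
  2: satisfaction (12.4%)
  3: fear (12.4%)
  4: high optimism (12.4%)
  5: concern (12.6%)
  6: excitement (10.8%)
  7: neutral (13.0%)
```

Reading the output: the encoder was built with its canonical
configuration (3,333 trainable parameters in the encoder half); BIC is
minimized at K = 8 components, matching the eight planted classes; the
raw-scale reconstruction RMSE is in reward/state-value units (the
synthetic corpus anchors rewards at mean 0.67, sd 5.60 and state-values
at mean 62.41, sd 18.99); and each cluster's prototype sequence was
matched to its nearest LOVE 2:5×6 reference profile — all eight planted
emotions are recovered, including the intensity variant *high optimism*
(average reward with expectations well above +σ). The run directory
contains every intermediate artifact (dataset archive, model weights,
spectrum, per-episode attribution CSVs, report.json).

The same stages are available as library functions
(`emospec.run_pipeline`, `emospec.train`, `emospec.fit_spectrum`,
`emospec.build_mapping`, ...) and as individual subcommands
(`emospec windowize | train-encoder | fit-spectrum | map-emotions |
interpret | validate-coherence | survey-stats | pad-map | synth`).

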