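# Methods

## Model overview

`emospec` treats an emotion as a temporal pattern in the values an agent
cares about. For an Order III agent (one that can anticipate future
rewards) those values are the instantaneous reward r_t and the critic's
state-value v_t. The pipeline is offline: a corpus of recorded episodes
(or a synthetic stand-in) is windowed, normalized, encoded, clustered and
interpreted; no interaction with an environment is required, and the
emotion-augmented policy extension is out of scope beyond the latent
vector Ψ_t that a policy could consume.

Assumptions worth stating explicitly:

* **Homeostasis.** "Positive", "average" and "negative" are relative to
  the agent's own history: per-variable mean μ_v and sd σ_v fitted on the
  *train partition only* (population sd, divide-by-N). Every judgement
  downstream — encoder input, LOVE band thresholds — is in these σ units.
* **Stationarity within a corpus.** One set of norms describes the whole
  training experience; drifting baselines (habituation, extinction) are
  not modelled.
* **Pattern sufficiency at W = 20.** A 20-step window is assumed long
  enough to expose the trends that distinguish, say, fear (a fall toward
  well-below-average expectations) from anger (a fall back to average).

## Windowing and splitting

Windows are all stride-1 slices of length W; an episode of length L
yields L−W+1 of them, the first ending at step W−1 (steps before that
carry no attribution). The default split unit is the *episode*, because
overlapping windows from one episode are nearly identical and would leak
across a window-level split; window-level splitting is available for
corpora of independent windows (the synthetic generator produces such
corpora, and the pipeline then splits at the window level). Missing
values are rejected, never imputed.

## The emotional encoder

Architecture (defaults): input W×V = 20×2 → Conv1D(32, k=5, s=2, same,
relu) → Conv1D(16, k=5, s=2, same, relu) → flatten (5·16 = 80) → Dense(5,
linear). Temporal lengths under 'same' padding follow ceil(L/s):
20→10→5. Parameter count is pure architecture arithmetic — conv:
k·C_in·F + F, dense: in·out + out — giving 352 + 2,576 + 405 = 3,333 for
the encoder half. The decoder is the transposed mirror (Dense 5→80 relu,
reshape, ConvT(32) relu, ConvT(V) linear, 3,394 parameters), chosen so
the reconstruction is shape-exact and "both parts" has a well-defined
count. The latent layer is linear, as is conventional for a dense
bottleneck feeding a Gaussian mixture; relu applies to the conv stacks.

Training minimizes mean squared error on normalized windows: batch size
10, validation split 0.1, Adam at 1e-3, early stopping with patience 5 on
validation loss (best weights restored), max 200 epochs. The
implementation is plain numpy with analytic gradients (verified against
central differences to ~1e-10 in the tests); one integer seed drives
weight init, shuffling and the validation split, so runs are bit-for-bit
reproducible. The model is a trend/magnitude compressor, not a denoiser:
per-variable RMSE is reported on the raw scale by default (normalized
RMSE × σ_v), where it is commensurate with reward/state-value units.

## The emotional spectrum

A full-covariance Gaussian mixture is fitted on the latents for each
candidate K (sklearn, reg_covar = 1e-6 diagonal jitter against
singularity, 3 initializations per seed). BIC
(−2·logL + params·ln n, params = K−1 + K·d + K·d(d+1)/2) selects K by
default; a `force_k` override exists because the component count is
ultimately an interpretive choice and can be seed-sensitive on real data.
Cluster prototypes are per-step mean ± sd of the raw member windows under
hard (max-responsibility) assignment — member averages, not decoded
centroids, so the sd shading reflects actual data spread.

Attribution smoothing is causal: a trailing 5-step moving average of the
posterior series (renormalized), with hysteresis — the displayed label
switches to cluster k only when smoothed p_k ≥ 0.9, or when k has been
the raw argmax for 10 consecutive steps ("either" by default; each rule
individually selectable). A one-step glitch therefore never flips the
label, at the cost of some latency. The ambiguous alternative of
smoothing the *observed values* before encoding is exposed as the
documented probability-series choice; values-mode smoothing can be
composed manually by pre-filtering windows.

## LOVE mappings

A mapping like 2:5×6 is the full grid of per-variable pattern
combinations: reward ∈ {positive, average, negative, increased,
decreased}, expectation ∈ {positive, average, negative, increased,
decreased_to_average, decreased_to_negative} — 30 profiles. Templates are
idealizations in σ units: levels are constants at 0/±1σ, trends are
linear ramps (increased 0→+1, decreased +1→0, decreased_to_negative
0→−1). Band thresholds (BandConfig): τ = 0.5σ separates average from
positive/negative, 1.5σ marks high intensity, δ = 0.5σ is the minimum
net change that counts as a trend. These defaults encode "around ±σ" /
"well beyond ±σ" qualitative bands and are fully configurable.

Trend detection estimates the net change across the window as twice the
difference between late- and early-half means (for a linear ramp this
equals the total rise; a regression-slope estimator is available as
`trend_estimator="slope"`). Comparing the *net change* rather than the
raw half-mean difference against δ keeps template classification robust:
every template classifies back to its generating labels with a wide
margin, and sd-0.1 noise flips fewer than 5% of draws. Falling
expectations are split by where they land: within ±τ → decreased
_to_average (anger-like), at or below −τ → decreased_to_negative
(fear-like).

The lexicon ships with the twelve canonical terms (happiness, distress,
concern, optimism, excitement, frustration, anger, fear, neutral,
satisfaction, high optimism, neutral/slight concern). Two are
intensity-qualified variants rather than grid cells: *high optimism* is
(average, positive) with expectation mean ≥ 1.5σ, and *neutral/slight
concern* is (average, average) with the expectation mean leaning below
−τ/2 — a deterministic rule for a nuance that is otherwise a judgement
call. The remaining 18 combinations of 2:5×6 are deliberately unnamed
and user-assignable.

Profile matching uses the per-variable mean squared deviation between a
(σ-unit) prototype sequence and each template, summed over variables;
ties prefer stable (level-only) profiles, then lexicographic ids. The
sequence-coherence test checks narrative scripts over profiles: start
stable, no beyond-scope transitions (a rise from an already-positive
level, or a fall from an already-negative one), abrupt positive↔negative
jumps flagged as warnings, stable or revisited endings, and full profile
coverage across a suite.

## PAD validation statistics

* **ICC(2,k)**: two-way random effects, absolute agreement, average of k
  raters; from the ANOVA decomposition,
  ICC = (MSR − MSE) / (MSR + (MSC − MSE)/n). Missing cells are an error;
  split-list survey designs are analyzed per complete sub-matrix and
  combined by cell-count weights. Cross-checked against pingouin in the
  tests.
* **Hotelling T²** (two-sample): T² = (n₁n₂/(n₁+n₂)) d'S_p⁻¹d with the
  exact F reference, F = T²(n₁+n₂−p−1)/((n₁+n₂−2)p) on (p, n₁+n₂−p−1)
  df. At p = 1 it equals the squared pooled t; the type-I rate at
  α = 0.05 is verified by simulation.
* **Literature mapping** (norm tables report means/sds but no
  covariances): Method 1 pools the sample covariance with diag(sd²)
  using (n₁−1, n₂−1) weights; Method 2 lends the sample covariance to
  the reference (the pooled matrix is then the sample covariance
  itself); Method 3 is the Euclidean distance between mean triples.
  Survey ratings on [1, 9] map to the literature's [−1, 1] by the affine
  bijection x ↦ (x−5)/4 — the simplest map carrying endpoints to
  endpoints and the midpoint to 0.
* **Top matches / collage**: per-source rankings (ascending distance or
  descending p) after an editable exclusion list (social, moral,
  self-conscious, bodily-need and non-emotion terms are data, not code);
  the collage merges sources and keeps the k best with ties broken by
  term then source, so it is independent of source order.

## Synthetic data

The generator plants LOVE templates: a window is template + iid N(0,
noise_sd²) in σ units, de-standardized with raw-scale anchors (reward
μ = 0.67, σ = 5.60; state-value μ = 62.41, σ = 18.99 — the magnitudes of
recorded lunar-landing rollouts). The default 8 classes are the learned
emotions of the landing case study: distress, optimism, neutral,
satisfaction, high optimism (its template holds the expectation at +2σ),
concern, excitement, fear; default noise sd 0.5, equal mixture weights.
Scripted toy episodes provide recognizable narratives: success (upward
expectation drift, +100-scale terminal reward) and failure (a one-window
expectation collapse from average to −1σ — the fear signature — then a
−100-scale terminal reward). Survey fixtures follow a two-way
random-effects model y_ij = μ + target_i + rater_j + ε_ij per dimension,
with the implied population ICC(2,k) = σ_t²/(σ_t² + (σ_r²+σ_e²)/k)
available analytically for parameter-recovery checks.

What the generator does *not* emulate: temporal dependence between
overlapping windows of a real episode, sparse heavy-tailed terminal
rewards inside training windows, class imbalance, and any
policy-dependent structure in the latents. Passing the recovery tests
therefore shows the machinery is correct and well-conditioned, not that
a particular RL agent's spectrum will contain eight clusters.

## Problem sizes and numerical choices

The test and validation runs use corpora of 300–2,000 windows, mixtures
over K ∈ {2..10}, and 5–20 seed replicates — sizes at which every result
in the suite reproduces on a single CPU in minutes. Degenerate inputs
are errors, not silent fixes: zero-variance variables, unnormalized
encoder input, singular covariances (after the 1e-6 jitter), missing
survey cells. Determinism: all randomness flows from integer seeds via
numpy Generators; the pipeline fans one global seed out to per-stage
seeds through a SeedSequence.

## Known limitations

* Only Order III (reward + state-value) mappings with 5/6 patterns are
  built in; world-model, social and higher-order emotions, habituation
  and extinction dynamics are out of scope.
* The 2:5×6 lexicon beyond the twelve canonical terms is intentionally
  left open.
* K selection by BIC is only a default; on weakly separated real latents
  the choice can be seed-dependent and deserves inspection.
* The encoder is a small fixed architecture; no architecture search is
  provided beyond the config fields.
* "Frustration" uses the +1→0 reward ramp template; a drop after a
  sustained plateau would also be a defensible idealization.
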