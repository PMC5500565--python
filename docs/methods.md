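# Methods note

This note documents the model implemented by `rpemap`, its parameters and
defaults, the scope of the synthetic-data generators, and the numerical
choices that matter for reproducing its outputs.  It makes no empirical
claims beyond what the test suite computes.

## 1. Task model

A probabilistic reversal-learning task over three symbols {A, B, C}.

- Each trial offers a pair of symbols drawn from the fixed cycle
  AB → BC → CA (configurable via `pair_cycle`).
- One symbol is designated "high": choosing it is rewarded with
  probability `p_high` = 0.7; any other symbol is rewarded with
  probability `p_low` = 0.3.
- Learning criterion: `criterion_hits` = 5 correct choices within the
  last `criterion_window` = 6 *criterion-eligible* trials since the last
  reversal.  Only trials that actually offer the high symbol are
  criterion-eligible — on the one pair per cycle that omits it, "choose
  the high symbol" is undefined, and counting those trials would make the
  5-of-6 criterion unattainable under this pair cycle.
- After the criterion is met, buffer trials follow.  The buffer length is
  drawn once, from a geometric distribution with per-trial hazard
  `buffer_hazard` = 0.3 truncated to [`buffer_min` = 1, `buffer_max` = 8]
  (all residual mass of the truncation is placed on `buffer_max`).  The
  reversal then reassigns the high symbol uniformly among the other two
  symbols.
- Defaults: `n_blocks` = 2, `trials_per_block` = 170.  Trial timing:
  stimulus duration 1.25 s, outcome duration 0.65 s, uniform
  stimulus-to-outcome delay drawn from `delay_range` = (1, 4) s.

Consequences used as acceptance targets: the long-run reward rate is 70%
on trials where the high symbol is chosen, 30% when it is avoided, and
the empirical buffer hazard away from the truncation boundaries is 0.3.

## 2. Reinforcement-learning models

All models start from value 0.5 and observe binary outcomes r ∈ {0, 1}.

**Model-free (`mf`), 3 free parameters (α, β, φ).**
δ(i) = r(i) − v(i);  v(i+1) = v(i) + α δ(i) for the chosen symbol.

**Dynamic learning rate (`dyn`), 4 free parameters (α₀, β, φ, γ).**
The learning rate adapts to the smoothed change in surprise.  With
s(i) an exponentially smoothed |δ| (smoothing constant 0.1, fixed) and
m(i) = s(i) − s(i−1):

- if m > 0: α(i+1) = α(i) + f(m) (1 − α(i))
- if m ≤ 0: α(i+1) = α(i) − f(m) α(i)

where f(m) = |m| / (|m| + e^γ).  Both branches move α toward its bound by
a fraction f(m), keeping it in (0, 1).

**Stimulus–outcome (`mb`), 3 free parameters (α, β, φ).**
A table SO(symbol, outcome) of outcome expectancies is updated for the
chosen symbol, SO ← SO + α (1 − SO) for the observed outcome column (the
other column decays correspondingly); the decision value is SO(s, 1).

**Choice rule.**  Softmax over the offered pair:
P(left) = 1 / (1 + exp(−(β (v_left − v_right) − φ))), with inverse
temperature β and side-bias φ.

**Fitting.**  Maximum likelihood via Nelder–Mead in a transformed space
(logit for α, log for β, free for φ and γ), default 10 random restarts,
choice probabilities floored at 1e−12.  The log likelihood is
class-normalized: trials are grouped by chosen symbol and each class
contributes its mean log probability, so a symbol chosen rarely is not
swamped by the frequent ones.  Model comparison uses
BIC = −2 logL + d log(n) with d = 3, 4, 3 for `mf`, `dyn`, `mb`.
Surprise values |δ| are binned into five levels
(0–0.2, 0.2–0.4, 0.4–0.6, 0.6–0.8, 0.8–1.0; labels `very_low` …
`very_high`).

## 3. Single-trial EEG discrimination

Epochs (trials × channels × samples, default 250 Hz, −200…700 ms) are
averaged within sliding windows of width 60 ms centred at −100…600 ms in
10 ms steps.  For each window:

- Class covariances are shrunk:  S̃ = (1 − λ) S + λ ν I with
  ν = trace(S)/D, which preserves the trace for every λ.
- Discriminant weights: w = S̃_c⁻¹ (m₂ − m₁), with S̃_c the average of
  the two regularized class covariances (solved, not explicitly
  inverted).  A literal inverse-free variant w = S̃_c (m₂ − m₁) is
  available behind `invert=False` for comparison.
- Discrimination is scored by leave-one-out cross-validated Az (area
  under the ROC curve) with a full retrain per fold; the peak window is
  the earliest centre attaining the maximum.
- λ is either fixed or selected from the grid
  (0, 0.001, 0.01, 0.028, 0.05, 0.1, 0.3, 1) by mean post-outcome Az,
  ties resolved toward the smaller value.
- Significance: label permutations yield a null Az distribution; the
  threshold is its (1 − p) quantile (default p = 0.01).
- Forward model: a = X y / (yᵀ y) maps discriminant amplitudes y back to
  a scalp coupling pattern for window-averaged data X.
- Held-out trials are projected through the peak-window weights and
  summarized per surprise bin; empty bins are NaN.

## 4. EEG-informed fMRI GLM

- HRF: difference of two gamma densities (shapes 6 and 16, the
  undershoot weighted 1/6), truncated at 32 s and normalized to unit
  peak; the positive lobe peaks near 5 s.
- Regressors: 100 ms boxcars at event onsets, amplitude-scaled, laid on a
  0.1 s grid, convolved with the HRF and read out at volume times
  (TR = 2.5 s default).  Parametric amplitudes are mean-centred before
  convolution so they are orthogonal to the unmodulated event regressor
  by construction.
- Design (outcome phase): UM (unmodulated outcome events), EEG_LateVal,
  MODEL_Sur, EEG_LateSur, EEG_EarlyVal (parametric), LOST (dropped with a
  warning when no trials qualify), DEC (stimulus-locked events), plus
  motion nuisance columns and an implicit intercept.
- Estimation: voxelwise OLS; t statistics are converted to Z through
  matched tail probabilities.  Rank-deficient designs raise an error
  naming the collinear columns.
- Group level: a one-sample t-test across subject betas per voxel,
  converted to Z.  This is a deliberate simplification of a full
  mixed-effects model: within-subject variance is ignored.
- Cluster inference: connected components of |Z| > 2.57 (26-connectivity
  default), positive and negative separately.  The minimum cluster size
  comes from resampling: parametric amplitude vectors are permuted across
  trials, the design rebuilt and refit, and the largest null cluster
  recorded per iteration; the threshold is the smallest size exceeding
  the (1 − p) quantile of those maxima (default p = 0.05, 100
  iterations).
- Conjunction: voxelwise intersection of independently thresholded maps.
- Percent signal change:  PSC_i(t) = 100 (X_i(t) − X_i^b) / X̄, with the
  baseline X_i^b the mean of the 2 volumes before the outcome volume and
  X̄ the run mean; the scalar summary is the mean over volumes +2…+4
  after the outcome.  Value updating is regressed on the PSC summary per
  subject; the group test is a one-tailed one-sample t on the slopes.
- The six-bin ROI profile splits trials by RPE sign and, within sign, by
  surprise terciles, fits one unmodulated regressor per bin and reports
  the mean beta per ROI; empty bins are NaN.

## 5. Synthetic-data generators (scope)

The generators produce data with *known* planted structure for
validation; they are not forward models of physiology.

- **Behaviour**: the softmax RL agent re-derives its values from the
  trial history the simulator exposes, so generated sessions are exactly
  consistent with the `mf` likelihood at the generating parameters.
- **EEG**: two components with unit-norm, near-orthogonal scalp patterns
  (|correlation| < 0.3) and Gaussian temporal envelopes (FWHM 60 ms):
  a categorical valence component at 308 ms with amplitude
  sign(δ)(1 + 0.25 jitter) — deliberately uninformative about |δ| — and a
  parametric surprise component at 320 ms with amplitude
  |δ| − mean|δ|.  Noise is unit-variance Gaussian with first-order
  neighbour channel correlation.
- **BOLD**: a constant baseline (100) plus white noise; four disjoint
  cubic ROIs load on the HRF-convolved valence amplitude, the surprise
  amplitude, their sum, or nothing.  Defaults: 32 × 32 × 12 grid,
  TR 2.5 s, 463 volumes.
- Response times: base 0.65 s minus 0.12 × previous-trial δ, clipped to
  [0.2, 1.25] s.

## 6. Numerical choices and limitations

- Choice probabilities are computed with a numerically stable logistic
  and floored at 1e−12 before taking logs.
- The buffer length is a truncated geometric draw, matching a constant
  per-trial hazard; the acceptance estimate of the hazard excludes the
  truncation boundaries, where the conditional stop probability is
  distorted by construction.
- Fisher weights use `solve` on the shrunk covariance; with λ = 0 and
  fewer trials than channels the matrix is singular and an error advises
  λ > 0.
- t → Z conversion saturates at |Z| = 40 to avoid infinities at extreme
  significance.
- Optimization is derivative-free (Nelder–Mead) and restarts from random
  draws; results are deterministic given the seed but only locally
  optimal in principle.
- The group model ignores first-level variance (summary-statistics
  shortcut); the cluster-resampling null permutes amplitudes only, so it
  calibrates parametric regressors, not the unmodulated event response.
- All estimators assume complete, artifact-free epochs/volumes; no
  artifact rejection, slice-timing or motion correction is implemented —
  motion enters only as nuisance columns supplied by the caller.
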