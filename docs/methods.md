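# Methods

## Data model and pre-processing

The raw input is an epoch-level activity-count series (1-min epochs in
the standard chain), optionally with a parallel 5-min skin-temperature
channel. Pre-processing follows standard actigraphy practice:

1. **Off-wrist marking.** When the device is removed, skin temperature
   drops towards room temperature. Maximal runs of at least
   `min_block_epochs` (default 2) consecutive temperature samples below
   `temp_drop_threshold` (default 30 °C; worn devices read ≈32–35 °C)
   flag all covered activity epochs as missing. The thresholds are
   configurable because devices and environments differ; the defaults
   are conservative.
2. **Aggregation** to the analysis epoch (default 300 s). A window's
   value is the mean of its non-missing minutes; the window is missing
   when more than `max_missing_fraction` (default 0.5) of its minutes
   are missing. The 50% rule balances bias (means over few minutes) and
   data loss; no published convention exists for partial windows.
3. **Square-root transform.** On the sqrt scale the state-conditional
   densities are modelled as Gaussian, which corresponds to a mixture of
   (scaled) non-central χ² distributions on the count scale — a family
   that respects non-negativity and positive skewness of averaged
   counts.

Timestamps are interpreted in local clock time with no daylight-saving
adjustment: circadian phase is socially entrained, and the covariate
clock `h` (hours since local midnight) should follow the wall clock.
All epochs are half-open `[start, start + epoch)`. Missing values are
never imputed; the likelihood marginalises them.

## Homogeneous Gaussian HMM

Scaled forward/backward recursions (per-step renormalisation) evaluate
the likelihood and the smoothing distribution; a missing epoch
contributes an identity emission matrix, i.e. the transition matrix is
propagated across the gap. The recursions are numba-compiled; the
scaled form was preferred over log-sum-exp for speed and the two agree
with a brute-force path-enumeration oracle to 1e-10 in the tests.

Fitting is Baum–Welch EM:

- **Initialisation.** State means at the (2j−1)/(2m) empirical
  quantiles of the observed values, common sd, 0.9-diagonal transition
  matrix, uniform δ. Additional starts (default 10) jitter the means
  with seeded Gaussian noise (scale 0.25·sd). The likelihood is
  multimodal, hence multiple starts.
- **Convergence.** Relative log-likelihood change < 1e-8 or 500
  iterations. The per-iteration log-likelihood trace is exposed
  (`loglik_trace_`) and is non-decreasing (EM ascent).
- **Degeneracy.** Emission sds are floored at 1e-4 (sqrt scale); a
  start whose sd collapses below the floor is discarded with a warning
  rather than crashing the fit. δ is estimated freely; degenerate
  (one-hot) estimates are expected and legitimate — the chain simply
  starts in the state the first observations favour.
- **Labelling.** States are relabelled by ascending emission mean, so
  state 0 is IA; relabelling leaves the likelihood invariant.

`n_params` counts (m−1) free entries of δ, 2m emission parameters and
m(m−1) transition parameters; `count_delta_in_params=False` excludes δ
from AIC/BIC penalties for sensitivity analysis. BIC uses the number of
non-missing epochs as sample size.

**Pseudo-residuals** are one-step-ahead forecast residuals
`z_t = Φ⁻¹(F_t(y_t))`, with `F_t` the Gaussian-mixture forecast CDF
weighted by the forward-predicted state probabilities. Under a correct
model they are exactly i.i.d. standard normal (conditional probability
integral transform), which the calibration test exploits. The forecast
form (rather than the smoothed "ordinary" variant) was chosen because
it has this clean distributional guarantee.

## Harmonic HMM

The transition matrix at epoch t is the row-wise softmax of
`γ⁰ + γ¹·X_t` with the diagonal coefficients pinned to zero for
identification; overflow is prevented by per-row max subtraction. The
basis includes both cosine and sine of the 24-h fundamental (d = 2) so
the first harmonic carries a free phase — a cosine-only basis would pin
the acrophase to midnight/noon; sine can be disabled. No subharmonics
are included: the parameter count grows with d·m(m−1), and even the
first harmonic produces markedly non-sinusoidal transition curves
through the softmax. Treatment windows double the basis with
indicator-gated copies of the harmonic pair, acting on the same m(m−1)
off-diagonal cells.

There is no closed-form EM for the time-varying link, so the
missing-aware forward log-likelihood is maximised directly (L-BFGS-B
over means, log-sds, δ-logits and the γ arrays), warm-started from the
homogeneous EM solution with zero slopes; further starts jitter the
parameter vector. A small L2 penalty (1e-6, switchable) on the γ
coefficients keeps them finite when a transition type is absent from
the data (separation). With slopes frozen at zero the model is exactly
the homogeneous HMM — the nesting is used as a correctness check
(equal likelihoods to 1e-4).

Covariates are evaluated at epoch start times; `Γ(t)` governs the
transition *into* epoch t. Since covariates repeat daily, only the
(≤ 2·288) unique covariate rows have their matrices computed per
objective evaluation.

## Circadian parameters

The **periodic profile** propagates a state-probability row vector
through the periodic transition matrices, cycling over whole days until
consecutive cycles differ by < 1e-10 in sup-norm (geometric convergence
is guaranteed for strictly positive matrices, which the softmax link
yields). The grid is the analysis epoch (288 cells at 5 min); each cell
is represented by its midpoint in all integrals and circular means,
which makes the rectangular worked example exact on the 5-min grid.

- **Rest amount** `a`: rectangle-rule integral of the IA curve
  (error O(epoch), negligible at 5 min).
- **Centre of rest** `c`: circular centre of mass
  `arg Σ P(h)·e^{i2πh/24}`; undefined (NaN, with warning) when the
  resultant is negligible — rest without circadian localisation.
- **Rhythm index** `RI = (∫_{I_c} P − a²/24) / (a − a²/24)`, the
  unique affine normalisation of `∫_{I_c} P` that is 1 for the
  rectangular profile and 0 for the constant profile `P ≡ a/24`.
  `I_c = [c − a/2, c + a/2]` is treated circularly (it may wrap across
  midnight). Undefined for a = 0 or 24 h (degenerate denominator).
  When `c` is undefined the window is anchored at an arbitrary clock
  time; for the exactly-constant profile the integral is then
  location-independent and RI = 0 regardless.
- **Rest spans** for the dichotomy index come from locally decoded IA
  runs: runs separated by gaps < `merge_gap_hours` (default 1 h) are
  merged, merged runs shorter than `min_span_hours` (default 3 h) are
  dropped, and the longest span per noon-to-noon window is kept as that
  night's rest span. Span determination is inherently ambiguous
  (evening naps near the main rest period); all thresholds are
  configurable and the probabilistic RI is the more robust companion
  index.
- **Dichotomy index** uses strict inequality ("below the wake median"),
  excludes missing epochs on both sides, and is computed on the
  mean-counts scale (it is rank-based, so any monotone rescaling of
  activity leaves it unchanged). Epochs at exactly the wake median
  count as not-below.
- **Count-scale state means** use the non-central χ² identity
  `E[Y²] = μ² + σ²`; the HA value estimates the activity amplitude.

## Synthetic data generator

The generator draws the state path from δ and the (possibly
time-varying) transition law, observations from the state Gaussians on
the sqrt scale, and returns both the sqrt-scale and squared
(mean-counts) channels. Defaults emulate the stylised features of
multi-day recordings from healthy adults:

- emissions IA ≈ N(1.0, 0.7²), MA ≈ N(3.1, 1.1²), HA ≈ N(5.4, 0.75²)
  on the sqrt scale — values typical of chest-worn triaxial sensors;
- a squarish circadian waveform with rest roughly midnight–08:30
  (limit profile of the "strong" model: a ≈ 8.9 h, c ≈ 02:08,
  RI ≈ 0.83, inside the healthy range);
- HA→IA transitions essentially impossible (rest is entered via MA);
- one 20-min off-wrist block per day at a seeded uniform daytime
  position (07:00–22:00), giving a 1.4% missing fraction — within the
  1–3% band typical of real deployments;
- an optional treatment window whose gated harmonic raises daytime rest
  and interrupts nights (sedation during a chemotherapy course).

Three named variants serve different purposes: `strong` (realistic
healthy subject), `absent` (slopes zero — no rhythm; RI ≈ 0), and
`moderate`, whose occupancies and transition probabilities stay bounded
away from 0 and 1 at every circadian phase. Recovery studies use
`moderate`: under a near-degenerate generator parts of the transition
curves (e.g. daytime IA exits when IA is never occupied by day) are
unidentified, so their estimates cannot be expected to concentrate —
a recovery experiment is only informative where the estimand is
identified.

What the generator does **not** emulate: zero-inflation and
integer-valued counts at short epochs, weekday/weekend structure,
naps with their own dynamics, device-specific filtering, gradual phase
drift (non-24-h periods). Passing tests therefore demonstrate
correctness of the estimators under the model class, not robustness to
these real-data departures.

## Parametric bootstrap

Replicate datasets are simulated from the fitted model with the
original series' length, epoch and missing pattern; each replicate is
refitted (warm-started from the original solution, one start — a
deliberate speed/robustness trade-off at desk scale) and the statistic
recomputed; percentile intervals are reported. Replicates whose refit
fails are dropped with a warning; more than 20% failures is an error.
The scaled-down coverage study in the tests (20 outer truths, B = 50,
two-day series) checks the 90% IA-mean interval attains coverage in
[0.75, 1.0] — percentile intervals with warm-started refits are
expected to be slightly anti-conservative at short series lengths.

## Problem sizes used in the test suite

Simulation-based checks run at sizes where their statistical
conclusions are stable yet the suite stays desk-scale: path-enumeration
oracles at T ≤ 8, m ≤ 3; homogeneous recovery at T = 10 000; harmonic
recovery at 14 days of 5-min epochs; the profile–frequency comparison
at 200 days; pseudo-residual calibration over 50 replicates of
T = 5 000; bootstrap coverage over 20×50 refits of two-day series.

The profile–frequency comparison makes 864 pointwise 3-standard-error
comparisons; ~0.3% of points are expected beyond 3 SE by chance under a
correct profile (expected maximum |z| ≈ 3.7 across that many
comparisons), so the check bounds the exceedance *fraction* at 1%
rather than requiring literally every point inside — a profile
mis-phased by a single 30-min step already exceeds the bound
several-fold, so discriminating power is retained.

## Known limitations

- Gaussian emissions on the sqrt scale break down for very short epochs
  (zero-inflated counts); a zero-inflated discrete emission family
  would be the natural extension.
- Local decoding is per-epoch; no most-probable-path (Viterbi) decoding
  is provided, matching the intended use (probabilistic thresholding,
  not path reconstruction).
- The harmonic optimiser uses finite-difference gradients; on weakly
  identified coefficients (transitions rarely observed) it may stop at
  the iteration cap with the likelihood converged but coefficients
  drifting in flat directions — the L2 penalty bounds this.
- Rest-span extraction is heuristic by nature; I<O values depend on the
  span thresholds, which is precisely the motivation for the
  profile-based RI.
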