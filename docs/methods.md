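# Methods

## The observer model

The stimulus stream is binary (0 = standard, 1 = deviant) and is treated as
a first-order Markov chain: the sufficient statistic is the 2×2 transition
matrix, reduced to the two free entries θ₀|₁ and θ₁|₀ because columns sum
to 1. The observer holds independent Beta beliefs over the two entries.
With transition counts n_{a|b} the posterior is
Beta(1+n₀|₁, 1+n₁|₁)·Beta(1+n₁|₀, 1+n₀|₀); the uniform Beta(1,1) prior
encodes the assumption that the observer starts a block expecting both
stimulus types to be equally likely. The first stimulus of a block induces
no transition, so its probability is fixed at ½ and the belief is unchanged
at trial 1.

**Leaky integration.** Limited memory is modelled by exponential
forgetting: at each trial all four counts are multiplied by e^{−1/w} before
the observed transition adds 1 (decay-then-increment). Unrolled, a
transition observed k trials ago carries weight e^{−k/w}; w is the e-folding
memory span in trials. The decay is applied uniformly to all four counts —
the alternative of decaying only the column matching the current context
would make the two Beta factors' effective sample sizes drift apart without
any principled target, and the uniform rule reproduces exact integer
tallies in the w → ∞ limit (verified against brute-force counting at
w = 10⁹). The sweep grid defaults to [1, 100].

**Prediction.** The predictive probability is the posterior mean of the
relevant Beta factor (Laplace rule), e.g. p(1|0) = (1+n₁|₀)/(2+n₁|₀+n₀|₀),
i.e. the posterior-predictive/marginal-likelihood point prediction rather
than the MAP; it is the Bayes-optimal point estimate under log loss and
keeps p(0|b) + p(1|b) = 1 exact.

## Surprise measures

All three are computed per trial from the belief trajectory, in nats by
default. Because every downstream decoding statistic is invariant under
affine transforms of the labels, the log base (nats vs bits) has no effect
on any R²; this invariance is asserted to 10⁻⁹ in the tests.

* **Shannon**: −log p(xₜ | xₜ₋₁, prior belief at t); trial 1 is ln 2.
* **Bayesian**: KL(posterior ‖ prior), summed over the two Beta factors
  (they are independent, so the joint KL factorizes into the sum); trial 1
  is 0. The orientation (posterior first) follows the belief-update reading;
  the reverse orientation is available behind a flag.
* **Confidence-corrected**: KL(current belief ‖ naive posterior), where the
  naive observer holds the uniform belief updated with only the most recent
  transition; trial 1 is 0. The naive observer's leading ½ factor for the
  first stimulus cancels in the factorized KL and is ignored. Orientation
  likewise configurable.

Beta–Beta KL uses the closed form in log-Beta and digamma functions and is
cross-checked against adaptive quadrature of the KL integrand to 10⁻⁶ over
a parameter grid spanning [0.5, 50]².

## Synthetic data

The generator emulates one oddball block as the study conditions: 405
i.i.d. Bernoulli(1/3) trials, 20 channels, 80 samples spanning
[−200, 600] ms. Each epoch receives
L_c · (β₀ + β₁·S(n)) · g(t) + noise, with S the z-scored true surprise
series (z-scoring makes β₁ comparable across measures, whose natural scales
differ by an order of magnitude), g an unnormalized Gaussian bump
(center 250 ms, width 50 ms — a generic middle-latency evoked component),
and L_c seeded standard-normal loadings scaled to unit RMS. Defaults:
β₀ = 0, β₁ = 0.5, noise sd 1 (signal-to-noise 0.5), Shannon at w = 16 as
ground truth.

Noise is Gaussian, optionally AR(1) along time (default ρ = 0.3, a mild
temporal correlation typical of low-pass-filtered sensor data), generated
independently per channel and trial; innovations are scaled by √(1−ρ²) so
the marginal sd equals `noise_sd` regardless of ρ. What the generator does
**not** emulate: forward head modelling and realistic cross-channel
covariance, 1/f spectra, artifacts, non-stationarity across a session.
Passing the recovery tests therefore demonstrates that the pipeline is
correct and sensitive under its own assumptions — a linear, time-localized,
spatially fixed encoding — not that real recordings encode surprise.

Subject-like replicates redraw the sequence, loadings and noise with
deterministic seed offsets; they model between-subject variability only as
independent sampling, with no systematic inter-individual differences.

## Decoder

Features are standardized inside each training fold; the L1 penalty is
selected by an inner fivefold CV over 15 log-spaced values down to
10⁻²·α_max (nested CV avoids the optimistic bias a single-level selection
would allow). Outer CV is fivefold with a seeded shuffle — trials are
treated as exchangeable, as the regression itself does. R² is computed per
outer test fold against that fold's label variance and averaged (the pooled
variant is behind a flag); held-out R² can be negative. Coordinate-descent
settings (tol 10⁻³, max 2000 iterations) keep a full 100-permutation chance
band tractable at the default problem size (405 × 1600) on one CPU.

Chance levels permute the label vector uniformly (identity permutation not
excluded) and rerun the entire nested fit; empirical p is
(1 + #{chance ≥ observed}) / (n_perm + 1). The permutation count defaults
to 100.

Because decoding power depends on w, `sweep_w` recomputes labels per w on a
grid and reports the maximum, ties broken toward smaller w (the smaller
memory span is the more parsimonious observer).

## Regimes and statistics

Feature regimes: entire epoch (C·T columns), single samples (C), intervals
(−200 ms through t), segments (half-open [start, end) time bands so each
sample belongs to exactly one segment; the late segment includes the final
sample), and per-channel spatial. Columns are channel-major; "nearest
sample" ties resolve to the earlier sample.

Segment boundaries are detected on the (replicate-averaged) samples curve:
t₁ is the earliest strictly post-stimulus time with power ≥ 10% of the
post-stimulus maximum (baseline power is noise and is excluded from the
maximum), t₂ the argmin over [250, 400] ms, earliest on ties. A
non-positive post-stimulus maximum is an error (no detectable response).

Decoding powers are compared to chance with paired t-tests across
replicates; the Bonferroni threshold defaults to 0.05/12, the joint
correction when three measures × four segments are examined. Segments are
compared with a one-way repeated-measures ANOVA (standard within-subject
decomposition, no sphericity correction) and three post-hoc paired t-tests
at 0.05/3 ≈ 0.0167. Degenerate inputs (zero between-condition variance)
report F = 0, p = 1 rather than NaN.

## Problem sizes and numerical choices

The end-to-end checks run the default 405 × 20 × 80 study with a
100-permutation chance band for the encoding and null datasets, a
10-replicate segment study with 10 permutations per segment chance estimate
(the chance mean enters a paired t-test across replicates, so a coarse
estimate suffices), and a w sweep over {1, 2, 4, 8, 16, 32, 64, 100} — a
coarse log grid over [1, 100], adequate because neighbouring w yield highly
correlated labels and only factor-level recovery is meaningful. The examples
use smaller blocks (150–200 trials, 6–8 channels) purely for interactivity.

## Known limitations

* The encoding model is rank-1 in space and unimodal in time; multi-
  component or moving sources are out of scope.
* FastICA component extraction is provided for sensor data but the synthetic
  generator produces data that does not need unmixing (an identity bypass is
  available and used in tests).
* The leak recursion assumes decay happens once per trial; sub-trial or
  volatility-adaptive forgetting is not modelled.
* Repeated-measures ANOVA is used without sphericity correction; with three
  levels the liberal bias is small but nonzero.
* Raw-recording preprocessing (filtering, artifact rejection, baseline
  correction, head-movement compensation) is upstream of this package; the
  optional MNE import hook converts already-epoched data only.
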