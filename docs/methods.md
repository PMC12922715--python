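# Methods

This note documents the models, estimators and numerical choices behind
the package, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the design was genuinely open.

## Error consistency

For two observers classifying the same items, correctness sequences are
reduced to the 2×2 joint table `(n11, n10, n01, n00)` (both correct /
only A / only B / both incorrect). Observed agreement is
`p_o = (n11 + n00)/n`; expected agreement treats the observers as
independent Bernoulli responders at their marginal accuracies,
`p_e = p1 p2 + (1−p1)(1−p2)`; error consistency is Cohen's kappa
`κ = (p_o − p_e)/(1 − p_e)`.

**Undefined kappa.** When both observers are at 0% or 100% accuracy,
`p_e = 1` and κ has no value. The package raises an explicit
`UndefinedKappaError` rather than reporting 0; pairwise-matrix and
aggregation code skips such cells and records them. This situation occurs
in practice exactly where the task is too easy or too hard for the
statistic to be meaningful.

**κ_max.** With both marginals fixed, observed agreement is maximal when
the smaller off-diagonal cell is empty, giving `p_o^max = 1 − |p1 − p2|`
and `κ_max = (p_o^max − p_e)/(1 − p_e)`. We do not take the closed form
on faith: the test suite verifies it against exhaustive breadth-first
search over every table reachable by accuracy-preserving pair-flips, for
all tables up to n = 20.

**Flip distance.** An accuracy-preserving modification flips a *pair* of
trials in one observer — one currently-correct trial together with one
currently-incorrect trial — so that observer's marginal accuracy is
unchanged. Each effective pair-flip moves one trial out of each
off-diagonal cell, so `min(n10, n01)` pair-flips (= `2·min(n10, n01)`
flipped trials) reach κ_max. The distance is reported in *trials* (the
pair count is exposed as a secondary field), and conditions with fewer
than 10 flipped trials are flagged unstable. The threshold of 10 is
deliberately conservative and configurable.

**Bootstrap.** Intervals are percentile intervals over paired trial
resampling: the same item indices are drawn with replacement for both
observers, preserving the joint correctness structure (the resampling
unit is the trial; resampling observers is meaningless at two, and
resampling items independently per observer would destroy the very
dependence κ measures). Degenerate resamples (`p_e = 1`) are dropped and
the effective resample count reported. Default coverage is 68%, i.e.
roughly ±1 SE.

**Small-sample bias.** The plug-in κ is a ratio estimator and is slightly
negative in expectation under true independence (order 1/n). Tests that
check the chance-level behaviour of independent observers therefore
compare against a Monte-Carlo null simulated at the same marginals and
trial count, not against literal zero.

**Group summaries** are unweighted means over pair values, excluding the
diagonal and undefined cells.

## Corruption operators

Images are H×W×3 float arrays in [0,1]; every operator preserves range
and shape, and quantisation happens only at PNG I/O.

* **Uniform noise** adds one draw per pixel from `[−w, w]` (default
  `w = 0.5`) identically to all three channels, then clips to [0,1].
  The achromatic reading (a single noise field) is the default because
  the manipulation targets luminance contrast; an option switches to
  independent per-channel noise, which is also plausible — the choice is
  exposed rather than hidden.
* **Gaussian lowpass** convolves each channel with a 2-D Gaussian
  (default σ = 5.0 px), padding with the experimental background gray
  0.454, truncating the kernel at 4σ (mass lost < 1e−4) and clipping.
* **Grayscale** uses BT.601 luma weights (0.299, 0.587, 0.114) replicated
  to three channels; gray images are fixed points.
* **Pink-noise mask** (the backward mask): seeded white noise shaped in
  the frequency domain by 1/f in radial spatial frequency, DC removed,
  min–max rescaled to [0,1], equal channels. The radially averaged
  amplitude spectrum regresses to a log-log slope of −1 (tested at
  512×512 with tolerance ±0.15). Min–max rescaling is the one step that
  slightly violates strict spectral purity; it is accepted to guarantee
  the [0,1] contract.

## Superclass aggregation

A fine-grained probability vector (e.g. 1,000 classes) is mapped to the
8 basic-level superclasses (airplane, bear, bike, bird, boat, car, dog,
elephant) by **averaging** the constituent probabilities per superclass.
The mean — not the sum — is the aggregation that correctly handles the
prior shift from an unbalanced fine training distribution to a balanced
superclass test; scores are deliberately *not* renormalised before the
argmax (a normalised view is available for reporting). Ties break by
canonical (alphabetical) label order, or uniformly at random under a
seed. Similarity scores are converted to probabilities by a
max-subtracted softmax with optional temperature. The concrete
fine-to-superclass map is a user-supplied two-column text file; tests use
a bundled toy map.

## Psychometric model

Accuracy vs presentation time is modelled on log time:

```
ψ(t) = γ + (1 − γ − λ) · F(log t),   F(z) = 1 − exp(−exp((z − m)/s)).
```

`F` is the reverse Gumbel (log-Weibull) CDF, increasing in `z`, so
`F(m) = 1 − 1/e`; `m` is the location in log-ms and `s` the scale in
log-ms units. The guess rate γ is fixed by design (1/8 for the 8-way
task, 1/2 for the binary animal task); the lapse rate λ is estimated
under a Beta(1.5, 20) prior rescaled to its [0, 0.1] bound (MAP). Fitting
maximises the binomial log-likelihood plus log-prior with L-BFGS-B from
5 fixed starts around a moment-based location anchor — deterministic
given the data. The prior density is evaluated with its argument clipped
1e−9 away from the support edges, where the log density diverges.
All-ceiling or all-floor data (observed proportions spanning < 0.05)
raise a degenerate-fit error instead of returning an unconstrained
estimate.

Criterion thresholds invert ψ:
`t(c) = exp(m + s·log(−log(1 − q)))` with `q = (c − γ)/(1 − γ − λ)`,
defined only for `γ < c < 1 − λ`. This MAP machinery is an approximation
of the psignifit approach validated by parameter recovery, not by
matching any external implementation bit for bit; the lapse prior induces
a small (≲0.1 log-ms) location bias that stays well inside the sampling
error at realistic trial counts.

## Trial tables and filters

One row per trial: observer, session/round/block/set/trial position,
image, true and responded class (or `NO_RESPONSE` for a missed
deadline), presentation frames and ms (locked to frames × 1000/120 within
0.01 ms), corruption, RT, practice and repeat flags. Schema violations
raise errors naming the offending rows.

Filter order is practice removal → repeat removal → (optional) RT median
split. The split is computed **within each (observer, time, corruption)
cell** rather than globally, so condition-level RT differences cannot
masquerade as a speed effect; ties at the median go to the faster half.
`NO_RESPONSE` counts as incorrect by default (an option drops such trials
instead — the right handling is genuinely ambiguous, so both paths exist
and are logged). Correctness series align observers by image id; by
default identical item sets are required, and the intersection is taken
only under an explicit `intersect=True` (practice trials are
position-based and observer-specific, so uncorrupted conditions typically
need it).

## Synthetic-data generator

The generator is the package's test bed; its defaults reproduce the
experimental design itself: 8 balanced classes, presentation times
{1, 2, 4, 8, 16, 32} frames at 120 Hz (8.33–266.67 ms), three corruption
conditions per block, two sessions × two rounds, 96-image sets (48 at the
two extreme times), three practice trials at the head of each block —
2·2·(2·3·48 + 4·3·96) = 5,760 trials per observer. Image pools hold 88
ids per class × time (44 at extremes), 22 shared across corruptions (11
at extremes); slots beyond the pool re-present images, flagged as
repeats.

The response model: each image carries a scalar latent difficulty
`d ~ N(0, σ_d²)` drawn once and **shared across observers** — this shared
axis is the entire source of above-chance between-observer error
consistency, mirroring the requirement that stimuli be heterogeneous in
difficulty for EC to be meaningful. An observer's correct-response
probability is its reverse-Gumbel ψ with location shifted by a
per-corruption offset and by its *effective* difficulty
`ρ·d + √(1−ρ²)·d_private`. The loading ρ is the single knob spanning the
human-versus-model contrast: ρ = 1 for human-like observers, ρ = 0 for a
"model" whose errors live on an independent axis (pairwise κ exactly 0
analytically). Wrong responses are uniform over the 7 other classes. RTs
are shifted-lognormal, drifting faster with longer presentation times
with an extra speed-up at the shortest time (a guessing bump) — a
qualitative stand-in sufficient for exercising the median split, not a
fitted RT model.

Defaults chosen once for realism: location 2.9 log-ms (≈18 ms to reach
`1−1/e` of the rise on clean images) with ±0.15 between-observer jitter,
scale 0.7, lapse 0.02, corruption offsets none/grayscale/lowpass/noise =
0/0.15/0.7/0.9 log-ms, difficulty SD 1.0 log-ms, RT shift 250 ms. These
synthetic observers are deliberately generic; they are *not* fitted to
any behavioural dataset, so passing tests demonstrates correctness of the
machinery (estimators recover the generator's analytic values), not
fidelity to real human parameters.

Analytic oracles accompany the generator: conditional on d the observers
are independent, so the pair's joint both-correct probability is
`E_d[E[p_a|d]·E[p_b|d]]`, evaluated by 61-node Gauss–Hermite quadrature
and mapped through the kappa formula; per-cell expected accuracy is the
difficulty-averaged ψ. End-to-end tests check pipeline estimates against
these values within 3 SE over replicate studies.

Seeding: one root `SeedSequence`; stream 0 drives image difficulties,
stream 1+k observer k, so observers regenerate independently.

The correlated binary-pair simulator inverts the kappa formula directly:
given `(p1, p2, κ)` it sets `p_o = κ(1−p_e) + p_e`, solves
`p11 = (p_o + p1 + p2 − 1)/2`, checks the Fréchet bounds
`max(0, p1+p2−1) ≤ p11 ≤ min(p1, p2)` (the feasibility range is exposed
and infeasible targets are rejected with the valid interval named), and
samples trials i.i.d. from the resulting 2×2 joint.

## Problem sizes

Stochastic checks run at sizes chosen to make 3·SE bands decisive while
keeping the full suite fast: binary-pair recovery at n = 10⁵ over a
3×3×3 (p1, p2, κ) grid; the end-to-end pipeline on 30 replicate
miniature studies (3 observers, 2 times × 2 corruptions, 40 trials per
cell); bootstrap coverage on 500 simulated pairs of 500 trials with 1,000
resamples each; psychometric recovery on 20 replicate 6-point curves of
200 trials per point. The exhaustive flip-oracle sweep covers all ≈10⁴
contingency tables with n ≤ 20.

## Known limitations

* The generator's difficulty axis is unidimensional; real image
  difficulty is plausibly multi-factorial, and partial human–model
  overlap (0 < ρ < 1) is a crude model of representational similarity.
* The psychometric MAP uses a single documented prior; no posterior
  uncertainty is produced, only point estimates (bootstrap the data if
  intervals are needed).
* κ is not corrected for accuracy differences between observers — by
  design; κ_max and the flip distance contextualise it instead.
* The corruption operators implement the final published parameters; no
  calibration against model accuracy is included.
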