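# Methods

## Model

A mother-cell lineage is observed for a window of W minutes (default 100
generations at a 26.6-min doubling time T_d). Replication errors arise as a
homogeneous Poisson process with rate λ (min⁻¹ lineage⁻¹). Each error is
repaired unless an independent Bernoulli trial with failure probability q
fails; nascent mutations are therefore a thinned (compound
Poisson-with-Bernoulli-increments) process of rate λq. A repaired error
carries a fluorescent-focus lifetime L ~ Exp(τ); an unrepaired one carries
L = T_d(1 + ε), ε ~ N(0, cv) — the focus persists until the next
replication cycle converts the error into a mutation, so its lifetime is
peaked at one doubling time.

Imaging samples the lineage at frames t_j = φ + jΔt. A focus alive on
[onset, onset+L) is recorded iff some frame time falls in that interval;
the record is (onset frame, span k), and the observed lifetime is kΔt, so a
focus caught on a single frame reports one frame interval. Optional
photobleaching extinguishes a visible focus after each exposure with fixed
probability b, truncating the span at a Geometric(b) number of exposures.

An optional two-state telegraph process modulates q (not λ): while "on",
the failure probability is q_high, with exponential dwell times in both
states. This models transient episodes of reduced repair capacity that
produce mutation bursts confined to single lineages; the defaults (q_high =
0.1 over a 0.005 baseline, mean on-dwell 40 min ≈ 1.5 generations, on
fraction ≈ 5%) keep the time-averaged failure probability at 1%.
`matched_burst_params` solves the on-rate for any requested mean.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| λ (error rate) | 0.14/26.6 ≈ 0.00526 | min⁻¹ | ~0.14 errors/generation in long-term mother-cell runs, so 1% failures give ~0.0014 mutations/generation; short-term analyses pass 0.065 min⁻¹ explicitly (the two accountings are not forced to agree) |
| q (failure probability) | 0.01 | — | ~1% of errors escape repair in wild-type cells |
| τ (repair lifetime) | 40 | s | observed mean short-focus lifetime |
| T_d (doubling time) | 26.6 | min | growth in rich medium |
| long-lifetime cv | 0.2 | — | free spread parameter; not asserted by data, sensitivity-checked by the ±2-min cutoff robustness tests |
| Δt (frame interval) | 120 (long-term); 7.5/15/30 (short-term) | s | acquisition settings of the two experiment styles |
| window | 100 | generations | mother-cell observation span |
| cutoff | 14 | min | short/long threshold at 2-min frames; `determine_cutoff` re-derives a valley from the data when asked |

Divisions are deterministic at interval T_d (generations = time/T_d):
growth-rate noise is orthogonal to every statistic computed here. One
lineage = one microchannel mother cell; daughter cells are out of scope.
Lineage i uses the RNG substream seeded by (seed, i), so any lineage is
reproducible independent of the batch size.

## Lifetime analysis

For a detected focus with Exp(τ) lifetime and uniform frame phase, the span
is exactly geometric: P(k) ∝ e^(−(k−1)Δt/τ) − e^(−kΔt/τ). The τ MLE is
therefore closed-form (r̂ = 1 − 1/k̄, τ̂ = −Δt/ln r̂), with a delta-method
Wald interval on log τ. This phase-marginalized likelihood is the
interval-censoring model the imaging geometry actually induces; a wider
"(k−1)Δt to (k+1)Δt" interval treatment is biased upward by ~9% at
Δt = 7.5 s, τ = 40 s and is not used. When every focus spans one frame
(Δt ≫ τ) the fit is flagged degenerate and only an upper bound on τ is
returned. The raw mean observed lifetime is always reported alongside the
MLE, since the two differ under censoring.

The short/long cutoff is the minimum of a Gaussian KDE on log-lifetime
between its two largest modes. The bandwidth is Silverman's rule × 0.5:
Silverman's rule targets unimodal data and at ×1 or above it merges the
one-frame mode (~2 min) with the doubling-time mode (~26 min); the real
contract — verified by tests — is that the valley lands between the modes
and that shifting it by ±2 min relabels <5% of foci. Classification is
strict ("long" ⇔ kΔt > cutoff), so the 14-min threshold at 2-min frames
makes k ≥ 8 long-lived; fewer than 50 foci are refused, and unimodal input
returns an explicit failure state instead of an arbitrary number.

Bleaching comparisons re-discretize both samples onto the coarser frame
grid of each pair before the two-sample KS test: for exponential lifetimes
the snapped span law is identical across frame intervals, so the test
responds to genuine lifetime distortions, not to discretization.

## Rates

Detection probability of an Exp(τ) focus at frame interval Δt is
p = (τ/Δt)(1 − e^(−Δt/τ)) (0.317 at τ = 40 s, Δt = 2 min). The corrected
total error-production rate is n_short/(p·E_short) + n_long/E_long. Two
accounting details remove window-edge bias: (i) foci whose spans touch the
first or last frame are discarded before classification (their class is
ambiguous), and each class receives the effective exposure inside which a
focus of its typical lifetime fits entirely (W − τ − 2Δt for short,
W − T_d − Δt for long); (ii) the 1/p correction is applied only to spans
consistent with an Exp(τ) lifetime (k ≤ ⌈6.9 τ/Δt⌉, beyond which the
exponential tail mass is <0.1%) — longer sub-cutoff spans are truncated
long-focus spans and enter at unit weight. Without (ii), fully
repair-deficient conditions overstate the corrected total by ~2%.

Poisson confidence intervals use the exact Garwood (chi-square)
construction — long-focus counts are a few hundred at best, and the zero
count yields the standard 3.69/exposure upper bound. The CI of a corrected
rate scales the Garwood interval of the observed count by the correction
factor; the leading variance term of the corrected count matches this
scaling. Rate-ratio (fold-change) intervals condition on the total count
(binomial) and transform the Clopper–Pearson interval. The
replicative-age endpoint comparison uses the unconditional exact 2×2 test
with the pooled score statistic maximized over a nuisance grid of step
0.001 (the score variant of Barnard's test; the CSM variant is heavier and
changes nothing at these sample sizes). MA+WGS rates are
n_mut/(lines × log₂(dilution) × cycles).

## Dynamics

Gaps are onset-frame to onset-frame within a lineage; onsets sharing a
frame collapse to one (spot tracking cannot resolve them), so every gap is
at least one frame, and the tail from the last onset to the window end is
right-censored. The onset rate is estimated by inverting frame occupancy,
λ̂ = −ln(1 − f)/Δt with f the occupied-frame fraction, which undoes the
collapse bias exactly under the null.

Under Poisson onsets each frame is occupied independently with
p = 1 − e^(−λΔt), so gaps are geometric, and the expected closed-gap count
at lag g pooled over windows of M_i frames is Σ_i max(M_i − g, 0)·p²(1−p)^(g−1).
Normalizing gives a closed-form finite-window null CDF; short windows
over-represent short gaps relative to the unconditional geometric law,
which is exactly the bias the null must carry. `null_prediction_mc`
generates the same curve by Monte Carlo through the
windowing/binning/collapse pipeline and is tested to agree with the closed
form to <0.005; the goodness-of-fit bootstrap uses the closed form for
speed.

The test statistic is the sup-norm distance between the empirical gap CDF
and the null CDF at the estimated rate, on the frame grid. Its p-value is
a parametric bootstrap (default 1999 replicates): each replicate simulates
the null through the same pipeline, re-estimates the rate, and recomputes
the statistic, so rate estimation does not make the test anticonservative.
Censored tails influence the statistic only through the identically
censored null. Fewer than 20 closed gaps are refused. Type-I error is
verified at 0.05 ± 0.02 over 200 datasets, and power against
telegraph-modulated failure (mean 1%, dwell <2 generations, ~500 gaps)
exceeds 0.8.

Short-gap enrichment compares the observed fraction of gaps below a
threshold (default 40 min) with the finite-window null probability via a
two-sided binomial test. Burst reports flag lineages with two onsets
within a window (default two generations), give the Monte-Carlo expected
flagged count under the Poisson null, and test cross-lineage independence
by a circular-shift permutation of each lineage's onset times (which
preserves within-lineage clustering while randomizing alignment).

## What the simulator does and does not establish

The generator reproduces the statistical structure of the measurement —
Poisson production, Bernoulli failure, the two lifetime classes, discrete
sampling, finite windows, bleaching, bursts — so recovery tests establish
that the estimators are correct under the stated model. It does not emulate
segmentation/tracking errors, fluorescence-intensity noise, cell-geometry
effects, growth-rate variability, or focus-merging artifacts; passing tests
therefore validate the inference chain, not the upstream image analysis.
The spread of long-focus lifetimes (cv) is a free parameter; conclusions
that depend on it are limited to the ±2-min cutoff-robustness guarantees.

## Numerical and design choices

- All frames are 0-based with half-open spans [onset, onset+n);
  user-facing times are minutes, frame intervals seconds, with one
  conversion site per reader.
- The long-lifetime draw is resampled until it exceeds 0.5 min, a floor
  that only matters for cv ≫ 0.2.
- Bootstrap/permutation p-values use the (1 + exceedances)/(1 + B)
  convention; identical seeds give bit-identical results.
- Pipeline runs write a manifest (config hash, seeds, package versions,
  stage timings); outputs of two runs with equal configs are byte-identical
  apart from the manifest's timings.
- Problem sizes in the test suite (e.g. 50 recovery replicates, 200
  calibration datasets, 10⁶-draw oracles) were chosen to make the
  statistical assertions sharp while keeping the full suite around a
  minute.

## Known limitations

- The detection correction assumes exponential short lifetimes with a τ
  estimated from fine-interval runs; a mis-specified τ propagates into the
  corrected totals roughly linearly in 1/p.
- The unconditional 2×2 test enumerates (n₁+1)(n₂+1) tables over a
  999-point nuisance grid; it is exact to grid resolution but quadratic in
  the bin counts (fine up to a few hundred per bin).
- Only detection of non-Poissonian dynamics is in scope; the package does
  not infer the hidden burst-state path or its switching rates.
- Reading microscope-software exports requires mapping their columns onto
  the documented CSV schema; native formats are not parsed.
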