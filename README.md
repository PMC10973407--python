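# mutltrace

Single-cell analysis of DNA mismatch-repair (MMR) efficiency from
fluorescently tagged MutL focus tracks in mother-machine lineages.

In *E. coli*, a YFP-MutL fusion forms a diffraction-limited focus on each
replication error. When repair succeeds the focus disappears within about a
minute; when repair fails the focus persists for roughly one doubling time,
until the next replication cycle fixes the error as a mutation. Tracking
foci in the mother cell of each microfluidic channel therefore turns
time-lapse movies into three quantitative readouts, which this package
computes from tabular focus/lineage tracks (or from its own ground-truth
simulator):

1. **Repair kinetics** — the mean short-focus lifetime τ, fitted by maximum
   likelihood under interval censoring: a focus seen on *k* frames of
   interval Δt has a geometric span law, P(k) ∝ e^(−(k−1)Δt/τ) − e^(−kΔt/τ),
   for an Exp(τ) lifetime at uniform frame phase.
2. **Rates and mutation rates** — focus rates corrected for discrete
   observation. A focus of exponential lifetime τ overlaps at least one
   frame with probability p = (τ/Δt)(1 − e^(−Δt/τ)); the corrected total
   error-production rate divides short-focus counts by p, while the rate of
   long-lived foci (observed lifetime above a cutoff found at the valley of
   the bimodal lifetime distribution) estimates the mutation rate per
   generation, with exact Poisson confidence intervals. MA+WGS bottleneck
   arithmetic (g = log₂ dilution) and Welch / unconditional-exact (Barnard
   score) comparisons cover the cross-condition and replicative-age checks.
3. **Mutation dynamics** — if errors are Poisson and repair failure is an
   independent Bernoulli trial, nascent mutations are a thinned Poisson
   process and inter-arrival times between focus onsets are exponential —
   geometric on the frame grid, CDF(kΔt) = 1 − e^(−λkΔt). The
   goodness-of-fit test compares empirical gap CDFs against a
   finite-window, discreteness-aware null (closed form, cross-checked by
   Monte Carlo through the same windowing/collapse pipeline) with a
   parametric-bootstrap p-value, plus short-gap (<40 min) enrichment and
   per-lineage burst detection.

A synthetic-data module simulates the whole measurement chain — Poisson
error production, Bernoulli repair failure (optionally modulated by a
two-state telegraph process that creates transient hypermutable episodes),
per-outcome focus lifetimes, discrete imaging at any frame interval, finite
windows and photobleaching — so every stage is testable against known truth.

## Worked example

```python
import mutltrace as mt
from mutltrace.rates import experiment_rates

# WT-like long-term run: 0.14 errors/generation, 1% repair failure,
# 1000 mother-cell lineages followed for 100 generations at 2-min frames
params = mt.SimulationParams(failure_prob=0.01, n_lineages=1000,
                             window_generations=100, seed=5)
imaging = mt.ImagingConfig(frame_interval_s=120.0)
traces, foci = mt.simulate_experiment(params, imaging)

r = experiment_rates(foci, [t.window_min for t in traces],
                     imaging.n_frames(traces[0].window_min))
print(r["total"].summary())
print(f'failure fraction: {r["failure_fraction"]:.4f}')
print(f'mutation rate: {r["mutation"].corrected_rate_per_generation:.5f} /generation')
```

```
Rate estimate
  events                   4549
  exposure                 2.66e+06 min (100000 generations)
  detection probability    0.3167
  raw rate                 0.00171 /min (0.04549 /generation)
  corrected rate           0.005299 /min (0.1409 /generation)
  95% CI                   0.005146 – 0.005455 /min (0.1369 – 0.1451 /generation)
failure fraction: 0.0095
mutation rate: 0.00134 /generation
```

The corrected total recovers the simulated error-production rate
(0.14/generation) from the ~32% of short foci that discrete 2-min imaging
actually detects; about 1% of foci are long-lived, giving a mutation rate
of ~0.0014 per generation.

The same stages are available from the shell:

```bash
mutltrace simulate --seed 1 --out-dir out
mutltrace lifetimes --foci out/foci.csv --out-dir out
mutltrace rates --foci out/foci.csv --lineages out/lineages.csv
mutltrace dynamics --foci out/foci.csv --lineages out/lineages.csv --class long
mutltrace run --out-dir out          # full pipeline + manifest
```

## Layout

- `mutltrace.simulate` — ground-truth lineage/foci generator and imaging layer
- `mutltrace.lifetimes` — lifetime histograms, censored-exponential fit,
  cutoff determination, classification, bleaching comparison
- `mutltrace.rates` — detection correction, rate/mutation-rate estimates,
  MA+WGS arithmetic, Welch and unconditional exact tests, age binning
- `mutltrace.dynamics` — inter-arrival sets, discrete/finite-window Poisson
  null, bootstrap goodness-of-fit, enrichment, burst reports
- `mutltrace.io` / `mutltrace.cli` — CSV schemas, YAML configs, the
  end-to-end pipeline with its run manifest, and the `mutltrace` CLI

See `docs/methods.md` for the statistical model, numerical choices and
known limitations.
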