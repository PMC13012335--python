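# flimbench

Simulation, lifetime fitting, and quality-control statistics for
characterizing **solid fluorescence-lifetime standards** and validating
fluorescence-lifetime imaging (FLIm) systems against them.

Clinical and research FLIm instruments — bench TCSPC spectrometers,
confocal FLIM microscopes, wide-field SPAD micro-cameras — need stable
physical references with known lifetimes to verify that the number they
report is right. Solid dyed-resin phantoms provide such references, but
qualifying a phantom (and then using it to benchmark a camera) requires a
reproducible analysis chain: decay fitting with well-defined windows,
replicate statistics, photostability metrics, and spatial-resolution
readout. `flimbench` implements that chain end to end, together with
seeded synthetic-data generators so every stage can be exercised and
tested without instrument data.

## The model

Time-correlated single-photon counting records a histogram of photon
arrival times relative to a pulsed laser (repetition period *T*, 50 ns at
20 MHz). For a monoexponential emitter with lifetime τ, the steady-state
arrival density over one period is

&nbsp;&nbsp;&nbsp;&nbsp;f(t) ∝ e^(−t/τ) / (1 − e^(−T/τ)),

the wrap factor accounting for incomplete decay between pulses. The
expected histogram is

&nbsp;&nbsp;&nbsp;&nbsp;μᵢ = A · (f ⊛ IRF)ᵢ + B,

a circular convolution with the measured instrument response function
(IRF), scaled by the expected signal photons *A* plus a uniform
background *B*. Two estimators of τ are provided:

- **Reconvolution fit** — minimizes Σ (cᵢ − μᵢ)²/max(cᵢ, 1) over a
  window from 80% of the maximum counts on the rising edge down to 1% of
  the maximum on the tail. Accurate even when τ is comparable to the IRF
  width; this is the bench method.
- **Tail fit** — count-weighted log-linear regression between 90% and
  20% of the peak, IRF-free; the per-pixel method for wide-field
  cameras, biased high for short lifetimes.

Goodness of fit is the Poisson-weighted reduced chi-squared (≈ 1 for a
well-specified fit). The QC layer adds replicate summaries
(mean, sample SD, CV% = 100·SD/mean), photostability metrics over
cumulative UV dose (J/cm² = irradiance × time), the inverse-excitation-
power relative-intensity proxy, Michelson bar contrast for resolution
targets, and a reabsorption/re-emission cascade model (geometric mixture
of Erlang arrival times, mean τ/(1−p)) that explains why bulk
measurements read longer lifetimes than confocal ones at high dye load.

## Worked example

```python
import pandas as pd
from flimbench import (bench_axis, simulate_irf, simulate_decay,
                       DecayModelParams, fit_reconvolution,
                       summarize_replicates)

axis = bench_axis()                        # 1024 bins over the 50 ns period
irf = simulate_irf(axis, fwhm=0.25, center=2.0)   # 250 ps Gaussian IRF

params = DecayModelParams(tau=2.43, amplitude=1e5) # a 2.43 ns standard
decay = simulate_decay(params, irf, axis, seed=42) # 1 s @ ~1e5 cps
result = fit_reconvolution(decay, irf)
print(f"fitted tau = {result.tau:.3f} ns  (true 2.43 ns)")
print(f"reduced chi2 = {result.chi2_reduced:.3f}")
print(f"fit window = bins {result.window.start_bin}-{result.window.end_bin}")

table = pd.DataFrame({"material": ["orange"] * 3,
                      "value": [3.59, 3.61, 3.63]})
print(summarize_replicates(table).round(3).to_string(index=False))
```

prints

```
fitted tau = 2.422 ns  (true 2.43 ns)
reduced chi2 = 0.953
fit window = bins 42-277
material  mean   sd  n  cv_percent
  orange  3.61 0.02  3       0.554
```

The fitted lifetime recovers the simulated 2.43 ns within photon noise
(~0.3%), the reduced chi-squared near 1 says the Poisson noise model is
consistent, and the replicate summary reports the repeatability of three
lifetime measurements as a 0.55% coefficient of variation.

A command-line interface mirrors the library:
`flimbench simulate | fit | flim | qc | contrast` (see `--help` on each).

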