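# Methods

This note documents the models, estimators, defaults, and numerical
choices behind `flimbench`, and what the synthetic-data generators do
and do not emulate.

## Forward model

A monoexponential emitter with lifetime τ under pulsed excitation at
repetition period *T* (50 ns, i.e. 20 MHz) reaches a periodic steady
state in which photons from all previous pulses overlap. Summing the
geometric series of shifted single-pulse decays gives the arrival
density on [0, *T*):

    f(t) = exp(-t/τ) / (1 - exp(-T/τ)) / Z.

Incomplete decay between pulses (material for τ ≳ 5 ns at 20 MHz)
rescales the kernel but does not change its exponential shape, so the
kernel is normalized to unit mass over the binned period. The expected
histogram is μᵢ = A·(f ⊛ IRF)ᵢ + B with a *circular* convolution over
the period — the periodic counterpart of the usual reconvolution
integral. Bin *centers* are the time convention everywhere, in both the
simulator and the fitters: bin i is read at tᵢ = (i + ½)·Δt. Fractional
IRF shifts interpolate linearly between adjacent whole-bin circular
shifts; whole-bin shifts are exact.

Circular convolution is computed by real FFT; round-off negatives are
clipped to zero and the mass balance (output sum = kernel sum) restored
exactly. The test suite checks this path against a brute-force fold of
the aperiodic convolution at 10⁻⁹ relative tolerance.

## Time grids

Two presets cover the two instrument classes:

| preset | bins | bin width | period | emulates |
|---|---|---|---|---|
| `bench_axis()` | 1024 | ~48.8 ps | 50 ns | point TCSPC spectrometer |
| `camera_axis()` | 50 | 370 ps | 50 ns | wide-field SPAD micro-camera |

The bench bin count is a deliberate compromise. TCSPC hardware can bin
far finer, but at the characterization protocol's ~10⁵ photons per
acquisition a 4096-bin grid leaves ~24 counts per bin, and the
least-squares objective with weights 1/max(cᵢ, 1) (see below) then
acquires a systematic downward lifetime bias of ~3% — the familiar
low-count pathology of Neyman weighting, in which downward-fluctuating
bins receive inflated weight. At 1024 bins (~100 counts/bin) the median
bias is below 1% for all four reference lifetimes while the grid still
resolves a 250 ps IRF with five bins across its FWHM. Users fitting
larger photon budgets can pass a finer grid explicitly.

The camera grid spans only 18.5 ns of the 50 ns period, as the sensor
records a partial window; the circular convolution then wraps at the
window edge rather than the true period. The approximation is only used
for simulation (camera fitting is tail-only and IRF-free) and the
wrapped mass is ≤ 0.6% of the peak for the longest reference lifetime.

## Fit windows

Window edges are read at whole bins from fractions of the peak count
(ties broken to the earliest peak bin; no sub-bin interpolation, so
windows are reproducible integers):

- **Reconvolution mode**: first bin at/before the peak with counts
  ≥ 80% of the maximum, through the last post-peak bin with counts
  ≥ 1% of the maximum.
- **Tail mode**: first post-peak bin with counts ≤ 90% of the maximum,
  through the last bin with counts ≥ 20% of the maximum.

## Estimators

**Reconvolution fit.** Bounded trust-region least squares
(`scipy.optimize.least_squares`) on residuals (cᵢ − μᵢ)/√max(cᵢ, 1)
over the window, free parameters (τ, A) by default with optional
background and IRF-shift terms (both off by default: a minimal model is
the appropriate default for background-free synthetic data and
matched-grid IRFs; both are config-switchable). Bounds τ ∈ [0.05 ns,
2*T*]; starting τ from a count-weighted log-linear regression on the
90%→5% tail, amplitude from the total counts. On non-convergence the
fit restarts from lifetimes spanning the bounds and keeps the best
result, reporting `converged` honestly. Convergence tolerances:
xtol 10⁻⁸, ftol 10⁻¹⁰. Zero-count bins inside the window are retained
with weight 1.

**Tail fit.** Weighted linear regression of ln cᵢ on tᵢ with weights
cᵢ (the variance-stabilizing weights for log-transformed Poisson data),
zero-count bins excluded, requiring ≥ 3 positive bins. Exact for
noise-free exponentials sampled at bin centers; biased high when the
IRF width is not small against τ, which is precisely the regime the
reconvolution fit exists for — the package's paired-bias tests quantify
this ordering.

**Goodness of fit.** χ²_red = Σ(cᵢ−μᵢ)²/max(cᵢ,1) / (n − n_params)
over the window. For well-specified Poisson simulations at 10⁵ photons
its mean over seeds lies in [0.9, 1.1].

## FLIM cubes

Per-pixel fitting computes each pixel's window independently from that
pixel's own counts (wide-field processing is per-pixel; a global window
would leak information between pixels). Pixels below `min_photons`
(default 100 — cubes carry no per-pixel QC metadata, so a simple photon
floor stands in) or under the defect mask are left NaN. Lifetime
histograms default to 0.05 ns bins; the reported mode refines the peak
bin by a three-point parabolic interpolation, removing the ±half-bin
quantization of the histogram grid (without it, a true lifetime lying
on a bin edge shows an apparent half-bin error). The intensity-weighted
render normalizes brightness to the 99th percentile of intensity, so it
is invariant to overall intensity scale.

## Re-emission cascade

At high dye density, emitted photons can be reabsorbed and re-emitted
before detection. Each re-emission adds one exponential dwell time, so
with per-generation probability p the arrival time is an
Erlang(n+1, 1/τ) variable with geometric n — and the untruncated
mixture collapses analytically to a single exponential with lifetime
τ/(1−p). The generator truncates at 30 generations (discarded mass
< 10⁻⁸ for p ≤ 0.6). This is the minimal forward model with a closed
form for testing: a bulk detector sees the full cascade (apparent
lifetime τ/(1−p), rising with dye load), while a confocal system's
spatial filtering rejects secondary emission (p = 0, flat lifetime) —
reproducing the bulk/confocal divergence qualitatively. Dye quantity
maps to p through a saturating law p(m) = p_max·m/(m + m_half)
(defaults p_max = 0.3, m_half = 320 mg), illustrative rather than
calibrated: no measured re-emission probability exists for these
materials.

## Synthetic-data generators

All generators are deterministic under a fixed seed
(`numpy.random.default_rng`). Defaults mirror the characterization
protocol: 1 s bench acquisitions at an expected 10⁵ detected photons;
Gaussian IRF of 250 ps FWHM (bench) or 370 ps (camera, one bin);
128×120-pixel cubes with 50 × 370 ps bins and an optional rectangular
defect mask; quadrant phantoms carrying the four reference materials
(0.80, 2.43, 2.56, 3.61 ns at relative intensities 0.24, 2.48, 0.50,
2.29 AU); bar targets as vertical opaque bars over a fluorescent slide,
optionally Gaussian-blurred to emulate resolution loss; photostability
series of 11 hourly points at 1.35 mW/cm² irradiance with three
lifetime replicates and one intensity reading per point, linear
lifetime drift in dose and mono-exponential photobleaching (the
simplest forms consistent with slow degradation), and multiplicative
measurement noise of 1% (lifetime) / 2% (intensity) relative SD —
chosen to reproduce repeatability of the order observed for photostable
solid standards (CV ≈ 0.5–2%, hour-to-hour intensity scatter a few
percent).

What the generators do *not* emulate: detector afterpulsing and
crosstalk, per-pixel IRF dispersion, dark counts, pile-up at high count
rates, spectral (wavelength-resolved) response, dye heterogeneity at
the microscale, and tissue-like scattering or absorption. Passing tests
therefore demonstrate correctness of the analysis chain under ideal
Poisson statistics, not robustness to every real-sensor artifact.

## Problem sizes and tolerances in the test suite

Monte-Carlo tests use 15–50 seeded replicates at 10⁵ photons (bench)
and 64×60 or 16×16 cubes at 10³–10⁶ photons/pixel — sizes at which the
checked effects are comfortably resolved while the full suite runs in
seconds. Recovery tests assert median relative error < 2%; quadrant
histogram modes within 3% of the generating lifetimes; the lifetime-SD
scaling exponent −0.5 ± 0.1 over three photon decades; convolution
identities at 10⁻⁹ relative tolerance.

## Known limitations

- Monoexponential decays only; multi-exponential and phasor analysis
  are out of scope.
- The bulk-system measured values of physical standards (lifetimes,
  intensities, USAF contrasts of the real targets) cannot be reproduced
  from synthetic data; the package validates the *methods* on
  generator-defined ground truth instead.
- The Michelson bar-contrast readout requires the bar period to be
  supplied; automatic USAF group/element detection is not implemented.
- Vendor TCSPC file formats (.ptu, .sdt) are not read; decays travel as
  plain two-column text, cubes as TIFF + JSON sidecar.
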