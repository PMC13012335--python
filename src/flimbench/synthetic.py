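"""Seeded generators for every input the characterization pipeline consumes.

These emulate the measurement protocols used to validate FLIm systems
against solid dyed-epoxy lifetime standards:

* bench TCSPC decays — 20 MHz excitation, ~1e5 detected photons per 1 s
  acquisition, Gaussian-like IRF;
* wide-field camera cubes — 128x120 pixels, 50 bins of 370 ps, quadrant
  phantoms (four materials in one field of view) and fluorescent
  bar-resolution targets;
* UV-dose photostability series — hourly lifetime triplicates and single
  intensity readings over a 10 h exposure;
* reabsorption/re-emission cascades — emitted photons reabsorbed and
  re-emitted by neighboring fluorophores delay detection and lengthen
  the apparent bulk lifetime, an effect confocal spatial filtering
  suppresses.  Modeled as a geometric mixture of Erlang arrival times
  with closed-form mean tau / (1 - p).

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import (
    DecayHistogram,
    DecayModelParams,
    InstrumentResponse,
    TimeAxis,
    expected_counts,
    monoexp_kernel,
)
from .imaging import FlimCube
from .qc import PhotostabilitySeries

__all__ = [
    "PhantomSpec",
    "PHANTOM_LIBRARY",
    "ReemissionParams",
    "PhantomLayout",
    "simulate_irf",
    "simulate_decay",
    "simulate_reemission_decay",
    "sample_reemission_arrivals",
    "dye_quantity_to_reemission",
    "make_quadrant_layout",
    "make_bar_target_layout",
    "simulate_flim_cube",
    "simulate_photostability_series",
]

_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """One solid lifetime-standard material: name, lifetime, brightness."""

    name: str
    tau: float  # ns
    relative_intensity: float  # AU, brightness relative to a 1 mW reference

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.relative_intensity <= 0:
            raise ValueError(
                f"relative_intensity must be positive, got {self.relative_intensity}"
            )


#: Default material library: the four dyed-epoxy standards (lifetime ns,
#: relative intensity AU) used throughout the bundled examples.
PHANTOM_LIBRARY: dict[str, PhantomSpec] = {
    "purple": PhantomSpec("purple", tau=0.80, relative_intensity=0.24),
    "yellow": PhantomSpec("yellow", tau=2.43, relative_intensity=2.48),
    "magenta": PhantomSpec("magenta", tau=2.56, relative_intensity=0.50),
    "orange": PhantomSpec("orange", tau=3.61, relative_intensity=2.29),
}


@dataclass(frozen=True)
class ReemissionParams:
    """Reabsorption/re-emission cascade: per-generation probability and cutoff.

    ``p`` is the probability that an emitted photon is reabsorbed and
    re-emitted (adding one more exponential dwell time); the cascade is
    truncated after ``max_generations`` re-emissions.  At p <= 0.6 and
    the default cutoff the discarded tail mass is below 1e-8.
    """

    p: float
    max_generations: int = 30

    def __post_init__(self) -> None:
        if not (0.0 <= self.p < 1.0):
            raise ValueError(f"re-emission probability must be in [0, 1), got {self.p}")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


def simulate_irf(
    axis: TimeAxis,
    fwhm: float = 0.25,
    center: float = 2.0,
    seed: int | None = None,
    center_jitter: float = 0.0,
) -> InstrumentResponse:
    """Gaussian instrument response of the given FWHM (ns) at ``center`` (ns).

    Emulates the scattered excitation pulse recorded with the emission
    filter removed.  ``center_jitter`` adds a seeded normal perturbation
    of the peak position (ns), emulating day-to-day timing drift.
    """
    if not (0 < fwhm < axis.period / 4):
        raise ValueError(
            f"IRF FWHM must be in (0, period/4) = (0, {axis.period / 4}) ns, "
            f"got {fwhm}"
        )
    if center_jitter > 0:
        rng = np.random.default_rng(seed)
        center = center + rng.normal(0.0, center_jitter)
    sigma = fwhm * _SIGMA_PER_FWHM
    w = np.exp(-0.5 * ((axis.centers - center) / sigma) ** 2)
    if w.sum() <= 0:  # extremely narrow pulse between bin centers
        w = np.zeros(axis.n_bins)
        w[int(np.clip(center / axis.bin_width, 0, axis.n_bins - 1))] = 1.0
    return InstrumentResponse(axis, w)


def simulate_decay(
    params: DecayModelParams,
    irf: InstrumentResponse,
    axis: TimeAxis,
    seed: int | None = None,
    acquisition_time: float = 1.0,
    excitation_power: float | None = None,
) -> DecayHistogram:
    """Poisson realization of the expected reconvolution model.

    Each bin is an independent Poisson draw with mean from
    ``expected_counts``; ``params.amplitude`` is therefore the expected
    (not exact) total signal photons.  Defaults emulate a 1 s
    acquisition at ~1e5 counts per second.
    """
    rng = np.random.default_rng(seed)
    mu = expected_counts(params, irf, axis)
    counts = rng.poisson(mu)
    return DecayHistogram(
        axis,
        counts,
        acquisition_time=acquisition_time,
        excitation_power=excitation_power,
    )


def simulate_decay_from_kernel(
    kernel: np.ndarray,
    irf: InstrumentResponse | None,
    axis: TimeAxis,
    amplitude: float = 1e5,
    background: float = 0.0,
    seed: int | None = None,
) -> DecayHistogram:
    """Poisson decay realization from an arbitrary per-bin emission kernel.

    Generalizes :func:`simulate_decay` to non-monoexponential kernels
    (e.g., re-emission cascades).  ``irf=None`` skips the instrument
    convolution — the spatially filtered (confocal-like) limit where
    only primary emission from the focal volume is detected.
    """
    from .core import convolve_periodic

    kernel = np.asarray(kernel, dtype=float)
    curve = kernel / kernel.sum()
    if irf is not None:
        curve = convolve_periodic(curve, irf)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(amplitude * curve + background)
    return DecayHistogram(axis, counts)


def simulate_reemission_decay(
    tau: float, reem: ReemissionParams, axis: TimeAxis
) -> np.ndarray:
    """Per-bin arrival probabilities for the re-emission cascade.

    A photon detected after n re-emission events has waited the sum of
    n+1 exponential dwell times, i.e. an Erlang(n+1, rate 1/tau)
    arrival time; n is geometric with success probability 1-p.  The
    density is the truncated mixture

        f(t) = sum_{n=0..N} (1-p) p^n t^n e^(-t/tau) / (tau^(n+1) n!),

    sampled at bin centers and renormalized.  The untruncated mixture
    collapses to a single exponential with lifetime tau/(1-p), so the
    mean arrival time is tau/(1-p): the cascade lengthens the apparent
    lifetime without leaving the monoexponential family.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    t = axis.centers
    term = (1.0 - reem.p) / tau * np.exp(-t / tau)  # n = 0
    density = term.copy()
    for n in range(1, reem.max_generations + 1):
        term = term * (reem.p * t) / (tau * n)
        density += term
    total = density.sum()
    if total <= 0:
        raise ValueError("cascade density vanished on this axis")
    return density / total


def sample_reemission_arrivals(
    tau: float, reem: ReemissionParams, n_photons: int, seed: int | None = None
) -> np.ndarray:
    """Monte-Carlo photon arrival times from the re-emission cascade (ns).

    Draws the number of re-emissions from the truncated geometric law
    and sums the corresponding exponential dwell times.  Used as an
    independent check of the closed-form mixture density.
    """
    rng = np.random.default_rng(seed)
    generations = rng.geometric(1.0 - reem.p, size=n_photons) - 1
    generations = np.minimum(generations, reem.max_generations)
    return np.array(
        [rng.exponential(tau, size=g + 1).sum() for g in generations]
    )


def dye_quantity_to_reemission(
    quantity_mg: float, p_max: float = 0.3, m_half: float = 320.0
) -> float:
    """Map dye quantity (mg) to a re-emission probability.

    Saturating law p(m) = p_max * m / (m + m_half): reabsorption grows
    with dye density but cannot exceed ``p_max``.  Illustrative, not
    calibrated to any material.
    """
    if quantity_mg < 0:
        raise ValueError("dye quantity must be non-negative")
    return p_max * quantity_mg / (quantity_mg + m_half)


@dataclass
class PhantomLayout:
    """Per-pixel phantom assignment: lifetime and relative-intensity maps."""

    tau: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.tau.size == 0:
            raise ValueError("empty layout")
        if self.tau.shape != self.intensity.shape or self.tau.ndim != 2:
            raise ValueError("tau and intensity maps must be equal-shape 2-D arrays")
        if np.any(self.tau <= 0) or np.any(self.intensity < 0):
            raise ValueError("layout requires tau > 0 and intensity >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.tau.shape


def make_quadrant_layout(
    shape: tuple[int, int], specs: tuple[PhantomSpec, PhantomSpec, PhantomSpec, PhantomSpec]
) -> PhantomLayout:
    """Quadrant phantom: one material per image quadrant.

    Material order is (top-left, top-right, bottom-left, bottom-right);
    every quadrant must be non-empty.
    """
    rows, cols = shape
    if len(specs) != 4:
        raise ValueError("quadrant layout needs exactly 4 phantom specs")
    if rows < 2 or cols < 2:
        raise ValueError(f"image {shape} too small for four quadrants")
    tau = np.empty(shape)
    inten = np.empty(shape)
    r2, c2 = rows // 2, cols // 2
    blocks = [
        (slice(0, r2), slice(0, c2)),
        (slice(0, r2), slice(c2, cols)),
        (slice(r2, rows), slice(0, c2)),
        (slice(r2, rows), slice(c2, cols)),
    ]
    for block, spec in zip(blocks, specs):
        tau[block] = spec.tau
        inten[block] = spec.relative_intensity
    return PhantomLayout(tau, inten)


def make_bar_target_layout(
    shape: tuple[int, int],
    bar_period_px: int,
    blur_sigma_px: float = 0.0,
    fluorescent_background: PhantomSpec = PHANTOM_LIBRARY["orange"],
) -> PhantomLayout:
    """Fluorescent bar-resolution target: opaque chrome bars over a bright slide.

    Vertical bars of period ``bar_period_px`` (half opaque, half open)
    along the column direction; zero emission under the bars, the
    material's intensity elsewhere.  ``blur_sigma_px`` Gaussian-blurs the
    bar mask to emulate optical resolution loss.  The lifetime map is
    uniform (the bars block light, they do not fluoresce).
    """
    rows, cols = shape
    if bar_period_px < 2:
        raise ValueError(f"bar_period_px must be >= 2, got {bar_period_px}")
    if cols < 2 * bar_period_px:
        raise ValueError(
            f"image width {cols} px holds fewer than two bar periods "
            f"of {bar_period_px} px"
        )
    x = np.arange(cols)
    mask = ((x % bar_period_px) < bar_period_px / 2).astype(float)
    if blur_sigma_px > 0:
        mask = gaussian_filter1d(mask, blur_sigma_px, mode="wrap")
    profile = np.tile(mask, (rows, 1))
    tau = np.full(shape, fluorescent_background.tau)
    return PhantomLayout(tau, profile * fluorescent_background.relative_intensity)


def simulate_flim_cube(
    layout: PhantomLayout,
    axis: TimeAxis,
    photons_per_pixel: float = 10_000.0,
    irf: InstrumentResponse | None = None,
    seed: int | None = None,
    defect_mask: np.ndarray | None = None,
) -> FlimCube:
    """Poisson FLIM-cube realization of a phantom layout.

    Each pixel's expected decay is the periodic monoexponential kernel
    for its lifetime (convolved with ``irf`` when given), scaled by
    ``photons_per_pixel * relative_intensity``.  Pixels under
    ``defect_mask`` are flagged invalid, emulating a defective sensor
    region; their counts are zeroed.
    """
    if photons_per_pixel < 0:
        raise ValueError("photons_per_pixel must be >= 0")
    rng = np.random.default_rng(seed)
    rows, cols = layout.shape
    mu = np.empty((rows, cols, axis.n_bins))
    for tau in np.unique(layout.tau):
        curve = monoexp_kernel(tau, axis)
        if irf is not None:
            from .core import convolve_periodic

            curve = convolve_periodic(curve, irf)
        where = layout.tau == tau
        mu[where] = curve
    mu *= (photons_per_pixel * layout.intensity)[..., None]
    counts = rng.poisson(mu)
    valid = np.ones((rows, cols), dtype=bool)
    if defect_mask is not None:
        defect_mask = np.asarray(defect_mask, dtype=bool)
        if defect_mask.shape != (rows, cols):
            raise ValueError("defect_mask shape does not match layout")
        valid &= ~defect_mask
        counts[defect_mask] = 0
    return FlimCube(counts, axis, valid)


def simulate_photostability_series(
    tau0: float,
    intensity0: float,
    dose_points: np.ndarray,
    lifetime_drift_per_dose: float = 0.0,
    bleach_rate: float = 0.0,
    lifetime_noise: float = 0.01,
    intensity_noise: float = 0.02,
    replicates: int = 3,
    irradiance: float = 1.35,
    seed: int | None = None,
) -> PhotostabilitySeries:
    """UV-dose photostability series with replicate lifetime readings.

    The underlying trends are the simplest forms consistent with a
    slowly degrading solid standard: lifetime drifts linearly in
    cumulative dose, ``tau(D) = tau0 * (1 + drift * D)``, and intensity
    photobleaches mono-exponentially, ``I(D) = I0 * exp(-bleach_rate * D)``.
    Measurement noise is multiplicative Gaussian with the given relative
    SDs.  Per protocol each time point carries ``replicates`` lifetime
    readings (default 3) and a single intensity reading.

    ``dose_points`` is in J/cm^2 and must start at 0 and increase;
    time points are back-computed from ``irradiance`` (mW/cm^2).
    """
    dose = np.asarray(dose_points, dtype=float)
    if dose.size < 2 or dose[0] != 0 or np.any(np.diff(dose) <= 0):
        raise ValueError("dose_points must start at 0 and strictly increase")
    if np.any(dose < 0):
        raise ValueError("doses must be non-negative")
    rng = np.random.default_rng(seed)
    tau_true = tau0 * (1.0 + lifetime_drift_per_dose * dose)
    if np.any(tau_true <= 0):
        raise ValueError("lifetime drift drives tau non-positive on this dose range")
    inten_true = intensity0 * np.exp(-bleach_rate * dose)
    lifetimes = tau_true[:, None] * (
        1.0 + lifetime_noise * rng.standard_normal((dose.size, replicates))
    )
    intensities = inten_true * (
        1.0 + intensity_noise * rng.standard_normal(dose.size)
    )
    hours = dose / (irradiance * 1e-3 * 3600.0)
    return PhotostabilitySeries(
        time_h=hours,
        dose=dose,
        lifetimes=lifetimes,
        intensity=intensities,
        irradiance=irradiance,
    )
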