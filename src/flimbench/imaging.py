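"""Per-pixel lifetime estimation on FLIM cubes and image-level summaries.

A FLIM cube is a rows x cols x time-bins array of photon counts, as
produced by a wide-field time-resolved sensor (e.g., a 128x120 SPAD
array recording 50 bins of 370 ps).  Each pixel is fitted independently
with its own fit window, mirroring per-pixel processing on camera data;
pixels under a defect mask or below a photon threshold are left
undefined (NaN in the lifetime map).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .core import DecayHistogram, InstrumentResponse, TimeAxis
from .fitting import WindowError, fit_reconvolution, fit_tail

__all__ = [
    "FlimCube",
    "LifetimeImage",
    "LifetimeHistogram",
    "fit_cube",
    "lifetime_histogram",
    "render_intensity_weighted",
]


@dataclass
class FlimCube:
    """Photon-count cube (rows x cols x n_bins) with a validity mask."""

    counts: np.ndarray
    axis: TimeAxis
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != self.axis.n_bins:
            raise ValueError(
                f"cube shape {self.counts.shape} inconsistent with "
                f"{self.axis.n_bins} time bins"
            )
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.counts.shape[:2], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.counts.shape[:2]:
                raise ValueError("valid_mask shape does not match image shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def intensity(self) -> np.ndarray:
        """Per-pixel total photon counts."""
        return self.counts.sum(axis=2)


@dataclass
class LifetimeImage:
    """Per-pixel fit products: lifetime (ns), intensity, goodness of fit.

    Undefined pixels (masked, too few photons, failed fits) are NaN in
    ``tau_map`` and ``chi2_map``.
    """

    tau_map: np.ndarray
    intensity_map: np.ndarray
    chi2_map: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.chi2_map is None:
            self.chi2_map = np.full_like(np.asarray(self.tau_map, dtype=float), np.nan)
        for name in ("tau_map", "intensity_map", "chi2_map"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.tau_map.shape:
                raise ValueError("lifetime/intensity/chi2 maps must share a shape")
        if np.any(self.intensity_map < 0):
            raise ValueError("intensity_map must be non-negative")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.tau_map)


def fit_cube(
    cube: FlimCube,
    mode: str = "tail",
    min_photons: int = 100,
    irf: InstrumentResponse | None = None,
    **fit_options,
) -> LifetimeImage:
    """Fit every valid pixel of a FLIM cube independently.

    ``mode`` is "tail" (IRF-free log-linear regression, the camera
    workflow) or "reconvolution" (requires ``irf``).  Pixels whose total
    counts fall below ``min_photons``, that are masked invalid, or whose
    fit fails are undefined in the output maps.
    """
    if mode not in ("tail", "reconvolution"):
        raise ValueError(f"unknown fit mode {mode!r}")
    if mode == "reconvolution" and irf is None:
        raise ValueError("reconvolution mode requires an IRF")
    rows, cols = cube.shape
    tau = np.full((rows, cols), np.nan)
    chi2 = np.full((rows, cols), np.nan)
    intensity = cube.intensity.astype(float)

    eligible = cube.valid_mask & (intensity >= min_photons)
    for r, c in zip(*np.nonzero(eligible)):
        decay = DecayHistogram(cube.axis, cube.counts[r, c])
        try:
            if mode == "tail":
                result = fit_tail(decay, **fit_options)
            else:
                result = fit_reconvolution(decay, irf, **fit_options)
        except (WindowError, ValueError):
            continue
        if result.converged and result.tau > 0:
            tau[r, c] = result.tau
            chi2[r, c] = result.chi2_reduced

    if not np.isfinite(tau).any():
        warnings.warn(
            "no pixel produced a defined lifetime (all masked, below the "
            "photon threshold, or failed to fit)",
            RuntimeWarning,
            stacklevel=2,
        )
    return LifetimeImage(tau_map=tau, intensity_map=intensity, chi2_map=chi2)


class LifetimeHistogram(NamedTuple):
    mean: float
    sd: float
    counts: np.ndarray
    bin_edges: np.ndarray

    @property
    def mode(self) -> float:
        """Histogram peak position with three-point parabolic refinement.

        Sub-bin localization of the modal lifetime: a parabola through
        the peak bin and its neighbors shifts the estimate off the bin
        center by up to half a bin, removing the quantization of the
        histogram grid.
        """
        i = int(np.argmax(self.counts))
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        if 0 < i < self.counts.size - 1:
            y0, y1, y2 = self.counts[i - 1 : i + 2].astype(float)
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                shift = 0.5 * (y0 - y2) / denom
                width = self.bin_edges[1] - self.bin_edges[0]
                return float(centers[i] + np.clip(shift, -0.5, 0.5) * width)
        return float(centers[i])


def lifetime_histogram(
    image: LifetimeImage,
    weights: str | None = None,
    bin_width: float = 0.05,
    tau_range: tuple[float, float] | None = None,
) -> LifetimeHistogram:
    """Lifetime distribution over defined pixels.

    ``weights=None`` gives the plain per-pixel histogram; ``"intensity"``
    weights each pixel by its total photon count.  The mean and SD are
    computed with the same weighting (population SD over pixels).
    """
    if weights not in (None, "intensity"):
        raise ValueError(f"unknown weighting {weights!r}")
    defined = image.defined
    if not defined.any():
        raise ValueError("no defined pixels to histogram")
    tau = image.tau_map[defined]
    w = image.intensity_map[defined] if weights == "intensity" else np.ones_like(tau)
    if w.sum() <= 0:
        raise ValueError("total weight is zero")
    mean = float(np.average(tau, weights=w))
    sd = float(np.sqrt(np.average((tau - mean) ** 2, weights=w)))
    if tau_range is None:
        lo = np.floor(tau.min() / bin_width) * bin_width
        hi = np.ceil(tau.max() / bin_width) * bin_width
        if hi <= lo:
            hi = lo + bin_width
        tau_range = (lo, hi)
    n_hist_bins = max(1, int(round((tau_range[1] - tau_range[0]) / bin_width)))
    counts, edges = np.histogram(tau, bins=n_hist_bins, range=tau_range, weights=w)
    return LifetimeHistogram(mean=mean, sd=sd, counts=counts, bin_edges=edges)


def render_intensity_weighted(
    image: LifetimeImage,
    tau_range: tuple[float, float],
    cmap: str = "turbo",
) -> np.ndarray:
    """Lifetime-coded hue with intensity-coded brightness (RGB float array).

    Lifetimes are mapped through a matplotlib colormap over ``tau_range``
    and multiplied by brightness normalized to the 99th percentile of
    intensity (so the render is invariant to an overall intensity scale).
    Undefined pixels render black.
    """
    import matplotlib

    lo, hi = tau_range
    if not hi > lo:
        raise ValueError(f"degenerate tau_range ({lo}, {hi})")
    norm_tau = np.clip((image.tau_map - lo) / (hi - lo), 0.0, 1.0)
    norm_tau = np.where(image.defined, norm_tau, 0.0)
    rgb = matplotlib.colormaps[cmap](norm_tau)[..., :3]

    inten = np.where(image.defined, image.intensity_map, 0.0)
    scale = np.percentile(inten, 99)
    brightness = np.clip(inten / scale, 0.0, 1.0) if scale > 0 else np.zeros_like(inten)
    return rgb * brightness[..., None]
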