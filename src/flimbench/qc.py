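"""Replicate, photostability, and dye-quantity QC statistics for lifetime standards.

This layer turns measurement tables into the descriptive summaries used
to qualify a solid lifetime standard: per-group mean / SD / CV%,
fabrication-batch comparisons, UV-dose photostability metrics (min, max
and percent change over an exposure series), the inverse-power relative
intensity proxy, and the bulk-vs-confocal dye-quantity trend report.

All statistics are descriptive; no hypothesis testing is performed.
Sample SD (n-1 denominator) is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhotostabilitySeries",
    "summarize_replicates",
    "relative_intensity",
    "cumulative_dose",
    "photostability_metrics",
    "compare_fabrications",
    "dye_quantity_trend",
]


@dataclass
class PhotostabilitySeries:
    """Lifetime/intensity measurements versus cumulative UV dose.

    time_h     : exposure times in hours, strictly increasing
    dose       : cumulative UV dose in J/cm^2, non-decreasing, dose[0] = 0
    lifetimes  : (n_points, n_replicates) lifetime readings in ns
    intensity  : (n_points,) intensity readings in AU
    irradiance : source irradiance in mW/cm^2
    """

    time_h: np.ndarray
    dose: np.ndarray
    lifetimes: np.ndarray
    intensity: np.ndarray
    irradiance: float = 1.35

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.dose = np.asarray(self.dose, dtype=float)
        self.lifetimes = np.atleast_2d(np.asarray(self.lifetimes, dtype=float))
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = self.time_h.size
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time points must strictly increase")
        if self.dose.shape != (n,) or np.any(np.diff(self.dose) < 0):
            raise ValueError("dose must be non-decreasing and match time points")
        if self.dose[0] != 0:
            raise ValueError("dose must start at 0")
        if self.lifetimes.shape[0] != n or self.intensity.shape != (n,):
            raise ValueError("lifetime/intensity arrays must match time points")

    @property
    def mean_lifetime(self) -> np.ndarray:
        """Per-time-point mean of the replicate lifetime readings."""
        return self.lifetimes.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per (time point, replicate) lifetime plus
        one intensity row per time point."""
        rows = []
        for i in range(self.time_h.size):
            for j, tau in enumerate(self.lifetimes[i]):
                rows.append(
                    dict(time_h=self.time_h[i], dose_j_cm2=self.dose[i],
                         quantity="lifetime_ns", replicate=j, value=tau)
                )
            rows.append(
                dict(time_h=self.time_h[i], dose_j_cm2=self.dose[i],
                     quantity="intensity_au", replicate=0,
                     value=self.intensity[i])
            )
        return pd.DataFrame(rows)


def summarize_replicates(
    table: pd.DataFrame,
    by: Sequence[str] | str = ("material",),
    value: str = "value",
) -> pd.DataFrame:
    """Per-group mean, sample SD and CV% of replicate measurements.

    ``table`` is long-form with one measurement per row.  CV% is
    100 * SD / mean; a zero group mean leaves the CV undefined (NaN).
    Every group must carry at least two values for the SD to exist.
    Rounding is left to the caller (presentation only).
    """
    if isinstance(by, str):
        by = [by]
    if not np.isfinite(table[value]).all():
        raise ValueError("replicate values must be finite")
    grouped = table.groupby(list(by), sort=False)[value]
    sizes = grouped.size()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 replicates: {bad}")
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size").reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * out["sd"] / out["mean"]
    out["cv_percent"] = np.where(out["mean"] != 0, cv, np.nan)
    return out


def relative_intensity(power_required_mw: float, k: float = 1.0) -> float:
    """Relative brightness proxy: inverse of the excitation power needed to
    reach the reference count rate (1e5 cps).

    Returns ``k / power_required_mw``; ``k`` (default 1 mW) sets the AU
    normalization.  Brighter samples need less power, so intensity is
    reciprocal in power.
    """
    if power_required_mw <= 0:
        raise ValueError(f"power must be positive, got {power_required_mw}")
    return k / power_required_mw


def cumulative_dose(irradiance_mw_cm2: float, hours: float) -> float:
    """Cumulative UV dose in J/cm^2 from irradiance (mW/cm^2) and hours.

    dose = irradiance * 1e-3 [W/cm^2] * hours * 3600 [s].
    """
    if irradiance_mw_cm2 < 0 or hours < 0:
        raise ValueError("irradiance and exposure time must be non-negative")
    return irradiance_mw_cm2 * 1e-3 * hours * 3600.0


def photostability_metrics(
    series: PhotostabilitySeries,
    exclude_points: Iterable[int] | None = None,
    denominator: str = "min",
) -> pd.DataFrame:
    """Min, max and percent change of lifetime and intensity over an exposure.

    Lifetime is summarized on the per-time-point replicate means;
    change% = 100 * (max - min) / min (or / max with
    ``denominator="max"``), computed on unrounded values.
    ``exclude_points`` drops time-point indices before summarizing —
    the mechanism for outlier analyses (e.g., a single anomalous
    intensity reading).  A zero minimum leaves change% undefined (NaN).
    """
    if denominator not in ("min", "max"):
        raise ValueError(f"denominator must be 'min' or 'max', got {denominator!r}")
    keep = np.ones(series.time_h.size, dtype=bool)
    if exclude_points is not None:
        keep[np.asarray(list(exclude_points), dtype=int)] = False
    if keep.sum() < 2:
        raise ValueError("fewer than 2 time points remain after exclusions")
    rows = []
    for name, values in (
        ("lifetime_ns", series.mean_lifetime[keep]),
        ("intensity_au", series.intensity[keep]),
    ):
        vmin, vmax = float(values.min()), float(values.max())
        denom = vmin if denominator == "min" else vmax
        change = 100.0 * (vmax - vmin) / denom if denom != 0 else np.nan
        rows.append(dict(quantity=name, min=vmin, max=vmax, change_percent=change))
    return pd.DataFrame(rows)


def compare_fabrications(
    batches: Sequence[pd.DataFrame],
    value: str = "value",
) -> dict:
    """Cross-batch repeatability report for repeated fabrications.

    Each batch is a long-form replicate table (one measured value per
    row).  Returns per-batch mean/SD/CV summaries plus the between-batch
    range of means (max - min), the headline repeatability number.  No
    hypothesis test is applied; the comparison is descriptive.
    """
    if len(batches) < 2:
        raise ValueError(f"need >= 2 fabrication batches, got {len(batches)}")
    frames = []
    for i, batch in enumerate(batches):
        tbl = batch.copy()
        tbl["fabrication"] = i + 1
        frames.append(tbl)
    summary = summarize_replicates(
        pd.concat(frames, ignore_index=True), by=["fabrication"], value=value
    )
    means = summary["mean"].to_numpy()
    return {
        "per_batch": summary,
        "range_of_means": float(means.max() - means.min()),
    }


def dye_quantity_trend(
    measurements: pd.DataFrame,
    flat_tolerance: float = 0.05,
) -> dict:
    """Bulk-vs-confocal lifetime trend across dye quantities.

    ``measurements`` has columns ``quantity_mg``, ``tau_bulk``,
    ``tau_confocal``, ``intensity``; rows are sorted by quantity and
    duplicate quantities averaged.  Flags report whether intensity and
    the bulk lifetime increase with dye load while the confocal
    lifetime stays flat (within ``flat_tolerance`` relative band around
    its mean) — the signature of reabsorption/re-emission lengthening
    bulk measurements but not spatially filtered confocal ones.
    """
    required = {"quantity_mg", "tau_bulk", "tau_confocal", "intensity"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = (
        measurements.groupby("quantity_mg", as_index=False)
        .mean()
        .sort_values("quantity_mg")
        .reset_index(drop=True)
    )
    if len(df) < 3:
        raise ValueError(f"need >= 3 distinct dye quantities, got {len(df)}")

    def increasing(v: np.ndarray) -> bool:
        return bool(np.all(np.diff(v) > 0))

    def flat(v: np.ndarray) -> bool:
        center = v.mean()
        return bool(np.all(np.abs(v - center) <= flat_tolerance * center))

    deltas = df.diff().iloc[1:].reset_index(drop=True)
    return {
        "table": df,
        "intensity_increasing": increasing(df["intensity"].to_numpy()),
        "tau_bulk_increasing": increasing(df["tau_bulk"].to_numpy()),
        "tau_confocal_flat": flat(df["tau_confocal"].to_numpy()),
        "per_pair_deltas": deltas,
    }
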