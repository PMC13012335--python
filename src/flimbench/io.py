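"""File formats: decay text files, FLIM-cube TIFFs with JSON sidecars, configs.

Conventions: times in nanoseconds, doses in J/cm^2, powers in mW.
Decay histograms and IRFs travel as two-column (time_ns, value)
whitespace-delimited text with a commented metadata header; cubes as
multi-page TIFF (page index = time bin) plus a ``<path>.json`` sidecar
holding the time axis and validity mask; float maps as 32-bit TIFF.
All parsers validate type invariants and fail loudly rather than
coercing.  Text output is locale-independent ('.' decimal separator).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import DecayHistogram, InstrumentResponse, TimeAxis
from .imaging import FlimCube

__all__ = [
    "write_decay",
    "read_decay",
    "write_irf",
    "read_irf",
    "write_cube",
    "read_cube",
    "write_map",
    "read_map",
    "load_config",
    "dump_config",
    "config_hash",
]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _write_columns(
    path: Path, axis: TimeAxis, values: np.ndarray, header: dict
) -> None:
    lines = [f"# {key} = {value}" for key, value in header.items()]
    lines.append("# columns: time_ns value")
    for t, v in zip(axis.centers, values):
        lines.append(f"{t:.9g}\t{v:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_columns(path: Path) -> tuple[dict, np.ndarray, np.ndarray]:
    meta: dict[str, str] = {}
    times, values = [], []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        try:
            times.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if values[-1] < 0:
            raise ParseError(f"{path}:{lineno}: negative value {values[-1]}")
    return meta, np.asarray(times), np.asarray(values)


def _axis_from_meta(meta: dict, path: Path, n_rows: int) -> TimeAxis:
    try:
        bin_width = float(meta["bin_width_ns"])
        period = float(meta["period_ns"])
        n_bins = int(meta["n_bins"])
    except KeyError as exc:
        raise ParseError(f"{path}: missing header field {exc}") from None
    if n_bins != n_rows:
        raise ParseError(
            f"{path}: header n_bins = {n_bins} but file has {n_rows} data rows"
        )
    if n_bins * bin_width > period * (1 + 1e-9):
        raise ParseError(
            f"{path}: header inconsistent — n_bins * bin_width = "
            f"{n_bins * bin_width} ns exceeds period {period} ns"
        )
    return TimeAxis(bin_width=bin_width, n_bins=n_bins, period=period)


def write_decay(path, decay: DecayHistogram) -> None:
    header = {
        "kind": "decay",
        "bin_width_ns": f"{decay.axis.bin_width:.9g}",
        "period_ns": f"{decay.axis.period:.9g}",
        "n_bins": decay.axis.n_bins,
        "acquisition_time_s": f"{decay.acquisition_time:.9g}",
    }
    if decay.excitation_power is not None:
        header["excitation_power_mw"] = f"{decay.excitation_power:.9g}"
    _write_columns(Path(path), decay.axis, decay.counts, header)


def read_decay(path) -> DecayHistogram:
    path = Path(path)
    meta, _, values = _read_columns(path)
    axis = _axis_from_meta(meta, path, values.size)
    counts = values.astype(np.int64)
    if np.any(counts != values):
        raise ParseError(f"{path}: decay counts must be integers")
    return DecayHistogram(
        axis,
        counts,
        acquisition_time=float(meta.get("acquisition_time_s", 1.0)),
        excitation_power=(
            float(meta["excitation_power_mw"])
            if "excitation_power_mw" in meta
            else None
        ),
    )


def write_irf(path, irf: InstrumentResponse) -> None:
    header = {
        "kind": "irf",
        "bin_width_ns": f"{irf.axis.bin_width:.9g}",
        "period_ns": f"{irf.axis.period:.9g}",
        "n_bins": irf.axis.n_bins,
    }
    _write_columns(Path(path), irf.axis, irf.weights, header)


def read_irf(path) -> InstrumentResponse:
    path = Path(path)
    meta, _, values = _read_columns(path)
    axis = _axis_from_meta(meta, path, values.size)
    return InstrumentResponse(axis, values)


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_cube(path, cube: FlimCube) -> None:
    """Multi-page TIFF (page = time bin) plus a JSON sidecar for metadata."""
    path = Path(path)
    pages = np.moveaxis(cube.counts.astype(np.uint32), 2, 0)
    tifffile.imwrite(path, pages)
    sidecar = {
        "bin_width_ns": cube.axis.bin_width,
        "period_ns": cube.axis.period,
        "n_bins": cube.axis.n_bins,
        "valid_mask": cube.valid_mask.astype(int).tolist(),
    }
    _sidecar(path).write_text(json.dumps(sidecar))


def read_cube(path) -> FlimCube:
    path = Path(path)
    sidecar_path = _sidecar(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"cube sidecar {sidecar_path} not found; cubes are written as a "
            "TIFF plus a '<name>.json' sidecar — keep both files together"
        )
    meta = json.loads(sidecar_path.read_text())
    axis = TimeAxis(
        bin_width=meta["bin_width_ns"],
        n_bins=meta["n_bins"],
        period=meta["period_ns"],
    )
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != axis.n_bins:
        raise ParseError(
            f"{path}: {pages.shape[0]} TIFF pages but sidecar says "
            f"{axis.n_bins} time bins"
        )
    counts = np.moveaxis(pages, 0, 2)
    mask = np.asarray(meta["valid_mask"], dtype=bool)
    return FlimCube(counts, axis, mask)


def write_map(path, array: np.ndarray) -> None:
    """Lifetime/intensity map as 32-bit float TIFF (NaN = undefined pixel)."""
    tifffile.imwrite(Path(path), np.asarray(array, dtype=np.float32))


def read_map(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float64)


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return config


def dump_config(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping, embedded in output artifacts."""
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
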