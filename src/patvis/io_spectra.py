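"""Data model and file I/O for in-line UV-Vis spectral time series.

The universal input of the pipeline is a :class:`SpectrumSeries`: a
time-indexed matrix of transmittance (or absorbance) values on a fixed
wavelength grid, together with per-run metadata (day label, reference API
concentration, extruder settings).

On-disk format is a wide CSV — first column ``time_s``, remaining column
headers numeric wavelengths in nm — with an optional JSON sidecar
(``<name>.meta.json``) holding the :class:`RunMeta` fields.  Instrument
exports are wide tables, so this is the natural interchange format.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "RunMeta",
    "SpectrumSeries",
    "SpectralFormatError",
    "SpectralDataError",
    "read_series",
    "write_series",
    "slice_wavelengths",
]

#: transmittance may exceed 1 by up to this much before being flagged an error
TRANSMITTANCE_NOISE_TOL = 0.05


class SpectralFormatError(ValueError):
    """Malformed spectral file (bad header, ragged rows, non-monotone grid)."""


class SpectralDataError(ValueError):
    """Structurally valid file with physically invalid values."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nm."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise SpectralFormatError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(values) <= 0):
            raise SpectralFormatError(
                "wavelength grid must be strictly increasing with no duplicates"
            )
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def step(self) -> float:
        """Median grid spacing in nm (exactly the spacing on uniform grids)."""
        return float(np.median(np.diff(self.values)))

    def index_range(self, lo_nm: float, hi_nm: float) -> tuple[int, int]:
        """Inclusive index bounds of the sub-grid [lo_nm, hi_nm]."""
        if lo_nm >= hi_nm:
            raise ValueError(f"need lo < hi, got [{lo_nm}, {hi_nm}]")
        if lo_nm < self.values[0] or hi_nm > self.values[-1]:
            raise ValueError(
                f"[{lo_nm}, {hi_nm}] nm outside grid span "
                f"[{self.values[0]}, {self.values[-1]}] nm"
            )
        idx = np.nonzero((self.values >= lo_nm) & (self.values <= hi_nm))[0]
        if idx.size == 0:
            raise ValueError(f"no grid points inside [{lo_nm}, {hi_nm}] nm")
        return int(idx[0]), int(idx[-1])


@dataclass
class RunMeta:
    """Per-run metadata.

    ``true_concentration`` is the off-line HPLC assay value in % w/w and is
    absent (None) for polymer-only reference runs or unknown samples.
    """

    day_id: str = "day1"
    true_concentration: Optional[float] = None
    feed_rate: Optional[float] = None
    screw_speed: Optional[float] = None
    is_polymer_reference: bool = False
    run_id: str = ""

    def __post_init__(self) -> None:
        if self.feed_rate is not None and self.feed_rate <= 0:
            raise ValueError(f"feed_rate must be > 0 g/min, got {self.feed_rate}")
        if self.screw_speed is not None and self.screw_speed <= 0:
            raise ValueError(f"screw_speed must be > 0 rpm, got {self.screw_speed}")
        if self.is_polymer_reference and self.true_concentration not in (None, 0.0):
            raise ValueError("polymer reference run cannot carry an API concentration")

    def to_dict(self) -> dict:
        return {
            "day_id": self.day_id,
            "true_concentration": self.true_concentration,
            "feed_rate": self.feed_rate,
            "screw_speed": self.screw_speed,
            "is_polymer_reference": self.is_polymer_reference,
            "run_id": self.run_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunMeta":
        known = {k: d[k] for k in (
            "day_id", "true_concentration", "feed_rate", "screw_speed",
            "is_polymer_reference", "run_id") if k in d}
        return cls(**known)


@dataclass
class SpectrumSeries:
    """Time series of spectra on a fixed wavelength grid.

    ``values`` has shape ``(n_times, n_wavelengths)``.  ``mode`` is either
    ``"transmittance"`` (unitless fraction, nominally in [0, 1]) or
    ``"absorbance"``.
    """

    grid: WavelengthGrid
    times: np.ndarray
    values: np.ndarray
    mode: str = "transmittance"
    meta: RunMeta = field(default_factory=RunMeta)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise SpectralFormatError("values must be 2-D (n_times x n_wavelengths)")
        if self.values.shape[0] != self.times.size:
            raise SpectralFormatError(
                f"{self.values.shape[0]} spectra but {self.times.size} time stamps"
            )
        if self.values.shape[1] != len(self.grid):
            raise SpectralFormatError(
                f"{self.values.shape[1]} columns but grid has {len(self.grid)} points"
            )
        if np.any(np.diff(self.times) < 0):
            raise SpectralFormatError("time stamps must be non-decreasing")
        if self.mode not in ("transmittance", "absorbance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "transmittance":
            if np.any(self.values < -TRANSMITTANCE_NOISE_TOL):
                raise SpectralDataError(
                    "transmittance below "
                    f"-{TRANSMITTANCE_NOISE_TOL} (min {self.values.min():.4g})"
                )
            n_high = int(np.count_nonzero(self.values > 1.0))
            if n_high and self.values.max() > 1.0 + TRANSMITTANCE_NOISE_TOL:
                warnings.warn(
                    f"{n_high} transmittance values exceed 1 "
                    f"(max {self.values.max():.4g})",
                    stacklevel=2,
                )

    @property
    def n_times(self) -> int:
        return self.times.size

    def copy_with(self, **kwargs) -> "SpectrumSeries":
        """Shallow copy with selected fields replaced."""
        return replace(self, **kwargs)

    def select_rows(self, index: np.ndarray) -> "SpectrumSeries":
        """Sub-series with the given row indices (order preserved)."""
        index = np.asarray(index)
        return self.copy_with(times=self.times[index], values=self.values[index])


def _meta_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def read_series(path: str | Path, dialect: str = "wide-csv") -> SpectrumSeries:
    """Read a wide-CSV spectral series (plus JSON metadata sidecar if present).

    Transmittance stored as percent (any value > 1.5) is auto-detected and
    converted to the fractional scale with a warning.
    """
    if dialect != "wide-csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectralFormatError(f"{path}: {exc}") from exc
    if frame.shape[1] < 2 or frame.columns[0] != "time_s":
        raise SpectralFormatError(
            f"{path}: first column must be 'time_s', got {list(frame.columns[:3])}"
        )
    try:
        wavelengths = np.array([float(c) for c in frame.columns[1:]])
    except ValueError as exc:
        raise SpectralFormatError(f"{path}: non-numeric wavelength header") from exc
    if frame.isna().any().any():
        raise SpectralFormatError(f"{path}: missing values (ragged rows?)")

    grid = WavelengthGrid(wavelengths)
    values = frame.iloc[:, 1:].to_numpy(dtype=float)

    meta = RunMeta()
    mpath = _meta_path(path)
    if mpath.exists():
        meta = RunMeta.from_dict(json.loads(mpath.read_text()))
    if not meta.run_id:
        meta.run_id = path.stem

    mode = "transmittance"
    if mode == "transmittance" and values.size and np.nanmax(values) > 1.5:
        warnings.warn(
            f"{path}: transmittance appears to be in percent "
            f"(max {np.nanmax(values):.3g}); converting to fraction",
            stacklevel=2,
        )
        values = values / 100.0
    return SpectrumSeries(grid=grid, times=frame["time_s"].to_numpy(float),
                          values=values, mode=mode, meta=meta)


def write_series(series: SpectrumSeries, path: str | Path,
                 dialect: str = "wide-csv", float_format: str = "%.10g") -> Path:
    """Write a series as wide CSV + JSON metadata sidecar; returns the CSV path."""
    if dialect != "wide-csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(series.values,
                         columns=[f"{w:g}" for w in series.grid.values])
    frame.insert(0, "time_s", series.times)
    frame.to_csv(path, index=False, float_format=float_format)
    _meta_path(path).write_text(json.dumps(series.meta.to_dict(), indent=1))
    return path


def slice_wavelengths(series: SpectrumSeries, lo_nm: float, hi_nm: float
                      ) -> SpectrumSeries:
    """Restrict to the inclusive wavelength band [lo_nm, hi_nm]; rows unchanged."""
    i0, i1 = series.grid.index_range(lo_nm, hi_nm)
    return series.copy_with(
        grid=WavelengthGrid(series.grid.values[i0:i1 + 1]),
        values=series.values[:, i0:i1 + 1],
    )
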