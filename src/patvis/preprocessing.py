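"""Spectral preprocessing: reference normalisation, absorbance, band selection.

The raw transmittance baseline shifts slightly whenever the instrument is
re-referenced (typically once per experiment day), so each sample spectrum
is divided by the mean steady-state spectrum of a pure-polymer run from
the same day.  Any multiplicative day factor cancels exactly in the ratio.
The normalised transmittance is then converted to absorbance,
A = -log10(T), under which the ratio becomes a baseline subtraction:
A_norm = A_sample - A_reference.

Wavelengths carrying API signal are selected from the first principal
component of the pooled calibration absorbance matrix: the longest
contiguous run of wavelengths whose |PC1 loading| exceeds a fraction of
the maximum |loading|.  On this instrument the useful band is 446-540 nm,
which is the default when selection is bypassed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_spectra import SpectrumSeries, WavelengthGrid
from .steady_state import fit_pca

__all__ = [
    "DEFAULT_BAND",
    "BandSelection",
    "DegenerateReferenceError",
    "normalise_to_reference",
    "to_absorbance",
    "select_band_by_pc1",
]

log = logging.getLogger(__name__)

#: default operating band (nm) when PC1 selection is bypassed
DEFAULT_BAND = (446.0, 540.0)

#: transmittance floor applied before the log transform
TRANSMITTANCE_FLOOR = 1e-6


class DegenerateReferenceError(ValueError):
    """Polymer reference spectrum has near-zero transmittance somewhere."""


def normalise_to_reference(series: SpectrumSeries,
                           polymer_series_same_day: SpectrumSeries,
                           min_reference_spectra: int = 10) -> SpectrumSeries:
    """Divide each sample spectrum by the same-day mean polymer spectrum.

    ``polymer_series_same_day`` should already be restricted to its
    steady-state window; its arithmetic mean spectrum is the reference.
    """
    ref = polymer_series_same_day
    if not np.array_equal(series.grid.values, ref.grid.values):
        raise ValueError("sample and polymer reference grids differ")
    if series.meta.day_id != ref.meta.day_id:
        raise ValueError(
            f"day mismatch: sample from {series.meta.day_id!r}, "
            f"reference from {ref.meta.day_id!r}"
        )
    if series.mode != "transmittance" or ref.mode != "transmittance":
        raise ValueError("normalisation operates on transmittance series")
    if ref.n_times < min_reference_spectra:
        raise ValueError(
            f"polymer reference has {ref.n_times} spectra; "
            f">= {min_reference_spectra} steady-state spectra required"
        )
    mean_ref = ref.values.mean(axis=0)
    if np.any(mean_ref < TRANSMITTANCE_FLOOR):
        raise DegenerateReferenceError(
            f"reference transmittance below {TRANSMITTANCE_FLOOR:g} at "
            f"{int(np.count_nonzero(mean_ref < TRANSMITTANCE_FLOOR))} wavelengths"
        )
    return series.copy_with(values=series.values / mean_ref)


def to_absorbance(series: SpectrumSeries) -> SpectrumSeries:
    """Convert transmittance to absorbance, A = -log10(T).

    Values in (0, floor) are raised to the floor (1e-6) with a logged
    count; values <= 0 are an error — the log transform has no sensible
    continuation there and silent clipping would hide detector problems.
    """
    if series.mode != "transmittance":
        raise ValueError("series is already in absorbance mode")
    T = series.values
    if np.any(T <= 0):
        raise ValueError(
            f"{int(np.count_nonzero(T <= 0))} non-positive transmittance values; "
            "cannot convert to absorbance"
        )
    n_floored = int(np.count_nonzero(T < TRANSMITTANCE_FLOOR))
    if n_floored:
        log.info("flooring %d transmittance values below %g before log",
                 n_floored, TRANSMITTANCE_FLOOR)
        T = np.maximum(T, TRANSMITTANCE_FLOOR)
    return series.copy_with(values=-np.log10(T), mode="absorbance")


@dataclass(frozen=True)
class BandSelection:
    """Contiguous wavelength band selected from PC1 loadings."""

    lo_nm: float
    hi_nm: float
    threshold_fraction: float
    loadings_used: np.ndarray
    evr_full: float        # PC1 explained-variance ratio on the full grid
    evr_band: float        # ... on the selected band

    def to_dict(self) -> dict:
        return {"lo_nm": self.lo_nm, "hi_nm": self.hi_nm,
                "threshold_fraction": self.threshold_fraction,
                "evr_full": self.evr_full, "evr_band": self.evr_band}


def select_band_by_pc1(absorbance_matrix: np.ndarray, grid: WavelengthGrid,
                       threshold_fraction: float = 0.1,
                       min_width_nm: float = 5.0) -> BandSelection:
    """Select the informative wavelength band from PC1 loadings.

    Takes the longest contiguous run of wavelengths with
    ``|loading| >= threshold_fraction * max|loading|``.  The matrix should
    pool spectra across concentration levels, otherwise PC1 is noise.
    """
    X = np.asarray(absorbance_matrix, dtype=float)
    if X.shape[1] != len(grid):
        raise ValueError("matrix column count does not match grid")
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    model = fit_pca(X, n_components=1)
    load = np.abs(model.loadings[0])
    qualifying = load >= threshold_fraction * load.max()
    # longest contiguous run of qualifying wavelengths
    best_len, best = 0, None
    i = 0
    n = load.size
    while i < n:
        if qualifying[i]:
            j = i
            while j + 1 < n and qualifying[j + 1]:
                j += 1
            if j - i + 1 > best_len:
                best_len, best = j - i + 1, (i, j)
            i = j + 1
        else:
            i += 1
    assert best is not None  # max |loading| always qualifies
    i0, i1 = best
    lo, hi = float(grid.values[i0]), float(grid.values[i1])
    if hi - lo < min_width_nm:
        raise ValueError(
            f"selected band [{lo}, {hi}] nm narrower than {min_width_nm} nm"
        )
    evr_full = float(model.explained_variance_ratio[0])
    band_model = fit_pca(X[:, i0:i1 + 1], n_components=1)
    evr_band = float(band_model.explained_variance_ratio[0])
    return BandSelection(lo_nm=lo, hi_nm=hi,
                         threshold_fraction=threshold_fraction,
                         loadings_used=model.loadings[0],
                         evr_full=evr_full, evr_band=evr_band)
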