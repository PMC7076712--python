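"""CIE tristimulus and CIELAB colour computation from transmittance spectra.

The colour of the melt seen through the die window is summarised by the
CIELAB coordinates (L*, a*, b*): L* is lightness, a* spans green-red and
b* spans blue-yellow.  For a yellow API such as piroxicam dispersed in a
colourless polymer, b* grows with drug content, which makes the b* time
trace a convenient in-process steady-state indicator.

Tristimulus values are discrete sums over the visible grid::

    X = k * sum_l T(l) S(l) xbar(l) dl     (likewise Y with ybar, Z with zbar)
    k = 100 / sum_l S(l) ybar(l) dl

so a perfect transmitter (T == 1) has Y = 100 by construction, and any
positive rescaling of the illuminant S cancels out of X, Y, Z.

The packaged default tables use the CIE 1931 2-degree observer via the
multi-lobe Gaussian analytic fit of Wyman, Sloan & Shirley (JCGT 2013)
tabulated at 5 nm from 380 to 780 nm, with a daylight-like illuminant
(6504 K Planckian radiator, 100 at 560 nm).  Absolute Lab values depend on
this observer/illuminant choice; the pipeline only relies on ordering and
linearity of the colour response, which do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_spectra import SpectrumSeries, WavelengthGrid, slice_wavelengths

__all__ = [
    "CIETables",
    "Tristimulus",
    "LabColor",
    "cmf_1931_analytic",
    "planckian_spd",
    "make_cie_tables",
    "load_cie_tables",
    "resample_to_grid",
    "tristimulus",
    "xyz_to_lab",
    "lab_timeseries",
]

_DELTA = 6.0 / 29.0  # CIELAB piecewise-function knee


@dataclass(frozen=True)
class Tristimulus:
    """CIE tristimulus values on the k-normalised scale (T==1 gives Y=100)."""

    X: float
    Y: float
    Z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z])


@dataclass(frozen=True)
class LabColor:
    L_star: float
    a_star: float
    b_star: float


@dataclass(frozen=True)
class CIETables:
    """Colour-matching functions and illuminant on a common visible grid.

    ``white`` is the tristimulus of the perfect transmitter and serves as
    the nominally white object (Xn, Yn, Zn); Yn = 100 by construction of k.
    """

    grid: WavelengthGrid
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray
    S: np.ndarray
    delta_lambda: float

    def __post_init__(self) -> None:
        n = len(self.grid)
        for name in ("xbar", "ybar", "zbar", "S"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} length {arr.shape} != grid length {n}")
            if np.any(arr < -1e-12):
                raise ValueError(f"{name} must be non-negative")
            object.__setattr__(self, name, arr)
        if self.delta_lambda <= 0:
            raise ValueError("delta_lambda must be positive")

    @property
    def k(self) -> float:
        """Normalisation making Y = 100 for the perfect transmitter."""
        return 100.0 / float(np.sum(self.S * self.ybar) * self.delta_lambda)

    @property
    def white(self) -> Tristimulus:
        ones = np.ones(len(self.grid))
        return tristimulus(self.grid.values, ones, self)


def _lobe(lam: np.ndarray, mu: float, s1: float, s2: float) -> np.ndarray:
    sigma = np.where(lam < mu, s1, s2)
    return np.exp(-0.5 * ((lam - mu) / sigma) ** 2)


def cmf_1931_analytic(lam: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CIE 1931 2-degree colour-matching functions, analytic multi-lobe fit.

    Coefficients from Wyman, Sloan & Shirley, "Simple analytic approximations
    to the CIE XYZ color matching functions", JCGT 2(2), 2013.
    """
    lam = np.asarray(lam, dtype=float)
    xbar = (1.056 * _lobe(lam, 599.8, 37.9, 31.0)
            + 0.362 * _lobe(lam, 442.0, 16.0, 26.7)
            - 0.065 * _lobe(lam, 501.1, 20.4, 26.2))
    ybar = (0.821 * _lobe(lam, 568.8, 46.9, 40.5)
            + 0.286 * _lobe(lam, 530.9, 16.3, 31.1))
    zbar = (1.217 * _lobe(lam, 437.0, 11.8, 36.0)
            + 0.681 * _lobe(lam, 459.0, 26.0, 13.8))
    # the x lobe difference can go fractionally negative in the green dip
    return np.clip(xbar, 0.0, None), ybar, zbar


def planckian_spd(lam: np.ndarray, temperature_k: float = 6504.0) -> np.ndarray:
    """Relative spectral power of a Planckian radiator, 100 at 560 nm.

    At 6504 K this is a smooth stand-in for average daylight.
    """
    lam_m = np.asarray(lam, dtype=float) * 1e-9
    c2 = 1.4388e-2  # m K, second radiation constant
    spd = lam_m ** -5 / np.expm1(c2 / (lam_m * temperature_k))
    ref = (560e-9) ** -5 / np.expm1(c2 / (560e-9 * temperature_k))
    return 100.0 * spd / ref


def make_cie_tables(lo_nm: float = 380.0, hi_nm: float = 780.0,
                    delta_lambda: float = 5.0,
                    illuminant: str = "d65a") -> CIETables:
    """Build tables on a uniform visible grid.

    illuminant: "d65a" (6504 K Planckian daylight approximation) or
    "e" (equal energy, S == 100).
    """
    lam = np.arange(lo_nm, hi_nm + delta_lambda / 2, delta_lambda)
    xbar, ybar, zbar = cmf_1931_analytic(lam)
    if illuminant == "d65a":
        S = planckian_spd(lam)
    elif illuminant == "e":
        S = np.full_like(lam, 100.0)
    else:
        raise ValueError(f"unknown illuminant {illuminant!r}")
    return CIETables(grid=WavelengthGrid(lam), xbar=xbar, ybar=ybar,
                     zbar=zbar, S=S, delta_lambda=delta_lambda)


def load_cie_tables(path: Optional[str | Path] = None) -> CIETables:
    """Load tables from CSV (columns wavelength_nm, xbar, ybar, zbar, S).

    Without a path, loads the packaged default table (380-780 nm, 5 nm).
    """
    if path is None:
        with resources.as_file(
            resources.files("patvis").joinpath("data/cie_tables_5nm.csv")
        ) as p:
            return load_cie_tables(p)
    frame = pd.read_csv(path, comment="#")
    lam = frame["wavelength_nm"].to_numpy(float)
    steps = np.diff(lam)
    if not np.allclose(steps, steps[0]):
        raise ValueError("CIE table grid must be uniform")
    return CIETables(
        grid=WavelengthGrid(lam),
        xbar=frame["xbar"].to_numpy(float),
        ybar=frame["ybar"].to_numpy(float),
        zbar=frame["zbar"].to_numpy(float),
        S=frame["S"].to_numpy(float),
        delta_lambda=float(steps[0]),
    )


def resample_to_grid(wavelengths: np.ndarray, values: np.ndarray,
                     tables: CIETables) -> np.ndarray:
    """Resample spectra onto the tables' grid.

    Spectra finer than the table step (e.g. 1 nm instrument data onto a
    5 nm table) are bin-averaged over windows centred on the table
    wavelengths, preserving the discrete-sum structure; coarser or
    non-nesting spectra are linearly interpolated.  Rows are spectra.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    target = tables.grid.values
    if wavelengths[0] > target[0] + 1e-9 or wavelengths[-1] < target[-1] - 1e-9:
        raise ValueError(
            f"spectrum span [{wavelengths[0]}, {wavelengths[-1]}] nm does not "
            f"cover the table grid [{target[0]}, {target[-1]}] nm"
        )
    in_step = float(np.median(np.diff(wavelengths)))
    if in_step < tables.delta_lambda - 1e-9:
        half = tables.delta_lambda / 2.0
        out = np.empty((values.shape[0], target.size))
        for j, lam in enumerate(target):
            sel = (wavelengths >= lam - half) & (wavelengths < lam + half)
            if not np.any(sel):
                raise ValueError(f"no samples in bin around {lam} nm")
            out[:, j] = values[:, sel].mean(axis=1)
        return out
    out = np.empty((values.shape[0], target.size))
    for i in range(values.shape[0]):
        out[i] = np.interp(target, wavelengths, values[i])
    return out


def tristimulus(wavelengths: np.ndarray, transmittance: np.ndarray,
                tables: CIETables) -> Tristimulus:
    """Tristimulus values of one transmittance spectrum.

    The spectrum is resampled to the tables' grid first; it must cover the
    tables' span.
    """
    T = resample_to_grid(wavelengths, transmittance, tables)[0]
    k, dl = tables.k, tables.delta_lambda
    X = k * float(np.sum(T * tables.S * tables.xbar)) * dl
    Y = k * float(np.sum(T * tables.S * tables.ybar)) * dl
    Z = k * float(np.sum(T * tables.S * tables.zbar)) * dl
    return Tristimulus(X, Y, Z)


def _f_piecewise(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA ** 3, np.cbrt(t), t / (3 * _DELTA ** 2) + 4.0 / 29.0)


def xyz_to_lab(tri: Tristimulus, white: Tristimulus,
               convention: str = "piecewise") -> LabColor:
    """CIELAB coordinates from tristimulus values.

    ``convention="piecewise"`` (default) uses the standard CIE function with
    a linear segment below (6/29)^3, so black maps to L* = 0;
    ``convention="cube_root"`` applies plain cube roots (the common printed
    shorthand), under which black maps to L* = -16.
    """
    w = white.as_array()
    if np.any(w <= 0):
        raise ValueError("white point components must be positive")
    ratios = tri.as_array() / w
    if convention == "piecewise":
        fx, fy, fz = _f_piecewise(ratios)
    elif convention == "cube_root":
        fx, fy, fz = np.cbrt(ratios)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return LabColor(
        L_star=float(116.0 * fy - 16.0),
        a_star=float(500.0 * (fx - fy)),
        b_star=float(200.0 * (fy - fz)),
    )


def lab_timeseries(series: SpectrumSeries, tables: Optional[CIETables] = None,
                   convention: str = "piecewise") -> pd.DataFrame:
    """Per-time-point CIELAB coordinates of a transmittance series.

    Returns a DataFrame with columns time_s, L, a, b.  The series is
    restricted to the tables' visible span before resampling.
    """
    if series.mode != "transmittance":
        raise ValueError("lab_timeseries needs a transmittance-mode series")
    if tables is None:
        tables = load_cie_tables()
    lo, hi = tables.grid.values[0], tables.grid.values[-1]
    gv = series.grid.values
    if gv[0] > lo or gv[-1] < hi:
        raise ValueError(
            f"series span [{gv[0]}, {gv[-1]}] nm does not cover the visible "
            f"table range [{lo}, {hi}] nm"
        )
    vis = slice_wavelengths(series, lo, hi)
    T = resample_to_grid(vis.grid.values, vis.values, tables)
    k, dl = tables.k, tables.delta_lambda
    weights = np.vstack([tables.S * tables.xbar,
                         tables.S * tables.ybar,
                         tables.S * tables.zbar]).T  # (n_lam, 3)
    XYZ = k * dl * T @ weights
    white = tables.white
    rows = [xyz_to_lab(Tristimulus(*xyz), white, convention) for xyz in XYZ]
    return pd.DataFrame({
        "time_s": series.times,
        "L": [r.L_star for r in rows],
        "a": [r.a_star for r in rows],
        "b": [r.b_star for r in rows],
    })
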