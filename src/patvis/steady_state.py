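"""Steady-state sample selection for continuous-process spectral series.

During hot-melt extrusion the melt composition drifts for a while after a
feed change (washout of the previous material); spectra collected during
that transition degrade any calibration built on them.  Two monitor
signals are supported:

* ``b_star`` — the CIELAB blue-yellow coordinate, which tracks content of
  a visibly absorbing API directly; and
* ``pc1`` — the first principal-component score of the (mean-centred)
  absorbance matrix, for APIs without a visible-range band.

A plateau is declared where both the rolling least-squares slope and the
rolling standard deviation of the monitor signal, normalised by the
signal's 5-95 percentile range, stay below configurable tolerances for a
minimum run length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d

from .io_spectra import SpectrumSeries
from . import colorimetry

__all__ = [
    "PCAModel",
    "SteadyStateWindow",
    "PlateauParams",
    "NoSteadyStateError",
    "fit_pca",
    "detect_plateau",
    "select_steady_state",
]


class NoSteadyStateError(RuntimeError):
    """No run of samples satisfied the plateau criterion."""


@dataclass
class PCAModel:
    """Mean-centred principal-component decomposition of a spectral matrix.

    ``loadings`` rows are orthonormal; ``scores = (X - mean) @ loadings.T``.
    The sign of each component is fixed so that its largest-magnitude
    loading element is positive, which keeps score traces comparable
    between runs.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray           # (n_components, n_wavelengths)
    scores: np.ndarray             # (n_samples, n_components)
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean_spectrum) @ self.loadings.T

    def reconstruct(self, scores: Optional[np.ndarray] = None) -> np.ndarray:
        s = self.scores if scores is None else scores
        return s @ self.loadings + self.mean_spectrum


def fit_pca(matrix: np.ndarray, n_components: int) -> PCAModel:
    """PCA by SVD of the mean-centred matrix (rows are samples)."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s ** 2))
    if total_var <= 1e-300:
        raise ValueError("matrix has zero variance; PCA undefined")
    # deterministic sign: largest |loading| element positive per component
    for i in range(n_components):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    loadings = Vt[:n_components]
    scores = U[:, :n_components] * s[:n_components]
    evr = (s[:n_components] ** 2) / total_var
    return PCAModel(mean_spectrum=mean, loadings=loadings, scores=scores,
                    explained_variance_ratio=evr)


@dataclass
class PlateauParams:
    """Plateau criterion settings.

    Tolerances are fractions of the signal's 5-95 percentile range:
    rolling OLS slope (per sample) and rolling SD over ``window_len``
    samples must both stay below them for at least ``min_run`` consecutive
    samples.  The SD threshold is additionally floored at
    ``sd_noise_factor`` times the run's noise level (median rolling SD),
    since the rolling SD of a true plateau equals the detector noise and
    can never fall below it.

    Defaults: 60-sample window (120 s at the 0.5 Hz acquisition rate) so
    the slope estimate resolves the smallest level-to-level signal change
    against detector noise, 0.3% slope tolerance, 1% SD tolerance with a
    2.5x noise floor, 30-sample minimum run.
    """

    window_len: int = 60
    rel_slope_tol: float = 0.003
    rel_sd_tol: float = 0.01
    sd_noise_factor: float = 2.5
    min_run: int = 30

    def __post_init__(self) -> None:
        if self.window_len < 3:
            raise ValueError("window_len must be >= 3")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.rel_slope_tol <= 0 or self.rel_sd_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class SteadyStateWindow:
    """Inclusive index window of plateau samples, with per-sample criteria."""

    run_id: str
    start_index: int
    end_index: int
    criterion_values: pd.DataFrame = field(repr=False)

    @property
    def n_kept(self) -> int:
        return self.end_index - self.start_index + 1

    def to_dict(self) -> dict:
        return {"run_id": self.run_id, "window": [self.start_index, self.end_index],
                "n_kept": self.n_kept}


def _window_slope_sd(signal: np.ndarray, window_len: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-window OLS slope and detrended SD, one entry per window start.

    The SD is taken about each window's own least-squares line (residual
    SD): a window sliding over a smooth ramp has a large raw SD even when
    the signal is locally linear, and trend is the slope criterion's job.
    """
    n = signal.size
    w = window_len
    n_win = n - w + 1
    t = np.arange(w) - (w - 1) / 2.0
    stt = float(np.sum(t * t))
    # windowed views: (n_win, w)
    windows = np.lib.stride_tricks.sliding_window_view(signal, w)
    slopes_w = windows @ t / stt
    ss_y = ((windows - windows.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    rss = np.clip(ss_y - slopes_w ** 2 * stt, 0.0, None)
    sds_w = np.sqrt(rss / (w - 2))
    return slopes_w, sds_w


def detect_plateau(signal: np.ndarray, params: Optional[PlateauParams] = None,
                   run_id: str = "") -> Optional[SteadyStateWindow]:
    """Find the trailing plateau of a monitor signal.

    The slope criterion is attributed to the window centre — it asks
    whether the signal is still moving *at* that sample, so the plateau
    onset tracks where the local derivative falls within tolerance.  The
    SD criterion uses the best (smallest detrended SD) window containing
    the sample — a sample that belongs to some locally quiet window is
    not itself irregular, and centre attribution would smear washout
    curvature half a window into the plateau.  Returns the last run of
    >= ``min_run`` consecutive in-plateau samples, or None when no such
    run exists (an explicit no-steady-state outcome).
    """
    params = params or PlateauParams()
    x = np.asarray(signal, dtype=float).ravel()
    w = params.window_len
    if x.size <= w:
        raise ValueError(
            f"signal length {x.size} must exceed window_len {w}"
        )
    n = x.size
    lo, hi = np.percentile(x, [5, 95])
    span = hi - lo
    slopes_w, sds_w = _window_slope_sd(x, w)
    n_win = slopes_w.size
    noise_floor = float(np.median(sds_w))
    # slope: centre attribution (edge samples reuse the nearest window)
    centre_idx = np.clip(np.arange(n) - (w - 1) // 2, 0, n_win - 1)
    slope_at = np.abs(slopes_w)[centre_idx]
    # SD: minimum over the windows containing the sample
    # (window j covers samples j .. j+w-1)
    pad_sd = np.full(n, np.inf)
    pad_sd[:n_win] = sds_w
    best_sd = minimum_filter1d(pad_sd, size=w, mode="constant", cval=np.inf,
                               origin=(w - 1) // 2)
    if span <= max(1e-12 * max(1.0, abs(hi)), 5.0 * noise_floor):
        # trendless signal: the whole-run excursion is within the noise
        # level, so there is no washout to wait out — all samples qualify
        ok = np.ones(n, dtype=bool)
        rel_slope = np.zeros(n)
        rel_sd = np.zeros(n)
    else:
        rel_slope = slope_at / span
        rel_sd = best_sd / span
        sd_limit = max(params.rel_sd_tol,
                       params.sd_noise_factor * noise_floor / span)
        ok = (rel_slope <= params.rel_slope_tol) & (rel_sd <= sd_limit)
    crit = pd.DataFrame({"rel_slope": rel_slope, "rel_sd": rel_sd, "ok": ok})
    # trailing run search: last maximal run of True with length >= min_run
    best: Optional[tuple[int, int]] = None
    i = 0
    n = x.size
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            if j - i + 1 >= params.min_run:
                best = (i, j)
            i = j + 1
        else:
            i += 1
    if best is None:
        return None
    return SteadyStateWindow(run_id=run_id, start_index=best[0],
                             end_index=best[1], criterion_values=crit)


def select_steady_state(series: SpectrumSeries, method: str = "b_star",
                        params: Optional[PlateauParams] = None,
                        tables: Optional["colorimetry.CIETables"] = None,
                        pca: Optional[PCAModel] = None,
                        ) -> tuple[SpectrumSeries, SteadyStateWindow]:
    """Keep only the plateau rows of a run.

    method "b_star" monitors the CIELAB b* trace (transmittance series);
    method "pc1" monitors the first principal-component score of the
    series' values (absorbance recommended), using ``pca`` if given or
    fitting one on the run itself.

    Raises :class:`NoSteadyStateError` when no plateau is found.
    """
    if method == "b_star":
        lab = colorimetry.lab_timeseries(series, tables=tables)
        signal = lab["b"].to_numpy()
    elif method == "pc1":
        if pca is None:
            pca = fit_pca(series.values, n_components=1)
            signal = pca.scores[:, 0]
        else:
            signal = pca.transform(series.values)[:, 0]
    else:
        raise ValueError(f"unknown method {method!r}")
    window = detect_plateau(signal, params=params, run_id=series.meta.run_id)
    if window is None:
        raise NoSteadyStateError(
            f"run {series.meta.run_id!r}: no steady-state plateau found "
            f"({method} monitor)"
        )
    kept = series.select_rows(np.arange(window.start_index, window.end_index + 1))
    return kept, window
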