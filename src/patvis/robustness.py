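"""Robustness DoE evaluation, response-surface fit and MODR extraction.

Robustness is probed with a small design of experiments over feed rate
(g/min) and screw speed (rpm) at fixed nominal drug load: each run's mean
predicted content is compared with the reference assay value and flagged
when its relative bias exceeds the ATP limit.  A full quadratic response
surface

    yhat(f, s) = b0 + b1 f + b2 s + b3 f^2 + b4 s^2 + b5 f s

is fitted to the mean predicted contents by ordinary least squares, and
the method operable design region (MODR) is the set of (f, s) settings
whose surface prediction stays inside the content limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DoERun",
    "ResponseSurface",
    "MODR",
    "evaluate_doe",
    "fit_response_surface",
    "extract_modr",
]

_TERMS = ("const", "feed_rate", "screw_speed", "feed_rate^2",
          "screw_speed^2", "feed_rate*screw_speed")


@dataclass
class DoERun:
    """One robustness run: settings, reference value and model output."""

    true_conc: float
    feed_rate: float
    screw_speed: float
    mean_predicted: float
    relative_bias: float = field(init=False)
    flagged: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.true_conc <= 0:
            raise ValueError("true concentration must be positive")
        self.relative_bias = (
            100.0 * (self.mean_predicted - self.true_conc) / self.true_conc
        )


def evaluate_doe(runs: Sequence[DoERun], atp_bias_limit: float = 2.0
                 ) -> list[DoERun]:
    """Flag runs whose |relative bias| exceeds the ATP limit (percent)."""
    if len(runs) < 3:
        raise ValueError("need at least 3 DoE runs")
    for run in runs:
        run.flagged = abs(run.relative_bias) > atp_bias_limit
    return list(runs)


def _design_matrix(f: np.ndarray, s: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(f), f, s, f ** 2, s ** 2, f * s])


@dataclass
class ResponseSurface:
    """Full quadratic OLS surface over (feed_rate, screw_speed)."""

    coefficients: np.ndarray          # ordered as _TERMS
    r_squared: float
    residuals: np.ndarray
    feed_range: tuple[float, float]
    speed_range: tuple[float, float]

    def predict(self, feed_rate, screw_speed) -> np.ndarray:
        f = np.asarray(feed_rate, dtype=float)
        s = np.asarray(screw_speed, dtype=float)
        shape = np.broadcast_shapes(f.shape, s.shape)
        f, s = np.broadcast_to(f, shape).ravel(), np.broadcast_to(s, shape).ravel()
        out = _design_matrix(f, s) @ self.coefficients
        return out.reshape(shape) if shape else float(out[0])

    def to_dict(self) -> dict:
        return {"terms": dict(zip(_TERMS, self.coefficients.tolist())),
                "r_squared": self.r_squared,
                "feed_range": list(self.feed_range),
                "speed_range": list(self.speed_range)}


def fit_response_surface(runs: Sequence[DoERun]) -> ResponseSurface:
    """OLS fit of the 6-term quadratic to mean predicted content."""
    f = np.array([r.feed_rate for r in runs], dtype=float)
    s = np.array([r.screw_speed for r in runs], dtype=float)
    y = np.array([r.mean_predicted for r in runs], dtype=float)
    if len(runs) < 6:
        raise ValueError("need at least 6 distinct design points for 6 terms")
    X = _design_matrix(f, s)
    rank = np.linalg.matrix_rank(X)
    if rank < 6:
        # name the terms whose removal restores full column rank
        missing = [
            _TERMS[j] for j in range(6)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; cannot estimate {missing}")
    fit = sm.OLS(y, X).fit()
    return ResponseSurface(
        coefficients=np.asarray(fit.params, dtype=float),
        r_squared=float(fit.rsquared),
        residuals=np.asarray(fit.resid, dtype=float),
        feed_range=(float(f.min()), float(f.max())),
        speed_range=(float(s.min()), float(s.max())),
    )


@dataclass
class MODR:
    """Grid classification of the operable region plus per-feed corners."""

    feed_grid: np.ndarray
    speed_grid: np.ndarray
    predicted: np.ndarray      # (n_feed, n_speed)
    passes: np.ndarray         # boolean, same shape
    lower_limit: float
    upper_limit: float

    @property
    def is_empty(self) -> bool:
        return not bool(self.passes.any())

    def contains(self, feed_rate: float, screw_speed: float) -> bool:
        i = int(np.argmin(np.abs(self.feed_grid - feed_rate)))
        j = int(np.argmin(np.abs(self.speed_grid - screw_speed)))
        return bool(self.passes[i, j])

    def corner_table(self) -> pd.DataFrame:
        """Per-feed-rate lower/upper screw-speed bounds of the pass set."""
        records = []
        for i, f in enumerate(self.feed_grid):
            idx = np.nonzero(self.passes[i])[0]
            if idx.size == 0:
                records.append({"feed_rate": f, "speed_lower": np.nan,
                                "speed_upper": np.nan})
            else:
                records.append({"feed_rate": f,
                                "speed_lower": self.speed_grid[idx[0]],
                                "speed_upper": self.speed_grid[idx[-1]]})
        return pd.DataFrame(records)

    def to_frame(self) -> pd.DataFrame:
        ff, ss = np.meshgrid(self.feed_grid, self.speed_grid, indexing="ij")
        return pd.DataFrame({
            "feed_rate": ff.ravel(),
            "screw_speed": ss.ravel(),
            "predicted": self.predicted.ravel(),
            "within_limits": self.passes.ravel(),
        })


def extract_modr(surface: ResponseSurface,
                 lower: float = 14.15, upper: float = 14.75,
                 feed_step: float = 0.05, speed_step: float = 1.0) -> MODR:
    """Classify a dense (feed, speed) grid against the content limits.

    Defaults correspond to a 14.45 % w/w nominal load with the ATP's
    +/- 2% bias limit.  The domain is the fitted design's range.
    """
    if lower >= upper:
        raise ValueError("limits must satisfy lower < upper")
    f0, f1 = surface.feed_range
    s0, s1 = surface.speed_range
    feed_grid = np.arange(f0, f1 + feed_step / 2, feed_step)
    speed_grid = np.arange(s0, s1 + speed_step / 2, speed_step)
    pred = surface.predict(feed_grid[:, None], speed_grid[None, :])
    # boundary equality counts as inside; guard against fit round-off
    atol = 1e-9 * max(1.0, abs(lower), abs(upper))
    passes = (pred >= lower - atol) & (pred <= upper + atol)
    return MODR(feed_grid=feed_grid, speed_grid=speed_grid, predicted=pred,
                passes=passes, lower_limit=lower, upper_limit=upper)
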