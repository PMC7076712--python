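"""Accuracy-profile method validation (trueness, precision, tolerance limits).

The validation design is balanced: p series (days) x n replicate
predictions at each of several concentration levels with known reference
values.  Per level the module computes

* trueness: relative bias and recovery of the mean prediction;
* precision: repeatability and intermediate-precision variances from the
  one-way random-effects analysis of variance (method of moments),
  reported as RSDs referenced to the mean predicted concentration;
* the 95% beta-expectation tolerance interval in the Mee form with
  Satterthwaite degrees of freedom — the interval expected to contain a
  proportion beta of future single measurements;
* total error |bias| + s_IP, and the uncertainty budget (uncertainty of
  the bias, measurement uncertainty, expanded uncertainty with k = 2).

The method passes when every level's tolerance interval lies inside the
acceptance band +/- lambda; the limit of quantitation is the lowest
passing level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ATPSpec",
    "LevelData",
    "VarianceComponents",
    "AccuracyProfileRow",
    "AccuracyProfile",
    "variance_components",
    "trueness",
    "tolerance_limits",
    "total_error",
    "uncertainty",
    "build_accuracy_profile",
    "check_atp",
    "round_half_away",
    "relative_total_error",
    "absolute_total_error",
    "profile_rows_from_summary",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ATPSpec:
    """Analytical target profile: the method's predefined acceptance limits."""

    bias_limit: float = 2.0          # max |mean relative bias|, %
    rsd_limit: float = 1.8           # max RSD (repeatability and IP), %
    acceptance_lambda: float = 5.0   # accuracy-profile acceptance band, +/- %
    beta: float = 0.95               # tolerance-interval expectation proportion

    def __post_init__(self) -> None:
        if min(self.bias_limit, self.rsd_limit, self.acceptance_lambda) <= 0:
            raise ValueError("ATP limits must be positive")
        if not 0 < self.beta < 1:
            raise ValueError("beta must be in (0, 1)")


@dataclass
class LevelData:
    """Balanced p x n prediction matrix at one concentration level."""

    true_conc: float
    predictions: np.ndarray   # shape (p, n): rows are series/days

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions, dtype=float)
        if self.predictions.ndim != 2:
            raise ValueError("predictions must be a p x n matrix")
        if self.true_conc <= 0:
            raise ValueError("true concentration must be positive")

    @property
    def p(self) -> int:
        return self.predictions.shape[0]

    @property
    def n(self) -> int:
        return self.predictions.shape[1]

    @property
    def mean_predicted(self) -> float:
        return float(self.predictions.mean())

    @property
    def day_means(self) -> np.ndarray:
        return self.predictions.mean(axis=1)


@dataclass(frozen=True)
class VarianceComponents:
    """Repeatability / between-series variance components, in (% w/w)^2."""

    s2_r: float
    s2_B: float

    @property
    def s2_IP(self) -> float:
        return self.s2_r + self.s2_B

    @property
    def R(self) -> float:
        """Between/within variance ratio; inf when s2_r = 0 and s2_B > 0."""
        if self.s2_r == 0.0:
            return math.inf if self.s2_B > 0 else 0.0
        return self.s2_B / self.s2_r


def variance_components(level: LevelData) -> VarianceComponents:
    """One-way random-effects ANOVA estimates (method of moments).

    MS_within is the pooled within-day variance; the between-day component
    is (MS_between - MS_within) / n, clipped at zero when the moment
    estimate goes negative.
    """
    Y = level.predictions
    p, n = level.p, level.n
    if p < 2:
        raise ValueError("need at least 2 series to separate variance components")
    if n < 2:
        raise ValueError("need at least 2 replicates per series")
    ms_within = float(Y.var(axis=1, ddof=1).mean())
    ms_between = float(n * Y.mean(axis=1).var(ddof=1))
    s2_B = (ms_between - ms_within) / n
    if s2_B < 0:
        log.info("between-series moment estimate %.3g < 0; clipped to 0", s2_B)
        s2_B = 0.0
    return VarianceComponents(s2_r=ms_within, s2_B=s2_B)


def trueness(level: LevelData) -> tuple[float, float]:
    """(relative bias %, recovery %) of the mean prediction."""
    rel_bias = 100.0 * (level.mean_predicted - level.true_conc) / level.true_conc
    return rel_bias, 100.0 + rel_bias


def _mee_interval_factors(vc: VarianceComponents, p: int, n: int, beta: float
                          ) -> tuple[float, float]:
    """(t quantile, widening factor sqrt(1 + 1/(p n B^2))) for the interval.

    B^2 = (R + 1) / (n R + 1) and the degrees of freedom are the
    Satterthwaite approximation for the intermediate-precision variance;
    R = inf (pure between-series variance) is handled by its limit
    (B^2 -> 1/n, df -> p - 1).
    """
    R = vc.R
    if math.isinf(R):
        B2 = 1.0 / n
        df = float(p - 1)
    else:
        B2 = (R + 1.0) / (n * R + 1.0)
        df = (R + 1.0) ** 2 / (
            (R + 1.0 / n) ** 2 / (p - 1) + (1.0 - 1.0 / n) / (p * n)
        )
    t_quant = float(stats.t.ppf((1.0 + beta) / 2.0, df))
    widen = math.sqrt(1.0 + 1.0 / (p * n * B2))
    return t_quant, widen


def tolerance_limits(level: LevelData, vc: Optional[VarianceComponents] = None,
                     beta: float = 0.95) -> tuple[float, float]:
    """Relative beta-expectation tolerance limits, % of the true value.

    Computed in absolute units as mean +/- t_(nu,(1+beta)/2) *
    sqrt(1 + 1/(p n B^2)) * s_IP, then expressed relative to the true
    concentration.  A zero-variance level degenerates to [bias, bias].
    """
    if level.p < 2:
        raise ValueError("tolerance limits need at least 2 series")
    if vc is None:
        vc = variance_components(level)
    rel_bias, _ = trueness(level)
    s_ip = math.sqrt(vc.s2_IP)
    if s_ip == 0.0:
        return rel_bias, rel_bias
    t_quant, widen = _mee_interval_factors(vc, level.p, level.n, beta)
    half_abs = t_quant * widen * s_ip
    half_rel = 100.0 * half_abs / level.true_conc
    return rel_bias - half_rel, rel_bias + half_rel


def total_error(level: LevelData, vc: Optional[VarianceComponents] = None
                ) -> tuple[float, float]:
    """(absolute total error % w/w, relative total error %).

    Total error combines the systematic and random parts:
    |bias| + s_IP absolute, |relative bias| + RSD_IP relative, with the
    RSD referenced to the mean predicted concentration.
    """
    if vc is None:
        vc = variance_components(level)
    rel_bias, _ = trueness(level)
    s_ip = math.sqrt(vc.s2_IP)
    abs_err = abs(level.mean_predicted - level.true_conc) + s_ip
    rsd_ip = 100.0 * s_ip / level.mean_predicted
    return abs_err, abs(rel_bias) + rsd_ip


def uncertainty(level: LevelData, vc: Optional[VarianceComponents] = None,
                k_coverage: float = 2.0) -> tuple[float, float, float]:
    """(u_bias, u_Y, U_Y) in % w/w.

    u_bias^2 = s2_B/p + s2_r/(p n) is the variance of the level mean;
    u_Y^2 = u_bias^2 + s2_IP combines it with a single future measurement;
    U_Y = k * u_Y is the expanded uncertainty.
    """
    if vc is None:
        vc = variance_components(level)
    u_bias = math.sqrt(vc.s2_B / level.p + vc.s2_r / (level.p * level.n))
    u_y = math.sqrt(u_bias ** 2 + vc.s2_IP)
    return u_bias, u_y, k_coverage * u_y


@dataclass
class AccuracyProfileRow:
    """Per-level validation statistics (percent quantities are % of scale)."""

    level: float
    mean_predicted: float
    relative_bias: float
    recovery: float
    rsd_repeatability: float
    rsd_IP: float
    tolerance_low: float
    tolerance_high: float
    abs_total_error: float
    rel_total_error: float
    u_bias: float
    u_Y: float
    U_Y: float
    within_acceptance: bool


@dataclass
class AccuracyProfile:
    rows: list[AccuracyProfileRow]
    atp: ATPSpec
    passes: bool
    loq: Optional[float]     # lowest passing level, None when all fail

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "true_conc": r.level,
            "mean_predicted": r.mean_predicted,
            "relative_bias_pct": r.relative_bias,
            "recovery_pct": r.recovery,
            "rsd_repeatability_pct": r.rsd_repeatability,
            "rsd_ip_pct": r.rsd_IP,
            "tolerance_low_pct": r.tolerance_low,
            "tolerance_high_pct": r.tolerance_high,
            "abs_total_error": r.abs_total_error,
            "rel_total_error_pct": r.rel_total_error,
            "u_bias": r.u_bias,
            "u_Y": r.u_Y,
            "U_Y": r.U_Y,
            "within_acceptance": r.within_acceptance,
        } for r in self.rows])


def build_accuracy_profile(levels: Sequence[LevelData],
                           atp: ATPSpec = ATPSpec()) -> AccuracyProfile:
    """Full accuracy profile over the validated levels.

    The method passes when every level's tolerance interval lies inside
    [-lambda, +lambda]; the limit of quantitation is the lowest passing
    level.
    """
    if len(levels) < 2:
        raise ValueError("an accuracy profile needs at least 2 levels")
    rows = []
    for level in sorted(levels, key=lambda s: s.true_conc):
        vc = variance_components(level)
        rel_bias, recovery = trueness(level)
        lo, hi = tolerance_limits(level, vc, beta=atp.beta)
        abs_err, rel_err = total_error(level, vc)
        u_b, u_y, u_exp = uncertainty(level, vc)
        lam = atp.acceptance_lambda
        rows.append(AccuracyProfileRow(
            level=level.true_conc,
            mean_predicted=level.mean_predicted,
            relative_bias=rel_bias,
            recovery=recovery,
            rsd_repeatability=100.0 * math.sqrt(vc.s2_r) / level.mean_predicted,
            rsd_IP=100.0 * math.sqrt(vc.s2_IP) / level.mean_predicted,
            tolerance_low=lo,
            tolerance_high=hi,
            abs_total_error=abs_err,
            rel_total_error=rel_err,
            u_bias=u_b,
            u_Y=u_y,
            U_Y=u_exp,
            within_acceptance=(lo >= -lam) and (hi <= lam),
        ))
    passing = [r.level for r in rows if r.within_acceptance]
    return AccuracyProfile(
        rows=rows, atp=atp,
        passes=all(r.within_acceptance for r in rows),
        loq=min(passing) if passing else None,
    )


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (report convention; banker's rounding off)."""
    q = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5), x) / q


def relative_total_error(relative_bias_pct: float, rsd_ip_pct: float) -> float:
    """Relative total error (%) from summary statistics: |bias| + RSD_IP."""
    return abs(relative_bias_pct) + rsd_ip_pct


def absolute_total_error(true_conc: float, mean_predicted: float,
                         rsd_ip_pct: float) -> float:
    """Absolute total error (% w/w) from summary statistics.

    |mean - true| plus the intermediate-precision SD expressed in
    concentration units via the mean predicted concentration.
    """
    return abs(mean_predicted - true_conc) + rsd_ip_pct / 100.0 * mean_predicted


def profile_rows_from_summary(summary: pd.DataFrame) -> list[AccuracyProfileRow]:
    """Rebuild profile rows from a per-level summary table.

    Expects columns true_conc, mean_predicted, relative_bias_pct,
    recovery_pct, rsd_repeatability_pct, rsd_ip_pct and (optionally) the
    tolerance-limit columns — the layout the accuracy-profile CSV export
    uses, also the layout published validation summaries come in.
    Error/uncertainty fields are recomputed where derivable; fields that
    need raw predictions are NaN.
    """
    rows = []
    for r in summary.itertuples():
        lo = getattr(r, "tolerance_low_pct", math.nan)
        hi = getattr(r, "tolerance_high_pct", math.nan)
        rows.append(AccuracyProfileRow(
            level=r.true_conc,
            mean_predicted=r.mean_predicted,
            relative_bias=r.relative_bias_pct,
            recovery=getattr(r, "recovery_pct", 100.0 + r.relative_bias_pct),
            rsd_repeatability=r.rsd_repeatability_pct,
            rsd_IP=r.rsd_ip_pct,
            tolerance_low=lo,
            tolerance_high=hi,
            abs_total_error=absolute_total_error(
                r.true_conc, r.mean_predicted, r.rsd_ip_pct),
            rel_total_error=relative_total_error(
                r.relative_bias_pct, r.rsd_ip_pct),
            u_bias=math.nan, u_Y=math.nan, U_Y=math.nan,
            within_acceptance=bool(not (math.isnan(lo) or math.isnan(hi))
                                   and lo >= -5.0 and hi <= 5.0),
        ))
    return rows


@dataclass
class ATPReport:
    max_abs_bias: float
    max_rsd_repeatability: float
    max_rsd_IP: float
    bias_ok: bool
    rsd_ok: bool
    offending_levels: list[float]

    @property
    def passes(self) -> bool:
        return self.bias_ok and self.rsd_ok


def check_atp(rows: Sequence[AccuracyProfileRow], atp: ATPSpec = ATPSpec()
              ) -> ATPReport:
    """Check trueness/precision ATP criteria over profile rows."""
    if not rows:
        raise ValueError("no profile rows to check")
    offending = [
        r.level for r in rows
        if abs(r.relative_bias) > atp.bias_limit
        or r.rsd_repeatability > atp.rsd_limit
        or r.rsd_IP > atp.rsd_limit
    ]
    max_bias = max(abs(r.relative_bias) for r in rows)
    max_rsd_r = max(r.rsd_repeatability for r in rows)
    max_rsd_ip = max(r.rsd_IP for r in rows)
    return ATPReport(
        max_abs_bias=max_bias,
        max_rsd_repeatability=max_rsd_r,
        max_rsd_IP=max_rsd_ip,
        bias_ok=max_bias <= atp.bias_limit,
        rsd_ok=max(max_rsd_r, max_rsd_ip) <= atp.rsd_limit,
        offending_levels=offending,
    )
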