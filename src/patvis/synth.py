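"""Synthetic in-line UV-Vis campaigns with known ground truth.

The generator emulates the features of melt-extrusion transmittance data
that the pipeline must cope with, each with a known true value so every
stage is testable:

* a single Gaussian absorber band in the blue-green region (centre 490 nm,
  SD 25 nm) whose Beer-Lambert absorbance scales linearly with drug
  content — about 1 AU at the band centre for 15 % w/w;
* a smooth, weakly absorbing polymer transmittance baseline;
* first-order washout between concentration levels,
  c(t) = c_target + (c_start - c_target) exp(-t / tau), mimicking mixing
  in the melt line after a feed change;
* a broad baseline tilt while the composition is changing (inhomogeneous
  melt during washout) — off-axis spectral variance that steady-state
  filtering is there to remove;
* a multiplicative per-day gain (lognormal, sigma 0.02) standing in for
  day-to-day re-referencing shifts — exactly what polymer normalisation
  is meant to cancel; and
* additive detector noise on transmittance (SD 0.002).

Validation campaigns additionally inject day and replicate effects as
concentration-equivalent shifts, so the downstream variance components
are analytically known.  Campaign generation is bit-reproducible given
the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .io_spectra import RunMeta, SpectrumSeries, WavelengthGrid, read_series, write_series
from .robustness import DoERun

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "Campaign",
    "CALIBRATION_LEVELS",
    "VALIDATION_LEVELS",
    "DOE_DESIGN",
    "simulate_run",
    "simulate_calibration_campaign",
    "simulate_validation_campaign",
    "simulate_doe",
    "read_campaign",
]

#: study calibration levels, % w/w
CALIBRATION_LEVELS = (10.58, 12.46, 14.45, 16.54, 18.46)
#: study validation levels, % w/w
VALIDATION_LEVELS = (11.66, 13.45, 15.45, 17.50)
#: robustness design: (feed g/min, speed rpm), 3 x 3 plus centre duplicate
DOE_DESIGN = ((5, 150), (5, 200), (5, 250),
              (7, 150), (7, 200), (7, 200), (7, 250),
              (9, 150), (9, 200), (9, 250))


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults are the emulated study conditions."""

    band_center: float = 490.0        # nm
    band_sd: float = 25.0             # nm
    epsilon_scale: float = 1.0 / 15.0  # absorbance per % w/w at band centre
    path_length: float = 1.0          # relative units, folds into epsilon
    polymer_t_lo: float = 0.2         # UV-side polymer transmittance
    polymer_t_hi: float = 0.95        # red-side polymer transmittance
    polymer_t_mid: float = 300.0      # logistic midpoint, nm
    polymer_t_width: float = 30.0     # logistic width, nm
    day_gain_sigma: float = 0.02      # lognormal sigma of the per-day gain
    noise_sd: float = 0.002           # additive transmittance noise
    washout_tau: float = 20.0         # washout time constant, samples
    transition_disturbance: float = 0.02  # peak off-axis absorbance during washout
    sampling_hz: float = 0.5
    grid_lo: float = 230.0            # nm
    grid_hi: float = 816.0            # nm
    grid_step: float = 1.0            # nm
    steady_rel_tol: float = 0.005     # |c - target| < tol * target => steady
    seed: int = 0

    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(
            np.arange(self.grid_lo, self.grid_hi + self.grid_step / 2,
                      self.grid_step)
        )

    def epsilon(self, wavelengths: np.ndarray) -> np.ndarray:
        """Molar-absorptivity-like band shape, absorbance per % w/w."""
        lam = np.asarray(wavelengths, dtype=float)
        return (self.epsilon_scale * self.path_length
                * np.exp(-0.5 * ((lam - self.band_center) / self.band_sd) ** 2))

    def polymer_transmittance(self, wavelengths: np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        rise = 1.0 / (1.0 + np.exp(-(lam - self.polymer_t_mid)
                                   / self.polymer_t_width))
        return self.polymer_t_lo + (self.polymer_t_hi - self.polymer_t_lo) * rise


@dataclass
class GroundTruth:
    """Per-sample truth attached to a simulated run."""

    concentration: np.ndarray        # scheduled concentration, % w/w
    effective_concentration: np.ndarray  # after injected shifts, % w/w
    steady: np.ndarray               # boolean labels
    target_concentration: float
    day_gain: float
    band_center: float
    band_sd: float

    def to_dict(self) -> dict:
        return {
            "concentration": self.concentration.tolist(),
            "effective_concentration": self.effective_concentration.tolist(),
            "steady": self.steady.astype(int).tolist(),
            "target_concentration": self.target_concentration,
            "day_gain": self.day_gain,
            "band_center": self.band_center,
            "band_sd": self.band_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            concentration=np.asarray(d["concentration"], float),
            effective_concentration=np.asarray(
                d["effective_concentration"], float),
            steady=np.asarray(d["steady"], int).astype(bool),
            target_concentration=float(d["target_concentration"]),
            day_gain=float(d["day_gain"]),
            band_center=float(d["band_center"]),
            band_sd=float(d["band_sd"]),
        )


def simulate_run(config: SynthConfig, target_conc: float, n_samples: int,
                 start_conc: float = 0.0, day_gain: float = 1.0,
                 rng: Optional[np.random.Generator] = None,
                 conc_shift_pct: Optional[np.ndarray] = None,
                 meta: Optional[RunMeta] = None,
                 ) -> tuple[SpectrumSeries, GroundTruth]:
    """Simulate one run: washout from ``start_conc`` towards ``target_conc``.

    ``conc_shift_pct`` (per-sample, percent of the scheduled concentration)
    injects bias / day / replicate effects in concentration units.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = rng or np.random.default_rng(config.seed)
    grid = config.grid()
    lam = grid.values
    t_idx = np.arange(n_samples, dtype=float)
    c_sched = target_conc + (start_conc - target_conc) * np.exp(
        -t_idx / config.washout_tau)
    if conc_shift_pct is None:
        c_eff = c_sched.copy()
    else:
        shifts = np.asarray(conc_shift_pct, dtype=float)
        if shifts.shape != (n_samples,):
            raise ValueError("conc_shift_pct must have one entry per sample")
        c_eff = c_sched * (1.0 + shifts / 100.0)
    if target_conc > 0:
        steady = np.abs(c_sched - target_conc) < config.steady_rel_tol * target_conc
    else:
        # washing out to pure polymer: steady once the residue is negligible
        steady = np.abs(c_sched) < max(1e-9, config.steady_rel_tol * start_conc)
        if start_conc == 0.0:
            steady = np.ones(n_samples, dtype=bool)
    absorbance = np.outer(c_eff, config.epsilon(lam))
    if config.transition_disturbance > 0 and target_conc != start_conc:
        # melt inhomogeneity while the composition changes: a broad
        # baseline tilt, decaying with the remaining washout fraction —
        # off-axis spectral variance that steady-state filtering removes
        washed = np.abs(c_sched - target_conc) / abs(start_conc - target_conc)
        tilt = np.linspace(-1.0, 1.0, lam.size)
        absorbance = absorbance + config.transition_disturbance * np.outer(
            washed, tilt)
    T = day_gain * config.polymer_transmittance(lam)[None, :] * 10.0 ** (-absorbance)
    if config.noise_sd > 0:
        T = T + rng.normal(0.0, config.noise_sd, size=T.shape)
        T = np.clip(T, 1e-9, None)
    series = SpectrumSeries(
        grid=grid,
        times=t_idx / config.sampling_hz,
        values=T,
        mode="transmittance",
        meta=meta or RunMeta(),
    )
    truth = GroundTruth(
        concentration=c_sched, effective_concentration=c_eff, steady=steady,
        target_concentration=target_conc, day_gain=day_gain,
        band_center=config.band_center, band_sd=config.band_sd,
    )
    return series, truth


def _transition_length(config: SynthConfig, start: float, target: float) -> int:
    """Samples until the washout schedule first counts as steady."""
    gap = abs(start - target)
    if gap == 0 or target <= 0:
        return 0
    tol = config.steady_rel_tol * target
    if gap <= tol:
        return 0
    return int(math.ceil(config.washout_tau * math.log(gap / tol))) + 1


@dataclass
class Campaign:
    """A set of simulated runs (per-day polymer references + sample runs)."""

    kind: str
    config: SynthConfig
    polymer_runs: dict[str, tuple[SpectrumSeries, GroundTruth]]
    sample_runs: list[tuple[SpectrumSeries, GroundTruth]]

    def runs_for_day(self, day_id: str) -> list[tuple[SpectrumSeries, GroundTruth]]:
        return [(s, g) for s, g in self.sample_runs if s.meta.day_id == day_id]

    @property
    def day_ids(self) -> list[str]:
        return list(self.polymer_runs)

    def write(self, out_dir: str | Path) -> Path:
        """Write every run as wide CSV + metadata + truth JSON plus a manifest."""
        out = Path(out_dir)
        runs_dir = out / "runs"
        runs_dir.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"kind": self.kind, "config": asdict(self.config),
                          "polymer": {}, "samples": []}
        for day_id, (series, truth) in self.polymer_runs.items():
            write_series(series, runs_dir / f"{series.meta.run_id}.csv")
            (runs_dir / f"{series.meta.run_id}.truth.json").write_text(
                json.dumps(truth.to_dict()))
            manifest["polymer"][day_id] = series.meta.run_id
        for series, truth in self.sample_runs:
            write_series(series, runs_dir / f"{series.meta.run_id}.csv")
            (runs_dir / f"{series.meta.run_id}.truth.json").write_text(
                json.dumps(truth.to_dict()))
            manifest["samples"].append(series.meta.run_id)
        (out / "campaign.json").write_text(json.dumps(manifest, indent=1))
        return out


def read_campaign(path: str | Path) -> Campaign:
    """Read a campaign directory written by :meth:`Campaign.write`."""
    path = Path(path)
    manifest = json.loads((path / "campaign.json").read_text())
    config = SynthConfig(**manifest["config"])
    runs_dir = path / "runs"

    def _load(run_id: str) -> tuple[SpectrumSeries, GroundTruth]:
        series = read_series(runs_dir / f"{run_id}.csv")
        truth = GroundTruth.from_dict(
            json.loads((runs_dir / f"{run_id}.truth.json").read_text()))
        return series, truth

    polymer = {day: _load(rid) for day, rid in manifest["polymer"].items()}
    samples = [_load(rid) for rid in manifest["samples"]]
    return Campaign(kind=manifest["kind"], config=config,
                    polymer_runs=polymer, sample_runs=samples)


def _polymer_run(config: SynthConfig, day_id: str, day_gain: float,
                 rng: np.random.Generator, n_samples: int = 150
                 ) -> tuple[SpectrumSeries, GroundTruth]:
    meta = RunMeta(day_id=day_id, true_concentration=None,
                   feed_rate=7.0, screw_speed=200.0,
                   is_polymer_reference=True, run_id=f"{day_id}_polymer")
    return simulate_run(config, target_conc=0.0, n_samples=n_samples,
                        start_conc=0.0, day_gain=day_gain, rng=rng, meta=meta)


def simulate_calibration_campaign(
        config: SynthConfig = SynthConfig(),
        levels: Sequence[float] = CALIBRATION_LEVELS,
        n_steady_per_level: int = 120,
        steady_margin: int = 60,
        conc_rsd_pct: float = 0.6,
        day_id: str = "cal_day1") -> Campaign:
    """Calibration campaign: one polymer reference run plus one run per level.

    Levels are visited in order with washout transitions from the previous
    level (the first from pure polymer); each run carries at least
    ``n_steady_per_level + steady_margin`` steady-labelled samples, so the
    study's 120 retained spectra per level are always available.

    ``conc_rsd_pct`` is per-sample concentration-equivalent scatter
    (melt inhomogeneity, % of the scheduled concentration); together with
    the detector noise it sets the calibration error floor.
    """
    rng = np.random.default_rng(config.seed)
    day_gain = float(np.exp(rng.normal(0.0, config.day_gain_sigma)))
    polymer = _polymer_run(config, day_id, day_gain, rng)
    runs = []
    prev = 0.0
    for i, level in enumerate(levels):
        n_trans = _transition_length(config, prev, level)
        n_samples = n_trans + n_steady_per_level + steady_margin
        meta = RunMeta(day_id=day_id, true_concentration=level,
                       feed_rate=7.0, screw_speed=200.0,
                       run_id=f"{day_id}_level{i + 1}")
        shifts = (rng.normal(0.0, conc_rsd_pct, size=n_samples)
                  if conc_rsd_pct > 0 else None)
        runs.append(simulate_run(config, target_conc=level,
                                 n_samples=n_samples, start_conc=prev,
                                 day_gain=day_gain, rng=rng,
                                 conc_shift_pct=shifts, meta=meta))
        prev = level
    return Campaign(kind="calibration", config=config,
                    polymer_runs={day_id: polymer}, sample_runs=runs)


def simulate_validation_campaign(
        config: SynthConfig = SynthConfig(),
        levels: Sequence[float] = VALIDATION_LEVELS,
        n_days: int = 2,
        n_replicates: int = 50,
        bias_pct: float = 0.0,
        rsd_r_pct: float = 0.6,
        rsd_day_pct: float = 0.6,
        steady_margin: int = 60) -> Campaign:
    """Validation campaign: per day, a polymer run plus one run per level.

    Day and replicate effects are injected as concentration-equivalent
    percent shifts (one shift ~ N(0, rsd_day_pct) per day, common to every
    level run that day — a day effect models instrument state, so it is
    shared within the day; per-sample shift ~ N(0, rsd_r_pct); constant
    ``bias_pct`` on top).  Per level the between-day and within-day
    variance components seen by the accuracy profile are then known by
    construction: (rsd_day_pct * level / 100)^2 and
    (rsd_r_pct * level / 100)^2.
    """
    if min(rsd_r_pct, rsd_day_pct) < 0:
        raise ValueError("RSD parameters must be >= 0")
    rng = np.random.default_rng(config.seed)
    polymer_runs: dict[str, tuple[SpectrumSeries, GroundTruth]] = {}
    sample_runs = []
    for d in range(1, n_days + 1):
        day_id = f"val_day{d}"
        day_gain = float(np.exp(rng.normal(0.0, config.day_gain_sigma)))
        day_shift = rng.normal(0.0, rsd_day_pct) if rsd_day_pct > 0 else 0.0
        polymer_runs[day_id] = _polymer_run(config, day_id, day_gain, rng)
        prev = 0.0
        for i, level in enumerate(levels):
            n_trans = _transition_length(config, prev, level)
            n_samples = n_trans + n_replicates + steady_margin
            rep_shift = (rng.normal(0.0, rsd_r_pct, size=n_samples)
                         if rsd_r_pct > 0 else np.zeros(n_samples))
            shifts = bias_pct + day_shift + rep_shift
            meta = RunMeta(day_id=day_id, true_concentration=level,
                           feed_rate=7.0, screw_speed=200.0,
                           run_id=f"{day_id}_level{i + 1}")
            sample_runs.append(simulate_run(
                config, target_conc=level, n_samples=n_samples,
                start_conc=prev, day_gain=day_gain, rng=rng,
                conc_shift_pct=shifts, meta=meta))
            prev = level
    return Campaign(kind="validation", config=config,
                    polymer_runs=polymer_runs, sample_runs=sample_runs)


def simulate_doe(config: SynthConfig = SynthConfig(),
                 surface_spec: Optional[Callable[[float, float], float]] = None,
                 design: Sequence[tuple[float, float]] = DOE_DESIGN,
                 true_conc: float = 14.45,
                 noise_pct: float = 0.05) -> list[DoERun]:
    """Robustness DoE: mean predicted content per (feed, speed) setting.

    ``surface_spec(feed, speed)`` returns the systematic relative bias in
    percent at that setting (default: no effect); ``noise_pct`` adds
    run-to-run noise on the same scale.
    """
    rng = np.random.default_rng(config.seed)
    surface = surface_spec or (lambda f, s: 0.0)
    runs = []
    for f, s in design:
        bias = surface(float(f), float(s))
        if noise_pct > 0:
            bias += rng.normal(0.0, noise_pct)
        runs.append(DoERun(true_conc=true_conc, feed_rate=float(f),
                           screw_speed=float(s),
                           mean_predicted=true_conc * (1.0 + bias / 100.0)))
    return runs
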