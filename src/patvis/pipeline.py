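"""End-to-end pipeline assembly: calibrate, validate, robustness.

Ties the stage modules together in the order the method prescribes:

1. steady-state sample selection per run (b* plateau by default),
2. same-day polymer-reference normalisation and absorbance conversion,
3. PC1-loading wavelength band selection on the pooled calibration set,
4. latent-variable count selection by seeded holdout cross-validation,
5. PLS1 fit / prediction,
6. accuracy-profile validation and DoE/MODR robustness evaluation.

Each function returns the domain object plus a JSON-serialisable report
embedding the resolved configuration, for audit trails.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .colorimetry import CIETables, load_cie_tables
from .io_spectra import SpectrumSeries
from .pls import PLSModel, fit_pls1, predict, select_n_lv
from .preprocessing import (DEFAULT_BAND, BandSelection, normalise_to_reference,
                            select_band_by_pc1, to_absorbance)
from .robustness import MODR, DoERun, ResponseSurface, evaluate_doe, \
    extract_modr, fit_response_surface
from .steady_state import PlateauParams, select_steady_state
from .synth import Campaign
from .validation import (AccuracyProfile, ATPSpec, LevelData,
                         build_accuracy_profile, check_atp)

__all__ = ["PipelineConfig", "calibrate", "validate", "robustness_report"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved pipeline settings; defaults are the method's settings."""

    steady_method: str = "b_star"
    plateau: PlateauParams = field(default_factory=PlateauParams)
    band_override: Optional[tuple[float, float]] = None
    band_threshold: float = 0.1
    n_keep_calibration: int = 120     # steady spectra kept per level run
    n_keep_validation: int = 50       # replicates kept per (day, level) run
    max_lv: int = 10
    holdout_fraction: float = 0.2
    lv_repeats: int = 1
    seed: int = 0
    atp: ATPSpec = field(default_factory=ATPSpec)
    doe_lower: float = 14.15          # content limits for the MODR, % w/w
    doe_upper: float = 14.75

    def __post_init__(self) -> None:
        if self.steady_method not in ("b_star", "pc1"):
            raise ValueError(f"unknown steady_method {self.steady_method!r}")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.max_lv < 1 or self.n_keep_calibration < 1 \
                or self.n_keep_validation < 1:
            raise ValueError("counts must be >= 1")
        if self.band_override is not None:
            lo, hi = self.band_override
            if lo >= hi:
                raise ValueError("band_override must satisfy lo < hi")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["package_version"] = __version__
        return d


def _steady_polymer_means(campaign: Campaign, cfg: PipelineConfig,
                          tables: CIETables) -> dict[str, SpectrumSeries]:
    """Steady-state-filtered polymer reference series per day."""
    out = {}
    for day_id, (series, _truth) in campaign.polymer_runs.items():
        kept, window = select_steady_state(
            series, method=cfg.steady_method, params=cfg.plateau, tables=tables)
        log.info("polymer %s: kept %d/%d steady spectra", day_id,
                 window.n_kept, series.n_times)
        out[day_id] = kept
    return out


def _preprocess_run(series: SpectrumSeries, polymer: SpectrumSeries,
                    cfg: PipelineConfig, tables: CIETables, n_keep: int
                    ) -> tuple[SpectrumSeries, dict]:
    """Steady-select, trim to the trailing n_keep rows, normalise, log10."""
    kept, window = select_steady_state(
        series, method=cfg.steady_method, params=cfg.plateau, tables=tables)
    if kept.n_times > n_keep:
        kept = kept.select_rows(np.arange(kept.n_times - n_keep, kept.n_times))
    normed = normalise_to_reference(kept, polymer)
    absorb = to_absorbance(normed)
    info = {"run_id": series.meta.run_id, "n_total": series.n_times,
            "window": [window.start_index, window.end_index],
            "n_kept": kept.n_times}
    return absorb, info


def calibrate(campaign: Campaign, cfg: Optional[PipelineConfig] = None,
              tables: Optional[CIETables] = None
              ) -> tuple[PLSModel, dict]:
    """Build the calibration model from a calibration campaign.

    Returns the fitted PLS model (band attached) and a report with
    per-stage counts, the selected band, the LV-selection table and the
    training summary.
    """
    cfg = cfg or PipelineConfig()
    tables = tables or load_cie_tables()
    if not campaign.polymer_runs:
        raise ValueError("campaign has no polymer reference run")
    polymer = _steady_polymer_means(campaign, cfg, tables)

    spectra, concs, run_infos = [], [], []
    grid = None
    for series, _truth in campaign.sample_runs:
        if series.meta.true_concentration is None:
            raise ValueError(f"run {series.meta.run_id!r} has no reference "
                             "concentration")
        if series.meta.day_id not in polymer:
            raise ValueError(f"no polymer reference for day "
                             f"{series.meta.day_id!r}")
        absorb, info = _preprocess_run(series, polymer[series.meta.day_id],
                                       cfg, tables, cfg.n_keep_calibration)
        spectra.append(absorb.values)
        concs.append(np.full(absorb.n_times, series.meta.true_concentration))
        run_infos.append(info)
        grid = absorb.grid
    X_full = np.vstack(spectra)
    y = np.concatenate(concs)

    if cfg.band_override is not None:
        lo, hi = cfg.band_override
        i0, i1 = grid.index_range(lo, hi)
        band = BandSelection(lo_nm=lo, hi_nm=hi, threshold_fraction=0.0,
                             loadings_used=np.array([]),
                             evr_full=float("nan"), evr_band=float("nan"))
    else:
        band = select_band_by_pc1(X_full, grid,
                                  threshold_fraction=cfg.band_threshold)
        i0, i1 = grid.index_range(band.lo_nm, band.hi_nm)
    X = X_full[:, i0:i1 + 1]

    lv_report = select_n_lv(X, y, max_lv=cfg.max_lv,
                            holdout_fraction=cfg.holdout_fraction,
                            seed=cfg.seed, n_repeats=cfg.lv_repeats)
    model = fit_pls1(X, y, n_lv=lv_report.chosen_n_lv, band=band)
    report = {
        "config": cfg.to_dict(),
        "runs": run_infos,
        "n_steady": int(X.shape[0]),
        "band": band.to_dict(),
        "n_lv": lv_report.chosen_n_lv,
        "lv_table": lv_report.table.to_dict(orient="list"),
        "training_summary": model.training_summary,
    }
    return model, report


def validate(campaign: Campaign, model: PLSModel,
             cfg: Optional[PipelineConfig] = None,
             tables: Optional[CIETables] = None
             ) -> tuple[AccuracyProfile, dict]:
    """Predict a validation campaign and build its accuracy profile.

    Predictions are grouped into a balanced days x replicates matrix per
    concentration level; imbalance (same level not run on every day, or
    unequal replicate counts) is an error.
    """
    cfg = cfg or PipelineConfig()
    tables = tables or load_cie_tables()
    if model.band is None:
        raise ValueError("model carries no band; cannot align spectra")
    polymer = _steady_polymer_means(campaign, cfg, tables)

    cells: dict[float, dict[str, np.ndarray]] = {}
    run_infos = []
    for series, _truth in campaign.sample_runs:
        level = series.meta.true_concentration
        if level is None:
            raise ValueError(f"run {series.meta.run_id!r} has no reference "
                             "concentration")
        absorb, info = _preprocess_run(series, polymer[series.meta.day_id],
                                       cfg, tables, cfg.n_keep_validation)
        i0, i1 = absorb.grid.index_range(model.band.lo_nm, model.band.hi_nm)
        preds = predict(model, absorb.values[:, i0:i1 + 1])
        cells.setdefault(level, {})[series.meta.day_id] = preds
        run_infos.append(info)

    day_ids = sorted(campaign.polymer_runs)
    levels = []
    for level, per_day in sorted(cells.items()):
        if sorted(per_day) != day_ids:
            raise ValueError(
                f"level {level}: runs on days {sorted(per_day)} but campaign "
                f"has days {day_ids}; balanced design required")
        counts = {d: v.size for d, v in per_day.items()}
        n = min(counts.values())
        if len(set(counts.values())) != 1:
            raise ValueError(
                f"level {level}: unequal replicate counts {counts}; "
                "balanced design required")
        matrix = np.vstack([per_day[d][:n] for d in day_ids])
        levels.append(LevelData(true_conc=level, predictions=matrix))

    profile = build_accuracy_profile(levels, atp=cfg.atp)
    atp_report = check_atp(profile.rows, cfg.atp)
    report = {
        "config": cfg.to_dict(),
        "runs": run_infos,
        "profile": profile.to_frame().to_dict(orient="list"),
        "passes": profile.passes,
        "loq": profile.loq,
        "atp_check": {
            "max_abs_bias": atp_report.max_abs_bias,
            "max_rsd_repeatability": atp_report.max_rsd_repeatability,
            "max_rsd_IP": atp_report.max_rsd_IP,
            "passes": atp_report.passes,
            "offending_levels": atp_report.offending_levels,
        },
    }
    return profile, report


def robustness_report(doe: pd.DataFrame, cfg: Optional[PipelineConfig] = None
                      ) -> tuple[list[DoERun], ResponseSurface, MODR, dict]:
    """Evaluate a robustness DoE table and extract the MODR.

    ``doe`` needs columns true_conc, feed_rate, screw_speed,
    mean_predicted (one row per run).
    """
    cfg = cfg or PipelineConfig()
    required = {"true_conc", "feed_rate", "screw_speed", "mean_predicted"}
    missing = required - set(doe.columns)
    if missing:
        raise ValueError(f"DoE table missing columns {sorted(missing)}")
    runs = [DoERun(true_conc=r.true_conc, feed_rate=r.feed_rate,
                   screw_speed=r.screw_speed, mean_predicted=r.mean_predicted)
            for r in doe.itertuples()]
    evaluate_doe(runs, atp_bias_limit=cfg.atp.bias_limit)
    surface = fit_response_surface(runs)
    modr = extract_modr(surface, lower=cfg.doe_lower, upper=cfg.doe_upper)
    report = {
        "config": cfg.to_dict(),
        "runs": [{"feed_rate": r.feed_rate, "screw_speed": r.screw_speed,
                  "mean_predicted": r.mean_predicted,
                  "relative_bias_pct": r.relative_bias, "flagged": r.flagged}
                 for r in runs],
        "surface": surface.to_dict(),
        "modr_empty": modr.is_empty,
        "corner_table": modr.corner_table().to_dict(orient="list"),
    }
    return runs, surface, modr, report
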