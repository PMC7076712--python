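"""Bundled example data: validation and robustness summaries.

These are the per-level summary statistics of an in-line UV-Vis method
for piroxicam in copovidone (Kollidon VA64) during hot-melt extrusion:
day-wise mean predictions, per-level trueness/precision summaries and a
robustness design-of-experiments table.  They serve as worked-example
inputs for the validation and robustness modules — the raw spectra behind
them are not distributed, so the summaries are the interchange format.

All concentrations are % w/w; RSDs and biases are percent.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "load_daily_means",
    "load_validation_summary",
    "load_doe_runs",
]


def load_daily_means() -> pd.DataFrame:
    """Day-wise true and mean predicted API content (validation sets)."""
    records = [
        (1, 11.56, 11.59), (2, 11.75, 11.70),
        (1, 13.46, 13.44), (2, 13.44, 13.59),
        (1, 15.44, 15.31), (2, 15.46, 15.50),
        (1, 17.50, 17.38), (2, 17.49, 17.57),
    ]
    return pd.DataFrame(records, columns=["day", "true_conc", "mean_predicted"])


def load_validation_summary() -> pd.DataFrame:
    """Per-level validation summary: trueness and precision statistics.

    Columns: true_conc and mean_predicted (% w/w), relative_bias_pct,
    recovery_pct, rsd_repeatability_pct, rsd_ip_pct (RSDs referenced to
    the mean predicted concentration), and the relative beta-expectation
    tolerance limits (percent of the true value).  The design behind each
    row is balanced: p = 2 days x n = 50 replicates.
    """
    records = [
        (11.66, 11.65, -0.12, 99.88, 0.55, 0.84, -2.92, 2.68),
        (13.45, 13.51, 0.47, 100.47, 0.54, 0.95, -3.51, 4.45),
        (15.45, 15.40, -0.29, 99.71, 0.65, 1.05, -4.05, 3.47),
        (17.50, 17.48, -0.14, 99.86, 0.80, 1.09, -3.13, 2.85),
    ]
    return pd.DataFrame(records, columns=[
        "true_conc", "mean_predicted", "relative_bias_pct", "recovery_pct",
        "rsd_repeatability_pct", "rsd_ip_pct",
        "tolerance_low_pct", "tolerance_high_pct",
    ])


def load_doe_runs() -> pd.DataFrame:
    """Robustness DoE: mean predicted content per (feed rate, screw speed).

    Ten runs at nominal 14.45 % w/w: a 3 x 3 grid over feed rate
    5/7/9 g/min and screw speed 150/200/250 rpm with a duplicated centre
    point.  ``published_bias_pct`` is the relative bias as printed in the
    source summary (2 decimals); recomputing it from the rounded means
    reproduces it to within rounding.
    """
    records = [
        (14.45, 5, 150, 13.77, -4.72),
        (14.45, 5, 200, 14.54, 0.61),
        (14.45, 5, 250, 14.82, 2.56),
        (14.45, 7, 150, 13.90, -3.77),
        (14.45, 7, 200, 14.60, 1.04),
        (14.45, 7, 200, 14.60, 1.01),
        (14.45, 7, 250, 14.94, 3.37),
        (14.45, 9, 150, 13.28, -8.09),
        (14.45, 9, 200, 14.16, -2.00),
        (14.45, 9, 250, 14.59, 0.95),
    ]
    return pd.DataFrame(records, columns=[
        "true_conc", "feed_rate", "screw_speed", "mean_predicted",
        "published_bias_pct",
    ])
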