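"""PLS1 calibration (NIPALS), prediction, and latent-variable selection.

The calibration model maps band-restricted absorbance spectra to API
content in % w/w.  Fitting uses the NIPALS deflation scheme for a single
response: each component extracts a weight vector proportional to the
covariance between the X residual and the y residual, scores t = X w,
loadings p = X't / t't, q = y't / t't, then deflates X by t p'.  The
composite regression vector is b = W (P'W)^-1 q, so prediction is a
single dot product plus centring:  yhat = (x - x_mean) b + y_mean.

The number of latent variables is chosen by seeded holdout
cross-validation: a stratified 20% split is predicted by models with
1..max_lv components and the smallest count whose RMSECV is within 5% of
the minimum wins — an operational version of the usual RMSECV-elbow read.
An optional repeated-split mode reports the median RMSECV over many
splits, which removes the seed fragility of a single split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .preprocessing import BandSelection

__all__ = [
    "PLSModel",
    "LVSelectionReport",
    "fit_pls1",
    "predict",
    "select_n_lv",
    "rmse",
    "r2",
    "save_model",
    "load_model",
]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-square error, in y units (% w/w)."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must have equal length >= 2")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("y_true and y_pred must have equal length >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("y_true has zero variance; R^2 undefined")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


@dataclass
class PLSModel:
    """Centred PLS1 calibration model on a fixed wavelength band."""

    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # W, (n_lv, n_wavelengths)
    x_loadings: np.ndarray    # P, (n_lv, n_wavelengths)
    y_loadings: np.ndarray    # q, (n_lv,)
    b: np.ndarray             # composite regression vector on the band grid
    n_lv: int
    band: Optional[BandSelection] = None
    training_summary: dict = field(default_factory=dict)


def fit_pls1(X: np.ndarray, y: np.ndarray, n_lv: int,
             band: Optional[BandSelection] = None) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` latent variables by NIPALS."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X rows must match y length")
    if X.shape[0] < n_lv + 1:
        raise ValueError(f"need at least n_lv + 1 = {n_lv + 1} samples")
    if np.var(y) <= 0:
        raise ValueError("y has zero variance; calibration undefined")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xr = X - x_mean
    yr = y - y_mean
    x_scale = float(np.abs(Xr).max()) or 1.0

    n, m = Xr.shape
    W = np.zeros((n_lv, m))
    P = np.zeros((n_lv, m))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    for a in range(n_lv):
        w = Xr.T @ yr
        norm_w = np.linalg.norm(w)
        if norm_w <= _NIPALS_TOL * x_scale * max(1.0, np.abs(yr).max()):
            raise RuntimeError(
                f"NIPALS component {a + 1}: no residual covariance left "
                "(X residual orthogonal to y residual)"
            )
        w /= norm_w
        # for a single response the NIPALS inner loop converges immediately,
        # but iterate for robustness to accumulated round-off
        for _ in range(_NIPALS_MAX_ITER):
            t = Xr @ w
            tt = float(t @ t)
            if tt <= 0:
                raise RuntimeError(f"NIPALS component {a + 1}: zero score vector")
            w_new = Xr.T @ yr
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < _NIPALS_TOL:
                w = w_new
                break
            w = w_new
        t = Xr @ w
        tt = float(t @ t)
        p = Xr.T @ t / tt
        qa = float(yr @ t / tt)
        Xr = Xr - np.outer(t, p)
        yr = yr - qa * t
        W[a], P[a], q[a], T[:, a] = w, p, qa, t

    b = W.T @ np.linalg.solve(P @ W.T, q)
    fitted = (X - x_mean) @ b + y_mean
    summary = {"R2_c": r2(y, fitted), "RMSEC": rmse(y, fitted)}
    return PLSModel(x_mean=x_mean, y_mean=y_mean, weights=W, x_loadings=P,
                    y_loadings=q, b=b, n_lv=n_lv, band=band,
                    training_summary=summary)


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict concentrations (% w/w) for spectra on the model's band grid."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.b.size:
        raise ValueError(
            f"X has {X_new.shape[1]} wavelengths, model expects {model.b.size}"
        )
    return (X_new - model.x_mean) @ model.b + model.y_mean


@dataclass
class LVSelectionReport:
    """Holdout cross-validation results for candidate LV counts."""

    table: pd.DataFrame          # columns n_lv, RMSECV, R2_cv
    chosen_n_lv: int
    split_seed: int
    holdout_fraction: float
    n_repeats: int = 1


def _stratified_split(y: np.ndarray, holdout_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Holdout indices stratified by distinct y value (concentration level).

    Falls back to a plain random split when y is continuous (no repeated
    levels to stratify on).
    """
    levels, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        n_test = max(1, int(round(holdout_fraction * y.size)))
        test = np.sort(rng.choice(y.size, size=n_test, replace=False))
    else:
        test_idx: list[int] = []
        for level in levels:
            members = np.nonzero(y == level)[0]
            n_test = max(1, int(round(holdout_fraction * members.size)))
            test_idx.extend(rng.choice(members, size=n_test, replace=False))
        test = np.sort(np.asarray(test_idx))
    train = np.setdiff1d(np.arange(y.size), test)
    return train, test


def select_n_lv(X: np.ndarray, y: np.ndarray, max_lv: int = 10,
                holdout_fraction: float = 0.2, seed: int = 0,
                rel_tol: float = 0.05, n_repeats: int = 1) -> LVSelectionReport:
    """Choose the number of latent variables by holdout cross-validation.

    Fits on the (1 - holdout) stratified subset and scores RMSECV / R2_cv
    on the holdout for 1..max_lv components; picks the smallest count whose
    RMSECV is within ``rel_tol`` of the minimum.  With ``n_repeats > 1``
    the RMSECV per candidate is the median over repeated seeded splits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    eff_max = min(max_lv, rank)
    if eff_max < max_lv:
        import warnings
        warnings.warn(f"max_lv {max_lv} exceeds X rank {rank}; truncating",
                      stacklevel=2)

    all_rmse = np.empty((n_repeats, eff_max))
    all_r2 = np.empty((n_repeats, eff_max))
    for rep in range(n_repeats):
        train, test = _stratified_split(y, holdout_fraction, rng)
        if test.size < eff_max + 1:
            raise ValueError(
                f"holdout has {test.size} samples; need > max_lv = {eff_max}"
            )
        for a in range(1, eff_max + 1):
            model = fit_pls1(X[train], y[train], n_lv=a)
            pred = predict(model, X[test])
            all_rmse[rep, a - 1] = rmse(y[test], pred)
            all_r2[rep, a - 1] = r2(y[test], pred)
    rmsecv = np.median(all_rmse, axis=0)
    r2cv = np.median(all_r2, axis=0)
    chosen = int(np.nonzero(rmsecv <= (1.0 + rel_tol) * rmsecv.min())[0][0]) + 1
    table = pd.DataFrame({"n_lv": np.arange(1, eff_max + 1),
                          "RMSECV": rmsecv, "R2_cv": r2cv})
    return LVSelectionReport(table=table, chosen_n_lv=chosen, split_seed=seed,
                             holdout_fraction=holdout_fraction,
                             n_repeats=n_repeats)


def save_model(model: PLSModel, path: str | Path) -> Path:
    """Persist a model (and its band) as JSON."""
    path = Path(path)
    payload = {
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "weights": model.weights.tolist(),
        "x_loadings": model.x_loadings.tolist(),
        "y_loadings": model.y_loadings.tolist(),
        "b": model.b.tolist(),
        "n_lv": model.n_lv,
        "band": model.band.to_dict() if model.band is not None else None,
        "training_summary": model.training_summary,
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_model(path: str | Path) -> PLSModel:
    d = json.loads(Path(path).read_text())
    band = None
    if d.get("band"):
        bd = d["band"]
        band = BandSelection(lo_nm=bd["lo_nm"], hi_nm=bd["hi_nm"],
                             threshold_fraction=bd["threshold_fraction"],
                             loadings_used=np.array([]),
                             evr_full=bd["evr_full"], evr_band=bd["evr_band"])
    return PLSModel(
        x_mean=np.array(d["x_mean"]), y_mean=float(d["y_mean"]),
        weights=np.array(d["weights"]), x_loadings=np.array(d["x_loadings"]),
        y_loadings=np.array(d["y_loadings"]), b=np.array(d["b"]),
        n_lv=int(d["n_lv"]), band=band,
        training_summary=d.get("training_summary", {}),
    )
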