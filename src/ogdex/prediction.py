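"""Index-age curves, age-to-target inversion, and raster mapping.

Predictions use the fixed-effect part of the model only — no plot
random effect, and measurement period taken as the reference (latest)
period.  The predicted index at age *t* for standardized covariates *z*
is ``inv_logit(beta0 + coeff(z) * t)`` with the development rate
``coeff(z) = beta1 + sum_k beta_k1 z_k + beta_k2 z_k^2``.

The stand age at which the index reaches a target q solves
``beta0 + coeff * t = logit(q)``; with a positive rate this has the
closed form ``(logit(q) - beta0) / coeff``, found here by bracketing
root-solving (and checked against the closed form in the tests).  Cells
whose rate is non-positive, or whose solution exceeds ``age_max``, never
reach the target and are flagged unreachable.

To avoid extrapolating the quadratic rate model, covariates are clamped
to the central 95% band (2.5/97.5% quantiles) of the training data
before prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .climate_terrain import COVARIATE_NAMES, Covariates
from .hierarchical_model import ModelParameters, StandardScaler
from .og_index import inv_logit
from .raster import RasterGrid, check_aligned

DEFAULT_AGE_MAX = 1000.0
#: sentinel written to t-target rasters where the index never reaches the target
UNREACHABLE = -1.0


@dataclass(frozen=True)
class ClampRule:
    """Per-covariate 2.5% and 97.5% training quantiles."""

    q_low: dict[str, float]
    q_high: dict[str, float]

    @classmethod
    def from_training(cls, samples: pd.DataFrame) -> "ClampRule":
        lo, hi = {}, {}
        for name in COVARIATE_NAMES:
            col = samples[name].to_numpy(dtype=float)
            lo[name], hi[name] = np.percentile(col, [2.5, 97.5])
        return cls(lo, hi)


@dataclass(frozen=True)
class AgeToTarget:
    """Years to reach a target index, or unreachable."""

    t: float
    reachable: bool


def _as_z(covariates) -> np.ndarray:
    if isinstance(covariates, Covariates):
        return covariates.as_array()
    z = np.asarray(covariates, dtype=float)
    if z.shape[-1] != len(COVARIATE_NAMES):
        raise ValueError(f"expected {len(COVARIATE_NAMES)} covariates, got {z.shape}")
    if np.any(~np.isfinite(z)):
        raise ValueError("covariates contain missing values")
    return z


def development_rate(params: ModelParameters, covariates) -> float | np.ndarray:
    """Age slope coeff = beta1 + sum_k (beta_k1 z_k + beta_k2 z_k^2).

    ``covariates`` must already be standardized with the fit's scaler;
    accepts a single vector or an (n, 6) array.  The rate may be <= 0.
    """
    z = _as_z(covariates)
    out = params.beta1 + z @ params.beta_lin + (z**2) @ params.beta_quad
    return float(out) if z.ndim == 1 else out


def predict_index(params: ModelParameters, covariates, age) -> float | np.ndarray:
    """Predicted index at a stand age (reference period, no plot effect)."""
    coeff = development_rate(params, covariates)
    return inv_logit(params.beta0 + np.asarray(coeff) * np.asarray(age, dtype=float))


def age_at_index(
    params: ModelParameters,
    covariates,
    target: float = 0.5,
    age_max: float = DEFAULT_AGE_MAX,
) -> AgeToTarget:
    """Stand age at which the predicted index reaches ``target``.

    Solves beta0 + coeff * t = logit(target) by bracketing root-finding
    on (0, age_max].  Unreachable when the rate is non-positive, the
    stand already exceeds the target at age 0, or the root lies beyond
    ``age_max``.
    """
    if not (0.0 < target < 1.0):
        raise ValueError("target must lie strictly inside (0, 1)")
    coeff = development_rate(params, covariates)
    lt = float(np.log(target / (1.0 - target)))

    def g(t: float) -> float:
        return params.beta0 + coeff * t - lt

    if coeff <= 0 or g(0.0) >= 0 or g(age_max) < 0:
        return AgeToTarget(float("nan"), False)
    t = brentq(g, 0.0, age_max, xtol=1e-9, rtol=1e-12)
    return AgeToTarget(float(t), True)


def clamp_covariates(covariates: pd.DataFrame, rule: ClampRule) -> pd.DataFrame:
    """Clamp each covariate into its training 95% band; idempotent."""
    out = covariates.copy()
    for name in COVARIATE_NAMES:
        out[name] = out[name].clip(rule.q_low[name], rule.q_high[name])
    return out


def _standardized_stack(
    covariate_stack: dict[str, RasterGrid],
    scaler: StandardScaler,
    clamp: ClampRule | None,
) -> tuple[np.ndarray, np.ndarray, RasterGrid]:
    missing = [n for n in COVARIATE_NAMES if n not in covariate_stack]
    if missing:
        raise ValueError(f"covariate stack missing raster(s) {missing}")
    grids = [covariate_stack[n] for n in COVARIATE_NAMES]
    check_aligned(*grids)
    ref = grids[0]
    z = np.stack([g.values for g in grids], axis=-1)  # (rows, cols, 6)
    valid = np.all(np.isfinite(z), axis=-1)
    for k, name in enumerate(COVARIATE_NAMES):
        col = z[:, :, k]
        if clamp is not None:
            col = np.clip(col, clamp.q_low[name], clamp.q_high[name])
        z[:, :, k] = (col - scaler.mean[name]) / scaler.sd[name]
    return z, valid, ref


def map_t_target(
    covariate_stack: dict[str, RasterGrid],
    params: ModelParameters,
    scaler: StandardScaler,
    clamp: ClampRule | None = None,
    target: float = 0.5,
    age_max: float = DEFAULT_AGE_MAX,
) -> RasterGrid:
    """Raster of years to reach the target index on every valid cell.

    Nodata propagates; cells that never reach the target carry the
    :data:`UNREACHABLE` sentinel (distinct from nodata, documented in
    the raster side-car by the pipeline).
    """
    if not (0.0 < target < 1.0):
        raise ValueError("target must lie strictly inside (0, 1)")
    z, valid, ref = _standardized_stack(covariate_stack, scaler, clamp)
    coeff = params.beta1 + z @ params.beta_lin + (z**2) @ params.beta_quad
    lt = float(np.log(target / (1.0 - target)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (lt - params.beta0) / coeff
    out = np.where((coeff > 0) & (t > 0) & (t <= age_max), t, UNREACHABLE)
    out = np.where(valid, out, np.nan)
    return ref.like(out)


def map_index(
    covariate_stack: dict[str, RasterGrid],
    stand_age: RasterGrid,
    mask: RasterGrid | None,
    params: ModelParameters,
    scaler: StandardScaler,
    clamp: ClampRule | None = None,
) -> RasterGrid:
    """Raster of the predicted index at each cell's current stand age.

    ``mask`` marks cells to predict (nonzero = keep, e.g. natural
    forest); masked-out or nodata cells become nodata.
    """
    z, valid, ref = _standardized_stack(covariate_stack, scaler, clamp)
    check_aligned(ref, stand_age, *( [mask] if mask is not None else [] ))
    coeff = params.beta1 + z @ params.beta_lin + (z**2) @ params.beta_quad
    idx = 1.0 / (1.0 + np.exp(-(params.beta0 + coeff * stand_age.values)))
    keep = valid & np.isfinite(stand_age.values)
    if mask is not None:
        keep &= np.isfinite(mask.values) & (mask.values != 0)
    return ref.like(np.where(keep, idx, np.nan))
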