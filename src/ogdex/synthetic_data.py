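"""Synthetic inventory-like data with the statistical structure the model assumes.

Real national-inventory plot data and the old-growth reference plots are
restricted; this module generates datasets that emulate their published
statistical structure so every stage of the pipeline is testable:

* six environmental covariates drawn through a Gaussian copula with the
  published correlation structure — snow depth vs warmth index r = -0.57,
  positive openness vs log10 catchment area r = -0.62, all other pairs
  uncorrelated (|r| < 0.3 in the source data);
* stand ages lognormal with median near 50 years (the most common stand
  age in the inventory), plots measured in up to three 5-year-spaced
  survey periods;
* index responses following the forward model: logistic trajectories in
  age whose slope is a quadratic function of the standardized
  covariates, plus a Gaussian plot random intercept, negative fixed
  offsets for the two older survey periods (emulating the measurement
  bias of earlier protocols), and residual noise;
* tree lists moment-matched to a target stand structure, and small DEMs
  (plane / V-valley / smooth noise) with analytically known terrain
  properties.

Marginal distributions are stand-ins chosen to be plausible for
temperate Japan; the copula correlations and the age concentration are
the features the source data actually constrain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .climate_terrain import COVARIATE_NAMES
from .hierarchical_model import ModelParameters
from .og_index import inv_logit
from .raster import RasterGrid
from .stand_metrics import StandStructure, TreeRecord

logger = logging.getLogger(__name__)

#: published covariate correlations the generator reproduces
CORR_SNOW_WARMTH = -0.57
CORR_OPENNESS_CATCHMENT = -0.62


def default_correlation() -> np.ndarray:
    r = np.eye(len(COVARIATE_NAMES))
    i = {n: k for k, n in enumerate(COVARIATE_NAMES)}
    r[i["snow_depth"], i["warmth_index"]] = CORR_SNOW_WARMTH
    r[i["warmth_index"], i["snow_depth"]] = CORR_SNOW_WARMTH
    r[i["positive_openness"], i["log10_catchment"]] = CORR_OPENNESS_CATCHMENT
    r[i["log10_catchment"], i["positive_openness"]] = CORR_OPENNESS_CATCHMENT
    return r


def default_true_params() -> ModelParameters:
    """True parameters of the stated world: slow logistic development.

    beta0 = -4 puts a freshly disturbed stand near index 0.02; beta1 =
    0.03/yr reaches index 0.5 around age 130 at average covariates.
    Period offsets are negative for the two older survey periods, larger
    for the oldest.
    """
    return ModelParameters(
        beta0=-4.0,
        beta1=0.03,
        beta_lin=np.array([0.004, -0.005, -0.003, 0.002, 0.005, -0.002]),
        beta_quad=np.array([-0.002, -0.003, 0.001, -0.001, 0.002, -0.001]),
        period_eff=np.array([-0.5, -0.25]),
        sigma_plot=0.3,
        sigma_resid=0.5,
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated world of the synthetic inventory."""

    n_plots: int = 1000
    #: probability a plot is measured in 1, 2 or 3 periods
    period_probs: tuple[float, float, float] = (0.05, 0.55, 0.40)
    #: marginal (mean, sd) per covariate; log10_catchment is already log-scale
    marginal_mean: dict = field(
        default_factory=lambda: {
            "snow_depth": 100.0, "warmth_index": 110.0, "slope_angle": 20.0,
            "positive_openness": 75.0, "log10_catchment": 3.0, "solar_radiation": 1.0,
        }
    )
    marginal_sd: dict = field(
        default_factory=lambda: {
            "snow_depth": 40.0, "warmth_index": 30.0, "slope_angle": 10.0,
            "positive_openness": 15.0, "log10_catchment": 0.8, "solar_radiation": 0.1,
        }
    )
    correlation: np.ndarray = field(default_factory=default_correlation)
    true_params: ModelParameters = field(default_factory=default_true_params)
    #: lognormal age distribution: median 50 y
    age_log_median: float = math.log(50.0)
    age_log_sd: float = 0.6
    years_between_periods: float = 5.0
    seed: int = 0


def gen_covariates(config: GeneratorConfig, n: int | None = None) -> pd.DataFrame:
    """Draw covariates through a Gaussian copula with normal marginals.

    With normal marginals the copula correlation is the Pearson
    correlation of the output, so the published values are matched
    directly.
    """
    n = config.n_plots if n is None else n
    r = np.asarray(config.correlation, dtype=float)
    eig = np.linalg.eigvalsh(r)
    if eig.min() <= 0:
        raise ValueError(
            "correlation matrix not positive-definite "
            f"(min eigenvalue {eig.min():.3g}); project to the nearest PD matrix "
            "(e.g. clip eigenvalues) before use"
        )
    rng = np.random.default_rng(config.seed)
    z = rng.multivariate_normal(np.zeros(len(COVARIATE_NAMES)), r, size=n,
                                method="cholesky")
    out = {}
    for k, name in enumerate(COVARIATE_NAMES):
        out[name] = config.marginal_mean[name] + config.marginal_sd[name] * z[:, k]
    return pd.DataFrame(out)


def gen_plot_samples(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the plot-sample table from the forward model.

    Returns one row per plot x period with plot_id, period, age, the six
    raw covariates and the response ``I_og`` in (0, 1).  The age slope
    is computed from covariates z-scored over this table, matching how
    the model standardizes at fit time.
    """
    p = config.true_params
    cov = gen_covariates(config)
    rng = np.random.default_rng(config.seed + 1)
    n_periods = 1 + rng.choice(3, size=config.n_plots, p=config.period_probs)
    plot_eff = rng.normal(0.0, p.sigma_plot, size=config.n_plots)
    base_age = np.exp(rng.normal(config.age_log_median, config.age_log_sd,
                                 size=config.n_plots))

    rows = []
    for i in range(config.n_plots):
        periods = list(range(4 - n_periods[i], 4))  # latest periods measured
        for t in periods:
            age = base_age[i] + config.years_between_periods * (t - periods[0])
            rows.append((f"P{i:05d}", i, t, max(age, 1.0)))
    frame = pd.DataFrame(rows, columns=["plot_id", "_i", "period", "age"])
    for name in COVARIATE_NAMES:
        frame[name] = cov[name].to_numpy()[frame["_i"]]

    z = np.stack(
        [
            (frame[n] - frame[n].mean()) / frame[n].std(ddof=1)
            for n in COVARIATE_NAMES
        ],
        axis=-1,
    )
    coeff = p.beta1 + z @ p.beta_lin + (z**2) @ p.beta_quad
    if np.all(coeff <= 0):
        logger.warning("all development rates <= 0; age-to-target undefined everywhere")
    period = frame["period"].to_numpy()
    period_eff = np.select([period == 1, period == 2], list(p.period_eff), 0.0)
    e = rng.normal(0.0, p.sigma_resid, size=len(frame))
    lin = (
        p.beta0
        + coeff * frame["age"].to_numpy()
        + plot_eff[frame["_i"]]
        + period_eff
        + e
    )
    frame["I_og"] = inv_logit(lin)
    return frame.drop(columns="_i")


def gen_tree_list(
    target: StandStructure,
    plot_area: float = 0.1,
    seed: int = 0,
    *,
    dbh_min: float = 5.0,
    large_dbh: float = 40.0,
) -> list[TreeRecord]:
    """Tree list whose recomputed structure matches ``target``.

    Draws round(density x area) dbh values from a gamma distribution
    moment-matched to (mean, SD), rescales to the exact sample moments,
    truncates at the small-tree cut, then adjusts the upper tail so
    exactly round(large_density x area) stems are at or above the
    large-tree threshold.  Densities and the large-tree count are exact;
    mean and SD are within a few percent (the tail adjustment perturbs
    them slightly).
    """
    if target.sd_dbh < 0 or target.large_tree_density > target.tree_density:
        raise ValueError("infeasible target structure")
    n = int(round(target.tree_density * plot_area))
    n_large = int(round(target.large_tree_density * plot_area))
    if n == 0:
        return []
    if not (math.isfinite(target.mean_dbh) and target.mean_dbh > dbh_min):
        raise ValueError("target mean dbh must exceed the small-tree cut")
    rng = np.random.default_rng(seed)
    if target.sd_dbh == 0 or n == 1:
        dbh = np.full(n, target.mean_dbh)
    else:
        shape = (target.mean_dbh / target.sd_dbh) ** 2
        scale = target.sd_dbh**2 / target.mean_dbh
        dbh = rng.gamma(shape, scale, size=n)
        dbh = (dbh - dbh.mean()) / dbh.std(ddof=1)  # exact sample moments
        dbh = target.mean_dbh + target.sd_dbh * dbh
        dbh = np.maximum(dbh, dbh_min + 0.1)
    dbh = np.sort(dbh)
    # enforce the large-tree count on the upper tail
    dbh[-n_large or len(dbh):] = np.maximum(dbh[-n_large or len(dbh):], large_dbh)
    if n_large < n:
        small = slice(0, n - n_large)
        dbh[small] = np.minimum(dbh[small], large_dbh - 0.1)
    plot_id, period = "SYN", 3
    return [TreeRecord(plot_id, period, float(d), "live") for d in dbh]


def gen_dem(
    kind: str,
    shape: tuple[int, int] = (50, 50),
    cell_size: float = 20.0,
    seed: int = 0,
    *,
    gradient: float = 0.1,
    relief: float = 50.0,
) -> RasterGrid:
    """Small DEM fixtures with known properties.

    ``plane``: z = gradient * x (exact analytic slope atan(gradient));
    ``valley``: symmetric V dropping toward the central column (axis
    cells have openness < 90 deg); ``random_smooth``: band-limited
    Gaussian noise, deterministic by seed.
    """
    nrows, ncols = shape
    if nrows < 5 or ncols < 5:
        raise ValueError("DEM fixtures must be at least 5x5")
    x = np.arange(ncols) * cell_size
    if kind == "plane":
        z = np.tile(gradient * x, (nrows, 1))
    elif kind == "valley":
        axis = (ncols - 1) / 2.0
        z = np.tile(gradient * np.abs(x - axis * cell_size), (nrows, 1))
        # tilt along rows so the valley floor drains off-grid
        z = z + 0.001 * cell_size * np.arange(nrows)[:, None]
    elif kind == "random_smooth":
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((nrows, ncols))
        z = ndimage.gaussian_filter(noise, sigma=3.0, mode="nearest")
        z *= relief / max(float(np.ptp(z)), 1e-12)
    else:
        raise ValueError(f"unknown DEM kind {kind!r}")
    return RasterGrid(z, cell_size)
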