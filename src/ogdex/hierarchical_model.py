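"""Varying-slope hierarchical Bayesian model of index development.

The logit-scale index of sample *j* develops linearly with stand age,

    logit(I_j) = beta0 + coeff_j * age_j + plot.eff_site(j)
                 + period.eff_term(j) + e_j,      e_j ~ N(0, sigma_resid^2)

with the age slope itself a quadratic function of the six standardized
environmental covariates,

    coeff_j = beta1 + sum_k ( beta_k1 * x_kj + beta_k2 * x_kj^2 ).

Substituting the second equation into the first gives a linear mixed
model with 16 fixed effects — intercept, age, six age*x_k and six
age*x_k^2 interactions, and two measurement-period indicators (period 3
is the reference) — plus a Gaussian random intercept per plot.  The
sampler is a blocked Gibbs scheme with fully conjugate updates: a joint
multivariate-normal draw for the fixed-effect block, independent normal
draws for plot effects, and inverse-gamma draws for the two variances.
Vague priors follow the common JAGS idiom: N(0, 1e6) on fixed effects,
inverse-gamma(0.001, 0.001) on precisions.

Convergence is judged by the Gelman-Rubin potential scale reduction
factor over (by default) 3 chains started from overdispersed initial
values; chains are automatically extended until every monitored
parameter has R-hat < 1.1 or a round limit is hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .climate_terrain import COVARIATE_NAMES
from .og_index import EpsilonRule, epsilon_from_data, logit_eps

logger = logging.getLogger(__name__)

N_COVARIATES = len(COVARIATE_NAMES)

FIXED_EFFECT_NAMES = (
    ["beta0", "beta1"]
    + [f"beta_lin[{k}]" for k in COVARIATE_NAMES]
    + [f"beta_quad[{k}]" for k in COVARIATE_NAMES]
    + ["period_eff[1]", "period_eff[2]"]
)
PARAM_NAMES = FIXED_EFFECT_NAMES + ["sigma_plot", "sigma_resid"]
N_FIXED = len(FIXED_EFFECT_NAMES)  # 16


@dataclass(frozen=True)
class StandardScaler:
    """Per-covariate training means and SDs, persisted for prediction."""

    mean: dict[str, float]
    sd: dict[str, float]

    def transform(self, samples: pd.DataFrame) -> pd.DataFrame:
        out = samples.copy()
        for name in self.mean:
            out[name] = (out[name] - self.mean[name]) / self.sd[name]
        return out


@dataclass(frozen=True)
class ModelParameters:
    """Point values for every symbol of the development-rate model."""

    beta0: float
    beta1: float
    beta_lin: np.ndarray  # (6,)
    beta_quad: np.ndarray  # (6,)
    period_eff: np.ndarray  # (2,) periods 1 and 2; period 3 is reference
    sigma_plot: float
    sigma_resid: float
    plot_eff: dict[str, float] = field(default_factory=dict)

    def fixed_vector(self) -> np.ndarray:
        return np.concatenate(
            [[self.beta0, self.beta1], self.beta_lin, self.beta_quad, self.period_eff]
        )

    @classmethod
    def from_fixed_vector(
        cls, v: np.ndarray, sigma_plot: float = 0.0, sigma_resid: float = 0.0
    ) -> "ModelParameters":
        v = np.asarray(v, dtype=float)
        k = N_COVARIATES
        return cls(
            beta0=float(v[0]),
            beta1=float(v[1]),
            beta_lin=v[2 : 2 + k].copy(),
            beta_quad=v[2 + k : 2 + 2 * k].copy(),
            period_eff=v[2 + 2 * k : 4 + 2 * k].copy(),
            sigma_plot=sigma_plot,
            sigma_resid=sigma_resid,
        )


@dataclass(frozen=True)
class Priors:
    """Conjugate vague priors (JAGS idiom)."""

    beta_var: float = 1e6
    ig_shape: float = 0.001
    ig_rate: float = 0.001


@dataclass(frozen=True)
class FitConfig:
    n_chains: int = 3
    burn_in: int = 1000
    iterations: int = 10_000
    max_extension_rounds: int = 3
    seed: int = 0
    priors: Priors = field(default_factory=Priors)
    init_sd: float = 2.0
    rhat_threshold: float = 1.1


@dataclass
class PosteriorChains:
    """Post-burn-in draws: (n_chains, n_draws, n_params) with names.

    Plot random intercepts are not stored per draw; their running
    posterior means live in ``plot_eff_mean``.
    """

    draws: np.ndarray
    names: list[str]
    burn_in: int
    seeds: list[int]
    plot_eff_mean: dict[str, float]

    def parameter(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.names.index(name)]

    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])


@dataclass(frozen=True)
class ConvergenceReport:
    rhat: dict[str, float]
    converged: bool
    extension_rounds: int


@dataclass
class FitResult:
    chains: PosteriorChains
    convergence: ConvergenceReport
    scaler: StandardScaler
    epsilon: EpsilonRule
    config: FitConfig
    response: str

    def params(self, estimator: str = "mean") -> ModelParameters:
        """Posterior point estimates as :class:`ModelParameters`."""
        flat = self.chains.flat()
        if estimator == "mean":
            point = flat.mean(axis=0)
        elif estimator == "median":
            point = np.median(flat, axis=0)
        else:
            raise ValueError("estimator must be 'mean' or 'median'")
        p = ModelParameters.from_fixed_vector(
            point[:N_FIXED], sigma_plot=float(point[-2]), sigma_resid=float(point[-1])
        )
        return replace(p, plot_eff=dict(self.chains.plot_eff_mean))

    def summary(self) -> pd.DataFrame:
        return posterior_summary(self.chains)


def standardize(
    samples: pd.DataFrame, scaler: StandardScaler | None = None
) -> tuple[pd.DataFrame, StandardScaler]:
    """Z-score the six covariates; fit a new scaler or apply a stored one."""
    if scaler is None:
        mean, sd = {}, {}
        for name in COVARIATE_NAMES:
            col = samples[name].to_numpy(dtype=float)
            s = float(col.std(ddof=1))
            if not np.isfinite(s) or s == 0.0:
                raise ValueError(f"covariate {name!r} has zero variance")
            mean[name] = float(col.mean())
            sd[name] = s
        scaler = StandardScaler(mean, sd)
    return scaler.transform(samples), scaler


def build_design(samples: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix for the combined model (16 fixed-effect columns).

    Columns: intercept, age, age*x_k (6), age*x_k^2 (6), period-1 and
    period-2 indicators.  Quadratic terms square the *standardized*
    covariate.  Returns (X, plot_index, plot_ids) where ``plot_index``
    maps each row to its plot for the random intercept.
    """
    n = len(samples)
    age = samples["age"].to_numpy(dtype=float)
    periods = samples["period"].to_numpy()
    if not np.isin(periods, (1, 2, 3)).all():
        bad = sorted(set(periods) - {1, 2, 3})
        raise ValueError(f"unknown period code(s) {bad}")
    X = np.empty((n, N_FIXED), dtype=float)
    X[:, 0] = 1.0
    X[:, 1] = age
    for k, name in enumerate(COVARIATE_NAMES):
        x = samples[name].to_numpy(dtype=float)
        X[:, 2 + k] = age * x
        X[:, 2 + N_COVARIATES + k] = age * x**2
    X[:, -2] = (periods == 1).astype(float)
    X[:, -1] = (periods == 2).astype(float)
    plot_ids = pd.unique(samples["plot_id"]).tolist()
    lookup = {p: i for i, p in enumerate(plot_ids)}
    plot_index = np.array([lookup[p] for p in samples["plot_id"]], dtype=np.int64)
    return X, plot_index, plot_ids


def log_likelihood(
    params: ModelParameters, y: np.ndarray, X: np.ndarray, plot_index: np.ndarray,
    plot_ids: list[str],
) -> float:
    """Gaussian log-likelihood given parameters (plot effects as given)."""
    u = np.array([params.plot_eff.get(p, 0.0) for p in plot_ids])
    mu = X @ params.fixed_vector() + u[plot_index]
    s2 = params.sigma_resid**2
    return float(-0.5 * np.sum((y - mu) ** 2 / s2 + np.log(2 * np.pi * s2)))


class _GibbsState:
    """Mutable state of one chain (allows extension runs).

    Initial values are overdispersed around the least-squares solution,
    scaled per coefficient by its standard error: design columns span
    orders of magnitude (age interactions vs period indicators), so a
    fixed-scale start would place chains absurdly far in likelihood
    terms and stall burn-in.
    """

    def __init__(self, rng, y, X, n_groups, init_sd):
        self.rng = rng
        n, p = X.shape
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ ols
        s2 = float(resid @ resid) / max(n - p, 1)
        se = np.sqrt(np.diag(s2 * np.linalg.pinv(X.T @ X)))
        self.beta = ols + init_sd * se * rng.standard_normal(p)
        self.u = np.zeros(n_groups)
        self.sigma2 = s2 * float(rng.uniform(0.5, 2.0))
        self.sigma2_u = float(rng.uniform(0.1, 1.0)) * s2


def _run_gibbs(
    state: _GibbsState,
    y: np.ndarray,
    X: np.ndarray,
    plot_index: np.ndarray,
    n_groups: int,
    n_iter: int,
    priors: Priors,
    *,
    include_group: bool = True,
    fixed_sigma2: float | None = None,
    record_from: int = 0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Run ``n_iter`` Gibbs sweeps, recording draws from ``record_from`` on.

    Returns (draws[(n_rec, p+2)], sum of u over recorded sweeps, n_rec).
    """
    rng = state.rng
    n, p = X.shape
    XtX = X.T @ X
    counts = np.bincount(plot_index, minlength=n_groups).astype(float)
    prior_prec = np.eye(p) / priors.beta_var
    a, b = priors.ig_shape, priors.ig_rate
    n_rec = n_iter - record_from
    draws = np.empty((n_rec, p + 2))
    u_sum = np.zeros(n_groups)
    rec = 0
    for it in range(n_iter):
        # plot random intercepts | rest
        if include_group:
            resid = y - X @ state.beta
            sums = np.bincount(plot_index, weights=resid, minlength=n_groups)
            var_u = 1.0 / (counts / state.sigma2 + 1.0 / state.sigma2_u)
            mean_u = var_u * sums / state.sigma2
            state.u = mean_u + np.sqrt(var_u) * rng.standard_normal(n_groups)
            # plot-effect variance | u
            state.sigma2_u = _inv_gamma(
                rng, a + 0.5 * n_groups, b + 0.5 * float(state.u @ state.u)
            )
        # fixed-effect block | rest (joint MVN draw)
        r = y - (state.u[plot_index] if include_group else 0.0)
        prec = XtX / state.sigma2 + prior_prec
        chol = np.linalg.cholesky(prec)
        rhs = X.T @ r / state.sigma2
        mean_beta = np.linalg.solve(prec, rhs)
        z = rng.standard_normal(p)
        state.beta = mean_beta + np.linalg.solve(chol.T, z)
        # residual variance | rest
        resid2 = r - X @ state.beta
        if fixed_sigma2 is None:
            state.sigma2 = _inv_gamma(
                rng, a + 0.5 * n, b + 0.5 * float(resid2 @ resid2)
            )
        else:
            state.sigma2 = fixed_sigma2
        if it >= record_from:
            draws[rec, :p] = state.beta
            draws[rec, p] = np.sqrt(state.sigma2_u)
            draws[rec, p + 1] = np.sqrt(state.sigma2)
            u_sum += state.u
            rec += 1
    return draws, u_sum, rec


def _inv_gamma(rng, shape: float, rate: float) -> float:
    return float(rate / rng.gamma(shape, 1.0))


def fit(
    samples: pd.DataFrame,
    response: str = "I_og",
    config: FitConfig = FitConfig(),
    *,
    scaler: StandardScaler | None = None,
    epsilon: EpsilonRule | None = None,
) -> FitResult:
    """Fit the varying-slope model to one index response by Gibbs MCMC.

    ``samples`` must carry plot_id, period, age, the six covariates (raw
    scale; standardization happens here) and the response column of
    proportions in [0, 1].  The epsilon rule for the logit transform is
    derived from the response unless given.  Chains are extended by
    ``config.iterations`` draws per round until all R-hat < threshold.
    """
    if samples["plot_id"].nunique() < 2:
        raise ValueError("need at least 2 plots to fit the hierarchical model")
    std, scaler = standardize(samples, scaler)
    X, plot_index, plot_ids = build_design(std)
    cond = np.linalg.cond(X)
    if cond > 1e10:
        raise ValueError(f"design matrix is singular/collinear (cond={cond:.2e})")
    p_obs = samples[response].to_numpy(dtype=float)
    if np.all(p_obs == p_obs[0]):
        raise ValueError("all response values identical; model unidentifiable")
    if epsilon is None:
        epsilon = epsilon_from_data(p_obs)
    y = logit_eps(p_obs, epsilon)
    n_groups = len(plot_ids)

    states = []
    seeds = []
    for c in range(config.n_chains):
        seed_c = (config.seed + c) % (2**31)
        seeds.append(seed_c)
        rng = np.random.default_rng(seed_c)
        states.append(_GibbsState(rng, y, X, n_groups, config.init_sd))

    chain_draws = [
        np.empty((0, N_FIXED + 2)) for _ in range(config.n_chains)
    ]
    u_total = np.zeros(n_groups)
    n_rec_total = 0
    rounds = 0
    converged = False
    rhats: dict[str, float] = {}
    while True:
        burn = config.burn_in if rounds == 0 else 0
        n_iter = burn + config.iterations
        for c, state in enumerate(states):
            draws, u_sum, n_rec = _run_gibbs(
                state, y, X, plot_index, n_groups, n_iter, config.priors,
                record_from=burn,
            )
            chain_draws[c] = np.vstack([chain_draws[c], draws])
            u_total += u_sum
        n_rec_total = chain_draws[0].shape[0]
        rounds += 1
        stacked = np.stack(chain_draws)  # (chains, draws, params)
        rhats = {
            name: rhat(stacked[:, :, i]) for i, name in enumerate(PARAM_NAMES)
        }
        converged = all(v < config.rhat_threshold for v in rhats.values())
        if converged or rounds > config.max_extension_rounds:
            break
        logger.info(
            "R-hat >= %.2f after round %d (max %.3f); extending chains",
            config.rhat_threshold, rounds, max(rhats.values()),
        )
    if not converged:
        logger.warning("chains not converged after %d rounds", rounds)

    plot_eff_mean = dict(
        zip(plot_ids, u_total / (n_rec_total * config.n_chains))
    )
    chains = PosteriorChains(
        draws=np.stack(chain_draws),
        names=list(PARAM_NAMES),
        burn_in=config.burn_in,
        seeds=seeds,
        plot_eff_mean={str(k): float(v) for k, v in plot_eff_mean.items()},
    )
    report = ConvergenceReport(rhats, converged, rounds - 1)
    return FitResult(chains, report, scaler, epsilon, config, response)


def rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor.

    ``chains`` is (n_chains, n_draws).  With chain means m_c, within-
    chain variance W = mean_c s_c^2 and between-chain variance
    B = n * var_c(m_c), the statistic is sqrt(((n-1)/n * W + B/n) / W).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least 2 chains")
    m, n = chains.shape
    if n < 10:
        raise ValueError("need at least 10 draws per chain")
    w = float(chains.var(axis=1, ddof=1).mean())
    if w == 0.0:
        raise ValueError("zero within-chain variance; R-hat undefined")
    b = n * float(chains.mean(axis=1).var(ddof=1))
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def posterior_summary(chains: PosteriorChains) -> pd.DataFrame:
    """Per-parameter mean, median, SD, 95% interval and significance flag.

    A parameter is flagged significant when its central 95% credible
    interval excludes zero.
    """
    flat = chains.flat()
    if flat.size == 0:
        raise ValueError("empty chains")
    q = np.percentile(flat, [2.5, 50.0, 97.5], axis=0)
    out = pd.DataFrame(
        {
            "mean": flat.mean(axis=0),
            "median": q[1],
            "sd": flat.std(axis=0, ddof=1),
            "q2.5": q[0],
            "q97.5": q[2],
        },
        index=chains.names,
    )
    out["significant"] = (out["q2.5"] > 0) | (out["q97.5"] < 0)
    return out
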