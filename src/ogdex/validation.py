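"""Goodness of fit, holdout cross-validation, and parameter recovery.

R^2 follows the logit-scale convention used for the development-rate
model: the squared Pearson correlation between the epsilon-logit of the
observed index and the fixed-effect linear predictor.  Plot random
effects are excluded from the prediction; measurement-period effects
are included.

Cross-validation is the holdout method: refit on a random 90% of the
sample rows, score R^2 on the held-out 10%, repeated (100 times in the
reference analysis).  The epsilon rule and covariate scaler are refit
on every training split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import hierarchical_model as hm
from .og_index import logit_eps
from .synthetic_data import GeneratorConfig, gen_plot_samples

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVResult:
    r2: np.ndarray  # one value per completed repetition
    mean: float
    sd: float
    train_fraction: float
    n_reps: int
    seed: int
    skipped: int = 0


def fixed_effect_predictor(fit: hm.FitResult, samples: pd.DataFrame) -> np.ndarray:
    """Linear predictor with period effects but without plot effects."""
    std = fit.scaler.transform(samples)
    X, _, _ = hm.build_design(std)
    return X @ fit.params("mean").fixed_vector()


def r_squared(fit: hm.FitResult, samples: pd.DataFrame) -> float:
    """Squared Pearson correlation of observed vs predicted, logit scale."""
    obs = logit_eps(samples[fit.response].to_numpy(dtype=float), fit.epsilon)
    pred = fixed_effect_predictor(fit, samples)
    if np.std(obs) == 0 or np.std(pred) == 0:
        raise ValueError("zero variance in observed or predicted values")
    r = np.corrcoef(obs, pred)[0, 1]
    return float(r * r)


def holdout_cv(
    samples: pd.DataFrame,
    response: str = "I_og",
    train_fraction: float = 0.9,
    n_reps: int = 100,
    seed: int = 0,
    fit_config: hm.FitConfig | None = None,
) -> CVResult:
    """Repeated random-split holdout validation.

    Splits are by sample row (repeated measurements of one plot may fall
    on both sides, as in the reference procedure; split by plot instead
    by grouping upstream if leakage matters for your question).
    Degenerate repetitions (zero-variance test response) are skipped
    with a warning.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie strictly inside (0, 1)")
    if fit_config is None:
        fit_config = hm.FitConfig()
    rng = np.random.default_rng(seed)
    n = len(samples)
    n_train = int(round(train_fraction * n))
    if n_train < 2 or n_train >= n:
        raise ValueError("split leaves an empty train or test set")
    r2s = []
    skipped = 0
    for rep in range(n_reps):
        perm = rng.permutation(n)
        train = samples.iloc[perm[:n_train]]
        test = samples.iloc[perm[n_train:]]
        if train["plot_id"].nunique() < 2 or test[response].std() == 0:
            logger.warning("repetition %d degenerate; skipped", rep)
            skipped += 1
            continue
        rep_config = replace(fit_config, seed=fit_config.seed + rep)
        fit = hm.fit(train, response, rep_config)
        r2s.append(r_squared(fit, test))
    r2 = np.array(r2s)
    return CVResult(
        r2=r2,
        mean=float(r2.mean()) if r2.size else float("nan"),
        sd=float(r2.std(ddof=1)) if r2.size > 1 else float("nan"),
        train_fraction=train_fraction,
        n_reps=n_reps,
        seed=seed,
        skipped=skipped,
    )


@dataclass(frozen=True)
class RecoveryReport:
    per_parameter: pd.DataFrame  # true value, mean estimate, bias, coverage
    coverage: float  # pooled 95% CI coverage over fixed effects
    sigma_resid_rel_error: float
    n_replicates: int
    n_converged: int


def recovery_experiment(
    generator: GeneratorConfig,
    fit_config: hm.FitConfig,
    n_replicates: int = 10,
    response: str = "I_og",
) -> RecoveryReport:
    """Simulate -> fit -> compare, replicated.

    For each replicate a fresh dataset is generated (seeds ``generator.seed
    + r``), the model fit, and each true fixed effect checked against its
    95% credible interval.  Coverage pools all fixed effects over
    converged replicates; non-converged replicates are excluded with a
    warning.
    """
    truth = generator.true_params.fixed_vector()
    hits = np.zeros(hm.N_FIXED)
    est_sum = np.zeros(hm.N_FIXED)
    sigma_est = []
    n_conv = 0
    for r in range(n_replicates):
        gcfg = replace(generator, seed=generator.seed + r)
        data = gen_plot_samples(gcfg)
        fcfg = replace(fit_config, seed=fit_config.seed + 1000 * r)
        fit = hm.fit(data, response, fcfg)
        if not fit.convergence.converged:
            logger.warning("replicate %d not converged; excluded from coverage", r)
            continue
        n_conv += 1
        summ = fit.summary()
        lo = summ["q2.5"].to_numpy()[: hm.N_FIXED]
        hi = summ["q97.5"].to_numpy()[: hm.N_FIXED]
        est = summ["mean"].to_numpy()[: hm.N_FIXED]
        hits += (truth >= lo) & (truth <= hi)
        est_sum += est
        sigma_est.append(summ.loc["sigma_resid", "mean"])
    if n_conv == 0:
        raise RuntimeError("no replicate converged; cannot report coverage")
    mean_est = est_sum / n_conv
    per_param = pd.DataFrame(
        {
            "true": truth,
            "mean_estimate": mean_est,
            "bias": mean_est - truth,
            "coverage": hits / n_conv,
        },
        index=hm.FIXED_EFFECT_NAMES,
    )
    sigma_true = generator.true_params.sigma_resid
    rel = float(np.mean(sigma_est) / sigma_true - 1.0)
    return RecoveryReport(
        per_parameter=per_param,
        coverage=float(hits.sum() / (hm.N_FIXED * n_conv)),
        sigma_resid_rel_error=rel,
        n_replicates=n_replicates,
        n_converged=n_conv,
    )
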