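"""Delimited-text table I/O with strict, line-citing validation.

All tables are comma-delimited with a fixed header.  Documented dialects:

* tree tables:       plot_id,period,dbh_cm,status
* structure tables:  plot_id,period,age,mean_dbh,sd_dbh,density,large_density
* sample tables:     plot_id,period,age,<6 covariates>,I_og[,I_*]
* chain tables:      one row per draw, one column per parameter

Malformed rows raise with the 1-based file line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .stand_metrics import TreeRecord

TREE_COLUMNS = ["plot_id", "period", "dbh_cm", "status"]


class TableFormatError(ValueError):
    pass


def _validated_read(path: str | Path, expected_first: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise TableFormatError(f"{path}: empty file")
    header = lines[0].split(",")
    if expected_first is not None and header[: len(expected_first)] != expected_first:
        raise TableFormatError(
            f"{path}: line 1: expected header starting {expected_first}, got {header}"
        )
    ncol = len(header)
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        if len(line.split(",")) != ncol:
            raise TableFormatError(
                f"{path}: line {lineno}: expected {ncol} column(s), "
                f"got {len(line.split(','))}"
            )
    return pd.read_csv(path)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read any documented comma-delimited table, validating column counts."""
    return _validated_read(path)


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_tree_table(path: str | Path) -> list[TreeRecord]:
    frame = _validated_read(path, TREE_COLUMNS)
    return [
        TreeRecord(str(r.plot_id), int(r.period), float(r.dbh_cm), str(r.status))
        for r in frame.itertuples()
    ]


def write_tree_table(trees: list[TreeRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(t.plot_id, t.period, t.dbh, t.status) for t in trees], columns=TREE_COLUMNS
    )
    frame.to_csv(path, index=False)


def write_chains(fit, path: str | Path) -> None:
    """Persist posterior draws as delimited text plus a JSON metadata side-car.

    The side-car records seeds, priors, burn-in, the covariate scaler and
    the epsilon rule, so predictions are reproducible from disk.
    """
    path = Path(path)
    flat = fit.chains.flat()
    chain_col = np.repeat(np.arange(fit.chains.draws.shape[0]), fit.chains.draws.shape[1])
    frame = pd.DataFrame(flat, columns=fit.chains.names)
    frame.insert(0, "chain", chain_col)
    frame.to_csv(path, index=False)
    meta = {
        "seeds": fit.chains.seeds,
        "burn_in": fit.chains.burn_in,
        "response": fit.response,
        "priors": {
            "beta_var": fit.config.priors.beta_var,
            "ig_shape": fit.config.priors.ig_shape,
            "ig_rate": fit.config.priors.ig_rate,
        },
        "epsilon": {"eps_low": fit.epsilon.eps_low, "eps_high": fit.epsilon.eps_high},
        "scaler": {"mean": fit.scaler.mean, "sd": fit.scaler.sd},
        "rhat": fit.convergence.rhat,
        "converged": fit.convergence.converged,
        "plot_eff_mean": fit.chains.plot_eff_mean,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(meta, fh, indent=2)
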