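"""Old-growth index and the epsilon-adjusted logit transform.

The old-growth index of a stand is the mean of four subindices, each a
structural variable rescaled between its young-forest and old-growth
reference medians::

    I_i = (x_i - x_i,young) / (x_i,old - x_i,young),  clipped to [0, 1]
    I_og = mean_i I_i

The formula handles variables that decrease with stand age (x_old <
x_young, e.g. live-tree density) without special-casing: the rescaled
value is still 0 at the young median and 1 at the old median.

Index values are proportions in [0, 1]; before regression they are
logit-transformed.  Exact 0s and 1s are moved inward by the smallest
nonzero observed value at each boundary (the "epsilon" adjustment for
proportion data), then logit applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stand_metrics import STRUCTURE_VARS, ReferenceBounds, StandStructure

__all__ = [
    "OldGrowthIndex",
    "EpsilonRule",
    "subindex",
    "og_index",
    "index_table",
    "epsilon_from_data",
    "logit_eps",
    "inv_logit",
]


@dataclass(frozen=True)
class OldGrowthIndex:
    """Composite index ``value`` plus the four subindices it averages."""

    subindices: dict[str, float]
    value: float


@dataclass(frozen=True)
class EpsilonRule:
    """Boundary adjustment for the logit of proportion data.

    ``eps_low`` replaces exact 0s, ``1 - eps_high`` replaces exact 1s.
    Both epsilons derive from the smallest nonzero value (resp. nonzero
    complement) observed in the data, capped at 0.5.
    """

    eps_low: float
    eps_high: float

    def __post_init__(self) -> None:
        for name, v in (("eps_low", self.eps_low), ("eps_high", self.eps_high)):
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @property
    def symmetric(self) -> "EpsilonRule":
        """Single-epsilon variant using min(eps_low, eps_high) at both ends."""
        e = min(self.eps_low, self.eps_high)
        return EpsilonRule(e, e)


def subindex(x: float, x_young: float, x_old: float):
    """Rescale ``x`` between the young and old reference values, clip to [0, 1].

    Works unchanged for decreasing variables (``x_old < x_young``): values
    beyond either reference are assigned that reference (i.e. clipped).
    Accepts scalars or arrays.
    """
    if x_young == x_old:
        raise ValueError("x_young and x_old must differ")
    raw = (np.asarray(x, dtype=float) - x_young) / (x_old - x_young)
    out = np.clip(raw, 0.0, 1.0)
    return float(out) if np.isscalar(x) or np.ndim(x) == 0 else out


def og_index(structure: StandStructure, bounds: ReferenceBounds) -> OldGrowthIndex:
    """Old-growth index of one stand: mean of the four subindices."""
    subs: dict[str, float] = {}
    for var in STRUCTURE_VARS:
        x = getattr(structure, var)
        if not math.isfinite(x):
            raise ValueError(f"structural variable {var!r} is missing")
        subs[var] = subindex(x, bounds.young[var], bounds.old[var])
    return OldGrowthIndex(subs, float(np.mean(list(subs.values()))))


def index_table(structures: pd.DataFrame, bounds: ReferenceBounds) -> pd.DataFrame:
    """Vectorised :func:`og_index` over a structure table.

    Returns the input with subindex columns ``I_<var>`` and the composite
    ``I_og`` appended.
    """
    out = structures.copy()
    subs = []
    for var in STRUCTURE_VARS:
        if out[var].isna().any():
            bad = out.index[out[var].isna()][0]
            raise ValueError(f"structural variable {var!r} missing at row {bad}")
        col = subindex(out[var].to_numpy(), bounds.young[var], bounds.old[var])
        out[f"I_{var}"] = col
        subs.append(col)
    out["I_og"] = np.mean(subs, axis=0)
    return out


def epsilon_from_data(values) -> EpsilonRule:
    """Derive the epsilon rule from observed proportions.

    ``eps_low`` is the smallest nonzero value; ``eps_high`` the smallest
    nonzero complement ``1 - v``; both capped at 0.5.  Errors when every
    value sits exactly on a boundary (the transform is then undefined).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.any((v < 0) | (v > 1)):
        raise ValueError("values must be proportions in [0, 1]")
    interior = v[(v > 0) & (v < 1)]
    if interior.size == 0:
        raise ValueError("all values lie on {0, 1}; epsilon undefined")
    eps_low = min(float(v[v > 0].min()), 0.5)
    comp = 1.0 - v
    eps_high = min(float(comp[comp > 0].min()), 0.5)
    return EpsilonRule(eps_low, eps_high)


def logit_eps(p, rule: EpsilonRule):
    """Logit of a proportion with boundary values moved inward by epsilon.

    p = 0 maps to ``eps_low``; p = 1 maps to ``1 - eps_high``; interior
    values pass through untouched.  Accepts scalars or arrays.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    adj = np.where(arr == 0.0, rule.eps_low, np.where(arr == 1.0, 1.0 - rule.eps_high, arr))
    out = np.log(adj / (1.0 - adj))
    return float(out) if np.ndim(p) == 0 else out


def inv_logit(x):
    """Inverse logit (logistic); maps the real line into (0, 1)."""
    out = 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
    return float(out) if np.ndim(x) == 0 else out
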