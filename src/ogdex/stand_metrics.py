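"""Stand structural variables from tree lists.

Four structural variables separate old-growth from young stands in
temperate broad-leaved forest inventory data:

* mean dbh of live trees with dbh > 5 cm,
* standard deviation of dbh for those trees,
* density (stems/ha) of live trees with dbh > 5 cm,
* density (stems/ha) of live "large" trees (dbh >= 40 cm).

The first three typically increase with stand age; live-tree density
typically decreases.  Plots are screened by Kira's warmth index to
restrict analyses to cool- and warm-temperate broad-leaved forest
(warmth index 45-180 degC month).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: dbh cut (cm) below/at which stems are excluded from all variables (strict ">").
DBH_MIN_CM = 5.0
#: dbh threshold (cm) at/above which a live stem counts as a large tree (inclusive).
LARGE_DBH_CM = 40.0
#: default plot area, ha (inventory plot geometry is configurable).
DEFAULT_PLOT_AREA_HA = 0.1
#: default upper age (years) of the young reference stands.
YOUNG_AGE_MAX = 30.0

STRUCTURE_VARS = ("mean_dbh", "sd_dbh", "tree_density", "large_tree_density")

WARMTH_MIN = 45.0
WARMTH_MAX = 180.0


@dataclass(frozen=True)
class TreeRecord:
    """One measured stem: plot, measurement period, dbh (cm), live/dead."""

    plot_id: str
    period: int
    dbh: float
    status: str  # "live" | "dead"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dbh) and self.dbh > 0):
            raise ValueError(f"dbh must be finite and positive, got {self.dbh}")
        if self.period not in (1, 2, 3):
            raise ValueError(f"period must be 1, 2 or 3, got {self.period}")
        if self.status not in ("live", "dead"):
            raise ValueError(f"status must be 'live' or 'dead', got {self.status!r}")


@dataclass(frozen=True)
class StandStructure:
    """The four structural variables of one plot x period sample.

    ``mean_dbh`` and ``sd_dbh`` are NaN when no stem qualifies;
    ``sd_dbh`` is 0 when exactly one stem qualifies (sample SD undefined,
    reported as zero spread).
    """

    mean_dbh: float
    sd_dbh: float
    tree_density: float
    large_tree_density: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_dbh": self.mean_dbh,
            "sd_dbh": self.sd_dbh,
            "tree_density": self.tree_density,
            "large_tree_density": self.large_tree_density,
        }

    def is_complete(self) -> bool:
        return all(math.isfinite(v) for v in self.as_dict().values())


@dataclass(frozen=True)
class ReferenceBounds:
    """Per-variable young/old medians anchoring the index rescaling.

    ``young[v]`` is the median of variable ``v`` over young reference
    stands, ``old[v]`` the median over old-growth reference plots.  The
    two must differ for every variable or the subindex is undefined.
    """

    young: dict[str, float]
    old: dict[str, float]

    def __post_init__(self) -> None:
        for var in STRUCTURE_VARS:
            if var not in self.young or var not in self.old:
                raise ValueError(f"reference bounds missing variable {var!r}")
            if self.young[var] == self.old[var]:
                raise ValueError(
                    f"young and old medians coincide for {var!r} "
                    f"({self.young[var]}); subindex undefined"
                )


def compute_stand_structure(
    trees: Iterable[TreeRecord],
    plot_area: float = DEFAULT_PLOT_AREA_HA,
    *,
    dbh_min: float = DBH_MIN_CM,
    large_dbh: float = LARGE_DBH_CM,
) -> StandStructure:
    """Compute the four structural variables for one plot x period tree list.

    Only live trees with dbh strictly above ``dbh_min`` enter any
    variable; large trees are those at or above ``large_dbh``.  Densities
    are per hectare (count / ``plot_area``).  SD uses the n-1 denominator.
    """
    if plot_area <= 0:
        raise ValueError(f"plot_area must be positive, got {plot_area}")
    trees = list(trees)
    if trees:
        keys = {(t.plot_id, t.period) for t in trees}
        if len(keys) > 1:
            raise ValueError(f"records span multiple plot x period keys: {sorted(keys)}")
    dbh = np.array(
        [t.dbh for t in trees if t.status == "live" and t.dbh > dbh_min], dtype=float
    )
    if dbh.size == 0:
        return StandStructure(float("nan"), float("nan"), 0.0, 0.0)
    mean = float(dbh.mean())
    sd = float(dbh.std(ddof=1)) if dbh.size >= 2 else 0.0
    density = dbh.size / plot_area
    large = int((dbh >= large_dbh).sum()) / plot_area
    return StandStructure(mean, sd, density, large)


def screen_by_warmth(
    samples: pd.DataFrame,
    *,
    wi_min: float = WARMTH_MIN,
    wi_max: float = WARMTH_MAX,
) -> pd.DataFrame:
    """Retain plot samples with warmth index in [wi_min, wi_max], inclusive.

    Rows with a missing warmth index are dropped with a logged warning.
    Row order is preserved; the operation is idempotent.
    """
    if "warmth_index" not in samples.columns:
        raise KeyError("samples must carry a 'warmth_index' column")
    wi = samples["warmth_index"]
    missing = wi.isna()
    if missing.any():
        logger.warning(
            "dropping %d sample(s) with missing warmth index", int(missing.sum())
        )
    keep = (wi >= wi_min) & (wi <= wi_max) & ~missing
    return samples.loc[keep]


def reference_bounds(
    young_samples: Sequence[StandStructure] | pd.DataFrame,
    old_samples: Sequence[StandStructure] | pd.DataFrame,
) -> ReferenceBounds:
    """Per-variable medians of the young and old reference sets.

    Medians (not means) damp the influence of outlier stands; even-sized
    sets take the midpoint of the two central order statistics.
    """
    young = _structure_frame(young_samples)
    old = _structure_frame(old_samples)
    if young.empty or old.empty:
        raise ValueError("both reference sets must be non-empty")
    return ReferenceBounds(
        young={v: float(young[v].median()) for v in STRUCTURE_VARS},
        old={v: float(old[v].median()) for v in STRUCTURE_VARS},
    )


def _structure_frame(samples: Sequence[StandStructure] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        missing = [v for v in STRUCTURE_VARS if v not in samples.columns]
        if missing:
            raise KeyError(f"structure table missing column(s) {missing}")
        return samples[list(STRUCTURE_VARS)]
    return pd.DataFrame([s.as_dict() for s in samples], columns=list(STRUCTURE_VARS))
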