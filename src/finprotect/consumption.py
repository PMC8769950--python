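"""Monthly consumption and out-of-pocket (OOP) aggregates.

The survey records food and non-food consumption per 30 days (both already
including in-kind and home-produced values; tobacco is part of non-food and
is never subtracted), outpatient and non-medical health payments on a 30-day
recall, and inpatient payments on a 12-month recall.  The aggregate
harmonizes everything to a 30-day window:

    total_exp      = food_exp + nonfood_exp
    per_capita_exp = total_exp / hh_size
    oop_monthly    = oop_outpatient_30d + oop_nonmedical_30d
                     + oop_inpatient_annual / inpatient_divisor

``inpatient_divisor`` defaults to 12 (annual -> monthly); it is exposed so
the downward bias this conversion puts on catastrophic-spending incidence
can be studied.  OOP is part of consumption and is *not* netted out of the
denominator here; consumption net of OOP appears only in the
impoverishment analysis.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import DomainError

log = logging.getLogger(__name__)


class ConsumptionAggregate(NamedTuple):
    total_exp: float
    food_exp: float
    nonfood_exp: float
    per_capita_exp: float
    oop_monthly: float


def aggregate_consumption(
    food_exp: float,
    nonfood_exp: float,
    hh_size: int,
    oop_outpatient_30d: float = 0.0,
    oop_inpatient_annual: float = 0.0,
    oop_nonmedical_30d: float = 0.0,
    inpatient_divisor: float = 12.0,
) -> ConsumptionAggregate:
    """Scalar aggregate for a single household (see module docstring)."""
    for name, v in (
        ("food_exp", food_exp),
        ("nonfood_exp", nonfood_exp),
        ("oop_outpatient_30d", oop_outpatient_30d),
        ("oop_inpatient_annual", oop_inpatient_annual),
        ("oop_nonmedical_30d", oop_nonmedical_30d),
    ):
        if v < 0:
            raise DomainError(f"{name} must be >= 0, got {v}")
    if hh_size < 1:
        raise DomainError(f"hh_size must be >= 1, got {hh_size}")
    total = food_exp + nonfood_exp
    if total == 0:
        raise DomainError("degenerate household: total expenditure is 0")
    oop = oop_outpatient_30d + oop_nonmedical_30d + oop_inpatient_annual / inpatient_divisor
    return ConsumptionAggregate(total, food_exp, nonfood_exp, total / hh_size, oop)


def add_aggregates(df: pd.DataFrame, inpatient_divisor: float = 12.0) -> pd.DataFrame:
    """Append ``total_exp``, ``per_capita_exp``, ``oop_monthly``, ``any_oop``
    and a ``degenerate`` flag to a household table.

    Households with zero total expenditure cannot enter ratio-based
    indicators; they are flagged (``degenerate=1``) and their count logged,
    for exclusion downstream via :func:`drop_degenerate`.
    """
    money = [
        "food_exp",
        "nonfood_exp",
        "oop_outpatient_30d",
        "oop_inpatient_annual",
        "oop_nonmedical_30d",
    ]
    arr = df[money].to_numpy(dtype=float)
    if (arr < 0).any():
        col = money[int(np.argwhere(arr < 0)[0][1])]
        raise DomainError(f"negative value in column '{col}'")
    out = df.copy()
    out["total_exp"] = out["food_exp"] + out["nonfood_exp"]
    out["per_capita_exp"] = out["total_exp"] / out["hh_size"]
    out["oop_monthly"] = (
        out["oop_outpatient_30d"]
        + out["oop_nonmedical_30d"]
        + out["oop_inpatient_annual"] / inpatient_divisor
    )
    out["any_oop"] = (out["oop_monthly"] > 0).astype(np.int64)
    degenerate = (out["total_exp"] == 0).to_numpy()
    out["degenerate"] = degenerate.astype(np.int64)
    if degenerate.any():
        log.warning("flagged %d degenerate households (total expenditure = 0)",
                    int(degenerate.sum()))
    return out


def drop_degenerate(df: pd.DataFrame) -> pd.DataFrame:
    """Remove rows flagged degenerate by :func:`add_aggregates`."""
    if "degenerate" not in df.columns:
        return df
    n = int(df["degenerate"].sum())
    if n:
        log.info("excluding %d degenerate households", n)
    return df.loc[df["degenerate"] == 0]
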