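"""Poverty lines, impoverishment from health payments, and Pen's parade.

Two poverty lines are supported:

* **Cost of basic needs (CBN).**  The food component prices a fixed food
  basket (quantities per person per day) at market prices; the caller
  attests the basket's caloric norm (stored, not verified).  The non-food
  component is the weighted median per-capita non-food spending of
  households whose per-capita *food* spending lies within a symmetric band
  around the food line.  The poverty line is the sum of the two components.
* **International poverty line (IPL).**  A dollars-per-day norm converted
  at a purchasing-power-parity rate and scaled to the 30-day period.

A household is poor when per-capita expenditure falls *strictly below* the
line.  Impoverishment compares poverty on gross consumption with poverty on
consumption net of out-of-pocket (OOP) health payments: an impoverished
household is gross-non-poor and net-poor.  Headcounts here are
person-weighted (design weight x household size) so they are population
proportions; already-poor households whose position merely deteriorates are
never counted as impoverished.

Pen's parade orders households by gross consumption as a multiple of the
line; the "paint drop" from the gross to the net multiple shows how far OOP
payments pull each household down, and a drop crossing 1 marks an
impoverished household.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd

from .design import DesignEstimate, SurveyDesign, weighted_median, weighted_proportion
from .exceptions import DomainError, PovertyLineError

log = logging.getLogger(__name__)

#: purchasing-power-parity conversion used for the default IPL (local
#: currency units per international dollar) and the daily norm.
DEFAULT_PPP_RATE = 28.27
DEFAULT_DOLLARS_PER_DAY = 1.9
DAYS_PER_PERIOD = 30.0

#: default 11-item food basket: quantities per person per day (kg or litre)
#: and market prices (currency per unit).  The basket is a stylized
#: staple-based diet attested at 2122 kcal/person/day; the package stores
#: but does not verify the caloric norm.
DEFAULT_FOOD_BASKET: dict[str, float] = {
    "rice": 0.380,
    "wheat": 0.040,
    "pulses": 0.030,
    "milk": 0.050,
    "oil": 0.020,
    "meat": 0.010,
    "fish": 0.030,
    "potato": 0.065,
    "vegetables": 0.120,
    "sugar": 0.015,
    "fruit": 0.017,
}
DEFAULT_FOOD_PRICES: dict[str, float] = {
    "rice": 34.0,
    "wheat": 32.0,
    "pulses": 105.0,
    "milk": 60.0,
    "oil": 100.0,
    "meat": 420.0,
    "fish": 180.0,
    "potato": 20.0,
    "vegetables": 25.0,
    "sugar": 55.0,
    "fruit": 60.0,
}
DEFAULT_KCAL_PER_DAY = 2122.0


@dataclass(frozen=True)
class PovertyLine:
    """Per-capita, per-30-day monetary poverty line with provenance."""

    value: float
    kind: Literal["cbn", "ipl", "external"]
    food_component: Optional[float] = None
    nonfood_component: Optional[float] = None
    provenance: str = ""

    def __post_init__(self):
        if self.value <= 0:
            raise DomainError(f"poverty line must be > 0, got {self.value}")
        if self.kind == "cbn":
            if self.food_component is None or self.nonfood_component is None:
                raise DomainError("cbn line requires food and non-food components")
            if abs(self.value - (self.food_component + self.nonfood_component)) > 1e-9:
                raise DomainError("cbn line must equal food + non-food components")


@dataclass
class ImpoverishmentResult:
    """Poverty headcounts gross/net of OOP and the implied impoverishment."""

    headcount_gross: float
    headcount_net: float
    absolute_difference: float
    relative_difference: float
    individuals_pushed: float
    ci_absolute: tuple[float, float]
    estimates: dict[str, DesignEstimate] = field(default_factory=dict)


def cbn_food_line(
    prices: Mapping[str, float],
    basket: Mapping[str, float],
    kcal_per_day: Optional[float] = None,
) -> float:
    """Monthly per-capita cost of the food basket.

    ``basket`` maps item -> units per person per day; ``prices`` maps item ->
    currency per unit.  ``kcal_per_day`` is the caller-attested caloric
    content of the basket (stored in provenance only).  Returns
    ``30 * sum(price * quantity)``.
    """
    total = 0.0
    for item, qty in basket.items():
        if item not in prices:
            raise PovertyLineError(f"no price for basket item '{item}'")
        if qty <= 0 or prices[item] <= 0:
            raise DomainError(f"price and quantity for '{item}' must be > 0")
        total += prices[item] * qty
    if not basket:
        raise PovertyLineError("empty food basket")
    return DAYS_PER_PERIOD * total


def cbn_nonfood_component(
    df: pd.DataFrame,
    food_line: float,
    band: float = 0.10,
    design: Optional[SurveyDesign] = None,
    min_households: int = 20,
) -> float:
    """Weighted median per-capita non-food spending of households whose
    per-capita food spending lies in ``[food_line*(1-band), food_line*(1+band)]``.

    Weights are person weights (design weight x household size).
    """
    if not 0.0 < band < 1.0:
        raise DomainError(f"band must be in (0,1), got {band}")
    if food_line <= 0:
        raise DomainError("food_line must be > 0")
    design = design or SurveyDesign()
    pc_food = df["food_exp"].to_numpy(dtype=float) / df["hh_size"].to_numpy(dtype=float)
    in_band = (pc_food >= food_line * (1.0 - band)) & (pc_food <= food_line * (1.0 + band))
    n_in = int(in_band.sum())
    if n_in < min_households:
        raise PovertyLineError(
            f"only {n_in} households within +/-{band:.0%} of the food line; "
            "widen the band"
        )
    pc_nonfood = df["nonfood_exp"].to_numpy(dtype=float) / df["hh_size"].to_numpy(dtype=float)
    pweights = (
        df[design.weight_column].to_numpy(dtype=float)
        * df["hh_size"].to_numpy(dtype=float)
    )
    return weighted_median(pc_nonfood[in_band], pweights[in_band])


def cbn_line(
    df: pd.DataFrame,
    prices: Mapping[str, float],
    basket: Mapping[str, float],
    band: float = 0.10,
    design: Optional[SurveyDesign] = None,
    kcal_per_day: Optional[float] = None,
) -> PovertyLine:
    """Full cost-of-basic-needs line: priced food basket plus band-median
    non-food allowance."""
    food = cbn_food_line(prices, basket, kcal_per_day)
    nonfood = cbn_nonfood_component(df, food, band=band, design=design)
    note = f"CBN, band +/-{band:.0%}"
    if kcal_per_day:
        note += f", basket attested at {kcal_per_day:g} kcal/person/day"
    return PovertyLine(food + nonfood, "cbn", food, nonfood, note)


def ipl_line(
    ppp_rate: float = DEFAULT_PPP_RATE,
    dollars_per_day: float = DEFAULT_DOLLARS_PER_DAY,
) -> PovertyLine:
    """International poverty line scaled to the 30-day period."""
    if ppp_rate <= 0 or dollars_per_day <= 0:
        raise DomainError("ppp_rate and dollars_per_day must be > 0")
    value = dollars_per_day * ppp_rate * DAYS_PER_PERIOD
    return PovertyLine(
        value, "ipl",
        provenance=f"{dollars_per_day:g} intl$/day at {ppp_rate:g} per intl$",
    )


def poverty_status(
    df: pd.DataFrame, line: PovertyLine, net_of_oop: bool = False
) -> np.ndarray:
    """0/1 poverty flags: per-capita expenditure strictly below the line.

    Net of OOP, per-capita expenditure is ``max(total - oop_monthly, 0) /
    hh_size``; households exactly at the line are non-poor.
    """
    total = df["total_exp"].to_numpy(dtype=float)
    size = df["hh_size"].to_numpy(dtype=float)
    if net_of_oop:
        pc = np.maximum(total - df["oop_monthly"].to_numpy(dtype=float), 0.0) / size
    else:
        pc = total / size
    return (pc < line.value).astype(np.int8)


def impoverishment_flags(df: pd.DataFrame, line: PovertyLine) -> np.ndarray:
    """Gross-non-poor AND net-poor flags per household."""
    gross = poverty_status(df, line, net_of_oop=False)
    net = poverty_status(df, line, net_of_oop=True)
    return ((gross == 0) & (net == 1)).astype(np.int8)


def _person_design(df: pd.DataFrame, design: SurveyDesign):
    pw = (
        df[design.weight_column].to_numpy(dtype=float)
        * df["hh_size"].to_numpy(dtype=float)
    )
    return df.assign(_pweight=pw), design.replace(weight_column="_pweight")


def impoverishment(
    df: pd.DataFrame,
    line: PovertyLine,
    design: SurveyDesign,
    population_total: float,
    relative_definition: Literal["of_gross", "of_net"] = "of_gross",
) -> ImpoverishmentResult:
    """Population impoverishment from OOP payments under a poverty line.

    Headcounts are person-weighted population proportions;
    ``individuals_pushed = absolute_difference * population_total``.  The
    relative difference is the absolute difference expressed in percent of
    the gross (default) or net headcount — the convention is configurable
    because usage varies across the financial-protection literature.
    """
    if population_total <= 0:
        raise DomainError("population_total must be > 0")
    pdf, pdesign = _person_design(df, design)
    gross = poverty_status(df, line, net_of_oop=False)
    net = poverty_status(df, line, net_of_oop=True)
    pushed = impoverishment_flags(df, line)
    est_gross = weighted_proportion(gross, pdf, pdesign)
    est_net = weighted_proportion(net, pdf, pdesign)
    est_pushed = weighted_proportion(pushed, pdf, pdesign)
    absolute = est_net.estimate - est_gross.estimate
    base = est_gross.estimate if relative_definition == "of_gross" else est_net.estimate
    relative = 100.0 * absolute / base if base > 0 else float("nan")
    return ImpoverishmentResult(
        headcount_gross=est_gross.estimate,
        headcount_net=est_net.estimate,
        absolute_difference=absolute,
        relative_difference=relative,
        individuals_pushed=absolute * population_total,
        ci_absolute=(est_pushed.ci_low, est_pushed.ci_high),
        estimates={"gross": est_gross, "net": est_net, "pushed": est_pushed},
    )


def pen_parade(df: pd.DataFrame, line: PovertyLine) -> pd.DataFrame:
    """Pen's parade data: households sorted ascending by gross consumption
    as a multiple of the line (ties broken by household_id), with the net
    multiple and the crossing flag."""
    total = df["total_exp"].to_numpy(dtype=float)
    size = df["hh_size"].to_numpy(dtype=float)
    oop = df["oop_monthly"].to_numpy(dtype=float)
    gross_mult = total / size / line.value
    net_mult = np.maximum(total - oop, 0.0) / size / line.value
    out = pd.DataFrame(
        {
            "household_id": df["household_id"].to_numpy(),
            "weight": df["weight"].to_numpy(dtype=float),
            "hh_size": size,
            "gross_multiple": gross_mult,
            "net_multiple": net_mult,
        }
    )
    out = out.sort_values(
        ["gross_multiple", "household_id"], kind="stable", ignore_index=True
    )
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    out["crossed"] = (
        (out["gross_multiple"] >= 1.0) & (out["net_multiple"] < 1.0)
    ).astype(np.int8)
    return out


def plot_pen_parade(parade: pd.DataFrame, path: str, max_drops: int = 20000) -> str:
    """Render the parade: gross curve, paint-drop bars, horizontal unit line.

    With more households than ``max_drops`` an evenly spaced subset of bars
    is drawn (the curve always uses every household).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    x = np.arange(1, len(parade) + 1) / len(parade)
    fig, ax = plt.subplots(figsize=(8, 5))
    idx = np.arange(len(parade))
    if len(idx) > max_drops:
        idx = np.linspace(0, len(parade) - 1, max_drops).astype(int)
    segs = np.stack(
        [
            np.column_stack([x[idx], parade["gross_multiple"].to_numpy()[idx]]),
            np.column_stack([x[idx], parade["net_multiple"].to_numpy()[idx]]),
        ],
        axis=1,
    )
    ax.add_collection(LineCollection(segs, colors="#d95f02", linewidths=0.3, alpha=0.6))
    ax.plot(x, parade["gross_multiple"], color="#1b5e8a", lw=1.2,
            label="gross consumption")
    ax.axhline(1.0, color="black", lw=1.0, ls="--", label="poverty line")
    ax.set_xlabel("cumulative share of households (ranked by gross consumption)")
    ax.set_ylabel("per-capita consumption / poverty line")
    ax.set_ylim(0, min(float(parade["gross_multiple"].max()) * 1.05, 10.0))
    ax.legend(loc="upper left", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
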