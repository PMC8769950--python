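"""Poverty lines, impoverishment accounting and Pen's parade."""

import numpy as np
import pandas as pd
import pytest

from finprotect import (
    PovertyLine,
    cbn_food_line,
    cbn_line,
    cbn_nonfood_component,
    impoverishment,
    impoverishment_flags,
    ipl_line,
    pen_parade,
    poverty_status,
)
from finprotect.design import SurveyDesign
from finprotect.exceptions import DomainError, PovertyLineError
from finprotect.poverty import DEFAULT_FOOD_BASKET, DEFAULT_FOOD_PRICES

from oracles import loop_impoverished_share, loop_weighted_median


def two_household_frame():
    """A: gross pc 2250, net pc 1875; B: gross pc 3000, net pc 2900."""
    return pd.DataFrame(
        {
            "household_id": [0, 1],
            "weight": [1.0, 1.0],
            "hh_size": [2, 2],
            "psu_id": [0, 1],
            "stratum_id": [0, 0],
            "total_exp": [4500.0, 6000.0],
            "oop_monthly": [750.0, 200.0],
        }
    )


# --- poverty lines ---------------------------------------------------------

def test_food_line_single_item():
    assert cbn_food_line({"rice": 2.0}, {"rice": 0.5}) == 30.0


def test_food_line_linearity_and_monotonicity():
    base = cbn_food_line(DEFAULT_FOOD_PRICES, DEFAULT_FOOD_BASKET)
    doubled = cbn_food_line(
        {k: 2 * v for k, v in DEFAULT_FOOD_PRICES.items()}, DEFAULT_FOOD_BASKET
    )
    assert doubled == pytest.approx(2 * base, rel=1e-12)
    bumped = dict(DEFAULT_FOOD_PRICES, rice=DEFAULT_FOOD_PRICES["rice"] + 1)
    assert cbn_food_line(bumped, DEFAULT_FOOD_BASKET) > base


def test_default_basket_equals_hand_sum():
    by_hand = 30.0 * (
        0.380 * 34.0 + 0.040 * 32.0 + 0.030 * 105.0 + 0.050 * 60.0 + 0.020 * 100.0
        + 0.010 * 420.0 + 0.030 * 180.0 + 0.065 * 20.0 + 0.120 * 25.0
        + 0.015 * 55.0 + 0.017 * 60.0
    )
    assert cbn_food_line(DEFAULT_FOOD_PRICES, DEFAULT_FOOD_BASKET) == pytest.approx(
        by_hand, rel=1e-12
    )


def test_missing_price_names_item():
    with pytest.raises(PovertyLineError, match="pulses"):
        cbn_food_line({"rice": 2.0}, {"rice": 0.5, "pulses": 0.1})


def test_ipl_line_value():
    assert ipl_line(28.27, 1.9).value == pytest.approx(1611.39, abs=1e-9)
    assert ipl_line(1.0, 1.0).value == 30.0
    with pytest.raises(DomainError):
        ipl_line(0.0, 1.9)


def test_nonfood_component_median_example():
    df = pd.DataFrame(
        {
            "food_exp": [1000.0, 1000.0, 1000.0],
            "nonfood_exp": [200.0, 600.0, 1800.0],
            "hh_size": [2, 2, 2],
            "weight": [1.0, 1.0, 1.0],
        }
    )
    # per-capita food = 500 for all, band around food line 500 captures all
    got = cbn_nonfood_component(df, 500.0, band=0.10, min_households=3)
    assert got == 300.0  # weighted median of (100, 300, 900)


def test_nonfood_component_empty_band_errors():
    df = pd.DataFrame(
        {"food_exp": [10.0] * 25, "nonfood_exp": [5.0] * 25,
         "hh_size": [1] * 25, "weight": [1.0] * 25}
    )
    with pytest.raises(PovertyLineError, match="band"):
        cbn_nonfood_component(df, 1000.0, band=0.10)


def test_nonfood_component_matches_filter_then_median(big_table):
    food_line = cbn_food_line(DEFAULT_FOOD_PRICES, DEFAULT_FOOD_BASKET)
    got = cbn_nonfood_component(big_table, food_line, band=0.10)
    pc_food = big_table["food_exp"] / big_table["hh_size"]
    mask = (pc_food >= food_line * 0.9) & (pc_food <= food_line * 1.1)
    sub = big_table[mask]
    brute = loop_weighted_median(
        list(sub["nonfood_exp"] / sub["hh_size"]),
        list(sub["weight"] * sub["hh_size"]),
    )
    assert got == brute


def test_cbn_line_is_sum_of_components(big_table):
    line = cbn_line(big_table, DEFAULT_FOOD_PRICES, DEFAULT_FOOD_BASKET)
    assert line.kind == "cbn"
    assert line.value == pytest.approx(line.food_component + line.nonfood_component)


# --- poverty status and impoverishment -------------------------------------

def test_poverty_status_boundary_is_non_poor():
    df = pd.DataFrame({"total_exp": [4000.0], "hh_size": [2], "oop_monthly": [0.0]})
    line = PovertyLine(2000.0, "external")
    assert poverty_status(df, line)[0] == 0  # exactly at the line
    below = PovertyLine(2000.000001, "external")
    assert poverty_status(df, below)[0] == 1


def test_two_household_worked_example(design):
    df = two_household_frame()
    line = PovertyLine(2000.0, "external")
    assert list(poverty_status(df, line, net_of_oop=False)) == [0, 0]
    assert list(poverty_status(df, line, net_of_oop=True)) == [1, 0]
    res = impoverishment(df, line, design, population_total=1000)
    assert res.headcount_gross == 0.0
    assert res.headcount_net == pytest.approx(0.5)
    assert res.absolute_difference == pytest.approx(0.5)
    assert res.individuals_pushed == pytest.approx(500.0)


def test_no_oop_means_no_impoverishment(table, design):
    t = table.assign(oop_monthly=0.0)
    res = impoverishment(t, PovertyLine(2200.0, "external"), design, 1e6)
    assert res.absolute_difference == 0.0
    assert res.individuals_pushed == 0.0


def test_impoverishment_matches_loop_oracle(big_table, design):
    line = PovertyLine(2200.0, "external")
    res = impoverishment(big_table, line, design, population_total=1.0)
    brute = loop_impoverished_share(
        big_table["total_exp"].to_numpy(),
        big_table["hh_size"].to_numpy(),
        big_table["oop_monthly"].to_numpy(),
        big_table["weight"].to_numpy(),
        2200.0,
    )
    assert res.absolute_difference == pytest.approx(brute, rel=1e-12)
    assert res.headcount_net >= res.headcount_gross
    assert res.absolute_difference == pytest.approx(
        res.headcount_net - res.headcount_gross, abs=1e-15
    )


def test_impoverishment_invariant_to_currency_rescaling(big_table, design):
    c = 3.7
    scaled = big_table.assign(
        total_exp=big_table["total_exp"] * c, oop_monthly=big_table["oop_monthly"] * c
    )
    a = impoverishment(big_table, PovertyLine(2200.0, "external"), design, 1e6)
    b = impoverishment(scaled, PovertyLine(2200.0 * c, "external"), design, 1e6)
    assert a.absolute_difference == pytest.approx(b.absolute_difference, abs=1e-15)


def test_relative_difference_definitions(big_table, design):
    line = PovertyLine(2200.0, "external")
    of_gross = impoverishment(big_table, line, design, 1e6, "of_gross")
    of_net = impoverishment(big_table, line, design, 1e6, "of_net")
    assert of_gross.relative_difference == pytest.approx(
        100 * of_gross.absolute_difference / of_gross.headcount_gross
    )
    assert of_net.relative_difference < of_gross.relative_difference


# --- Pen's parade ----------------------------------------------------------

def test_pen_parade_worked_example():
    df = two_household_frame()
    parade = pen_parade(df, PovertyLine(2000.0, "external"))
    assert list(parade["gross_multiple"]) == pytest.approx([1.125, 1.5])
    assert list(parade["crossed"]) == [1, 0]
    assert (parade["gross_multiple"] >= parade["net_multiple"] - 1e-15).all()


def test_pen_parade_zero_oop_has_zero_drops(table):
    t = table.assign(oop_monthly=0.0)
    parade = pen_parade(t, PovertyLine(2200.0, "external"))
    assert np.allclose(parade["gross_multiple"], parade["net_multiple"])
    assert parade["crossed"].sum() == 0


def test_pen_parade_sorted_and_consistent_with_impoverishment(big_table, design):
    line = PovertyLine(2200.0, "external")
    parade = pen_parade(big_table, line)
    gm = parade["gross_multiple"].to_numpy()
    assert (np.diff(gm) >= -1e-15).all()
    assert parade["crossed"].sum() == impoverishment_flags(big_table, line).sum()
    # person-weighted crossed share equals the headcount difference
    pw = parade["weight"] * parade["hh_size"]
    share = float((pw * parade["crossed"]).sum() / pw.sum())
    res = impoverishment(big_table, line, design, 1.0)
    assert share == pytest.approx(res.absolute_difference, rel=1e-12)


def test_plot_pen_parade_writes_file(table, tmp_path):
    from finprotect import plot_pen_parade

    parade = pen_parade(table, PovertyLine(2200.0, "external"))
    out = plot_pen_parade(parade, str(tmp_path / "parade.png"))
    assert (tmp_path / "parade.png").stat().st_size > 0
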