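"""Generator: determinism, degenerate cases, and Monte-Carlo consistency of
the hurdle OOP process with its stated generative equations."""

import math

import numpy as np
import pandas as pd
import pytest

from finprotect import GeneratorConfig, generate_households, true_parameters
from finprotect.consumption import add_aggregates
from finprotect.design import SurveyDesign, weighted_proportion
from finprotect.exceptions import ConfigurationError

from conftest import reconfig


def test_row_count_is_psu_times_households():
    t = generate_households(GeneratorConfig(n_psu=50, households_per_psu=20, seed=7))
    assert len(t) == 1000
    assert t["household_id"].is_unique
    assert (t.groupby("psu_id").size() == 20).all()


def test_fixed_seed_gives_bitwise_identical_tables(small_config):
    a = generate_households(small_config)
    b = generate_households(small_config)
    pd.testing.assert_frame_equal(a, b, check_exact=True)


def test_different_seed_changes_table(small_config):
    a = generate_households(small_config)
    b = generate_households(reconfig(small_config, seed=small_config.seed + 1))
    assert not a["food_exp"].equals(b["food_exp"])


def test_zero_oop_prob_one_zeroes_all_oop(small_config):
    t = generate_households(reconfig(small_config, zero_oop_prob=1.0))
    for col in ("oop_outpatient_30d", "oop_inpatient_annual", "oop_nonmedical_30d"):
        assert (t[col] == 0).all()


def test_basic_invariants(table):
    assert (table["weight"] > 0).all()
    assert (table["hh_size"] >= 1).all()
    for col in ("food_exp", "nonfood_exp", "oop_outpatient_30d",
                "oop_inpatient_annual", "oop_nonmedical_30d"):
        assert (table[col] >= 0).all()
    assert (table["food_exp"] + table["nonfood_exp"] > 0).all()
    # geography is PSU-level
    per_psu = table.groupby("psu_id")[["rural", "division", "stratum_id", "weight"]].nunique()
    assert (per_psu == 1).all().all()
    # weights constant within stratum
    assert (table.groupby("stratum_id")["weight"].nunique() == 1).all()
    # every stratum has >= 2 PSUs
    assert (table.groupby("stratum_id")["psu_id"].nunique() >= 2).all()


def _oracle_mean_oop_by_chronic(config: GeneratorConfig, n: int, seed: int):
    """Direct simulation of the stated two-part OOP equations, written out
    longhand and independently of the generator implementation.  Returns
    (mean OOP | chronic=1, mean OOP | chronic=0), design-weighted.
    """
    rng = np.random.default_rng(seed)
    prev = config.covariate_prevalences
    b = dict(config.logit_true_betas)
    names = ("head_female", "has_child", "has_elderly", "chronic_care",
             "inpatient_use", "used_public", "used_private", "used_ngo",
             "used_other")
    x = {k: (rng.random(n) < prev[k]).astype(float) for k in names}
    edu_p = np.array([config.education_probs[k] for k in
                      ("none", "primary", "secondary", "higher_secondary", "university")])
    edu = np.searchsorted(np.cumsum(edu_p), rng.random(n), side="right")
    sizes = np.array(sorted(config.hh_size_pmf))
    size_p = np.array([config.hh_size_pmf[s] for s in sizes])
    hh = sizes[np.searchsorted(np.cumsum(size_p) / np.sum(size_p), rng.random(n), side="right")]
    urban = (rng.random(n) < config.urban_share).astype(float)
    div = rng.integers(0, len(config.divisions), n)

    eta = np.full(n, b["const"])
    eta += b["head_male"] * (1 - x["head_female"])
    for i, lvl in enumerate(("primary", "secondary", "higher_secondary", "university"), 1):
        eta += b[f"edu_{lvl}"] * (edu == i)
    eta += b["has_child"] * x["has_child"] + b["has_elderly"] * x["has_elderly"]
    eta += b["hhsize_3_4"] * ((hh >= 3) & (hh <= 4)) + b["hhsize_5plus"] * (hh >= 5)
    for k in ("chronic_care", "inpatient_use", "used_public", "used_private",
              "used_ngo", "used_other"):
        eta += b[k] * x[k]
    eta += b["rural"] * (1 - urban)
    div_names = [d.lower() for d in config.divisions]
    for j, dname in enumerate(div_names):
        key = f"div_{dname}"
        if key in b:
            eta += b[key] * (div == j)
    p = 1.0 / (1.0 + np.exp(-eta))
    flagged = rng.random(n) < p

    logm = np.zeros(n)
    cov_values = {
        **x,
        "hhsize_3_4": ((hh >= 3) & (hh <= 4)).astype(float),
        "hhsize_5plus": (hh >= 5).astype(float),
    }
    for k, c in config.oop_coefficients.items():
        logm += math.log(c) * cov_values[k]
    m = np.exp(logm)

    excess = rng.lognormal(config.oop_excess_log_mean + logm, config.oop_excess_log_sd)
    rho_f = np.minimum(0.10 * (1 + excess), config.max_oop_share)
    rho_s = 0.10 * rng.random(n) ** (config.oop_subthreshold_shape / m)
    has = rng.random(n) >= config.zero_oop_prob
    rho = np.where(flagged, rho_f, np.where(has, rho_s, 0.0))

    sigma_hh = math.sqrt(max(config.consumption_sigma**2 - config.psu_sigma**2, 1e-4))
    log_pc = (config.consumption_location + config.urban_log_premium * urban
              + config.education_log_premium * edu
              + rng.normal(0, config.psu_sigma, n)
              + rng.normal(0, sigma_hh, n))
    base = np.exp(log_pc) * hh
    oop = base * rho / (1 - rho)
    lo, hi = config.selection_prob_range
    w = 1.0 / np.exp(math.log(lo) + (math.log(hi) - math.log(lo))
                     * div / max(len(config.divisions) - 1, 1))
    chronic = x["chronic_care"] == 1
    return (np.average(oop[chronic], weights=w[chronic]),
            np.average(oop[~chronic], weights=w[~chronic]))


def test_chronic_oop_elevation_matches_direct_simulation():
    """Weighted mean OOP among chronic-care households vs others, compared
    with a 200 000-draw Monte-Carlo oracle of the same generative equations."""
    cfg = GeneratorConfig(
        n_psu=50, households_per_psu=20, seed=1,
        oop_coefficients={"chronic_care": 3.0},
    )
    t = add_aggregates(generate_households(cfg))
    chronic = t["chronic_care"] == 1
    w = t["weight"]

    def group_stats(mask):
        vals = t.loc[mask, "oop_monthly"].to_numpy()
        wts = w[mask].to_numpy()
        mean = np.average(vals, weights=wts)
        se_log = vals.std() / max(mean, 1e-12) / math.sqrt(len(vals))
        return mean, se_log

    mean_c, se_c = group_stats(chronic)
    mean_n, se_n = group_stats(~chronic)
    oracle_c, oracle_n = _oracle_mean_oop_by_chronic(cfg, 200_000, seed=99)

    assert mean_c > mean_n  # elevation direction
    log_gap = abs(math.log(mean_c / mean_n) - math.log(oracle_c / oracle_n))
    assert log_gap < 3.0 * math.sqrt(se_c**2 + se_n**2) + 0.05


def test_true_parameters_passthrough(small_config):
    tp = true_parameters(small_config)
    assert tp.logit_betas == small_config.logit_true_betas
    assert tp.oop_effects == small_config.oop_coefficients
    unit = reconfig(small_config, oop_coefficients={"chronic_care": 1.0, "used_private": 1.0})
    assert all(v == 1.0 for v in true_parameters(unit).oop_effects.values())


def test_true_marginal_matches_independent_resimulation(small_config):
    """The simulated CHE-10% marginal agrees with a fresh large-sample
    re-simulation within 3 Monte-Carlo standard errors."""
    tp = true_parameters(reconfig(small_config, seed=1))
    resim = add_aggregates(generate_households(
        reconfig(small_config, n_psu=6000, households_per_psu=20, seed=31415)
    ))
    flags = (resim["oop_monthly"] > 0.10 * resim["total_exp"]).to_numpy()
    est = weighted_proportion(flags, resim, SurveyDesign())
    assert abs(tp.marginal_rates["che_total_10"] - est.estimate) < 3 * max(est.se, 1e-4) * 2


def test_weighted_prevalences_converge(design):
    t = generate_households(GeneratorConfig(n_psu=600, households_per_psu=10, seed=41))
    for col, truth in (("chronic_care", 0.489), ("has_elderly", 0.183)):
        est = weighted_proportion(t[col].to_numpy(), t, design)
        assert abs(est.estimate - truth) < 3 * est.se
    # urban/rural is fixed within strata, so its design-based SE is ~0
    # (stratification removes that variance); compare against the Monte-Carlo
    # error of the random PSU allocation instead: 3*sqrt(p(1-p)/n_psu).
    urban = 1 - t["rural"].to_numpy()
    est = weighted_proportion(urban, t, design)
    assert abs(est.estimate - 0.303) < 3 * np.sqrt(0.303 * 0.697 / 600)


@pytest.mark.parametrize(
    "overrides, field",
    [
        ({"n_psu": 0}, "n_psu"),
        ({"consumption_sigma": -1.0}, "consumption_sigma"),
        ({"zero_oop_prob": 1.5}, "zero_oop_prob"),
        ({"n_psu": 10, "n_strata": 14}, "n_psu"),
        ({"logit_true_betas": {"const": -2.0, "not_a_term": 1.0}}, "not_a_term"),
        ({"oop_coefficients": {"nonexistent": 2.0}}, "nonexistent"),
    ],
)
def test_invalid_config_names_offending_field(overrides, field):
    with pytest.raises((ConfigurationError, Exception)) as err:
        generate_households(GeneratorConfig(n_psu=50, households_per_psu=10, seed=0,
                                            **overrides))
    assert field in str(err.value)
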