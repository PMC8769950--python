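"""Synthetic household expenditure survey generator.

Emulates the structure of a two-stage stratified cluster sample of the kind
national statistics offices run for living-standards measurement: PSUs
(clusters) are drawn within geographic strata defined by division x
urban/rural cells, a fixed number of households is taken per PSU, and the
design weight is the inverse of the stratum selection probability (constant
within stratum, i.e. self-weighting within PSU).

Generative model
----------------
* Monthly per-capita baseline (non-health) consumption is log-normal with a
  PSU-level random intercept, an urban premium and an education gradient, so
  consumption is right-skewed and intra-cluster correlated.
* The catastrophic-spending indicator at the 10%-of-total threshold is drawn
  from a logistic model in the configured covariates
  (``logit_true_betas``), giving known ground-truth log-odds for parameter
  recovery tests.
* The out-of-pocket (OOP) ratio of total consumption is then drawn
  conditionally on that indicator: flagged households get a right-skewed
  excess above 10% (log-normal, scaled multiplicatively by
  ``oop_coefficients``); unflagged households get zero spending with
  probability ``zero_oop_prob`` or a sub-threshold ratio otherwise.  OOP is
  therefore a hurdle process with a point mass at zero and a skewed
  positive part, and thresholding the emitted components at 10% of total
  expenditure reproduces the generative indicator exactly.
* OOP is split into outpatient (30-day), non-medical (30-day) and inpatient
  spending, the latter reported on an *annual* recall window so downstream
  aggregation must divide by 12.  Health spending is part of non-food
  consumption; third-party/insurance payments are never emitted.
* Twelve categorical/binary asset indicators (housing materials, water,
  sanitation, durables, livestock) are driven by a latent wealth score
  correlated with consumption.

Fixed seed implies bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .config import EDUCATION_LEVELS, GeneratorConfig, validated
from .determinants import term_matrix
from .exceptions import ConfigurationError
from .io import read_table, write_table  # noqa: F401  (re-exported table I/O)

__all__ = [
    "generate_households",
    "true_parameters",
    "TrueParameterSet",
    "write_table",
    "read_table",
    "ASSET_SPECS",
]

#: (column, levels poor->rich, marginal probabilities, wealth slope).
#: Binary indicators use levels ("0","1") and are emitted as integers.
ASSET_SPECS: tuple[tuple[str, tuple[str, ...], tuple[float, ...], float], ...] = (
    ("asset_roof", ("thatch", "tin", "concrete"), (0.12, 0.72, 0.16), 1.0),
    ("asset_wall", ("mud", "tin", "brick"), (0.35, 0.40, 0.25), 1.0),
    ("asset_floor", ("earth", "cement"), (0.62, 0.38), 1.0),
    ("asset_water", ("surface", "tubewell", "piped"), (0.08, 0.80, 0.12), 0.8),
    ("asset_sanitation", ("open", "pit", "flush"), (0.10, 0.65, 0.25), 1.0),
    ("asset_electricity", ("0", "1"), (0.25, 0.75), 1.0),
    ("asset_tv", ("0", "1"), (0.56, 0.44), 1.0),
    ("asset_fridge", ("0", "1"), (0.77, 0.23), 1.2),
    ("asset_phone", ("0", "1"), (0.15, 0.85), 0.7),
    ("asset_motorcycle", ("0", "1"), (0.93, 0.07), 0.9),
    ("asset_bicycle", ("0", "1"), (0.74, 0.26), 0.3),
    ("asset_livestock", ("0", "1"), (0.70, 0.30), -0.3),
)


@dataclass(frozen=True)
class TrueParameterSet:
    """Ground truth behind a generated table, for recovery tests."""

    logit_betas: dict[str, float]
    oop_effects: dict[str, float]
    marginal_rates: dict[str, float]


# ---------------------------------------------------------------------------
# sampling frame: strata, PSUs, weights
# ---------------------------------------------------------------------------

def _strata_for_cells(n_strata: int, n_cells: int) -> list[list[int]]:
    """Map each division x urban cell to the strata that cover it."""
    if n_strata >= n_cells:
        return [[s for s in range(n_strata) if s % n_cells == c] for c in range(n_cells)]
    return [[c % n_strata] for c in range(n_cells)]


def _cell_of_stratum(n_strata: int, n_cells: int) -> list[int]:
    if n_strata >= n_cells:
        return [s % n_cells for s in range(n_strata)]
    # a stratum spanning several cells is anchored at its first cell
    return [min(c for c in range(n_cells) if c % n_strata == s) for s in range(n_strata)]


def _assign_psus(config: GeneratorConfig, rng: np.random.Generator):
    n_div = len(config.divisions)
    n_cells = 2 * n_div
    strata_for_cell = _strata_for_cells(config.n_strata, n_cells)
    cell_anchor = _cell_of_stratum(config.n_strata, n_cells)

    urban = rng.random(config.n_psu) < config.urban_share
    div = rng.integers(0, n_div, config.n_psu)
    cell = urban.astype(int) * n_div + div
    pick = rng.random(config.n_psu)
    stratum = np.empty(config.n_psu, dtype=int)
    for i in range(config.n_psu):
        options = strata_for_cell[cell[i]]
        stratum[i] = options[int(pick[i] * len(options))]

    # every stratum used in variance estimation needs >= 2 PSUs; top up
    # deficient strata from the largest one (the moved PSU adopts the
    # deficient stratum's geography)
    counts = np.bincount(stratum, minlength=config.n_strata)
    while counts.min() < 2:
        needy = int(np.argmin(counts))
        donor = int(np.argmax(counts))
        movable = np.flatnonzero(stratum == donor)[0]
        stratum[movable] = needy
        anchor = cell_anchor[needy]
        urban[movable] = anchor >= n_div
        div[movable] = anchor % n_div
        cell[movable] = anchor
        counts = np.bincount(stratum, minlength=config.n_strata)

    # selection probability varies by the stratum's division (log-linear
    # between the configured bounds) and is identical for the urban and
    # rural stratum of a division, so weighting leaves the urban share
    # unbiased while still exercising unequal weights.
    lo, hi = config.selection_prob_range
    denom = max(n_div - 1, 1)
    div_of_stratum = np.array([c % n_div for c in cell_anchor])
    p_sel = np.exp(
        math.log(lo) + (math.log(hi) - math.log(lo)) * div_of_stratum / denom
    )
    weight_of_stratum = 1.0 / p_sel
    return urban, div, stratum, weight_of_stratum


def _categorical(rng: np.random.Generator, probs: np.ndarray, n: int) -> np.ndarray:
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(n), side="right")


def _asset_columns(rng: np.random.Generator, wealth: np.ndarray) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    n = len(wealth)
    for name, levels, probs, slope in ASSET_SPECS:
        latent = slope * wealth + rng.normal(0.0, 1.0, n)
        scale = math.sqrt(1.0 + slope * slope)
        cuts = ndtri(np.cumsum(probs[:-1])) * scale
        idx = np.searchsorted(cuts, latent, side="right")
        if levels == ("0", "1"):
            out[name] = idx.astype(np.int64)
        else:
            out[name] = np.asarray(levels, dtype=object)[idx]
    return out


# ---------------------------------------------------------------------------
# main entry points
# ---------------------------------------------------------------------------

def generate_households(config: GeneratorConfig | None = None, **overrides) -> pd.DataFrame:
    """Generate a household table of ``n_psu * households_per_psu`` rows.

    Deterministic for a fixed ``config.seed``.  See the module docstring for
    the generative model.
    """
    config = validated(config, **overrides)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_div = len(config.divisions)
    H = config.households_per_psu
    n = config.n_households

    urban_psu, div_psu, stratum_psu, weight_of_stratum = _assign_psus(config, rng)
    psu_eff = rng.normal(0.0, config.psu_sigma, config.n_psu)

    psu = np.repeat(np.arange(config.n_psu), H)
    stratum = stratum_psu[psu]
    urban = urban_psu[psu].astype(np.int64)
    division = np.asarray(config.divisions, dtype=object)[div_psu[psu]]
    weight = weight_of_stratum[stratum]

    # covariates (iid within the configured marginals; geography is
    # PSU-level by construction)
    prev = config.covariate_prevalences
    covs = {
        name: (rng.random(n) < prev.get(name, 0.0)).astype(np.int64)
        for name in (
            "head_female",
            "has_child",
            "has_elderly",
            "chronic_care",
            "inpatient_use",
            "used_public",
            "used_private",
            "used_ngo",
            "used_other",
        )
    }
    edu_probs = np.array([config.education_probs[k] for k in EDUCATION_LEVELS])
    edu_idx = _categorical(rng, edu_probs, n)
    head_education = np.asarray(EDUCATION_LEVELS, dtype=object)[edu_idx]
    sizes = np.array(sorted(config.hh_size_pmf))
    size_probs = np.array([config.hh_size_pmf[s] for s in sizes], dtype=float)
    hh_size = sizes[_categorical(rng, size_probs, n)]

    # baseline (non-health) consumption
    sigma_hh = math.sqrt(max(config.consumption_sigma**2 - config.psu_sigma**2, 1e-4))
    log_pc = (
        config.consumption_location
        + config.urban_log_premium * urban
        + config.education_log_premium * edu_idx
        + psu_eff[psu]
        + rng.normal(0.0, sigma_hh, n)
    )
    base = np.exp(log_pc) * hh_size

    cov_frame = pd.DataFrame(
        {
            **covs,
            "head_education": head_education,
            "hh_size": hh_size,
            "rural": 1 - urban,
            "division": division,
        }
    )
    X = term_matrix(cov_frame)
    for key in config.logit_true_betas:
        if key not in X.columns:
            raise ConfigurationError(f"logit_true_betas: unknown term '{key}'")
    beta = pd.Series(0.0, index=X.columns)
    beta.update(pd.Series(config.logit_true_betas))
    eta = X.to_numpy() @ beta.to_numpy()
    flagged = rng.random(n) < expit(eta)
    if config.zero_oop_prob >= 1.0:
        # degenerate boundary: no household makes any health payment, so no
        # household can be catastrophic either
        flagged[:] = False

    for key in config.oop_coefficients:
        if key not in X.columns:
            raise ConfigurationError(f"oop_coefficients: unknown term '{key}'")
    log_mult = np.zeros(n)
    for key, coef in config.oop_coefficients.items():
        log_mult += math.log(coef) * X[key].to_numpy()
    mult = np.exp(log_mult)

    # conditional OOP ratio of total consumption
    excess = rng.lognormal(config.oop_excess_log_mean + log_mult, config.oop_excess_log_sd)
    sub_u = rng.random(n)
    any_oop = rng.random(n) >= config.zero_oop_prob
    rho_flagged = np.minimum(0.10 * (1.0 + excess), config.max_oop_share)
    rho_sub = 0.10 * sub_u ** (config.oop_subthreshold_shape / mult)
    rho = np.where(flagged, rho_flagged, np.where(any_oop, rho_sub, 0.0))

    oop = base * rho / (1.0 - rho)
    total = base + oop

    share_mean = np.clip(
        config.food_share_mean
        - config.engel_slope * (log_pc - config.consumption_location),
        0.10,
        0.90,
    )
    conc = config.food_share_concentration
    share = rng.beta(share_mean * conc, (1.0 - share_mean) * conc)
    food = share * base
    nonfood = total - food  # includes health spending and tobacco/in-kind values

    # recall-window split: inpatient spending is reported annually
    nm_frac = rng.beta(2.0, 18.0, n)
    inp_frac = rng.beta(5.0, 5.0, n) * covs["inpatient_use"]
    oop_nonmedical = nm_frac * oop
    inpatient_monthly = inp_frac * (oop - oop_nonmedical)
    oop_inpatient_annual = inpatient_monthly * 12.0
    oop_outpatient = oop - oop_nonmedical - inpatient_monthly

    wealth = log_pc + rng.normal(0.0, 0.5 * config.consumption_sigma, n)
    wealth = (wealth - wealth.mean()) / wealth.std()
    assets = _asset_columns(rng, wealth)

    table = pd.DataFrame(
        {
            "household_id": np.arange(n, dtype=np.int64),
            "psu_id": psu.astype(np.int64),
            "stratum_id": stratum.astype(np.int64),
            "weight": weight,
            "hh_size": hh_size.astype(np.int64),
            "food_exp": food,
            "nonfood_exp": nonfood,
            "oop_outpatient_30d": oop_outpatient,
            "oop_inpatient_annual": oop_inpatient_annual,
            "oop_nonmedical_30d": oop_nonmedical,
            **covs,
            "head_education": head_education,
            "rural": (1 - urban).astype(np.int64),
            "division": division,
            **assets,
        }
    )
    return table


def true_parameters(config: GeneratorConfig | None = None, *, sim_n: int = 120_000,
                    **overrides) -> TrueParameterSet:
    """Exact generative parameters plus simulated marginal rates.

    ``marginal_rates`` are design-weighted population rates obtained by
    re-running the generator at a large sample size (``sim_n`` households,
    default 120 000) under a seed derived deterministically from
    ``config.seed``.
    """
    config = validated(config, **overrides)
    sim_seed = (config.seed * 1_000_003 + 12_345) % (2**31)
    n_psu = max(2 * config.n_strata, math.ceil(sim_n / config.households_per_psu))
    sim_cfg = validated(config, n_psu=n_psu, seed=sim_seed)
    table = generate_households(sim_cfg)

    total = table["food_exp"] + table["nonfood_exp"]
    oop = (
        table["oop_outpatient_30d"]
        + table["oop_nonmedical_30d"]
        + table["oop_inpatient_annual"] / 12.0
    )
    w = table["weight"]
    pw = w * table["hh_size"]
    ipl_value = 1.9 * 28.27 * 30.0
    pc_gross = total / table["hh_size"]
    pc_net = np.maximum(total - oop, 0.0) / table["hh_size"]
    impoverished = (pc_gross >= ipl_value) & (pc_net < ipl_value)

    def wmean(x, weights):
        return float(np.average(x, weights=weights))

    marginal_rates = {
        "che_total_10": wmean(oop > 0.10 * total, w),
        "che_nonfood_40": wmean(oop > 0.40 * table["nonfood_exp"], w),
        "impoverished_ipl": wmean(impoverished, pw),
        "any_oop": wmean(oop > 0, w),
    }
    return TrueParameterSet(
        logit_betas=dict(config.logit_true_betas),
        oop_effects=dict(config.oop_coefficients),
        marginal_rates=marginal_rates,
    )
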