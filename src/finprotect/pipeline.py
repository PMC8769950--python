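"""End-to-end pipeline: from a config (or CSV) to the full output bundle.

Outputs mirror the standard reporting layout of a financial-risk-protection
study: sample characteristics, the OOP spending summary (unconditional and
conditional on any payment), catastrophic-spending incidence by subgroup,
the impoverishment summary under the national and international lines,
Pen's parade (CSV + figure) and the four determinant models — plus a run
manifest (config hash, seed, package versions) that fully determines the
outputs.  A stage failure is logged and skips only its dependents.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .assets import assign_asset_quintiles
from .che import ThresholdSpec, che_by_subgroup, che_indicator
from .config import GeneratorConfig, RelativeDefinition
from .consumption import add_aggregates, drop_degenerate
from .design import SurveyDesign, weighted_mean, weighted_proportion
from .determinants import default_model_specs, model_table, run_models
from .exceptions import ConfigurationError
from .io import read_table, write_table
from .poverty import (
    DEFAULT_DOLLARS_PER_DAY,
    DEFAULT_FOOD_BASKET,
    DEFAULT_FOOD_PRICES,
    DEFAULT_KCAL_PER_DAY,
    DEFAULT_PPP_RATE,
    PovertyLine,
    cbn_line,
    impoverishment,
    impoverishment_flags,
    ipl_line,
    pen_parade,
    plot_pen_parade,
    poverty_status,
)
from .synthetic import generate_households

log = logging.getLogger(__name__)

import numpy as np
import pandas as pd

#: variables summarized in the characteristics table
TABLE1_VARIABLES = (
    "head_female",
    "head_education",
    "has_child",
    "has_elderly",
    "hh_size_category",
    "chronic_care",
    "inpatient_use",
    "used_public",
    "used_private",
    "used_ngo",
    "used_other",
    "rural",
    "asset_quintile",
)

SUBGROUP_COLUMNS = tuple(v for v in TABLE1_VARIABLES)


class PipelineConfig(BaseModel):
    """Everything one run needs; exactly one input source."""

    model_config = ConfigDict(extra="forbid")

    input_csv: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    seed: Optional[int] = None  # overrides generator.seed when set
    output_dir: str = "finprotect_out"
    weight_column: str = "weight"
    psu_column: str = "psu_id"
    stratum_column: str = "stratum_id"
    single_psu: Literal["error", "center"] = "error"
    thresholds: tuple[str, ...] = ("total:0.10", "nonfood:0.40")
    national_line: Optional[float] = None  # external CBN value, else estimated
    cbn_band: float = Field(default=0.10, gt=0.0, lt=1.0)
    food_prices: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_FOOD_PRICES))
    food_basket: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_FOOD_BASKET))
    ppp_rate: float = Field(default=DEFAULT_PPP_RATE, gt=0)
    dollars_per_day: float = Field(default=DEFAULT_DOLLARS_PER_DAY, gt=0)
    population_total: float = Field(default=191_300_000.0, gt=0)
    relative_definition: RelativeDefinition = "of_gross"
    share_method: Literal["mean_of_ratios", "ratio_of_means"] = "mean_of_ratios"
    inpatient_divisor: float = Field(default=12.0, gt=0)
    weighted_models: bool = False
    make_figure: bool = True

    @model_validator(mode="after")
    def _one_source(self) -> "PipelineConfig":
        if (self.input_csv is None) == (self.generator is None):
            raise ValueError(
                "exactly one input source required: set input_csv or generator"
            )
        return self

    @property
    def design(self) -> SurveyDesign:
        return SurveyDesign(
            self.weight_column, self.psu_column, self.stratum_column, self.single_psu
        )

    @property
    def threshold_specs(self) -> tuple[ThresholdSpec, ...]:
        return tuple(ThresholdSpec.parse(t) for t in self.thresholds)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _table1(df: pd.DataFrame, design: SurveyDesign) -> pd.DataFrame:
    rows = []
    for var in TABLE1_VARIABLES:
        if var not in df.columns:
            continue
        series = df[var]
        levels = sorted(pd.unique(series.astype(str)))
        for level in levels:
            flag = (series.astype(str) == level).to_numpy(dtype=float)
            est = weighted_proportion(flag, df, design)
            rows.append(
                {
                    "variable": var,
                    "level": level,
                    "percent": 100 * est.estimate,
                    "ci_low": 100 * est.ci_low,
                    "ci_high": 100 * est.ci_high,
                    "n": est.n,
                }
            )
    return pd.DataFrame(rows)


def _table2(df: pd.DataFrame, design: SurveyDesign, share_method: str) -> pd.DataFrame:
    """OOP summary, unconditional and conditional on any payment."""
    oop = df["oop_monthly"].to_numpy(dtype=float)
    any_oop = df["any_oop"].to_numpy(dtype=float)
    share_total = oop / df["total_exp"].to_numpy(dtype=float)
    share_nonfood = np.divide(
        oop,
        df["nonfood_exp"].to_numpy(dtype=float),
        out=np.zeros_like(oop),
        where=df["nonfood_exp"].to_numpy(dtype=float) > 0,
    )
    rows = []

    def emit(population: str, domain):
        mean = weighted_mean(oop, df, design, domain=domain)
        rows.append(("mean_oop_bdt", population, mean.estimate, mean.ci_low,
                     mean.ci_high))
        for name, ratio in (("oop_share_total_pct", share_total),
                            ("oop_share_nonfood_pct", share_nonfood)):
            if share_method == "mean_of_ratios":
                est = weighted_mean(ratio, df, design, domain=domain)
                rows.append((name, population, 100 * est.estimate,
                             100 * est.ci_low, 100 * est.ci_high))
            else:
                num = weighted_mean(oop, df, design, domain=domain).estimate
                den_col = "total_exp" if "total" in name else "nonfood_exp"
                den = weighted_mean(
                    df[den_col].to_numpy(dtype=float), df, design, domain=domain
                ).estimate
                rows.append((name, population, 100 * num / den, np.nan, np.nan))

    emit("all", None)
    reported = weighted_proportion(any_oop, df, design)
    rows.append(("any_oop_pct", "all", 100 * reported.estimate,
                 100 * reported.ci_low, 100 * reported.ci_high))
    emit("with_any_oop", any_oop)
    return pd.DataFrame(
        rows, columns=["measure", "population", "estimate", "ci_low", "ci_high"]
    )


def _table4(
    df: pd.DataFrame,
    lines: dict[str, PovertyLine],
    design: SurveyDesign,
    config: PipelineConfig,
) -> pd.DataFrame:
    rows = []
    for name, line in lines.items():
        res = impoverishment(
            df, line, design, config.population_total, config.relative_definition
        )
        rows.append(
            {
                "poverty_line": name,
                "line_value": line.value,
                "headcount_gross_pct": 100 * res.headcount_gross,
                "headcount_net_pct": 100 * res.headcount_net,
                "absolute_difference_pct": 100 * res.absolute_difference,
                "ci_low_pct": 100 * res.ci_absolute[0],
                "ci_high_pct": 100 * res.ci_absolute[1],
                "relative_difference_pct": res.relative_difference,
                "individuals_pushed": res.individuals_pushed,
                "individuals_pushed_millions": res.individuals_pushed / 1e6,
            }
        )
    return pd.DataFrame(rows)


def _hh_size_category(size: pd.Series) -> pd.Series:
    return pd.Series(
        np.where(size <= 2, "1-2", np.where(size <= 4, "3-4", "5plus")),
        index=size.index,
        name="hh_size_category",
    )


def load_input(config: PipelineConfig) -> pd.DataFrame:
    if config.input_csv is not None:
        return read_table(config.input_csv)
    gen = config.generator
    if config.seed is not None:
        gen = GeneratorConfig(**{**gen.model_dump(), "seed": config.seed})
    return generate_households(gen)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing the bundle into ``config.output_dir``.

    Returns ``{"paths": {...}, "failures": {...}, "frames": {...}}``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design
    paths: dict[str, Path] = {}
    failures: dict[str, str] = {}
    frames: dict[str, object] = {}

    def stage(name: str, func, *deps: str):
        if any(d in failures for d in deps):
            failures[name] = f"skipped: upstream stage failed ({deps})"
            log.warning("stage %s skipped", name)
            return None
        try:
            return func()
        except Exception as exc:  # noqa: BLE001 - reported per stage
            failures[name] = str(exc)
            log.error("stage %s failed: %s", name, exc)
            return None

    # --- input + aggregates -------------------------------------------------
    def _load():
        df = load_input(config)
        df = add_aggregates(df, inpatient_divisor=config.inpatient_divisor)
        df = drop_degenerate(df).reset_index(drop=True)
        df["hh_size_category"] = _hh_size_category(df["hh_size"])
        return df

    df = stage("input", _load)
    if df is None:
        raise ConfigurationError(f"pipeline input failed: {failures.get('input')}")

    # --- asset quintiles ----------------------------------------------------
    def _assets():
        enriched, result = assign_asset_quintiles(df, design.weight_column)
        loadings = result.loadings.rename_axis("dummy").reset_index(name="loading")
        loadings["explained_share"] = result.explained_share
        paths["asset_loadings"] = out / "asset_loadings.csv"
        loadings.to_csv(paths["asset_loadings"], index=False)
        return enriched

    enriched = stage("assets", _assets)
    if enriched is None:
        enriched = df  # CHE/poverty can proceed without quintiles

    # --- CHE flags + incidence ---------------------------------------------
    specs = config.threshold_specs

    def _che():
        for spec in specs:
            enriched[spec.label] = che_indicator(enriched, spec)
        by = [c for c in SUBGROUP_COLUMNS if c in enriched.columns]
        table3 = che_by_subgroup(enriched, specs, by, design)
        paths["table3_che_by_subgroup"] = out / "table3_che_by_subgroup.csv"
        table3.to_csv(paths["table3_che_by_subgroup"], index=False)
        return table3

    frames["table3"] = stage("che", _che, "input")

    # --- poverty lines + impoverishment ------------------------------------
    def _lines():
        if config.national_line is not None:
            national = PovertyLine(
                config.national_line, "external", provenance="externally supplied"
            )
        else:
            national = cbn_line(
                enriched,
                config.food_prices,
                config.food_basket,
                band=config.cbn_band,
                design=design,
                kcal_per_day=DEFAULT_KCAL_PER_DAY,
            )
        ipl = ipl_line(config.ppp_rate, config.dollars_per_day)
        return {"national": national, "ipl": ipl}

    lines = stage("poverty_lines", _lines, "input")

    def _poverty():
        for name, line in lines.items():
            enriched[f"poor_gross_{name}"] = poverty_status(enriched, line, False)
            enriched[f"poor_net_{name}"] = poverty_status(enriched, line, True)
            enriched[f"impoverished_{name}"] = impoverishment_flags(enriched, line)
        table4 = _table4(enriched, lines, design, config)
        paths["table4_impoverishment"] = out / "table4_impoverishment.csv"
        table4.to_csv(paths["table4_impoverishment"], index=False)
        return table4

    frames["table4"] = stage("poverty", _poverty, "poverty_lines")

    def _parade():
        parade = pen_parade(enriched, lines["national"])
        paths["pen_parade_csv"] = out / "pen_parade_national.csv"
        parade.to_csv(paths["pen_parade_csv"], index=False)
        if config.make_figure:
            paths["pen_parade_png"] = out / "pen_parade_national.png"
            plot_pen_parade(parade, str(paths["pen_parade_png"]))
        return parade

    frames["parade"] = stage("pen_parade", _parade, "poverty_lines")

    # --- descriptives -------------------------------------------------------
    def _t1():
        table1 = _table1(enriched, design)
        paths["table1_characteristics"] = out / "table1_characteristics.csv"
        table1.to_csv(paths["table1_characteristics"], index=False)
        return table1

    def _t2():
        table2 = _table2(enriched, design, config.share_method)
        paths["table2_oop_summary"] = out / "table2_oop_summary.csv"
        table2.to_csv(paths["table2_oop_summary"], index=False)
        return table2

    frames["table1"] = stage("table1", _t1, "input")
    frames["table2"] = stage("table2", _t2, "input")

    # --- determinant models -------------------------------------------------
    def _models():
        results = run_models(
            enriched,
            default_model_specs(),
            weighted=config.weighted_models,
            weight_column=design.weight_column,
            psu_column=design.psu_column,
        )
        for table_name, ids in (("table5_models_che", (1, 2)),
                                ("table6_models_impoverishment", (3, 4))):
            parts = []
            for mid in ids:
                res = results.get(mid)
                if isinstance(res, Exception) or res is None:
                    failures[f"model_{mid}"] = str(res)
                    continue
                part = model_table(res)
                part.insert(0, "model", mid)
                part["n_used"] = res.n_used
                part["log_likelihood"] = res.log_likelihood
                part["lr_chi2"] = res.lr_chi2
                part["df"] = res.df
                part["pseudo_r2"] = res.pseudo_r2
                parts.append(part)
            if parts:
                paths[table_name] = out / f"{table_name}.csv"
                pd.concat(parts, ignore_index=True).to_csv(paths[table_name], index=False)
        return results

    frames["models"] = stage("models", _models, "che", "poverty", "assets")

    # --- enriched table + manifest ------------------------------------------
    def _write_enriched():
        paths["households_enriched"] = out / "households_enriched.csv"
        return write_table(enriched, paths["households_enriched"])

    stage("write_enriched", _write_enriched, "input")

    def _manifest():
        import pandas, numpy, scipy, statsmodels

        manifest = {
            "config": config.model_dump(mode="json"),
            "config_sha256": _config_hash(config),
            "seed": config.seed if config.seed is not None else (
                config.generator.seed if config.generator else None
            ),
            "n_households": int(len(enriched)),
            "failures": failures,
            "versions": {
                "finprotect": __version__,
                "numpy": numpy.__version__,
                "pandas": pandas.__version__,
                "scipy": scipy.__version__,
                "statsmodels": statsmodels.__version__,
            },
        }
        paths["manifest"] = out / "manifest.json"
        with open(paths["manifest"], "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest

    frames["manifest"] = stage("manifest", _manifest)

    frames["households"] = enriched
    frames["lines"] = lines
    return {"paths": paths, "failures": failures, "frames": frames}
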