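"""Logistic determinant models for catastrophic spending and impoverishment.

Four models share one covariate structure: household-head gender and
education, presence of children and older persons, household-size category,
chronic-illness care, inpatient use, provider type (public / private / NGO /
other), urban-rural location and administrative division.  Models 1-2 (the
two catastrophic-expenditure outcomes) additionally adjust for asset
quintiles; models 3-4 (impoverishment under the national and international
poverty lines) do not.  Reference levels: female head, no institutional
education, household of 1-2 members, "no" for every binary exposure, urban
location, the first division label, poorest quintile.

Fitting is ordinary (unweighted) maximum likelihood by default, with Wald
95% CIs exponentiated to the odds-ratio scale; a design-weighted
pseudo-likelihood variant with PSU-cluster-robust standard errors is
available via ``weighted=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .config import DIVISIONS, EDUCATION_LEVELS, QUINTILE_LABELS
from .exceptions import ModelError, SeparationError

log = logging.getLogger(__name__)

Z975 = 1.959963984540054

#: columns consumed by the base covariate structure
BASE_COVARIATE_COLUMNS = (
    "head_female",
    "head_education",
    "has_child",
    "has_elderly",
    "hh_size",
    "chronic_care",
    "inpatient_use",
    "used_public",
    "used_private",
    "used_ngo",
    "used_other",
    "rural",
    "division",
)


@dataclass(frozen=True)
class ModelSpec:
    """One of the four determinant models."""

    model_id: int
    outcome: str
    include_quintiles: bool
    label: str = ""

    def __post_init__(self):
        if self.model_id not in (1, 2, 3, 4):
            raise ModelError(f"model_id must be in 1..4, got {self.model_id}")


def default_model_specs() -> tuple[ModelSpec, ...]:
    return (
        ModelSpec(1, "che_total_10", True, "CHE >10% of total expenditure"),
        ModelSpec(2, "che_nonfood_40", True, "CHE >40% of non-food expenditure"),
        ModelSpec(3, "impoverished_national", False, "impoverished, national line"),
        ModelSpec(4, "impoverished_ipl", False, "impoverished, international line"),
    )


@dataclass
class LogisticModelResult:
    """Fitted model: per-term betas/ORs/CIs plus fit statistics."""

    terms: pd.DataFrame  # index: term; columns beta, se, odds_ratio, ci_low, ci_high, p_value, stars
    log_likelihood: float
    ll_null: float
    lr_chi2: float
    df: int
    pseudo_r2: float
    n_used: int
    n_dropped: int
    outcome: str = ""
    model_id: int = 0
    weighted: bool = False
    converged: bool = True

    def odds_ratio(self, term: str) -> float:
        return float(self.terms.loc[term, "odds_ratio"])


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _division_levels(observed: Sequence[str]) -> list[str]:
    seen = set(observed)
    levels = [d for d in DIVISIONS if d in seen]
    levels += sorted(seen - set(DIVISIONS))
    return levels


def term_matrix(df: pd.DataFrame, include_quintiles: bool = False) -> pd.DataFrame:
    """Treatment-coded design matrix (with ``const``) for the shared
    covariate structure.  Column order is fixed and deterministic."""
    for col in BASE_COVARIATE_COLUMNS:
        if col not in df.columns:
            raise ModelError(f"missing covariate column '{col}'")
    if include_quintiles and "asset_quintile" not in df.columns:
        raise ModelError("missing covariate column 'asset_quintile'")

    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["head_male"] = 1.0 - df["head_female"].astype(float)
    edu = df["head_education"].astype(str)
    for level in EDUCATION_LEVELS[1:]:
        X[f"edu_{level}"] = (edu == level).astype(float)
    X["has_child"] = df["has_child"].astype(float)
    X["has_elderly"] = df["has_elderly"].astype(float)
    size = df["hh_size"].astype(float)
    X["hhsize_3_4"] = ((size >= 3) & (size <= 4)).astype(float)
    X["hhsize_5plus"] = (size >= 5).astype(float)
    for col in (
        "chronic_care",
        "inpatient_use",
        "used_public",
        "used_private",
        "used_ngo",
        "used_other",
        "rural",
    ):
        X[col] = df[col].astype(float)
    division = df["division"].astype(str)
    for level in _division_levels(division.unique())[1:]:
        X[f"div_{level.lower()}"] = (division == level).astype(float)
    if include_quintiles:
        quintile = df["asset_quintile"].astype(str)
        for level in QUINTILE_LABELS[1:]:
            X[f"quintile_{level}"] = (quintile == level).astype(float)
    return X


def build_design_matrix(
    df: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Design matrix + outcome vector for one model, complete cases only.

    Returns ``(X, y, n_dropped)``; the dropped (incomplete) row count is also
    logged, mirroring the fall from the full sample to the model N.
    """
    if spec.outcome not in df.columns:
        raise ModelError(f"missing outcome column '{spec.outcome}'")
    used = list(BASE_COVARIATE_COLUMNS) + [spec.outcome]
    if spec.include_quintiles:
        used.append("asset_quintile")
    for col in used:
        if col not in df.columns:
            raise ModelError(f"missing covariate column '{col}'")
    complete = df[used].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("model %d: dropped %d incomplete rows", spec.model_id, n_dropped)
    sub = df.loc[complete]
    X = term_matrix(sub, include_quintiles=spec.include_quintiles)
    y = sub[spec.outcome].astype(float)
    if not set(np.unique(y.to_numpy())) <= {0.0, 1.0}:
        raise ModelError(f"outcome '{spec.outcome}' is not binary 0/1")
    return X, y, n_dropped


def _check_separation(params: pd.Series) -> None:
    worst = params.drop(labels=["const"], errors="ignore").abs()
    if len(worst) and worst.max() > 15.0:
        raise SeparationError(
            f"perfect separation suspected: term '{worst.idxmax()}' diverged "
            f"to |beta| = {worst.max():.2f}"
        )


def fit_logistic(
    X: pd.DataFrame,
    y: pd.Series,
    *,
    weights: Optional[np.ndarray] = None,
    cluster: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogisticModelResult:
    """Maximum-likelihood logistic fit with Wald 95% CIs on the OR scale.

    ``weights`` switches to a survey-weighted pseudo-likelihood (GLM with
    variance weights); pass PSU identifiers as ``cluster`` to get
    linearized cluster-robust standard errors in that case.
    """
    y_arr = np.asarray(y, dtype=float)
    classes = np.unique(y_arr)
    if len(classes) < 2:
        raise ModelError(f"outcome has a single class ({classes[0]:g}); cannot fit")

    if weights is None:
        model = sm.Logit(y_arr, X)
        try:
            res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=0,
                            warn_convergence=False)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise SeparationError(f"logistic fit failed: {exc}") from exc
        params = pd.Series(res.params, index=X.columns)
        _check_separation(params)
        bse = pd.Series(res.bse, index=X.columns)
        pvalues = pd.Series(res.pvalues, index=X.columns)
        llf, llnull = float(res.llf), float(res.llnull)
        converged = bool(res.mle_retvals.get("converged", True))
    else:
        w = np.asarray(weights, dtype=float)
        model = sm.GLM(y_arr, X, family=sm.families.Binomial(), var_weights=w)
        if cluster is not None:
            res = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(cluster)})
        else:
            res = model.fit()
        params = pd.Series(res.params, index=X.columns)
        _check_separation(params)
        bse = pd.Series(res.bse, index=X.columns)
        pvalues = pd.Series(res.pvalues, index=X.columns)
        llf = float(res.llf)
        null = sm.GLM(
            y_arr, np.ones((len(y_arr), 1)), family=sm.families.Binomial(), var_weights=w
        ).fit()
        llnull = float(null.llf)
        converged = True

    ci_lo_beta = params - Z975 * bse
    ci_hi_beta = params + Z975 * bse
    terms = pd.DataFrame(
        {
            "beta": params,
            "se": bse,
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(ci_lo_beta),
            "ci_high": np.exp(ci_hi_beta),
            "p_value": pvalues,
        }
    )
    terms["stars"] = [_stars(p) for p in terms["p_value"]]
    df_model = X.shape[1] - 1
    return LogisticModelResult(
        terms=terms,
        log_likelihood=llf,
        ll_null=llnull,
        lr_chi2=2.0 * (llf - llnull),
        df=df_model,
        pseudo_r2=1.0 - llf / llnull if llnull != 0 else np.nan,
        n_used=len(y_arr),
        n_dropped=0,
        weighted=weights is not None,
        converged=converged,
    )


def run_models(
    df: pd.DataFrame,
    specs: Optional[Sequence[ModelSpec]] = None,
    *,
    weighted: bool = False,
    weight_column: str = "weight",
    psu_column: str = "psu_id",
) -> dict[int, LogisticModelResult | Exception]:
    """Fit all determinant models; a failure in one model is recorded as the
    exception and does not abort the others."""
    if specs is None:
        specs = default_model_specs()
    out: dict[int, LogisticModelResult | Exception] = {}
    for spec in specs:
        try:
            X, y, n_dropped = build_design_matrix(df, spec)
            kwargs = {}
            if weighted:
                sub = df.loc[X.index]
                kwargs["weights"] = sub[weight_column].to_numpy()
                kwargs["cluster"] = sub[psu_column].to_numpy()
            result = fit_logistic(X, y, **kwargs)
            result.n_dropped = n_dropped
            result.outcome = spec.outcome
            result.model_id = spec.model_id
            out[spec.model_id] = result
        except Exception as exc:  # noqa: BLE001 - collected per model
            log.warning("model %d failed: %s", spec.model_id, exc)
            out[spec.model_id] = exc
    return out


def model_table(result: LogisticModelResult) -> pd.DataFrame:
    """Flat publication-style table (one row per term plus fit statistics)."""
    rows = result.terms.reset_index(names="term")
    rows["or_ci"] = [
        f"{o:.3f}{s} ({lo:.3f} to {hi:.3f})"
        for o, s, lo, hi in zip(
            rows["odds_ratio"], rows["stars"], rows["ci_low"], rows["ci_high"]
        )
    ]
    return rows
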