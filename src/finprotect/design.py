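"""Design-based estimation for stratified, clustered, weighted samples.

Point estimates are Hajek ratio means ``sum(w*y)/sum(w)``.  Variances use
first-stage Taylor linearization, the standard approach for multi-stage
household surveys when second-stage sampling fractions are small: the
linearized residuals ``u_i = w_i (y_i - est)`` are totalled per PSU and the
between-PSU, within-stratum variance of those totals

    var_h = n_h / (n_h - 1) * sum_c (t_hc - mean_h)^2

is summed over strata and divided by ``(sum w)^2``.  Confidence intervals
are normal-theory ``estimate +/- 1.96 * SE``, truncated to [0, 1] for
proportions.  Domain (subpopulation) estimation keeps the full PSU
structure, zeroing residuals outside the domain.

A stratum with a single PSU has no within-stratum variance contribution and
is a hard error by default; ``single_psu="center"`` switches to measuring
such strata against the grand mean of PSU totals (the usual fallback for
real-world designs with certainty units).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import DesignError, DomainError

Z975 = 1.959963984540054


@dataclass(frozen=True)
class SurveyDesign:
    """Column names of the design variables plus variance options."""

    weight_column: str = "weight"
    psu_column: str = "psu_id"
    stratum_column: str = "stratum_id"
    single_psu: Literal["error", "center"] = "error"

    def replace(self, **kw) -> "SurveyDesign":
        from dataclasses import replace

        return replace(self, **kw)


@dataclass(frozen=True)
class DesignEstimate:
    """Weighted point estimate with a design-based 95% CI."""

    estimate: float
    ci_low: float
    ci_high: float
    se: float
    n: int
    weighted_n: float

    def __post_init__(self):
        if not (np.isnan(self.estimate) or self.ci_low <= self.estimate <= self.ci_high):
            raise DesignError("confidence interval does not bracket the estimate")


def _columns(df: pd.DataFrame, design: SurveyDesign):
    for col in (design.weight_column, design.psu_column, design.stratum_column):
        if col not in df.columns:
            raise DesignError(f"design column '{col}' not in table")
    w = df[design.weight_column].to_numpy(dtype=float)
    if len(w) == 0:
        raise DesignError("empty table")
    if np.any(w <= 0) or np.any(np.isnan(w)):
        raise DomainError("weights must be positive")
    return w, df[design.psu_column].to_numpy(), df[design.stratum_column].to_numpy()


def _linearized_se(
    u: np.ndarray, psu: np.ndarray, stratum: np.ndarray, denom: float,
    single_psu: str,
) -> float:
    """SE of a ratio estimator from linearized residuals ``u`` (already
    weight-multiplied), totalled per PSU within strata."""
    frame = pd.DataFrame({"u": u, "psu": psu, "stratum": stratum})
    totals = frame.groupby(["stratum", "psu"], sort=True)["u"].sum()
    var = 0.0
    grand_mean = float(totals.mean())
    for _, t in totals.groupby(level="stratum", sort=True):
        n_h = len(t)
        if n_h < 2:
            if single_psu == "center":
                var += float(((t - grand_mean) ** 2).sum())
                continue
            raise DesignError(
                "stratum with a single PSU: collapse strata or use "
                "single_psu='center'"
            )
        dev = t.to_numpy() - t.to_numpy().mean()
        var += n_h / (n_h - 1) * float((dev**2).sum())
    return float(np.sqrt(var) / denom)


def _ratio_estimate(
    y: np.ndarray,
    df: pd.DataFrame,
    design: SurveyDesign,
    domain: Optional[np.ndarray],
    is_proportion: bool,
) -> DesignEstimate:
    w, psu, stratum = _columns(df, design)
    y = np.asarray(y, dtype=float)
    if len(y) != len(w):
        raise DesignError("values and table lengths differ")
    d = np.ones(len(w)) if domain is None else np.asarray(domain, dtype=float)
    wd = w * d
    weighted_n = float(wd.sum())
    n = int(np.count_nonzero(d))
    if weighted_n == 0:
        return DesignEstimate(np.nan, np.nan, np.nan, np.nan, n, 0.0)
    est = float((wd * y).sum() / weighted_n)
    u = wd * (y - est)
    se = _linearized_se(u, psu, stratum, weighted_n, design.single_psu)
    lo, hi = est - Z975 * se, est + Z975 * se
    if is_proportion:
        lo, hi = max(lo, 0.0), min(hi, 1.0)
        # truncation never inverts: est itself lies in [0,1]
    return DesignEstimate(est, lo, hi, se, n, weighted_n)


def weighted_proportion(
    indicator: Union[np.ndarray, pd.Series, Sequence[float]],
    df: pd.DataFrame,
    design: SurveyDesign,
    domain: Optional[np.ndarray] = None,
) -> DesignEstimate:
    """Design-based estimate of a population proportion from a 0/1 vector."""
    y = np.asarray(indicator, dtype=float)
    if not np.isin(y[~np.isnan(y)], (0.0, 1.0)).all():
        raise DomainError("indicator must be binary 0/1")
    return _ratio_estimate(y, df, design, domain, is_proportion=True)


def weighted_mean(
    values: Union[np.ndarray, pd.Series, Sequence[float]],
    df: pd.DataFrame,
    design: SurveyDesign,
    domain: Optional[np.ndarray] = None,
) -> DesignEstimate:
    """Design-based estimate of a population mean; ``domain`` restricts to a
    subpopulation (e.g. households with any health payment) while keeping
    the full PSU structure for the variance."""
    return _ratio_estimate(np.asarray(values, dtype=float), df, design, domain,
                           is_proportion=False)


def weighted_quantile(
    values: Sequence[float], weights: Sequence[float], q: Union[float, Sequence[float]]
):
    """Lower weighted quantile(s): the smallest observed value whose
    cumulative weight share reaches ``q``."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(v) == 0:
        raise DomainError("empty input")
    if np.any(w < 0) or w.sum() <= 0:
        raise DomainError("weights must be nonnegative with positive sum")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w) / w.sum()
    qs = np.atleast_1d(np.asarray(q, dtype=float))
    idx = np.searchsorted(cum, qs - 1e-12, side="left")
    idx = np.clip(idx, 0, len(v) - 1)
    out = v[idx]
    return float(out[0]) if np.isscalar(q) else out


def weighted_median(values: Sequence[float], weights: Sequence[float]) -> float:
    """Lower weighted median (see :func:`weighted_quantile`)."""
    return float(weighted_quantile(values, weights, 0.5))
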