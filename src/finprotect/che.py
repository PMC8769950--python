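"""Catastrophic health expenditure (CHE) indicators and weighted incidence.

A household faces catastrophic spending when its monthly out-of-pocket
payments *strictly exceed* a threshold share z of a capacity denominator:
total consumption expenditure (the canonical z = 0.10) or non-food
expenditure (the canonical z = 0.40).  With a zero denominator, any
positive OOP is catastrophic and zero OOP is not — both conventions follow
directly from the strict inequality.

Incidence is the household-level weighted headcount sum(w*E)/sum(w) with a
design-based CI; a person-weighted variant (w * household size) is
available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .design import DesignEstimate, SurveyDesign, weighted_proportion
from .exceptions import DomainError

CANONICAL_SPECS: tuple["ThresholdSpec", ...]


@dataclass(frozen=True)
class ThresholdSpec:
    """A CHE rule: denominator kind plus threshold fraction z in (0,1)."""

    denominator: Literal["total", "nonfood"]
    z: float

    def __post_init__(self):
        if self.denominator not in ("total", "nonfood"):
            raise DomainError(f"denominator must be 'total' or 'nonfood', got "
                              f"{self.denominator!r}")
        if not 0.0 < self.z < 1.0:
            raise DomainError(f"threshold z must be in (0,1), got {self.z}")

    @property
    def label(self) -> str:
        return f"che_{self.denominator}_{round(self.z * 100):g}"

    @classmethod
    def parse(cls, text: str) -> "ThresholdSpec":
        """Parse 'total:0.10' / 'nonfood:0.40' CLI syntax."""
        kind, _, frac = text.partition(":")
        return cls(kind.strip(), float(frac))  # type: ignore[arg-type]


CANONICAL_SPECS = (ThresholdSpec("total", 0.10), ThresholdSpec("nonfood", 0.40))


def che_indicator(df: pd.DataFrame, spec: ThresholdSpec) -> np.ndarray:
    """Per-household 0/1 catastrophic-spending flags.

    Requires the aggregate columns ``total_exp`` / ``nonfood_exp`` and
    ``oop_monthly`` (see :func:`finprotect.consumption.add_aggregates`).
    """
    oop = df["oop_monthly"].to_numpy(dtype=float)
    denom_col = "total_exp" if spec.denominator == "total" else "nonfood_exp"
    denom = df[denom_col].to_numpy(dtype=float)
    if np.any(oop < 0) or np.any(denom < 0):
        raise DomainError("negative OOP or denominator")
    return (oop > spec.z * denom).astype(np.int8)


def che_headcount(
    df: pd.DataFrame,
    spec: ThresholdSpec,
    design: SurveyDesign,
    domain: Optional[np.ndarray] = None,
    person_weighted: bool = False,
) -> DesignEstimate:
    """Weighted CHE incidence with a design-based 95% CI."""
    flags = che_indicator(df, spec)
    if person_weighted:
        df = df.assign(
            _pw=df[design.weight_column].to_numpy(dtype=float)
            * df["hh_size"].to_numpy(dtype=float)
        )
        design = design.replace(weight_column="_pw")
    return weighted_proportion(flags, df, design, domain=domain)


def che_by_subgroup(
    df: pd.DataFrame,
    specs: Sequence[ThresholdSpec],
    by: Sequence[str],
    design: SurveyDesign,
) -> pd.DataFrame:
    """Weighted incidence per subgroup level and threshold, plus overall.

    One row per (grouping variable, level, threshold); subgroups with zero
    weighted mass yield a flagged row with an undefined estimate.
    """
    for col in by:
        if col not in df.columns:
            raise DomainError(f"grouping column '{col}' not in table")
    rows = []

    def emit(group_var: str, level, mask: Optional[np.ndarray]):
        for spec in specs:
            est = che_headcount(df, spec, design, domain=mask)
            rows.append(
                {
                    "group_var": group_var,
                    "level": level,
                    "threshold": spec.label,
                    "estimate": est.estimate,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "n": est.n,
                    "weighted_n": est.weighted_n,
                    "undefined": int(np.isnan(est.estimate)),
                }
            )

    for col in by:
        levels = pd.unique(df[col])
        try:
            levels = np.sort(levels)
        except TypeError:
            pass
        for level in levels:
            emit(col, level, (df[col] == level).to_numpy(dtype=float))
    emit("overall", "all", None)
    return pd.DataFrame(rows)
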