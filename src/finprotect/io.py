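"""Reading and writing household tables as delimited text.

The on-disk format is UTF-8 CSV with a header row, ``.`` as the decimal
separator and the single sentinel ``NA`` for missing values.  Floats are
written with full (round-trippable) precision so that
``read_table(write_table(t)) == t``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .exceptions import SchemaError

log = logging.getLogger(__name__)

NA_SENTINEL = "NA"

#: design columns
DESIGN_COLUMNS = ("household_id", "psu_id", "stratum_id", "weight", "hh_size")
#: monetary columns (currency per the recall window in the name)
MONEY_COLUMNS = (
    "food_exp",
    "nonfood_exp",
    "oop_outpatient_30d",
    "oop_inpatient_annual",
    "oop_nonmedical_30d",
)
#: binary 0/1 covariates
BINARY_COLUMNS = (
    "head_female",
    "has_child",
    "has_elderly",
    "chronic_care",
    "inpatient_use",
    "used_public",
    "used_private",
    "used_ngo",
    "used_other",
    "rural",
)
#: categorical covariates
CATEGORICAL_COLUMNS = ("head_education", "division")

REQUIRED_COLUMNS = DESIGN_COLUMNS + MONEY_COLUMNS + BINARY_COLUMNS + CATEGORICAL_COLUMNS

#: columns appended by downstream stages that read_table tolerates
DERIVED_COLUMNS = (
    "total_exp",
    "per_capita_exp",
    "oop_monthly",
    "degenerate",
    "asset_score",
    "asset_quintile",
    "che_total_10",
    "che_nonfood_40",
    "poor_gross_national",
    "poor_net_national",
    "impoverished_national",
    "poor_gross_ipl",
    "poor_net_ipl",
    "impoverished_ipl",
    "any_oop",
)

ASSET_PREFIX = "asset_"


def _known(column: str) -> bool:
    return (
        column in REQUIRED_COLUMNS
        or column in DERIVED_COLUMNS
        or column.startswith(ASSET_PREFIX)
    )


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate the household schema, raising :class:`SchemaError` with the
    offending column (and row index where applicable)."""
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column '{col}'")
    for col in df.columns:
        if not _known(col):
            raise SchemaError(f"unknown column '{col}'")
    for col in MONEY_COLUMNS + ("weight",):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(f"non-numeric value in column '{col}' at row {row}")
        df[col] = values.astype(float)
    nonpos = df["weight"].to_numpy() <= 0
    if np.any(nonpos | np.isnan(df["weight"].to_numpy())):
        row = int(np.flatnonzero(nonpos | np.isnan(df["weight"].to_numpy()))[0])
        raise SchemaError(f"nonpositive weight at row {row}")
    for col in MONEY_COLUMNS:
        neg = df[col].to_numpy() < 0
        if neg.any():
            row = int(np.flatnonzero(neg)[0])
            raise SchemaError(f"negative value in column '{col}' at row {row}")
    small = df["hh_size"].to_numpy() < 1
    if small.any():
        row = int(np.flatnonzero(small)[0])
        raise SchemaError(f"hh_size < 1 at row {row}")
    return df


def write_table(df: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Write a household table as CSV (header row, ``NA`` sentinel)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees binary64 -> text -> binary64 round-trips exactly
    df.to_csv(path, index=False, na_rep=NA_SENTINEL, float_format="%.17g")
    return path


def read_table(path: Union[str, Path], validate: bool = True) -> pd.DataFrame:
    """Read a household table written by :func:`write_table`.

    With ``validate=True`` (default) the schema is checked and a
    :class:`SchemaError` is raised on unknown columns, non-numeric monetary
    fields or nonpositive weights.
    """
    df = pd.read_csv(
        path, na_values=[NA_SENTINEL], keep_default_na=False,
        float_precision="round_trip",
    )
    if validate:
        df = validate_table(df)
    return df
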