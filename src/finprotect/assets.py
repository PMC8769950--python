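"""PCA-based household wealth index and population quintiles.

Categorical asset/housing indicators are dummy-coded (reference = first
sorted level; binary 0/1 columns pass through), standardized to weighted
mean 0 / variance 1, and the first principal component of the weighted
correlation matrix is the socioeconomic score — the Filmer-Pritchett
convention.  Household size enters as a frequency weight: for integer
weights the result is identical to unweighted PCA on a row-replicated
matrix.  The eigenvector sign is arbitrary, so scores are oriented to make
the summed loadings on a whitelist of wealth-indicating dummies positive
(electricity, piped water, flush sanitation by default), which makes
"richest" reproducible across runs and platforms.

Quintiles are cut at weighted score quantiles 0.2/0.4/0.6/0.8 (person
weights by default: design weight x household size, so quintiles are
population fifths).  Tied scores always share a quintile, assigned to the
lower one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import QUINTILE_LABELS
from .exceptions import AssetIndexError
from .io import ASSET_PREFIX

log = logging.getLogger(__name__)

#: substrings marking dummies that indicate wealth, used for sign orientation
DEFAULT_WEALTH_MARKERS = (
    "electricity",
    "water_piped",
    "sanitation_flush",
    "fridge",
)


@dataclass
class AssetIndexResult:
    """First-component loadings, per-household scores and quintiles."""

    loadings: pd.Series
    scores: np.ndarray
    explained_share: float
    quintile: Optional[pd.Series] = None
    dropped_columns: tuple[str, ...] = ()


def asset_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith(ASSET_PREFIX)
            and c not in ("asset_score", "asset_quintile")]
    if not cols:
        raise AssetIndexError("no asset_* columns in table")
    return cols


def encode_assets(df: pd.DataFrame, columns: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Dummy-code the asset indicators.

    One column per non-reference level (reference = first sorted level);
    numeric 0/1 columns are kept as single columns.  Constant columns are
    dropped with a logged warning; a matrix with no variation at all is an
    error.  Column order is deterministic: sorted by variable then level.
    """
    columns = list(columns) if columns is not None else asset_columns(df)
    pieces: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for col in sorted(columns):
        if col not in df.columns:
            raise AssetIndexError(f"asset column '{col}' not in table")
        series = df[col]
        if pd.api.types.is_numeric_dtype(series):
            values = set(pd.unique(series.dropna()))
            if values <= {0, 1}:
                if len(values) < 2:
                    dropped.append(col)
                    continue
                pieces[col] = series.to_numpy(dtype=float)
                continue
        levels = sorted(pd.unique(series.astype(str)))
        if len(levels) < 2:
            dropped.append(col)
            continue
        as_str = series.astype(str)
        for level in levels[1:]:
            pieces[f"{col}_{level}"] = (as_str == level).to_numpy(dtype=float)
    if dropped:
        log.warning("dropped constant asset columns: %s", ", ".join(dropped))
    if not pieces:
        raise AssetIndexError("all asset columns are constant; nothing to analyze")
    return pd.DataFrame(pieces, index=df.index)


def pca_first_component(
    matrix: pd.DataFrame,
    freq_weights: Optional[Sequence[float]] = None,
    wealth_markers: Sequence[str] = DEFAULT_WEALTH_MARKERS,
) -> AssetIndexResult:
    """Leading component of the frequency-weighted correlation matrix.

    Columns are standardized to weighted mean 0 and weighted (population)
    variance 1; loadings are the unit-norm leading eigenvector; scores are
    the standardized matrix times the loadings; ``explained_share`` is the
    leading eigenvalue over the trace.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise AssetIndexError("need at least 2 non-constant dummy columns")
    w = np.ones(n) if freq_weights is None else np.asarray(freq_weights, dtype=float)
    if np.any(w <= 0):
        raise AssetIndexError("frequency weights must be positive")
    wsum = w.sum()
    mean = (w @ X) / wsum
    centered = X - mean
    var = (w @ centered**2) / wsum
    if np.all(var <= 0):
        raise AssetIndexError("degenerate asset matrix: zero variance")
    keep = var > 0
    if not keep.all():
        log.warning("dropping zero-variance dummies: %s",
                    ", ".join(matrix.columns[~keep]))
    kept_cols = matrix.columns[keep]
    Z = centered[:, keep] / np.sqrt(var[keep])
    corr = (Z * w[:, None]).T @ Z / wsum
    corr = (corr + corr.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals[-1] <= 0:
        raise AssetIndexError("degenerate (rank-0) asset matrix")
    leading = eigvecs[:, -1]
    loadings = pd.Series(leading, index=kept_cols)

    marked = [c for c in kept_cols if any(m in c for m in wealth_markers)]
    orient = loadings[marked].sum() if marked else loadings.iloc[np.argmax(np.abs(loadings))]
    if orient < 0:
        loadings = -loadings
    scores = Z @ loadings.to_numpy()
    explained = float(eigvals[-1] / eigvals.sum())
    return AssetIndexResult(
        loadings=loadings,
        scores=scores,
        explained_share=explained,
        dropped_columns=tuple(matrix.columns[~keep]),
    )


def weighted_quintiles(
    scores: Sequence[float],
    person_weights: Sequence[float],
    labels: Sequence[str] = QUINTILE_LABELS,
) -> pd.Series:
    """Assign quintile labels so each fifth of the weighted population falls
    in one class; identical scores share the lower applicable quintile."""
    s = np.asarray(scores, dtype=float)
    w = np.asarray(person_weights, dtype=float)
    if np.any(w <= 0):
        raise AssetIndexError("person weights must be positive")
    order = np.argsort(s, kind="stable")
    sorted_s = s[order]
    sorted_w = w[order]
    # cumulative weight share strictly below each distinct score group
    starts = np.flatnonzero(np.r_[True, np.diff(sorted_s) != 0])
    group_of_sorted = np.cumsum(np.r_[True, np.diff(sorted_s) != 0]) - 1
    cum = np.cumsum(sorted_w)
    below = np.r_[0.0, cum[:-1]][starts] / cum[-1]
    n_classes = len(labels)
    q_of_group = np.minimum((below / (1.0 / n_classes) + 1e-12).astype(int),
                            n_classes - 1)
    if len(starts) == 1:
        log.warning("all asset scores identical; single quintile assigned")
    labels_arr = np.asarray(labels, dtype=object)
    out = np.empty(len(s), dtype=object)
    out[order] = labels_arr[q_of_group[group_of_sorted]]
    return pd.Series(out, name="asset_quintile")


def assign_asset_quintiles(
    df: pd.DataFrame,
    design_weight_column: str = "weight",
    columns: Optional[Sequence[str]] = None,
    wealth_markers: Sequence[str] = DEFAULT_WEALTH_MARKERS,
) -> tuple[pd.DataFrame, AssetIndexResult]:
    """Encode assets, run the frequency-weighted PCA (household size as
    frequency weights), cut person-weighted quintiles and append
    ``asset_score`` / ``asset_quintile`` columns."""
    dummies = encode_assets(df, columns)
    result = pca_first_component(
        dummies, freq_weights=df["hh_size"].to_numpy(dtype=float),
        wealth_markers=wealth_markers,
    )
    pweights = (
        df[design_weight_column].to_numpy(dtype=float)
        * df["hh_size"].to_numpy(dtype=float)
    )
    quintile = weighted_quintiles(result.scores, pweights)
    quintile.index = df.index
    result.quintile = quintile
    out = df.copy()
    out["asset_score"] = result.scores
    out["asset_quintile"] = quintile
    return out, result
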