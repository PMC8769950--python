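"""Independent brute-force oracles used by the test suite.

Every function here re-implements a package operation from its definition,
with plain Python loops and dictionaries, deliberately sharing no code with
the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np


def loop_che_flags(oop, denom, z):
    """Literal strict-inequality catastrophic flags."""
    return [1 if o > z * d else 0 for o, d in zip(oop, denom)]


def loop_weighted_headcount(flags, weights):
    num = 0.0
    den = 0.0
    for f, w in zip(flags, weights):
        num += w * f
        den += w
    return num / den


def loop_impoverished_share(total, hh_size, oop, weights, line):
    """Person-weighted share of gross-non-poor households made net-poor."""
    num = 0.0
    den = 0.0
    for t, s, o, w in zip(total, hh_size, oop, weights):
        gross_pc = t / s
        net_pc = max(t - o, 0.0) / s
        pushed = 1.0 if (gross_pc >= line and net_pc < line) else 0.0
        num += w * s * pushed
        den += w * s
    return num / den


def loop_weighted_median(values, weights):
    """Lower weighted median: sort, walk the cumulative weight to 1/2."""
    pairs = sorted(zip(values, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    for v, w in pairs:
        cum += w
        if cum >= 0.5 * total - 1e-12:
            return v
    return pairs[-1][0]


def loop_linearized_se(y, weights, psu, stratum):
    """First-stage Taylor linearization SE of sum(w*y)/sum(w), coded from
    the variance formula with dictionaries."""
    wsum = sum(weights)
    est = sum(w * yi for w, yi in zip(weights, y)) / wsum
    psu_totals: dict[tuple, float] = {}
    strata: dict[object, set] = {}
    for yi, w, p, h in zip(y, weights, psu, stratum):
        psu_totals[(h, p)] = psu_totals.get((h, p), 0.0) + w * (yi - est)
        strata.setdefault(h, set()).add(p)
    var = 0.0
    for h, psus in strata.items():
        totals = [psu_totals[(h, p)] for p in psus]
        n_h = len(totals)
        mean_h = sum(totals) / n_h
        var += n_h / (n_h - 1) * sum((t - mean_h) ** 2 for t in totals)
    return math.sqrt(var) / wsum


def replicated_pca(matrix, int_weights):
    """Unweighted correlation PCA on the row-replicated matrix.

    Returns (loadings, scores_of_original_rows, explained_share); the
    loading sign is unoriented.
    """
    X = np.repeat(np.asarray(matrix, dtype=float), np.asarray(int_weights), axis=0)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD, ddof=0
    Z = (X - mean) / sd
    corr = Z.T @ Z / len(Z)
    eigvals, eigvecs = np.linalg.eigh(corr)
    loadings = eigvecs[:, -1]
    Z_orig = (np.asarray(matrix, dtype=float) - mean) / sd
    return loadings, Z_orig @ loadings, eigvals[-1] / eigvals.sum()


def crosstab_odds_ratio(x, y):
    """ad/bc from the 2x2 table of a binary covariate and outcome."""
    a = sum(1 for xi, yi in zip(x, y) if xi == 1 and yi == 1)
    b = sum(1 for xi, yi in zip(x, y) if xi == 1 and yi == 0)
    c = sum(1 for xi, yi in zip(x, y) if xi == 0 and yi == 1)
    d = sum(1 for xi, yi in zip(x, y) if xi == 0 and yi == 0)
    return (a * d) / (b * c)
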