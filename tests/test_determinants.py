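"""Logistic determinant models: design matrix, ML fit, closed-form oracles."""

import numpy as np
import pandas as pd
import pytest

from finprotect import (
    GeneratorConfig,
    ModelSpec,
    build_design_matrix,
    default_model_specs,
    fit_logistic,
    run_models,
)
from finprotect.determinants import term_matrix
from finprotect.exceptions import ModelError, SeparationError

from oracles import crosstab_odds_ratio


def test_division_coding_drops_reference(enriched_table):
    X = term_matrix(enriched_table)
    assert "div_barisal" not in X.columns
    assert {"div_chittagong", "div_dhaka", "div_khulna", "div_rangpur",
            "div_rajshahi", "div_sylhet"} <= set(X.columns)
    assert X["const"].eq(1.0).all()
    # model 1 has 26 non-constant terms, models 3-4 have 22
    assert term_matrix(enriched_table, include_quintiles=True).shape[1] == 27
    assert X.shape[1] == 23


def test_design_matrix_matches_hand_construction():
    df = pd.DataFrame(
        {
            "head_female": [1, 0],
            "head_education": ["none", "university"],
            "has_child": [0, 1],
            "has_elderly": [1, 0],
            "hh_size": [2, 6],
            "chronic_care": [1, 0],
            "inpatient_use": [0, 0],
            "used_public": [0, 1],
            "used_private": [1, 0],
            "used_ngo": [0, 0],
            "used_other": [0, 1],
            "rural": [1, 0],
            "division": ["Barisal", "Sylhet"],
        }
    )
    X = term_matrix(df)
    assert X.loc[0, "head_male"] == 0 and X.loc[1, "head_male"] == 1
    assert X.loc[1, "edu_university"] == 1 and X.loc[0, "edu_university"] == 0
    assert X.loc[0, "hhsize_3_4"] == 0 and X.loc[0, "hhsize_5plus"] == 0
    assert X.loc[1, "hhsize_5plus"] == 1
    assert X.loc[1, "div_sylhet"] == 1 and X.loc[0].filter(like="div_").sum() == 0


def test_incomplete_rows_dropped_and_counted(enriched_table):
    df = enriched_table.head(50).copy()
    df.loc[df.index[3], "head_education"] = np.nan
    X, y, n_dropped = build_design_matrix(df, ModelSpec(1, "che_total_10", True))
    assert n_dropped == 1
    assert len(X) == 49


def test_missing_covariate_column_named(enriched_table):
    df = enriched_table.drop(columns=["chronic_care"])
    with pytest.raises(ModelError, match="chronic_care"):
        build_design_matrix(df, ModelSpec(1, "che_total_10", True))


def test_intercept_only_closed_form():
    y = pd.Series([1] * 30 + [0] * 70, dtype=float)
    X = pd.DataFrame({"const": np.ones(100)})
    res = fit_logistic(X, y)
    assert res.odds_ratio("const") == pytest.approx(30 / 70, rel=1e-6)


def test_single_binary_covariate_matches_crosstab_oracle():
    rng = np.random.default_rng(4)
    x = (rng.random(2000) < 0.4).astype(float)
    p = 1 / (1 + np.exp(-(-1.0 + 1.2 * x)))
    y = (rng.random(2000) < p).astype(float)
    X = pd.DataFrame({"const": np.ones(2000), "x": x})
    res = fit_logistic(X, y)
    assert res.odds_ratio("x") == pytest.approx(crosstab_odds_ratio(x, y), rel=1e-6)
    assert res.log_likelihood >= res.ll_null
    assert 0 <= res.pseudo_r2 < 1


def test_or_equals_exp_beta_and_ci_order(enriched_table):
    X, y, _ = build_design_matrix(enriched_table, ModelSpec(1, "che_total_10", True))
    res = fit_logistic(X, y)
    np.testing.assert_allclose(res.terms["odds_ratio"], np.exp(res.terms["beta"]))
    assert (res.terms["ci_low"] <= res.terms["odds_ratio"]).all()
    assert (res.terms["odds_ratio"] <= res.terms["ci_high"]).all()


def test_result_invariant_to_column_order(enriched_table):
    X, y, _ = build_design_matrix(enriched_table, ModelSpec(1, "che_total_10", True))
    res_a = fit_logistic(X, y)
    shuffled = X[list(X.columns[::-1])]
    res_b = fit_logistic(shuffled, y)
    for term in X.columns:
        assert res_a.terms.loc[term, "odds_ratio"] == pytest.approx(
            res_b.terms.loc[term, "odds_ratio"], rel=1e-8
        )


def test_deterministic_refit(enriched_table):
    X, y, _ = build_design_matrix(enriched_table, ModelSpec(2, "che_nonfood_40", True))
    a = fit_logistic(X, y)
    b = fit_logistic(X, y)
    pd.testing.assert_frame_equal(a.terms, b.terms, check_exact=True)


def test_separation_names_term():
    y = pd.Series([0] * 50 + [1] * 50, dtype=float)
    X = pd.DataFrame({"const": np.ones(100), "leak": y.to_numpy()})
    with pytest.raises(SeparationError):
        fit_logistic(X, y)


def test_single_class_outcome_errors():
    X = pd.DataFrame({"const": np.ones(10)})
    with pytest.raises(ModelError, match="single class"):
        fit_logistic(X, pd.Series(np.zeros(10)))


def test_run_models_isolates_failures(enriched_table):
    df = enriched_table.assign(impoverished_ipl=0)
    results = run_models(df)
    assert isinstance(results[4], Exception)
    for mid in (1, 2, 3):
        assert not isinstance(results[mid], Exception)
        assert results[mid].n_used == len(df)


def test_weighted_variant_runs(enriched_table):
    results = run_models(enriched_table, specs=default_model_specs()[:1], weighted=True)
    res = results[1]
    assert not isinstance(res, Exception)
    assert res.weighted
    assert res.odds_ratio("used_private") > 1


def test_known_effects_recovered_in_direction(enriched_table):
    results = run_models(enriched_table, specs=default_model_specs()[:1])
    res = results[1]
    assert res.odds_ratio("used_private") > 1
    assert res.odds_ratio("chronic_care") > 1
    assert res.terms.loc["used_private", "p_value"] < 0.001
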