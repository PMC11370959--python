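"""Summary tables, eligibility screening, z-scores and the logistic harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ewas_hypogen.cohort import (
    eligibility,
    logistic_test,
    round_half_up,
    run_battery,
    summarize,
    zscore,
)
from ewas_hypogen.catalog import HypothesisSet


# ---------------------------------------------------------------- summarize

# printed cells of the published cohort table: (variable, condition, group,
# positive count, percent)
PRINTED_BINARY_CELLS = [
    ("oral_contraception", "dysmenorrhea", "cases", 445, 69.4),
    ("oral_contraception", "dysmenorrhea", "controls", 271, 21.6),
    ("oral_contraception", "hmb", "cases", 390, 74.0),
    ("oral_contraception", "hmb", "controls", 511, 24.5),
    ("smoked_by_13", "dysmenorrhea", "cases", 99, 15.4),
    ("smoked_by_13", "dysmenorrhea", "controls", 92, 7.3),
    ("smoked_by_13", "hmb", "cases", 91, 17.3),
    ("smoked_by_13", "hmb", "controls", 160, 7.7),
    ("prenatal_smoking", "dysmenorrhea", "cases", 142, 22.2),
    ("prenatal_smoking", "hmb", "cases", 132, 25.0),
    ("maternal_university_degree", "dysmenorrhea", "cases", 70, 10.9),
    ("maternal_university_degree", "hmb", "controls", 361, 17.3),
    ("prenatal_alcohol", "dysmenorrhea", "cases", 394, 61.5),
    ("prenatal_hdp", "hmb", "cases", 97, 18.4),
    ("prenatal_preeclampsia", "dysmenorrhea", "cases", 9, 1.4),
    ("alcohol_by_13", "hmb", "controls", 430, 20.6),
    ("comorbidity", "dysmenorrhea", "controls", 30, 2.4),
]


@pytest.mark.parametrize("variable,condition,group,count,percent", PRINTED_BINARY_CELLS)
def test_summarize_reproduces_printed_binary_cells(table1, variable, condition, group, count, percent):
    summary = summarize(table1, condition, variables=[variable])
    assert summary.loc[variable, f"{group}_positive"] == count
    assert summary.loc[variable, f"{group}_percent"] == percent
    assert summary.loc[variable, f"{group}_display"] == f"{count} ({percent:.1f}%)"


def test_summarize_reproduces_printed_continuous_cells(table1):
    summary = summarize(table1, "dysmenorrhea", variables=["aam_months", "crp_age9"])
    assert summary.loc["aam_months", "cases_display"] == "146.0 (12.8)"
    assert summary.loc["aam_months", "controls_display"] == "151.5 (12.6)"
    assert summary.loc["crp_age9", "cases_display"] == "1.2 (3.7)"
    assert summary.loc["crp_age9", "controls_display"] == "0.7 (1.4)"
    hmb = summarize(table1, "hmb", variables=["ace_score_16"])
    assert hmb.loc["ace_score_16", "cases_display"] == "2.1 (1.9)"
    assert hmb.loc["ace_score_16", "controls_display"] == "1.5 (1.5)"


def test_summarize_group_sizes_match_published(table1):
    s = summarize(table1, "dysmenorrhea", variables=["smoked_by_13"])
    assert s.loc["smoked_by_13", "cases_n"] == 641
    assert s.loc["smoked_by_13", "controls_n"] == 1254
    s = summarize(table1, "hmb", variables=["smoked_by_13"])
    assert s.loc["smoked_by_13", "cases_n"] == 527
    assert s.loc["smoked_by_13", "controls_n"] == 2083


def test_summarize_missing_counts_match_published(table1):
    s = summarize(table1, "dysmenorrhea", variables=["alcohol_by_13", "ace_score_16"])
    assert s.loc["alcohol_by_13", "cases_missing"] == 311
    assert s.loc["alcohol_by_13", "controls_missing"] == 649
    assert s.loc["ace_score_16", "cases_missing"] == 419
    assert s.loc["ace_score_16", "controls_missing"] == 892


def test_summarize_zero_positive_group():
    pheno = pd.DataFrame({"cond": [1, 1, 0, 0], "var": [0.0, 0.0, 1.0, 0.0]})
    s = summarize(pheno, "cond", variables=["var"])
    assert s.loc["var", "cases_display"] == "0 (0.0%)"


def test_summarize_unknown_condition_errors(table1):
    with pytest.raises(KeyError):
        summarize(table1, "not_a_condition")


def test_round_half_up_convention():
    assert round_half_up(0.05, 1) == 0.1
    assert round_half_up(69.4414, 1) == 69.4
    assert round_half_up(7.35, 1) == 7.4


# -------------------------------------------------------------- eligibility

def binary_pheno(cells):
    """cells = (exposed cases, unexposed cases, exposed controls, unexposed controls)."""
    a, b, c, d = cells
    return pd.DataFrame({
        "cond": [1] * (a + b) + [0] * (c + d),
        "var": [1] * a + [0] * b + [1] * c + [0] * d,
    }, dtype=float)


def test_eligibility_sparse_cell_blocks_with_named_reason():
    ok, reason = eligibility(binary_pheno((100, 50, 4, 80)), "var", "cond")
    assert not ok
    assert "controls" in reason and "4" in reason


def test_eligibility_all_cells_at_minimum_is_eligible():
    ok, _ = eligibility(binary_pheno((5, 5, 5, 5)), "var", "cond")
    assert ok  # "fewer than five" is strict


def test_eligibility_continuous_counts_non_missing_per_group():
    pheno = pd.DataFrame({
        "cond": [1] * 6 + [0] * 6,
        "var": [1.2, 2.3, np.nan, np.nan, 0.5, 0.7] + [1.0] * 6,
    })
    ok, reason = eligibility(pheno, "var", "cond", var_type="continuous")
    assert not ok and "cases" in reason


# ------------------------------------------------------------------ zscore

def test_zscore_small_example():
    out = zscore(pd.Series([1.0, 2.0, 3.0]))
    assert np.allclose(out, [-1.0, 0.0, 1.0])


def test_zscore_contract_and_missing_preserved():
    rng = np.random.default_rng(1)
    s = pd.Series(rng.normal(10, 3, 50))
    s.iloc[[3, 17]] = np.nan
    out = zscore(s)
    assert abs(out.dropna().mean()) < 1e-12
    assert abs(out.dropna().std(ddof=1) - 1) < 1e-12
    assert out.isna().sum() == 2


def test_zscore_zero_sd_errors():
    with pytest.raises(ValueError, match="zero"):
        zscore(pd.Series([5.0, 5.0, 5.0]))
    with pytest.raises(ValueError):
        zscore(pd.Series([5.0]))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.lists(st.floats(-50, 50), min_size=3, max_size=40).filter(lambda v: np.std(v) > 1e-6),
    st.floats(-10, 10),
    st.floats(0.1, 10),
)
def test_zscore_idempotent_and_affine_invariant(values, shift, scale):
    s = pd.Series(values, dtype=float)
    z = zscore(s)
    assert np.allclose(zscore(z), z, atol=1e-10)
    assert np.allclose(zscore(s * scale + shift), z, atol=1e-8)


# ---------------------------------------------------------- logistic_test

def test_logistic_2x2_equals_cross_product_odds_ratio():
    pheno = binary_pheno((20, 10, 10, 20))
    res = logistic_test(pheno, "var", "cond")
    assert res.odds_ratio == pytest.approx(4.0, abs=1e-8)


def test_logistic_balanced_table_is_null():
    pheno = binary_pheno((25, 25, 25, 25))
    res = logistic_test(pheno, "var", "cond")
    assert res.odds_ratio == pytest.approx(1.0, abs=1e-8)
    assert res.p == pytest.approx(1.0, abs=1e-6)


def newton_raphson_logit(y, x, tol=1e-12):
    beta = np.zeros(x.shape[1])
    for _ in range(200):
        mu = 1.0 / (1.0 + np.exp(-(x @ beta)))
        grad = x.T @ (y - mu)
        hess = x.T @ (x * (mu * (1 - mu))[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    cov = np.linalg.inv(hess)
    return beta, np.sqrt(np.diag(cov))


def test_logistic_continuous_exposure_matches_newton_oracle():
    rng = np.random.default_rng(12)
    n = 60
    x_raw = rng.normal(2.0, 1.5, n)
    logit = -0.5 + 0.8 * (x_raw - x_raw.mean()) / x_raw.std(ddof=1)
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
    pheno = pd.DataFrame({"cond": y, "var": x_raw})
    res = logistic_test(pheno, "var", "cond")
    z = (x_raw - x_raw.mean()) / x_raw.std(ddof=1)
    design = np.column_stack([np.ones(n), z])
    beta, se = newton_raphson_logit(y, design)
    assert np.log(res.odds_ratio) == pytest.approx(beta[1], abs=1e-8)
    assert np.log(res.ci_high / res.odds_ratio) / 1.959963984540054 == pytest.approx(se[1], abs=1e-6)


def test_logistic_perfect_separation_is_flagged_not_estimated():
    pheno = pd.DataFrame({"cond": [0] * 10 + [1] * 10,
                          "var": [0.0] * 10 + [1.0] * 10})
    res = logistic_test(pheno, "var", "cond")
    assert res.omitted
    assert res.odds_ratio is None


def test_logistic_single_class_outcome_omitted():
    pheno = pd.DataFrame({"cond": [1.0] * 12, "var": [0, 1] * 6})
    res = logistic_test(pheno, "var", "cond")
    assert res.omitted and "single class" in res.reason


def test_adjusted_model_unchanged_when_adjusters_independent():
    rng = np.random.default_rng(5)
    n = 4000
    var = rng.integers(0, 2, n).astype(float)
    cond = (rng.random(n) < 1 / (1 + np.exp(-(0.7 * var - 0.5)))).astype(float)
    pheno = pd.DataFrame({
        "cond": cond, "var": var,
        "sep": rng.integers(0, 2, n).astype(float),
        "aam": rng.normal(150, 13, n),
    })
    raw = logistic_test(pheno, "var", "cond")
    adj = logistic_test(pheno, "var", "cond", adjusters=["sep", "aam"])
    assert adj.odds_ratio == pytest.approx(raw.odds_ratio, rel=0.05)


# ------------------------------------------------------------- run_battery

def hypothesis_set(traits):
    entries = pd.DataFrame({
        "trait": traits, "trait_key": [t.casefold() for t in traits],
        "provenance": "cpg", "sources": [("cg1",)] * len(traits), "study_count": 1,
    })
    return HypothesisSet(condition="cond", entries=entries)


def battery_pheno(seed=0, n=300):
    rng = np.random.default_rng(seed)
    smoking = rng.integers(0, 2, n).astype(float)
    cond = (rng.random(n) < 1 / (1 + np.exp(-(1.0 * smoking - 1.0)))).astype(float)
    return pd.DataFrame({
        "cond": cond, "smoking": smoking,
        "bmi": rng.normal(22, 3, n),
        "sep": rng.integers(0, 2, n).astype(float),
        "aam_months": rng.normal(150, 13, n),
    })


def test_battery_runs_mapped_traits_both_models():
    pheno = battery_pheno()
    results, unmapped = run_battery(
        pheno, hypothesis_set(["Smoking"]), {"smoking": "smoking"},
        conditions=["cond"], adjusters=["sep", "aam_months"],
    )
    assert set(results["model"]) == {"unadjusted", "adjusted"}
    assert len(results) == 2
    assert unmapped.empty
    assert (results["n"] > 0).all()


def test_battery_reports_unmapped_traits_not_fatal():
    pheno = battery_pheno()
    results, unmapped = run_battery(
        pheno, hypothesis_set(["Smoking", "primary Sjögren's syndrome"]),
        {"smoking": "smoking"}, conditions=["cond"],
    )
    assert list(unmapped["trait"]) == ["primary sjögren's syndrome"]
    assert set(results["exposure"]) == {"smoking"}


def test_battery_empty_hypotheses_runs_a_priori_list():
    pheno = battery_pheno()
    results, _ = run_battery(
        pheno, HypothesisSet(), {}, conditions=["cond"],
        a_priori=["smoking", "bmi"],
    )
    assert set(results["exposure"]) == {"smoking", "bmi"}


def test_battery_unadjusted_or_matches_planted_direction():
    agree = 0
    for seed in range(10):
        pheno = battery_pheno(seed=seed)
        results, _ = run_battery(
            pheno, hypothesis_set(["Smoking"]), {"smoking": "smoking"}, conditions=["cond"],
        )
        row = results[(results["exposure"] == "smoking") & (results["model"] == "unadjusted")]
        agree += float(row["odds_ratio"].iloc[0]) > 1.0
    assert agree >= 9


def test_battery_omits_ineligible_variable_with_reason():
    pheno = battery_pheno()
    pheno["rare"] = 0.0
    pheno.loc[pheno.index[:3], "rare"] = 1.0  # exposed cells < 5
    results, _ = run_battery(
        pheno, hypothesis_set(["Rare"]), {"rare": "rare"}, conditions=["cond"],
    )
    assert results["omitted"].all()
    assert (results["reason"].str.len() > 0).all()
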