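"""Per-probe OLS against an independent normal-equations oracle, plus scan
diagnostics (genomic lambda, QQ data, hit selection)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ewas_hypogen as eh
from ewas_hypogen.ewas import (
    EWASScan,
    build_design,
    fit_probe,
    genomic_lambda,
    qq_data,
    run_ewas,
    select_hits,
)
from conftest import status_from_condition


def ols_oracle(y, x, j):
    """Brute-force OLS: explicit normal equations + t distribution."""
    xtx_inv = np.linalg.inv(x.T @ x)
    coef = xtx_inv @ x.T @ y
    resid = y - x @ coef
    n, k = x.shape
    sigma2 = (resid @ resid) / (n - k)
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    t = coef[j] / se
    p = 2 * stats.t.sf(abs(t), n - k)
    tcrit = stats.t.ppf(0.975, n - k)
    return coef[j], se, coef[j] - tcrit * se, coef[j] + tcrit * se, p


def random_instance(rng, n=None, k=None):
    n = n or int(rng.integers(8, 31))
    k = k or int(rng.integers(2, 6))
    x = np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float),
                         rng.standard_normal((n, k - 2))]) if k > 2 else \
        np.column_stack([np.ones(n), rng.integers(0, 2, n).astype(float)])
    # guarantee both exposure groups present
    x[0, 1], x[1, 1] = 0.0, 1.0
    y = rng.standard_normal(n)
    return y, x


def test_fit_probe_matches_oracle_on_thousand_instances():
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        y, x = random_instance(rng)
        fit = fit_probe(y, x, exposure_index=1)
        beta, se, lo, hi, p = ols_oracle(y, x, 1)
        assert fit.beta == pytest.approx(beta, abs=1e-10)
        assert fit.se == pytest.approx(se, abs=1e-10)
        assert fit.ci_low == pytest.approx(lo, abs=1e-10)
        assert fit.ci_high == pytest.approx(hi, abs=1e-10)
        assert fit.p == pytest.approx(p, abs=1e-10)
        assert fit.n == len(y)


def test_constant_outcome_is_degenerate_with_zero_beta():
    x = np.column_stack([np.ones(12), np.repeat([0.0, 1.0], 6)])
    fit = fit_probe(np.full(12, 0.4), x)
    assert fit.beta == pytest.approx(0.0, abs=1e-12)
    assert fit.degenerate and np.isnan(fit.p)


def test_outcome_equal_to_exposure_is_noise_free_unit_effect():
    case = np.repeat([0.0, 1.0], 6)
    x = np.column_stack([np.ones(12), case])
    fit = fit_probe(case.copy(), x)
    assert fit.beta == pytest.approx(1.0)
    assert fit.degenerate


def test_fit_probe_drops_missing_cells():
    rng = np.random.default_rng(3)
    y, x = random_instance(rng, n=20, k=3)
    y_missing = y.copy()
    y_missing[[2, 7]] = np.nan
    fit = fit_probe(y_missing, x)
    keep = ~np.isnan(y_missing)
    beta, se, *_ = ols_oracle(y[keep], x[keep], 1)
    assert fit.n == 18
    assert fit.beta == pytest.approx(beta, abs=1e-12)
    assert fit.se == pytest.approx(se, abs=1e-12)


def test_genomic_lambda_identities():
    assert genomic_lambda(np.full(200, 0.5)) == pytest.approx(1.0)
    rng = np.random.default_rng(0)
    p = rng.uniform(size=5000)
    lam = genomic_lambda(p)
    assert genomic_lambda(p / 2) > lam  # halving p-values inflates lambda
    with pytest.raises(ValueError):
        genomic_lambda(np.full(50, 0.5))


def test_genomic_lambda_near_one_for_uniform_p():
    inside = 0
    for seed in range(10):
        p = np.random.default_rng(seed).uniform(size=10_000)
        inside += 0.95 <= genomic_lambda(p) <= 1.05
    assert inside >= 9


def test_qq_data_single_point_and_lengths():
    out = qq_data([0.5])
    assert out.shape == (1, 2)
    assert out.loc[0, "expected"] == pytest.approx(-np.log10(0.5))
    assert out.loc[0, "observed"] == pytest.approx(-np.log10(0.5))
    many = qq_data(np.random.default_rng(1).uniform(size=321))
    assert len(many) == 321


def test_qq_observed_tracks_expected_for_uniform_p():
    p = np.random.default_rng(7).uniform(size=100_000)
    out = qq_data(p)
    # Glivenko-Cantelli: uniform p-values hug the diagonal away from the tail
    body = out[out["expected"] < 3]
    assert np.max(np.abs(body["observed"] - body["expected"])) < 0.12


def test_select_hits_strict_threshold_and_ordering():
    table = pd.DataFrame(
        {"p": [1e-6, 1e-5, 2e-6, np.nan, 0.5]},
        index=["b", "at_threshold", "a", "deg", "null"],
    )
    hits = select_hits(table, threshold=1e-5)
    assert hits == ["b", "a"]  # 1e-5 exactly is excluded; sorted by p
    assert select_hits(table.iloc[0:0]) == []


def test_tied_p_values_break_by_probe_id():
    table = pd.DataFrame({"p": [1e-7, 1e-7]}, index=["z", "a"])
    assert select_hits(table) == ["a", "z"]


def test_scan_with_zero_svs_reduces_to_age_only_design(small_dataset):
    beta, pheno, _, _ = small_dataset
    status = status_from_condition(pheno)
    direct = run_ewas(beta, pheno, status, svs=None)
    empty = eh.SurrogateVariableSet(n_sv=0, data=pd.DataFrame(index=pheno.index))
    via_empty = run_ewas(beta, pheno, status, svs=empty)
    pd.testing.assert_frame_equal(direct.table, via_empty.table)
    assert direct.covariates == ["intercept", "case", "age"]


def test_scan_invariant_to_consistent_sample_permutation(small_dataset):
    beta, pheno, _, _ = small_dataset
    status = status_from_condition(pheno)
    ref = run_ewas(beta, pheno, status).table
    perm = np.random.default_rng(0).permutation(beta.columns)
    out = run_ewas(beta[perm], pheno.loc[perm], status.loc[perm]).table
    pd.testing.assert_frame_equal(ref, out)


def test_null_scan_is_calibrated():
    config = eh.SimulationConfig(
        n_samples=200, n_probes=5000, n_direct_probes=0, n_confounded_probes=0,
        n_batch_probes=0, seed=42,
    )
    beta, pheno, _, _ = eh.generate_dataset(config)
    res = run_ewas(beta, pheno, status_from_condition(pheno))
    frac = float((res.table["p"] < 0.05).mean())
    half_width = 2.576 * np.sqrt(0.05 * 0.95 / 5000)
    assert abs(frac - 0.05) < half_width
    assert 0.9 < res.lambda_ < 1.1


def test_planted_direct_probe_ranks_at_top():
    top10 = 0
    for seed in range(10):
        config = eh.SimulationConfig(
            n_samples=500, n_probes=1000, n_direct_probes=1, n_confounded_probes=0,
            n_batch_probes=0, direct_effect=0.05, noise_sd=0.02, seed=seed,
        )
        beta, pheno, _, truth = eh.generate_dataset(config)
        res = run_ewas(beta, pheno, status_from_condition(pheno))
        planted = truth.probes_with_role("direct")[0]
        top10 += planted in list(res.table.index[:10])
    assert top10 >= 9


def test_confounded_probes_surface_as_hits():
    """The leveraged-confounding behaviour: probes moved only by a shared
    upstream exposure still reach the suggestive threshold."""
    surfaced = 0
    for seed in range(10):
        config = eh.SimulationConfig(
            n_samples=500, n_probes=1000, n_direct_probes=0, n_confounded_probes=10,
            n_batch_probes=0, confounder_effect_meth=0.05,
            confounder_effect_logodds=1.0, noise_sd=0.02, seed=seed,
        )
        beta, pheno, _, truth = eh.generate_dataset(config)
        res = run_ewas(beta, pheno, status_from_condition(pheno))
        hits = set(res.select_hits())
        surfaced += bool(hits & set(truth.probes_with_role("confounded")))
    assert surfaced >= 8


def test_scan_requires_ten_usable_samples():
    config = eh.SimulationConfig(n_samples=8, n_probes=20, n_direct_probes=1,
                                 n_confounded_probes=1, n_batch_probes=1, seed=0)
    beta, pheno, _, _ = eh.generate_dataset(config)
    with pytest.raises(ValueError, match="usable"):
        EWASScan.from_phenotypes(beta, pheno, status_from_condition(pheno))
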