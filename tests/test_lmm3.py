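"""Estimation-core tests: design matrix, moments, Gibbs, oracle, deviance, DIC."""

import numpy as np
import pandas as pd
import pytest

from nestedvar.lmm3 import (MCMCSettings, ModelSpec, NestedLinearMixedModel,
                            VarianceComponents, design_matrix, deviance, dic,
                            fit_gibbs, fit_mom, oracle_direct)
from nestedvar.synthgen import default_config, empty_model_config, sample_cohort

from conftest import balanced_cohort


# ---------------------------------------------------------------------------
# design matrix

def test_design_matrix_empty_model_is_intercept_only(small_cohort):
    X, names = design_matrix(small_cohort, ModelSpec.model(1))
    assert names == ["intercept"]
    assert np.all(X == 1.0)


def test_design_matrix_stature_block(small_cohort):
    X, names = design_matrix(small_cohort, ModelSpec.model(2))
    assert names[0] == "intercept"
    assert set(names[1:]) == {"stature_cat[<150]", "stature_cat[150-159]",
                              "stature_cat[170-179]", "stature_cat[>179]",
                              "stature_cat[missing]"}
    # reference category rows have all-zero dummies
    ref_rows = small_cohort["stature_cat"] == "160-169"
    assert np.all(X[ref_rows.to_numpy(), 1:] == 0.0)


def test_design_matrix_centers_gestational_age(small_cohort):
    X, names = design_matrix(small_cohort, ModelSpec.model(4))
    ga = X[:, names.index("gestational_age")]
    assert abs(ga.mean()) < 1e-9


def test_design_matrix_unknown_category_errors(small_cohort):
    bad = small_cohort.head(10).copy()
    bad.loc[bad.index[3], "smoking"] = "pipe"
    with pytest.raises(ValueError, match="smoking"):
        design_matrix(bad, ModelSpec.model(4))


def test_model_spec_requires_intercept():
    with pytest.raises(ValueError, match="intercept"):
        ModelSpec(fixed_terms=("sex",))


# ---------------------------------------------------------------------------
# method of moments

def _nested_anova_oracle(df):
    """Classical balanced nested ANOVA estimators by explicit mean squares."""
    y = df["birthweight"].to_numpy()
    groups = df.groupby("country_id")["birthweight"]
    mothers = df.groupby("mother_id")["birthweight"]
    K = df["country_id"].nunique()
    J = df["mother_id"].nunique()
    n = len(df)
    m_per_c = J // K
    b_per_m = n // J
    grand = y.mean()
    ms_a = b_per_m * m_per_c * ((groups.mean() - grand) ** 2).sum() / (K - 1)
    mother_mean = mothers.mean()
    country_of_mother = df.drop_duplicates("mother_id").set_index("mother_id")["country_id"]
    ms_b = b_per_m * ((mother_mean - groups.mean()[country_of_mother].set_axis(
        mother_mean.index)) ** 2).sum() / (J - K)
    ms_w = ((y - mother_mean[df["mother_id"]].to_numpy()) ** 2).sum() / (n - J)
    s2_b = ms_w
    s2_m = (ms_b - ms_w) / b_per_m
    s2_c = (ms_a - ms_b) / (b_per_m * m_per_c)
    return s2_c, s2_m, s2_b


def test_mom_matches_classical_nested_anova_on_balanced_toy():
    df = balanced_cohort(4, 3, 2, (400.0, 900.0, 1600.0), seed=7)
    result = fit_mom(df, ModelSpec.model(1))
    expected = _nested_anova_oracle(df)
    got = result.variances.as_tuple()
    np.testing.assert_allclose(got, expected, rtol=1e-8)


def test_mom_intercept_equals_grand_mean_when_balanced():
    df = balanced_cohort(6, 3, 2, (400.0, 900.0, 1600.0), seed=8)
    result = fit_mom(df, ModelSpec.model(1))
    assert result.fixed["estimate"].iloc[0] == pytest.approx(
        df["birthweight"].mean(), abs=1e-8)


def test_mom_floors_null_component():
    cfg = empty_model_config().replace(
        n_countries=200, n_mothers=8000,
        true_variances=(0.0, 111583.0, 119871.0))
    df = sample_cohort(cfg, seed=21)
    result = fit_mom(df, ModelSpec.model(1))
    s2_c = result.variances.sigma2_mcb
    total = result.variances.total()
    assert 0.0 < s2_c < 0.01 * total


def test_mom_order_invariance(small_empty_cohort):
    spec = ModelSpec.model(1)
    a = fit_mom(small_empty_cohort, spec)
    shuffled = small_empty_cohort.sample(frac=1.0, random_state=5)
    b = fit_mom(shuffled, spec)
    np.testing.assert_allclose(a.variances.as_tuple(), b.variances.as_tuple(),
                               rtol=1e-8)
    np.testing.assert_allclose(a.fixed["estimate"], b.fixed["estimate"], rtol=1e-8)


def test_mom_rejects_single_country():
    df = balanced_cohort(1, 5, 2, (0.0, 900.0, 1600.0), seed=1)
    with pytest.raises(ValueError):
        fit_mom(df, ModelSpec.model(1))


# ---------------------------------------------------------------------------
# Gibbs sampler

def test_gibbs_identical_seed_identical_chains():
    df = balanced_cohort(10, 3, 2, (400.0, 900.0, 1600.0), seed=2)
    settings = MCMCSettings(burn_in=50, n_iter=200, seed=33)
    a = fit_gibbs(df, ModelSpec.model(1), settings, compute_dic=False)
    b = fit_gibbs(df, ModelSpec.model(1), settings, compute_dic=False)
    np.testing.assert_array_equal(a.chains["sigma2"], b.chains["sigma2"])
    np.testing.assert_array_equal(a.chains["beta"], b.chains["beta"])


def test_gibbs_variance_draws_strictly_positive():
    df = balanced_cohort(8, 3, 2, (400.0, 900.0, 1600.0), seed=3)
    fit = fit_gibbs(df, ModelSpec.model(1),
                    MCMCSettings(burn_in=100, n_iter=500, seed=4),
                    compute_dic=False)
    assert np.all(fit.chains["sigma2"] > 0)
    assert all(v > 0 for v in fit.variances.as_tuple())
    assert fit.variances.se_mcb > 0


def test_gibbs_close_to_dense_ml_oracle():
    spec = ModelSpec.model(1)
    for seed in range(3):
        df = balanced_cohort(25, 4, 2, (4000.0, 1500.0, 800.0), seed=seed)
        g = fit_gibbs(df, spec, MCMCSettings(burn_in=500, n_iter=2500, seed=seed + 100),
                      compute_dic=False)
        o = oracle_direct(df, spec)
        rel = np.abs(np.array(g.variances.as_tuple()) -
                     np.array(o.variances.as_tuple())) / np.array(o.variances.as_tuple())
        assert rel.max() < 0.25, (seed, rel)


def test_gibbs_short_chain_warns_in_metadata():
    df = balanced_cohort(5, 2, 2, (400.0, 900.0, 1600.0), seed=5)
    fit = fit_gibbs(df, ModelSpec.model(1),
                    MCMCSettings(burn_in=10, n_iter=50, seed=6), compute_dic=False)
    assert "warnings" in fit.meta


def test_estimator_sklearn_interface(small_empty_cohort):
    from sklearn.base import clone
    est = NestedLinearMixedModel(burn_in=50, n_iter=200, seed=1, compute_dic=False)
    cloned = clone(est)
    assert cloned.get_params()["n_iter"] == 200
    est.set_params(n_iter=300).fit(small_empty_cohort)
    assert est.variances_.sigma2_mcb > 0
    assert set(est.fixed_effects_.columns) == {"term", "estimate", "se"}
    pred = est.predict(small_empty_cohort.head(20))
    assert pred.shape == (20,)
    assert np.isfinite(pred).all()


# ---------------------------------------------------------------------------
# dense oracle

def test_oracle_two_level_matches_balanced_closed_form():
    # one mother per country, mother level excluded: balanced one-way model.
    # With balanced groups the likelihood separates into within-group
    # contrasts (residual variance) and group means (total mean variance).
    df = balanced_cohort(8, 1, 4, (5000.0, 0.0, 1600.0), seed=9)
    spec = ModelSpec(fixed_terms=("intercept",), random_levels=("country",))
    fit = oracle_direct(df, spec)
    y = df["birthweight"].to_numpy()
    K, m = 8, 4
    means = df.groupby("country_id")["birthweight"].mean().to_numpy()
    ssw = float(((y - np.repeat(means, m)) ** 2).sum())
    s2_e = ssw / (K * m - K)
    tau2 = float(((means - means.mean()) ** 2).sum()) / K
    s2_c = tau2 - s2_e / m
    assert s2_c > 0, "toy must have an interior optimum"
    assert fit.variances.sigma2_b == pytest.approx(s2_e, rel=1e-4)
    assert fit.variances.sigma2_mcb == pytest.approx(s2_c, rel=1e-3)
    assert fit.fixed["estimate"].iloc[0] == pytest.approx(means.mean(), rel=1e-6)


def test_oracle_degenerates_to_ols_without_random_levels():
    df = balanced_cohort(4, 2, 2, (0.0, 0.0, 1600.0), seed=10)
    spec = ModelSpec(fixed_terms=("intercept",), random_levels=())
    fit = oracle_direct(df, spec)
    y = df["birthweight"].to_numpy()
    assert fit.fixed["estimate"].iloc[0] == pytest.approx(y.mean(), abs=1e-6)
    assert fit.variances.sigma2_b == pytest.approx(y.var(), rel=1e-4)


def test_oracle_likelihood_not_worse_than_mom():
    df = balanced_cohort(8, 3, 2, (400.0, 900.0, 1600.0), seed=11)
    spec = ModelSpec.model(1)
    mom = fit_mom(df, spec)
    oracle = oracle_direct(df, spec)
    dev_mom = deviance(df, spec, mom.fixed, mom.variances)
    assert oracle.meta["neg2ll"] <= dev_mom + 1e-6


def test_oracle_rejects_large_problems(small_cohort):
    with pytest.raises(ValueError, match="rows"):
        oracle_direct(small_cohort, ModelSpec.model(1))


def test_oracle_agrees_with_statsmodels_two_level():
    # independent cross-check of the marginal likelihood machinery
    import statsmodels.formula.api as smf
    df = balanced_cohort(12, 1, 6, (2000.0, 0.0, 1500.0), seed=12)
    spec = ModelSpec(fixed_terms=("intercept",), random_levels=("country",))
    ours = oracle_direct(df, spec)
    sm_fit = smf.mixedlm("birthweight ~ 1", df, groups=df["country_id"]).fit(reml=False)
    assert ours.variances.sigma2_mcb == pytest.approx(
        float(sm_fit.cov_re.iloc[0, 0]), rel=0.02)
    assert ours.variances.sigma2_b == pytest.approx(float(sm_fit.scale), rel=0.02)
    assert ours.fixed["estimate"].iloc[0] == pytest.approx(
        float(sm_fit.params.iloc[0]), rel=1e-4)


# ---------------------------------------------------------------------------
# deviance and DIC

def test_deviance_scalar_closed_form():
    df = pd.DataFrame({"baby_id": ["B0"], "country_id": ["C0"],
                       "mother_id": ["M0"], "birthweight": [3500.0]})
    spec = ModelSpec(fixed_terms=("intercept",), random_levels=())
    mu, s2 = 3400.0, 1600.0
    got = deviance(df, spec, [mu], VarianceComponents(None, None, s2))
    expected = np.log(2 * np.pi * s2) + (3500.0 - mu) ** 2 / s2
    assert got == pytest.approx(expected, rel=1e-12)


def test_deviance_matches_dense_density_oracle():
    from scipy import stats
    df = balanced_cohort(4, 5, 2, (400.0, 900.0, 1600.0), seed=13)
    spec = ModelSpec.model(1)
    beta = [3480.0]
    vc = VarianceComponents(350.0, 1000.0, 1500.0)
    got = deviance(df, spec, beta, vc)
    c = pd.factorize(df["country_id"])[0]
    m = pd.factorize(df["mother_id"])[0]
    V = (350.0 * (c[:, None] == c[None, :])
         + 1000.0 * (m[:, None] == m[None, :])
         + 1500.0 * np.eye(len(df)))
    dense = -2.0 * stats.multivariate_normal.logpdf(
        df["birthweight"], mean=np.full(len(df), beta[0]), cov=V)
    assert got == pytest.approx(dense, rel=1e-10)


def test_deviance_continuous_at_null_country_component():
    df = balanced_cohort(4, 3, 2, (400.0, 900.0, 1600.0), seed=14)
    spec = ModelSpec.model(1)
    base = deviance(df, spec, [3500.0], VarianceComponents(0.0, 900.0, 1600.0))
    near = deviance(df, spec, [3500.0], VarianceComponents(1e-10, 900.0, 1600.0))
    assert abs(near - base) < 1e-6


def test_dic_degenerate_chain_has_zero_pd():
    df = balanced_cohort(4, 3, 2, (400.0, 900.0, 1600.0), seed=15)
    spec = ModelSpec.model(1)
    draw = {"beta": np.full((60, 1), 3500.0),
            "sigma2": np.tile([300.0, 800.0, 1500.0], (60, 1))}
    dbar, p_d, dic_val = dic(draw, df, spec)
    single = deviance(df, spec, [3500.0], VarianceComponents(300.0, 800.0, 1500.0))
    assert p_d == pytest.approx(0.0, abs=1e-8)
    assert dic_val == pytest.approx(single, rel=1e-12)


def test_dic_matches_loop_oracle():
    from scipy import stats
    df = balanced_cohort(4, 5, 2, (400.0, 900.0, 1600.0), seed=16)
    spec = ModelSpec.model(1)
    rng = np.random.default_rng(17)
    chains = {"beta": 3500.0 + rng.normal(0, 10, (100, 1)),
              "sigma2": np.abs(rng.normal([400, 900, 1600], 50, (100, 3)))}
    dbar, p_d, dic_val = dic(chains, df, spec)
    c = pd.factorize(df["country_id"])[0]
    m = pd.factorize(df["mother_id"])[0]
    y = df["birthweight"].to_numpy()
    devs = []
    for b, s2 in zip(chains["beta"], chains["sigma2"]):
        V = (s2[0] * (c[:, None] == c[None, :])
             + s2[1] * (m[:, None] == m[None, :]) + s2[2] * np.eye(len(df)))
        devs.append(-2.0 * stats.multivariate_normal.logpdf(
            y, mean=np.full(len(df), b[0]), cov=V))
    assert dbar == pytest.approx(np.mean(devs), rel=1e-10)


def test_dic_requires_enough_draws():
    df = balanced_cohort(4, 3, 2, (400.0, 900.0, 1600.0), seed=18)
    chains = {"beta": np.full((10, 1), 3500.0),
              "sigma2": np.tile([300.0, 800.0, 1500.0], (10, 1))}
    with pytest.raises(ValueError, match="50"):
        dic(chains, df, ModelSpec.model(1))


def test_dic_prefers_generating_model():
    # data carry a strong sex effect; the model including it should win DIC
    hits = 0
    settings = lambda s: MCMCSettings(burn_in=200, n_iter=600, seed=s)
    for seed in range(10):
        cfg = default_config().replace(
            n_countries=10, n_mothers=1400,
            true_fixed_effects={"intercept": 3500.0, "sex[female]": -300.0},
            true_variances=(2000.0, 20000.0, 40000.0))
        df = sample_cohort(cfg, seed=seed)
        small = ModelSpec(fixed_terms=("intercept",))
        large = ModelSpec(fixed_terms=("intercept", "sex"))
        dic_small = fit_gibbs(df, small, settings(seed + 1)).dic
        dic_large = fit_gibbs(df, large, settings(seed + 1)).dic
        hits += dic_large < dic_small
    assert hits >= 9


# ---------------------------------------------------------------------------
# parameter recovery at reduced study structure

def test_variance_recovery_across_replicates():
    # mean of replicate estimates within 3 Monte-Carlo SEs of the truth
    truth = np.array([7699.0, 111583.0, 119871.0])
    estimates = []
    for seed in range(10):
        cfg = empty_model_config().replace(n_countries=50, n_mothers=8000)
        df = sample_cohort(cfg, seed=seed)
        fit = fit_gibbs(df, ModelSpec.model(1),
                        MCMCSettings(burn_in=300, n_iter=1200, seed=seed + 500),
                        compute_dic=False)
        estimates.append(fit.variances.as_tuple())
    estimates = np.array(estimates)
    se = estimates.std(axis=0, ddof=1) / np.sqrt(len(estimates))
    assert np.all(np.abs(estimates.mean(axis=0) - truth) <= 3.0 * se)


def test_fixed_effect_recovery_of_injected_coefficients():
    # fully adjusted model recovers the injected coefficients
    targets = {"sex[female]": -123.0, "gestational_age": 149.0,
               "smoking[>9/day]": -179.0, "diabetes[yes]": 314.0}
    rows = []
    for seed in range(8):
        cfg = default_config().replace(n_countries=15, n_mothers=2500)
        df = sample_cohort(cfg, seed=seed + 30)
        fit = fit_gibbs(df, ModelSpec.model(5),
                        MCMCSettings(burn_in=200, n_iter=700, seed=seed + 40),
                        compute_dic=False)
        est = dict(zip(fit.fixed["term"], fit.fixed["estimate"]))
        rows.append([est[t] for t in targets])
    rows = np.array(rows)
    se = rows.std(axis=0, ddof=1) / np.sqrt(len(rows))
    truth = np.array(list(targets.values()))
    assert np.all(np.abs(rows.mean(axis=0) - truth) <= 3.0 * se)
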