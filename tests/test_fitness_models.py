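import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.special import expit, gammaln

import statsmodels.api as sm

from perchmon.fitness_models import (
    GlmmFit,
    SurvivalTableError,
    _design_matrix,
    _group_laplace_terms,
    _irls_start,
    age_from_length,
    build_survival_table,
    fit_gompertz,
    fit_survival_glmm,
    growth_residual_lmm,
    laplace_loglik,
    pair_fingerlings,
    pseudo_r2,
    select_model,
)


# ---------------------------------------------------------------------------
# fingerling apportionment
# ---------------------------------------------------------------------------
def test_pair_fingerlings_hand_arithmetic():
    np.testing.assert_array_equal(pair_fingerlings([500], 1000), [1000])
    np.testing.assert_array_equal(pair_fingerlings([100, 300], 1000), [250, 750])
    with pytest.raises(ValueError):
        pair_fingerlings([0, 0], 100)


def test_pair_fingerlings_conserves_season_totals():
    """Season totals 3909...15000 (94,029 fish) survive apportionment exactly."""
    totals = [3909, 6320, 40500, 13600, 6400, 8300, 15000]
    rng = np.random.default_rng(1)
    grand = 0
    for total in totals:
        larvae = rng.integers(100, 8000, size=rng.integers(3, 19))
        shares = pair_fingerlings(larvae, total)
        assert shares.sum() == total
        grand += shares.sum()
    assert grand == 94_029


# ---------------------------------------------------------------------------
# survival table
# ---------------------------------------------------------------------------
def _pairs(**kw):
    base = dict(pair_id=["P1"], cross_type=["DxD"], birth_year=[2012],
                stock_year=[2013], fingerlings=[1000])
    base.update(kw)
    return pd.DataFrame(base)


def test_carry_back_single_capture():
    ages = pd.DataFrame(dict(individual_id=["o1"], pair_id=["P1"], age_class=[2]))
    tab = build_survival_table(ages, _pairs(), final_year=2018)
    got = tab.set_index("age_class").survivors
    assert got.loc[0] == got.loc[1] == got.loc[2] == 1
    assert got.loc[3] == got.loc[4] == got.loc[5] == 0


def test_carry_back_two_offspring_hand_count():
    ages = pd.DataFrame(
        dict(individual_id=["o1", "o2"], pair_id=["P1", "P1"], age_class=[1, 3])
    )
    tab = build_survival_table(ages, _pairs(), final_year=2018)
    got = tab.set_index("age_class").survivors
    assert list(got.loc[[0, 1, 2, 3]]) == [2, 2, 1, 1]


def test_age_classes_capped_by_cohort_age():
    tab = build_survival_table(
        pd.DataFrame(columns=["individual_id", "pair_id", "age_class"]),
        _pairs(birth_year=[2016]), final_year=2018,
    )
    assert tab.age_class.max() == 1  # cohort is only age 1 by final year


def test_impossible_offspring_age_raises():
    ages = pd.DataFrame(dict(individual_id=["o1"], pair_id=["P1"], age_class=[4]))
    with pytest.raises(SurvivalTableError):
        build_survival_table(ages, _pairs(birth_year=[2016]), final_year=2018)


def test_recaptured_offspring_counted_once_per_age():
    ages = pd.DataFrame(
        dict(individual_id=["o1", "o1"], pair_id=["P1", "P1"], age_class=[1, 3])
    )
    tab = build_survival_table(ages, _pairs(), final_year=2018)
    got = tab.set_index("age_class").survivors
    assert list(got.loc[[0, 1, 2, 3]]) == [1, 1, 1, 1]


# ---------------------------------------------------------------------------
# binomial GLMM
# ---------------------------------------------------------------------------
def _sim_table(rng, offsets=(0.0, 1.6, 2.28), intercept=-8.0, age_slope=-0.2,
               year_sd=0.3, n_years=6, pairs_per_year=9, nf_range=(500, 3000)):
    rows = []
    for y in range(2013, 2013 + n_years):
        u = rng.normal(0, year_sd)
        for i in range(pairs_per_year):
            ct = ("DxD", "DxY", "YxY")[i % 3]
            off = dict(zip(("DxD", "DxY", "YxY"), offsets))[ct]
            nf = int(rng.integers(*nf_range))
            d = {"DxD": 0.054, "DxY": 0.068, "YxY": 0.072}[ct] + rng.normal(0, 0.004)
            for a in range(0, min(2018 - y, 5) + 1):
                eta = intercept + off + age_slope * a + u
                rows.append(
                    dict(pair_id=f"P{y}_{i}", cross_type=ct, stock_year=y,
                         dissimilarity=d, age_class=a,
                         survivors=rng.binomial(nf, expit(eta)), fingerlings=nf)
                )
    return pd.DataFrame(rows)


def test_zero_variance_limit_equals_weighted_glm():
    """With the random effect pinned near zero the fit is plain weighted IRLS."""
    rng = np.random.default_rng(2)
    tab = _sim_table(rng, year_sd=0.0)
    fit = fit_survival_glmm(tab, use_diss=False, standardize=False)
    X, _ = _design_matrix(tab, True, False, False, standardize=False)
    glm = sm.GLM(
        np.column_stack([tab.survivors, tab.fingerlings - tab.survivors]),
        X, family=sm.families.Binomial(),
    ).fit()
    if fit.sigma2_group < 1e-4:
        np.testing.assert_allclose(fit.params, glm.params, atol=2e-3)


def _agh_loglik(beta, log_sigma, X, k, n, gidx, ngroups, nodes=41):
    """Adaptive Gauss-Hermite oracle: expand each group integral at its mode."""
    x, w = np.polynomial.hermite.hermgauss(nodes)
    sigma2 = np.exp(2 * log_sigma)
    eta0 = X @ beta
    _, uhat = _group_laplace_terms(eta0, k, n, gidx, ngroups, sigma2)
    ll = 0.0
    for j in range(ngroups):
        m = gidx == j

        def h(uu):
            mu = np.clip(expit(eta0[m] + uu), 1e-14, 1 - 1e-14)
            return (
                np.sum(k[m] * np.log(mu) + (n[m] - k[m]) * np.log(1 - mu))
                - uu**2 / (2 * sigma2) - 0.5 * np.log(2 * np.pi * sigma2)
            )

        mu = np.clip(expit(eta0[m] + uhat[j]), 1e-14, 1 - 1e-14)
        H = np.sum(n[m] * mu * (1 - mu)) + 1 / sigma2
        s = 1 / np.sqrt(H)
        vals = np.array(
            [x[t] ** 2 + h(uhat[j] + np.sqrt(2) * s * x[t]) for t in range(nodes)]
        )
        mx = vals.max()
        ll += np.log(np.sqrt(2) * s) + mx + np.log(np.sum(w * np.exp(vals - mx)))
    return ll + np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def test_laplace_matches_adaptive_gauss_hermite_oracle():
    """Coefficients from the Laplace fit match a 41-node AGQ fit on 3 groups."""
    rng = np.random.default_rng(3)
    tab = _sim_table(rng, intercept=-4.0, n_years=3, pairs_per_year=6,
                     nf_range=(400, 600), year_sd=0.5)
    fit = fit_survival_glmm(tab, use_diss=False, standardize=False)
    X, _ = _design_matrix(tab, True, False, False, standardize=False)
    k = tab.survivors.to_numpy(float)
    n = tab.fingerlings.to_numpy(float)
    _, gidx = np.unique(tab.stock_year.to_numpy(), return_inverse=True)
    ng = gidx.max() + 1

    def neg_agh(theta):
        return -_agh_loglik(theta[:-1], theta[-1], X, k, n, gidx, ng)

    x0 = np.concatenate([fit.params, [0.5 * np.log(max(fit.sigma2_group, 1e-8))]])
    res = optimize.minimize(neg_agh, x0, method="Nelder-Mead",
                            options=dict(xatol=1e-10, fatol=1e-12,
                                         maxiter=20000, maxfev=20000))
    assert np.max(np.abs(res.x[:-1] - fit.params)) < 1e-3
    # and the two log-likelihood surfaces agree at the optimum
    lap = laplace_loglik(fit.params, x0[-1], X, k, n, gidx, ng)
    assert abs(lap - (-res.fun)) < 1e-3 * abs(res.fun)


def test_pseudo_r2_closed_forms():
    X = np.column_stack([np.ones(4), np.array([-1.0, 1.0, -1.0, 1.0])])
    coef = pd.DataFrame(dict(term=["Intercept", "x"], estimate=[0.0, 0.0],
                             se=np.nan, z=np.nan, p=np.nan))
    fit = GlmmFit("f", ["Intercept", "x"], coef, sigma2_group=0.7, loglik=0.0,
                  aic=0.0, r2_marginal=np.nan, converged=True, n_obs=4,
                  n_params=3, X=X)
    assert pseudo_r2(fit) == 0.0
    scale = np.pi / np.sqrt(3)  # makes var(X beta) = pi^2/3 exactly
    coef2 = coef.assign(estimate=[0.0, scale])
    fit2 = GlmmFit("f", fit.terms, coef2, sigma2_group=0.0, loglik=0.0,
                   aic=0.0, r2_marginal=np.nan, converged=True, n_obs=4,
                   n_params=3, X=X)
    assert pseudo_r2(fit2) == pytest.approx(0.5)


def test_pseudo_r2_by_hand_on_a_fit():
    rng = np.random.default_rng(4)
    tab = _sim_table(rng)
    fit = fit_survival_glmm(tab)
    var_fixed = np.var(fit.X @ fit.params)
    by_hand = var_fixed / (var_fixed + fit.sigma2_group + np.pi**2 / 3)
    assert fit.r2_marginal == pytest.approx(by_hand)
    assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)


def test_model_selection_prefers_the_generating_structure():
    """Cross-type-only data ranks the cross-type model over dissimilarity-only."""
    rng = np.random.default_rng(5)
    wins = 0
    n_rep = 20
    for _ in range(n_rep):
        tab = _sim_table(rng, nf_range=(1000, 3000))
        ranking, best, fits, failed = select_model(tab)
        cross = ranking[ranking.formula.str.contains("cross")
                        & ~ranking.formula.str.contains("dissimilarity")]
        diss_only = ranking[ranking.formula.str.contains("dissimilarity")
                            & ~ranking.formula.str.contains("cross")]
        if cross.aic.min() < diss_only.aic.min():
            wins += 1
    assert wins / n_rep >= 0.9


def test_duplicate_candidates_identical_aic():
    rng = np.random.default_rng(6)
    tab = _sim_table(rng)
    f1 = fit_survival_glmm(tab, use_cross=True, use_diss=False)
    f2 = fit_survival_glmm(tab, use_cross=True, use_diss=False)
    assert f1.aic == pytest.approx(f2.aic, abs=1e-6)


def test_glmm_requires_two_stocking_years():
    rng = np.random.default_rng(7)
    tab = _sim_table(rng, n_years=1)
    with pytest.raises(ValueError):
        fit_survival_glmm(tab)


# ---------------------------------------------------------------------------
# Gompertz
# ---------------------------------------------------------------------------
def test_noiseless_parameter_recovery_to_1e4():
    ages = np.array([0.3, 0.8, 1.3, 1.9, 2.4, 3.1, 3.9, 4.6])
    lengths = 350.0 * np.exp(-np.exp(-0.8 * (ages - 1.2)))
    fit = fit_gompertz(lengths, ages)
    assert fit.linf == pytest.approx(350.0, abs=1e-4)
    assert fit.k == pytest.approx(0.8, abs=1e-4)
    assert fit.t0 == pytest.approx(1.2, abs=1e-4)


def test_length_at_inflection_is_linf_over_e():
    ages = np.linspace(0.5, 5, 10)
    lengths = 300.0 * np.exp(-np.exp(-0.6 * (ages - 1.0)))
    fit = fit_gompertz(lengths, ages)
    assert fit.predict(fit.t0) == pytest.approx(fit.linf / np.e)


def test_residuals_sum_near_zero_under_least_squares():
    rng = np.random.default_rng(8)
    ages = np.tile(np.arange(1, 6, dtype=float), 20)
    lengths = 320 * np.exp(-np.exp(-0.7 * (ages - 1.1))) + rng.normal(0, 8, len(ages))
    fit = fit_gompertz(lengths, ages)
    assert abs(fit.residuals.mean()) < 0.5


def test_gompertz_identifiability_guards():
    with pytest.raises(ValueError):
        fit_gompertz([100, 120, 130], [1, 2, 3])
    with pytest.raises(ValueError):
        fit_gompertz([100, 120, 130, 140], [2, 2, 2, 2])


def test_age_from_length_inverse_identity():
    ages = np.linspace(0.4, 4.5, 9)
    lengths = 340.0 * np.exp(-np.exp(-0.75 * (ages - 1.15)))
    fit = fit_gompertz(lengths, ages)
    for t in (0.7, 1.5, 2.5, 4.0):
        assert age_from_length(float(fit.predict(t)), fit) == pytest.approx(
            t, abs=1e-6
        )
    assert age_from_length(fit.linf / np.e, fit) == pytest.approx(fit.t0, abs=1e-6)
    with pytest.raises(ValueError):
        age_from_length(fit.linf + 1, fit)


# ---------------------------------------------------------------------------
# growth-residual mixed models
# ---------------------------------------------------------------------------
def test_zero_variance_response_gives_zero_coefficients():
    df = pd.DataFrame(
        dict(residual=np.zeros(30),
             cross_type=np.tile(("DxD", "DxY", "YxY"), 10),
             pht=np.linspace(0.05, 0.1, 30),
             dissimilarity=np.linspace(0.05, 0.08, 30),
             stock_year=np.repeat([2014, 2015, 2016], 10))
    )
    ranking, coefs = growth_residual_lmm(df)
    for tab in coefs.values():
        assert np.allclose(tab.estimate, 0.0)


def test_reml_matches_closed_form_balanced_anova():
    """One-way random-effects REML equals the classic balanced MS estimators."""
    rng = np.random.default_rng(9)
    n_groups, per = 6, 25
    u = rng.normal(0, 3.0, n_groups)
    y = np.concatenate([10 + u[g] + rng.normal(0, 2.0, per)
                        for g in range(n_groups)])
    groups = np.repeat(np.arange(n_groups), per)
    res = sm.MixedLM(y, np.ones((len(y), 1)), groups).fit(reml=True)
    means = y.reshape(n_groups, per).mean(axis=1)
    msb = per * np.var(means, ddof=1)
    msw = np.mean([np.var(y.reshape(n_groups, per)[g], ddof=1)
                   for g in range(n_groups)])
    sigma_b2 = (msb - msw) / per
    assert float(res.fe_params[0]) == pytest.approx(means.mean(), abs=1e-6)
    assert float(np.asarray(res.cov_re)[0, 0]) == pytest.approx(sigma_b2, rel=1e-3)
    assert float(res.scale) == pytest.approx(msw, rel=1e-3)


def test_growth_advantage_recovered_by_model_selection():
    """A planted YxY growth advantage puts cross-type in the minimum-AIC model."""
    rng = np.random.default_rng(10)
    hits = 0
    n_rep = 10
    for _ in range(n_rep):
        n = 120
        ct = rng.choice(("DxD", "DxY", "YxY"), n)
        adv = np.where(ct == "YxY", 12.0, 0.0)
        df = pd.DataFrame(
            dict(residual=adv + rng.normal(0, 8, n),
                 cross_type=ct,
                 pht=rng.uniform(0.05, 0.11, n),
                 dissimilarity=rng.uniform(0.05, 0.08, n),
                 stock_year=rng.choice([2013, 2014, 2015, 2016], n))
        )
        ranking, coefs = growth_residual_lmm(df)
        best = ranking.iloc[0].formula
        if "cross_type" in best:
            tab = coefs[best].set_index("term")
            if tab.loc["cross[YxY]", "estimate"] > 0:
                hits += 1
    assert hits / n_rep >= 0.9
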