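"""Post-stocking survival and growth inference.

Survival: for each broodstock pair, a minimum-number-alive reconstruction
over six age classes (an offspring captured at age a is carried back as
alive at every earlier age), scaled by the pair's estimated fingerling
output.  Relative survival is modelled as a weighted binomial GLMM with
logit link — weights are the stocked fingerling counts — with stocking year
as a random intercept, fitted by Laplace-approximated maximum likelihood.
Candidate fixed-effect structures are compared by AIC and summarised with a
marginal pseudo-R2 on the latent scale.

Growth: a standard three-parameter Gompertz curve
``L(t) = Linf * exp(-exp(-k (t - t0)))`` fitted to length-at-age of fish of
known age; its residuals feed Gaussian mixed models (year random
intercept), and its inverse converts lengths to ages for fish of unknown
birth season.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln

AGE_CLASSES = (0, 1, 2, 3, 4, 5)
LOGIT_RESIDUAL_VARIANCE = np.pi**2 / 3.0


# ---------------------------------------------------------------------------
# fingerling attribution and table construction
# ---------------------------------------------------------------------------
def pair_fingerlings(larvae_counts, stocked_total: int) -> np.ndarray:
    """Apportion a season's stocked fingerlings to pairs by larvae share.

    ``N_f = larvae_pair / sum(larvae) * stocked_total`` with
    largest-remainder rounding, so the integer shares conserve the season
    total exactly.  A pair with zero larvae gets zero fingerlings; a season
    with zero total larvae but positive stocking is an error.
    """
    from .simdata import largest_remainder

    return largest_remainder(larvae_counts, stocked_total)


class SurvivalTableError(ValueError):
    pass


def build_survival_table(
    offspring_ages: pd.DataFrame,
    pairs: pd.DataFrame,
    dissimilarities: pd.DataFrame | None = None,
    final_year: int = 2018,
) -> pd.DataFrame:
    """Minimum-survivor counts per pair and age class.

    ``offspring_ages`` has one row per capture of a stocked offspring with
    columns ``individual_id``, ``pair_id``, ``age_class`` (recaptures of an
    individual may repeat; the carry-back rule uses its oldest capture).
    ``pairs`` needs ``pair_id``, ``cross_type``, ``birth_year``,
    ``stock_year``, ``fingerlings``.  Rows are emitted only for age classes
    observable for a cohort by ``final_year``, and k_a is non-increasing in
    age by construction.
    """
    per_ind = (
        offspring_ages.groupby(["pair_id", "individual_id"])["age_class"]
        .max()
        .reset_index()
        if len(offspring_ages)
        else pd.DataFrame(columns=["pair_id", "individual_id", "age_class"])
    )
    diss = None
    if dissimilarities is not None:
        diss = dict(zip(dissimilarities.pair_id, dissimilarities.dissimilarity))
    rows = []
    for pair in pairs.itertuples():
        max_obs = min(final_year - int(pair.birth_year) - 1, max(AGE_CLASSES))
        if max_obs < 0 or pair.fingerlings <= 0:
            continue
        ages = per_ind.loc[per_ind.pair_id == pair.pair_id, "age_class"]
        if len(ages) and ages.max() > max_obs:
            raise SurvivalTableError(
                f"pair {pair.pair_id}: offspring captured at age {ages.max()} "
                f"but cohort can only be {max_obs} by {final_year}"
            )
        for a in range(0, max_obs + 1):
            k = int((ages >= a).sum())
            rows.append(
                dict(
                    pair_id=pair.pair_id,
                    cross_type=pair.cross_type,
                    stock_year=int(pair.stock_year),
                    dissimilarity=(
                        np.nan if diss is None else diss.get(pair.pair_id, np.nan)
                    ),
                    age_class=a,
                    survivors=k,
                    fingerlings=int(pair.fingerlings),
                )
            )
    table = pd.DataFrame(rows)
    if len(table) and (table.survivors > table.fingerlings).any():
        raise SurvivalTableError("survivor count exceeds fingerlings stocked")
    return table


# ---------------------------------------------------------------------------
# binomial GLMM with one random intercept (Laplace)
# ---------------------------------------------------------------------------
@dataclass
class GlmmFit:
    """A fitted weighted binomial logit GLMM with a year random intercept."""

    formula: str
    terms: list
    coefficients: pd.DataFrame  # term, estimate, se, z, p
    sigma2_group: float
    loglik: float
    aic: float
    r2_marginal: float
    converged: bool
    n_obs: int
    n_params: int
    X: np.ndarray = field(repr=False, default=None)

    @property
    def params(self) -> np.ndarray:
        return self.coefficients["estimate"].to_numpy()


def _group_laplace_terms(eta_fixed, k, n, group_idx, n_groups, sigma2):
    """Per-group Laplace log-marginal contributions and the modes."""
    u = np.zeros(n_groups)
    for _ in range(100):
        eta = eta_fixed + u[group_idx]
        mu = expit(eta)
        score = np.bincount(group_idx, weights=k - n * mu, minlength=n_groups)
        score -= u / sigma2
        w = np.bincount(group_idx, weights=n * mu * (1 - mu), minlength=n_groups)
        hess = w + 1.0 / sigma2
        step = score / hess
        u += step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta_fixed + u[group_idx]
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    ll_data = k * np.log(mu) + (n - k) * np.log(1 - mu)
    ll_by_group = np.bincount(group_idx, weights=ll_data, minlength=n_groups)
    w = np.bincount(group_idx, weights=n * mu * (1 - mu), minlength=n_groups)
    ll = ll_by_group - u**2 / (2 * sigma2) - 0.5 * np.log1p(sigma2 * w)
    return ll, u


def laplace_loglik(beta, log_sigma, X, k, n, group_idx, n_groups) -> float:
    """Laplace-approximated marginal log-likelihood (with binomial constant)."""
    sigma2 = float(np.exp(2.0 * log_sigma))
    eta_fixed = X @ beta
    ll, _ = _group_laplace_terms(eta_fixed, k, n, group_idx, n_groups, sigma2)
    const = float(np.sum(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)))
    return float(ll.sum()) + const


def _design_matrix(
    table: pd.DataFrame,
    use_cross: bool,
    use_diss: bool,
    age_interactions: bool,
    standardize: bool = True,
):
    """Design for the survival GLMM; DxD is the cross-type reference level."""
    n = len(table)
    cols = [np.ones(n)]
    names = ["Intercept"]

    age = table["age_class"].to_numpy(dtype=float)
    if standardize and age.std() > 0:
        age = (age - age.mean()) / age.std()
    cols.append(age)
    names.append("age_class")

    diss = None
    if use_diss:
        diss = table["dissimilarity"].to_numpy(dtype=float)
        if np.isnan(diss).any():
            raise ValueError("dissimilarity missing for some table rows")
        if standardize and diss.std() > 0:
            diss = (diss - diss.mean()) / diss.std()
        cols.append(diss)
        names.append("dissimilarity")

    dummies = {}
    if use_cross:
        for level in ("DxY", "YxY"):
            d = (table["cross_type"] == level).to_numpy(dtype=float)
            if d.any():
                cols.append(d)
                names.append(f"cross[{level}]")
                dummies[level] = d

    if age_interactions:
        if use_diss:
            cols.append(age * diss)
            names.append("age:dissimilarity")
        for level, d in dummies.items():
            cols.append(age * d)
            names.append(f"age:cross[{level}]")
    return np.column_stack(cols), names


def fit_survival_glmm(
    table: pd.DataFrame,
    use_cross: bool = True,
    use_diss: bool = True,
    age_interactions: bool = False,
    standardize: bool = True,
) -> GlmmFit:
    """Fit the weighted binomial logit GLMM by Laplace maximum likelihood.

    ``survivors ~ Binomial(fingerlings, logit^-1(X beta + u_year))`` with
    ``u_year ~ N(0, sigma^2)`` on stocking year.  Continuous predictors
    (age class, dissimilarity) are z-scored before fitting by default.
    Needs >=2 stocking years.  Returns estimates, Wald SEs and p-values,
    AIC (ML) and the marginal latent-scale pseudo-R2.
    """
    if table["stock_year"].nunique() < 2:
        raise ValueError("random effect needs >=2 stocking years")
    X, names = _design_matrix(table, use_cross, use_diss, age_interactions,
                              standardize)
    k = table["survivors"].to_numpy(dtype=float)
    n = table["fingerlings"].to_numpy(dtype=float)
    years, group_idx = np.unique(table["stock_year"].to_numpy(), return_inverse=True)
    n_groups = len(years)

    beta0 = _irls_start(X, k, n)
    x0 = np.concatenate([beta0, [np.log(0.3)]])

    def negll(theta):
        return -laplace_loglik(theta[:-1], theta[-1], X, k, n, group_idx, n_groups)

    bounds = [(None, None)] * X.shape[1] + [(-8.0, 3.0)]
    res = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                            options=dict(maxiter=500, ftol=1e-12, gtol=1e-8))
    theta = res.x
    loglik = -float(res.fun)
    sigma2 = float(np.exp(2 * theta[-1]))
    beta = theta[:-1]

    H = _numeric_hessian(negll, theta)
    se = _wald_se(H, len(beta))
    z = np.where(se > 0, beta / se, np.nan)
    p = 2 * stats.norm.sf(np.abs(z))
    coef = pd.DataFrame(dict(term=names, estimate=beta, se=se, z=z, p=p))

    n_params = len(beta) + 1
    aic = 2 * n_params - 2 * loglik
    label = _formula_label(use_cross, use_diss, age_interactions)
    fit = GlmmFit(
        formula=label, terms=names, coefficients=coef, sigma2_group=sigma2,
        loglik=loglik, aic=aic, r2_marginal=np.nan, converged=bool(res.success),
        n_obs=len(table), n_params=n_params, X=X,
    )
    fit.r2_marginal = pseudo_r2(fit)
    return fit


def _formula_label(use_cross, use_diss, age_interactions):
    terms = ["age_class"]
    if use_diss:
        terms.append("dissimilarity")
    if use_cross:
        terms.append("cross_type")
    if age_interactions:
        terms.append("age interactions")
    return " + ".join(terms) + " + (1|stock_year)"


def _irls_start(X, k, n, n_iter: int = 25) -> np.ndarray:
    """Plain weighted logistic regression (no random effect) as a start."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log((k.sum() + 0.5) / (n.sum() - k.sum() + 0.5))
    for _ in range(n_iter):
        mu = np.clip(expit(X @ beta), 1e-10, 1 - 1e-10)
        w = n * mu * (1 - mu)
        z = X @ beta + (k - n * mu) / w
        WX = X * w[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta


def _numeric_hessian(f, x, rel_step: float = 1e-4) -> np.ndarray:
    p = len(x)
    h = rel_step * (1.0 + np.abs(x))
    H = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            H[i, j] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
            H[j, i] = H[i, j]
    return H


def _wald_se(H, n_beta) -> np.ndarray:
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:n_beta], 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        se = np.full(n_beta, np.nan)
    return se


def pseudo_r2(fit: GlmmFit) -> float:
    """Marginal latent-scale pseudo-R2 for the binomial logit GLMM.

    ``var(X beta) / (var(X beta) + sigma2_year + pi^2/3)`` — the fixed-effect
    share of latent variance, with the logit distribution-specific residual
    pi^2/3.
    """
    if fit.X is None:
        raise ValueError("fit lacks its design matrix")
    var_fixed = float(np.var(fit.X @ fit.params))
    return var_fixed / (var_fixed + fit.sigma2_group + LOGIT_RESIDUAL_VARIANCE)


def select_model(table: pd.DataFrame, standardize: bool = True):
    """Fit the candidate survival models and rank them by AIC.

    Candidates: {cross-type; dissimilarity; cross-type + dissimilarity},
    each with and without age interactions; every model keeps the age-class
    main effect and the stocking-year random intercept.  Non-convergent
    candidates are excluded from the ranking and reported.
    """
    candidates = [
        dict(use_cross=c, use_diss=d, age_interactions=i)
        for (c, d), i in itertools.product(
            [(True, False), (False, True), (True, True)], [False, True]
        )
    ]
    fits, failed = {}, []
    for cand in candidates:
        try:
            fit = fit_survival_glmm(table, standardize=standardize, **cand)
        except Exception as exc:  # pragma: no cover - defensive
            failed.append(dict(candidate=cand, error=str(exc)))
            continue
        if not fit.converged:
            failed.append(dict(candidate=cand, error="non-convergence"))
            continue
        fits[fit.formula] = fit
    ranking = pd.DataFrame(
        [dict(formula=f.formula, aic=f.aic, loglik=f.loglik,
              n_params=f.n_params, r2_marginal=f.r2_marginal)
         for f in fits.values()]
    ).sort_values("aic").reset_index(drop=True)
    ranking["delta_aic"] = ranking["aic"] - ranking["aic"].min()
    best = fits[ranking.iloc[0]["formula"]] if len(ranking) else None
    return ranking, best, fits, failed


# ---------------------------------------------------------------------------
# Gompertz growth
# ---------------------------------------------------------------------------
@dataclass
class GompertzFit:
    linf: float
    k: float
    t0: float
    residuals: np.ndarray
    fitted: np.ndarray
    sse: float

    def predict(self, age):
        return self.linf * np.exp(-np.exp(-self.k * (np.asarray(age) - self.t0)))


def fit_gompertz(lengths, ages) -> GompertzFit:
    """Least-squares Gompertz growth fit with multi-start initialisation.

    Starts: Linf = 1.05 x max length, k in {0.3, 0.8, 1.5}, t0 = median
    age; the best SSE solution wins.  Needs >=4 points spanning >=2
    distinct ages (a single age cannot identify a growth curve).
    """
    lengths = np.asarray(lengths, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if len(lengths) != len(ages):
        raise ValueError("lengths and ages differ in size")
    if len(lengths) < 4:
        raise ValueError("need at least 4 (age, length) observations")
    if len(np.unique(ages)) < 2:
        raise ValueError("growth curve not identifiable from a single age")

    def resid(theta):
        linf, k, t0 = theta
        return linf * np.exp(-np.exp(-k * (ages - t0))) - lengths

    best = None
    linf0 = 1.05 * lengths.max()
    for k0 in (0.3, 0.8, 1.5):
        sol = optimize.least_squares(
            resid, x0=[linf0, k0, float(np.median(ages))],
            bounds=([1e-6, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        sse = float(2 * sol.cost)
        if best is None or sse < best[0]:
            best = (sse, sol.x)
    sse, (linf, k, t0) = best
    fitted = linf * np.exp(-np.exp(-k * (ages - t0)))
    return GompertzFit(linf=float(linf), k=float(k), t0=float(t0),
                       residuals=lengths - fitted, fitted=fitted, sse=sse)


def age_from_length(length: float, fit: GompertzFit) -> float:
    """Invert the Gompertz curve: the age whose expected length is given.

    Undefined at or above the asymptote (and at non-positive lengths).
    """
    if not 0 < length < fit.linf:
        raise ValueError(
            f"length {length} outside invertible range (0, {fit.linf:.1f})"
        )
    return float(fit.t0 - np.log(-np.log(length / fit.linf)) / fit.k)


# ---------------------------------------------------------------------------
# growth-residual linear mixed models
# ---------------------------------------------------------------------------
def growth_residual_lmm(data: pd.DataFrame):
    """Rank Gaussian mixed models of growth residuals by AIC.

    ``data`` columns: ``residual``, ``cross_type``, ``pht``,
    ``dissimilarity``, ``stock_year``.  Candidates: {cross-type; PHt;
    dissimilarity; cross-type + PHt; cross-type + dissimilarity}, all with a
    stocking-year random intercept.  Coefficients come from REML fits;
    ranking AICs from ML refits, which are comparable across fixed-effect
    structures.
    """
    import statsmodels.api as sm

    candidates = {
        "cross_type": ["cross_type"],
        "pht": ["pht"],
        "dissimilarity": ["dissimilarity"],
        "cross_type+pht": ["cross_type", "pht"],
        "cross_type+dissimilarity": ["cross_type", "dissimilarity"],
    }
    if float(np.var(data["residual"])) == 0.0:
        # degenerate response: every slope is exactly zero
        rows, coefs = [], {}
        for name, terms in candidates.items():
            X, names = _lmm_design(data, terms)
            coefs[name] = pd.DataFrame(
                dict(term=names, estimate=np.zeros(len(names)),
                     se=np.nan, p=np.nan)
            )
            rows.append(dict(formula=name, aic=-np.inf, converged=True))
        return pd.DataFrame(rows), coefs

    import warnings

    rows, coefs = [], {}
    for name, terms in candidates.items():
        X, names = _lmm_design(data, terms)
        groups = data["stock_year"].to_numpy()
        try:
            with warnings.catch_warnings():
                # boundary (zero) year variance is a legitimate optimum here
                warnings.simplefilter("ignore")
                reml = sm.MixedLM(data["residual"].to_numpy(), X, groups).fit(
                    reml=True
                )
                ml = sm.MixedLM(data["residual"].to_numpy(), X, groups).fit(
                    reml=False
                )
        except Exception as exc:
            rows.append(dict(formula=name, aic=np.nan, converged=False,
                             error=str(exc)))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # SEs undefined at boundary fits
            coefs[name] = pd.DataFrame(
                dict(term=names, estimate=reml.fe_params,
                     se=reml.bse_fe, p=reml.pvalues[: len(names)])
            )
        rows.append(dict(formula=name, aic=float(ml.aic), converged=True))
    ranking = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    ranking["delta_aic"] = ranking["aic"] - ranking["aic"].min()
    return ranking, coefs


def _lmm_design(data: pd.DataFrame, terms):
    n = len(data)
    cols = [np.ones(n)]
    names = ["Intercept"]
    for t in terms:
        if t == "cross_type":
            for level in ("DxY", "YxY"):
                d = (data["cross_type"] == level).to_numpy(dtype=float)
                if d.any():
                    cols.append(d)
                    names.append(f"cross[{level}]")
        else:
            cols.append(data[t].to_numpy(dtype=float))
            names.append(t)
    return np.column_stack(cols), names
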