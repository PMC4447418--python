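"""Two- and three-level nested random-intercept Gaussian linear models.

The model for baby i of mother j born in country k is

    y_ijk = x_ijk' b + v_k + u_jk + e_ijk,
    v_k ~ N(0, s2_country),  u_jk ~ N(0, s2_mother),  e_ijk ~ N(0, s2_baby),

with mothers strictly nested in countries.  Estimation is a blocked Gibbs
sampler with closed-form full conditionals (flat prior on the fixed effects,
inverse-gamma priors on the variances), started from Henderson-type
method-of-moments values.  All per-iteration work is linear in the number of
babies: the nested covariance is never assembled.  A dense-covariance
maximum-likelihood oracle is provided for small problems.

The central entry point is :class:`NestedLinearMixedModel`, a scikit-learn
style estimator; :func:`fit_mom`, :func:`fit_gibbs` and
:func:`oracle_direct` are thin functional wrappers around it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from sklearn.base import BaseEstimator

from .synthgen import (
    AGE_CATS, FLAG_CATS, INCOME_CATS, MARITAL_CATS, SEX_CATS, SMOKING_CATS,
    STATURE_CATS, WB_CATS,
)

__all__ = [
    "ModelSpec", "MCMCSettings", "VarianceComponents", "FitResult",
    "NestedLinearMixedModel", "design_matrix", "fit_mom", "fit_gibbs",
    "oracle_direct", "deviance", "dic",
]

# term -> (cohort column, canonical category order, default reference)
TERM_INFO: dict[str, tuple[str, list[str], str]] = {
    "stature": ("stature_cat", STATURE_CATS, "160-169"),
    "age": ("age_cat", AGE_CATS, "25-34"),
    "sex": ("sex", SEX_CATS, "male"),
    "income": ("income_cat", INCOME_CATS, "highest"),
    "marital": ("marital", MARITAL_CATS, "married/cohabiting"),
    "smoking": ("smoking", SMOKING_CATS, "none"),
    "hypertension": ("hypertension", FLAG_CATS, "no"),
    "diabetes": ("diabetes", FLAG_CATS, "no"),
    "wb_class": ("wb_class", WB_CATS, "high"),
}

#: Cumulative fixed-effect blocks of the five-model sequence.
MODEL_TERMS: dict[int, tuple[str, ...]] = {
    1: ("intercept",),
    2: ("intercept", "stature"),
    3: ("intercept", "stature", "age"),
    4: ("intercept", "stature", "age", "sex", "gestational_age", "income",
        "marital", "smoking", "hypertension", "diabetes"),
    5: ("intercept", "stature", "age", "sex", "gestational_age", "income",
        "marital", "smoking", "hypertension", "diabetes", "wb_class"),
}

_VALID_TERMS = set(TERM_INFO) | {"intercept", "gestational_age"}


@dataclass(frozen=True)
class ModelSpec:
    """Which fixed-effect blocks and random levels a fit includes."""

    fixed_terms: tuple[str, ...] = ("intercept",)
    random_levels: tuple[str, ...] = ("country", "mother")
    reference_categories: Mapping[str, str] = field(default_factory=dict)
    center_gestational_age: bool = True
    outcome: str = "birthweight"

    def __post_init__(self):
        if "intercept" not in self.fixed_terms:
            raise ValueError("the intercept is always part of the model")
        bad = set(self.fixed_terms) - _VALID_TERMS
        if bad:
            raise ValueError(f"unknown fixed terms: {sorted(bad)}")
        bad = set(self.random_levels) - {"country", "mother"}
        if bad:
            raise ValueError(f"unknown random levels: {sorted(bad)}")

    def reference(self, term: str) -> str:
        return self.reference_categories.get(term, TERM_INFO[term][2])

    @classmethod
    def model(cls, number: int, random_levels=("country", "mother"), **kwargs) -> "ModelSpec":
        """Preset spec for the consecutive model sequence (1..5)."""
        return cls(fixed_terms=MODEL_TERMS[int(number)],
                   random_levels=tuple(random_levels), **kwargs)


@dataclass
class MCMCSettings:
    """Gibbs-chain settings; inverse-gamma(prior_a, prior_b) on each variance."""

    burn_in: int = 500
    n_iter: int = 5000
    thin: int = 1
    seed: int = 0
    prior_a: float = 0.001
    prior_b: float = 0.001

    def validate(self) -> None:
        if self.burn_in < 0 or self.n_iter < 1 or self.thin < 1:
            raise ValueError("burn_in >= 0, n_iter >= 1 and thin >= 1 required")
        if self.prior_a <= 0 or self.prior_b <= 0:
            raise ValueError("inverse-gamma prior parameters must be positive")


@dataclass
class VarianceComponents:
    """Variance components in g^2; a level absent from the fit is None."""

    sigma2_mcb: float | None
    sigma2_m: float | None
    sigma2_b: float
    se_mcb: float | None = None
    se_m: float | None = None
    se_b: float | None = None

    def as_tuple(self) -> tuple[float, float, float]:
        """(country, mother, baby) with absent levels as 0."""
        return (self.sigma2_mcb or 0.0, self.sigma2_m or 0.0, self.sigma2_b)

    def total(self) -> float:
        return float(sum(self.as_tuple()))


@dataclass
class FitResult:
    """A fitted nested model: estimates, chains and fit criteria."""

    spec: ModelSpec
    fixed: pd.DataFrame              # columns: term, estimate, se
    variances: VarianceComponents
    deviance_bar: float | None = None
    p_d: float | None = None
    dic: float | None = None
    chains: dict[str, np.ndarray] = field(default_factory=dict)
    method: str = "gibbs"
    meta: dict = field(default_factory=dict)

    @property
    def country_labels(self) -> np.ndarray:
        return self.meta["country_labels"]


# ---------------------------------------------------------------------------
# design matrix and data preparation

def design_matrix(cohort: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded design matrix against the spec's reference categories.

    Categorical blocks expand to one column per non-reference category that
    occurs in the cohort (canonical category order); gestational age enters
    as a single continuous column, grand-mean centred by default.
    """
    n = len(cohort)
    cols: list[np.ndarray] = []
    names: list[str] = []
    for term in spec.fixed_terms:
        if term == "intercept":
            cols.append(np.ones(n))
            names.append("intercept")
        elif term == "gestational_age":
            ga = np.asarray(cohort["gestational_age"], dtype=float)
            if spec.center_gestational_age:
                ga = ga - ga.mean()
            cols.append(ga)
            names.append("gestational_age")
        else:
            col, cats, _ = TERM_INFO[term]
            ref = spec.reference(term)
            values = np.asarray(cohort[col], dtype=object)
            known = set(cats)
            bad = [i for i, val in enumerate(values) if val not in known]
            if bad:
                raise ValueError(
                    f"unknown category {values[bad[0]]!r} in column {col!r} "
                    f"at row {bad[0]}")
            present = set(values)
            for cat in cats:
                if cat == ref or cat not in present:
                    continue
                cols.append((values == cat).astype(float))
                names.append(f"{col}[{cat}]")
    return np.column_stack(cols), names


@dataclass
class _Prepared:
    y: np.ndarray
    X: np.ndarray
    names: list[str]
    c_idx: np.ndarray | None     # country index per baby
    m_idx: np.ndarray | None     # mother index per baby
    country_labels: np.ndarray | None
    mother_labels: np.ndarray | None
    n_per_country: np.ndarray | None
    n_per_mother: np.ndarray | None
    country_of_mother: np.ndarray | None


def _prepare(cohort: pd.DataFrame, spec: ModelSpec) -> _Prepared:
    y = np.asarray(cohort[spec.outcome], dtype=float)
    X, names = design_matrix(cohort, spec)
    c_idx = m_idx = None
    country_labels = mother_labels = None
    n_per_country = n_per_mother = country_of_mother = None
    if "country" in spec.random_levels:
        country_labels, c_idx = np.unique(np.asarray(cohort["country_id"]),
                                          return_inverse=True)
        n_per_country = np.bincount(c_idx, minlength=country_labels.size)
    if "mother" in spec.random_levels:
        mother_labels, m_idx = np.unique(np.asarray(cohort["mother_id"]),
                                         return_inverse=True)
        n_per_mother = np.bincount(m_idx, minlength=mother_labels.size)
        if c_idx is not None:
            country_of_mother = np.full(mother_labels.size, -1, dtype=int)
            country_of_mother[m_idx] = c_idx
            # nesting integrity: a mother may not appear in two countries
            chk = pd.Series(c_idx).groupby(pd.Series(m_idx)).nunique()
            if (chk > 1).any():
                bad = mother_labels[chk[chk > 1].index[0]]
                raise ValueError(f"mother {bad!r} appears in more than one country")
    return _Prepared(y, X, names, c_idx, m_idx, country_labels, mother_labels,
                     n_per_country, n_per_mother, country_of_mother)


# ---------------------------------------------------------------------------
# O(n) nested-covariance kernels

def _vinv_apply(x, s2_c, s2_m, s2_b, prep: _Prepared):
    """V^{-1} x for V = s2_b I + s2_m Zm Zm' + s2_c Zc Zc', in O(n).

    Uses the Woodbury identity level-wise: first the mother blocks (block
    diagonal), then the country level (diagonal capacitance because mothers
    nest in countries).
    """
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    if one_d:
        x = x[:, None]
    if prep.m_idx is not None and s2_m > 0:
        n_j = prep.n_per_mother
        t = np.zeros((n_j.size, x.shape[1]))
        np.add.at(t, prep.m_idx, x)
        coef = s2_m / (s2_b * (s2_b + n_j * s2_m))
        ax = x / s2_b - coef[prep.m_idx, None] * t[prep.m_idx]
        unit = 1.0 / (s2_b + n_j * s2_m)         # elementwise A^{-1} 1_block
    else:
        ax = x / s2_b
        unit = None
    if prep.c_idx is not None and s2_c > 0:
        g = np.zeros((prep.n_per_country.size, x.shape[1]))
        np.add.at(g, prep.c_idx, ax)
        if unit is not None:
            d = np.bincount(prep.country_of_mother,
                            weights=prep.n_per_mother * unit,
                            minlength=prep.n_per_country.size)
            w_elem = unit[prep.m_idx]
        else:
            d = prep.n_per_country / s2_b
            w_elem = np.full(x.shape[0], 1.0 / s2_b)
        h = g * (s2_c / (1.0 + s2_c * d))[:, None]
        ax = ax - w_elem[:, None] * h[prep.c_idx]
    return ax[:, 0] if one_d else ax


def _logdet_v(s2_c, s2_m, s2_b, prep: _Prepared) -> float:
    n = prep.y.size
    if prep.m_idx is not None and s2_m > 0:
        n_j = prep.n_per_mother
        logdet = float(np.sum((n_j - 1) * np.log(s2_b) + np.log(s2_b + n_j * s2_m)))
        unit = 1.0 / (s2_b + n_j * s2_m)
    else:
        logdet = n * np.log(s2_b)
        unit = None
    if prep.c_idx is not None and s2_c > 0:
        if unit is not None:
            d = np.bincount(prep.country_of_mother,
                            weights=prep.n_per_mother * unit,
                            minlength=prep.n_per_country.size)
        else:
            d = prep.n_per_country / s2_b
        logdet += float(np.sum(np.log1p(s2_c * d)))
    return logdet


def _deviance_arrays(beta, s2_c, s2_m, s2_b, prep: _Prepared) -> float:
    r = prep.y - prep.X @ beta
    quad = float(r @ _vinv_apply(r, s2_c, s2_m, s2_b, prep))
    n = prep.y.size
    return n * np.log(2.0 * np.pi) + _logdet_v(s2_c, s2_m, s2_b, prep) + quad


def deviance(cohort: pd.DataFrame, spec: ModelSpec,
             fixed: pd.DataFrame | Sequence[float],
             variances: VarianceComponents) -> float:
    """Exact marginal deviance (-2 log likelihood) of the nested model.

    Computed level-wise in O(n); the n-by-n covariance is never formed.
    ``fixed`` may be a FixedEffects table or a coefficient vector in
    design-matrix column order.
    """
    prep = _prepare(cohort, spec)
    if isinstance(fixed, pd.DataFrame):
        est = dict(zip(fixed["term"], fixed["estimate"]))
        beta = np.array([est[name] for name in prep.names])
    else:
        beta = np.asarray(fixed, dtype=float)
    s2_c, s2_m, s2_b = variances.as_tuple()
    if not np.all(np.isfinite(beta)) or s2_b <= 0:
        raise ValueError("parameters must be finite with a positive residual variance")
    return _deviance_arrays(beta, s2_c, s2_m, s2_b, prep)


def _gls(prep: _Prepared, s2_c, s2_m, s2_b):
    w = _vinv_apply(prep.X, s2_c, s2_m, s2_b, prep)
    xtvx = prep.X.T @ w
    try:
        cov = linalg.inv(xtvx)
    except linalg.LinAlgError as err:
        raise ValueError(f"singular design matrix (terms: {prep.names})") from err
    beta = cov @ (w.T @ prep.y)
    return beta, np.sqrt(np.diag(cov))


# ---------------------------------------------------------------------------
# method-of-moments (nested ANOVA on OLS residuals)

def _mom_components(prep: _Prepared, floor: float):
    """Henderson-type moment estimators from OLS residuals.

    For the empty model this is the classical (unbalanced) nested ANOVA; with
    covariates the residuals of the OLS fit stand in for the raw outcome,
    which is only a starting value, not the production estimate.
    """
    y, X = prep.y, prep.X
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    n = y.size
    p = X.shape[1]
    have_c = prep.c_idx is not None
    have_m = prep.m_idx is not None
    s2_c = s2_m = None

    if have_m and have_c:
        n_j = prep.n_per_mother.astype(float)
        n_k = prep.n_per_country.astype(float)
        J, K = n_j.size, n_k.size
        if J <= K or K < 2:
            raise ValueError("need >=2 countries and >=2 mothers per included level")
        sum_j = np.bincount(prep.m_idx, weights=r, minlength=int(J))
        sum_k = np.bincount(prep.c_idx, weights=r, minlength=int(K))
        rbar_j2 = sum_j ** 2 / n_j
        rbar_k2 = sum_k ** 2 / n_k
        ssw = float(r @ r - rbar_j2.sum())
        ssb = float(rbar_j2.sum() - rbar_k2.sum())
        ssa = float(rbar_k2.sum() - r.sum() ** 2 / n)
        s2_b = ssw / (n - J)
        s2k = np.bincount(prep.country_of_mother, weights=n_j ** 2, minlength=int(K))
        c1 = (n - float((s2k / n_k).sum())) / (J - K)
        s2_m = (ssb / (J - K) - s2_b) / c1
        c2 = (float((s2k / n_k).sum()) - float((n_j ** 2).sum()) / n) / (K - 1)
        c3 = (n - float((n_k ** 2).sum()) / n) / (K - 1)
        s2_c = (ssa / (K - 1) - s2_b - c2 * s2_m) / c3
    elif have_c or have_m:
        idx = prep.c_idx if have_c else prep.m_idx
        n_g = (prep.n_per_country if have_c else prep.n_per_mother).astype(float)
        G = n_g.size
        if G < 2:
            raise ValueError("need >=2 groups at the included random level")
        sums = np.bincount(idx, weights=r, minlength=int(G))
        rbar_g2 = sums ** 2 / n_g
        ssw = float(r @ r - rbar_g2.sum())
        ssa = float(rbar_g2.sum() - r.sum() ** 2 / n)
        s2_b = ssw / (n - G)
        c3 = (n - float((n_g ** 2).sum()) / n) / (G - 1)
        est = (ssa / (G - 1) - s2_b) / c3
        if have_c:
            s2_c = est
        else:
            s2_m = est
    else:
        s2_b = float(r @ r) / max(n - p, 1)

    def _floor(v):
        return None if v is None else max(float(v), floor)
    return _floor(s2_c), _floor(s2_m), max(float(s2_b), floor)


# ---------------------------------------------------------------------------
# Gibbs sampler

def _run_gibbs(prep: _Prepared, settings: MCMCSettings,
               start: tuple[float | None, float | None, float],
               store_mother_chain: bool):
    rng = np.random.default_rng(settings.seed)
    y, X = prep.y, prep.X
    n, p = X.shape
    have_c = prep.c_idx is not None
    have_m = prep.m_idx is not None
    K = prep.n_per_country.size if have_c else 0
    J = prep.n_per_mother.size if have_m else 0

    xtx = X.T @ X
    try:
        L = linalg.cho_factor(xtx, lower=True)
    except linalg.LinAlgError as err:
        raise ValueError(f"singular design matrix (terms: {prep.names})") from err
    # upper Cholesky factor R with R'R = X'X, for sampling N(0, s2 (X'X)^-1)
    R = linalg.cholesky(xtx, lower=False)
    i0 = prep.names.index("intercept")

    s2_c0, s2_m0, s2_b = start
    s2_c = s2_c0 if have_c else 0.0
    s2_m = s2_m0 if have_m else 0.0
    v = np.zeros(K)
    u = np.zeros(J)
    beta = np.zeros(p)

    a, b = settings.prior_a, settings.prior_b
    n_keep = settings.n_iter // settings.thin
    chain_beta = np.empty((n_keep, p))
    chain_s2 = np.empty((n_keep, 3))
    chain_v = np.empty((n_keep, K)) if have_c else None
    chain_u = np.empty((n_keep, J)) if (have_m and store_mother_chain) else None

    n_k = prep.n_per_country.astype(float) if have_c else None
    n_j = prep.n_per_mother.astype(float) if have_m else None

    kept = 0
    total = settings.burn_in + settings.n_iter
    for it in range(total):
        # fixed effects | effects, variances
        resid = y.copy()
        if have_c:
            resid -= v[prep.c_idx]
        if have_m:
            resid -= u[prep.m_idx]
        bhat = linalg.cho_solve(L, X.T @ resid)
        beta = bhat + np.sqrt(s2_b) * linalg.solve_triangular(
            R, rng.standard_normal(p), lower=False)

        xb = X @ beta
        # country effects | rest
        if have_c:
            r = y - xb
            if have_m:
                r = r - u[prep.m_idx]
            s = np.bincount(prep.c_idx, weights=r, minlength=K)
            prec = n_k / s2_b + 1.0 / s2_c
            v = s / s2_b / prec + rng.standard_normal(K) / np.sqrt(prec)
            # translation move: shift between intercept and country effects
            delta = rng.normal(v.mean(), np.sqrt(s2_c / K))
            v -= delta
            beta[i0] += delta
            xb = X @ beta
        # mother effects | rest
        if have_m:
            r = y - xb
            if have_c:
                r = r - v[prep.c_idx]
            s = np.bincount(prep.m_idx, weights=r, minlength=J)
            prec = n_j / s2_b + 1.0 / s2_m
            u = s / s2_b / prec + rng.standard_normal(J) / np.sqrt(prec)
            delta = rng.normal(u.mean(), np.sqrt(s2_m / J))
            u -= delta
            beta[i0] += delta
            xb = X @ beta
        # variances | effects
        e = y - xb
        if have_c:
            e = e - v[prep.c_idx]
        if have_m:
            e = e - u[prep.m_idx]
        if have_c:
            s2_c = (b + 0.5 * float(v @ v)) / rng.gamma(a + 0.5 * K)
        if have_m:
            s2_m = (b + 0.5 * float(u @ u)) / rng.gamma(a + 0.5 * J)
        s2_b = (b + 0.5 * float(e @ e)) / rng.gamma(a + 0.5 * n)
        if not (np.isfinite(s2_b) and np.isfinite(beta).all()):
            raise RuntimeError(f"non-finite draw at iteration {it}")

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            chain_beta[kept] = beta
            chain_s2[kept] = (s2_c, s2_m, s2_b)
            if chain_v is not None:
                chain_v[kept] = v
            if chain_u is not None:
                chain_u[kept] = u
            kept += 1

    chains = {"beta": chain_beta[:kept], "sigma2": chain_s2[:kept]}
    if chain_v is not None:
        chains["country_effects"] = chain_v[:kept]
    if chain_u is not None:
        chains["mother_effects"] = chain_u[:kept]
    return chains


# ---------------------------------------------------------------------------
# estimator

class NestedLinearMixedModel(BaseEstimator):
    """Nested random-intercept Gaussian linear model, scikit-learn style.

    Parameters
    ----------
    fixed_terms : tuple of str
        Fixed-effect blocks; always includes ``"intercept"``.  ``model=k``
        presets are available through :meth:`ModelSpec.model`.
    random_levels : tuple of str
        Ordered subset of ``("country", "mother")``; the baby-level residual
        is always present.
    method : {"gibbs", "mom"}
        ``"gibbs"`` runs the blocked sampler started at the method-of-moments
        values; ``"mom"`` stops at the moment/GLS fit (no chains).
    burn_in, n_iter, thin, seed, prior_a, prior_b
        Chain settings; inverse-gamma(prior_a, prior_b) prior on each
        variance component, flat prior on the fixed effects.
    store_mother_chain : bool
        Keep the mother-effect draws (memory-heavy on large cohorts).
    compute_dic : bool
        Evaluate the deviance information criterion after sampling, using at
        most ``dic_max_draws`` equally spaced retained draws.

    Attributes
    ----------
    result_ : FitResult
    fixed_effects_ : pandas.DataFrame with columns (term, estimate, se)
    variances_ : VarianceComponents
    dic_, deviance_bar_, p_d_ : float or None
    chains_ : dict of posterior draw arrays
    """

    def __init__(self, fixed_terms=("intercept",), random_levels=("country", "mother"),
                 reference_categories=None, center_gestational_age=True,
                 outcome="birthweight", method="gibbs",
                 burn_in=500, n_iter=5000, thin=1, seed=0,
                 prior_a=0.001, prior_b=0.001,
                 store_mother_chain=False, compute_dic=True, dic_max_draws=1000):
        self.fixed_terms = fixed_terms
        self.random_levels = random_levels
        self.reference_categories = reference_categories
        self.center_gestational_age = center_gestational_age
        self.outcome = outcome
        self.method = method
        self.burn_in = burn_in
        self.n_iter = n_iter
        self.thin = thin
        self.seed = seed
        self.prior_a = prior_a
        self.prior_b = prior_b
        self.store_mother_chain = store_mother_chain
        self.compute_dic = compute_dic
        self.dic_max_draws = dic_max_draws

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            fixed_terms=tuple(self.fixed_terms),
            random_levels=tuple(self.random_levels),
            reference_categories=dict(self.reference_categories or {}),
            center_gestational_age=self.center_gestational_age,
            outcome=self.outcome,
        )

    def _settings(self) -> MCMCSettings:
        s = MCMCSettings(burn_in=self.burn_in, n_iter=self.n_iter,
                         thin=self.thin, seed=self.seed,
                         prior_a=self.prior_a, prior_b=self.prior_b)
        s.validate()
        return s

    def fit(self, X: pd.DataFrame, y=None) -> "NestedLinearMixedModel":
        """Fit the model on a cohort table (one row per baby)."""
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a cohort DataFrame")
        if self.method not in ("gibbs", "mom"):
            raise ValueError("method must be 'gibbs' or 'mom'")
        spec = self._spec()
        missing = {spec.outcome} - set(X.columns)
        if missing:
            raise ValueError(f"cohort lacks columns: {sorted(missing)}")
        prep = _prepare(X, spec)
        floor = 1e-8 * float(np.var(prep.y)) if np.var(prep.y) > 0 else 1e-8
        s2_c, s2_m, s2_b = _mom_components(prep, floor)

        if self.method == "mom":
            beta, se = _gls(prep, s2_c or 0.0, s2_m or 0.0, s2_b)
            fixed = pd.DataFrame({"term": prep.names, "estimate": beta, "se": se})
            variances = VarianceComponents(s2_c, s2_m, s2_b)
            result = FitResult(spec=spec, fixed=fixed, variances=variances,
                               method="mom", meta=self._meta(prep))
        else:
            settings = self._settings()
            warnings = []
            if settings.n_iter < 100:
                warnings.append("fewer than 100 monitoring iterations")
            chains = _run_gibbs(prep, settings, (s2_c, s2_m, s2_b),
                                self.store_mother_chain)
            result = self._summarise(spec, prep, settings, chains, warnings)
        self.result_ = result
        self.fixed_effects_ = result.fixed
        self.variances_ = result.variances
        self.chains_ = result.chains
        self.deviance_bar_ = result.deviance_bar
        self.p_d_ = result.p_d
        self.dic_ = result.dic
        self.n_terms_ = len(prep.names)
        return self

    def _meta(self, prep: _Prepared) -> dict:
        meta = {"n_babies": int(prep.y.size)}
        if prep.country_labels is not None:
            meta["country_labels"] = prep.country_labels
            meta["n_per_country"] = prep.n_per_country
        if prep.mother_labels is not None:
            meta["n_mothers"] = int(prep.mother_labels.size)
        return meta

    def _summarise(self, spec, prep, settings, chains, warnings) -> FitResult:
        beta_c = chains["beta"]
        s2_chain = chains["sigma2"]
        have_c = prep.c_idx is not None
        have_m = prep.m_idx is not None
        fixed = pd.DataFrame({
            "term": prep.names,
            "estimate": beta_c.mean(axis=0),
            "se": beta_c.std(axis=0, ddof=1),
        })
        variances = VarianceComponents(
            sigma2_mcb=float(s2_chain[:, 0].mean()) if have_c else None,
            sigma2_m=float(s2_chain[:, 1].mean()) if have_m else None,
            sigma2_b=float(s2_chain[:, 2].mean()),
            se_mcb=float(s2_chain[:, 0].std(ddof=1)) if have_c else None,
            se_m=float(s2_chain[:, 1].std(ddof=1)) if have_m else None,
            se_b=float(s2_chain[:, 2].std(ddof=1)),
        )
        meta = self._meta(prep)
        meta["settings"] = dataclasses.asdict(settings)
        if warnings:
            meta["warnings"] = warnings
        result = FitResult(spec=spec, fixed=fixed, variances=variances,
                           chains=chains, method="gibbs", meta=meta)
        if self.compute_dic:
            dbar, pd_, dic_ = _dic_from_chains(chains, prep,
                                               max_draws=self.dic_max_draws)
            result.deviance_bar, result.p_d, result.dic = dbar, pd_, dic_
        return result

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Fixed-effect prediction plus the posterior-mean country effect
        for countries seen during fitting."""
        result = self.result_
        prep_names = list(result.fixed["term"])
        mat, names = design_matrix(X, result.spec)
        if names != prep_names:
            est = dict(zip(result.fixed["term"], result.fixed["estimate"]))
            beta = np.array([est.get(nm, 0.0) for nm in names])
        else:
            beta = result.fixed["estimate"].to_numpy()
        pred = mat @ beta
        if "country_effects" in result.chains:
            eff = result.chains["country_effects"].mean(axis=0)
            lookup = dict(zip(result.meta["country_labels"], eff))
            pred = pred + np.array([lookup.get(c, 0.0) for c in X["country_id"]])
        return pred


# ---------------------------------------------------------------------------
# DIC

def _dic_from_chains(chains, prep: _Prepared, max_draws=None):
    beta_c = chains["beta"]
    s2_c = chains["sigma2"]
    n_draws = beta_c.shape[0]
    if max_draws and n_draws > max_draws:
        idx = np.linspace(0, n_draws - 1, max_draws).astype(int)
    else:
        idx = np.arange(n_draws)
    devs = np.array([
        _deviance_arrays(beta_c[i], s2_c[i, 0], s2_c[i, 1], max(s2_c[i, 2], 1e-300), prep)
        for i in idx
    ])
    dbar = float(devs.mean())
    dev_at_mean = _deviance_arrays(beta_c.mean(axis=0),
                                   float(s2_c[:, 0].mean()),
                                   float(s2_c[:, 1].mean()),
                                   float(s2_c[:, 2].mean()), prep)
    p_d = dbar - dev_at_mean
    return dbar, p_d, dbar + p_d


def dic(chains: Mapping[str, np.ndarray], cohort: pd.DataFrame,
        spec: ModelSpec) -> tuple[float, float, float]:
    """(mean posterior deviance, effective parameters, DIC) from chains.

    ``chains`` must hold "beta" (draws x terms, design-matrix order) and
    "sigma2" (draws x 3, country/mother/baby; absent levels as zero).
    """
    if chains["beta"].shape[0] < 50:
        raise ValueError("need at least 50 retained draws for the DIC")
    prep = _prepare(cohort, spec)
    return _dic_from_chains(dict(chains), prep)


# ---------------------------------------------------------------------------
# functional wrappers and the dense oracle

def _estimator_kwargs(spec: ModelSpec) -> dict:
    return dict(fixed_terms=spec.fixed_terms, random_levels=spec.random_levels,
                reference_categories=dict(spec.reference_categories),
                center_gestational_age=spec.center_gestational_age,
                outcome=spec.outcome)


def fit_mom(cohort: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Method-of-moments variance components + feasible-GLS fixed effects."""
    est = NestedLinearMixedModel(method="mom", **_estimator_kwargs(spec))
    return est.fit(cohort).result_


def fit_gibbs(cohort: pd.DataFrame, spec: ModelSpec,
              settings: MCMCSettings | None = None,
              start: FitResult | None = None,
              store_mother_chain: bool = False,
              compute_dic: bool = True) -> FitResult:
    """Blocked Gibbs fit started from the method-of-moments values.

    ``start`` is accepted for interface completeness; the sampler always
    recomputes its start from the data unless one is supplied.
    """
    settings = settings or MCMCSettings()
    settings.validate()
    est = NestedLinearMixedModel(
        method="gibbs", burn_in=settings.burn_in, n_iter=settings.n_iter,
        thin=settings.thin, seed=settings.seed, prior_a=settings.prior_a,
        prior_b=settings.prior_b, store_mother_chain=store_mother_chain,
        compute_dic=compute_dic, **_estimator_kwargs(spec))
    if start is not None:
        # run the sampler directly from the provided start values
        prep = _prepare(cohort, spec)
        chains = _run_gibbs(prep, settings, start.variances.as_tuple(),
                            store_mother_chain)
        warnings = [] if settings.n_iter >= 100 else ["fewer than 100 monitoring iterations"]
        return est._summarise(spec, prep, settings, chains, warnings)
    return est.fit(cohort).result_


def oracle_direct(cohort: pd.DataFrame, spec: ModelSpec,
                  max_rows: int = 500) -> FitResult:
    """Dense-covariance maximum-likelihood fit for small problems.

    Assembles V = s2_c Zc Zc' + s2_m Zm Zm' + s2_b I explicitly and
    maximises the exact multivariate-normal likelihood (profile over the
    fixed effects) by generic numerical optimisation.  Test oracle only.
    """
    prep = _prepare(cohort, spec)
    n = prep.y.size
    if n > max_rows:
        raise ValueError(f"oracle_direct limited to {max_rows} rows, got {n}")
    have_c = prep.c_idx is not None
    have_m = prep.m_idx is not None
    zc = (prep.c_idx[:, None] == prep.c_idx[None, :]).astype(float) if have_c else 0.0
    zm = (prep.m_idx[:, None] == prep.m_idx[None, :]).astype(float) if have_m else 0.0

    floor = 1e-8 * float(np.var(prep.y))
    s2_c0, s2_m0, s2_b0 = _mom_components(prep, floor)
    theta0 = [np.log(t) for t in (s2_c0, s2_m0, s2_b0) if t is not None]

    def unpack(theta):
        vals = list(np.exp(theta))
        s2_c = vals.pop(0) if have_c else 0.0
        s2_m = vals.pop(0) if have_m else 0.0
        return s2_c, s2_m, vals[0]

    def neg2ll(theta):
        s2_c, s2_m, s2_b = unpack(theta)
        V = s2_b * np.eye(n)
        if have_c:
            V = V + s2_c * zc
        if have_m:
            V = V + s2_m * zm
        try:
            cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return np.inf
        vx = linalg.cho_solve(cf, prep.X)
        vy = linalg.cho_solve(cf, prep.y)
        xtvx = prep.X.T @ vx
        beta = np.linalg.solve(xtvx, prep.X.T @ vy)
        r = prep.y - prep.X @ beta
        quad = float(r @ linalg.cho_solve(cf, r))
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return n * np.log(2 * np.pi) + logdet + quad

    res = optimize.minimize(neg2ll, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 4000})
    s2_c, s2_m, s2_b = unpack(res.x)
    beta, se = _gls(prep, s2_c, s2_m, s2_b)
    fixed = pd.DataFrame({"term": prep.names, "estimate": beta, "se": se})
    variances = VarianceComponents(s2_c if have_c else None,
                                   s2_m if have_m else None, s2_b)
    meta = {"n_babies": n, "neg2ll": float(res.fun), "converged": bool(res.success)}
    if prep.country_labels is not None:
        meta["country_labels"] = prep.country_labels
        meta["n_per_country"] = prep.n_per_country
    return FitResult(spec=spec, fixed=fixed, variances=variances,
                     method="oracle", meta=meta)
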