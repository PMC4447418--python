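"""Synthetic birth-register cohorts with a three-level nested structure.

The generator draws country-of-birth effects, mother effects and baby-level
residuals from independent normal distributions and assembles birthweights as

    y_ijk = intercept + x'b + v_k + u_jk + e_ijk,

with v_k ~ N(0, s2_country), u_jk ~ N(0, s2_mother), e_ijk ~ N(0, s2_baby).
Covariates are sampled independently at their natural level (country, mother
or baby) from configurable category frequencies.  Defaults reproduce the
statistical structure of a national birth register dominated by one country
of origin: ~109 countries, one holding ~80-85% of mothers, 1-3 babies per
mother (mean ~1.42), and variance components 7,699 / 111,583 / 119,871 g^2
at the country / mother / baby levels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SynthConfig",
    "CohortLatents",
    "default_config",
    "sample_cohort",
    "sample_maternal_stature",
    "write_cohort",
    "read_cohort",
    "load_config",
    "save_config",
    "COHORT_COLUMNS",
]

STATURE_CATS = ["<150", "150-159", "160-169", "170-179", ">179", "missing"]
AGE_CATS = ["<20", "20-24", "25-34", ">34"]
SEX_CATS = ["male", "female"]
INCOME_CATS = ["highest", "middle", "lowest", "missing"]
MARITAL_CATS = ["married/cohabiting", "single", "widowed/divorced", "missing"]
SMOKING_CATS = ["none", "1-9/day", ">9/day", "missing"]
FLAG_CATS = ["no", "yes"]
WB_CATS = ["low", "lower-middle", "upper-middle", "high"]

#: Column order of a written cohort table; one row per baby.
COHORT_COLUMNS = [
    "baby_id", "mother_id", "country_id", "birthweight", "gestational_age",
    "sex", "stature_cat", "age_cat", "marital", "smoking", "income_cat",
    "hypertension", "diabetes", "wb_class",
]

# Covariates constant within a mother (all her babies share them).
MOTHER_LEVEL_COVARIATES = [
    "stature_cat", "age_cat", "marital", "smoking", "income_cat",
    "hypertension", "diabetes",
]

_CATEGORY_SETS: dict[str, list[str]] = {
    "stature_cat": STATURE_CATS,
    "age_cat": AGE_CATS,
    "sex": SEX_CATS,
    "income_cat": INCOME_CATS,
    "marital": MARITAL_CATS,
    "smoking": SMOKING_CATS,
    "hypertension": FLAG_CATS,
    "diabetes": FLAG_CATS,
    "wb_class": WB_CATS,
}


def _norm(freqs: Mapping[str, float]) -> dict[str, float]:
    total = float(sum(freqs.values()))
    return {k: float(v) / total for k, v in freqs.items()}


def _default_covariate_freqs() -> dict[str, dict[str, float]]:
    # Whole-population category proportions of the emulated register
    # (percentages of the "all economies" column; vectors that do not sum
    # exactly to one due to printed rounding are renormalised).
    return {
        "stature_cat": _norm({"<150": 0.0037, "150-159": 0.1162,
                              "160-169": 0.5165, "170-179": 0.2910,
                              ">179": 0.0195, "missing": 0.0540}),
        "age_cat": _norm({"<20": 0.0163, "20-24": 0.1255,
                          "25-34": 0.6520, ">34": 0.2061}),
        "sex": {"male": 0.5104, "female": 0.4896},
        "income_cat": _norm({"highest": 0.3303, "middle": 0.3292,
                             "lowest": 0.3286, "missing": 0.0119}),
        "marital": _norm({"married/cohabiting": 0.9018, "single": 0.0167,
                          "widowed/divorced": 0.0356, "missing": 0.0459}),
        "smoking": _norm({"none": 0.8779, "1-9/day": 0.0558,
                          ">9/day": 0.0182, "missing": 0.0480}),
        "hypertension": {"no": 0.9640, "yes": 0.0360},
        "diabetes": {"no": 0.9950, "yes": 0.0050},
    }


def _default_fixed_effects() -> dict[str, float]:
    # Fully adjusted model coefficients, in grams, keyed by design-matrix
    # column name.  Gestational age enters centred (grams per week).
    return {
        "intercept": 3595.0,
        "stature_cat[<150]": -184.0,
        "stature_cat[150-159]": -98.0,
        "stature_cat[170-179]": 99.0,
        "stature_cat[>179]": 202.0,
        "stature_cat[missing]": 6.0,
        "age_cat[<20]": -106.0,
        "age_cat[20-24]": -60.0,
        "age_cat[>34]": 51.0,
        "sex[female]": -123.0,
        "gestational_age": 149.0,
        "income_cat[middle]": 76.0,
        "income_cat[lowest]": 107.0,
        "income_cat[missing]": 12.0,
        "marital[single]": -39.0,
        "marital[widowed/divorced]": -44.0,
        "marital[missing]": 7.0,
        "smoking[1-9/day]": -129.0,
        "smoking[>9/day]": -179.0,
        "smoking[missing]": 4.0,
        "hypertension[yes]": -108.0,
        "diabetes[yes]": 314.0,
        "wb_class[low]": -88.0,
        "wb_class[lower-middle]": -52.0,
        "wb_class[upper-middle]": -16.0,
    }


@dataclass
class SynthConfig:
    """Parameters of the synthetic birth register.

    ``true_variances`` is the (country, mother, baby) variance triple in g^2;
    ``true_fixed_effects`` maps design-column names to coefficients in grams.
    ``wb_class_probs`` gives the per-country probability of each World-Bank
    income class in the order (low, lower-middle, upper-middle, high).
    """

    n_countries: int = 109
    dominant_country_share: float = 0.80
    country_size_concentration: float = 0.5
    n_mothers: int = 571_876
    parity_probs: tuple[float, ...] = (0.62, 0.34, 0.04)
    true_fixed_effects: dict[str, float] = field(default_factory=_default_fixed_effects)
    true_variances: tuple[float, float, float] = (7699.0, 111583.0, 119871.0)
    covariate_freqs: dict[str, dict[str, float]] = field(default_factory=_default_covariate_freqs)
    ga_mean: float = 39.66
    ga_sd: float = 1.27
    stature_icc: float = 0.24
    stature_mean_cm: float = 165.0
    stature_var_cm2: float = 40.0
    wb_class_probs: tuple[float, ...] = (14 / 109, 25 / 109, 37 / 109, 33 / 109)
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.dominant_country_share < 1.0):
            raise ValueError("dominant_country_share must lie in (0, 1)")
        if self.n_countries < 1 or self.n_mothers < 1:
            raise ValueError("n_countries and n_mothers must be positive")
        if self.country_size_concentration <= 0:
            raise ValueError("country_size_concentration must be positive")
        for name, probs in [("parity_probs", self.parity_probs),
                            ("wb_class_probs", self.wb_class_probs)]:
            p = np.asarray(probs, dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must be a probability vector summing to 1")
        for cov, freqs in self.covariate_freqs.items():
            p = np.asarray(list(freqs.values()), dtype=float)
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"covariate_freqs[{cov!r}] must sum to 1")
            unknown = set(freqs) - set(_CATEGORY_SETS.get(cov, freqs))
            if unknown:
                raise ValueError(f"unknown categories for {cov!r}: {sorted(unknown)}")
        if any(v < 0 for v in self.true_variances):
            raise ValueError("variances must be non-negative")
        if not (0.0 <= self.stature_icc < 1.0):
            raise ValueError("stature_icc must lie in [0, 1)")
        if self.ga_sd <= 0:
            raise ValueError("ga_sd must be positive")

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class CohortLatents:
    """True latent effects behind a sampled cohort, for oracle checks."""

    country_effects: pd.Series  # indexed by country_id, grams
    mother_effects: pd.Series   # indexed by mother_id, grams
    residuals: np.ndarray       # one per baby, grams


def default_config() -> SynthConfig:
    """Configuration reproducing the emulated study's printed quantities."""
    return SynthConfig()


def empty_model_config() -> SynthConfig:
    """Default config with all covariate effects switched off.

    For empty-model (variance decomposition) scenarios: the configured
    level variances are then exactly the marginal variances of the outcome,
    because the printed empty-model components of the emulated study already
    include covariate-driven variation.  The intercept is the empty-model
    grand mean.
    """
    return SynthConfig(true_fixed_effects={"intercept": 3490.0})


def _sample_categories(rng: np.random.Generator, cats: Sequence[str],
                       freqs: Mapping[str, float], size: int) -> np.ndarray:
    labels = [c for c in cats if c in freqs]
    p = np.array([freqs[c] for c in labels], dtype=float)
    idx = rng.choice(len(labels), size=size, p=p / p.sum())
    return np.asarray(labels, dtype=object)[idx]


def _sample_gestational_age(rng: np.random.Generator, n: int,
                            mean: float, sd: float) -> np.ndarray:
    """Normal, rounded to integer weeks, truncated to [37, 42] by resampling."""
    ga = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    bad = (ga < 37) | (ga > 42)
    while bad.any():
        ga[bad] = np.rint(rng.normal(mean, sd, size=int(bad.sum()))).astype(int)
        bad = (ga < 37) | (ga > 42)
    return ga


def _country_shares(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    k = cfg.n_countries
    if k == 1:
        return np.array([1.0])
    rest = rng.dirichlet(np.full(k - 1, cfg.country_size_concentration))
    return np.concatenate([[cfg.dominant_country_share],
                           (1.0 - cfg.dominant_country_share) * rest])


def sample_cohort(
    cfg: SynthConfig,
    seed: int | None = None,
    return_latents: bool = False,
    country_mean_shifts: Mapping[int, float] | None = None,
    covariate_sampler: Callable[[np.random.Generator, int], Mapping[str, np.ndarray]] | None = None,
):
    """Draw a full synthetic cohort; one row per baby.

    Parameters
    ----------
    cfg : SynthConfig
    seed : int, optional
        Overrides ``cfg.seed``.
    return_latents : bool
        Also return the :class:`CohortLatents` drawn under the hood.
    country_mean_shifts : mapping of country index -> grams, optional
        Deterministic shifts added to the named countries' means on top of
        their random effects (planted-signal scenarios).
    covariate_sampler : callable(rng, n_mothers) -> mapping, optional
        Override for the mother-level covariate draw; must return one array
        of length ``n_mothers`` per mother-level covariate name.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    mean_parity = float(np.dot(np.arange(1, len(cfg.parity_probs) + 1), cfg.parity_probs))
    if cfg.n_mothers * mean_parity / cfg.n_countries < 1.0:
        raise ValueError("config implies fewer than one expected baby per country")

    shares = _country_shares(rng, cfg)
    mothers_per_country = rng.multinomial(cfg.n_mothers, shares)
    mother_country = np.repeat(np.arange(cfg.n_countries), mothers_per_country)
    n_mothers = mother_country.size

    parity = rng.choice(np.arange(1, len(cfg.parity_probs) + 1),
                        size=n_mothers, p=np.asarray(cfg.parity_probs))
    baby_mother = np.repeat(np.arange(n_mothers), parity)
    baby_country = mother_country[baby_mother]
    n_babies = baby_mother.size

    s2_c, s2_m, s2_b = cfg.true_variances
    v = rng.normal(0.0, np.sqrt(s2_c), size=cfg.n_countries)
    if country_mean_shifts:
        for k_idx, shift in country_mean_shifts.items():
            v[int(k_idx)] += float(shift)
    u = rng.normal(0.0, np.sqrt(s2_m), size=n_mothers)
    e = rng.normal(0.0, np.sqrt(s2_b), size=n_babies)

    wb_country = _sample_categories(rng, WB_CATS,
                                    dict(zip(WB_CATS, cfg.wb_class_probs)),
                                    cfg.n_countries)

    if covariate_sampler is not None:
        mother_cov = dict(covariate_sampler(rng, n_mothers))
        missing = set(MOTHER_LEVEL_COVARIATES) - set(mother_cov)
        if missing:
            raise ValueError(f"covariate_sampler omitted {sorted(missing)}")
    else:
        mother_cov = {
            name: _sample_categories(rng, _CATEGORY_SETS[name],
                                     cfg.covariate_freqs[name], n_mothers)
            for name in MOTHER_LEVEL_COVARIATES
        }

    sex = _sample_categories(rng, SEX_CATS, cfg.covariate_freqs["sex"], n_babies)
    ga = _sample_gestational_age(rng, n_babies, cfg.ga_mean, cfg.ga_sd)

    fx = cfg.true_fixed_effects
    lp = np.full(n_babies, fx.get("intercept", 0.0))
    for name in MOTHER_LEVEL_COVARIATES:
        cats = mother_cov[name][baby_mother]
        table = {c: fx.get(f"{name}[{c}]", 0.0) for c in _CATEGORY_SETS[name]}
        lp += np.vectorize(table.__getitem__, otypes=[float])(cats)
    sex_table = {c: fx.get(f"sex[{c}]", 0.0) for c in SEX_CATS}
    lp += np.vectorize(sex_table.__getitem__, otypes=[float])(sex)
    wb_table = {c: fx.get(f"wb_class[{c}]", 0.0) for c in WB_CATS}
    lp += np.vectorize(wb_table.__getitem__, otypes=[float])(wb_country[baby_country])
    lp += fx.get("gestational_age", 0.0) * (ga - cfg.ga_mean)

    birthweight = lp + v[baby_country] + u[baby_mother] + e

    kw = len(str(max(cfg.n_countries - 1, 1)))
    mw = len(str(max(n_mothers - 1, 1)))
    bw_ = len(str(max(n_babies - 1, 1)))
    country_ids = np.array([f"C{k:0{kw}d}" for k in range(cfg.n_countries)], dtype=object)
    mother_ids = np.array([f"M{j:0{mw}d}" for j in range(n_mothers)], dtype=object)

    table = pd.DataFrame({
        "baby_id": [f"B{i:0{bw_}d}" for i in range(n_babies)],
        "mother_id": mother_ids[baby_mother],
        "country_id": country_ids[baby_country],
        "birthweight": birthweight,
        "gestational_age": ga,
        "sex": sex,
        "stature_cat": mother_cov["stature_cat"][baby_mother],
        "age_cat": mother_cov["age_cat"][baby_mother],
        "marital": mother_cov["marital"][baby_mother],
        "smoking": mother_cov["smoking"][baby_mother],
        "income_cat": mother_cov["income_cat"][baby_mother],
        "hypertension": mother_cov["hypertension"][baby_mother],
        "diabetes": mother_cov["diabetes"][baby_mother],
        "wb_class": wb_country[baby_country],
    }, columns=COHORT_COLUMNS)

    if not return_latents:
        return table
    latents = CohortLatents(
        country_effects=pd.Series(v, index=country_ids, name="country_effect"),
        mother_effects=pd.Series(u, index=mother_ids, name="mother_effect"),
        residuals=e,
    )
    return table, latents


def sample_maternal_stature(
    cfg: SynthConfig,
    mothers_per_country: Sequence[int],
    seed: int | None = None,
) -> pd.DataFrame:
    """Continuous maternal stature with a configurable between-country share.

    Two-level normal model: country means carry ``stature_icc`` of
    ``stature_var_cm2``, mothers the remainder.  Returns one row per mother
    with columns (mother_id, country_id, stature_cm).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    counts = np.asarray(mothers_per_country, dtype=int)
    k = counts.size
    between = cfg.stature_icc * cfg.stature_var_cm2
    within = (1.0 - cfg.stature_icc) * cfg.stature_var_cm2
    means = cfg.stature_mean_cm + rng.normal(0.0, np.sqrt(between), size=k)
    n = int(counts.sum())
    country_idx = np.repeat(np.arange(k), counts)
    stature = means[country_idx] + rng.normal(0.0, np.sqrt(within), size=n)
    kw = len(str(max(k - 1, 1)))
    mw = len(str(max(n - 1, 1)))
    return pd.DataFrame({
        "mother_id": [f"M{j:0{mw}d}" for j in range(n)],
        "country_id": [f"C{c:0{kw}d}" for c in country_idx],
        "stature_cm": stature,
    })


def write_cohort(table: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a cohort as delimiter-separated text with the documented header."""
    table.to_csv(path, sep=sep, index=False)


def read_cohort(path, sep: str = "\t",
                column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a cohort table; ``column_map`` renames external headers to ours."""
    table = pd.read_csv(path, sep=sep, dtype={"hypertension": str, "diabetes": str})
    if column_map:
        table = table.rename(columns=dict(column_map))
    return table


def save_config(cfg: SynthConfig, path) -> None:
    data = dataclasses.asdict(cfg)
    for key in ("parity_probs", "true_variances", "wb_class_probs"):
        data[key] = list(data[key])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_config(path) -> SynthConfig:
    """Read a config file; omitted fields fall back to the defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SynthConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    for key in ("parity_probs", "true_variances", "wb_class_probs"):
        if key in data:
            data[key] = tuple(data[key])
    cfg = SynthConfig(**data)
    cfg.validate()
    return cfg
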