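"""The study workflow: inclusion filters, derived variables, the five-model
sequence, and sensitivity analyses.

The canonical analysis fits five consecutive models to a filtered cohort —
an empty (random-intercepts-only) model, then cumulative fixed-effect blocks
(stature; age; all individual variables; country income class) — and reports
fixed effects, variance components, VPC/ICC/PCV against the empty model, and
the empty model's shrunken country effects.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import partition, shrinkage
from .lmm3 import (FitResult, MCMCSettings, ModelSpec, NestedLinearMixedModel,
                   VarianceComponents, fit_gibbs)
from .synthgen import SynthConfig, default_config, sample_cohort

__all__ = [
    "ExclusionTally", "StudyReport", "apply_inclusion_filters",
    "assign_income_tertiles", "run_model_sequence",
    "sensitivity_drop_lowest", "sensitivity_two_level_stature",
    "sensitivity_drop_mother_level", "sensitivity_subsample_reference",
    "planted_scenario_cohort",
]

logger = logging.getLogger("nestedvar")

MIN_BIRTHWEIGHT_G = 500.0
GESTATION_RANGE_WEEKS = (37, 42)
MIN_BABIES_PER_COUNTRY = 100


@dataclass
class ExclusionTally:
    """Ordered record of how many rows each inclusion rule removed."""

    initial: int
    steps: list[tuple[str, int]] = field(default_factory=list)

    @property
    def final(self) -> int:
        return self.initial - sum(n for _, n in self.steps)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "removed"])


@dataclass
class StudyReport:
    """Everything the five-model analysis produces."""

    fits: dict[str, FitResult]
    fixed_effects: pd.DataFrame           # long format: model, term, estimate, se
    partition: pd.DataFrame               # partition_report table
    shrunken: pd.DataFrame                # empty-model league table input
    tally: ExclusionTally | None
    settings: MCMCSettings


def apply_inclusion_filters(records: pd.DataFrame,
                            min_birthweight: float = MIN_BIRTHWEIGHT_G,
                            gestation_range: tuple[int, int] = GESTATION_RANGE_WEEKS,
                            min_per_country: int = MIN_BABIES_PER_COUNTRY,
                            ) -> tuple[pd.DataFrame, ExclusionTally]:
    """Apply the self-contained study-selection rules, in a fixed order.

    1. missing maternal age or birth-order fields (when those columns exist);
    2. birthweight below 500 g;
    3. missing country of birth;
    4. gestational age outside 37-42 completed weeks;
    5. countries left with fewer than 100 babies (one pass, after all
       row-level rules).

    Row order is preserved; the tally lists rows removed per rule.  The
    thresholds are parameters so scaled-down cohorts can use proportional
    cut-offs; the defaults are the study rules.
    """
    tally = ExclusionTally(initial=len(records))
    df = records

    mask = pd.Series(False, index=df.index)
    for col in ("age_cat", "birth_order"):
        if col in df.columns:
            mask |= df[col].isna()
    tally.steps.append(("missing maternal age or birth order", int(mask.sum())))
    df = df[~mask]

    mask = df["birthweight"].isna() | (df["birthweight"] < min_birthweight)
    tally.steps.append(("birthweight below 500 g", int(mask.sum())))
    df = df[~mask]

    mask = df["country_id"].isna()
    tally.steps.append(("missing country of birth", int(mask.sum())))
    df = df[~mask]

    lo, hi = gestation_range
    mask = df["gestational_age"].isna() | (df["gestational_age"] < lo) | (df["gestational_age"] > hi)
    tally.steps.append(("gestational age outside 37-42 weeks", int(mask.sum())))
    df = df[~mask]

    counts = df["country_id"].value_counts()
    small = counts[counts < min_per_country].index
    mask = df["country_id"].isin(small)
    tally.steps.append(("country with fewer than 100 babies", int(mask.sum())))
    df = df[~mask]

    logger.info("inclusion filters: %d -> %d rows", tally.initial, tally.final)
    return df.copy(), tally


def assign_income_tertiles(incomes) -> np.ndarray:
    """Household-income categories by tertile cut points.

    Cut points are the 1/3 and 2/3 quantiles of the non-missing values
    (linear interpolation); values exactly at a cut point fall in the lower
    category; missing values stay "missing".
    """
    values = np.asarray(pd.Series(incomes, dtype=float))
    out = np.full(values.shape, "missing", dtype=object)
    ok = np.isfinite(values)
    if ok.sum() == 0:
        return out
    q1, q2 = np.quantile(values[ok], [1 / 3, 2 / 3])
    out[ok] = "highest"
    out[ok & (values <= q2)] = "middle"
    out[ok & (values <= q1)] = "lowest"
    return out


def _model_fits(cohort: pd.DataFrame, settings: MCMCSettings,
                models=(1, 2, 3, 4, 5),
                random_levels=("country", "mother"),
                store_mother_chain=False,
                compute_dic=True) -> dict[str, FitResult]:
    fits = {}
    for number in models:
        spec = ModelSpec.model(number, random_levels=random_levels)
        logger.info("fitting model %d (seed %d)", number, settings.seed)
        fits[f"Model {number}"] = fit_gibbs(
            cohort, spec, settings, store_mother_chain=store_mother_chain,
            compute_dic=compute_dic)
    return fits


def run_model_sequence(cohort: pd.DataFrame, settings: MCMCSettings | None = None,
                       models=(1, 2, 3, 4, 5), compute_dic=True) -> StudyReport:
    """Fit the consecutive models and assemble the full study report.

    The first fitted model is the PCV reference; shrunken country effects
    are taken from it (the unadjusted league table).
    """
    settings = settings or MCMCSettings()
    settings.validate()
    fits = _model_fits(cohort, settings, models=models, compute_dic=compute_dic)
    labels = list(fits)
    components = {lab: fits[lab].variances for lab in labels}
    report = partition.partition_report(components, reference=labels[0])
    fixed_rows = []
    for lab in labels:
        fx = fits[lab].fixed.copy()
        fx.insert(0, "model", lab)
        fixed_rows.append(fx)
    shrunken = shrinkage.country_effects(fits[labels[0]])
    return StudyReport(fits=fits, fixed_effects=pd.concat(fixed_rows, ignore_index=True),
                       partition=report, shrunken=shrunken, tally=None,
                       settings=settings)


# ---------------------------------------------------------------------------
# sensitivity analyses

def sensitivity_drop_lowest(cohort: pd.DataFrame, k: int = 9,
                            settings: MCMCSettings | None = None,
                            base_fit: FitResult | None = None) -> pd.DataFrame:
    """Refit the empty model without the k lowest-ranked countries.

    Returns a partition table with the full-cohort empty model as the PCV
    reference; attrs carry the dropped country ids.
    """
    settings = settings or MCMCSettings()
    spec = ModelSpec.model(1)
    if base_fit is None:
        base_fit = fit_gibbs(cohort, spec, settings, compute_dic=False)
    effects = shrinkage.country_effects(base_fit)
    if k >= len(effects):
        raise ValueError("k must be smaller than the number of countries")
    dropped = list(effects.nsmallest(k, "rank")["country_id"]) if k else []
    reduced = cohort[~cohort["country_id"].isin(dropped)]
    refit = fit_gibbs(reduced, spec, settings, compute_dic=False)
    report = partition.partition_report(
        {"all countries": base_fit.variances,
         f"drop {k} lowest": refit.variances},
        reference="all countries")
    report.attrs["dropped_countries"] = dropped
    return report


def sensitivity_two_level_stature(stature: pd.DataFrame,
                                  settings: MCMCSettings | None = None) -> float:
    """Between-country clustering of continuous maternal stature, in percent.

    Fits the two-level empty model (mothers in countries) to a table with
    columns (mother_id, country_id, stature_cm) and returns
    100 * s2_country / (s2_country + s2_within).
    """
    settings = settings or MCMCSettings()
    spec = ModelSpec(fixed_terms=("intercept",), random_levels=("country",),
                     outcome="stature_cm")
    fit = fit_gibbs(stature, spec, settings, compute_dic=False)
    s2_c = fit.variances.sigma2_mcb
    return 100.0 * s2_c / (s2_c + fit.variances.sigma2_b)


def sensitivity_drop_mother_level(cohort: pd.DataFrame,
                                  settings: MCMCSettings | None = None) -> pd.DataFrame:
    """Empty model with and without the mother level, side by side.

    The two-level fit pools the mother and baby variance into its residual;
    the comparison shows how the country-level share responds.
    """
    settings = settings or MCMCSettings()
    fit3 = fit_gibbs(cohort, ModelSpec.model(1), settings, compute_dic=False)
    fit2 = fit_gibbs(cohort, ModelSpec.model(1, random_levels=("country",)),
                     settings, compute_dic=False)
    rows = {
        "three-level": [*fit3.variances.as_tuple(),
                        partition.vpc(fit3.variances)[0]],
        "two-level (no mother)": [*fit2.variances.as_tuple(),
                                  partition.vpc(fit2.variances)[0]],
    }
    return pd.DataFrame(rows, index=["sigma2_mcb", "sigma2_m", "sigma2_b", "vpc_mcb"])


def sensitivity_subsample_reference(cohort: pd.DataFrame, fraction: float,
                                    seed: int = 0,
                                    settings: MCMCSettings | None = None) -> pd.DataFrame:
    """Refit the empty model keeping only a random fraction of the dominant
    country's mothers (each mother kept or dropped with all her babies).

    Returns a partition table: full cohort vs subsampled cohort.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    settings = settings or MCMCSettings()
    counts = cohort["country_id"].value_counts()
    dominant = counts.index[0]
    if fraction == 1.0:
        sub = cohort
    else:
        rng = np.random.default_rng(seed)
        mothers = cohort.loc[cohort["country_id"] == dominant, "mother_id"].unique()
        keep = rng.random(mothers.size) < fraction
        kept = set(mothers[keep])
        sub = cohort[(cohort["country_id"] != dominant)
                     | cohort["mother_id"].isin(kept)]
    spec = ModelSpec.model(1)
    fit_full = fit_gibbs(cohort, spec, settings, compute_dic=False)
    fit_sub = fit_gibbs(sub, spec, settings, compute_dic=False)
    report = partition.partition_report(
        {"full cohort": fit_full.variances,
         f"{fraction:.0%} dominant-country mothers": fit_sub.variances},
        reference="full cohort")
    report.attrs["dominant_country"] = dominant
    report.attrs["n_babies_subsample"] = int(len(sub))
    return report


# ---------------------------------------------------------------------------
# planted-signal scenario

def planted_scenario_cohort(k: int = 9, shift: float = -250.0,
                            n_countries: int = 30, n_mothers: int = 30_000,
                            dominant_share: float = 0.5,
                            size_concentration: float = 100.0,
                            sigma2_country: float = 900.0,
                            seed: int = 0,
                            config: SynthConfig | None = None):
    """Cohort in which k non-dominant countries sit ``shift`` grams below
    the rest, on top of a reduced residual between-country variance.

    The non-dominant countries are near-equal in size (high size
    concentration) so that every planted country carries enough babies for
    its shrunken effect to stay close to the planted shift, and the residual
    between-country standard deviation (default 30 g) is kept small against
    the shift (>8 SD) so that exact rank recovery of the planted set is
    well-posed at truth level.
    Returns (cohort, planted_country_ids).  The planted countries are the
    last k country indices (never the dominant one).
    """
    cfg = config or default_config()
    cfg = cfg.replace(n_countries=n_countries, n_mothers=n_mothers,
                      dominant_country_share=dominant_share,
                      country_size_concentration=size_concentration,
                      true_variances=(sigma2_country,
                                      cfg.true_variances[1], cfg.true_variances[2]))
    planted = list(range(n_countries - k, n_countries))
    cohort = sample_cohort(cfg, seed=seed,
                           country_mean_shifts={i: shift for i in planted})
    width = len(str(max(n_countries - 1, 1)))
    planted_ids = [f"C{i:0{width}d}" for i in planted]
    return cohort, planted_ids
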