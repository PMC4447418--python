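"""Country-level shrunken effects and within-country distribution summaries.

The "league table" ranks countries by the posterior mean of their random
intercept v_k — the empirical-Bayes (shrunken) deviation of each country's
mean outcome from the grand mean.  Small countries are pulled towards zero
in proportion to their imprecision, so a noisy extreme mean does not top the
table.  Box-plot five-number summaries of the raw outcome serve as the
distribution-overlap companion view.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .lmm3 import FitResult

__all__ = ["country_effects", "league_table", "overlap_summary", "plot_league_table"]


def country_effects(fit: FitResult, level: tuple[float, float] = (2.5, 97.5)) -> pd.DataFrame:
    """Posterior-mean country deviations with equal-tailed intervals.

    Returns one row per country: country_id, n_babies, effect (grams),
    lower, upper (interval bounds in grams) and rank (1 = lowest effect,
    ties broken by country_id).
    """
    if "country_effects" not in fit.chains:
        raise ValueError("fit has no retained country-effect chain "
                         "(country level absent or chains not stored)")
    chain = fit.chains["country_effects"]
    labels = np.asarray(fit.meta["country_labels"])
    counts = np.asarray(fit.meta["n_per_country"])
    effect = chain.mean(axis=0)
    lower, upper = np.percentile(chain, level, axis=0)
    table = pd.DataFrame({
        "country_id": labels,
        "n_babies": counts,
        "effect": effect,
        "lower": lower,
        "upper": upper,
    })
    order = np.lexsort((labels, effect))
    ranks = np.empty(len(table), dtype=int)
    ranks[order] = np.arange(1, len(table) + 1)
    table["rank"] = ranks
    return table


def league_table(effects: pd.DataFrame) -> pd.DataFrame:
    """Effects sorted ascending (ties by country_id), flagging countries
    whose interval excludes zero."""
    out = effects.sort_values(["effect", "country_id"], kind="mergesort").reset_index(drop=True)
    out["interval_excludes_zero"] = (out["lower"] > 0) | (out["upper"] < 0)
    return out


def overlap_summary(cohort: pd.DataFrame, countries: Sequence[str],
                    outcome: str = "birthweight") -> pd.DataFrame:
    """Tukey five-number summaries of the outcome per listed country.

    Quartiles by linear interpolation; whiskers at the most extreme
    observations within 1.5 * IQR of the quartiles.
    """
    present = set(cohort["country_id"])
    rows = []
    for cid in countries:
        if cid not in present:
            raise ValueError(f"unknown country {cid!r}")
        values = np.asarray(
            cohort.loc[cohort["country_id"] == cid, outcome], dtype=float)
        q1, med, q3 = np.percentile(values, [25, 50, 75])
        iqr = q3 - q1
        in_fence = values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]
        rows.append({
            "country_id": cid,
            "n_babies": values.size,
            "whisker_low": float(in_fence.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "whisker_high": float(in_fence.max()),
        })
    return pd.DataFrame(rows)


def plot_league_table(effects: pd.DataFrame, ax=None):
    """Caterpillar plot of the shrunken effects (optional; needs matplotlib)."""
    import matplotlib.pyplot as plt

    table = league_table(effects)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.18 * len(table) + 1))
    y = np.arange(len(table))
    ax.errorbar(table["effect"], y,
                xerr=[table["effect"] - table["lower"],
                      table["upper"] - table["effect"]],
                fmt="o", ms=3, lw=1, capsize=2)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(y, table["country_id"])
    ax.set_xlabel("deviation from grand mean (g)")
    return ax
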