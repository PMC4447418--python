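"""Variance partitioning statistics for nested models: VPC, ICC and PCV.

VPC_level = 100 * s2_level / (s2_country + s2_mother + s2_baby) is the share
of total outcome variance at one level of the hierarchy.  The ICC at the
country level equals its VPC; at the mother level it is the variance at or
above the mother level over the total, i.e. the correlation between two
babies of the same mother.  The PCV is the relative change of a component
between a covariate-adjusted model and the empty (random-intercepts-only)
reference model.

Computations run at full precision; reported values are rounded to one
decimal, half away from zero, matching the usual tabular presentation.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .lmm3 import VarianceComponents

__all__ = ["vpc", "icc", "pcv", "partition_report", "write_report", "round1"]

_LEVELS = ("mcb", "mother", "newborn")


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (not banker's rounding)."""
    return float(np.sign(x) * np.floor(np.abs(x) * 10.0 + 0.5 + 1e-9) / 10.0)


def _components(vc: VarianceComponents | tuple) -> tuple[float, float, float]:
    if isinstance(vc, VarianceComponents):
        out = vc.as_tuple()
    else:
        out = tuple(float(x) for x in vc)
        if len(out) != 3:
            raise ValueError("expected a (country, mother, baby) variance triple")
    if any(x < 0 for x in out):
        raise ValueError("variance components must be non-negative")
    return out


def vpc(vc: VarianceComponents | tuple, decimals: int | None = 1):
    """(VPC_country, VPC_mother, VPC_baby) in percent.

    A two-level fit (absent component None) contributes 0 to the total;
    pass ``decimals=None`` for unrounded values.
    """
    s2 = _components(vc)
    total = sum(s2)
    if total <= 0:
        raise ValueError("VPC undefined: all variance components are zero")
    out = tuple(100.0 * x / total for x in s2)
    if decimals is None:
        return out
    return tuple(round1(x) for x in out)


def icc(vc: VarianceComponents | tuple, decimals: int | None = 1):
    """(ICC_country, ICC_mother) in percent.

    ICC_country is the country-level VPC; ICC_mother is the share of total
    variance at or above the mother level, the correlation in outcome
    between two babies of the same mother.
    """
    s2_c, s2_m, s2_b = _components(vc)
    total = s2_c + s2_m + s2_b
    if total <= 0:
        raise ValueError("ICC undefined: all variance components are zero")
    out = (100.0 * s2_c / total, 100.0 * (s2_c + s2_m) / total)
    if decimals is None:
        return out
    return tuple(round1(x) for x in out)


def pcv(vc_model: VarianceComponents | tuple,
        vc_reference: VarianceComponents | tuple,
        decimals: int | None = 1) -> dict[str, float]:
    """Proportional change in variance versus the reference (empty) model.

    Per level: 100 * (s2_model - s2_ref) / s2_ref; the "total" entry uses
    the summed components.  Requires strictly positive reference components.
    """
    model = _components(vc_model)
    ref = _components(vc_reference)
    if any(x <= 0 for x in ref):
        raise ValueError("PCV undefined: a reference component is zero")
    vals = {lvl: 100.0 * (m - r) / r for lvl, m, r in zip(_LEVELS, model, ref)}
    vals["total"] = 100.0 * (sum(model) - sum(ref)) / sum(ref)
    if decimals is None:
        return vals
    return {k: round1(v) for k, v in vals.items()}


def partition_report(components: Mapping[str, VarianceComponents],
                     reference: str | None = None,
                     decimals: int | None = 1) -> pd.DataFrame:
    """Assemble the full variance-partition table across models.

    Rows are statistics (components, total, VPC, ICC, PCV), columns are
    model labels in insertion order; the PCV row of the reference model
    (first label by default) is zero by definition.
    """
    labels = list(components)
    if not labels:
        raise ValueError("no models given")
    reference = reference if reference is not None else labels[0]
    if reference not in components:
        raise ValueError(f"reference {reference!r} not among models")
    rows = ["sigma2_mcb", "sigma2_m", "sigma2_b", "sigma2_total",
            "vpc_mcb", "vpc_m", "vpc_b", "icc_mcb", "icc_m",
            "pcv_mcb", "pcv_m", "pcv_b", "pcv_total"]
    data = {}
    ref_vc = components[reference]
    for label in labels:
        vc = components[label]
        s2 = _components(vc)
        v = vpc(vc, decimals=decimals)
        ic = icc(vc, decimals=decimals)
        if label == reference:
            p = {lvl: 0.0 for lvl in (*_LEVELS, "total")}
        else:
            p = pcv(vc, ref_vc, decimals=decimals)
        data[label] = [s2[0], s2[1], s2[2], sum(s2), *v, *ic,
                       p["mcb"], p["mother"], p["newborn"], p["total"]]
    report = pd.DataFrame(data, index=rows)
    report.attrs["reference"] = reference
    return report


def write_report(report: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write the partition table as delimiter-separated text."""
    report.to_csv(path, sep=sep, index_label="statistic")
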