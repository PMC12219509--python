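"""Cooperativity (dddG) profiling and burial-stratified slope statistics.

A point mutation is made in two double-biotin backgrounds, probing the
stability of the N- and C-subdomains separately.  The differential
destabilization

    dddG = ddG^N - ddG^C

measures how localized the perturbation is: a residue whose mutation
destabilizes both subdomains equally (|dddG| <= RT) participates in a
cooperatively coupled network; larger |dddG| localizes the interaction
to one subdomain.  Cutoffs are multiples of the thermal energy RT
(0.59 kcal/mol at 24.5 C, printed as 0.6):

* standard scheme: boundaries at +-RT and +-2RT,
* narrow scheme:   boundaries at +-RT/2 and +-RT.

The "cooperative" interval is closed ([-RT, +RT]); outer classes are
half-open so every finite dddG maps to exactly one label.

Mutational ddG correlations between environments are compared with
ordinary least squares, and equality of slopes across burial classes is
tested with Chow's F test:

    F = [(S_C - (S_1 + S_2)) / k] / [(S_1 + S_2) / (N_1 + N_2 - 2k)]

with k = 2 regression coefficients (slope and intercept) per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InputError
from .thermo import ROOM_CONTEXT, ThermoContext

__all__ = [
    "CooperativityClass",
    "BurialClass",
    "CooperativityCall",
    "SlopeFit",
    "SlopeComparison",
    "compute_dddg",
    "classify_cooperativity",
    "burial_class",
    "slope_regression",
    "chow_test",
    "profile_panel",
]


class CooperativityClass(str, Enum):
    LOCALIZED_N = "localized_N"
    MODERATELY_LOCALIZED_N = "moderately_localized_N"
    COOPERATIVE = "cooperative"
    MODERATELY_LOCALIZED_C = "moderately_localized_C"
    LOCALIZED_C = "localized_C"


class BurialClass(str, Enum):
    BURIED = "buried"
    PARTIALLY_BURIED = "partially_buried"
    EXPOSED = "exposed"


@dataclass
class CooperativityCall:
    """A residue's dddG with its five-way class label."""

    mutation: str
    dddg: float               # kcal/mol
    se: float                 # kcal/mol
    label: CooperativityClass
    scheme: str               # "standard" or "narrow"


@dataclass
class SlopeFit:
    slope: float
    intercept: float
    pearson_r: float
    sse: float
    n: int


@dataclass
class SlopeComparison:
    """Chow's test result for two groups' regressions."""

    group_labels: tuple
    fits: tuple               # (SlopeFit, SlopeFit)
    chow_f: float             # nan when degenerate
    chow_p: float             # nan when degenerate
    dof: tuple                # (k, N1 + N2 - 2k)
    degenerate: bool = False


def compute_dddg(ddg_n: float, ddg_c: float, se_n: float = 0.0, se_c: float = 0.0):
    """dddG = ddG^N - ddG^C with quadrature-combined standard error."""
    for v, name in ((ddg_n, "ddg_n"), (ddg_c, "ddg_c")):
        if v is None or not np.isfinite(v):
            raise InputError(f"{name} missing or non-finite")
    return ddg_n - ddg_c, math.hypot(se_n, se_c)


_SCHEMES = {
    # scheme -> (inner cutoff, outer cutoff) as multiples of RT
    "standard": (1.0, 2.0),
    "narrow": (0.5, 1.0),
}


def classify_cooperativity(
    dddg: float,
    context: ThermoContext = ROOM_CONTEXT,
    scheme: str = "standard",
    rt: float | None = None,
) -> CooperativityClass:
    """Assign the five-way cooperativity label.

    ``rt`` overrides the context thermal energy (e.g. the rounded
    0.6 kcal/mol used in figure legends).  The cooperative interval is
    inclusive at both ends; the moderate classes are half-open outward.
    """
    if dddg is None or not np.isfinite(dddg):
        raise InputError("dddg must be finite")
    if scheme not in _SCHEMES:
        raise InputError(f"unknown scheme {scheme!r}")
    thermal = context.rt if rt is None else rt
    inner, outer = (m * thermal for m in _SCHEMES[scheme])

    if -inner <= dddg <= inner:
        return CooperativityClass.COOPERATIVE
    if inner < dddg <= outer:
        return CooperativityClass.MODERATELY_LOCALIZED_N
    if dddg > outer:
        return CooperativityClass.LOCALIZED_N
    if -outer <= dddg < -inner:
        return CooperativityClass.MODERATELY_LOCALIZED_C
    return CooperativityClass.LOCALIZED_C


def burial_class(f_asa: float) -> BurialClass:
    """Classify residue burial from the fractional solvent-accessible area.

    f_ASA = 0 -> buried; 0 < f_ASA <= 0.1 -> partially buried;
    f_ASA > 0.1 -> exposed.
    """
    if f_asa is None or not np.isfinite(f_asa) or not 0.0 <= f_asa <= 1.0:
        raise InputError(f"f_asa must be within [0, 1], got {f_asa}")
    if f_asa == 0.0:
        return BurialClass.BURIED
    if f_asa <= 0.1:
        return BurialClass.PARTIALLY_BURIED
    return BurialClass.EXPOSED


def slope_regression(x, y) -> SlopeFit:
    """Ordinary least squares of y on x with Pearson r and residual SSE."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InputError("need >= 3 paired finite points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("values must be finite")
    if np.ptp(x) == 0:
        raise DegenerateInputError("zero variance in x")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        sse=float(np.sum(resid**2)),
        n=x.size,
    )


def chow_test(group1, group2, labels=("group1", "group2")) -> SlopeComparison:
    """Chow's test for equality of two regressions (slope + intercept, k = 2).

    ``group1``/``group2`` are (x, y) pairs.  Perfectly collinear groups
    (S_1 + S_2 = 0) make F undefined; the result is flagged degenerate
    with NaN statistics rather than an arbitrary number.
    """
    (x1, y1), (x2, y2) = group1, group2
    fit1 = slope_regression(x1, y1)
    fit2 = slope_regression(x2, y2)
    xc = np.concatenate([np.asarray(x1, float), np.asarray(x2, float)])
    yc = np.concatenate([np.asarray(y1, float), np.asarray(y2, float)])
    res = stats.linregress(xc, yc)
    s_c = float(np.sum((yc - (res.slope * xc + res.intercept)) ** 2))

    k = 2
    n1, n2 = fit1.n, fit2.n
    dof2 = n1 + n2 - 2 * k
    pooled = fit1.sse + fit2.sse
    if pooled == 0.0:
        return SlopeComparison(
            group_labels=tuple(labels), fits=(fit1, fit2),
            chow_f=math.nan, chow_p=math.nan, dof=(k, dof2), degenerate=True,
        )
    f_stat = ((s_c - pooled) / k) / (pooled / dof2)
    p = float(stats.f.sf(f_stat, k, dof2))
    return SlopeComparison(
        group_labels=tuple(labels), fits=(fit1, fit2),
        chow_f=float(f_stat), chow_p=p, dof=(k, dof2),
    )


def profile_panel(
    panel: pd.DataFrame,
    context: ThermoContext = ROOM_CONTEXT,
    scheme: str = "standard",
    rt: float | None = None,
) -> pd.DataFrame:
    """Compute dddG and the class label for every row of a mutant panel.

    Expects columns ``mutation, ddg_N, se_N, ddg_C, se_C`` (``f_asa`` and
    ``environment`` carried through when present).  Returns a DataFrame
    with ``dddg``, ``se`` and ``label`` columns appended.
    """
    required = {"mutation", "ddg_N", "ddg_C"}
    missing = required - set(panel.columns)
    if missing:
        raise InputError(f"panel missing columns: {sorted(missing)}")
    out = panel.copy()
    dddg, se, label = [], [], []
    for _, row in panel.iterrows():
        d, s = compute_dddg(row["ddg_N"], row["ddg_C"],
                            row.get("se_N", 0.0), row.get("se_C", 0.0))
        dddg.append(d)
        se.append(s)
        label.append(classify_cooperativity(d, context, scheme, rt).value)
    out["dddg"] = dddg
    out["se"] = se
    out["label"] = label
    out["scheme"] = scheme
    return out
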