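"""Chronological-lifespan quantification for yeast deletion strains.

Stationary-phase survival is recorded as viability fractions over days
(day 0 through a 22-day horizon; the wild type is fully dead by day 22).
A strain's lifespan outcome is summarized as *relative survival*: the mean
area under its viability-vs-day curve as a percentage of the wild-type
mean.  Strains fall into five categories relative to wild type —

    strongly_reduced    < 50%
    slightly_reduced    50% .. < 85%
    not_affected        85% .. 115%   (wild type +/- 15%)
    slightly_increased  > 115% .. 150%
    strongly_increased  > 150%

Boundary percentages are attached to the band nearer wild type.  Replicate
AUCs are compared to wild type with a two-sided pooled-variance Student
t-test; stars mark p < 0.05 (*), < 0.01 (**), < 0.001 (***).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SurvivalTable

__all__ = [
    "CATEGORIES",
    "DEFAULT_HORIZON",
    "curve_auc",
    "replicate_aucs",
    "relative_survival",
    "categorize",
    "compare_to_wildtype",
    "LifespanCall",
    "lifespan_calls",
    "screen_report",
]

DEFAULT_HORIZON = 22.0

CATEGORIES = (
    "strongly_reduced",
    "slightly_reduced",
    "not_affected",
    "slightly_increased",
    "strongly_increased",
)


def curve_auc(days: Sequence[float], viability: Sequence[float], horizon: float) -> float:
    """Trapezoid area under one viability curve on [0, horizon].

    The curve must span the horizon; if it extends past it, the value at
    the horizon is obtained by linear interpolation (equivalent to the
    trapezoid rule on any refinement of the grid).
    """
    d = np.asarray(days, dtype=float)
    v = np.asarray(viability, dtype=float)
    if d.ndim != 1 or d.shape != v.shape:
        raise ValueError("days and viability must be equal-length 1-D")
    if np.any(np.diff(d) <= 0):
        raise ValueError("days must be strictly increasing")
    if d[0] != 0:
        raise ValueError("curve must start at day 0")
    if d[-1] < horizon:
        raise ValueError(f"curve ends at day {d[-1]}, before the horizon {horizon}")
    mask = d <= horizon
    dd = d[mask]
    vv = v[mask]
    if dd[-1] < horizon:
        v_h = float(np.interp(horizon, d, v))
        dd = np.append(dd, horizon)
        vv = np.append(vv, v_h)
    return float(np.trapezoid(vv, dd))


def replicate_aucs(
    table: SurvivalTable, strain: str, horizon: float = DEFAULT_HORIZON
) -> np.ndarray:
    """AUC per replicate curve of one strain, in replicate order."""
    curves = table.curves(strain)
    return np.array(
        [curve_auc(c["day"], c["viability"], horizon) for c in curves.values()]
    )


def relative_survival(
    mutant_aucs: Sequence[float], wildtype_aucs: Sequence[float]
) -> float:
    """Mean mutant AUC as a percentage of the mean wild-type AUC."""
    mut = np.asarray(mutant_aucs, dtype=float)
    wt = np.asarray(wildtype_aucs, dtype=float)
    if len(mut) == 0 or len(wt) == 0:
        raise ValueError("need at least one replicate per strain")
    if wt.mean() <= 0:
        raise ValueError("wild-type AUC is zero; relative survival undefined")
    return float(100.0 * mut.mean() / wt.mean())


def categorize(relative_percent: float) -> str:
    """Assign the five-band lifespan category for a relative-survival percent.

    Bands: [0, 50) -> strongly_reduced, [50, 85) -> slightly_reduced,
    [85, 115] -> not_affected, (115, 150] -> slightly_increased,
    (150, inf) -> strongly_increased.
    """
    x = float(relative_percent)
    if x < 0:
        raise ValueError(f"relative survival must be >= 0, got {x}")
    if x < 50:
        return "strongly_reduced"
    if x < 85:
        return "slightly_reduced"
    if x <= 115:
        return "not_affected"
    if x <= 150:
        return "slightly_increased"
    return "strongly_increased"


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_to_wildtype(
    mutant_aucs: Sequence[float], wildtype_aucs: Sequence[float]
) -> tuple[float, float, str]:
    """Two-sided pooled-variance t-test of replicate AUCs vs wild type.

    Returns (t statistic, p-value, star string).  Identical degenerate
    groups yield t = 0, p = 1.
    """
    mut = np.asarray(mutant_aucs, dtype=float)
    wt = np.asarray(wildtype_aucs, dtype=float)
    if len(mut) < 2 or len(wt) < 2:
        raise ValueError("need >= 2 replicates per strain for the t-test")
    t, p = stats.ttest_ind(mut, wt, equal_var=True)
    if np.isnan(t):  # zero variance in both groups, equal means
        t, p = 0.0, 1.0
    return float(t), float(p), _stars(float(p))


@dataclass
class LifespanCall:
    """One strain's screen outcome relative to wild type."""

    strain_id: str
    relative_survival: float
    category: str
    t: float
    p: float
    stars: str


def lifespan_calls(
    table: SurvivalTable,
    wildtype: str = "WT",
    horizon: float = DEFAULT_HORIZON,
) -> pd.DataFrame:
    """Relative survival, category, and t-test per non-wild-type strain.

    Returns a frame with columns strain_id, relative_survival, category,
    t, p, stars, ordered by strain id.
    """
    if wildtype not in table.strains:
        raise ValueError(f"wild-type strain {wildtype!r} absent from the table")
    wt_aucs = replicate_aucs(table, wildtype, horizon)
    if wt_aucs.mean() <= 0:
        raise ValueError("wild-type AUC is zero")
    rows = []
    for strain in sorted(s for s in table.strains if s != wildtype):
        aucs = replicate_aucs(table, strain, horizon)
        rel = relative_survival(aucs, wt_aucs)
        if len(aucs) >= 2 and len(wt_aucs) >= 2:
            t, p, stars = compare_to_wildtype(aucs, wt_aucs)
        else:
            t, p, stars = float("nan"), float("nan"), ""
        rows.append((strain, rel, categorize(rel), t, p, stars))
    return pd.DataFrame(
        rows, columns=["strain_id", "relative_survival", "category", "t", "p", "stars"]
    )


def screen_report(calls: pd.DataFrame) -> dict:
    """Group lifespan calls by category (alphabetical within category).

    Returns ``{"categories": {name: [strains]}, "counts": {name: int},
    "total": int}`` with all five categories always present.
    """
    cats: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for _, row in calls.iterrows():
        cats[row["category"]].append(row["strain_id"])
    for c in cats:
        cats[c] = sorted(cats[c])
    counts = {c: len(v) for c, v in cats.items()}
    return {"categories": cats, "counts": counts, "total": sum(counts.values())}
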