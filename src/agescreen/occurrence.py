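"""Value-counting core: fold-change calls, occurrence tables, selection rules.

The meta-analysis avoids replicate-aware differential-expression models
entirely.  Each of the 35 treated/control pairs is evaluated on its own: a
probe set is called up- or down-regulated in a comparison when the linear
fold change crosses a symmetric threshold (default 1.5-fold, inclusive), and
the number of comparisons in which each probe set is called — its
*occurrence* k — is the ranking statistic.  Supporting utilities cover
probe-to-gene collapsing, average-linkage sample clustering, and the
regression concordance check used to validate arrays against qPCR.

Signed-fold convention: a ratio r = treated/control is reported as r when
r >= 1 and as -1/r otherwise, so the up and down thresholds are the
symmetric pair +/-1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist
from scipy import stats

from .io import ComparisonDesign, ExpressionMatrix, FormatError, ProbeGeneMap, GROUPS

__all__ = [
    "FoldChangeCalls",
    "OccurrenceTable",
    "SelectionRule",
    "fold_change_calls",
    "count_occurrences",
    "collapse_to_genes",
    "apply_selection",
    "majority_cutoff",
    "cluster_samples",
    "linkage_to_newick",
    "concordance",
    "ConcordanceResult",
]

DEFAULT_FOLD_THRESHOLD = 1.5
DEFAULT_EPS = 1e-6


@dataclass
class FoldChangeCalls:
    """Per (probe, comparison) signed folds and up/down/unchanged calls.

    ``signed_fold`` and ``calls`` are probes-x-comparisons frames; calls are
    coded +1 (up), -1 (down), 0 (unchanged).
    """

    signed_fold: pd.DataFrame
    calls: pd.DataFrame
    threshold: float

    def de_mask(self) -> pd.DataFrame:
        """Boolean probes-x-comparisons mask of DE in either direction."""
        return self.calls != 0


def fold_change_calls(
    matrix: ExpressionMatrix,
    design: ComparisonDesign,
    threshold: float = DEFAULT_FOLD_THRESHOLD,
    eps: float = DEFAULT_EPS,
) -> FoldChangeCalls:
    """Call up/down/unchanged per (probe, comparison) on linear intensities.

    Both numerator and denominator are clamped below by ``eps`` so that
    synthetic zeros cannot divide by zero.  The threshold is inclusive:
    a signed fold of exactly +1.5 is an "up" call.
    """
    if threshold < 1:
        raise ValueError(f"fold threshold must be >= 1, got {threshold}")
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    design.validate_against(matrix)

    vals = matrix.values
    treated = vals[list(design.table["treated"])].to_numpy(dtype=float)
    control = vals[list(design.table["control"])].to_numpy(dtype=float)
    ratio = np.maximum(treated, eps) / np.maximum(control, eps)
    signed = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    calls = np.zeros(signed.shape, dtype=np.int8)
    calls[signed >= threshold] = 1
    calls[signed <= -threshold] = -1

    cols = design.comparison_ids
    idx = matrix.values.index
    return FoldChangeCalls(
        signed_fold=pd.DataFrame(signed, index=idx, columns=cols),
        calls=pd.DataFrame(calls, index=idx, columns=cols),
        threshold=float(threshold),
    )


@dataclass
class OccurrenceTable:
    """Per-id occurrence counts: EG1 up/down, EG2 up/down, totals.

    ``table`` columns: eg1_up, eg1_down, eg2_up, eg2_down, eg1_total,
    eg2_total, combined_total; the index holds probe (or gene) identifiers.
    ``n_per_group`` records the number of comparisons per group (the symbol
    n of the cumulative-binomial model).
    """

    table: pd.DataFrame
    n_per_group: dict[str, int]
    level: Literal["probe", "gene"] = "probe"

    def __post_init__(self) -> None:
        for g in GROUPS:
            lg = g.lower()
            tot = self.table[f"{lg}_up"] + self.table[f"{lg}_down"]
            n = self.n_per_group[g]
            if ((tot < 0) | (tot > n)).any():
                raise ValueError(f"{g} up+down counts outside [0, n={n}]")

    def sorted_by_occurrence(self) -> pd.DataFrame:
        """Rows ranked by combined occurrence, descending (stable)."""
        return self.table.sort_values(
            "combined_total", ascending=False, kind="stable"
        )


def count_occurrences(calls: FoldChangeCalls, design: ComparisonDesign) -> OccurrenceTable:
    """Count up/down calls per probe within each experimental group."""
    if calls.calls.columns.duplicated().any():
        dup = calls.calls.columns[calls.calls.columns.duplicated()][0]
        raise ValueError(f"duplicate call column for comparison {dup!r}")
    missing = set(design.comparison_ids) - set(calls.calls.columns)
    if missing:
        raise ValueError(f"calls missing comparisons {sorted(missing)[:5]}")

    out: dict[str, np.ndarray] = {}
    n_per_group: dict[str, int] = {}
    for g in GROUPS:
        ids = list(design.table.loc[design.table["group"] == g, "comparison_id"])
        n_per_group[g] = len(ids)
        sub = calls.calls[ids].to_numpy() if ids else np.zeros((len(calls.calls), 0), dtype=np.int8)
        out[f"{g.lower()}_up"] = (sub > 0).sum(axis=1)
        out[f"{g.lower()}_down"] = (sub < 0).sum(axis=1)
    table = pd.DataFrame(out, index=calls.calls.index)
    for g in GROUPS:
        lg = g.lower()
        table[f"{lg}_total"] = table[f"{lg}_up"] + table[f"{lg}_down"]
    table["combined_total"] = table["eg1_total"] + table["eg2_total"]
    return OccurrenceTable(table, n_per_group, level="probe")


def collapse_to_genes(
    table: OccurrenceTable,
    pmap: ProbeGeneMap | None,
    policy: Literal["max", "best_probe"] = "max",
) -> OccurrenceTable:
    """Collapse a probe-level table to gene level.

    ``max`` (default): each gene's count in every column is the maximum over
    its probes, totals recomputed from the collapsed up/down counts.
    ``best_probe``: each gene inherits the whole row of its highest-combined
    probe (first probe in input order on ties).  Probes absent from the map
    pass through under their own identifier.
    """
    if policy not in ("max", "best_probe"):
        raise ValueError(f"unknown collapse policy {policy!r}")
    if pmap is None or len(pmap.pairs) == 0:
        import warnings

        warnings.warn("empty probe-gene map: identity collapse", stacklevel=2)
        return OccurrenceTable(table.table.copy(), dict(table.n_per_group), level="gene")

    gene_of = pmap.gene_of()
    count_cols = ["eg1_up", "eg1_down", "eg2_up", "eg2_down"]
    rows: dict[str, list[str]] = {}  # gene -> probe ids
    for probe in table.table.index:
        for gene in gene_of.get(probe, [probe]):
            rows.setdefault(gene, []).append(probe)

    records = {}
    for gene, probes in rows.items():
        sub = table.table.loc[probes]
        if policy == "max":
            rec = {c: int(sub[c].max()) for c in count_cols}
        else:  # best_probe
            best = sub["combined_total"].to_numpy().argmax()
            rec = {c: int(sub.iloc[best][c]) for c in count_cols}
        records[gene] = rec
    out = pd.DataFrame.from_dict(records, orient="index")[count_cols]
    for g in GROUPS:
        lg = g.lower()
        out[f"{lg}_total"] = out[f"{lg}_up"] + out[f"{lg}_down"]
    out["combined_total"] = out["eg1_total"] + out["eg2_total"]
    return OccurrenceTable(out, dict(table.n_per_group), level="gene")


def majority_cutoff(n: int) -> int:
    """Smallest count that is strictly more than half of n: floor(n/2) + 1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return n // 2 + 1


@dataclass
class SelectionRule:
    """A candidate-selection rule over an occurrence table.

    kinds:
      * ``per_group_majority`` — occurrence in > 50% of a group's
        comparisons (cutoff floor(n/2)+1; n=17 -> 9, n=18 -> 10);
        ``group`` may be "EG1", "EG2" or "any" (union).
      * ``combined_at_least`` — combined occurrence >= threshold
        (default 18 of 35).
      * ``screen_at_least`` — occurrence >= threshold (default 6) in either
        group; the broad funnel feeding the orthology arm.
    """

    kind: Literal["per_group_majority", "combined_at_least", "screen_at_least"]
    threshold: int | None = None
    group: Literal["EG1", "EG2", "any"] = "any"


def apply_selection(
    table: OccurrenceTable, rule: SelectionRule, design: ComparisonDesign
) -> list[str]:
    """Return ids selected by a rule, in table order."""
    df = table.table
    if rule.kind == "per_group_majority":
        groups = list(GROUPS) if rule.group == "any" else [rule.group]
        mask = pd.Series(False, index=df.index)
        for g in groups:
            n = design.n_group(g)
            if n == 0:
                continue
            mask |= df[f"{g.lower()}_total"] >= majority_cutoff(n)
    elif rule.kind == "combined_at_least":
        t = 18 if rule.threshold is None else int(rule.threshold)
        if t > design.n_total:
            raise ValueError(f"threshold {t} exceeds total comparisons {design.n_total}")
        mask = df["combined_total"] >= t
    elif rule.kind == "screen_at_least":
        t = 6 if rule.threshold is None else int(rule.threshold)
        if t > max(design.n_eg1, design.n_eg2):
            raise ValueError(f"threshold {t} exceeds both group sizes")
        mask = (df["eg1_total"] >= t) | (df["eg2_total"] >= t)
    else:  # pragma: no cover
        raise ValueError(f"unknown rule kind {rule.kind!r}")
    return list(df.index[mask])


# ---------------------------------------------------------------------------
# Clustering and concordance utilities
# ---------------------------------------------------------------------------

def cluster_samples(
    matrix: ExpressionMatrix, top_k_by_variance: int = 20_000
) -> tuple[np.ndarray, list[str]]:
    """Average-linkage (UPGMA) clustering of samples on Euclidean distances.

    Probes are first filtered to the ``top_k_by_variance`` most variable
    (ties broken by input order); returns the scipy linkage matrix and the
    leaf (sample) labels.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if top_k_by_variance < 1:
        raise ValueError("top_k_by_variance must be >= 1")
    vals = matrix.values
    k = min(top_k_by_variance, vals.shape[0])
    variances = vals.var(axis=1, ddof=0).to_numpy()
    # stable sort keeps input order among variance ties
    order = np.argsort(-variances, kind="stable")[:k]
    sub = vals.iloc[np.sort(order)]
    dist = pdist(sub.to_numpy().T, metric="euclidean")
    Z = linkage(dist, method="average")
    return Z, matrix.sample_ids


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(Z)

    def _recurse(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = _recurse(node.left, node.dist)
        right = _recurse(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    root = f"({_recurse(tree.left, tree.dist)},{_recurse(tree.right, tree.dist)});"
    return root


@dataclass
class ConcordanceResult:
    """OLS concordance between paired measurement series.

    ``n_within`` of ``n_total`` points sit inside the 95% prediction band of
    the fitted line — the report format used to validate array fold changes
    against qPCR.
    """

    r: float
    slope: float
    intercept: float
    n_within: int
    n_total: int

    def __str__(self) -> str:  # e.g. "r = 0.68, 362 of 380 within the 95% PI"
        return (
            f"r = {self.r:.2f}, {self.n_within} of {self.n_total} pairs "
            f"within the 95% prediction interval"
        )


def concordance(x: Sequence[float], y: Sequence[float]) -> ConcordanceResult:
    """OLS fit of y on x with Pearson r and 95% prediction-band coverage."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")

    fit = stats.linregress(x, y)
    yhat = fit.intercept + fit.slope * x
    resid = y - yhat
    df = n - 2
    s = np.sqrt(np.sum(resid**2) / df) if df > 0 else 0.0
    xbar = x.mean()
    sxx = np.sum((x - xbar) ** 2)
    se_pred = s * np.sqrt(1.0 + 1.0 / n + (x - xbar) ** 2 / sxx)
    tcrit = stats.t.ppf(0.975, df)
    within = int(np.sum(np.abs(resid) <= tcrit * se_pred))
    return ConcordanceResult(
        r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_within=within,
        n_total=n,
    )
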