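"""Significance model for recurrent differential expression.

The null hypothesis for a probe set is that its DE calls across the n
comparisons of a group are independent Bernoulli trials with a background
success probability p, estimated from the data as the mean per-comparison
fraction of the probe universe called DE.  The p-value is the upper tail of
the binomial — the probability of being called DE at least as often as
observed (the cumulative binomial distribution, CBD):

    P(K >= k) = sum_{i=k}^{n} C(n, i) p^i (1 - p)^(n - i)

q-values follow Storey's FDR estimator with the bootstrap choice of the
pi0 tuning parameter lambda and the "robust" small-p correction.  Pathway
enrichment of candidate lists is a one-sided Fisher exact
(hypergeometric-tail) test against the full probe universe (54,675 probe
sets by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .io import ComparisonDesign, GeneSetCollection, GROUPS
from .occurrence import FoldChangeCalls, OccurrenceTable

__all__ = [
    "BackgroundRate",
    "estimate_background",
    "cbd_pvalue",
    "storey_qvalues",
    "QValueResult",
    "infer_occurrence_table",
    "fisher_enrichment",
    "EnrichmentResult",
    "DEFAULT_UNIVERSE_SIZE",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_UNIVERSE_SIZE = 54_675
# 0.00-0.90 in 0.05 steps: the classical default grid of Storey's q-value
# software; stopping at 0.90 keeps the variance of pi0(lambda) in check.
DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 0.901, 0.05), 2))
DEFAULT_BOOTSTRAP = 100


@dataclass
class BackgroundRate:
    """Background probability that any probe set is DE in one comparison.

    ``p`` is the arithmetic mean over a group's comparisons of (DE probe
    sets in the comparison) / (probe universe size m).
    """

    group: str
    p: float
    per_comparison_fractions: tuple[float, ...]
    m: int


def estimate_background(
    calls: FoldChangeCalls, design: ComparisonDesign, group: str, m: int | None = None
) -> BackgroundRate:
    """Estimate the per-comparison DE probability for one group.

    ``m`` defaults to the number of probes carried by ``calls``; pass the
    full array universe (e.g. 54,675) when the call matrix is a subset.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    ids = list(design.table.loc[design.table["group"] == group, "comparison_id"])
    if not ids:
        raise ValueError(f"no comparisons in group {group}")
    if m is None:
        m = calls.calls.shape[0]
    de_counts = (calls.calls[ids] != 0).sum(axis=0).to_numpy()
    if m < de_counts.max():
        raise ValueError(f"universe size m={m} smaller than a per-comparison DE count")
    fractions = de_counts / m
    return BackgroundRate(
        group=group,
        p=float(fractions.mean()),
        per_comparison_fractions=tuple(float(f) for f in fractions),
        m=int(m),
    )


def cbd_pvalue(k: int, n: int, p: float) -> float:
    """Upper-tail binomial probability P(K >= k) for K ~ Binomial(n, p).

    Computed by log-space accumulation of the exact term series, so it is
    stable out to n ~ 1e4 and for tail probabilities far below float
    underflow of individual factors.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if k == 0:
        return 1.0
    if p == 0.0:
        return 0.0 if k > 0 else 1.0
    if p == 1.0:
        return 1.0
    i = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
        + i * np.log(p) + (n - i) * np.log1p(-p)
    )
    return float(min(1.0, np.exp(logsumexp(log_terms))))


@dataclass
class QValueResult:
    """Storey q-values with the pi0 estimate and its tuning trace."""

    qvalues: np.ndarray
    pi0: float
    lambda_star: float
    pi0_by_lambda: dict[float, float]
    robust: bool
    n_bootstrap: int


def storey_qvalues(
    pvals: Sequence[float],
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    robust: bool = True,
    seed: int | np.random.Generator | None = 0,
    pi0: float | None = None,
) -> QValueResult:
    """Storey FDR q-values with bootstrap selection of the pi0 parameter.

    pi0 is estimated as #{p_i > lambda} / (m (1 - lambda)) on a grid of
    lambda values; the grid point minimizing the bootstrap-estimated MSE of
    pi0 (against the minimum pi0 over the grid, B resamples) is chosen.
    The i-th ranked p-value receives q_(i) = min_{j >= i} pi0 * m * p_(j) / j;
    with ``robust`` the denominator j becomes j * (1 - (1 - p_(j))^m), which
    tightens the estimate for very small p.  ``pi0`` may be supplied
    explicitly to bypass estimation.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    grid = np.asarray(sorted(set(float(l) for l in lambda_grid)))
    if np.any((grid < 0) | (grid >= 1)):
        raise ValueError("lambda grid must lie in [0, 1)")

    pi0_by_lambda = {
        float(lam): float(min(1.0, np.sum(p > lam) / (m * (1.0 - lam)))) for lam in grid
    }
    if pi0 is not None:
        pi0_hat = float(pi0)
        lam_star = float("nan")
    elif len(grid) == 1:
        lam_star = float(grid[0])
        pi0_hat = pi0_by_lambda[lam_star]
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        min_pi0 = min(pi0_by_lambda.values())
        mse = np.zeros(len(grid))
        for _ in range(int(n_bootstrap)):
            pb = rng.choice(p, size=m, replace=True)
            counts = np.array([np.sum(pb > lam) for lam in grid])
            pi0_b = np.minimum(1.0, counts / (m * (1.0 - grid)))
            mse += (pi0_b - min_pi0) ** 2
        lam_star = float(grid[int(np.argmin(mse))])
        pi0_hat = pi0_by_lambda[lam_star]
    if pi0_hat <= 0:
        pi0_hat = min(pi0_by_lambda.values()) or 1.0 / m
    pi0_hat = float(min(1.0, max(pi0_hat, 1.0 / m)))

    order = np.argsort(p, kind="stable")
    ranked = p[order]
    ranks = np.arange(1, m + 1, dtype=float)
    if robust:
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = ranks * -np.expm1(m * np.log1p(-ranked))
        denom[~np.isfinite(denom) | (denom <= 0)] = np.finfo(float).tiny  # p in {0, 1} edges
    else:
        denom = ranks
    raw = pi0_hat * m * ranked / denom
    q_ranked = np.minimum.accumulate(raw[::-1])[::-1]
    q_ranked = np.minimum(q_ranked, 1.0)
    q = np.empty(m)
    q[order] = q_ranked
    return QValueResult(
        qvalues=q,
        pi0=pi0_hat,
        lambda_star=lam_star,
        pi0_by_lambda=pi0_by_lambda,
        robust=bool(robust),
        n_bootstrap=int(n_bootstrap),
    )


def infer_occurrence_table(
    table: OccurrenceTable,
    design: ComparisonDesign,
    backgrounds: dict[str, BackgroundRate],
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    robust: bool = True,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Attach per-group CBD p-values and Storey q-values to an occurrence table.

    For each group, k is the probe's total occurrence in that group (up +
    down) and n the group's comparison count.  Returns a copy of the table
    with ``<group>_cbd_p`` and ``<group>_q`` columns.
    """
    out = table.table.copy()
    rng = np.random.default_rng(seed)
    for g in GROUPS:
        lg = g.lower()
        n = design.n_group(g)
        if n == 0:
            continue
        bg = backgrounds[g]
        k = out[f"{lg}_total"].to_numpy()
        unique_p = {int(kk): cbd_pvalue(int(kk), n, bg.p) for kk in np.unique(k)}
        pvals = np.array([unique_p[int(kk)] for kk in k])
        out[f"{lg}_cbd_p"] = pvals
        res = storey_qvalues(
            pvals, lambda_grid=lambda_grid, n_bootstrap=n_bootstrap,
            robust=robust, seed=rng,
        )
        out[f"{lg}_q"] = res.qvalues
    return out


@dataclass
class EnrichmentResult:
    """One-sided Fisher exact enrichment of a candidate list in one gene set."""

    set_name: str
    overlap: int
    candidates: int
    set_size: int
    universe: int
    p: float

    @property
    def significant_05(self) -> bool:
        return self.p < 0.05

    @property
    def significant_001(self) -> bool:
        return self.p < 0.001


def fisher_enrichment(
    candidates: Iterable[str],
    sets: GeneSetCollection,
    universe_size: int = DEFAULT_UNIVERSE_SIZE,
) -> list[EnrichmentResult]:
    """Fisher exact (hypergeometric upper-tail) enrichment per gene set.

    ``universe_size`` is the size of the identifier universe both the
    candidate list and the sets are drawn from — the full probe universe
    (54,675) when testing probe-level lists.  Results are sorted by p
    ascending, ties by set name.
    """
    cand = set(candidates)
    n_cand = len(cand)
    if n_cand > universe_size:
        raise ValueError("candidate list larger than the universe")
    results = []
    for name, members in sets.items():
        memb = set(members)
        set_size = len(memb)
        if set_size > universe_size:
            raise ValueError(f"gene set {name!r} larger than the universe")
        overlap = len(cand & memb)
        if overlap > min(n_cand, set_size):  # pragma: no cover - defensive
            raise ValueError("overlap bookkeeping inconsistent")
        # P(X >= overlap), X ~ Hypergeom(M=universe, n=set_size, N=n_cand)
        p = float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, n_cand))
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap=overlap,
                candidates=n_cand,
                set_size=set_size,
                universe=universe_size,
                p=min(1.0, p),
            )
        )
    results.sort(key=lambda r: (r.p, r.set_name))
    return results
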