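"""Human-to-yeast ortholog assignment by reciprocal best hit (RBH).

A human gene and a yeast gene form an ortholog pair when each is the other's
unique highest-scoring partner in a cross-species similarity table.  Ties
for a best hit yield no call by default (the pipeline wants *the* closest
homologous pair); a lexicographic tie-break is available behind a flag.
Pairs whose yeast member is essential for viability are removed before the
lifespan screen, since deletion strains cannot be grown for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "rbh_orthologs",
    "filter_nonessential",
    "candidate_to_ortholog_pipeline",
    "OrthologFunnel",
    "similarity_from_sequences",
]


def _best_hits(
    df: pd.DataFrame, by: str, other: str, tie_break: str
) -> dict[str, str]:
    """id -> its unique best partner (ties dropped or broken lexically)."""
    best: dict[str, str] = {}
    for key, grp in df.groupby(by, sort=False):
        scores = grp["score"].to_numpy()
        top = scores.max()
        winners = sorted(grp.loc[grp["score"] == top, other])
        if len(winners) == 1 or tie_break == "lexicographic":
            best[key] = winners[0]
        # tie_break == "none": ambiguous best hit -> no call for this id
    return best


def rbh_orthologs(
    similarity: pd.DataFrame,
    tie_break: Literal["none", "lexicographic"] = "none",
) -> pd.DataFrame:
    """Reciprocal-best-hit pairs from a (human_id, yeast_id, score) table.

    Returns a frame with columns human_id, yeast_id, score sorted by
    human_id.  A pair is emitted iff the yeast gene is the human gene's
    unique best hit and vice versa (unless ``tie_break`` resolves ties
    lexicographically).
    """
    if len(similarity) == 0:
        raise ValueError("empty similarity table")
    if similarity["score"].isna().any() or not np.all(np.isfinite(similarity["score"])):
        raise ValueError("similarity table contains NaN/non-finite scores")
    best_y = _best_hits(similarity, "human_id", "yeast_id", tie_break)
    best_h = _best_hits(similarity, "yeast_id", "human_id", tie_break)
    score_of = {
        (h, y): s
        for h, y, s in zip(similarity["human_id"], similarity["yeast_id"], similarity["score"])
    }
    pairs = [
        (h, y, score_of[(h, y)])
        for h, y in best_y.items()
        if best_h.get(y) == h
    ]
    out = pd.DataFrame(pairs, columns=["human_id", "yeast_id", "score"])
    return out.sort_values("human_id", kind="stable").reset_index(drop=True)


def filter_nonessential(pairs: pd.DataFrame, essential: Iterable[str]) -> pd.DataFrame:
    """Drop pairs whose yeast gene appears in the essential-gene list."""
    essential = set(essential)
    keep = ~pairs["yeast_id"].isin(essential)
    return pairs[keep].reset_index(drop=True)


@dataclass
class OrthologFunnel:
    """Per-stage counts of the candidate -> ortholog -> nonessential funnel."""

    n_candidates: int
    n_with_ortholog: int
    n_nonessential: int
    pairs: pd.DataFrame

    def stages(self) -> dict[str, int]:
        return {
            "candidate_genes": self.n_candidates,
            "yeast_orthologs": self.n_with_ortholog,
            "nonessential_yeast_orthologs": self.n_nonessential,
        }

    def __str__(self) -> str:
        return (
            f"{self.n_candidates} candidate genes -> "
            f"{self.n_with_ortholog} yeast orthologs -> "
            f"{self.n_nonessential} nonessential yeast orthologs"
        )


def candidate_to_ortholog_pipeline(
    selected_human_ids: Sequence[str],
    similarity: pd.DataFrame,
    essential: Iterable[str],
    tie_break: Literal["none", "lexicographic"] = "none",
) -> OrthologFunnel:
    """Selection -> RBH -> essentiality filter, with per-stage counts.

    The funnel mirrors the screen's right arm: human candidate genes, the
    subset with a reciprocal-best-hit yeast ortholog, and the nonessential
    orthologs that can actually be put through a deletion-strain lifespan
    assay.
    """
    selected = list(dict.fromkeys(selected_human_ids))
    if not selected:
        return OrthologFunnel(0, 0, 0, pd.DataFrame(columns=["human_id", "yeast_id", "score"]))
    sub = similarity[similarity["human_id"].isin(set(selected))]
    if len(sub) == 0:
        pairs = pd.DataFrame(columns=["human_id", "yeast_id", "score"])
    else:
        pairs = rbh_orthologs(sub, tie_break=tie_break)
    surviving = filter_nonessential(pairs, essential)
    return OrthologFunnel(
        n_candidates=len(selected),
        n_with_ortholog=len(pairs),
        n_nonessential=len(surviving),
        pairs=surviving,
    )


def similarity_from_sequences(
    human_seqs: dict[str, str],
    yeast_seqs: dict[str, str],
    match: float = 2.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> pd.DataFrame:
    """Score all cross-species pairs by local alignment (toy worlds only).

    Smith-Waterman local alignment with simple match/mismatch scoring and a
    linear gap penalty, so synthetic ortholog worlds can be generated from
    short protein sequences.  Not intended for real proteomes.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    rows = []
    for h, hs in human_seqs.items():
        for y, ys in yeast_seqs.items():
            rows.append((h, y, float(aligner.score(hs, ys))))
    return pd.DataFrame(rows, columns=["human_id", "yeast_id", "score"])
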