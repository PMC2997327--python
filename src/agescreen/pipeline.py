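"""End-to-end orchestration of the two-armed screening workflow.

Left arm: fold-change calls -> occurrence counting -> cumulative-binomial
inference with Storey FDR -> candidate selection -> pathway enrichment.
Right arm: broad screen selection -> gene collapse -> reciprocal-best-hit
orthology -> essentiality filter -> chronological-lifespan categorization.

Every output TSV carries a provenance header (package version, seed, config
hash), and a machine-readable JSON run summary with the per-stage funnel
counts is written alongside.  Reruns with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .io import (
    ComparisonDesign,
    ExpressionMatrix,
    GeneSetCollection,
    ProbeGeneMap,
    SurvivalTable,
    read_design,
    read_essential_list,
    read_expression_matrix,
    read_gmt,
    read_probe_gene_map,
    read_similarity,
    read_survival,
    write_table,
)
from .inference import (
    DEFAULT_LAMBDA_GRID,
    DEFAULT_UNIVERSE_SIZE,
    estimate_background,
    fisher_enrichment,
    infer_occurrence_table,
)
from .lifespan import DEFAULT_HORIZON, lifespan_calls, screen_report
from .occurrence import (
    DEFAULT_FOLD_THRESHOLD,
    SelectionRule,
    apply_selection,
    collapse_to_genes,
    count_occurrences,
    fold_change_calls,
)
from .orthology import candidate_to_ortholog_pipeline

__all__ = ["PipelineConfig", "PipelineResult", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    Optional inputs (gene sets, similarity, essentials, survival) switch
    their stages off when absent.
    """

    matrix: str
    design: str
    probe_gene_map: str | None = None
    gene_sets: str | None = None
    similarity: str | None = None
    essential: str | None = None
    survival: str | None = None
    out_dir: str = "results"

    fold_threshold: float = DEFAULT_FOLD_THRESHOLD
    majority_group: str = "any"
    combined_threshold: int = 18
    screen_threshold: int = 6
    universe_size: int = DEFAULT_UNIVERSE_SIZE
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    n_bootstrap: int = 100
    robust: bool = True
    orthology_tie_break: str = "none"
    lifespan_horizon: float = DEFAULT_HORIZON
    wildtype: str = "WT"
    seed: int = 0

    def config_hash(self) -> str:
        """Hash of the analysis parameters (file locations excluded)."""
        params = asdict(self)
        for key in ("matrix", "design", "probe_gene_map", "gene_sets",
                    "similarity", "essential", "survival", "out_dir"):
            params.pop(key, None)
        blob = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    occurrence: pd.DataFrame
    inference: pd.DataFrame
    selected_majority: list[str]
    selected_combined: list[str]
    selected_screen: list[str]
    enrichment: pd.DataFrame | None
    funnel: dict[str, int]
    lifespan: pd.DataFrame | None
    summary: dict[str, Any]


def _header(cfg: PipelineConfig) -> list[str]:
    return [
        f"agescreen {__version__}",
        f"seed {cfg.seed}",
        f"config {cfg.config_hash()}",
    ]


def run_full_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute both arms of the workflow and write all result tables."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = _header(cfg)

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    with stage("read inputs"):
        matrix = read_expression_matrix(cfg.matrix)
        design = read_design(cfg.design)
        design.validate_against(matrix)
        pmap: ProbeGeneMap | None = (
            read_probe_gene_map(cfg.probe_gene_map) if cfg.probe_gene_map else None
        )
        gene_sets: GeneSetCollection | None = (
            read_gmt(cfg.gene_sets) if cfg.gene_sets else None
        )
        similarity = read_similarity(cfg.similarity) if cfg.similarity else None
        essential = read_essential_list(cfg.essential) if cfg.essential else set()
        survival: SurvivalTable | None = (
            read_survival(cfg.survival) if cfg.survival else None
        )

    with stage("occurrence"):
        calls = fold_change_calls(matrix, design, threshold=cfg.fold_threshold)
        occ = count_occurrences(calls, design)
        occ_sorted = occ.sorted_by_occurrence()
        write_table(
            occ_sorted, out / "occurrence.tsv", header=header,
            index=True, index_label="id",
        )

    with stage("inference"):
        backgrounds = {
            g: estimate_background(calls, design, g, m=None)
            for g in ("EG1", "EG2")
            if design.n_group(g) > 0
        }
        inferred = infer_occurrence_table(
            occ, design, backgrounds,
            lambda_grid=cfg.lambda_grid, n_bootstrap=cfg.n_bootstrap,
            robust=cfg.robust, seed=cfg.seed,
        )
        write_table(
            inferred.sort_values("combined_total", ascending=False, kind="stable"),
            out / "inference.tsv", header=header, index=True, index_label="id",
        )

    with stage("selection"):
        sel_major = apply_selection(
            occ, SelectionRule("per_group_majority", group=cfg.majority_group), design
        )
        sel_comb = apply_selection(
            occ, SelectionRule("combined_at_least", threshold=cfg.combined_threshold), design
        )
        gene_table = collapse_to_genes(occ, pmap) if pmap else occ
        sel_screen = apply_selection(
            gene_table, SelectionRule("screen_at_least", threshold=cfg.screen_threshold), design
        )
        for name, ids in (
            ("selected_majority", sel_major),
            ("selected_combined", sel_comb),
            ("selected_screen", sel_screen),
        ):
            write_table(pd.DataFrame({"id": ids}), out / f"{name}.tsv", header=header)

    enrichment_df = None
    if gene_sets is not None:
        with stage("enrichment"):
            cand = sel_major
            if pmap is not None:
                gene_of = pmap.gene_of()
                cand = sorted({g for p in sel_major for g in gene_of.get(p, [p])})
            results = fisher_enrichment(cand, gene_sets, universe_size=cfg.universe_size)
            enrichment_df = pd.DataFrame(
                [
                    {
                        "set": r.set_name,
                        "overlap": r.overlap,
                        "candidates": r.candidates,
                        "set_size": r.set_size,
                        "universe": r.universe,
                        "p": r.p,
                        "significant_05": r.significant_05,
                        "significant_001": r.significant_001,
                    }
                    for r in results
                ]
            )
            write_table(enrichment_df, out / "enrichment.tsv", header=header)

    funnel: dict[str, int] = {
        "comparisons": design.n_total,
        "probes": matrix.shape[0],
        "selected_majority": len(sel_major),
        "selected_combined": len(sel_comb),
        "screen_candidates": len(sel_screen),
    }
    lifespan_df = None
    if similarity is not None:
        with stage("orthology"):
            orth = candidate_to_ortholog_pipeline(
                sel_screen, similarity, essential, tie_break=cfg.orthology_tie_break
            )
            funnel.update(orth.stages())
            write_table(orth.pairs, out / "orthologs.tsv", header=header)
        if survival is not None:
            with stage("lifespan"):
                calls_df = lifespan_calls(
                    survival, wildtype=cfg.wildtype, horizon=cfg.lifespan_horizon
                )
                screen_strains = set(orth.pairs["yeast_id"])
                calls_df = calls_df[calls_df["strain_id"].isin(screen_strains)].reset_index(
                    drop=True
                )
                write_table(calls_df, out / "lifespan.tsv", header=header)
                report = screen_report(calls_df)
                funnel["lifespan_strains"] = report["total"]
                lifespan_df = calls_df

    config_dump = asdict(cfg)
    config_dump.pop("out_dir", None)  # location of results, not an analysis choice
    summary: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": config_dump,
        "funnel": funnel,
        "backgrounds": {g: b.p for g, b in backgrounds.items()},
    }
    if lifespan_df is not None:
        summary["lifespan_categories"] = screen_report(lifespan_df)["counts"]
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n", encoding="utf-8"
    )

    return PipelineResult(
        occurrence=occ_sorted,
        inference=inferred,
        selected_majority=sel_major,
        selected_combined=sel_comb,
        selected_screen=sel_screen,
        enrichment=enrichment_df,
        funnel=funnel,
        lifespan=lifespan_df,
        summary=summary,
    )
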