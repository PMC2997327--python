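"""Seeded synthetic worlds for exercising the whole pipeline.

The generator emulates the structure of the original screen: two
experimental groups of treated/control array pairs (17 oxidative-stress and
18 cellular-aging comparisons over 47 baseline arrays by default), a probe
universe with a minority of planted "conserved aging" genes that respond in
a configurable fraction of comparisons, a toy two-species ortholog world
with essentiality labels, and noisy chronological-lifespan survival curves
with known category labels.  Every draw flows from one explicit seed through
a documented generator-splitting scheme (``numpy`` ``SeedSequence.spawn``:
child 0 expression, child 1 ortholog world, child 2 survival, child 3 gene
sets), so regenerating with the same seed and parameters is bit-exact.

Noise models:

* expression — multiplicative log-normal noise on treated intensities
  (standard microarray error model); the default sd of 0.25 on the natural
  log scale puts ~10% of probes past the 1.5-fold threshold per comparison,
  matching the study-scale background rates (0.11/0.12);
* survival — additive Gaussian noise on viability, clipped to [0, 1];
  day-0 points and fully dead (viability 0) points are left exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import (
    ComparisonDesign,
    ExpressionMatrix,
    GeneSetCollection,
    ProbeGeneMap,
    SurvivalTable,
)
from .lifespan import CATEGORIES, curve_auc
from .reference import STUDY_CONTROL_ARRAYS, STUDY_GROUP_SIZES

__all__ = [
    "DesignSpec",
    "PlantedSpec",
    "PlantedTruth",
    "ExpressionWorld",
    "SyntheticWorld",
    "gen_expression",
    "gen_ortholog_world",
    "gen_survival",
    "gen_world",
    "CATEGORY_TARGETS",
]


@dataclass
class DesignSpec:
    """Shape of the comparison design to emulate.

    Defaults mirror the study: 17 EG1 (oxidative stress) and 18 EG2
    (cellular aging) treated/control pairs drawn over 47 control/baseline
    arrays spread across six cell models.  Controls are shared between
    comparisons (each comparison pairs a fresh treated array with one of
    its model's control arrays, cycling).
    """

    n_eg1: int = STUDY_GROUP_SIZES["EG1"]
    n_eg2: int = STUDY_GROUP_SIZES["EG2"]
    controls_per_model: Mapping[str, int] = field(
        default_factory=lambda: dict(STUDY_CONTROL_ARRAYS)
    )

    @property
    def n_controls(self) -> int:
        return sum(self.controls_per_model.values())

    @property
    def n_total(self) -> int:
        return self.n_eg1 + self.n_eg2


@dataclass
class PlantedSpec:
    """Ground-truth effect specification for the planted gene set.

    ``fold`` f >= 1 is the multiplicative effect; ``penetrance`` phi in
    (0, 1] is the fraction of each group's comparisons showing it (the
    effect is planted in exactly ceil(phi * n) comparisons per group);
    ``direction`` is up, down, or mixed (drawn per gene and comparison).
    """

    n_genes: int = 0
    fold: float = 3.0
    penetrance: float = 0.8
    direction: Literal["up", "down", "mixed"] = "mixed"

    def __post_init__(self) -> None:
        if self.n_genes > 0:
            if self.fold < 1:
                raise ValueError(f"fold must be >= 1, got {self.fold}")
            if not 0 < self.penetrance <= 1:
                raise ValueError(
                    f"penetrance must be in (0, 1], got {self.penetrance}"
                )
            if self.direction not in ("up", "down", "mixed"):
                raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class PlantedTruth:
    """Which genes carry effects, where, and in which direction.

    ``effects`` is a genes-x-comparisons frame of {+1, -1, 0} giving the
    planted direction per comparison (0 = no effect there).
    """

    gene_ids: list[str]
    spec: PlantedSpec
    effects: pd.DataFrame

    def active_count(self, gene: str, comparison_ids: Sequence[str]) -> int:
        return int((self.effects.loc[gene, list(comparison_ids)] != 0).sum())


@dataclass
class ExpressionWorld:
    matrix: ExpressionMatrix
    design: ComparisonDesign
    truth: PlantedTruth
    probe_gene_map: ProbeGeneMap


def _gene_probe_layout(m_probes: int, probes_per_gene: int) -> pd.DataFrame:
    """Assign probe ids to gene ids, ``probes_per_gene`` probes per gene."""
    n_genes = math.ceil(m_probes / probes_per_gene)
    width_p = max(6, len(str(m_probes)))
    width_g = max(5, len(str(n_genes)))
    rows = []
    for i in range(m_probes):
        gene = i // probes_per_gene
        rows.append((f"P{i + 1:0{width_p}d}", f"G{gene + 1:0{width_g}d}"))
    return pd.DataFrame(rows, columns=["probe_id", "gene_symbol"])


def gen_expression(
    m_probes: int,
    design_spec: DesignSpec | None = None,
    planted_spec: PlantedSpec | None = None,
    noise_sd: float = 0.25,
    seed: int | np.random.Generator = 0,
    probes_per_gene: int = 2,
    baseline_log_mean: float = math.log(100.0),
    baseline_log_sd: float = 1.0,
    discordant_probes: bool = False,
) -> ExpressionWorld:
    """Generate a matrix, design, probe->gene map and planted truth.

    Control intensities are log-normal per (probe, control array).  Each
    treated array copies its paired control column, applies the planted
    fold to planted genes in their active comparisons, and multiplies
    log-normal noise (sd ``noise_sd`` on the log scale) onto every cell.
    With ``noise_sd = 0`` the treated/control ratio of an unaffected probe
    is exactly 1 and of a planted probe exactly the fold.

    ``discordant_probes`` leaves the last probe of each multi-probe planted
    gene unaffected, to exercise gene-collapse policies.
    """
    if m_probes < 1:
        raise ValueError("m_probes must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    design_spec = design_spec or DesignSpec()
    planted_spec = planted_spec or PlantedSpec(n_genes=0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    layout = _gene_probe_layout(m_probes, probes_per_gene)
    gene_ids = list(dict.fromkeys(layout["gene_symbol"]))
    if planted_spec.n_genes > len(gene_ids):
        raise ValueError(
            f"cannot plant {planted_spec.n_genes} genes into {len(gene_ids)} genes "
            f"({m_probes} probes)"
        )

    # --- design -----------------------------------------------------------
    models = list(design_spec.controls_per_model)
    control_ids: list[str] = []
    control_model: dict[str, list[str]] = {m: [] for m in models}
    for model in models:
        for j in range(design_spec.controls_per_model[model]):
            cid = f"C_{model}_{j + 1:02d}"
            control_ids.append(cid)
            control_model[model].append(cid)
    if not control_ids:
        raise ValueError("design needs at least one control array")

    rows = []
    used_per_model: dict[str, int] = {m: 0 for m in models}
    for group, n_group in (("EG1", design_spec.n_eg1), ("EG2", design_spec.n_eg2)):
        for i in range(n_group):
            model = models[i % len(models)]
            pool = control_model[model] or control_ids
            ctrl = pool[used_per_model[model] % len(pool)]
            used_per_model[model] += 1
            cid = f"{group}_{i + 1:02d}"
            rows.append((cid, group, f"T_{cid}", ctrl, model))
    design = ComparisonDesign(
        pd.DataFrame(rows, columns=["comparison_id", "group", "treated", "control", "model"])
    )

    # --- planted truth ----------------------------------------------------
    planted_genes = (
        sorted(rng.choice(gene_ids, size=planted_spec.n_genes, replace=False))
        if planted_spec.n_genes
        else []
    )
    effects = pd.DataFrame(
        0, index=pd.Index(planted_genes, name="gene"), columns=design.comparison_ids,
        dtype=np.int8,
    )
    for group in ("EG1", "EG2"):
        ids = list(design.table.loc[design.table["group"] == group, "comparison_id"])
        n = len(ids)
        if n == 0:
            continue
        n_active = math.ceil(planted_spec.penetrance * n)
        for gene in planted_genes:
            active = rng.choice(ids, size=n_active, replace=False)
            if planted_spec.direction == "up":
                signs = np.ones(n_active, dtype=np.int8)
            elif planted_spec.direction == "down":
                signs = -np.ones(n_active, dtype=np.int8)
            else:
                signs = rng.choice(np.array([-1, 1], dtype=np.int8), size=n_active)
            effects.loc[gene, active] = signs
    truth = PlantedTruth(gene_ids=list(planted_genes), spec=planted_spec, effects=effects)

    # --- intensities ------------------------------------------------------
    probe_index = pd.Index(layout["probe_id"], name="probe_id")
    controls = np.exp(
        rng.normal(baseline_log_mean, baseline_log_sd, size=(m_probes, len(control_ids)))
    )
    columns: dict[str, np.ndarray] = {
        cid: controls[:, j] for j, cid in enumerate(control_ids)
    }

    probe_rows_of_gene: dict[str, np.ndarray] = {}
    probe_pos = {p: i for i, p in enumerate(layout["probe_id"])}
    for gene, grp in layout.groupby("gene_symbol", sort=False):
        probe_rows_of_gene[gene] = np.array([probe_pos[p] for p in grp["probe_id"]])

    fold = planted_spec.fold
    for _, row in design.table.iterrows():
        base = columns[row["control"]].copy()
        for gene in planted_genes:
            sign = int(effects.loc[gene, row["comparison_id"]])
            if sign == 0:
                continue
            idx = probe_rows_of_gene[gene]
            if discordant_probes and len(idx) > 1:
                idx = idx[:-1]
            base[idx] *= fold if sign > 0 else 1.0 / fold
        if noise_sd > 0:
            base *= np.exp(rng.normal(0.0, noise_sd, size=m_probes))
        columns[row["treated"]] = base

    matrix = ExpressionMatrix(pd.DataFrame(columns, index=probe_index))
    return ExpressionWorld(
        matrix=matrix, design=design, truth=truth, probe_gene_map=ProbeGeneMap(layout)
    )


# ---------------------------------------------------------------------------
# Ortholog world
# ---------------------------------------------------------------------------

def gen_ortholog_world(
    n_human: int,
    n_yeast: int,
    n_true_pairs: int,
    essential_fraction: float = 0.2,
    score_noise: float = 0.0,
    seed: int | np.random.Generator = 0,
    human_ids: Sequence[str] | None = None,
    decoys_per_gene: int = 3,
    true_pair_humans: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str], pd.DataFrame]:
    """Similarity table, essential-gene list and true ortholog pairs.

    True pairs score ~100; decoy edges score in [10, 60] and are always
    incident to a true-paired gene, so with ``score_noise = 0`` reciprocal
    best hit recovers exactly the true pairs (recall and precision 1).  A
    ``essential_fraction`` of yeast genes is flagged essential.
    """
    if n_true_pairs > min(n_human, n_yeast):
        raise ValueError("n_true_pairs exceeds min(n_human, n_yeast)")
    if not 0.0 <= essential_fraction <= 1.0:
        raise ValueError(f"essential_fraction must be in [0, 1], got {essential_fraction}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    humans = list(human_ids) if human_ids is not None else [
        f"H{i + 1:05d}" for i in range(n_human)
    ]
    if len(humans) != n_human:
        raise ValueError("human_ids length must equal n_human")
    yeasts = [f"Y{i + 1:05d}" for i in range(n_yeast)]

    if true_pair_humans is not None:
        pair_humans = list(true_pair_humans)
        if len(pair_humans) != n_true_pairs:
            raise ValueError("true_pair_humans length must equal n_true_pairs")
    else:
        pair_humans = list(rng.choice(humans, size=n_true_pairs, replace=False))
    pair_yeasts = list(rng.choice(yeasts, size=n_true_pairs, replace=False))

    edges: dict[tuple[str, str], float] = {}
    true_rows = []
    for h, y in zip(pair_humans, pair_yeasts):
        edges[(h, y)] = 100.0 + rng.uniform(0.0, 5.0)
        true_rows.append((h, y))
    # decoy edges, always touching a true-paired gene on at least one side
    for h in pair_humans:
        others = [y for y in yeasts if (h, y) not in edges]
        if others:
            k = min(decoys_per_gene, len(others))
            for y in rng.choice(others, size=k, replace=False):
                edges[(h, y)] = rng.uniform(10.0, 60.0)
    unpaired_humans = [h for h in humans if h not in set(pair_humans)]
    for h in unpaired_humans:
        if pair_yeasts:
            k = min(decoys_per_gene, len(pair_yeasts))
            for y in rng.choice(pair_yeasts, size=k, replace=False):
                if (h, y) not in edges:
                    edges[(h, y)] = rng.uniform(10.0, 60.0)

    sim = pd.DataFrame(
        [(h, y, s) for (h, y), s in edges.items()],
        columns=["human_id", "yeast_id", "score"],
    )
    if score_noise > 0:
        sim["score"] = sim["score"] + rng.normal(0.0, score_noise, size=len(sim))
    sim = sim.sort_values(["human_id", "yeast_id"], kind="stable").reset_index(drop=True)

    n_essential = int(round(essential_fraction * n_yeast))
    essential = sorted(rng.choice(yeasts, size=n_essential, replace=False))
    true_pairs = pd.DataFrame(true_rows, columns=["human_id", "yeast_id"]).sort_values(
        "human_id", kind="stable"
    ).reset_index(drop=True)
    return sim, essential, true_pairs


# ---------------------------------------------------------------------------
# Survival curves
# ---------------------------------------------------------------------------

# Band-interior relative-survival targets used when only a category is given
CATEGORY_TARGETS = {
    "strongly_reduced": 35.0,
    "slightly_reduced": 70.0,
    "not_affected": 100.0,
    "slightly_increased": 130.0,
    "strongly_increased": 160.0,
}

_WT_MIDPOINT = 11.0  # day of half-maximal viability (mean lifespan)
_WT_SHAPE = 2.0      # logistic steepness, days
_HORIZON = 22.0


def _wildtype_viability(t: np.ndarray) -> np.ndarray:
    """Declining sigmoid: exactly 1 at day 0 and 0 at day 22, midpoint ~11."""
    s = 1.0 / (1.0 + np.exp((np.asarray(t, dtype=float) - _WT_MIDPOINT) / _WT_SHAPE))
    s0 = 1.0 / (1.0 + np.exp(-_WT_MIDPOINT / _WT_SHAPE))
    s22 = 1.0 / (1.0 + np.exp((_HORIZON - _WT_MIDPOINT) / _WT_SHAPE))
    return (s - s22) / (s0 - s22)


def _stretched_viability(t: np.ndarray, stretch: float) -> np.ndarray:
    """Time-stretched wild-type curve; values past day 22/stretch are 0."""
    u = np.asarray(t, dtype=float) / stretch
    v = np.where(u <= _HORIZON, _wildtype_viability(np.minimum(u, _HORIZON)), 0.0)
    return np.clip(v, 0.0, 1.0)


def _stretch_for_target(target_percent: float, days: np.ndarray) -> float:
    """Stretch factor whose noiseless AUC ratio to wild type hits the target."""
    wt_auc = curve_auc(days, _wildtype_viability(days), _HORIZON)

    def ratio(c: float) -> float:
        return curve_auc(days, _stretched_viability(days, c), _HORIZON) / wt_auc

    goal = target_percent / 100.0
    lo, hi = 1e-3, 1.0
    while ratio(hi) < goal:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError(f"target {target_percent}% unreachable by time stretch")
    return float(brentq(lambda c: ratio(c) - goal, lo, hi, xtol=1e-10))


def gen_survival(
    categories_per_strain: Mapping[str, str | float],
    replicates: int = 3,
    days: Sequence[float] = tuple(range(0, 23, 2)),
    noise_sd: float = 0.02,
    seed: int | np.random.Generator = 0,
    wildtype: str = "WT",
    max_retries: int = 10,
) -> tuple[SurvivalTable, dict[str, str]]:
    """Survival curves with known lifespan categories.

    ``categories_per_strain`` maps strain id to either a category name or a
    numeric relative-survival target in percent.  The wild type (declining
    sigmoid, viability 1 at day 0 and 0 at day 22) is always included under
    ``wildtype``.  Mutant curves are time-stretched copies of the wild-type
    curve whose noiseless AUC ratio matches the target; Gaussian noise
    (sd ``noise_sd``) is added to viabilities, clipped to [0, 1], leaving
    day-0 and fully dead points exact.  After noise, the realized category
    is re-checked against the target; strains falling outside their band
    are re-drawn up to ``max_retries`` times.

    Returns the table and the true category per strain (wild type included
    as ``not_affected``).
    """
    d = np.asarray(sorted(set(float(x) for x in days)))
    if d[0] != 0:
        raise ValueError("days must include 0")
    if d[-1] < _HORIZON:
        raise ValueError(f"days must extend to at least {_HORIZON}")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    targets: dict[str, float] = {}
    true_category: dict[str, str] = {wildtype: "not_affected"}
    for strain, spec in categories_per_strain.items():
        if strain == wildtype:
            raise ValueError(f"{wildtype!r} is reserved for the wild type")
        if isinstance(spec, str):
            if spec not in CATEGORY_TARGETS:
                raise ValueError(f"unknown category {spec!r} for strain {strain!r}")
            targets[strain] = CATEGORY_TARGETS[spec]
            true_category[strain] = spec
        else:
            targets[strain] = float(spec)
            from .lifespan import categorize

            true_category[strain] = categorize(float(spec))

    wt_clean = _wildtype_viability(d)
    wt_auc = curve_auc(d, wt_clean, _HORIZON)

    def noisy(clean: np.ndarray) -> np.ndarray:
        if noise_sd == 0:
            return clean.copy()
        out = clean + rng.normal(0.0, noise_sd, size=len(clean))
        out = np.clip(out, 0.0, 1.0)
        out[0] = clean[0]          # plating is normalized to day 0
        out[clean == 0.0] = 0.0    # dead cultures stay dead
        return out

    records: list[tuple[str, str, float, float]] = []

    # wild type first; its replicate AUCs anchor every relative call
    wt_reps = [noisy(wt_clean) for _ in range(replicates)]
    for r, curve in enumerate(wt_reps, 1):
        records += [(wildtype, f"R{r}", day, v) for day, v in zip(d, curve)]
    wt_rep_aucs = np.array([curve_auc(d, c, _HORIZON) for c in wt_reps])
    wt_mean_auc = wt_rep_aucs.mean()
    if wt_mean_auc <= 0:
        raise ValueError("wild-type AUC degenerated to zero under noise")

    from .lifespan import categorize as _categorize

    for strain, target in targets.items():
        stretch = _stretch_for_target(target, d)
        clean = _stretched_viability(d, stretch)
        want = true_category[strain]
        for attempt in range(max_retries + 1):
            reps = [noisy(clean) for _ in range(replicates)]
            aucs = np.array([curve_auc(d, c, _HORIZON) for c in reps])
            realized = _categorize(100.0 * aucs.mean() / wt_mean_auc)
            if realized == want:
                break
        else:  # pragma: no cover - only reachable at extreme noise
            raise ValueError(
                f"could not realize category {want!r} for strain {strain!r} "
                f"at noise_sd={noise_sd} after {max_retries} retries"
            )
        for r, curve in enumerate(reps, 1):
            records += [(strain, f"R{r}", day, v) for day, v in zip(d, curve)]

    table = SurvivalTable(
        pd.DataFrame(records, columns=["strain_id", "replicate_id", "day", "viability"])
    )
    return table, true_category


# ---------------------------------------------------------------------------
# Full synthetic world
# ---------------------------------------------------------------------------

@dataclass
class SyntheticWorld:
    """Everything the end-to-end pipeline consumes, plus its ground truth."""

    matrix: ExpressionMatrix
    design: ComparisonDesign
    probe_gene_map: ProbeGeneMap
    truth: PlantedTruth
    gene_sets: GeneSetCollection
    similarity: pd.DataFrame
    essential: list[str]
    true_pairs: pd.DataFrame
    survival: SurvivalTable
    survival_truth: dict[str, str]
    seed: int


def gen_world(
    seed: int = 0,
    m_probes: int = 2_000,
    n_planted: int = 40,
    fold: float = 3.0,
    penetrance: float = 0.8,
    noise_sd: float = 0.25,
    design_spec: DesignSpec | None = None,
    probes_per_gene: int = 2,
    ortholog_fraction: float = 0.5,
    essential_fraction: float = 0.2,
    score_noise: float = 0.0,
    survival_noise_sd: float = 0.02,
    survival_replicates: int = 3,
    n_decoy_sets: int = 5,
) -> SyntheticWorld:
    """One coherent synthetic study with ground truth at every stage.

    The ortholog world is built over the expression gene universe, with the
    planted genes guaranteed a true yeast partner so the right-arm funnel
    (selection -> RBH -> nonessential -> lifespan) has substance.  Survival
    curves are generated for the nonessential yeast orthologs of planted
    genes, with categories cycling through all five bands.
    """
    ss = np.random.SeedSequence(seed)
    rng_expr, rng_orth, rng_surv, rng_sets = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    expr = gen_expression(
        m_probes=m_probes,
        design_spec=design_spec,
        planted_spec=PlantedSpec(
            n_genes=n_planted, fold=fold, penetrance=penetrance, direction="mixed"
        ),
        noise_sd=noise_sd,
        seed=rng_expr,
        probes_per_gene=probes_per_gene,
    )

    gene_ids = list(dict.fromkeys(expr.probe_gene_map.pairs["gene_symbol"]))
    n_true = max(n_planted, int(round(ortholog_fraction * len(gene_ids))))
    n_true = min(n_true, len(gene_ids))
    non_planted = [g for g in gene_ids if g not in set(expr.truth.gene_ids)]
    extra = list(
        rng_orth.choice(non_planted, size=n_true - n_planted, replace=False)
    ) if n_true > n_planted else []
    pair_humans = list(expr.truth.gene_ids) + extra

    sim, essential, true_pairs = gen_ortholog_world(
        n_human=len(gene_ids),
        n_yeast=max(n_true, int(1.2 * n_true) or 1),
        n_true_pairs=n_true,
        essential_fraction=essential_fraction,
        score_noise=score_noise,
        seed=rng_orth,
        human_ids=gene_ids,
        true_pair_humans=pair_humans,
    )

    yeast_of = dict(zip(true_pairs["human_id"], true_pairs["yeast_id"]))
    essential_set = set(essential)
    screen_strains = [
        str(yeast_of[g]) for g in expr.truth.gene_ids
        if g in yeast_of and yeast_of[g] not in essential_set
    ]
    categories = {
        strain: CATEGORIES[i % len(CATEGORIES)] for i, strain in enumerate(screen_strains)
    }
    survival, survival_truth = gen_survival(
        categories, replicates=survival_replicates,
        noise_sd=survival_noise_sd, seed=rng_surv,
    )

    sets = {"planted": list(expr.truth.gene_ids) or ["none"]}
    descriptions = {"planted": "ground-truth conserved aging genes"}
    for i in range(n_decoy_sets):
        name = f"decoy_{i + 1}"
        size = int(rng_sets.integers(5, max(6, min(50, len(gene_ids)))))
        sets[name] = sorted(rng_sets.choice(gene_ids, size=size, replace=False))
        descriptions[name] = "random gene set"
    gene_sets = GeneSetCollection(sets, descriptions)

    return SyntheticWorld(
        matrix=expr.matrix,
        design=expr.design,
        probe_gene_map=expr.probe_gene_map,
        truth=expr.truth,
        gene_sets=gene_sets,
        similarity=sim,
        essential=essential,
        true_pairs=true_pairs,
        survival=survival,
        survival_truth=survival_truth,
        seed=seed,
    )
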