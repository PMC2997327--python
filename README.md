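# agescreen

Cross-model meta-analysis of differential expression for discovering
evolutionarily conserved regulators of cellular aging.

Transcriptional profiles of aging and senescence are notoriously
heterogeneous: different primary cell types, donors, and stressors disagree
about the expression of individual genes even when the underlying biology is
shared. `agescreen` implements an occurrence-counting ("value counting")
meta-analysis built for exactly this setting. Instead of fitting a
replicate-aware model, each treated/control array pair is evaluated on its
own, and a gene's evidence is the *number of comparisons* in which it
responds. The pipeline was designed around a two-group screen — 17
oxidative-stress comparisons (EG1) and 18 cellular-aging comparisons (EG2)
drawn over 47 baseline arrays — and carries candidates all the way to a
yeast chronological-lifespan screen of the corresponding deletion strains.

It is aimed at computational biologists who want a tested, reusable, and
fully seeded implementation of this workflow, together with a synthetic-data
generator that emulates the study structure with known ground truth.

## The method

**Occurrence counting.** For probe set *g* and comparison *e* with linear
intensities *t* (treated) and *c* (control), the signed fold is *r = t/c*
if *t ≥ c*, else *−c/t*. The probe is called differentially expressed (DE)
in *e* when |signed fold| ≥ 1.5 (inclusive, configurable). The occurrence
*k<sub>g</sub>* is the number of DE calls across a group's *n* comparisons;
up- and down-calls are also tabulated separately.

**Cumulative-binomial significance.** Under the null, a probe's calls are
Bernoulli(*p*) across comparisons, where the background rate *p* is the mean
per-comparison fraction of the probe universe called DE. The p-value is the
binomial upper tail:

P(K ≥ k) = Σ<sub>i=k</sub><sup>n</sup> C(n, i) p<sup>i</sup> (1−p)<sup>n−i</sup>

computed in log space. At the study's constants (*k* = 9 of *n* = 17,
*p* = 0.11) this gives 2.5 × 10⁻⁵. False discovery rates are Storey
q-values with bootstrap selection of the π₀ tuning parameter λ and the
"robust" small-p correction.

**Selection rules.** Three selection rules mirror the screen: DE in more
than 50% of a group's comparisons (cutoff ⌊n/2⌋+1: 9 of 17, 10 of 18), a
combined occurrence of at least 18 of 35, and the broad ≥ 6-of-either-group
rule feeding orthology.

**Downstream arms.** Candidate lists are tested for pathway enrichment with
a one-sided Fisher exact test against the full probe universe (54,675 by
default); human candidates are mapped to budding-yeast orthologs by
reciprocal best hit over a similarity table, filtered to nonessential
genes, and the surviving deletion strains are classified by relative
survival — the area under the viability-vs-day curve over a 22-day
stationary-phase horizon, as a percentage of wild type — into five bands
(< 50%, 50–85%, ±15% of wild type, 115–150%, > 150%), with two-sided
pooled-variance t-tests (*p* < 0.05/0.01/0.001 starred).

## Worked example

Generate a synthetic study (500 probes, 2 probes per gene, 20 planted
conserved-aging genes at 3-fold effect with 80% penetrance) and run the
full two-armed pipeline:

```sh
agescreen simulate --seed 7 --m-probes 500 --n-planted 20 --noise-sd 0.1 --out-dir sim
agescreen run --config config.yaml --seed 7     # paths of the sim/ files
```

The run logs the per-stage funnel:

```
comparisons                  35
probes                       500
selected_majority            40
selected_combined            40
screen_candidates            20
candidate_genes              20
yeast_orthologs              20
nonessential_yeast_orthologs 15
lifespan_strains             15
```

All 40 probe sets passing the majority rule are the 2-probe pairs of the 20
planted genes; all 20 collapse to gene-level screen candidates, each has a
reciprocal-best-hit yeast ortholog, 15 are nonessential, and all 15 enter
the lifespan screen. `results/occurrence.tsv` ranks probes by combined
occurrence:

```
id       eg1_up  eg1_down  eg2_up  eg2_down  eg1_total  eg2_total  combined_total
P000025  8       6         8       7         14         15         29
P000031  9       5         10      5         14         15         29
```

(a planted gene with mixed directions: DE in 14 of 17 EG1 and 15 of 18 EG2
comparisons, combined score 29 of 35). `results/lifespan.tsv` carries the
screen outcomes:

```
strain_id  relative_survival  category           t        p         stars
Y00004     70.57              slightly_reduced   -23.24   2.03e-05  ***
Y00010     131.09             slightly_increased  32.93   5.07e-06  ***
Y00039     35.21              strongly_reduced   -65.88   3.18e-07  ***
```

Every stage is also available standalone (`occurrence`, `infer`, `enrich`,
`orthologs`, `lifespan`, `cluster`) on plain TSV/GMT files; outputs carry a
provenance header (version, seed, config hash) and a rerun with the same
seed and config is byte-identical.

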