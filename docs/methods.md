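# Methods

This note documents the statistical model, the parameters that matter, the
synthetic-data generator, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The occurrence model

The pipeline deliberately avoids replicate-aware differential-expression
models (moderated t-statistics, empirical-Bayes shrinkage). The data it is
built for — treated/control array pairs from unrelated donors and diverse
cell models — violate the homogeneity those models assume. Instead, each
comparison is reduced to a ternary call per probe set (up / down /
unchanged at a symmetric linear fold threshold), and evidence is aggregated
by counting calls across comparisons.

Conventions and parameters:

* **Fold threshold** (default 1.5, inclusive). Intensities are linear-scale
  post-normalization values; ratios below 1 are reported as negative
  reciprocals (−c/t) so the threshold is the symmetric pair ±1.5. The
  inclusive reading ("≥") was adopted where the two plausible readings
  differ; the threshold is a public parameter.
* **ε-clamping** (default 10⁻⁶). Numerator and denominator are clamped
  below by ε before ratioing so synthetic zeros cannot divide by zero.
* **Groups.** Comparisons belong to one of two experimental groups, EG1
  (oxidative stress, n = 17 by default) and EG2 (cellular aging, n = 18).
  Occurrence is counted per group and combined; per-direction counts are
  retained because up/down asymmetry is itself informative.

### Significance: cumulative binomial

Under the global null a probe's calls are independent Bernoulli(p) trials
within a group, where the background rate p is estimated as the mean over
the group's comparisons of (DE probe sets in that comparison)/(probe
universe m). The p-value for occurrence k in n comparisons is the exact
binomial upper tail, accumulated in log space (stable for n up to ~10⁴ and
far-tail probabilities). k counts DE in either direction, matching the
estimation of p from either-direction calls.

Because k is discrete and p is shared across probes, the test is
conservative: the realized fraction of null probes with p-value ≤ α sits at
or below α. The test suite checks ≤ 1.5 α at α ∈ {0.01, 0.05} on a 5,000
probe null world.

When the two groups are pooled, the package ranks by combined occurrence
only; a pooled-rate CBD ((n₁p₁ + n₂p₂)/(n₁ + n₂)) is available but is an
extension, not part of the core model.

### False discovery rates: Storey q-values

π̂₀(λ) = #{pᵢ > λ}/(m(1−λ)) on a λ grid of 0.00–0.90 in steps of 0.05; λ*
minimizes the bootstrap-estimated MSE of π̂₀ against the grid minimum
(B = 100 resamples, seeded). The grid stops at 0.90 — the classical default
of Storey's q-value software generation this pipeline emulates — because
π̂₀(0.95) has roughly twice the sampling variance and degrades calibration.
The i-th ranked p receives q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ π̂₀ m p₍ⱼ₎ / j; with the robust
option (default on) the denominator j is replaced by j(1 − (1−p₍ⱼ₎)ᵐ),
which floors the q-values of very small p near π̂₀/j and is the appropriate
form when many p-values sit at the test's minimum achievable value. π̂₀ is
clamped to [1/m, 1]. With π₀ fixed at 1 and robust off, the estimator
reduces exactly to Benjamini–Hochberg, which the tests exploit as an
oracle.

### Pathway enrichment

One-sided Fisher exact test (hypergeometric upper tail P(X ≥ overlap)) of a
candidate list against each gene set, with the full probe universe
(54,675 probe sets) as the default sampling frame; a gene-level universe is
a parameter. Pathway p-values are reported raw with flags at 0.05 and
0.001; step-up correction across sets is deliberately off by default,
matching the reporting convention the pipeline emulates.

## Orthology

Reciprocal best hit over a (human, yeast, score) similarity table: a pair
is emitted iff each member is the other's unique maximal-score partner.
Ties yield no call by default — the screen wants *the* closest homologous
pair, and an ambiguous best hit is not that — with a lexicographic
tie-break behind a flag. Pre-made cross-reference pair lists can bypass RBH
entirely by being written as a similarity table with one row per pair. A
toy local-alignment scorer (Smith–Waterman via Biopython's
`PairwiseAligner`, linear gap penalty) exists solely so synthetic worlds
can be generated from short sequences; it is cross-checked against a
brute-force dynamic-programming oracle and is not meant for real proteomes.

The essentiality filter removes pairs whose yeast gene is in a provided
essential-gene list (deletion strains cannot be built for them). The
funnel — candidates → orthologs → nonessential — is reported with
per-stage counts.

## Chronological lifespan

Viability-vs-day curves (fractions in [0,1], day 0 through a 22-day
horizon) are summarized per replicate by the trapezoid area under the
curve; curves extending past the horizon are linearly interpolated at it.
A strain's **relative survival** is 100 × mean(mutant AUC)/mean(wild-type
AUC). The AUC statistic was chosen because the five published bands are not
tied to any stated day; an endpoint-viability alternative at a fixed day is
available (`--metric`-style parameter in the API). Relative survival is
scale-invariant and equals 100 exactly for identical curves.

Bands: [0, 50) strongly reduced, [50, 85) slightly reduced, [85, 115] not
affected, (115, 150] slightly increased, (150, ∞) strongly increased.
The printed inequalities leave the boundary percentages unassigned; they
are attached to the band nearer wild type (50 → slightly reduced, 85 and
115 → not affected, 150 → slightly increased), and this policy is
documented in the output.

Replicate AUCs are compared with a classical two-sided pooled-variance
Student t-test (identical degenerate groups are reported as t = 0, p = 1);
stars at p < 0.05 / 0.01 / 0.001.

## Synthetic data

The generator's defaults are the study conditions, not tuning knobs:

* **Design**: 17 EG1 + 18 EG2 comparisons over 47 control/baseline arrays
  spread across six cell models, controls shared between comparisons. The
  published per-model group counts do not sum to the group totals the text
  states; the totals (17/18/47) are authoritative here and the per-model
  allocation is configuration.
* **Intensities**: control values log-normal (median 100, σ = 1 on the
  natural log). Treated arrays copy their paired control column, apply the
  planted fold (default f = 3) to planted genes in ⌈φ·n⌉ randomly chosen
  comparisons per group (penetrance φ, default 0.8; direction up, down, or
  drawn per comparison), and multiply log-normal noise onto every cell.
  The default noise sd of 0.25 on the log scale yields a per-comparison DE
  fraction of ~0.10 at the 1.5-fold threshold — the study-scale background
  rate. With zero noise, unaffected ratios are exactly 1 and planted ratios
  exactly f, which the truth-consistency tests rely on.
* **Probes per gene** (default 2): effects are planted at gene level and
  broadcast to all probes; a discordant-probe option leaves one probe of
  each multi-probe gene unaffected to exercise collapse policies.
* **Ortholog world**: true pairs score ~100, decoy edges 10–60 and always
  incident to a true-paired gene, so at zero score noise RBH recovers the
  true pairs exactly (precision and recall 1 by construction). A stated
  fraction of yeast genes is flagged essential.
* **Survival**: the wild type is a normalized declining logistic with
  viability exactly 1 at day 0 and 0 at day 22 and midpoint at day 11 (the
  ~11-day mean lifespan). Mutants are time-stretched copies whose stretch
  factor is solved (Brent's method) so the noiseless AUC ratio hits a
  band-interior target (35 / 70 / 100 / 130 / 160% by category, or a
  numeric target). Additive Gaussian noise (default sd 0.02) is clipped to
  [0,1]; day-0 points and fully dead points stay exact (plating is
  normalized at day 0, and dead cultures do not resurrect). After noise,
  the realized category is re-checked and out-of-band strains are redrawn
  a bounded number of times, so generated worlds carry exact category
  labels.
* **Seeding**: one seed feeds `numpy.random.SeedSequence`, whose spawned
  children drive expression, orthology, survival, and gene-set draws;
  identical parameters and seed reproduce all outputs bit-exactly.

What the generator does **not** emulate: probe-level hybridization
artifacts, batch effects, inter-gene correlation, heavy-tailed intensity
noise, or annotation noise in probe→gene maps. Passing recovery tests on
these worlds therefore demonstrates the pipeline's arithmetic and its
behavior under the stated noise model, not performance on real arrays.

## Numerical choices and degenerate inputs

* CBD tail: log-space `logsumexp` accumulation; k = 0 → 1; p ∈ {0, 1}
  handled explicitly; result clipped to [0, 1].
* Storey: p ∈ {0, 1} edges in the robust denominator handled explicitly;
  bootstrap resampling is seeded and deterministic.
* Clustering: average linkage on Euclidean distances over the top-20,000
  most-variable probes (variance ties broken by input order) via scipy;
  scipy's merge order is deterministic given the input, and exact distance
  ties are measure-zero for this pipeline's data.
* Concordance: OLS with the standard 95% prediction band
  s·√(1 + 1/n + (x−x̄)²/Sxx) and t(0.975, n−2); zero variance in x is an
  error.
* Lifespan: wild-type mean AUC of 0 is an error; curves not reaching the
  horizon are errors rather than silently extrapolated.

## Problem sizes in the checked runs

The test suite and acceptance script run the synthetic studies at 5,000
probes × 35 comparisons (recovery and null calibration), 2,000 p-values
(π₀ calibration), 93 strains × 3 replicates (lifespan screen), and a
250–500 probe world for end-to-end determinism — sizes chosen so the whole
suite completes in well under a minute while keeping the per-comparison
and per-group structure of the full-scale design. The IO layer is
additionally exercised once at the full 54,675-probe scale.

## Known limitations

* The background rate p is a point estimate plugged into the CBD; its
  sampling uncertainty is not propagated.
* Occurrence counting ignores effect magnitude beyond the threshold and
  treats comparisons as exchangeable within a group.
* The probe→gene collapse (default: per-column maximum over a gene's
  probes, totals recomputed) is one of several defensible policies; the
  published collapse procedure is unstated, so the policy is a parameter
  (`best_probe` inherits the single strongest probe's row instead).
* RBH orthology is one-to-one by construction and cannot represent
  many-to-many homology; that is intentional for a deletion-strain screen.
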