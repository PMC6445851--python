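# Methods

## Scope and model

`targetgene` nominates the target genes of trait-associated
(GWAS) SNPs in a chosen cell type by requiring three independent lines
of evidence to coincide, then characterises the surviving genes'
regulatory and network context. The package operates on desk-scale
inputs: tabular exports (TSV/GMT/BED) and a synthetic cohort generator;
it does not query any external service.

### eQTL stage

Association between SNP dosage and gene expression uses the additive
model standard in eQTL mapping: `E = β₀ + β₁·G + ε` with `G ∈ {0,1,2}`
and a two-sided t-test on `β₁` (OLS via statsmodels). The filter keeps
nominal *p* < 0.05, strict, with no multiple-testing correction: at
this stage the intersection with independent differential-expression
evidence acts as the orthogonal filter, and true regulatory SNP–gene
pairs may show only modest eQTL signal. Monomorphic genotypes yield an
`untestable` flag instead of an exception so batch scans survive them.

### Rank-product meta-analysis

For each study, case-vs-control comparisons provide per-gene log2 fold
changes; within each comparison genes are ranked (descending for the
up-regulation analysis, ascending for down; ties get mid-ranks) and the
rank product is the geometric mean `RP_g = (∏_c r_{g,c})^{1/k}`. Up and
down are evaluated and reported separately.

Significance uses the percentage-of-false-positives statistic. For
`b = 1..B` rounds the observed rank vector of every comparison is
independently and uniformly permuted; the expected number of null genes
with rank product at or below `RP_g` is `E[x](g)` = total count / B,
and `PFP(g) = E[x](g) / rank(g by ascending RP)` — an estimate of the
false discovery rate of the gene list cut at *g*. Raw PFP is reported
untruncated together with a step-down cumulative-minimum variant that
is monotone in RP. Differential expression calls require
min(PFP_up, PFP_down) < 0.05 and |FC| > 1.2 (both strict); the signed
fold change pools per-study log2 case/control ratios of geometric means
by unweighted mean and maps the ratio *r* to *r* (if ≥ 1) or −1/*r*, so
thresholds are symmetric in direction.

**Comparison scheme.** The default pairing is *disjoint*: a seeded
random matching in which every sample is used at most once per study,
giving `k = min(n_cases, n_controls, cap)` comparisons per study
(cap 50). The all-pairs scheme (every case × control pair, seeded
subset beyond the cap) is available as `scheme="all_pairs"`, but it
makes comparisons share samples and hence positively correlates
fold-change vectors across comparisons — a dependence the independent
within-comparison permutation null cannot represent, which inflates the
fraction of null genes at PFP < 0.05 from effectively 0 to ~0.15 in
simulation. Disjoint pairing keeps the comparisons independent under
the null, so PFP retains its FDR interpretation; that calibration,
together with sensitivity ≥ 0.9 for genes planted at fold change 2
with log2 noise SD 0.3, is asserted by the test suite. Permutation is
always within a comparison, never across studies, preserving study
structure under the null. `B = 100` permutation rounds by default;
configurable.

### Preprocessing

Expression intensities are log2-transformed (values must be positive;
violations are reported with gene and sample coordinates), quantile
normalised across arrays (each column's sorted values become the
per-rank column means; ties receive the reference distribution
interpolated at the mid-rank — stated for bit-reproducibility), and,
when probe-level data carry a probe→gene map, summarised by Tukey
median polish (rows swept first, tolerance 1e-6, at most 20
iterations; the per-sample gene summary is overall + column effect).
Median polish is cross-checked against R's `stats::medpolish` in the
test suite. Quantile normalisation is idempotent and monotone, so
within-array rank order is never changed.

### Integration and annotation

A (SNP, gene) pair enters the target table only if eQTL *p* < 0.05,
PFP < 0.05 and |FC| > 1.2, all strict; rows sort by chromosome then
position, a gene reached by several SNPs keeps one row per SNP, and
up/down counts are over distinct genes. Gene location classes
(5′/3′/intron/exon) are read from annotation input, never computed.
SNP positions are 1-based as printed in GWAS summaries; histone-mark
intervals are BED (0-based half-open); the single conversion `p − 1`
lives in `annotate_histone_overlap`, where a SNP overlaps `[s, e)` iff
`s ≤ p−1 < e`. Overlap uses an interval tree and is checked against a
brute-force scan in tests.

### Methylation (meQTL) stage

Each SNP is tested against the M-values (log2 methylated/unmethylated
intensity ratio, taken as given) of every probe in its target gene(s):
`M = β₀ + β₁·G + sex + age + PC₁…PC₁₀ + ε`, two-sided t-test on `β₁`.
Designs with too few observations, constant genotype or collinear
covariates are flagged untestable with a diagnostic. The experiment-
wide threshold is Bonferroni α/n over all testable SNP–probe pairs,
displayed at 2 significant figures (0.05/144 → 3.5e-04, matching the
case-study convention); significance is strict `p < cutoff`.

### Network enrichment

The first-order network is the subgraph induced by the seed genes
present in the interactome plus their direct interactors; absent seeds
are reported, never silently dropped, and isolated present seeds are
retained. Pathway enrichment is the upper hypergeometric tail
P(X ≥ Hits) with population the background universe, successes the
pathway size in the universe and draws the network genes in the
universe; Expected = Total × draws/|universe|. The **universe** is the
set of genes both present in the interactome and carrying at least one
pathway annotation — the published analysis never states its
background size, so this documented, configurable choice keeps
observed and resampled lists judged against the same population.

Multiple testing uses hand-rolled Benjamini–Hochberg step-up
(`adj_(i) = min_{j≥i} p_(j)·m/j`, capped at 1) because the family size
*m* may exceed the number of p-values at hand (needed when adjusting a
printed subset of a larger family); it agrees with statsmodels'
`fdr_bh` whenever `m = len(p)`.

The empirical pathway P repeats seed-list → first-order network →
enrichment → BH for R random gene lists of the same size, drawn
uniformly without replacement from the enrichment universe (not from
an unconstrained genome-wide pool — this keeps the null comparable to
the observed analysis and is configurable via the `universe`
argument). A pathway significant (FDR < 0.05) in *b* of *R* resamples
gets empirical P = b/R, rendered `<1/R` (e.g. `<0.01` at R = 100) when
b = 0, since "never recurred in R resamples" bounds rather than
measures the probability. R = 100 by default.

## Synthetic-data generator

All randomness flows from one master seed through named substreams
(`SimulationConfig.rng`), so a fixed config reproduces every output
byte-for-byte. The generator emulates:

- **Expression**: per study, per gene log2 intensity = baseline
  N(7, 1) + N(0, noise_sd), exponentiated so preprocessing's log2 is
  exercised; planted genes shift the case class by ±log2(FC). Default
  two cohorts of 18 cases/13 controls (the case study totals 36/26;
  the per-cohort split is not recorded anywhere, so an even split is
  the default and a free parameter). Default noise_sd 0.3 on the log2
  scale, a typical microarray residual spread.
- **Genotypes**: Binomial(2, MAF) per subject and SNP —
  Hardy–Weinberg equilibrium, no linkage disequilibrium. Default MAF
  0.3, n = 200 subjects.
- **Methylation**: M = probe intercept + planted slope·G + probe-
  specific sex/age/PC coefficients (N(0, 0.1)) + N(0, 0.1); 11 probes
  per gene, matching the ~11-probe-per-gene density of 450k-style
  arrays.
- **Interactome**: preferential-attachment (Barabási–Albert) graph,
  m = 2, relabelled with synthetic gene symbols G0001… — connected,
  simple, scale-free-ish degree tail.
- **Pathways**: uniform random sets (sizes 10–150) plus one planted
  set taking 10 of its 15 members from the seed genes' first-order
  neighbourhood.
- **`study_scale_config`** wires these into the case study's shape:
  10 SNPs → 13 eQTL pairs over 11 genes (5 up/6 down at FC 1.5, two
  SNP pairs sharing their two genes), extra eQTL-only and DE-only
  genes so the intersection genuinely filters, 143 SNP × probe
  methylation tests with 4 planted meQTL effects of slope 0.8.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: probe-level microarray artefacts and
background correction, correlated noise between genes, linkage
disequilibrium between SNPs, beta/M-value distribution shapes, hub
biases of curated interactomes, or overlapping/nested real pathway
structure.

## Numerical conventions and degenerate inputs

- All threshold comparisons are strict (`<`, `>`); boundary values are
  excluded.
- PFP counting uses a 1e-9 slack in log space when comparing null to
  observed rank products, absorbing round-off in the geometric mean;
  tied observed RPs share the `max` rank.
- Quantile-normalisation ties: reference interpolated at mid-ranks.
- Median polish: tolerance 1e-6 on the largest effect change, 20
  iterations, rows first.
- Fold-change ratio r = 1 maps to +1.0.
- Empty stages (no DEGs, no passing pairs) propagate as empty tables,
  not errors; report files are still written.
- Seeds: models split a master seed into per-purpose substreams via
  `numpy.random.SeedSequence.spawn`, so pair selection and the two
  PFP permutation streams are independent and reproducible.

## Problem sizes used by the packaged checks

The test suite and `scripts/acceptance.py` run the stochastic checks at
the sizes the package treats as its reference desk-scale conditions:
rank-product calibration on 1000 genes × two 18/13 cohorts with B = 100
over 10–20 replicates; planted-pathway recovery over 10–20 replicates
of R = 100 resamples on a 1000-node interactome with 50 + 1 pathways;
meQTL recovery at n = 200 subjects. A full run of either completes in
well under a minute on one CPU.

## Known limitations

- PFP is a permutation estimate; with B = 100 its resolution per gene
  list is limited and very small PFPs are noisy. Increase B for finer
  resolution.
- The disjoint comparison scheme discards the excess samples of the
  larger class within each study (k is the smaller class size), a
  deliberate trade of a little power for a calibrated null.
- The published analysis reports two different sizes for its eQTL gene
  set (238 and 264); the pipeline reports a single distinct-gene count
  computed from its own inputs and does not attempt to reconcile the
  two.
- Published FDR columns recomputed from printed (3-significant-figure)
  p-values inherit up to ~0.5% relative rounding error; the replay
  checks assert agreement at that precision, not beyond it.
- Location classes, probe→gene maps and interactome edges are taken as
  given inputs; the package performs no genome annotation of its own.
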