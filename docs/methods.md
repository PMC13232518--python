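# Methods

`crelink` implements an MPRA-informed enhancer–gene (E–G) interaction
predictor and the network/enrichment analyses that sit on top of it. This
note records the models, the defaults and why they were chosen, the
numerical conventions, what the synthetic fixtures do and do not emulate,
and the known limitations.

## Candidate elements and pairs

Candidate cis-regulatory elements (CREs) come from accessibility peaks:
peaks are resized to a fixed 500 bp scoring width around the floor
midpoint, ranked by total read count, and the top 150 000 retained
(`n_top`, configurable; ties break deterministically by position). One
promoter element per gene (TSS ± 500 bp by default — annotations may
override it; the ±500 bp half-width is a package choice, exposed in
config) is appended. Every CRE–gene combination on the same chromosome
with |CRE midpoint − TSS| ≤ 5 Mb (boundary inclusive) is a candidate pair.
The window is measured midpoint-to-TSS; element-edge measurement would be
the main alternative, and for 500 bp elements the two differ by at most
250 bp — immaterial at a 5 Mb scale.

Each candidate keeps two geometries: the fixed 500 bp scoring interval and
its native peak coordinates (`CandidateCRE.region`). Overlap-based
analyses (variant intersection, length-matched background sampling, region
merging) use the native coordinates, because length matching is only
meaningful for native-width peaks; feature scoring uses the fixed width.
Two further deterministic input-geometry utilities exist for preparing
sequence-model inputs: a 200 bp center resize (reporter-model input
width) and a 4096 bp summit-centered window that truncates at chromosome
ends and reports left/right pad counts for N-padding
(`resize_on_summit`; the invariant `length + pads = 4096` always holds).

## Activity-by-contact score

For pair (e, g): `ABC(e,g) = A_e·C_eg / Σ_{e'∈window(g)} A_e'·C_e'g`, with
activity `A = sqrt(DNase × H3K27ac)` (geometric mean) and contact `C` the
supplied per-pair 3D contact value, with a pseudocount of 1e−6 replacing
zeros. Per-gene scores therefore sum to 1 (or to 0 for a gene whose whole
window is inactive, which is logged). The geometric-mean activity and
zero-contact pseudocount follow the ABC model family; both are
configurable.

## External per-element scores

Reporter-assay activity arrives as per-element forward/reverse scores from
an ensemble of 10 models: orientations are averaged first (reduces strand
bias), then the ensemble mean is taken; fewer than 10 members is accepted
with a warning. Chromatin-probability tables may contain several outputs
for the same biological feature; duplicate columns are collapsed by
row-wise mean. Feature assembly left-joins pair-keyed and element-keyed
tables onto the candidate pairs, imputes missing values with the column
median, and adds a binary missingness indicator per imputed column, so the
classifier stays well-defined when an element lacks a score. Each column
carries a provenance tag (`re2g`, `mpralegnet`, `sei`, `abc`) in a JSON
manifest.

## Classifier

A logistic regression with L2 (ridge) penalty over the assembled features,
labeled by CRISPRi outcomes (1 = perturbation significantly reduced the
target gene's expression, 0 = otherwise). Features are z-scored with
training means/scales — without standardization a single penalty strength
is meaningless across features whose scales differ by orders of magnitude.
Default inverse penalty C = 1.0; solver lbfgs, tolerance 1e−8, max 10 000
iterations; no class weighting by default (a flag exists given the extreme
imbalance typical of CRISPRi data). The fitted model serializes to JSON
(feature names, standardization, coefficients, intercept, seed) so it can
re-score feature tables from other cellular contexts without retraining.

## Benchmark statistics

- **AUPRC** by step-wise summation Σ (R_i − R_{i−1})·P_i over descending
  unique thresholds (average-precision convention; no interpolation and no
  monotone-precision envelope — raw step-wise values). Tied scores
  collapse to one threshold.
- **Bootstrap CI**: 10 000 resamples of the labeled pair list with
  replacement (not stratified); single-class replicates are redrawn and
  counted; 95% interval by the percentile method. Bit-reproducible for a
  fixed seed.
- **Operating point**: the largest threshold t with recall(score > t) ≥
  0.70 — numerically, the float just below the ⌈0.7·n_pos⌉-th positive
  score — with the precision achieved there. Binary calls use strict
  `score > t`, matching the network-construction rule.
- **Spearman ρ** between scores and CRISPRi effect sizes (percent change
  in expression), average-rank ties. Because effects of true enhancers are
  negative (expression drops), ρ is expected negative.

## Networks and substructures

Predicted pairs with score strictly above the threshold form a bipartite
graph (CRE and gene nodes). Promoter-class elements keep only the edge to
their own gene. Named threshold presets: 0.283 (standard contact maps) and
0.234 (aggregated "megamap" contact), the model's 70%-recall operating
points. Communities come from seeded multi-level modularity optimization
(Louvain, networkx implementation, resolution 1.0) on the unweighted graph
(edge presence only; score-weighted modularity is available behind a
flag). A community with exactly one CRE is non-redundant (NR) — a single
enhancer with no regulatory buffering — otherwise redundant (R);
communities with no CRE (isolated genes) are excluded from the %NR
denominator. %NR = 100 · #NR / #communities-with-≥1-CRE.

## Matched-background permutation tests

**Variant enrichment.** Observed statistic: unique variants (1-based input
positions converted once at ingestion; dedup key (chrom, pos, id)) inside
≥ 1 network CRE. Null: per network CRE, sample with replacement a whole
catalog peak from the same chromosome and the same (length,
distance-to-nearest-TSS) bin; default bins are deciles of the catalog
distributions; a value on a bin edge falls in the right-hand (upper) bin.
Empty bins relax hierarchically: rings of adjacent bins at increasing
Chebyshev distance in (length, distance) bin space, same chromosome only;
relaxation events are counted and logged. Repeats within one sampled set
are allowed (sampling is with replacement) and overlap is counted on the
union of sampled intervals. p = (#{null ≥ observed} + 1)/(n_perm + 1) — so
the smallest attainable p at 1000 permutations is 1/1001 ≈ 9.9 × 10⁻⁴ —
and fold enrichment FE = observed / mean(null). The test runs over
peak-derived network elements; promoter windows have no counterpart in a
peak catalog and their fixed 1 kb width would collapse length matching.

**eQTL concordance.** Observed statistic: unique (variant, gene) pairs
where the variant sits in a network CRE that the model links to that gene.
The null additionally matches on CRE class (promoter / genic enhancer /
intergenic enhancer) and on the number of model-predicted targets: exact
count first, then joint relaxation in which level r widens the
(length, distance) rings by Chebyshev radius r **and** the target count by
±r (chromosome and class never relax). Each sampled element keeps its own
model-predicted links, rebuilt with the same threshold and
promoter-self-link rule.

Both tests are bit-reproducible given a seed, and p ∈ [1/(n_perm+1), 1]
by construction.

## Motif and gene-set enrichment

CREs from all conditions' networks merge into maximal regions connected by
≥ 1 bp overlaps (half-open intervals; abutting intervals do **not**
merge). A merged region contributed by exactly one condition is
condition-specific. Per TF, a region is motif-present if ≥ 1 scanner hit
(p ≤ 1e−5) from that condition's network CREs falls in it; hits keyed
either by CRE id or by coordinate-encoded sequence names. The 2×2 table
(present/absent × specific/agnostic) is tested with a one-sided Fisher
exact test (greater), the headline effect size is the 0.5
continuity-corrected log2 odds ratio (the raw odds ratio ad/bc is reported
alongside, infinite when bc = 0), and BH FDR is applied across TFs within
each condition, never pooled. Gene-set enrichment uses the hypergeometric
survival function sf(x − 1; M, n, k): background M, set members n, network
genes k, overlap x.

## Synthetic fixtures

The generators emulate a small genome with planted regulatory structure;
all randomness flows from one top-level seed through named child streams.

- **World**: uniform TSS positions; log-normal peak lengths (median 500 bp,
  σ_log 0.35) and gamma read counts (shape 2, scale 50); two chromosomes.
- **Contact**: C(d) = (d + d₀)^−γ with log-normal noise (σ 0.5); γ = 1 and
  d₀ = 5 kb by default, the power-law behavior assumed by the ABC family.
- **Links**: true-link log-odds = β₀ + β·z over z-scored realized feature
  columns (defaults β = 1.2 on the reporter-activity column, 0.8 on log
  contact, 0.6 on one nuisance column; β₀ = −3), so a correctly specified
  logistic fit recovers β. Labels flip at rate 0.05 by default; the
  coefficient-recovery experiment uses flip rate 0 because label noise
  makes the logistic model misspecified and attenuates coefficients —
  noise-free labels *are* the planted-logistic condition. Effect sizes are
  strongly negative for true links, near zero otherwise.
- **Scales**: the default scale (2 × 5 Mb, 100 genes, 2500-peak catalog,
  top 300 entering the model, 20 000 pairs) serves classifier, benchmark
  and permutation experiments. `FixtureConfig.network_scale` (2 × 50 Mb,
  200 genes, sharply local links: β_logcontact = 3, β₀ = −6.5) emulates
  genome sparseness; its predicted networks fragment into ~120–170
  communities with a ~30–50% NR fraction, the regime genome-wide networks
  occupy. One scale cannot serve both purposes: pair volume requires
  density, community structure requires sparseness.
- **Variants**: N background variants uniform over the genome plus E extra
  variants inside network CREs, with
  E = N·c·(f−1)/(1 − f·(c + q)) where c is network coverage and q the
  null's self-resampling rate (a network CRE can be drawn as its own
  match; q is computed from the same binning the test uses). This makes
  the expected permutation FE equal the planted fold f. Infeasible f
  errors with the maximum achievable value.
- **eQTLs**: uniform variants; one landing in a network CRE takes one of
  that CRE's target genes with the configured concordance probability,
  drawn proportionally to link strength (eQTLs corroborate strong links);
  otherwise a random gene.
- **Motif hits**: per (region, TF), presence odds in condition-specific
  regions are the background odds times the TF's planted odds ratio, so
  the population 2×2 odds ratio equals the planted value.

What the fixtures do **not** emulate: sequence content, chromatin
covariance between assays, LD among variants, realistic peak/gene density
ratios, or the size of real candidate universes. Consequences worth
knowing: with a 400-element universe (vs ~150 000 in genome-scale data)
the eQTL null inherits part of the observed signal through self- and
neighbor-resampling, so fixture-scale eQTL fold enrichments (~1.2) are
attenuated relative to what the same machinery reports on large universes;
the permutation machinery's unattenuated FE recovery is verified
separately with a constructed well-populated universe. Passing tests show
the statistics are computed correctly and are well calibrated under the
planted models — not that the defaults transfer to any particular real
dataset.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open internally; 1-based inputs (VCF POS,
variant/eQTL TSV, scanner start/stop) convert exactly once at the I/O
boundary. Even-length midpoints take the floor. Resizing to a fixed width
shifts inward at chromosome boundaries (length preserved); summit-centered
windows truncate and report pads instead. Variant tables with a p-value
column are filtered to p < 0.01 at ingestion. Empty contingency tables
give Fisher p = 1 (logged); constant vectors make Spearman an error rather
than a NaN; a gene whose window has zero total activity×contact gets
all-zero ABC scores with a warning; single-class training labels and
single-class PR inputs are errors. FE is reported as NaN when the null
mean is 0.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run entirely on the fixture
scales above: 20 000 pairs for coefficient recovery (10% relative-error
band), 200 runs × 200 permutations for null calibration
(Kolmogorov–Smirnov uniformity of p, mean FE in [0.9, 1.1]), 50 seeds ×
100 permutations for fold-2 recovery, 40 seeds for planted-motif ranking,
1000 permutations and 2000 bootstrap replicates in the acceptance
pipeline runs. These sizes are the package's chosen experiment designs;
all are parameters.

## Known limitations

- The neural networks whose scores feed the model (reporter-activity and
  chromatin-probability predictors) are out of scope; their outputs are
  inputs here, and the input-geometry utilities only prepare their
  windows.
- No Hi-C extraction or normalization: contact arrives as a per-pair
  table. No peak calling, motif scanning, liftover, or LD handling.
- Chromosome names match by exact string; no alias normalization.
- The promoter definition (TSS ± 500 bp) is a convention, not a learned
  quantity; analyses that class CREs inherit it.
- Louvain is greedy and seed-dependent; %NR is reported per seed and its
  across-seed spread (≤ ~2 percentage points at fixture scale) is part of
  the shipped checks.
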