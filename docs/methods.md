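# Methods

## The analysis model

The package reimplements a six-array pooled microarray design: three
compartments (heart tissue, whole blood, plasma), each with one heart-failure
(HF) array and one control array hybridized with pooled RNA. With a single
array per condition there is no replicate variance, so differential
expression is by design a pure fold-change filter between the paired arrays,
with no probe-level p-value:

* a probe enters the comparison only if its detection flag is Present (P) or
  Marginal (M) on **both** arrays of the pair ("2 of 2");
* fold change FC = max(HF, floor) / max(control, floor) with floor = 1.0
  guarding against ratios of background-level intensities (the floor is
  configurable and irrelevant for realistically scaled intensities);
* direction is *up* iff FC ≥ 2.0 and *down* iff FC ≤ 0.5, both inclusive.

Quantile normalization forces all arrays onto one intensity distribution
(per-rank column means; ties receive the mean of the tied ranks' targets).
It is provided, tested (fixed-point, equal-distribution and rank-preservation
properties) and exposed in the CLI; for simulated input it is skipped by
default because the generator emits intensities on the post-normalization
scale (`already_normalized: true`), which keeps planted fold changes exact.

### Positional classification

Each lncRNA is classified against the coding catalog by the precedence order
sense_overlap > intronic > antisense_overlap > nonantisense_overlap >
bidirectional > intergenic, i.e. exon-level same-strand evidence dominates
proximity evidence. Definitions:

* *sense_overlap*: lncRNA exon overlaps a coding exon, same strand;
* *intronic*: the lncRNA's genomic span lies wholly inside one intron of a
  same-strand coding transcript. The published wording for this class is
  self-referential ("lncRNA intron overlaps the coding intron"), so whole-
  span intron containment was adopted as the operational rule;
* *antisense_overlap*: exon–exon overlap on opposite strands;
* *nonantisense_overlap*: genomic spans overlap on opposite strands with no
  exon–exon overlap;
* *bidirectional*: opposite strands, disjoint spans, divergent (head-to-head)
  orientation, TSS-to-TSS distance ≤ window (default 1000 bp, inclusive);
* *intergenic*: none of the above.

For reporting, intronic folds into sense_overlap and nonantisense_overlap
into antisense_overlap (four-class view). Partner ties break by smaller
TSS-to-TSS distance, then lexicographic gene id. Coordinates are 0-based
half-open internally; GFF3 is converted on read.

A geometric note: class labels are invariant under coordinate translation
and under mirror reflection of the genome (coordinate reversal plus strand
flip). They are *not* invariant under a bare global strand flip for the
bidirectional class — flipping both strands turns a divergent promoter pair
convergent — so the test suite asserts strand-flip invariance only for the
four overlap classes and full mirror symmetry for all six.

### Statistics

* **Spearman ρ** with average ranks for ties. Two-sided p: exact permutation
  (all n! permutations, vectorized) for n ≤ 9, the t-approximation
  t = ρ√((n−2)/(1−ρ²)) above. The switch point keeps exactness where
  enumeration is feasible and the standard approximation at array scale.
* **Fisher's exact test**: two-sided p is the sum of hypergeometric
  probabilities of all tables with the observed margins at most as probable
  as the observed table (no mid-p). The odds ratio is the unconditional
  cross-product ad/bc with 0/∞ conventions for zero cells; optional Haldane
  +0.5 smoothing. p comes from scipy; the OR conventions are the package's
  own, and tests verify p against a full enumeration oracle.
* **Fold-change concordance** between two compartments: Spearman ρ over
  log2 FC of probes flag-passing in both; the 2×2 direction table and Fisher
  test over probes called up/down in both. The two universes differ on
  purpose: the correlation uses all measurable probes, the table only
  confident calls.
* **Length–expression grid**: Spearman(spliced length, intensity) per
  collapsed class and sample over probes flagged P/M in that sample, with a
  pooled Total row; cells with n < 3 are reported absent. Spliced length
  (sum of exon lengths) is used because probes interrogate transcripts, not
  genomic spans.
* **Classical MDS**: Torgerson double centering of −D²/2, top-k non-negative
  eigenpairs, centroid at the origin; exact for embeddable metrics (verified
  to 1e-9 on planar configurations). Distance is the correlation distance
  1 − ρ (range [0, 2]).
* **Bi-clustering** of the grid: average-linkage agglomerative clustering on
  Euclidean distances, rows and columns independently; scipy's deterministic
  merge order is the tie-break; trees are exported as newick text.
* No multiple-testing correction is applied anywhere, matching the
  replicate-free design.

### qPCR

2^(−ΔΔCt) with technical replicates averaged on the Ct scale, ΔCt against a
reference (housekeeping) gene per animal, ΔΔCt against the control-group mean
ΔCt, amplification efficiency fixed at 2. Group comparison by the classical
pooled-variance unpaired t-test (Welch available by flag). Plate offsets
cancel exactly; lowering one group's target Ct by c multiplies its relative
expression by 2^c. Plasma targets are normalized to GAPDH exactly as in the
emulated protocol, without endorsing GAPDH as a cell-free reference.

## The synthetic-data generator

The generator *is* the study conditions: its defaults
(`data/paper_profile.yaml`) encode the published design — 30,000 lncRNA
probes, 20,000 coding genes, class mixture 12/8/12/8/10/50% (six-way;
collapsing to 20/20/10/50%), planted DE counts heart 518/908, plasma
1619/1582, whole blood 1139/1506, the per-sample per-class length–expression
ρ grid, heart–plasma fold-change coupling −0.24, and sense-overlap
concordance odds ratios 4.9 / 2.5 / 4.0 (heart / plasma / whole blood).
Antisense-class odds ratios are not printed in the source study; the profile
sets 2.0 / 0.4 / 0.4 to reproduce its qualitative statement (agreement in
heart, opposition in the circulation).

Parameters a user may care about:

| parameter | default | meaning |
| --- | --- | --- |
| `length_distribution` | lognormal(7.3, 1.0), truncated [200, 50000] nt | lncRNA spliced lengths, median ≈ 1.5 kb |
| `intensity_distribution` | lognormal(8.52, 1.2) (natural log) | post-normalization intensity scale; spans ≈ 3 decades |
| `flag_absent_rate` | 0.10 | per-cell probability of an Absent flag (the rest split 0.85 P / 0.15 M) |
| `fc_magnitudes.up` / `.down` | log-uniform [2, 8] / [0.125, 0.5] | planted fold-change magnitudes |
| `fc_magnitudes.background_log2` | U(−0.9, 0.9) | jitter of unchanged probes, strictly inside (0.5, 2) |
| `bidirectional_window_bp` | 1000 | TSS window for the bidirectional class |

The background jitter is a deliberate extension of the planted-count scheme:
with fold change 1 for every unchanged probe, a cross-compartment rank
correlation over all shared probes would be undefined (massive ties), so
unchanged probes get a jitter that can never cross the DE thresholds.

### Annotation construction

Loci are packed into disjoint 150 kb genome slots — one lncRNA plus, where
its class requires one, a partner gene per slot — so each lncRNA satisfies
exactly its intended class rule and nothing else (slots are separated by far
more than the bidirectional window). Free-standing coding genes fill the
catalog to `n_coding`. The classifier recovers 100% of planted labels; this
round-trip is a standing test.

### Copula calibration

All rank couplings go through Gaussian copulas, converting each target
Spearman ρs to the latent Pearson r = 2·sin(πρs/6) (exact for bivariate
normal ranks). Per compartment:

1. The **control column** is logI = μ + σ(r·z_len + √(1−r²)ε), with r from
   the control sample's per-class target and z_len the normal scores of the
   length ranks: its length coupling is exact by construction.
2. The **fold-change vector** has a fixed marginal (exactly n_up up values,
   n_down down values, background jitter) assigned to probes by the ranks of
   a latent w = α·z_len + β·u + γ·ε, where u is a factor shared between the
   coupled compartment pair (β products solved per class from the target
   cross-compartment coupling) and α is a per-class length weight.
3. The **HF column** is the control column times the planted fold change.
   Its length coupling is therefore emergent, and α is solved (fixed point,
   using Stein's identity Cov(z_len, lnFC) = α·E[w·Q(Φ(w))]) so the HF
   column lands on the HF sample's own target. This is what lets the heart
   keep ρ ≈ −0.17 in both conditions while HF plasma collapses to ≈ −0.05
   against a normal-plasma −0.17 — the headline contrast.
4. DE is planted only among probes already flag-passing in that compartment,
   so the Present/Marginal filter can never erode the planted counts and —
   equally important — flag-filtered subsets remain unbiased samples of the
   planted couplings. (Forcing planted probes' flags to P instead measurably
   inflates the flag-filtered cross-compartment |ρ| by ~0.02, because forced
   probes survive the filter at rate 1 versus ~0.81 for background.)

Partner-gene mRNA directions are drawn per DE lncRNA from 2×2 cell
probabilities solved from the class/compartment target odds ratio with
balanced margins (P(up|up) = √OR/(1+√OR)), giving the target OR in
expectation.

Determinism: every stage draws from `default_rng([seed, stage_id])`, so one
master seed reproduces byte-identical outputs across all generators.

### What the generator does and does not emulate

It emulates the statistical structure the analysis measures: lognormal
intensities, detection flags, planted rank couplings, exact DE counts,
direction concordance, Ct noise. It does **not** emulate probe
cross-hybridization, dye or batch effects, background correction, sequence
content, within-pool biological variance (pooling is represented only as one
array per condition), or quantile-normalization distortion of raw scanner
data. Passing tests therefore demonstrate that the pipeline measures what it
claims on data with known truth — not that the published biological findings
replicate on real arrays, whose probe-level data live in a public repository
and are out of scope here.

## Numerical choices and degenerate inputs

* Spearman on a constant vector is reported absent with a reason, not NaN-
  silent; n = 2 yields ρ without a p.
* The exact-permutation p includes the identity permutation, so p > 0 always.
* Correlation-distance matrices reject constant columns by name.
* classical MDS pads with zero coordinates and warns when fewer than k
  positive eigenvalues exist (e.g. all-zero distances).
* An all-zero contingency table is an error; zero cells follow the 0/∞ OR
  conventions above.
* Fold-change thresholds are validated (up > 1 > down > 0, floor > 0);
  expression tables are validated on read with line-numbered errors.
* Infeasible planting (more planted DE probes than flag-passing probes, or
  copula loadings with α² + β² > 1) raises a configuration error rather than
  silently clamping.

## Problem sizes

The packaged profile runs at the published scale (30,000 lncRNA probes,
20,000 genes; ≈ 9 s for a full generation plus ≈ 1.5 s classification on one
CPU). The test suite uses 2,000-probe reductions for structural checks and
20,000-probe runs for correlation-recovery checks, with seed counts chosen to
keep the whole suite around a minute.

## Known limitations

* One shared latent factor couples at most one compartment pair; the profile
  couples heart–plasma (the published pair). Heart–whole-blood and
  plasma–whole-blood couplings are emergent and weak.
* The Total row of the correlation grid is emergent (mixture-weighted), not
  independently plantable; with the packaged mixture it lands within ≈ 0.005
  of the published Total values.
* The HF-column length coupling relies on a near-normal approximation of
  log intensity plus the fold-change term; residual bias is well under the
  ±0.03 recovery tolerance but not exactly zero.
* The 2×2 concordance planting controls the OR in expectation only; at 1,000
  pairs the sampling sd of log OR is ≈ 0.13.
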