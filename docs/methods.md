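# Methods

This note documents the statistical procedures implemented in
`crevar`, the defaults they run with, what the synthetic-data
generators emulate, and the design choices made where the underlying
methodology left room.

## Coordinate and reporting conventions

All intervals are BED-style 0-based half-open `[start, end)`; VCF
positions are converted at the I/O boundary (`POS − 1`). A variant is
"inside" a peak iff `start ≤ pos < end`. Gene TSSs follow strand:
`start` for `+` genes, `end − 1` for `−` genes; promoters are
−2000/+100 bp around the TSS in the direction of transcription.
Percentages in reports are rounded half-to-even to one decimal. Floats
are serialized at 6 significant digits, which together with the single
seeded RNG path (numpy `default_rng`; one global seed expanded to
per-generator child streams by fixed offsets) makes all tables
byte-reproducible.

## Pseudo-bulk statistics and feature tests

Counts are aggregated per cell type (pseudo-bulk sums) or tested per
cell on counts-per-million; because the Wilcoxon rank-sum statistic is
rank-based, any monotone normalization gives the same p value, and the
reported log2 fold changes are taken on group means of the linear CPM
values with a pseudocount ε = 1 (guards empty groups; standard
practice). Two-sided p values use exact enumeration of all label
assignments (midranks, so ties are exact) when both groups have ≤ 5
observations, and the midrank normal approximation with tie and
continuity correction otherwise. BH correction runs across features
within each group's comparison. Mode thresholds: marker peaks
lfc ≥ 0.5 & FDR ≤ 0.1; differential peaks lfc ≥ 0.5 & FDR ≤ 0.25;
marker genes lfc ≥ 1 & expressing fraction ≥ 0.6; pairwise genes
lfc ≥ 0.5, fraction ≥ 0.3, adjusted p < 0.05. Groups with fewer than
3 cells yield p = 1 with a warning rather than an unstable test.

## Metacells and correlation linking

Correlation estimates on single cells are noisy, so cells are
aggregated into metacells: within each cell type, a seeded random
partition into blocks of exactly `k` cells (default 10; remainder
cells dropped). A randomized partition was chosen over
nearest-neighbor aggregation because the aggregation scheme is
internal to the upstream frameworks and unspecified; random blocks
keep the contract simple and testable. Metacell values are member
means of log2(CPM + 1) signal.

Both linking strategies use the product-moment correlation across
metacells with a **signed** cutoff (r > 0.3, not |r|): the linking
semantics are activating (an enhancer opening with its target's
promoter or expression). "Resolution 1" style positional binning is
not applied — peaks enter the correlation individually. Links are
restricted to 250 kb peak-midpoint-to-TSS on the same chromosome. For
promoter co-accessibility, a peak links to a gene when it correlates
with at least one peak overlapping the gene's promoter window; the
promoter peak is never its own partner. Pairs with undefined
correlation (constant vectors) are omitted with a warning.

Marker-gene enrichment of link targets samples 457 markers per tissue
(the size of the focal-tissue marker set in the motivating use case),
computes the fraction found among link targets, and normalizes by the
mean fraction over control tissues.

## Activity-by-contact

Element activity is the geometric mean of ATAC and H3K27ac signal in
the element; contact is read from a symmetric 5-kb binned matrix at
(element-midpoint bin, TSS bin), offset by a pseudocount equal to the
smallest nonzero contact in the scoring window (fallback 1e-6) so
zero-contact bins are not silently dropped; no power-law imputation is
performed. Scores are normalized over all elements within 5 Mb of the
TSS and therefore sum to 1 per gene. Connections require score
strictly above 0.025 and element–TSS distance ≥ 500 bp; elements
overlapping the TSS bin are scored like any other and then removed by
the distance rule. Cross-chromosome pairs are never scored.

## STARR-seq statistics

The module re-implements the statistical essence of the standard
count-based tools rather than wrapping them, so the decision rules are
explicit and testable:

* **QC** — a SNP is kept iff every measured (allele, condition,
  replicate) has ≥ 5 unique barcodes.
* **Size factors** — median-of-ratios over oligos with all-positive
  counts (the DESeq-style estimator). Factors are defined up to a
  common scale; all downstream quantities are ratios, so this is
  immaterial.
* **Enhancer call** — reference and alternative counts are combined
  per SNP; normalized output is compared against input with a Wald
  test under a negative-binomial variance `μ + αμ²`, with a single
  method-of-moments dispersion `α = median((v − m)/m²)` pooled over
  oligos and replicate groups (small replicate numbers preclude
  per-oligo estimates). BH runs across SNPs within each condition;
  the flag needs |log2FC| > 0.585 and adjusted p < 0.05, both strict.
* **Allelic effects** — per replicate `d_r = log2((alt + ε)/(ref + ε))`
  on normalized counts with ε = 0.5 (half-pseudocount; prevents
  infinities; it also means global-depth invariance of the effect is
  exact only in the ε → 0 limit — at depth ~1000 the perturbation is
  in the third decimal). The test statistic is a moderated paired t:
  the per-SNP variance is shrunk toward the pooled across-SNP variance
  with weight `d0/(d0 + n − 1)` (`d0` = pooled degrees of freedom) and
  referred to `d0 + n − 1` df. With 4 replicates the shrinkage is
  strong, which is what makes the test usable at n = 4; per-SNP
  variance heterogeneity beyond the NB model is therefore absorbed
  into the pooled estimate. Degenerate zero-variance cases report the
  floating-point minimum p rather than 0.
* **Functional rule** — functional ⇔ in an enhancer of the same
  condition AND adjusted p < 0.05 AND |log2FC| strictly above the
  80th percentile (linear-interpolation sample quantile) of absolute
  control-SNP effects. The threshold is computed per condition from
  that condition's controls (controls are measured alongside each
  condition); this is configurable, as pooling across conditions is
  an equally defensible reading.
* Technical replicate indexes can be summed into biological
  replicates (`sum_technical_replicates`) before testing, since
  barcode counts are aggregates.

BH families are per condition, separately for enhancer calls and for
allelic effects. Numerical agreement with any specific external
normalization/testing engine is not claimed; the published decision
thresholds are what is reproduced.

## Variant evidence and prioritization

The risk set is the union of variants in LD (R² strictly > 0.5) with
any index variant and the 95% credible set, deduplicated by
(chrom, pos, ref, alt); index variants missing from the LD table are
kept with a warning (proxy substitution is out of scope). Missense
scores classify as likely benign (< 0.34), likely pathogenic
(> 0.565), ambiguous otherwise (boundaries are ambiguous). Peak
enrichment merges each tissue's constituent peaks to a union before
counting variants and unique bases, and normalizes densities to the
control-tissue mean.

Predicted allelic effects aggregate per (variant, cell type) by
averaging log2(alt/ref) over model folds; the one-sided Poisson test
evaluates the fold-averaged alternative count against the
fold-averaged reference count as rate, with the tail chosen by the
sign of the fold change (p = 1 at zero — equal predictions carry no
directional evidence). Fold-averaged counts are generally non-integer,
so the tails use the continuous extension via regularized incomplete
gamma functions, which coincides with the discrete tails at integers.
Cell types combine by Fisher's method (χ², 2k df), BH runs across
variants, and high effect requires any-cell-type |log2FC| > 0.25 with
variant FDR < 0.01.

The HiChIP criterion is operationalized as *variant inside a loop
anchor whose partner anchor overlaps a gene promoter* — the published
rule names only "linked to a gene", and anchoring the gene end at a
promoter window is the strictest reading that yields a target gene.
Variants are single-base events for all intersections; an indel is
represented by its POS base (the assays analyze SNPs; this is a
documented convention, not a claim about indel biology). Inclusive vs
strict boundaries follow the printed inequality of each rule: eQTL
FDR ≤ 0.05 inclusive; ABC > 0.025, R² > 0.5, |log2FC| > 0.25 strict;
FDR < 0.01 strict; prioritized ⇔ criteria ≥ 3.

## Synthetic data: what it emulates and what it cannot show

All sequencing-like counts are negative-binomial via a gamma–Poisson
mixture, matching the overdispersion assumed by the downstream tests.
The default genome is two synthetic 10-Mb chromosomes, which keeps
runtimes in seconds while still exercising cross-chromosome exclusion
rules.

* **Multiome** (600 cells, 3 types, 300 peaks, 120 genes by default):
  planted marker features are 4-fold elevated in their type; each of
  the 50 planted links ties a distal peak, a promoter peak and a gene
  to a shared log-normal latent factor such that the log-rate
  correlation equals the configured strength (0.8). Observed metacell
  correlations are attenuated below the target by count noise —
  by roughly 25% at the default rates — which the recovery tests
  account for; in the noise-free limit (`count_noise=False`, strength
  1.0) planted pairs are exactly proportional and correlate at 1.
* **STARR** (1,000 SNPs + 400 controls, 4 replicates, 3 conditions):
  mean depth 1,000 unique barcodes per oligo and NB dispersion 0.02.
  The depth matches the scale of output libraries in the motivating
  assays; the dispersion reflects their very high replicate
  reproducibility and is chosen once for testability — real input
  libraries are substantially deeper and real dispersions are not
  published. Planted enhancers multiply output means by 2^lfc; planted
  allelic SNPs multiply the alternative allele by 2^lfc. A planted
  enhancer flagged must-detect with |log2FC| ≤ 0.585 is rejected at
  generation time, since the call could never fire on it.
* **ABC**: contacts decay as `(1 + |i − j|)^(−γ)` (γ = 1) with
  optional symmetric log-normal noise; one planted high-activity
  element (activity 50 vs background mean 0.5) sits 3–10 bins from
  each TSS, so planted connections dominate the score mass while an
  occasional background element near a TSS keeps the false-call test
  honest.
* **Variant sets**: 6 loci with index variants, LD satellites above
  and below the R² cutoff, credible-set-only variants and deliberate
  overlap to exercise deduplication. A configurable number of variants
  is planted with ≥ 3 evidence channels (default 8) or 1–2 channels
  (default 10); each planted channel has a noise-free support record
  (link row, loop, eQTL row, predicted counts), so channel recovery is
  deterministic given the seed. Because a functional SNP is by
  definition inside an enhancer, planting `functional_snp` implies
  `in_starr_enhancer`. In the assembled dataset the STARR channels of
  channelled variants are planted as real effects in the count tables
  and recovered statistically by the STARR stage.

What passing tests do **not** show about real data: the generators
plant block-structured cell types with independent features (no
batch/donor structure, no compositional coupling beyond library size,
no LD-induced correlation among variant effects, no sequence content
at all), so the suites validate the decision rules and their
calibration, not robustness to the confounders of real tissue atlases.

## Problem sizes

Defaults were chosen so the full test suite runs in well under a
minute on one CPU: 600-cell multiome, 1,000–1,400 oligo STARR tables,
20-seed null-calibration loops, 60-element ABC inputs. All are
configuration fields, and every generator scales linearly in its
dimensions if larger studies are wanted.

## Known limitations

* The NB Wald enhancer test with a single pooled dispersion is
  anti-conservative when true dispersions vary strongly across oligos;
  the null-calibration suite covers the homogeneous-dispersion regime
  only.
* The moderated allelic test shrinks hard toward the pooled variance
  (pooled df ≫ per-SNP df), effectively assuming exchangeable
  replicate noise across SNPs.
* Enrichment densities use merged-peak unique bases with no GC/width
  matching of control peak sets.
* The pipeline's linking, ABC and STARR stages run on the synthetic
  dataset generated from the configured seed; wiring external tables
  through the pipeline requires using the module functions directly
  (each reads/writes the documented TSV/BED/VCF formats).
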