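# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `humiclink`.

## Study system and design assumptions

The analysis targets a two-ecotype lake system: 8 humic lakes (high dissolved
organic carbon, water colour ~172–752 mgPt/L) and 8 clear-water lakes (colour
~15–30 mgPt/L), with 1–2 fish sampled per lake and up to five tissues per
fish (gill, spleen, olfactory rosette, whole eye, liver). Genotypes come from
RNA-seq-derived variant calls, so every layer operates on the same
individuals. Outlier SNPs — putative targets of divergent selection — are an
*input* label set (10,245 of 810,591 genome-wide SNPs in the reference
tallies); their discovery (genome-scan δ thresholding plus
genotype–environment association) is out of scope here, though the package
ships the δ utilities (`compute_delta`, `flag_outliers_by_delta`) used to
validate the generator.

## Differential expression

DESeq2-style negative-binomial machinery is deliberately replaced by a
Gaussian linear model on log2 normalized counts: per-gene OLS with design
`~ log10(latitude) + log10(total length) + sex + ecotype` (clear = 0,
humic = 1, so a positive coefficient means up-in-humic), two-sided p from the
t distribution with n − k df, BH within tissue, DEG at p-adj ≤ 0.05. The
rationale: the package's scientific surface is the enrichment and integration
layers; DEG calls are pluggable (`ingest_deg_table`) so externally computed
tables can be substituted bit-for-bit. At the planted effect sizes used in
validation (|log2FC| = 2, n = 32) the Gaussian approximation recovers 100% of
planted DEGs with unbiased effect estimates (|mean bias| < 0.1), and under a
global-null simulation the per-gene p-values are uniform (KS test).

Normalization is plain median-of-ratios: size factor = median over genes
positive in all samples of count / geometric mean, output
log2(count/sf + 1); if no gene is positive everywhere the code falls back to
total-count scaling with a logged notice.

Sample QC replaces by-eye MDS outlier exclusion with an auditable rule:
classical (Torgerson) MDS on a pluggable distance (default Euclidean on the
log2 matrix; the original analysis used a Poisson distance, which is QC-only
and not part of the scientific surface), flagging samples whose distance from
the coordinate-wise median exceeds the median distance by more than 4 MADs.
Flagged samples are recorded in the manifest.

The up/down direction-imbalance test is a plain 1-df 50:50 goodness-of-fit
chi-square (continuity correction available as a toggle). Note: the source
analysis reports imbalance chi-squares that match neither the plain nor the
corrected statistic on the printed counts (e.g. liver (144, 97) gives 9.17
plain, not the printed 4.62); since the exact form used there is unknowable
from the text, both variants are surfaced and neither is forced to agree.

## Outlier enrichment permutation test

Statistic: `freq_DEG − freq_nonDEG`, `freq = outliers/(outliers+non-outliers)`
within the DEG-window and nonDEG-expressed-window SNP classes. Null:
reassign the fixed number of outlier labels uniformly at random without
replacement across **all** SNPs (including unassigned), which preserves the
genome-wide outlier count and inherits the SNP-density differences among
genes. Class-wise outlier counts under this shuffle are multivariate
hypergeometric, so replicates are drawn directly from that distribution —
distribution-identical to an explicit label shuffle at O(1) cost per
replicate. Exhaustive mode enumerates (x, z) outlier-count pairs with exact
integer combinatorics, covering all C(n, k) placements without materializing
them; it switches on automatically at ≤ 10⁵ placements.

Two p-values are reported: `p_paper` = #{permuted statistic **strictly**
greater than observed}/n_perm (this is the convention of the source tables
and can return 0) and the add-one Monte-Carlo estimator
`p_mc` = (#greater + 1)/(n_perm + 1). Ties favour significance under the
strict comparison; tie counts are reported (`n_perm_equal`) and a fully tied
null is flagged degenerate. Deficiency uses the mirrored strictly-smaller
count. Tie comparisons are exact integer cross-multiplications
(`m·(x−od) vs d·(z−on)`), never float equality. Calibration: type-I error at
α = 0.05 using `p_mc` is ~0.05 (measured 0.0515 over 2000 null simulations).

SNPs in overlapping DEG and non-DEG windows are classed DEG (precedence
rule, recorded in the manifest); the per-tissue gene universe is the set of
genes surviving the low-count filter in that tissue.

Per-category contrasts: for each annotation category, a 2×2 of
(outlier, non-outlier) × (SNPs of that category in DEG windows, in all
expressed-gene windows), chi-square with Yates correction by default
(toggleable — whether the original analysis corrected is unstated, so both
variants are available); categories with an expected cell < 1 or absent from
DEG windows are skipped with a notice.

## cis-eQTL scan

Candidate pairs: SNP within [gene start − 50 kb, gene end + 50 kb], same
chromosome, closed interval. Model: OLS of log2 normalized expression on
dosage + sex + ecotype + PC1 + PC2 (genotype PCA on standardized dosages,
scores z-normalized, sign fixed by the largest loading). Including ecotype
means detected eQTLs are effects *beyond* the ecotype mean shift. The
implementation residualizes both expression and dosage on the covariates
(Frisch–Waugh–Lovell), giving exact OLS t statistics at vectorized cost;
p-values use n − k df and are floored at 1e-300. BH is applied across all
tested pairs within a tissue (not per gene); significance at FDR ≤ 0.05.
Variant filters before the scan: MAF ≥ 0.10 (inclusive) and removal of SNPs
whose observed genotypes are exclusively heterozygous (no homozygote
observed ⇒ no additive contrast).

eSNP outlier enrichment: 2×2 rows are (genome-wide outlier, genome-wide
non-outlier) and (eSNP outlier, eSNP non-outlier) — the rows are kept
non-disjoint exactly as tabulated in the reference analysis, which is what
reproduces its printed p-values (0.087 gill, 0.809 eye, 0.741 liver) —
Yates statistic Σ(max(|O−E|−0.5, 0))²/E with 1 df. Combined-tissue counts
are unions of distinct pairs/SNPs/genes across tissues.

## Synthetic-data generator

The generator's defaults are the study conditions; everything downstream is
validated against planted truth.

* **Lakes/samples**: 8 + 8 lakes with ecotype-conditional DOC and colour
  drawn uniformly from the observed (disjoint) survey ranges; latitude
  57.5–59.5; 2 fish per lake, sexes alternating, total length ~N(185, 30) mm.
* **Genotypes**: per-SNP ancestral frequency uniform in [0.05, 0.95];
  per-lake frequency Beta(p(1−F)/F, (1−p)(1−F)/F) (Balding–Nichols) with
  default F = 0.15, which realizes pairwise Hudson FST ≈ 0.14–0.16, inside
  the study's observed 0.07–0.43 range; F = 0 is the exact no-drift limit;
  genotypes Binomial(2, lake frequency), never missing. Outliers
  (default 1.26% of SNPs) get their two ecotype base frequencies separated by
  δ (default 0.35) *before* drift, centred on the ancestral frequency and
  clipped into [0.01, 0.99] to avoid fixation artifacts; the realized
  pair-mean δ at planted outliers is within ±0.05 of the target.
* **Expression**: log2 mean = baseline + covariate effects + ecotype × log2FC
  (planted DEGs, per tissue) + β × dosage (planted cis-eQTLs, shared across
  tissues, SNP drawn inside the ±50 kb window from a configurable
  realized-MAF band, default 0.10–0.50). Baseline log2 means are uniform in
  [5, 12] (32–4096 mean counts) — the regime of genes that *survive* the
  low-count filter, which is the population the DE test actually sees.
  Counts are NB with variance μ + μ²·dispersion (default dispersion 0.1)
  scaled by log-normal(0, 0.1) library factors. Default per-tissue DEG
  fractions follow the observed DEG/expressed ratios (gill 0.234 … liver
  0.016); planted log2FCs are uniform in [0.5, 2] with random sign.
* **δ conventions**: the pair-mean definition (mean over all humic×clear
  lake pairs of |p_h − p_c|) is the default, read literally from "difference
  between humic and clear-water lakes"; the ecotype-mean contrast is
  available as an option since the source text does not disambiguate.
* **RNG**: one root seed; every stage draws from a named CRC32-keyed
  SeedSequence substream, so stages are independently reproducible and
  identical config+seed gives byte-identical outputs.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
independent given lake frequencies), read-level artefacts (mapping bias,
GC/length effects), isoform structure, shared-environment expression
covariance beyond the modelled covariates, and gene–gene correlation.
Passing tests therefore demonstrate correctness of the statistical machinery
under the stated model, not robustness to LD-induced dependence among SNP
labels (the permutation test shuffles labels independently, as the original
analysis did) or to count artefacts the NB model misses.

## Problem sizes and numerical choices

Validation and the acceptance script use deliberately scaled-down instances
chosen to keep each check well-powered: 300 genes × 6000 SNPs × 32 samples
for the recovery analyses (3 replicate seeds, ≥180 planted effects per
rate), 400 null datasets × 400 permutations for type-I calibration, and a
50-gene two-tissue configuration for the byte-reproducibility check. The
default pipeline configuration (400 genes, 8000 SNPs, 5 tissues, 1000
permutations) runs in a few seconds.

Tolerances and conventions: medians are the mean of the central order
statistics; Mann–Whitney U is exact for group sizes ≤ 20 (two-sided by
doubling the smaller tail), tie-corrected normal approximation above — with
ties at small n the exact method is unavailable and the code falls back to
the normal form; MAF thresholds are inclusive; flanks extend closed
intervals and are clamped at position 1; percentages print to 1 dp,
frequencies to 4 dp, p-values to 3 dp in human-readable tables with full
precision in machine-readable output; a zero-variance gene gets p = 1 and a
flag rather than an error; a monomorphic-everywhere population pair yields
FST = NaN with a warning.

## Known limitations

* The Gaussian DE stand-in loses power relative to a dispersion-shrinking NB
  model at small counts; at the planted effect sizes used for validation
  this is immaterial, but real borderline DEGs may differ — hence the
  pluggable DEG-table entry point.
* The automated MDS exclusion rule is a reproducible proxy for a judgement
  call; with real data its 4-MAD threshold should be reviewed against the
  plots.
* Strand-aware upstream/downstream labels are kept for the category table,
  but window assignment itself is symmetric (the enrichment needs only the
  window).
* Up to 5 sets in Venn region counts; larger collections should be reported
  as pairwise overlap matrices.
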