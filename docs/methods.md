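# Methods

`methylink` analyzes a tumor cohort profiled by whole-genome bisulfite
sequencing (WGBS) and RNA-seq against a panel of normal controls.  Its
stages are: (1) build an averaged control methylation profile, (2) call
differentially methylated cytosines (DMCs) and regions (DMRs) per
tumor, (3) annotate calls to genomic elements, (4) compute per-tumor
expression fold changes with a significance contract, (5) intersect
calls across tumors into recurrence signatures and integrate promoter
methylation change with expression change.  A synthetic-data generator
with recorded ground truth makes every stage testable offline.

## Differential methylation model

**Control profile.**  Each control contributes a per-CpG methylation
percent (methylated reads / coverage) at CpGs covered at least 5x
(after optional symmetric-CpG strand merging, on by default).  The
profile keeps CpGs covered in *all* controls (configurable to "any")
and averages the per-control percents with equal weight — not pooled
read counts — so deeply sequenced controls do not dominate.

**DMCs.**  A CpG common to tumor and profile is hypomethylated when
tumor − control ≤ −10 percentage points, hypermethylated when ≥ +10,
otherwise unchanged; thresholds are inclusive ("at least 10%").  Every
common CpG receives exactly one class, so the three counts always sum
to the common-set size.

**Why no per-site rank test.**  A rank test of one tumor value against
five control values cannot reach p < 0.05 (the best attainable
two-sided p is 1/3 at n=1 vs 5), so significance is assessed at the
region level.  An optional per-site Fisher exact test on read counts
(tumor meth/unmeth vs pooled control counts) is available behind
`site_test="proportion"`, off by default.

**DMR segmentation.**  Sorted DMCs are split into maximal runs that
share a chromosome and direction and whose adjacent positions are at
most 100 bp apart; runs of at least 3 CpGs become candidates.  The
segmentation is exactly the maximal-run decomposition: a unit test
checks equality with exhaustive search over random inputs.

**Region test.**  Each candidate is tested with a Mann–Whitney U over
its member CpGs: the k tumor percents versus the k control-mean
percents.  For k ≤ 8 per side the null distribution is enumerated over
all C(2k, k) assignments of the pooled values, which is exact under
ties as well (midranks are used for the statistic; the permutation is
over the observed values).  For larger k a normal approximation with
midranks, tie-corrected variance and continuity correction is used.
The test is one-sided in the candidate's direction with an inclusive
acceptance threshold p ≤ 0.05, so that the minimal 3-CpG region with
complete separation (exactly p = 1/20 = 0.05) is callable — under a
strict inequality the stated minimum region size could never pass.
Both choices are flags (`sided`, `alpha`).  No multiple-testing
correction is applied by default (raw p-values throughout);
Benjamini–Hochberg is available behind `bh_correct`.

## Annotation

Promoters span −1500 bp to +500 bp around the TSS, strand-relative,
with the TSS base itself counted as downstream position +1: a
plus-strand TSS at 1-based t gives the BED interval
[t−1−1500, t−1+500), mirrored for minus strand and clipped at zero
(width 2000 bp before clipping).  Features are annotated to every
element class they overlap by ≥ 1 bp (non-exclusive, matching
`bedtools intersect` semantics); an exclusive mode with priority
promoter > exon > intron > gene body > enhancer > repeat is provided
for distribution summaries.  Promoter methylation is the unweighted
mean of covered member-CpG percents; means are binned with edges
[0,25], (25,50], (50,75], (75,100] — the bin labels are integer-styled
but the means are continuous, so the left bin is closed at exactly 25.
Expression-by-bin comparisons use Welch's two-tailed t-test by default
(a pooled-variance flag exists); bins with fewer than two genes report
NaN rather than erroring.

## Expression

FPKM = count · 10⁹ / (gene length in bp · library size), with library
size the raw column sum — hence invariant to rescaling a column's
counts.  Per-tumor fold change versus the control mean uses a
pseudocount ε = 0.1 on both sides: FC = (tumor + ε)/(mean(controls) + ε),
keeping zero-expression genes finite with negligible distortion at
FPKM ≥ 1.  Significance per gene per tumor comes either from an
imported differential-expression table (e.g. a DESeq2 export, passed
through unchanged) or from an internal two-sided normal z of the
tumor's log2(FPKM+ε) against the control-replicate distribution.  The
internal test is an explicit approximation for the one-tumor-versus-
replicates design, not a negative-binomial model; fold changes are
computed from FPKM in both modes so the routes agree on FC.
"Decreased at least 2-fold" is interpreted symmetrically: FC ≤ 0.5.

## Recurrence signatures and integration

Cross-tumor DMR identity is ≥ 1 bp overlap with single-linkage
clustering of same-direction calls; each cluster's merged interval is
the union of its members (contiguous, since clusters are chained by
overlap), and a cluster supported by at least `n_required` distinct
tumors becomes one signature region.  Because clusters do not depend
on `n_required`, signatures are nested (anti-monotone) in it.  An
optional reciprocal-overlap fraction can be demanded on top.

Promoter DMR frequency counts, per gene and direction, the number of
tumors with at least one overlapping DMR in the promoter window (a
tumor counts once regardless of multiplicity).  Integration classifies
a gene hypo_up when its promoter is hypomethylated in at least
`meth_min_tumors` tumors (default 6 of 7) *and* it is up-regulated
(FC ≥ threshold, p < alpha) in at least `expr_min_tumors` tumors
(default: a majority); hyper_down is the mirror.  Two named threshold
profiles are shipped, `fig5a` (FC ≥ 2.0) and `text25` (FC ≥ 1.5),
because the source analyses quote both; the choice is a config knob.
The gene-effect lethality screen thresholds a supplied genes × cell
lines matrix at ≤ −1 (inclusive) and counts lines by lineage; the
matrix semantics are the caller's responsibility.

## Synthetic cohorts

The generator emulates the structure such a study observes:

- **Genome**: 2 chromosomes × 1 Mb, 300 genes in fixed slots with
  alternating strand, two 500 bp exons per gene, enhancers in the
  intergenic slack, repeats tiled to cover 15% ± 2% of the genome.
- **CpGs**: exponential spacing with 100 bp mean; background
  methylation from a two-component Beta mixture, Beta(8,1) at weight
  0.7 (high mode) and Beta(1,8) at 0.3, reproducing the dominant
  ≥ 75% bin of real T-cell methylomes.
- **Samples**: 5 control and 7 tumor methylomes, 4 control and 10
  tumor expression libraries — the cohort shape of the study design
  the package targets.  Controls deviate from the shared latent state
  by per-sample per-CpG logit-normal jitter (σ = 0.3); tumors deviate
  only through the planted shifts plus read sampling.
- **Reads**: coverage ~ Poisson(30) floored at 5; methylated counts
  Binomial(coverage, μ).
- **Planted DMRs**: blocks of 6 CpGs spaced 50 bp inside a chosen
  element class, shifted by ±30 points in a configurable subset of
  tumors ("all", k-of-n, or an explicit mask).  Each block draws one
  regional baseline (so member CpGs are coherent, as in real
  methylation domains) from a range that keeps baseline + shift inside
  [0, 100].  The default plants 20 hypomethylated and 10
  hypermethylated promoter blocks present in every tumor.
- **Expression**: negative-binomial (Gamma–Poisson) counts with
  dispersion 0.1 around log-uniform base means (10^1.3–10^3); 15
  universally up (FC 4) and 5 universally down (FC 0.25) genes planted
  among genes without promoter blocks; 60% of hypo-promoter genes are
  coupled up (FC 4) and 80% of hyper-promoter genes coupled down
  (FC 0.25), giving 12 + 8 coupled genes at the defaults.
- **Noise-free mode**: the infinite-coverage analog — methylation
  percents equal the latent state to 0.01%, and expression is emitted
  as exact per-gene abundances in FPKM units — used for limit checks
  where estimates must equal planted values exactly.

Identical config + seed reproduces every output byte for byte (one
`numpy` Generator drives all draws).

**What the generator does not model**, and hence what passing tests do
not show about real data: tumor purity and copy-number effects,
bisulfite conversion error, positionally correlated background
methylation outside planted blocks, isoform structure, batch effects,
and library-composition extremes.  On composition: FPKM's total-count
normalization means a large planted fold-change mass deflates the
estimated FCs of other genes; at the default 300-gene complement this
shift is a few percent, which is why the default gene count is not
smaller.

## Calibration notes and known limitations

- At ~30x coverage, read sampling alone places roughly 11% of CpGs
  past the 10-point threshold when one control is compared to the
  average of the others; with the default σ = 0.3 jitter the
  leave-one-out "unchanged" fraction is ~85%.  A higher concordance
  would require deeper simulated coverage, not a code change.
- Genome-wide false DMR calls under the null are far rarer (< 0.1% of
  candidate 3-CpG windows) because a false region needs three
  same-direction exceedances plus a passing rank test.
- Benchmarks and tests run on scaled-down cohorts (tens to hundreds of
  genes, 0.2–2 Mb genomes, 2–7 tumors); these sizes were chosen so the
  full suite exercises every stage end-to-end in well under a minute
  per scenario while keeping Monte-Carlo error small relative to the
  asserted margins.
- The internal expression test is a z-approximation; for
  publication-grade differential expression an imported DESeq2 table
  should be supplied via `de_table(source="imported")`.
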