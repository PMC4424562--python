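# Methods

This note documents the models, the statistical procedures, the synthetic
data they are validated on, and the design choices made where the design
was genuinely open.

## The assay model

MBD-capture sequencing enriches methylated DNA with a methyl-CpG-binding
domain protein, so read density at a locus reflects methylated-CpG density
— the product of CpG density and methylation level. Two consequences shape
the pipeline. First, loci with few CpGs are invisible to the assay
regardless of their methylation state; the *assayable-locus mask* is
therefore built from a fully methylated (SssI-treated) control, keeping
only 300 bp windows whose control coverage reaches the tag threshold
of 18, with greedy selection by descending count and suppression of
candidates within 300 bp of a selected locus. Second, differential read
density between conditions at an assayable locus reflects differential
methylation, which is tested on counts, not on inferred methylation
levels — the pipeline never converts capture counts to absolute
methylation.

## Statistical core

**Negative-binomial exact test.** Counts are scaled to the mean library
size (total count within the mask), summed per group, and the observed
split of the locus total is compared with its conditional null
distribution: group sums are NB with means proportional to group sizes and
per-group size n_g/φ (Poisson when φ = 0, in which case the conditional
law is binomial and the test reduces to the exact binomial test). The
two-sided p is the sum of probabilities of outcomes as or less likely than
the observed one, ties included — this convention is what the enumeration
oracle in the test suite checks exactly.

**Common dispersion.** A single φ is estimated by pooled method of
moments on library-size-scaled counts: φ = max(0, Σ(v−m)/Σm²) over rows,
with row moments taken *within* condition groups so genuine
between-condition differences do not inflate the estimate.

**Moderated t.** Per-row pooled variances are shrunk toward a prior
(d₀, s₀²) fitted by method of moments on log sample variances (matching
the mean and excess variance of log s² under the scaled-F model, with a
Newton inversion of the trigamma function); the posterior variance
s̃² = (d₀s₀² + ds²)/(d₀+d) feeds a t statistic on d₀+d df. The moment fit
was chosen over full maximum likelihood because it is stable at the
four-donor sample sizes this pipeline targets; at that scale the
difference is immaterial.

**Tile aggregation.** Adjacent significant 1 kb tiles of the same sign
are merged and their p-values combined by Fisher's method
(X = −2 Σ ln pᵢ ~ χ²₂ₖ). Fisher's method is the standard aggregate
statistic over per-tile p-values; a 2×2 exact test has no natural role in
combining tile statistics, so this is the implemented interpretation.

**Permutation enrichment.** The null re-draws |query| loci uniformly with
replacement from the universe members (a bootstrap of loci) rather than
shuffling intervals across the genome. This preserves the length and
CpG-density structure of the assayable compartment, which drives MBD
coverage; genomic shuffling would compare against placements the assay
could never produce. The empirical p uses (1 + exceedances)/(1 + n_perm),
mirrored for depletion.

**Multiple testing.** Benjamini–Hochberg step-up within each testing
family (per contrast, per mark, per enrichment family), never pooled
across families.

## Stable DMRs

"Stably maintained" is operationalised as: BH-adjusted p < 0.05 in *both*
the early-vs-HMEC and late-vs-HMEC contrasts with the same fold-change
sign. This is the strictest reading consistent with reporting both time
points; a fused three-group model would be less specific about
maintenance.

## Chromatin states

Mark presence/absence over segments (flat segmentation at every region
boundary) maps to states by precedence: K4me3∧K27me3 → Bivalent Promoter;
K4me3∧K27ac → Promoter 1; K4me3∧K36me3 → Promoter 3; K4me3 alone →
Promoter 2; K27ac∧K36me3 → Transcribed Enhancer; K27ac (without K27me3) →
Enhancer; K27me3 without K4me3 → Polycomb Repressed; K36me3 alone →
Transcribed; nothing → Unclassified. Bivalency dominates; the conflicting
K27ac∧K27me3 (no K4me3) vector falls to repression, which dominates in the
literature for that combination. The table is exhaustively tested over all
16 vectors and is swappable in code.

## LREA/LRES detection

A window of five consecutive genes (by TSS order) seeds a domain when at
least three genes exceed |t| > 3 concordantly in one data type —
activation meaning expression or promoter H3K9ac up, or H3K27me3 down;
silencing the mirror image. Overlapping same-type seed windows merge and
the domain spans its first to last concordant gene. Missing statistics
count as non-concordant. The window size and concordance count are the
conventional declared defaults; the t threshold of 3 (rather than 2) is
this package's choice: with three to four samples per condition the
chromatin t statistics carry only ~4 df, and at |t| > 2 chance concordance
produces several false domains per few-hundred-gene null genome, while at
|t| > 3 the null genome is clean and implanted blocks are still fully
recovered. All three parameters are exposed.

## Biomarker ROC selection

Regions are scored per sample by mean beta over member probes (per-probe
AUC is also available; the region mean is the default because the
published analysis scored regions by their overlapping probes). The cohort
is split 75/25 by seeded stratified sampling; regions are ranked by
training AUC and gated on test AUC — 0.95 for tumour vs normal, 0.7 for
basal-like vs other tumours, the basal path additionally requiring at
least one member probe significantly hypermethylated in basal tumours
within the training cohort. Differential probes are tested on M-values,
M = log2((β+ε)/(1−β+ε)) with ε = 0.01, which keeps β = 0 and 1 finite.
Spread extension walks outward probe by probe while the next probe is
significantly hypermethylated in the *training* cohort (BH < 0.05,
Δβ > 0.1), tolerating one non-significant probe; it is idempotent and
never consults the test cohort, which is also verified by a hash check on
all training outputs.

## miRNA quantification

ΔCt = Ct − mean(control Ct) per sample; ΔΔCt = mean ΔCt(target) −
mean ΔCt(reference); fold = 2^−ΔΔCt. Lowly expressed miRNAs (undetected,
Ct = 40, in more than half the samples) and invariant miRNAs (ΔCt
variance < 0.05) are excluded before testing; the Ct = 40 sentinel and
both filter thresholds are declared conventions, exposed in the API.
Differential calls use a per-donor paired t on ΔCt with raw p < 0.05 as
the primary call (BH-adjusted p is reported alongside). Predicted targets
require mirSVR strictly below −0.5; validated targets pass regardless.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the analysis assumes,
at a desk scale of two chromosomes totalling 10 Mb with ~400 genes:

* **Capture counts**: NB per 300 bp window with mean
  depth × CpG-weight × methylation level; depth 30; dispersion 0.05,
  reflecting replicate cultures of isogenic donor lines rather than the
  larger dispersions typical of tissue cohorts. CpG weight is a
  two-component mixture (low background, high in islands); baseline
  methylation is low at most island windows and intermediate-to-high
  elsewhere. Implanted DMRs shift the vHMEC level by ±0.4 over 2–3
  consecutive CpG-dense (weight ≥ 0.8) windows — capture-based calling
  can only see change where the assay attracts reads at all, so
  implanting DMRs at CpG-poor windows would test the assay, not the
  caller. Counts are simulated per window, not per read: the pipeline's
  first computation is window counting, so read-level simulation would
  add cost without exercising more code.
* **ChIP counts**: NB over 200 bp windows, background mean 2, enrichment
  fold 8; punctate TSS peaks for narrow marks, multi-kilobase domains for
  broad marks; LRES blocks gain H3K27me3 and lose H3K9ac in vHMEC with
  expression down, LREA blocks the reverse. H3K9ac is simulated as window
  counts even though it can equally arrive as pre-normalised array
  signal; the TSS-block statistics consume either.
* **Expression**: Gaussian log2 values with per-donor random effects
  (sd 0.3), noise sd 0.5, and a ±2 log2 shift for affected genes applied
  to every vHMEC sample — consistent between early and late passages.
* **Beta matrices**: Beta-distributed with concentration 30; 120 tumours
  and 60 normals (a ~5× scale-down of the real cohort — shrinking
  further makes the 25% test cohort too small to support the 0.95-AUC
  specificity the selection relies on); marker probes +0.4 in tumours,
  basal markers +0.4 only in basal-like tumours (30% of tumours), one
  flanking probe per side +0.25 ("spread").
* **Ct tables**: Ct = base + donor effect − log2(fold) + noise
  (technical sd 0.3, donor sd 0.7); donor effects are shared by the
  paired cultures and cancel in paired contrasts. Four miRNAs are
  implanted at fold 0.25; undetected miRNAs carry the Ct = 40 sentinel.

What the generators do **not** emulate: per-molecule methylation
patterns (a continuous level per window summarises clonal heterogeneity,
since capture resolves density, not patterns), copy-number structure,
read-level artefacts (duplicates, mappability), array probe cross-
reactivity, batch effects, and the tail behaviour of real cohort
variability. Passing recovery tests therefore demonstrates correctness of
the algorithms under their stated model, not robustness to artefacts the
model excludes.

## Numerical choices and degenerate inputs

Coordinates are 0-based half-open everywhere; 1-based gene tables convert
at the reader boundary; chromosome names compare as exact strings. NB
enumeration includes ties with a relative tolerance of 1e-9. Fisher
combination clamps p = 0 to the smallest positive double. AUC counts ties
as ½ via midranks. Zero within-group variance in every row of a moderated-
t input falls back to a floored variance with a warning flag; a constant
count matrix yields dispersion 0 with a warning; an empty window set
yields an empty mask with a warning. All randomised operations take
explicit integer seeds; splits and permutations are reproducible.

## Scale of the shipped analyses

The test suite and the acceptance script run the full pipeline at the
desk scale above (33,333 windows, ~1,100 assayable loci, 50,000 ChIP
windows, ~1,900 array probes, 180-sample cohorts, twenty cohort draws for
the biomarker specificity check) — sizes chosen so a complete run
finishes in about a minute while every stage still operates well inside
its asymptotic regime.

## Known limitations

The broad-caller's FDR refinement is exposed but defaults to the fixed
tag-threshold path; input-chromatin normalisation and local-background
filtering are deliberately absent (the profiled settings disabled them);
the gene-set module implements the hypergeometric overlap test, not the
weighted running-sum enrichment statistic; and the LRER caller reports
one region per seeding data type, so a block supported by all three data
types appears once per type rather than as a single fused record.
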