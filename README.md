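# epiremodel

Analysis pipeline for long-range epigenetic remodelling in the HMEC/vHMEC
model of early breast carcinogenesis.

Human mammary epithelial cells (HMEC) grown past the stress-associated
senescence barrier give rise to variant cells (vHMEC) that resemble the
basal-like breast-cancer subtype. Profiling these isogenic pairs reveals
the very first epigenetic changes of carcinogenesis: focal DNA methylation
change at CpG-dense loci, redistribution of histone marks, and multi-gene
domains of concordant activation (LREA) or silencing (LRES). This package
re-implements that computational analysis as a tested, reusable library:

* **MBD-capture methylome** — an *assayable-locus* mask is built from a
  fully methylated (SssI-treated) control, because MBD capture coverage
  tracks methylated-CpG density (windows of 300 bp, minimum spacing
  300 bp, tag threshold 18); read-density change between HMEC and vHMEC
  is then tested per locus with a negative-binomial exact test
  (counts scaled to a common library size, conditioned on the locus
  total, common dispersion by pooled method of moments). A locus is a
  **stable DMR** when both the early- and late-passage contrasts are
  significant (Benjamini–Hochberg adjusted p < 0.05) with the same sign.
* **ChIP domains and chromatin states** — narrow peaks
  (H3K4me3-like: threshold 10, size 600, spacing 600) and broad domains
  (H3K27me3/H3K36me3/H3K27ac: threshold 40, size 2000, spacing 4000) are
  called from window counts; large regions are split into 1 kb tiles,
  tested per tile, and adjacent significant tiles are re-merged with an
  aggregate p-value from Fisher's combined probability method
  (X = −2 Σ ln pᵢ ~ χ² with 2k df). Mark combinations classify segments
  into eight functional states (Promoter 1–3, Bivalent Promoter,
  Enhancer, Transcribed Enhancer, Transcribed, Polycomb Repressed).
* **LREA/LRES domains** — per-gene t-statistics for expression
  (empirical-Bayes moderated t), promoter H3K9ac and H3K27me3 (ordinary t
  on TSS ± 2 kb signal) are scanned in windows of five consecutive genes;
  three or more concordant genes (|t| > 3) seed a domain.
* **Enrichment** — interval overlap enrichment by locus-bootstrap
  permutation (fold and empirical p), and hypergeometric gene-set tests.
* **Methylation biomarkers** — candidate regions are scored by mean beta
  over member array probes, the cohort is split 75/25 (stratified,
  seeded) into training and test sets, regions are ranked by training
  AUC, and kept only when the *test* AUC exceeds 0.95 (tumour vs normal)
  or 0.7 (basal-like vs other tumours, additionally requiring a
  basal-hypermethylated member probe). Selected regions are extended over
  immediately adjacent probes that are themselves hypermethylated in the
  training cohort ("methylation spread").
* **miRNA qPCR** — ΔΔCt quantification against control genes
  (fold = 2^−ΔΔCt), low/invariant expression filters, per-donor paired t
  tests, and intersection of silenced-miRNA targets (mirSVR < −0.5, plus
  validated entries) with up-regulated genes.

A first-class synthetic-data module generates every input with the
statistical structure the analysis assumes — CpG-density-dependent capture
counts with an SssI control, peak/domain ChIP counts, donor-structured
expression, tumour/normal beta matrices with implanted markers and spread
probes, and Ct tables — together with a ground-truth manifest, so the whole
pipeline is exercisable and scoreable without any downloads.

## Worked example

```python
from epiremodel import pipeline

pipeline.run_simulate("demo", seed=7)       # writes all synthetic inputs
loci = pipeline.run_assayable("demo")       # SssI mask
print("assayable loci:", len(loci))
results = pipeline.run_dmr("demo")          # stable DMR calling
```

prints

```
assayable loci: 1144
DMR summary: {'n_hyper': 83, 'n_hypo': 15, 'n_loci_tested': 1144, 'n_stable': 98}
```

— of 33,333 genome windows, 1,144 attract enough SssI-control reads to be
assayable, and 98 of them change methylation stably across both vHMEC
passages (83 hyper-, 15 hypomethylated; the generator implanted 60 hyper
and 20 hypo regions of 2–3 windows each, so multi-window regions produce
more than one stable locus). The miRNA stage on the same workspace
recovers the four implanted silenced miRNAs:

```
mir-001  p=0.0010  fold=0.2208
mir-002  p=0.0001  fold=0.1699
mir-003  p=0.0014  fold=0.3144
mir-004  p=0.0000  fold=0.2543
```

all near the implanted four-fold loss (fold 0.25). The same stages are
available from the shell:

```sh
epiremodel simulate --seed 7 --out-dir demo
epiremodel assayable --out-dir demo
epiremodel dmr --out-dir demo
epiremodel mirna --out-dir demo
```

## Layout

```
src/epiremodel/
  intervals.py   interval algebra (0-based half-open, sorted sweeps)
  io.py          BED / TSV / GMT / refFlat-like / YAML readers and writers
  stats.py       moderated t, NB exact test, BH, Fisher combination,
                 Mann-Whitney AUC, hypergeometric, permutation enrichment
  simulate.py    synthetic genome, truth manifest, all input generators
  methylome.py   assayable-locus mask and stable DMR calling
  chip.py        region calling, 1 kb tiling, differential blocks, TSS stats
  states.py      chromatin-state classification and segmentation
  lrer.py        LREA/LRES domain detection
  enrichment.py  interval and gene-set enrichment
  biomarker.py   ROC train/test selection and probe-spread extension
  mirna.py       ddCt quantification and target intersection
  pipeline.py    file-level stage runners
  cli.py         `epiremodel` command-line interface
```
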