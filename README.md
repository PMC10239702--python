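# cohescan

Identification of **cancer-aberrant cohesin-binding sites (CASs)** from
cohorts of cohesin ChIP-seq data, and quantification of their association
with dysregulated genes, 3D-genome changes, cis-regulatory modules, DNA
methylation/mutation and clinical outcome.

Cohesin is the ring-shaped complex that anchors chromatin loops and TADs.
When its binding landscape shifts between cancer and normal tissue, the
regulatory wiring of nearby genes can shift with it.  `cohescan`
implements the complete statistical pipeline for detecting such shifts
from cohort-scale peak data and characterising their downstream
consequences — exercised end-to-end on a seeded synthetic-cohort
generator with planted ground truth, so every stage is testable without
any external download.

The package is aimed at computational epigenomics researchers who have
per-sample peak calls (BED), read-intensity matrices (TSV),
differential-expression tables, Hi-C 1D tracks (bedGraph), loop calls
(BEDPE) and clinical tables, and who want a reproducible, tested
implementation of the CAS statistics rather than a pile of one-off
scripts.

## The statistics at the core

**CAS calling.** For each consensus cohesin site (peaks merged across
samples, kept when seen in ≥ 2 datasets; chrY/chrM excluded), peak
occupancy per condition is `PO = N_observed / N_all` and its change is
`POC = PO_cancer − PO_normal`, tested with Fisher's exact test; binding
level is compared as `logFC = mean(log2 I_cancer) − mean(log2 I_normal)`
with Welch's t-test.  Both p-value families are Benjamini–Hochberg
adjusted across sites.  A site is a CAS when `|POC| > 0.5` with
`q_occ < 0.01` **and** `|logFC| > 1` with `q_int < 0.01`, with concordant
signs — *gained* when both point up in cancer, *lost* when both point
down.  Tissue specificity is summarised by the Simpson overlap index
`|X∩Y| / min(|X|, |Y|)`.

**DEG enrichment (nearby model).** With `f(x)` the fraction of genes at
distance `x` (0–200 kb, nearest site) that are differentially expressed,
and `S = ∫₀²⁰⁰ᵏᵇ f(x) dx`, the DEG ratio score against 500 size-matched
random cohesin-site backgrounds is

```
DRS = (S_CAS − S_B) / max(S_CAS, S_B)  ∈ [−1, 1]
```

**Loop model.** A gene is connected to a site when a chromatin loop
(span 200 kb–5 Mb) joins the site's anchor to the gene's TSS anchor; the
DEG ratio `R` among connected genes is rank-tested against size-matched
random site draws.

**3D genome.** Compartment switches: `E_cancer × E_normal < 0` and
`|E_cancer − E_normal| > 0.05`, with `E` the replicate-mean PC1 at 50 kb.
Insulation score per bin: `log2` of the diamond mean over the
chromosome-wide expectation; TAD boundaries at deep insulation minima;
ISC = IS_cancer − IS_normal; APA = center-pixel over lower-left-corner
mean of loop-centered aggregate submatrices, normalised so the normal
condition equals 1.

**Clinical.** Patient clustering on CAS-DEG genes scored by the adjusted
Rand index (computed from the contingency table `n_ij`), gene-set sample
scores (mean per-gene z-score) with median-split Kaplan–Meier and
log-rank tests, and hypergeometric over-representation for gene lists.

## Worked example

The numbered drivers under `analysis/` run the full study on the default
synthetic cohort (3 tissues, 10,000 sites, 20 cancer + 20 normal samples
per tissue, 2% gained + 2% lost planted sites):

```
$ python analysis/02_call_cas.py
liver: 305 CASs (155 gained, 150 lost); sensitivity 0.762, empirical FDR 0.000
lung: 329 CASs (162 gained, 167 lost); sensitivity 0.823, empirical FDR 0.000
breast: 314 CASs (152 gained, 162 lost); sensitivity 0.785, empirical FDR 0.000
Simpson index off-diagonal max 0.041 (independently planted tissue CAS sets are highly specific)

$ python analysis/03_deg_enrichment.py
gained-CAS x up-DEG: DRS 0.409 (background 97.5% envelope 0.102)
lost-CAS x down-DEG: DRS 0.439 (background 97.5% envelope 0.100)

$ python analysis/04_3d_genome.py
switch classes at CASs: {'A-to-B': 0.4825, 'B-to-A': 0.5175, ...}
mean ISC at gained CASs: +0.400
APA cancer/normal ratio at gained-CAS loops: 1.99
```

Reading the numbers: every called CAS matches a planted site (empirical
FDR 0) with the correct direction; sensitivity is bounded by the exact
Fisher test at 20 + 20 samples.  The DRS of planted gained (lost) CASs
against up- (down-) regulated genes sits far above the 97.5% quantile of
the resampled background, planted compartment flips are recovered by the
deterministic switch rule, insulation rises where contacts were added,
and APA recovers the planted two-fold cancer/normal loop-strength change.

The same stages are available as a console tool:

```
cas-pipeline simulate --seed 1 --out results/cohort
cas-pipeline run --config config.yaml --out results/pipeline
cas-pipeline callcas --peaks manifest.tsv --intensity intensity.tsv --out cas
```

## Layout

```
src/cohescan/      library: genome.py, tracks.py, io.py, stats.py,
                   simulate.py, cas.py, deg.py, structure3d.py, crm.py,
                   clinical.py, pipeline.py, cli.py
analysis/          numbered narrative drivers writing results/
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    model, assumptions, parameter choices, limitations
```
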