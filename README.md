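# mitodel

Detection, clustering and quantification of large-scale mitochondrial DNA
(mtDNA) deletions from amplification-free long-read alignments.

## The problem

Single large-scale mtDNA deletions (SLSMD) and multiple mtDNA deletions
(MMD) are major classes of pathogenic variation in primary mitochondrial
disease. Short-read clinical assays amplify the mitogenome with long-range
PCR before sequencing, which biases molecule counts and prevents direct
deletion heteroplasmy quantification — a second assay (two-probe ddPCR) is
needed, and breakpoints remain imprecise because of microhomology at
deletion junctions. Amplification-free long reads (e.g. PacBio HiFi)
sequence native mtDNA molecules through the deletion junction, so a single
assay can detect a deletion, place its breakpoints at base resolution, and
count deleted vs intact molecules.

`mitodel` implements that analysis for reads aligned to the circular
16,569 bp mitochondrial reference (rCRS, NC_012920.1):

* **Deletion calling** — deletions of 500–15,000 bp (inclusive) are
  extracted from CIGAR `D` operations and from query-adjacent
  supplementary (split) alignment pairs. A deletion is the half-open
  circular segment `[b5, b3)` — `b5` the first deleted base, `b3` the
  first retained base — so the common deletion chrM:8470–13447 has length
  `13447 − 8470 = 4977` bp.
* **Breakpoint clustering** — events are points `(b5, b3)` in breakpoint
  space; DBSCAN (ε = 50 bp, minPts = 2, wrap-aware Euclidean metric)
  groups them. A cluster supported by more than one read is *recurrent*.
  One recurrent cluster holding all events ⇒ SLSMD; two or more clusters ⇒
  MMD; no events ⇒ Negative.
* **Heteroplasmy** — the percentage of sequenced molecules carrying a
  deletion, `h = 100 · n_del / cov(MT-RNR2)`, where the denominator is the
  mean coverage of the MT-RNR2 gene (the locus the clinical ddPCR assay
  uses to count total mtDNA molecules). The ddPCR counterpart
  `[1 − ND4/RNR2] × 100` is provided for comparison, with Pearson
  correlation and Bland–Altman agreement (bias ± 1.96·SD limits, sample
  SD) between the two.
* **Microhomology** — 20 bp either side of each breakpoint (40 bp windows,
  circular wrap allowed); microhomology length is the run of position-wise
  identical bases through the junction, summarised per sample and
  comparable against MITOMAP/MitoBreak-style breakpoint catalogues
  (D-loop breakends excluded).
* **Synthetic data** — a truth-tracked generator of heteroplasmic molecule
  populations and long-read SAM alignments (lognormal fragment lengths,
  median ~10 kb, uniform starts on each circular molecule) used to
  validate every stage end to end.

## Worked example

`examples/01_detect_deletions.py` simulates a sample carrying the common
4,977 bp deletion at 35% heteroplasmy and 200× coverage, then runs the full
workflow:

```
planted: [{'b5': 8470, 'b3': 13447, 'fraction': 0.35, 'heteroplasmy_pct': 35.0, 'del_len': 4977}]
summary: {'sample_id': 'example', 'mean_mtdna_coverage': 200.3, 'n_deletions_in_window': 79,
          'mean_rnr2_coverage': 222.87, 'heteroplasmy_pct': 35.45, 'classification': 'SLSMD'}
cluster 0: breakpoints (8470, 13447), 79 reads, recurrent=True
```

79 junction-spanning reads against a mean MT-RNR2 coverage of 222.87
molecules gives 35.45% heteroplasmy — within sampling noise of the planted
35% — and the single recurrent cluster at exactly (8470, 13447) classifies
the sample as SLSMD.

`examples/02_concordance.py` compares long-read and ddPCR heteroplasmy for
four SLSMD samples:

```
n = 4 SLSMD samples
Pearson r = 0.96
bias = -9.6%  (negative: LRS underestimates ddPCR)
limits of agreement = [-19.37%, 0.18%]
```

The other examples cover microhomology measurement
(`03_microhomology.py`) and the coverage-titration precision experiment
(`04_downsampling.py`). A thin CLI wraps the same functions:

```sh
mitodel simulate --preset slsmd --seed 7 --coverage 200 --out fixture/
mitodel detect --bam fixture/reads.sam --ref fixture/reference.fasta --out report/
```

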