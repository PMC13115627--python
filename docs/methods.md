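# Methods

## Coordinate model

All positions are 1-based on a circle of length L (default 16,569 bp, the
rCRS). A deletion is the half-open circular segment `[b5, b3)`: `b5` is the
first deleted base and `b3` the first retained base, so the deleted length
is `gap(b5, b3) = b3 − b5` when `b3 > b5` and `b3 − b5 + L` when the
deletion spans the replication origin. This convention makes the common
deletion chrM:8470–13447 exactly 4,977 bp. Reported deletion names follow
the HGVS-like pattern `m.{b5}_{b3−1}del{len}` (inclusive deleted-segment
bounds in the label, half-open internally); published deletion labels are
not internally consistent between the inclusive and exclusive readings, so
the package fixes one convention and documents it rather than guessing
per-sample intent.

Region annotations default to rCRS coordinates — MT-RNR2 1671–3229, MT-ND4
10760–12137, D-loop 16024–576 (wrapping) — and are overridable through a
region config, which also supports proportionally scaled toy genomes.

## Alignment ingestion and coverage

Primary and supplementary alignments on the mitochondrial contig with
mapping quality ≥ 10 are accepted; secondary and unmapped records are
dropped. The contig restriction plus the mapq threshold also serves as the
NUMT guard: reads that align best to a nuclear mtDNA-like locus never
enter. No homology-based NUMT masking is attempted. A single CIGAR that
would run past the contig end is rejected; origin-wrapping molecules must
be represented as supplementary segment pairs (which is what the simulator
emits).

Depth counts only M/=/X operations. Deletion (D) and skip (N) gaps consume
reference without adding depth, so an SLSMD produces the characteristic
sharp coverage dip between its breakpoints, and the MT-RNR2 denominator
counts only molecules physically covering MT-RNR2.

The mtDNA-content utility returns `2 × mean(mtDNA cov) / mean(nDNA cov)` —
copies per diploid cell, anchored by the two nuclear copies. The source
study reports the inputs but not the formula; this is the standard
coverage-ratio estimator.

## Deletion calling

D operations with length in the inclusive window [500, 15,000] bp become
events with `b5` at the first deleted reference base. Optionally
(`merge_gap`, default off since no merging is described for the original
workflow), D runs separated by ≤ `merge_gap` matched bases are merged
before filtering, to absorb aligner wobble.

Split evidence: segments of one read are ordered by their aligned query
interval (clip-aware, strand-corrected); each query-adjacent pair
(|query gap| ≤ 50 bp) whose reference footprints leave a circular gap in
the window yields an event with `b5 = left.ref_end + 1` (mod L) and
`b3 = right.ref_start`. Pairs contiguous around the origin (gap 0) are the
linearised representation of an intact circular fragment, not deletions.
Mixed-strand segment sets are skipped with a warning. Within one read,
identical junctions seen through both evidence classes are deduplicated
(CIGAR preferred); the dedup tolerance is exact `(b5, b3)` equality.

The per-sample deletion count is the number of distinct deletion-bearing
reads, not events: heteroplasmy is a molecule fraction, and a read carrying
two junctions is still one molecule. For single-junction reads the two
counts coincide.

## Clustering and classification

Events are clustered with DBSCAN over `(b5, b3)` using a precomputed
wrap-aware Euclidean metric (per-axis distance `min(|Δ|, L − |Δ|)`).
Defaults ε = 50 bp, minPts = 2: HiFi breakpoint jitter is a few bases, so
50 bp separates genuine junctions while absorbing wobble, and minPts = 2
encodes "more than one supporting read ⇒ recurrent". Noise points are kept
as singleton clusters — single-molecule deletions count toward a sample's
deletion burden. Cluster representatives are per-coordinate wrap-aware
medians (origin-straddling member sets are unwrapped by +L before taking
the median, even-count medians round to the nearest integer position).

Classification: no events ⇒ Negative; exactly one cluster and it is
recurrent ⇒ SLSMD; one singleton cluster with `min_support > 1` ⇒
LowEvidence (one supporting molecule is reported but not classified);
two or more clusters of any mix ⇒ MMD. Samples known to carry deletions
from prior clinical data but with zero observed long-read deletion
molecules are reported Negative — clinical override is the caller's
decision, not the tool's.

## Heteroplasmy and concordance

`h = 100 · n_del / cov(MT-RNR2)`, full precision internally, two decimals
in reports (half-away-from-zero). Values above 100% are flagged as
pathological rather than clamped. The ddPCR formula `[1 − ND4/RNR2] × 100`
clamps negative values (probe noise) to 0 with a warning.

Bland–Altman uses differences `LRS − ddPCR`, bias = mean difference, and
limits of agreement `bias ± 1.96 · SD` with the *sample* SD (n−1 divisor);
only that divisor reproduces the published limits from the published
sample table, so it is fixed here. Pearson correlation is the standard
product-moment statistic (scipy), with zero-variance input rejected.

Benchmark metrics follow the published conventions: sensitivity = recall =
100·TP/(TP+FN), specificity = 100·TN/(TN+FP), precision = 100·TP/(TP+FP),
any 0/0 ratio reported as 0.00, and TN = L − (truth-set call count). The
published TN cells are consistent only with the truth-set (short-read)
call count, not the long-read call count, so `BenchmarkCounts.total_called`
is documented as the truth-set size.

The downsampling experiment mirrors the published design: fractions 5% to
100% of reads in 5% increments, 5 sub-replicates each, drawn without
replacement (supplementary segments travel with their read), rerunning
deletion calling and quantification per subset and summarising the
per-fraction SD across replicates. Deterministic given the seed.

## Synthetic data generator

The generator emulates the study conditions: a random circular genome with
scaled region annotations; a molecule population of intact genomes and
deletion species at configured fractions (SLSMD-like presets use one
junction at 35%, MMD-like presets five junctions at 4% each, negatives
none; per-scenario fractions are configurable over the cohort's 0–65%
range); mean coverage default 800× (the cohort's median coverage scale);
error-free reads with lognormal fragment lengths (median 10 kb,
σ = 0.35, truncated to [1 kb, shortest molecule − 1]); optional
substitution errors (never indels). Fragments start uniformly on each
circular molecule; reads spanning a configured junction carry it as a D
operation with exact breakpoints.

Two modelling choices make the heteroplasmy estimator unbiased by
construction, both stated as the shearing physics:

1. a fragment's molecule class is drawn with probability proportional to
   `fraction × molecule length` — shearing yields fragment counts
   proportional to molecule mass;
2. fragment length is drawn from one distribution truncated to the
   shortest molecule present, so length is independent of class.

With class weight `w_c ∝ f_c·L_c`, the expected number of junction-spanning
reads for deletion d is `N·f_d·(E[r]−1)/norm` while the expected depth at
any non-deleted position is `N·E[r]/norm`, so the ratio estimator recovers
`f_d` up to a factor `(E[r]−1)/E[r] ≈ 1` and binomial noise.

Fragments crossing the reference origin are emitted as a primary +
supplementary record pair (soft-clipped complements of one another), the
split-read representation an aligner produces for a circular contig. A
`wrap_mode="linear"` option instead confines fragment starts so alignments
never cross the origin; it is not the default because with ~10 kb fragments
on a 16.6 kb circle the confinement sharply depresses coverage near the
origin and junction-spanning probability (start-counting shows several-fold
distortion), breaking both the even-coverage condition and estimator
unbiasedness.

Planted microhomology copies the k bases starting at `b3` onto the k bases
starting at `b5` and then forces a mismatch one base beyond each end of the
run, so the junction-anchored measurement returns exactly k; `k = 0` leaves
the sequence untouched (chance background homology of 0–2 bp is then
typical, occasionally more — as in real junctions).

What the generator does not emulate: HiFi error profiles (homopolymer
indels, quality values), breakpoint jitter from alignment ambiguity
(junctions are recovered exactly on synthetic data; cluster-level tests add
jitter directly to points instead), mixed-strand alignments, nuclear
background reads, and mtDNA duplications (out of scope). Passing end-to-end
tests therefore demonstrate correctness of the calling/clustering/
quantification machinery under clean alignments, not robustness to aligner
noise.

## Microhomology

Windows of 2w bases (w = 20) centered on each breakpoint, circular wrap
allowed: `flank5 = [b5−w, b5+w−1]`, `flank3 = [b3−w, b3+w−1]`, so offset w
is the breakpoint in both. The microhomology length is the forward run of
position-wise matches starting at offset w plus the backward run ending at
offset w−1, capped at 2w. "Perfect matches between the two windows" is
ambiguous between this junction-anchored rule and an unanchored longest
common substring; the junction-anchored rule is the field's convention for
breakpoint repeats and is the default, with the substring rule available
as `mode="substring"` (it can only report equal-or-longer lengths and
inflates on 40 bp windows). Summaries report the fraction of deletions with
≥ 1 bp homology and the length histogram over unique deletions (cluster
representatives), after excluding deletions with either breakend in the
D-loop. Catalogue comparisons accept TSV breakpoint tables with per-source
column dialects (1-based inclusive pairs by default); published catalogue
percentages depend on database snapshots and are not reproduction targets.

## Numerical conventions and degenerate inputs

* Rounding: full precision internally; two decimals
  (half-away-from-zero) at reporting boundaries only.
* Zero-length deletions (`b5 == b3`), zero-length regions, non-positive
  RNR2 coverage/droplet counts, negative benchmark counts, < 2 concordance
  pairs, and zero-variance correlation inputs all raise errors rather than
  returning sentinel values.
* Downsampling fractions yielding zero reads produce rows with undefined
  (NaN) heteroplasmy rather than failing the run.
* Cluster ordering is deterministic: by support (descending), then
  representative breakpoints; event ordering by `(b5, b3, read_id)` makes
  all outputs independent of read order.
* All randomness flows from explicit integer seeds (numpy Generator);
  identical seeds give byte-identical SAM output and reports.

## Problem sizes in the test suite

End-to-end recovery tests run three SLSMD scenarios (5%, 25%, 65%
heteroplasmy) plus an MMD and a negative scenario at 800× coverage
(~1,300–1,700 reads each); the downsampling test uses one 30% sample at
1000× with the full 20 × 5 titration; the microhomology oracle compares
1,000 random flank pairs and planted lengths 1–13 bp (the in-cohort
range). These sizes give stable statistics (3-binomial-SE recovery bounds)
while keeping the suite quick.

## Known limitations

* Deletion detection requires junction-spanning reads; heteroplasmy below
  ~1/coverage is invisible, mirroring the real assay's detection floor.
* The RNR2-denominator estimator assumes no deletion removes MT-RNR2; a
  deletion overlapping MT-RNR2 would bias the denominator (the same
  limitation the two-probe ddPCR assay has).
* mtDNA duplications and other complex structural variants are not called.
* The simulator's clean alignments mean aligner-induced breakpoint
  ambiguity (microhomology sliding) is untested end to end; the clustering
  radius is the designed defence.
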