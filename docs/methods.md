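# Methods

## Coordinates and instance selection

All internal coordinates are 0-based half-open (BED convention). UCSC rmsk
`genoStart`/`genoEnd` are consumed as already 0-based half-open; the
optional leading bin column is auto-detected from the column count. Each
instance gets the deterministic id `chrom:start-end:name`, with a numeric
suffix on byte-identical rows.

"Any overlap" with the blocklist means ≥ 1 shared base under half-open
semantics; touching intervals do not overlap. Blocklist filtering is
idempotent and partitions the input exactly into kept and removed sets. A
chromosome absent from the blocklist is treated as unblocked (logged), not
as an error. Strand is parsed but never used: coverage tracks are
unstranded.

## Enrichment model

The element-level statistic is the clamped log2 fold change

    log2FC = max(0, log2((m_c/M_c + 1) / (m_i/M_i + 1)))

with `m` the length-weighted mean signal over the element (uncovered bases
count 0) and `M` the median of the per-base signal distribution over the
analyzed chromosomes. Choices that needed fixing:

* **Median convention.** The genome median is computed from run lengths
  without per-base expansion, and *includes* uncovered (zero) bases by
  default (`include_zeros=True`): density tracks leave genuine gaps, and a
  defined convention is required. A zero median is fatal — it means the
  track is degenerate for normalization, and the error message says so.
  Even base counts take the mean of the central pair. Medians are cached
  per (track, chromosome set).
* **Pseudocount before the ratio.** The +1 is added to the
  median-normalized means, so both numerator and denominator are ≥ 1 and
  the ratio is finite; the statistic is exactly invariant to independent
  positive rescaling of either track (sequencing-depth normalization), a
  property the tests assert to 1e-9.
* **Clamping.** Negative log2 values correspond to input exceeding ChIP,
  treated as nonspecific; clamping them to 0 makes the matrix non-negative,
  which the binomial dissimilarity downstream requires.
* **Precomputed FC tracks** (the multi-stage design) bypass normalization:
  the element value is the length-weighted mean linear FC, stored as
  max(0, log2(·)) in the matrix; the linear value is retained for
  stage-mean summaries.
* Negative raw track values (possible in some track dialects) are floored
  at 0 on read, with a warning.

Window profiles extend an element by one element-length up- and downstream,
clip at chromosome bounds (never wrap; the profile carries a `clipped`
flag), and tile the region with at least 50 equal consecutive windows whose
integer widths differ by ≤ 1 bp and sum exactly to the region length.
Regions shorter than the window count reduce it with a warning. Larger
window counts (e.g. 500 for a long cluster) are a per-call override.

## Differential testing

**Two-group mode** runs a per-element Welch unequal-variance *t*-test on
the clamped log2 FC values (the test scale is log2; the matrix is the
object the heatmap/density summaries use, so it is also what gets tested).
The headline differential set uses unadjusted p < 0.05: with a broad mark,
a handful of samples, and thousands of elements, family-wise correction is
known to be very conservative, so the Bonferroni-adjusted flag is reported
in the same record rather than replacing the headline set. Degenerate rows
get explicit conventions instead of NaNs: both groups constant and equal →
p = 1; constant and different → p = 0 with a `degenerate` flag; all-zero
rows are tested and flagged `all_zero`.

**Stage mode** chains one-way ANOVA per element (stages as groups, tissues
as independent replicates — no nesting structure is modeled), Bonferroni
across elements, Tukey HSD (studentized range with the Tukey–Kramer
correction for unequal stage sizes) on elements with adjusted p < 0.01, and
the relevance filter: stage means of clamped log2 FC are shifted by +1 and
the pair ratio is the larger of the two directions, relevant iff ≥ 1.5
(inclusive, symmetric under stage swap). An element is reported iff at
least one pair is simultaneously Tukey-significant (p < 0.05) and relevant.
The +1 shift exists because two near-zero means — 0.1 and 0.01, both
practically FC 1 — differ ten-fold on the raw scale but carry no biology.

Family over-representation in a differential set uses the upper-tail
hypergeometric probability P(X ≥ k) with fold = (k/n)/(K/N).

## Sample-level structure

Rows (elements) are z-scored (ddof 1; constant rows become zeros and are
flagged) before PCA. PCA is SVD-based with samples as observations;
variance explained sums to 1 over the full rank, and each component's sign
is fixed so its largest-magnitude loading is positive, making output
deterministic.

The binomial dissimilarity between samples x, y is

    d(x,y) = Σ_i [ x_i log(x_i/n_i) + y_i log(y_i/n_i) + n_i log 2 ] / n_i

with n_i = x_i + y_i, 0·log 0 := 0, and n_i = 0 features contributing 0 —
the standard ecological index (the expected scaled deviance of an even
split), which the implementation reproduces to 9 decimals against an
independent reference computation frozen in the tests. It requires
non-negative count-like input, which the clamped matrix satisfies; the
dissimilarity is computed on the raw (unscaled) matrix.

PERMANOVA partitions the squared-distance matrix by the Gower identity
(SS_total = Σ d²/n, within-group analogues per group) into a pseudo-F, and
permutes sample labels freely (no strata): p = (1 + #{F_perm ≥ F_obs}) /
(1 + n_perm), deterministic under the seed. A `method="exhaustive"` mode
enumerates every permutation and reports the exact tie-inclusive fraction,
practical for n ≲ 8 and used to validate the sampled mode.

## Highly repetitive satellites

Coverage at collapsed arrays is uninformative, so the pipeline works at
read level: duplicates and unmapped reads are removed, replicates merged,
ChIP and input downsampled to the same total (unequal totals are fatal —
they defeat the normalization), and the MAPQ-0 reads re-mapped onto
consensus *dimers* so reads spanning the monomer junction align end-to-end.

The built-in matcher scans every ungapped end-to-end placement of the read
on each dimer, both strands, counting N as a mismatch; a read is assigned
to the family with the fewest mismatches if the rate is ≤ 0.1 (ties between
families leave the read unassigned and separately counted). This is a
deliberate design: satellite monomers diverge by point mutation far more
than by indels, so an ungapped scan with a mismatch cap captures the
biology while remaining exactly testable against a brute-force oracle; a
SAM stream from any external sensitive end-to-end aligner can be ingested
through the same interface instead. Per-position coverage along each dimer
is accumulated and a windowed max/mean statistic > 10 flags families whose
"alignment" is really a pile-up on a low-complexity insert rather than
genuine homology.

Family enrichment is chip_aligned / input_aligned; a family with ChIP reads
but zero input reads reports a missing fc with a flag, and a family with no
reads at all is reported as such rather than dropped.

## Synthetic data

The generator emits a complete bundle from one seed: rmsk table, blocklist,
per-sample tracks, SAM reads, consensus FASTA, RNA contigs, segmentation,
peaks, genes, metadata, and a ground-truth table, byte-identical across
runs.

What it emulates: a small genome (two autosome-analogs of 1.5 and 1.0 Mb
plus a 0.3 Mb X-analog); 200 analyzed elements — a 30-element clustered
block beside a blocklisted pericentromere-analog plus dispersed singletons
— with 20 extra elements planted inside blocklist regions (carrying
anomalously high signal, log2FC 3) and 8 on the X; a six-family palette;
gamma-distributed background coverage (shape 20, mean depth 10, 200 bp
runs, short-range smoothing) so the run-length code paths are exercised;
per-element baseline log2FC ~ U(0.2, 1.0), matching the overall ~0.6
average enrichment scale of real satellite compartments.

Two scenarios define the study conditions. *cancer_hypomethylation*: 8
normal vs 13 cancer samples; 20 true elements (12 clustered, 8 dispersed)
with Δlog2FC = 1.0 (normal above cancer) and within-group sd 0.3;
enrichment spreads into the one-length flanks of clustered differential
elements. *fetal_wave*: 8 stages × 9 tissues = 72 precomputed-FC samples;
true elements follow +1-shifted stage means (2.0, 0.5, 1.0, 1.1, 1.2, 1.0,
0.8, 0.5) — highest at the earliest stage, sharp drop, partial recovery,
drop at birth — whose largest pairwise shifted ratio is exactly 2.0.

Planted values are exact by construction: for each element the ChIP
multiplier is solved from the actually generated background (the element's
input mean and both genome medians), iterated three times to absorb the
small median shift the multipliers themselves cause, so the pipeline's
measured log2FC matches the planted value to ~1e-3 (the residual is
bedGraph 6-significant-digit rounding plus the median shift of the ~5% of
bases under elements). Read files plant 1800 ChIP vs 600 input
consensus-derived MAPQ-0 reads (3× enrichment) at the cluster, 2%
per-base mutation off the consensus, plus flagged duplicates and unmapped
records that preprocessing must remove.

What it does **not** emulate — and hence what passing tests do not show
about real data: genuine genome sequence (background reads are random, so
mapping ambiguity is declared via MAPQ rather than arising from alignment);
fragment-level coverage autocorrelation beyond the short smoothing window;
GC or copy-number bias; inter-replicate variance structure; realistic
monomer phylogenies (consensus sequences are random). Recovery results on
the bundle validate the pipeline's arithmetic and decision chain, not its
robustness to alignment artifacts.

## Problem sizes and numerics

Default desk-scale sizes — 200 analyzed elements, 21 or 72 samples, ~2.8 Mb
genome, 6,000 reads per assay — were chosen so the full pipeline runs in
seconds while every statistical regime (Bonferroni across elements,
Tukey–Kramer with unequal sizes, binomial-error bounds on read ratios) is
genuinely exercised. TSV outputs print floats at 6 significant digits;
missing values are NA; all randomness flows from explicit seeds through
`numpy.random.Generator`, and stage manifests record only input base names
so reruns are byte-identical across directories.

## Known limitations

* The relevance filter and clamping make the matrix non-Gaussian near 0;
  Welch/ANOVA p-values are therefore slightly conservative for elements
  with baselines close to 0 (clamped mass at zero shrinks variance).
* PERMANOVA assumes exchangeable samples; tissue structure within stages is
  not stratified.
* The ungapped consensus matcher will undercount families whose copies
  diverge by indels; use the external-SAM path for those.
* Chromosome-mode filtering recognizes chrX/chrY/chrM naming and
  underscore-containing scaffolds; exotic naming schemes need the custom
  chromosome list.
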