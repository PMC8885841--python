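# Methods

`dnamod` implements a desk-scale analysis pipeline for N4-methylcytosine
(4mC) and N6-methyladenine (6mA) DNA methylomes of the kind found in
bdelloid rotifers, where 4mC — deposited by a bacterial-origin
N4-cytosine methyltransferase — concentrates over transposable elements
(TEs) and tandem repeats while 6mA is dispersed at GA-context adenines.
Every stage runs on synthetic data produced by the package's own
generator, so the statistical behaviour of each method is measurable
against a known truth.

## The synthetic genome and methylome

`sim.simulate_genome` tiles non-overlapping feature blocks — gene models
(UTRs, exons, introns, a 2-kb promoter upstream of the TSS), TE copies and
tandem-repeat arrays — onto contigs separated by random gaps, over a
background sequence of configurable GC content (default 0.31, an AT-rich
invertebrate-like genome). TE copies are 5'-anchored prefixes of a
per-family random consensus, so copy integrity (span/consensus) is exact:
full ≥ 0.95, medium 0.5–0.9, short 0.1–0.5. Consensus sequences are
CpG-enriched (P(G|preceding C) = 0.3 by default) because the
methyltransferase's TE targets are CpG-containing; without this, CpG
availability inside a single 3-kb consensus is so variable between seeds
that context statistics are not reproducible. A configurable fraction of
genes is TE-derived: these carry an intact TE insertion inside one intron
and are flagged, mirroring the annotation flag a homology search would
set.

`sim.plant_methylome` places 4mC on cytosines (either strand) inside
full/medium TE copies and tandem repeats. Site weights combine
dinucleotide context (CG:8, CA:4, other 1 — yielding CpG/CpA as the
dominant modified doublets), an exponential decay from the TE 5' boundary
(scale 1 kb; the 5' enrichment is shown but not parameterized in the
source material) and a per-copy factor integrity² so intact copies carry
most marks. Fractions have a point mass at 1.0 (default 0.58) plus a
high-skewed Beta(6, 1.5) tail. 6mA is planted genome-wide on adenines
with GA-context weighting and Beta(5, 2) fractions (mean ≈ 0.71).
Methylation is mostly single-strand: a site gains an opposite-strand
partner (across the palindromic CpG or ApT doublet) with a probability
calibrated so the configured `symmetric_fraction` (default 0.1) equals the
expected fraction of modified positions that belong to a pair; pairs
planted incidentally by two independent draws are collapsed first, so the
dial is the sole source of symmetry.

Per-pass polymerase kinetics are log-normal inter-pulse durations (IPDs):
log IPD ~ N(0, sigma) with sigma = 0.4, and a modified pass multiplies the
median IPD by the configured multiplier (default 3). At a site with
fraction f each pass is modified independently with probability f.
Coverage is Poisson with mean 25 passes per strand. The table carries the
planted sites plus a 10,000-site subsample of unmodified positions — a
desk-scale stand-in for testing every genomic position that makes
false-positive behaviour observable without a genome-sized table. The
in-silico control is the known log-scale model (mu = 0, sigma); sampled
control observations are also supported.

Sequencing observations are emitted as alignment intervals (BED-like), not
base sequences; read mapping is out of scope. DIP-seq draws 200–400-bp
fragments uniformly, weights capture odds as background + enrichment ×
(summed fraction of matching marks covered) with 10× default enrichment,
and reports 50-bp 5'-prefix reads; the input assay skips capture. ChIP-seq
places H3K4me3 fragment centres bimodally (±300 bp ± N(0,150)) around the
TSS of expressed genes and H3K9me3/H3K27me3 uniformly over TE bodies plus
a 500-bp spread, over a 30% uniform background; reads are 75 bp. RNA-seq
counts are multinomial with per-gene rate = log-normal baseline × exonic
length, × 0.25 for TE-derived genes carrying 4mC and × 2 for genes with
6mA within ±500 bp (directions as in the source study; magnitudes are
package choices, configurable).

## Modification calling

The IPD ratio is mean(native IPD)/mean(control IPD). The modification
quality score (mQv) is Phred-scaled one-sided evidence that native
log-IPDs exceed the control: a one-sample t-test against the known control
log-mean for the in-silico control, or a one-sided Welch test for sampled
controls; score = −10·log10(p), capped at 120. Under the log-normal null
the test is exact, so the score threshold 22 corresponds to a per-site
level of 10^−2.2. Filtering mirrors standard SMRT methylome practice:
sites under 10× coverage are dropped; calls require mQv ≥ 22 and IPD
ratio > 1; primary calls additionally require 20× coverage (both
thresholds are exposed because different analyses of such data use the
10× or the 20× set). Marks follow the reference base on the tested strand
(C → 4mC, A → 6mA; other bases discarded). Strand calls are independent
records — no symmetric merging, since this methylation is mostly
asymmetric.

Fractions are estimated by classifying each pass to the nearer log-IPD
component mean (the midpoint rule, optimal for equal-variance log-normal
components) and reporting the modified share. The estimator has a known
shrink-toward-0.5 bias of ε(1−2f) with ε = Φ(−log m/(2σ)) ≈ 0.085 at the
default multiplier and sigma; a method-of-moments correction was evaluated
and rejected because dividing by (1−2ε) inflates variance enough to hurt
classification near the 0.8 boundary more than the bias helps. At 50×
coverage the per-level mean absolute error is ≤ 0.09 for planted levels
0.25–1.0. Fraction classes follow the standard bins: sub-threshold
(< 0.1), low [0.1, 0.5), moderate [0.5, 0.8), high [0.8, 1]. A planted
level exactly at 0.5 is intrinsically ambiguous — any unbiased estimator
classifies ~half of such sites as low.

## Enrichment tracks and peak calling

Reads are extended to a fixed length from their 5' end and binned (10-bp
bins); bin values are mean per-bp coverage, so binned tracks equal a
per-bp pileup aggregated to bins exactly. RPGC normalization rescales to
1× mean coverage over an effective genome size; IP-vs-input comparison is
a per-bin log2 ratio with pseudocount 1 on the RPGC scale.

The peak caller is a defined global-Poisson procedure reflecting the
"nomodel nolambda" mode of the MACS family rather than a reimplementation
of its heuristics: per-bin counts of overlapping extended reads are tested
against the genome-wide mean rate (one-sided Poisson upper tail), bins
with p < 1e−5 are merged across gaps ≤ 300 bp (the fragment scale), peaks
narrower than 150 bp are dropped, and the summit is the centre of the
leftmost maximal-count bin. Estimating the background rate from the whole
genome (including enriched regions) is slightly conservative. On
no-enrichment simulations the number of significant bins stays within
3 SD of threshold × n_bins (typically zero).

Summit localization is evaluated on point-like planted clusters (4mC at
TE 5' ends with a 50-bp decay scale): when a cluster is much wider than a
fragment the coverage maximum wanders on a plateau and "distance to the
cluster centre" stops being meaningful. With compact clusters, ≥ 95% of
summits land within 100 bp of the nearest planted cluster centre.

## Association statistics

Occupancy profiles count items (sites, or read midpoints) in fixed bins
around per-feature anchors (5' end, TSS, TTS or summit), divided by the
number of features; feature strand flips the axis so upstream is always
left. Metaprofiles rescale feature bodies to a fixed number of bins
(0–100% length) with absolute-bp flanks. Fraction profiles average call
fractions per bin with a coverage mask. Normalized density is
(sites in class / number of annotations) / genome fraction of the class —
with marks planted in TEs this reproduces TE ≫ genes for 4mC, and tandem
repeats show the extreme densities their small genome share implies.
TE-integrity stratification reports mean ± SD of per-copy call counts for
full/medium/short classes; the full/medium boundary is set at 0.9 of the
consensus (the source material defines only short < 0.5).

Spatial correlation between interval sets uses base-pair Jaccard (after
per-set self-merge) or mean nearest distance, with a permutation null that
relocates query intervals uniformly, preserving lengths and contig
assignment; p = (1 + #extreme)/(n_perm + 1). The Jaccard null is computed
with an array identity |A∩B| = |A| + |B| − |A∪B| over vectorized merges,
equivalent to the generic path but ~70× faster. Calibration: a uniformly
relocated query yields p > 0.05 in ≈ 95% of runs, so the "≥ 90% of 50
runs" check carries an inherent ~4% failure probability per seed.

DIP×ChIP co-localization reports the percentage of DIP peaks overlapping
≥ 1 peak of each chromatin class (and class unions such as
H3K9me3+H3K27me3). Summit signal profiles average log2-ratio track values
in ±3 kb around DIP summits. On this synthetic genome 4mC summits show
positive H3K9me3/H3K27me3 and *negative* H3K4me3 log2 ratios (≈ −0.6):
because genes occupy ~a quarter of the 200-kb genome, concentrating the
H3K4me3 library at TSSs necessarily depletes it over TEs relative to
input. Real genomes, where promoters are a tiny genome share, show the
flat ≈ 0 H3K4me3 profile instead; the tests therefore assert the
direction content (heterochromatic marks positive, H3K4me3 non-positive
and below both).

Strand symmetry counts positions whose opposite-strand partner (across
the palindromic doublet) is also called. The observed/expected CpG ratio
is the standard (N_CpG × L)/(N_C × N_G) per window, with a non-overlapping
scan (equivalent to the naive count, as CG cannot overlap itself). RPKM is
counts/(exon kb × million mapped); group tests are a two-tailed Student's
t-test on log2(RPKM+1) for two-group (mark present/absent) comparisons and
one-way ANOVA with Tukey's post hoc for histone-class groupings, with
groups of n < 2 skipped and flagged. The two planned t-tests are reported
unadjusted; Tukey handles the ANOVA family.

## Sequence context

Windows of ±flank bp (5/10/20 supported) are extracted on the modified
strand, so the centre base is C for 4mC and A for 6mA; edge-truncated
windows are dropped and centre-base mismatches rejected, both counted.
Doublet/triplet proportions are tabulated at the centre (the
centre,+1 doublet by default; a flag switches to −1,centre for marks
signatured 5' of the base). K-mer over-representation replaces
position-specific motif discovery with an exhaustive, deterministic test:
per k-mer presence/absence 2×2 tables of foreground windows against 5×
as many random genome windows matched on centre base, one-sided Fisher's
exact test, Benjamini–Hochberg correction across all tested k-mers. For
dinucleotides the ±5-bp window is the informative one — presence/absence
in wider windows saturates.

## Problem sizes and determinism

Default experiment sizes (chosen as a desk-scale working point): 200-kb
genome, 2 contigs, 40 genes, 38 TE copies, ~2,500 planted marks, 50,000
reads per assay, 25,000 null kinetic sites for calibration, 1,000 sites
per planted fraction level, 999 permutations for spatial power and 50×199
for calibration, and an 800-gene / 2.5-Mb configuration for the
expression grouping (≈ 200 genes per group). A full pipeline run takes a
few seconds; the complete acceptance recomputation about 10 s.

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` streams, so identical configurations produce
byte-identical FASTA/GFF3/BED/TSV artifacts and run reports (the report
contains per-artifact SHA-256 checksums and no timestamps).

## What passing tests do and do not show

The generator emulates the statistical structure the analyses assume —
log-normal kinetics acting multiplicatively, independent passes, uniform
fragmentation, capture odds linear in covered marks, multinomial
expression — and omits base-call errors, mappability structure, PCR
duplicates, diploid/allelic effects, batch effects and contamination.
Passing recovery tests therefore demonstrate correctness and calibration
of the estimators under their own model assumptions, not performance on
real sequencing data. Known limitations: the mQv reimplementation is a
defined test, not the vendor's proprietary score; the peak caller is a
minimal global-Poisson procedure (no duplicate removal, local lambda, or
broad-peak mode); fraction estimation assumes the two kinetic components
are known; and the H3K4me3 depletion artefact described above.
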