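# Methods

`cobindkit` implements the downstream analysis of multi-factor, multi-cell-
line ChIP-seq binding data: deciding which called peaks are reproducible,
which transcription factors bind together, whether their overlap is more
than genomic clustering would produce, what the binding looks like at base
resolution, which sequence motifs underlie it, where in the gene annotation
it falls, and whether it sits near the genes whose expression distinguishes
the cell lines. All stages run against a seeded synthetic-data generator so
the complete pipeline is testable end to end without any external data.

## Coordinates and peak algebra

All coordinates are 0-based half-open (BED convention). MACS-style tabular
peak files, which use 1-based starts and report the summit as an offset from
the region start, are converted on read. Two peaks *overlap* when they share
at least one base pair; with half-open intervals `[s1, e1)` and `[s2, e2)`
that is `s1 < e2 and s2 < e1`.

A *consensus* (replicate-consistent) peak is a peak overlapping at least one
peak of the other biological replicate. The reported intervals are those of
a designated anchor replicate (default replicate 1, configurable) rather
than merged unions: merging changes peak counts and widths in ways that
depend on fragmentation details, whereas anchoring keeps every reported
interval a real called peak. Counts depend mildly on the anchor choice; both
anchors are available.

Co-binding classification takes the CTCF consensus set as the anchor and
partitions it into four categories (CTCF only, CTCF+ER, CTCF+FOXA1,
CTCF+ER+FOXA1) by presence/absence of a one-base-pair overlap with the ER
and FOXA1 consensus sets. Because each anchor peak is tested independently
against the two subject sets, the categories partition the anchor set
exactly — the four counts always sum to the CTCF consensus count.

A *cell-line-specific* peak is a consensus peak of one line overlapping no
peak of any replicate of any other line. "Common" peaks and peaks shared by
a subset of lines need an anchor line to report concrete intervals; the
anchor is the first (or a user-designated reference) line. Duplicate
identical intervals in the input are retained as distinct peaks.

Overlap queries run on a sorted sweep (per-chromosome arrays sorted by
start with a running prefix-maximum of ends), giving `O((n+m) log m)` per
query set; the contract is identical to an all-pairs scan and is
property-tested against one.

## Overlap significance: block-rotation null

Binding sites cluster along the genome, so testing an observed overlap
count against uniformly re-scattered intervals grossly overstates
significance. The package uses a *block-rotation* null in the spirit of
genome-structural-correction statistics: each chromosome is partitioned
into consecutive blocks of fixed length `B` (default 1 Mb; for small
synthetic genomes one tenth of the chromosome length), intervals are
assigned to the block containing their midpoint, and each block's intervals
are circularly shifted together by one uniform random offset. Interval
lengths, per-block counts and within-block clustering are preserved
exactly; only the placement relative to the query set is destroyed. An
interval whose shifted position would overhang its (possibly truncated)
block is moved left to abut the block end; with peaks of a few hundred base
pairs in ~1 Mb blocks this affects of order 0.1% of placements, and the
calibration test below confirms the null p-value stays uniform.

The statistic is the number of query (A) intervals overlapping the subject
(B) set by at least one base pair; it is asymmetric, and the pipeline
reports both directions. The one-sided enrichment p-value uses the add-one
rule

    p = (1 + #{null >= observed}) / (iterations + 1),

which is strictly positive and exact under exchangeability. The default is
10,000 iterations, so the smallest reportable p is ~1e-4. The null requires
`B` at least twice the longest subject interval.

Calibration and power are verified by simulation: for independent uniform
interval sets the fraction of p-values below 0.05 over 200 simulated pairs
stays inside the binomial 99% band around 0.05; planting half of the query
set onto subject intervals drives p below 1e-3 in every run.

## Binned signal matrices

For a region set, each region contributes one row covering
`[centre − 5 kb, centre + 5 kb)` split into 100 bins of 100 bp. Regions are
centred on the interval midpoint (summit-centring is an option). A bin's
value is the treatment read count minus the input (control) count, each
scaled to a 10-million-read library first:

    value(r, j) = (1e7 / N_t) · t(r, j)  −  (1e7 / N_c) · c(r, j),

where counts are of read 5′ starts falling in the half-open bin. Reads are
counted at their 5′ start with no fragment extension or strand shift; a
fixed extension is available but off by default. Subtraction can make bins
negative; negative values are kept in all data and sums and clamped to zero
only when a heat map is rendered, so displayed intensity matches a
non-negative colour scale while totals remain exact. Totals are reported
both raw and clamped because the two conventions differ once input noise is
appreciable. Windows truncated at a chromosome start are counted over their
valid range and flagged.

Row ordering for heat maps groups regions by co-binding category (triple,
pairs, single) and sorts by descending row sum within category, stably.

## Motif enrichment with a permuted-matrix null

For a peak class, the 2 kb of sequence around each summit is scanned with a
position weight matrix on both strands. A window of length L at offset i
scores `S = Σ_j f[b_{i+j}, j]` with pseudocount-1 column frequencies
`f = (count + 1) / (total + 4)`; the *similarity score* is the min–max
normalisation `(S − S_min) / (S_max − S_min)`, where `S_min`/`S_max` sum
the column-wise minimum/maximum frequencies, so the consensus scores
exactly 1 and the anti-consensus exactly 0. Matches at similarity ≥ 0.85
are counted in twenty non-overlapping 100-bp windows by match start
position, strands pooled, over all sequences. Windows containing N never
match. Log-odds scoring is available as an alternative.

The null: the matrix columns are randomly permuted (default 1,000 times)
and the windowed counts recomputed for each permuted matrix over the same
sequences. A column permutation preserves the column multiset — hence the
per-position information content and the expected genome-wide hit rate
under an i.i.d. background — while destroying base order, so the null
isolates exactly the positional and base-order signal. Per window, the
p-value is the upper tail of a Gaussian fitted to the null counts (sd with
denominator n−1). A zero-spread null returns p = 1 when the observation
does not exceed the mean and the smallest positive float otherwise, as a
documented sentinel. Within-column shuffling is available as an alternative
permutation scheme; column permutation is the default because it keeps
whole columns intact.

**Known limitation.** The permutation null captures between-matrix
variability but not the sampling noise of the observed count itself, and
for *palindromic* motifs it is anti-conservative: a palindrome's matches
are counted once per strand (hits arrive in pairs), doubling the variance
of observed window counts, while permuted matrices are generally not
palindromic and show no such pairing. In background windows this inflates
the Gaussian z by about √2, so isolated windows can reach nominal p ≈ 0.002
by chance at roughly a 5% per-window rate. Planted-signal calls (p ≪ 1e-3
in the planted windows) are unaffected for practical purposes, but isolated
marginal windows for palindromic matrices should be read with caution.

The scanner is exact (property-tested against per-offset recomputation,
both strands, N handling included), and the enrichment engine pools all
sequences into one concatenated array with N spacers so the per-permutation
rescan is a handful of vectorised adds; 500 sequences × 200 permutations ×
10 matrices runs in well under a minute.

The packaged matrix collection (`data/synthetic_core_motifs.jaspar`) is a
set of **synthetic stand-in** matrices written from published consensus
sequences (a CTCF-like GC-rich 15-mer, the GGTCAnnnTGACC estrogen-response
palindrome, the TGTTTACT forkhead word, an E-box and an AP-1-like word);
it is not a redistribution of any curated database. Any JASPAR-format file
can be supplied instead.

## Genomic-distribution annotation

Each peak is reduced to a single anchor point (summit if present, else
midpoint) and assigned to exactly one category with priority
promoter > exonic > intronic > intergenic, so category counts always
partition the peak set. "Promoter" means the anchor lies within 1 kb of
some TSS on either side; because promoter proximity is also often quoted as
"within 1 kb upstream", the strand-aware upstream-only percentage is
computed and reported alongside rather than choosing one reading. A gene
with no exon annotation treats its whole span as intronic for anchors
inside it. The anchor-point design (rather than interval overlap) is what
makes the partition exact; wide peaks spanning several features are
assigned by their single most representative position.

## Expression, DE and enrichment

Differential expression between two cell lines is a per-gene two-sample
Welch t-test on log2 expression (two-sided, Benjamini–Hochberg adjusted,
direction by the sign of the mean difference). This is a deliberately plain
stand-in for a moderated-t pipeline: with typical replicate counts (n = 3)
the Welch test has ~4 degrees of freedom and no variance moderation, so the
BH-adjusted p < 0.01 cut that a moderated analysis supports retains almost
no genes here even at 16-fold true shifts. The per-line *candidate* gene
lists (genes DE against both other lines but not between those two) used in
the peak-proximity enrichment therefore apply the raw p < 0.01 cut, which
under the simulated conditions recovers ≥ 90% of truly shifted genes at a
~0.5% false-positive rate and yields candidate lists of a realistic size
(~5–15% of the universe). Both cuts are exposed
(`candidate_de_genes(..., use_adjusted=...)`), and externally produced gene
lists can be substituted for the DE caller everywhere a gene set is
consumed.

Genes are linked to peaks through a ±20 kb window around the TSS
(half-open, one-base-pair intersection). Enrichment of candidate DE genes
among peak-proximal genes uses Fisher's exact test on the 2×2 table over
the full gene universe of the expression table. The generic
`fisher_enrichment` defaults to the two-sided minimum-likelihood convention
(matching R's `fisher.test`); the cell-line enrichment matrix asks the
directional question "are this line's DE genes over-represented near this
line's unique peaks" and uses the one-sided `greater` alternative. The
reported odds ratio is the sample (ad)/(bc), with 0.5 added to every cell
only when a cell is zero (flagged). Proximity percentages of two peak
classes are compared with a 1-df chi-squared test without continuity
correction; a zero expected cell raises an error recommending Fisher.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
raw sequencing realism:

- **Genome** — i.i.d. uniform ACGT, default two 5-Mb chromosomes. No GC
  bias, repeats or mappability structure.
- **Binding truth** — CTCF sites drawn with a minimum spacing (default
  1.5 kb) and assigned sharing classes across three cell lines (common to
  all; shared by the two ER-positive lines; specific to one line, default
  8% per line). Co-binding copies site centres across factors: ER and/or
  FOXA1 centres are offset uniformly within ±500 bp of the CTCF summit, so
  co-bound factors are near but not on the CTCF summit. Default co-binding
  rates (4.8% ER, 19.6% FOXA1, 4.8% triple) reproduce the regime where
  about a third of CTCF events are co-bound and most co-binding involves
  FOXA1. Standalone ER/FOXA1 sites fill each factor's total (default 1,000
  sites/factor), a fraction of standalone ER sites carrying FOXA1 but not
  CTCF as a control class. ER and FOXA1 are absent from the ER-negative
  line.
- **Replicate peaks** — each truth site is emitted per replicate with
  probability 1 − dropout (default 0.05), with Normal summit jitter
  (sd 30 bp) and Normal widths (400 ± 100 bp), plus replicate-private
  uniform noise peaks (default 100). Consensus survival is therefore
  (1 − dropout)² per site, and two independently emitted conditions of the
  same truth overlap at ~90%, the treatment-invariance regime.
- **Reads** — treatment libraries mix Normal(summit, 100 bp) reads with a
  uniform background at a 2:1 signal ratio, 200,000 reads per library;
  one shared uniform input library. Read 5′ starts are written as BED —
  the pipeline consumes positions only, and alignment is out of scope.
- **Motifs** — consensus instances of the factor's own matrix are written
  over the background within ±25 bp of the factor's site centre at a 70%
  plant rate; instances that would cross a chromosome end are skipped.
- **Genes and expression** — uniformly placed TSSs (default 400 genes on
  10 Mb so promoter/genic fractions resemble a mammalian annotation; the
  DE-recovery scenario uses 2,000 genes on 40 Mb so that ±20-kb windows of
  different lines' specific sites stay mostly disjoint). Genes whose TSS
  lies within 20 kb of a line-specific site become DE in that line with
  probability 0.3 versus 0.05 background, with a ±2 log2-fold shift and
  Normal(0, 0.25) replicate noise, 3 replicates/line. "Estrogen-regulated"
  labels are planted preferentially (0.4 vs 0.08) on genes near
  ER-and-CTCF co-bound sites.

Everything is driven by one flat config and a seed; identical configs
produce byte-identical files (stage rngs are spawned from one seed
sequence). What passing tests show is that the *analysis* recovers planted
structure under these idealised conditions; they say nothing about
alignment artefacts, copy-number effects, antibody efficiency or other
properties of real ChIP-seq that the generator does not model.

## Problem sizes and numerical choices

Simulation-based checks run at deliberately modest scales chosen for a
single CPU: the default end-to-end scenario (2 × 5 Mb, 1,000 sites/factor,
8 × 200k reads) completes in ~20 s; null-calibration sweeps use 200
simulated pairs × 500 rotation iterations and 500 sequences × 200 matrix
permutations; recovery scenarios use 20 seeded runs. The planted-co-binding
power demonstration uses 2,000 rotation iterations because the add-one rule
bounds p at 1/(iterations+1), so demonstrating p < 1e-3 needs more than
1,000 iterations. Ties in row ordering are broken stably by input order;
BH adjustment is the standard step-up; Welch p-values for zero-variance
equal-mean genes are set to 1.

## Known limitations

- The block-rotation null is a documented variant of structural-correction
  testing, validated by calibration, not a reimplementation of any specific
  published segmentation scheme; segment-level variance estimators and
  confidence intervals are out of scope.
- The permuted-matrix motif null is anti-conservative for palindromic
  matrices (see above).
- The Welch DE caller is a stand-in without variance moderation; adjusted-p
  cuts at n = 3 are severely underpowered, which is why the candidate cut
  is on raw p (both exposed).
- Peak calling, read alignment, quantile normalisation and full CEAS-style
  category sets (UTRs, downstream regions) are out of scope; peaks, reads
  and normalised expression are inputs.
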