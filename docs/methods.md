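# Methods

This note documents the models and conventions behind `holosplit`: what each
stage computes, the defaults and why, what the synthetic holobiont generator
emulates, and the known limitations. Nothing here states a result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward strand. GFF3
(1-based inclusive) and BED (0-based half-open) are converted at the I/O
boundary only, so the conversion is tested once; round trips preserve
printed coordinates. GC and tetramer denominators exclude N bases; windows
with more than 50% N are masked and excluded from all fractions. The
canonical read-mapping input is a tab-separated table of mapped intervals
(`read_id, contig, start, end, mapq`); a plain-text SAM parser is provided
as an independent cross-check, not as a required route, so the package
builds without an alignment library.

## Chimera detection and splitting

A chimeric contig erroneously fuses segments of different organisms. GC is
profiled in 200 bp non-overlapping windows; a candidate breakpoint is a
window boundary where the mean GC of the 5 windows on each side differs by
at least 20 percentage points, with runs of qualifying boundaries merged to
the boundary of maximal difference. "Abrupt change" has no unique
quantitative definition; the 20 pp / 5-window default is this package's
convention, chosen to sit far above window-level GC sampling noise
(sd ≈ 1.6 pp for a 1 kb flank at 48% GC) while far below the contrast
between a RIP-degraded fungal segment (~16% GC) and a bacterial segment
(~60%).

Within one fungal genome, genic (≈48%) to RIP-degraded (≈16%) transitions
also exceed 20 pp. `scan_contig` therefore keeps, by default, only
breakpoints whose flanks straddle 50% GC with a ±4 pp guard band (low flank
< 46%, high flank > 54%): fusions between a eukaryotic (<50% GC) and a
bacterial (>50% GC) segment pass, intra-fungal compartment boundaries do
not. The guard band absorbs flank-mean noise (a 48% genic flank exceeds 54%
with negligible probability). Passing `interkingdom_gc=None` disables the
filter and exposes raw `detect_breakpoints` semantics.

Candidates are refined within a 2 kb radius: ≥ 3 tandem copies of the
fungal telomere motif CCCTAA (either strand) snap the breakpoint to the
motif edge facing the higher-GC flank — a telomere belongs to the
eukaryotic side, so that edge is the fusion point; otherwise a C or G
homopolymer ≥ 20 bp snaps it to the run midpoint. Splitting names parts
`id.p1 … id.p(k+1)`, conserves total length exactly, and tags parts with
their source contig. Dot-plot self-alignment, used interactively in the
original analyses of such junctions, is deliberately replaced by the motif
search: it is deterministic and testable.

## Kingdom classification

Tetramer profiles count all 256 forward-strand 4-mers at step 1 (no
reverse-complement collapsing — the 256 words are the feature space),
skipping windows containing N, normalized to frequencies. Contigs shorter
than 10 kb are excluded from the embedding because their profiles are too
noisy (multinomial sd per word ≈ sqrt(p/n)).

The profiles are mean-centered and embedded by PCA (3 components, full SVD,
component signs fixed so each component's largest-magnitude loading is
positive), then clustered by k-means with k = 3 — the three organism groups
a lichen contributes — with 10 restarts and a fixed seed. Because k-means
depends on row order through its initialization sampling, profiles are
sorted by contig id first; classification is therefore invariant to input
permutation. Clusters are mapped to kingdoms by evidence votes rather than
by eye: the cluster with the largest fraction of contigs carrying a RIP
signature is the fungus (ties broken by the largest GC interquartile range,
the fungal hallmark); among the rest, the cluster with the most
eukaryotic-TE/ITS evidence is the alga; the remainder is bacteria. With no
evidence at all, calls are still produced but routed `manual`.

Short contigs are assigned by homology against fungal and algal reference
contig sets: an exact 21-mer seed index over both strands, same-diagonal
chaining, ungapped X-drop extension (+1 match, −2 mismatch, drop 20 — exact
seeds fragment at ~86% identity even though the homologous span is
contiguous), and per-span rescoring. A qualifying hit spans > 300 bp at
≥ 85% identity (the identity floor is this package's convention); the
contig goes to the reference with the longest qualifying hit, and hits to
both references within 10% of each other are ambiguous → unassigned.
Contigs without a homology call are checked for a fungal RIP signature:
overall GC < 30%, or an internal ≥ 20 pp block-mean GC shift. Organelle
contigs are routed by supplied tags, not detected de novo.

## RIP compartments

Window size is 500 bp, non-overlapping: the ripped/unripped fractions are
then literally window counts. The separating threshold is estimated from a
Gaussian KDE of window GC values on a 0.1 pp grid: the density minimum
between the two highest modes. If fewer than 1000 windows are available or
no interior minimum has prominence ≥ 5% of the maximum density, the
conventional 35% threshold is returned with a warning flag. On the default
synthetic fungal genome the estimate lands near 31% and the resulting
ripped fraction equals the designed 0.375; at the fixed 35% convention the
window split is 37.5% / 62.5%.

Flank GC uses 1 kb flanks, strand-aware (for a − feature the 5′ flank is
genomic-right); flanks truncated by a contig edge are reported missing
rather than shortened. Metaprofiles cover a 10 kb flank in 200 bp windows
on each side plus a length-normalized body resampled into 50 equal bins;
rows of − features are flipped; column means ignore missing cells.

Centromere-scale RIP blocks are maximal runs of ripped windows, tolerating
up to 2 unripped windows inside a run, of length ≥ 50 kb; per chromosome
the largest block is flagged as the centromere call. The run-merge gap and
the 50 kb floor are this package's conventions — block sizes in RIP-active
fungal genomes are reported in the 100–500 kb range but no calling rule
accompanies them. "Centromere" here covers both the functional centromere
and pericentromeric repeats; no attempt is made to distinguish them without
epigenetic data.

Algal centromeres are called from retrotransposon annotation density:
non-overlapping 50 kb windows with ≥ 50% retrotransposon coverage are
merged into loci, and chromosomes with a locus count other than one are
flagged. TE-family GC ranking reports each family's copy GC values sorted
descending (families ordered by copy number): a strongly RIP-affected
retrotransposon family shows a sharp drop after its few unripped copies,
while a family that escapes RIP shows the inverse shape.

## Bacterial consensus binning

Coverage tables are per-contig × per-sample mean depths. Before
correlating, depths are normalized per sample (relative abundance) and
log10(x+1)-stabilized — whether to normalize is a config option
(`transform=`), since raw-versus-normalized input is an open choice;
stabilization of lognormal abundance variance motivates the default.
Zero-variance contigs are flagged and given correlation 0. Hierarchical
binning clusters distance 1 − r with average linkage, cut at 0.25;
singletons stay unbinned; ids are sorted first so results are
order-invariant.

The composition+coverage binner concatenates the first 3 tetramer PCs with
per-sample log-depths, standardizes, and fits Gaussian mixtures over a k
range, selecting k by BIC. Two numerical guards matter at this problem
size (tens of contigs in ~15 dimensions): the covariance is tied (shared
across components) and only solutions whose smallest component holds ≥ 3
contigs enter the BIC comparison — unconstrained per-component covariances
let BIC reward carving noise within a single species into sub-clusters.
Verified on 1-, 2-, 3- and 6-species subsets of the synthetic data, this
recovers the true k each time. Externally produced binner tables can be
substituted or added at this stage.

Consensus: each approach contributes co-binning votes for contig pairs; an
edge joins a pair supported by ≥ 2 approaches, and consensus genomes are
connected components of size ≥ 2 ("common to bins from at least two
approaches" formalized as pairwise support + components — the set-overlap
reading is ambiguous and this rule is the documented choice). rDNA-carrying
contigs anchor a bin's taxonomy, so they obey a stricter rule: at least 3
approaches must each place the contig in a bin containing > 50% of its
component's other members, else it moves to unassigned. Raising
`min_support` only removes edges, so it refines the partition
(monotonicity), and consensus is idempotent.

Known limitation: connected components are transitive, so *correlated*
mis-assignments — two independent approaches both placing the same contig
into the same wrong species' bin — create bridges that merge genomes. The
robustness the consensus adds is against approach-specific failures
(fragmentation, unbinned contigs, junk bins), which is the typical
real-binner failure mode and the corruption model used in the tests; it is
not a defence against systematically correlated errors.

## rDNA taxonomy and enrichment

16S/ITS loci are located with the same seed-and-extend engine (hits ≥ 80%
identity over ≥ 70% of a reference length; overlapping hits resolved
best-first). Pairwise identity uses biopython's global aligner (match +1,
mismatch −1, gap open −2, extend −0.5, end gaps free); identity = matches /
columns, excluding terminal-gap columns, with internal gaps counted as
non-matches. Arguments are ordered canonically before aligning because
co-optimal alignments of unrelated sequences would otherwise make the
measure asymmetric under argument swap.

Rank thresholds are strict inequalities per the caption convention: > 98%
species, > 96% genus, > 90% family, else above_family; eukaryote ITS: > 99%
species, else no call. The alternative genus threshold of 95% that appears
in methods prose is available via `genus_threshold=95`. Bin validation
reports, per bin with ≥ 2 rDNA records, the minimum within-bin and maximum
between-bin identity and flags bins where the former is below the latter —
rDNA operons within one genome are homogenized by gene conversion, so a
violation indicates a mis-attached contig.

Family enrichment between habitats is
`((c_lichen + 0.5)/N_lichen) / ((c_soil + 0.5)/N_soil)` with N the total
classified reads per habitat; families absent from soil are additionally
flagged `lichen_exclusive` rather than given an infinite factor.

## HGT screen

Candidates are genes on eukaryotic contigs overlapped (≥ 1 bp) by ≥ 2
distinct bacteria-classified reads; "multiple reads" is parameterized with
default 2 since no fixed count is canonical, and the candidate set is
monotone non-increasing in that threshold. A minimum mapping quality is
exposed (default 0). The identity contrast takes per-candidate homolog
identity lists (bacterial vs eukaryotic) as inputs — remote database
retrieval is out of scope — and supports a candidate when the bacterial
mean exceeds the eukaryotic mean by ≥ 20 pp. Coverage continuity computes
per-500 bp-window read depth over the gene ± 5 kb and calls the locus
uniform iff every window reaches ≥ 50% of the contig-wide median window
depth; a mis-assembled insertion would show a break at its boundary.

## The synthetic holobiont

The generator's defaults are the package's study conditions; they are
chosen once and the tests measure against them.

* **Fungus**: 4 chromosomes × 300 kb. Each chromosome alternates genic
  blocks (48% GC) with ripped blocks (16% GC) summing to exactly 37.5% of
  its length, including one 100 kb centromeric ripped block and one smaller
  ripped island; block boundaries are 500 bp-aligned so window truth is
  exact. Genes (1.5 kb, alternating strands) populate genic blocks;
  a retrotransposon family tiles ripped blocks with 2 unripped copies
  planted in genic sequence, and a DNA-transposon family is mostly genic
  with 2 ripped copies — producing the two opposite family GC-ranking
  shapes. Telomeres are CCCTAA multimers.
* **Alga**: 3 chromosomes × 350 kb at 52% GC, TTTAGGG telomeres (the
  fungal motif is the documented one; the algal motif is a synthetic
  convention), and one 50 kb centromere of 8 mutated copies of a
  retrotransposon consensus (two alternating families), aligned to a 50 kb
  window boundary; arms carry genes and sparse (~4%-coverage)
  retrotransposon copies as a negative control for the density caller.
* **Bacteria**: 6 species × 180 kb in 8 contigs each. Sequences come from
  order-3 Markov chains in which every step emits G/C with probability
  exactly the species GC target (62–66%), while context-dependent A-vs-T
  and G-vs-C splits carry kingdom-level (amplitude 0.30) and
  species-level (amplitude 0.10) signatures. This pins genome GC to its
  target (binomial noise only) while giving tetramer profiles real
  kingdom- and species-separation — composition classification does not
  ride on GC alone. Each species carries 3 near-identical 16S copies
  (within-species ≥ 99.5% identity) derived from a shared synthetic
  reference at species identities 99/97/95/91/88/86%, bracketing every
  rank threshold.
* **Coverage**: 12 samples, two tables (mq0/mq60) sharing abundance draws
  with independent multiplicative noise (cv = 0.1). The fungus and alga
  share a per-sample thallus abundance factor (lognormal σ = 0.4) with
  small independent jitter (σ = 0.15) — one physical organism per sample —
  so the designed 220× / 21× depth ratio is recoverable from sample means;
  bacterial abundances are independent lognormals (σ = 1.0), the signal
  correlation binning needs.
* **Chimeras and HGT**: chimeric contigs are a fungal segment (genic then
  ripped tail) joined to a bacterial segment through a telomere motif, a
  poly-C run, or nothing, with the truth breakpoint at the motif's outer
  edge / run midpoint / GC boundary respectively. Reads are mapped
  intervals, not FASTQ: a eukaryote-classified background tiles one algal
  chromosome and 10 bacteria-classified reads cover one gene, the planted
  HGT candidate. A dedicated chimera test set (50 compositionally uniform
  clean contigs + 5 chimeras) measures junction recovery and false splits.

What the generator does **not** emulate: sequencing error and read-level
noise, indels (rDNA divergence is substitution-only, which the homology
engine's diagonal chaining exploits), strain-level heterogeneity and second
haplotypes, organelle genomes, repeat-induced assembly fragmentation, GC
coverage bias, and between-approach correlated binning errors. Passing
tests therefore demonstrate that the implementations recover planted
structure of the designed kind at realistic magnitudes — not performance on
raw sequencing data.

## Problem sizes and determinism

The default synthetic holobiont is ~3.4 Mb in 68 contigs — large enough
that every window statistic is in its asymptotic regime (2,400 fungal RIP
windows, ≥ 20 kb of sequence per tetramer profile) and small enough that
the full pipeline, including generation, runs in seconds. Every random draw
descends from a single seed through tagged child generators, so identical
configs produce byte-identical outputs; the pipeline run report contains
content digests of every stage output to make reruns comparable.
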