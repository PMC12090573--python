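# Methods

## The problem

Immunoglobulin loci (IGH; the IGK/IGL light chains) carry large, repetitive,
highly heterozygous V/D/J gene families that long-read assemblers still get
wrong: whole haplotype segments go missing, inversions are introduced at
spurious overlaps, and near-identical copies collapse. Genome-wide quality
metrics (N50, BUSCO, k-mer completeness) are insensitive to these localized
failures. `igassess` evaluates the loci directly from the evidence that
built the assembly: the HiFi reads aligned back to it. For a correct
assembly, almost every read has an almost perfect alignment; systematic
departures from that expectation are localized, categorized and reported.

## Error model and statistics

Let G be the assembly and, for every position j, let J_j be the set of
retained reads covering j.

**Read-oriented view.** For each read r with n(r) aligned columns
(CIGAR M/=/X), the substitution count against the assembly is
d(r, g) = Σ_i 1(r_i ≠ g_i), and the read mismatch rate is
e_r = d(r, g) / n(r). With E_j = Σ_{x∈J_j} 1(e_x > θ), position j is
**poorly supported** iff E_j > `min_bad_reads`. Defaults: θ = 0.01
(the HiFi error-rate allowance) with a strict `>` comparison, and
`min_bad_reads` = 5, also strict. Indels and soft clips are excluded from
d and tracked separately (`--count-indels-in-e` folds indel bases into
e_r for sensitivity analyses): the statistic is a substitution rate, and
clipping/indel burden are reported as their own read-level metrics.

**Basepair-oriented view.** δ_j counts reads whose base at j disagrees
with G_j; a deletion spanning j counts as disagreement (a gene can lose
base support through a deletion), an insertion between positions counts
toward neither depth nor δ. The per-position support fraction is
(depth − δ)/depth, undefined (NaN) at zero depth and at reference-N
positions — absence of data is never reported as perfect support.

**Coverage breaks.** Maximal runs of positions with depth ≤
`max_break_depth` (default 2 — two reads being the minimum that can
establish an overlap; the comparison is `≤`, matching the operational
rule used in the diagnostic figures). Runs are merged across gaps ≤
`break_merge_gap` (default 0) and categorized with precedence
n_gap (≥50% reference N) → zero_coverage → low_coverage_edge (touching a
region/contig end) → low_coverage_internal. No minimum break length is
imposed by default (`min_break_len` = 1).

**Coverage spikes.** Collapsed duplications double local read depth. The
detector flags non-overlapping 1 kb windows whose median depth reaches
`spike_factor` (default 2.0) × a locus baseline, merges adjacent flagged
windows and drops intervals shorter than `spike_min_len` (1 kb). The
baseline is a one-pass contamination-robust median: windows already at
≥1.5× the raw locus median are masked and the median re-estimated over
the rest, as in read-depth CNV calling. A plain locus median is itself
inflated by the spike and by orphan-read spillover around it, which
biases an exactly two-fold collapse below a two-fold threshold; the
robust baseline removes that self-contamination. Each spike reports a
representative `fold_change` (median of its window medians over the
baseline) and a `peak_fold`; the peak rides sampling noise upward
(max over ~dozens of windows at σ/µ ≈ 18% at 30×) and is for display.

**Filtering.** Unmapped, secondary, QC-fail and duplicate records are
excluded (the samtools-mpileup default), so the BAM and mpileup pileup
paths agree exactly. Supplementary alignments count toward depth, δ and
clip statistics — the split-read signal around inversions — but never
toward E or gene read-view calls, whose unit is the read, represented by
its primary record. No MAPQ filter is applied: MAPQ-0 placement between
identical copies is ambiguity, not error; depth is stratified by MAPQ
bins (0 / 1–59 / 60) for display instead.

## Gene and locus verdicts

A gene is **read-view affected** iff more than `min_bad_reads` primary
reads with e_r > θ overlap its interval by ≥1 bp (HiFi reads dwarf gene
lengths, so the overlap definition is insensitive). A gene is
**base-view affected** iff any covered position has support ≤
`base_support_min` (default 0.80: the rule is *more than* 80% support at
every position, so exactly 0.80 fails), evaluated only over positions
with data.

A locus is classified **mismatch** iff it contains a run of consecutive
poorly supported positions of at least `mismatch_run_min` bp (default
100). The run-length requirement separates the large missing-sequence
signature from isolated SNP-like flags; a single-position rule would
call every residual heterozygous site an assembly error. A locus is
**break** iff it has at least one coverage break, excluding
edge-touching breaks by default (`--count-edge-breaks` restores them):
contig ends legitimately lose coverage. The flags are independent
(`both` is possible); **good** is exactly "neither". Aggregation tables
therefore have non-exclusive mismatch/break columns with
good + |mismatch ∪ break| = n loci per cell. Haplotype resolution is
taken from contig labels (hap1/hap2 = resolved; primary/alternate or
unassigned = unresolved), supplied by the user or a `haplotype=` FASTA
header tag, never inferred from contig names.

## Coordinates and I/O

All internal coordinates are 0-based half-open; 1-based values exist
only at parse/render boundaries (IgDetective-style TSV input is 1-based
inclusive; mpileup text is 1-based; report TSVs print 1-based worst
positions). Locus regions are evaluated exactly as given (an optional
`--pad`, default 0, widens them). Genes outside every region are dropped
with a warning (configurable to a hard error); genes straddling a region
boundary are clipped, since upstream locus boundaries are heuristic.

The mpileup ingestion path accepts samtools-mpileup default text
produced with the reference (`-f`); `-aa -B -Q 0` reproduces the BAM
path's (depth, δ) tracks exactly. E and MAPQ stratification cannot be
recovered from mpileup and are marked absent; read-oriented flagging on
such profiles raises an error directing to the BAM path, and locus
classification then rests on coverage signals alone.

## The synthetic study conditions

The simulator emulates the data regime the assessment targets, at desk
scale: a diploid IG-like locus (default 300 kb) inside 30 kb flanks
(≥ max read length, so locus edges reach full coverage), V/D/J segments
placed at homologous coordinates in the field's V→D→J order (defaults
40 V ≈ 300 bp, 16 D ≈ 20 bp, 6 J ≈ 60 bp), 0.5% baseline haplotype
divergence with two multi-kb diverged blocks at 2%, truncated-normal
15–25 kb reads (mean 20 kb) with i.i.d. substitution errors at 0.3%,
and 30× mean depth per haplotype. All randomness flows from one seed;
identical specs give byte-identical outputs.

Injections corrupt **the assembly only**; reads always come from the
uncorrupted truth — the causal model of alignment-based error detection.
`drop_segment` (default 50 kb) sits inside a diverged block: orphaned
reads land on the homolog at block divergence (~2.3% with sequencing
error), safely above θ; at baseline divergence they would align at
~0.8% and the missing segment would be invisible to a mismatch
statistic — which is precisely why real assemblers fail, and real
assessments alarm, where haplotypes diverge. `inversion_with_gap`
reverse-complements a segment and inserts an 8 kb N run at the proximal
breakpoint. `collapse_duplication` (default 60 kb = 2× max read length
+ 10 kb core, so the interior reaches the full 2× plateau) first makes
the segment identical between haplotypes in the truth, then deletes one
assembly copy; orphan reads align perfectly, making depth the only
signature.

Reads are aligned with `minimap2 -ax map-hifi` when available; otherwise
a bundled deterministic seed-and-place aligner for the simulator's
substitution-only reads (exact 21-mer voting over (contig, strand,
diagonal), gapless extension bounded by contig ends and N runs,
mismatch-penalized scoring, split primary/supplementary output, MAPQ 0
on exact score ties) produces the SAM.

**What the simulator does not model:** HiFi homopolymer-indel error
spectra, chimeric reads, coverage biases, germline indels between
haplotypes, structural variants beyond the three injection types, and
multi-contig fragmented assemblies. Passing the synthetic suite shows
the statistics and detectors implement their definitions and recover
planted truth under the stated regime; it does not certify recall on
real assemblies, where divergence structure and repeat content are far
richer.

Known cross-talk, visible in the fixtures and expected on real data:
reads crossing a misassembly junction prefer a collinear alignment on
the homologous haplotype over a split alignment, so a corrupted hap2
also paints a mismatch signature onto hap1 (for the dropped segment
this *is* the primary signal; for the inversion and a collapse flanked
by diverged sequence it is a side effect). Breakpoint flanks can also
dip to ≤2 reads over tens of bp (split anchors), occasionally adding a
short internal break next to the planted N-gap.

## Problem sizes and numerical choices

The test suite and the acceptance script regenerate all fixtures at the
defaults above (300 kb loci; ~1030 reads per fixture); unit tests use
scaled variants (30–60 kb loci, 2–5 kb reads) where the full conditions
add nothing. The truth-recovery checks fix the simulation seed, as
recovery is specified deterministically given the seed. Tie-breaks and
degenerate inputs: empty read sets are an error at summary level and
"uncovered" at gene level; zero-length regions cannot be rendered;
NaN marks every undefined rate; candidate placements in the builtin
aligner break score ties by (contig, position) for determinism.
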