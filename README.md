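# igassess

Alignment-based assembly quality assessment for the immunoglobulin loci
(IGH, IGK, IGL) of long-read genome assemblies.

The IG loci carry large, repetitive, highly heterozygous V/D/J gene
families that assemblers still misrepresent — dropped haplotype
segments, false inversions, collapsed duplications — while genome-wide
metrics (N50, BUSCO, k-mer spectra) stay green. `igassess` evaluates
these loci directly from the HiFi reads aligned back to the assembly:
for a correct assembly nearly every read should align nearly perfectly,
so systematic disagreement is evidence of error. It is aimed at genome
assembly and immunogenomics groups curating IG regions in vertebrate
assemblies; locus boundaries and V/D/J gene coordinates come from an
upstream annotator (IgDetective-style TSV or BED), and alignments from
`minimap2 -ax map-hifi`.

## Statistics

With assembly `G`, covering-read set `J_j` at position `j`, and each
read `r` spanning `n(r)` aligned columns:

- **read-oriented**: `d(r,g) = Σ_i 1(r_i ≠ g_i)`, `e_r = d(r,g)/n(r)`,
  and `E_j = Σ_{x∈J_j} 1(e_x > θ)` with θ = 0.01; position `j` is
  *poorly supported* iff `E_j > 5`;
- **basepair-oriented**: `δ_j = Σ_{x∈J_j} 1(x_j ≠ G_j)` (a deletion at
  `j` disagrees); base support is `(depth − δ_j)/depth`, and a gene
  lacks *perfect support* unless support exceeds 0.80 at every covered
  position;
- **coverage breaks**: maximal runs with depth ≤ 2 (two reads being the
  minimum that establishes an overlap), categorized as N-gap / zero
  coverage / edge / internal;
- **coverage spikes**: ≥1 kb of windowed median depth at ≥2× a robust
  locus baseline, the collapsed-duplication signature.

Each locus is classified `mismatch` / `break` / `both` / `good`; per-gene
affected calls are made from both views; MAPQ-0 placement in repeats is
stratified for display, never auto-called as error. Details, defaults
and design rationale: [docs/methods.md](docs/methods.md).

A synthetic module generates diploid IG-like loci (divergent haplotype
blocks, 15–25 kb reads at 0.3% error, 30× per haplotype) with injectable
misassemblies and truth files, so every detector is exercised end to end
without downloads.

## Worked example

Simulate an assembly whose second haplotype is missing a 50 kb segment,
then evaluate it:

```
igassess simulate --name dropped_segment --seed 1 --out drop/
igassess evaluate --assembly drop/assembly.fasta --bam drop/alignments.bam \
    --loci drop/loci.bed --genes drop/genes.bed --out drop/report
```

`drop/report/locus_summary.tsv` (columns abridged):

```
locus_type  contig  classification  pct_positions_poorly_supported  pct_genes_read_affected  n_breaks  frac_high_mismatch
IGH         hap1    mismatch        25.0720                         20.97                    0         0.1596
IGH         hap2    good            0.0000                          0.00                     0         0.0000
```

The reads orphaned by the missing hap2 segment pile onto the homologous
hap1 interval: 25% of hap1 positions are poorly supported, 21% of hap1
genes are overlapped by >5 poorly aligned reads, and ~16% of reads show
high mismatch rates — while hap2 itself looks clean, exactly the
haplotype-asymmetric signature of missing sequence. `genes_quality.tsv`
lists per-gene calls with worst positions; `breaks.bed`,
`poorly_supported.bed` and `spikes.bed` hold the intervals; each panel
PNG has a JSON sidecar with every drawn mark. On the false-inversion
fixture the same run instead reports one break, `hap2 150000 158000
n_gap` in `breaks.bed`, coinciding exactly with the planted 8 kb N run.

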