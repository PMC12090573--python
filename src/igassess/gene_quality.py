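"""Gene-level "affected" calls and locus-level classification.

A gene can be affected from two complementary views:

* read view -- the gene is overlapped (by >= 1 bp of reference span) by
  strictly more than ``min_bad_reads`` primary reads whose whole-read
  mismatch rate exceeds theta ("covered by > 5 poorly aligned reads");
* base view -- some covered position in the gene has base support at or
  below ``base_support_min`` (the "> 80% support at every position" rule,
  so support exactly 0.80 is affected).

A locus is classified ``mismatch`` / ``break`` / ``both`` / ``good``:
``mismatch`` when it contains a run of consecutive poorly supported
positions of at least ``mismatch_run_min`` bp (isolated SNP-like flags do
not make a locus-level verdict), ``break`` when it contains at least one
coverage break (edge-touching breaks excluded unless ``count_edge_breaks``).
The two flags are independent; ``good`` means neither.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .error_detect import ErrorCallSet
from .ig_model import GeneAnnotation, LocusRegion, RESOLVED_LABELS, RunConfig
from .pileup_profile import PositionProfiles, ReadAlignment, ReadSummary

CLASSIFICATIONS = ("good", "mismatch", "break", "both")


@dataclass
class GeneQuality:
    """Both views for one gene.  ``None`` flags mean "no data"."""

    gene_id: str
    segment_type: str
    contig: str
    start: int
    end: int
    read_view_affected: bool | None = None
    bad_read_overlap_count: int = 0
    uncovered: bool = False
    base_view_affected: bool | None = None
    min_support_fraction: float = float("nan")
    worst_position: int | None = None


def assess_gene_read_view(
    gene: GeneAnnotation,
    reads: Sequence[ReadAlignment],
    config: RunConfig | None = None,
) -> GeneQuality:
    """Count poorly aligned primary reads whose reference span overlaps the
    gene by >= 1 bp; affected iff the count is strictly > min_bad_reads.
    A gene with zero covering reads is not affected but flagged uncovered."""
    config = config or RunConfig()
    covering = 0
    bad = 0
    for rd in reads:
        if rd.is_secondary or rd.is_supplementary:
            continue
        if rd.contig != gene.contig or not rd.overlaps(gene.start, gene.end):
            continue
        covering += 1
        if rd.is_poorly_aligned(config.theta):
            bad += 1
    return GeneQuality(
        gene_id=gene.gene_id,
        segment_type=gene.segment_type,
        contig=gene.contig,
        start=gene.start,
        end=gene.end,
        read_view_affected=bad > config.min_bad_reads,
        bad_read_overlap_count=bad,
        uncovered=covering == 0,
    )


def assess_gene_base_view(
    gene: GeneAnnotation,
    profiles: PositionProfiles,
    config: RunConfig | None = None,
) -> GeneQuality:
    """Affected iff any covered gene position has support <= base_support_min
    (evaluated only over positions with depth > 0 and a non-N reference
    base).  If no gene position has data the flag is None ("no data")."""
    config = config or RunConfig()
    support = profiles.support_fraction
    s = max(gene.start, profiles.start) - profiles.start
    e = min(gene.end, profiles.end) - profiles.start
    gq = GeneQuality(
        gene_id=gene.gene_id,
        segment_type=gene.segment_type,
        contig=gene.contig,
        start=gene.start,
        end=gene.end,
    )
    window = support[s:e]
    defined = ~np.isnan(window)
    if s >= e or not defined.any():
        gq.base_view_affected = None
        return gq
    vals = window[defined]
    idx = np.flatnonzero(defined)
    argmin = int(idx[np.argmin(vals)])
    gq.min_support_fraction = float(vals.min())
    gq.worst_position = profiles.start + s + argmin
    gq.base_view_affected = gq.min_support_fraction <= config.base_support_min
    return gq


def assess_genes(
    genes: Sequence[GeneAnnotation],
    reads: Sequence[ReadAlignment],
    profiles: PositionProfiles,
    config: RunConfig | None = None,
) -> list[GeneQuality]:
    """Both views for every gene on the profile's contig."""
    config = config or RunConfig()
    out = []
    for gene in genes:
        if gene.contig != profiles.contig:
            continue
        gq = assess_gene_read_view(gene, reads, config)
        base = assess_gene_base_view(gene, profiles, config)
        gq.base_view_affected = base.base_view_affected
        gq.min_support_fraction = base.min_support_fraction
        gq.worst_position = base.worst_position
        out.append(gq)
    return out


# ---------------------------------------------------------------------------
# Locus classification
# ---------------------------------------------------------------------------

@dataclass
class LocusSummary:
    """Per-locus verdict plus summary metrics."""

    locus_type: str
    contig: str
    haplotype: str
    resolution: str  # haplotype-resolved | haplotype-unresolved
    locus_length: int
    has_mismatch_error: bool
    has_coverage_break: bool
    classification: str
    pct_positions_poorly_supported: float
    pct_genes_read_affected: float
    pct_genes_base_affected: float
    n_genes: int
    n_breaks: int
    n_spikes: int
    read_summary: ReadSummary | None = None
    read_view_available: bool = True


def classify_locus(
    error_calls: ErrorCallSet,
    gene_qualities: Sequence[GeneQuality],
    config: RunConfig | None = None,
    read_summary: ReadSummary | None = None,
) -> LocusSummary:
    """Derive the locus verdict from the complete call set.

    The two error flags are independent; a locus may be ``both``.  ``good``
    is exactly "neither flag".
    """
    config = config or RunConfig()
    region = error_calls.region
    runs = error_calls.poorly_supported_runs()
    has_mismatch = any(e - s >= config.mismatch_run_min for s, e in runs)
    countable = [
        b for b in error_calls.coverage_breaks
        if config.count_edge_breaks or b.category != "low_coverage_edge"
    ]
    has_break = len(countable) > 0
    if has_mismatch and has_break:
        classification = "both"
    elif has_mismatch:
        classification = "mismatch"
    elif has_break:
        classification = "break"
    else:
        classification = "good"

    L = len(region)
    n_flagged = int(len(error_calls.poorly_supported_positions))
    genes = list(gene_qualities)
    n_genes = len(genes)
    read_aff = sum(1 for g in genes if g.read_view_affected)
    base_aff = sum(1 for g in genes if g.base_view_affected)
    return LocusSummary(
        locus_type=region.locus_type,
        contig=region.contig,
        haplotype=region.haplotype,
        resolution=(
            "haplotype-resolved" if region.haplotype in RESOLVED_LABELS
            else "haplotype-unresolved"
        ),
        locus_length=L,
        has_mismatch_error=has_mismatch,
        has_coverage_break=has_break,
        classification=classification,
        pct_positions_poorly_supported=100.0 * n_flagged / L,
        pct_genes_read_affected=100.0 * read_aff / n_genes if n_genes else float("nan"),
        pct_genes_base_affected=100.0 * base_aff / n_genes if n_genes else float("nan"),
        n_genes=n_genes,
        n_breaks=len(countable),
        n_spikes=len(error_calls.coverage_spikes),
        read_summary=read_summary,
        read_view_available=error_calls.read_view_available,
    )


def aggregate_summary_table(summaries: Sequence[LocusSummary]) -> pd.DataFrame:
    """Counts by (locus_type, resolution): mismatch / break / good.

    The mismatch and break columns may overlap (a locus with both flags is
    counted in each); ``good`` is the complement of their union, so
    ``good + |mismatch OR break| = n_loci`` in every row.
    """
    if not summaries:
        raise ValueError("need at least one locus summary")
    rows = []
    keys = sorted({(s.locus_type, s.resolution) for s in summaries})
    for locus_type, resolution in keys:
        cell = [s for s in summaries
                if s.locus_type == locus_type and s.resolution == resolution]
        n = len(cell)
        mism = sum(s.has_mismatch_error for s in cell)
        brk = sum(s.has_coverage_break for s in cell)
        good = sum(
            not s.has_mismatch_error and not s.has_coverage_break for s in cell
        )
        rows.append({
            "locus_type": locus_type,
            "resolution": resolution,
            "n_loci": n,
            "mismatch": mism,
            "break": brk,
            "good": good,
            "pct_mismatch": 100.0 * mism / n,
            "pct_break": 100.0 * brk / n,
            "pct_good": 100.0 * good / n,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _flag(x: bool | None) -> str:
    return "NA" if x is None else ("yes" if x else "no")


def write_genes_quality_tsv(
    gene_qualities: Sequence[GeneQuality], path: str | Path
) -> None:
    """gene_id, both flags, min support, worst position (1-based)."""
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tsegment_type\tcontig\tstart\tend\tread_view_affected\t"
            "bad_read_overlap_count\tuncovered\tbase_view_affected\t"
            "min_support_fraction\tworst_position_1based\n"
        )
        for g in gene_qualities:
            worst = g.worst_position + 1 if g.worst_position is not None else "NA"
            minsup = (
                "NA" if np.isnan(g.min_support_fraction)
                else f"{g.min_support_fraction:.4f}"
            )
            fh.write(
                f"{g.gene_id}\t{g.segment_type}\t{g.contig}\t{g.start}\t{g.end}\t"
                f"{_flag(g.read_view_affected)}\t{g.bad_read_overlap_count}\t"
                f"{_flag(g.uncovered)}\t{_flag(g.base_view_affected)}\t"
                f"{minsup}\t{worst}\n"
            )


def write_locus_summary_tsv(
    summaries: Sequence[LocusSummary], path: str | Path
) -> None:
    cols = [
        "locus_type", "contig", "haplotype", "resolution", "locus_length",
        "classification", "has_mismatch_error", "has_coverage_break",
        "pct_positions_poorly_supported", "pct_genes_read_affected",
        "pct_genes_base_affected", "n_genes", "n_breaks", "n_spikes",
        "n_primary_reads", "frac_mapq60", "frac_softclipped",
        "frac_high_mismatch", "frac_large_indels",
        "frac_high_mismatch_or_indels",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in summaries:
            rs = s.read_summary
            fh.write("\t".join(str(v) for v in [
                s.locus_type, s.contig, s.haplotype, s.resolution,
                s.locus_length, s.classification,
                _flag(s.has_mismatch_error), _flag(s.has_coverage_break),
                f"{s.pct_positions_poorly_supported:.4f}",
                f"{s.pct_genes_read_affected:.2f}",
                f"{s.pct_genes_base_affected:.2f}",
                s.n_genes, s.n_breaks, s.n_spikes,
                rs.n_primary if rs else "NA",
                f"{rs.frac_mapq60:.4f}" if rs else "NA",
                f"{rs.frac_softclipped:.4f}" if rs else "NA",
                f"{rs.frac_high_mismatch:.4f}" if rs else "NA",
                f"{rs.frac_large_indels:.4f}" if rs else "NA",
                f"{rs.frac_high_mismatch_or_indels:.4f}" if rs else "NA",
            ]) + "\n")


def write_aggregate_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.2f")
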