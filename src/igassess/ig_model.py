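"""Domain types and file readers/writers for IG-locus assembly assessment.

All coordinate conventions are fixed here: every interval handled by this
package is **0-based, half-open** (`[start, end)`).  One-based coordinates
appear only at the boundaries -- when parsing IgDetective-style TSV gene
tables (1-based inclusive) or samtools-mpileup text, and when rendering
human-readable reports.

The module houses:

* :class:`AssemblySequences` -- the assembly under evaluation, one nucleotide
  string per contig plus a haplotype label per contig;
* :class:`LocusRegion` -- an IGH/IGK/IGL locus interval on a contig;
* :class:`GeneAnnotation` -- a V/D/J gene segment interval;
* :class:`RunConfig` -- every threshold used downstream, with the published
  defaults (per-read mismatch-rate threshold theta = 0.01, the strict
  ">5 poorly aligned reads" rule, the "coverage <= 2" break rule, 80% base
  support, and the ">2 consecutive bp" large-indel definition).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO

logger = logging.getLogger("igassess")

LOCUS_TYPES = ("IGH", "IGK", "IGL")
SEGMENT_TYPES = ("V", "D", "J")
HAPLOTYPE_LABELS = ("primary", "alternate", "hap1", "hap2", "unassigned")

#: haplotype labels that indicate a haplotype-resolved assembly
RESOLVED_LABELS = frozenset({"hap1", "hap2"})

_N_BYTE = ord("N")


class InputError(ValueError):
    """Raised when an input file violates a loader contract."""


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class AssemblySequences:
    """The assembly G: per-contig nucleotide strings over {A,C,G,T,N}.

    Sequences are stored uppercase; lowercase input is normalized on load.
    ``haplotype_of`` maps each contig to one of :data:`HAPLOTYPE_LABELS`.
    """

    contigs: dict[str, str]
    haplotype_of: dict[str, str] = field(default_factory=dict)
    _byte_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if len(seq) < 1:
                raise InputError(f"contig {name!r} has length 0")
            self.haplotype_of.setdefault(name, "unassigned")
        for name, label in self.haplotype_of.items():
            if label not in HAPLOTYPE_LABELS:
                raise InputError(
                    f"haplotype label {label!r} for contig {name!r} not in "
                    f"{HAPLOTYPE_LABELS}"
                )

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def seq_array(self, contig: str) -> np.ndarray:
        """Contig sequence as a uint8 array of ASCII codes (cached)."""
        arr = self._byte_cache.get(contig)
        if arr is None:
            arr = np.frombuffer(self.contigs[contig].encode("ascii"), dtype=np.uint8)
            self._byte_cache[contig] = arr
        return arr

    def n_mask(self, contig: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of reference-N positions over ``[start, end)``."""
        return self.seq_array(contig)[start:end] == _N_BYTE


def _haplotype_from_description(description: str) -> str | None:
    # a "haplotype=LABEL" token anywhere in the FASTA header line
    for token in description.replace(";", " ").split():
        if token.startswith("haplotype="):
            return token.split("=", 1)[1]
    return None


def load_assembly(
    fasta_path: str | Path,
    haplotype_map: Mapping[str, str] | None = None,
) -> AssemblySequences:
    """Load an assembly FASTA into an :class:`AssemblySequences`.

    Haplotype labels come from ``haplotype_map`` (contig -> label) or, failing
    that, from a ``haplotype=<label>`` token in the FASTA header description.
    They are never inferred from contig names.  Contigs with no label are
    ``unassigned``.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise InputError(f"assembly FASTA not found: {fasta_path}")
    contigs: dict[str, str] = {}
    hap_of: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in contigs:
            raise InputError(f"duplicate contig name in FASTA: {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
        tag = _haplotype_from_description(rec.description)
        if tag is not None:
            hap_of[rec.id] = tag
    if not contigs:
        raise InputError(f"no sequences found in FASTA: {fasta_path}")
    if haplotype_map:
        hap_of.update(haplotype_map)
    return AssemblySequences(contigs=contigs, haplotype_of=hap_of)


# ---------------------------------------------------------------------------
# Locus regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusRegion:
    """One IG locus interval ``[start, end)`` on a contig."""

    locus_type: str
    contig: str
    start: int
    end: int
    haplotype: str = "unassigned"

    def __post_init__(self) -> None:
        if self.locus_type not in LOCUS_TYPES:
            raise InputError(
                f"locus_type {self.locus_type!r} not in {LOCUS_TYPES}"
            )
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid locus interval [{self.start}, {self.end}) on "
                f"{self.contig}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.locus_type}_{self.contig}_{self.start}_{self.end}"


def load_locus_regions(
    path: str | Path,
    assembly: AssemblySequences,
    pad: int = 0,
) -> list[LocusRegion]:
    """Load locus regions from a BED4+ file (``contig start end locus_type``).

    A TSV with a header line containing ``locus``/``locus_type`` is accepted
    as well.  Regions are validated against contig lengths, optionally padded
    by ``pad`` bp on each side (clamped to the contig), and overlapping
    same-type regions on one contig are merged with a warning.  The evaluated
    intervals are exactly those given (plus any padding); no other adjustment
    is applied.
    """
    rows = _read_table(path)
    raw: list[LocusRegion] = []
    for lineno, parts in rows:
        if len(parts) < 4:
            raise InputError(f"{path}:{lineno}: expected >=4 columns, got {len(parts)}")
        contig, start_s, end_s, ltype = parts[0], parts[1], parts[2], parts[3]
        if contig not in assembly.contigs:
            raise InputError(f"{path}:{lineno}: unknown contig {contig!r}")
        start, end = int(start_s), int(end_s)
        clen = assembly.length(contig)
        if pad:
            start, end = max(0, start - pad), min(clen, end + pad)
        if not (0 <= start < end <= clen):
            raise InputError(
                f"{path}:{lineno}: locus interval [{start}, {end}) outside "
                f"contig {contig!r} (length {clen})"
            )
        raw.append(
            LocusRegion(
                locus_type=ltype,
                contig=contig,
                start=start,
                end=end,
                haplotype=assembly.haplotype_of.get(contig, "unassigned"),
            )
        )
    # merge overlapping same-(contig, type) regions; half-open abutment is kept
    merged: list[LocusRegion] = []
    raw.sort(key=lambda r: (r.contig, r.locus_type, r.start))
    for reg in raw:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.contig == reg.contig
            and prev.locus_type == reg.locus_type
            and reg.start < prev.end
        ):
            logger.warning(
                "merging overlapping %s regions on %s: [%d,%d) + [%d,%d)",
                reg.locus_type, reg.contig, prev.start, prev.end, reg.start, reg.end,
            )
            merged[-1] = replace(prev, end=max(prev.end, reg.end))
        else:
            merged.append(reg)
    merged.sort(key=lambda r: (r.contig, r.start))
    return merged


def write_locus_bed(regions: Sequence[LocusRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for reg in sorted(regions, key=lambda r: (r.contig, r.start)):
            fh.write(f"{reg.contig}\t{reg.start}\t{reg.end}\t{reg.locus_type}\n")


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """One V/D/J gene segment, ``[start, end)`` on a contig."""

    gene_id: str
    segment_type: str
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.segment_type not in SEGMENT_TYPES:
            raise InputError(
                f"gene {self.gene_id!r}: segment_type {self.segment_type!r} "
                f"not in {SEGMENT_TYPES}"
            )
        if self.end - self.start < 1:
            raise InputError(f"gene {self.gene_id!r}: empty interval")
        if self.strand not in ("+", "-"):
            raise InputError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def segment_type_from_name(name: str) -> str | None:
    """Infer V/D/J from a gene name like ``IGHV1-2`` or ``IGLJ3``."""
    upper = name.upper()
    for lt in LOCUS_TYPES:
        if upper.startswith(lt) and len(upper) > 3 and upper[3] in SEGMENT_TYPES:
            return upper[3]
    return None


def _read_table(path: str | Path) -> list[tuple[int, list[str]]]:
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            rows.append((lineno, line.replace(",", "\t").split("\t") if "\t" in line else line.split()))
    return rows


_TSV_COLUMN_ALIASES = {
    "contig": "contig", "chrom": "contig", "chromosome": "contig", "reference": "contig",
    "start": "start", "pos": "start", "start_pos": "start",
    "end": "end", "stop": "end", "end_pos": "end",
    "strand": "strand",
    "segment_type": "segment_type", "gene_type": "segment_type", "type": "segment_type",
    "gene_id": "gene_id", "id": "gene_id", "gene": "gene_id", "name": "gene_id",
}


def load_gene_annotations(
    path: str | Path,
    assembly: AssemblySequences,
    regions: Sequence[LocusRegion],
    on_outside: str = "warn",
) -> list[GeneAnnotation]:
    """Load gene annotations from BED6 or an IgDetective-style TSV.

    BED is taken as-is (0-based half-open); a TSV with a recognized header is
    treated as 1-based inclusive and converted.  Genes must lie within exactly
    one locus region: genes overlapping a region boundary are clipped with a
    warning, and genes outside every region are dropped with a warning
    (``on_outside="error"`` raises instead).  Output is sorted by
    ``(contig, start)``.
    """
    if on_outside not in ("warn", "error"):
        raise ValueError("on_outside must be 'warn' or 'error'")
    rows = _read_table(path)
    if not rows:
        return []

    header_map = _detect_tsv_header(rows[0][1])
    genes: list[GeneAnnotation] = []
    if header_map is not None:
        for lineno, parts in rows[1:]:
            rec = {name: parts[idx] for name, idx in header_map.items() if idx < len(parts)}
            start = int(rec["start"]) - 1  # 1-based inclusive -> 0-based half-open
            end = int(rec["end"])
            genes.append(
                _validated_gene(
                    gene_id=rec.get("gene_id", f"gene_{lineno}"),
                    segment_type=rec.get("segment_type", "").upper(),
                    contig=rec["contig"], start=start, end=end,
                    strand=rec.get("strand", "+"), assembly=assembly,
                    source=f"{path}:{lineno}",
                )
            )
    else:
        for lineno, parts in rows:
            if len(parts) < 4:
                raise InputError(f"{path}:{lineno}: BED gene line needs >=4 columns")
            contig, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) >= 6 else "+"
            seg = segment_type_from_name(name)
            if seg is None:
                raise InputError(
                    f"{path}:{lineno}: cannot infer V/D/J segment type from "
                    f"gene name {name!r}"
                )
            genes.append(
                _validated_gene(
                    gene_id=name, segment_type=seg, contig=contig, start=start,
                    end=end, strand=strand, assembly=assembly,
                    source=f"{path}:{lineno}",
                )
            )

    out: list[GeneAnnotation] = []
    for gene in genes:
        host = _containing_region(gene, regions)
        if host is None:
            msg = f"gene {gene.gene_id!r} lies outside every locus region"
            if on_outside == "error":
                raise InputError(msg)
            logger.warning("%s; dropped", msg)
            continue
        if gene.start < host.start or gene.end > host.end:
            clipped = replace(
                gene,
                start=max(gene.start, host.start),
                end=min(gene.end, host.end),
            )
            logger.warning(
                "gene %s clipped to region boundary [%d,%d) -> [%d,%d)",
                gene.gene_id, gene.start, gene.end, clipped.start, clipped.end,
            )
            gene = clipped
        out.append(gene)
    out.sort(key=lambda g: (g.contig, g.start))
    return out


def _detect_tsv_header(first_row: list[str]) -> dict[str, int] | None:
    mapped = {}
    for idx, col in enumerate(first_row):
        alias = _TSV_COLUMN_ALIASES.get(col.strip().lower())
        if alias is not None and alias not in mapped:
            mapped[alias] = idx
    required = {"contig", "start", "end"}
    if required.issubset(mapped):
        return mapped
    return None


def _validated_gene(
    gene_id: str, segment_type: str, contig: str, start: int, end: int,
    strand: str, assembly: AssemblySequences, source: str,
) -> GeneAnnotation:
    if contig not in assembly.contigs:
        raise InputError(f"{source}: gene {gene_id!r} on unknown contig {contig!r}")
    if end > assembly.length(contig):
        raise InputError(
            f"{source}: gene {gene_id!r} extends past end of contig "
            f"{contig!r} ({end} > {assembly.length(contig)})"
        )
    if start < 0:
        raise InputError(f"{source}: gene {gene_id!r} has negative start")
    return GeneAnnotation(
        gene_id=gene_id, segment_type=segment_type, contig=contig,
        start=start, end=end, strand=strand,
    )


def _containing_region(
    gene: GeneAnnotation, regions: Sequence[LocusRegion]
) -> LocusRegion | None:
    best = None
    for reg in regions:
        if reg.contig == gene.contig and gene.start < reg.end and gene.end > reg.start:
            if best is None or min(gene.end, reg.end) - max(gene.start, reg.start) > (
                min(gene.end, best.end) - max(gene.start, best.start)
            ):
                best = reg
    return best


def write_gene_bed(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    """Write genes as BED6 (name = gene_id; score column 0)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.contig, g.start)):
            fh.write(f"{g.contig}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """All thresholds for the evaluation, with published defaults.

    theta
        Per-read mismatch-rate threshold; a read is "poorly aligned" iff its
        mismatch rate e_r strictly exceeds theta.  Default 0.01, the HiFi
        error-rate allowance.
    min_bad_reads
        A position is poorly supported iff the number E of covering poorly
        aligned reads is strictly greater than this.  Default 5.  The same
        strict-> rule makes a gene read-view affected.
    max_break_depth
        A position is break-covered iff its depth is <= this.  Default 2,
        the minimum read count that can establish an overlap.
    base_support_min
        A gene is base-view affected iff any covered position has base
        support <= this fraction (the ">80% support at every position" rule).
    indel_min_len
        Minimum run length (bp) for an insertion/deletion to count as a
        large indel; default 3, i.e. ">2 consecutive base pairs".
    spike_factor, spike_min_len
        Coverage-spike call: windowed median depth >= spike_factor x the
        robust locus baseline over at least spike_min_len bp (windows of
        spike_window bp).
    break_merge_gap
        Merge coverage-break runs separated by gaps <= this many bp.
    min_break_len
        Minimum reported break length (bp); default 1 (no minimum).
    mismatch_run_min
        Minimum run (bp) of consecutive poorly supported positions for a
        locus-level "mismatch" verdict; default 100.
    count_edge_breaks
        Whether breaks touching a region/contig end count toward the
        locus-level "break" verdict; default False.
    count_indels_in_e
        If True, indel bases are folded into the per-read mismatch rate
        (numerator d + indel bases, denominator aligned + inserted bases);
        default False: substitutions only.
    """

    theta: float = 0.01
    min_bad_reads: int = 5
    max_break_depth: int = 2
    base_support_min: float = 0.80
    indel_min_len: int = 3
    spike_factor: float = 2.0
    spike_min_len: int = 1000
    spike_window: int = 1000
    break_merge_gap: int = 0
    min_break_len: int = 1
    mismatch_run_min: int = 100
    count_edge_breaks: bool = False
    count_indels_in_e: bool = False
    pad: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise InputError("theta must be in (0, 1)")
        if not 0 < self.base_support_min < 1:
            raise InputError("base_support_min must be in (0, 1)")
        for name in (
            "min_bad_reads", "max_break_depth", "indel_min_len",
            "break_merge_gap", "min_break_len", "mismatch_run_min",
            "spike_min_len", "pad",
        ):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.spike_window < 1:
            raise InputError("spike_window must be >= 1")
        if self.spike_factor <= 1.0:
            raise InputError("spike_factor must exceed 1.0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
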