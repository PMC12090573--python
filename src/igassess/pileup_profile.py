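"""Per-read alignment statistics and per-position pileup profiles.

Implements the two mismatch views used throughout the assessment:

* read-oriented -- for each retained alignment r, the substitution count
  ``d(r, g) = sum_i 1(r_i != g_i)`` over its aligned columns (CIGAR M/=/X),
  its aligned length ``n(r)`` and mismatch rate ``e_r = d / n(r)``;
* basepair-oriented -- for each reference position j, the covering-read
  count (depth, the set J_j), the disagreement count ``delta_j`` (a deletion
  at j counts as a disagreement), and ``E_j``, the number of covering
  primary reads whose e_r strictly exceeds theta.

Mismatches are always recomputed against the assembly sequence, never taken
from MD tags.  Two pileup sources are supported: direct BAM traversal
(:func:`build_position_profiles`) and samtools-mpileup text ingestion
(:func:`ingest_mpileup`); both produce identical (depth, delta) tracks on
the same alignments, but only the BAM path carries E and MAPQ-stratified
depth.

Filtering mirrors the samtools-mpileup default: unmapped, secondary,
QC-fail and duplicate records are excluded; supplementary alignments are
retained for coverage/clip accounting but never contribute to E (their
primary record already represents the read).  No MAPQ filter is applied --
MAPQ-0 placement in repeats is ambiguity, not error, and is stratified for
display instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pysam

from .ig_model import (
    AssemblySequences,
    InputError,
    LocusRegion,
    RunConfig,
    _N_BYTE,
)

# CIGAR operation codes (pysam)
_M, _I, _D, _N, _S, _H, _EQ, _X = 0, 1, 2, 3, 4, 5, 7, 8
_ALIGNED_OPS = (_M, _EQ, _X)


# ---------------------------------------------------------------------------
# Read-level records
# ---------------------------------------------------------------------------

@dataclass
class ReadAlignment:
    """One retained alignment record with its mismatch accounting.

    ``covered_blocks`` are the maximal reference intervals covered by an
    aligned base or a deletion (CIGAR M/=/X/D runs; reference skips break
    blocks).  ``mismatch_ref_positions`` hold the substitution columns
    (reference-N columns never count); ``deletion_ref_positions`` the
    deleted reference positions.
    """

    read_id: str
    contig: str
    ref_start: int
    ref_end: int
    mapq: int
    aligned_len: int
    mismatches: int
    softclip_len: int
    hardclip_len: int
    large_indel_events: int
    inserted_bases: int
    deleted_bases: int
    is_secondary: bool
    is_supplementary: bool
    covered_blocks: list[tuple[int, int]]
    mismatch_ref_positions: np.ndarray
    deletion_ref_positions: np.ndarray
    count_indels_in_e: bool = False

    @property
    def e_r(self) -> float:
        """Per-read mismatch rate e_r = d / n(r) (optionally with indels)."""
        if self.count_indels_in_e:
            num = self.mismatches + self.inserted_bases + self.deleted_bases
            den = self.aligned_len + self.inserted_bases
        else:
            num, den = self.mismatches, self.aligned_len
        return num / den if den else 0.0

    def is_poorly_aligned(self, theta: float) -> bool:
        """Strict comparison: the read is flagged iff e_r > theta."""
        return self.e_r > theta

    def iter_mismatch_positions(self) -> Iterator[int]:
        """Reference positions of substitution columns, ascending."""
        yield from self.mismatch_ref_positions.tolist()

    def overlaps(self, start: int, end: int) -> bool:
        return self.ref_start < end and self.ref_end > start


def _check_bam_ready(bam_path: Path, assembly: AssemblySequences,
                     region: LocusRegion) -> pysam.AlignmentFile:
    if not bam_path.exists():
        raise InputError(f"BAM not found: {bam_path}")
    try:
        bam = pysam.AlignmentFile(str(bam_path), "rb")
    except ValueError as exc:  # pragma: no cover - malformed file
        raise InputError(f"cannot open BAM {bam_path}: {exc}") from exc
    if not bam.has_index():
        bam.close()
        raise InputError(
            f"BAM {bam_path} has no index; run `samtools index {bam_path}`"
        )
    bam_refs = set(bam.references)
    missing = sorted(set(assembly.contigs) - bam_refs)
    if region.contig not in bam_refs:
        bam.close()
        raise InputError(
            f"region contig {region.contig!r} absent from BAM header; "
            f"assembly contigs missing from BAM: {missing}"
        )
    return bam


def collect_read_alignments(
    bam_path: str | Path,
    assembly: AssemblySequences,
    region: LocusRegion,
    config: RunConfig | None = None,
) -> list[ReadAlignment]:
    """Extract one :class:`ReadAlignment` per retained record overlapping
    ``region`` from a coordinate-sorted, indexed BAM.

    Secondary, unmapped, QC-fail and duplicate records are skipped;
    supplementary records are retained and flagged.  Substitutions are
    counted by comparing read bases with the assembly sequence column by
    column over CIGAR-aligned runs.
    """
    config = config or RunConfig()
    bam_path = Path(bam_path)
    bam = _check_bam_ready(bam_path, assembly, region)
    ref_arr = assembly.seq_array(region.contig)
    out: list[ReadAlignment] = []
    try:
        for rec in bam.fetch(region.contig, region.start, region.end):
            if rec.is_unmapped or rec.is_secondary or rec.is_qcfail or rec.is_duplicate:
                continue
            out.append(_record_to_alignment(rec, ref_arr, config))
    finally:
        bam.close()
    return out


def _record_to_alignment(
    rec: pysam.AlignedSegment,
    ref_arr: np.ndarray,
    config: RunConfig,
) -> ReadAlignment:
    seq = rec.query_sequence
    if seq is None:
        raise InputError(f"record {rec.query_name!r} has no sequence (SEQ='*')")
    q_arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)

    q = 0
    r = rec.reference_start
    aligned = 0
    sclip = hclip = big_indels = ins_bases = del_bases = 0
    mm_chunks: list[np.ndarray] = []
    del_chunks: list[np.ndarray] = []
    blocks: list[tuple[int, int]] = []
    block_start: int | None = None

    for op, ln in rec.cigartuples:
        if op in _ALIGNED_OPS:
            refseg = ref_arr[r:r + ln]
            qseg = q_arr[q:q + ln]
            ne = (refseg != qseg) & (refseg != _N_BYTE)
            if ne.any():
                mm_chunks.append(np.flatnonzero(ne).astype(np.int64) + r)
            aligned += ln
            if block_start is None:
                block_start = r
            q += ln
            r += ln
        elif op == _I:
            ins_bases += ln
            if ln >= config.indel_min_len:
                big_indels += 1
            q += ln
        elif op == _D:
            del_chunks.append(np.arange(r, r + ln, dtype=np.int64))
            del_bases += ln
            if ln >= config.indel_min_len:
                big_indels += 1
            if block_start is None:
                block_start = r
            r += ln
        elif op == _N:
            if block_start is not None:
                blocks.append((block_start, r))
                block_start = None
            r += ln
        elif op == _S:
            sclip += ln
            q += ln
        elif op == _H:
            hclip += ln
        # PAD (6) consumes neither

    if block_start is not None:
        blocks.append((block_start, r))

    if aligned < 1:
        raise InputError(f"record {rec.query_name!r} has no aligned columns")

    mism_pos = (
        np.concatenate(mm_chunks) if mm_chunks else np.empty(0, dtype=np.int64)
    )
    del_pos = (
        np.concatenate(del_chunks) if del_chunks else np.empty(0, dtype=np.int64)
    )
    return ReadAlignment(
        read_id=rec.query_name,
        contig=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=r,
        mapq=rec.mapping_quality,
        aligned_len=aligned,
        mismatches=int(mism_pos.size),
        softclip_len=sclip,
        hardclip_len=hclip,
        large_indel_events=big_indels,
        inserted_bases=ins_bases,
        deleted_bases=del_bases,
        is_secondary=rec.is_secondary,
        is_supplementary=rec.is_supplementary,
        covered_blocks=blocks,
        mismatch_ref_positions=mism_pos,
        deletion_ref_positions=del_pos,
        count_indels_in_e=config.count_indels_in_e,
    )


# ---------------------------------------------------------------------------
# Read-summary metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSummary:
    """Fractions over primary alignments, as reported in locus summaries."""

    n_primary: int
    frac_mapq60: float
    frac_softclipped: float
    frac_high_mismatch: float
    frac_large_indels: float
    frac_high_mismatch_or_indels: float


def read_summary_metrics(
    reads: Sequence[ReadAlignment], config: RunConfig | None = None
) -> ReadSummary:
    """Summarize primary alignments: MAPQ-60, soft-clipped, high-mismatch
    (e_r > theta) and large-indel (any indel run >= indel_min_len) fractions,
    with the mismatch/indel union reported as well."""
    config = config or RunConfig()
    primary = [rd for rd in reads if not rd.is_secondary and not rd.is_supplementary]
    if not primary:
        raise InputError("no primary alignments to summarize")
    n = len(primary)
    mapq60 = sum(rd.mapq == 60 for rd in primary)
    softclipped = sum(rd.softclip_len > 0 for rd in primary)
    high_mm = sum(rd.is_poorly_aligned(config.theta) for rd in primary)
    indels = sum(rd.large_indel_events > 0 for rd in primary)
    union = sum(
        rd.is_poorly_aligned(config.theta) or rd.large_indel_events > 0
        for rd in primary
    )
    return ReadSummary(
        n_primary=n,
        frac_mapq60=mapq60 / n,
        frac_softclipped=softclipped / n,
        frac_high_mismatch=high_mm / n,
        frac_large_indels=indels / n,
        frac_high_mismatch_or_indels=union / n,
    )


# ---------------------------------------------------------------------------
# Position profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionProfile:
    """Single-position view (mostly for interactive inspection/tests)."""

    contig: str
    pos: int
    depth: int
    delta: int
    bad_read_count: int | None
    depth_by_mapq: tuple[int, int, int] | None
    ref_is_n: bool

    @property
    def support_fraction(self) -> float:
        if self.depth == 0 or self.ref_is_n:
            return float("nan")
        return (self.depth - self.delta) / self.depth


@dataclass
class PositionProfiles:
    """Per-position track bundle over one locus region.

    Arrays are indexed by ``pos - start``.  ``bad`` (the E track) and the
    MAPQ-stratified depths are ``None`` when the profiles came from mpileup
    text, which carries neither read-level mismatch rates nor MAPQ.
    ``support_fraction`` and ``mismatch_rate`` use NaN as the "undefined"
    sentinel at zero-depth and reference-N positions: no data is not the
    same as perfect support.
    """

    contig: str
    start: int
    end: int
    depth: np.ndarray
    delta: np.ndarray
    ref_is_n: np.ndarray
    bad: np.ndarray | None = None
    mapq0: np.ndarray | None = None
    mapq_mid: np.ndarray | None = None
    mapq60: np.ndarray | None = None

    def __post_init__(self) -> None:
        L = self.end - self.start
        for name in ("depth", "delta", "ref_is_n"):
            if len(getattr(self, name)) != L:
                raise ValueError(f"{name} length != region length")
        if np.any(self.delta > self.depth):
            raise ValueError("delta exceeds depth")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def has_read_stats(self) -> bool:
        return self.bad is not None

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.start, self.end, dtype=np.int64)

    @property
    def support_fraction(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = (self.depth - self.delta) / self.depth
        frac = np.asarray(frac, dtype=float)
        frac[(self.depth == 0) | self.ref_is_n] = np.nan
        return frac

    @property
    def mismatch_rate(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = self.delta / self.depth
        rate = np.asarray(rate, dtype=float)
        rate[(self.depth == 0) | self.ref_is_n] = np.nan
        return rate

    def at(self, pos: int) -> PositionProfile:
        i = pos - self.start
        if not 0 <= i < len(self):
            raise IndexError(f"position {pos} outside [{self.start}, {self.end})")
        mapq = None
        if self.mapq0 is not None:
            mapq = (int(self.mapq0[i]), int(self.mapq_mid[i]), int(self.mapq60[i]))
        return PositionProfile(
            contig=self.contig,
            pos=pos,
            depth=int(self.depth[i]),
            delta=int(self.delta[i]),
            bad_read_count=int(self.bad[i]) if self.bad is not None else None,
            depth_by_mapq=mapq,
            ref_is_n=bool(self.ref_is_n[i]),
        )

    def slice_counts(self, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """(depth, delta) over ``[start, end)`` clipped to the region."""
        s = max(start, self.start) - self.start
        e = min(end, self.end) - self.start
        return self.depth[s:e], self.delta[s:e]

    def to_tsv(self, path: str | Path) -> None:
        """Export as TSV: contig, pos (1-based), depth, delta, E, MAPQ bins."""
        bad = self.bad if self.bad is not None else np.full(len(self), -1, dtype=np.int64)
        zeros = np.zeros(len(self), dtype=np.int64)
        m0 = self.mapq0 if self.mapq0 is not None else zeros
        mm = self.mapq_mid if self.mapq_mid is not None else zeros
        m60 = self.mapq60 if self.mapq60 is not None else zeros
        with open(path, "w") as fh:
            fh.write("contig\tpos1based\tdepth\tdelta\tE\tmapq0\tmapq1_59\tmapq60\n")
            for i in range(len(self)):
                fh.write(
                    f"{self.contig}\t{self.start + i + 1}\t{self.depth[i]}\t"
                    f"{self.delta[i]}\t{bad[i]}\t{m0[i]}\t{mm[i]}\t{m60[i]}\n"
                )


def _add_blocks(diff: np.ndarray, blocks: Sequence[tuple[int, int]],
                start: int, end: int) -> None:
    for bs, be in blocks:
        s = max(bs, start) - start
        e = min(be, end) - start
        if s < e:
            diff[s] += 1
            diff[e] -= 1


def build_position_profiles(
    reads: Sequence[ReadAlignment],
    assembly: AssemblySequences,
    region: LocusRegion,
    config: RunConfig | None = None,
) -> PositionProfiles:
    """Stack :class:`ReadAlignment` records into per-position tracks.

    Depth counts reads with an aligned base *or a deletion* at the position;
    a deletion likewise counts toward delta (a read disagreeing with the
    reference by deleting it still disputes the base).  Insertions between
    positions affect neither track.  Reference-N positions get delta = 0.
    """
    config = config or RunConfig()
    if region.contig not in assembly.contigs:
        raise InputError(f"region contig {region.contig!r} not in assembly")
    if region.end > assembly.length(region.contig):
        raise InputError("region extends past contig end")
    L = len(region)
    depth_diff = np.zeros(L + 1, dtype=np.int64)
    bad_diff = np.zeros(L + 1, dtype=np.int64)
    mapq_diff = {0: np.zeros(L + 1, dtype=np.int64),
                 1: np.zeros(L + 1, dtype=np.int64),
                 2: np.zeros(L + 1, dtype=np.int64)}
    delta = np.zeros(L, dtype=np.int64)
    ref_is_n = assembly.n_mask(region.contig, region.start, region.end)

    for rd in reads:
        if rd.is_secondary:
            continue
        if rd.contig != region.contig:
            continue
        _add_blocks(depth_diff, rd.covered_blocks, region.start, region.end)
        mapq_bin = 0 if rd.mapq == 0 else (2 if rd.mapq == 60 else 1)
        _add_blocks(mapq_diff[mapq_bin], rd.covered_blocks, region.start, region.end)
        if not rd.is_supplementary and rd.is_poorly_aligned(config.theta):
            _add_blocks(bad_diff, rd.covered_blocks, region.start, region.end)
        disagree = np.concatenate([rd.mismatch_ref_positions,
                                   rd.deletion_ref_positions])
        if disagree.size:
            disagree = disagree[(disagree >= region.start) & (disagree < region.end)]
            offs = disagree - region.start
            # reference-N columns never count as disagreement
            offs = offs[~ref_is_n[offs]]
            np.add.at(delta, offs, 1)

    depth = np.cumsum(depth_diff[:-1])
    bad = np.cumsum(bad_diff[:-1])
    return PositionProfiles(
        contig=region.contig,
        start=region.start,
        end=region.end,
        depth=depth,
        delta=delta,
        ref_is_n=ref_is_n,
        bad=bad,
        mapq0=np.cumsum(mapq_diff[0][:-1]),
        mapq_mid=np.cumsum(mapq_diff[1][:-1]),
        mapq60=np.cumsum(mapq_diff[2][:-1]),
    )


# ---------------------------------------------------------------------------
# mpileup ingestion (alternate pileup source)
# ---------------------------------------------------------------------------

def _parse_mpileup_bases(bases: str, lineno: int) -> tuple[int, int, bool]:
    """Parse one mpileup base column.

    Returns ``(depth, delta, ref_is_n)`` where depth counts aligned bases,
    deletions ('*') and reference skips, and delta counts mismatching bases
    plus deletions.  ``ref_is_n`` is decided by the caller from the ref
    column; here we only parse the grammar.
    """
    depth = delta = 0
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise InputError(f"mpileup line {lineno}: dangling '^'")
            i += 2  # skip mapping-quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise InputError(
                    f"mpileup line {lineno}: '+/-' not followed by a length"
                )
            ln = int(bases[i + 1:j])
            if j + ln > n:
                raise InputError(
                    f"mpileup line {lineno}: indel run past end of base string"
                )
            i = j + ln  # the inserted/deleted sequence itself
            continue
        if c in ".,":
            depth += 1
        elif c in "ACGTNacgtn":
            depth += 1
            delta += 1
        elif c == "*":
            depth += 1
            delta += 1
        elif c in "><":
            depth += 1  # reference skip: covered, no base claim
        else:
            raise InputError(
                f"mpileup line {lineno}: unexpected character {c!r} in base column"
            )
        i += 1
    return depth, delta, False


def ingest_mpileup(
    mpileup_path: str | Path,
    region: LocusRegion,
) -> PositionProfiles:
    """Build (depth, delta) profiles from samtools-mpileup default text.

    The mpileup must have been produced with the reference (``-f``) so that
    match/mismatch is encoded as '.'/',' vs letters; recommended invocation
    for exact agreement with the BAM path is
    ``samtools mpileup -aa -B -Q 0 -d 0 -f asm.fa -r <region> aln.bam``.
    E and MAPQ-stratified depth are unavailable from this source and are
    marked absent (``None``).  Positions missing from the file get depth 0.
    """
    L = len(region)
    depth = np.zeros(L, dtype=np.int64)
    delta = np.zeros(L, dtype=np.int64)
    ref_is_n = np.zeros(L, dtype=bool)
    with open(mpileup_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise InputError(
                    f"mpileup line {lineno}: expected >=5 columns, got {len(parts)}"
                )
            contig, pos1, refbase, depth_col, bases = parts[:5]
            if contig != region.contig:
                continue
            pos = int(pos1) - 1  # mpileup is 1-based
            if not region.start <= pos < region.end:
                continue
            if int(depth_col) == 0:
                # '-a' emits a '*' placeholder base column at depth 0
                d, dl = 0, 0
            else:
                d, dl, _ = _parse_mpileup_bases(bases, lineno)
            i = pos - region.start
            depth[i] = d
            if refbase.upper() == "N":
                ref_is_n[i] = True
                delta[i] = 0
            else:
                delta[i] = dl
    return PositionProfiles(
        contig=region.contig,
        start=region.start,
        end=region.end,
        depth=depth,
        delta=delta,
        ref_is_n=ref_is_n,
        bad=None,
    )
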