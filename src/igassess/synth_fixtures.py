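"""Synthetic diploid IG-like loci, HiFi-like reads and injected misassemblies.

The generator emulates the data regime the assessment is designed for: a
diploid locus pair (~300 kb by default) inside flanking sequence, V/D/J
gene segments placed at homologous coordinates on both haplotypes, 0.5%
baseline haplotype divergence with multi-kb diverged blocks at ~2%, HiFi-
like reads of 15-25 kb at 0.3% substitution error, and ~30x depth per
haplotype.

Misassembly injections corrupt **the assembly only** -- reads are always
sampled from the uncorrupted diploid truth, which is the causal model of
alignment-based error detection (the reads are ground truth; the assembly
is the hypothesis under test):

* ``drop_segment`` -- a haplotype segment is missing from the assembly;
  its reads pile onto the homologous interval of the other haplotype with
  elevated mismatch rates (the "missing sequence" signature);
* ``inversion_with_gap`` -- a segment is written in reverse orientation
  with an N-gap at the proximal breakpoint (the false-inversion signature:
  a coverage break over the Ns);
* ``collapse_duplication`` -- a segment carried identically by both
  haplotypes is represented once; reads from both pile onto the single
  copy, doubling depth without mismatches (the collapsed-duplication
  spike signature).

Injection sites sit inside diverged blocks (for ``drop_segment``) because
that is where real assemblers fail and where orphaned reads exceed the
theta = 0.01 flagging threshold; at baseline divergence orphan alignments
would be indistinguishable from sequencing error.

All randomness flows from ``SimSpec.rng_seed``; identical specs produce
byte-identical FASTA/FASTQ/BED/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import shutil
import subprocess
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .ig_model import (
    AssemblySequences,
    GeneAnnotation,
    InputError,
    LocusRegion,
    write_gene_bed,
    write_locus_bed,
)

INJECTION_KINDS = ("drop_segment", "inversion_with_gap", "collapse_duplication")
FIXTURE_NAMES = ("clean", "dropped_segment", "inversion_gap", "collapsed_dup",
                 "both_errors")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Injection:
    """One misassembly, in locus coordinates on one haplotype's contig."""

    kind: str
    start: int
    length: int
    gap_len: int = 8000
    hap: str = "hap2"

    def __post_init__(self) -> None:
        if self.kind not in INJECTION_KINDS:
            raise InputError(f"unknown injection kind {self.kind!r}")
        if self.start < 0 or self.length < 1:
            raise InputError("injection interval must be non-empty and >= 0")
        if self.hap not in ("hap1", "hap2"):
            raise InputError("injection hap must be 'hap1' or 'hap2'")


@dataclass(frozen=True)
class SimSpec:
    """All simulation parameters; every random draw derives from rng_seed."""

    rng_seed: int = 0
    locus_len: int = 300_000
    flank: int = 30_000
    locus_type: str = "IGH"
    n_v: int = 40
    n_d: int = 16
    n_j: int = 6
    v_len: tuple[int, int] = (290, 310)
    d_len: tuple[int, int] = (15, 25)
    j_len: tuple[int, int] = (50, 70)
    haplotype_divergence: float = 0.005
    diverged_block_rate: float = 0.02
    #: (start, length) in locus coordinates; None = default fractional blocks
    diverged_blocks: tuple[tuple[int, int], ...] | None = None
    read_len_mean: float = 20_000.0
    read_len_sd: float = 2_500.0
    read_len_min: int = 15_000
    read_len_max: int = 25_000
    read_error_rate: float = 0.003
    coverage: float = 30.0  # per-haplotype mean depth
    injections: tuple[Injection, ...] = ()

    @property
    def contig_len(self) -> int:
        return self.locus_len + 2 * self.flank

    def resolved_blocks(self) -> tuple[tuple[int, int], ...]:
        if self.diverged_blocks is not None:
            return self.diverged_blocks
        L = self.locus_len
        return ((int(0.30 * L), int(7 * L / 30)), (int(2 * L / 3), int(2 * L / 15)))

    def validate(self) -> None:
        if self.coverage <= 0:
            raise InputError("coverage must be positive")
        if not self.read_len_min <= self.read_len_mean <= self.read_len_max:
            raise InputError("read_len_mean outside [read_len_min, read_len_max]")
        if self.flank < self.read_len_max:
            raise InputError(
                "flank must be at least read_len_max so locus edges reach "
                "full coverage"
            )
        by_hap: dict[str, int] = {}
        for inj in self.injections:
            if inj.start + inj.length > self.locus_len:
                raise InputError(
                    f"injection {inj.kind} interval [{inj.start}, "
                    f"{inj.start + inj.length}) outside locus of length "
                    f"{self.locus_len}"
                )
            by_hap[inj.hap] = by_hap.get(inj.hap, 0) + 1
            if by_hap[inj.hap] > 1:
                raise InputError("at most one injection per haplotype")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        inj = [Injection(**d) for d in data.pop("injections", [])]
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown SimSpec keys: {sorted(unknown)}")
        for key in ("v_len", "d_len", "j_len"):
            if key in data:
                data[key] = tuple(data[key])
        if data.get("diverged_blocks") is not None:
            data["diverged_blocks"] = tuple(tuple(b) for b in data["diverged_blocks"])
        spec = cls(injections=tuple(inj), **data)
        spec.validate()
        return spec

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["injections"] = [asdict(i) for i in self.injections]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

@dataclass
class SimulatedLocus:
    """Truth genomes, (possibly corrupted) assembly, annotations and truth."""

    spec: SimSpec
    truth_seqs: dict[str, str]
    assembly: AssemblySequences
    genes: list[GeneAnnotation]
    regions: list[LocusRegion]
    truth: dict

    def write_outputs(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "assembly": out_dir / "assembly.fasta",
            "genes": out_dir / "genes.bed",
            "loci": out_dir / "loci.bed",
            "truth": out_dir / "truth.json",
            "simspec": out_dir / "simspec.yaml",
        }
        with open(paths["assembly"], "w") as fh:
            for name in sorted(self.assembly.contigs):
                fh.write(f">{name} haplotype={self.assembly.haplotype_of[name]}\n")
                seq = self.assembly.contigs[name]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        write_gene_bed(self.genes, paths["genes"])
        write_locus_bed(self.regions, paths["loci"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
        self.spec.to_yaml(paths["simspec"])
        return paths


def _place_genes(spec: SimSpec, rng: np.random.Generator) -> list[dict]:
    """Non-overlapping V/D/J placement in locus coordinates.

    V segments occupy the proximal ~78% of the locus, D the 80-88% band and
    J the 90-95% band, echoing the V->D->J order of real IG loci.
    """
    L = spec.locus_len
    layout = [
        ("V", spec.n_v, spec.v_len, 0, int(0.78 * L)),
        ("D", spec.n_d, spec.d_len, int(0.80 * L), int(0.88 * L)),
        ("J", spec.n_j, spec.j_len, int(0.90 * L), int(0.95 * L)),
    ]
    genes: list[dict] = []
    for seg, n, (lo, hi), rstart, rend in layout:
        if n == 0:
            continue
        slot = (rend - rstart) // n
        if slot <= hi:
            raise InputError(f"{seg} region too small for {n} genes")
        for i in range(n):
            glen = int(rng.integers(lo, hi + 1))
            offset = int(rng.integers(0, slot - glen))
            start = rstart + i * slot + offset
            strand = "+" if rng.random() < 0.9 else "-"
            genes.append({
                "base_id": f"{spec.locus_type}{seg}{i + 1}",
                "segment_type": seg,
                "start": start,
                "end": start + glen,
                "strand": strand,
            })
    genes.sort(key=lambda g: g["start"])
    return genes


def _map_genes_through_injection(
    genes: list[dict], inj: Injection, flank: int
) -> tuple[list[dict], list[str]]:
    """Project gene intervals (contig coords) through one injection."""
    s = flank + inj.start
    e = s + inj.length
    shift = inj.gap_len if inj.kind == "inversion_with_gap" else -inj.length
    kept: list[dict] = []
    dropped: list[str] = []
    for g in genes:
        if g["end"] <= s:
            kept.append(dict(g))
        elif g["start"] >= e:
            ng = dict(g)
            ng["start"] += shift
            ng["end"] += shift
            kept.append(ng)
        elif inj.kind == "inversion_with_gap" and s <= g["start"] and g["end"] <= e:
            ng = dict(g)
            ng["start"] = s + inj.gap_len + (e - g["end"])
            ng["end"] = s + inj.gap_len + (e - g["start"])
            ng["strand"] = "-" if g["strand"] == "+" else "+"
            kept.append(ng)
        else:
            # removed from, or straddling the edge of, the corrupted segment
            dropped.append(g["base_id"])
    kept.sort(key=lambda g: g["start"])
    return kept, dropped


def simulate_diploid_locus(spec: SimSpec) -> SimulatedLocus:
    """Build the diploid truth pair, apply injections to the assembly copy,
    and derive gene/locus annotations plus the truth record."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    C = spec.contig_len
    flank = spec.flank

    hap1_arr = _BASES[rng.integers(0, 4, size=C)]

    # divergence: baseline everywhere, elevated inside the diverged blocks
    rate = np.full(C, spec.haplotype_divergence)
    for bs, bl in spec.resolved_blocks():
        rate[flank + bs: flank + bs + bl] = spec.diverged_block_rate
    div_mask = rng.random(C) < rate
    hap2_arr = hap1_arr.copy()
    idx = np.flatnonzero(div_mask)
    hap2_arr[idx] = _BASES[
        (np.searchsorted(_BASES, hap1_arr[idx]) + rng.integers(1, 4, size=idx.size)) % 4
    ]

    # collapse injections make the segment identical between haplotypes in
    # the *truth* (a recent duplication-like identity) before the assembly
    # drops one copy
    arrs = {"hap1": hap1_arr, "hap2": hap2_arr}
    for inj in spec.injections:
        if inj.kind == "collapse_duplication":
            s, e = flank + inj.start, flank + inj.start + inj.length
            other = "hap1" if inj.hap == "hap2" else "hap2"
            arrs[inj.hap][s:e] = arrs[other][s:e]

    truth_seqs = {h: arr.tobytes().decode("ascii") for h, arr in arrs.items()}

    gene_rows = _place_genes(spec, rng)
    contig_genes = {
        h: [
            {**g, "start": g["start"] + flank, "end": g["end"] + flank}
            for g in gene_rows
        ]
        for h in ("hap1", "hap2")
    }

    assembly_seqs = dict(truth_seqs)
    truth_injections = []
    for inj in spec.injections:
        seq = assembly_seqs[inj.hap]
        s = flank + inj.start
        e = s + inj.length
        other = "hap1" if inj.hap == "hap2" else "hap2"
        rec: dict = {
            "kind": inj.kind,
            "hap": inj.hap,
            "locus_start": inj.start,
            "length": inj.length,
        }
        if inj.kind in ("drop_segment", "collapse_duplication"):
            assembly_seqs[inj.hap] = seq[:s] + seq[e:]
            rec["hotspot_contig"] = other
            rec["hotspot_interval"] = [s, e]
            if inj.kind == "collapse_duplication":
                rec["expected_fold_change"] = 2.0
        else:  # inversion_with_gap
            assembly_seqs[inj.hap] = (
                seq[:s] + "N" * inj.gap_len + _revcomp(seq[s:e]) + seq[e:]
            )
            rec["gap_len"] = inj.gap_len
            rec["n_gap_interval"] = [s, s + inj.gap_len]
            rec["n_gap_contig"] = inj.hap
        mapped, dropped = _map_genes_through_injection(
            contig_genes[inj.hap], inj, flank
        )
        contig_genes[inj.hap] = mapped
        rec["dropped_gene_ids"] = [f"{gid}.{inj.hap}" for gid in dropped]
        if inj.kind == "drop_segment":
            # orphan reads carry the diverged-block variants, so homologous
            # genes fully inside the hotspot absorb >theta-mismatch reads;
            # collapse orphans align perfectly and affect no gene
            hs, he = rec["hotspot_interval"]
            rec["expected_affected_genes"] = [
                f"{g['base_id']}.{other}"
                for g in contig_genes[other]
                if g["start"] >= hs and g["end"] <= he
            ]
        truth_injections.append(rec)

    assembly = AssemblySequences(
        contigs=assembly_seqs,
        haplotype_of={"hap1": "hap1", "hap2": "hap2"},
    )
    genes = [
        GeneAnnotation(
            gene_id=f"{g['base_id']}.{hap}",
            segment_type=g["segment_type"],
            contig=hap,
            start=g["start"],
            end=g["end"],
            strand=g["strand"],
        )
        for hap in ("hap1", "hap2")
        for g in contig_genes[hap]
    ]
    regions = [
        LocusRegion(
            locus_type=spec.locus_type,
            contig=hap,
            start=flank,
            end=len(assembly_seqs[hap]) - flank,
            haplotype=hap,
        )
        for hap in ("hap1", "hap2")
    ]
    truth = {
        "rng_seed": spec.rng_seed,
        "locus_len": spec.locus_len,
        "flank": flank,
        "coverage_per_hap": spec.coverage,
        "diverged_blocks": [list(b) for b in spec.resolved_blocks()],
        "injections": truth_injections,
    }
    return SimulatedLocus(
        spec=spec,
        truth_seqs=truth_seqs,
        assembly=assembly,
        genes=genes,
        regions=regions,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReads:
    """Reads plus their true origin (haplotype, start, length)."""

    records: list[tuple[str, str]]  # (read_id, sequence); quality is constant
    origin: pd.DataFrame

    def write_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for read_id, seq in self.records:
                fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")

    def write_origin_tsv(self, path: str | Path) -> None:
        self.origin.to_csv(path, sep="\t", index=False)


def _truncated_normal_lengths(
    n: int, spec: SimSpec, rng: np.random.Generator
) -> np.ndarray:
    out = np.empty(0, dtype=np.int64)
    while out.size < n:
        draw = rng.normal(spec.read_len_mean, spec.read_len_sd, size=2 * n)
        draw = draw[(draw >= spec.read_len_min) & (draw <= spec.read_len_max)]
        out = np.concatenate([out, draw.astype(np.int64)])
    return out[:n]


def simulate_reads(sim: SimulatedLocus, spec: SimSpec | None = None) -> SimulatedReads:
    """Sample reads from the *uncorrupted* truth haplotypes.

    Each haplotype is sampled at ``spec.coverage`` mean depth with
    truncated-normal lengths and i.i.d. substitution errors at
    ``read_error_rate``.  A derived stream of the genome seed keeps read
    sampling reproducible but decoupled from genome construction.
    """
    spec = spec or sim.spec
    if spec.coverage <= 0:
        raise InputError("coverage must be positive")
    rng = np.random.default_rng((spec.rng_seed, 0xC0FFEE))
    records: list[tuple[str, str]] = []
    origin_rows = []
    for hap in sorted(sim.truth_seqs):
        seq = sim.truth_seqs[hap]
        C = len(seq)
        n_reads = int(round(spec.coverage * C / spec.read_len_mean))
        lengths = _truncated_normal_lengths(n_reads, spec, rng)
        starts = rng.integers(0, C - lengths + 1)
        for i in range(n_reads):
            start, ln = int(starts[i]), int(lengths[i])
            read = np.frombuffer(
                seq[start:start + ln].encode("ascii"), dtype=np.uint8
            ).copy()
            n_err = rng.binomial(ln, spec.read_error_rate)
            if n_err:
                pos = rng.choice(ln, size=n_err, replace=False)
                read[pos] = _BASES[
                    (np.searchsorted(_BASES, read[pos])
                     + rng.integers(1, 4, size=n_err)) % 4
                ]
            read_id = f"{hap}_read{i:05d}"
            records.append((read_id, read.tobytes().decode("ascii")))
            origin_rows.append(
                {"read_id": read_id, "haplotype": hap, "start": start, "length": ln}
            )
    return SimulatedReads(records=records, origin=pd.DataFrame(origin_rows))


# ---------------------------------------------------------------------------
# Alignment: minimap2 when available, builtin seed-and-place fallback
# ---------------------------------------------------------------------------

def minimap2_available() -> bool:
    return shutil.which("minimap2") is not None


def align_with_minimap2(
    fasta: Path, fastq: Path, out_bam: Path, threads: int = 1
) -> None:
    """HiFi-preset minimap2 alignment, coordinate-sorted and indexed."""
    sam = out_bam.with_suffix(".tmp.sam")
    with open(sam, "wb") as fh:
        subprocess.run(
            ["minimap2", "-ax", "map-hifi", "-t", str(threads),
             str(fasta), str(fastq)],
            stdout=fh, stderr=subprocess.DEVNULL, check=True,
        )
    pysam.sort("-o", str(out_bam), "-@", str(threads), str(sam))
    pysam.index(str(out_bam))
    sam.unlink()


def _builtin_align_one(
    seq: str,
    index: dict[bytes, list[tuple[str, int]]],
    contigs: dict[str, str],
    k: int,
    stride: int,
) -> tuple[list[dict], int]:
    """Seed-and-place alignment of one substitution-only read.

    Exact k-mer seeds vote for (contig, strand, diagonal) placements; each
    candidate diagonal is extended gaplessly (bounded by contig ends and
    reference-N runs) and scored as matches - 9*mismatches.  Non-redundant
    candidates become primary/supplementary segments; the primary gets
    MAPQ 0 when a competing placement of the same read span ties its score
    exactly (ambiguous placement between identical copies), else 60.
    Returns (selected segments sorted by score, mapq).
    """
    votes: dict[tuple[str, int, int], list[int]] = {}
    oriented = {0: seq, 1: _revcomp(seq)}
    for strand in (0, 1):
        enc = oriented[strand].encode("ascii")
        for q in range(0, len(enc) - k + 1, stride):
            for contig, rpos in index.get(enc[q:q + k], ()):
                votes.setdefault((contig, strand, rpos - q), []).append(q)

    candidates: list[dict] = []
    for (contig, strand, diag), qlist in votes.items():
        if len(qlist) < 2 and len(votes) > 1:
            continue  # lone stray hit amid better-supported diagonals
        qs, qe = min(qlist), max(qlist) + k
        ref = contigs[contig]
        ext_qs = max(0, -diag)
        ext_qe = min(len(seq), len(ref) - diag)
        window = ref[diag + ext_qs: diag + ext_qe]
        lo, hi = ext_qs, ext_qe
        left_n = window.rfind("N", 0, qs - ext_qs)
        if left_n != -1:
            lo = ext_qs + left_n + 1
        right_n = window.find("N", qe - ext_qs)
        if right_n != -1:
            hi = ext_qs + right_n
        qs, qe = lo, hi
        if qe - qs < k:
            continue
        rseg = np.frombuffer(
            ref[diag + qs: diag + qe].encode("ascii"), dtype=np.uint8)
        qseg = np.frombuffer(
            oriented[strand][qs:qe].encode("ascii"), dtype=np.uint8)
        mism = int(np.count_nonzero(rseg != qseg))
        span_fwd = (len(seq) - qe, len(seq) - qs) if strand else (qs, qe)
        candidates.append({
            "contig": contig, "strand": strand, "qs": qs, "qe": qe,
            "rstart": diag + qs, "support": len(qlist),
            "score": (qe - qs - mism) - 9 * mism, "span_fwd": span_fwd,
        })

    candidates.sort(key=lambda c: (-c["score"], c["contig"], c["rstart"]))
    selected: list[dict] = []
    claimed: list[tuple[int, int]] = []
    for cand in candidates:
        s, e = cand["span_fwd"]
        overlap = sum(
            max(0, min(e, ce) - max(s, cs)) for cs, ce in claimed
        )
        if overlap > 0.5 * (e - s):
            continue
        claimed.append((s, e))
        selected.append(cand)
    mapq = 60
    if selected:
        best = selected[0]
        bs, be = best["span_fwd"]
        for cand in candidates:
            if cand is best or cand in selected:
                continue
            s, e = cand["span_fwd"]
            if (min(e, be) - max(s, bs)) > 0.5 * (be - bs) and (
                cand["score"] >= best["score"]
            ):
                mapq = 0
                break
    return selected, mapq


def align_builtin(
    assembly: AssemblySequences,
    reads: SimulatedReads,
    out_bam: Path,
    k: int = 21,
    stride: int = 64,
) -> None:
    """Deterministic internal aligner for simulator reads.

    Handles the substitution-only error model of the simulator: every read
    is a (possibly reverse-complemented, possibly split) gapless substring
    of some contig up to substitutions.  Produces primary + supplementary
    soft-clipped records, MAPQ 60 unless a competing placement of similar
    support covers the same read span (then 0).
    """
    max_hits = 4
    index: dict[bytes, list[tuple[str, int]]] = {}
    for contig in sorted(assembly.contigs):
        enc = assembly.contigs[contig].encode("ascii")
        for pos in range(0, len(enc) - k + 1):
            hits = index.setdefault(enc[pos:pos + k], [])
            if len(hits) <= max_hits:
                hits.append((contig, pos))
    # drop hyper-repetitive k-mers entirely
    index = {kmer: hits for kmer, hits in index.items() if len(hits) <= max_hits}

    names = sorted(assembly.contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": assembly.length(n)} for n in names],
    }
    sam = out_bam.with_suffix(".tmp.sam")
    with pysam.AlignmentFile(str(sam), "w", header=header) as out:
        for read_id, seq in reads.records:
            segments, mapq = _builtin_align_one(
                seq, index, assembly.contigs, k, stride
            )
            if not segments:
                continue
            for rank, seg in enumerate(segments):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = read_id
                oriented = seq if seg["strand"] == 0 else _revcomp(seq)
                rec.query_sequence = oriented
                rec.flag = (16 if seg["strand"] else 0) | (2048 if rank else 0)
                rec.reference_id = names.index(seg["contig"])
                rec.reference_start = seg["rstart"]
                rec.mapping_quality = mapq if rank == 0 else 0
                cig = []
                if seg["qs"]:
                    cig.append((4, seg["qs"]))
                cig.append((0, seg["qe"] - seg["qs"]))
                if len(seq) - seg["qe"]:
                    cig.append((4, len(seq) - seg["qe"]))
                rec.cigartuples = cig
                rec.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(oriented)
                )
                out.write(rec)
    pysam.sort("-o", str(out_bam), str(sam))
    pysam.index(str(out_bam))
    sam.unlink()


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    name: str
    dir: Path
    assembly_fasta: Path
    reads_fastq: Path
    bam: Path
    genes_bed: Path
    loci_bed: Path
    truth_json: Path
    origin_tsv: Path
    sim: SimulatedLocus
    reads: SimulatedReads

    @property
    def truth(self) -> dict:
        return self.sim.truth


def default_spec(name: str, seed: int = 0, locus_len: int = 300_000,
                 **overrides) -> SimSpec:
    """The four standard study conditions (plus a dual-error variant)."""
    L = locus_len
    gap = 8000 if L >= 150_000 else max(200, L // 37)
    injections: tuple[Injection, ...]
    if name == "clean":
        injections = ()
    elif name == "dropped_segment":
        injections = (Injection("drop_segment", L // 3, L // 6),)
    elif name == "inversion_gap":
        injections = (Injection("inversion_with_gap", 2 * L // 5, L // 5,
                                gap_len=gap),)
    elif name == "collapsed_dup":
        # long enough that the segment interior exceeds a read length on
        # both sides, so the collapsed-copy plateau reaches the full 2x fold
        injections = (Injection("collapse_duplication", int(0.55 * L), L // 5),)
    elif name == "both_errors":
        injections = (
            Injection("drop_segment", L // 3, L // 6, hap="hap2"),
            Injection("inversion_with_gap", 2 * L // 3, L // 5, gap_len=gap,
                      hap="hap1"),
        )
    else:
        raise InputError(f"unknown fixture name {name!r}; choose from {FIXTURE_NAMES}")
    return SimSpec(rng_seed=seed, locus_len=L, injections=injections, **overrides)


def make_fixture_bundle(
    name: str,
    out_dir: str | Path,
    seed: int = 0,
    spec: SimSpec | None = None,
    aligner: str = "auto",
    threads: int = 1,
) -> FixtureBundle:
    """Generate a ready-to-evaluate directory for one study condition.

    ``aligner`` is ``auto`` (minimap2 if on PATH, else the builtin
    seed-and-place aligner), ``minimap2`` or ``builtin``.
    """
    if spec is None:
        spec = default_spec(name, seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate_diploid_locus(spec)
    paths = sim.write_outputs(out_dir)
    reads = simulate_reads(sim, spec)
    fastq = out_dir / "reads.fastq"
    reads.write_fastq(fastq)
    origin = out_dir / "origin.tsv"
    reads.write_origin_tsv(origin)
    bam = out_dir / "alignments.bam"
    if aligner == "auto":
        aligner = "minimap2" if minimap2_available() else "builtin"
    if aligner == "minimap2":
        align_with_minimap2(paths["assembly"], fastq, bam, threads=threads)
    elif aligner == "builtin":
        align_builtin(sim.assembly, reads, bam)
    else:
        raise InputError(f"unknown aligner {aligner!r}")
    return FixtureBundle(
        name=name,
        dir=out_dir,
        assembly_fasta=paths["assembly"],
        reads_fastq=fastq,
        bam=bam,
        genes_bed=paths["genes"],
        loci_bed=paths["loci"],
        truth_json=paths["truth"],
        origin_tsv=origin,
        sim=sim,
        reads=reads,
    )


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
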