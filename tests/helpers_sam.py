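"""Helpers to build tiny FASTA/BAM fixtures for pileup unit tests."""

from __future__ import annotations

from pathlib import Path

import pysam


def write_fasta(path: Path, contigs: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")
    return path


def make_bam(
    tmp_path: Path,
    contigs: dict[str, str],
    reads: list[dict],
    name: str = "mini",
) -> Path:
    """Write a coordinate-sorted, indexed BAM from read dicts.

    Each read dict: name, contig, start, cigar (pysam tuples), seq, and
    optional mapq (default 60), flag extras (secondary/supplementary/
    reverse), quals.
    """
    names = sorted(contigs)
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": n, "LN": len(contigs[n])} for n in names],
    }
    sam = tmp_path / f"{name}.sam"
    with pysam.AlignmentFile(str(sam), "w", header=header) as out:
        for rd in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = rd["name"]
            rec.query_sequence = rd["seq"]
            rec.reference_id = names.index(rd["contig"])
            rec.reference_start = rd["start"]
            rec.cigartuples = rd["cigar"]
            rec.mapping_quality = rd.get("mapq", 60)
            flag = 0
            if rd.get("reverse"):
                flag |= 16
            if rd.get("secondary"):
                flag |= 256
            if rd.get("supplementary"):
                flag |= 2048
            rec.flag = flag
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(rd["seq"]))
            out.write(rec)
    bam = tmp_path / f"{name}.bam"
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    return bam


def mutate(seq: str, pos: int) -> str:
    """Substitute the base at pos with a different one."""
    nxt = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}
    return seq[:pos] + nxt[seq[pos]] + seq[pos + 1:]
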