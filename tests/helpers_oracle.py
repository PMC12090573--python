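"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized code paths of the package: pileups
are stacked column by column with plain Python loops over CIGAR-expanded
alignments, and per-read mismatch counts come from a naive string walk.
"""

from __future__ import annotations

import numpy as np
import pysam


def naive_read_mismatches(rec: pysam.AlignedSegment, ref: str) -> tuple[int, int]:
    """(d, n): substitutions and aligned columns by naive string walk."""
    seq = rec.query_sequence
    q, r = 0, rec.reference_start
    d = n = 0
    for op, ln in rec.cigartuples:
        if op in (0, 7, 8):
            for i in range(ln):
                rb = ref[r + i]
                if rb != "N" and seq[q + i] != rb:
                    d += 1
            n += ln
            q += ln
            r += ln
        elif op == 1:
            q += ln
        elif op == 2:
            r += ln
        elif op == 3:
            r += ln
        elif op == 4:
            q += ln
    return d, n


def naive_pileup(bam_path, assembly, region, theta: float = 0.01):
    """Column-stacking pileup oracle: (depth, delta, E) over the region.

    Depth counts aligned bases and deletions; delta counts mismatching
    bases and deletions (never at reference-N positions); E counts, per
    position, covering primary reads whose naive mismatch rate exceeds
    theta.
    """
    L = region.end - region.start
    depth = [0] * L
    delta = [0] * L
    bad = [0] * L
    ref = assembly.contigs[region.contig]
    per_read = []
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for rec in bam.fetch(region.contig, region.start, region.end):
            if (rec.is_unmapped or rec.is_secondary or rec.is_qcfail
                    or rec.is_duplicate):
                continue
            seq = rec.query_sequence
            q, r = 0, rec.reference_start
            covered = []
            mism = aligned = 0
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8):
                    for i in range(ln):
                        rp = r + i
                        rb = ref[rp]
                        in_region = region.start <= rp < region.end
                        if in_region:
                            depth[rp - region.start] += 1
                        if rb != "N" and seq[q + i] != rb:
                            mism += 1
                            if in_region:
                                delta[rp - region.start] += 1
                        aligned += 1
                    covered.append((r, r + ln))
                    q += ln
                    r += ln
                elif op == 1:
                    q += ln
                elif op == 2:
                    for i in range(ln):
                        rp = r + i
                        if region.start <= rp < region.end:
                            depth[rp - region.start] += 1
                            if ref[rp] != "N":
                                delta[rp - region.start] += 1
                    covered.append((r, r + ln))
                    r += ln
                elif op == 3:
                    r += ln
                elif op == 4:
                    q += ln
            per_read.append((mism / aligned, covered, rec.is_supplementary))
    for e_r, covered, supplementary in per_read:
        if not supplementary and e_r > theta:
            for s, t in covered:
                for rp in range(max(s, region.start), min(t, region.end)):
                    bad[rp - region.start] += 1
    return np.array(depth), np.array(delta), np.array(bad)


def naive_break_scan(depth: np.ndarray, max_break_depth: int, offset: int = 0):
    """Brute-force scan for maximal runs of depth <= threshold."""
    runs = []
    start = None
    for i, d in enumerate(depth):
        if d <= max_break_depth:
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((start + offset, i + offset))
                start = None
    if start is not None:
        runs.append((start + offset, len(depth) + offset))
    return runs
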