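"""Error signals from position profiles.

Three signals, mirroring the read-oriented / basepair-oriented / coverage
views of the assessment:

1. poorly supported positions -- positions where more than ``min_bad_reads``
   covering primary reads have a whole-read mismatch rate above theta
   (strictly ``E > min_bad_reads``);
2. the basepair-oriented mismatch-rate track delta_j / depth_j;
3. coverage breaks -- maximal runs of positions with depth at or below
   ``max_break_depth``, categorized from depth and the reference sequence
   alone (N gap / zero coverage / edge / internal low coverage);

plus coverage-spike flagging (sustained depth well above the locus median),
the signature of collapsed duplications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ig_model import AssemblySequences, InputError, LocusRegion, RunConfig
from .pileup_profile import PositionProfiles

BREAK_CATEGORIES = ("n_gap", "zero_coverage", "low_coverage_edge",
                    "low_coverage_internal")


@dataclass(frozen=True)
class CoverageBreak:
    """Maximal run ``[start, end)`` of break-covered positions."""

    start: int
    end: int
    category: str
    max_depth: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CoverageSpike:
    """Interval of sustained elevated depth.

    ``fold_change`` is the representative fold of the spike (median of the
    flagged window medians over the locus median); ``peak_fold`` the maximal
    window, which rides sampling noise upward and is reported for display.
    """

    start: int
    end: int
    fold_change: float
    peak_fold: float = 0.0

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ErrorCallSet:
    """All error calls for one locus region."""

    region: LocusRegion
    poorly_supported_positions: np.ndarray
    mismatch_track: np.ndarray
    coverage_breaks: list[CoverageBreak] = field(default_factory=list)
    coverage_spikes: list[CoverageSpike] = field(default_factory=list)
    read_view_available: bool = True

    def poorly_supported_runs(self) -> list[tuple[int, int]]:
        """Maximal runs of consecutive flagged positions, as intervals."""
        return positions_to_runs(self.poorly_supported_positions)


# ---------------------------------------------------------------------------
# interval helpers
# ---------------------------------------------------------------------------

def runs_from_mask(mask: np.ndarray, offset: int = 0) -> list[tuple[int, int]]:
    """Maximal True-runs of ``mask`` as ``[start, end)`` intervals."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask.astype(bool), [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    return [(int(s) + offset, int(e) + offset) for s, e in zip(starts, ends)]


def positions_to_runs(positions: np.ndarray) -> list[tuple[int, int]]:
    """Collapse a sorted position array into maximal consecutive runs."""
    if len(positions) == 0:
        return []
    pos = np.asarray(positions, dtype=np.int64)
    cut = np.flatnonzero(np.diff(pos) > 1)
    starts = np.concatenate(([0], cut + 1))
    ends = np.concatenate((cut, [len(pos) - 1]))
    return [(int(pos[s]), int(pos[e]) + 1) for s, e in zip(starts, ends)]


def merge_intervals(
    intervals: Sequence[tuple[int, int]], max_gap: int = 0
) -> list[tuple[int, int]]:
    """Merge sorted intervals separated by gaps <= ``max_gap``."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------

def flag_poorly_supported_positions(
    profiles: PositionProfiles, config: RunConfig | None = None
) -> np.ndarray:
    """Positions with E strictly greater than ``min_bad_reads``, ascending.

    Requires BAM-derived profiles: the E track cannot be recovered from
    mpileup text (no read-level mismatch rates there).
    """
    config = config or RunConfig()
    if profiles.bad is None:
        raise InputError(
            "profiles carry no per-read mismatch counts (mpileup source); "
            "use the BAM path to flag poorly supported positions"
        )
    idx = np.flatnonzero(profiles.bad > config.min_bad_reads)
    return idx.astype(np.int64) + profiles.start


def compute_mismatch_track(profiles: PositionProfiles) -> np.ndarray:
    """Basepair-oriented rate delta_j / depth_j; NaN where depth is 0 or the
    reference base is N (no data is not a perfect position)."""
    return profiles.mismatch_rate


def detect_coverage_breaks(
    profiles: PositionProfiles,
    assembly: AssemblySequences | None = None,
    config: RunConfig | None = None,
) -> list[CoverageBreak]:
    """Maximal runs of positions with depth <= ``max_break_depth``.

    Runs separated by gaps <= ``break_merge_gap`` are merged, runs shorter
    than ``min_break_len`` dropped, and each run is categorized in order of
    precedence: ``n_gap`` if at least half of its reference bases are N,
    ``zero_coverage`` if no read touches it, ``low_coverage_edge`` if it
    touches a region or contig end, else ``low_coverage_internal``.
    """
    config = config or RunConfig()
    mask = profiles.depth <= config.max_break_depth
    runs = merge_intervals(
        runs_from_mask(mask, offset=profiles.start), config.break_merge_gap
    )
    contig_len = assembly.length(profiles.contig) if assembly is not None else None
    out: list[CoverageBreak] = []
    for s, e in runs:
        if e - s < config.min_break_len:
            continue
        i, j = s - profiles.start, e - profiles.start
        n_frac = float(np.mean(profiles.ref_is_n[i:j]))
        max_depth = int(profiles.depth[i:j].max())
        if n_frac >= 0.5:
            cat = "n_gap"
        elif max_depth == 0:
            cat = "zero_coverage"
        elif (
            s == profiles.start or e == profiles.end
            or s == 0 or (contig_len is not None and e == contig_len)
        ):
            cat = "low_coverage_edge"
        else:
            cat = "low_coverage_internal"
        out.append(CoverageBreak(start=s, end=e, category=cat, max_depth=max_depth))
    return out


def detect_coverage_spikes(
    profiles: PositionProfiles, config: RunConfig | None = None
) -> list[CoverageSpike]:
    """Sustained depth elevation: non-overlapping ``spike_window``-bp windows
    whose median depth reaches ``spike_factor`` x the locus baseline;
    adjacent flagged windows merge, and merged intervals shorter than
    ``spike_min_len`` are dropped.

    The baseline is a contamination-robust locus median: windows already
    elevated to >= 1.5x the raw median are masked and the median is
    re-estimated over the rest (one masking pass, as in read-depth CNV
    calling), so a spike cannot inflate its own reference level.  Fold
    changes are reported against this baseline."""
    config = config or RunConfig()
    L = len(profiles)
    if L < config.spike_min_len:
        raise InputError(
            f"locus length {L} is below spike_min_len={config.spike_min_len}"
        )
    w = config.spike_window
    n_win = L // w
    if n_win == 0:
        return []
    win_medians = np.median(
        profiles.depth[: n_win * w].reshape(n_win, w), axis=1
    )
    raw_median = float(np.median(win_medians))
    if raw_median == 0:
        return []
    keep = win_medians < 1.5 * raw_median
    baseline = float(np.median(win_medians[keep])) if keep.any() else raw_median
    if baseline == 0:
        return []
    hot = win_medians >= config.spike_factor * baseline
    out: list[CoverageSpike] = []
    for ws, we in runs_from_mask(hot):
        s = profiles.start + ws * w
        e = profiles.start + we * w
        if e - s < config.spike_min_len:
            continue
        fold = float(np.median(win_medians[ws:we]) / baseline)
        peak = float(win_medians[ws:we].max() / baseline)
        out.append(CoverageSpike(start=s, end=e, fold_change=fold, peak_fold=peak))
    return out


def build_error_callset(
    profiles: PositionProfiles,
    region: LocusRegion,
    assembly: AssemblySequences | None = None,
    config: RunConfig | None = None,
) -> ErrorCallSet:
    """Run all detectors over one locus and bundle the calls."""
    config = config or RunConfig()
    if profiles.has_read_stats:
        flagged = flag_poorly_supported_positions(profiles, config)
        read_view = True
    else:
        flagged = np.empty(0, dtype=np.int64)
        read_view = False
    spikes: list[CoverageSpike] = []
    if len(profiles) >= config.spike_min_len:
        spikes = detect_coverage_spikes(profiles, config)
    return ErrorCallSet(
        region=region,
        poorly_supported_positions=flagged,
        mismatch_track=compute_mismatch_track(profiles),
        coverage_breaks=detect_coverage_breaks(profiles, assembly, config),
        coverage_spikes=spikes,
        read_view_available=read_view,
    )


# ---------------------------------------------------------------------------
# BED writers
# ---------------------------------------------------------------------------

def write_breaks_bed(
    callsets: Sequence[ErrorCallSet], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for cs in callsets:
            for brk in cs.coverage_breaks:
                fh.write(
                    f"{cs.region.contig}\t{brk.start}\t{brk.end}\t"
                    f"{brk.category}\t{brk.max_depth}\t.\n"
                )


def write_spikes_bed(
    callsets: Sequence[ErrorCallSet], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for cs in callsets:
            for spk in cs.coverage_spikes:
                fh.write(
                    f"{cs.region.contig}\t{spk.start}\t{spk.end}\t"
                    f"spike\t{spk.fold_change:.3f}\t.\n"
                )


def write_poorly_supported_bed(
    callsets: Sequence[ErrorCallSet], path: str | Path
) -> None:
    """Per-position flags collapsed to maximal runs."""
    with open(path, "w") as fh:
        for cs in callsets:
            for s, e in cs.poorly_supported_runs():
                fh.write(f"{cs.region.contig}\t{s}\t{e}\tpoorly_supported\n")
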