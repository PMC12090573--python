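"""Diagnostic panels and machine-readable report bundles.

Each locus panel stacks three tracks: a windowed heatmap strip of
poorly-supported-position frequency, read coverage stacked by MAPQ bin
(0 / 1-59 / 60), and the basepair-oriented mismatch-rate line.  Poorly
supported runs are drawn as light-red highlight spans; coverage breaks as
purple bars under the coverage track.

Every visual mark has a machine-readable twin: each figure is accompanied
by a JSON sidecar listing the exact intervals and values drawn, and tests
assert on sidecars, never on pixels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.figure import Figure

from .error_detect import (
    ErrorCallSet,
    write_breaks_bed,
    write_poorly_supported_bed,
    write_spikes_bed,
)
from .gene_quality import (
    GeneQuality,
    LocusSummary,
    aggregate_summary_table,
    write_aggregate_table_tsv,
    write_genes_quality_tsv,
    write_locus_summary_tsv,
)
from .ig_model import InputError, RunConfig
from .pileup_profile import PositionProfiles, ReadAlignment

logger = logging.getLogger("igassess")

# documented default palette (the published figures' exact colors are
# cosmetic; these are ours)
MAPQ_COLORS = {"mapq0": "#c7c7c7", "mapq1_59": "#7fb2d6", "mapq60": "#1f5fa6"}
HIGHLIGHT_COLOR = "#f4a6a6"  # light red: poorly supported runs
BREAK_COLOR = "#7a3fb5"      # purple: coverage breaks


@dataclass
class PanelSpec:
    """Rendering parameters for one locus panel."""

    window_size: int = 10_000
    dpi: int = 150
    fig_width: float = 12.0
    fig_height: float = 5.0


def _heatmap_counts(
    calls: ErrorCallSet, window_size: int
) -> tuple[list[int], list[int]]:
    start, end = calls.region.start, calls.region.end
    n_win = max(1, -(-(end - start) // window_size))
    counts = np.zeros(n_win, dtype=np.int64)
    if len(calls.poorly_supported_positions):
        idx = (calls.poorly_supported_positions - start) // window_size
        np.add.at(counts, idx, 1)
    edges = [start + i * window_size for i in range(n_win)]
    return edges, counts.tolist()


def render_locus_panel(
    profiles: PositionProfiles,
    error_calls: ErrorCallSet,
    panel_spec: PanelSpec | None = None,
    out_path: str | Path = "panel.png",
) -> dict:
    """Render the coverage/mismatch panel for one locus haplotype.

    Returns the sidecar dict (also written next to the image as
    ``<out_path>.json``) listing every drawn highlight span, break bar,
    heatmap window count and coverage-track sum.
    """
    if len(profiles) == 0:
        raise InputError("zero-length region; nothing to render")
    panel_spec = panel_spec or PanelSpec()
    out_path = Path(out_path)
    region = error_calls.region
    x = profiles.positions

    fig = Figure(figsize=(panel_spec.fig_width, panel_spec.fig_height),
                 dpi=panel_spec.dpi)
    FigureCanvasAgg(fig)
    gs = fig.add_gridspec(
        3, 1, height_ratios=[0.12, 1.0, 0.6], hspace=0.15
    )
    ax_heat = fig.add_subplot(gs[0])
    ax_cov = fig.add_subplot(gs[1])
    ax_mm = fig.add_subplot(gs[2], sharex=ax_cov)

    # heatmap strip: flagged-position frequency per window
    win_edges, win_counts = _heatmap_counts(error_calls, panel_spec.window_size)
    heat = np.asarray(win_counts, dtype=float)[None, :]
    ax_heat.imshow(
        heat, aspect="auto", cmap="Reds", interpolation="nearest",
        extent=(region.start, region.end, 0, 1),
        vmin=0.0, vmax=max(1.0, heat.max()),
    )
    ax_heat.set_yticks([])
    ax_heat.set_xticks([])
    ax_heat.set_ylabel("flags", rotation=0, ha="right", va="center", fontsize=7)

    # coverage stacked by MAPQ bin
    zeros = np.zeros(len(profiles))
    m0 = profiles.mapq0 if profiles.mapq0 is not None else zeros
    mm_ = profiles.mapq_mid if profiles.mapq_mid is not None else zeros
    m60 = profiles.mapq60 if profiles.mapq60 is not None else profiles.depth
    ax_cov.stackplot(
        x, m0, mm_, m60,
        colors=[MAPQ_COLORS["mapq0"], MAPQ_COLORS["mapq1_59"],
                MAPQ_COLORS["mapq60"]],
        labels=["MAPQ 0", "MAPQ 1-59", "MAPQ 60"],
        linewidth=0,
    )
    ax_cov.set_ylabel("coverage")
    ax_cov.legend(loc="upper right", fontsize=7, frameon=False)

    highlight_spans = error_calls.poorly_supported_runs()
    for s, e in highlight_spans:
        ax_cov.axvspan(s, e, color=HIGHLIGHT_COLOR, alpha=0.5, linewidth=0)
        ax_mm.axvspan(s, e, color=HIGHLIGHT_COLOR, alpha=0.5, linewidth=0)

    break_bars = [(b.start, b.end, b.category) for b in error_calls.coverage_breaks]
    ymax = float(max(profiles.depth.max(), 1))
    for s, e, _cat in break_bars:
        ax_cov.axvspan(
            s, e, ymin=0.0, ymax=0.05, color=BREAK_COLOR, linewidth=0
        )

    # basepair-oriented mismatch-rate line (NaN leaves gaps where no data)
    ax_mm.plot(x, error_calls.mismatch_track, linewidth=0.4, color="#333333")
    ax_mm.set_ylim(0, 1)
    ax_mm.set_ylabel("mismatch rate")
    ax_mm.set_xlabel(f"{region.contig} position (bp)")

    fig.suptitle(
        f"{region.locus_type} {region.contig} [{region.start:,}-{region.end:,}) "
        f"({region.haplotype})",
        fontsize=9,
    )
    fig.savefig(out_path, dpi=panel_spec.dpi)

    sidecar = {
        "locus": {
            "locus_type": region.locus_type,
            "contig": region.contig,
            "start": region.start,
            "end": region.end,
            "haplotype": region.haplotype,
        },
        "highlights": [[int(s), int(e)] for s, e in highlight_spans],
        "break_bars": [[int(s), int(e), cat] for s, e, cat in break_bars],
        "spikes": [
            [int(sp.start), int(sp.end), round(sp.fold_change, 4)]
            for sp in error_calls.coverage_spikes
        ],
        "heatmap": {
            "window_size": panel_spec.window_size,
            "window_starts": [int(w) for w in win_edges],
            "flag_counts": [int(c) for c in win_counts],
        },
        "coverage_sums": {
            "mapq0": int(np.sum(m0)),
            "mapq1_59": int(np.sum(mm_)),
            "mapq60": int(np.sum(m60)),
            "depth": int(np.sum(profiles.depth)),
        },
    }
    with open(out_path.with_suffix(out_path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return sidecar


def render_comparison_barchart(
    locus_lengths: dict[str, int],
    out_path: str | Path,
    dpi: int = 150,
) -> dict:
    """Bar chart comparing locus lengths across haplotypes, with sidecar."""
    if not locus_lengths:
        raise InputError("need at least one haplotype length")
    out_path = Path(out_path)
    labels = sorted(locus_lengths)
    values = [locus_lengths[k] for k in labels]
    fig = Figure(figsize=(3 + len(labels), 4), dpi=dpi)
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    ax.bar(labels, [v / 1e6 for v in values], color="#1f5fa6", width=0.6)
    ax.set_ylabel("locus length (Mbp)")
    fig.savefig(out_path, dpi=dpi)
    sidecar = {k: int(v) for k, v in locus_lengths.items()}
    with open(out_path.with_suffix(out_path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return sidecar


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

@dataclass
class LocusResult:
    """Everything computed for one locus region."""

    region_name: str
    profiles: PositionProfiles
    error_calls: ErrorCallSet
    gene_qualities: list[GeneQuality] = field(default_factory=list)
    summary: LocusSummary | None = None
    reads: list[ReadAlignment] | None = None


def write_report(
    results: Sequence[LocusResult],
    out_dir: str | Path,
    config: RunConfig | None = None,
    panel_spec: PanelSpec | None = None,
    render_panels: bool = True,
) -> dict[str, Path]:
    """Write the full report bundle for a set of locus results.

    The bundle contains locus_summary.tsv, genes_quality.tsv, the three
    call BEDs, per-locus panels (PNG + JSON sidecar), the exact thresholds
    used (run_config.yaml), a length-comparison chart and a log file.
    TSV/BED content is a pure function of (inputs, config): re-running
    reproduces the files byte for byte.
    """
    config = config or RunConfig()
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise InputError(f"cannot write to {out_dir}: {exc}") from exc

    callsets = [r.error_calls for r in results]
    summaries = [r.summary for r in results if r.summary is not None]
    genes = [g for r in results for g in r.gene_qualities]

    paths: dict[str, Path] = {
        "locus_summary": out_dir / "locus_summary.tsv",
        "genes_quality": out_dir / "genes_quality.tsv",
        "breaks_bed": out_dir / "breaks.bed",
        "spikes_bed": out_dir / "spikes.bed",
        "poorly_supported_bed": out_dir / "poorly_supported.bed",
        "run_config": out_dir / "run_config.yaml",
        "log": out_dir / "igassess.log",
    }
    write_locus_summary_tsv(summaries, paths["locus_summary"])
    write_genes_quality_tsv(genes, paths["genes_quality"])
    write_breaks_bed(callsets, paths["breaks_bed"])
    write_spikes_bed(callsets, paths["spikes_bed"])
    write_poorly_supported_bed(callsets, paths["poorly_supported_bed"])
    config.to_yaml(paths["run_config"])
    if summaries:
        table = aggregate_summary_table(summaries)
        paths["aggregate_table"] = out_dir / "aggregate_table.tsv"
        write_aggregate_table_tsv(table, paths["aggregate_table"])

    if render_panels:
        panels_dir = out_dir / "panels"
        panels_dir.mkdir(exist_ok=True)
        for res in results:
            png = panels_dir / f"{res.region_name}.png"
            render_locus_panel(res.profiles, res.error_calls, panel_spec, png)
            paths[f"panel_{res.region_name}"] = png
        lengths: dict[str, int] = {}
        for res in results:
            reg = res.error_calls.region
            lengths[f"{reg.locus_type}_{reg.haplotype}_{reg.contig}"] = len(reg)
        if lengths:
            chart = out_dir / "locus_lengths.png"
            render_comparison_barchart(lengths, chart)
            paths["locus_lengths"] = chart

    with open(paths["log"], "w") as fh:
        fh.write("igassess report\n")
        for res in results:
            s = res.summary
            if s is not None:
                fh.write(
                    f"{res.region_name}: {s.classification} "
                    f"(mismatch={s.has_mismatch_error}, "
                    f"break={s.has_coverage_break})\n"
                )
    return paths
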