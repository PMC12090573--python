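"""Gene-level affected calls and locus classification."""

import numpy as np
import pytest

from igassess.error_detect import CoverageBreak, ErrorCallSet
from igassess.gene_quality import (
    aggregate_summary_table,
    assess_gene_base_view,
    assess_gene_read_view,
    classify_locus,
)
from igassess.ig_model import GeneAnnotation, LocusRegion, RunConfig
from igassess.pileup_profile import PositionProfiles, ReadAlignment


def fake_read(start, end, e_r, contig="chrT", supplementary=False):
    """A minimal primary alignment with a prescribed mismatch rate."""
    n = end - start
    d = round(e_r * n)
    return ReadAlignment(
        read_id=f"fk_{start}_{end}", contig=contig, ref_start=start,
        ref_end=end, mapq=60, aligned_len=n, mismatches=d, softclip_len=0,
        hardclip_len=0, large_indel_events=0, inserted_bases=0,
        deleted_bases=0, is_secondary=False, is_supplementary=supplementary,
        covered_blocks=[(start, end)],
        mismatch_ref_positions=np.empty(0, np.int64),
        deletion_ref_positions=np.empty(0, np.int64),
    )


def profiles_with_support(support, depth=13, start=0, contig="chrT"):
    """Profiles whose support fraction equals the given values exactly."""
    support = np.asarray(support, dtype=float)
    depth_arr = np.full(len(support), depth, np.int64)
    delta = np.round(depth * (1 - support)).astype(np.int64)
    return PositionProfiles(
        contig=contig, start=start, end=start + len(support),
        depth=depth_arr, delta=delta,
        ref_is_n=np.zeros(len(support), bool),
        bad=np.zeros(len(support), np.int64),
    )


GENE = GeneAnnotation("IGHV1", "V", "chrT", 100, 400)


class TestReadView:
    def test_six_poorly_aligned_reads_affect_gene(self):
        reads = [fake_read(50, 450, 0.02) for _ in range(6)]
        gq = assess_gene_read_view(GENE, reads, RunConfig())
        assert gq.read_view_affected and gq.bad_read_overlap_count == 6

    def test_five_reads_do_not_strict_inequality(self):
        reads = [fake_read(50, 450, 0.02) for _ in range(5)]
        gq = assess_gene_read_view(GENE, reads, RunConfig())
        assert not gq.read_view_affected

    def test_one_bp_overlap_counts(self):
        reads = [fake_read(0, 101, 0.02) for _ in range(6)]
        gq = assess_gene_read_view(GENE, reads, RunConfig())
        assert gq.bad_read_overlap_count == 6

    def test_non_overlapping_and_clean_reads_ignored(self):
        reads = (
            [fake_read(500, 900, 0.05) for _ in range(10)]  # no overlap
            + [fake_read(50, 450, 0.0) for _ in range(10)]  # clean
            + [fake_read(50, 450, 0.05, supplementary=True)] * 10
        )
        gq = assess_gene_read_view(GENE, reads, RunConfig())
        assert not gq.read_view_affected
        assert gq.bad_read_overlap_count == 0

    def test_uncovered_gene_flagged_not_affected(self):
        gq = assess_gene_read_view(GENE, [], RunConfig())
        assert gq.uncovered and not gq.read_view_affected


class TestBaseView:
    def test_ten_of_thirteen_supporting_reads_affect_gene(self):
        # 10/13 = 76.9% support at one position fails the >80% rule
        support = np.ones(500)
        support[250] = 10 / 13
        prof = profiles_with_support(support)
        gq = assess_gene_base_view(GENE, prof, RunConfig())
        assert gq.base_view_affected
        assert gq.min_support_fraction == pytest.approx(10 / 13)
        assert gq.worst_position == 250

    def test_perfect_support_not_affected(self):
        prof = profiles_with_support(np.ones(500))
        assert not assess_gene_base_view(GENE, prof, RunConfig()).base_view_affected

    def test_exact_080_boundary_is_affected(self):
        support = np.ones(500)
        support[300] = 0.80
        prof = profiles_with_support(support, depth=10)
        assert assess_gene_base_view(GENE, prof, RunConfig()).base_view_affected
        support[300] = 0.801
        prof = profiles_with_support(support, depth=1000)
        assert not assess_gene_base_view(GENE, prof, RunConfig()).base_view_affected

    def test_all_positions_uncovered_reports_no_data(self):
        prof = profiles_with_support(np.ones(500), depth=0)
        gq = assess_gene_base_view(GENE, prof, RunConfig())
        assert gq.base_view_affected is None

    def test_lowering_support_threshold_monotone(self):
        rng = np.random.default_rng(3)
        support = 0.7 + 0.3 * rng.random(500)
        prof = profiles_with_support(support, depth=1000)
        genes = [GeneAnnotation(f"IGHV{i}", "V", "chrT", i * 50, i * 50 + 40)
                 for i in range(10)]
        prev = None
        for threshold in (0.95, 0.9, 0.85, 0.8, 0.75):
            cfg = RunConfig(base_support_min=threshold)
            affected = {
                g.gene_id for g in
                (assess_gene_base_view(gene, prof, cfg) for gene in genes)
                if g.base_view_affected
            }
            if prev is not None:
                assert affected <= prev
            prev = affected


def make_callset(flagged_positions=(), breaks=(), region=None):
    region = region or LocusRegion("IGH", "chrT", 0, 10_000, haplotype="hap1")
    return ErrorCallSet(
        region=region,
        poorly_supported_positions=np.asarray(flagged_positions, np.int64),
        mismatch_track=np.zeros(len(region)),
        coverage_breaks=list(breaks),
    )


class TestClassifyLocus:
    def test_clean_locus_is_good(self):
        summary = classify_locus(make_callset(), [], RunConfig())
        assert summary.classification == "good"
        assert not summary.has_mismatch_error
        assert not summary.has_coverage_break

    def test_single_internal_zero_coverage_break(self):
        cs = make_callset(breaks=[CoverageBreak(500, 600, "zero_coverage", 0)])
        assert classify_locus(cs, [], RunConfig()).classification == "break"

    def test_edge_breaks_excluded_by_default(self):
        cs = make_callset(breaks=[CoverageBreak(0, 50, "low_coverage_edge", 2)])
        assert classify_locus(cs, [], RunConfig()).classification == "good"
        assert classify_locus(
            cs, [], RunConfig(count_edge_breaks=True)).classification == "break"

    def test_short_flag_run_is_not_a_locus_mismatch(self):
        cs = make_callset(flagged_positions=range(100, 150))
        assert classify_locus(cs, [], RunConfig()).classification == "good"

    def test_long_flag_run_is_a_locus_mismatch(self):
        cs = make_callset(flagged_positions=range(100, 250))
        assert classify_locus(cs, [], RunConfig()).classification == "mismatch"

    def test_both_flags(self):
        cs = make_callset(
            flagged_positions=range(100, 250),
            breaks=[CoverageBreak(500, 600, "zero_coverage", 0)],
        )
        assert classify_locus(cs, [], RunConfig()).classification == "both"

    def test_resolution_label_follows_haplotype(self):
        hap = LocusRegion("IGH", "chrT", 0, 1000, haplotype="hap2")
        prim = LocusRegion("IGH", "chrT", 0, 1000, haplotype="primary")
        assert classify_locus(
            make_callset(region=hap), [], RunConfig()
        ).resolution == "haplotype-resolved"
        assert classify_locus(
            make_callset(region=prim), [], RunConfig()
        ).resolution == "haplotype-unresolved"


class TestAggregateTable:
    def _summary(self, mismatch, brk, locus="IGH", resolution="haplotype-resolved"):
        region = LocusRegion(
            locus, "chrT", 0, 1000,
            haplotype="hap1" if resolution == "haplotype-resolved" else "primary",
        )
        cs = make_callset(
            flagged_positions=range(0, 150) if mismatch else (),
            breaks=[CoverageBreak(500, 600, "zero_coverage", 0)] if brk else (),
            region=region,
        )
        return classify_locus(cs, [], RunConfig())

    def test_three_loci_one_per_category(self):
        rows = aggregate_summary_table([
            self._summary(True, False),
            self._summary(False, True),
            self._summary(False, False),
        ])
        row = rows.iloc[0]
        assert (row["mismatch"], row["break"], row["good"]) == (1, 1, 1)

    def test_both_flags_counted_in_both_columns(self):
        rows = aggregate_summary_table([
            self._summary(True, True), self._summary(False, False)])
        row = rows.iloc[0]
        assert (row["mismatch"], row["break"], row["good"]) == (1, 1, 1)

    def test_planted_contingency_recovered(self):
        plan = [
            ("IGH", "haplotype-resolved", True, False),
            ("IGH", "haplotype-resolved", False, True),
            ("IGH", "haplotype-resolved", False, False),
            ("IGH", "haplotype-unresolved", True, True),
            ("IGK", "haplotype-resolved", False, False),
            ("IGK", "haplotype-unresolved", True, False),
            ("IGL", "haplotype-resolved", False, True),
            ("IGL", "haplotype-unresolved", False, False),
            ("IGL", "haplotype-unresolved", True, False),
            ("IGL", "haplotype-unresolved", False, False),
            ("IGH", "haplotype-unresolved", False, False),
            ("IGK", "haplotype-resolved", True, True),
        ]
        table = aggregate_summary_table(
            [self._summary(m, b, locus=l, resolution=r) for l, r, m, b in plan]
        ).set_index(["locus_type", "resolution"])
        for (locus, resolution), group in (
            (key, [p for p in plan if (p[0], p[1]) == key])
            for key in {(p[0], p[1]) for p in plan}
        ):
            row = table.loc[(locus, resolution)]
            assert row["n_loci"] == len(group)
            assert row["mismatch"] == sum(p[2] for p in group)
            assert row["break"] == sum(p[3] for p in group)
            assert row["good"] == sum(
                not p[2] and not p[3] for p in group)
            # good + |mismatch OR break| partitions every cell
            assert row["good"] + sum(p[2] or p[3] for p in group) == len(group)
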