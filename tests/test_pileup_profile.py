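"""Read-level mismatch accounting and per-position pileup tracks."""

import numpy as np
import pysam
import pytest

from igassess.ig_model import AssemblySequences, InputError, LocusRegion, RunConfig
from igassess.pileup_profile import (
    _parse_mpileup_bases,
    build_position_profiles,
    collect_read_alignments,
    ingest_mpileup,
    read_summary_metrics,
)

from helpers_oracle import naive_read_mismatches
from helpers_sam import make_bam, mutate, write_fasta


@pytest.fixture()
def ref_seq():
    rng = np.random.default_rng(11)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bases[rng.integers(0, 4, 400)].tobytes().decode()
    # an N run for reference-N semantics
    return seq[:300] + "N" * 10 + seq[310:]


@pytest.fixture()
def setting(tmp_path, ref_seq):
    contigs = {"chrT": ref_seq}
    asm = AssemblySequences(contigs=dict(contigs))
    region = LocusRegion("IGH", "chrT", 0, 400)
    return tmp_path, contigs, asm, region


def _collect(tmp_path, contigs, asm, region, reads, config=None):
    bam = make_bam(tmp_path, contigs, reads)
    return collect_read_alignments(bam, asm, region, config or RunConfig())


class TestReadMismatchAccounting:
    def test_identity_alignment(self, setting):
        tmp_path, contigs, asm, region = setting
        ref = contigs["chrT"]
        reads = [dict(name="r0", contig="chrT", start=10,
                      cigar=[(0, 100)], seq=ref[10:110])]
        (ra,) = _collect(tmp_path, contigs, asm, region, reads)
        assert (ra.mismatches, ra.aligned_len, ra.e_r) == (0, 100, 0.0)

    def test_mismatch_rate_exceeding_theta_flags_read(self, setting):
        tmp_path, contigs, asm, region = setting
        ref = contigs["chrT"]
        seq = ref[0:200]
        for pos in (5, 50, 150):  # 3 substitutions / 200 columns = 1.5%
            seq = mutate(seq, pos)
        reads = [dict(name="r0", contig="chrT", start=0,
                      cigar=[(0, 200)], seq=seq)]
        (ra,) = _collect(tmp_path, contigs, asm, region, reads)
        assert ra.mismatches == 3 and ra.e_r == pytest.approx(0.015)
        assert ra.is_poorly_aligned(0.01)
        assert not ra.is_poorly_aligned(0.015)  # strict >

    def test_clip_and_indel_accounting(self, setting):
        tmp_path, contigs, asm, region = setting
        ref = contigs["chrT"]
        # 10S 40M 5I 40M 3D 20M: one large insertion (5 >= 3), one large
        # deletion (3 >= 3), 10 bp soft clip
        seq = "A" * 10 + ref[20:60] + "ACGTA" + ref[60:100] + ref[103:123]
        reads = [dict(name="r0", contig="chrT", start=20,
                      cigar=[(4, 10), (0, 40), (1, 5), (0, 40), (2, 3), (0, 20)],
                      seq=seq)]
        (ra,) = _collect(tmp_path, contigs, asm, region, reads)
        assert ra.softclip_len == 10
        assert ra.large_indel_events == 2
        assert ra.aligned_len == 100
        assert ra.mismatches == 0
        assert ra.inserted_bases == 5 and ra.deleted_bases == 3
        assert (ra.ref_start, ra.ref_end) == (20, 123)
        assert list(ra.deletion_ref_positions) == [100, 101, 102]

    def test_small_indels_do_not_count_as_large(self, setting):
        tmp_path, contigs, asm, region = setting
        ref = contigs["chrT"]
        seq = ref[20:60] + "AC" + ref[60:80]
        reads = [dict(name="r0", contig="chrT", start=20,
                      cigar=[(0, 40), (1, 2), (0, 20)], seq=seq)]
        (ra,) = _collect(tmp_path, contigs, asm, region, reads)
        assert ra.large_indel_events == 0

    def test_reference_n_columns_never_mismatch(self, setting):
        tmp_path, contigs, asm, region = setting
        # read spans the N run [300, 310) with arbitrary bases
        seq = "ACGT" * 10
        reads = [dict(name="r0", contig="chrT", start=295,
                      cigar=[(0, 40)], seq=seq)]
        (ra,) = _collect(tmp_path, contigs, asm, region, reads)
        assert all(p < 300 or p >= 310 for p in ra.iter_mismatch_positions())

    def test_secondary_excluded_supplementary_flagged(self, setting):
        tmp_path, contigs, asm, region = setting
        ref = contigs["chrT"]
        reads = [
            dict(name="r0", contig="chrT", start=10, cigar=[(0, 50)],
                 seq=ref[10:60]),
            dict(name="r0", contig="chrT", start=100, cigar=[(0, 50)],
                 seq=ref[100:150], secondary=True),
            dict(name="r1", contig="chrT", start=200, cigar=[(0, 50)],
                 seq=ref[200:250], supplementary=True),
        ]
        out = _collect(tmp_path, contigs, asm, region, reads)
        assert len(out) == 2
        assert sum(ra.is_supplementary for ra in out) == 1

    def test_missing_index_instructs_indexing(self, setting):
        tmp_path, contigs, asm, region = setting
        bam = make_bam(tmp_path, contigs, [
            dict(name="r0", contig="chrT", start=0, cigar=[(0, 50)],
                 seq=contigs["chrT"][:50])])
        bam.with_suffix(".bam.bai").unlink()
        with pytest.raises(InputError, match="index"):
            collect_read_alignments(bam, asm, region, RunConfig())

    def test_contig_mismatch_lists_offenders(self, setting, tmp_path):
        _, contigs, _, _ = setting
        bam = make_bam(tmp_path, contigs, [
            dict(name="r0", contig="chrT", start=0, cigar=[(0, 50)],
                 seq=contigs["chrT"][:50])])
        other = AssemblySequences(contigs={"weird": "ACGT" * 100})
        region = LocusRegion("IGH", "weird", 0, 400)
        with pytest.raises(InputError, match="weird"):
            collect_read_alignments(bam, other, region, RunConfig())

    def test_d_matches_naive_walk_on_simulated_reads(self, small_bundles):
        """[DERIVED] d per read equals a brute-force CIGAR-expanded walk."""
        b = small_bundles["dropped_segment"]
        asm = b.sim.assembly
        region = b.sim.regions[0]
        cfg = RunConfig()
        got = {}
        for ra in collect_read_alignments(b.bam, asm, region, cfg):
            got[(ra.read_id, ra.ref_start, ra.is_supplementary)] = (
                ra.mismatches, ra.aligned_len)
        checked = 0
        with pysam.AlignmentFile(str(b.bam)) as bam:
            for rec in bam.fetch(region.contig, region.start, region.end):
                if rec.is_unmapped or rec.is_secondary:
                    continue
                ref = asm.contigs[region.contig]
                key = (rec.query_name, rec.reference_start, rec.is_supplementary)
                assert got[key] == naive_read_mismatches(rec, ref)
                checked += 1
        assert checked >= 20


class TestReadSummary:
    def _mk(self, tmp_path, contigs, asm, region, n60=9, n_total=10):
        ref = contigs["chrT"]
        reads = []
        for i in range(n_total):
            reads.append(dict(
                name=f"r{i}", contig="chrT", start=0, cigar=[(0, 100)],
                seq=ref[:100], mapq=60 if i < n60 else 30))
        return _collect(tmp_path, contigs, asm, region, reads)

    def test_mapq60_fraction(self, setting):
        tmp_path, contigs, asm, region = setting
        out = self._mk(tmp_path, contigs, asm, region)
        rs = read_summary_metrics(out)
        assert rs.frac_mapq60 == pytest.approx(0.9)

    def test_clean_reads_have_zero_defect_fractions(self, setting):
        tmp_path, contigs, asm, region = setting
        out = self._mk(tmp_path, contigs, asm, region, n60=10)
        rs = read_summary_metrics(out)
        assert rs.frac_softclipped == 0.0
        assert rs.frac_high_mismatch == 0.0
        assert rs.frac_large_indels == 0.0
        assert rs.frac_high_mismatch_or_indels == 0.0

    def test_empty_list_is_an_error(self):
        with pytest.raises(InputError):
            read_summary_metrics([])

    def test_orphan_fraction_tracks_planted_truth(self, small_bundles):
        """[DERIVED] high-mismatch/indel union vs origin-table truth.

        In the dropped-segment condition, hap2 reads mostly inside the
        deleted segment are forced onto the hap1 homolog at diverged-block
        mismatch rates; the union fraction of defect reads over the whole
        read set should track the planted orphan fraction within 5
        percentage points.
        """
        b = small_bundles["dropped_segment"]
        cfg = RunConfig()
        inj = b.truth["injections"][0]
        s = b.sim.spec.flank + inj["locus_start"]
        e = s + inj["length"]
        org = b.reads.origin
        inside = np.minimum(org.start + org.length, e) - np.maximum(org.start, s)
        majority_inside = (org.haplotype == "hap2") & (
            inside > 0.5 * org.length)
        planted = majority_inside.sum() / len(org)
        all_reads = []
        for region in b.sim.regions:
            all_reads.extend(
                collect_read_alignments(b.bam, b.sim.assembly, region, cfg))
        rs = read_summary_metrics(all_reads, cfg)
        assert rs.frac_high_mismatch_or_indels == pytest.approx(
            planted, abs=0.05)


class TestPositionProfiles:
    def test_all_matching_reads(self, setting):
        tmp_path, contigs, asm, region = setting
        ref = contigs["chrT"]
        reads = [dict(name=f"r{i}", contig="chrT", start=10,
                      cigar=[(0, 100)], seq=ref[10:110]) for i in range(3)]
        out = _collect(tmp_path, contigs, asm, region, reads)
        prof = build_position_profiles(out, asm, region, RunConfig())
        p = prof.at(50)
        assert (p.depth, p.delta, p.support_fraction) == (3, 0, 1.0)

    def test_deletion_counts_toward_depth_and_delta(self, setting):
        tmp_path, contigs, asm, region = setting
        ref = contigs["chrT"]
        j = 50
        reads = [
            dict(name="m1", contig="chrT", start=10, cigar=[(0, 100)],
                 seq=ref[10:110]),
            dict(name="m2", contig="chrT", start=10, cigar=[(0, 100)],
                 seq=ref[10:110]),
            dict(name="sub", contig="chrT", start=10, cigar=[(0, 100)],
                 seq=mutate(ref[10:110], j - 10)),
            dict(name="del", contig="chrT", start=10,
                 cigar=[(0, j - 10), (2, 1), (0, 110 - j - 1)],
                 seq=ref[10:j] + ref[j + 1:110]),
        ]
        out = _collect(tmp_path, contigs, asm, region, reads)
        prof = build_position_profiles(out, asm, region, RunConfig())
        p = prof.at(j)
        assert (p.depth, p.delta) == (4, 2)
        assert p.support_fraction == pytest.approx(0.5)

    def test_insertion_affects_neither_depth_nor_delta(self, setting):
        tmp_path, contigs, asm, region = setting
        ref = contigs["chrT"]
        reads = [dict(name="ins", contig="chrT", start=10,
                      cigar=[(0, 40), (1, 5), (0, 40)],
                      seq=ref[10:50] + "ACGTA" + ref[50:90])]
        out = _collect(tmp_path, contigs, asm, region, reads)
        prof = build_position_profiles(out, asm, region, RunConfig())
        assert prof.depth[10:90].tolist() == [1] * 80
        assert prof.delta.sum() == 0

    def test_uncovered_positions_have_zero_depth_nan_support(self, setting):
        tmp_path, contigs, asm, region = setting
        ref = contigs["chrT"]
        reads = [dict(name="r0", contig="chrT", start=10, cigar=[(0, 50)],
                      seq=ref[10:60])]
        out = _collect(tmp_path, contigs, asm, region, reads)
        prof = build_position_profiles(out, asm, region, RunConfig())
        assert prof.depth[0] == 0
        assert np.isnan(prof.support_fraction[0])
        assert np.isnan(prof.mismatch_rate[0])

    def test_reference_n_positions_undefined(self, setting):
        tmp_path, contigs, asm, region = setting
        seq = "ACGT" * 10
        reads = [dict(name="r0", contig="chrT", start=295, cigar=[(0, 40)],
                      seq=seq)]
        out = _collect(tmp_path, contigs, asm, region, reads)
        prof = build_position_profiles(out, asm, region, RunConfig())
        assert prof.delta[300:310].sum() == 0
        assert np.isnan(prof.support_fraction[300:310]).all()

    def test_track_invariants_on_fixture(self, small_bundles):
        b = small_bundles["inversion_gap"]
        cfg = RunConfig()
        for region in b.sim.regions:
            reads = collect_read_alignments(b.bam, b.sim.assembly, region, cfg)
            prof = build_position_profiles(reads, b.sim.assembly, region, cfg)
            assert np.all(prof.delta <= prof.depth)
            assert np.all(prof.bad <= prof.depth)
            assert np.array_equal(
                prof.mapq0 + prof.mapq_mid + prof.mapq60, prof.depth)

    def test_e_r_invariant_under_region_offset(self, setting):
        tmp_path, contigs, asm, _ = setting
        ref = contigs["chrT"]
        reads = [dict(name="r0", contig="chrT", start=100, cigar=[(0, 200)],
                      seq=mutate(mutate(ref[100:300], 10), 50))]
        bam = make_bam(tmp_path, contigs, reads)
        cfg = RunConfig()
        e_values = set()
        for start, end in [(0, 400), (50, 350), (100, 300)]:
            region = LocusRegion("IGH", "chrT", start, end)
            (ra,) = collect_read_alignments(bam, asm, region, cfg)
            e_values.add(ra.e_r)
        assert len(e_values) == 1


class TestMpileupIngestion:
    def _region(self, length=400):
        return LocusRegion("IGH", "chrP", 0, length)

    def test_match_line(self, tmp_path):
        mp = tmp_path / "x.mpileup"
        mp.write_text("chrP\t101\tA\t3\t..,\tIII\n")
        prof = ingest_mpileup(mp, self._region())
        assert (prof.depth[100], prof.delta[100]) == (3, 0)

    def test_mismatch_line(self, tmp_path):
        mp = tmp_path / "x.mpileup"
        mp.write_text("chrP\t102\tC\t4\t.,Ta\tIIII\n")
        prof = ingest_mpileup(mp, self._region())
        assert (prof.depth[101], prof.delta[101]) == (4, 2)

    def test_grammar_markers_consumed(self, tmp_path):
        mp = tmp_path / "x.mpileup"
        # read start with mapq char, indel runs, read end, deletion
        mp.write_text("chrP\t103\tG\t5\t^].,+2AC.-3TTT.$*\tIIIII\n")
        prof = ingest_mpileup(mp, self._region())
        assert (prof.depth[102], prof.delta[102]) == (5, 1)

    def test_zero_depth_placeholder(self, tmp_path):
        mp = tmp_path / "x.mpileup"
        mp.write_text("chrP\t104\tG\t0\t*\t*\n")
        prof = ingest_mpileup(mp, self._region())
        assert (prof.depth[103], prof.delta[103]) == (0, 0)

    def test_reference_n_forces_zero_delta(self, tmp_path):
        mp = tmp_path / "x.mpileup"
        mp.write_text("chrP\t105\tN\t3\tACa\tIII\n")
        prof = ingest_mpileup(mp, self._region())
        assert (prof.depth[104], prof.delta[104]) == (3, 0)
        assert prof.ref_is_n[104]

    def test_dangling_indel_marker_reports_line(self, tmp_path):
        mp = tmp_path / "x.mpileup"
        mp.write_text("chrP\t101\tA\t2\t..\tII\nchrP\t102\tA\t2\t.+\tII\n")
        with pytest.raises(InputError, match="line 2"):
            ingest_mpileup(mp, self._region())

    def test_profiles_lack_read_stats(self, tmp_path):
        mp = tmp_path / "x.mpileup"
        mp.write_text("chrP\t101\tA\t1\t.\tI\n")
        prof = ingest_mpileup(mp, self._region())
        assert not prof.has_read_stats


@pytest.mark.parametrize(
    "bases,expected",
    [
        ("....", (4, 0)),
        (",,g,", (4, 1)),
        ("*", (1, 1)),
        (">><<", (4, 0)),
        ("^I..$", (2, 0)),
        (".+10AAAAAAAAAA.", (2, 0)),
    ],
)
def test_mpileup_base_grammar(bases, expected):
    assert _parse_mpileup_bases(bases, 1)[:2] == expected
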