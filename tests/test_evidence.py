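"""Single-pass evidence collection: depth, alleles, candidates, anchoring."""

import numpy as np
import pysam
import pytest

from omnicall.evidence import (
    BreakpointCandidate,
    ScanOptions,
    apply_clip_anchoring,
    candidates_from_cigar,
    candidates_from_discordant_pair,
    scan_chromosome,
)
from omnicall.insertsize import PairClass, PairGeometry, classify_pair

from conftest import make_header, make_pair, make_read, write_bam


def scan(tmp_path, records, model, chrom="chr1", **opts):
    path = write_bam(tmp_path / "t.bam", make_header(), records)
    with pysam.AlignmentFile(str(path)) as bam:
        return scan_chromosome(bam, chrom, model, ScanOptions(**opts) if opts else None)


class TestCandidatesFromCigar:
    def test_two_base_deletion_within_read(self, header):
        read = make_read(header, "r", "chr1", 10_000, "50M2D50M", mate_pos=10_400)
        cands, clips = candidates_from_cigar(read)
        assert clips == []
        dels = {(c.side, c.pos, c.length, c.weight) for c in cands}
        assert dels == {("start", 10_050, 2.0, 1.0), ("end", 10_052, 2.0, 1.0)}
        assert all(c.exact for c in cands)

    def test_insertion_candidates_carry_sequence(self, header):
        read = make_read(header, "r", "chr1", 5_000, "40M5I55M",
                         seq="A" * 40 + "CGTCG" + "A" * 55, mate_pos=5_400)
        cands, _ = candidates_from_cigar(read)
        assert {(c.side, c.pos, c.length) for c in cands} == {
            ("start", 5_040, 5.0), ("end", 5_040, 5.0)}
        assert all(c.inserted_seq == "CGTCG" for c in cands)

    def test_four_base_clip_is_not_a_boundary(self, header):
        read = make_read(header, "r", "chr1", 2_000, "4S96M", mate_pos=2_400)
        cands, clips = candidates_from_cigar(read)
        assert cands == [] and clips == []

    def test_five_base_clips_mark_both_edges(self, header):
        left = make_read(header, "l", "chr1", 2_000, "5S95M", mate_pos=2_400)
        right = make_read(header, "r", "chr1", 2_000, "95M5S", mate_pos=2_400)
        _, cl = candidates_from_cigar(left)
        _, cr = candidates_from_cigar(right)
        assert [(b.pos, b.side) for b in cl] == [(2_000, "left")]
        assert [(b.pos, b.side) for b in cr] == [(2_095, "right")]

    def test_split_alignment_yields_deletion_candidates(self, header):
        read = make_read(header, "s", "chr1", 1_000, "50M50S", mate_pos=1_400,
                         tags=[("SA", "chr1,2051,+,50S50M,60,0;")])
        cands, _ = candidates_from_cigar(read)
        split = {(c.side, c.pos, c.sv_type, c.length) for c in cands}
        assert ("start", 1_050, "DEL", 1_000.0) in split
        assert ("end", 2_050, "DEL", 1_000.0) in split

    def test_short_split_segment_contributes_nothing(self, header):
        read = make_read(header, "s", "chr1", 1_000, "85M15S", mate_pos=1_400,
                         tags=[("SA", "chr1,2051,+,85S15M,60,0;")])
        cands, _ = candidates_from_cigar(read)
        assert [c for c in cands if c.sv_type != "INS"] == []

    def test_inverted_split_gives_inversion_candidates(self, header):
        # forward half then reverse-strand half: an inversion junction
        read = make_read(header, "s", "chr1", 1_000, "50M50S", mate_pos=1_400,
                         tags=[("SA", "chr1,2951,-,50M50S,60,0;")])
        cands, _ = candidates_from_cigar(read)
        inv = {(c.side, c.pos) for c in cands if c.sv_type == "INV"}
        assert ("start", 1_050) in inv
        assert len(inv) == 2

    def test_cross_chromosome_split_gives_breakend_pair(self, header):
        read = make_read(header, "s", "chr1", 1_000, "60M40S", mate_pos=1_400,
                         tags=[("SA", "chr2,5001,+,60S40M,60,0;")])
        cands, _ = candidates_from_cigar(read)
        tra = [(c.chrom, c.pos, c.mate_chrom, c.mate_pos) for c in cands
               if c.sv_type == "TRA"]
        assert ("chr1", 1_060, "chr2", 5_000) in tra
        assert ("chr2", 5_000, "chr1", 1_060) in tra


class TestDiscordantWindows:
    def test_deletion_window_width_and_length(self, model):
        insert = int(model.i_median) + 1_200
        geom = PairGeometry("chr1", 1_000, 1_100, False, "chr1",
                            1_000 + insert - 100, True, insert)
        assert classify_pair(geom, model) is PairClass.DISCORDANT_DELETION
        pw = candidates_from_discordant_pair(geom, PairClass.DISCORDANT_DELETION, model)
        W = int(model.i_max - model.i_min)
        assert pw.sv_type == "DEL"
        assert pw.length == pytest.approx(1_200.0)
        assert pw.start_window == (1_100, 1_100 + W)
        assert pw.end_window[1] - pw.end_window[0] == W
        assert pw.end_window[1] == geom.mate_start

    def test_insert_at_i_max_is_concordant_no_candidates(self, model):
        insert = int(model.i_max)
        geom = PairGeometry("chr1", 1_000, 1_100, False, "chr1",
                            1_000 + insert - 100, True, insert)
        assert classify_pair(geom, model) is PairClass.CONCORDANT

    def test_small_insert_gives_insertion_length(self, model):
        geom = PairGeometry("chr1", 1_000, 1_100, False, "chr1", 1_100, True, 200)
        pw = candidates_from_discordant_pair(geom, PairClass.DISCORDANT_INSERTION, model)
        assert pw.sv_type == "INS"
        assert pw.length == pytest.approx(model.i_median - 200)

    def test_duplication_length_estimator(self, model):
        # everted pair around a tandem-duplication junction
        geom = PairGeometry("chr1", 10_000, 10_100, True, "chr1", 11_500, False, 1_600)
        pw = candidates_from_discordant_pair(geom, PairClass.DISCORDANT_DUPLICATION, model)
        span = (11_500 + 100) - 10_000
        assert pw.length == pytest.approx(span + model.i_median - 200)
        assert pw.start_window[1] == 10_000
        assert pw.end_window[0] == 11_600


class TestClipAnchoring:
    def mk(self, positions):
        return [BreakpointCandidate("chr1", p, "start", "DEL", 1_000.0, 1.0, f"r{i}")
                for i, p in enumerate(positions)]

    def test_no_boundary_leaves_weights(self):
        cands = self.mk(range(100, 110))
        out = apply_clip_anchoring(cands, [])
        assert all(c.weight == 1.0 for c in out)

    def test_single_boundary_halves_the_rest(self):
        cands = self.mk(range(100, 110))
        apply_clip_anchoring(cands, [105])
        assert {c.pos: c.weight for c in cands}[105] == 1.0
        assert sum(1 for c in cands if c.weight == 0.5) == 9

    def test_multiple_boundaries_all_keep_full_weight(self):
        cands = self.mk(range(100, 110))
        apply_clip_anchoring(cands, [103, 107])
        w = {c.pos: c.weight for c in cands}
        assert w[103] == 1.0 and w[107] == 1.0
        assert sum(1 for c in cands if c.weight == 0.5) == 8

    def test_boundary_outside_region_is_ignored(self):
        cands = self.mk(range(100, 110))
        apply_clip_anchoring(cands, [500])
        assert all(c.weight == 1.0 for c in cands)


class TestScanChromosome:
    def test_empty_region_empty_streams(self, tmp_path, model):
        res = scan(tmp_path, [], model)
        assert res.candidates == []
        assert res.evidence.physical_depth.sum() == 0

    def test_concordant_pair_covers_intermate_gap(self, tmp_path, model):
        recs = make_pair(make_header(), "p", "chr1", 1_000, 1_400)
        res = scan(tmp_path, list(recs), model)
        d = res.evidence.physical_depth
        assert (d[1_000:1_500] == 1).all()
        assert d[999] == 0 and d[1_500] == 0
        assert int(d.sum()) == 500  # exactly the fragment span

    def test_depth_conservation_concordant_only(self, tmp_path, model):
        header = make_header()
        recs = []
        inserts = []
        for i in range(20):
            ins = 400 + 10 * i
            inserts.append(ins)
            recs.extend(make_pair(header, f"p{i}", "chr1", 2_000 * i,
                                  2_000 * i + ins - 100))
        res = scan(tmp_path, recs, model)
        assert int(res.evidence.physical_depth.sum()) == sum(inserts)

    def test_discordant_pair_depth_includes_windows(self, tmp_path, model):
        header = make_header()
        recs = make_pair(header, "d", "chr1", 10_000, 11_600)  # insert 1700
        res = scan(tmp_path, list(recs), model)
        W = model.window_width
        # two reads (200) plus the two feasibility windows (2 * W)
        assert int(res.evidence.physical_depth.sum()) == 200 + 2 * W
        dels = [c for c in res.candidates if c.sv_type == "DEL"]
        assert len(dels) == 2 * W
        assert all(c.length == pytest.approx(1_700 - model.i_median) for c in dels)
        starts = sorted(c.pos for c in dels if c.side == "start")
        assert starts[0] == 10_100 and len(starts) == W

    def test_candidate_windows_clamped_to_chromosome(self, tmp_path, model):
        header = make_header()
        # discordant pair near the chromosome end
        recs = make_pair(header, "d", "chr1", 98_000, 99_700)
        res = scan(tmp_path, list(recs), model)
        assert all(0 <= c.pos < 100_000 for c in res.candidates)

    def test_mapq0_counts_depth_but_no_candidates(self, tmp_path, model):
        header = make_header()
        recs = make_pair(header, "d", "chr1", 10_000, 11_600, mapq=0)
        res = scan(tmp_path, list(recs), model)
        assert res.candidates == []
        assert int(res.evidence.physical_depth.sum()) == 200  # reads only

    def test_excluded_qnames_skipped_entirely(self, tmp_path, model):
        header = make_header()
        recs = list(make_pair(header, "keep", "chr1", 1_000, 1_400)) + list(
            make_pair(header, "drop", "chr1", 1_000, 1_400)
        )
        path = write_bam(tmp_path / "x.bam", header, recs)
        with pysam.AlignmentFile(str(path)) as bam:
            res = scan_chromosome(bam, "chr1", model, exclude_qnames={"drop"})
        assert res.n_reads == 2
        assert int(res.evidence.physical_depth.max()) == 1

    def test_unknown_chromosome_is_hard_error(self, tmp_path, model):
        path = write_bam(tmp_path / "y.bam", make_header(), [])
        with pysam.AlignmentFile(str(path)) as bam:
            with pytest.raises(ValueError, match="unknown chromosome"):
                scan_chromosome(bam, "chrZ", model)

    def test_unsorted_bam_rejected(self, tmp_path, model):
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6", "SO": "queryname"},
             "SQ": [{"SN": "chr1", "LN": 100_000}]}
        )
        path = tmp_path / "u.bam"
        with pysam.AlignmentFile(str(path), "wb", header=header) as bf:
            pass
        with pysam.AlignmentFile(str(path)) as bam:
            with pytest.raises(ValueError, match="coordinate-sorted"):
                scan_chromosome(bam, "chr1", model)

    def test_allele_counts_and_quality_means(self, tmp_path, model):
        header = make_header()
        recs = list(make_pair(header, "p", "chr1", 1_000, 1_400))
        res = scan(tmp_path, recs, model)
        be = res.evidence.base_evidence(1_050)
        assert be.allele_counts["A"] == 1
        assert be.read_depth == 1
        assert be.physical_depth == 1
        assert be.mean_baseq["A"] == pytest.approx(35.0)
        assert be.mean_mapq == pytest.approx(60.0)

    def test_mean_physical_depth_matches_fragment_coverage(self, tmp_path):
        from omnicall.simulate import SimSpec, simulate
        from omnicall.insertsize import fit_insert_model, sample_insert_sizes

        spec = SimSpec(chromosomes={"chr1": 100_000}, coverage=30.0, seed=3)
        out = simulate(spec, tmp_path / "flat")
        with pysam.AlignmentFile(str(out.bam)) as bam:
            sizes = sample_insert_sizes(bam.fetch(), min_pairs=100)
            m = fit_insert_model(sizes, 100)
            res = scan_chromosome(bam, "chr1", m)
        expected = spec.coverage * spec.insert_mean / (2 * spec.read_length)
        interior = res.evidence.physical_depth[2_000:-2_000]
        assert abs(interior.mean() - expected) / expected < 0.10
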