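import textwrap

import pytest

from telinc import genome_io as gio
from telinc.intervals import IntervalSet

RM_HEADER = (
    "   SW  perc perc perc  query position in query matching repeat\n"
    "score  div. del. ins.  sequence begin end (left) repeat class/family begin end (left) ID\n"
    "\n"
)


def _rm_file(tmp_path, rows):
    p = tmp_path / "test.out"
    p.write_text(RM_HEADER + "".join(rows))
    return p


def _row(chrom, begin, end, family, rm_class, rid=1):
    return f"463 12.5 0.0 0.0 {chrom} {begin} {end} (0) + {family} {rm_class} 1 100 (0) {rid}\n"


class TestRepeatMaskerParse:
    def test_empty_file_gives_empty_set(self, tmp_path):
        assert gio.parse_repeatmasker(_rm_file(tmp_path, [])) == []

    def test_merge_boundary_gap_9_merges_gap_10_does_not(self, tmp_path):
        # 1-based [101,200] + [209,300]: gap 8 in half-open -> merged
        p = _rm_file(tmp_path, [_row("chr1", 101, 200, "L1MA4", "LINE/L1"),
                                _row("chr1", 209, 300, "L1MA4", "LINE/L1", 2)])
        frags = gio.parse_repeatmasker(p, min_merge_gap=10)
        assert [(f.start, f.end) for f in frags] == [(100, 300)]
        # second piece at [211,300]: gap exactly 10 -> two fragments
        p2 = _rm_file(tmp_path, [_row("chr1", 101, 200, "L1MA4", "LINE/L1"),
                                 _row("chr1", 211, 300, "L1MA4", "LINE/L1", 2)])
        frags2 = gio.parse_repeatmasker(p2, min_merge_gap=10)
        assert [(f.start, f.end) for f in frags2] == [(100, 200), (210, 300)]

    def test_simple_repeat_between_tes_is_dropped(self, tmp_path):
        p = _rm_file(
            tmp_path,
            [
                _row("chr1", 101, 200, "L1MA4", "LINE/L1"),
                _row("chr1", 300, 340, "(TA)n", "Simple_repeat", 2),
                _row("chr1", 500, 700, "AluY", "SINE/Alu", 3),
            ],
        )
        frags = gio.parse_repeatmasker(p)
        assert sorted(f.family for f in frags) == ["AluY", "L1MA4"]

    @pytest.mark.parametrize("rm_class", ["Low_complexity", "Satellite", "snRNA", "tRNA"])
    def test_non_te_classes_filtered(self, tmp_path, rm_class):
        p = _rm_file(tmp_path, [_row("chr1", 101, 200, "X", rm_class)])
        assert gio.parse_repeatmasker(p) == []

    def test_family_blacklist(self, tmp_path):
        p = _rm_file(tmp_path, [_row("chr1", 101, 200, "MutSatRep1", "DNA/hAT"),
                                _row("chr1", 500, 600, "hAT1", "DNA/hAT", 2)])
        frags = gio.parse_repeatmasker(p, family_blacklist=["MutSatRep1"])
        assert [f.family for f in frags] == ["hAT1"]

    def test_ltr_internal_subpart(self, tmp_path):
        p = _rm_file(tmp_path, [_row("chr1", 101, 300, "HERVK-int", "LTR/ERVK"),
                                _row("chr1", 500, 600, "LTR5", "LTR/ERVK", 2)])
        frags = gio.parse_repeatmasker(p)
        by_fam = {f.family: f for f in frags}
        assert by_fam["HERVK-int"].class_label == "LTR/int"
        assert by_fam["LTR5"].class_label == "LTR/LTR"

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.out"
        p.write_text(RM_HEADER + "463 12.5 0.0 0.0 chr1 101\n")
        with pytest.raises(ValueError, match="line 4"):
            gio.parse_repeatmasker(p)

    def test_parse_export_parse_idempotent(self, tmp_path):
        p = _rm_file(
            tmp_path,
            [
                _row("chr1", 101, 200, "L1MA4", "LINE/L1"),
                _row("chr1", 209, 300, "L1MA4", "LINE/L1", 2),
                _row("chr2", 50, 400, "AluY", "SINE/Alu", 3),
            ],
        )
        frags = gio.parse_repeatmasker(p)
        out = tmp_path / "roundtrip.out"
        gio.write_repeatmasker(frags, out)
        again = gio.parse_repeatmasker(out)
        key = lambda fs: [(f.chrom, f.start, f.end, f.family, f.te_class) for f in fs]
        assert key(again) == key(frags)

    def test_length_conserved_through_coordinate_conversion(self, tmp_path):
        p = _rm_file(tmp_path, [_row("chr1", 101, 200, "L1MA4", "LINE/L1")])
        (f,) = gio.parse_repeatmasker(p)
        assert f.length == 200 - 101 + 1  # 1-based inclusive span length


GTF_3EXON = textwrap.dedent("""\
    chr1\tx\texon\t101\t200\t.\t{strand}\t.\tgene_id "g1"; transcript_id "t1"; gene_biotype "lincRNA";
    chr1\tx\texon\t301\t400\t.\t{strand}\t.\tgene_id "g1"; transcript_id "t1"; gene_biotype "lincRNA";
    chr1\tx\texon\t501\t700\t.\t{strand}\t.\tgene_id "g1"; transcript_id "t1"; gene_biotype "lincRNA";
""")


class TestGtfParse:
    @pytest.mark.parametrize("strand,first_exon", [("+", (100, 200)), ("-", (500, 700))])
    def test_first_exon_resolved_by_strand(self, tmp_path, strand, first_exon):
        p = tmp_path / "a.gtf"
        p.write_text(GTF_3EXON.format(strand=strand))
        (t,) = gio.parse_transcripts(p)
        assert t.n_exons == 3
        idx = 0 if strand == "+" else 2
        assert t.exons[idx] == first_exon
        assert t.exon_ordinal(idx) == 1
        assert t.biotype == "lncRNA_intergenic"

    def test_pc_without_utr5_excluded_from_feature_view_only(self, tmp_path):
        gtf = (
            'chr1\tx\texon\t101\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; gene_biotype "protein_coding";\n'
            'chr1\tx\tthree_prime_utr\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; gene_biotype "protein_coding";\n'
        )
        p = tmp_path / "b.gtf"
        p.write_text(gtf)
        raw = gio.parse_transcripts(p)
        assert len(raw) == 1  # retained in the raw view
        assert gio.feature_analysis_view(raw) == []

    def test_one_isoform_selection_reproducible(self, tmp_path):
        gtf = "".join(
            f'chr1\tx\texon\t{s}\t{s + 99}\t.\t+\t.\tgene_id "g1"; transcript_id "t{i}"; gene_biotype "lincRNA";\n'
            for i, s in [(1, 101), (2, 101)]
        )
        p = tmp_path / "c.gtf"
        p.write_text(gtf)
        picks = {gio.parse_transcripts(p, one_isoform_per_gene=True, seed=7)[0].transcript_id
                 for _ in range(3)}
        assert len(picks) == 1  # same seed, same choice
        only = gio.parse_transcripts(p, one_isoform_per_gene=True, seed=7)
        assert len(only) == 1

    def test_transcript_on_two_strands_rejected(self, tmp_path):
        gtf = (
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t301\t400\t.\t-\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        p = tmp_path / "d.gtf"
        p.write_text(gtf)
        # the offending record is dropped and logged, not fatal
        assert gio.parse_transcripts(p) == []

    def test_gtf_round_trip(self, tmp_path, small_bundle):
        out = tmp_path / "rt.gtf"
        gio.write_gtf(small_bundle.transcripts, out)
        again = gio.parse_transcripts(out)
        orig = sorted(small_bundle.transcripts, key=lambda t: t.transcript_id)
        new = sorted(again, key=lambda t: t.transcript_id)
        assert [(t.transcript_id, t.exons, t.strand, t.biotype) for t in orig] == [
            (t.transcript_id, t.exons, t.strand, t.biotype) for t in new
        ]


class TestBedAndTracks:
    def test_bed_round_trip_preserves_overlaps(self, tmp_path):
        ivs = IntervalSet({"chr1": [(0, 10), (5, 20), (5, 20)], "chr2": [(3, 4)]})
        p = tmp_path / "a.bed"
        gio.write_intervals(ivs, p)
        back = gio.read_intervals(p)
        assert back == ivs
        assert len(back) == 4  # no silent merge

    def test_single_bed_line_convention(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("chr1\t0\t10\n")
        back = gio.read_intervals(p)
        assert back.covered_bp() == 10

    def test_bad_bed_interval_raises(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("chr1\t10\t10\n")
        with pytest.raises(ValueError):
            gio.read_intervals(p)

    def test_score_track_lookup_and_mean(self, tmp_path):
        p = tmp_path / "t.bedGraph"
        p.write_text("chr1\t0\t5\t1.0\nchr1\t5\t10\t2.0\nchr1\t20\t24\t-1.0\n")
        track = gio.read_score_track(p)
        assert track.covered_bp() == 14
        region = IntervalSet({"chr1": [(0, 30)]})
        vals = track.values_in(region)
        assert vals.size == 14  # adjacent records not double-counted
        # hand-computed weighted mean: (5*1 + 5*2 + 4*(-1)) / 14
        assert track.mean_in(region) == pytest.approx(11 / 14)
        assert track.values_in(IntervalSet({"chr1": [(12, 18)]})).size == 0

    def test_chrom_sizes_round_trip(self, tmp_path):
        sizes = {"chr1": 100, "chr2": 250}
        p = tmp_path / "g.sizes"
        gio.write_chrom_sizes(sizes, p)
        assert gio.read_chrom_sizes(p) == sizes
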