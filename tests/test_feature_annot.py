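from collections import Counter

import pytest

from oracle_utils import bitmap_classify
from telinc import feature_annot as fa
from telinc.genome_io import TEFragment, TranscriptModel


def _te(start, end, chrom="chr1", tid=None):
    return TEFragment(
        id=tid or f"te_{start}_{end}", chrom=chrom, start=start, end=end,
        family="AluSyn", te_class="SINE",
    )


def _tx(exons, strand="+", tid="t1", chrom="chr1"):
    return TranscriptModel(
        transcript_id=tid, gene_id=f"g_{tid}", chrom=chrom, strand=strand,
        exons=tuple(exons), biotype="lncRNA_intergenic",
    )


THREE_EXON = [(100, 150), (250, 290), (400, 460)]  # 50/40/60 bp


class TestSingleCalls:
    def test_te_spanning_internal_exon_is_both_spl(self):
        t = _tx(THREE_EXON)
        call = fa.classify_te_exon(_te(240, 300), t, 1)
        assert call.category == "BOTH_SPL" and call.exon_role == "internal"

    def test_interior_only_overlap_is_exonized(self):
        t = _tx(THREE_EXON)
        call = fa.classify_te_exon(_te(405, 455), t, 2)
        assert call.category == "EXONIZED"

    def test_tss_requires_coverage_of_five_prime_base(self):
        t = _tx(THREE_EXON)
        assert fa.classify_te_exon(_te(90, 120), t, 0).category == "TSS"
        t_minus = _tx(THREE_EXON, strand="-")
        # on minus strand the 5'-most base of the transcript is at 459
        assert fa.classify_te_exon(_te(430, 470), t_minus, 2).category == "TSS"
        assert fa.classify_te_exon(_te(90, 120), t_minus, 0).category == "POLYA"

    def test_sub_threshold_overlap_gives_no_call(self):
        t = _tx(THREE_EXON)
        assert fa.classify_te_exon(_te(145, 200), t, 0) is None  # 5 bp

    def test_full_single_exon_transcript(self):
        t = _tx([(100, 200)])
        assert fa.classify_te_exon(_te(90, 210), t, 0).category == "FULL_SINGLE"
        assert fa.classify_te_exon(_te(90, 150), t, 0).category == "TSS"
        assert fa.classify_te_exon(_te(150, 210), t, 0).category == "POLYA"


class TestOracleEquivalence:
    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("te_len", [12, 30, 75])
    def test_exhaustive_slide_matches_bitmap_oracle(self, strand, te_len):
        """Slide a TE across a 3-exon transcript; every placement must agree
        with the independent per-base classifier."""
        t = _tx(THREE_EXON, strand=strand)
        for start in range(0, 520):
            te = _te(start, start + te_len)
            for idx in range(3):
                got = fa.classify_te_exon(te, t, idx)
                expected = bitmap_classify((start, start + te_len), t, idx)
                assert (got.category if got else None) == expected, (
                    f"start={start} len={te_len} exon={idx} strand={strand}"
                )

    def test_strand_flip_swaps_tss_and_polya(self):
        """Relabelling the strand (same coordinates) swaps TSS<->POLYA calls."""
        t_plus = _tx(THREE_EXON, strand="+")
        t_minus = _tx(THREE_EXON, strand="-")
        swap = {"TSS": "POLYA", "POLYA": "TSS", "TSS_SPL": "POLYA_SPL",
                "POLYA_SPL": "TSS_SPL"}
        for start in range(0, 560, 3):
            for te_len in (15, 40):
                for idx in range(3):
                    te = _te(start, start + te_len)
                    c = fa.classify_te_exon(te, t_plus, idx)
                    cm = fa.classify_te_exon(te, t_minus, idx)
                    got_plus = c.category if c else None
                    got_minus = cm.category if cm else None
                    assert got_minus == swap.get(got_plus, got_plus)

    def test_mirror_and_flip_preserves_categories(self):
        """Reverse-complementing the locus (mirror + strand flip) is
        orientation-preserving, so every call keeps its category."""
        L = 600
        t_plus = _tx(THREE_EXON, strand="+")
        mirrored = tuple(sorted((L - e, L - s) for s, e in THREE_EXON))
        t_minus = _tx(list(mirrored), strand="-")
        for start in range(0, 560, 3):
            for te_len in (15, 40):
                for idx in range(3):
                    c = fa.classify_te_exon(_te(start, start + te_len), t_plus, idx)
                    m_start, m_end = L - (start + te_len), L - start
                    cm = fa.classify_te_exon(_te(m_start, m_end), t_minus, 2 - idx)
                    assert (c.category if c else None) == (cm.category if cm else None)


class TestClassifyAll:
    def test_no_tes_all_exons_unhit(self):
        t = _tx(THREE_EXON)
        calls, summary = fa.classify_all([], [t])
        assert calls == [] and summary.unhit_exons == 3

    def test_te_hitting_two_exons_yields_two_calls(self):
        t = _tx(THREE_EXON)
        calls, summary = fa.classify_all([_te(120, 270)], [t])
        assert len(calls) == 2
        assert {c.exon_ordinal for c in calls} == {1, 2}

    def test_exon_accounting_identity(self, small_bundle):
        """Exons hit in >=1 category plus unhit exons equals total exons."""
        from telinc.genome_io import feature_analysis_view

        view = feature_analysis_view(small_bundle.transcripts)
        calls, summary = fa.classify_all(small_bundle.tes, view)
        hit = {(c.transcript_id, c.exon_ordinal) for c in calls}
        assert len(hit) + summary.unhit_exons == summary.total_exons

    def test_classify_all_matches_oracle_on_random_toys(self, small_bundle):
        """Sweep-based classification equals the per-base oracle on a subset."""
        view = [t for t in small_bundle.transcripts if t.biotype.startswith("lncRNA")][:5]
        tes = small_bundle.tes[:50]
        calls, _ = fa.classify_all(tes, view)
        got = Counter((c.te_id, c.transcript_id, c.exon_ordinal, c.category) for c in calls)
        expected = Counter()
        for t in view:
            for f in tes:
                if f.chrom != t.chrom:
                    continue
                for idx in range(t.n_exons):
                    cat = bitmap_classify((f.start, f.end), t, idx)
                    if cat:
                        expected[(f.id, t.transcript_id, t.exon_ordinal(idx), cat)] += 1
        assert got == expected


class TestSiteInventory:
    def test_shared_tss_deduplicated(self):
        t1 = _tx([(100, 200), (300, 400)], tid="a")
        t2 = _tx([(100, 250), (300, 400)], tid="b")
        inv = fa.site_inventory([t1, t2], [])
        tss = [r for r in inv if r.kind == "TSS"]
        assert len(tss) == 1
        assert tss[0].transcript_ids == ("a", "b")

    def test_empty_transcripts_empty_inventory(self):
        assert fa.site_inventory([], []) == []

    def test_te_derived_requires_10bp_exon_overlap(self):
        t = _tx([(100, 200), (300, 400)])
        grazing = _te(95, 103)  # covers TSS base but only 3 bp of exon
        inv = fa.site_inventory([t], [grazing])
        assert not [r for r in inv if r.kind == "TSS"][0].te_derived
        solid = _te(95, 115)  # covers TSS base with 15 bp overlap
        inv2 = fa.site_inventory([t], [solid])
        assert [r for r in inv2 if r.kind == "TSS"][0].te_derived

    def test_site_counts_multi_exon(self):
        t = _tx(THREE_EXON)
        inv = fa.site_inventory([t], [])
        kinds = Counter(r.kind for r in inv)
        assert kinds == {"TSS": 1, "polyA": 1, "splice": 4}

    def test_fully_te_first_exon_detection(self):
        t = _tx(THREE_EXON)
        assert fa.fully_te_first_exons([t], [_te(90, 160)]) == ["t1"]
        # two TEs jointly covering the first exon also count
        assert fa.fully_te_first_exons([t], [_te(90, 130), _te(120, 160)]) == ["t1"]
        assert fa.fully_te_first_exons([t], [_te(105, 160)]) == []
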