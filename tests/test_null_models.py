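import numpy as np
import pytest
from scipy import stats

from telinc import null_models as nm
from telinc.genome_io import GenomeLayout, TEFragment
from telinc.intervals import IntervalSet


def _te(start, end, chrom="chr1", family="L1Syn", te_class="LINE", tid=None):
    return TEFragment(
        id=tid or f"te_{chrom}_{start}", chrom=chrom, start=start, end=end,
        family=family, te_class=te_class,
    )


class TestShuffle:
    def test_lengths_families_chromosomes_conserved(self):
        layout = GenomeLayout({"chr1": 10_000, "chr2": 5_000})
        tes = [_te(0, 100), _te(500, 800), _te(1000, 1050, chrom="chr2")]
        shuffled = nm.shuffle_tes(layout, tes, seed=3)
        key = lambda fs: sorted((f.chrom, f.length, f.family) for f in fs)
        assert key(shuffled) == key(tes)

    def test_avoids_gaps_and_mutual_overlap(self):
        gaps = IntervalSet({"chr1": [(2_000, 6_000)]})
        layout = GenomeLayout({"chr1": 10_000}, gaps)
        tes = [_te(i * 300, i * 300 + 200, tid=f"x{i}") for i in range(6)]
        for seed in range(20):
            sh = nm.shuffle_tes(layout, tes, seed)
            spans = sorted((f.start, f.end) for f in sh)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 >= e1  # no mutual overlap
            for s, e in spans:
                assert not (s < 6_000 and e > 2_000)  # avoids the gap

    def test_forced_single_slot(self):
        gaps = IntervalSet({"chr1": [(0, 40), (50, 100)]})
        layout = GenomeLayout({"chr1": 100}, gaps)
        sh = nm.shuffle_tes(layout, [_te(0, 10)], seed=0)
        assert (sh[0].start, sh[0].end) == (40, 50)

    def test_infeasible_chromosome_reported(self):
        layout = GenomeLayout({"chr1": 100})
        tes = [_te(0, 60), _te(0, 60, tid="y")]
        with pytest.raises(ValueError, match="chr1"):
            nm.shuffle_tes(layout, tes, seed=0)

    def test_single_te_placement_uniform(self):
        """10-bp TE on a gapless 100-bp chromosome: start uniform on [0, 90]."""
        layout = GenomeLayout({"chr1": 100})
        te = [_te(20, 30)]
        starts = [nm.shuffle_tes(layout, te, seed)[0].start for seed in range(10_000)]
        counts = np.bincount(starts, minlength=91)
        assert counts.size == 91
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.01


class TestFeatureNull:
    def test_seeded_determinism(self, small_bundle):
        from telinc.genome_io import feature_analysis_view

        view = feature_analysis_view(small_bundle.transcripts)[:10]
        d1 = nm.feature_null(small_bundle.layout, view, small_bundle.tes[:60], K=5, seed=9)
        d2 = nm.feature_null(small_bundle.layout, view, small_bundle.tes[:60], K=5, seed=9)
        assert d1.pvalues == d2.pvalues
        for c in d1.replicates:
            assert (d1.replicates[c] == d2.replicates[c]).all()

    def test_tie_and_tail_semantics(self):
        dist = nm.NullDistribution(
            observed={"SPL": 5},
            replicates={"SPL": np.array([5, 5, 6, 7])},
            K=4,
        )
        # strict 'lower' rule: ties contribute nothing
        assert dist.pvalues["SPL"] == 0.0
        dist.conservative = True
        assert dist.pvalues["SPL"] == pytest.approx(1 / 5)
        dist2 = nm.NullDistribution(
            observed={"SPL": 8}, replicates={"SPL": np.array([5, 5, 6, 7])}, K=4
        )
        dist2.conservative = False
        assert dist2.pvalues["SPL"] == 1.0

    def test_p_resolution_is_one_over_k(self, small_bundle):
        from telinc.genome_io import feature_analysis_view

        view = feature_analysis_view(small_bundle.transcripts)[:8]
        dist = nm.feature_null(small_bundle.layout, view, small_bundle.tes[:40], K=8, seed=2)
        for p in dist.pvalues.values():
            assert (p * 8) == int(p * 8)  # multiples of 1/K


class TestJaccard:
    def test_identity_and_disjoint(self):
        a = IntervalSet({"chr1": [(0, 100), (200, 250)]})
        assert nm.jaccard(a, a) == 1.0
        b = IntervalSet({"chr1": [(500, 600)]})
        assert nm.jaccard(a, b) == 0.0

    def test_hand_computed_three_interval_fixture(self):
        a = IntervalSet({"chr1": [(0, 100), (200, 300)]})
        b = IntervalSet({"chr1": [(50, 250)]})
        # intersection = [50,100) + [200,250) = 100; union = [0,300) = 300
        assert nm.jaccard(a, b) == pytest.approx(100 / 300)

    def test_permutation_mean_matches_enumeration(self):
        """One shuffled interval vs one fixed interval on a gapless
        chromosome: simulated mean Jaccard within 3 SE of the exact mean
        over all feasible placements."""
        L, a_len = 200, 30
        layout = GenomeLayout({"chr1": L})
        b = IntervalSet({"chr1": [(80, 140)]})
        te = [_te(0, a_len)]
        exact = []
        for s in range(0, L - a_len + 1):
            a = IntervalSet({"chr1": [(s, s + a_len)]})
            exact.append(nm.jaccard(a, b))
        exact_mean = np.mean(exact)
        sims = []
        for seed in range(2_000):
            sh = nm.shuffle_tes(layout, te, seed)
            sims.append(nm.jaccard(IntervalSet({"chr1": [(sh[0].start, sh[0].end)]}), b))
        se = np.std(sims, ddof=1) / np.sqrt(len(sims))
        assert abs(np.mean(sims) - exact_mean) < 3 * se

    def test_jaccard_test_tails(self):
        layout = GenomeLayout({"chr1": 1_000})
        tes = [_te(100, 200)]
        b = IntervalSet({"chr1": [(100, 200)]})
        res = nm.jaccard_test(tes, b, layout, n_perm=50, seed=1)
        assert res.statistic == 1.0
        assert res.p_enrichment <= 1 / 50  # perfect overlap essentially unbeatable
        assert res.p_depletion == 1.0


class TestScorePermutation:
    def test_identical_vectors_give_p_one(self):
        x = np.arange(50, dtype=float)
        obs, p = nm.score_permutation_test(x, x.copy(), n_perm=200, seed=0)
        assert obs == 0.0
        assert p == 1.0

    def test_detects_planted_shift(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 500)
        b = rng.normal(0.0, 1.0, 500)
        _, p = nm.score_permutation_test(a, b, n_perm=500, seed=1)
        assert p < 0.01

    def test_variance_statistic(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.5, 400)
        b = rng.normal(0, 2.0, 400)
        obs, p = nm.score_permutation_test(a, b, n_perm=300, statistic="var_diff", seed=2)
        assert obs < 0
        assert p < 0.05


class TestNeutralSetAndMatchedRandom:
    def _transcript(self, exons, chrom="chr1"):
        from telinc.genome_io import TranscriptModel

        return TranscriptModel(
            transcript_id="t", gene_id="g", chrom=chrom, strand="+",
            exons=tuple(exons), biotype="lncRNA_intergenic",
        )

    def test_mark_bisecting_a_te(self):
        t = self._transcript([(0, 100), (1_000, 1_100)])
        te = [_te(300, 700)]
        marks = IntervalSet({"chr1": [(450, 550)]})
        neutral = nm.neutral_intronic_te_set(te, [t], marks, splice_pad=10)
        assert neutral.intervals("chr1") == [(300, 450), (550, 700)]

    def test_splice_pads_and_marks_everywhere(self):
        t = self._transcript([(0, 100), (200, 300)])
        te = [_te(100, 200)]
        no_marks = nm.neutral_intronic_te_set(te, [t], IntervalSet(), splice_pad=10)
        assert no_marks.intervals("chr1") == [(110, 190)]
        everything = nm.neutral_intronic_te_set(
            te, [t], IntervalSet({"chr1": [(0, 300)]})
        )
        assert everything.covered_bp() == 0

    def test_matched_random_preserves_count_and_lengths(self):
        layout = GenomeLayout({"chr1": 50_000, "chr2": 50_000})
        template = IntervalSet({"chr1": [(0, 100), (500, 900), (2_000, 2_050)]})
        rand = nm.matched_random_regions(layout, template, seed=4)
        assert len(rand) == 3
        assert sorted(e - s for _, s, e in rand.records()) == [50, 100, 400]
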