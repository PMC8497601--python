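"""Permutation shuffling and observed/expected enrichment."""

import numpy as np
import pytest

from methdiverge.enrichment import (
    oe_enrichment,
    shuffle_intervals,
    te_divergence_profile,
    te_family_enrichment,
)
from methdiverge.features import FeatureMap, IntervalSet, TeInterval, annotate_intervals
from methdiverge.stats import chi2_goodness_of_fit

SIZES = {"chr1": 1_000_000}


def single_feature_map(feature: IntervalSet, sizes=None) -> FeatureMap:
    empty = IntervalSet({})
    return FeatureMap(
        promoter=feature, gene_body=empty, intergenic=empty,
        cgi_promoter=empty, cgi_orphan=empty, te=empty,
        contig_sizes=dict(sizes or SIZES),
    )


@pytest.fixture
def tenpct_feature():
    # 10% of a 1-Mb genome as 100 spread-out 1-kb blocks
    return IntervalSet.from_pairs(("chr1", i * 10_000, i * 10_000 + 1000) for i in range(100))


class TestShuffle:
    def test_conservation_and_determinism(self):
        intervals = [("chr1", i * 1000, i * 1000 + 100 + i) for i in range(100)]
        c1, s1, e1 = shuffle_intervals(intervals, SIZES, np.random.default_rng(5))
        c2, s2, e2 = shuffle_intervals(intervals, SIZES, np.random.default_rng(5))
        assert len(s1) == 100
        assert sorted(e1 - s1) == sorted(e - s for _, s, e in intervals)
        assert (s1 == s2).all() and (e1 == e2).all()

    def test_placements_within_bounds(self):
        c, s, e = shuffle_intervals([("chr1", 0, 5000)] * 200, SIZES, np.random.default_rng(1))
        assert (s >= 0).all() and (e <= SIZES["chr1"]).all()

    def test_interval_longer_than_contigs(self):
        with pytest.raises(ValueError, match="longer than every contig"):
            shuffle_intervals([("chr1", 0, 2_000_000)], SIZES, np.random.default_rng(0))

    def test_start_positions_uniform(self):
        rng = np.random.default_rng(7)
        starts = []
        for _ in range(10_000):
            _, s, _ = shuffle_intervals([("chr1", 0, 100)], SIZES, rng)
            starts.append(int(s[0]))
        hist, _ = np.histogram(starts, bins=10, range=(0, SIZES["chr1"] - 99))
        r = chi2_goodness_of_fit(hist, [1000.0] * 10)
        assert r.p_value > 0.001

    def test_contig_choice_proportional_to_length(self):
        sizes = {"a": 900_000, "b": 100_000}
        rng = np.random.default_rng(3)
        c, _, _ = shuffle_intervals([("a", 0, 100)] * 5000, sizes, rng)
        frac_a = float(np.mean(c == "a"))
        assert frac_a == pytest.approx(0.9, abs=0.02)


class TestOeEnrichment:
    def test_null_oe_near_one(self, tenpct_feature):
        """Mean observed count over 50 independent null DMR draws, against a
        1000-iteration shuffle expectation, stays within 10% of expected."""
        fmap = single_feature_map(tenpct_feature)
        rng = np.random.default_rng(11)
        obs = []
        expected = None
        for r in range(50):
            dmrs = list(zip(*shuffle_intervals([("chr1", 0, 100)] * 200, SIZES, rng)))
            if expected is None:
                res = oe_enrichment(dmrs, fmap, n_iter=1000, rng=np.random.default_rng(12))
                expected = res["promoter"].expected_mean
            obs.append(tenpct_feature.count_overlapping(*map(np.asarray, zip(*dmrs))))
        oe_null = float(np.mean(obs)) / expected
        assert 0.9 <= oe_null <= 1.1

    def test_planted_enrichment(self, tenpct_feature):
        rng = np.random.default_rng(21)
        starts = rng.integers(0, 100, 200) * 10_000 + rng.integers(0, 900, 200)
        planted = [("chr1", int(s), int(s) + 100) for s in starts]
        res = oe_enrichment(planted, single_feature_map(tenpct_feature), n_iter=1000,
                            rng=np.random.default_rng(22))
        r = res["promoter"]
        assert r.oe_ratio == pytest.approx(10.0, rel=0.15)
        assert r.empirical_p == pytest.approx(1 / 1001, abs=1e-12)

    def test_observed_matches_annotate_intervals(self, small_refset, small_groups):
        from methdiverge.dmrcall import call_dmrs
        from methdiverge.features import build_feature_map, predict_cgi

        fmap = build_feature_map(
            small_refset.genes, predict_cgi(small_refset.contigs), small_refset.tes,
            small_refset.contig_sizes,
        )
        dmrs = call_dmrs(*small_groups)
        res = oe_enrichment(dmrs, fmap, n_iter=100, seed=0)
        _, counts = annotate_intervals([(d.contig, d.start, d.end) for d in dmrs], fmap)
        for name, r in res.items():
            assert r.observed == counts[name]

    def test_empty_dmrs_error(self, tenpct_feature):
        with pytest.raises(ValueError, match="empty DMR set"):
            oe_enrichment([], single_feature_map(tenpct_feature), n_iter=100, seed=0)

    def test_too_few_iterations(self, tenpct_feature):
        with pytest.raises(ValueError):
            oe_enrichment([("chr1", 0, 100)], single_feature_map(tenpct_feature), n_iter=10, seed=0)


class TestTeFamilyEnrichment:
    def tes(self):
        out = [TeInterval("chr1", 1000 + i * 10_000, 1400 + i * 10_000, "hAT6", "DNA/hAT", 4.0) for i in range(40)]
        out += [TeInterval("chr1", 5000 + i * 10_000, 5400 + i * 10_000, "Gypsy", "LTR/Gypsy", 25.0) for i in range(40)]
        return out

    def test_planted_family_enriched_avoided_family_depleted(self):
        tes = self.tes()
        dmrs = [("chr1", t.start + 50, t.start + 250) for t in tes if t.family == "hAT6"]
        filtered, full = te_family_enrichment(dmrs, tes, SIZES, n_iter=200, seed=1)
        assert "hAT6" in filtered and full["hAT6"].oe_ratio > 2
        # the untouched family is actively avoided here: O/E = 0 <= 0.5,
        # retained by the depletion side of the display rule
        assert full["Gypsy"].observed == 0
        assert "Gypsy" in filtered and filtered["Gypsy"].oe_ratio <= 0.5

    def test_random_dmrs_all_filtered_out(self):
        tes = self.tes()
        dmrs = list(zip(*shuffle_intervals([("chr1", 0, 200)] * 400, SIZES, np.random.default_rng(8))))
        filtered, full = te_family_enrichment(dmrs, tes, SIZES, n_iter=300, seed=2)
        assert all(0.5 < r.oe_ratio < 2.0 for r in full.values())  # O/E ~ 1
        assert filtered == {}

    def test_min_ratio_one_keeps_everything(self):
        tes = self.tes()
        dmrs = [("chr1", 1050, 1250)]
        filtered, full = te_family_enrichment(dmrs, tes, SIZES, n_iter=200, seed=1, min_abs_ratio=1.0)
        assert set(filtered) == set(full)

    def test_absent_family_absent_from_output(self):
        _, full = te_family_enrichment([("chr1", 0, 100)], self.tes(), SIZES, n_iter=200, seed=1)
        assert set(full) == {"hAT6", "Gypsy"}


class TestTeDivergence:
    def test_young_tes_under_dmrs(self, rng):
        young = [TeInterval("chr1", i * 20_000, i * 20_000 + 500, "hAT6", "DNA/hAT", float(max(0, rng.normal(5, 1.5)))) for i in range(25)]
        old = [TeInterval("chr1", 10_000 + i * 20_000, 10_000 + i * 20_000 + 500, "Gypsy", "LTR/Gypsy", float(rng.normal(25, 4))) for i in range(25)]
        dmrs = [("chr1", t.start + 100, t.start + 300) for t in young]
        prof = te_divergence_profile(dmrs, young + old, SIZES, n_shuffles=100, seed=2)
        med = prof.medians()
        assert med["inside"] < med["outside"]
        assert prof.omnibus.p_value < 1e-6

    def test_uniform_dmrs_match_shuffle(self, rng):
        tes = [TeInterval("chr1", int(p), int(p) + 400, "f", "c", float(rng.uniform(0, 30)))
               for p in rng.integers(0, 990_000, 120)]
        dmrs = list(zip(*shuffle_intervals([("chr1", 0, 300)] * 60, SIZES, np.random.default_rng(9))))
        prof = te_divergence_profile(dmrs, tes, SIZES, n_shuffles=200, seed=10)
        med = prof.medians()
        assert abs(med["inside"] - med["shuffled"]) < 6.0  # same distribution up to MC noise

    def test_degenerate_single_te(self):
        with pytest.raises(ValueError):
            te_divergence_profile([("chr1", 0, 100)], [TeInterval("chr1", 0, 100, "f", "c", 1.0)], SIZES, n_shuffles=10, seed=0)
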