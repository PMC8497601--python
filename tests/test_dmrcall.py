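"""Per-CpG testing, DMR segmentation thresholds, and classification."""

import numpy as np
import pytest

from methdiverge.dmrcall import (
    ClassifiedDmr,
    Dmr,
    DmrParams,
    call_dmrs,
    classify_species_dmrs,
    classify_tissue_scope,
    percpg_test,
)

from conftest import uniform_group


class TestPerCpgTest:
    def test_identical_groups(self):
        diff, p = percpg_test([(5, 10), (5, 10)], [(5, 10), (5, 10)])
        assert diff == 0.0
        assert p == pytest.approx(1.0)

    def test_fisher_fallback_exact_value(self):
        # 10/10 vs 0/10 single replicate: two-sided Fisher p = 2 / C(20,10)
        diff, p = percpg_test([(10, 10)], [(0, 10)])
        assert diff == pytest.approx(1.0)
        assert p == pytest.approx(2 / 184756, rel=1e-12)

    def test_all_zero_coverage_error(self):
        with pytest.raises(ValueError, match="coverage"):
            percpg_test([(0, 0)], [(1, 10)])

    def test_strong_difference_significant(self):
        _, p = percpg_test([(28, 30), (29, 30)], [(3, 30), (2, 30)])
        assert p < 1e-6


class TestThresholdEnforcement:
    """Constructed candidate regions violating exactly one criterion."""

    def call(self, positions, meth_a, meth_b, cov=60):
        n = len(positions)
        a = uniform_group(positions, [meth_a] * n, [cov] * n, species="spA")
        b = uniform_group(positions, [meth_b] * n, [cov] * n, species="spB", start_rep=3)
        return call_dmrs(a, b, DmrParams())

    def test_all_pass_accepted(self):
        positions = [0, 20, 40, 60, 80, 100]
        dmrs = self.call(positions, 55, 5)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.length >= 50 and d.n_cpgs >= 4 and abs(d.mean_diff) >= 0.25

    def test_too_short_rejected(self):
        # 5 strong CpGs spanning only 42 bp (< 50)
        assert self.call([0, 10, 20, 30, 40], 55, 5) == []

    def test_too_few_cpgs_rejected(self):
        # 3 strong CpGs over 102 bp (>= 50 bp but < 4 CpG)
        assert self.call([0, 50, 100], 55, 5) == []

    def test_small_difference_rejected(self):
        # individually significant at high coverage but only 20% difference
        assert self.call([0, 20, 40, 60, 80, 100], 30, 18, cov=300) == []

    def test_nonsignificant_rejected(self):
        assert self.call([0, 20, 40, 60, 80, 100], 30, 30) == []

    def test_gap_rule_splits_chains(self):
        # two clusters 150 bp apart (> max_gap=100) -> two separate DMRs
        positions = [0, 20, 40, 60, 80, 100, 250, 270, 290, 310, 330, 350]
        dmrs = self.call(positions, 55, 5)
        assert len(dmrs) == 2


class TestCallDmrsOnSynthetic:
    def test_planted_region_recovered(self, small_refset, small_groups):
        a, b = small_groups
        dmrs = call_dmrs(a, b)
        hits = 0
        for t in small_refset.dmr_truth:
            for d in dmrs:
                ov = max(0, min(d.end, t.end) - max(d.start, t.start)) if d.contig == t.contig else 0
                if ov >= 0.5 * (d.end - d.start) and ov >= 0.5 * (t.end - t.start):
                    hits += 1
                    break
        assert hits >= 0.9 * len(small_refset.dmr_truth)

    def test_output_sorted_disjoint_and_thresholded(self, small_groups):
        a, b = small_groups
        params = DmrParams()
        dmrs = call_dmrs(a, b, params)
        for prev, cur in zip(dmrs, dmrs[1:]):
            if prev.contig == cur.contig:
                assert cur.start >= prev.end
        for d in dmrs:
            assert d.length >= params.min_length
            assert d.n_cpgs >= params.min_cpgs
            assert abs(d.mean_diff) >= params.min_diff
            assert 0 <= d.region_p <= 1

    def test_groups_must_be_disjoint(self, small_groups):
        a, b = small_groups
        with pytest.raises(ValueError, match="disjoint"):
            call_dmrs(a, a)


def dmr(start, end, diff, comparison, contig="c1"):
    return Dmr(contig, start, end, 10, diff, 1e-4, comparison)


class TestClassifySpecies:
    TRIPLE = ("A", "B", "C")

    def test_supported_in_both_comparisons(self):
        pw = {
            ("A", "B"): [dmr(100, 400, 0.5, ("A", "B"))],
            ("A", "C"): [dmr(150, 450, 0.4, ("A", "C"))],
            ("B", "C"): [],
        }
        out = classify_species_dmrs(pw, self.TRIPLE)
        assert len(out) == 1
        r = out[0]
        assert r.focal_species == "A" and r.direction == 1
        assert (r.start, r.end) == (100, 450)  # coordinate union

    def test_single_comparison_unassigned(self):
        pw = {("A", "B"): [dmr(100, 400, 0.5, ("A", "B"))], ("A", "C"): [], ("B", "C"): []}
        assert classify_species_dmrs(pw, self.TRIPLE) == []

    def test_direction_conflict_unassigned(self):
        pw = {
            ("A", "B"): [dmr(100, 400, 0.5, ("A", "B"))],
            ("A", "C"): [dmr(150, 450, -0.4, ("A", "C"))],
            ("B", "C"): [],
        }
        assert classify_species_dmrs(pw, self.TRIPLE) == []

    def test_veto_by_other_pair(self):
        pw = {
            ("A", "B"): [dmr(100, 400, 0.5, ("A", "B"))],
            ("A", "C"): [dmr(150, 450, 0.4, ("A", "C"))],
            ("B", "C"): [dmr(300, 500, 0.3, ("B", "C"))],
        }
        assert classify_species_dmrs(pw, self.TRIPLE) == []

    def test_symmetric_under_nonfocal_relabelling(self):
        pw = {
            ("A", "B"): [dmr(100, 400, 0.5, ("A", "B"))],
            ("A", "C"): [dmr(150, 450, 0.4, ("A", "C"))],
            ("B", "C"): [],
        }
        swapped = {
            ("A", "C"): [dmr(100, 400, 0.5, ("A", "C"))],
            ("A", "B"): [dmr(150, 450, 0.4, ("A", "B"))],
            ("C", "B"): [],
        }
        a = classify_species_dmrs(pw, self.TRIPLE)
        b = classify_species_dmrs(swapped, ("A", "C", "B"))
        assert [(r.focal_species, r.start, r.end, r.direction) for r in a] == [
            (r.focal_species, r.start, r.end, r.direction) for r in b
        ]

    def test_missing_pair_error(self):
        with pytest.raises(ValueError, match="missing pairwise"):
            classify_species_dmrs({("A", "B"): []}, self.TRIPLE)

    def test_flipped_orientation_direction(self):
        # hypo in A reported from the (B, A) orientation as hyper in B
        pw = {
            ("B", "A"): [dmr(100, 400, 0.5, ("B", "A"))],
            ("A", "C"): [dmr(150, 450, -0.4, ("A", "C"))],
            ("B", "C"): [],
        }
        out = classify_species_dmrs(pw, self.TRIPLE)
        assert len(out) == 1 and out[0].focal_species == "A" and out[0].direction == -1


class TestTissueScope:
    def cd(self, start, end, species="A", direction=1, tissue="liver"):
        return ClassifiedDmr("c1", start, end, species, direction, tissue)

    def test_overlap_same_direction_is_multi(self):
        records, table = classify_tissue_scope([self.cd(100, 400)], [self.cd(300, 600, tissue="muscle")])
        assert len(records) == 1
        r = records[0]
        assert r.tissue_scope == "multi_tissue" and (r.start, r.end) == (100, 600)
        assert table.loc["A", "multi_tissue"] == 1.0

    def test_unmatched_stay_tissue_specific(self):
        records, table = classify_tissue_scope(
            [self.cd(100, 400)], [self.cd(5000, 5400, tissue="muscle")]
        )
        scopes = sorted(r.tissue_scope for r in records)
        assert scopes == ["liver_specific", "muscle_specific"]
        assert table.loc["A"].sum() == pytest.approx(1.0)

    def test_direction_mismatch_not_merged(self):
        records, _ = classify_tissue_scope(
            [self.cd(100, 400, direction=1)], [self.cd(300, 600, direction=-1, tissue="muscle")]
        )
        assert sorted(r.tissue_scope for r in records) == ["liver_specific", "muscle_specific"]

    def test_disjoint_species_error(self):
        with pytest.raises(ValueError, match="common"):
            classify_tissue_scope([self.cd(0, 10, "A")], [self.cd(0, 10, "B")])

    def test_proportions_sum_to_one_per_species(self):
        liver = [self.cd(100, 400, "A"), self.cd(1000, 1300, "A"), self.cd(2000, 2300, "B")]
        muscle = [self.cd(200, 500, "A", tissue="muscle")]
        _, table = classify_tissue_scope(liver, muscle)
        assert np.allclose(table.sum(axis=1), 1.0)
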