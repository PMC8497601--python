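"""DMR-gene assignment, DEG filtering, pfDMR test, binning, clustering."""

import numpy as np
import pandas as pd
import pytest

from methdiverge.dmrcall import Dmr
from methdiverge.features import GeneModel, build_feature_map
from methdiverge.integration import (
    ExpressionMatrix,
    assign_dmr_to_gene,
    bin_and_correlate,
    cluster_methylomes,
    filter_degs,
    pfdmr_overlap_test,
)

from conftest import make_sample


def mkdmr(start, end, contig="c"):
    return Dmr(contig, start, end, 6, 0.4, 1e-3, ("A", "B"))


@pytest.fixture
def gene_map():
    # '+' gene: extent [10000, 16001), promoter [9500, 10500), body [10500, 16001)
    genes = [GeneModel("g1", "c", "+", 10_000, 16_000), GeneModel("g2", "c", "+", 40_000, 44_000)]
    return build_feature_map(genes, [], [], {"c": 100_000})


class TestAssignDmrToGene:
    def test_promoter_assignment(self, gene_map):
        out = assign_dmr_to_gene([mkdmr(9_600, 9_900)], gene_map)
        assert [(a.gene_id, a.location_class) for a in out] == [("g1", "promoter")]

    def test_promoter_takes_precedence_over_body(self, gene_map):
        out = assign_dmr_to_gene([mkdmr(10_400, 11_000)], gene_map)
        assert out[0].location_class == "promoter"

    def test_gene_body(self, gene_map):
        out = assign_dmr_to_gene([mkdmr(12_000, 12_400)], gene_map)
        assert out[0].location_class == "gene_body"

    def test_vicinity_two_kb_upstream(self, gene_map):
        # 2 kb from the gene extent, beyond the 500-bp promoter flank
        out = assign_dmr_to_gene([mkdmr(18_001, 18_200)], gene_map)
        assert out[0].location_class == "vicinity_0.5_4kb" and out[0].gene_id == "g1"

    def test_beyond_four_kb_unassigned(self, gene_map):
        assert assign_dmr_to_gene([mkdmr(25_000, 25_200)], gene_map) == []

    def test_downstream_within_buffer_unassigned(self, gene_map):
        # 400 bp past the gene end: not promoter/body, gap <= 500 so not vicinity
        assert assign_dmr_to_gene([mkdmr(16_401, 16_500)], gene_map) == []

    def test_nearest_gene_wins_vicinity_tie(self, gene_map):
        # between the genes: 3 kb past g1's extent, ~3.2 kb before g2
        out = assign_dmr_to_gene([mkdmr(19_100, 19_300)], gene_map)
        assert out[0].gene_id == "g1"


def expression_fixture():
    tpm = pd.DataFrame(
        {
            "A_r1": [100.0, 100, 100, 0.0],
            "A_r2": [110.0, 90, 100, 0.0],
            "B_r1": [40.0, 55, 100, 0.0],
            "B_r2": [40.0, 65, 100, 0.0],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["A_r1", "A_r2", "B_r1", "B_r2"],
            "species": ["A", "A", "B", "B"],
            "tissue": ["liver"] * 4,
            "replicate": [1, 2, 1, 2],
        }
    )
    return ExpressionMatrix(tpm, meta)


class TestFilterDegs:
    def de(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "q_value"])

    def test_both_thresholds_enforced(self):
        expr = expression_fixture()
        # g1: diff 65 TPM; g2: diff 40; g3: diff 0
        kept = filter_degs(self.de([("g1", 0.005), ("g2", 0.005), ("g3", 0.005)]), expr)
        assert [d.gene_id for d in kept] == ["g1"]

    def test_q_threshold(self):
        expr = expression_fixture()
        kept = filter_degs(self.de([("g1", 0.02)]), expr)
        assert kept == []

    def test_missing_gene_error(self):
        with pytest.raises(ValueError, match="absent"):
            filter_degs(self.de([("nope", 0.001)]), expression_fixture())


class TestPfdmrOverlap:
    def test_saturation_p_one(self):
        from methdiverge.integration import DegRecord, PfDmr

        universe = {f"g{i}" for i in range(10)}
        degs = [DegRecord(g, 0.001, 100.0) for g in universe]
        assigned = [PfDmr(mkdmr(0, 100), g, "promoter") for g in universe]
        pf, res, _ = pfdmr_overlap_test(assigned, degs, universe)
        assert res.p_value == 1.0
        assert len(pf) == 10

    def test_worked_hypergeometric_case(self):
        from methdiverge.integration import DegRecord, PfDmr

        universe = {f"g{i}" for i in range(20)}
        degs = [DegRecord(f"g{i}", 0.001, 100.0) for i in range(5)]  # K = 5
        assigned = [PfDmr(mkdmr(0, 100), g, "promoter") for g in ["g0", "g1", "g7", "g8"]]  # n=4, k=2
        _, res, _ = pfdmr_overlap_test(assigned, degs, universe)
        assert res.p_value == pytest.approx(1205 / 4845, abs=1e-12)

    def test_empty_universe_error(self):
        with pytest.raises(ValueError):
            pfdmr_overlap_test([], [], set())


class TestBinAndCorrelate:
    def build(self, n=60, coupling=-1.0, off=4, seed=0):
        """Gene set with promoter methylation anti-monotone to expression."""
        rng = np.random.default_rng(seed)
        genes, rows_meth = [], []
        meth_levels = {}
        for i in range(n):
            tss = 10_000 + i * 1_500
            genes.append(GeneModel(f"g{i:03d}", "c", "+", tss, tss + 900))
            level = (i + 1) / (n + 1)
            meth_levels[f"g{i:03d}"] = level
            for pos in range(tss - 400, tss + 400, 40):  # CpGs across the promoter
                m = int(round(level * 50))
                rows_meth.append(("c", pos, m, 50 - m))
        fmap = build_feature_map(genes, [], [], {"c": 10_000 + n * 1_500 + 10_000})
        sample = make_sample(rows_meth, "A_r1", "A", "liver", 1)
        tpm_vals = []
        for i in range(n):
            if i < off:
                tpm_vals.append(0.0)
            else:
                tpm_vals.append(float(2 ** (8 + coupling * 6 * meth_levels[f"g{i:03d}"])))
        tpm = pd.DataFrame({"A_r1": tpm_vals}, index=pd.Index([g.gene_id for g in genes], name="gene_id"))
        meta = pd.DataFrame({"sample_id": ["A_r1"], "species": ["A"], "tissue": ["liver"], "replicate": [1]})
        return ExpressionMatrix(tpm, meta), [sample], fmap

    def test_off_bin_contains_exactly_zero_tpm_genes(self):
        expr, samples, fmap = self.build()
        e_prof, m_prof, _ = bin_and_correlate(expr, samples, fmap, "A", "liver")
        assert sorted(e_prof.bins["OFF"]) == [f"g{i:03d}" for i in range(4)]

    def test_expressed_bins_balanced_and_partition(self):
        expr, samples, fmap = self.build()
        e_prof, _, _ = bin_and_correlate(expr, samples, fmap, "A", "liver")
        sizes = [len(v) for k, v in e_prof.bins.items() if k != "OFF"]
        assert max(sizes) - min(sizes) <= 1
        all_genes = [g for v in e_prof.bins.values() for g in v]
        assert len(all_genes) == len(set(all_genes)) == 60

    def test_perfect_anti_monotone_rho(self):
        expr, samples, fmap = self.build(off=0)
        _, _, tests = bin_and_correlate(expr, samples, fmap, "A", "liver")
        assert tests["promoter"].statistic == pytest.approx(-1.0, abs=0.02)

    def test_methylation_bins_partition(self):
        expr, samples, fmap = self.build()
        _, m_prof, _ = bin_and_correlate(expr, samples, fmap, "A", "liver")
        total = sum(len(v) for v in m_prof.bins.values())
        assert total == 60

    def test_too_few_genes_error(self):
        expr, samples, fmap = self.build(n=10)
        with pytest.raises(ValueError, match="genes"):
            bin_and_correlate(expr, samples, fmap, "A", "liver")


class TestClusterMethylomes:
    def test_identical_samples_correlation_one(self, rng):
        base = rng.uniform(size=200)
        mat = pd.DataFrame({"a": base, "b": base, "c": rng.uniform(size=200)})
        res = cluster_methylomes(mat)
        assert res.correlation.loc["a", "b"] == pytest.approx(1.0)

    def test_leaf_count_and_newick(self, rng):
        mat = pd.DataFrame(rng.uniform(size=(300, 5)), columns=list("abcde"))
        res = cluster_methylomes(mat)
        assert len(res.sample_ids) == 5
        assert res.newick.endswith(";") and res.newick.count(",") == 4

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError):
            cluster_methylomes(pd.DataFrame(rng.uniform(size=(10, 2)), columns=["a", "b"]))

    def test_planted_structure_recovered(self, small_refset, small_samples):
        """Replicates of one species pair together on the tree."""
        from methdiverge.methio import conserved_cpg_matrix

        mat = conserved_cpg_matrix(small_samples, small_refset.snps)
        res = cluster_methylomes(mat)
        cl = res.clusters(2)
        species_of = {s.sample_id: s.species for s in small_samples}
        for label in (1, 2):
            members = {species_of[s] for s, c in cl.items() if c == label}
            assert len(members) == 1
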