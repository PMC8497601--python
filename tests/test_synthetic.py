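"""Generator contracts: determinism, conservation, distributional checks."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from methdiverge import synthetic
from methdiverge.stats import kruskal_dunn, spearman_rho
from methdiverge.synthetic import SimulationDesign, generate_reference_set, simulate_expression, simulate_methylomes


def tiny(**kw):
    base = dict(
        seed=3, n_contigs=1, contig_length=300_000, n_species=2, n_tissues=1,
        n_replicates=2, n_dmrs=8, n_genes=12, n_tes=40, n_cgis=8, species_effect=0.0,
    )
    base.update(kw)
    return SimulationDesign(**base)


class TestDesignValidation:
    @pytest.mark.parametrize(
        "field,value",
        [
            ("background_meth", 1.5),
            ("dispersion", 1.0),
            ("dmr_delta", 0.0),
            ("n_contigs", 0),
            ("dmr_length_range", (800, 300)),
        ],
    )
    def test_invalid_fields_rejected(self, field, value):
        with pytest.raises(ValueError):
            tiny(**{field: value})

    def test_infeasible_placement_names_constraint(self):
        with pytest.raises(ValueError, match="infeasible placement"):
            generate_reference_set(tiny(contig_length=100_000, n_genes=20, n_dmrs=30))


class TestReferenceSet:
    def test_forced_counts(self, small_design, small_refset):
        assert len(small_refset.contigs) == small_design.n_contigs
        assert all(len(s) == small_design.contig_length for s in small_refset.contigs.values())
        assert len(small_refset.tes) == small_design.n_tes
        assert len(small_refset.genes) == small_design.n_genes
        assert len(small_refset.dmr_truth) == small_design.n_dmrs

    def test_truth_counts_match_design(self, small_design, small_refset):
        kinds = {}
        for t in small_refset.truth:
            kinds[t.kind] = kinds.get(t.kind, 0) + 1
        assert kinds["dmr"] == small_design.n_dmrs
        assert kinds["te"] == small_design.n_tes
        assert kinds["cgi"] == small_design.n_cgis
        assert kinds["gene"] == small_design.n_genes

    def test_truth_within_bounds_and_dmrs_disjoint(self, small_refset):
        sizes = small_refset.contig_sizes
        for t in small_refset.truth:
            assert 0 <= t.start < t.end <= sizes[t.contig]
        by_contig = {}
        for t in small_refset.dmr_truth:
            by_contig.setdefault(t.contig, []).append((t.start, t.end))
        for spans in by_contig.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_cpg_density_above_floor(self, small_refset):
        total = sum(len(p) for p in small_refset.cpg_positions.values())
        genome = sum(small_refset.contig_sizes.values())
        assert total / genome >= 0.01  # at least one CpG per 100 bp

    def test_snp_mixture_and_ref_alleles(self, small_design, small_refset):
        per_species = {}
        for s in small_refset.snps:
            assert small_refset.contigs[s.contig][s.position - 1] == s.ref_allele
            per_species.setdefault(s.species, []).append(s)
        for sp, snps in per_species.items():
            assert len(snps) == small_design.n_snps_per_species
            n_bis = sum(1 for s in snps if (s.ref_allele, s.alt_allele) in (("C", "T"), ("G", "A")))
            assert n_bis == round(small_design.frac_bisulfite_snps * small_design.n_snps_per_species)

    def test_deterministic_output_files(self, tmp_path):
        d = tiny()
        h = []
        for sub in ("a", "b"):
            synthetic.write_dataset(d, tmp_path / sub)
            h.append(
                {
                    f.name: hashlib.sha256(f.read_bytes()).hexdigest()
                    for f in sorted((tmp_path / sub).rglob("*"))
                    if f.is_file()
                }
            )
        assert h[0] == h[1]


class TestMethylomes:
    def test_sample_count(self):
        d = tiny(n_species=3, n_tissues=2, n_replicates=2, n_dmrs=6)
        sims = simulate_methylomes(d, generate_reference_set(d), build_reports=False)
        assert len(sims) == 12

    def test_count_conservation(self, small_methylomes):
        sm = small_methylomes[0]
        rep = sm.report
        cg = rep[(rep["context"] == "CG") & (rep["contig"] != "lambda_spike")]
        for contig, (pos, m, cov) in sm.counts.items():
            sub = cg[cg["contig"] == contig]
            assert sub["count_methylated"].sum() == m.sum()
            assert (sub["count_methylated"] + sub["count_unmethylated"]).sum() == cov.sum()

    def test_planted_hyper_dmr_reaches_target_level(self):
        # hyper-DMR with delta 0.5 on background 0.3: target species ~0.8
        d = tiny(seed=5, background_meth=0.3, dmr_delta=0.5, n_dmrs=6, tissue_effect=0.0)
        ref = generate_reference_set(d)
        sims = simulate_methylomes(d, ref, build_reports=False)
        checked = 0
        for t in ref.dmr_truth:
            if "gene_id" in t.attributes or t.attributes["delta"] < 0:
                continue
            target = t.attributes["species"]
            for sm in sims:
                if sm.species != target:
                    continue
                pos, m, cov = sm.counts[t.contig]
                sel = (pos >= t.start) & (pos < t.end)
                if sel.sum() < 4 or cov[sel].sum() == 0:
                    continue
                level = m[sel].sum() / cov[sel].sum()
                se = np.sqrt(0.8 * 0.2 * 1.7 / cov[sel].sum())
                assert level == pytest.approx(0.8, abs=max(4 * se, 0.06))
                checked += 1
        assert checked >= 4

    def test_zero_dispersion_variance_is_binomial(self):
        d = tiny(seed=9, dispersion=0.0, n_dmrs=0, n_genes=0, n_tes=0, n_cgis=0,
                 frac_promoter_dmrs=0.0, tissue_effect=0.0, background_meth=0.6,
                 n_replicates=4)
        ref = generate_reference_set(d)
        sims = simulate_methylomes(d, ref, build_reports=False)
        p = 0.6 + (1 - 0.6) * d.nonconversion_rate
        z2 = []
        for sm in sims:
            pos, m, cov = sm.counts["chr1"]
            ok = cov > 0
            z2.append(((m[ok] - cov[ok] * p) / np.sqrt(cov[ok] * p * (1 - p))) ** 2)
        mean_z2 = float(np.mean(np.concatenate(z2)))
        n = sum(len(v) for v in z2)
        assert mean_z2 == pytest.approx(1.0, abs=4 * np.sqrt(2.0 / n))

    def test_overdispersion_inflates_variance(self):
        d = tiny(seed=9, dispersion=0.1, n_dmrs=0, n_genes=0, n_tes=0, n_cgis=0,
                 frac_promoter_dmrs=0.0, tissue_effect=0.0, background_meth=0.6)
        ref = generate_reference_set(d)
        sims = simulate_methylomes(d, ref, build_reports=False)
        p = 0.6 + 0.4 * d.nonconversion_rate
        z2 = []
        for sm in sims:
            pos, m, cov = sm.counts["chr1"]
            ok = cov > 0
            z2.append(((m[ok] - cov[ok] * p) / np.sqrt(cov[ok] * p * (1 - p))) ** 2)
        assert float(np.mean(np.concatenate(z2))) > 1.5  # ~1 + (n-1) phi


class TestExpression:
    def test_exact_off_count(self):
        d = tiny(seed=11, n_genes=20, off_fraction=0.2, frac_promoter_dmrs=0.0, n_dmrs=4)
        ref = generate_reference_set(d)
        expr = simulate_expression(d, ref)
        all_zero = (expr.tpm == 0).all(axis=1)
        assert int(all_zero.sum()) == 4  # round(0.2 * 20)
        truth_off = {t.attributes["gene_id"] for t in expr.truth if t.attributes["off"]}
        assert set(expr.tpm.index[all_zero]) == truth_off

    def test_zero_coupling_no_expression_shift(self):
        d = tiny(seed=13, n_contigs=2, contig_length=400_000, n_genes=60, n_dmrs=20,
                 frac_promoter_dmrs=0.5, expr_coupling=0.0, genebody_coupling=0.0,
                 off_fraction=0.0)
        ref = generate_reference_set(d)
        expr = simulate_expression(d, ref)
        coupled = {t.attributes["gene_id"] for t in ref.truth if t.kind == "coupling"}
        log_tpm = np.log2(expr.tpm.mean(axis=1) + 1)
        a = [log_tpm[g] for g in expr.tpm.index if g in coupled]
        b = [log_tpm[g] for g in expr.tpm.index if g not in coupled]
        om, _ = kruskal_dunn([a, b])
        assert om.p_value > 0.01

    def test_negative_coupling_sign_recovered(self):
        d = tiny(seed=17, n_contigs=2, contig_length=400_000, n_genes=60, n_dmrs=0,
                 frac_promoter_dmrs=0.0, expr_coupling=-3.0, off_fraction=0.0)
        ref = generate_reference_set(d)
        expr = simulate_expression(d, ref)
        prom = np.array([ref.gene_prom_meth[g] for g in expr.tpm.index])
        tpm = expr.tpm.mean(axis=1).values
        r = spearman_rho(prom, tpm)
        assert r.statistic < 0 and r.p_value < 0.01

    def test_no_genes_error(self):
        d = tiny(n_genes=0, n_dmrs=0, frac_promoter_dmrs=0.0, n_cgis=0)
        ref = generate_reference_set(d)
        with pytest.raises(ValueError, match="no genes"):
            simulate_expression(d, ref)
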