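"""End-to-end orchestration from one YAML config.

Stage order: SNP-corrected references -> methylome loading -> DMR calling
(all species pairs per tissue) -> species/tissue classification ->
annotation universe -> permutation enrichment -> expression integration
and methylome clustering.  Every output file lands in the run directory
and is listed, with SHA-256 hashes of inputs and outputs plus all seeds,
in ``manifest.json``; re-running the same config reproduces identical
hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bsref, dmrcall, enrichment, features, integration, methio
from .synthetic import SPIKE_CONTIG

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    data_dir: str
    out_dir: str
    seed: int = 0
    species: list[str] = dataclasses.field(default_factory=list)
    tissues: list[str] = dataclasses.field(default_factory=list)
    min_coverage: int = methio.DEFAULT_MIN_COVERAGE
    max_coverage: int = methio.DEFAULT_MAX_COVERAGE
    dmr: dict = dataclasses.field(default_factory=dict)
    enrichment_iterations: int = 1000
    te_divergence_shuffles: int = 500
    genome: str = "genome.fa"
    snps: str = "snps.vcf"
    genes: str = "genes.tsv"
    tes: str = "tes.tsv"
    expression: str = "expression_tpm.tsv"
    de_table: str = "de_table.tsv"
    samples: str = "samples.tsv"
    reports_dir: str = "reports"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def input_path(self, name: str) -> Path:
        p = Path(self.data_dir) / getattr(self, name)
        if not p.exists():
            raise FileNotFoundError(f"missing input: {p}")
        return p


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {
        name: config.input_path(name)
        for name in ("genome", "snps", "genes", "tes", "expression", "de_table", "samples")
    }
    reports_dir = Path(config.data_dir) / config.reports_dir
    if not reports_dir.is_dir():
        raise FileNotFoundError(f"missing input: {reports_dir}")
    outputs: dict[str, Path] = {}

    genome = bsref.read_fasta(inputs["genome"])
    meta = pd.read_csv(inputs["samples"], sep="\t")
    species = config.species or sorted(meta["species"].unique())
    tissues = config.tissues or sorted(meta["tissue"].unique())

    # stage 1: SNP-corrected reference per species
    for sp in species:
        snps = bsref.read_snps_vcf(inputs["snps"], species=sp)
        corrected, report = bsref.build_snp_corrected_reference(genome, snps, sp)
        fa = out / f"reference_{sp}.fa"
        bsref.write_fasta(corrected, fa)
        rp = out / f"reference_{sp}_substitutions.tsv"
        bsref.write_substitution_report(report, rp)
        outputs[f"reference_{sp}"] = fa
        outputs[f"reference_{sp}_report"] = rp
    all_snps = bsref.read_snps_vcf(inputs["snps"], species=None)

    # stage 2: methylomes, window tracks, non-conversion estimates
    samples: list[methio.MethylomeSample] = []
    nonconv = {}
    for row in meta.itertuples():
        path = reports_dir / f"{row.sample_id}.CpG_report.txt"
        if not path.exists():
            raise FileNotFoundError(f"missing cytosine report: {path}")
        s = methio.load_methylome(
            path,
            sample_id=row.sample_id,
            species=row.species,
            tissue=row.tissue,
            replicate=int(row.replicate),
            min_coverage=config.min_coverage,
            max_coverage=config.max_coverage,
        )
        samples.append(s)
        try:
            nonconv[row.sample_id] = methio.estimate_nonconversion(path, SPIKE_CONTIG)
        except ValueError:
            nonconv[row.sample_id] = None
    track = methio.window_methylation(samples[0], window=50)
    bg = out / f"{samples[0].sample_id}_mCG_50bp.bedGraph"
    track.to_bedgraph(bg)
    outputs["window_track_example"] = bg
    with open(out / "nonconversion.tsv", "w") as fh:
        fh.write("sample_id\tnonconversion_rate\n")
        for sid, rate in nonconv.items():
            fh.write(f"{sid}\t{'NA' if rate is None else f'{rate:.6g}'}\n")
    outputs["nonconversion"] = out / "nonconversion.tsv"

    def group(sp: str, ti: str) -> list[methio.MethylomeSample]:
        return [s for s in samples if s.species == sp and s.tissue == ti]

    # stage 3: pairwise DMRs per tissue
    params = dmrcall.DmrParams(**config.dmr)
    pairwise: dict[str, dict[tuple[str, str], list[dmrcall.Dmr]]] = {}
    for ti in tissues:
        pairwise[ti] = {}
        for a, b in itertools.combinations(species, 2):
            ga, gb = group(a, ti), group(b, ti)
            if not ga or not gb:
                continue
            dmrs = dmrcall.call_dmrs(ga, gb, params, comparison=(a, b), tissue=ti)
            pairwise[ti][(a, b)] = dmrs
            bed = out / f"dmrs_{ti}_{a}_vs_{b}.bed"
            dmrcall.write_dmr_bed(dmrs, bed)
            outputs[f"dmrs_{ti}_{a}_vs_{b}"] = bed

    # stage 4: species-specific and multi-tissue classification
    classified: dict[str, list[dmrcall.ClassifiedDmr]] = {}
    if len(species) >= 3:
        triple = tuple(species[:3])
        for ti in tissues:
            if all(pair in pairwise[ti] or pair[::-1] in pairwise[ti] for pair in itertools.combinations(triple, 2)):
                classified[ti] = dmrcall.classify_species_dmrs(pairwise[ti], triple, tissue=ti)
    if len(tissues) >= 2 and tissues[0] in classified and tissues[1] in classified:
        records, proportions = dmrcall.classify_tissue_scope(
            classified[tissues[0]], classified[tissues[1]], (tissues[0], tissues[1])
        )
        proportions.to_csv(out / "tissue_scope_proportions.tsv", sep="\t", index_label="species")
        outputs["tissue_scope_proportions"] = out / "tissue_scope_proportions.tsv"
        with open(out / "classified_dmrs.tsv", "w") as fh:
            fh.write("contig\tstart\tend\tspecies\tdirection\ttissue\ttissue_scope\n")
            for r in records:
                fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.focal_species}\t{r.direction}\t{r.tissue}\t{r.tissue_scope}\n")
        outputs["classified_dmrs"] = out / "classified_dmrs.tsv"

    # stage 5: annotation universe
    genes = features.read_gene_table(inputs["genes"])
    tes = features.parse_repeatmasker_out(inputs["tes"])
    cgis = features.predict_cgi(genome)
    contig_sizes = {name: len(seq) for name, seq in genome.items()}
    fmap = features.build_feature_map(genes, cgis, tes, contig_sizes)
    for name, iset in fmap.categories().items():
        bed = out / f"feature_{name}.bed"
        iset.write_bed(bed, name=name)
        outputs[f"feature_{name}"] = bed

    # stage 6: enrichment on the union of liver (first-tissue) DMRs
    ti0 = tissues[0]
    dmrs0 = [d for lst in pairwise.get(ti0, {}).values() for d in lst]
    if dmrs0:
        rng = np.random.default_rng([config.seed, 10])
        oe = enrichment.oe_enrichment(dmrs0, fmap, n_iter=config.enrichment_iterations, rng=rng)
        enrichment.results_to_frame(oe).to_csv(out / f"enrichment_{ti0}.tsv", sep="\t", index=False)
        outputs[f"enrichment_{ti0}"] = out / f"enrichment_{ti0}.tsv"
        _filtered, full = enrichment.te_family_enrichment(
            dmrs0, tes, contig_sizes, n_iter=config.enrichment_iterations,
            rng=np.random.default_rng([config.seed, 11]),
        )
        enrichment.results_to_frame(full).to_csv(out / f"te_family_enrichment_{ti0}.tsv", sep="\t", index=False)
        outputs[f"te_family_enrichment_{ti0}"] = out / f"te_family_enrichment_{ti0}.tsv"
        try:
            prof = enrichment.te_divergence_profile(
                dmrs0, tes, contig_sizes, n_shuffles=config.te_divergence_shuffles,
                rng=np.random.default_rng([config.seed, 12]),
            )
            with open(out / f"te_divergence_{ti0}.tsv", "w") as fh:
                fh.write("group\tmedian\tmean\tn\n")
                med, mean = prof.medians(), prof.means()
                for grp, arr in (("inside", prof.inside), ("outside", prof.outside), ("shuffled", prof.shuffled)):
                    fh.write(f"{grp}\t{med[grp]:.4g}\t{mean[grp]:.4g}\t{len(arr)}\n")
                fh.write(f"# kruskal_H={prof.omnibus.statistic:.4g} p={prof.omnibus.p_value:.3g}\n")
            outputs[f"te_divergence_{ti0}"] = out / f"te_divergence_{ti0}.tsv"
        except ValueError as exc:
            log.warning("TE divergence profile skipped: %s", exc)

    # stage 7: integration
    tpm = pd.read_csv(inputs["expression"], sep="\t", index_col="gene_id")
    expr = integration.ExpressionMatrix(tpm, meta)
    de_table = pd.read_csv(inputs["de_table"], sep="\t")
    if dmrs0:
        assigned = integration.assign_dmr_to_gene(dmrs0, fmap)
        degs = integration.filter_degs(de_table, expr, tissue=ti0)
        pf, test, comp = integration.pfdmr_overlap_test(assigned, degs, set(tpm.index), fmap)
        with open(out / "pfdmr_test.tsv", "w") as fh:
            fh.write("N\tK\tn\tk\tp_value\n")
            e = test.extra
            fh.write(f"{e['N']}\t{e['K']}\t{e['n']}\t{e['k']}\t{test.p_value:.6g}\n")
        comp.to_csv(out / "pfdmr_composition.tsv", sep="\t", index=False)
        outputs["pfdmr_test"] = out / "pfdmr_test.tsv"
        outputs["pfdmr_composition"] = out / "pfdmr_composition.tsv"
    sp0 = species[0]
    try:
        _e, _m, tests = integration.bin_and_correlate(expr, samples, fmap, sp0, ti0)
        with open(out / "meth_expression_correlation.tsv", "w") as fh:
            fh.write("feature\trho\tp_value\tn\n")
            for name, tr in tests.items():
                fh.write(f"{name}\t{tr.statistic:.4f}\t{tr.p_value:.3g}\t{tr.n}\n")
        outputs["meth_expression_correlation"] = out / "meth_expression_correlation.tsv"
    except ValueError as exc:
        log.warning("bin/correlate skipped: %s", exc)
    matrix = methio.conserved_cpg_matrix(samples, all_snps)
    clust = integration.cluster_methylomes(matrix)
    clust.correlation.to_csv(out / "sample_correlation.tsv", sep="\t")
    with open(out / "dendrogram.nwk", "w") as fh:
        fh.write(clust.newick + "\n")
    outputs["sample_correlation"] = out / "sample_correlation.tsv"
    outputs["dendrogram"] = out / "dendrogram.nwk"

    manifest = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
        "outputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in outputs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
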