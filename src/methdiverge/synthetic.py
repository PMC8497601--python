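"""Synthetic multi-species WGBS + RNA-seq dataset with planted truth.

Generates an internally consistent toy dataset — genome, SNPs, genes, TEs,
CpG islands, per-sample cytosine reports and an expression matrix — whose
statistical structure mirrors what the comparative methylome analysis
assumes: a globally methylated vertebrate-like genome (background ~0.8),
mostly unmethylated promoters, highly methylated gene bodies and orphan
CGIs, beta-binomial replicate overdispersion, planted species-specific
DMRs with configurable effect size and tissue scope, young transposons
under DMRs, and a planted promoter-methylation -> expression coupling with
negative sign.  Every planted element is recorded as a TruthRecord so the
downstream callers can be scored against ground truth.

Randomness is fully deterministic in the design seed: the same design
produces byte-identical output files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .bsref import SnpRecord, write_fasta
from .features import GeneModel, IntervalSet, TeInterval
from .methio import MethylomeSample

log = logging.getLogger(__name__)

SPIKE_CONTIG = "lambda_spike"

_TE_FAMILIES = [
    ("hAT6", "DNA/hAT"),
    ("Tc2-Mar", "DNA/TcMar"),
    ("LINE-I", "LINE/I"),
    ("LINE-R2", "LINE/R2"),
    ("SINE-Alu", "SINE/Alu"),
    ("Maverick", "DNA/Maverick"),
    ("Gypsy", "LTR/Gypsy"),
    ("Unknown", "Unknown"),
]

__all__ = [
    "SimulationDesign",
    "TruthRecord",
    "ReferenceSet",
    "SimulatedMethylome",
    "ExpressionData",
    "generate_reference_set",
    "simulate_methylomes",
    "simulate_expression",
    "write_dataset",
]


@dataclass
class SimulationDesign:
    """All knobs of the generator; defaults describe the standard study
    conditions: 3 species x 2 tissues x 2 replicates at ~15x coverage on a
    1-Mb genome with background methylation 0.8, 50 planted DMRs of
    |delta| 0.5, and 45% of species-DMRs shared by both tissues."""

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 500_000
    n_species: int = 3
    n_tissues: int = 2
    n_replicates: int = 2
    mean_coverage: float = 15.0
    dispersion: float = 0.05
    background_meth: float = 0.8
    n_dmrs: int = 50
    dmr_length_range: tuple[int, int] = (300, 800)
    dmr_delta: float = 0.5
    frac_multi_tissue: float = 0.45
    frac_promoter_dmrs: float = 0.25
    n_genes: int = 40
    n_tes: int = 200
    te_young_divergence: float = 5.0
    te_old_divergence: float = 25.0
    te_age_coupling: bool = True
    expr_coupling: float = -3.0  # log2 TPM per unit promoter methylation
    genebody_coupling: float = 2.5
    off_fraction: float = 0.2
    n_cgis: int = 20
    cgi_length_range: tuple[int, int] = (250, 600)
    n_snps_per_species: int = 120
    frac_bisulfite_snps: float = 0.5
    nonconversion_rate: float = 0.002
    spike_contig_length: int = 20_000
    tissue_effect: float = 0.12  # sd of per-1kb-block tissue offsets
    species_effect: float = 0.04  # sd of per-1kb-block species offsets
    gene_length_range: tuple[int, int] = (2_000, 5_000)
    expr_log2_mean: float = 7.0
    expr_log2_sd: float = 1.2
    expr_rep_sd: float = 0.25

    def __post_init__(self):
        for name in ("background_meth", "frac_multi_tissue", "frac_promoter_dmrs", "off_fraction", "frac_bisulfite_snps", "nonconversion_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if not (0.0 <= self.dispersion < 1.0):
            raise ValueError("dispersion must lie in [0, 1)")
        if not (0.0 < self.dmr_delta <= 1.0):
            raise ValueError("dmr_delta must lie in (0, 1]")
        for name in ("n_contigs", "contig_length", "n_species", "n_tissues", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for rng_name in ("dmr_length_range", "cgi_length_range", "gene_length_range"):
            lo, hi = getattr(self, rng_name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"bad {rng_name}: ({lo}, {hi})")

    @property
    def species(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]

    @property
    def tissues(self) -> list[str]:
        base = ["liver", "muscle"]
        return base[: self.n_tissues] + [f"tissue{i + 1:02d}" for i in range(max(0, self.n_tissues - 2))]

    def sample_ids(self) -> list[tuple[str, str, str, int]]:
        out = []
        for sp in self.species:
            for ti in self.tissues:
                for r in range(1, self.n_replicates + 1):
                    out.append((f"{sp}_{ti}_r{r}", sp, ti, r))
        return out


@dataclass
class TruthRecord:
    kind: str  # dmr | te | cgi | gene | coupling
    contig: str
    start: int  # 0-based half-open
    end: int
    attributes: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reference set


def _sample_bases(rng: np.random.Generator, length: int, gc_rich: bool) -> np.ndarray:
    probs = [0.2, 0.3, 0.3, 0.2] if gc_rich else [0.29, 0.21, 0.21, 0.29]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)


def _slot_place(
    rng: np.random.Generator,
    contig_sizes: dict[str, int],
    n: int,
    length_sampler,
    min_gap: int,
    what: str,
) -> list[tuple[str, int, int]]:
    """Place n non-overlapping intervals by partitioning each contig into
    slots and dropping one interval at a random offset inside each slot."""
    names = list(contig_sizes)
    sizes = np.array([contig_sizes[c] for c in names], dtype=float)
    alloc = np.floor(n * sizes / sizes.sum()).astype(int)
    while alloc.sum() < n:
        alloc[int(np.argmax(sizes / np.maximum(alloc + 1, 1)))] += 1
    out = []
    for contig, k in zip(names, alloc):
        if k == 0:
            continue
        L = contig_sizes[contig]
        width = L // k
        lengths = np.array([length_sampler() for _ in range(k)])
        if width < lengths.max() + min_gap:
            raise ValueError(
                f"infeasible placement: {n} non-overlapping {what} of up to "
                f"{int(lengths.max())} bp (+{min_gap} bp gap) do not fit in "
                f"{sum(contig_sizes.values())} bp of sequence"
            )
        for i, ln in enumerate(lengths):
            offset = int(rng.integers(0, width - ln - min_gap + 1))
            start = i * width + offset + min_gap // 2
            out.append((contig, start, start + int(ln)))
    return out


def _cpg_spacing_ok(
    pos: np.ndarray,
    start: int,
    end: int,
    min_cpgs: int,
    max_internal_gap: int = 100,
    max_edge_gap: int = 50,
) -> bool:
    """True when [start, end) holds >= min_cpgs CpGs, with no internal CpG
    gap above ``max_internal_gap`` and CpGs within ``max_edge_gap`` of both
    edges.  Planted DMRs must satisfy this so they are callable as a single
    region by a chaining segmenter with a 100-bp gap rule."""
    inside = pos[(pos >= start) & (pos < end - 1)]
    if len(inside) < min_cpgs:
        return False
    if inside[0] - start > max_edge_gap or (end - 2) - inside[-1] > max_edge_gap:
        return False
    return len(inside) < 2 or int(np.max(np.diff(inside))) <= max_internal_gap


def _reject_place(
    rng: np.random.Generator,
    contig_sizes: dict[str, int],
    n: int,
    length_sampler,
    avoid: IntervalSet,
    cpg_positions: dict[str, np.ndarray],
    min_cpgs: int,
    min_gap: int,
    what: str,
    max_tries: int = 2000,
) -> list[tuple[str, int, int]]:
    """Rejection-sample n non-overlapping intervals outside ``avoid`` that
    contain at least ``min_cpgs`` CpGs each."""
    names = list(contig_sizes)
    sizes = np.array([contig_sizes[c] for c in names], dtype=float)
    probs = sizes / sizes.sum()
    placed: list[tuple[str, int, int]] = []
    occupied = {c: [] for c in names}
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries * max(n, 1):
            raise ValueError(
                f"infeasible placement: only {len(placed)}/{n} {what} placed; "
                "genome too small or too crowded for the requested elements"
            )
        contig = names[int(rng.choice(len(names), p=probs))]
        ln = int(length_sampler())
        L = contig_sizes[contig]
        if L <= ln + 2:
            continue
        start = int(rng.integers(0, L - ln))
        end = start + ln
        if avoid.overlaps(contig, start - min_gap, end + min_gap):
            continue
        if any(s < end + min_gap and start - min_gap < e for s, e in occupied[contig]):
            continue
        if min_cpgs and not _cpg_spacing_ok(cpg_positions[contig], start, end, min_cpgs):
            continue
        occupied[contig].append((start, end))
        placed.append((contig, start, end))
    return placed


@dataclass
class ReferenceSet:
    """In-memory reference bundle produced by generate_reference_set."""

    design: SimulationDesign
    contigs: dict[str, str]
    spike: str
    genes: list[GeneModel]
    tes: list[TeInterval]
    cgis: list[tuple[str, int, int, str]]  # contig, start, end, class
    snps: list[SnpRecord]
    truth: list[TruthRecord]
    cpg_positions: dict[str, np.ndarray]
    baseline_p: dict[str, np.ndarray]
    dmr_truth: list[TruthRecord]
    gene_prom_meth: dict[str, float]
    gene_body_meth: dict[str, float]
    tissue_block_offsets: dict[str, dict[str, np.ndarray]]
    species_block_offsets: dict[str, dict[str, np.ndarray]]

    @property
    def contig_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def gene_table(self) -> pd.DataFrame:
        rows = [
            # gene table file is 1-based inclusive
            (g.gene_id, g.contig, g.strand, g.tss + 1, g.tes + 1)
            for g in self.genes
        ]
        return pd.DataFrame(rows, columns=["gene_id", "contig", "strand", "tss", "tes"])

    def te_table(self) -> pd.DataFrame:
        rows = [(t.contig, t.start, t.end, t.family, t.te_class, round(t.divergence, 2)) for t in self.tes]
        return pd.DataFrame(rows, columns=["contig", "start", "end", "family", "class", "divergence"])

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "spike": outdir / "spike.fa",
            "snps": outdir / "snps.vcf",
            "genes": outdir / "genes.tsv",
            "tes": outdir / "tes.tsv",
            "truth_tsv": outdir / "truth.tsv",
            "truth_json": outdir / "truth.json",
        }
        write_fasta(self.contigs, paths["genome"])
        write_fasta({SPIKE_CONTIG: self.spike}, paths["spike"])
        _write_vcf(self.snps, self.contig_sizes, paths["snps"])
        self.gene_table().to_csv(paths["genes"], sep="\t", index=False)
        self.te_table().to_csv(paths["tes"], sep="\t", index=False)
        write_truth(self.truth, paths["truth_tsv"], paths["truth_json"])
        return paths


def _write_vcf(snps: list[SnpRecord], contig_sizes: dict[str, int], path: Path) -> None:
    grouped: dict[tuple[str, int, str, str], list[str]] = {}
    for s in snps:
        grouped.setdefault((s.contig, s.position, s.ref_allele, s.alt_allele), []).append(s.species)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig, size in contig_sizes.items():
            fh.write(f"##contig=<ID={contig},length={size}>\n")
        fh.write('##INFO=<ID=SPECIES,Number=.,Type=String,Description="Species carrying the ALT allele">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for (contig, pos, ref, alt), species in sorted(grouped.items()):
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tSPECIES={','.join(sorted(set(species)))}\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.str_,)):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_truth(truth: list[TruthRecord], tsv_path: Path, json_path: Path) -> None:
    with open(tsv_path, "w") as fh:
        fh.write("kind\tcontig\tstart\tend\tattributes\n")
        for t in truth:
            attrs = json.dumps(t.attributes, sort_keys=True, default=_jsonable)
            fh.write(f"{t.kind}\t{t.contig}\t{t.start}\t{t.end}\t{attrs}\n")
    with open(json_path, "w") as fh:
        json.dump([asdict(t) for t in truth], fh, indent=1, sort_keys=True, default=_jsonable)


def generate_reference_set(design: SimulationDesign) -> ReferenceSet:
    """Build genome, annotations, SNPs and planted-truth records."""
    rng = np.random.default_rng([design.seed, 0])
    contig_names = [f"chr{i + 1}" for i in range(design.n_contigs)]
    contig_sizes = {c: design.contig_length for c in contig_names}

    # gene placement first (gene margin leaves room for promoter + vicinity)
    glo, ghi = design.gene_length_range
    gene_spans = _slot_place(
        rng, contig_sizes, design.n_genes, lambda: rng.integers(glo, ghi + 1), 1500, "genes"
    )
    genes: list[GeneModel] = []
    for i, (contig, s, e) in enumerate(sorted(gene_spans)):
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tes = (s, e - 1) if strand == "+" else (e - 1, s)
        genes.append(GeneModel(f"gene{i + 1:05d}", contig, strand, tss, tes))

    # CGI intervals, half in promoters, half orphan; decided before base
    # sampling so the sequence really is CpG-rich there
    clo, chi = design.cgi_length_range
    n_prom_cgi = design.n_cgis // 2
    cgi_spans: list[tuple[str, int, int, str]] = []
    prom_gene_idx = rng.choice(len(genes), size=min(n_prom_cgi, len(genes)), replace=False)
    for gi in prom_gene_idx:
        g = genes[gi]
        ln = int(rng.integers(clo, chi + 1))
        start = max(0, g.tss - ln // 2)
        cgi_spans.append((g.contig, start, min(start + ln, contig_sizes[g.contig]), "promoter"))
    gene_pad = IntervalSet.from_pairs(
        (g.contig, max(0, min(g.tss, g.tes) - 1000), min(contig_sizes[g.contig], max(g.tss, g.tes) + 1000))
        for g in genes
    )
    orphan = _reject_place(
        rng, contig_sizes, design.n_cgis - len(prom_gene_idx), lambda: rng.integers(clo, chi + 1),
        gene_pad, {}, 0, 200, "orphan CGIs",
    )
    cgi_spans += [(c, s, e, "orphan") for c, s, e in orphan]

    # base sampling: background composition everywhere, GC/CpG-rich in CGIs
    contigs: dict[str, str] = {}
    cpg_positions: dict[str, np.ndarray] = {}
    for contig in contig_names:
        arr = _sample_bases(rng, design.contig_length, gc_rich=False)
        for c, s, e, _cls in cgi_spans:
            if c == contig:
                arr[s:e] = _sample_bases(rng, e - s, gc_rich=True)
        seq = arr.tobytes().decode("ascii")
        contigs[contig] = seq
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        cpg_positions[contig] = np.flatnonzero(is_c[:-1] & is_g[1:]).astype(np.int64)
    spike = _sample_bases(rng, design.spike_contig_length, gc_rich=False).tobytes().decode("ascii")

    mean_density = sum(len(p) for p in cpg_positions.values()) / sum(contig_sizes.values())
    if mean_density < 0.01:
        log.warning("CpG density %.4f per bp below 1/100", mean_density)

    # TEs: independent slot partition; may overlap genes, never each other
    te_spans = _slot_place(
        rng, contig_sizes, design.n_tes, lambda: rng.integers(150, 1200), 50, "TEs"
    )

    # planted DMRs: a fraction centred on gene promoters (these drive the
    # expression coupling), the rest away from genes, all with >= 4 CpGs
    n_prom_dmr = int(round(design.frac_promoter_dmrs * design.n_dmrs))
    dmr_spans: list[tuple[str, int, int]] = []
    dmr_gene: list[str | None] = []
    candidates = []
    for gi, g in enumerate(genes):
        pos = cpg_positions[g.contig]
        lo, hi = g.tss - 500, g.tss + 500
        if np.searchsorted(pos, hi) - np.searchsorted(pos, lo) >= 6:
            candidates.append(gi)
    dlo, dhi = design.dmr_length_range
    n_placed = 0
    for gi in (candidates[j] for j in rng.permutation(len(candidates))):
        if n_placed == n_prom_dmr:
            break
        g = genes[gi]
        for _try in range(4):
            ln = int(min(rng.integers(dlo, dhi + 1), 900))
            start = max(0, g.tss - ln // 2)
            end = min(start + ln, contig_sizes[g.contig])
            if _cpg_spacing_ok(cpg_positions[g.contig], start, end, 4):
                dmr_spans.append((g.contig, start, end))
                dmr_gene.append(g.gene_id)
                n_placed += 1
                break
    if n_placed < n_prom_dmr:
        raise ValueError(
            f"infeasible placement: only {n_placed} of {n_prom_dmr} requested promoter "
            "DMRs fit a promoter with enough well-spaced CpGs"
        )
    far_pad = IntervalSet.from_pairs(
        (g.contig, max(0, min(g.tss, g.tes) - 4500), min(contig_sizes[g.contig], max(g.tss, g.tes) + 4500))
        for g in genes
    )
    # 800-bp separation keeps planted regions callable as distinct units
    # by a segmenter with 100-bp chaining and 500-bp smoothing
    for span in _reject_place(
        rng, contig_sizes, design.n_dmrs - n_prom_dmr, lambda: rng.integers(dlo, dhi + 1),
        far_pad, cpg_positions, 4, 800, "DMRs",
    ):
        dmr_spans.append(span)
        dmr_gene.append(None)

    # per-gene promoter/body methylation levels (species/tissue invariant)
    gene_prom_meth: dict[str, float] = {}
    gene_body_meth: dict[str, float] = {}
    for g in genes:
        if rng.random() < 0.7:
            gene_prom_meth[g.gene_id] = float(rng.beta(2, 10))  # unmethylated promoter
        else:
            gene_prom_meth[g.gene_id] = float(rng.beta(6, 3))
        gene_body_meth[g.gene_id] = float(rng.beta(12, 3))

    # baseline per-CpG methylation from background + promoters + bodies
    baseline_p: dict[str, np.ndarray] = {}
    for contig in contig_names:
        pos = cpg_positions[contig]
        p = np.full(len(pos), design.background_meth)
        for g in genes:
            if g.contig != contig:
                continue
            lo_e, hi_e = g.extent
            sl = slice(np.searchsorted(pos, lo_e), np.searchsorted(pos, hi_e))
            p[sl] = gene_body_meth[g.gene_id]
            sl = slice(np.searchsorted(pos, g.tss - 500), np.searchsorted(pos, g.tss + 500))
            p[sl] = gene_prom_meth[g.gene_id]
        baseline_p[contig] = p

    # DMR truth: target species, tissue scope (exact multi-tissue count),
    # delta signed away from the local baseline so the full effect is
    # realised without clamping
    tissues = design.tissues
    scopes = ["multi"] * int(round(design.frac_multi_tissue * design.n_dmrs))
    i = 0
    while len(scopes) < design.n_dmrs:
        scopes.append(tissues[i % len(tissues)])
        i += 1
    if design.n_tissues == 1:
        scopes = [tissues[0]] * design.n_dmrs
    scopes = list(np.array(scopes)[rng.permutation(design.n_dmrs)])
    dmr_truth: list[TruthRecord] = []
    species = design.species
    for (contig, s, e), gene_id, scope in zip(dmr_spans, dmr_gene, scopes):
        target = species[int(rng.integers(0, len(species)))]
        pos = cpg_positions[contig]
        sl = slice(np.searchsorted(pos, s), np.searchsorted(pos, e))
        local = float(np.mean(baseline_p[contig][sl])) if sl.stop > sl.start else design.background_meth
        delta = -design.dmr_delta if local >= 0.5 else design.dmr_delta
        attrs = {
            "species": target,
            "tissue_scope": scope,
            "delta": delta,
            "n_cpgs": int(sl.stop - sl.start),
        }
        if gene_id is not None:
            attrs["gene_id"] = gene_id
        dmr_truth.append(TruthRecord("dmr", contig, s, e, attrs))

    # TE divergence: young under planted DMRs, old elsewhere
    dmr_set = IntervalSet.from_pairs((t.contig, t.start, t.end) for t in dmr_truth)
    tes: list[TeInterval] = []
    fam_idx = rng.integers(0, len(_TE_FAMILIES), size=len(te_spans))
    for (contig, s, e), fi in zip(te_spans, fam_idx):
        fam, cls = _TE_FAMILIES[fi]
        young = design.te_age_coupling and dmr_set.overlaps(contig, s, e)
        mu = design.te_young_divergence if young else design.te_old_divergence
        sd = 1.5 if young else 4.0
        div = float(max(0.0, rng.normal(mu, sd)))
        tes.append(TeInterval(contig, s, e, fam, cls, div))

    # SNPs: a stated mix of bisulfite-confounded (C>T / G>A) and other
    # substitution classes per species
    snps: list[SnpRecord] = []
    n_bis = int(round(design.frac_bisulfite_snps * design.n_snps_per_species))
    for sp in species:
        used: set[tuple[str, int]] = set()
        placed_bis = placed_other = 0
        while placed_bis < n_bis or placed_other < design.n_snps_per_species - n_bis:
            contig = contig_names[int(rng.integers(0, len(contig_names)))]
            idx = int(rng.integers(0, contig_sizes[contig]))
            if (contig, idx) in used:
                continue
            ref = contigs[contig][idx]
            if placed_bis < n_bis:
                if ref == "C":
                    alt = "T"
                elif ref == "G":
                    alt = "A"
                else:
                    continue
                placed_bis += 1
            else:
                if ref == "C":
                    alt = "AG"[int(rng.integers(0, 2))]
                elif ref == "G":
                    alt = "CT"[int(rng.integers(0, 2))]
                else:
                    alt = {"A": "CGT", "T": "ACG"}.get(ref)
                    if alt is None:
                        continue
                    alt = alt[int(rng.integers(0, 3))]
                placed_other += 1
            used.add((contig, idx))
            snps.append(SnpRecord(contig, idx + 1, ref, alt, sp))

    # per-1kb-block tissue and species offsets (genome-wide covariance
    # structure: tissue > species > replicate)
    nblocks = {c: design.contig_length // 1000 + 1 for c in contig_names}
    tissue_off = {
        ti: {c: rng.normal(0.0, design.tissue_effect, nblocks[c]) for c in contig_names}
        for ti in tissues
    }
    species_off = {
        sp: {c: rng.normal(0.0, design.species_effect, nblocks[c]) for c in contig_names}
        for sp in species
    }

    truth: list[TruthRecord] = []
    truth.extend(dmr_truth)
    for c, s, e, cls in cgi_spans:
        truth.append(TruthRecord("cgi", c, s, e, {"class": cls}))
    for t in tes:
        truth.append(TruthRecord("te", t.contig, t.start, t.end, {"family": t.family, "divergence": round(t.divergence, 2)}))
    for g in genes:
        truth.append(
            TruthRecord("gene", g.contig, *g.extent, {
                "gene_id": g.gene_id,
                "strand": g.strand,
                "promoter_meth": round(gene_prom_meth[g.gene_id], 4),
                "body_meth": round(gene_body_meth[g.gene_id], 4),
            })
        )
    for t in dmr_truth:
        if "gene_id" in t.attributes:
            truth.append(
                TruthRecord("coupling", t.contig, t.start, t.end, {
                    "gene_id": t.attributes["gene_id"],
                    "species": t.attributes["species"],
                    "tissue_scope": t.attributes["tissue_scope"],
                    "delta": t.attributes["delta"],
                    "expr_log2_shift": design.expr_coupling * t.attributes["delta"],
                })
            )

    return ReferenceSet(
        design=design,
        contigs=contigs,
        spike=spike,
        genes=genes,
        tes=tes,
        cgis=cgi_spans,
        snps=snps,
        truth=truth,
        cpg_positions=cpg_positions,
        baseline_p=baseline_p,
        dmr_truth=dmr_truth,
        gene_prom_meth=gene_prom_meth,
        gene_body_meth=gene_body_meth,
        tissue_block_offsets=tissue_off,
        species_block_offsets=species_off,
    )


# ---------------------------------------------------------------------------
# methylomes


@dataclass
class SimulatedMethylome:
    """One sample's simulated CpG counts plus report-file emission."""

    sample_id: str
    species: str
    tissue: str
    replicate: int
    # per analysis contig: positions (0-based C), methylated, coverage
    counts: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    report: pd.DataFrame = field(repr=False, default=None)

    def to_sample(self, min_coverage: int = 5, max_coverage: int = 100) -> MethylomeSample:
        """Destranded MethylomeSample equivalent to loading the report."""
        frames = []
        for contig, (pos, m, cov) in self.counts.items():
            frames.append(
                pd.DataFrame(
                    {
                        "contig": contig,
                        "position": pos,
                        "count_methylated": m,
                        "count_unmethylated": cov - m,
                    }
                )
            )
        sites = pd.concat(frames, ignore_index=True)
        total = sites["count_methylated"] + sites["count_unmethylated"]
        sites = sites[(total >= min_coverage) & (total <= max_coverage)]
        return MethylomeSample(self.sample_id, self.species, self.tissue, self.replicate, sites.reset_index(drop=True))

    def write_report(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / f"{self.sample_id}.CpG_report.txt"
        self.report.to_csv(path, sep="\t", header=False, index=False)
        return path


def _context_plus(seq: str, i: int) -> tuple[str, str]:
    tri = (seq[i : i + 3] + "NN")[:3]
    if i + 1 < len(seq) and seq[i + 1] == "G":
        return "CG", tri
    if i + 2 < len(seq) and seq[i + 2] == "G":
        return "CHG", tri
    return "CHH", tri


_COMP = str.maketrans("ACGT", "TGCA")


def _context_minus(seq: str, i: int) -> tuple[str, str]:
    # cytosine on the minus strand sits at a genomic G; its downstream
    # bases are i-1, i-2 read on the reverse complement
    tri = seq[max(0, i - 2) : i + 1].translate(_COMP)[::-1]
    tri = (tri + "NN")[:3]
    if i - 1 >= 0 and seq[i - 1] == "C":
        return "CG", tri
    if i - 2 >= 0 and seq[i - 2] == "C":
        return "CHG", tri
    return "CHH", tri


def _betabin(rng: np.random.Generator, n: np.ndarray, p: np.ndarray, phi: float) -> np.ndarray:
    """Beta-binomial draw with mean p and overdispersion phi; phi=0 is
    plain binomial.  alpha = p (1 - phi) / phi, beta = (1 - p)(1 - phi)/phi."""
    if phi <= 0:
        return rng.binomial(n, p)
    a = p * (1 - phi) / phi
    b = (1 - p) * (1 - phi) / phi
    theta = np.where(
        (p <= 0) | (p >= 1), p, rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))
    )
    return rng.binomial(n, theta)


def simulate_methylomes(
    design: SimulationDesign,
    refset: ReferenceSet,
    build_reports: bool = True,
) -> list[SimulatedMethylome]:
    """Draw per-sample CpG counts and assemble cytosine reports.

    Coverage is Poisson(mean_coverage) per CpG; methylated counts are
    beta-binomial around the site's level, which is the baseline plus the
    sample's tissue/species block offsets plus any planted DMR delta
    whose target species and tissue scope match.  Counts are split
    binomially across strands, and the unmethylated spike contig is
    reported over all cytosine contexts at the non-conversion rate.
    """
    samples = []
    clamped = 0
    spike_rows = _spike_template(refset) if build_reports else None
    tri_cache: dict[str, tuple[list[str], list[str]]] = {}
    if build_reports:
        for contig, seq in refset.contigs.items():
            pos = refset.cpg_positions[contig]
            tri_cache[contig] = (
                [_context_plus(seq, int(i))[1] for i in pos],
                [_context_minus(seq, int(i) + 1)[1] for i in pos],
            )
    for sidx, (sample_id, sp, ti, rep) in enumerate(design.sample_ids()):
        rng = np.random.default_rng([design.seed, 1, sidx])
        counts: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        frames = []
        for contig, seq in refset.contigs.items():
            pos = refset.cpg_positions[contig]
            p = refset.baseline_p[contig].copy()
            blocks = pos // 1000
            p += refset.tissue_block_offsets[ti][contig][blocks]
            p += refset.species_block_offsets[sp][contig][blocks]
            for t in refset.dmr_truth:
                if t.contig != contig or t.attributes["species"] != sp:
                    continue
                scope = t.attributes["tissue_scope"]
                if scope != "multi" and scope != ti:
                    continue
                sl = slice(np.searchsorted(pos, t.start), np.searchsorted(pos, t.end))
                p[sl] += t.attributes["delta"]
            below, above = p < 0.0, p > 1.0
            clamped += int(below.sum() + above.sum())
            p = np.clip(p, 0.0, 1.0)
            p_eff = p + (1.0 - p) * design.nonconversion_rate
            cov = rng.poisson(design.mean_coverage, len(pos))
            m = _betabin(rng, cov, p_eff, design.dispersion)
            counts[contig] = (pos, m, cov)
            # strand split: reads assigned to '+' C or '-' G binomially
            n_plus = rng.binomial(cov, 0.5)
            m_plus = np.zeros_like(m)
            ok = cov > 0
            m_plus[ok] = rng.hypergeometric(m[ok], (cov - m)[ok], n_plus[ok])
            u_plus = n_plus - m_plus
            m_minus = m - m_plus
            u_minus = (cov - n_plus) - m_minus
            if build_reports:
                tri_p, tri_m = tri_cache[contig]
                frames.append(pd.DataFrame({
                    "contig": contig, "position": pos + 1, "strand": "+",
                    "count_methylated": m_plus, "count_unmethylated": u_plus,
                    "context": "CG", "trinucleotide": tri_p,
                }))
                frames.append(pd.DataFrame({
                    "contig": contig, "position": pos + 2, "strand": "-",
                    "count_methylated": m_minus, "count_unmethylated": u_minus,
                    "context": "CG", "trinucleotide": tri_m,
                }))
        # spike counts are drawn even when reports are skipped so that the
        # random stream (and hence every emitted count) is mode-invariant
        n_spike = len(spike_rows) if spike_rows is not None else refset.spike.count("C") + refset.spike.count("G")
        cov_s = rng.poisson(design.mean_coverage, n_spike)
        m_s = rng.binomial(cov_s, design.nonconversion_rate)
        report = None
        if build_reports:
            spike = spike_rows.copy()
            spike["count_methylated"] = m_s
            spike["count_unmethylated"] = cov_s - m_s
            frames.append(spike)
            report = pd.concat(frames, ignore_index=True)
            report = report.sort_values(["contig", "position", "strand"], kind="mergesort").reset_index(drop=True)
            report = report[["contig", "position", "strand", "count_methylated", "count_unmethylated", "context", "trinucleotide"]]
        samples.append(SimulatedMethylome(sample_id, sp, ti, rep, counts, report))
    if clamped:
        log.warning("%d site levels clamped into [0, 1] during simulation", clamped)
    return samples


def _spike_template(refset: ReferenceSet) -> pd.DataFrame:
    seq = refset.spike
    rows = []
    for i, base in enumerate(seq):
        if base == "C":
            ctx, tri = _context_plus(seq, i)
            rows.append((SPIKE_CONTIG, i + 1, "+", 0, 0, ctx, tri))
        elif base == "G":
            ctx, tri = _context_minus(seq, i)
            rows.append((SPIKE_CONTIG, i + 1, "-", 0, 0, ctx, tri))
    return pd.DataFrame(rows, columns=["contig", "position", "strand", "count_methylated", "count_unmethylated", "context", "trinucleotide"])


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionData:
    tpm: pd.DataFrame  # genes x samples
    meta: pd.DataFrame  # sample_id, species, tissue, replicate
    de_table: pd.DataFrame  # gene_id, q_value
    truth: list[TruthRecord]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tpm": outdir / "expression_tpm.tsv",
            "meta": outdir / "samples.tsv",
            "de": outdir / "de_table.tsv",
        }
        self.tpm.to_csv(paths["tpm"], sep="\t", index_label="gene_id", float_format="%.4f")
        self.meta.to_csv(paths["meta"], sep="\t", index=False)
        self.de_table.to_csv(paths["de"], sep="\t", index=False)
        return paths


def simulate_expression(design: SimulationDesign, refset: ReferenceSet) -> ExpressionData:
    """Log-normal TPM per gene/sample with planted methylation coupling.

    Expression couples to promoter methylation with sign ``expr_coupling``
    (negative by default: a planted promoter hyper-DMR lowers the target
    species' expression) and to gene-body methylation with sign
    ``genebody_coupling``.  An exact ``off_fraction`` of genes is silent
    (TPM 0 in every sample); silent genes are drawn from genes without a
    planted promoter DMR so the planted coupling stays observable.
    """
    if not refset.genes:
        raise ValueError("reference set has no genes (no promoters to couple to)")
    rng = np.random.default_rng([design.seed, 2])
    genes = [g.gene_id for g in refset.genes]
    coupled = {
        t.attributes["gene_id"]: t.attributes
        for t in refset.dmr_truth
        if "gene_id" in t.attributes
    }
    n_off = int(round(design.off_fraction * len(genes)))
    eligible = [g for g in genes if g not in coupled]
    if n_off > len(eligible):
        raise ValueError("off_fraction leaves too few expressed genes after excluding coupled genes")
    off = set(np.array(eligible)[rng.choice(len(eligible), size=n_off, replace=False)]) if n_off else set()

    base = {g: float(rng.normal(design.expr_log2_mean, design.expr_log2_sd)) for g in genes}
    sample_ids = design.sample_ids()
    columns = {}
    mean_prom = float(np.mean(list(refset.gene_prom_meth.values())))
    mean_body = float(np.mean(list(refset.gene_body_meth.values())))
    for sidx, (sample_id, sp, ti, rep) in enumerate(sample_ids):
        vals = np.zeros(len(genes))
        noise = rng.normal(0.0, design.expr_rep_sd, len(genes))
        for i, g in enumerate(genes):
            if g in off:
                continue
            prom = refset.gene_prom_meth[g]
            info = coupled.get(g)
            if info is not None and info["species"] == sp and info["tissue_scope"] in ("multi", ti):
                prom = min(1.0, max(0.0, prom + info["delta"]))
            mu = (
                base[g]
                + design.expr_coupling * (prom - mean_prom)
                + design.genebody_coupling * (refset.gene_body_meth[g] - mean_body)
            )
            vals[i] = 2.0 ** (mu + noise[i])
        columns[sample_id] = vals
    tpm = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    meta = pd.DataFrame(
        [(sid, sp, ti, rep) for sid, sp, ti, rep in sample_ids],
        columns=["sample_id", "species", "tissue", "replicate"],
    )
    q = {}
    for g in genes:
        if g in coupled and g not in off:
            q[g] = 10.0 ** (-float(rng.uniform(4, 10)))
        else:
            q[g] = float(rng.uniform(0.02, 1.0))
    de_table = pd.DataFrame({"gene_id": genes, "q_value": [q[g] for g in genes]})
    truth = [
        TruthRecord("gene", refset.genes[i].contig, *refset.genes[i].extent, {
            "gene_id": g, "off": bool(g in off), "base_log2_tpm": round(base[g], 3),
        })
        for i, g in enumerate(genes)
    ]
    return ExpressionData(tpm=tpm, meta=meta, de_table=de_table, truth=truth)


def write_dataset(design: SimulationDesign, outdir: str | Path) -> dict:
    """Generate and write the complete dataset; returns a path manifest."""
    outdir = Path(outdir)
    refset = generate_reference_set(design)
    paths = {k: str(v) for k, v in refset.write(outdir).items()}
    reports = outdir / "reports"
    for sm in simulate_methylomes(design, refset):
        paths[f"report_{sm.sample_id}"] = str(sm.write_report(reports))
    expr = simulate_expression(design, refset)
    paths.update({k: str(v) for k, v in expr.write(outdir).items()})
    try:
        import yaml

        with open(outdir / "design.yaml", "w") as fh:
            yaml.safe_dump(asdict(design), fh, sort_keys=True)
        paths["design"] = str(outdir / "design.yaml")
    except ImportError:  # pragma: no cover
        pass
    return paths
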