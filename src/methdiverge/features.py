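"""Annotation universe: CpG islands, promoters, gene bodies, intergenic
space and transposable elements, plus interval intersection helpers.

Conventions: promoters are TSS +/- 500 bp; gene bodies are the gene extent
minus the first 500 bp downstream of the TSS (in transcription direction);
intergenic space lies more than 500 bp away from any gene; CpG islands
overlapping a promoter by >= 1 bp are promoter CGIs, the rest are orphan
CGIs.  All internal coordinates are 0-based half-open; file formats keep
their native conventions (gene table and RepeatMasker .out 1-based
inclusive, BED and the 6-column TE TSV 0-based half-open).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PROMOTER_FLANK = 500  # bp either side of the TSS
GENE_BODY_TRIM = 500  # bp downstream of TSS excluded from the gene body
INTERGENIC_PAD = 500  # bp buffer around gene extents

CGI_MIN_LENGTH = 200
CGI_MIN_GC = 0.5
CGI_MIN_OBS_EXP = 0.6

FEATURE_CATEGORIES = ("promoter", "gene_body", "intergenic", "cgi_promoter", "cgi_orphan", "te")

__all__ = [
    "GeneModel",
    "CgiInterval",
    "TeInterval",
    "IntervalSet",
    "FeatureMap",
    "read_gene_table",
    "predict_cgi",
    "build_feature_map",
    "parse_repeatmasker_out",
    "annotate_intervals",
]


@dataclass(frozen=True)
class GeneModel:
    """A gene as TSS/TES on a strand; 0-based positions of the first and
    last transcribed base.  On '-' genes ``tss > tes``."""

    gene_id: str
    contig: str
    strand: str
    tss: int
    tes: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.tss == self.tes:
            raise ValueError(f"tss == tes for {self.gene_id}")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"'+' gene {self.gene_id} has tss > tes")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(f"'-' gene {self.gene_id} has tss < tes")

    @property
    def extent(self) -> tuple[int, int]:
        """0-based half-open genomic span."""
        lo, hi = sorted((self.tss, self.tes))
        return lo, hi + 1


@dataclass
class CgiInterval:
    contig: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float
    cgi_class: str | None = None  # "promoter" | "orphan" once classified


@dataclass
class TeInterval:
    contig: str
    start: int
    end: int
    family: str
    te_class: str
    divergence: float  # CpG-adjusted Kimura substitution level, percent

    def __post_init__(self):
        if self.divergence < 0:
            raise ValueError(f"negative divergence for TE at {self.contig}:{self.start}")


class IntervalSet:
    """Sorted, merged intervals per contig with fast existence queries."""

    def __init__(self, by_contig: dict[str, np.ndarray] | None = None):
        # each value: (n, 2) int array of merged half-open intervals
        self.by_contig: dict[str, np.ndarray] = by_contig or {}

    @classmethod
    def from_pairs(cls, pairs) -> "IntervalSet":
        """Build from an iterable of (contig, start, end); merges overlaps."""
        grouped: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in pairs:
            if end > start:
                grouped.setdefault(contig, []).append((int(start), int(end)))
        merged = {}
        for contig, ivals in grouped.items():
            ivals.sort()
            out = [list(ivals[0])]
            for s, e in ivals[1:]:
                if s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[contig] = np.asarray(out, dtype=np.int64)
        return cls(merged)

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any interval by >= 1 bp."""
        arr = self.by_contig.get(contig)
        if arr is None or arr.size == 0 or end <= start:
            return False
        idx = int(np.searchsorted(arr[:, 0], end, side="left"))
        return idx > 0 and arr[idx - 1, 1] > start

    def count_overlapping(self, contigs, starts, ends) -> int:
        """Number of query intervals overlapping the set (each counted once)."""
        total = 0
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        contigs = np.asarray(contigs)
        for contig in np.unique(contigs):
            arr = self.by_contig.get(str(contig))
            mask = contigs == contig
            if arr is None or arr.size == 0:
                continue
            qs, qe = starts[mask], ends[mask]
            idx = np.searchsorted(arr[:, 0], qe, side="left")
            hit = (idx > 0) & (arr[np.maximum(idx - 1, 0), 1] > qs)
            total += int(np.sum(hit))
        return total

    def total_length(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.by_contig.values()))

    def n_intervals(self) -> int:
        return int(sum(len(arr) for arr in self.by_contig.values()))

    def to_pairs(self) -> list[tuple[str, int, int]]:
        out = []
        for contig in sorted(self.by_contig):
            for s, e in self.by_contig[contig]:
                out.append((contig, int(s), int(e)))
        return out

    def write_bed(self, path: str | Path, name: str = ".") -> None:
        with open(path, "w") as fh:
            for contig, s, e in self.to_pairs():
                fh.write(f"{contig}\t{s}\t{e}\t{name}\n")


@dataclass
class FeatureMap:
    """The derived annotation universe used for enrichment and assignment."""

    promoter: IntervalSet
    gene_body: IntervalSet
    intergenic: IntervalSet
    cgi_promoter: IntervalSet
    cgi_orphan: IntervalSet
    te: IntervalSet
    contig_sizes: dict[str, int]
    promoter_by_gene: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    gene_body_by_gene: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    extent_by_gene: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def category(self, name: str) -> IntervalSet:
        if name not in FEATURE_CATEGORIES:
            raise KeyError(f"unknown feature category {name!r}")
        return getattr(self, name)

    def categories(self) -> dict[str, IntervalSet]:
        return {name: getattr(self, name) for name in FEATURE_CATEGORIES}


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read the 5-column gene table (gene_id, contig, strand, tss, tes;
    1-based inclusive positions) into GeneModels with 0-based positions."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str})
    required = {"gene_id", "contig", "strand", "tss", "tes"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene table missing columns: {sorted(required - set(df.columns))}")
    return [
        GeneModel(r.gene_id, r.contig, r.strand, int(r.tss) - 1, int(r.tes) - 1)
        for r in df.itertuples()
    ]


def _window_stats(c: np.ndarray, g: np.ndarray, cpg: np.ndarray, start: int, end: int):
    n = end - start
    nc = int(c[start:end].sum())
    ng = int(g[start:end].sum())
    ncpg = int(cpg[start : end - 1].sum()) if end - 1 > start else 0
    gc = (nc + ng) / n if n else 0.0
    oe = (ncpg * n / (nc * ng)) if nc and ng else 0.0
    return gc, oe, ncpg


def predict_cgi(genome: dict[str, str], window: int = 200) -> list[CgiInterval]:
    """Predict CpG islands with the classic sliding-window rule.

    A 200-bp window (step 1) qualifies when GC >= 50% and observed/expected
    CpG >= 0.6, with O/E = n_CpG * N / (n_C * n_G).  Overlapping qualifying
    windows are merged and the merged interval re-evaluated against all
    three thresholds (length >= 200 included) before being reported.
    """
    islands: list[CgiInterval] = []
    for contig, seq in genome.items():
        L = len(seq)
        if L < window:
            log.warning("contig %s shorter than %d bp, skipped for CGI scan", contig, window)
            continue
        arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        c = (arr == ord("C")).astype(np.int32)
        g = (arr == ord("G")).astype(np.int32)
        cpg = (c[:-1] & g[1:]).astype(np.int32)
        cs = np.concatenate(([0], np.cumsum(c)))
        gs = np.concatenate(([0], np.cumsum(g)))
        ps = np.concatenate(([0], np.cumsum(cpg)))
        starts = np.arange(0, L - window + 1)
        nc = cs[starts + window] - cs[starts]
        ng = gs[starts + window] - gs[starts]
        ncpg = ps[np.minimum(starts + window - 1, L - 1)] - ps[starts]
        gc = (nc + ng) / window
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where((nc > 0) & (ng > 0), ncpg * window / np.maximum(nc * ng, 1), 0.0)
        ok = (gc >= CGI_MIN_GC) & (oe >= CGI_MIN_OBS_EXP)
        if not ok.any():
            continue
        # merge runs of consecutive qualifying window starts
        idx = np.flatnonzero(ok)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [idx.size - 1]))
        for rs, re_ in zip(run_starts, run_ends):
            s = int(idx[rs])
            e = int(idx[re_]) + window
            gc_m, oe_m, _ = _window_stats(c, g, cpg, s, e)
            if e - s >= CGI_MIN_LENGTH and gc_m >= CGI_MIN_GC and oe_m >= CGI_MIN_OBS_EXP:
                islands.append(CgiInterval(contig, s, e, gc_m, oe_m))
            else:
                log.debug("merged CGI candidate %s:%d-%d fails re-evaluation, dropped", contig, s, e)
    return islands


def build_feature_map(
    genes: list[GeneModel],
    cgis: list[CgiInterval],
    tes: list[TeInterval],
    contig_sizes: dict[str, int],
) -> FeatureMap:
    """Assemble the feature universe from gene models, CGIs and TEs."""
    prom_pairs, body_pairs, pad_pairs = [], [], []
    promoter_by_gene, body_by_gene, extent_by_gene = {}, {}, {}
    for gene in genes:
        size = contig_sizes.get(gene.contig)
        if size is None:
            raise ValueError(f"gene {gene.gene_id} on unknown contig {gene.contig}")
        lo, hi = gene.extent
        if hi > size:
            log.warning("gene %s extends past contig end, clipped", gene.gene_id)
            hi = size
        ps = max(0, gene.tss - PROMOTER_FLANK)
        pe = min(size, gene.tss + PROMOTER_FLANK)
        prom_pairs.append((gene.contig, ps, pe))
        promoter_by_gene[gene.gene_id] = (gene.contig, ps, pe)
        if gene.strand == "+":
            bs, be = min(gene.tss + GENE_BODY_TRIM, hi), hi
        else:
            bs, be = lo, max(lo, min(gene.tss - GENE_BODY_TRIM + 1, size))
        if be > bs:
            body_pairs.append((gene.contig, bs, be))
            body_by_gene[gene.gene_id] = (gene.contig, bs, be)
        pad_pairs.append((gene.contig, max(0, lo - INTERGENIC_PAD), min(size, hi + INTERGENIC_PAD)))
        extent_by_gene[gene.gene_id] = (gene.contig, lo, hi)

    promoter = IntervalSet.from_pairs(prom_pairs)
    gene_body = IntervalSet.from_pairs(body_pairs)
    padded = IntervalSet.from_pairs(pad_pairs)

    # intergenic = complement of the padded gene space
    inter_pairs = []
    for contig, size in contig_sizes.items():
        arr = padded.by_contig.get(contig)
        cursor = 0
        if arr is not None:
            for s, e in arr:
                if s > cursor:
                    inter_pairs.append((contig, cursor, int(s)))
                cursor = max(cursor, int(e))
        if cursor < size:
            inter_pairs.append((contig, cursor, size))
    intergenic = IntervalSet.from_pairs(inter_pairs)

    cgi_prom_pairs, cgi_orph_pairs = [], []
    for cgi in cgis:
        if promoter.overlaps(cgi.contig, cgi.start, cgi.end):
            cgi.cgi_class = "promoter"
            cgi_prom_pairs.append((cgi.contig, cgi.start, cgi.end))
        else:
            cgi.cgi_class = "orphan"
            cgi_orph_pairs.append((cgi.contig, cgi.start, cgi.end))

    te_set = IntervalSet.from_pairs((t.contig, t.start, t.end) for t in tes)
    return FeatureMap(
        promoter=promoter,
        gene_body=gene_body,
        intergenic=intergenic,
        cgi_promoter=IntervalSet.from_pairs(cgi_prom_pairs),
        cgi_orphan=IntervalSet.from_pairs(cgi_orph_pairs),
        te=te_set,
        contig_sizes=dict(contig_sizes),
        promoter_by_gene=promoter_by_gene,
        gene_body_by_gene=body_by_gene,
        extent_by_gene=extent_by_gene,
    )


def parse_repeatmasker_out(path: str | Path) -> list[TeInterval]:
    """Parse TE annotations from RepeatMasker .out (3 header lines, 1-based
    inclusive positions) or the 6-column TSV fallback (contig, start, end,
    family, class, divergence; 0-based half-open)."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    first = lines[0] if lines else ""
    is_tsv = "\t" in first and len(first.rstrip("\n").split("\t")) == 6
    tes: list[TeInterval] = []
    if is_tsv:
        header = first.rstrip("\n").split("\t")
        start_at = 1 if header[0].lower() in ("contig", "chrom", "chr") else 0
        for lineno, line in enumerate(lines[start_at:], start=start_at + 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                contig, start, end, family, te_class, div = parts
                tes.append(TeInterval(contig, int(start), int(end), family, te_class, float(div)))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"unparseable TE TSV row at line {lineno}: {exc}") from exc
    else:
        for lineno, line in enumerate(lines[3:], start=4):  # 3 header lines
            if not line.strip():
                continue
            parts = line.split()
            try:
                div = float(parts[1])
                contig = parts[4]
                start = int(parts[5]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(parts[6])
                family = parts[9]
                te_class = parts[10]
                tes.append(TeInterval(contig, start, end, family, te_class, div))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"unparseable RepeatMasker row at line {lineno}: {exc}") from exc
    return tes


def annotate_intervals(
    queries: list[tuple[str, int, int]],
    feature_map: FeatureMap,
) -> tuple[list[set[str]], dict[str, int]]:
    """Label each query interval with every feature category it overlaps.

    Overlap is >= 1 bp and categories are not mutually exclusive; a query in
    unannotated space gets no label apart from ``intergenic`` if it falls
    there.  Returns (labels per query, count of queries per category).
    Queries carrying the ``te`` label are the TE-DMRs of the analysis.
    """
    labels: list[set[str]] = []
    counts = {name: 0 for name in FEATURE_CATEGORIES}
    sets = feature_map.categories()
    for contig, start, end in queries:
        if contig not in feature_map.contig_sizes:
            raise ValueError(f"query on unknown contig {contig!r}")
        hit = {name for name, iset in sets.items() if iset.overlaps(contig, start, end)}
        labels.append(hit)
        for name in hit:
            counts[name] += 1
    return labels, counts
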