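"""DMR-expression integration: gene assignment, DEG filtering, the
putative-functional-DMR (pfDMR) overlap test, expression/methylation
binning with Spearman correlation, and methylome clustering.

A DMR is assigned to a gene when it overlaps the gene's promoter
(TSS +/- 500 bp), its gene body (extent minus the first 500 bp downstream
of the TSS), or lies 0.5-4 kbp away from the gene, with precedence
promoter > gene body > vicinity so the classes are mutually exclusive.
pfDMRs are gene-assigned DMRs whose gene is differentially expressed; the
excess of pfDMRs over chance is scored with an exact hypergeometric test
on gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .features import FeatureMap
from .methio import MethylomeSample, window_methylation
from .stats import TestResult, hypergeom_tail, spearman_rho

log = logging.getLogger(__name__)

VICINITY_MIN = 500
VICINITY_MAX = 4000

DEFAULT_Q_MAX = 0.01
DEFAULT_MIN_TPM_DIFF = 50.0

__all__ = [
    "ExpressionMatrix",
    "DegRecord",
    "PfDmr",
    "BinProfile",
    "assign_dmr_to_gene",
    "filter_degs",
    "pfdmr_overlap_test",
    "bin_and_correlate",
    "cluster_methylomes",
    "ClusterResult",
]


@dataclass
class ExpressionMatrix:
    """TPM values (genes x samples) plus sample metadata."""

    tpm: pd.DataFrame
    meta: pd.DataFrame  # sample_id, species, tissue, replicate

    def __post_init__(self):
        if (self.tpm.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        missing = set(self.meta["sample_id"]) - set(self.tpm.columns)
        if missing:
            raise ValueError(f"metadata samples absent from TPM matrix: {sorted(missing)}")

    def species_means(self, tissue: str | None = None) -> pd.DataFrame:
        """Per-species mean TPM (replicates averaged), optionally one tissue."""
        meta = self.meta
        if tissue is not None:
            meta = meta[meta["tissue"] == tissue]
        cols = {}
        for sp, sub in meta.groupby("species"):
            cols[sp] = self.tpm[list(sub["sample_id"])].mean(axis=1)
        return pd.DataFrame(cols)

    def replicate_columns(self, species: str, tissue: str) -> list[str]:
        sub = self.meta[(self.meta["species"] == species) & (self.meta["tissue"] == tissue)]
        return list(sub["sample_id"])


@dataclass
class DegRecord:
    gene_id: str
    q_value: float
    max_pairwise_tpm_diff: float


@dataclass
class PfDmr:
    dmr: object  # Dmr or ClassifiedDmr
    gene_id: str
    location_class: str  # promoter | gene_body | vicinity_0.5_4kb


def _interval_of(dmr) -> tuple[str, int, int]:
    return dmr.contig, dmr.start, dmr.end


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp separation of two half-open intervals; 0 when they touch/overlap."""
    if a_start < b_end and b_start < a_end:
        return 0
    return b_start - a_end if b_start >= a_end else a_start - b_end


def assign_dmr_to_gene(dmrs, feature_map: FeatureMap) -> list[PfDmr]:
    """Assign each DMR to at most one gene with precedence
    promoter > gene body > vicinity (0.5-4 kbp from the gene extent).

    Within a class, the gene with the largest overlap (promoter/body) or
    the smallest distance (vicinity) wins; DMRs farther than 4 kbp from
    every gene are dropped (unassigned is a valid outcome).
    """
    assigned: list[PfDmr] = []
    by_contig_genes: dict[str, list[str]] = {}
    for gid, (contig, _s, _e) in feature_map.extent_by_gene.items():
        by_contig_genes.setdefault(contig, []).append(gid)
    for dmr in dmrs:
        contig, start, end = _interval_of(dmr)
        best: tuple[int, float, str, str] | None = None  # (class rank, score, gene, label)
        for gid in by_contig_genes.get(contig, []):
            pc, ps, pe = feature_map.promoter_by_gene[gid]
            if ps < end and start < pe:
                ov = min(end, pe) - max(start, ps)
                cand = (0, -ov, gid, "promoter")
                if best is None or cand < best:
                    best = cand
                continue
            body = feature_map.gene_body_by_gene.get(gid)
            if body is not None:
                bc, bs, be = body
                if bs < end and start < be:
                    ov = min(end, be) - max(start, bs)
                    cand = (1, -ov, gid, "gene_body")
                    if best is None or cand < best:
                        best = cand
                    continue
            gc, gs, ge = feature_map.extent_by_gene[gid]
            gap = _gap(start, end, gs, ge)
            if VICINITY_MIN < gap <= VICINITY_MAX:
                cand = (2, float(gap), gid, "vicinity_0.5_4kb")
                if best is None or cand < best:
                    best = cand
        if best is not None:
            assigned.append(PfDmr(dmr, best[2], best[3]))
    return assigned


def filter_degs(
    de_table: pd.DataFrame,
    expression: ExpressionMatrix,
    tissue: str | None = None,
    q_max: float = DEFAULT_Q_MAX,
    min_diff: float = DEFAULT_MIN_TPM_DIFF,
) -> list[DegRecord]:
    """Retain differentially expressed genes passing both filters:
    q < ``q_max`` and a maximum between-species mean-TPM difference of at
    least ``min_diff`` in some species pair."""
    means = expression.species_means(tissue=tissue)
    missing = set(de_table["gene_id"]) - set(means.index)
    if missing:
        raise ValueError(f"DE-table genes absent from expression matrix: {sorted(missing)[:5]}")
    out: list[DegRecord] = []
    vals = means.values
    idx = {g: i for i, g in enumerate(means.index)}
    for row in de_table.itertuples():
        if row.q_value >= q_max:
            continue
        v = vals[idx[row.gene_id]]
        diff = float(np.max(v) - np.min(v))
        if diff >= min_diff:
            out.append(DegRecord(row.gene_id, float(row.q_value), diff))
    return out


def pfdmr_overlap_test(
    assigned: list[PfDmr],
    degs: list[DegRecord],
    universe: set[str],
    feature_map: FeatureMap | None = None,
) -> tuple[list[PfDmr], TestResult, pd.DataFrame]:
    """pfDMRs and the exact hypergeometric overlap test.

    pfDMRs are assigned DMRs whose gene is a filtered DEG.  The test draws
    n = genes with >= 1 assigned DMR from a universe of N genes holding
    K = DEG genes and observes k genes in the intersection; the reported p
    is the upper tail P(X >= k).  The composition table gives pfDMR
    fractions per location class plus TE/CGI content flags when a feature
    map is supplied.
    """
    if not universe:
        raise ValueError("empty gene universe")
    deg_genes = {d.gene_id for d in degs} & universe
    dmr_genes = {a.gene_id for a in assigned} & universe
    inter = deg_genes & dmr_genes
    pf = [a for a in assigned if a.gene_id in deg_genes]
    p = hypergeom_tail(len(universe), len(deg_genes), len(dmr_genes), len(inter))
    result = TestResult(
        float(len(inter)), p, "hypergeometric_overlap",
        n=len(universe),
        extra={"N": len(universe), "K": len(deg_genes), "n": len(dmr_genes), "k": len(inter)},
    )
    rows = []
    for cls in ("promoter", "gene_body", "vicinity_0.5_4kb"):
        members = [a for a in pf if a.location_class == cls]
        frac = len(members) / len(pf) if pf else 0.0
        te_frac = cgi_frac = np.nan
        if feature_map is not None and members:
            te_hits = sum(1 for a in members if feature_map.te.overlaps(*_interval_of(a.dmr)))
            cgi_hits = sum(
                1
                for a in members
                if feature_map.cgi_promoter.overlaps(*_interval_of(a.dmr))
                or feature_map.cgi_orphan.overlaps(*_interval_of(a.dmr))
            )
            te_frac = te_hits / len(members)
            cgi_frac = cgi_hits / len(members)
        rows.append((cls, len(members), frac, te_frac, cgi_frac))
    table = pd.DataFrame(rows, columns=["location_class", "n_pfdmrs", "fraction", "te_fraction", "cgi_fraction"])
    return pf, result, table


@dataclass
class BinProfile:
    """Gene bins along one axis (expression or methylation) with per-bin
    mean expression and methylation."""

    axis: str  # "expression" | "methylation"
    bins: dict[str, list[str]]  # label -> gene ids
    mean_expression: dict[str, float]
    mean_methylation: dict[str, float]

    def labels(self) -> list[str]:
        return list(self.bins)


def _gene_feature_methylation(
    samples: list[MethylomeSample],
    feature_by_gene: dict[str, tuple[str, int, int]],
    window: int = 50,
) -> pd.Series:
    """Mean 50-bp-window methylation per gene feature, averaged over the
    given samples.  Genes whose feature has no covered window are NaN."""
    tracks = []
    for s in samples:
        track = window_methylation(s, window=window)
        tracks.append(
            {c: (ser.index.values, ser.values) for c, ser in track.values.items()}
        )
    out = {}
    for gid, (contig, start, end) in feature_by_gene.items():
        vals = []
        for track in tracks:
            if contig not in track:
                continue
            starts, values = track[contig]
            # windows overlapping [start, end) by >= 1 bp
            lo = int(np.searchsorted(starts, start - window + 1, side="left"))
            hi = int(np.searchsorted(starts, end, side="left"))
            if hi > lo:
                vals.append(float(values[lo:hi].mean()))
        out[gid] = float(np.mean(vals)) if vals else np.nan
    return pd.Series(out)


def bin_and_correlate(
    expression: ExpressionMatrix,
    methylomes: list[MethylomeSample],
    feature_map: FeatureMap,
    species: str,
    tissue: str,
    min_genes: int = 30,
) -> tuple[BinProfile, BinProfile, dict[str, TestResult]]:
    """Expression/methylation bin profiles and gene-wise correlations.

    Expression bins: OFF (TPM 0 in every replicate of the species/tissue)
    plus 10 equal-count bins of expressed genes (increasing expression).
    Methylation bins (promoter methylation): 0% plus ten 10%-increment
    bins.  Spearman rho is computed gene-wise between mean methylation and
    mean TPM, separately for promoters and gene bodies.
    """
    rep_cols = expression.replicate_columns(species, tissue)
    if not rep_cols:
        raise ValueError(f"no expression samples for {species}/{tissue}")
    group = [m for m in methylomes if m.species == species and m.tissue == tissue]
    if not group:
        raise ValueError(f"no methylome samples for {species}/{tissue}")
    tpm = expression.tpm[rep_cols]
    mean_tpm = tpm.mean(axis=1)
    off_mask = (tpm == 0).all(axis=1)

    prom_meth = _gene_feature_methylation(group, feature_map.promoter_by_gene)
    body_meth = _gene_feature_methylation(group, feature_map.gene_body_by_gene)

    measured = mean_tpm.index[mean_tpm.notna() & prom_meth.reindex(mean_tpm.index).notna()]
    if len(measured) < min_genes:
        raise ValueError(f"only {len(measured)} genes with both measures (< {min_genes})")

    # expression axis: OFF + 10 equal-count bins of expressed genes
    expressed = [g for g in measured if not off_mask.get(g, False)]
    order = sorted(expressed, key=lambda g: (mean_tpm[g], g))
    chunks = np.array_split(np.array(order, dtype=object), 10)
    expr_bins: dict[str, list[str]] = {"OFF": [g for g in measured if off_mask.get(g, False)]}
    for i, chunk in enumerate(chunks, start=1):
        expr_bins[f"expr_{i:02d}"] = [str(g) for g in chunk]
    expr_profile = BinProfile(
        "expression",
        expr_bins,
        {k: float(mean_tpm[v].mean()) if v else np.nan for k, v in expr_bins.items()},
        {k: float(prom_meth[v].mean()) if v else np.nan for k, v in expr_bins.items()},
    )

    # methylation axis: exactly-zero bin + ten 10% increments (0,10] ... (90,100]
    meth_bins: dict[str, list[str]] = {"meth_0": []}
    for i in range(1, 11):
        meth_bins[f"meth_{(i - 1) * 10}_{i * 10}"] = []
    for g in measured:
        v = prom_meth[g] * 100.0
        if v == 0:
            meth_bins["meth_0"].append(g)
        else:
            i = min(10, int(np.ceil(v / 10.0)))
            meth_bins[f"meth_{(i - 1) * 10}_{i * 10}"].append(g)
    meth_profile = BinProfile(
        "methylation",
        meth_bins,
        {k: float(mean_tpm[v].mean()) if v else np.nan for k, v in meth_bins.items()},
        {k: float(prom_meth[v].mean()) if v else np.nan for k, v in meth_bins.items()},
    )

    tests: dict[str, TestResult] = {}
    tests["promoter"] = spearman_rho(prom_meth[measured].values, mean_tpm[measured].values)
    body_measured = [g for g in measured if pd.notna(body_meth.get(g, np.nan))]
    if len(body_measured) >= min_genes:
        tests["gene_body"] = spearman_rho(
            body_meth[body_measured].values, mean_tpm[body_measured].values
        )
    return expr_profile, meth_profile, tests


@dataclass
class ClusterResult:
    correlation: pd.DataFrame
    linkage: np.ndarray
    newick: str
    sample_ids: list[str]
    top_split: dict[str, int]  # sample -> 1/2 from cutting the top merge

    def clusters(self, k: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.sample_ids, (int(x) for x in labels)))


def _to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_methylomes(matrix: pd.DataFrame) -> ClusterResult:
    """Hierarchically cluster methylome samples.

    ``matrix`` holds methylation fractions at conserved CpGs (rows) per
    sample (columns).  Samples are compared by Spearman rank correlation;
    clustering is complete-linkage on Euclidean distances between the
    correlation-matrix rows.  Columns are ordered by sample id first so
    ties break deterministically.
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least three samples to cluster")
    matrix = matrix[sorted(matrix.columns)]
    corr = matrix.corr(method="spearman")
    dist = pdist(corr.values, metric="euclidean")
    Z = hierarchy.linkage(dist, method="complete")
    tree = hierarchy.to_tree(Z)
    labels = list(corr.columns)
    newick = _to_newick(tree, labels) + ";"
    split = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    return ClusterResult(
        correlation=corr,
        linkage=Z,
        newick=newick,
        sample_ids=labels,
        top_split=dict(zip(labels, (int(x) for x in split))),
    )
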