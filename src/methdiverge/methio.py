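"""Loading and shaping per-CpG methylation counts.

Input is the 7-column cytosine report (contig, 1-based position, strand,
count_methylated, count_unmethylated, context, trinucleotide) as emitted by
standard WGBS methylation extractors.  A CpG is symmetric: the plus-strand
C and the minus-strand G one base downstream carry the same methylation
state, so their counts are summed onto the C position ("destranding")
before the coverage filter is applied.  Internally all coordinates are
0-based; levels are methylated / (methylated + unmethylated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bsref import SnpRecord

log = logging.getLogger(__name__)

# paper-style coverage rule: keep sites with > 4 and <= 100 reads
DEFAULT_MIN_COVERAGE = 5
DEFAULT_MAX_COVERAGE = 100

REPORT_COLUMNS = ["contig", "position", "strand", "count_methylated", "count_unmethylated", "context", "trinucleotide"]

__all__ = [
    "MethylomeSample",
    "WindowTrack",
    "load_methylome",
    "window_methylation",
    "estimate_nonconversion",
    "conserved_cpg_matrix",
]


@dataclass
class MethylomeSample:
    """Destranded, coverage-filtered CpG counts for one individual tissue.

    ``sites`` is a DataFrame with columns contig, position (0-based C of
    the CpG), count_methylated, count_unmethylated, sorted and unique on
    (contig, position).
    """

    sample_id: str
    species: str
    tissue: str
    replicate: int
    sites: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        if self.sites is not None:
            self.sites = (
                self.sites.sort_values(["contig", "position"], kind="mergesort")
                .drop_duplicates(["contig", "position"])
                .reset_index(drop=True)
            )

    @property
    def coverage(self) -> pd.Series:
        return self.sites["count_methylated"] + self.sites["count_unmethylated"]

    @property
    def levels(self) -> pd.Series:
        cov = self.coverage
        return self.sites["count_methylated"] / cov.where(cov > 0)

    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class WindowTrack:
    """Mean methylation per fixed non-overlapping window; windows with no
    CpG are absent (missing, not zero)."""

    window: int
    values: dict[str, pd.Series]  # contig -> Series indexed by window start

    def get(self, contig: str, start: int) -> float | None:
        s = self.values.get(contig)
        if s is None or start not in s.index:
            return None
        return float(s.loc[start])

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for contig in sorted(self.values):
                s = self.values[contig]
                for start, val in s.items():
                    fh.write(f"{contig}\t{start}\t{start + self.window}\t{val:.6g}\n")


def _read_report(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=REPORT_COLUMNS,
            dtype={
                "contig": str,
                "position": np.int64,
                "strand": str,
                "count_methylated": np.int64,
                "count_unmethylated": np.int64,
                "context": str,
                "trinucleotide": str,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed cytosine report {path}: {exc}") from exc
    if df["position"].min() is not None and len(df) and df["position"].min() < 1:
        bad = int(df.index[df["position"] < 1][0]) + 1
        raise ValueError(f"non-positive position in {path} at line {bad}")
    return df


def load_methylome(
    path: str | Path,
    sample_id: str | None = None,
    species: str = "",
    tissue: str = "",
    replicate: int = 0,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    max_coverage: int = DEFAULT_MAX_COVERAGE,
    destrand: bool = True,
) -> MethylomeSample:
    """Load a cytosine report into a MethylomeSample.

    Non-CG context rows are dropped.  With ``destrand`` (default) the
    plus-strand C counts and the paired minus-strand G counts (file
    position + 1) are summed onto the C position; a minus-strand record
    without a plus partner keeps its own site at position - 1 with a
    warning.  The coverage filter (min <= coverage <= max) runs after
    destranding; coordinates come out 0-based.
    """
    df = _read_report(path)
    cg = df[df["context"] == "CG"]
    if cg.empty:
        log.warning("%s: no CG-context rows, sample is empty", path)
    if destrand:
        plus = cg[cg["strand"] == "+"]
        minus = cg[cg["strand"] == "-"]
        # 0-based C position of the CpG each row belongs to
        plus_keyed = plus.assign(cpos=plus["position"] - 1)
        minus_keyed = minus.assign(cpos=minus["position"] - 2)
        merged = pd.concat([plus_keyed, minus_keyed])
        orphan_minus = set(minus_keyed["cpos"]) - set(plus_keyed["cpos"])
        if orphan_minus:
            log.warning("%s: %d minus-strand records without a CpG partner", path, len(orphan_minus))
        sites = (
            merged.groupby(["contig", "cpos"], as_index=False)[["count_methylated", "count_unmethylated"]]
            .sum()
            .rename(columns={"cpos": "position"})
        )
    else:
        sites = cg.assign(position=cg["position"] - 1)[
            ["contig", "position", "count_methylated", "count_unmethylated"]
        ].copy()
    cov = sites["count_methylated"] + sites["count_unmethylated"]
    sites = sites[(cov >= min_coverage) & (cov <= max_coverage)].reset_index(drop=True)
    return MethylomeSample(
        sample_id=sample_id or Path(path).stem,
        species=species,
        tissue=tissue,
        replicate=replicate,
        sites=sites,
    )


def window_methylation(sample: MethylomeSample, window: int = 50, pooled: bool = False) -> WindowTrack:
    """Mean methylation over non-overlapping windows (default 50 bp).

    A CpG belongs to the window containing its C start position (half-open
    [w*k, w*(k+1))).  The default window value is the unweighted mean of
    per-site levels; ``pooled`` switches to pooled counts
    (sum methylated / sum coverage) instead.
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    values: dict[str, pd.Series] = {}
    sites = sample.sites
    if sites is None or sites.empty:
        return WindowTrack(window, values)
    df = sites.assign(win=(sites["position"] // window) * window)
    cov = df["count_methylated"] + df["count_unmethylated"]
    if pooled:
        msum = df.groupby(["contig", "win"])["count_methylated"].sum()
        covsum = df.assign(cov=cov).groupby(["contig", "win"])["cov"].sum()
        level = msum / covsum
    else:
        level = df.assign(level=df["count_methylated"] / cov).groupby(["contig", "win"])["level"].mean()
    for contig, sub in level.groupby(level="contig"):
        values[str(contig)] = sub.droplevel("contig").sort_index()
    return WindowTrack(window, values)


def estimate_nonconversion(path: str | Path, spike_contig: str) -> float:
    """Bisulfite non-conversion rate from an unmethylated spike-in contig.

    rate = methylated calls / total calls over all cytosine contexts on the
    spike contig; conversion efficiency is 1 - rate.
    """
    df = _read_report(path)
    spike = df[df["contig"] == spike_contig]
    total = int(spike["count_methylated"].sum() + spike["count_unmethylated"].sum())
    if total == 0:
        raise ValueError(f"no calls on spike contig {spike_contig!r} in {path}")
    return float(spike["count_methylated"].sum() / total)


def conserved_cpg_matrix(
    samples: list[MethylomeSample],
    snps: list[SnpRecord] | None = None,
) -> pd.DataFrame:
    """Methylation-level matrix at conserved CpG sites.

    Rows are CpG positions (a) covered (post-filter) in every sample and
    (b) whose C or G base does not carry a bisulfite-confounded C>T/G>A SNP
    in any species; columns are sample ids; values are methylation
    fractions.  Raises on an empty intersection.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    levels = []
    for s in samples:
        lv = s.levels
        lv.index = pd.MultiIndex.from_frame(s.sites[["contig", "position"]])
        levels.append(lv.rename(s.sample_id))
    mat = pd.concat(levels, axis=1, join="inner")
    if snps:
        bad = set()
        for snp in snps:
            if (snp.ref_allele, snp.alt_allele) in (("C", "T"), ("G", "A")):
                p0 = snp.position - 1
                bad.add((snp.contig, p0))  # site where the C itself mutated
                bad.add((snp.contig, p0 - 1))  # CpG whose G (at p0) mutated
        keep = [idx for idx in mat.index if (idx[0], idx[1]) not in bad]
        mat = mat.loc[keep]
    if mat.empty:
        raise ValueError(
            "no CpG site is covered in every sample; relax the coverage thresholds"
        )
    return mat
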