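"""Differential methylation testing, DMR segmentation and classification.

Per-CpG two-group testing uses a beta-binomial Wald/score statistic: group
methylation levels are pooled-count proportions, the beta-binomial
overdispersion phi is estimated per site by method of moments from the
replicate scatter and stabilised by pooling the moment sums over a 500-bp
neighbourhood, and the variance of the group difference uses the pooled
proportion (score-type), which keeps the test calibrated under the null.
With a single replicate per group the test falls back to Fisher's exact
test on the 2x2 count table.

Significant CpGs (site p below ``site_p``) are chained while consecutive
gaps stay within ``max_gap``; a chained region is reported as a DMR only if
it is at least ``min_length`` bp long, holds at least ``min_cpgs`` CpGs,
shows an absolute mean group difference of at least ``min_diff`` and has at
least ``min_sig_fraction`` significant CpGs.  Defaults mirror the standard
comparative criteria: >=50 bp, >=4 CpG, >=25% difference, p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .methio import MethylomeSample

log = logging.getLogger(__name__)

_Z_CAP = 37.0  # |z| beyond this underflows the normal tail anyway

__all__ = [
    "DmrParams",
    "Dmr",
    "ClassifiedDmr",
    "percpg_test",
    "call_dmrs",
    "classify_species_dmrs",
    "classify_tissue_scope",
    "write_dmr_bed",
]


@dataclass
class DmrParams:
    min_diff: float = 0.25
    min_length: int = 50
    min_cpgs: int = 4
    site_p: float = 0.05
    max_gap: int = 100
    min_sig_fraction: float = 0.5
    smooth_bp: int = 500  # neighbourhood for dispersion pooling + smoothing
    smooth: bool = True  # window-pooled segmentation p-values

    def __post_init__(self):
        if not (0 < self.min_diff <= 1):
            raise ValueError("min_diff must lie in (0, 1]")
        for name in ("min_length", "min_cpgs", "max_gap", "smooth_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.site_p < 1):
            raise ValueError("site_p must lie in (0, 1)")
        if not (0 < self.min_sig_fraction <= 1):
            raise ValueError("min_sig_fraction must lie in (0, 1]")


@dataclass
class Dmr:
    contig: str
    start: int  # 0-based half-open
    end: int
    n_cpgs: int
    mean_diff: float  # group A minus group B
    region_p: float
    comparison: tuple[str, str]
    tissue: str = ""
    direction: str = ""  # "hyper"/"hypo" in group A

    def __post_init__(self):
        if not self.direction:
            self.direction = "hyper" if self.mean_diff > 0 else "hypo"

    @property
    def length(self) -> int:
        return self.end - self.start

    def direction_for(self, species: str) -> int:
        """+1 if this DMR is hypermethylated in ``species``, -1 if hypo."""
        sign = 1 if self.mean_diff > 0 else -1
        if species == self.comparison[0]:
            return sign
        if species == self.comparison[1]:
            return -sign
        raise ValueError(f"{species!r} not part of comparison {self.comparison}")


@dataclass
class ClassifiedDmr:
    contig: str
    start: int
    end: int
    focal_species: str
    direction: int  # +1 hyper / -1 hypo in the focal species
    tissue: str
    tissue_scope: str = "unassigned"


# ---------------------------------------------------------------------------
# per-CpG testing


def _group_moments(m: np.ndarray, cov: np.ndarray):
    """Per-site pooled proportion plus method-of-moments sums for phi.

    Returns (p_hat, msum, covsum, mom_num, mom_den); the last two are the
    numerator/denominator contributions to phi = num/den, zero when the
    group has a single replicate.
    """
    msum = m.sum(axis=1)
    covsum = cov.sum(axis=1)
    p_hat = np.divide(msum, covsum, out=np.zeros_like(msum, dtype=float), where=covsum > 0)
    R = m.shape[1]
    if R < 2:
        z = np.zeros_like(p_hat)
        return p_hat, msum, covsum, z, z
    with np.errstate(divide="ignore", invalid="ignore"):
        prep = np.where(cov > 0, m / np.maximum(cov, 1), np.nan)
    pbar = np.nanmean(prep, axis=1)
    ss = np.nansum((prep - pbar[:, None]) ** 2, axis=1) * R / (R - 1)
    ptilde = (msum + 0.5) / (covsum + 1.0)
    vq = ptilde * (1 - ptilde)
    inv_n = np.where(cov > 0, 1.0 / np.maximum(cov, 1), 0.0).sum(axis=1)
    frac = np.where(cov > 0, (cov - 1.0) / np.maximum(cov, 1), 0.0).sum(axis=1)
    num = ss - vq * inv_n
    den = vq * frac
    return p_hat, msum, covsum, num, den


def _smooth_ratio(
    positions: np.ndarray,
    num: np.ndarray,
    den: np.ndarray,
    window: int,
    shrink_sites: int = 30,
) -> np.ndarray:
    """phi estimate from moment sums pooled over +/- window/2 bp.

    The windowed method-of-moments ratio is shrunk toward the genome-wide
    ratio with a pseudo-weight of ``shrink_sites`` sites; with few
    replicates the per-window ratio alone is noisy enough to distort the
    site variance over whole windows."""
    half = window // 2
    cnum = np.concatenate(([0.0], np.cumsum(num)))
    cden = np.concatenate(([0.0], np.cumsum(den)))
    lo = np.searchsorted(positions, positions - half, side="left")
    hi = np.searchsorted(positions, positions + half, side="right")
    snum = cnum[hi] - cnum[lo]
    sden = cden[hi] - cden[lo]
    total_den = float(cden[-1])
    if total_den > 0:
        phi_global = max(0.0, float(cnum[-1]) / total_den)
        dbar = total_den / len(positions)
        snum = snum + shrink_sites * dbar * phi_global
        sden = sden + shrink_sites * dbar
    phi = np.divide(snum, sden, out=np.zeros_like(snum), where=sden > 0)
    return np.clip(phi, 0.0, 0.8)


def _window_sum(positions: np.ndarray, values: np.ndarray, window: int) -> np.ndarray:
    """Sum of ``values`` over sites within +/- window/2 bp of each site."""
    half = window // 2
    c = np.concatenate(([0.0], np.cumsum(values)))
    lo = np.searchsorted(positions, positions - half, side="left")
    hi = np.searchsorted(positions, positions + half, side="right")
    return c[hi] - c[lo]


def _site_test_arrays(
    positions: np.ndarray,
    mA: np.ndarray,
    covA: np.ndarray,
    mB: np.ndarray,
    covB: np.ndarray,
    smooth_bp: int = 500,
    smooth: bool = False,
):
    """Vectorised beta-binomial score test over aligned sites of one contig.

    Returns ``(diff, p_raw, p_seg)``: the raw per-site group difference and
    two-sided p, plus the segmentation p.  With ``smooth`` the segmentation
    p pools counts over the 500-bp neighbourhood (the moving-window
    smoothing standard WGBS differential callers apply), which restores
    per-site power at low replicate numbers; the raw statistics are left
    untouched so effect sizes and combined region p-values stay per-site.
    """
    pA, msA, csA, numA, denA = _group_moments(mA, covA)
    pB, msB, csB, numB, denB = _group_moments(mB, covB)
    if np.any(csA == 0) or np.any(csB == 0):
        raise ValueError("site with all-zero coverage in one group")
    phi = _smooth_ratio(positions, numA + numB, denA + denB, smooth_bp)
    diff = pA - pB
    infl_A = (covA * (1.0 + (covA - 1.0) * phi[:, None])).sum(axis=1)
    infl_B = (covB * (1.0 + (covB - 1.0) * phi[:, None])).sum(axis=1)

    def score_p(ma, ca, ia, mb, cb, ib):
        # pooled-proportion (score) variance; a degenerate pooled p of 0 or
        # 1 forces equal groups, where p = 1 is exact
        pp = (ma + mb) / (ca + cb)
        vq = pp * (1 - pp)
        var = vq * (ia / np.maximum(ca, 1) ** 2 + ib / np.maximum(cb, 1) ** 2)
        d = ma / np.maximum(ca, 1) - mb / np.maximum(cb, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var > 0, d / np.sqrt(var), 0.0)
        z = np.clip(z, -_Z_CAP, _Z_CAP)
        return 2.0 * sps.norm.sf(np.abs(z))

    p_raw = score_p(msA, csA, infl_A, msB, csB, infl_B)
    if not smooth:
        return diff, p_raw, p_raw
    sA = _window_sum(positions, msA, smooth_bp)
    cA = _window_sum(positions, csA, smooth_bp)
    iA = _window_sum(positions, infl_A, smooth_bp)
    sB = _window_sum(positions, msB, smooth_bp)
    cB = _window_sum(positions, csB, smooth_bp)
    iB = _window_sum(positions, infl_B, smooth_bp)
    p_seg = score_p(sA, cA, iA, sB, cB, iB)
    return diff, p_raw, p_seg


def percpg_test(group_a, group_b) -> tuple[float, float]:
    """Two-group differential methylation test at a single CpG.

    ``group_a``/``group_b`` are per-replicate ``(methylated, coverage)``
    pairs.  With >= 2 replicates in both groups a beta-binomial Wald/score
    test (method-of-moments dispersion from this site alone) is used; with
    a single replicate in either group, Fisher's exact test on the pooled
    2x2 table.  Returns (signed difference A - B, two-sided p).
    """
    a = np.asarray(group_a, dtype=float).reshape(-1, 2)
    b = np.asarray(group_b, dtype=float).reshape(-1, 2)
    if a.shape[0] < 1 or b.shape[0] < 1:
        raise ValueError("each group needs at least one replicate")
    if a[:, 1].sum() == 0 or b[:, 1].sum() == 0:
        raise ValueError("all-zero coverage in one group")
    if min(a.shape[0], b.shape[0]) < 2:
        ma, ca = a[:, 0].sum(), a[:, 1].sum()
        mb, cb = b[:, 0].sum(), b[:, 1].sum()
        diff = ma / ca - mb / cb
        table = [[ma, ca - ma], [mb, cb - mb]]
        _, p = sps.fisher_exact(np.asarray(table, dtype=np.int64), alternative="two-sided")
        return float(diff), float(p)
    pos = np.zeros(1, dtype=np.int64)
    diff, p, _ = _site_test_arrays(
        pos,
        a[None, :, 0],
        a[None, :, 1],
        b[None, :, 0],
        b[None, :, 1],
        smooth_bp=1,
    )
    return float(diff[0]), float(p[0])


def site_tests(
    samples_a: list[MethylomeSample],
    samples_b: list[MethylomeSample],
    params: DmrParams | None = None,
) -> pd.DataFrame:
    """Per-CpG differential table over all sites covered in every sample.

    Columns: contig, position, diff (group A - B), p (raw per-site),
    p_smoothed (window-pooled segmentation p)."""
    params = params or DmrParams()
    frames = []
    for contig, positions, mA, covA, mB, covB in _aligned_counts(samples_a, samples_b):
        diff, p_raw, p_seg = _site_test_arrays(
            positions, mA, covA, mB, covB, params.smooth_bp, smooth=params.smooth
        )
        frames.append(
            pd.DataFrame(
                {"contig": contig, "position": positions, "diff": diff, "p": p_raw, "p_smoothed": p_seg}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["contig", "position", "diff", "p", "p_smoothed"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# segmentation


def _aligned_counts(samples_a: list[MethylomeSample], samples_b: list[MethylomeSample]):
    """Inner-join sites covered in every sample of both groups.

    Yields (contig, positions, mA, covA, mB, covB) per contig."""
    cols_m, cols_c = [], []
    for s in samples_a + samples_b:
        idx = pd.MultiIndex.from_frame(s.sites[["contig", "position"]])
        cols_m.append(pd.Series(s.sites["count_methylated"].values, index=idx, name=f"m_{s.sample_id}"))
        cols_c.append(pd.Series(s.sites["count_methylated"].values + s.sites["count_unmethylated"].values, index=idx, name=f"c_{s.sample_id}"))
    meth = pd.concat(cols_m, axis=1, join="inner")
    cov = pd.concat(cols_c, axis=1, join="inner")
    nA = len(samples_a)
    for contig in meth.index.get_level_values(0).unique():
        sub_m = meth.xs(contig, level=0)
        sub_c = cov.xs(contig, level=0)
        order = np.argsort(sub_m.index.values, kind="mergesort")
        positions = sub_m.index.values[order].astype(np.int64)
        m = sub_m.values[order]
        c = sub_c.values[order]
        yield str(contig), positions, m[:, :nA], c[:, :nA], m[:, nA:], c[:, nA:]


def _stouffer(p: np.ndarray, diff: np.ndarray) -> float:
    z = sps.norm.isf(np.minimum(p, 1.0) / 2.0)
    z = np.clip(z, -_Z_CAP, _Z_CAP) * np.sign(np.where(diff == 0, 1.0, diff))
    Z = z.sum() / np.sqrt(len(z))
    return float(min(1.0, 2.0 * sps.norm.sf(abs(Z))))


def call_dmrs(
    samples_a: list[MethylomeSample],
    samples_b: list[MethylomeSample],
    params: DmrParams | None = None,
    comparison: tuple[str, str] | None = None,
    tissue: str = "",
) -> list[Dmr]:
    """Call DMRs between two groups of methylome samples.

    Only sites covered in every sample enter the test.  See the module
    docstring for the segmentation rules; output regions never overlap and
    every reported DMR satisfies all four thresholds.
    """
    params = params or DmrParams()
    if comparison is None:
        comparison = (
            samples_a[0].species or "groupA",
            samples_b[0].species or "groupB",
        )
    ids_a = {s.sample_id for s in samples_a}
    if ids_a & {s.sample_id for s in samples_b}:
        raise ValueError("groups must be disjoint")
    dmrs: list[Dmr] = []
    n_sites_total = 0
    for contig, positions, mA, covA, mB, covB in _aligned_counts(samples_a, samples_b):
        n_sites_total += len(positions)
        diff, p_raw, p_seg = _site_test_arrays(
            positions, mA, covA, mB, covB, params.smooth_bp, smooth=params.smooth
        )
        sig = p_seg < params.site_p
        if not sig.any():
            continue
        cand = np.flatnonzero(sig)
        gaps = np.diff(positions[cand])
        breaks = np.flatnonzero(gaps > params.max_gap)
        chain_starts = np.concatenate(([0], breaks + 1))
        chain_ends = np.concatenate((breaks, [cand.size - 1]))
        for cs, ce in zip(chain_starts, chain_ends):
            members = cand[cs : ce + 1]
            # boundary refinement: window smoothing bleeds significance a
            # few hundred bp past a region's true edge, so the reported
            # region is clipped to the outermost chain members that are
            # individually significant in the same direction
            chain_sign = np.sign(np.sum(diff[members]))
            anchor = members[
                (p_raw[members] < params.site_p)
                & (np.sign(diff[members]) == (chain_sign if chain_sign != 0 else 1))
            ]
            if anchor.size == 0:
                continue
            start = int(positions[anchor[0]])
            end = int(positions[anchor[-1]]) + 2  # cover the G of the last CpG
            inside = slice(int(anchor[0]), int(anchor[-1]) + 1)
            n_cpgs = inside.stop - inside.start
            mean_diff = float(np.mean(diff[inside]))
            sig_frac = float(np.mean(sig[inside]))
            if (
                end - start >= params.min_length
                and n_cpgs >= params.min_cpgs
                and abs(mean_diff) >= params.min_diff
                and sig_frac >= params.min_sig_fraction
            ):
                region_p = _stouffer(p_raw[inside], diff[inside])
                dmrs.append(
                    Dmr(contig, start, end, n_cpgs, mean_diff, region_p, comparison, tissue)
                )
    if n_sites_total == 0:
        log.warning("no CpG site covered in every sample of both groups; empty result")
    dmrs.sort(key=lambda d: (d.contig, d.start))
    _assert_valid(dmrs, params)
    return dmrs


def _assert_valid(dmrs: list[Dmr], params: DmrParams) -> None:
    prev: Dmr | None = None
    for d in dmrs:
        assert d.length >= params.min_length
        assert d.n_cpgs >= params.min_cpgs
        assert abs(d.mean_diff) >= params.min_diff
        if prev is not None and prev.contig == d.contig:
            assert d.start >= prev.end, "overlapping DMRs in one comparison"
        prev = d


# ---------------------------------------------------------------------------
# classification


def _get_pair(pairwise: dict, a: str, b: str) -> list[Dmr]:
    if (a, b) in pairwise:
        return pairwise[(a, b)]
    if (b, a) in pairwise:
        return pairwise[(b, a)]
    raise ValueError(f"missing pairwise DMR list for ({a}, {b})")


def _overlap(d1, d2) -> bool:
    return d1.contig == d2.contig and d1.start < d2.end and d2.start < d1.end


def _merge_regions(regions: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    regions = sorted(regions)
    out: list[list] = []
    for contig, s, e in regions:
        if out and out[-1][0] == contig and s <= out[-1][2]:
            out[-1][2] = max(out[-1][2], e)
        else:
            out.append([contig, s, e])
    return [tuple(r) for r in out]


def classify_species_dmrs(
    pairwise: dict[tuple[str, str], list[Dmr]],
    species: tuple[str, str, str],
    tissue: str = "",
) -> list[ClassifiedDmr]:
    """Identify species-specific methylome patterns from three pairwise
    DMR lists of one tissue.

    A region is specific to species S when DMRs overlapping it (>= 1 bp)
    exist in both comparisons involving S with the same direction relative
    to S, and no DMR between the two other species overlaps it.  The output
    region is the coordinate union of the supporting DMRs; overlapping
    supports of the same species and direction are merged.
    """
    if len(species) != 3:
        raise ValueError("species must be a triple")
    for a, b in ((species[0], species[1]), (species[0], species[2]), (species[1], species[2])):
        _get_pair(pairwise, a, b)  # raises if any pair is missing
    out: list[ClassifiedDmr] = []
    for focal in species:
        others = [s for s in species if s != focal]
        list1 = _get_pair(pairwise, focal, others[0])
        list2 = _get_pair(pairwise, focal, others[1])
        veto = _get_pair(pairwise, others[0], others[1])
        for direction in (+1, -1):
            l1 = [d for d in list1 if d.direction_for(focal) == direction]
            l2 = [d for d in list2 if d.direction_for(focal) == direction]
            unions = []
            for d1 in l1:
                for d2 in l2:
                    if _overlap(d1, d2):
                        unions.append(
                            (d1.contig, min(d1.start, d2.start), max(d1.end, d2.end))
                        )
            for contig, s, e in _merge_regions(unions):
                probe = Dmr(contig, s, e, 0, float(direction), 1.0, (focal, "other"))
                if any(_overlap(probe, v) for v in veto):
                    continue
                out.append(ClassifiedDmr(contig, s, e, focal, direction, tissue))
    out.sort(key=lambda c: (c.contig, c.start, c.focal_species))
    return out


def classify_tissue_scope(
    liver: list[ClassifiedDmr],
    muscle: list[ClassifiedDmr],
    tissues: tuple[str, str] = ("liver", "muscle"),
) -> tuple[list[ClassifiedDmr], pd.DataFrame]:
    """Split species-specific regions into tissue-specific and multi-tissue.

    A liver region overlapping (>= 1 bp) a muscle region of the same focal
    species and direction becomes one multi-tissue record spanning the
    coordinate union; unmatched records stay tissue-specific.  Returns the
    combined list plus a per-species proportion table whose rows sum to 1.
    """
    species_l = {c.focal_species for c in liver}
    species_m = {c.focal_species for c in muscle}
    if species_l and species_m and species_l.isdisjoint(species_m):
        raise ValueError("no species in common between tissue lists")
    records: list[ClassifiedDmr] = []
    matched_m: set[int] = set()
    for cl in liver:
        partners = [
            j
            for j, cm in enumerate(muscle)
            if cm.focal_species == cl.focal_species
            and cm.direction == cl.direction
            and cm.contig == cl.contig
            and cl.start < cm.end
            and cm.start < cl.end
        ]
        if partners:
            start = min([cl.start] + [muscle[j].start for j in partners])
            end = max([cl.end] + [muscle[j].end for j in partners])
            matched_m.update(partners)
            records.append(
                ClassifiedDmr(cl.contig, start, end, cl.focal_species, cl.direction, "both", "multi_tissue")
            )
        else:
            records.append(
                ClassifiedDmr(cl.contig, cl.start, cl.end, cl.focal_species, cl.direction, tissues[0], f"{tissues[0]}_specific")
            )
    for j, cm in enumerate(muscle):
        if j not in matched_m:
            records.append(
                ClassifiedDmr(cm.contig, cm.start, cm.end, cm.focal_species, cm.direction, tissues[1], f"{tissues[1]}_specific")
            )
    scopes = [f"{tissues[0]}_specific", f"{tissues[1]}_specific", "multi_tissue"]
    all_species = sorted(species_l | species_m)
    rows = []
    for sp in all_species:
        counts = {
            scope: sum(1 for r in records if r.focal_species == sp and r.tissue_scope == scope)
            for scope in scopes
        }
        total = sum(counts.values())
        rows.append([counts[s] / total if total else 0.0 for s in scopes])
    table = pd.DataFrame(rows, index=all_species, columns=scopes)
    return records, table


def read_dmr_bed(path) -> list[Dmr]:
    """Read DMRs from the BED6+ layout written by :func:`write_dmr_bed`."""
    dmrs: list[Dmr] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                contig, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                n_cpgs, mean_diff, region_p = int(parts[6]), float(parts[7]), float(parts[8])
                tissue = parts[9] if len(parts) > 9 else ""
                a, _, b = name.partition("_vs_")
                dmrs.append(Dmr(contig, start, end, n_cpgs, mean_diff, region_p, (a, b), tissue))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"unparseable DMR BED row at line {lineno}: {exc}") from exc
    return dmrs


def write_dmr_bed(dmrs: list[Dmr], path) -> None:
    """Export DMRs as BED6+ (name=comparison, score=1000*|mean diff|)."""
    with open(path, "w") as fh:
        for d in dmrs:
            name = f"{d.comparison[0]}_vs_{d.comparison[1]}"
            score = int(min(1000, round(1000 * abs(d.mean_diff))))
            fh.write(
                f"{d.contig}\t{d.start}\t{d.end}\t{name}\t{score}\t.\t"
                f"{d.n_cpgs}\t{d.mean_diff:.4f}\t{d.region_p:.3g}\t{d.tissue}\n"
            )
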