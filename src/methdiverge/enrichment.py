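"""Permutation-based observed/expected enrichment of DMRs.

Expected overlap counts come from shuffling the DMR intervals uniformly
across the genome (lengths preserved, contig chosen with probability
proportional to its length among contigs long enough), re-counting per
feature category, and averaging over iterations.  The default of 1000
shuffle iterations for feature enrichment and 500 for the TE-divergence
profile follows common practice for this analysis.  Overlap is counted per
DMR (a DMR overlapping a category counts once); base-pair coverage is
available as an alternative unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMap, IntervalSet, TeInterval
from .stats import TestResult, chi2_goodness_of_fit, kruskal_dunn

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "shuffle_intervals",
    "oe_enrichment",
    "te_family_enrichment",
    "te_divergence_profile",
    "TeDivergenceProfile",
]


@dataclass
class EnrichmentResult:
    category: str
    observed: float
    expected_mean: float
    expected_sd: float
    oe_ratio: float
    empirical_p: float
    chi2: TestResult | None = None


def _as_arrays(intervals) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    contigs, starts, ends = [], [], []
    for iv in intervals:
        if hasattr(iv, "contig"):
            contigs.append(iv.contig)
            starts.append(iv.start)
            ends.append(iv.end)
        else:
            contigs.append(iv[0])
            starts.append(iv[1])
            ends.append(iv[2])
    return np.asarray(contigs), np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def shuffle_intervals(
    intervals,
    contig_sizes: dict[str, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Place the given intervals uniformly at random across the genome.

    The multiset of lengths is preserved; for each interval a contig is
    drawn with probability proportional to its length among contigs at
    least as long as the interval, then a start uniform in the feasible
    range.  Returns (contigs, starts, ends) arrays.
    """
    contigs, starts, ends = _as_arrays(intervals)
    lengths = ends - starts
    names = np.array(sorted(contig_sizes))
    sizes = np.array([contig_sizes[n] for n in names], dtype=np.int64)
    out_contig = np.empty(len(lengths), dtype=names.dtype)
    out_start = np.empty(len(lengths), dtype=np.int64)
    for ulen in np.unique(lengths):
        ok = sizes >= ulen
        if not ok.any():
            raise ValueError(f"interval of length {ulen} longer than every contig")
        probs = sizes[ok] / sizes[ok].sum()
        mask = lengths == ulen
        n = int(mask.sum())
        chosen = rng.choice(np.flatnonzero(ok), size=n, p=probs)
        max_start = sizes[chosen] - ulen + 1
        st = (rng.random(n) * max_start).astype(np.int64)
        out_contig[mask] = names[chosen]
        out_start[mask] = st
    return out_contig, out_start, out_start + lengths


def _counts(category_sets: dict[str, IntervalSet], contigs, starts, ends) -> dict[str, int]:
    return {name: iset.count_overlapping(contigs, starts, ends) for name, iset in category_sets.items()}


def _empirical_p(perm_counts: np.ndarray, observed: float) -> float:
    n = len(perm_counts)
    p_ge = (1 + int(np.sum(perm_counts >= observed))) / (n + 1)
    p_le = (1 + int(np.sum(perm_counts <= observed))) / (n + 1)
    expected = perm_counts.mean()
    return p_ge if observed >= expected else p_le


def _oe_core(
    category_sets: dict[str, IntervalSet],
    dmr_arrays,
    contig_sizes: dict[str, int],
    n_iter: int,
    rng: np.random.Generator,
) -> dict[str, EnrichmentResult]:
    contigs, starts, ends = dmr_arrays
    observed = _counts(category_sets, contigs, starts, ends)
    perm = {name: np.empty(n_iter) for name in category_sets}
    for it in range(n_iter):
        sc, ss, se = shuffle_intervals(list(zip(contigs, starts, ends)), contig_sizes, rng)
        for name, iset in category_sets.items():
            perm[name][it] = iset.count_overlapping(sc, ss, se)
    results: dict[str, EnrichmentResult] = {}
    names = [n for n in category_sets if perm[n].mean() > 0]
    chi2 = None
    if len(names) >= 2:
        chi2 = chi2_goodness_of_fit(
            [observed[n] for n in names], [perm[n].mean() for n in names]
        )
    for name in category_sets:
        exp_mean = float(perm[name].mean())
        exp_sd = float(perm[name].std(ddof=1)) if n_iter > 1 else 0.0
        oe = observed[name] / exp_mean if exp_mean > 0 else np.inf
        results[name] = EnrichmentResult(
            category=name,
            observed=float(observed[name]),
            expected_mean=exp_mean,
            expected_sd=exp_sd,
            oe_ratio=float(oe),
            empirical_p=_empirical_p(perm[name], observed[name]),
            chi2=chi2,
        )
    return results


def oe_enrichment(
    dmrs,
    feature_map: FeatureMap,
    n_iter: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, EnrichmentResult]:
    """Observed/expected enrichment of DMRs per feature category.

    observed = DMRs overlapping each category (>= 1 bp, multi-label);
    expected = mean count over ``n_iter`` genome-wide shuffles; the add-one
    empirical p is (1 + #{permutations at least as extreme}) / (n_iter + 1)
    in the direction of the deviation.  A chi-square goodness-of-fit of
    observed against expected across categories is attached to each result.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be at least 100")
    arrays = _as_arrays(dmrs)
    if arrays[0].size == 0:
        raise ValueError("empty DMR set")
    rng = rng if rng is not None else np.random.default_rng(seed)
    sets = feature_map.categories()
    if all(s.total_length() == 0 for s in sets.values()):
        raise ValueError("feature map has only zero-width categories")
    return _oe_core(sets, arrays, feature_map.contig_sizes, n_iter, rng)


def te_family_enrichment(
    dmrs,
    tes: list[TeInterval],
    contig_sizes: dict[str, int],
    n_iter: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    min_abs_ratio: float = 2.0,
) -> tuple[dict[str, EnrichmentResult], dict[str, EnrichmentResult]]:
    """Per-TE-family O/E enrichment of DMRs.

    Returns ``(filtered, full)``: the full table and the display-filtered
    one keeping families with O/E >= min_abs_ratio or <= 1/min_abs_ratio.
    """
    arrays = _as_arrays(dmrs)
    if arrays[0].size == 0:
        raise ValueError("empty DMR set")
    rng = rng if rng is not None else np.random.default_rng(seed)
    families: dict[str, list] = {}
    for te in tes:
        families.setdefault(te.family, []).append((te.contig, te.start, te.end))
    family_sets = {fam: IntervalSet.from_pairs(pairs) for fam, pairs in families.items()}
    full = _oe_core(family_sets, arrays, contig_sizes, n_iter, rng)
    if all(r.observed == 0 for r in full.values()):
        log.warning("no DMR overlaps any TE; filtered table is empty")
    filtered = {
        fam: r
        for fam, r in full.items()
        if np.isfinite(r.oe_ratio)
        and (r.oe_ratio >= min_abs_ratio or r.oe_ratio <= 1.0 / min_abs_ratio)
    }
    return filtered, full


@dataclass
class TeDivergenceProfile:
    """Kimura-divergence samples for TEs inside DMRs, outside DMRs, and
    under shuffled DMRs, with the omnibus/post-hoc comparison."""

    inside: np.ndarray
    outside: np.ndarray
    shuffled: np.ndarray
    omnibus: TestResult
    pairwise: pd.DataFrame

    def medians(self) -> dict[str, float]:
        return {
            "inside": float(np.median(self.inside)),
            "outside": float(np.median(self.outside)),
            "shuffled": float(np.median(self.shuffled)),
        }

    def means(self) -> dict[str, float]:
        return {
            "inside": float(np.mean(self.inside)),
            "outside": float(np.mean(self.outside)),
            "shuffled": float(np.mean(self.shuffled)),
        }


def te_divergence_profile(
    dmrs,
    tes: list[TeInterval],
    contig_sizes: dict[str, int],
    n_shuffles: int = 500,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TeDivergenceProfile:
    """Compare TE sequence divergence inside vs outside DMRs vs shuffles.

    Group 1: divergence of TEs overlapping a DMR; group 2: TEs overlapping
    none; group 3: TEs overlapping shuffled DMR placements, pooled over
    ``n_shuffles`` iterations.  Young (low-divergence) TEs under DMRs push
    the group-1 median below the others.
    """
    if len(tes) < 2:
        raise ValueError("need at least two TEs for a divergence profile")
    arrays = _as_arrays(dmrs)
    if arrays[0].size == 0:
        raise ValueError("empty DMR set")
    rng = rng if rng is not None else np.random.default_rng(seed)
    dmr_set = IntervalSet.from_pairs(zip(*arrays))
    te_contigs = np.array([t.contig for t in tes])
    te_starts = np.array([t.start for t in tes], dtype=np.int64)
    te_ends = np.array([t.end for t in tes], dtype=np.int64)
    te_div = np.array([t.divergence for t in tes])

    def te_hits(iset: IntervalSet) -> np.ndarray:
        hit = np.zeros(len(tes), dtype=bool)
        for contig in np.unique(te_contigs):
            arr = iset.by_contig.get(str(contig))
            mask = te_contigs == contig
            if arr is None or arr.size == 0:
                continue
            idx = np.searchsorted(arr[:, 0], te_ends[mask], side="left")
            hit[mask] = (idx > 0) & (arr[np.maximum(idx - 1, 0), 1] > te_starts[mask])
        return hit

    inside_mask = te_hits(dmr_set)
    inside = te_div[inside_mask]
    outside = te_div[~inside_mask]
    shuffled_parts = []
    for _ in range(n_shuffles):
        sc, ss, se = shuffle_intervals(list(zip(*arrays)), contig_sizes, rng)
        shuffled_parts.append(te_div[te_hits(IntervalSet.from_pairs(zip(sc, ss, se)))])
    shuffled = np.concatenate(shuffled_parts) if shuffled_parts else np.array([])
    for name, grp in (("inside", inside), ("outside", outside), ("shuffled", shuffled)):
        if grp.size == 0:
            raise ValueError(f"empty TE-divergence group: {name}")
    omnibus, pairwise = kruskal_dunn([inside, outside, shuffled])
    return TeDivergenceProfile(inside, outside, shuffled, omnibus, pairwise)


def results_to_frame(results: dict[str, EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for name, r in results.items():
        rows.append(
            dict(
                category=name,
                observed=r.observed,
                expected_mean=r.expected_mean,
                expected_sd=r.expected_sd,
                oe_ratio=r.oe_ratio,
                empirical_p=r.empirical_p,
                chi2_p=r.chi2.p_value if r.chi2 else np.nan,
            )
        )
    return pd.DataFrame(rows)
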