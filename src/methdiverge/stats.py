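"""Statistical kernels shared across the pipeline.

Small, self-contained wrappers around the tests the comparative-methylome
analysis needs: an exact hypergeometric upper tail (gene-set overlap),
chi-square goodness of fit (observed vs permutation-expected counts),
Kruskal-Wallis with Dunn's post-hoc comparisons (TE-divergence groups),
Spearman rank correlation (methylation vs expression) and
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy import stats as sps

__all__ = [
    "TestResult",
    "hypergeom_tail",
    "chi2_goodness_of_fit",
    "kruskal_dunn",
    "spearman_rho",
    "bh_adjust",
]


@dataclass
class TestResult:
    """Outcome of a single statistical test."""

    statistic: float
    p_value: float
    method: str
    df: int | None = None
    n: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability P(X >= k) of a hypergeometric draw.

    X counts marked items among ``n`` draws without replacement from a
    universe of ``N`` items of which ``K`` are marked.  The tail is the
    exact sum of point masses from ``k`` to ``min(n, K)``, accumulated in
    log space to stay accurate for very small probabilities.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if N < 0 or K < 0 or n < 0 or k < 0:
        raise ValueError("hypergeometric arguments must be non-negative")
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(n, K):
        raise ValueError(f"k={k} exceeds min(n, K)={min(n, K)}")
    lo = max(0, n + K - N)  # smallest achievable overlap
    if k <= lo:
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    logpmf = sps.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(special.logsumexp(logpmf))))


def chi2_goodness_of_fit(observed, expected) -> TestResult:
    """Chi-square goodness of fit of observed counts against expected counts.

    statistic = sum (O - E)^2 / E with df = n_categories - 1.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise ValueError("observed and expected must be 1-D of equal length")
    if np.any(exp <= 0):
        raise ValueError("expected counts must be strictly positive")
    stat = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    if df <= 0:
        raise ValueError("need at least two categories")
    p = float(sps.chi2.sf(stat, df))
    return TestResult(stat, p, "chi2_goodness_of_fit", df=df, n=obs.size)


def _tie_term(values: np.ndarray) -> float:
    # sum over tie groups of (t^3 - t)
    _, counts = np.unique(values, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t**3 - t))


def kruskal_dunn(groups, adjust: str = "bh") -> tuple[TestResult, "pd.DataFrame"]:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post-hoc comparisons.

    Dunn's z statistics are built from mean ranks of the pooled sample with
    tie-corrected variance; two-sided p-values are adjusted across pairs
    with Benjamini-Hochberg (``adjust='bh'``, the default) or Bonferroni
    (``adjust='bonferroni'``).

    Returns ``(omnibus, pairwise)`` where ``pairwise`` is a DataFrame with
    columns group_a, group_b, z, p_value, p_adjusted.
    """
    import pandas as pd

    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(arrays)
    ntot = pooled.size
    if ntot < 3:
        raise ValueError("need at least three observations in total")

    if np.all(pooled == pooled[0]):
        # degenerate: no variation at all
        omnibus = TestResult(0.0, 1.0, "kruskal_wallis", df=len(arrays) - 1, n=ntot)
        rows = [
            (i, j, 0.0, 1.0, 1.0)
            for i, j in itertools.combinations(range(len(arrays)), 2)
        ]
        pairwise = pd.DataFrame(
            rows, columns=["group_a", "group_b", "z", "p_value", "p_adjusted"]
        )
        return omnibus, pairwise

    H, p = sps.kruskal(*arrays)
    omnibus = TestResult(float(H), float(p), "kruskal_wallis", df=len(arrays) - 1, n=ntot)

    ranks = sps.rankdata(pooled)
    sizes = [a.size for a in arrays]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [
        float(np.mean(ranks[offsets[i] : offsets[i + 1]])) for i in range(len(arrays))
    ]
    tie = _tie_term(pooled)
    base_var = ntot * (ntot + 1) / 12.0 - tie / (12.0 * (ntot - 1))

    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        pij = float(2.0 * sps.norm.sf(abs(z)))
        rows.append((i, j, float(z), min(1.0, pij)))
    pvals = [r[3] for r in rows]
    if adjust == "bh":
        padj = bh_adjust(pvals)
    elif adjust == "bonferroni":
        padj = [min(1.0, p * len(pvals)) for p in pvals]
    else:
        raise ValueError(f"unknown adjustment: {adjust!r}")
    pairwise = pd.DataFrame(
        [r + (a,) for r, a in zip(rows, padj)],
        columns=["group_a", "group_b", "z", "p_value", "p_adjusted"],
    )
    return omnibus, pairwise


def spearman_rho(x, y, exact_max_n: int = 9) -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  For n <= ``exact_max_n`` the p-value is an
    exact permutation tail P(|rho_perm| >= |rho|); above that the usual
    t-approximation is used.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("missing values are not allowed")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rho undefined for a constant vector")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))
    rho = float(np.sum(rx_c * ry_c) / denom)

    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(ry_c)))
        rhos = perms @ rx_c / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return TestResult(rho, min(1.0, p), "spearman", n=n)


def bh_adjust(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjustment.

    Returns adjusted values (p * m / rank with monotone enforcement from the
    largest p downwards, capped at 1) in the original input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(m)
    out[order] = ranked
    return [float(v) for v in out]
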