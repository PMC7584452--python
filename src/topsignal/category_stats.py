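"""Rank-based category analysis and gene-set overlap enrichment.

Category screens compare the TOPscores of genes inside a functional category
against all other scored genes with a two-sided Mann-Whitney U test (exact by
full enumeration for small tieless samples, otherwise a tie-corrected normal
approximation with continuity correction), then control the family-wise false
discovery rate with the Benjamini-Yekutieli procedure, which is valid under
arbitrary dependence between categories.  Set overlaps are tested against the
hypergeometric null: expected overlap n*K/N and the exact upper-tail
probability P(X >= k).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .topscore import TopScoreRecord

__all__ = [
    "CategoryMap",
    "RankTestResult",
    "OverlapTestResult",
    "mann_whitney_u",
    "benjamini_yekutieli",
    "hypergeometric_upper_tail",
    "overlap_enrichment",
    "category_topscore_analysis",
    "read_category_map_tsv",
    "write_category_results_tsv",
]

logger = logging.getLogger(__name__)

# scipy's exact Mann-Whitney path enumerates the full null distribution of U;
# restrict it to small, tieless inputs and fall back to the normal
# approximation elsewhere.
_EXACT_MAX_TOTAL = 20


@dataclass
class CategoryMap:
    """category_id -> gene set, with optional display names."""

    members: dict[str, frozenset]
    names: dict[str, str]

    def __post_init__(self):
        for cat, genes in self.members.items():
            if not genes:
                raise ValueError(f"category {cat!r} is empty")

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], names: Mapping[str, str] | None = None
    ) -> "CategoryMap":
        members: dict[str, set] = {}
        for cat, gene in pairs:
            members.setdefault(cat, set()).add(gene)
        names = dict(names or {})
        return cls(
            members={c: frozenset(g) for c, g in members.items()},
            names={c: names.get(c, c) for c in members},
        )


@dataclass(frozen=True)
class RankTestResult:
    category_id: str
    n_in: int
    n_out: int
    u_statistic: float
    z: float
    p: float
    direction: str  # 'higher' | 'lower'
    p_adj: float | None = None
    m_tests: int | None = None


@dataclass(frozen=True)
class OverlapTestResult:
    universe_size: int  # N
    size_a: int  # K
    size_b: int  # n
    overlap: int  # k
    expected: float  # n*K/N
    p_upper: float  # P(X >= k)
    exceeds_twice_expected: bool


def _tie_corrected_z(x: np.ndarray, y: np.ndarray, u: float) -> float:
    """Normal-approximation z for U with midrank tie correction and a 0.5
    continuity correction."""
    nx, ny = len(x), len(y)
    n = nx + ny
    combined = np.concatenate([x, y])
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    mu = nx * ny / 2.0
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 0.0
    diff = u - mu
    cc = 0.5 if diff != 0 else 0.0
    return (diff - math.copysign(cc, diff)) / math.sqrt(var)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], category_id: str = ""
) -> RankTestResult:
    """Two-sided Mann-Whitney U test of x vs y.

    U is the statistic for x over y (number of (x_i, y_j) pairs with
    x_i > y_j, ties counted half).  Exact p by full enumeration when the
    pooled sample has <= 20 tieless observations, otherwise the tie-corrected
    continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= _EXACT_MAX_TOTAL and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u = float(res.statistic)
    z = _tie_corrected_z(x, y, u)
    direction = "higher" if np.median(x) >= np.median(y) else "lower"
    return RankTestResult(
        category_id=category_id,
        n_in=len(x),
        n_out=len(y),
        u_statistic=u,
        z=z,
        p=float(min(res.pvalue, 1.0)),
        direction=direction,
    )


def benjamini_yekutieli(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli FDR-adjusted p-values, in the input order.

    adj_(i) = min_{j>=i} min(1, p_(j) * m * c(m) / j) with c(m) = sum 1/i;
    conservative under arbitrary dependence.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_by")
    return adjusted


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); exact up to floating error."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got N={N}, K={K}, n={n}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k > min(K, n) + 1:
        raise ValueError(f"k={k} exceeds max overlap {min(K, n)} + 1")
    if k == 0:
        return 1.0
    if k > min(K, n):
        return 0.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def overlap_enrichment(
    set_a: Iterable, set_b: Iterable, universe: Iterable
) -> OverlapTestResult:
    """Hypergeometric enrichment of the overlap between two gene/protein sets.

    The universe must be stated explicitly (e.g. everything detected in both
    compared experiments); both sets must be subsets of it.
    """
    universe = set(universe)
    a, b = set(set_a), set(set_b)
    if not a <= universe or not b <= universe:
        outside = (a | b) - universe
        raise ValueError(f"sets contain elements outside the universe: {sorted(outside)[:5]}")
    N, K, n = len(universe), len(a), len(b)
    k = len(a & b)
    expected = n * K / N if N else 0.0
    return OverlapTestResult(
        universe_size=N,
        size_a=K,
        size_b=n,
        overlap=k,
        expected=expected,
        p_upper=hypergeometric_upper_tail(N, K, n, k),
        exceeds_twice_expected=k > 2 * expected,
    )


def category_topscore_analysis(
    categories: CategoryMap,
    scores: Sequence[TopScoreRecord],
    min_size: int = 5,
) -> list[RankTestResult]:
    """Mann-Whitney screen of per-category TOPscores vs all other scored genes,
    BY-adjusted across every category tested in this run.

    Categories with fewer than ``min_size`` scored members are skipped (and
    logged); a category must also leave at least one gene outside it.
    """
    if not scores:
        raise ValueError("no scored genes supplied")
    score_by_gene = {rec.gene_id: rec.topscore for rec in scores}
    results = []
    for cat in sorted(categories.members):
        inside = [
            score_by_gene[g] for g in categories.members[cat] if g in score_by_gene
        ]
        if len(inside) < min_size:
            logger.debug("category %s: only %d scored members; skipped", cat, len(inside))
            continue
        member_set = categories.members[cat]
        outside = [s for g, s in score_by_gene.items() if g not in member_set]
        if not outside:
            logger.debug("category %s covers all scored genes; skipped", cat)
            continue
        results.append(mann_whitney_u(inside, outside, category_id=cat))
    if not results:
        return []
    adjusted = benjamini_yekutieli([r.p for r in results])
    m = len(results)
    return [
        RankTestResult(
            category_id=r.category_id,
            n_in=r.n_in,
            n_out=r.n_out,
            u_statistic=r.u_statistic,
            z=r.z,
            p=r.p,
            direction=r.direction,
            p_adj=float(adj),
            m_tests=m,
        )
        for r, adj in zip(results, adjusted)
    ]


def read_category_map_tsv(path: str | Path) -> CategoryMap:
    """TSV with columns category_id, category_name, gene_id (one row per pair)."""
    pairs = []
    names = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["category_id", "category_name", "gene_id"]:
            raise ValueError(f"{path}: unexpected category header {header}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cat, name, gene = line.split("\t")[:3]
            pairs.append((cat, gene))
            names[cat] = name
    return CategoryMap.from_pairs(pairs, names)


def write_category_results_tsv(
    results: Iterable[RankTestResult], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("category\tn\tU\tz\tp\tp_adj\tdirection\n")
        for r in sorted(results, key=lambda r: r.category_id):
            p_adj = "NA" if r.p_adj is None else f"{r.p_adj:.6g}"
            fh.write(
                f"{r.category_id}\t{r.n_in}\t{r.u_statistic:.6g}\t{r.z:.6g}\t"
                f"{r.p:.6g}\t{p_adj}\t{r.direction}\n"
            )
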