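"""Independent brute-force oracles for the exact tests and read counting.

These deliberately avoid the code paths (and libraries) they check:
rank-test p-values come from full enumeration of rank assignments / sign
patterns, Fisher p-values from integer hypergeometric enumeration, and
read counts from a nested per-read per-exon overlap scan.
"""

from __future__ import annotations

import math
from collections import Counter
from functools import lru_cache
from itertools import combinations


@lru_cache(maxsize=None)
def mann_whitney_U_distribution(n_x: int, n_y: int) -> tuple[Counter, int]:
    """Exact distribution of U (for x) over all rank assignments."""
    n = n_x + n_y
    dist: Counter = Counter()
    base = n_x * (n_x + 1) // 2
    for ranks in combinations(range(1, n + 1), n_x):
        dist[sum(ranks) - base] += 1
    return dist, math.comb(n, n_x)


def mann_whitney_exact_p(x: list[float], y: list[float]) -> float:
    """Two-sided exact Mann-Whitney p for tie-free samples."""
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free input"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u = sum(ranks[v] for v in x) - len(x) * (len(x) + 1) // 2
    dist, total = mann_whitney_U_distribution(len(x), len(y))
    p_le = sum(c for s, c in dist.items() if s <= u) / total
    p_ge = sum(c for s, c in dist.items() if s >= u) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


@lru_cache(maxsize=None)
def signed_rank_distribution(n: int) -> Counter:
    """Distribution of W+ over all 2^n sign patterns on ranks 1..n."""
    dist = Counter({0: 1})
    for rank in range(1, n + 1):
        new: Counter = Counter()
        for w, c in dist.items():
            new[w] += c
            new[w + rank] += c
        dist = new
    return dist


def wilcoxon_exact_p(diffs: list[float]) -> float:
    """Two-sided exact signed-rank p for tie-free nonzero differences."""
    d = [v for v in diffs if v != 0]
    mags = sorted(abs(v) for v in d)
    assert len(set(mags)) == len(mags), "oracle requires tie-free magnitudes"
    rank = {m: i + 1 for i, m in enumerate(mags)}
    w_plus = sum(rank[abs(v)] for v in d if v > 0)
    dist = signed_rank_distribution(len(d))
    total = 2 ** len(d)
    p_le = sum(c for s, c in dist.items() if s <= w_plus) / total
    p_ge = sum(c for s, c in dist.items() if s >= w_plus) / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def fisher_exact_p(n1: int, n2: int, n3: int, n4: int) -> float:
    """Two-sided Fisher p via integer hypergeometric enumeration.

    Sums the probabilities of all tables (with the observed margins)
    whose probability does not exceed the observed table's; comparisons
    use exact integer numerators over the common denominator.
    """
    r1, r2 = n1 + n2, n3 + n4
    c1 = n1 + n3
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return float("nan")
    lo, hi = max(0, c1 - r2), min(c1, r1)
    nums = {a: math.comb(r1, a) * math.comb(r2, c1 - a)
            for a in range(lo, hi + 1)}
    obs = nums[n1]
    total = sum(nums.values())
    return sum(v for v in nums.values() if v <= obs) / total


def brute_force_exon_counts(reads, exons) -> dict[str, int]:
    """Per-exon read counts via an exhaustive per-read overlap scan.

    ``reads``: iterable of (read_id, [(chrom, start, end), ...]) blocks;
    ``exons``: iterable of (exon_id, chrom, start, end).
    """
    exons = list(exons)
    counts = {eid: 0 for eid, *_ in exons}
    for _read_id, blocks in reads:
        for eid, chrom, es, ee in exons:
            for bc, bs, be in blocks:
                if bc == chrom and bs < ee and es < be:
                    counts[eid] += 1
                    break
    return counts
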