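"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results by the most literal route available
(explicit loops, exhaustive enumeration, pairwise merge closure) and share
no code with the package implementation.
"""

from __future__ import annotations

import itertools
from math import comb

DEFAULT_MIN_N = {"CG": 4, "CHG": 5, "CHH": 6}
DEFAULT_MIN_D = {"CG": 0.4, "CHG": 0.2, "CHH": 0.1}


def brute_force_dmrs(
    a_df,
    b_df,
    bin_size: int = 100,
    min_n: dict[str, int] | None = None,
    min_d: dict[str, float] | None = None,
    merge_distance: int = 200,
    min_coverage: int = 4,
):
    """Exhaustive DMR caller: classify every cytosine, scan every bin, merge
    by repeated pairwise closure.  Returns a set of
    (chrom, start, end, context, direction, n_support) tuples."""
    min_n = min_n or DEFAULT_MIN_N
    min_d = min_d or DEFAULT_MIN_D

    def table_to_dict(df):
        out = {}
        for row in df.itertuples(index=False):
            out[(row.chrom, int(row.pos), row.strand, row.context)] = (
                int(row.meth),
                int(row.unmeth),
            )
        return out

    a = table_to_dict(a_df)
    b = table_to_dict(b_df)

    # per-cytosine status
    statuses = {}
    for key in set(a) & set(b):
        ma, ua = a[key]
        mb, ub = b[key]
        cov_a, cov_b = ma + ua, mb + ub
        if cov_a < min_coverage or cov_b < min_coverage:
            continue
        la, lb = ma / cov_a, mb / cov_b
        ctx = key[3]
        if abs(la - lb) >= min_d[ctx] - 1e-12:
            statuses[key] = ("hypo" if la < lb else "hyper", la, lb)

    # candidate bins
    bins = {}
    for (chrom, pos, _strand, ctx), (direction, la, lb) in statuses.items():
        bkey = (chrom, pos // bin_size, ctx, direction)
        bins.setdefault(bkey, []).append((la, lb))
    candidates = []
    for (chrom, b_idx, ctx, direction), support in bins.items():
        if len(support) >= min_n[ctx]:
            candidates.append(
                {
                    "chrom": chrom,
                    "start": b_idx * bin_size,
                    "end": (b_idx + 1) * bin_size,
                    "context": ctx,
                    "direction": direction,
                    "n": len(support),
                }
            )

    # exhaustive pairwise merge closure
    clusters = [dict(c) for c in candidates]
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(clusters)), 2):
            ci, cj = clusters[i], clusters[j]
            if (ci["chrom"], ci["context"], ci["direction"]) != (
                cj["chrom"],
                cj["context"],
                cj["direction"],
            ):
                continue
            gap = max(ci["start"], cj["start"]) - min(ci["end"], cj["end"])
            if gap <= merge_distance:
                merged = {
                    "chrom": ci["chrom"],
                    "start": min(ci["start"], cj["start"]),
                    "end": max(ci["end"], cj["end"]),
                    "context": ci["context"],
                    "direction": ci["direction"],
                    "n": ci["n"] + cj["n"],
                }
                clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
                clusters.append(merged)
                changed = True
                break
    return {
        (c["chrom"], c["start"], c["end"], c["context"], c["direction"], c["n"])
        for c in clusters
    }


def enum_intersection_counts(n: int, n1: int, n2: int) -> list[int]:
    """Counts of |A ∩ B| = s over every second subset of size n2 (the first
    subset fixed as {0..n1-1} by exchangeability)."""
    a = set(range(n1))
    counts = [0] * (min(n1, n2) + 1)
    for b in itertools.combinations(range(n), n2):
        counts[len(a & set(b))] += 1
    return counts


def enum_two_set_tail(n: int, n1: int, n2: int, k: int) -> float:
    """P(|A ∩ B| >= k) by enumerating every second subset (first fixed by
    exchangeability)."""
    counts = enum_intersection_counts(n, n1, n2)
    return sum(counts[k:]) / comb(n, n2)


def enum_three_set_tail_exhaustive(n: int, n1: int, n2: int, n3: int, k: int) -> float:
    """P(|A ∩ B ∩ C| >= k) by full enumeration of B and C (A fixed)."""
    a = set(range(n1))
    total = comb(n, n2) * comb(n, n3)
    hits = 0
    for b in itertools.combinations(range(n), n2):
        ab = a & set(b)
        for c in itertools.combinations(range(n), n3):
            if len(ab & set(c)) >= k:
                hits += 1
    return hits / total


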