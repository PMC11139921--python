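"""Multi-set intersection significance and category enrichment.

The intersection statistic: given m subsets of fixed sizes n_1..n_m drawn
independently and uniformly from an N-element universe, the upper-tail
probability P(X >= k) of their total intersection size X.  For m = 2 this
is the hypergeometric survival function.  Two exact routes are implemented:

- a chained hypergeometric mixture (the intersection of the first i sets,
  conditioned on its size, intersects the next set hypergeometrically) —
  all-positive terms, numerically robust; default for moderate universes;
- the inclusion-exclusion tail formula with log-domain binomial
  coefficients and max-shifted signed summation, for large N where the
  O(N^2) mixture is too slow.

Category enrichment (e.g. TE superfamilies among differentially expressed
siRNA loci) is the classical hypergeometric over-representation test with
BH adjustment across categories.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .diffexpr import bh_adjust

_MIXTURE_MAX_N = 4096


@dataclass
class SetSystem:
    """A universe, m subset sizes, and an observed total intersection."""

    universe_size: int
    set_sizes: list[int]
    observed_intersection: int
    sets: list[frozenset] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.universe_size <= 0:
            raise ValueError("universe_size must be positive")
        if not self.set_sizes:
            raise ValueError("need at least one set")
        if any(n < 0 or n > self.universe_size for n in self.set_sizes):
            raise ValueError("set sizes must lie in [0, universe_size]")
        if self.observed_intersection < 0:
            raise ValueError("observed intersection must be non-negative")
        if self.observed_intersection > min(self.set_sizes):
            raise ValueError(
                f"observed intersection {self.observed_intersection} exceeds "
                f"smallest set size {min(self.set_sizes)}"
            )

    @classmethod
    def from_sets(cls, sets: Sequence[Iterable], universe: Iterable) -> "SetSystem":
        uni = frozenset(universe)
        fsets = [frozenset(s) & uni for s in sets]
        inter = frozenset(uni)
        for s in fsets:
            inter &= s
        return cls(
            universe_size=len(uni),
            set_sizes=[len(s) for s in fsets],
            observed_intersection=len(inter),
            sets=fsets,
        )

    @property
    def expected_intersection(self) -> float:
        e = float(self.universe_size)
        for n in self.set_sizes:
            e *= n / self.universe_size
        return e


def multiset_intersection_pvalue(system: SetSystem, method: str = "auto") -> float:
    """Exact upper-tail P(X >= k) of the multi-set intersection size."""
    n, sizes, k = system.universe_size, system.set_sizes, system.observed_intersection
    if k == 0:
        return 1.0
    if len(sizes) == 1:
        return 1.0 if k <= sizes[0] else 0.0
    if method == "auto":
        method = "mixture" if n <= _MIXTURE_MAX_N else "inclusion-exclusion"
    if method == "mixture":
        return _pvalue_mixture(n, sizes, k)
    if method == "inclusion-exclusion":
        return _pvalue_inclusion_exclusion(n, sizes, k)
    raise ValueError(f"unknown method {method!r}")


def intersection_distribution(n: int, sizes: Sequence[int]) -> np.ndarray:
    """Exact pmf of the intersection size via the chained hypergeometric
    mixture; index s gives P(X = s)."""
    sizes = sorted(sizes, reverse=True)
    support = sizes[0]
    dist = np.zeros(support + 1)
    dist[sizes[0]] = 1.0
    s_grid = np.arange(support + 1)
    for n_i in sizes[1:]:
        new = np.zeros(support + 1)
        for s in np.flatnonzero(dist > 0):
            # P(next intersection = s' | current = s) is hypergeometric
            new += dist[s] * stats.hypergeom.pmf(s_grid, n, s, n_i)
        dist = new
    return dist


def _pvalue_mixture(n: int, sizes: Sequence[int], k: int) -> float:
    dist = intersection_distribution(n, sizes)
    return float(min(1.0, max(0.0, dist[k:].sum())))


def _log_binom(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return np.where((b < 0) | (b > a), -np.inf, out)


def _pvalue_inclusion_exclusion(n: int, sizes: Sequence[int], k: int) -> float:
    """P(X >= k) = sum_{j>=k} (-1)^(j-k) C(j-1, k-1) C(N, j) prod_i
    C(N-j, n_i - j) / C(N, n_i), summed in the log domain with a max shift."""
    j_max = min(sizes)
    if k > j_max:
        return 0.0
    j = np.arange(k, j_max + 1, dtype=float)
    log_terms = _log_binom(j - 1, k - 1) + _log_binom(n, j)
    for n_i in sizes:
        log_terms = log_terms + _log_binom(n - j, n_i - j) - _log_binom(n, n_i)
    signs = np.where((np.arange(k, j_max + 1) - k) % 2 == 0, 1.0, -1.0)
    finite = np.isfinite(log_terms)
    if not finite.any():
        return 0.0
    shift = log_terms[finite].max()
    total = float(np.sum(signs[finite] * np.exp(log_terms[finite] - shift)))
    return float(min(1.0, max(0.0, total * np.exp(shift))))


# ---------------------------------------------------------------------------
# region universes
# ---------------------------------------------------------------------------

def build_region_universe(
    region_lists: Sequence[Sequence],
    chrom_lengths: Mapping[str, int],
    bin_size: int = 100,
    callable_bins: Iterable[int] | None = None,
) -> SetSystem:
    """Map region lists to genome-bin sets and build a SetSystem.

    The genome is tiled into ``bin_size`` bins (globally indexed across
    chromosomes); each list becomes the set of bins it overlaps
    (any-overlap).  The universe is all bins, optionally restricted to a
    callable subset (e.g. bins with covered cytosines in every sample).
    Region objects need ``chrom``/``start``/``end`` attributes (DMRs or
    GenomicIntervals).
    """
    if len(region_lists) < 2:
        raise ValueError("need at least two region lists")
    offsets: dict[str, int] = {}
    total = 0
    for chrom in sorted(chrom_lengths):
        offsets[chrom] = total
        total += -(-chrom_lengths[chrom] // bin_size)  # ceil division
    universe: Iterable[int] = range(total)
    if callable_bins is not None:
        universe = sorted(set(callable_bins))
    bin_sets = []
    for regions in region_lists:
        bins: set[int] = set()
        for r in regions:
            if r.chrom not in offsets:
                raise ValueError(f"region on unknown chromosome {r.chrom!r}")
            first = r.start // bin_size
            last = (r.end - 1) // bin_size
            bins.update(offsets[r.chrom] + b for b in range(first, last + 1))
        bin_sets.append(bins)
    return SetSystem.from_sets(bin_sets, universe)


def overlap_report(system: SetSystem) -> pd.DataFrame:
    """One-row summary: sizes, expected and observed intersection, fold, p."""
    p = multiset_intersection_pvalue(system)
    exp = system.expected_intersection
    fold = system.observed_intersection / exp if exp > 0 else float("inf")
    return pd.DataFrame(
        [
            {
                "universe_size": system.universe_size,
                "set_sizes": ",".join(map(str, system.set_sizes)),
                "expected_intersection": exp,
                "observed_intersection": system.observed_intersection,
                "fold_enrichment": fold,
                "p_value": p,
            }
        ]
    )


# ---------------------------------------------------------------------------
# category enrichment
# ---------------------------------------------------------------------------

def category_enrichment(
    members: Iterable,
    category_map: Mapping,
    universe: Iterable,
) -> pd.DataFrame:
    """Hypergeometric over-representation of categories in a member list.

    Elements without a category fall into "other".  Returns one row per
    category present in the universe with hit counts, fold enrichment
    ((hits/list size) / (category frequency in universe)), the
    hypergeometric upper-tail p, and the BH-adjusted p across categories.
    """
    uni = list(dict.fromkeys(universe))
    mem = [m for m in dict.fromkeys(members) if m in set(uni)]
    if not mem:
        raise ValueError("empty member list (after restriction to the universe)")
    n_uni = len(uni)
    n_list = len(mem)
    cat_of = lambda e: category_map.get(e) or "other"  # noqa: E731
    uni_counts: dict[str, int] = {}
    for e in uni:
        uni_counts[cat_of(e)] = uni_counts.get(cat_of(e), 0) + 1
    list_counts: dict[str, int] = {}
    for e in mem:
        list_counts[cat_of(e)] = list_counts.get(cat_of(e), 0) + 1
    rows = []
    for cat in sorted(uni_counts):
        k_hit = list_counts.get(cat, 0)
        k_uni = uni_counts[cat]
        p = float(stats.hypergeom.sf(k_hit - 1, n_uni, k_uni, n_list))
        fold = (k_hit / n_list) / (k_uni / n_uni)
        rows.append(
            {
                "category": cat,
                "hits_in_list": k_hit,
                "list_size": n_list,
                "hits_in_universe": k_uni,
                "universe_size": n_uni,
                "fold_enrichment": fold,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows).set_index("category")
    table["adjusted_p"] = bh_adjust(table["p_value"])
    return table.reset_index()
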