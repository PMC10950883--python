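"""Independent oracles used by the tests.

These deliberately avoid the package's own matching code path: the optimal
one-to-one peak assignment is computed with the Hungarian algorithm
(exact for the maximize-matches-then-minimize-total-|delta| objective),
and set overlaps are recomputed with plain Python set arithmetic.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

from nitroscope.similarity import PeakAlignment

_BIG = 1.0e6


def optimal_alignment(a, b, tolerance: float) -> PeakAlignment:
    """Exact optimal one-to-one matching (max matches, min total |delta m/z|)."""
    na, nb = len(a), len(b)
    n = max(na, nb)
    cost = np.full((n, n), _BIG)
    for i in range(na):
        for j in range(nb):
            d = abs(a.mz[i] - b.mz[j])
            if d <= tolerance:
                cost[i, j] = d
    ri, ci = linear_sum_assignment(cost)
    pairs = [(i, j) for i, j in zip(ri, ci) if i < na and j < nb and cost[i, j] < _BIG]
    a_used = {i for i, _ in pairs}
    b_used = {j for _, j in pairs}
    slots = [(a.intensity[i], b.intensity[j], a.mz[i], b.mz[j]) for i, j in pairs]
    slots += [(a.intensity[i], 0.0, a.mz[i], np.nan) for i in range(na) if i not in a_used]
    slots += [(0.0, b.intensity[j], np.nan, b.mz[j]) for j in range(nb) if j not in b_used]
    arr = np.array(slots, dtype=float).reshape(-1, 4)
    return PeakAlignment(u=arr[:, 0], v=arr[:, 1], mz_a=arr[:, 2], mz_b=arr[:, 3])


def matching_cost(al: PeakAlignment) -> tuple[int, float]:
    m = al.matched
    return al.matched_count, float(np.nansum(np.abs(al.mz_a - al.mz_b)[m]))


def brute_force_overlap(sets: dict[str, set]):
    """Exclusive Venn-region and subset-intersection counts by set arithmetic."""
    from itertools import combinations

    names = sorted(sets)
    universe = set().union(*sets.values())
    regions: dict[frozenset, int] = {}
    for el in universe:
        key = frozenset(n for n in names if el in sets[n])
        regions[key] = regions.get(key, 0) + 1
    inters: dict[frozenset, int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inters[frozenset(combo)] = len(set.intersection(*(sets[n] for n in combo)))
    return regions, inters, len(universe)
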