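"""Independent brute-force oracles, kept free of the package's geodesic engine.

Splits are handled as frozensets of leaf indices and geodesic lengths are
minimized by exhaustive enumeration of ordered support partitions, so these
routines share no code path with the GTP implementation they check.
"""

import itertools
import math


def _compatible(a: frozenset, b: frozenset) -> bool:
    # away-from-root sides: compatible iff disjoint or nested
    return not (a & b) or a <= b or b <= a


def _ordered_partitions(items):
    """All ordered partitions of a set into nonempty blocks."""
    items = list(items)
    if not items:
        yield []
        return
    n = len(items)
    for nblocks in range(1, n + 1):
        for assignment in itertools.product(range(nblocks), repeat=n):
            if set(assignment) != set(range(nblocks)):
                continue
            blocks = [
                [items[i] for i in range(n) if assignment[i] == j]
                for j in range(nblocks)
            ]
            yield blocks


def brute_force_distance(x, y, internal_only=True):
    """Geodesic distance by enumeration over valid ordered supports.

    Valid path: every split of A-block l is compatible with every split of
    B-block j for j < l.  Only partitions with weakly ascending block
    ratios are scored; any other valid partition is dominated by a coarser
    merged partition that also appears in the enumeration.
    """
    ex = {s.leaves(x.taxa): l for s, l in x.edges.items()
          if s.is_internal or not internal_only}
    ey = {s.leaves(y.taxa): l for s, l in y.edges.items()
          if s.is_internal or not internal_only}
    common = set()
    for s in set(ex) | set(ey):
        if all(_compatible(s, t) for t in ex) and all(_compatible(s, t) for t in ey):
            common.add(s)
    a0 = [s for s in ex if s not in common]
    b0 = [s for s in ey if s not in common]
    common_sq = sum((ex.get(s, 0.0) - ey.get(s, 0.0)) ** 2 for s in common)
    if not a0 or not b0:
        extra = sum(ex[s] ** 2 for s in a0) + sum(ey[s] ** 2 for s in b0)
        return math.sqrt(common_sq + extra)
    best = math.inf
    for ablocks in _ordered_partitions(a0):
        for bblocks in _ordered_partitions(b0):
            if len(ablocks) != len(bblocks):
                continue
            ok = True
            for l in range(len(ablocks)):
                for j in range(l):
                    if any(
                        not _compatible(a, b)
                        for a in ablocks[l]
                        for b in bblocks[j]
                    ):
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                continue
            anorms = [math.sqrt(sum(ex[s] ** 2 for s in blk)) for blk in ablocks]
            bnorms = [math.sqrt(sum(ey[s] ** 2 for s in blk)) for blk in bblocks]
            ratios = [a / b for a, b in zip(anorms, bnorms)]
            if any(ratios[i] > ratios[i + 1] + 1e-12 for i in range(len(ratios) - 1)):
                continue
            total = sum((a + b) ** 2 for a, b in zip(anorms, bnorms)) + common_sq
            best = min(best, math.sqrt(total))
    return best


def euclidean_weighted_mean(trees, weights, internal_only=True):
    """Coordinate-wise weighted average; valid when all trees share a topology."""
    total = sum(weights)
    keys = set()
    for t in trees:
        keys |= {
            s for s in t.edges if s.is_internal or not internal_only
        }
    return {
        s: sum(w * t.length_of(s) for w, t in zip(weights, trees)) / total
        for s in keys
    }
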