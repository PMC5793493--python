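"""BHV geodesics via the geodesic tree path (GTP) algorithm.

The geodesic between two trees is characterized by its *support*: ordered
partitions (A^(1),...,A^(l)) of the splits dropped from ``x`` and
(B^(1),...,B^(l)) of the splits gained towards ``y``, plus the set C of
splits compatible with both trees (interpolated linearly).  The squared
geodesic length is

    d(x, y)^2 = sum_j (||A^(j)||_x + ||B^(j)||_y)^2 + sum_{e in C} (|e|_x - |e|_y)^2.

Supports are computed by successive refinement starting from the cone path:
each block is split whenever the minimum-weight vertex cover of its bipartite
incompatibility graph (vertex weights |e|_x^2/||A||^2 and |f|_y^2/||B||^2)
weighs less than 1.  Covers are found by exact subset enumeration for small
blocks and by max-flow/min-cut for large ones.  The refined support satisfies
the valid-path and ascending-ratio conditions that characterize the geodesic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .treespace import PhyloTree, Split, _masks_compatible

__all__ = [
    "GeodesicSupport",
    "Geodesic",
    "compute_support",
    "support_of",
    "distance",
    "geodesic",
    "geodesic_point",
    "is_simple",
]

_RATIO_TOL = 1e-12  # absolute tolerance for cover-weight / ratio comparisons
_ENUM_LIMIT = 14    # enumerate min covers up to 2^14 subsets, flow beyond


# ---------------------------------------------------------------------------
# mask-level engine
# ---------------------------------------------------------------------------


def _common_and_disjoint(ex: dict[int, float], ey: dict[int, float]):
    """Split E(x) and E(y) into the common set C(x,y) and the leftovers.

    C(x,y) holds every split of either tree compatible with all splits of
    both trees (pendant splits, when present, are always in C).
    """
    xmasks = list(ex)
    ymasks = list(ey)
    a0 = []
    common: set[int] = set()
    for m in xmasks:
        for o in ymasks:
            mo = m & o
            if mo and mo != m and mo != o:
                a0.append(m)
                break
        else:
            common.add(m)
    b0 = []
    for m in ymasks:
        if m in ex:
            continue  # already handled from x's side (shared split => common)
        for o in xmasks:
            mo = m & o
            if mo and mo != m and mo != o:
                b0.append(m)
                break
        else:
            common.add(m)
    return a0, b0, common


def _min_cover(amasks, bmasks, aw, bw, adj):
    """Minimum-weight vertex cover of the bipartite incompatibility graph.

    ``aw``/``bw`` are normalized squared weights (summing to 1 per side);
    ``adj[i]`` is a bitmask over B-indices incompatible with A-index i.
    Returns (weight, a_cover_indices_mask, b_cover_indices_mask).
    """
    na, nb = len(amasks), len(bmasks)
    if na == 1 or nb == 1:
        # every vertex retains an incompatibility edge within its block, so
        # a singleton side is fully adjacent and any cover weighs >= 1
        return (1.0, 0, 0)
    if min(na, nb) <= _ENUM_LIMIT:
        # enumerate over subsets of the smaller side
        if na <= nb:
            best = (math.inf, 0, 0)
            for s in range(1 << na):
                # A-vertices in cover: s ; B must cover edges from A\s
                need = 0
                w = 0.0
                for i in range(na):
                    if s >> i & 1:
                        w += aw[i]
                    else:
                        need |= adj[i]
                if w >= best[0]:
                    continue
                for j in range(nb):
                    if need >> j & 1:
                        w += bw[j]
                if w < best[0]:
                    best = (w, s, need)
            return best
        # enumerate subsets of B instead
        radj = [0] * nb
        for i in range(na):
            ai = adj[i]
            for j in range(nb):
                if ai >> j & 1:
                    radj[j] |= 1 << i
        best = (math.inf, 0, 0)
        for t in range(1 << nb):
            need = 0
            w = 0.0
            for j in range(nb):
                if t >> j & 1:
                    w += bw[j]
                else:
                    need |= radj[j]
            if w >= best[0]:
                continue
            for i in range(na):
                if need >> i & 1:
                    w += aw[i]
            if w < best[0]:
                best = (w, need, t)
        return best
    return _min_cover_flow(na, nb, aw, bw, adj)


def _min_cover_flow(na, nb, aw, bw, adj):
    """Max-flow/min-cut fallback for large blocks."""
    import networkx as nx

    g = nx.DiGraph()
    for i in range(na):
        g.add_edge("s", ("a", i), capacity=aw[i])
        for j in range(nb):
            if adj[i] >> j & 1:
                g.add_edge(("a", i), ("b", j), capacity=math.inf)
    for j in range(nb):
        g.add_edge(("b", j), "t", capacity=bw[j])
    weight, (src_side, _) = nx.minimum_cut(g, "s", "t")
    amask = 0
    bmask = 0
    for i in range(na):
        if ("a", i) not in src_side:
            amask |= 1 << i
    for j in range(nb):
        if ("b", j) in src_side:
            bmask |= 1 << j
    return weight, amask, bmask


def _refine(amasks, bmasks, ex, ey):
    """Recursively refine one support block; returns a list of (A, B) tuples."""
    na2 = sum(ex[m] * ex[m] for m in amasks)
    nb2 = sum(ey[m] * ey[m] for m in bmasks)
    aw = [ex[m] * ex[m] / na2 for m in amasks]
    bw = [ey[m] * ey[m] / nb2 for m in bmasks]
    adj = []
    for am in amasks:
        row = 0
        for j, bm in enumerate(bmasks):
            if not _masks_compatible(am, bm):
                row |= 1 << j
        adj.append(row)
    weight, sa, sb = _min_cover(amasks, bmasks, aw, bw, adj)
    if weight >= 1.0 - _RATIO_TOL:
        return [(tuple(amasks), tuple(bmasks))]
    c1 = [m for i, m in enumerate(amasks) if sa >> i & 1]
    c2 = [m for i, m in enumerate(amasks) if not sa >> i & 1]
    d2 = [m for j, m in enumerate(bmasks) if sb >> j & 1]
    d1 = [m for j, m in enumerate(bmasks) if not sb >> j & 1]
    return _refine(c1, d1, ex, ey) + _refine(c2, d2, ex, ey)


def _support(ex: dict[int, float], ey: dict[int, float]):
    """GTP support of the geodesic between mask-edge maps.

    Returns ``(blocks, common)`` where ``blocks`` is a list of
    ``(amasks, bmasks, ||A||_x, ||B||_y)`` in ascending ratio order.
    """
    a0, b0, common = _common_and_disjoint(ex, ey)
    if not a0:
        blocks = []
        if b0:
            blocks = [((), tuple(b0), 0.0, math.sqrt(sum(ey[m] ** 2 for m in b0)))]
        return blocks, common
    if not b0:
        return [
            (tuple(a0), (), math.sqrt(sum(ex[m] ** 2 for m in a0)), 0.0)
        ], common
    raw = _refine(a0, b0, ex, ey)
    blocks = [
        (
            a,
            b,
            math.sqrt(sum(ex[m] ** 2 for m in a)),
            math.sqrt(sum(ey[m] ** 2 for m in b)),
        )
        for a, b in raw
    ]
    blocks.sort(key=lambda blk: blk[2] / blk[3])
    return blocks, common


def _length(blocks, common, ex, ey) -> float:
    total = 0.0
    for _, _, an, bn in blocks:
        total += (an + bn) ** 2
    for m in common:
        total += (ex.get(m, 0.0) - ey.get(m, 0.0)) ** 2
    return math.sqrt(total)


def _distance(ex: dict[int, float], ey: dict[int, float]) -> float:
    blocks, common = _support(ex, ey)
    return _length(blocks, common, ex, ey)


def _point(blocks, common, ex, ey, lam: float) -> dict[int, float]:
    """Edge-mask map of the tree at arc-length fraction ``lam`` along the geodesic."""
    out: dict[int, float] = {}
    for m in common:
        l = (1.0 - lam) * ex.get(m, 0.0) + lam * ey.get(m, 0.0)
        if l > 0.0:
            out[m] = l
    for amasks, bmasks, an, bn in blocks:
        fa = (1.0 - lam) - lam * (bn / an) if an > 0.0 else -1.0
        if fa > 0.0:
            for m in amasks:
                out[m] = ex[m] * fa
        else:
            fb = lam - (1.0 - lam) * (an / bn) if bn > 0.0 else -1.0
            if fb > 0.0:
                for m in bmasks:
                    out[m] = ey[m] * fb
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeodesicSupport:
    """The support (A, B, C) of a geodesic.

    ``A``/``B`` are equal-length tuples of split sets in ascending ratio
    order; ``C`` is the set of splits compatible with both endpoints.
    """

    A: tuple[frozenset[Split], ...]
    B: tuple[frozenset[Split], ...]
    C: frozenset[Split]

    def __len__(self) -> int:
        return len(self.A)

    @property
    def is_cone_path(self) -> bool:
        return len(self.A) <= 1

    def to_record(self) -> dict:
        """JSON-serializable record (splits as sorted leaf-index lists)."""
        key = lambda s: sorted(s.indices())  # noqa: E731
        return {
            "A": [[key(s) for s in blk] for blk in self.A],
            "B": [[key(s) for s in blk] for blk in self.B],
            "C": [key(s) for s in sorted(self.C, key=lambda s: s.mask)],
        }


class Geodesic:
    """The unique geodesic between two trees, with lazy point evaluation."""

    __slots__ = ("x", "y", "internal_only", "_ex", "_ey", "_blocks", "_common", "length")

    def __init__(self, x: PhyloTree, y: PhyloTree, internal_only: bool = True):
        if x.taxa != y.taxa:
            raise ValueError("trees are on different leaf sets")
        self.x = x
        self.y = y
        self.internal_only = internal_only
        self._ex = x._mask_edges(internal_only)
        self._ey = y._mask_edges(internal_only)
        self._blocks, self._common = _support(self._ex, self._ey)
        self.length = _length(self._blocks, self._common, self._ex, self._ey)

    @property
    def support(self) -> GeodesicSupport:
        n = self.x.n_leaves
        return GeodesicSupport(
            A=tuple(frozenset(Split(m, n) for m in a) for a, _, _, _ in self._blocks),
            B=tuple(frozenset(Split(m, n) for m in b) for _, b, _, _ in self._blocks),
            C=frozenset(Split(m, n) for m in self._common),
        )

    def point(self, lam: float) -> PhyloTree:
        """Tree at arc-length fraction ``lam`` in [0, 1] along the geodesic.

        Splits shared by both endpoints interpolate linearly; the splits of
        block j of ``x`` contract to zero at the breakpoint
        ``||A^(j)|| / (||A^(j)|| + ||B^(j)||)`` where block j of ``y`` starts
        growing, so the topology schedule matches
        B^(1..j) + A^(j+1..l) + C.
        """
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda={lam} outside [0, 1]")
        if lam == 0.0:
            return self.x
        if lam == 1.0:
            return self.y
        masks = _point(self._blocks, self._common, self._ex, self._ey, lam)
        return PhyloTree._from_masks(self.x.taxa, masks)


def compute_support(
    x: PhyloTree, y: PhyloTree, internal_only: bool = True
) -> GeodesicSupport:
    """Support of the geodesic from ``x`` to ``y`` (deterministic)."""
    return Geodesic(x, y, internal_only=internal_only).support


# Alias emphasising support-region membership tests: two trees lie in the same
# support region w.r.t. ``v`` iff their supports are equal.
support_of = compute_support


def geodesic(x: PhyloTree, y: PhyloTree, internal_only: bool = True) -> Geodesic:
    return Geodesic(x, y, internal_only=internal_only)


def distance(x: PhyloTree, y: PhyloTree, internal_only: bool = True) -> float:
    """BHV geodesic distance between two trees on the same leaf set."""
    if x.taxa != y.taxa:
        raise ValueError("trees are on different leaf sets")
    return _distance(x._mask_edges(internal_only), y._mask_edges(internal_only))


def geodesic_point(g: Geodesic, lam: float) -> PhyloTree:
    return g.point(lam)


def is_simple(g: Geodesic) -> bool:
    """True iff every support block is a singleton pair (Euclidean-like path).

    Defined for fully resolved endpoints; unresolved endpoints yield False
    with a warning.
    """
    if not (g.x.is_fully_resolved and g.y.is_fully_resolved):
        warnings.warn(
            "simplicity is defined for fully resolved endpoints; returning False",
            stacklevel=2,
        )
        return False
    return all(len(a) == 1 and len(b) == 1 for a, b, _, _ in g._blocks)
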