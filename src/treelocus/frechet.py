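"""Weighted Frechet means in BHV tree space.

The weighted Frechet mean of vertex trees ``V = {v_0, ..., v_k}`` with
weights ``p`` in the k-simplex is the unique (tree space is CAT(0))
minimizer of the objective

    Omega(x, p) = sum_i p_i d(x, v_i)^2.

Two iterative solvers are provided: Sturm's stochastic algorithm (sample a
vertex with probability p_j, move a proportion 1/(i+2) along the geodesic
towards it) and a deterministic cyclic variant in the style of Bacak (visit
vertices cyclically, weights absorbed into the step proportions).  The
cyclic solver optionally *polishes* its iterate by solving the first-order
conditions

    dOmega/dx_j = 2 x_j + 2 sum_i p_i { x_j ||B^(r_ij)|| / ||A^(r_ij)|| (1 - C_ij)
                                        - |e_j|_{v_i} C_ij } = 0

by fixed-point iteration inside the mutual support region located by the
iteration; this reaches machine-level accuracy in a handful of support
computations, where the plain O(1/i) iteration would need millions of steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geodesic import GeodesicSupport, _distance, _point, _support
from .treespace import PhyloTree, Split

__all__ = [
    "WeightVector",
    "MeanResult",
    "omega",
    "grad_omega",
    "frechet_mean_sturm",
    "frechet_mean_bacak",
    "local_affine_solution",
]


class WeightVector:
    """A probability vector on the k-simplex driving the weighted mean.

    Nonnegative weights are normalized to sum to one on construction (the
    Frechet mean is invariant under positive scaling of the weights).
    """

    __slots__ = ("weights",)

    def __init__(self, weights: Sequence[float]):
        w = [float(x) for x in weights]
        if any(x < 0 for x in w):
            raise ValueError("weights must be nonnegative")
        total = sum(w)
        if total <= 0:
            raise ValueError("weights must not all be zero")
        self.weights = tuple(x / total for x in w)

    def __len__(self):
        return len(self.weights)

    def __getitem__(self, i):
        return self.weights[i]

    def __iter__(self):
        return iter(self.weights)

    def __eq__(self, other):
        if isinstance(other, WeightVector):
            other = other.weights
        return tuple(self.weights) == tuple(other)

    def __hash__(self):
        return hash(self.weights)

    def __repr__(self):
        return f"WeightVector({list(self.weights)})"


@dataclass
class MeanResult:
    """Outcome of a Frechet-mean computation."""

    mean: PhyloTree
    iterations: int
    final_step: float
    converged: bool
    objective: float


def _as_weights(p, k1: int) -> tuple[float, ...]:
    if not isinstance(p, WeightVector):
        p = WeightVector(p)
    if len(p) != k1:
        raise ValueError(f"expected {k1} weights, got {len(p)}")
    return p.weights


def _check_taxa(V: Sequence[PhyloTree]):
    taxa = V[0].taxa
    for v in V[1:]:
        if v.taxa != taxa:
            raise ValueError("vertex trees are on different leaf sets")
    return taxa


def omega(x: PhyloTree, V: Sequence[PhyloTree], p, internal_only: bool = True) -> float:
    """Weighted sum of squared geodesic distances from ``x`` to the vertices."""
    taxa = _check_taxa(V)
    if x.taxa != taxa:
        raise ValueError("x is on a different leaf set from the vertices")
    w = _as_weights(p, len(V))
    ex = x._mask_edges(internal_only)
    return sum(
        pi * _distance(ex, v._mask_edges(internal_only)) ** 2
        for pi, v in zip(w, V)
    )


def _omega_masks(ex, vmasks, w) -> float:
    return sum(pi * _distance(ex, ev) ** 2 for pi, ev in zip(w, vmasks))


def _grad_masks(ex: dict[int, float], vmasks, w) -> dict[int, float]:
    """Gradient of Omega w.r.t. the edge lengths of x, at mask level."""
    grad = {m: 2.0 * l for m, l in ex.items()}
    for pi, ev in zip(w, vmasks):
        blocks, common = _support(ex, ev)
        for amasks, bmasks, an, bn in blocks:
            ratio = bn / an if an > 0 else 0.0
            for m in amasks:
                grad[m] += 2.0 * pi * ex[m] * ratio
        for m in ex:
            if m in common:
                grad[m] -= 2.0 * pi * ev.get(m, 0.0)
    return grad


def grad_omega(
    x: PhyloTree, V: Sequence[PhyloTree], p, internal_only: bool = True
) -> dict[Split, float]:
    """dOmega/dx_j for every internal edge of ``x``.

    Valid for ``x`` fully resolved and interior to a mutual support region
    with respect to the vertices (where Omega is differentiable); on region
    boundaries the one-sided derivatives differ and the returned values are
    those of the region containing the computed supports.
    """
    taxa = _check_taxa(V)
    if x.taxa != taxa:
        raise ValueError("x is on a different leaf set from the vertices")
    if not x.is_fully_resolved:
        raise ValueError("gradient requires a fully resolved tree")
    w = _as_weights(p, len(V))
    ex = x._mask_edges(internal_only)
    vmasks = [v._mask_edges(internal_only) for v in V]
    grad = _grad_masks(ex, vmasks, w)
    n = x.n_leaves
    return {Split(m, n): g for m, g in grad.items()}


# ---------------------------------------------------------------------------
# iterative solvers
# ---------------------------------------------------------------------------


def _geodesic_step(ex, ev, s):
    """Move a proportion ``s`` along the geodesic from ex to ev.

    Returns (new edge map, step displacement)."""
    blocks, common = _support(ex, ev)
    length = 0.0
    for _, _, an, bn in blocks:
        length += (an + bn) ** 2
    for m in common:
        length += (ex.get(m, 0.0) - ev.get(m, 0.0)) ** 2
    length = math.sqrt(length)
    if length == 0.0 or s == 0.0:
        return dict(ex), 0.0
    if s >= 1.0:
        return dict(ev), length
    return _point(blocks, common, ex, ev, s), s * length


def _scale(vmasks) -> float:
    """Rough diameter of the vertex configuration (for burn-in heuristics)."""
    best = 0.0
    for i in range(len(vmasks)):
        for j in range(i + 1, len(vmasks)):
            best = max(best, _distance(vmasks[i], vmasks[j]))
    return best


def _growth_bounds(e, vmasks, w):
    """Bounds on the one-sided derivative of Omega/2 growing split ``e``.

    The downhill pull comes from vertices containing ``e`` (where it
    interpolates as a common split); the uphill penalty from vertices whose
    splits it is incompatible with.  The penalty is at most
    ``p_i ||incompatible splits of v_i||`` (attained when the new edge
    crosses alone against all of them) and at least 0 (when it joins a
    support block with other shrinking edges, the marginal cost vanishes).
    Returns ``(gain, max_penalty)``; the true derivative lies in
    ``[-gain, -gain + max_penalty]``.
    """
    from .treespace import _masks_compatible

    gain = 0.0
    pen_max = 0.0
    for pi, ev in zip(w, vmasks):
        inc_sq = 0.0
        for f in ev:
            if not _masks_compatible(e, f):
                inc_sq += ev[f] ** 2
        if inc_sq > 0.0:
            pen_max += pi * math.sqrt(inc_sq)
        else:
            gain += pi * ev.get(e, 0.0)
    return gain, pen_max


def _growth_rate_exact(e, mu, vmasks, w, seed_len):
    """Exact one-sided derivative of Omega/2, from supports with ``e`` seeded."""
    mu_test = dict(mu)
    mu_test[e] = seed_len
    der = seed_len
    for pi, ev in zip(w, vmasks):
        blocks, common = _support(mu_test, ev)
        if e in common:
            der -= pi * ev.get(e, 0.0)
            continue
        for amasks, bmasks, an, bn in blocks:
            if e in amasks:
                der += pi * seed_len * bn / an
                break
    return der


def _polish(mu, vmasks, w, contract_tol=1e-11, max_rounds=40):
    """Solve the first-order conditions within the current support region.

    Returns ``(edge_map, success)``.  Splits driven to zero are contracted
    (the mean lies on an orthant boundary); conversely, a vertex split that
    is compatible with the current topology and has a negative one-sided
    growth derivative is seeded at infinitesimal length so the fixed point
    can carry the mean across the orthant wall.  Each contracted or seeded
    split is handled at most once per call, which bounds the work.
    """
    from .treespace import _masks_compatible

    mu = {m: l for m, l in mu.items() if l > contract_tol}
    scale = max((max(ev.values(), default=0.0) for ev in vmasks), default=1.0)
    seed_len = max(1e-9 * scale, 10 * contract_tol)
    union = set()
    for ev in vmasks:
        union.update(ev)
    banned: set[int] = set()
    prev_sig = None

    def seed_candidates(mu, exact):
        """Grow-gate pass; exact (support-based) derivatives only at
        acceptance time -- they cost one support set per candidate."""
        seeded = False
        for e in union:
            if e in mu or e in banned:
                continue
            if not all(_masks_compatible(e, m) for m in mu):
                continue
            gain, pen_max = _growth_bounds(e, vmasks, w)
            if gain <= 1e-14:
                continue
            if gain <= pen_max + 1e-14:  # ambiguous without exact check
                if not exact:
                    continue
                if _growth_rate_exact(e, mu, vmasks, w, seed_len) >= -1e-14:
                    continue
            mu[e] = seed_len
            banned.add(e)
            seeded = True
        return seeded

    for _ in range(max_rounds):
        if seed_candidates(mu, exact=False):
            prev_sig = None
        structs = [_support(mu, ev) for ev in vmasks]
        sig = tuple(
            (tuple(tuple(sorted(a)) for a, _, _, _ in blocks), tuple(sorted(common)))
            for blocks, common in structs
        )
        # candidate coordinates: every split of mu, plus splits common to all
        # vertices' supports (these have linear equations and may regrow)
        candidates = set(mu)
        common_all = None
        for blocks, common in structs:
            common_all = set(common) if common_all is None else common_all & common
        if common_all:
            candidates |= common_all
        # per-candidate terms: (p_i, const) for common, (p_i, block_masks, bnorm)
        terms: dict[int, list] = {m: [] for m in candidates}
        consistent = True
        for (blocks, common), ev, pi in zip(structs, vmasks, w):
            in_block = {}
            for amasks, bmasks, an, bn in blocks:
                for m in amasks:
                    in_block[m] = (amasks, bn)
            for m in candidates:
                if m in in_block:
                    amasks, bn = in_block[m]
                    terms[m].append((pi, None, amasks, bn))
                elif m in common:
                    terms[m].append((pi, ev.get(m, 0.0), None, None))
                else:
                    consistent = False
        if not consistent:
            return mu, False
        x = {m: mu.get(m, 0.0) for m in candidates}
        # splits only in common_all start from their linear solution
        for m in candidates:
            if m not in mu:
                x[m] = sum(pi * c for pi, c, a, b in terms[m] if a is None)
        for _inner in range(2000):
            maxdiff = 0.0
            newx = {}
            for m, tlist in terms.items():
                num = 0.0
                den = 1.0
                dead = False
                for pi, c, amasks, bn in tlist:
                    if amasks is None:
                        num += pi * c
                    else:
                        anorm = math.sqrt(sum(x[a] * x[a] for a in amasks if a in x))
                        if anorm <= contract_tol:
                            dead = True
                            break
                        den += pi * bn / anorm
                newx[m] = 0.0 if dead else num / den
                maxdiff = max(maxdiff, abs(newx[m] - x[m]))
            x = newx
            if maxdiff < 1e-13 * max(scale, 1.0):
                break
        dropped = {m for m, l in x.items() if l <= contract_tol}
        mu = {m: l for m, l in x.items() if l > contract_tol}
        if dropped:
            banned |= dropped
            prev_sig = None
            continue
        settled = maxdiff <= 1e-10 * max(scale, 1.0)
        if settled and sig == prev_sig:
            if seed_candidates(mu, exact=True):
                prev_sig = None
                continue
            return mu, True
        # verify support stability at the new point
        new_structs = [_support(mu, ev) for ev in vmasks]
        new_sig = tuple(
            (tuple(tuple(sorted(a)) for a, _, _, _ in blocks), tuple(sorted(common)))
            for blocks, common in new_structs
        )
        if settled and new_sig == sig:
            if seed_candidates(mu, exact=True):
                prev_sig = None
                continue
            return mu, True
        prev_sig = new_sig
    return mu, False


def _probe(mu, vmasks, w, delta=1e-3):
    """Step a proportion ``delta`` towards each vertex and evaluate Omega.

    Coordinate-wise stationarity can hold at cone-point saddles where only
    a *joint* block of splits grows downhill; a short step towards a vertex
    moves whole blocks together and exposes such points.  Returns
    ``(ok, best_nu)`` where ``ok`` means no vertex direction decreases
    Omega and ``best_nu`` is the most-improving probe point otherwise.
    """
    base = _omega_masks(mu, vmasks, w)
    tol = 1e-10 * (1.0 + abs(base))
    best_val, best_nu = base - tol, None
    for ev in vmasks:
        nu, disp = _geodesic_step(mu, ev, delta)
        if disp == 0.0:
            continue
        val = _omega_masks(nu, vmasks, w)
        if val < best_val:
            best_val, best_nu = val, nu
    return best_nu is None, best_nu


def _polish_full(mu, vmasks, w, full_dim=None, retries=8):
    """Polish with saddle escapes: re-polish from the best probe point
    whenever a vertex direction still descends.

    The probe is skipped when the result is fully resolved and polish
    touched no boundary: an interior stationary point of the convex
    objective is the global minimum.
    """
    cand, ok = _polish(mu, vmasks, w)
    if not ok:
        return mu, False
    for _ in range(retries):
        if full_dim is not None and len(cand) >= full_dim:
            return cand, True
        stationary, nu = _probe(cand, vmasks, w)
        if stationary:
            return cand, True
        cand, ok = _polish(nu, vmasks, w)
        if not ok:
            return mu, False
    return mu, False


def _iterate_mean(
    vmasks,
    w,
    choose,  # callable(i) -> vertex index
    step,    # callable(i, j) -> proportion
    eps,
    m,
    max_iter,
    init=None,
    init_iter=0,
    polish=False,
    full_dim=None,
):
    mu = dict(init) if init is not None else dict(vmasks[int(np.argmax(w))])
    K = len(vmasks)
    scale = _scale(vmasks)
    recent: list[float] = []
    it = init_iter
    last_step = 0.0
    converged = False
    burn = init_iter + max(60, 25 * K) if init is None else 0
    next_polish = burn
    for count in range(max_iter):
        if polish and it >= next_polish:
            cand, ok = _polish_full(mu, vmasks, w, full_dim=full_dim)
            if ok:
                mu = cand
                last_step = 0.0
                converged = True
                it += 1
                break
            next_polish = it + 200
        j = choose(it)
        mu, disp = _geodesic_step(mu, vmasks[j], step(it, j))
        last_step = disp
        recent.append(disp)
        if len(recent) > m - 1:
            recent.pop(0)
        it += 1
        # conservative form of the eps/m rule: if the last m-1 displacements
        # sum below eps, the last m iterates are pairwise within eps
        if len(recent) == m - 1 and sum(recent) < eps and (not polish or scale == 0):
            converged = True
            break
        if len(recent) == m - 1 and sum(recent) < eps and polish:
            cand, ok = _polish_full(mu, vmasks, w, full_dim=full_dim)
            if ok:
                mu = cand
            converged = True
            break
    return mu, it - init_iter, last_step, converged


def frechet_mean_sturm(
    V: Sequence[PhyloTree],
    p,
    seed=None,
    eps: float = 1e-6,
    m: int = 5,
    max_iter: int = 100000,
    internal_only: bool = True,
) -> MeanResult:
    """Sturm's stochastic algorithm for the weighted Frechet mean.

    At iteration i a vertex is sampled with probability p_j and the estimate
    moves a proportion 1/(i+2) along the geodesic towards it.
    """
    taxa = _check_taxa(V)
    w = _as_weights(p, len(V))
    keep = [i for i, pi in enumerate(w) if pi > 0]
    vmasks = [V[i]._mask_edges(internal_only) for i in keep]
    wk = np.array([w[i] for i in keep])
    wk = wk / wk.sum()
    rng = np.random.default_rng(seed)
    order = rng.choice(len(vmasks), size=max_iter, p=wk)
    mu, its, last, conv = _iterate_mean(
        vmasks,
        tuple(wk),
        choose=lambda i: int(order[i % max_iter]),
        step=lambda i, j: 1.0 / (i + 2),
        eps=eps,
        m=m,
        max_iter=max_iter,
    )
    mean = PhyloTree._from_masks(taxa, mu)
    return MeanResult(mean, its, last, conv, _omega_masks(mu, vmasks, wk))


def frechet_mean_bacak(
    V: Sequence[PhyloTree],
    p,
    eps: float = 1e-6,
    m: int = 5,
    max_iter: int = 100000,
    internal_only: bool = True,
    polish: bool = True,
    init: PhyloTree | None = None,
    init_iter: int = 0,
) -> MeanResult:
    """Deterministic cyclic algorithm for the weighted Frechet mean.

    Vertices with positive weight are visited cyclically; the step towards
    vertex j at overall iteration i is ``min(1, p_j (k+1) / (i+2))``, which
    reduces to Sturm's 1/(i+2) schedule for uniform weights.  With
    ``polish=True`` (default) the iterate is refined by solving the
    first-order conditions inside the located mutual support region.

    ``init``/``init_iter`` warm-start the iteration (used when sampling the
    locus over a lattice of nearby weight vectors).
    """
    taxa = _check_taxa(V)
    w = _as_weights(p, len(V))
    keep = [i for i, pi in enumerate(w) if pi > 0]
    vmasks = [V[i]._mask_edges(internal_only) for i in keep]
    wk = tuple(w[i] / sum(w[i] for i in keep) for i in keep)
    K = len(vmasks)
    if K == 1:
        v = PhyloTree._from_masks(taxa, vmasks[0])
        return MeanResult(v, 0, 0.0, True, 0.0)
    mu, its, last, conv = _iterate_mean(
        vmasks,
        wk,
        choose=lambda i: i % K,
        step=lambda i, j: min(1.0, wk[j] * K / (i + 2)),
        eps=eps,
        m=m,
        max_iter=max_iter,
        init=init._mask_edges(internal_only) if init is not None else None,
        init_iter=init_iter,
        polish=polish,
        full_dim=(len(taxa) - 3) + (0 if internal_only else len(taxa)),
    )
    mean = PhyloTree._from_masks(taxa, mu)
    return MeanResult(mean, its, last, conv, _omega_masks(mu, vmasks, wk))


def local_affine_solution(
    V: Sequence[PhyloTree],
    p,
    region_supports: Sequence[GeodesicSupport],
    internal_only: bool = True,
) -> PhyloTree:
    """Closed-form mean in a region where all vertex geodesics are simple.

    With every support block a singleton, the first-order conditions become
    linear, ``x_j = sum_i p_i alpha_ij`` with ``alpha_ij`` equal to
    ``|e_j|_{v_i}`` when the split is shared with (or compatible towards)
    ``v_i`` and ``-|f|_{v_i}`` when it exchanges with split ``f`` of ``v_i``
    along the geodesic.  Raises if any support is non-simple or the solution
    leaves the region's orthant.
    """
    taxa = _check_taxa(V)
    w = _as_weights(p, len(V))
    if len(region_supports) != len(V):
        raise ValueError("need one support per vertex")
    n = V[0].n_leaves
    candidates: set[Split] = set()
    common_all: set[Split] | None = None
    for sup in region_supports:
        for blk in sup.A:
            if len(blk) != 1:
                raise ValueError(
                    "non-simple support: use the iterative solvers instead"
                )
            candidates |= set(blk)
        for blk in sup.B:
            if len(blk) != 1:
                raise ValueError(
                    "non-simple support: use the iterative solvers instead"
                )
        cs = set(sup.C)
        common_all = cs if common_all is None else common_all & cs
    if common_all:
        candidates |= common_all
    edges: dict[Split, float] = {}
    for s in candidates:
        total = 0.0
        for pi, v, sup in zip(w, V, region_supports):
            in_a = None
            for blk_a, blk_b in zip(sup.A, sup.B):
                if s in blk_a:
                    in_a = next(iter(blk_b))
                    break
            if in_a is not None:
                total -= pi * v.length_of(in_a)
            elif s in sup.C:
                total += pi * v.length_of(s)
            else:
                raise ValueError(f"split {s} not classified by support")
        if total < -1e-12:
            raise ValueError(
                "affine solution leaves the orthant; the weight vector is "
                "outside the simple region"
            )
        if total > 0:
            edges[s] = total
    return PhyloTree(taxa, edges, validate=True)
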