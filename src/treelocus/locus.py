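"""The locus of the weighted Frechet mean, Pi(V), and projection onto it.

Pi(V) = { mu(V, p) : p in the k-simplex } plays the role of a k-th principal
component in BHV tree space: it contains the vertices, every vertex-pair
geodesic, and Pi(W) for any subset W of V.  Data are projected onto Pi(V)
either by exhaustive search over a simplex lattice (the accuracy benchmark)
or by the geometric projection algorithm, a greedy Sturm-type iteration that
repeatedly steps towards whichever vertex brings the estimate closest to the
data point.  Fit quality is summarized by the sum of squared projection
distances D^2 and a non-Euclidean r^2 statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .frechet import WeightVector, _check_taxa, frechet_mean_bacak
from .geodesic import _distance, _point, _support
from .treespace import PhyloTree, Topology

__all__ = [
    "ProjectionResult",
    "LocusFit",
    "simplex_lattice",
    "locus_sample",
    "project_exhaustive",
    "project_geometric",
    "project_all",
    "sum_squared_projected",
    "r_squared",
    "evaluate_locus",
    "simplex_topology_map",
]


@dataclass
class ProjectionResult:
    """A projection of one data tree onto Pi(V).

    ``weights`` is the estimated simplex position of the projected point;
    it is reported as found, with no claim of uniqueness (stickiness can
    make the minimizing p non-unique even when the projection is unique).
    """

    projected: PhyloTree
    weights: WeightVector
    distance: float
    iterations: int
    converged: bool


@dataclass
class LocusFit:
    """A fitted locus: vertices, per-datum projections, D^2 and r^2."""

    vertices: list[PhyloTree]
    projections: list[ProjectionResult]
    d_squared: float
    r_squared: float


def simplex_lattice(resolution: int, k: int = 2) -> list[tuple[float, ...]]:
    """The triangular lattice {(a_0,...,a_k)/r : sum a_i = r} on the simplex."""
    r = int(resolution)
    if r < 1:
        raise ValueError("resolution must be >= 1")
    if k == 1:
        return [(a / r, (r - a) / r) for a in range(r, -1, -1)]
    if k == 2:
        pts = []
        for a in range(r, -1, -1):
            for b in range(r - a, -1, -1):
                pts.append((a / r, b / r, (r - a - b) / r))
        return pts
    raise ValueError("triangular lattices are provided for k <= 2")


def locus_sample(
    V: Sequence[PhyloTree],
    resolution: int = 32,
    internal_only: bool = True,
    eps: float = 1e-6,
    m: int = 5,
    max_iter: int = 100000,
    polish: bool = True,
) -> dict[tuple[float, ...], PhyloTree]:
    """Sample Pi(V) at every point of a simplex lattice (cyclic-mean solver).

    Neighbouring lattice points warm-start each other: mu(V, .) is
    continuous, so the previous mean is an excellent initial estimate.
    """
    _check_taxa(V)
    k = len(V) - 1
    r = int(resolution)
    out: dict[tuple[float, ...], PhyloTree] = {}
    if k == 2:
        by_abc: dict[tuple[int, int, int], PhyloTree] = {}
        for a in range(r, -1, -1):
            for b in range(r - a, -1, -1):
                c = r - a - b
                init = (
                    by_abc.get((a + 1, b, c - 1))
                    or by_abc.get((a + 1, b - 1, c))
                    or by_abc.get((a, b + 1, c - 1))
                )
                res = frechet_mean_bacak(
                    V,
                    (a / r, b / r, c / r),
                    eps=eps,
                    m=m,
                    max_iter=max_iter,
                    internal_only=internal_only,
                    polish=polish,
                    init=init,
                    init_iter=0 if init is None else 40,
                )
                by_abc[(a, b, c)] = res.mean
                out[(a / r, b / r, c / r)] = res.mean
        return out
    prev = None
    for p in simplex_lattice(r, k=k):
        res = frechet_mean_bacak(
            V,
            p,
            eps=eps,
            m=m,
            max_iter=max_iter,
            internal_only=internal_only,
            polish=polish,
            init=prev,
            init_iter=0 if prev is None else 40,
        )
        prev = res.mean
        out[p] = res.mean
    return out


def project_exhaustive(
    z: PhyloTree,
    V: Sequence[PhyloTree],
    resolution: int = 32,
    internal_only: bool = True,
    sample: Mapping[tuple[float, ...], PhyloTree] | None = None,
    refine_levels: int = 0,
    refine_factor: int = 4,
    cache: dict | None = None,
    **mean_kwargs,
) -> ProjectionResult:
    """Project ``z`` onto Pi(V) by exhaustive search over a simplex lattice.

    Computationally expensive; used as the benchmark for the geometric
    algorithm.  A precomputed ``sample`` (from :func:`locus_sample`) may be
    supplied to amortize the base lattice over many data points.  An
    accurate benchmark needs a fine lattice; ``refine_levels > 0``
    subdivides the winning cell ``refine_levels`` times by
    ``refine_factor`` (evaluating means only near the current optimum),
    giving the accuracy of a lattice ``refine_factor**refine_levels`` times
    finer at a fraction of its cost.  A ``cache`` dict (keyed by refined
    weight vector) can be shared across calls with the same vertices to
    amortize refined means over clustered data points.
    """
    taxa = _check_taxa(V)
    if z.taxa != taxa:
        raise ValueError("data tree on a different leaf set")
    if len(V) != 3 and refine_levels:
        raise ValueError("local refinement is implemented for k = 2")
    if sample is None:
        sample = locus_sample(
            V, resolution, internal_only=internal_only, **mean_kwargs
        )
    ez = z._mask_edges(internal_only)
    best_p, best_tree, best_d = None, None, math.inf
    for p, tree in sample.items():
        d = _distance(ez, tree._mask_edges(internal_only))
        if d < best_d:
            best_p, best_tree, best_d = p, tree, d
    evaluated = len(sample)
    r = int(resolution)
    for _ in range(refine_levels):
        f = int(refine_factor)
        r_new = r * f
        a0 = round(best_p[0] * r_new)
        b0 = round(best_p[1] * r_new)
        for a in range(max(0, a0 - f), min(r_new, a0 + f) + 1):
            for b in range(max(0, b0 - f), min(r_new - a, b0 + f) + 1):
                c = r_new - a - b
                p = (a / r_new, b / r_new, c / r_new)
                if p == best_p:
                    continue
                mean = cache.get(p) if cache is not None else None
                if mean is None:
                    mean = frechet_mean_bacak(
                        V,
                        p,
                        internal_only=internal_only,
                        init=best_tree,
                        init_iter=40,
                    ).mean
                    if cache is not None:
                        cache[p] = mean
                evaluated += 1
                d = _distance(ez, mean._mask_edges(internal_only))
                if d < best_d:
                    best_p, best_tree, best_d = p, mean, d
        r = r_new
    return ProjectionResult(
        projected=best_tree,
        weights=WeightVector(best_p),
        distance=best_d,
        iterations=evaluated,
        converged=True,
    )


def _project_geometric_once(ez, vmasks, rng, eps, m, max_iter):
    K = len(vmasks)
    # initial estimate: uniform w.r.t. arc length on the perimeter of Pi(V)
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
    supports = []
    lens = []
    for i, j in pairs:
        blocks, common = _support(vmasks[i], vmasks[j])
        length = math.sqrt(
            sum((an + bn) ** 2 for _, _, an, bn in blocks)
            + sum(
                (vmasks[i].get(mm, 0.0) - vmasks[j].get(mm, 0.0)) ** 2
                for mm in common
            )
        )
        supports.append((blocks, common))
        lens.append(length)
    total = sum(lens)
    if total == 0.0:
        mu = dict(vmasks[0])
    else:
        u = rng.random() * total
        idx = 0
        while u > lens[idx] and idx < len(pairs) - 1:
            u -= lens[idx]
            idx += 1
        i, j = pairs[idx]
        blocks, common = supports[idx]
        lam = u / lens[idx] if lens[idx] > 0 else 0.0
        mu = _point(blocks, common, vmasks[i], vmasks[j], min(max(lam, 0.0), 1.0))

    p = np.zeros(K)
    recent: list[float] = []
    converged = False
    it = 0
    for it in range(max_iter):
        s = 1.0 / (it + 2)
        best_r, best_d, best_mu, best_disp = -1, math.inf, None, 0.0
        for jdx in range(K):
            blocks, common = _support(mu, vmasks[jdx])
            glen = math.sqrt(
                sum((an + bn) ** 2 for _, _, an, bn in blocks)
                + sum(
                    (mu.get(mm, 0.0) - vmasks[jdx].get(mm, 0.0)) ** 2
                    for mm in common
                )
            )
            y = _point(blocks, common, mu, vmasks[jdx], s) if glen > 0 else dict(mu)
            d = _distance(ez, y)
            if d < best_d:
                best_r, best_d, best_mu, best_disp = jdx, d, y, s * glen
        mu = best_mu
        p = it * p / (it + 1)
        p[best_r] += 1.0 / (it + 1)
        recent.append(best_disp)
        if len(recent) > m - 1:
            recent.pop(0)
        if len(recent) == m - 1 and sum(recent) < eps:
            converged = True
            it += 1
            break
    return mu, p, _distance(ez, mu), it, converged


def project_geometric(
    z: PhyloTree,
    V: Sequence[PhyloTree],
    seed=None,
    eps: float = 1e-3,
    m: int = 5,
    max_iter: int = 5000,
    internal_only: bool = True,
    restarts: int = 1,
) -> ProjectionResult:
    """Greedy geometric projection of ``z`` onto Pi(V).

    The initial estimate is sampled uniformly (by arc length) from the
    perimeter of Pi(V); at each iteration the estimate moves a proportion
    1/(i+2) along the geodesic towards whichever vertex minimizes the
    distance to ``z``, and the running vertex-visit frequencies estimate the
    simplex weights of the projection.  The algorithm can be trapped in
    local minima of the perpendicular distance; ``restarts > 1`` keeps the
    best of several starts.
    """
    taxa = _check_taxa(V)
    if z.taxa != taxa:
        raise ValueError("data tree on a different leaf set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ez = z._mask_edges(internal_only)
    vmasks = [v._mask_edges(internal_only) for v in V]
    best = None
    for _ in range(max(1, restarts)):
        mu, p, d, its, conv = _project_geometric_once(
            ez, vmasks, rng, eps, m, max_iter
        )
        if best is None or d < best[2]:
            best = (mu, p, d, its, conv)
    mu, p, d, its, conv = best
    return ProjectionResult(
        projected=PhyloTree._from_masks(taxa, mu),
        weights=WeightVector(p if p.sum() > 0 else np.ones(len(V))),
        distance=d,
        iterations=its,
        converged=conv,
    )


def project_all(
    Z: Sequence[PhyloTree],
    V: Sequence[PhyloTree],
    method: str = "geometric",
    seed=None,
    resolution: int = 32,
    internal_only: bool = True,
    **kwargs,
) -> list[ProjectionResult]:
    """Project every tree of ``Z`` onto Pi(V)."""
    if method == "exhaustive":
        sample = locus_sample(V, resolution, internal_only=internal_only)
        return [
            project_exhaustive(
                z, V, resolution, internal_only=internal_only, sample=sample
            )
            for z in Z
        ]
    if method != "geometric":
        raise ValueError(f"unknown projection method {method!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [
        project_geometric(z, V, seed=rng, internal_only=internal_only, **kwargs)
        for z in Z
    ]


def sum_squared_projected(
    Z: Sequence[PhyloTree],
    V: Sequence[PhyloTree],
    method: str = "geometric",
    seed=None,
    internal_only: bool = True,
    **kwargs,
) -> float:
    """D^2_Z{Pi(V)}: the sum of squared projection distances of the data."""
    results = project_all(
        Z, V, method=method, seed=seed, internal_only=internal_only, **kwargs
    )
    return sum(r.distance**2 for r in results)


def r_squared(
    Z: Sequence[PhyloTree],
    V: Sequence[PhyloTree],
    mode: str = "explained",
    projections: Sequence[ProjectionResult] | None = None,
    seed=None,
    internal_only: bool = True,
    **kwargs,
) -> float:
    """Non-Euclidean proportion-of-variance statistic for Pi(V).

    With residual R = sum_i d(z_i, pi(z_i))^2 and explained
    E = sum_i d(pibar, pi(z_i))^2, where pibar is the Frechet mean of the
    projections:

    - ``mode="explained"`` (default) returns E / (R + E), which behaves as a
      proportion of variance explained (larger when the data hug the
      surface and spread across it);
    - ``mode="literal"`` returns R / (R + E), the printed form of the
      statistic, retained verbatim for comparison.

    If all projections coincide (E = 0, e.g. a sticky point) the explained
    mode returns 0.
    """
    if projections is None:
        projections = project_all(
            Z, V, seed=seed, internal_only=internal_only, **kwargs
        )
    residual = sum(r.distance**2 for r in projections)
    proj_trees = [r.projected for r in projections]
    pibar = frechet_mean_bacak(
        proj_trees,
        [1.0] * len(proj_trees),
        internal_only=internal_only,
    ).mean
    eb = pibar._mask_edges(internal_only)
    explained = sum(
        _distance(eb, t._mask_edges(internal_only)) ** 2 for t in proj_trees
    )
    if residual + explained == 0.0:
        return 0.0
    if mode == "explained":
        return explained / (residual + explained)
    if mode == "literal":
        return residual / (residual + explained)
    raise ValueError(f"unknown r^2 mode {mode!r}")


def evaluate_locus(
    Z: Sequence[PhyloTree],
    V: Sequence[PhyloTree],
    seed=None,
    internal_only: bool = True,
    r2_mode: str = "explained",
    **kwargs,
) -> LocusFit:
    """Project a dataset onto Pi(V) and assemble the fit summary."""
    projections = project_all(
        Z, V, seed=seed, internal_only=internal_only, **kwargs
    )
    d2 = sum(r.distance**2 for r in projections)
    r2 = r_squared(
        Z, V, mode=r2_mode, projections=projections, internal_only=internal_only
    )
    return LocusFit(list(V), projections, d2, r2)


def simplex_topology_map(
    V: Sequence[PhyloTree],
    resolution: int = 32,
    internal_only: bool = True,
    sample: Mapping[tuple[float, ...], PhyloTree] | None = None,
) -> dict[tuple[float, ...], Topology]:
    """Topology of mu(V, p) at every lattice point (for simplex shading plots).

    Sticky regions show up as a single (often unresolved) topology occupying
    positive lattice area.
    """
    if len(V) != 3:
        raise ValueError("the simplex map is defined for k = 2")
    if sample is None:
        sample = locus_sample(V, resolution, internal_only=internal_only)
    return {p: tree.topology for p, tree in sample.items()}
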