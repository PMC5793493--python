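"""Synthetic data generation for validating tree-space principal components.

Everything needed to exercise the geometry without external data: Kingman
coalescent species trees, gene trees from the multispecies coalescent
contained in a species tree, coalescent-topology trees with gamma edge
lengths, NNI and SPR rearrangements, random walks in tree space,
Dirichlet-sampled datasets scattered around a known locus Pi(W), the
explicit three-vertex example in T_5 used throughout the tests, and the
projection validation harness.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from .frechet import frechet_mean_bacak
from .geodesic import distance
from .locus import locus_sample, project_exhaustive, project_geometric
from .treespace import PhyloTree, Split

__all__ = [
    "SimConfig",
    "sim_species_tree",
    "sim_gene_trees",
    "random_tree_gamma",
    "nni",
    "nni_neighbors",
    "random_nni",
    "spr",
    "random_spr",
    "random_walk",
    "make_surface_dataset",
    "validation_harness",
    "t5_example",
    "t5_coords",
]


@dataclass
class SimConfig:
    """Configuration for the surface-dataset generator.

    Defaults reproduce the simulation design used throughout: trees on
    N = 10 non-root taxa with coalescent topologies and Gamma(shape 2,
    rate 20) edge lengths, vertex trees obtained by topological
    rearrangements of a base tree, 100 Dirichlet(4,4,4) points on the
    surface, and 5-step Gaussian random-walk perturbations whose step size
    sets the low- or high-dispersion regime.
    """

    n_taxa: int = 10
    seed: int | None = None
    gamma_shape: float = 2.0
    gamma_rate: float = 20.0
    dirichlet: tuple[float, ...] = (4.0, 4.0, 4.0)
    walk_steps: int = 5
    walk_step_size: float = 0.01
    n_points: int = 100
    op_kind: str = "nni"  # "nni" or "spr"
    n_ops: int = 2

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        if min(self.dirichlet) <= 0 or self.gamma_shape <= 0 or self.gamma_rate <= 0:
            raise ValueError("distribution parameters must be positive")
        if self.walk_steps < 0 or self.walk_step_size < 0:
            raise ValueError("walk parameters must be nonnegative")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _taxa(n: int) -> tuple[str, ...]:
    return tuple(str(i) for i in range(n + 1))


# ---------------------------------------------------------------------------
# coalescent simulators
# ---------------------------------------------------------------------------


def sim_species_tree(N: int, seed=None, root_edge: float = 1.0) -> PhyloTree:
    """A rooted binary species tree on taxa 1..N from the Kingman coalescent.

    Waiting time to the next coalescence with j lineages is exponential
    with rate j(j-1)/2, and the merging pair is uniform.  Branch lengths
    are in coalescent units; the root leaf 0 is attached above the final
    coalescence with pendant length ``root_edge``.
    """
    if N < 3:
        raise ValueError("need N >= 3")
    rng = _rng(seed)
    lineages = [(1 << i, 0.0) for i in range(N)]
    t = 0.0
    edges: dict[int, float] = {}
    while len(lineages) > 1:
        j = len(lineages)
        t += rng.exponential(2.0 / (j * (j - 1)))
        a, b = rng.choice(j, size=2, replace=False)
        (ma, ta) = lineages[a]
        (mb, tb) = lineages[b]
        for m, t0 in ((ma, ta), (mb, tb)):
            edges[m] = t - t0
        lineages = [lineages[i] for i in range(j) if i not in (a, b)]
        lineages.append((ma | mb, t))
    edges[(1 << N) - 1] = float(root_edge)
    return PhyloTree(_taxa(N), {Split(m, N): l for m, l in edges.items()})


class _SNode:
    __slots__ = ("mask", "length", "children", "age")

    def __init__(self, mask, length, children):
        self.mask = mask
        self.length = length
        self.children = children
        self.age = 0.0


def _to_nodes(x: PhyloTree) -> tuple[list[_SNode], float]:
    """Nested clade structure below the root-leaf attachment point.

    Returns (top-level nodes, root edge length).  Node ages are set
    assuming contemporaneous leaves.
    """
    n = x.n_leaves
    full = (1 << n) - 1
    imasks = {s.mask: l for s, l in x.internal_edges().items()}
    pend = {s.mask: l for s, l in x.pendant_edges().items()}

    def build(m: int) -> _SNode:
        if m.bit_count() == 1:
            return _SNode(m, pend.get(m, 0.0), [])
        kids = [build(c) for c in _components_under(imasks, m, n)]
        node = _SNode(m, imasks.get(m, 0.0) if m != full else pend.get(full, 0.0), kids)
        node.age = max(k.age + k.length for k in kids)
        return node

    top = [build(c) for c in _components_under(imasks, full, n)]
    return top, pend.get(full, 0.0)


def _components_under(imasks, m: int, n: int) -> list[int]:
    """Maximal internal splits strictly inside mask m, plus leftover leaves."""
    inside = [s for s in imasks if s & m == s and s != m]
    maximal = [s for s in inside if not any(s != t and s & t == s for t in inside)]
    covered = 0
    for s in maximal:
        covered |= s
    leaves = [1 << i for i in range(n) if m >> i & 1 and not covered >> i & 1]
    return maximal + leaves


def sim_gene_trees(
    u: PhyloTree, count: int, seed=None, root_edge: float = 1.0
) -> list[PhyloTree]:
    """Gene trees from the multispecies coalescent contained in ``u``.

    One lineage is sampled per species; within each species-tree branch,
    lineages coalesce at rate j(j-1)/2 for the branch's duration (branch
    lengths are read as coalescent units) and the survivors are carried
    into the parent branch.  Remaining lineages coalesce freely above the
    species root.
    """
    rng = _rng(seed)
    n = u.n_leaves
    top, _ = _to_nodes(u)
    out = []
    for _ in range(count):
        edges: dict[int, float] = {}

        def coalesce(lineages, start, duration):
            t = start
            while len(lineages) > 1:
                j = len(lineages)
                dt = rng.exponential(2.0 / (j * (j - 1)))
                if t + dt > start + duration:
                    return lineages
                t += dt
                a, b = rng.choice(j, size=2, replace=False)
                (ma, ta) = lineages[a]
                (mb, tb) = lineages[b]
                edges[ma] = edges.get(ma, 0.0) + (t - ta)
                edges[mb] = edges.get(mb, 0.0) + (t - tb)
                lineages = [lineages[i] for i in range(j) if i not in (a, b)]
                lineages.append((ma | mb, t))
            return lineages

        def within(node: _SNode):
            if not node.children:
                lineages = [(node.mask, node.age)]
            else:
                lineages = []
                for c in node.children:
                    lineages.extend(within(c))
            return coalesce(lineages, node.age, node.length)

        lineages = []
        for c in top:
            lineages.extend(within(c))
        root_age = max(c.age + c.length for c in top) if top else 0.0
        lineages = coalesce(lineages, root_age, math.inf)
        # close the pendant edge of the final lineage via the root edge
        (mfull, tf) = lineages[0]
        edges.pop(mfull, None)
        edges[(1 << n) - 1] = float(root_edge)
        out.append(
            PhyloTree(u.taxa, {Split(m, n): l for m, l in edges.items() if l > 0})
        )
    return out


def random_tree_gamma(
    N: int, alpha: float = 2.0, beta: float = 20.0, seed=None
) -> PhyloTree:
    """Coalescent-topology tree with i.i.d. Gamma(alpha, rate beta) edge lengths."""
    rng = _rng(seed)
    base = sim_species_tree(N, rng)
    edges = {
        s: rng.gamma(alpha, 1.0 / beta) for s in base.edges
    }
    return PhyloTree(base.taxa, edges)


# ---------------------------------------------------------------------------
# topological rearrangements
# ---------------------------------------------------------------------------


def _nni_context(x: PhyloTree, e: int):
    """(children X1, X2 below edge e; sibling S across it) for a binary context."""
    n = x.n_leaves
    full = (1 << n) - 1
    imasks = {s.mask: l for s, l in x.internal_edges().items()}
    if e not in imasks:
        raise ValueError("edge is not an internal split of the tree")
    kids = _components_under(imasks, e, n)
    supersets = [s for s in imasks if e & s == e and s != e]
    parent = min(supersets, key=lambda s: s.bit_count(), default=full)
    sibs = [c for c in _components_under(imasks, parent, n) if c != e]
    if len(kids) != 2 or len(sibs) != 1:
        raise ValueError("NNI requires a binary context around the edge")
    return kids[0], kids[1], sibs[0]


def nni(x: PhyloTree, edge: Split, choice: int) -> PhyloTree:
    """Nearest-neighbour interchange across an internal edge.

    The edge separates subtrees {X1, X2} from sibling S; choice 0 swaps X1
    with S (new split X2|S), choice 1 swaps X2 with S (new split X1|S).
    The new edge inherits the old edge's length; all other lengths persist.
    """
    if choice not in (0, 1):
        raise ValueError("choice must be 0 or 1")
    n = x.n_leaves
    x1, x2, s = _nni_context(x, edge.mask)
    new_mask = (x2 | s) if choice == 0 else (x1 | s)
    edges = dict(x.edges)
    length = edges.pop(edge)
    edges[Split(new_mask, n)] = length
    return PhyloTree(x.taxa, edges)


def nni_neighbors(x: PhyloTree) -> list[PhyloTree]:
    """All NNI rearrangements of a binary tree (2 per internal edge)."""
    return [
        nni(x, s, c) for s in x.internal_edges() for c in (0, 1)
    ]


def random_nni(x: PhyloTree, seed=None) -> PhyloTree:
    rng = _rng(seed)
    internals = sorted(x.internal_edges(), key=lambda s: s.mask)
    e = internals[int(rng.integers(len(internals)))]
    return nni(x, e, int(rng.integers(2)))


def spr(x: PhyloTree, prune_edge: Split, regraft_edge: Split) -> PhyloTree:
    """Subtree prune and regraft.

    The subtree below ``prune_edge`` is detached (the suppressed degree-2
    vertex's remaining edge keeps its own length) and reattached in the
    middle of ``regraft_edge``, whose length persists below the new vertex;
    the newly created edge above the attachment inherits the length of the
    edge removed during pruning.  An edge that contained the pruned subtree
    is identified, after pruning, by its remaining leaf set.
    """
    n = x.n_leaves
    full = (1 << n) - 1
    d = prune_edge.mask
    r = regraft_edge.mask
    if prune_edge not in x.edges or regraft_edge not in x.edges:
        raise ValueError("edges must belong to the tree")
    if d == full or r == full:
        raise ValueError("cannot prune or regraft at the root edge")
    if (r & d) == r:
        raise ValueError("regraft edge lies within the pruned subtree")
    top, rootlen = _to_nodes(x)
    root = _SNode(full, rootlen, top)

    def find_parent(node, target):
        for c in node.children:
            if c.mask == target:
                return node
            if target & c.mask == target:
                return find_parent(c, target)
        return None

    parent = find_parent(root, d)
    if parent is None:
        raise ValueError("prune edge not found")
    dnode = next(c for c in parent.children if c.mask == d)
    parent.children.remove(dnode)
    if parent is root:
        removed_len = dnode.length
        if len(root.children) == 1:
            only = root.children[0]
            removed_len = only.length
            root.children = only.children
    elif len(parent.children) == 1:
        only = parent.children[0]
        removed_len = parent.length
        gp = find_parent(root, parent.mask)
        gp.children[gp.children.index(parent)] = only
    else:
        removed_len = dnode.length

    def refresh(node):
        if node.children:
            node.mask = 0
            for c in node.children:
                refresh(c)
                node.mask |= c.mask

    refresh(root)
    r_eff = (r & ~d) if (r & d) == d else r
    if r_eff == 0:
        raise ValueError("regraft edge vanishes after pruning")
    pr = find_parent(root, r_eff)
    if pr is None:
        raise ValueError("regraft edge not found after pruning")
    rnode = next(c for c in pr.children if c.mask == r_eff)
    newnode = _SNode(r_eff | d, removed_len, [rnode, dnode])
    pr.children[pr.children.index(rnode)] = newnode
    if len(root.children) == 1:
        only = root.children[0]
        rootlen += only.length
        root.children = only.children
    refresh(root)

    edges: dict[int, float] = {full: rootlen} if rootlen > 0 else {}

    def collect(node):
        for c in node.children:
            if c.length > 0:
                edges[c.mask] = edges.get(c.mask, 0.0) + c.length
            collect(c)

    collect(root)
    return PhyloTree(x.taxa, {Split(m, n): l for m, l in edges.items()})


def random_spr(x: PhyloTree, seed=None) -> PhyloTree:
    rng = _rng(seed)
    n = x.n_leaves
    full = (1 << n) - 1
    candidates = sorted(
        (s for s in x.edges if s.mask != full), key=lambda s: s.mask
    )
    for _ in range(200):
        pr = candidates[int(rng.integers(len(candidates)))]
        targets = [
            s
            for s in candidates
            if s.mask != pr.mask and (s.mask & pr.mask) != s.mask
            and (s.mask | pr.mask) != s.mask
        ]
        if not targets:
            continue
        rg = targets[int(rng.integers(len(targets)))]
        try:
            return spr(x, pr, rg)
        except ValueError:
            continue
    raise RuntimeError("no valid SPR move found")


# ---------------------------------------------------------------------------
# random walks and surface datasets
# ---------------------------------------------------------------------------


def random_walk(
    x: PhyloTree, steps: int, step_size: float, seed=None
) -> PhyloTree:
    """Isotropic Gaussian random walk on the internal-edge coordinates.

    Each step perturbs every internal edge length by N(0, step_size^2).  A
    coordinate crossing zero contracts its split; when the resulting vertex
    has degree 4 the walk enters one of the three adjacent resolutions of
    that vertex uniformly at random (carrying the crossed magnitude as the
    new length), otherwise the step reflects.  Pendant edges are untouched.
    """
    rng = _rng(seed)
    n = x.n_leaves
    edges = dict(x.edges)
    for _ in range(int(steps)):
        internals = sorted(
            (s for s in edges if s.is_internal), key=lambda s: s.mask
        )
        if not internals:
            break
        incr = rng.normal(0.0, step_size, size=len(internals))
        crossed = []
        for s, dl in zip(internals, incr):
            newl = edges[s] + dl
            if newl > 0:
                edges[s] = newl
            else:
                crossed.append((s, -newl))
        for s, overshoot in crossed:
            del edges[s]
            try:
                x1, x2, sib = _nni_context(
                    PhyloTree(x.taxa, {**edges, s: 1.0}, validate=False), s.mask
                )
                options = [s.mask, x1 | sib, x2 | sib]
                pick = options[int(rng.integers(3))]
            except ValueError:
                pick = s.mask  # degenerate vertex: reflect
            edges[Split(pick, n)] = overshoot if overshoot > 0 else 1e-12
    return PhyloTree(x.taxa, edges)


def make_surface_dataset(
    config: SimConfig, seed=None
) -> tuple[list[PhyloTree], list[PhyloTree]]:
    """Generate vertices W and a dataset scattered around Pi(W).

    A base tree w0 has a coalescent topology and Gamma(shape, rate) edge
    lengths; w1 and w2 are obtained by applying ``n_ops`` random NNI or SPR
    operations to w0.  Points on Pi(W) at Dirichlet-sampled weights are
    computed with the cyclic mean algorithm and perturbed by random walks.
    With zero walk steps the data lie exactly on the surface.
    """
    rng = _rng(seed if seed is not None else config.seed)
    w0 = random_tree_gamma(
        config.n_taxa, config.gamma_shape, config.gamma_rate, rng
    )
    op = random_nni if config.op_kind == "nni" else random_spr
    w1, w2 = w0, w0
    while w1.topology == w0.topology:
        w1 = w0
        for _ in range(config.n_ops):
            w1 = op(w1, rng)
    while w2.topology in (w0.topology, w1.topology):
        w2 = w0
        for _ in range(config.n_ops):
            w2 = op(w2, rng)
    W = [w0, w1, w2]
    weights = rng.dirichlet(config.dirichlet, size=config.n_points)
    Z = []
    prev = None
    for p in weights:
        res = frechet_mean_bacak(
            W,
            p,
            internal_only=False,
            init=prev,
            init_iter=0 if prev is None else 40,
        )
        prev = res.mean
        z = res.mean
        if config.walk_steps > 0 and config.walk_step_size > 0:
            z = random_walk(z, config.walk_steps, config.walk_step_size, rng)
        Z.append(z)
    return W, Z


# ---------------------------------------------------------------------------
# projection validation harness
# ---------------------------------------------------------------------------


def validation_harness(
    reps: int,
    N: int = 6,
    lattice_resolution: int = 16,
    seed=None,
    eps: float = 1e-6,
    m: int = 5,
    max_iter: int = 12000,
    restarts: int = 1,
    check1_rel_tol: float = 1e-3,
    refine_levels: int = 2,
) -> dict:
    """Compare geometric and exhaustive projection on coalescent simulations.

    Per replication: a Kingman species tree on N taxa; vertex trees
    v0, v1, v2 and a test tree z as gene trees from the contained
    coalescent; z projected onto Pi(V) by both algorithms, ignoring pendant
    edges.  The exhaustive benchmark must be accurate to be meaningful, so
    its base lattice is locally refined (``refine_levels``) around the
    optimum; with the default two 4-fold refinements its effective
    resolution is 16x the base.  Check 1 passes when the geometric distance does not exceed the
    exhaustive-search distance (with relative slack ``check1_rel_tol``,
    separating genuine local-minimum trapping from iteration truncation
    noise in two approximately computed distances); check 2 when the two
    projected trees lie within 1% of z's total internal length of each
    other.  Failure diagnostics: mean excess perpendicular distance (% of
    the exhaustive distance) and mean disagreement (% of internal length)
    among failing replications.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = _rng(seed)
    n_pass = 0
    excess = []
    disagree = []
    for _ in range(reps):
        u = sim_species_tree(N, rng)
        v0, v1, v2, z = sim_gene_trees(u, 4, rng)
        V = [v0, v1, v2]
        sample = locus_sample(V, lattice_resolution)
        exh = project_exhaustive(
            z,
            V,
            resolution=lattice_resolution,
            sample=sample,
            refine_levels=refine_levels,
        )
        geo = project_geometric(
            z, V, seed=rng, eps=eps, m=m, max_iter=max_iter, restarts=restarts
        )
        check1 = geo.distance <= exh.distance * (1.0 + check1_rel_tol) + 1e-12
        gap = distance(geo.projected, exh.projected)
        scale = z.total_internal_length()
        check2 = gap <= 0.01 * scale
        if check1 and check2:
            n_pass += 1
        else:
            if exh.distance > 0:
                excess.append(100.0 * (geo.distance - exh.distance) / exh.distance)
            if scale > 0:
                disagree.append(100.0 * gap / scale)
    n_fail = reps - n_pass
    return {
        "reps": reps,
        "pass_fraction": n_pass / reps,
        "n_fail": n_fail,
        "mean_excess_pct": float(np.mean(excess)) if excess else 0.0,
        "mean_disagreement_pct": float(np.mean(disagree)) if disagree else 0.0,
    }


# ---------------------------------------------------------------------------
# the explicit T_5 example
# ---------------------------------------------------------------------------


def t5_example() -> tuple[PhyloTree, PhyloTree, PhyloTree]:
    """Three vertex trees in T_5 whose locus has flat and curved pieces.

    Under the identification of the three relevant orthants with coordinates
    (xi1, xi2, xi3) -- xi1 = x({2,3}) or -x({3,4,5}), xi2 = x({4,5}) or
    -x({2,3,4}), xi3 = x({0,1}) -- the vertices sit at v0 = (1, 1, 2),
    v1 = (-2, 1, 1) and v2 = (1, -2, 1).  Pendant edges are omitted.
    """
    taxa = _taxa(5)

    def sp(*idx):
        return Split.from_indices(idx, 5)

    v0 = PhyloTree(taxa, {sp(2, 3): 1.0, sp(4, 5): 1.0, sp(2, 3, 4, 5): 2.0})
    v1 = PhyloTree(taxa, {sp(3, 4, 5): 2.0, sp(4, 5): 1.0, sp(2, 3, 4, 5): 1.0})
    v2 = PhyloTree(taxa, {sp(2, 3): 1.0, sp(2, 3, 4): 2.0, sp(2, 3, 4, 5): 1.0})
    return v0, v1, v2


def t5_coords(tree: PhyloTree) -> tuple[float, float, float]:
    """Coordinates (xi1, xi2, xi3) of a tree in the T_5 example's orthants."""

    def sp(*idx):
        return Split.from_indices(idx, 5)

    xi1 = tree.length_of(sp(2, 3)) - tree.length_of(sp(3, 4, 5))
    xi2 = tree.length_of(sp(4, 5)) - tree.length_of(sp(2, 3, 4))
    xi3 = tree.length_of(sp(2, 3, 4, 5))
    return xi1, xi2, xi3
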