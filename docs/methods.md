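# Methods

## The space and its geodesics

`treelocus` works in the Billera–Holmes–Vogtmann (BHV) space T_N of rooted
phylogenetic trees on leaves 0..N, with the root attached at the leaf
labelled 0. Cutting an edge of a tree bipartitions the leaf set; a tree is
the set of its splits together with strictly positive lengths, and the set
of trees sharing a topology is a Euclidean orthant in the internal-edge
coordinates. Orthants are glued along the boundaries obtained by
contracting edges; the whole complex is CAT(0), so any two trees are joined
by a unique geodesic. Pendant edges contribute a Euclidean factor that
every analysis here ignores by default (`internal_only=True`); all the
geometry below concerns the internal coordinates.

The geodesic between trees `x` and `y` is characterized by its *support*:
ordered partitions A^(1..l) of the splits unique to `x` and B^(1..l) of the
splits unique to `y`, plus the set C of splits compatible with both trees.
Its squared length is

    d(x,y)^2 = sum_j ( ||A^(j)||_x + ||B^(j)||_y )^2
             + sum_{e in C} ( |e|_x - |e|_y )^2 .

Supports are computed by the geodesic tree path scheme: start from the cone
path (one block containing everything incompatible) and repeatedly split a
block when the minimum-weight vertex cover of its bipartite incompatibility
graph — vertex weights `|e|_x^2/||A||^2` and `|f|_y^2/||B||^2` — weighs
less than 1. Covers are found by exact subset enumeration when the smaller
side has at most 14 elements (always, at the problem sizes this package
targets) and by max-flow/min-cut otherwise. A cover of weight exactly 1 is
treated as "do not split", which yields a canonical support without
changing the length. Points along a geodesic interpolate the common splits
linearly; the splits of block j shrink to zero at arc-length fraction
`||A^(j)||/(||A^(j)||+||B^(j)||)` where block j of `y` starts growing, so
positions are affine in the arc-length parameter and speed is constant.

Splits are stored as integer bitmasks over the non-root leaves, which makes
the four-point compatibility test two machine operations; this matters
because the validation studies below execute tens of millions of support
computations.

## Weighted Fréchet means

The weighted Fréchet mean of vertices V = {v_0..v_k} with simplex weights p
minimizes `Omega(x,p) = sum_i p_i d(x,v_i)^2`; CAT(0) convexity makes the
minimizer unique. Two iterative solvers are provided:

- **Sturm's algorithm**: sample vertex j with probability p_j, move a
  proportion `1/(i+2)` along the geodesic towards it.
- **Cyclic algorithm**: visit positive-weight vertices cyclically with step
  `min(1, p_j (k+1)/(i+2))` towards vertex j at overall iteration i. For
  uniform weights this reduces to the Sturm schedule; zero-weight vertices
  are dropped first, so a unit weight returns that vertex exactly.

Both stop under an ε/m rule: the run ends when the last m iterates are
pairwise within ε (implemented conservatively as the sum of the last m−1
step displacements falling below ε; defaults ε = 1e-6, m = 5,
max_iter = 1e5).

These schemes converge at rate O(1/i), too slow for the 1e-4-level checks
the explicit T_5 example admits. The cyclic solver therefore *polishes* its
iterate: within the mutual support region located by the iteration, the
stationarity conditions

    x_j ( 1 + sum_i p_i ||B^(r_ij)||/||A^(r_ij)|| ) = sum_i p_i C_ij |e_j|_{v_i}

(`C_ij` indicating splits interpolating as common towards v_i) are solved
by fixed-point iteration, recomputing supports until they stabilize.
Coordinates driven to zero are contracted (the mean lies on an orthant
boundary — "sticky" means are represented simply by split absence), and a
vertex-tree split compatible with the current topology is seeded at
infinitesimal length whenever its one-sided growth derivative is negative,
letting the mean cross an orthant wall. The derivative is bracketed
cheaply — the downhill pull is `sum_{i: e in v_i} p_i |e|_{v_i}`, the
uphill penalty at most `p_i ||incompatible splits of v_i||` per vertex and
at least zero (it vanishes when the edge joins a support block with other
shrinking edges) — and evaluated exactly from seeded supports when the
bracket is ambiguous. Each contracted or seeded split is handled at most
once per polish call, bounding the work.

Coordinate-wise stationarity is necessary but not sufficient at cone
points, where only a *joint* block of splits descends. A polished
candidate that is not fully resolved (an interior stationary point of the
convex objective in a top-dimensional orthant is already the global
minimum) is therefore probed: a short step towards each vertex — which
moves whole blocks together — must not decrease Ω; if one does, polishing
restarts from the best probe point. Polish is accepted only when the
support signature is stable, the inner iteration has settled, and the
probe passes; otherwise the cyclic iteration continues and retries later.
Even so, positional accuracy is ultimately limited by objective flatness:
across some orthant walls Ω varies by less than 1e-7 while positions
differ by ~1e-4, and there the solver guarantees the objective value, not
the position. Sturm's solver is never polished, so Sturm-vs-cyclic agreement tests
compare genuinely different routes. When all vertex geodesics from a region
are simple (all support blocks singletons) the same equations are linear
and `local_affine_solution` evaluates them in closed form; on the T_5
example this reproduces the planar piece `xi = (p0-2p1+p2, p0+p1-2p2,
1+p0)` of the locus to machine precision, and the curved piece follows the
closed form with `f(p) = (p0+p1)/(p0-2p1)`.

## The locus Π(V), projection, and summaries

Π(V) = { mu(V,p) : p in the simplex } is sampled over a triangular lattice
`{(a,b,c)/r}` (default r = 32), warm-starting each mean from a neighbouring
lattice point — mu(V,·) is continuous, so this costs a handful of support
computations per point.

**Exhaustive projection** returns the lattice point minimizing the distance
to the data tree. As a benchmark it must be accurate, so the winning cell
can be refined locally (default two 4-fold refinements in the validation
harness, giving the accuracy of a 16× finer lattice at ~50 extra means).

**Geometric projection** is a greedy Sturm-type iteration: from a start
drawn uniformly by arc length on the perimeter of Π(V), move a proportion
`1/(i+2)` towards whichever vertex yields the candidate closest to the
data tree; the running visit frequencies estimate the simplex weights. The
ε/m rule cannot trigger for interior projections until displacements
(~1/i) sum below ε, i.e. after ~1/ε iterations, so `max_iter` is the
effective accuracy knob; positional truncation error scales like
(configuration diameter)/max_iter. The algorithm can settle in stable
non-optimal fixed points of its own dynamics — moving along the chord
towards any single vertex can increase the distance even when a direction
along the surface would decrease it. Restarts (`restarts>1`) mitigate some
but not all such traps; the reported weights carry no uniqueness claim
(stickiness can make the minimizing p non-unique).

Fit quality uses `D^2 = sum_i d(z_i, pi(z_i))^2` and a non-Euclidean r².
With residual R = D² and dispersion E = `sum_i d(pibar, pi(z_i))^2` around
the Fréchet mean of the projections, the default "explained" mode reports
`E/(R+E)`; a "literal" mode reporting `R/(R+E)` — the formula as usually
printed — is kept because the two disagree about direction: under the
printed form a surface hugging the data more tightly would score *lower*,
contradicting the interpretation as a proportion of variance explained.
Both modes are exposed; all defaults use "explained".

## Fitting Π(V) to data

`fit_locus` performs a greedy stochastic search over vertex configurations:
sweep the three vertices, propose replacements from three families — a
uniform draw from the data; a Beta(2,2)-distributed point along the
geodesic from the vertex to a uniform data draw; Gaussian random walks (one
long step at 25% of the data's mean internal edge length, and five short
steps at 5%) — and accept whenever D², evaluated by geometric projection,
decreases. Acceptance continues the sweep from the next (vertex, proposal)
pair. A run stops when the relative D² decrease over a 10-sweep window
falls below 1e-3; three independently seeded runs are kept by default and
the best returned. Candidate evaluation aborts early once the partial D²
exceeds the incumbent. Projections depend on the whole vertex set, so no
caching survives a vertex move.

## Synthetic data

All validation inputs are generated internally:

- **Species trees**: Kingman coalescent on taxa 1..N (waiting times
  exponential with rate j(j−1)/2, uniform merges), branch lengths in
  coalescent units; the root leaf 0 is attached above the final
  coalescence. The units are a deliberate choice — the studies this design
  follows do not state them — and they matter: in raw coalescent units a
  6-taxon species tree has internal branches of order 0.1–0.5, so gene
  trees are highly discordant (full-topology concordance ~3%), which makes
  the projection validation study's instances geometrically hard (many
  interior projection targets far from the vertex trees). Deeper species
  trees make the study markedly easier.
- **Gene trees**: multispecies coalescent contained in the species tree,
  one lineage per species, rate j(j−1)/2 within each branch, survivors
  carried to the parent, free coalescence above the root.
- **Gamma trees**: coalescent topology with i.i.d. Gamma(shape 2, rate 20)
  lengths on every edge (mean edge length 0.1).
- **Rearrangements**: NNI swaps one of the two subtrees below an internal
  edge with the sibling subtree across it; SPR detaches a subtree and
  reattaches it in the middle of another edge (persisting edges keep their
  lengths; the newly created edge inherits the length of the edge removed
  by pruning).
- **Random walks**: per step, every internal coordinate receives N(0, σ²)
  noise; a coordinate crossing zero contracts its split and the walk enters
  one of the three resolutions of the resulting degree-4 vertex uniformly
  at random, carrying the crossed magnitude (a degenerate higher-degree
  vertex reflects instead). Pendant edges are untouched.
- **Surface datasets**: a gamma base tree w0; w1, w2 from `n_ops` random
  NNI or SPR moves; 100 (default) Dirichlet(4,4,4) weights; cyclic-solver
  means on Π(W); random-walk perturbation. Walk step sizes of 0.01 (low
  dispersion) and 0.035 (high dispersion) with 5 steps were fixed once to
  realize D² regimes of roughly 0.003·n and 0.025·n at N = 10 — the two
  qualitative regimes the fitting study needs — and are not tuned further.

What the generators do *not* emulate: sequence-level noise and gene-tree
estimation error, outlying trees, rate variation across genes, or
non-contemporaneous sampling. Passing tests therefore show that the
geometry, solvers and search behave correctly on coalescent-shaped inputs
of known provenance, not that inference pipelines based on estimated gene
trees will enjoy the same accuracy.

## The projection validation harness

Per replication: species tree on N = 6 taxa; vertex trees v0, v1, v2 and a
test tree z from the contained coalescent; z projected on Π(V) with both
algorithms, internal edges only. Check 1: the geometric distance does not
exceed the (locally refined) exhaustive benchmark distance, with relative
slack 1e-3 to keep float ties from counting as failures; check 2: the two
projected trees are within 1% of z's total internal length of each other.
The summary reports the pass fraction and, among failures, the mean excess
distance (% of the benchmark distance) and the mean disagreement (% of
internal length). At 200 replications with single-start projection
(`max_iter` 12000) the pass fraction measured here is ≈ 0.5–0.7 depending
on the seed; the failures are genuine attractors of the greedy dynamics
(deepening the iteration by 50× and multi-restarting does not move them)
with per-failure excess around 3%, and the rate tracks how discordant the
gene trees are (see the coalescent-units note above).

## Numerical choices and scales

- Cover-weight and ratio comparisons use absolute tolerance 1e-12; a block
  splits only when the minimum cover weighs below 1 − 1e-12.
- Polish contracts coordinates below 1e-11 and accepts only when the inner
  fixed point has settled below 1e-10·scale with a stable support
  signature.
- Default problem sizes in `scripts/acceptance.py` (chosen as the package's
  standing validation suite): 200 harness replications, 300 oracle pairs,
  5000 CAT(0) triples, 30 containment configurations, and the 2×NNI / 2×SPR
  low/high-dispersion fitting scenarios at n = 30 with 4-sweep single-run
  searches. During the vertex search, candidate D² comparisons use shallow
  projections (300 iterations — the truncation bias is common-mode across
  candidates); the reported D², r² and projections are re-evaluated at
  depth 2000.
- All randomness flows through explicitly seeded `numpy` generators; every
  public stochastic function takes a seed or generator, and fixed seeds
  reproduce results bit-for-bit.

## Known limitations

- The fitting search is restricted to k = 2 (three vertices), mirroring the
  method it implements; k = 1 is available implicitly as a two-vertex
  locus.
- The geometric projection offers no convergence guarantee; its failure
  modes are quantified by the harness rather than bounded theoretically.
- Means at extremely degenerate configurations (e.g. all data at a single
  sticky point) report r² = 0 with no attempt to disambiguate.
- Newick input requires branch lengths on every edge; zero-length internal
  edges are interpreted as contracted (boundary trees), not as soft
  polytomies to be resolved.
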