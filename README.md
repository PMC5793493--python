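# treelocus

Principal component analysis for collections of phylogenetic trees, in the
Billera–Holmes–Vogtmann (BHV) tree space.

A phylogenomic analysis typically yields one tree per gene, all on the same
species. The set of such trees is not a vector space — topologies differ —
but it is a CAT(0) geodesic space: one Euclidean orthant per topology, glued
along shared boundaries, with a unique shortest path between any two trees.
`treelocus` implements descriptive statistics in that space:

- **geodesics and distances** `d(x, y)` via the polynomial-time geodesic
  tree path (support refinement by minimum-weight vertex cover);
- **weighted Fréchet means** `mu(V, p) = argmin_x sum_i p_i d(x, v_i)^2`
  (Sturm's stochastic algorithm and a deterministic cyclic solver with an
  exact first-order polish);
- the **locus of the Fréchet mean** `Pi(V) = { mu(V,p) : p in the
  k-simplex }`, a k-dimensional surface through the vertex trees that plays
  the role of a k-th principal component;
- **projection** of data trees onto `Pi(V)` (a fast greedy geometric
  algorithm, plus an exhaustive lattice benchmark with local refinement);
- **fitting** `Pi(V)` to a sample of gene trees by greedy stochastic search
  over vertex configurations, summarized by the sum of squared projection
  distances `D^2` and a non-Euclidean `r^2`;
- **simulation**: Kingman species trees, multispecies-coalescent gene
  trees, gamma-length random trees, NNI/SPR rearrangements, tree-space
  random walks, and datasets scattered around a known surface.

It is intended for methodologically inclined phylogeneticists and
statisticians working with samples of trees on up to a dozen or so taxa.

## A worked example

Three trees on six leaves (the root is the leaf `0`), with the third pair
of vertices separated by a geodesic that passes through the star-tree cone
point:

```python
from treelocus import Geodesic, frechet_mean_bacak, project_geometric
from treelocus.synthdata import t5_example, t5_coords

v0, v1, v2 = t5_example()
print(Geodesic(v0, v1).length)        # 3.1622776601683795  (= sqrt(10))
print(Geodesic(v1, v2).length)        # 4.47213595499958    (= 2 sqrt(5))

res = frechet_mean_bacak([v0, v1, v2], (0.5, 0.3, 0.2))
print(tuple(round(x, 9) for x in t5_coords(res.mean)))   # (0.1, 0.4, 1.5)
```

The mean's coordinates land exactly on the plane
`(p0 - 2 p1 + p2, p0 + p1 - 2 p2, 1 + p0)` — in this region of weight
space the locus is an affine patch, because every geodesic from the mean to
a vertex crosses orthant walls one edge at a time. Elsewhere the surface
curves; the package reproduces its closed form there too (see
`examples/02_frechet_mean.py`).

Projecting a perturbed surface point back (from
`examples/03_projection.py`):

```text
geometric : distance=0.03672 weights=[0.469 0.307 0.224]
exhaustive: distance=0.03745 weights=[0.469 0.309 0.223]
```

The two algorithms agree on where the point sits on the surface (simplex
weights near the generating `(0.5, 0.3, 0.2)`); the geometric distance is
the perpendicular BHV distance from the data tree to the surface, and the
greedy algorithm here even edges out the lattice benchmark.

The `examples/` directory contains one short script per capability
(geodesics, means, projection, simulation + fitting, the validation study),
each printing the numbers it computes with a line on what they mean.

## Command line

A thin CLI wraps the library for shell use:

```sh
treelocus distance trees.nwk 0 1
treelocus mean trees.nwk --weights 0.5,0.3,0.2
treelocus project data.nwk --vertices-file vertices.nwk --seed 1
treelocus fit genes.nwk --seed 1 --out report.json --map-out simplex.tsv
treelocus simulate surface --n-taxa 10 --count 100 --seed 7
treelocus validate --reps 50 --seed 1
```

Inputs are Newick lists (one tree per line, branch lengths mandatory, taxon
`0` — configurable via `--root-label` — anchoring the split orientation).

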