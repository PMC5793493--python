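"""Geodesic distance between phylogenetic trees in BHV tree space.

Builds the explicit three-vertex configuration in T_5 (six leaves, the
root labelled 0) and prints pairwise geodesic distances and the structure
of each geodesic's support.  A geodesic with a single multi-split support
block "kinks" through the star-tree cone point instead of crossing one
orthant wall at a time.
"""

from treelocus import Geodesic, is_simple
from treelocus.synthdata import t5_example

v0, v1, v2 = t5_example()
for name, a, b in [("v0-v1", v0, v1), ("v0-v2", v0, v2), ("v1-v2", v1, v2)]:
    g = Geodesic(a, b)
    kind = "simple (one edge swaps at a time)" if is_simple(g) else "cone path"
    print(f"d({name}) = {g.length:.6f}   blocks={len(g.support)}   {kind}")

mid = Geodesic(v1, v2).point(0.5)
print("\nmidpoint of the v1-v2 geodesic (an unresolved tree at the cone point):")
print(" ", mid.to_newick())
print("  internal splits:", {tuple(sorted(s.indices())): l for s, l in mid.internal_edges().items()})
# d(v1,v2) = 2*sqrt(5): the path contracts both v1 splits to zero together,
# passes the {0,1}-axis, then grows both v2 splits.
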