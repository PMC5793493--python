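"""Weighted Frechet means and the locus they trace out.

The weighted Frechet mean mu(V, p) minimizes sum_i p_i d(x, v_i)^2 over
tree space.  As p sweeps the probability simplex, the means trace the
surface Pi(V) -- the tree-space analogue of a (k=2nd) principal component.
On the explicit T_5 configuration part of this surface is an exact plane:
the mean at p has coordinates (p0-2p1+p2, p0+p1-2p2, 1+p0) whenever all
three vertex geodesics are "simple".
"""

from treelocus import frechet_mean_bacak, frechet_mean_sturm
from treelocus.synthdata import t5_coords, t5_example

V = list(t5_example())
for p in [(1.0, 0.0, 0.0), (0.5, 0.3, 0.2), (0.4, 0.35, 0.25)]:
    res = frechet_mean_bacak(V, p)
    xi = t5_coords(res.mean)
    plane = (p[0] - 2 * p[1] + p[2], p[0] + p[1] - 2 * p[2], 1 + p[0])
    print(
        f"p={p}  mean=({xi[0]:+.6f},{xi[1]:+.6f},{xi[2]:+.6f})  "
        f"plane prediction=({plane[0]:+.6f},{plane[1]:+.6f},{plane[2]:+.6f})"
    )

# Sturm's stochastic algorithm converges to the same point, more slowly:
p = (0.5, 0.3, 0.2)
sturm = frechet_mean_sturm(V, p, seed=1, eps=1e-5, max_iter=200000)
print("\nSturm iterate coordinates:", tuple(round(c, 4) for c in t5_coords(sturm.mean)))
print("(stochastic approximation of the same mean; the deterministic cyclic")
print(" solver above is the one used for locus sampling)")
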