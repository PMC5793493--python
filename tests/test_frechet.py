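import math

import numpy as np
import pytest

from conftest import t5_point
from oracles import euclidean_weighted_mean
from treelocus.frechet import (
    MeanResult,
    WeightVector,
    frechet_mean_bacak,
    frechet_mean_sturm,
    grad_omega,
    local_affine_solution,
    omega,
)
from treelocus.geodesic import Geodesic, compute_support, distance
from treelocus.synthdata import random_tree_gamma, t5_coords
from treelocus.treespace import PhyloTree


def plane_point(p):
    """Frozen closed form for the planar piece of the T_5 locus.

    Derived from the first-order conditions with all three supports simple
    and cross-checked against the iterative solvers; note the symmetric
    second coordinate p0 + p1 - 2 p2.
    """
    p0, p1, p2 = p
    return (p0 - 2 * p1 + p2, p0 + p1 - 2 * p2, 1 + p0)


def curved_point(p):
    """Frozen closed form for the curved piece (p0 < 2 p1 region)."""
    p0, p1, p2 = p
    f = (p0 + p1) / (p0 - 2 * p1)
    xi1 = p0 - 2 * p1 + p2 * math.sqrt(5.0 / (1.0 + f * f))
    xi2 = p0 + p1 - p2 * math.sqrt(5.0 / (1.0 + f**-2))
    return (xi1, xi2, p0 + 1)


class TestWeightVector:
    def test_normalization_and_scale_invariance(self):
        assert WeightVector([2, 1, 1]).weights == (0.5, 0.25, 0.25)
        assert WeightVector([0.2, 0.1, 0.1]) == WeightVector([2, 1, 1])

    @pytest.mark.parametrize("bad", [[-1, 2], [0, 0, 0]])
    def test_invalid_weights(self, bad):
        with pytest.raises(ValueError):
            WeightVector(bad)


class TestOmega:
    def test_zero_at_supported_vertex(self, t5):
        v0, v1, v2 = t5
        assert omega(v1, [v0, v1, v2], (0, 1, 0)) == 0.0

    def test_curved_region_closed_form(self, t5):
        # squared distances from a point with xi1<0, xi2>0: straight to v0
        # and v1, cone path to v2
        v0, v1, v2 = t5
        for xi in [(-0.5, 0.8, 1.3), (-1.2, 0.4, 1.8)]:
            x = t5_point(*xi)
            d0 = (1 - xi[0]) ** 2 + (1 - xi[1]) ** 2 + (2 - xi[2]) ** 2
            d1 = (2 + xi[0]) ** 2 + (1 - xi[1]) ** 2 + (1 - xi[2]) ** 2
            d2 = (math.sqrt(5) + math.hypot(*xi[:2])) ** 2 + (1 - xi[2]) ** 2
            p = (0.3, 0.45, 0.25)
            expected = p[0] * d0 + p[1] * d1 + p[2] * d2
            assert omega(x, [v0, v1, v2], p) == pytest.approx(expected, rel=1e-12)

    def test_midpoint_of_two(self, t5):
        v0, v1, _ = t5
        mid = Geodesic(v0, v1).point(0.5)
        d2 = distance(v0, v1) ** 2
        assert omega(mid, [v0, v1], (0.5, 0.5)) == pytest.approx(d2 / 4, rel=1e-9)


class TestGradOmega:
    def test_zero_at_interior_mean(self, t5):
        V = list(t5)
        p = (0.5, 0.3, 0.2)
        res = frechet_mean_bacak(V, p)
        g = grad_omega(res.mean, V, p)
        assert max(abs(v) for v in g.values()) < 1e-6

    def test_printed_gradient_in_curved_region(self, t5):
        # components of grad Omega for xi1 < 0, xi2 > 0 (the typo-corrected
        # second component has p2*xi2, verified by finite differences below)
        V = list(t5)
        p = (0.25, 0.45, 0.30)
        xi = (-0.6, 0.7, 1.4)
        x = t5_point(*xi)
        r = math.hypot(xi[0], xi[1])
        expected = {
            1: 2 * xi[0] + 2 * p[2] * xi[0] * math.sqrt(5) / r + 4 * p[1] - 2 * p[0],
            2: 2 * xi[1] + 2 * p[2] * xi[1] * math.sqrt(5) / r - 2 * p[1] - 2 * p[0],
            3: 2 * xi[2] - 2 - 2 * p[0],
        }
        g = grad_omega(x, V, p)
        got = {}
        for s, val in g.items():
            idx = tuple(sorted(s.indices()))
            if idx == (3, 4, 5):
                got[1] = -val  # d/dxi1 = -d/dx({3,4,5})
            elif idx == (4, 5):
                got[2] = val
            else:
                got[3] = val
        assert got[1] == pytest.approx(expected[1], rel=1e-10)
        assert got[2] == pytest.approx(expected[2], rel=1e-10)
        assert got[3] == pytest.approx(expected[3], rel=1e-10)

    def test_matches_finite_differences(self, t5):
        V = list(t5)
        rng = np.random.default_rng(3)
        h = 1e-6
        for _ in range(15):
            xi = (-rng.uniform(0.3, 1.5), rng.uniform(0.3, 1.5), rng.uniform(0.8, 2))
            x = t5_point(*xi)
            p = tuple(rng.dirichlet((2, 2, 2)))
            g = grad_omega(x, V, p)
            for s, val in g.items():
                up = dict(x.edges)
                dn = dict(x.edges)
                up[s] += h
                dn[s] -= h
                fd = (
                    omega(PhyloTree(x.taxa, up), V, p)
                    - omega(PhyloTree(x.taxa, dn), V, p)
                ) / (2 * h)
                assert val == pytest.approx(fd, rel=1e-5, abs=1e-5)

    def test_unresolved_tree_rejected(self, t5):
        V = list(t5)
        star = PhyloTree(V[0].taxa, {})
        with pytest.raises(ValueError, match="resolved"):
            grad_omega(star, V, (1 / 3, 1 / 3, 1 / 3))


class TestSturm:
    def test_unit_weight_recovers_vertex(self, t5):
        v0, v1, v2 = t5
        res = frechet_mean_sturm([v0, v1, v2], (0, 1, 0), seed=1, eps=1e-4)
        assert distance(res.mean, v1) < 1e-2

    def test_identical_vertices(self, t5):
        v0, _, _ = t5
        res = frechet_mean_sturm([v0, v0, v0], (0.3, 0.3, 0.4), seed=2, eps=1e-5)
        assert res.mean.approx_equal(v0, tol=1e-4)

    def test_single_orthant_euclidean_mean(self, rng):
        base = random_tree_gamma(6, seed=rng)
        V = [
            PhyloTree(base.taxa, {s: l * f for s, l in base.edges.items()})
            for f in (1.0, 1.5, 2.5)
        ]
        p = (0.5, 0.25, 0.25)
        res = frechet_mean_sturm(V, p, seed=3, eps=1e-5, max_iter=200000)
        expected = euclidean_weighted_mean(V, p)
        for s, l in expected.items():
            assert res.mean.length_of(s) == pytest.approx(l, abs=5e-3)


class TestBacak:
    def test_unit_weight_recovers_vertex_exactly(self, t5):
        v0, v1, v2 = t5
        for i, v in enumerate(t5):
            e = [0.0, 0.0, 0.0]
            e[i] = 1.0
            res = frechet_mean_bacak([v0, v1, v2], e)
            assert res.mean.approx_equal(v, tol=1e-12)

    def test_two_point_midpoint(self, t5):
        v0, v1, _ = t5
        res = frechet_mean_bacak([v0, v1], (0.5, 0.5))
        mid = Geodesic(v0, v1).point(0.5)
        assert distance(res.mean, mid) < 1e-8

    def test_flat_region_plane(self, t5):
        V = list(t5)
        for p in [(0.5, 0.3, 0.2), (0.6, 0.2, 0.2), (0.4, 0.25, 0.35)]:
            res = frechet_mean_bacak(V, p)
            xi = t5_coords(res.mean)
            expected = plane_point(p)
            assert xi == pytest.approx(expected, abs=1e-8)

    def test_curved_region_closed_form(self, t5):
        V = list(t5)
        for p in [(0.2, 0.5, 0.3), (0.1, 0.55, 0.35), (0.25, 0.45, 0.3)]:
            res = frechet_mean_bacak(V, p)
            assert t5_coords(res.mean) == pytest.approx(curved_point(p), abs=1e-8)

    def test_agrees_with_sturm(self, rng):
        for n in (6, 8):
            V = [random_tree_gamma(n, seed=rng) for _ in range(3)]
            p = tuple(rng.dirichlet((3, 3, 3)))
            b = frechet_mean_bacak(V, p)
            s = frechet_mean_sturm(V, p, seed=int(rng.integers(2**31)),
                                   eps=1e-5, max_iter=200000)
            assert distance(b.mean, s.mean) < 0.05

    def test_scale_invariant_in_weights(self, t5):
        V = list(t5)
        a = frechet_mean_bacak(V, (0.5, 0.3, 0.2))
        b = frechet_mean_bacak(V, (5.0, 3.0, 2.0))
        assert a.mean.approx_equal(b.mean, tol=1e-10)

    def test_returns_mean_result(self, t5):
        res = frechet_mean_bacak(list(t5), (0.4, 0.3, 0.3))
        assert isinstance(res, MeanResult)
        assert res.converged
        assert res.objective > 0


class TestHessian:
    def test_numerically_positive_definite(self, t5):
        # finite-difference Hessian of Omega at interior points has positive
        # eigenvalues: every stationary point is a minimum
        V = list(t5)
        h = 1e-5
        for p in [(0.5, 0.3, 0.2), (0.2, 0.5, 0.3)]:
            x = frechet_mean_bacak(V, p).mean
            splits = sorted(x.edges, key=lambda s: s.mask)
            k = len(splits)
            H = np.zeros((k, k))
            for i in range(k):
                for j in range(k):
                    vals = []
                    for si, sj in [(h, h), (h, -h), (-h, h), (-h, -h)]:
                        e = dict(x.edges)
                        e[splits[i]] += si
                        e[splits[j]] += sj
                        vals.append(omega(PhyloTree(x.taxa, e), V, p))
                    H[i, j] = (vals[0] - vals[1] - vals[2] + vals[3]) / (4 * h * h)
            assert np.linalg.eigvalsh(H).min() > 0


class TestLocalAffineSolution:
    def test_vertex_weight_recovers_vertex(self, t5):
        V = list(t5)
        x = t5_point(0.5, 0.5, 1.5)
        sups = [compute_support(x, v) for v in V]
        sol = local_affine_solution(V, (1, 0, 0), sups)
        assert sol.approx_equal(V[0], tol=1e-12)

    def test_matches_bacak_in_flat_region(self, t5):
        V = list(t5)
        x = t5_point(0.5, 0.5, 1.5)
        sups = [compute_support(x, v) for v in V]
        p = (0.5, 0.3, 0.2)
        sol = local_affine_solution(V, p, sups)
        res = frechet_mean_bacak(V, p)
        assert distance(sol, res.mean) < 1e-8

    def test_two_points_linear_interpolation(self, rng):
        base = random_tree_gamma(6, seed=rng)
        other = PhyloTree(base.taxa, {s: 2 * l for s, l in base.edges.items()})
        sups = [compute_support(base, base), compute_support(base, other)]
        sol = local_affine_solution([base, other], (0.25, 0.75), sups)
        expected = euclidean_weighted_mean([base, other], (0.25, 0.75))
        for s, l in expected.items():
            assert sol.length_of(s) == pytest.approx(l, rel=1e-12)

    def test_non_simple_support_rejected(self, t5):
        v0, v1, v2 = t5
        x = t5_point(-0.5, 0.8, 1.3)  # geodesic to v2 is a cone path
        sups = [compute_support(x, v) for v in (v0, v1, v2)]
        with pytest.raises(ValueError, match="simple"):
            local_affine_solution([v0, v1, v2], (0.3, 0.4, 0.3), sups)
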