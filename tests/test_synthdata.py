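import numpy as np
import pytest
from scipy import stats

from treelocus.geodesic import distance
from treelocus.locus import project_geometric
from treelocus.synthdata import (
    SimConfig,
    _to_nodes,
    make_surface_dataset,
    nni,
    nni_neighbors,
    random_spr,
    random_tree_gamma,
    random_walk,
    sim_gene_trees,
    sim_species_tree,
    spr,
    validation_harness,
)
from treelocus.treespace import PhyloTree, Split, validate_topology


def tree_height(t):
    top, _ = _to_nodes(t)
    return max(c.age + c.length for c in top)


class TestSpeciesTreeSimulator:
    def test_reproducible(self):
        a = sim_species_tree(6, seed=11)
        b = sim_species_tree(6, seed=11)
        assert a == b

    def test_shape(self):
        t = sim_species_tree(8, seed=1)
        assert t.is_fully_resolved
        assert len(t.internal_edges()) == 6
        assert all(l > 0 for l in t.edges.values())

    def test_topologies_exchangeable_n3(self):
        # the three resolved rooted topologies on {1,2,3} are equally likely
        rng = np.random.default_rng(0)
        counts = {}
        for _ in range(900):
            t = sim_species_tree(3, rng)
            counts[t.topology] = counts.get(t.topology, 0) + 1
        assert len(counts) == 3
        _, pval = stats.chisquare(list(counts.values()))
        assert pval > 1e-3

    def test_expected_height(self):
        # Kingman: E[height] = 2 (1 - 1/N)
        rng = np.random.default_rng(1)
        hs = [tree_height(sim_species_tree(6, rng)) for _ in range(1500)]
        se = np.std(hs) / np.sqrt(len(hs))
        assert np.mean(hs) == pytest.approx(2 * (1 - 1 / 6), abs=4 * se)


class TestGeneTreeSimulator:
    def test_reproducible(self):
        u = sim_species_tree(5, seed=2)
        a = sim_gene_trees(u, 3, seed=3)
        b = sim_gene_trees(u, 3, seed=3)
        assert a == b

    def test_long_branches_concordant(self):
        # deep species divergences: gene trees almost always match the
        # species topology
        u0 = sim_species_tree(6, seed=4)
        scaled = PhyloTree(
            u0.taxa,
            {s: (8.0 if s.is_internal else l) for s, l in u0.edges.items()},
        )
        genes = sim_gene_trees(scaled, 150, seed=5)
        match = sum(g.topology == scaled.topology for g in genes)
        assert match / len(genes) > 0.95

    def test_short_branches_anomalous(self):
        # near-zero internal branches: topologies approach the unconstrained
        # coalescent, i.e. all three rooted resolutions equally likely (N=3)
        u0 = sim_species_tree(3, seed=6)
        tiny = PhyloTree(
            u0.taxa,
            {s: (1e-6 if s.is_internal else l) for s, l in u0.edges.items()},
        )
        genes = sim_gene_trees(tiny, 900, seed=7)
        counts = {}
        for g in genes:
            counts[g.topology] = counts.get(g.topology, 0) + 1
        assert len(counts) == 3
        _, pval = stats.chisquare(list(counts.values()))
        assert pval > 1e-3

    def test_valid_trees(self):
        u = sim_species_tree(7, seed=8)
        for g in sim_gene_trees(u, 10, seed=9):
            assert validate_topology(g.edges)
            assert g.is_fully_resolved


class TestGammaTree:
    def test_mean_edge_length(self):
        rng = np.random.default_rng(10)
        lengths = []
        for _ in range(400):
            t = random_tree_gamma(6, alpha=2, beta=20, seed=rng)
            lengths.extend(t.internal_edges().values())
        # Gamma(2, rate 20): mean 0.1
        se = np.std(lengths) / np.sqrt(len(lengths))
        assert np.mean(lengths) == pytest.approx(0.1, abs=4 * se)

    def test_positive_lengths_and_reproducible(self):
        a = random_tree_gamma(10, seed=12)
        b = random_tree_gamma(10, seed=12)
        assert a == b
        assert all(l > 0 for l in a.edges.values())


class TestRearrangements:
    def test_nni_involution(self):
        t = random_tree_gamma(8, seed=13)
        e = sorted(t.internal_edges(), key=lambda s: s.mask)[1]
        t2 = nni(t, e, 0)
        new_edge = (set(t2.internal_edges()) - set(t.internal_edges())).pop()
        undone = {nni(t2, new_edge, c).topology for c in (0, 1)}
        assert t.topology in undone

    def test_nni_neighborhood_size(self):
        t = random_tree_gamma(7, seed=14)
        tops = {x.topology for x in nni_neighbors(t)}
        assert len(tops) == 2 * len(t.internal_edges())
        assert t.topology not in tops

    def test_nni_preserves_other_lengths(self):
        t = random_tree_gamma(7, seed=15)
        e = sorted(t.internal_edges(), key=lambda s: s.mask)[0]
        t2 = nni(t, e, 1)
        for s, l in t.edges.items():
            if s != e:
                assert t2.length_of(s) == l

    def test_every_nni_reachable_by_spr(self):
        t = random_tree_gamma(5, seed=16)
        nni_tops = {x.topology for x in nni_neighbors(t)}
        spr_tops = set()
        full = (1 << 5) - 1
        edges = [s for s in t.edges if s.mask != full]
        for pr in edges:
            for rg in edges:
                if rg.mask == pr.mask or (rg.mask & pr.mask) == rg.mask:
                    continue
                try:
                    spr_tops.add(spr(t, pr, rg).topology)
                except ValueError:
                    continue
        assert nni_tops <= spr_tops

    def test_spr_validity(self):
        rng = np.random.default_rng(17)
        t = random_tree_gamma(9, seed=rng)
        for _ in range(20):
            s = random_spr(t, rng)
            assert validate_topology(s.edges)
            assert s.is_fully_resolved

    def test_invalid_regraft_rejected(self):
        t = random_tree_gamma(6, seed=18)
        internals = sorted(t.internal_edges(), key=lambda s: s.size)
        small, big = internals[0], internals[-1]
        if small.mask & big.mask == small.mask:
            with pytest.raises(ValueError):
                spr(t, big, small)


class TestRandomWalk:
    def test_zero_step_size_identity(self):
        t = random_tree_gamma(8, seed=19)
        assert random_walk(t, 5, 0.0, seed=20) == t

    def test_reproducible(self):
        t = random_tree_gamma(8, seed=21)
        assert random_walk(t, 5, 0.05, seed=22) == random_walk(t, 5, 0.05, seed=22)

    def test_displacement_grows_linearly_within_orthant(self):
        # with long edges the walk stays in one orthant and E d^2 ~ steps
        t = random_tree_gamma(6, seed=23)
        big = PhyloTree(t.taxa, {s: l + 10.0 for s, l in t.edges.items()})
        rng = np.random.default_rng(24)
        d2 = {steps: np.mean([
            distance(big, random_walk(big, steps, 0.1, rng)) ** 2
            for _ in range(300)
        ]) for steps in (1, 4)}
        assert d2[4] / d2[1] == pytest.approx(4.0, rel=0.25)

    def test_topology_change_possible(self):
        t = random_tree_gamma(6, seed=25)
        rng = np.random.default_rng(26)
        changed = any(
            random_walk(t, 10, 0.2, rng).topology != t.topology
            for _ in range(20)
        )
        assert changed


class TestSurfaceDataset:
    def test_dirichlet_concentrates_away_from_corners(self):
        rng = np.random.default_rng(27)
        draws = rng.dirichlet((4, 4, 4), size=4000)
        assert np.quantile(draws, 0.05, axis=0).min() > 0.05

    def test_zero_walk_points_on_surface(self):
        cfg = SimConfig(n_taxa=6, n_points=6, walk_steps=0, seed=28)
        W, Z = make_surface_dataset(cfg)
        rng = np.random.default_rng(0)
        d2 = sum(
            project_geometric(z, W, seed=rng, eps=1e-6, max_iter=20000).distance ** 2
            for z in Z
        )
        assert d2 < 1e-4

    def test_dispersion_monotone_in_step_size(self):
        rng = np.random.default_rng(0)
        d2 = {}
        for size in (0.01, 0.035):
            cfg = SimConfig(n_taxa=6, n_points=10, walk_steps=5,
                            walk_step_size=size, seed=29)
            W, Z = make_surface_dataset(cfg)
            d2[size] = sum(
                project_geometric(z, W, seed=rng, eps=1e-5,
                                  max_iter=20000).distance ** 2
                for z in Z
            )
        assert d2[0.035] > d2[0.01]

    def test_vertices_distinct_topologies(self):
        cfg = SimConfig(n_taxa=8, n_points=1, walk_steps=0, seed=30, op_kind="spr")
        W, _ = make_surface_dataset(cfg)
        tops = {w.topology for w in W}
        assert len(tops) == 3


class TestValidationHarness:
    def test_smoke_and_determinism(self):
        a = validation_harness(2, N=5, lattice_resolution=8, seed=31,
                               eps=1e-4, max_iter=3000, refine_levels=1)
        b = validation_harness(2, N=5, lattice_resolution=8, seed=31,
                               eps=1e-4, max_iter=3000, refine_levels=1)
        assert a == b
        assert set(a) == {"reps", "pass_fraction", "n_fail", "mean_excess_pct",
                          "mean_disagreement_pct"}
        assert 0.0 <= a["pass_fraction"] <= 1.0
        assert a["n_fail"] == round((1 - a["pass_fraction"]) * 2)
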