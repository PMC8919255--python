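"""Cluster identification, size/bond statistics and shape analysis."""

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from salrmix import clusters as cl
from salrmix.fixtures import make_fixture

R0 = 1.2423773782094654


def _partition_signature(labels):
    """Canonical form of a partition: tuple of sorted member tuples."""
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return tuple(sorted(tuple(g) for g in groups.values()))


def _oracle_labels(positions, L, bond_length):
    """Independent route: explicit adjacency + sparse connected components."""
    n = len(positions)
    delta = positions[:, None, :] - positions[None, :, :]
    delta -= L * np.round(delta / L)
    d2 = (delta**2).sum(-1)
    adj = (d2 < bond_length**2) & ~np.eye(n, dtype=bool)
    _, lab = connected_components(coo_matrix(adj), directed=False)
    return lab


class TestFindClusters:
    def test_all_monomers(self):
        fx = make_fixture("monomers", 27)
        rep = cl.find_clusters(fx.config.positions, fx.config.L, R0)
        assert rep.n_clusters == 27
        assert rep.n_isolated == 27
        assert np.all(rep.bond_counts == 0)

    def test_chain_is_one_cluster(self):
        fx = make_fixture("chain", 10, spacing=1.1)
        rep = cl.find_clusters(fx.config.positions, fx.config.L, R0)
        assert rep.n_clusters == 1
        assert rep.largest_size == 10
        # end particles have one bonded neighbour, interior two
        assert sorted(rep.bond_counts.tolist()) == sorted(fx.truth["bond_counts"])
        assert sorted(rep.bond_counts.tolist()) == sorted([1] + [2] * 8 + [1])

    def test_two_droplets(self):
        fx = make_fixture("two_droplets", sizes=(30, 20), gap=5.0)
        rep = cl.find_clusters(fx.config.positions, fx.config.L, R0)
        assert rep.n_clusters == 2
        assert sorted(rep.sizes.tolist(), reverse=True) == [30, 20]

    def test_against_connected_components_oracle(self):
        """Union-find labelling agrees with an independent sparse-graph route
        on 200 random low-density configurations."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(10, 60))
            L = float(rng.uniform(6.0, 12.0))
            pos = rng.random((n, 3)) * L
            rep = cl.find_clusters(pos, L, R0)
            oracle = _oracle_labels(pos, L, R0)
            assert _partition_signature(rep.labels) == _partition_signature(oracle)
            assert rep.sizes.sum() == n

    def test_deterministic_labels_by_min_index(self):
        fx = make_fixture("two_droplets", sizes=(5, 8), gap=6.0)
        rep = cl.find_clusters(fx.config.positions, fx.config.L, R0)
        # cluster 0 must contain particle 0
        assert rep.labels[0] == 0

    def test_species_blind(self, rng):
        pos = rng.random((40, 3)) * 9.0
        a = cl.find_clusters(pos, 9.0, R0,
                             species=np.ones(40, dtype=np.int8))
        flipped = np.full(40, 2, dtype=np.int8)
        b = cl.find_clusters(pos, 9.0, R0, species=flipped)
        assert np.array_equal(a.labels, b.labels)

    def test_bond_length_monotonicity(self, rng):
        pos = rng.random((50, 3)) * 10.0
        prev_largest, prev_nc = 0, np.inf
        for bl in np.linspace(0.4, 3.0, 12):
            rep = cl.find_clusters(pos, 10.0, bl)
            assert rep.largest_size >= prev_largest
            assert rep.n_clusters <= prev_nc
            prev_largest, prev_nc = rep.largest_size, rep.n_clusters


class TestCSD:
    def test_all_monomers(self):
        fx = make_fixture("monomers", 16)
        rep = cl.find_clusters(fx.config.positions, fx.config.L, R0)
        s, w = cl.csd([rep])
        assert s.tolist() == [1]
        assert w.tolist() == [1.0]

    def test_single_big_cluster(self):
        fx = make_fixture("fcc_droplet", 20, spacing=1.05)
        rep = cl.find_clusters(fx.config.positions, fx.config.L, R0)
        s, w = cl.csd([rep])
        assert s.tolist() == [20]
        assert w.tolist() == [1.0]

    def test_dimer_plus_two_monomers(self):
        # n(1)=2, n(2)=1, N=4: N(1) = 1*2/4 = 0.5, N(2) = 2*1/4 = 0.5
        pos = np.array([[2.0, 2, 2], [3.1, 2, 2], [8.0, 8, 8], [14.0, 14, 14]])
        rep = cl.find_clusters(pos, 20.0, R0)
        s, w = cl.csd([rep])
        assert s.tolist() == [1, 2]
        assert w.tolist() == [0.5, 0.5]

    def test_normalisation_on_ensembles(self, rng):
        reports = []
        for _ in range(20):
            pos = rng.random((35, 3)) * 7.0
            reports.append(cl.find_clusters(pos, 7.0, R0))
        _, w = cl.csd(reports)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_droplet_truth(self):
        fx = make_fixture("two_droplets", sizes=(30, 20), gap=5.0)
        rep = cl.find_clusters(fx.config.positions, fx.config.L, R0)
        s, w = cl.csd([rep])
        assert dict(zip(s.tolist(), w.tolist())) == fx.truth["csd"]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cl.csd([])


class TestBondDistribution:
    def test_fcc_interior_coordination_is_twelve(self):
        fx = make_fixture("fcc_droplet", 250, spacing=1.05)
        rep = cl.find_clusters(fx.config.positions, fx.config.L, R0)
        assert np.array_equal(np.sort(rep.bond_counts),
                              np.sort(fx.truth["bond_counts"]))
        nb, p = cl.bond_distribution(rep)
        assert rep.bond_counts.max() == 12   # inner particles of the droplet
        assert p[12] > 0

    def test_monomers_all_zero_bonds(self):
        fx = make_fixture("monomers", 8)
        rep = cl.find_clusters(fx.config.positions, fx.config.L, R0)
        nb, p = cl.bond_distribution(rep)
        assert p[0] == 1.0

    def test_dimer(self):
        fx = make_fixture("dimer", spacing=1.1)
        rep = cl.find_clusters(fx.config.positions, fx.config.L, R0)
        nb, p = cl.bond_distribution(rep)
        assert p[1] == 1.0


class TestEccentricity:
    def test_uniform_ball_is_nearly_spherical(self):
        fx = make_fixture("ellipsoid_cloud", 4000, semi_axes=(2.0, 2.0, 2.0),
                          seed=5, L=50.0)
        pts = fx.config.positions[None]
        stats = cl.eccentricity(pts, 50.0, bond_length=50.0 / 2 - 1e-9)
        assert stats.e_c < 0.05

    def test_collinear_points_are_degenerate(self):
        fx = make_fixture("chain", 12, spacing=1.1)
        stats = cl.eccentricity(fx.config.positions[None], fx.config.L, R0)
        assert stats.e_c == pytest.approx(1.0, abs=1e-12)

    def test_ellipsoid_matches_gyration_oracle(self):
        fx = make_fixture("ellipsoid_cloud", 3000, semi_axes=(1.0, 1.0, 2.0),
                          seed=3, L=30.0)
        stats = cl.eccentricity(fx.config.positions[None], 30.0,
                                bond_length=30.0 / 2 - 1e-9)
        assert stats.e_c == pytest.approx(fx.truth["e_c"], abs=1e-9)
        # and the population value for semi-axes (1,1,2): 1 - 1/2
        assert stats.e_c == pytest.approx(0.5, abs=0.05)

    def test_unwrapping_across_the_boundary(self):
        # the larger droplet of this fixture straddles a box face
        fx = make_fixture("two_droplets", sizes=(40, 20), gap=5.0)
        stats = cl.eccentricity(fx.config.positions[None], fx.config.L, R0)
        assert stats.e_c < 0.35    # compact FCC droplet, nearly spherical


class TestSummariesAndTaxonomy:
    def test_all_monomer_ensemble(self):
        fx = make_fixture("monomers", 27)
        reps = [cl.find_clusters(fx.config.positions, fx.config.L, R0)] * 3
        out = cl.cluster_summaries(reps)
        assert out["n_isolated"] == (27.0, 0.0)
        assert out["largest_size"] == (1.0, 0.0)
        assert out["n_clusters"] == (27.0, 0.0)

    def test_single_cluster_ensemble(self):
        fx = make_fixture("fcc_droplet", 30, spacing=1.05)
        reps = [cl.find_clusters(fx.config.positions, fx.config.L, R0)] * 2
        out = cl.cluster_summaries(reps)
        assert out["n_isolated"][0] == 0.0
        assert out["largest_size"][0] == 30.0
        assert out["n_clusters"][0] == 1.0

    def test_mixed_fixture_hand_enumeration(self):
        pos = np.array([[2.0, 2, 2], [3.1, 2, 2], [8.0, 8, 8], [14.0, 14, 14]])
        rep = cl.find_clusters(pos, 20.0, R0)
        out = cl.cluster_summaries([rep, rep])
        assert out["n_isolated"][0] == 2.0
        assert out["largest_size"][0] == 2.0
        assert out["n_clusters"][0] == 3.0

    def test_percolation_flag(self):
        fx = make_fixture("fcc_droplet", 30, spacing=1.05)
        rep = cl.find_clusters(fx.config.positions, fx.config.L, R0)
        assert rep.percolated        # 30 of 30 particles in one network

    @pytest.mark.parametrize("s,w,largest,expected", [
        ([1], [1.0], 1, "dispersed"),
        ([100], [1.0], 100, "random percolated"),
        ([1, 10], [0.5, 0.5], 10, "cluster fluid"),
        ([1, 10, 80], [0.2, 0.3, 0.5], 80, "cluster percolated"),
    ])
    def test_taxonomy(self, s, w, largest, expected):
        out = cl.classify_csd(np.array(s), np.array(w), 100, largest)
        assert out == expected
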