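"""Metropolis engine: initial states, energetics, sampling correctness."""

import dataclasses

import numpy as np
import pytest

from salrmix import structure as st
from salrmix.mc import (Configuration, MoveSchedule, SystemSpec,
                        big_cluster_initial_config, mc_cycles,
                        random_initial_config, run_simulation, total_energy,
                        tune_schedule)
from salrmix.clusters import find_clusters
from salrmix.model import PotentialParams


def _two_particle_config(d, species, L=10.0):
    pos = np.array([[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]])
    return Configuration(pos, np.array(species, dtype=np.int8), L)


class TestInitialConfigs:
    def test_box_edge_and_no_overlaps(self):
        spec = SystemSpec(500, 0, rho=0.05, T=0.25, seed=1)
        assert spec.L == pytest.approx(21.544, abs=1e-3)
        cfg = random_initial_config(spec)
        assert not cfg.has_overlap()
        assert (cfg.species == 1).sum() == 500

    def test_single_particle(self):
        cfg = random_initial_config(SystemSpec(1, 0, 0.05, 0.25, seed=2))
        assert cfg.positions.shape == (1, 3)

    def test_determinism(self):
        spec = SystemSpec(50, 50, 0.05, 0.25, seed=9)
        a = random_initial_config(spec)
        b = random_initial_config(spec)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.species, b.species)

    def test_mixture_box_edge(self):
        assert SystemSpec(1024, 1024, 0.05, 0.25).L == pytest.approx(34.46, abs=0.02)

    def test_density_guard(self):
        with pytest.raises(ValueError):
            random_initial_config(SystemSpec(500, 0, rho=0.5, T=0.25))


class TestBigClusterConfig:
    def test_all_particles_in_one_cluster(self):
        spec = SystemSpec(100, 100, rho=0.05, T=0.25, seed=3)
        cfg = big_cluster_initial_config(spec)
        assert not cfg.has_overlap()
        rep = find_clusters(cfg.positions, cfg.L, PotentialParams().r0)
        assert rep.n_clusters == 1
        assert rep.largest_size == 200

    def test_compact_13_seed(self):
        cfg = big_cluster_initial_config(SystemSpec(13, 0, 0.05, 0.25))
        rep = find_clusters(cfg.positions, cfg.L, PotentialParams().r0)
        assert rep.n_clusters == 1

    def test_droplet_must_fit(self):
        with pytest.raises(ValueError):
            big_cluster_initial_config(SystemSpec(400, 0, rho=0.05, T=0.25),
                                       spacing=3.0)


class TestTotalEnergy:
    def test_two_hsty_at_r0_is_zero(self, params):
        cfg = _two_particle_config(params.r0, [1, 1])
        assert total_energy(cfg, params) == pytest.approx(0.0, abs=1e-10)

    def test_single_square_well_bond(self):
        p = PotentialParams(eps12=0.75)
        cfg = _two_particle_config(1.1, [1, 2])
        assert total_energy(cfg, p) == pytest.approx(-0.75)

    def test_beyond_cutoff_is_zero(self, params):
        pos = np.array([[0.0, 0, 0], [9.0, 0, 0], [0.0, 9.0, 0]])
        cfg = Configuration(pos, np.ones(3, np.int8), 20.0)
        # u11 truncated at the 4-sigma cutoff: pairs at 9 sigma contribute 0
        assert total_energy(cfg, params, cutoff=4.0) == 0.0

    def test_overlap_gives_inf(self, params):
        cfg = _two_particle_config(0.8, [1, 1])
        assert total_energy(cfg, params) == np.inf

    def test_truncated_not_shifted(self, params):
        # just inside the cutoff the full tail value applies (no shift)
        from salrmix.model import u11
        cfg = _two_particle_config(3.0, [1, 1], L=10.0)
        assert total_energy(cfg, params) == pytest.approx(u11(3.0, params),
                                                          rel=1e-12)


class TestSampling:
    def test_athermal_system_stays_at_zero_energy(self):
        spec = SystemSpec(0, 64, rho=0.05, T=0.25, seed=4)
        cfg = random_initial_config(spec)
        sched = MoveSchedule()
        energies, acc, _ = mc_cycles(cfg, PotentialParams(eps12=0.0), sched,
                                     0.25, 300, seed=5)
        assert np.all(energies == 0.0)
        assert 0 < acc["long"] < 1
        assert not cfg.has_overlap()

    def test_energy_bookkeeping_matches_recompute(self):
        spec = SystemSpec(50, 50, rho=0.05, T=0.25, seed=6)
        cfg = random_initial_config(spec)
        p = PotentialParams(eps12=0.75)
        energies, _, _ = mc_cycles(cfg, p, MoveSchedule(), 0.25, 2000, seed=7)
        assert abs(energies[-1] - total_energy(cfg, p)) < 1e-8 * spec.n

    def test_snapshot_energies_match_trace(self):
        spec = SystemSpec(40, 40, rho=0.05, T=0.25, seed=8)
        cfg = random_initial_config(spec)
        p = PotentialParams(eps12=0.5)
        stride = 100
        energies, _, snaps = mc_cycles(cfg, p, MoveSchedule(), 0.25, 1000,
                                       seed=9, snapshot_stride=stride,
                                       n_snapshots=10)
        for i, pos in enumerate(snaps):
            e = total_energy(Configuration(pos, cfg.species, cfg.L), p)
            assert abs(e - energies[(i + 1) * stride - 1]) < 1e-8 * spec.n

    def test_swap_moves_conserve_composition(self):
        spec = SystemSpec(30, 70, rho=0.05, T=0.25, seed=10)
        cfg = random_initial_config(spec)
        sched = MoveSchedule(swap_attempts_per_cycle=20)
        mc_cycles(cfg, PotentialParams(eps12=0.75), sched, 0.25, 200, seed=11)
        assert (cfg.species == 1).sum() == 30
        assert (cfg.species == 2).sum() == 70

    def test_run_determinism(self):
        spec = SystemSpec(32, 32, rho=0.05, T=0.25, seed=12)
        p = PotentialParams(eps12=0.75)
        a = run_simulation(spec, p, n_equil_cycles=200, n_prod_cycles=400,
                           target_snapshots=4)
        b = run_simulation(spec, p, n_equil_cycles=200, n_prod_cycles=400,
                           target_snapshots=4)
        assert np.array_equal(a.energy_trace, b.energy_trace)
        assert np.array_equal(a.snapshots, b.snapshots)

    def test_detailed_balance_two_particle_bond_occupancy(self):
        """Sampled bond-state occupancy of a single square-well pair must
        match the Boltzmann ratio of configurational volumes within 3 SE."""
        L, eps, T = 8.0, 1.0, 0.3
        p = PotentialParams(eps12=eps)
        r0 = p.r0
        cfg = _two_particle_config(3.0, [1, 2], L=L)
        sched = MoveSchedule(mrd_long=2.0, mrd_short=0.5,
                             swap_attempts_per_cycle=1)
        energies, _, _ = mc_cycles(cfg, p, sched, T, 300_000, seed=13)
        bonded = energies < -0.5 * eps
        v_bond = 4.0 * np.pi / 3.0 * (r0**3 - 1.0)
        v_free = L**3 - 4.0 * np.pi / 3.0 * r0**3
        ratio = v_bond * np.exp(eps / T) / v_free
        p_exact = ratio / (1.0 + ratio)
        blocks = np.array_split(bonded[1000:], 30)
        means = np.array([b.mean() for b in blocks])
        se = means.std(ddof=1) / np.sqrt(len(blocks))
        assert abs(bonded[1000:].mean() - p_exact) < 3 * se + 1e-3

    def test_dilute_hard_spheres_have_flat_gr(self):
        """At rho=0.05 and eps12=0, chi=0 the fluid is nearly ideal:
        g(r) = 1 within statistical error beyond contact."""
        spec = SystemSpec(0, 150, rho=0.05, T=1.0, seed=14)
        p = PotentialParams(eps12=0.0)
        rec = run_simulation(spec, p, n_equil_cycles=300, n_prod_cycles=1500,
                             target_snapshots=150)
        pc = st.compute_gr(rec.snapshots, rec.metadata["species"], spec.L,
                           (2, 2), bin_width=0.1)
        sel = (pc.r > 1.2) & (pc.r < spec.L / 2 * 0.9)
        assert np.abs(pc.g[sel].mean() - 1.0) < 0.05
        assert np.abs(pc.g[sel] - 1.0).max() < 0.4


class TestTuning:
    def test_feedback_raises_amplitude_when_acceptance_high(self):
        spec = SystemSpec(0, 60, rho=0.02, T=1.0, seed=15)
        cfg = random_initial_config(spec)
        sched = MoveSchedule(mrd_long=0.05, mrd_short=0.01)
        with pytest.warns(UserWarning):
            tuned = tune_schedule(cfg, PotentialParams(), 1.0, sched, seed=16,
                                  max_rounds=6)
        # nearly-free particles accept everything: amplitudes must grow
        assert tuned.mrd_long > sched.mrd_long

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            MoveSchedule(mrd_long=0.01, mrd_short=0.1)
        with pytest.raises(ValueError):
            MoveSchedule(frac_long=0.0)

    def test_production_amplitudes_reach_two_scales(self):
        """In a clustered mixture the tuned amplitudes approach the two
        characteristic scales (~0.1 and ~0.01 sigma)."""
        spec = SystemSpec(64, 64, rho=0.05, T=0.25, seed=17)
        p = PotentialParams(eps12=0.75)
        rec = run_simulation(spec, p, n_equil_cycles=3000, n_prod_cycles=1000,
                             target_snapshots=10)
        assert 0.02 < rec.schedule.mrd_long < 1.0
        assert rec.schedule.mrd_short < rec.schedule.mrd_long
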