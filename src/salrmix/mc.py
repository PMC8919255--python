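"""Canonical (NVT) Metropolis Monte Carlo for the HSTY / hard-sphere mixture.

The sampling protocol mirrors standard practice for cluster-forming
fluids: particles start from an ideal-gas (infinite-temperature) random
configuration, are quenched instantaneously to the target temperature,
equilibrated while the two translation amplitudes are tuned, and then
sampled with a frozen move schedule so that detailed balance holds exactly
during production.

Two maximum-random-displacement (mrd) classes accommodate the two length
scales of a clustered fluid: long moves (~0.1 sigma, tuned to ~30%
acceptance) relocate particles between clusters, short moves (~0.01 sigma,
tuned to ~80%) relax particles inside a cluster.  Species-swap moves
exchange the positions of a random HSTY / hard-sphere pair to speed up
compositional relaxation.  The move class is drawn at random per attempt,
making the kernel a fixed mixture and detailed balance exact.

u11 is truncated (not shifted) at half the box edge; no tail corrections.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import PotentialParams

__all__ = [
    "SystemSpec",
    "Configuration",
    "MoveSchedule",
    "TrajectoryRecord",
    "random_initial_config",
    "big_cluster_initial_config",
    "total_energy",
    "mc_cycles",
    "tune_schedule",
    "run_simulation",
]


@dataclass(frozen=True)


class SystemSpec:
    """Thermodynamic state of the mixture: composition, density, temperature."""

    n1: int                     # HSTY particles
    n2: int                     # hard spheres
    rho: float                  # number density (sigma^-3)
    T: float                    # temperature (eps11 / k_B)
    seed: int = 0

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    @property
    def chi(self) -> float:
        return self.n1 / self.n

    @property
    def L(self) -> float:
        """Cubic box edge (N / rho)^(1/3), in sigma."""
        return (self.n / self.rho) ** (1.0 / 3.0)


@dataclass


class Configuration:
    positions: np.ndarray       # (N, 3) in [0, L)
    species: np.ndarray         # (N,) labels in {1, 2}
    L: float

    def copy(self) -> "Configuration":
        return Configuration(self.positions.copy(), self.species.copy(), self.L)

    def min_image_distances(self) -> np.ndarray:
        delta = self.positions[:, None, :] - self.positions[None, :, :]
        delta -= self.L * np.round(delta / self.L)
        d2 = np.einsum("ijk,ijk->ij", delta, delta)
        iu, ju = np.triu_indices(len(self.positions), k=1)
        return np.sqrt(d2[iu, ju])

    def has_overlap(self) -> bool:
        if len(self.positions) < 2:
            return False
        return bool(self.min_image_distances().min() < 1.0)

    def validate(self) -> None:
        if self.has_overlap():
            raise ValueError("configuration contains hard-core overlaps")


@dataclass


class MoveSchedule:
    mrd_long: float = 0.1
    mrd_short: float = 0.01
    frac_long: float = 0.5
    swap_attempts_per_cycle: int | None = None  # default max(1, N // 10)
    target_acc_long: float = 0.30
    target_acc_short: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.mrd_short < self.mrd_long):
            raise ValueError("require 0 < mrd_short < mrd_long")
        if not (0 < self.frac_long < 1):
            raise ValueError("frac_long must lie in (0, 1)")

    def swaps(self, n: int) -> int:
        if self.swap_attempts_per_cycle is not None:
            return self.swap_attempts_per_cycle
        return max(1, n // 10)


@dataclass


class TrajectoryRecord:
    energy_trace: np.ndarray            # potential energy per particle vs cycle
    snapshots: np.ndarray               # (n_snap, N, 3)
    snapshot_stride: int
    spec: SystemSpec
    params: PotentialParams
    schedule: MoveSchedule
    acceptance: dict[str, float]
    metadata: dict = field(default_factory=dict)

    @property
    def configurations(self):
        for pos in self.snapshots:
            yield Configuration(pos, self.metadata["species"], self.spec.L)


def _kernel_args(params: PotentialParams, L: float, cutoff: float | None = None):
    rc = cutoff if cutoff is not None else L / 2
    amp = params.eps11 / (1.0 - params.alpha) if params.alpha < 1 else params.eps11
    return (params.z_a, params.z_r, amp, params.alpha, params.eps12,
            params.r0**2, rc**2)


def random_initial_config(spec: SystemSpec, max_attempts_per_particle: int = 10_000
                          ) -> Configuration:
    """Random non-overlapping placement by rejection insertion (T = infinity).

    Species are assigned so exactly n1 particles are HSTY; reproducible for
    a fixed ``spec.seed``.
    """
    if spec.rho > 0.2:
        raise ValueError("rejection insertion is only reliable for rho <= 0.2")
    rng = np.random.default_rng(spec.seed)
    L = spec.L
    pos = np.empty((spec.n, 3))
    placed = 0
    attempts = 0
    budget = max_attempts_per_particle * spec.n
    while placed < spec.n:
        if attempts > budget:
            raise RuntimeError("insertion failed: density too high for rejection")
        trial = rng.random(3) * L
        d = trial - pos[:placed]
        d -= L * np.round(d / L)
        if placed == 0 or np.min(np.einsum("ij,ij->i", d, d)) >= 1.0:
            pos[placed] = trial
            placed += 1
        attempts += 1
    species = np.full(spec.n, 2, dtype=np.int8)
    species[:spec.n1] = 1
    rng.shuffle(species)
    # enforce exact counts after shuffle (shuffle preserves them)
    return Configuration(pos, species, L)


def _fcc_sites(spacing: float, radius: float) -> np.ndarray:
    """FCC lattice points within a sphere, nearest-neighbour distance ``spacing``."""
    a = spacing * np.sqrt(2.0)
    nmax = int(np.ceil(radius / a)) + 2
    basis = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    cells = np.arange(-nmax, nmax + 1)
    i, j, k = np.meshgrid(cells, cells, cells, indexing="ij")
    corners = np.stack([i, j, k], axis=-1).reshape(-1, 3).astype(float)
    sites = (corners[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
    return sites[np.einsum("ij,ij->i", sites, sites) <= radius**2]


def big_cluster_initial_config(spec: SystemSpec, spacing: float = 1.05
                               ) -> Configuration:
    """All N particles packed into one compact FCC droplet at the box centre.

    Species are randomly interleaved through the droplet.  Errors out when
    the droplet radius would exceed half the box.
    """
    L = spec.L
    # grow the radius until enough sites fit
    radius = (spec.n * spacing**3 / 4.0) ** (1.0 / 3.0)  # generous initial guess
    sites = _fcc_sites(spacing, radius)
    while len(sites) < spec.n:
        radius *= 1.1
        sites = _fcc_sites(spacing, radius)
    order = np.argsort(np.einsum("ij,ij->i", sites, sites))
    chosen = sites[order[:spec.n]]
    max_r = np.sqrt(np.einsum("ij,ij->i", chosen, chosen).max())
    if max_r > L / 2 - 1.0:
        raise ValueError("droplet radius exceeds half the box edge")
    rng = np.random.default_rng(spec.seed)
    species = np.full(spec.n, 2, dtype=np.int8)
    species[:spec.n1] = 1
    rng.shuffle(species)
    pos = (chosen + L / 2) % L
    return Configuration(pos, species, L)


def total_energy(config: Configuration, params: PotentialParams,
                 cutoff: float | None = None) -> float:
    """Exact total potential energy; ``inf`` when any pair overlaps.

    u11 is truncated (not shifted) at ``cutoff`` (default L/2).
    """
    L = config.L
    rc = cutoff if cutoff is not None else L / 2
    if rc > L / 2 + 1e-12:
        raise ValueError("cutoff beyond half the box edge")
    e, overlap = _kernels.total_energy_kernel(
        np.ascontiguousarray(config.positions, dtype=np.float64),
        np.ascontiguousarray(config.species, dtype=np.int8),
        L, *_kernel_args(params, L, rc))
    return np.inf if overlap else float(e)


def mc_cycles(config: Configuration, params: PotentialParams,
              schedule: MoveSchedule, T: float, n_cycles: int, seed: int,
              snapshot_stride: int = 0, n_snapshots: int = 0):
    """Run Metropolis cycles in place; returns (energy trace, acceptance, snaps).

    One cycle is N attempted translations plus the scheduled swap attempts.
    The energy trace is total potential energy (not per particle).
    """
    pos = np.ascontiguousarray(config.positions, dtype=np.float64)
    species = np.ascontiguousarray(config.species, dtype=np.int8)
    idx1 = np.nonzero(species == 1)[0].astype(np.int64)
    idx2 = np.nonzero(species == 2)[0].astype(np.int64)
    L = config.L
    e0 = total_energy(config, params)
    if not np.isfinite(e0):
        raise ValueError("initial configuration overlaps")
    energies = np.empty(n_cycles)
    snaps = np.empty((n_snapshots, len(pos), 3))
    counters = np.zeros(6, dtype=np.int64)
    _kernels.run_mc(pos, species, idx1, idx2, L, T,
                    *_kernel_args(params, L),
                    schedule.mrd_long, schedule.mrd_short, schedule.frac_long,
                    schedule.swaps(len(pos)),
                    n_cycles, int(seed) % (2**31 - 1), e0,
                    energies, snapshot_stride, snaps, counters)
    config.positions = pos
    acc = {
        "long": counters[1] / max(counters[0], 1),
        "short": counters[3] / max(counters[2], 1),
        "swap": counters[5] / max(counters[4], 1),
        "attempts": counters.copy(),
    }
    return energies, acc, snaps


def tune_schedule(config: Configuration, params: PotentialParams, T: float,
                  schedule: MoveSchedule, seed: int,
                  window: int = 200, max_rounds: int = 20,
                  tol: float = 0.05, mrd_cap: float = 2.0) -> MoveSchedule:
    """Tune the two mrd amplitudes toward their target acceptances.

    Multiplicative feedback over short equilibration windows; the returned
    schedule is then frozen for production.  Non-convergence after
    ``max_rounds`` keeps the last values (with a warning when an amplitude
    has hit its cap, e.g. in a non-interacting system where acceptance is 1
    regardless of amplitude).
    """

    sched = dataclasses.replace(schedule)
    rng = np.random.default_rng(seed)
    for _ in range(max_rounds):
        _, acc, _ = mc_cycles(config, params, sched, T, window,
                              seed=int(rng.integers(2**31 - 1)))
        ok_long = abs(acc["long"] - sched.target_acc_long) <= tol
        ok_short = abs(acc["short"] - sched.target_acc_short) <= tol
        if ok_long and ok_short:
            return sched
        new_long = sched.mrd_long * _feedback(acc["long"], sched.target_acc_long)
        new_short = sched.mrd_short * _feedback(acc["short"], sched.target_acc_short)
        new_long = min(new_long, mrd_cap)
        new_short = min(new_short, new_long * 0.99, mrd_cap)
        sched = dataclasses.replace(sched, mrd_long=new_long, mrd_short=new_short)
    if sched.mrd_long >= mrd_cap * 0.999:
        warnings.warn("mrd tuning hit its amplitude cap without converging")
    else:
        warnings.warn("mrd tuning did not converge; keeping last amplitudes")
    return sched


def _feedback(measured: float, target: float) -> float:
    """Multiplicative update factor: acceptance too high -> larger amplitude."""
    ratio = (1.0 - target) / max(1.0 - measured, 1e-3)
    return float(np.clip(ratio, 0.5, 2.0))


def run_simulation(spec: SystemSpec, params: PotentialParams,
                   schedule: MoveSchedule | None = None,
                   n_equil_cycles: int = 5_000, n_prod_cycles: int = 20_000,
                   snapshot_stride: int | None = None,
                   initial: Configuration | str = "random",
                   target_snapshots: int = 1000,
                   drift_check: bool = True) -> TrajectoryRecord:
    """Quench-equilibrate-produce protocol; fully reproducible per seed.

    Equilibration runs with amplitude tuning; production uses the frozen
    schedule and stores up to ``target_snapshots`` equispaced
    configurations plus the per-cycle energy trace (per particle).
    """
    schedule = schedule or MoveSchedule()
    if isinstance(initial, str):
        if initial == "random":
            config = random_initial_config(spec)
        elif initial == "bigcluster":
            config = big_cluster_initial_config(spec)
        else:
            raise ValueError(f"unknown initial condition {initial!r}")
    else:
        config = initial.copy()
    config.validate()

    ss = np.random.SeedSequence(spec.seed)
    n_windows = 20
    seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(n_windows + 2)]

    # equilibrate in windows, adjusting the two amplitudes between windows;
    # the schedule is frozen before production so detailed balance holds
    # exactly while observables are measured
    tuned = dataclasses.replace(schedule)
    window = max(1, n_equil_cycles // n_windows)
    eq_parts = []
    done = 0
    w_idx = 0
    while done < n_equil_cycles:
        w = min(window, n_equil_cycles - done)
        e_w, acc, _ = mc_cycles(config, params, tuned, spec.T, w,
                                seed=seeds[w_idx])
        eq_parts.append(e_w)
        done += w
        w_idx += 1
        if done < n_equil_cycles:
            new_long = np.clip(
                tuned.mrd_long * _feedback(acc["long"], tuned.target_acc_long),
                1e-3, 2.0)
            new_short = np.clip(
                tuned.mrd_short * _feedback(acc["short"], tuned.target_acc_short),
                1e-4, new_long * 0.99)
            tuned = dataclasses.replace(tuned, mrd_long=float(new_long),
                                        mrd_short=float(new_short))
    e_eq = np.concatenate(eq_parts) if eq_parts else np.empty(0)

    if snapshot_stride is None:
        snapshot_stride = max(1, n_prod_cycles // target_snapshots)
    n_snap = n_prod_cycles // snapshot_stride
    e_prod, acc, snaps = mc_cycles(config, params, tuned, spec.T,
                                   n_prod_cycles, seed=seeds[-1],
                                   snapshot_stride=snapshot_stride,
                                   n_snapshots=n_snap)
    drift = None
    if drift_check:
        recomputed = total_energy(config, params)
        drift = abs(recomputed - e_prod[-1])
        if drift > 1e-8 * spec.n:
            raise RuntimeError(f"energy bookkeeping drift {drift:.3e} exceeds "
                               f"1e-8 N eps11")

    trace = np.concatenate([e_eq, e_prod]) / spec.n
    return TrajectoryRecord(
        energy_trace=trace,
        snapshots=snaps,
        snapshot_stride=snapshot_stride,
        spec=spec,
        params=params,
        schedule=tuned,
        acceptance=acc,
        metadata={
            "species": config.species.copy(),
            "n_equil_cycles": n_equil_cycles,
            "n_prod_cycles": n_prod_cycles,
            "seeds": seeds,
            "cutoff": spec.L / 2,
            "u11_form": "eps11/(1-alpha)*[-exp(-z_a(r-1))+alpha*exp(-z_r(r-1))]/r",
            "energy_drift": drift,
            "final_energy_per_particle": float(e_prod[-1] / spec.n),
        },
    )
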