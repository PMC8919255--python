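"""Numba kernels for the canonical Monte Carlo engine.

The u11 cutoff equals half the box edge, which rules out cell lists, so
every move recomputes the moved particle's interaction with all others
(an O(N) incremental update).  The hard core is a Boolean overlap test:
moves into overlap are rejected outright, never weighted by a large
finite energy.

Species are encoded as 1 (HSTY) and 2 (hard sphere) in an int8 array.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["particle_energy", "total_energy_kernel", "run_mc"]


@njit(cache=True)
def _min_image(d, L):
    return d - L * np.floor(d / L + 0.5)


@njit(cache=True)
def particle_energy(pos, spec, i_skip, x, y, z, si,
                    L, za, zr, amp, alpha, eps12, r02, rc2):
    """Energy of a particle of species ``si`` at (x, y, z) with all others.

    Returns (energy, overlap); energy is meaningless when overlap is True.
    """
    n = pos.shape[0]
    e = 0.0
    for j in range(n):
        if j == i_skip:
            continue
        dx = _min_image(x - pos[j, 0], L)
        dy = _min_image(y - pos[j, 1], L)
        dz = _min_image(z - pos[j, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1.0:
            return 0.0, True
        sj = spec[j]
        if si == 1 and sj == 1:
            if r2 < rc2:
                r = np.sqrt(r2)
                e += amp * (-np.exp(-za * (r - 1.0))
                            + alpha * np.exp(-zr * (r - 1.0))) / r
        elif si != sj:
            if r2 < r02:
                e -= eps12
    return e, False


@njit(cache=True)
def total_energy_kernel(pos, spec, L, za, zr, amp, alpha, eps12, r02, rc2):
    """Total potential energy by a full pair sum; (energy, overlap)."""
    n = pos.shape[0]
    e = 0.0
    for i in range(n - 1):
        si = spec[i]
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], L)
            dy = _min_image(pos[i, 1] - pos[j, 1], L)
            dz = _min_image(pos[i, 2] - pos[j, 2], L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < 1.0:
                return 0.0, True
            sj = spec[j]
            if si == 1 and sj == 1:
                if r2 < rc2:
                    r = np.sqrt(r2)
                    e += amp * (-np.exp(-za * (r - 1.0))
                                + alpha * np.exp(-zr * (r - 1.0))) / r
            elif si != sj:
                if r2 < r02:
                    e -= eps12
    return e, False


@njit(cache=True)
def _swap_delta(pos, spec, i, j, L, za, zr, amp, alpha, eps12, r02, rc2):
    """Energy change of exchanging the positions of particles i and j.

    Equivalent to exchanging their species labels in place; the mutual i-j
    term is invariant because both interactions are evaluated at the same
    separation with the same (unordered) species pair.
    """
    n = pos.shape[0]
    de = 0.0
    si = spec[i]
    sj = spec[j]
    for k in range(n):
        if k == i or k == j:
            continue
        sk = spec[k]
        for (a, sa_old, sa_new) in ((i, si, sj), (j, sj, si)):
            dx = _min_image(pos[a, 0] - pos[k, 0], L)
            dy = _min_image(pos[a, 1] - pos[k, 1], L)
            dz = _min_image(pos[a, 2] - pos[k, 2], L)
            r2 = dx * dx + dy * dy + dz * dz
            # old contribution
            if sa_old == 1 and sk == 1:
                if r2 < rc2:
                    r = np.sqrt(r2)
                    de -= amp * (-np.exp(-za * (r - 1.0))
                                 + alpha * np.exp(-zr * (r - 1.0))) / r
            elif sa_old != sk:
                if r2 < r02:
                    de += eps12
            # new contribution
            if sa_new == 1 and sk == 1:
                if r2 < rc2:
                    r = np.sqrt(r2)
                    de += amp * (-np.exp(-za * (r - 1.0))
                                 + alpha * np.exp(-zr * (r - 1.0))) / r
            elif sa_new != sk:
                if r2 < r02:
                    de -= eps12
    return de


@njit(cache=True)
def run_mc(pos, spec, idx1, idx2, L, T,
           za, zr, amp, alpha, eps12, r02, rc2,
           mrd_long, mrd_short, frac_long, n_swap,
           n_cycles, seed, e_start,
           energies, snap_stride, snaps, counters):
    """Run ``n_cycles`` Metropolis cycles in place.

    One cycle = N attempted single-particle translations (each drawn from
    the long- or short-amplitude class with probability ``frac_long``) plus
    ``n_swap`` attempted species swaps.  ``energies[c]`` records the total
    potential energy after cycle c (incremental bookkeeping).  Snapshots
    are written into ``snaps`` every ``snap_stride`` cycles when ``snaps``
    has room.  ``counters`` accumulates [att_long, acc_long, att_short,
    acc_short, att_swap, acc_swap].  Returns the final total energy.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    e_tot = e_start
    snap_idx = 0
    for c in range(n_cycles):
        for _ in range(n):
            i = np.random.randint(0, n)
            use_long = np.random.random() < frac_long
            mrd = mrd_long if use_long else mrd_short
            if use_long:
                counters[0] += 1
            else:
                counters[2] += 1
            x = pos[i, 0] + mrd * (2.0 * np.random.random() - 1.0)
            y = pos[i, 1] + mrd * (2.0 * np.random.random() - 1.0)
            z = pos[i, 2] + mrd * (2.0 * np.random.random() - 1.0)
            si = spec[i]
            e_new, overlap = particle_energy(pos, spec, i, x, y, z, si,
                                             L, za, zr, amp, alpha, eps12,
                                             r02, rc2)
            if overlap:
                continue
            e_old, _ = particle_energy(pos, spec, i, pos[i, 0], pos[i, 1],
                                       pos[i, 2], si, L, za, zr, amp, alpha,
                                       eps12, r02, rc2)
            de = e_new - e_old
            if de <= 0.0 or np.random.random() < np.exp(-de / T):
                pos[i, 0] = x - L * np.floor(x / L)
                pos[i, 1] = y - L * np.floor(y / L)
                pos[i, 2] = z - L * np.floor(z / L)
                e_tot += de
                if use_long:
                    counters[1] += 1
                else:
                    counters[3] += 1
        if idx1.size > 0 and idx2.size > 0:
            for _ in range(n_swap):
                counters[4] += 1
                i = idx1[np.random.randint(0, idx1.size)]
                j = idx2[np.random.randint(0, idx2.size)]
                de = _swap_delta(pos, spec, i, j, L, za, zr, amp, alpha,
                                 eps12, r02, rc2)
                if de <= 0.0 or np.random.random() < np.exp(-de / T):
                    for d in range(3):
                        tmp = pos[i, d]
                        pos[i, d] = pos[j, d]
                        pos[j, d] = tmp
                    e_tot += de
                    counters[5] += 1
        energies[c] = e_tot
        if snap_stride > 0 and (c + 1) % snap_stride == 0 and snap_idx < snaps.shape[0]:
            snaps[snap_idx] = pos
            snap_idx += 1
    return e_tot
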