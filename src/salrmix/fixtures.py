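"""Synthetic particle configurations with known ground truth.

Every analysis stage (pair correlations, structure factors, cluster
labelling, bond counting, shape statistics) can be exercised on these
hand-built configurations without running Monte Carlo.  The annotations
are computed at construction time, from the generating geometry, never by
the analysis code under test.

All fixtures live in the same periodic-box representation as MC output;
the two-droplet fixture deliberately straddles a box face so that
minimum-image wrapping paths are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mc import Configuration, _fcc_sites

__all__ = ["Fixture", "make_fixture"]

_R0_DEFAULT = 1.2423773782094654  # bond range of the studied parametrisation


@dataclass
class Fixture:
    config: Configuration
    truth: dict = field(default_factory=dict)


def _wrap(pos: np.ndarray, L: float) -> np.ndarray:
    return pos % L


def _chain(n: int, spacing: float, L: float) -> np.ndarray:
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * spacing
    return pos + L / 4


def make_fixture(kind: str, size: int = 10, *, spacing: float = 1.1,
                 gap: float = 5.0, L: float | None = None,
                 sizes: tuple[int, int] = (30, 20),
                 semi_axes: tuple[float, float, float] = (1.0, 1.0, 2.0),
                 seed: int = 0, bond_length: float = _R0_DEFAULT) -> Fixture:
    """Build a named fixture; see the module docstring for the catalogue.

    kinds: monomers, dimer, chain, fcc_droplet, two_droplets,
    ellipsoid_cloud, poisson_gas.
    """
    rng = np.random.default_rng(seed)

    if kind == "monomers":
        # cubic grid with spacing safely above the bond range
        step = max(2.0 * bond_length, 3.0)
        side = int(np.ceil(size ** (1 / 3)))
        box = L if L is not None else side * step
        if box < side * step:
            raise ValueError("box too small for non-bonded monomers")
        g = np.stack(np.meshgrid(*[np.arange(side)] * 3, indexing="ij"),
                     axis=-1).reshape(-1, 3)[:size] * step + 0.5
        species = np.ones(size, dtype=np.int8)
        truth = {"n_clusters": size, "sizes": [1] * size,
                 "bond_counts": [0] * size,
                 "csd": {1: 1.0}}
        return Fixture(Configuration(_wrap(g.astype(float), box), species, box),
                       truth)

    if kind == "dimer":
        box = L if L is not None else 20.0
        pos = np.array([[0.0, 0.0, 0.0], [spacing, 0.0, 0.0]]) + box / 2
        truth = {"n_clusters": 1, "sizes": [2], "bond_counts": [1, 1],
                 "csd": {2: 1.0}}
        return Fixture(Configuration(_wrap(pos, box), np.ones(2, np.int8), box),
                       truth)

    if kind == "chain":
        box = L if L is not None else max(20.0, 2.5 * size * spacing)
        pos = _chain(size, spacing, box)
        bonded = spacing < bond_length
        nb = ([1] + [2] * (size - 2) + [1]) if (bonded and size > 1) else [0] * size
        truth = {
            "n_clusters": 1 if bonded else size,
            "sizes": [size] if bonded else [1] * size,
            "bond_counts": nb,
            "csd": {size: 1.0} if bonded else {1: 1.0},
        }
        return Fixture(Configuration(_wrap(pos, box), np.ones(size, np.int8), box),
                       truth)

    if kind == "fcc_droplet":
        sites = _fcc_sites(spacing, radius=1.0)
        r = 1.0
        while len(sites) < size:
            r *= 1.15
            sites = _fcc_sites(spacing, r)
        order = np.argsort(np.einsum("ij,ij->i", sites, sites))
        pts = sites[order[:size]]
        box = L if L is not None else 4.0 * (np.abs(pts).max() + bond_length)
        # construction-side neighbour count: exact FCC distances
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        nb = ((d > 1e-9) & (d < bond_length)).sum(axis=1)
        truth = {"n_clusters": 1, "sizes": [size],
                 "bond_counts": nb.tolist(),
                 "interior_nb": 12,
                 "csd": {size: 1.0}}
        pos = _wrap(pts + box / 2, box)
        return Fixture(Configuration(pos, np.ones(size, np.int8), box), truth)

    if kind == "two_droplets":
        n_a, n_b = sizes
        fa = make_fixture("fcc_droplet", n_a, spacing=spacing, L=100.0)
        fb = make_fixture("fcc_droplet", n_b, spacing=spacing, L=100.0)
        pa = fa.config.positions - 50.0
        pb = fb.config.positions - 50.0
        extent_a = np.abs(pa[:, 0]).max()
        extent_b = np.abs(pb[:, 0]).max()
        shift = extent_a + extent_b + gap
        box = L if L is not None else 3.0 * shift
        # droplet A straddles the x = 0 face; droplet B sits in the middle
        pos = np.concatenate([pa, pb + np.array([shift, 0.0, 0.0])])
        pos = _wrap(pos, box)
        n = n_a + n_b
        truth = {
            "n_clusters": 2,
            "sizes": sorted([n_a, n_b], reverse=True),
            "csd": {n_a: n_a / n, n_b: n_b / n},
        }
        species = np.ones(n, np.int8)
        species[n_a:] = 2
        return Fixture(Configuration(pos, species, box), truth)

    if kind == "ellipsoid_cloud":
        a, b, c = semi_axes
        # uniform filling of the ellipsoid by rescaling uniform ball samples
        u = rng.normal(size=(size, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        radii = rng.random(size) ** (1 / 3)
        pts = u * radii[:, None] * np.array([a, b, c])
        box = L if L is not None else 10.0 * max(semi_axes)
        # construction-side shape truth: explicit gyration eigen-decomposition
        cc = pts - pts.mean(axis=0)
        ev = np.linalg.eigvalsh(cc.T @ cc / size)
        truth = {
            "e_c": float(1.0 - np.sqrt(max(ev[0], 0.0) / ev[-1])),
            "rg_min": float(np.sqrt(max(ev[0], 0.0))),
            "rg_max": float(np.sqrt(ev[-1])),
        }
        pos = _wrap(pts + box / 2, box)
        return Fixture(Configuration(pos, np.ones(size, np.int8), box), truth)

    if kind == "poisson_gas":
        box = L if L is not None else 20.0
        pos = rng.random((size, 3)) * box
        return Fixture(Configuration(pos, np.ones(size, np.int8), box),
                       {"ideal": True})

    raise ValueError(f"unknown fixture kind {kind!r}")
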