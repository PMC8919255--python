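"""Real- and reciprocal-space correlations of the binary mixture.

Partial radial distribution functions g_ij(r) are accumulated as
minimum-image pair histograms normalised by ideal-gas shell counts.  The
partial structure factors follow the Ashcroft-Langreth convention,

    S_ij(k) = delta_ij + 4 pi rho sqrt(x_i x_j)
              \\int_0^{r_max} [g_ij(r) - 1] r sin(kr)/k dr,

evaluated by quadrature on the binned grid with r_max = L/2 (no window or
damping is applied; low-k values are only reported for k >= 2 pi / L).
With this convention S_11, S_22 -> 1 and S_12 -> 0 as k -> infinity, and
for a one-component system S_NN(k) = S_11(k) identically.

The Bhatia-Thornton combinations resolve total-density and concentration
fluctuations:

    S_NN = x1 S11 + x2 S22 + 2 sqrt(x1 x2) S12
    S_cc = x1 x2 [x2 S11 + x1 S22 - 2 sqrt(x1 x2) S12]
    S_Nc = x1 x2 (S11 - S22) + (x2 - x1) sqrt(x1 x2) S12

A low-k peak of the structure factor at k0 well below the main diffraction
peak signals intermediate-range order; empirically a height above ~3 marks
a cluster (or cluster-percolated) fluid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PairCorrelation",
    "StructureSet",
    "compute_gr",
    "gr_to_sk",
    "bhatia_thornton",
    "low_k_peak",
    "is_clustered",
]

#: Empirical low-k peak height marking the onset of a cluster phase.
CLUSTER_PEAK_THRESHOLD = 3.0


@dataclass
class PairCorrelation:
    r: np.ndarray               # bin centres (sigma)
    g: np.ndarray               # g_ij on the bins
    bin_width: float
    pair: tuple[int, int]       # species labels, e.g. (1, 1)
    n_configs: int


@dataclass
class StructureSet:
    k: np.ndarray               # wavenumbers (1/sigma), k >= 2 pi / L
    S11: np.ndarray
    S12: np.ndarray
    S22: np.ndarray
    x1: float
    x2: float
    S_NN: np.ndarray | None = None
    S_cc: np.ndarray | None = None
    S_Nc: np.ndarray | None = None


def _min_image_dists(a: np.ndarray, b: np.ndarray | None, L: float) -> np.ndarray:
    """Minimum-image pair distances: within a (i<j) or between a and b."""
    if b is None:
        delta = a[:, None, :] - a[None, :, :]
        delta -= L * np.round(delta / L)
        d2 = np.einsum("ijk,ijk->ij", delta, delta)
        iu, ju = np.triu_indices(len(a), k=1)
        return np.sqrt(d2[iu, ju])
    delta = a[:, None, :] - b[None, :, :]
    delta -= L * np.round(delta / L)
    return np.sqrt(np.einsum("ijk,ijk->ij", delta, delta)).ravel()


def compute_gr(snapshots: np.ndarray, species: np.ndarray, L: float,
               pair: tuple[int, int], bin_width: float = 0.02,
               r_max: float | None = None) -> PairCorrelation:
    """Partial radial distribution function averaged over snapshots.

    ``snapshots`` has shape (n_configs, N, 3); ``species`` holds labels 1/2.
    Like pairs are normalised by N_i(N_i-1)/2 ideal pairs, unlike pairs by
    N_i N_j.  Species label 0 selects all particles (total g(r)).
    """
    snaps = np.asarray(snapshots, dtype=float)
    if snaps.ndim == 2:
        snaps = snaps[None]
    if r_max is None:
        r_max = L / 2
    if r_max > L / 2 + 1e-12:
        raise ValueError("r_max beyond half the box edge")
    species = np.asarray(species)
    sel_i = np.ones(len(species), bool) if pair[0] == 0 else species == pair[0]
    sel_j = np.ones(len(species), bool) if pair[1] == 0 else species == pair[1]
    ni, nj = int(sel_i.sum()), int(sel_j.sum())
    if ni == 0 or nj == 0:
        raise ValueError(f"no particles of species pair {pair}")

    like = pair[0] == pair[1]
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    for pos in snaps:
        if like:
            d = _min_image_dists(pos[sel_i], None, L)
            npairs = ni * (ni - 1) / 2
        else:
            d = _min_image_dists(pos[sel_i], pos[sel_j], L)
            npairs = ni * nj
        hist += np.histogram(d, bins=edges)[0]
    hist /= len(snaps)

    vol = L**3
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = npairs * shell / vol
    g = np.divide(hist, ideal, out=np.zeros_like(hist), where=ideal > 0)
    r = 0.5 * (edges[:-1] + edges[1:])
    return PairCorrelation(r=r, g=g, bin_width=bin_width, pair=pair,
                           n_configs=len(snaps))


def gr_to_sk(gr: dict[tuple[int, int], PairCorrelation], rho: float, L: float,
             x1: float, x2: float, k_max: float = 25.0,
             k_grid: np.ndarray | None = None) -> StructureSet:
    """Partial structure factors from binned g_ij(r) by Fourier quadrature.

    The default k grid is the box's allowed set k_n = 2 pi n / L up to
    ``k_max``; an explicit ``k_grid`` (all entries >= 2 pi / L) overrides it.
    """
    dk = 2.0 * np.pi / L
    if k_grid is not None:
        k = np.asarray(k_grid, dtype=float)
        if np.any(k < dk - 1e-12):
            raise ValueError("k grid extends below the box wavevector")
    else:
        k = np.arange(1, int(k_max / dk) + 1) * dk
    out = {}
    for pair, key in [((1, 1), "S11"), ((1, 2), "S12"), ((2, 2), "S22")]:
        pc = gr.get(pair)
        delta_ij = 1.0 if pair[0] == pair[1] else 0.0
        xi = x1 if pair[0] == 1 else x2
        xj = x1 if pair[1] == 1 else x2
        if pc is None or xi == 0 or xj == 0:
            out[key] = np.full_like(k, delta_ij)
            continue
        if pc.r[-1] > L / 2 + pc.bin_width:
            raise ValueError("g(r) grid extends beyond L/2")
        h = pc.g - 1.0
        integrand = h * pc.r  # times sin(kr)/k below
        sin_kr = np.sin(np.outer(k, pc.r))
        integral = np.trapezoid(integrand * sin_kr, pc.r, axis=1) / k
        out[key] = delta_ij + 4.0 * np.pi * rho * np.sqrt(xi * xj) * integral
    return StructureSet(k=k, S11=out["S11"], S12=out["S12"], S22=out["S22"],
                        x1=x1, x2=x2)


def bhatia_thornton(S11: np.ndarray, S12: np.ndarray, S22: np.ndarray,
                    x1: float, x2: float):
    """Number-number, concentration-concentration and cross structure factors."""
    if abs(x1 + x2 - 1.0) > 1e-9:
        raise ValueError("concentrations must sum to 1")
    rt = np.sqrt(x1 * x2)
    S_NN = x1 * S11 + x2 * S22 + 2.0 * rt * S12
    S_cc = x1 * x2 * (x2 * S11 + x1 * S22 - 2.0 * rt * S12)
    S_Nc = x1 * x2 * (S11 - S22) + (x2 - x1) * rt * S12
    return S_NN, S_cc, S_Nc


def with_bhatia_thornton(ss: StructureSet) -> StructureSet:
    ss.S_NN, ss.S_cc, ss.S_Nc = bhatia_thornton(ss.S11, ss.S12, ss.S22, ss.x1, ss.x2)
    return ss


def low_k_peak(k: np.ndarray, S: np.ndarray, k_cut: float = 3.0):
    """Largest interior local maximum of S(k) below the main diffraction peak.

    Returns (k0, height) or None when S is monotone on the window (a
    monomer-fluid indicator).  Three-point local maxima on the raw values.
    """
    sel = k < k_cut
    kk, ss = k[sel], S[sel]
    if len(kk) < 3:
        return None
    interior = np.nonzero((ss[1:-1] > ss[:-2]) & (ss[1:-1] >= ss[2:]))[0] + 1
    if interior.size == 0:
        return None
    best = interior[np.argmax(ss[interior])]
    return float(kk[best]), float(ss[best])


def is_clustered(peak_height: float | None, csd_has_interior_max: bool) -> bool:
    """Cluster-fluid flag: low-k peak above ~3 AND a non-monotonic CSD."""
    return (peak_height is not None and peak_height > CLUSTER_PEAK_THRESHOLD
            and csd_has_interior_max)
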