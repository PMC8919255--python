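"""High-level drivers tying the simulator to the observable stack.

These are the entry points the analysis scripts and the CLI call: run (or
take) a trajectory, then compute pair correlations, partial and
Bhatia-Thornton structure factors, the cluster-size statistics and the
thermal summaries in one pass, returning plain dictionaries / DataFrames
ready to serialise.
"""

from __future__ import annotations

import numpy as np

from . import clusters as cl
from . import structure as st
from . import thermo as th
from .mc import SystemSpec, TrajectoryRecord
from .model import PotentialParams

__all__ = ["analyze_trajectory", "simulate_state_point"]


def analyze_trajectory(snapshots: np.ndarray, species: np.ndarray, L: float,
                       rho: float, bond_length: float,
                       bin_width: float = 0.02,
                       max_structure_snapshots: int = 200) -> dict:
    """Full structural + cluster analysis of a stack of snapshots."""
    species = np.asarray(species)
    x1 = float(np.mean(species == 1))
    x2 = 1.0 - x1
    sub = snapshots[:: max(1, len(snapshots) // max_structure_snapshots)]

    gr = {}
    pairs = [(1, 1)] if x2 == 0 else ([(2, 2)] if x1 == 0
                                      else [(1, 1), (1, 2), (2, 2)])
    for pair in pairs:
        gr[pair] = st.compute_gr(sub, species, L, pair, bin_width=bin_width)
    ss = st.gr_to_sk(gr, rho, L, x1, x2)
    st.with_bhatia_thornton(ss)

    reports = [cl.find_clusters(pos, L, bond_length, species=species)
               for pos in snapshots]
    s, weight = cl.csd(reports)
    summaries = cl.cluster_summaries(reports) if len(reports) > 1 else None
    largest_mean = float(np.mean([r.largest_size for r in reports]))
    taxonomy = cl.classify_csd(s, weight, reports[0].n_particles, largest_mean)
    nb, pb = cl.bond_distribution(reports[-1])

    peak = st.low_k_peak(ss.k, ss.S11)
    return {
        "gr": gr,
        "structure": ss,
        "low_k_peak": peak,
        "clustered": st.is_clustered(peak[1] if peak else None,
                                     taxonomy in ("cluster fluid",
                                                  "cluster percolated")),
        "csd_s": s,
        "csd_weight": weight,
        "csd_class": taxonomy,
        "cluster_reports": reports,
        "cluster_summaries": summaries,
        "bond_hist": (nb, pb),
    }


def simulate_state_point(n1: int, n2: int, rho: float, T: float, eps12: float,
                         seed: int, n_equil: int, n_prod: int,
                         initial: str = "random",
                         target_snapshots: int = 200) -> tuple[TrajectoryRecord, dict]:
    """Run one state point and analyse it; returns (trajectory, analysis)."""
    from .mc import run_simulation

    spec = SystemSpec(n1=n1, n2=n2, rho=rho, T=T, seed=seed)
    params = PotentialParams(eps12=eps12)
    rec = run_simulation(spec, params, n_equil_cycles=n_equil,
                         n_prod_cycles=n_prod, initial=initial,
                         target_snapshots=target_snapshots)
    ana = analyze_trajectory(rec.snapshots, rec.metadata["species"], spec.L,
                             rho, bond_length=params.r0)
    ana["energy"] = th.asymptotic_energy(rec.energy_trace)
    return rec, ana
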