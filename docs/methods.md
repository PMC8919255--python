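# Methods

## Model

Two species share a hard core of diameter `sigma`. Species 1 carries the
SALR (hard-sphere two-Yukawa) tail

```
u11(r) = eps11/(1-alpha) * [ -exp(-z_a (r*-1)) + alpha exp(-z_r (r*-1)) ] / r*,
r* = r/sigma,  r >= sigma,
```

with defaults `z_a = 10`, `z_r = 0.5`, `alpha = 0.1`. The `1/(1-alpha)`
prefactor normalises the contact value to exactly `-eps11`, which is the
stated meaning of the energy unit; with it, every analytic crossing locus
below lands on the reference values to four decimals, which is how the
transcription was fixed. The first zero of the tail is analytic for this
form, `r0 = 1 + ln(1/alpha)/(z_a - z_r) = 1.2424 sigma`; `compute_r0`
nevertheless root-finds it numerically (bracketed scan + Brent to 1e-12)
so that it remains correct for any admissible parameters. Species 2 is a
bare hard sphere; the 1–2 interaction is a square well of depth `eps12`
on `[sigma, r0)`. Ties at exactly `sigma` (contact) are allowed and ties
at exactly `r0` are outside the well/bond: both sets have measure zero,
and strict inequalities avoid spurious floating-point rejections.

Reduced units: `sigma = eps11 = k_B = 1`; temperatures in `eps11/k_B`,
densities in `sigma^-3`, `B2` in `sigma^3`.

## Monte Carlo

Canonical (NVT) Metropolis sampling of `N = N1 + N2` particles in a cubic
periodic box `L = (N/rho)^(1/3)`. `u11` is truncated — not shifted — at
`L/2`, with no tail corrections, so reported energies are raw truncated
energies. Because the cutoff is half the box, cell lists are pointless;
each move recomputes the moved particle's interaction with all others in
a compiled (numba) O(N) pass, and total energies are tracked
incrementally. A full recomputation at the end of every run must agree
with the bookkeeping to `1e-8 N eps11` or the run aborts.

Moves per cycle: `N` attempted translations plus `max(1, N/10)` attempted
species swaps (positions of a random 1–2 pair exchanged). Each
translation draws its amplitude class at random — probability 1/2 for the
long amplitude, 1/2 for the short — making the kernel a fixed mixture, so
detailed balance holds exactly at every step. Displacements are uniform
in a cube of side `2*mrd`. The two amplitudes accommodate intercluster
and intracluster motion; they are tuned during equilibration by
multiplicative feedback toward 30% (long) and 80% (short) acceptance over
~20 windows, clipped to `[1e-3, 2] sigma`, and frozen before production.
In dilute or athermal states almost everything is accepted regardless of
amplitude, so the long amplitude saturates at its cap; in clustered
states the tuned values come out near the characteristic `~0.1 sigma` /
`~0.01 sigma` scales. Hard-core overlap is a Boolean test (strict
`r < sigma`) and overlapping proposals are rejected outright, never
weighted by a large finite energy.

The protocol is quench-from-random: non-overlapping uniform insertion
(an infinite-temperature state), instantaneous quench to the target `T`,
tuned equilibration, production with the frozen schedule. A second
initial condition, a compact FCC droplet containing all particles with
randomly interleaved species, supports relaxation tests from the opposite
(over-aggregated) side. Runs are bit-reproducible for a fixed seed; all
window seeds derive from one `SeedSequence`.

## Observables

**Pair correlations.** Partial `g_ij(r)` from minimum-image pair
histograms (default bin `0.02 sigma`, `r_max = L/2`), normalised by
`N_i(N_i-1)/2` or `N_i N_j` ideal pair counts.

**Structure factors.** Ashcroft–Langreth partials
`S_ij(k) = delta_ij + 4 pi rho sqrt(x_i x_j) ∫ [g_ij - 1] r sin(kr)/k dr`
by trapezoidal quadrature on the binned grid, evaluated on the box's
allowed wavenumbers `k_n = 2 pi n / L` up to `k sigma = 25`. No window or
damping is applied to the truncated integral; values are only reported
for `k >= 2 pi / L`, and truncation ripple at the lowest wavenumbers is
the known artifact of this choice. Bhatia–Thornton combinations:
`S_NN = x1 S11 + x2 S22 + 2 sqrt(x1 x2) S12`,
`S_cc = x1 x2 [x2 S11 + x1 S22 - 2 sqrt(x1 x2) S12]`,
`S_Nc = x1 x2 (S11 - S22) + (x2 - x1) sqrt(x1 x2) S12`; these reduce
correctly in the `chi -> 1` and ideal-mixture limits, which fixes the
convention. The low-`k` peak is the largest 3-point local maximum below
`k sigma = 3` (raw values; no smoothing by default), and the empirical
"clustered" flag requires both height > 3 and a non-monotonic CSD.

**Clusters.** Two particles of any species are bonded when their
minimum-image separation is strictly below `r0`. Labelling is a
Hoshen–Kopelman sweep, i.e. sequential union-find with path compression
over the bond list, relabelled so clusters are numbered by their smallest
member index. The CSD is `N(s) = s <n(s)> / N`, normalised to 1 by
construction; percolation means more than half of all particles in one
network (no box-spanning test — the >50% rule is applied as stated).
Cluster morphology taxonomy (dispersed / cluster fluid / random
percolated / cluster percolated) is decided on a log-binned (factor 1.6)
CSD weight *density*, because raw 3-point extrema at large `s` are
dominated by sampling noise; an interior local maximum of the binned
density — or a rising final bin below half the system size — marks a
preferred cluster size.

**Shape.** The largest cluster is unwrapped across periodic images by
breadth-first traversal (each member placed at its minimum-image position
relative to its parent), its gyration tensor diagonalised, and the
eccentricity `e_c = 1 - Rg_min/Rg_max` formed from the square roots of
the extreme eigenvalues, averaged over configurations: 0 for a sphere,
approaching 1 for elongated aggregates. Percolating clusters cannot be
unwrapped and raise instead.

**Thermal.** `c_V = (<H^2> - <H>^2)/(N k_B T^2)` per particle from
production-phase fluctuations only (tuning breaks stationarity); errors
by block averaging (10 blocks), or, given several independent runs, the
maximum dispersion of per-run values about their mean. Asymptotic
energies are means over the final 20% of a trace, with a drift flag when
the linear trend over that window is both statistically significant
(3 standard errors) and material against the window's own noise — the
flag marks runs still creeping toward equilibrium. The energy-vs-`eps12`
knee is located by a two-segment least-squares fit scanned over all
breakpoints with at least two points per side.

## The second-virial criterion

Reference attractive fluids: all interactions truncated to zero beyond
`r0` (the long-range repulsion is discarded). `B2_22 = 2 pi /3` exactly;
the square-well coefficient has the closed form
`B2_12 = (2 pi/3)[1 - (r0^3 - 1)(e^{eps12/T} - 1)]`; `B2_11` combines the
analytic hard-core term with adaptive quadrature of the truncated SALR
well on `[sigma, r0]` (absolute tolerance well below `1e-8 sigma^3`).
The mixture coefficient is the quadratic concentration combination, and
the criterion compares `B2_mix` with `B2_11`. Crossing loci are computed
twice — closed form and an independent root-finder (bisection in
`eps12`; explicit quadratic roots in `chi`, discarding the trivial
`chi = 1` root) — and must agree to 1e-6. The `B2`-minimising
concentration is the quadratic's vertex when convex; in the concave case
(e.g. `eps12 = 0`) the minimising boundary is returned with a flag.

## Problem sizes and what the scaled-down runs show

The literal production-scale study uses `N = 2048` and `10^6`–`10^8`
cycles; this package's default analyses and its end-to-end tests run
`N = 500` with `10^4`-scale cycle counts (a few minutes per state point
on one CPU), the sizes used by `analysis/0*.py` and
`tests/test_acceptance.py`. At that scale the *qualitative* structure is
reproduced and is what the tests assert: the pure SALR fluid's low-`k`
peak sits near 1.8 at `T = 0.25` (matching the reference value ≈1.8) and crosses the
≈3 threshold by `T = 0.22`; the equimolar mixture at `T = 0.25` stays
dispersed at `eps12 = 0.50` but becomes a cluster fluid at
`eps12 = 0.75`, with the energy per particle dropping well below −1
(−2 at full scale, which short runs approach from above); preferred
cluster sizes come out at roughly half the full-scale values (peaks near
`s ≈ 10–30` rather than 20–60) because aggregates are still coarsening
when sampling starts. Peak heights deep in the clustered regime keep
growing with run length, so only threshold crossings — not exact heights
— are meaningful at this scale. The criterion/simulation consistency
check (enhanced vs suppressed at four state points) is insensitive to
the scaling because it compares the mixture against the pure fluid
simulated under identical conditions.

The synthetic-data fixtures (monomer grids, chains, FCC droplets —
including one straddling a box face — ellipsoid clouds, Poisson gases)
carry construction-time ground truth and exercise every analysis stage
without MC; what they cannot emulate is equilibration itself, which is
why the simulation-tier tests exist.

## Known limitations

* Single-particle translations plus swaps only: no cluster moves, no
  parallel tempering, so deep-quench states (`eps12 = 1`, `T < 0.20`)
  equilibrate slowly and may carry a drift flag at desk scale.  The
  big-cluster relaxation test (analysis/05) in particular does not reach
  convergence at desk scale: the all-particle droplet only relaxes
  internally within `10^4`-scale runs, and its entropy-driven
  fragmentation into the cluster fluid needs production-scale cycles.
* The truncated Fourier transform produces small ripple near `k_min`;
  peak heights at `k0 ~ 2 pi/L` should be read with that in mind.
* The `B2` criterion is a two-body proxy: it predicts the direction of
  the clustering response, not cluster sizes or absolute thresholds (its
  `chi* = 0.145` vs the simulated onset near `chi ~ 0.05` is the known
  quantitative gap at full scale).
* No crystalline-order analysis inside clusters and no size-asymmetric
  cores; both are outside this package's scope.
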