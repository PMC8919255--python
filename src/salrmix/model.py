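"""Pair interactions of the binary SALR / hard-sphere mixture.

Species 1 is a hard-sphere two-Yukawa (HSTY) particle: a hard core of
diameter ``sigma`` plus a short-range attractive Yukawa tail (inverse range
``z_a``) competing with a weaker long-range repulsive Yukawa tail (inverse
range ``z_r``, relative strength ``alpha``).  Species 2 is a plain hard
sphere.  The cross interaction is a square well of depth ``eps12`` whose
range coincides with ``r0``, the first zero of the HSTY tail, so that both
attractions act over the same distances.

Everything is expressed in reduced units: ``sigma`` is the unit of length,
``eps11`` the unit of energy and k_B = 1.  The tail of u11 is normalised so
that its contact value is exactly ``-eps11``:

    u11(r) = eps11/(1-alpha) * [-exp(-z_a (r*-1)) + alpha exp(-z_r (r*-1))]/r*

with r* = r/sigma.  The hard core is represented as a Boolean overlap test
(strict ``r < sigma``), never as a large finite energy, so that Metropolis
rejection of overlapping moves is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = ["PotentialParams", "u11", "u12", "u22", "compute_r0"]


@dataclass(frozen=True)
class PotentialParams:
    """Interaction constants of the mixture, in reduced units.

    Defaults are the studied parametrisation: ``z_a=10``, ``z_r=0.5``,
    ``alpha=0.1``, for which ``r0 = 1.242 sigma``.
    """

    z_a: float = 10.0
    z_r: float = 0.5
    alpha: float = 0.1
    eps11: float = 1.0
    eps12: float = 0.0
    sigma: float = 1.0
    r0: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.z_a > self.z_r > 0):
            raise ValueError("require z_a > z_r > 0")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")
        if self.eps12 < 0:
            raise ValueError("eps12 must be non-negative")
        if self.sigma <= 0 or self.eps11 <= 0:
            raise ValueError("sigma and eps11 must be positive")
        object.__setattr__(self, "r0", compute_r0(self))


def _tail11(rstar: np.ndarray | float, p: PotentialParams) -> np.ndarray | float:
    """HSTY tail as a function of r* = r/sigma (no hard core)."""
    amp = p.eps11 / (1.0 - p.alpha) if p.alpha < 1 else p.eps11
    return amp * (
        -np.exp(-p.z_a * (rstar - 1.0)) + p.alpha * np.exp(-p.z_r * (rstar - 1.0))
    ) / rstar


def u11(r, params: PotentialParams):
    """HSTY pair potential.  ``inf`` inside the hard core (r < sigma)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    rstar = r / params.sigma
    out = np.where(rstar < 1.0, np.inf, _tail11(np.maximum(rstar, 1.0), params))
    return out.item() if out.ndim == 0 else out


def u12(r, params: PotentialParams):
    """Square-well cross interaction: depth eps12 on [sigma, r0), zero beyond."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    rstar = r / params.sigma
    out = np.where(rstar < 1.0, np.inf, np.where(rstar < params.r0, -params.eps12, 0.0))
    return out.item() if out.ndim == 0 else out


def u22(r):
    """Hard-sphere interaction of species 2: ``inf`` for r < sigma, else 0."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    out = np.where(r < 1.0, np.inf, 0.0)
    return out.item() if out.ndim == 0 else out


def compute_r0(params: PotentialParams, r_max: float = 20.0) -> float:
    """First zero of the HSTY tail beyond the core, in units of sigma.

    Found by bracketing the sign change of the tail on (1, r_max) and
    polishing with Brent's method to 1e-12.  With alpha = 1 and equal
    prefactors the zero sits at contact and ``1.0`` is returned.

    Raises
    ------
    ValueError
        If the tail has no sign change in (sigma, r_max*sigma).
    """
    if params.alpha == 1.0:
        return 1.0  # equal prefactors: the zero sits exactly at contact
    f = lambda x: _tail11(x, params)
    lo = 1.0 + 1e-12
    flo = f(lo)
    if flo == 0.0 or abs(flo) < 1e-13:
        return 1.0
    # scan for a bracket; the zero is near 1 + ln(1/alpha)/(z_a - z_r)
    grid = np.linspace(lo, r_max, 4096)
    vals = f(grid)
    sign_change = np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
    if sign_change.size == 0:
        raise ValueError("tail has no zero in (sigma, %.1f sigma)" % r_max)
    i = sign_change[0]
    return float(brentq(f, grid[i], grid[i + 1], xtol=1e-12))
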