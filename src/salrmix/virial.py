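"""Second-virial clustering criterion for the HSTY / hard-sphere mixture.

The criterion compares the "reference attractive" fluids: every interaction
is truncated to zero beyond r0 (the long-range Yukawa repulsion of the SALR
species is discarded), leaving only the hard core plus the attractive well.
The second virial coefficient of such a fluid proxies the strength of the
liquid--vapour-driving attraction, and the mixture clusters more readily
than the pure SALR fluid whenever

    B2_mix(chi, T, eps12) < B2_11(T),

where the mixture coefficient is the quadratic concentration combination

    B2_mix = chi^2 B2_11 + 2 chi (1-chi) B2_12 + (1-chi)^2 B2_22,

B2_22 = 2 pi sigma^3 / 3 exactly (hard spheres) and, for ij = 11 or 12,

    B2_ij = 2 pi \\int_0^inf [1 - exp(-u_ij(r)/T)] r^2 dr

with u_ij the reference attractive (truncated-at-r0) interaction.  For the
square-well cross interaction this integral has the closed form

    B2_12 = (2 pi /3) [1 - (r0^3 - 1)(exp(eps12/T) - 1)].

All lengths in sigma, energies in eps11, so B2 values are in sigma^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .model import PotentialParams, _tail11

__all__ = [
    "VirialResult",
    "b2_hs",
    "b2_sw",
    "b2_hsty_ref",
    "b2_pair",
    "b2_mixture",
    "eps12_star",
    "chi_star",
    "b2_min_chi",
    "clustering_prediction",
]

#: Hard-sphere second virial coefficient, 2 pi sigma^3 / 3.
B2_HS = 2.0 * np.pi / 3.0


@dataclass(frozen=True)
class VirialResult:
    """Pair and mixture virial coefficients at one state point (sigma^3)."""

    T: float
    chi: float
    eps12: float
    b2_11: float
    b2_12: float
    b2_22: float
    b2_mix: float


def b2_hs() -> float:
    """B2 of pure hard spheres: 2 pi sigma^3 / 3, exact."""
    return B2_HS


def b2_sw(T: float, eps12: float, r0: float) -> float:
    """Closed-form B2 of the square-well cross interaction (range r0)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    return B2_HS * (1.0 - (r0**3 - 1.0) * np.expm1(eps12 / T))


def b2_hsty_ref(T: float, params: PotentialParams | None = None) -> float:
    """B2 of the reference attractive HSTY fluid (tail truncated at r0).

    Hard-core contribution is analytic; the well contribution on [sigma, r0]
    is evaluated by adaptive quadrature to 1e-10 sigma^3 absolute.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    p = params if params is not None else PotentialParams()
    integrand = lambda x: (1.0 - np.exp(-_tail11(x, p) / T)) * x * x
    well, _ = quad(integrand, 1.0, p.r0, epsabs=1e-12, epsrel=1e-12)
    return B2_HS + 2.0 * np.pi * well


def b2_pair(pair: str, T: float, eps12: float = 0.0,
            params: PotentialParams | None = None) -> float:
    """B2 of one reference attractive pair interaction; pair in {'11','12','22'}."""
    p = params if params is not None else PotentialParams()
    if pair == "11":
        return b2_hsty_ref(T, p)
    if pair == "12":
        return b2_sw(T, eps12, p.r0)
    if pair == "22":
        return B2_HS
    raise ValueError(f"unknown pair {pair!r}")


def b2_mixture(chi: float, T: float, eps12: float,
               params: PotentialParams | None = None) -> VirialResult:
    """Mixture B2 at HSTY concentration chi (quadratic combination)."""
    if not (0.0 <= chi <= 1.0):
        raise ValueError("chi must lie in [0, 1]")
    p = params if params is not None else PotentialParams()
    b11 = b2_hsty_ref(T, p)
    b12 = b2_sw(T, eps12, p.r0)
    b22 = B2_HS
    bmix = chi**2 * b11 + 2.0 * chi * (1.0 - chi) * b12 + (1.0 - chi) ** 2 * b22
    return VirialResult(T=T, chi=chi, eps12=eps12,
                        b2_11=b11, b2_12=b12, b2_22=b22, b2_mix=bmix)


def eps12_star(T: float, chi: float = 0.5,
               params: PotentialParams | None = None,
               method: str = "closed") -> float:
    """Cross-attraction strength at which B2_mix(chi) = B2_11.

    Above this value the reference attractive mixture is more attractive
    than the reference attractive pure SALR fluid, and clustering in the
    mixture is predicted to be enhanced.

    ``method='closed'`` uses the analytic solution of the quadratic
    combination for the square-well B2; ``method='bisect'`` root-finds on
    the monotone map eps12 -> B2_mix - B2_11.  Both agree to 1e-9.
    """
    if not (0.0 < chi < 1.0):
        raise ValueError("chi must lie in (0, 1) for a crossing in eps12")
    p = params if params is not None else PotentialParams()
    b11 = b2_hsty_ref(T, p)
    b22 = B2_HS
    # B2_mix = B2_11 requires B2_12 = [(1+chi) b11 - (1-chi) b22] / (2 chi)
    b12_star = ((1.0 + chi) * b11 - (1.0 - chi) * b22) / (2.0 * chi)
    # invert the closed-form SW virial coefficient
    arg = 1.0 + (1.0 - b12_star / b22) / (p.r0**3 - 1.0)
    if arg <= 1.0:
        raise ValueError("no crossing: mixture never exceeds the pure-fluid attraction")
    closed = T * np.log(arg)
    if method == "closed":
        return float(closed)
    if method == "bisect":
        f = lambda e: b2_mixture(chi, T, e, p).b2_mix - b11
        if f(0.0) * f(5.0) > 0:
            raise ValueError("no crossing in eps12 in [0, 5]")
        return float(brentq(f, 0.0, 5.0, xtol=1e-12))
    raise ValueError(f"unknown method {method!r}")


def chi_star(T: float, eps12: float = 0.75,
             params: PotentialParams | None = None,
             method: str = "closed") -> float:
    """Nontrivial concentration at which B2_mix(chi) = B2_11 (chi = 1 is trivial).

    Below chi* the mixture is less attractive than the pure SALR fluid;
    above it (up to 1) clustering is enhanced even though SALR particles
    are being replaced by hard spheres.
    """
    p = params if params is not None else PotentialParams()
    b11 = b2_hsty_ref(T, p)
    b12 = b2_sw(T, eps12, p.r0)
    b22 = B2_HS
    denom = 2.0 * b12 - b11 - b22
    if denom == 0:
        raise ValueError("degenerate crossing")
    root = (b11 - b22) / denom
    if not (0.0 < root < 1.0):
        raise ValueError("no nontrivial crossing in (0, 1); increase eps12")
    if method == "closed":
        return float(root)
    if method == "quadratic":
        # explicit quadratic-root cross-check on the full combination
        a = b11 - 2.0 * b12 + b22
        b = 2.0 * (b12 - b22)
        c = b22 - b11
        roots = np.roots([a, b, c])
        roots = roots[np.isreal(roots)].real
        # drop the trivial chi = 1 root (to rounding) before selecting
        interior = roots[(roots > 0) & (roots < 1) & (np.abs(roots - 1) > 1e-6)]
        if interior.size == 0:
            raise ValueError("no nontrivial crossing in (0, 1)")
        return float(interior.min())
    raise ValueError(f"unknown method {method!r}")


def b2_min_chi(T: float, eps12: float,
               params: PotentialParams | None = None,
               with_flag: bool = False):
    """Concentration minimising B2_mix over [0, 1].

    For a convex quadratic this is the closed-form vertex (clipped to the
    physical range); for the concave case the minimising boundary is
    returned instead.  With ``with_flag=True`` returns (chi, interior) where
    ``interior`` is False when the minimum sits on a boundary.
    """
    p = params if params is not None else PotentialParams()
    b11 = b2_hsty_ref(T, p)
    b12 = b2_sw(T, eps12, p.r0)
    b22 = B2_HS
    curv = b11 - 2.0 * b12 + b22
    if curv > 0:
        vertex = float(np.clip((b22 - b12) / curv, 0.0, 1.0))
        interior = 0.0 < vertex < 1.0
    else:
        vertex = 1.0 if b11 <= b22 else 0.0   # concave: boundary minimum
        interior = False
    return (vertex, interior) if with_flag else vertex


def clustering_prediction(T: float, chi: float, eps12: float,
                          params: PotentialParams | None = None) -> tuple[str, float]:
    """Predict whether the mixture clusters more or less readily than pure SALR.

    Returns ``('enhanced', d)`` if B2_mix < B2_11 (mixture more attractive)
    or ``('suppressed', d)`` otherwise, with d = |B2_mix - B2_11| in sigma^3.
    """
    res = b2_mixture(chi, T, eps12, params)
    dist = abs(res.b2_mix - res.b2_11)
    label = "enhanced" if res.b2_mix < res.b2_11 else "suppressed"
    return label, float(dist)
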