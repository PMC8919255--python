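"""Energy-trace analysis: asymptotic energies, fluctuation specific heat,
and the two-regime linear fit of asymptotic energy versus cross attraction.

The constant-volume specific heat per particle comes from canonical energy
fluctuations, c_V = (<H^2> - <H>^2) / (N k_B T^2), evaluated over the
production window only (tuning breaks stationarity).  Uncertainties come
from block averaging, or, when several independent runs are supplied, from
the maximum dispersion of the per-run means about the grand mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ThermoSummary", "specific_heat", "asymptotic_energy", "two_regime_fit"]


@dataclass
class ThermoSummary:
    value: float
    error: float
    drift: bool = False


def specific_heat(energy_traces, T: float, N: int, burn_in: int = 0,
                  n_blocks: int = 10, min_samples: int = 100) -> ThermoSummary:
    """Fluctuation specific heat per particle (units of k_B).

    ``energy_traces`` is one total-energy trace or a list of independent
    traces.  With one trace the error is the block-average dispersion of
    per-block c_V estimates; with several, the maximum dispersion of the
    per-run values about their mean.
    """
    traces = energy_traces if isinstance(energy_traces, (list, tuple)) \
        else [energy_traces]
    vals = []
    for tr in traces:
        h = np.asarray(tr, dtype=float)[burn_in:]
        if h.size < min_samples:
            raise ValueError("trace too short after burn-in")
        vals.append(h.var() / (N * T * T))
    if len(vals) > 1:
        vals = np.array(vals)
        mean = float(vals.mean())
        return ThermoSummary(value=mean, error=float(np.abs(vals - mean).max()))
    h = np.asarray(traces[0], dtype=float)[burn_in:]
    blocks = np.array_split(h, n_blocks)
    block_cv = np.array([b.var() / (N * T * T) for b in blocks])
    return ThermoSummary(value=float(vals[0]),
                         error=float(block_cv.std(ddof=1) / np.sqrt(n_blocks)))


def asymptotic_energy(energy_trace, window_fraction: float = 0.2) -> ThermoSummary:
    """Mean over the final window of the trace, with a drift flag.

    The drift flag is raised when the linear trend over the window exceeds
    three times its standard error — the signature of a run still slowly
    approaching equilibrium.
    """
    h = np.asarray(energy_trace, dtype=float)
    n = max(int(round(len(h) * window_fraction)), 2)
    w = h[-n:]
    value = float(w.mean())
    err = float(w.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    drift = False
    if n >= 3:
        x = np.arange(n, dtype=float)
        slope, intercept = np.polyfit(x, w, 1)
        resid = w - (slope * x + intercept)
        denom = np.sqrt(((x - x.mean()) ** 2).sum())
        se = np.sqrt(resid.var(ddof=2)) / denom if denom > 0 else np.inf
        total_trend = abs(slope) * n
        drift = bool(se > 0 and abs(slope) > 3 * se
                     and total_trend > 3 * (w.std(ddof=1) / np.sqrt(n)))
    return ThermoSummary(value=value, error=err, drift=drift)


def two_regime_fit(x_values, y_values):
    """Least-squares piecewise-linear fit with one breakpoint.

    Scans candidate breakpoints between consecutive x values, fits a line
    on each side, and keeps the split minimising the total squared
    residual.  Returns a dict with both (slope, intercept) pairs, the
    breakpoint (midpoint of the straddled interval) and a 'collinear' flag
    when a single line already fits to machine precision.
    """
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    if len(x) < 4:
        raise ValueError("need at least 4 points for a two-regime fit")

    def fit(xs, ys):
        coef = np.polyfit(xs, ys, 1)
        resid = ys - np.polyval(coef, xs)
        return coef, float(resid @ resid)

    single_coef, single_sse = fit(x, y)
    best = None
    for split in range(2, len(x) - 1):  # >=2 points on each side
        cl, sl = fit(x[:split], y[:split])
        cr, sr = fit(x[split:], y[split:])
        sse = sl + sr
        if best is None or sse < best["sse"]:
            best = {
                "left": (float(cl[0]), float(cl[1])),
                "right": (float(cr[0]), float(cr[1])),
                "breakpoint": float(0.5 * (x[split - 1] + x[split])),
                "sse": sse,
            }
    best["collinear"] = bool(best["sse"] >= single_sse - 1e-12 * max(1.0, single_sse)
                             or single_sse < 1e-20)
    if best["collinear"]:
        best["left"] = best["right"] = (float(single_coef[0]), float(single_coef[1]))
    return best
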