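"""Communication-through-coherence factors on entrained orbits.

Four scalars quantify whether the strength of a periodic input is
transmitted to the firing rate of the receiving E-population once the
network is p:q locked to it:

* ``delta_tau``    — normalised timing (t_inh - t_p)/T between the I-volley
  peak and the (preceding) input peak; small values mean the input lands
  under inhibition and is shadowed.
* ``delta_alpha_bar`` — ratio of cycle-averaged E-rates, forced/unforced.
* ``delta_alpha``  — ratio of the E-volley peak rates.
* ``delta_sigma``  — ratio of E-volley half-widths, each normalised by its
  own period.

At A = 0 all three ratios are exactly 1 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .forcing import ForcingSpec, VonMisesInput
from .locking import LockedOrbit, full_model_locking, plateau_interval
from .meanfield import IDX_RE, IDX_RI, LimitCycle, ModelParams, Trajectory
from .phase import IPRC

__all__ = [
    "CTCFactors",
    "delta_tau",
    "response_factors",
    "tongue_section_sweep",
]


@dataclass(frozen=True)
class CTCFactors:
    """Communication factors of one entrained orbit."""

    delta_tau: float
    delta_alpha_bar: float
    delta_alpha: float
    delta_sigma: float
    #: per-volley (Delta-tau_1, Delta-tau_2, ...) for multi-volley (2:1) orbits
    delta_tau_per_volley: Tuple[float, ...] = ()
    delta_alpha_per_volley: Tuple[float, ...] = ()


def _quadratic_peak(t: np.ndarray, y: np.ndarray, i: int) -> Tuple[float, float]:
    """Sub-sample peak (time, value) by a parabola through 3 points."""
    n = len(t)
    im, ip = (i - 1) % n, (i + 1) % n
    y0, y1, y2 = y[im], y[i], y[ip]
    h = t[1] - t[0]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return t[i], y1
    d = 0.5 * (y0 - y2) / denom
    return t[i] + d * h, y1 - 0.25 * (y0 - y2) * d


def _volley_peaks(t: np.ndarray, r: np.ndarray, period: float,
                  rel_height: float = 0.2) -> List[Tuple[float, float]]:
    """All volley peaks (time, height) of a periodic rate trace, tallest
    first.  Minor wiggles below ``rel_height`` of the range are ignored."""
    if np.ptp(r) == 0:
        raise ValueError("flat rate trace has no volleys")
    rr = r[:-1]
    tt = t[:-1]
    n = len(rr)
    lo, hi = rr.min(), rr.max()
    thr = lo + rel_height * (hi - lo)
    peaks = []
    for i in range(n):
        if rr[i] >= rr[(i - 1) % n] and rr[i] > rr[(i + 1) % n] and rr[i] > thr:
            tp, vp = _quadratic_peak(tt, rr, i)
            peaks.append((float(np.mod(tp, period)), float(vp)))
    peaks.sort(key=lambda pv: -pv[1])
    return peaks


def _input_peak_times(inp: VonMisesInput, period: float) -> np.ndarray:
    """Peak times of a von Mises input within [0, period)."""
    first = np.mod(inp.mu, inp.T)
    k = int(np.ceil((period - first) / inp.T))
    return np.mod(first + inp.T * np.arange(max(k, 1)), period)


def delta_tau(orbit: LockedOrbit, forcing: ForcingSpec,
              q: int = 1) -> Tuple[float, Tuple[float, ...]]:
    """Input-to-inhibition timing factor(s) on a locked qT-periodic orbit.

    For each I-volley the preceding input peak is used; the timing is
    (t_inh - t_p)/T wrapped into [0, 1).  Returns (value for the tallest
    volley, per-volley tuple ordered by descending volley height)."""
    traj = orbit.trajectory
    T = orbit.period / q
    peaks_i = _volley_peaks(traj.t, traj.states[:, IDX_RI], orbit.period)
    if len(peaks_i) > 1:
        close = [p for p in peaks_i if abs(p[1] - peaks_i[0][1]) < 1e-12]
        if len(close) > 1:
            warnings.warn("multiple equal r_i maxima; using the earliest")
            peaks_i = sorted(close, key=lambda pv: pv[0]) + peaks_i[len(close):]
    tp_all = np.sort(np.concatenate(
        [_input_peak_times(inp, orbit.period) for inp in forcing.inputs]))
    vals = []
    for t_inh, _h in peaks_i:
        # preceding input peak (cyclically)
        diffs = np.mod(t_inh - tp_all, orbit.period)
        t_p = tp_all[int(np.argmin(diffs))]
        vals.append(float(np.mod((t_inh - t_p) / T, 1.0)))
    return vals[0], tuple(vals)


def _half_width(t: np.ndarray, r: np.ndarray, period: float) -> float:
    """Half of the distance between the two half-maximum crossings that
    flank the tallest volley; the level is (max + min)/2 of the trace."""
    rr = r[:-1].copy()
    tt = t[:-1]
    n = len(rr)
    level = 0.5 * (rr.max() + rr.min())
    i_max = int(np.argmax(rr))
    # walk left and right from the peak to the first level crossings
    def cross(direction: int) -> float:
        h = t[1] - t[0]
        i = i_max
        for _ in range(n):
            j = (i + direction) % n
            if rr[j] <= level:
                frac = (rr[i] - level) / (rr[i] - rr[j])
                return tt[i] + direction * frac * h
            i = j
        raise ValueError("no half-maximum crossing found")

    t1 = cross(-1)
    t2 = cross(+1)
    width = np.mod(t2 - t1, period)
    return 0.5 * float(width)


def response_factors(orbit: LockedOrbit, reference: LimitCycle,
                     forcing: ForcingSpec, q: int = 1) -> CTCFactors:
    """All four communication factors of a locked orbit relative to the
    unperturbed cycle."""
    traj = orbit.trajectory
    re = traj.states[:, IDX_RE]
    if np.ptp(re) == 0:
        raise ValueError("flat r_e trace on the orbit")
    re0 = reference["r_e"]

    mean_A = float(np.mean(re[:-1]))
    mean_0 = float(np.mean(re0[:-1]))
    d_abar = mean_A / mean_0

    peaks_A = _volley_peaks(traj.t, re, orbit.period)
    max_A = peaks_A[0][1]
    max_0 = _volley_peaks(reference.t, re0, reference.period)[0][1]
    d_alpha = max_A / max_0
    d_alpha_pv = tuple(h / max_0 for _tp, h in peaks_A)

    hw_A = _half_width(traj.t, re, orbit.period)
    hw_0 = _half_width(reference.t, re0, reference.period)
    d_sigma = (hw_A / orbit.period) / (hw_0 / reference.period)

    dt, dt_pv = delta_tau(orbit, forcing, q=q)
    return CTCFactors(delta_tau=dt, delta_alpha_bar=d_abar,
                      delta_alpha=d_alpha, delta_sigma=d_sigma,
                      delta_tau_per_volley=dt_pv,
                      delta_alpha_per_volley=d_alpha_pv)


def tongue_section_sweep(p: int, q: int, A_values: Sequence[float],
                         kappa: float, params: ModelParams,
                         cycle: LimitCycle, iprc: IPRC,
                         n_T: int = 10, edge_inset: float = 0.05,
                         ) -> pd.DataFrame:
    """Communication factors along constant-A sections of the p:q tongue.

    For each amplitude the phase-reduction plateau bounds the section; the
    interior is sampled on ``n_T`` points (inset from the edges by a
    fraction ``edge_inset`` of the width), the full-model locked orbit is
    computed at each, and unlocked points are recorded as missing rather
    than interpolated."""
    rows = []
    for A in A_values:
        # coarse edges suffice here: they only place the section samples
        edges = plateau_interval(iprc, A, kappa, p, q, step=0.01,
                                 refine_tol=1e-3, n_iter=500)
        if edges is None:
            continue
        lo, hi = edges
        w = hi - lo
        ratios = np.linspace(lo + edge_inset * w, hi - edge_inset * w, n_T)
        guess = None
        for r in ratios:
            T = r * cycle.period
            f = ForcingSpec(inputs=(VonMisesInput(A=A, T=T, kappa=kappa),))
            orb = full_model_locking(params, f, T, p, q, x_guess=guess,
                                     cycle=cycle, iprc=iprc)
            if orb.found and orb.stable:
                guess = orb.x0
                fac = response_factors(orb, cycle, f, q=q)
                rows.append((A, r, fac.delta_tau, fac.delta_alpha_bar,
                             fac.delta_alpha, fac.delta_sigma, True))
            else:
                guess = None
                rows.append((A, r, np.nan, np.nan, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["A", "T_over_Tstar", "dtau",
                                       "dalpha_bar", "dalpha", "dsigma",
                                       "locked"])
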