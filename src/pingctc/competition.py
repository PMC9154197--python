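"""Two-input experiments: distractor robustness, synchronisation indices,
distractor effects on the E-volley and pulse-induced switching.

A primary von Mises input entrains the network inside its 1:1 tongue and a
second (distractor) input competes with it.  With equal periods the
combined forcing is still periodic and the rotation number decides whether
entrainment survives; with unequal periods the time-T1 map of the phase
equation is no longer autonomous and the vector strength (Kuramoto order
parameter / synchronisation index) of its iterates is used instead, with
entrainment declared at r > 0.8.  Brief square pulses to the E-cells can
switch which of two identical antiphase streams the network attends to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .forcing import (ForcingSpec, SquarePulse, VonMisesInput,
                      arrange_two_inputs)
from .locking import StroboscopicMap, full_model_locking, rotation_number
from .meanfield import IDX_RE, IDX_RI, LimitCycle, ModelParams, integrate
from .phase import IPRC

__all__ = [
    "CompetitionSpec",
    "SwitchResult",
    "time_T1_map_phases",
    "vector_strength",
    "robustness_scan",
    "distractor_response_factors",
    "pulse_switch_prc",
]


@dataclass(frozen=True)
class CompetitionSpec:
    """A primary/distractor pair (distractor already placed by the
    antiphase / midpoint rule), with iterate count and the vector-strength
    threshold for declaring entrainment."""

    primary: VonMisesInput
    distractor: VonMisesInput
    n_iter: int = 1000
    threshold: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("robustness threshold must lie in (0, 1)")

    @property
    def forcing(self) -> ForcingSpec:
        return ForcingSpec(inputs=(self.primary, self.distractor))

    @classmethod
    def from_unplaced(cls, primary: VonMisesInput, distractor: VonMisesInput,
                      n_iter: int = 1000, threshold: float = 0.8
                      ) -> "CompetitionSpec":
        spec = arrange_two_inputs(primary, distractor)
        return cls(primary=spec.inputs[0], distractor=spec.inputs[1],
                   n_iter=n_iter, threshold=threshold)


def time_T1_map_phases(spec: CompetitionSpec, iprc: IPRC,
                       theta0: float = 0.0) -> np.ndarray:
    """Unwrapped phases of the time-T1 map over ``n_iter`` iterates.

    The phase equation with g = A1 p1 + A2 p2 is integrated continuously
    (the map is time-dependent when the periods differ, so there is no
    restart between iterates); the phase is recorded every T1.  Returns
    the lift including the initial phase (length n_iter + 1)."""
    m = StroboscopicMap(iprc, spec.forcing, spec.primary.T)
    return m.lift(theta0, spec.n_iter)


def vector_strength(angles: np.ndarray) -> float:
    """Modulus of the mean unit vector of the given phase angles
    (1 = perfectly clustered, 0 = uniformly scattered)."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("vector strength needs at least one phase")
    return float(np.abs(np.mean(np.exp(1j * angles))))


def synchronization_index(spec: CompetitionSpec, iprc: IPRC,
                          theta0: float = 0.0, burn_in: int = 0) -> float:
    """Vector strength of the time-T1 map phases, as angles 2*pi*theta/T*.

    ``burn_in`` iterates are discarded before the index is computed (0
    keeps every recorded phase)."""
    lift = time_T1_map_phases(spec, iprc, theta0)
    phases = lift[1 + burn_in:]
    return vector_strength(2.0 * np.pi * phases / iprc.period)


def robustness_scan(cycle: LimitCycle, iprc: IPRC, mode: str,
                    kappa2_values: Sequence[float],
                    ratio_values: Sequence[float],
                    T1_over_Tstar: Optional[float] = None,
                    kappa1: float = 2.0, A1: float = 0.1, A2: float = 0.1,
                    n_iter: int = 1000, burn_in: int = 100,
                    threshold: float = 0.8) -> pd.DataFrame:
    """Grid scan of entrainment robustness to a distractor.

    mode='equal'   : T2 = T1 = T, antiphase; ``ratio_values`` are T/T* and
                     the verdict is rho_hat = 1 (tol 1e-4) of the combined
                     T-periodic stroboscopic map.
    mode='unequal' : fixed T1 = T1_over_Tstar * T*; ``ratio_values`` are
                     T2/T1 and the verdict is vector strength > threshold
                     over ``n_iter`` time-T1 iterates (after ``burn_in``).
    """
    Tstar = cycle.period
    rows = []
    if mode == "equal":
        for r in ratio_values:
            T = r * Tstar
            for k2 in kappa2_values:
                f = arrange_two_inputs(
                    VonMisesInput(A=A1, T=T, kappa=kappa1),
                    VonMisesInput(A=A2, T=T, kappa=k2))
                m = StroboscopicMap(iprc, f, T)
                rho = rotation_number(m, n_iter=750).rho_hat
                rows.append((r, k2, rho, abs(rho - 1.0) < 1e-4))
        return pd.DataFrame(rows, columns=["T_over_Tstar", "kappa2",
                                           "rho_hat", "locked"])
    if mode == "unequal":
        if T1_over_Tstar is None:
            raise ValueError("unequal mode needs T1_over_Tstar")
        T1 = T1_over_Tstar * Tstar
        for r2 in ratio_values:
            for k2 in kappa2_values:
                spec = CompetitionSpec.from_unplaced(
                    VonMisesInput(A=A1, T=T1, kappa=kappa1),
                    VonMisesInput(A=A2, T=r2 * T1, kappa=k2),
                    n_iter=n_iter + burn_in, threshold=threshold)
                r = synchronization_index(spec, iprc, burn_in=burn_in)
                rows.append((r2, k2, r, r > threshold))
        return pd.DataFrame(rows, columns=["T2_over_T1", "kappa2",
                                           "vector_strength", "locked"])
    raise ValueError(f"unknown robustness mode {mode!r}")


# ----------------------------------------------------------------------
# distractor effects on the E-cell evoked response
# ----------------------------------------------------------------------

def _window_factors(t: np.ndarray, re: np.ndarray, T1: float,
                    ref_mean: float, ref_max: float, ref_hw_norm: float
                    ) -> Tuple[float, float, float]:
    """(Delta-alpha, Delta-sigma, Delta-alpha-bar) of one primary cycle."""
    d_abar = float(np.mean(re)) / ref_mean
    i = int(np.argmax(re))
    d_alpha = float(re[i]) / ref_max
    level = 0.5 * (re.max() + re.min())
    # crossings flanking the maximum, inside the window
    j = i
    while j > 0 and re[j] > level:
        j -= 1
    k = i
    while k < len(re) - 1 and re[k] > level:
        k += 1
    if re[j] > level or re[k] > level:
        return d_alpha, np.nan, d_abar
    h = t[1] - t[0]
    t1 = t[j] + h * (level - re[j]) / (re[j + 1] - re[j]) if re[j + 1] != re[j] else t[j]
    t2 = t[k - 1] + h * (re[k - 1] - level) / (re[k - 1] - re[k]) if re[k - 1] != re[k] else t[k]
    hw = 0.5 * (t2 - t1)
    d_sigma = (hw / T1) / ref_hw_norm
    return d_alpha, float(d_sigma), d_abar


def distractor_response_factors(params: ModelParams, cycle: LimitCycle,
                                primary: VonMisesInput,
                                distractor: VonMisesInput,
                                vary: str, values: Sequence[float],
                                n_cycles: int = 10, burn_cycles: int = 30,
                                rtol: float = 1e-8, atol: float = 1e-10
                                ) -> pd.DataFrame:
    """Mean and standard deviation of the E-volley response factors over
    ``n_cycles`` primary cycles while one amplitude is varied.

    ``vary`` is 'A1' or 'A2'; the other amplitude stays at its value in
    the supplied inputs.  The doubly forced full model is integrated past
    ``burn_cycles`` primary periods before the factors are measured, and
    each primary cycle is compared against the unperturbed cycle."""
    if vary not in ("A1", "A2"):
        raise ValueError("vary must be 'A1' or 'A2'")
    T1 = primary.T
    ref_re = cycle["r_e"]
    ref_mean = float(np.mean(ref_re[:-1]))
    ref_max = float(np.max(ref_re))
    from .ctc import _half_width

    ref_hw_norm = _half_width(cycle.t, ref_re, cycle.period) / cycle.period

    rows = []
    for v in values:
        p = VonMisesInput(A=v if vary == "A1" else primary.A, T=primary.T,
                          kappa=primary.kappa, mu=primary.mu)
        d = VonMisesInput(A=v if vary == "A2" else distractor.A,
                          T=distractor.T, kappa=distractor.kappa,
                          mu=distractor.mu)
        f = ForcingSpec(inputs=(p, d))
        x0 = cycle.samples[0]
        burn = integrate(x0, (0.0, burn_cycles * T1), params, f,
                         rtol=rtol, atol=atol)
        t0 = burn_cycles * T1
        n_per = 256
        t_eval = t0 + np.linspace(0.0, n_cycles * T1, n_cycles * n_per,
                                  endpoint=False)
        sol = integrate(burn.y[:, -1], (t0, t0 + n_cycles * T1), params, f,
                        t_eval=t_eval, rtol=rtol, atol=atol)
        re = sol.y[IDX_RE]
        da, ds, dab = [], [], []
        for k in range(n_cycles):
            seg = slice(k * n_per, (k + 1) * n_per)
            a, s, ab = _window_factors(sol.t[seg], re[seg], T1, ref_mean,
                                       ref_max, ref_hw_norm)
            da.append(a)
            ds.append(s)
            dab.append(ab)
        rows.append((v,
                     np.mean(da), np.std(da),
                     np.nanmean(ds), np.nanstd(ds),
                     np.mean(dab), np.std(dab)))
    return pd.DataFrame(rows, columns=[
        vary, "dalpha_mean", "dalpha_sd", "dsigma_mean", "dsigma_sd",
        "dalpha_bar_mean", "dalpha_bar_sd"])


# ----------------------------------------------------------------------
# pulse-induced switching between identical streams
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchResult:
    """Outcome of one square-pulse perturbation of the doubly entrained
    network."""

    pulse_phase: float       # t/T in [0, 1)
    prc: float               # (T0 - T1)/T0, positive = phase advance
    d_before: float
    d_after: float
    switched: bool
    entrained: bool = True


def _volley_times_events(params, forcing, x0, t_end, rtol, atol):
    """Times of r_e maxima along a forced trajectory (event detection),
    keeping only genuine volleys (peak rate above half the global max)."""
    P = params.as_array()
    fargs = forcing.kernel_args()

    def ev(t, y):
        return _kernels.mf_rhs(t, y, P, *fargs)[IDX_RE]

    ev.direction = -1.0
    sol = integrate(x0, (0.0, t_end), params, forcing, rtol=rtol, atol=atol,
                    events=ev, dense_output=True)
    tev = np.asarray(sol.t_events[0])
    if tev.size == 0:
        return tev, sol
    if hasattr(sol, "piece_sols"):
        def eval_at(tt):
            for ps in sol.piece_sols:
                if ps.t[0] - 1e-12 <= tt <= ps.t[-1] + 1e-12:
                    return ps.sol(tt)
            return sol.piece_sols[-1].sol(tt)
        heights = np.array([eval_at(tt)[IDX_RE] for tt in tev])
    else:
        heights = np.array([sol.sol(tt)[IDX_RE] for tt in tev])
    # genuine volleys: above half the *typical* height (the pulse itself
    # can transiently overshoot the volleys severalfold)
    keep = heights > 0.5 * np.median(heights)
    return tev[keep], sol


def _d_signature(t_e: float, T: float) -> float:
    """Signed distance difference (Eq-style switch detector): distances
    from an E-volley at t_e to the preceding peaks of input 1 (at 0 mod T)
    and input 2 (at T/2 mod T), d = (t_e - tp1) - (t_e - tp2)."""
    tp1 = t_e - np.mod(t_e, T)                 # last input-1 peak <= t_e
    tp2 = t_e - np.mod(t_e - T / 2.0, T)       # last input-2 peak <= t_e
    return float((t_e - tp1) - (t_e - tp2))


def pulse_switch_prc(params: ModelParams, cycle: LimitCycle, iprc: IPRC,
                     phase_grid: Optional[np.ndarray] = None,
                     kappa: float = 2.0, A: float = 0.1,
                     T_over_Tstar: float = 0.84,
                     pulse: Optional[SquarePulse] = None,
                     relax_periods: int = 30,
                     rtol: float = 1e-9, atol: float = 1e-11
                     ) -> List[SwitchResult]:
    """Square-pulse phase response and switching detector for a network
    entrained by two identical antiphase streams.

    The base state is the stable T-periodic orbit with two equal von Mises
    inputs (mu1 = 0, mu2 = T/2).  For each pulse phase t/T the pulse is
    applied to the E-cell voltage, the PRC is read from the shortening of
    the cycle containing the pulse, and the before/after signed distance
    between the E-volley and the two input peaks decides whether the
    network switched its effective input (sign change after
    ``relax_periods`` base periods of relaxation)."""
    if phase_grid is None:
        phase_grid = np.linspace(0.0, 1.0, 21, endpoint=False)
    T = T_over_Tstar * cycle.period
    f0 = arrange_two_inputs(VonMisesInput(A=A, T=T, kappa=kappa),
                            VonMisesInput(A=A, T=T, kappa=kappa))
    orbit = full_model_locking(params, f0, T, 1, 1, cycle=cycle, iprc=iprc)
    if not orbit.found:
        raise RuntimeError("no entrained base orbit for the switching run")

    # reference E-volley timing of the unpulsed orbit
    tev0, _ = _volley_times_events(params, f0, orbit.x0, 4 * T, rtol, atol)
    d_base = _d_signature(tev0[-1], T)
    T0 = T
    # primary = the input whose peak most closely precedes the E-volley;
    # pulse phases are measured within the primary's cycle
    t_e = float(np.mod(tev0[-1], T))
    primary_offset = 0.0 if np.mod(t_e, T) < np.mod(t_e - T / 2.0, T) else T / 2.0

    results: List[SwitchResult] = []
    wait = 3  # whole periods before the pulse
    amp = pulse.amplitude if pulse is not None else 1.5
    dur = pulse.duration if pulse is not None else 2.0
    for s in phase_grid:
        onset = (wait + s) * T + primary_offset
        t_end = onset + (relax_periods + 6) * T
        fp = ForcingSpec(inputs=f0.inputs,
                         pulse=SquarePulse(amplitude=amp, duration=dur,
                                           onset=onset))
        tev, _sol = _volley_times_events(params, fp, orbit.x0, t_end,
                                         rtol, atol)
        before = tev[tev <= onset]
        after = tev[tev > onset]
        if len(before) < 1 or len(after) < 3:
            results.append(SwitchResult(s, np.nan, np.nan, np.nan, False,
                                        entrained=False))
            continue
        T1 = after[0] - before[-1]
        prc = (T0 - T1) / T0
        d_bf = d_base
        d_af = _d_signature(after[-1], T)
        # entrainment after relaxation: inter-volley interval back to T0
        tail = np.diff(after[-3:])
        entrained = bool(np.all(np.abs(tail - T0) < 0.05 * T0))
        switched = bool(np.sign(d_bf * d_af) == -1.0) and entrained
        results.append(SwitchResult(float(s), float(prc), float(d_bf),
                                    float(d_af), switched, entrained))
    return results
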