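"""Exact E-I mean-field model of a PING gamma network.

The model is the exact (thermodynamic-limit) firing-rate reduction of a
network of quadratic integrate-and-fire neurons with Lorentzian-distributed
bias currents: four variables per population — mean rate r, mean voltage V
and the two incoming synaptic currents — giving an 8-dimensional system

    tau_a dr_a/dt = Delta_a/(pi tau_a) + 2 r_a V_a,
    tau_a dV_a/dt = V_a^2 + eta_a + I_a - (tau_a pi r_a)^2,
    tau_sb dS_ab/dt = -S_ab + J_ab r_b,        a, b in {e, i},

with I_a = Ibar_a^ext + tau_a g(t) + tau_a (S_a-exc - S_a-inh).  Time is in
ms, rates in spikes/ms, voltages dimensionless.  For suitable tonic drives
the system has a stable limit cycle: the PING gamma oscillator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, root

from . import _kernels
from .forcing import ForcingSpec, NO_FORCING

__all__ = [
    "STATE_NAMES",
    "ModelParams",
    "Trajectory",
    "LimitCycle",
    "Equilibrium",
    "rhs_meanfield",
    "jacobian_meanfield",
    "integrate",
    "find_limit_cycle",
    "integral_mean_rates",
    "ei_latency",
    "find_equilibria",
    "hopf_crossing",
]

STATE_NAMES = ("r_e", "V_e", "S_ee", "S_ei", "r_i", "V_i", "S_ie", "S_ii")

IDX_RE, IDX_VE, IDX_SEE, IDX_SEI, IDX_RI, IDX_VI, IDX_SIE, IDX_SII = range(8)

#: default initial state used when none is supplied (small positive rates)
DEFAULT_STATE = np.array([0.05, -1.0, 0.0, 0.0, 0.05, -1.0, 0.0, 0.0])


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the 8-D mean-field model.

    The defaults are the reference parameter set used throughout: equal
    membrane constants tau = 8 ms, unit Lorentzian half-widths, centers
    eta = -5, AMPA/GABA_A synaptic constants 1 ms / 5 ms, no recurrent
    self-coupling and cross-coupling strength 13, with tonic drives
    Ie_ext_bar = 10, Ii_ext_bar = 0 (the reference gamma oscillator).
    """

    tau_e: float = 8.0
    tau_i: float = 8.0
    delta_e: float = 1.0
    delta_i: float = 1.0
    eta_e: float = -5.0
    eta_i: float = -5.0
    tau_se: float = 1.0
    tau_si: float = 5.0
    J_ee: float = 0.0
    J_ei: float = 13.0
    J_ie: float = 13.0
    J_ii: float = 0.0
    Ie_ext_bar: float = 10.0
    Ii_ext_bar: float = 0.0

    def __post_init__(self) -> None:
        for name in ("tau_e", "tau_i", "tau_se", "tau_si"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delta_e <= 0 or self.delta_i <= 0:
            raise ValueError("Lorentzian half-widths must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([
            self.tau_e, self.tau_i, self.delta_e, self.delta_i,
            self.eta_e, self.eta_i, self.tau_se, self.tau_si,
            self.J_ee, self.J_ei, self.J_ie, self.J_ii,
            self.Ie_ext_bar, self.Ii_ext_bar,
        ])

    def with_drives(self, Ie: Optional[float] = None,
                    Ii: Optional[float] = None) -> "ModelParams":
        kw = {}
        if Ie is not None:
            kw["Ie_ext_bar"] = Ie
        if Ii is not None:
            kw["Ii_ext_bar"] = Ii
        return replace(self, **kw)


def rhs_meanfield(state: np.ndarray, t: float, params: ModelParams,
                  forcing: ForcingSpec = NO_FORCING) -> np.ndarray:
    """Time derivative of the 8 mean-field coordinates at time t.

    The periodic drive enters dV/dt directly: the external current is
    Ibar + tau*g(t), and the tau cancels the membrane constant dividing
    the voltage equation.
    """
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite mean-field state (blow-up?)")
    fargs = forcing.kernel_args()
    return _kernels.mf_rhs(float(t), state, params.as_array(), *fargs)


def jacobian_meanfield(state: np.ndarray, params: ModelParams) -> np.ndarray:
    """Analytic Jacobian of the vector field (forcing is additive)."""
    return _kernels.mf_jac(np.asarray(state, dtype=float), params.as_array())


@dataclass
class Trajectory:
    """A sampled solution of the mean-field system."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), 8)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            np.column_stack([self.t, self.states]),
            columns=("t",) + STATE_NAMES,
        )


def _split_times(t0: float, t1: float, forcing: ForcingSpec) -> List[float]:
    """Break points where the square pulse switches, to keep the
    integrator away from the discontinuity."""
    pts = [t0, t1]
    if forcing.pulse is not None:
        for edge in (forcing.pulse.onset, forcing.pulse.onset + forcing.pulse.duration):
            if t0 < edge < t1:
                pts.append(edge)
    return sorted(set(pts))


def integrate(initial: np.ndarray, t_span: Tuple[float, float],
              params: ModelParams, forcing: ForcingSpec = NO_FORCING,
              t_eval: Optional[np.ndarray] = None,
              rtol: float = 1e-10, atol: float = 1e-12,
              events: Optional[Callable] = None,
              dense_output: bool = False):
    """Integrate the mean-field system with an explicit RK45 scheme.

    Returns the scipy OdeResult (fields t, y, optional sol and t_events).
    A zero-length span returns the initial state unchanged.  The time
    span is split at square-pulse edges so the discontinuous drive never
    degrades the error control.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not (np.isfinite(t0) and np.isfinite(t1)):
        raise ValueError("t_span must be finite")
    y0 = np.asarray(initial, dtype=float).copy()
    if y0.shape != (8,):
        raise ValueError("initial state must have 8 components")

    P = params.as_array()
    fargs = forcing.kernel_args()

    def f(t, y):
        return _kernels.mf_rhs(t, y, P, *fargs)

    if t1 == t0:
        class _Zero:
            pass

        res = _Zero()
        res.t = np.array([t0])
        res.y = y0[:, None]
        res.success = True
        return res

    pieces = _split_times(t0, t1, forcing)
    ts: List[np.ndarray] = []
    ys: List[np.ndarray] = []
    sols = []
    all_events: List[np.ndarray] = []
    y = y0
    for a, b in zip(pieces[:-1], pieces[1:]):
        te = None
        if t_eval is not None:
            mask = (t_eval >= a) & (t_eval <= b) if b == pieces[-1] else \
                (t_eval >= a) & (t_eval < b)
            te = t_eval[mask]
            if te.size == 0:
                te = None
        sol = solve_ivp(f, (a, b), y, method="RK45", rtol=rtol, atol=atol,
                        t_eval=te, events=events, dense_output=dense_output)
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        if not np.all(np.isfinite(sol.y)):
            raise FloatingPointError("trajectory blew up (non-finite state)")
        y = sol.y[:, -1] if sol.y.size else y
        # when t_eval filtered everything out we still need the end state
        if sol.y.size == 0:
            tail = solve_ivp(f, (a, b), y, method="RK45", rtol=rtol, atol=atol)
            y = tail.y[:, -1]
        ts.append(sol.t)
        ys.append(sol.y)
        sols.append(sol)
        if events is not None and sol.t_events:
            all_events.append(sol.t_events[0])

    out = sols[-1]
    out.t = np.concatenate(ts) if ts else np.array([t0])
    out.y = np.concatenate(ys, axis=1) if ys else y0[:, None]
    if events is not None:
        out.t_events = [np.concatenate(all_events) if all_events else np.empty(0)]
    if dense_output and len(sols) > 1:
        out.piece_sols = sols
    return out


def integrate_trajectory(initial, t_span, params,
                         forcing: ForcingSpec = NO_FORCING, n_samples: int = 2000,
                         rtol: float = 1e-10, atol: float = 1e-12) -> Trajectory:
    """Convenience wrapper returning a uniformly sampled ``Trajectory``."""
    t_eval = np.linspace(t_span[0], t_span[1], n_samples)
    sol = integrate(initial, t_span, params, forcing, t_eval=t_eval,
                    rtol=rtol, atol=atol)
    return Trajectory(t=sol.t, states=sol.y.T)


# ----------------------------------------------------------------------
# limit cycles
# ----------------------------------------------------------------------

@dataclass
class LimitCycle:
    """A converged periodic orbit, sampled uniformly over one period.

    ``samples`` has ``n+1`` rows including the repeated endpoint; index 0
    (phase 0) is the maximum of the mean excitatory voltage V_e.
    """

    t: np.ndarray
    samples: np.ndarray
    period: float
    params: ModelParams
    multipliers: Optional[np.ndarray] = None
    _splines: Optional[list] = field(default=None, repr=False)

    @property
    def period_T_star(self) -> float:
        return self.period

    @property
    def phase_origin(self) -> int:
        return 0

    @property
    def stable(self) -> bool:
        if self.multipliers is None:
            return True
        nontrivial = np.sort(np.abs(self.multipliers))[:-1]
        return bool(np.all(nontrivial < 1.0))

    def __getitem__(self, name: str) -> np.ndarray:
        return self.samples[:, STATE_NAMES.index(name)]

    def splines(self) -> list:
        """Periodic cubic splines, one per coordinate."""
        if self._splines is None:
            self._splines = [
                CubicSpline(self.t, self.samples[:, i], bc_type="periodic")
                for i in range(8)
            ]
        return self._splines

    def state_at(self, t) -> np.ndarray:
        tt = np.mod(t, self.period)
        sp = self.splines()
        return np.stack([s(tt) for s in sp], axis=-1)

    def deriv_at(self, t) -> np.ndarray:
        """Vector field along the cycle (gamma'(t))."""
        return np.apply_along_axis(
            lambda x: rhs_meanfield(x, 0.0, self.params), -1, self.state_at(t)
        )

    def spline_coeffs(self) -> Tuple[np.ndarray, float, int]:
        """(8, 4, n) coefficient block for the jitted evaluators."""
        sp = self.splines()
        n = len(self.t) - 1
        c8 = np.stack([s.c for s in sp], axis=0)
        h = self.t[1] - self.t[0]
        return np.ascontiguousarray(c8), h, n


def _ve_max_event(P, fargs):
    def ev(t, y):
        # dV_e/dt; zero crossings falling => V_e maximum
        return _kernels.mf_rhs(t, y, P, *fargs)[IDX_VE]

    ev.direction = -1.0
    return ev


def find_limit_cycle(params: ModelParams,
                     initial: Optional[np.ndarray] = None,
                     n_samples: int = 1024,
                     transient_periods: int = 50,
                     amp_threshold: float = 1e-4,
                     rtol: float = 1e-10, atol: float = 1e-12,
                     refine: bool = True) -> Optional[LimitCycle]:
    """Locate the stable limit cycle of the unforced system.

    Integrates past a transient of ``transient_periods`` putative periods,
    detects V_e maxima by event location, declares an oscillation when the
    V_e peak-to-trough over the last five putative periods exceeds
    ``amp_threshold``, and polishes period and anchor point with a Newton
    shooting step on the Poincare section {dV_e/dt = 0, V_e falling}.

    Returns None when the trajectory settles to equilibrium ("no cycle"),
    so parameter sweeps can proceed without exception handling.
    """
    y0 = DEFAULT_STATE.copy() if initial is None else np.asarray(initial, float)
    P = params.as_array()
    fargs = NO_FORCING.kernel_args()
    ev = _ve_max_event(P, fargs)

    def global_maxima(sol, times):
        """Keep only events near the global V_e maximum; V_e can carry a
        secondary (clearly lower) local maximum within one cycle."""
        if len(times) == 0:
            return times
        ve = np.array([sol.sol(s)[IDX_VE] for s in times])
        swing = np.ptp(sol.y[IDX_VE])  # full V_e range of the trajectory
        return times[ve > ve.max() - 0.25 * max(swing, 1e-12)]

    # pilot run to estimate the period
    sol = integrate(y0, (0.0, 400.0), params, rtol=rtol, atol=atol,
                    events=ev, dense_output=True)
    tev = sol.t_events[0]
    tev = global_maxima(sol, tev[tev > 200.0])
    if len(tev) < 4:
        return None
    T0 = float(np.mean(np.diff(tev[-4:])))

    # discard a transient of `transient_periods` periods
    t_end = transient_periods * T0 + 5 * T0
    sol = integrate(sol.y[:, -1], (0.0, t_end), params, rtol=rtol, atol=atol,
                    events=ev, dense_output=True)
    tev = sol.t_events[0]
    tev = global_maxima(sol, tev[tev > t_end - 6 * T0])
    if len(tev) < 3:
        return None
    T0 = float(np.mean(np.diff(tev)))

    # amplitude over the last five putative periods
    tt = np.linspace(t_end - 5 * T0, t_end, 600)
    ve = np.array([sol.sol(s)[IDX_VE] for s in tt]) if hasattr(sol, "sol") and sol.sol else None
    if ve is None:
        samp = integrate(sol.y[:, -1], (0.0, 5 * T0), params, rtol=rtol,
                         atol=atol, t_eval=np.linspace(0, 5 * T0, 600))
        ve = samp.y[IDX_VE]
    if np.ptp(ve) < amp_threshold:
        return None

    # state on the section at the last V_e maximum
    x_sec = sol.sol(tev[-1]) if hasattr(sol, "sol") and sol.sol else sol.y[:, -1]

    period = T0
    x0 = np.asarray(x_sec, dtype=float)

    if refine:
        x0, period = _newton_polish_cycle(x0, period, params, rtol=rtol, atol=atol)

    # sample one period starting exactly at the V_e maximum
    t_samp = np.linspace(0.0, period, n_samples + 1)
    sol = integrate(x0, (0.0, period), params, rtol=rtol, atol=atol,
                    t_eval=t_samp)
    samples = sol.y.T.copy()
    # enforce exact periodicity of the stored samples for the splines
    samples[-1] = samples[0]

    mult = _floquet_multipliers(x0, period, params, rtol=rtol, atol=atol)

    return LimitCycle(t=t_samp, samples=samples, period=period, params=params,
                      multipliers=mult)


def _newton_polish_cycle(x0, T0, params, rtol=1e-10, atol=1e-12):
    """Newton shooting for (x0, T): periodicity plus the section condition
    dV_e/dt(x0) = 0 anchoring phase 0 at the V_e maximum."""
    P = params.as_array()
    fargs = NO_FORCING.kernel_args()

    def F(w):
        x = w[:8]
        T = w[8]
        sol = integrate(x, (0.0, T), params, rtol=rtol, atol=atol)
        res = np.empty(9)
        res[:8] = sol.y[:, -1] - x
        res[8] = _kernels.mf_rhs(0.0, x, P, *fargs)[IDX_VE]
        return res

    w = np.concatenate([x0, [T0]])
    sol = root(F, w, method="hybr", options={"xtol": 1e-12})
    if sol.success and abs(sol.x[8] - T0) < 0.2 * T0:
        return sol.x[:8].copy(), float(sol.x[8])
    return x0, T0


def _floquet_multipliers(x0, T, params, rtol=1e-10, atol=1e-12):
    """Eigenvalues of the monodromy matrix over one period."""
    P = params.as_array()
    fargs = NO_FORCING.kernel_args()

    def f(t, y):
        return _kernels.mf_rhs_var(t, y, P, *fargs)

    y0 = np.concatenate([x0, np.eye(8).ravel()])
    sol = solve_ivp(f, (0.0, T), y0, method="RK45", rtol=rtol, atol=atol)
    M = sol.y[8:, -1].reshape(8, 8)
    return np.linalg.eigvals(M)


def integral_mean_rates(cycle: LimitCycle,
                        n: Optional[int] = None) -> Tuple[float, float]:
    """Time-averaged firing rates (R_e, R_i) over one period.

    Periodic trapezoid rule on the uniform samples (spectrally accurate
    for smooth periodic integrands); pass ``n`` to resample the stored
    splines on a different grid.
    """
    if n is None:
        re = cycle["r_e"][:-1]
        ri = cycle["r_i"][:-1]
    else:
        tt = np.linspace(0.0, cycle.period, n, endpoint=False)
        st = cycle.state_at(tt)
        re = st[:, IDX_RE]
        ri = st[:, IDX_RI]
    return float(np.mean(re)), float(np.mean(ri))


def _refine_peak(spline: CubicSpline, t_guess: float, period: float) -> float:
    """Locate a maximum of a periodic spline near t_guess via its
    derivative root (sub-sample accuracy)."""
    d = spline.derivative()
    h = period / 50.0
    a, b = t_guess - h, t_guess + h
    fa, fb = d(np.mod(a, period)), d(np.mod(b, period))
    if fa > 0 > fb:
        try:
            return brentq(lambda s: d(np.mod(s, period)), a, b, xtol=1e-10)
        except ValueError:
            pass
    return t_guess


def peak_time(t: np.ndarray, values: np.ndarray, period: float) -> float:
    """Time of the maximum of a sampled periodic signal, refined by a
    periodic-spline derivative root."""
    if np.ptp(values) == 0:
        raise ValueError("flat trace has no unique maximum")
    vals = values.copy()
    vals[-1] = vals[0]
    sp = CubicSpline(t, vals, bc_type="periodic")
    i = int(np.argmax(vals[:-1]))
    return float(np.mod(_refine_peak(sp, t[i], period), period))


def ei_latency(cycle: LimitCycle) -> Tuple[float, float]:
    """I-to-E latency: time from the r_e maximum to the r_i maximum,
    wrapped into [0, T*), and the same normalised by the period."""
    t_e = peak_time(cycle.t, cycle["r_e"], cycle.period)
    t_i = peak_time(cycle.t, cycle["r_i"], cycle.period)
    lat = float(np.mod(t_i - t_e, cycle.period))
    return lat, lat / cycle.period


# ----------------------------------------------------------------------
# equilibria and Hopf detection
# ----------------------------------------------------------------------

@dataclass
class Equilibrium:
    state: np.ndarray
    eigenvalues: np.ndarray
    residual: float

    @property
    def stable(self) -> bool:
        return bool(np.all(self.eigenvalues.real < 0))

    @property
    def leading_pair(self) -> complex:
        """Complex eigenvalue with the largest real part among those with
        nonzero imaginary part (the candidate Hopf pair)."""
        cplx = self.eigenvalues[np.abs(self.eigenvalues.imag) > 1e-12]
        if cplx.size == 0:
            return complex(np.max(self.eigenvalues.real), 0.0)
        return complex(cplx[np.argmax(cplx.real)])


def _equilibrium_residual(re_ri, params: ModelParams) -> np.ndarray:
    """Reduced 2-D equilibrium conditions in (r_e, r_i).

    At equilibrium the synapses satisfy S_ab = J_ab r_b and the rate
    equations give V_a = -Delta_a/(2 pi tau_a r_a); substituting into the
    voltage equations leaves two equations in the two rates.
    """
    re, ri = re_ri
    p = params
    if re <= 0 or ri <= 0:
        return np.array([1e6, 1e6])
    Ve = -p.delta_e / (2.0 * np.pi * p.tau_e * re)
    Vi = -p.delta_i / (2.0 * np.pi * p.tau_i * ri)
    f1 = (Ve ** 2 + p.eta_e + p.Ie_ext_bar
          + p.tau_e * (p.J_ee * re - p.J_ei * ri)
          - (p.tau_e * np.pi * re) ** 2)
    f2 = (Vi ** 2 + p.eta_i + p.Ii_ext_bar
          + p.tau_i * (p.J_ie * re - p.J_ii * ri)
          - (p.tau_i * np.pi * ri) ** 2)
    return np.array([f1, f2])


def find_equilibria(params: ModelParams,
                    seeds: Optional[Sequence[Tuple[float, float]]] = None,
                    ) -> List[Equilibrium]:
    """All equilibria found from a grid of (r_e, r_i) seeds.

    Each equilibrium carries the eigenvalues of the full 8-D Jacobian;
    duplicates (within 1e-8 in the rates) are merged.
    """
    if seeds is None:
        grid = [1e-3, 1e-2, 0.05, 0.2, 1.0]
        seeds = [(a, b) for a in grid for b in grid]
    found: List[Equilibrium] = []
    for s in seeds:
        sol = root(_equilibrium_residual, np.asarray(s, float),
                   args=(params,), method="hybr", options={"xtol": 1e-13})
        if not sol.success:
            continue
        re, ri = sol.x
        if re <= 0 or ri <= 0:
            continue
        if any(abs(re - e.state[IDX_RE]) < 1e-8 and
               abs(ri - e.state[IDX_RI]) < 1e-8 for e in found):
            continue
        p = params
        state = np.array([
            re, -p.delta_e / (2 * np.pi * p.tau_e * re),
            p.J_ee * re, p.J_ei * ri,
            ri, -p.delta_i / (2 * np.pi * p.tau_i * ri),
            p.J_ie * re, p.J_ii * ri,
        ])
        resid = float(np.linalg.norm(rhs_meanfield(state, 0.0, params)))
        eig = np.linalg.eigvals(jacobian_meanfield(state, params))
        found.append(Equilibrium(state=state, eigenvalues=eig, residual=resid))
    return found


def hopf_crossing(param_of: Callable[[float], ModelParams],
                  lo: float, hi: float, tol: float = 1e-6) -> Tuple[float, float]:
    """Locate a Hopf bifurcation along a one-parameter family by bisection
    on the real part of the leading complex eigenvalue pair.

    ``param_of`` maps the scalar sweep parameter to ModelParams.  Returns
    (parameter value, |imaginary part| at the crossing).
    """

    def lead_real(c: float) -> float:
        eqs = find_equilibria(param_of(c))
        if not eqs:
            raise RuntimeError(f"no equilibrium at sweep value {c}")
        # track the equilibrium whose leading pair is closest to crossing
        return max(e.leading_pair.real for e in eqs)

    flo, fhi = lead_real(lo), lead_real(hi)
    if flo * fhi > 0:
        raise ValueError("no sign change of the leading eigenvalue pair "
                         "between the sweep endpoints")
    a, b = lo, hi
    while b - a > tol:
        m = 0.5 * (a + b)
        fm = lead_real(m)
        if fm * flo <= 0:
            b = m
        else:
            a, flo = m, fm
    c = 0.5 * (a + b)
    eqs = find_equilibria(param_of(c))
    pair = max((e.leading_pair for e in eqs), key=lambda z: z.real)
    return c, abs(pair.imag)
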