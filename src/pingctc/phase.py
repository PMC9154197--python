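"""Phase reduction of the PING oscillator: adjoint iPRC and phase equation.

For a hyperbolic stable limit cycle gamma(t) of period T*, the phase of a
weakly forced oscillator obeys

    d theta / dt = 1 + g(t) * (Z_Ve(theta) + Z_Vi(theta)),

where Z is the infinitesimal phase response curve — the T*-periodic
solution of the adjoint equation dZ/dt = -M(gamma(t))^T Z normalised by
Z(t) . gamma'(t) = 1, with M the Jacobian of the vector field along the
cycle.  The adjoint is solved here by backward-time integration, which
makes its periodic solution attracting, and the iPRC is stored on a
uniform grid of phases with periodic cubic-spline interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from . import _kernels
from .forcing import ForcingSpec
from .meanfield import (IDX_VE, IDX_VI, LimitCycle, jacobian_meanfield,
                        rhs_meanfield)

__all__ = [
    "IPRC",
    "linearize_along_cycle",
    "solve_adjoint",
    "iprc_derivative_fft",
    "phase_ode_rhs",
    "direct_phase_shift",
]


def linearize_along_cycle(cycle: LimitCycle, phase: float) -> np.ndarray:
    """Analytic 8x8 Jacobian of the vector field evaluated on the cycle."""
    return jacobian_meanfield(cycle.state_at(phase), cycle.params)


def iprc_derivative_fft(values: np.ndarray, period: float) -> np.ndarray:
    """Spectral derivative of a periodic signal sampled on a uniform,
    endpoint-exclusive grid."""
    n = len(values)
    freqs = np.fft.fftfreq(n, d=period / n)
    return np.real(np.fft.ifft(np.fft.fft(values) * (2j * np.pi * freqs)))


def _periodic_coeffs(theta: np.ndarray, values: np.ndarray,
                     period: float) -> np.ndarray:
    """Periodic cubic-spline coefficients on the closed grid (shape (4, n))."""
    t_closed = np.append(theta, period)
    v_closed = np.append(values, values[0])
    return np.ascontiguousarray(CubicSpline(t_closed, v_closed,
                                            bc_type="periodic").c)


@dataclass
class IPRC:
    """The 8-component infinitesimal phase response curve of a limit cycle.

    Sampled on ``n`` uniform phases over [0, T*); phase 0 is the V_e
    maximum.  ``Z_ei = Z_Ve + Z_Vi`` is the sensitivity to a common drive
    on both voltage equations; its spectral derivative feeds the
    variational equation of the phase ODE.
    """

    theta: np.ndarray
    Z: np.ndarray  # (n, 8)
    period: float
    normalization_residual: float = 0.0
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def Z_Ve(self) -> np.ndarray:
        return self.Z[:, IDX_VE]

    @property
    def Z_Vi(self) -> np.ndarray:
        return self.Z[:, IDX_VI]

    @property
    def Z_ei(self) -> np.ndarray:
        return self.Z_Ve + self.Z_Vi

    def effective_samples(self, drive_e: bool = True,
                          drive_i: bool = True) -> np.ndarray:
        return (self.Z_Ve if drive_e else 0.0) + (self.Z_Vi if drive_i else 0.0)

    def zeff_coeffs(self, drive_e: bool = True, drive_i: bool = True
                    ) -> Tuple[np.ndarray, float, int]:
        """Spline coefficients of the effective iPRC for the jitted
        integrators: (coeffs, breakpoint spacing, n)."""
        key = ("z", drive_e, drive_i)
        if key not in self._cache:
            vals = np.asarray(self.effective_samples(drive_e, drive_i), float)
            self._cache[key] = _periodic_coeffs(self.theta, vals, self.period)
        n = len(self.theta)
        return self._cache[key], self.period / n, n

    def dzeff_coeffs(self, drive_e: bool = True, drive_i: bool = True
                     ) -> Tuple[np.ndarray, float, int]:
        """Spline coefficients of the FFT derivative of the effective iPRC."""
        key = ("dz", drive_e, drive_i)
        if key not in self._cache:
            vals = np.asarray(self.effective_samples(drive_e, drive_i), float)
            dvals = iprc_derivative_fft(vals, self.period)
            self._cache[key] = _periodic_coeffs(self.theta, dvals, self.period)
        n = len(self.theta)
        return self._cache[key], self.period / n, n

    def interp(self, component, phases):
        """Periodic interpolation of one component ('Z_ei', 'Z_Ve', 'Z_Vi'
        or a column index) at arbitrary phases."""
        if component == "Z_ei":
            vals = self.Z_ei
        elif component == "Z_Ve":
            vals = self.Z_Ve
        elif component == "Z_Vi":
            vals = self.Z_Vi
        else:
            vals = self.Z[:, int(component)]
        key = ("interp", component)
        if key not in self._cache:
            t_closed = np.append(self.theta, self.period)
            v_closed = np.append(vals, vals[0])
            self._cache[key] = CubicSpline(t_closed, v_closed, bc_type="periodic")
        return self._cache[key](np.mod(phases, self.period))

    def to_frame(self):
        import pandas as pd

        from .meanfield import STATE_NAMES

        data = {"theta_norm": self.theta / self.period}
        for i, nm in enumerate(STATE_NAMES):
            data[f"Z_{nm}"] = self.Z[:, i]
        data["Z_ei"] = self.Z_ei
        return pd.DataFrame(data)


def solve_adjoint(cycle: LimitCycle, n_grid: int = 1024,
                  min_periods: int = 5, max_periods: int = 80,
                  tol: float = 1e-8,
                  rtol: float = 1e-11, atol: float = 1e-13) -> IPRC:
    """Compute the iPRC by backward integration of the adjoint equation.

    Backward in time the periodic adjoint solution is attracting (the
    decaying Floquet modes of the forward flow become decaying again),
    so plain integration over a handful of periods converges; successive
    periods are compared until the change drops below ``tol``, then the
    solution is rescaled so that Z . gamma' = 1 at phase 0 and the
    normalisation is verified at every grid point.
    """
    T = cycle.period
    P = cycle.params.as_array()
    gc, gh, gn = cycle.spline_coeffs()

    def f(s, Z):
        return _kernels.adjoint_rhs(s, Z, gc, gh, gn, T, P)

    # initial guess: unit vector along gamma'(0)
    gp0 = rhs_meanfield(cycle.samples[0], 0.0, cycle.params)
    Z = gp0 / float(gp0 @ gp0)

    prev = Z.copy()
    k = 0
    while k < max_periods:
        sol = solve_ivp(f, (k * T, (k + 1) * T), Z, method="RK45",
                        rtol=rtol, atol=atol)
        Z = sol.y[:, -1]
        k += 1
        change = np.linalg.norm(Z - prev) / max(np.linalg.norm(Z), 1e-300)
        prev = Z.copy()
        if k >= min_periods and change < tol:
            break
    else:
        raise RuntimeError("adjoint iteration did not converge")

    # sample the converged periodic solution on the phase grid:
    # Z(theta_j) corresponds to backward time s = (k+1)*T - theta_j
    theta = np.linspace(0.0, T, n_grid, endpoint=False)
    s_targets = (k + 1) * T - theta  # descending in theta
    order = np.argsort(s_targets)
    sol = solve_ivp(f, (k * T, (k + 1) * T), Z, method="RK45",
                    rtol=rtol, atol=atol, t_eval=s_targets[order])
    Zgrid = np.empty((n_grid, 8))
    Zgrid[order, :] = sol.y.T  # row i of sol is theta index order[i]

    # normalise by Z . gamma' at phase 0
    gp = cycle.deriv_at(theta)
    c0 = float(Zgrid[0] @ gp[0])
    if abs(c0) < 1e-14:
        raise RuntimeError("degenerate normalization in adjoint solve")
    Zgrid = Zgrid / c0
    resid = float(np.max(np.abs(np.einsum("ij,ij->i", Zgrid, gp) - 1.0)))

    return IPRC(theta=theta, Z=Zgrid, period=T,
                normalization_residual=resid)


def phase_ode_rhs(theta: float, t: float, iprc: IPRC,
                  forcing: ForcingSpec) -> float:
    """Scalar phase equation d theta/dt = 1 + g(t) * Z_eff(theta).

    For drive on both populations Z_eff = Z_Ve + Z_Vi; for E-only forcing
    only Z_Ve enters (the perturbation direction selects the iPRC
    components)."""
    g = float(forcing.g(t))
    zeff = 0.0
    if forcing.drive_e:
        zeff += float(iprc.interp("Z_Ve", theta))
    if forcing.drive_i:
        zeff += float(iprc.interp("Z_Vi", theta))
    return 1.0 + g * zeff


def direct_phase_shift(cycle: LimitCycle, component: int, eps: float,
                       phase: float, n_periods: int = 20,
                       rtol: float = 1e-11, atol: float = 1e-13) -> float:
    """Asymptotic phase shift caused by a small instantaneous kick.

    Applies ``eps`` to one state component at the given phase, integrates
    until the trajectory has relaxed back to the cycle and measures the
    asymptotic shift from the timing of V_e maxima; shift/eps converges to
    the corresponding iPRC component as eps -> 0.  Positive = advance.
    """
    from .meanfield import integrate

    T = cycle.period
    y0 = cycle.state_at(phase).copy()
    y0[component] += eps
    P = cycle.params.as_array()
    fargs = ForcingSpec().kernel_args()

    def ev(t, y):
        return _kernels.mf_rhs(t, y, P, *fargs)[IDX_VE]

    ev.direction = -1.0
    sol = integrate(y0, (0.0, n_periods * T), cycle.params, rtol=rtol,
                    atol=atol, events=ev, dense_output=True)
    tev = sol.t_events[0]
    if len(tev) < 2:
        raise RuntimeError("no V_e maxima found after the kick")
    # keep only the global V_e maxima (V_e has a lower secondary peak)
    ve = np.array([sol.sol(s)[IDX_VE] for s in tev])
    tev = tev[ve > ve.max() - 0.25 * np.ptp(sol.y[IDX_VE])]
    t_last = tev[-1]
    # unperturbed from gamma(phase): V_e maxima at t = -phase mod T + k*T
    expected = np.mod(-phase, T)
    shift = np.mod(expected - t_last + 0.5 * T, T) - 0.5 * T
    return float(shift)
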