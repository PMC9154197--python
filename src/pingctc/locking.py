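"""Phase-locking analysis: stroboscopic maps, rotation numbers, devil's
staircases, Arnold tongues and full-model locked orbits.

The stroboscopic (time-T) map of the phase equation advances the oscillator
phase by one forcing period; its rotation number identifies p:q locking
(plateaus at rho = p/q on the devil's staircase), and the tongue boundaries
are the saddle-node loci of the map, continued in (theta, T, A) by a
pseudo-arclength method.  For pulsatile forcing (kappa -> inf) the map and
the tongue boundaries are available in closed form.  Locked orbits of the
full 8-D forced system are found by Newton shooting with the monodromy
matrix from the variational equations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import _kernels
from .forcing import ForcingSpec, VonMisesInput
from .meanfield import LimitCycle, ModelParams, Trajectory, integrate
from .phase import IPRC

__all__ = [
    "StroboscopicMap",
    "PulsatileMap",
    "RotationResult",
    "ArnoldTongue",
    "LockedOrbit",
    "rotation_number",
    "devils_staircase",
    "plateau_interval",
    "tongue_boundary_continuation",
    "pulsatile_tongue_analytic",
    "full_model_locking",
    "full_model_locking_interval",
]

#: rotation numbers within this distance of p/q count as locked
PLATEAU_TOL = 1e-4


def _steps_for_kappa(kappa: float) -> int:
    """RK4 steps per forcing period; sharper volleys need finer steps."""
    if kappa <= 30:
        return 1500
    return 6000


@dataclass
class StroboscopicMap:
    """Time-T map of the phase equation under a T-periodic forcing."""

    iprc: IPRC
    forcing: ForcingSpec
    T: float
    n_steps: int = 0  # 0 -> choose from the sharpest input

    def __post_init__(self) -> None:
        if self.n_steps == 0:
            kmax = max((inp.kappa for inp in self.forcing.inputs), default=0.0)
            self.n_steps = _steps_for_kappa(kmax)

    def _zargs(self):
        return self.iprc.zeff_coeffs(self.forcing.drive_e, self.forcing.drive_i)

    def lift(self, theta0: float = 0.0, n_iter: int = 1,
             t0: float = 0.0) -> np.ndarray:
        """Unwrapped phases at iterates 0..n_iter from one continuous
        integration of the phase ODE."""
        zc, zh, zn = self._zargs()
        fA, fT, fk, fmu, fi0inv, *_ = self.forcing.kernel_args()
        return _kernels.phase_strobe(theta0, t0, self.T, n_iter, self.n_steps,
                                     zc, zh, zn, self.iprc.period,
                                     fA, fT, fk, fmu, fi0inv)

    def step(self, theta: float) -> Tuple[float, float]:
        """One application: (next phase mod T*, lift value)."""
        lift = self.lift(theta, 1)
        return float(np.mod(lift[1], self.iprc.period)), float(lift[1])

    def __call__(self, theta: float) -> float:
        return self.step(theta)[0]

    def q_map_with_derivative(self, theta: float, q: int = 1
                              ) -> Tuple[float, float]:
        """(P^q(theta) on the lift, dP^q/dtheta) via the variational
        equation, which needs the FFT derivative of the iPRC."""
        zc, zh, zn = self._zargs()
        dzc, _, _ = self.iprc.dzeff_coeffs(self.forcing.drive_e,
                                           self.forcing.drive_i)
        fA, fT, fk, fmu, fi0inv, *_ = self.forcing.kernel_args()
        th, psi = _kernels.phase_map_var(theta, 0.0, q * self.T,
                                         q * self.n_steps, zc, dzc, zh, zn,
                                         self.iprc.period,
                                         fA, fT, fk, fmu, fi0inv)
        return float(th), float(psi)


@dataclass
class PulsatileMap:
    """Closed-form stroboscopic map for delta-pulse forcing:
    theta_{n+1} = theta_n + T + A*T*Z_ei(theta_n)."""

    iprc: IPRC
    A: float
    T: float

    def check_monotone(self) -> None:
        dz = np.max(np.abs(np.real(np.fft.ifft(
            np.fft.fft(self.iprc.Z_ei) * (2j * np.pi * np.fft.fftfreq(
                len(self.iprc.Z_ei), d=self.iprc.period / len(self.iprc.Z_ei)))))))
        if self.A * self.T * dz >= 1.0:
            raise ValueError("pulsatile map is not orientation preserving "
                             "at this amplitude (weak-coupling violated)")

    def lift(self, theta0: float = 0.0, n_iter: int = 1) -> np.ndarray:
        self.check_monotone()
        out = np.empty(n_iter + 1)
        out[0] = th = theta0
        for k in range(n_iter):
            th = th + self.T + self.A * self.T * float(
                self.iprc.interp("Z_ei", th))
            out[k + 1] = th
        return out

    def step(self, theta: float) -> Tuple[float, float]:
        lift = self.lift(theta, 1)
        return float(np.mod(lift[1], self.iprc.period)), float(lift[1])


@dataclass(frozen=True)
class RotationResult:
    """Normalised rotation number rho_hat (units of T* per forcing period)."""

    rho_hat: float
    rho_time: float
    n_iter: int
    convergence: float


def rotation_number(m, n_iter: int = 750, theta0: float = 0.0) -> RotationResult:
    """Weighted-Birkhoff rotation number of a stroboscopic map.

    The exponential-bump weighting reaches ~1e-6 accuracy with the default
    750 iterates (far beyond the O(1/N) plain average).  The lift is
    accumulated from monotone continuous solutions, never reconstructed
    from wrapped values.
    """
    Tstar = m.iprc.period
    lift = m.lift(theta0, n_iter)
    rho_hat = float(_kernels.birkhoff_rotation(lift, Tstar))
    half = float(_kernels.birkhoff_rotation(lift[: n_iter // 2 + 1], Tstar))
    return RotationResult(rho_hat=rho_hat, rho_time=rho_hat * Tstar,
                          n_iter=n_iter, convergence=abs(rho_hat - half))


def _single_input_map(iprc: IPRC, A: float, kappa: float,
                      ratio: float) -> StroboscopicMap:
    T = ratio * iprc.period
    f = ForcingSpec(inputs=(VonMisesInput(A=A, T=T, kappa=kappa, mu=0.0),))
    return StroboscopicMap(iprc, f, T)


def devils_staircase(iprc: IPRC, A: float, kappa: float,
                     ratios: np.ndarray, n_iter: int = 750,
                     theta0: float = 0.0) -> pd.DataFrame:
    """Rotation number versus T/T* on a grid (the devil's staircase)."""
    rows = []
    for r in np.asarray(ratios, dtype=float):
        res = rotation_number(_single_input_map(iprc, A, kappa, r),
                              n_iter=n_iter, theta0=theta0)
        rows.append((r, res.rho_hat, res.convergence))
    return pd.DataFrame(rows, columns=["T_over_Tstar", "rho_hat",
                                       "convergence"])


def _locked(iprc, A, kappa, ratio, p, q, n_iter=750) -> bool:
    res = rotation_number(_single_input_map(iprc, A, kappa, ratio),
                          n_iter=n_iter)
    return abs(res.rho_hat - p / q) < PLATEAU_TOL


def plateau_interval(iprc: IPRC, A: float, kappa: float,
                     p: int = 1, q: int = 1,
                     scan: Optional[Tuple[float, float]] = None,
                     step: float = 0.002, refine_tol: float = 5e-5,
                     n_iter: int = 750) -> Optional[Tuple[float, float]]:
    """The maximal contiguous rho = p/q plateau in T/T*.

    Scans a grid (default a window around the tip p/q), then refines both
    edges by bisection between the outermost locked and unlocked grid
    points.  Returns None when no grid point locks.
    """
    tip = p / q
    if scan is None:
        scan = (tip - 0.25 * tip, tip + 0.2 * tip)
    ratios = np.arange(scan[0], scan[1] + 0.5 * step, step)
    flags = np.array([_locked(iprc, A, kappa, r, p, q, n_iter)
                      for r in ratios])
    if not flags.any():
        return None
    idx = np.flatnonzero(flags)
    # maximal contiguous run containing the most points
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    run = max(runs, key=len)
    i_lo, i_hi = run[0], run[-1]

    lo = ratios[i_lo]
    if i_lo > 0:
        a, b = ratios[i_lo - 1], ratios[i_lo]
        while b - a > refine_tol:
            mm = 0.5 * (a + b)
            if _locked(iprc, A, kappa, mm, p, q, n_iter):
                b = mm
            else:
                a = mm
        lo = b
    hi = ratios[i_hi]
    if i_hi < len(ratios) - 1:
        a, b = ratios[i_hi], ratios[i_hi + 1]
        while b - a > refine_tol:
            mm = 0.5 * (a + b)
            if _locked(iprc, A, kappa, mm, p, q, n_iter):
                a = mm
            else:
                b = mm
        hi = a
    return float(lo), float(hi)


# ----------------------------------------------------------------------
# Arnold tongues
# ----------------------------------------------------------------------

@dataclass
class ArnoldTongue:
    """p:q tongue boundaries as (T/T*, A, theta) triples per side."""

    p: int
    q: int
    left: np.ndarray
    right: np.ndarray
    provenance: str = "continuation"

    def width_at(self, A: float) -> Optional[Tuple[float, float]]:
        """Interpolated (left, right) boundary ratios at amplitude A."""
        out = []
        for side in (self.left, self.right):
            if side.size == 0:
                return None
            a = side[:, 1]
            if A < a.min() - 1e-9 or A > a.max() + 1e-9:
                return None
            order = np.argsort(a)
            out.append(float(np.interp(A, a[order], side[order, 0])))
        return out[0], out[1]


def _tongue_G(u: np.ndarray, p: int, q: int, iprc: IPRC,
              kappa: float) -> np.ndarray:
    """Saddle-node conditions G(theta, T, A) = 0 in tip-scaled variables
    u = (theta/T*, T/T*, A): fixed point of P^q on the lift after p turns,
    with unit derivative."""
    Tstar = iprc.period
    theta, T, A = u[0] * Tstar, u[1] * Tstar, u[2]
    m = _single_input_map(iprc, A, kappa, T / Tstar)
    th, psi = m.q_map_with_derivative(theta, q)
    return np.array([(th - theta - p * Tstar) / Tstar, psi - 1.0])


def _tongue_seed(p: int, q: int, iprc: IPRC, kappa: float, A_seed: float,
                 side: str, edges: Tuple[float, float]) -> Optional[np.ndarray]:
    """Seed (theta/T*, T/T*, A) on one boundary from a staircase edge."""
    ratio = edges[0] if side == "left" else edges[1]
    Tstar = iprc.period
    m = _single_input_map(iprc, A_seed, kappa, ratio)
    # at the edge the fixed points of P^q form a parabolic pair: take the
    # grid phase where |P^q(theta) - theta - p T*| is smallest
    thetas = np.linspace(0.0, Tstar, 48, endpoint=False)
    F = np.array([m.q_map_with_derivative(th, q)[0] - th - p * Tstar
                  for th in thetas])
    th0 = thetas[int(np.argmin(np.abs(F)))]
    u0 = np.array([th0 / Tstar, ratio, A_seed])

    def G2(v):
        return _tongue_G(np.array([v[0], v[1], A_seed]), p, q, iprc, kappa)

    sol = root(G2, u0[:2], method="hybr", options={"xtol": 1e-12})
    if not sol.success:
        return None
    return np.array([sol.x[0] % 1.0, sol.x[1], A_seed])


def tongue_boundary_continuation(p: int, q: int, iprc: IPRC, kappa: float,
                                 A_min: float = 0.004, A_max: float = 0.2,
                                 A_seed: float = 0.02,
                                 ds: float = 2e-3, ds_max: float = 1e-2,
                                 newton_tol: float = 1e-9,
                                 max_points: int = 4000) -> ArnoldTongue:
    """Both saddle-node boundary curves of the p:q tongue by
    pseudo-arclength continuation of G(theta, T, A) = 0.

    The corrector is a bordered Newton step (minimum-norm update via the
    tangent constraint); the derivative of the stroboscopic map comes from
    the variational equation of the phase ODE with the FFT-differentiated
    iPRC.  Each curve is traced from a staircase-seeded point at A_seed
    down to A_min and up to A_max.
    """
    # one coarse staircase scan at A_seed seeds both boundary curves (the
    # seed Newton then lands exactly on the saddle-node conditions)
    edges = plateau_interval(iprc, A_seed, kappa, p, q, step=0.01,
                             refine_tol=1e-3, n_iter=500)
    if edges is None:
        return ArnoldTongue(p=p, q=q, left=np.empty((0, 3)),
                            right=np.empty((0, 3)),
                            provenance="continuation")
    sides = {}
    for side in ("left", "right"):
        u0 = _tongue_seed(p, q, iprc, kappa, A_seed, side, edges)
        if u0 is None:
            sides[side] = np.empty((0, 3))
            continue
        pts = [u0.copy()]
        for direction in (+1.0, -1.0):
            u = u0.copy()
            tang = None
            h = ds
            count = 0
            while count < max_points:
                J = _fd_jacobian(lambda v: _tongue_G(v, p, q, iprc, kappa), u)
                t_new = _null_vector(J)
                if tang is None:
                    # first step: orient toward the requested A direction
                    if t_new[2] * direction < 0:
                        t_new = -t_new
                else:
                    if np.dot(t_new, tang) < 0:
                        t_new = -t_new
                tang = t_new
                u_pred = u + h * tang
                if u_pred[2] < A_min:
                    # reached the tongue tip; the boundaries meet at A = 0
                    break
                u_corr, ok = _bordered_newton(
                    lambda v: _tongue_G(v, p, q, iprc, kappa),
                    u_pred, tang, newton_tol)
                if not ok:
                    h *= 0.5
                    if h < 1e-5:
                        break
                    continue
                u = u_corr
                pts.append(u.copy())
                count += 1
                h = min(h * 1.3, ds_max)
                if u[2] > A_max or u[2] < A_min:
                    break
        arr = np.array(pts)
        arr = arr[np.argsort(arr[:, 2])]
        # to (T/T*, A, theta)
        sides[side] = np.column_stack([arr[:, 1], arr[:, 2],
                                       np.mod(arr[:, 0], 1.0) * iprc.period])
    return ArnoldTongue(p=p, q=q, left=sides["left"], right=sides["right"],
                        provenance="continuation")


def _fd_jacobian(G: Callable, u: np.ndarray, h: float = 1e-7) -> np.ndarray:
    g0 = G(u)
    J = np.empty((len(g0), len(u)))
    for j in range(len(u)):
        up = u.copy()
        up[j] += h
        J[:, j] = (G(up) - g0) / h
    return J


def _null_vector(J: np.ndarray) -> np.ndarray:
    _, _, vt = np.linalg.svd(J)
    v = vt[-1]
    return v / np.linalg.norm(v)


def _bordered_newton(G: Callable, u: np.ndarray, tang: np.ndarray,
                     tol: float, max_iter: int = 10
                     ) -> Tuple[np.ndarray, bool]:
    """Newton corrector constrained to the hyperplane normal to the
    tangent (the minimum-norm / Lagrange-multiplier update)."""
    u = u.copy()
    u_ref = u.copy()
    for _ in range(max_iter):
        g = G(u)
        if np.linalg.norm(g) < tol:
            return u, True
        J = _fd_jacobian(G, u)
        Aext = np.vstack([J, tang])
        rhs = np.concatenate([-g, [np.dot(tang, u_ref - u)]])
        try:
            du = np.linalg.solve(Aext, rhs)
        except np.linalg.LinAlgError:
            return u, False
        u = u + du
    return u, bool(np.linalg.norm(G(u)) < tol)


def pulsatile_tongue_analytic(p: int, q: int, iprc: IPRC,
                              A_grid: Optional[np.ndarray] = None
                              ) -> ArnoldTongue:
    """Closed-form tongue boundaries in the delta-pulse limit.

    The pulsatile map theta -> theta + T + A*T*Z_ei(theta) has p:q locked
    orbits while T*/T lies between (q/p)(1 + A*Z_min) and
    (q/p)(1 + A*Z_max); the extreme iPRC values give the two lines.
    """
    if A_grid is None:
        A_grid = np.linspace(0.0, 0.2, 41)
    zmax = float(np.max(iprc.Z_ei))
    zmin = float(np.min(iprc.Z_ei))
    rp = p / q
    left = np.column_stack([rp / (1.0 + A_grid * zmax), A_grid,
                            np.zeros_like(A_grid)])
    right = np.column_stack([rp / (1.0 + A_grid * zmin), A_grid,
                             np.zeros_like(A_grid)])
    return ArnoldTongue(p=p, q=q, left=left, right=right,
                        provenance="analytic-pulsatile")


# ----------------------------------------------------------------------
# locked orbits of the full 8-D forced system
# ----------------------------------------------------------------------

@dataclass
class LockedOrbit:
    """Result of Newton shooting for a qT-periodic orbit of the forced
    full model.  ``found`` is False when shooting failed ("unlocked")."""

    found: bool
    x0: Optional[np.ndarray] = None
    period: float = np.nan
    multipliers: Optional[np.ndarray] = None
    trajectory: Optional[Trajectory] = None
    residual: float = np.inf
    message: str = ""

    @property
    def stable(self) -> bool:
        if not self.found or self.multipliers is None:
            return False
        return bool(np.max(np.abs(self.multipliers)) < 1.0 + 1e-6)


def _propagate(x, T, params, forcing, rtol, atol):
    sol = integrate(x, (0.0, T), params, forcing, rtol=rtol, atol=atol)
    return sol.y[:, -1]


def _monodromy(x, T, params, forcing, rtol=1e-8, atol=1e-9):
    P = params.as_array()
    fargs = forcing.kernel_args()

    def f(t, y):
        return _kernels.mf_rhs_var(t, y, P, *fargs)

    y0 = np.concatenate([x, np.eye(8).ravel()])
    sol = solve_ivp(f, (0.0, T), y0, method="RK45", rtol=rtol, atol=atol)
    return sol.y[8:, -1].reshape(8, 8)


def full_model_locking(params: ModelParams, forcing: ForcingSpec,
                       T: float, p: int = 1, q: int = 1,
                       x_guess: Optional[np.ndarray] = None,
                       cycle: Optional[LimitCycle] = None,
                       iprc: Optional[IPRC] = None,
                       tol: float = 1e-9, max_iter: int = 12,
                       rtol: float = 1e-10, atol: float = 1e-12,
                       n_samples: int = 1024,
                       relax_periods: Optional[int] = None) -> LockedOrbit:
    """Newton shooting for a stable qT-periodic orbit of the forced
    8-D system (a p:q locked state).

    The initial guess is either supplied (warm start in sweeps) or built
    from the phase reduction: the stroboscopic map is iterated to its
    attracting phase and the unperturbed cycle is evaluated there.
    """
    Tq = q * T
    if x_guess is None:
        if cycle is None or iprc is None:
            raise ValueError("either x_guess or (cycle, iprc) is required")
        m = StroboscopicMap(iprc, forcing, T)
        th = float(np.mod(m.lift(0.0, 300)[-1], iprc.period))
        x = cycle.state_at(th).copy()
        n_relax = 60 if relax_periods is None else relax_periods
    else:
        x = np.asarray(x_guess, dtype=float).copy()
        n_relax = 5 if relax_periods is None else relax_periods
    if n_relax > 0:
        # ride the attracting orbit for whole forcing periods so Newton
        # starts inside its (narrow, volley-sharp) convergence basin
        try:
            x = _propagate(x, n_relax * Tq, params, forcing,
                           max(rtol, 1e-9), max(atol, 1e-11))
        except (RuntimeError, FloatingPointError) as exc:
            return LockedOrbit(found=False, message=f"relaxation failed: {exc}")

    resid_prev = np.inf
    for it in range(max_iter):
        try:
            xT = _propagate(x, Tq, params, forcing, rtol, atol)
        except (RuntimeError, FloatingPointError) as exc:
            return LockedOrbit(found=False, message=f"integration failed: {exc}")
        F = xT - x
        resid = float(np.max(np.abs(F)))
        if resid < tol:
            break
        if not np.isfinite(resid) or resid > 1e3:
            return LockedOrbit(found=False, message="diverged")
        M = _monodromy(x, Tq, params, forcing)
        try:
            dx = np.linalg.solve(M - np.eye(8), -F)
        except np.linalg.LinAlgError:
            return LockedOrbit(found=False, message="singular shooting matrix")
        # damped update if the full step grows the residual badly
        lam = 1.0
        for _ in range(4):
            x_new = x + lam * dx
            try:
                r_new = float(np.max(np.abs(
                    _propagate(x_new, Tq, params, forcing, rtol, atol) - x_new)))
            except (RuntimeError, FloatingPointError):
                r_new = np.inf
            if r_new < max(resid, resid_prev):
                break
            lam *= 0.5
        x = x + lam * dx
        resid_prev = resid
    else:
        return LockedOrbit(found=False, residual=resid,
                           message="Newton did not converge")

    xT = _propagate(x, Tq, params, forcing, rtol, atol)
    resid = float(np.max(np.abs(xT - x)))
    if resid > 10 * tol:
        return LockedOrbit(found=False, residual=resid,
                           message="residual above tolerance")
    M = _monodromy(x, Tq, params, forcing)
    mult = np.linalg.eigvals(M)

    t_samp = np.linspace(0.0, Tq, n_samples + 1)
    sol = integrate(x, (0.0, Tq), params, forcing, t_eval=t_samp,
                    rtol=rtol, atol=atol)
    traj = Trajectory(t=sol.t, states=sol.y.T)
    return LockedOrbit(found=True, x0=x, period=Tq, multipliers=mult,
                       trajectory=traj, residual=resid, message="converged")


def full_model_locking_interval(params: ModelParams, cycle: LimitCycle,
                                iprc: IPRC, kappa: float, A: float,
                                p: int = 1, q: int = 1,
                                ratio_start: float = 1.0,
                                step: float = 0.004,
                                refine_tol: float = 0.001,
                                scan_halfwidth: float = 0.25
                                ) -> Tuple[float, float]:
    """Edges (in T/T*) of the interval where the forced full model has a
    stable p:q locked orbit, by warm-started outward sweeps from
    ``ratio_start`` and bisection refinement at each end."""
    Tstar = cycle.period

    def attempt(ratio: float, guess) -> LockedOrbit:
        T = ratio * Tstar
        f = ForcingSpec(inputs=(VonMisesInput(A=A, T=T, kappa=kappa),))
        return full_model_locking(params, f, T, p, q, x_guess=guess,
                                  cycle=cycle, iprc=iprc)

    center = attempt(ratio_start, None)
    if not (center.found and center.stable):
        raise RuntimeError("no stable locked orbit at the sweep start")

    edges = []
    for direction in (-1.0, +1.0):
        r = ratio_start
        orb = center
        while abs(r - ratio_start) < scan_halfwidth:
            r_next = r + direction * step
            nxt = attempt(r_next, orb.x0)
            if not (nxt.found and nxt.stable):
                break
            r, orb = r_next, nxt
        # bisection between the last good r and the first bad r
        a, b = r, r + direction * step
        while abs(b - a) > refine_tol:
            mid = 0.5 * (a + b)
            nxt = attempt(mid, orb.x0)
            if nxt.found and nxt.stable:
                a, orb = mid, nxt
            else:
                b = mid
        edges.append(a)
    return float(min(edges)), float(max(edges))
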