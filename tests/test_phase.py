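"""Phase reduction: Jacobian along the cycle, adjoint iPRC, phase ODE."""

import numpy as np
import pytest

from pingctc import (ForcingSpec, VonMisesInput, iprc_derivative_fft,
                     linearize_along_cycle, phase_ode_rhs, solve_adjoint)
from pingctc.meanfield import IDX_RE, IDX_SEE, rhs_meanfield


def test_synaptic_jacobian_entry_is_exact(cycle10):
    J = linearize_along_cycle(cycle10, 3.7)
    p = cycle10.params
    assert J[IDX_SEE, IDX_RE] == pytest.approx(p.J_ee / p.tau_se)


def test_jacobian_along_cycle_matches_finite_differences(cycle10):
    rng = np.random.default_rng(3)
    h = 1e-6
    for phase in rng.uniform(0, cycle10.period, 10):
        x = cycle10.state_at(phase)
        J = linearize_along_cycle(cycle10, phase)
        for j in range(8):
            e = np.zeros(8)
            e[j] = h
            col = (rhs_meanfield(x + e, 0.0, cycle10.params)
                   - rhs_meanfield(x - e, 0.0, cycle10.params)) / (2 * h)
            np.testing.assert_allclose(J[:, j], col, atol=1e-5)


def test_jacobian_trace_is_periodic(cycle10):
    tr0 = np.trace(linearize_along_cycle(cycle10, 1.0))
    tr1 = np.trace(linearize_along_cycle(cycle10, 1.0 + cycle10.period))
    assert tr0 == pytest.approx(tr1, abs=1e-9)


def test_adjoint_normalization_holds_everywhere(iprc10):
    # Z . gamma' = 1 at every sampled phase
    assert iprc10.normalization_residual < 1e-6


def test_reference_iprc_is_mostly_positive(iprc10):
    """Fast-gamma oscillator: the voltage iPRC is ~0 during the I-volley
    and positive elsewhere, peaking shortly before the E-volley."""
    z = iprc10.Z_ei
    assert z.max() > 0
    assert z.min() > -0.15 * z.max()
    # the peak sits in the last fifth of the cycle (just before phase 0,
    # i.e. right before the E-volley / V_e maximum)
    assert iprc10.theta[np.argmax(z)] / iprc10.period > 0.8


def test_hopf_proximal_iprc_changes_sign(iprc84):
    z = iprc84.Z_ei
    assert z.max() > 0 and z.min() < 0
    assert -z.min() > 0.2 * z.max()


def test_direct_perturbation_matches_adjoint(cycle10, iprc10):
    """Defining property of the iPRC: the asymptotic phase shift of a
    small V_e kick, divided by its size, equals Z_Ve at the kick phase."""
    from pingctc import direct_phase_shift
    from pingctc.meanfield import IDX_VE

    eps = 1e-4
    phases = np.linspace(0, cycle10.period, 4, endpoint=False) + 1.3
    scale = np.max(np.abs(iprc10.Z_Ve))
    for ph in phases:
        shift = direct_phase_shift(cycle10, IDX_VE, eps, ph, n_periods=15)
        z_est = shift / eps
        z_ref = float(iprc10.interp("Z_Ve", ph))
        assert abs(z_est - z_ref) < 0.02 * scale


def test_grid_refinement_changes_little(cycle10, iprc10):
    fine = solve_adjoint(cycle10, n_grid=2048)
    coarse_on_fine = np.interp(fine.theta, iprc10.theta, iprc10.Z_ei,
                               period=iprc10.period)
    assert np.max(np.abs(fine.Z_ei - coarse_on_fine)) < 1e-4


def test_fft_derivative_of_sine_is_cosine():
    T = 7.0
    t = np.linspace(0, T, 256, endpoint=False)
    d = iprc_derivative_fft(np.sin(2 * np.pi * t / T), T)
    np.testing.assert_allclose(d, 2 * np.pi / T * np.cos(2 * np.pi * t / T),
                               atol=1e-10)


def test_fft_derivative_zero_mean_and_matches_central_differences(iprc10):
    z = iprc10.Z_ei
    d = iprc_derivative_fft(z, iprc10.period)
    assert abs(np.mean(d)) < 1e-10
    h = iprc10.period / len(z)
    central = (np.roll(z, -1) - np.roll(z, 1)) / (2 * h)
    # central differences carry an O(h^2) truncation error; the spectral
    # derivative must sit within that error of them
    assert np.max(np.abs(d - central)) < 0.02 * np.max(np.abs(d))


def test_phase_rhs_unforced_is_unit_speed(iprc10):
    assert phase_ode_rhs(3.0, 11.0, iprc10, ForcingSpec()) == 1.0


def test_phase_rhs_two_inputs_sum_into_one_term(iprc10):
    a = VonMisesInput(A=0.1, T=20.0, kappa=2.0)
    b = VonMisesInput(A=0.05, T=24.0, kappa=5.0, mu=10.0)
    both = ForcingSpec(inputs=(a, b))
    fa = ForcingSpec(inputs=(a,))
    fb = ForcingSpec(inputs=(b,))
    t, th = 4.2, 8.0
    lhs = phase_ode_rhs(th, t, iprc10, both) - 1.0
    rhs = (phase_ode_rhs(th, t, iprc10, fa) - 1.0) + \
          (phase_ode_rhs(th, t, iprc10, fb) - 1.0)
    assert lhs == pytest.approx(rhs, rel=1e-12)


def test_phase_rhs_e_only_uses_z_ve(iprc10):
    f = ForcingSpec(inputs=(VonMisesInput(A=0.1, T=20.0, kappa=2.0),),
                    drive_i=False)
    th, t = 5.0, 2.0
    g = float(f.g(t))
    expected = 1.0 + g * float(iprc10.interp("Z_Ve", th))
    assert phase_ode_rhs(th, t, iprc10, f) == pytest.approx(expected,
                                                            rel=1e-10)
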