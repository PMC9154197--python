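"""Mean-field model: vector field, integration, cycles, equilibria."""

import numpy as np
import pytest

from pingctc import (ModelParams, ei_latency, find_equilibria,
                     find_limit_cycle, hopf_crossing, integral_mean_rates,
                     integrate, jacobian_meanfield, rhs_meanfield)
from pingctc.meanfield import DEFAULT_STATE, IDX_RE, IDX_RI, IDX_VE


def test_default_params_are_the_reference_set():
    p = ModelParams()
    assert (p.tau_e, p.tau_i) == (8.0, 8.0)
    assert (p.delta_e, p.delta_i) == (1.0, 1.0)
    assert (p.eta_e, p.eta_i) == (-5.0, -5.0)
    assert (p.tau_se, p.tau_si) == (1.0, 5.0)
    assert (p.J_ee, p.J_ii) == (0.0, 0.0)
    assert (p.J_ei, p.J_ie) == (13.0, 13.0)


@pytest.mark.parametrize("bad", [{"tau_e": -1.0}, {"delta_i": 0.0},
                                 {"tau_si": -5.0}])
def test_invalid_params_rejected(bad):
    with pytest.raises(ValueError):
        ModelParams(**bad)


def test_rates_self_repel_from_zero():
    # at r_e = 0 the rate derivative is the positive Lorentzian term
    p = ModelParams()
    y = np.array([0.0, -3.0, 0.0, 0.0, 0.0, -3.0, 0.0, 0.0])
    dy = rhs_meanfield(y, 0.0, p)
    assert dy[IDX_RE] == pytest.approx(p.delta_e / (np.pi * p.tau_e ** 2))
    assert dy[IDX_RE] > 0
    assert dy[IDX_RI] > 0


def test_jacobian_matches_finite_differences():
    p = ModelParams()
    rng = np.random.default_rng(7)
    y = np.abs(rng.normal(size=8)) * 0.3
    J = jacobian_meanfield(y, p)
    h = 1e-6
    for j in range(8):
        e = np.zeros(8)
        e[j] = h
        col = (rhs_meanfield(y + e, 0.0, p) - rhs_meanfield(y - e, 0.0, p)) / (2 * h)
        np.testing.assert_allclose(J[:, j], col, atol=1e-5)


def test_zero_length_span_returns_initial_state():
    sol = integrate(DEFAULT_STATE, (0.0, 0.0), ModelParams())
    np.testing.assert_array_equal(sol.y[:, -1], DEFAULT_STATE)


def test_nonnegative_rates_along_trajectories():
    sol = integrate(DEFAULT_STATE, (0.0, 150.0), ModelParams(),
                    t_eval=np.linspace(0, 150, 1500))
    assert sol.y[IDX_RE].min() >= -1e-9
    assert sol.y[IDX_RI].min() >= -1e-9


def test_reference_cycle_period_and_periodicity(cycle10):
    assert cycle10.period == pytest.approx(24.234, abs=0.05)
    assert np.max(np.abs(cycle10.samples[-1] - cycle10.samples[0])) < 1e-7
    # phase origin anchored at the V_e maximum
    assert np.argmax(cycle10["V_e"][:-1]) in (0, len(cycle10.t) - 2)
    assert cycle10.stable


def test_hopf_proximal_cycle_period(cycle84):
    assert cycle84.period == pytest.approx(30.5, abs=0.1)
    assert 1000.0 / cycle84.period == pytest.approx(32.78, abs=0.15)


def test_no_cycle_at_zero_drive():
    assert find_limit_cycle(ModelParams().with_drives(Ie=0.0)) is None


def test_period_self_convergence_in_tolerance():
    # tightening the integration tolerance barely moves the period
    loose = find_limit_cycle(ModelParams(), rtol=1e-8, atol=1e-10)
    tight = find_limit_cycle(ModelParams(), rtol=1e-12, atol=1e-13)
    assert abs(loose.period - tight.period) < 1e-4


def test_integral_mean_rates(cycle10):
    re, ri = integral_mean_rates(cycle10)
    # individual cells fire about once per network cycle
    assert re == pytest.approx(1.0 / cycle10.period, rel=0.15)
    # quadrature refinement: halving the sampling step changes nothing
    re2, _ = integral_mean_rates(cycle10, n=len(cycle10.t) // 2)
    assert abs(re - re2) < 1e-8


def test_mean_rate_of_constant_trace_is_the_constant(cycle10):
    flat = cycle10.samples.copy()
    flat[:, IDX_RE] = 0.125
    c = type(cycle10)(t=cycle10.t, samples=flat, period=cycle10.period,
                      params=cycle10.params)
    re, _ = integral_mean_rates(c)
    assert re == pytest.approx(0.125, abs=1e-14)


def test_ei_latency_reference_values(cycle10):
    lat, phase = ei_latency(cycle10)
    assert lat == pytest.approx(4.0, abs=0.5)
    assert phase == pytest.approx(0.18, abs=0.02)


def test_ei_latency_identical_traces_is_zero(cycle10):
    samples = cycle10.samples.copy()
    samples[:, IDX_RI] = samples[:, IDX_RE]
    c = type(cycle10)(t=cycle10.t, samples=samples, period=cycle10.period,
                      params=cycle10.params)
    lat, phase = ei_latency(c)
    assert lat == pytest.approx(0.0, abs=1e-6) or \
        lat == pytest.approx(cycle10.period, abs=1e-6)


def test_frequency_increases_with_tonic_drive():
    # oscillations set in just above Ie ~ 8; across the oscillatory range
    # the gamma frequency rises monotonically from ~30 toward ~70 Hz
    freqs = []
    for ie in (8.4, 9.0, 11.0, 13.0, 15.0):
        cyc = find_limit_cycle(ModelParams().with_drives(Ie=ie))
        assert cyc is not None
        freqs.append(1000.0 / cyc.period)
    assert all(a < b for a, b in zip(freqs, freqs[1:]))
    assert freqs[0] < 35.0 < 55.0 < freqs[-1] < 80.0


def test_equilibria_residual_and_instability_in_oscillatory_regime():
    eqs = find_equilibria(ModelParams())
    assert eqs, "expected at least one equilibrium"
    for e in eqs:
        assert e.residual < 1e-10
    # the drive point sits inside the oscillatory region: the coexisting
    # equilibrium must be unstable (consistent with the stable cycle)
    assert all(not e.stable for e in eqs)


def test_hopf_detected_with_nonzero_frequency():
    c, w = hopf_crossing(lambda ie: ModelParams().with_drives(Ie=ie),
                         6.0, 10.0)
    assert 6.0 < c < 10.0
    assert 1000.0 * w / (2 * np.pi) > 10.0  # frequency bounded away from 0


def test_blowup_raises():
    with pytest.raises(FloatingPointError):
        rhs_meanfield(np.full(8, np.nan), 0.0, ModelParams())
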