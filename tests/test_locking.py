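"""Stroboscopic maps, rotation numbers, staircases and Arnold tongues."""

import numpy as np
import pytest

from pingctc import (ForcingSpec, PulsatileMap, StroboscopicMap,
                     VonMisesInput, devils_staircase, full_model_locking,
                     plateau_interval, pulsatile_tongue_analytic,
                     rotation_number, tongue_boundary_continuation)


def _vm_map(iprc, A, kappa, ratio):
    T = ratio * iprc.period
    f = ForcingSpec(inputs=(VonMisesInput(A=A, T=T, kappa=kappa),))
    return StroboscopicMap(iprc, f, T)


class TestStroboscopicMap:
    def test_unforced_map_is_rigid_rotation(self, iprc10):
        m = _vm_map(iprc10, 0.0, 2.0, 0.9)
        th, lift = m.step(3.0)
        assert lift == pytest.approx(3.0 + m.T, abs=1e-12)
        assert th == pytest.approx((3.0 + m.T) % iprc10.period, abs=1e-10)

    def test_pulsatile_map_closed_form(self, iprc10):
        pm = PulsatileMap(iprc10, A=0.05, T=20.0)
        th0 = 4.0
        _, lift = pm.step(th0)
        expected = th0 + 20.0 + 0.05 * 20.0 * float(iprc10.interp("Z_ei", th0))
        assert lift == pytest.approx(expected, rel=1e-12)

    def test_lift_is_orientation_preserving(self, iprc10):
        m = _vm_map(iprc10, 0.1, 2.0, 0.9)
        delta = 1e-3
        for th in np.linspace(0, iprc10.period, 7, endpoint=False):
            assert m.step(th + delta)[1] > m.step(th)[1]

    def test_variational_derivative_matches_finite_difference(self, iprc10):
        m = _vm_map(iprc10, 0.08, 2.0, 0.92)
        th = 5.0
        _, dP = m.q_map_with_derivative(th, q=1)
        h = 1e-5
        fd = (m.step(th + h)[1] - m.step(th - h)[1]) / (2 * h)
        assert dP == pytest.approx(fd, rel=1e-6)


class TestRotationNumber:
    def test_rigid_rotation_is_exact(self, iprc10):
        m = _vm_map(iprc10, 0.0, 2.0, 1.137)
        res = rotation_number(m, n_iter=200)
        assert res.rho_hat == pytest.approx(1.137, abs=1e-9)

    def test_zero_amplitude_any_period(self, iprc10):
        for ratio in (0.5, 0.845, 1.0, 2.0):
            res = rotation_number(_vm_map(iprc10, 0.0, 2.0, ratio))
            assert res.rho_hat == pytest.approx(ratio, abs=1e-9)

    def test_locked_inside_the_one_one_plateau(self, iprc10):
        res = rotation_number(_vm_map(iprc10, 0.1, 2.0, 0.9))
        assert res.rho_hat == pytest.approx(1.0, abs=1e-4)
        assert res.convergence < 1e-6

    def test_nondecreasing_in_forcing_period(self, iprc10):
        ratios = np.linspace(0.8, 1.1, 13)
        rhos = [rotation_number(_vm_map(iprc10, 0.05, 2.0, r),
                                n_iter=400).rho_hat for r in ratios]
        assert all(b - a > -1e-7 for a, b in zip(rhos, rhos[1:]))

    def test_pulsatile_non_monotone_amplitude_rejected(self, iprc10):
        pm = PulsatileMap(iprc10, A=5.0, T=20.0)
        with pytest.raises(ValueError):
            pm.lift(0.0, 10)


class TestStaircase:
    def test_zero_amplitude_staircase_is_identity(self, iprc10):
        ratios = np.linspace(0.85, 1.1, 9)
        df = devils_staircase(iprc10, 0.0, 2.0, ratios, n_iter=100)
        np.testing.assert_allclose(df.rho_hat, df.T_over_Tstar, atol=1e-9)

    def test_higher_coherence_widens_the_plateau(self, iprc10):
        lo = plateau_interval(iprc10, 0.1, 0.5, scan=(0.75, 1.08),
                              step=0.01, refine_tol=1e-3, n_iter=400)
        hi = plateau_interval(iprc10, 0.1, 20.0, scan=(0.75, 1.08),
                              step=0.01, refine_tol=1e-3, n_iter=400)
        assert lo is not None and hi is not None
        assert (hi[1] - hi[0]) > (lo[1] - lo[0])

    def test_hopf_proximal_plateau_extends_both_sides(self, iprc84):
        edges = plateau_interval(iprc84, 0.05, 2.0, scan=(0.85, 1.15),
                                 step=0.005, refine_tol=1e-3, n_iter=500)
        assert edges is not None
        lo, hi = edges
        assert lo < 1.0 < hi  # entrains both faster and slower inputs


@pytest.fixture(scope="module")
def tongue_k2(iprc10):
    return tongue_boundary_continuation(1, 1, iprc10, 2.0, A_max=0.12)


class TestArnoldTongues:
    def test_continuation_closure(self, iprc10, tongue_k2):
        from pingctc.locking import _tongue_G

        for side in (tongue_k2.left, tongue_k2.right):
            for T_over, A, theta in side[::5]:
                u = np.array([theta / iprc10.period, T_over, A])
                g = _tongue_G(u, 1, 1, iprc10, 2.0)
                assert np.linalg.norm(g) < 1e-9

    def test_tip_at_unit_period_ratio(self, tongue_k2):
        for side in (tongue_k2.left, tongue_k2.right):
            i = np.argmin(side[:, 1])  # smallest continued amplitude
            assert side[i, 0] == pytest.approx(1.0, abs=0.02)

    def test_boundaries_bracket_the_staircase_plateau(self, iprc10,
                                                      tongue_k2):
        edges = plateau_interval(iprc10, 0.1, 2.0, scan=(0.75, 1.08),
                                 step=0.005, refine_tol=1e-4)
        w = tongue_k2.width_at(0.1)
        assert edges is not None and w is not None
        assert w[0] == pytest.approx(edges[0], abs=0.005)
        assert w[1] == pytest.approx(edges[1], abs=0.005)

    def test_lower_coherence_tongues_are_enclosed(self, iprc10, tongue_k2):
        t05 = tongue_boundary_continuation(1, 1, iprc10, 0.5, A_max=0.12)
        t20 = tongue_boundary_continuation(1, 1, iprc10, 20.0, A_max=0.12)
        A = 0.1
        w05, w2, w20 = t05.width_at(A), tongue_k2.width_at(A), t20.width_at(A)
        assert w05 is not None and w2 is not None and w20 is not None
        assert w2[0] <= w05[0] and w05[1] <= w2[1] + 1e-6
        assert w20[0] <= w2[0] and w2[1] <= w20[1] + 1e-6


class TestPulsatileTongue:
    def test_boundaries_meet_at_the_tip(self, iprc10):
        t = pulsatile_tongue_analytic(1, 1, iprc10)
        assert t.left[0, 0] == pytest.approx(1.0)
        assert t.right[0, 0] == pytest.approx(1.0)

    def test_right_boundary_nearly_vertical_for_type_i_prc(self, iprc10):
        # Z_min ~ 0 for the fast-gamma oscillator: the right edge stays
        # near T/T* = 1 for every amplitude
        t = pulsatile_tongue_analytic(1, 1, iprc10)
        assert np.all(np.abs(t.right[:, 0] - 1.0) < 0.08)

    def test_left_slope_is_set_by_z_max(self, iprc10):
        t = pulsatile_tongue_analytic(1, 1, iprc10)
        zmax = float(np.max(iprc10.Z_ei))
        A = t.left[:, 1]
        np.testing.assert_allclose(1.0 / t.left[:, 0], 1.0 + A * zmax,
                                   rtol=1e-12)


class TestFullModelLocking:
    def test_zero_amplitude_recovers_the_unperturbed_cycle(self, params10,
                                                           cycle10, iprc10):
        T = cycle10.period
        f = ForcingSpec(inputs=(VonMisesInput(A=0.0, T=T, kappa=2.0),))
        orb = full_model_locking(params10, f, T, cycle=cycle10, iprc=iprc10)
        assert orb.found
        re_max = orb.trajectory.states[:, 0].max()
        assert re_max == pytest.approx(cycle10["r_e"].max(), rel=1e-5)

    def test_locked_orbit_inside_the_tongue(self, params10, cycle10, iprc10):
        T = 0.9 * cycle10.period
        f = ForcingSpec(inputs=(VonMisesInput(A=0.1, T=T, kappa=2.0),))
        orb = full_model_locking(params10, f, T, cycle=cycle10, iprc=iprc10)
        assert orb.found and orb.stable
        assert orb.residual < 1e-8

    def test_unlocked_outside_the_tongue(self, params10, cycle10, iprc10):
        T = 1.25 * cycle10.period  # far right of the (left-bent) tongue
        f = ForcingSpec(inputs=(VonMisesInput(A=0.05, T=T, kappa=2.0),))
        orb = full_model_locking(params10, f, T, cycle=cycle10, iprc=iprc10)
        assert not (orb.found and orb.stable)
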