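"""Two-input competition: vector strength, robustness, switching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pingctc import (CompetitionSpec, VonMisesInput, robustness_scan,
                     synchronization_index, time_T1_map_phases,
                     vector_strength)


class TestVectorStrength:
    def test_identical_phases_give_one(self):
        assert vector_strength(np.full(100, 1.234)) == pytest.approx(1.0)

    def test_equally_spaced_phases_cancel(self):
        angles = 2 * np.pi * np.arange(12) / 12
        assert vector_strength(angles) == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            vector_strength(np.empty(0))

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-10.0, 10.0), min_size=1, max_size=40))
    def test_bounded_between_zero_and_one(self, angles):
        r = vector_strength(np.array(angles))
        assert -1e-12 <= r <= 1.0 + 1e-12


class TestTimeT1Map:
    def test_single_input_converges_to_a_fixed_phase(self, cycle10, iprc10):
        # distractor amplitude zero, primary inside the 1:1 tongue
        T1 = 0.9 * cycle10.period
        spec = CompetitionSpec.from_unplaced(
            VonMisesInput(A=0.1, T=T1, kappa=2.0),
            VonMisesInput(A=0.0, T=T1, kappa=2.0), n_iter=300)
        lift = time_T1_map_phases(spec, iprc10)
        wrapped = np.mod(lift[-50:], iprc10.period)
        assert np.ptp(wrapped) < 1e-4

    def test_antiphase_equal_periods_still_converges(self, cycle10, iprc10):
        T1 = 0.845 * cycle10.period
        spec = CompetitionSpec.from_unplaced(
            VonMisesInput(A=0.1, T=T1, kappa=2.0),
            VonMisesInput(A=0.1, T=T1, kappa=20.0), n_iter=400)
        assert spec.distractor.mu == pytest.approx(T1 / 2)
        r = synchronization_index(spec, iprc10, burn_in=100)
        assert r > 0.99

    def test_incommensurate_case_fills_the_circle(self, cycle10, iprc10):
        T1 = cycle10.period  # right edge: entrainment broken
        spec = CompetitionSpec.from_unplaced(
            VonMisesInput(A=0.1, T=T1, kappa=2.0),
            VonMisesInput(A=0.1, T=T1, kappa=20.0), n_iter=1000)
        lift = time_T1_map_phases(spec, iprc10)
        r = vector_strength(2 * np.pi * lift[1:] / iprc10.period)
        assert r < 0.3
        # the wrapped phases spread over most of the circle
        wrapped = np.mod(lift[1:], iprc10.period) / iprc10.period
        hist, _ = np.histogram(wrapped, bins=10, range=(0, 1))
        assert np.all(hist > 0)


class TestRobustness:
    def test_left_edge_primary_resists_all_distractors(self, cycle10,
                                                       iprc10):
        df = robustness_scan(cycle10, iprc10, "unequal",
                             kappa2_values=[0.01, 1.0, 20.0],
                             ratio_values=[0.5, 1.0, 1.5],
                             T1_over_Tstar=0.845, n_iter=400, burn_in=50)
        assert bool(df.locked.all())
        assert float(df.vector_strength.min()) > 0.8

    def test_right_edge_primary_loses_to_any_distractor(self, cycle10,
                                                        iprc10):
        df = robustness_scan(cycle10, iprc10, "unequal",
                             kappa2_values=[0.5, 20.0],
                             ratio_values=[0.75, 1.25],
                             T1_over_Tstar=1.0, n_iter=400, burn_in=50)
        assert float(df.vector_strength.max()) < 0.5

    def test_center_broken_only_by_faster_coherent_distractors(self, cycle10,
                                                               iprc10):
        df = robustness_scan(cycle10, iprc10, "unequal",
                             kappa2_values=[5.0],
                             ratio_values=[0.75, 1.25],
                             T1_over_Tstar=0.93, n_iter=400, burn_in=50)
        fast = df[df.T2_over_T1 == 0.75].iloc[0]
        slow = df[df.T2_over_T1 == 1.25].iloc[0]
        assert not fast.locked      # faster coherent distractor breaks it
        assert bool(slow.locked)    # slower one does not

    def test_equal_period_branch_reports_rotation_number(self, cycle10,
                                                         iprc10):
        df = robustness_scan(cycle10, iprc10, "equal",
                             kappa2_values=[0.1, 10.0],
                             ratio_values=[0.86], A1=0.1, A2=0.1)
        assert "rho_hat" in df.columns
        assert bool(df.locked.all())  # left-side entrainment survives


@pytest.fixture(scope="module")
def switch_results(params10, cycle10, iprc10):
    from pingctc import pulse_switch_prc

    grid = np.arange(0.0, 1.0, 0.05)
    return pulse_switch_prc(params10, cycle10, iprc10, phase_grid=grid)


class TestSwitching:
    def test_switching_window_is_contiguous(self, switch_results):
        flags = [r.switched for r in switch_results]
        runs = np.flatnonzero(np.diff(np.array(flags, dtype=int)) != 0)
        assert any(flags)
        assert len(runs) <= 2  # one contiguous block (possibly wrapping)

    def test_window_contains_half_but_not_point_three(self, switch_results):
        by_phase = {round(r.pulse_phase, 2): r for r in switch_results}
        assert by_phase[0.5].switched
        assert not by_phase[0.3].switched

    def test_pulse_near_i_volley_barely_shifts_phase(self, switch_results):
        # the I-volley region is input-insensitive: |PRC| small there,
        # well below the peak advance
        prcs = np.array([r.prc for r in switch_results])
        peak = np.nanmax(np.abs(prcs))
        assert min(abs(r.prc) for r in switch_results
                   if round(r.pulse_phase, 2) in (0.0, 0.05, 0.25, 0.3)) \
            < 0.1 * peak

    def test_symmetry_of_the_two_locked_solutions(self, switch_results):
        # d keeps one sign before the pulse and flips sign exactly for
        # switching phases: the two attractors are half-period images
        for r in switch_results:
            if not r.entrained:
                continue
            assert abs(r.d_before) == pytest.approx(abs(r.d_after), rel=1e-3)
            if r.switched:
                assert np.sign(r.d_before) == -np.sign(r.d_after)

    def test_zero_amplitude_pulse_changes_nothing(self, params10, cycle10,
                                                  iprc10):
        from pingctc import SquarePulse, pulse_switch_prc

        res = pulse_switch_prc(params10, cycle10, iprc10,
                               phase_grid=np.array([0.25, 0.5]),
                               pulse=SquarePulse(amplitude=0.0,
                                                 duration=2.0))
        for r in res:
            assert r.prc == pytest.approx(0.0, abs=1e-6)
            assert not r.switched
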