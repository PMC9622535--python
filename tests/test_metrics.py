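"""Hemodynamic metric formulas and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fontanflow import (FlowWaveform, InvalidInputError, hfd_lpa,
                        low_wss_area_fraction, pfd_lpa, power_loss,
                        pulsatility_index, tawss, wall_faces, weighted_pi,
                        wss_field)
from fontanflow.errors import GeometryError
from conftest import CROSS_Q


class TestFlowSplits:
    @pytest.mark.parametrize("qlpa,qrpa,expected", [
        (2.0, 3.0, 40.0), (1.0, 1.0, 50.0), (5.0, 0.0, 100.0)])
    def test_pfd_cases(self, qlpa, qrpa, expected):
        assert pfd_lpa(qlpa, qrpa) == pytest.approx(expected)

    def test_pfd_complement_sums_to_100(self):
        assert pfd_lpa(0.37, 0.63) + pfd_lpa(0.63, 0.37) == pytest.approx(100.0)

    def test_pfd_undefined_for_zero_flows(self):
        with pytest.raises(InvalidInputError):
            pfd_lpa(0.0, 0.0)

    @pytest.mark.parametrize("flux,qivc,expected", [
        (0.5, 1.0, 50.0), (0.0, 1.0, 0.0)])
    def test_hfd_cases(self, flux, qivc, expected):
        assert hfd_lpa(flux, qivc) == pytest.approx(expected)

    def test_hfd_requires_positive_ivc_flow(self):
        with pytest.raises(InvalidInputError):
            hfd_lpa(0.5, 0.0)


class TestPulsatility:
    def test_sinusoid_pi_equals_relative_amplitude(self):
        harm = np.zeros(15, complex)
        harm[0] = 0.25 * np.exp(-1j * np.pi / 2)  # Q = 1 + 0.5 sin
        wf = FlowWaveform.from_harmonics(1.0, harm, 1.0)
        assert pulsatility_index(wf) == pytest.approx(50.0, abs=1e-6)

    def test_constant_flow_has_zero_pi(self):
        assert pulsatility_index(FlowWaveform.constant(2.0)) == 0.0

    def test_extrema_tuple_accepted(self):
        assert pulsatility_index((1.5, 0.5, 1.0)) == pytest.approx(50.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(InvalidInputError):
            pulsatility_index((1.0, -1.0, 0.0))

    def test_wpi_hand_sums(self):
        assert weighted_pi([40.0], [1.0]) == pytest.approx(40.0)
        assert weighted_pi([40.0, 60.0], [1.0, 1.0]) == pytest.approx(50.0)
        # flows 1:2:1 with PIs 20/40/60 -> 20/4 + 40/2 + 60/4 = 40
        assert weighted_pi([20.0, 40.0, 60.0], [1.0, 2.0, 1.0]) == \
            pytest.approx(40.0)

    def test_wpi_raw_convention(self):
        # C_i = Q_i / mean(Q): equal flows give sum of PIs
        assert weighted_pi([40.0, 60.0], [1.0, 1.0], normalized=False) == \
            pytest.approx(100.0)

    @given(st.floats(min_value=0.0, max_value=200.0),
           st.lists(st.floats(min_value=0.1, max_value=10.0),
                    min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_wpi_of_identical_pis_is_that_pi(self, pi, flows):
        pis = [pi] * len(flows)
        assert weighted_pi(pis, flows) == pytest.approx(pi, rel=1e-9, abs=1e-9)


class TestTawss:
    def test_constant_history_returns_itself(self):
        tau = np.array([0.7, 1.3])
        times = np.linspace(0.0, 0.9, 10)
        out = tawss([tau] * 10, times, period=1.0)
        assert np.allclose(out, tau)

    def test_rectified_sine_integrates_to_2A_over_pi(self):
        amp = 1.7
        times = np.linspace(0.0, 1.0, 401)[:-1]
        snaps = [np.array([amp * abs(np.sin(np.pi * t))]) for t in times]
        out = tawss(snaps, times, period=1.0)
        assert out[0] == pytest.approx(2 * amp / np.pi, rel=1e-4)

    def test_single_snapshot_is_steady_wss(self):
        tau = np.array([0.4, 0.9])
        assert np.array_equal(tawss([tau], [0.0], period=1.0), tau)

    def test_incomplete_cycle_rejected(self):
        tau = np.array([1.0])
        with pytest.raises(InvalidInputError):
            tawss([tau, tau], [0.0, 0.3], period=1.0)


class TestLowWssArea:
    def test_all_below_and_all_above(self):
        assert low_wss_area_fraction(np.full(10, 0.2)) == 100.0
        assert low_wss_area_fraction(np.full(10, 1.0)) == 0.0

    def test_constructed_half_split(self):
        tau = np.concatenate([np.full(25, 0.1), np.full(25, 2.0)])
        assert low_wss_area_fraction(tau) == pytest.approx(50.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        tau = rng.uniform(0, 2, 500)
        fracs = [low_wss_area_fraction(tau, threshold=thr)
                 for thr in np.linspace(0.05, 2.0, 20)]
        assert np.all(np.diff(fracs) >= 0)

    def test_empty_wall_set_rejected(self):
        with pytest.raises(GeometryError):
            low_wss_area_fraction(np.array([]))


class TestWssField:
    def test_quiescent_field_has_zero_wss(self, cross_symmetric):
        sim, field, _, _ = cross_symmetric
        still = field.copy()
        still.u[:] = 0.0
        still.v[:] = 0.0
        still.w[:] = 0.0
        tau = wss_field(still, sim.grid)
        assert np.max(tau) == 0.0

    def test_wss_linear_in_velocity(self, tube_solves):
        grid, sim, field, _ = tube_solves[8]
        walls = wall_faces(grid)
        tau1 = wss_field(field, grid, walls)
        doubled = field.copy()
        doubled.u *= 2.0
        doubled.v *= 2.0
        doubled.w *= 2.0
        tau2 = wss_field(doubled, grid, walls)
        assert np.allclose(tau2, 2 * tau1, rtol=1e-9, atol=1e-12)

    def test_wall_area_model(self, cross_grid):
        walls = wall_faces(cross_grid)
        assert np.all(walls.areas == cross_grid.dx ** 2)
        assert walls.total_area > 0


class TestPowerLoss:
    def test_zero_flow_zero_loss(self, cross_symmetric):
        sim, field, _, _ = cross_symmetric
        still = field.copy()
        for arr in (still.u, still.v, still.w, still.p):
            arr[:] = 0.0
        assert power_loss(still, sim) == 0.0

    def test_positive_for_nontrivial_flow(self, cross_symmetric):
        sim, field, _, _ = cross_symmetric
        assert power_loss(field, sim) > 0.0

    def test_gauge_invariance_under_pressure_offset(self, cross_symmetric):
        sim, field, _, _ = cross_symmetric
        e0 = power_loss(field, sim)
        shifted = field.copy()
        shifted.p = field.p + 137.0
        e1 = power_loss(shifted, sim)
        # offset couples only to the net mass imbalance (~1e-15)
        assert e1 == pytest.approx(e0, rel=1e-6)
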