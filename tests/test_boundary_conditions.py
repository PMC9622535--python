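"""Waveform harmonics, plug inlets, resistances and the 0-D divider."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fontanflow import (FlowWaveform, InvalidInputError, OutletModel,
                        SamplingError, apc_factor, baffle_pressure_drop,
                        fourier_decompose, plug_inlet_velocity,
                        predict_split_0d, read_waveform_csv,
                        reconstruct_flow, straight_tube, voxelize)
from fontanflow.boundary_conditions import write_waveform_csv


def sampled(fn, period=1.0, n=64):
    t = np.arange(n) * period / n
    return np.column_stack([t, fn(t)])


class TestFourier:
    def test_constant_signal_has_zero_harmonics(self):
        mean, harm, rms = fourier_decompose(sampled(lambda t: 3.7 + 0 * t))
        assert mean == pytest.approx(3.7)
        assert np.allclose(np.abs(harm), 0.0, atol=1e-12)

    def test_single_sinusoid_amplitude_recovered(self):
        q0 = 2.0e-5
        mean, harm, _ = fourier_decompose(
            sampled(lambda t: q0 * (1 + 0.3 * np.sin(2 * np.pi * t))))
        assert mean == pytest.approx(q0, rel=1e-12)
        amps = 2 * np.abs(harm)
        assert amps[0] == pytest.approx(0.3 * q0, rel=1e-10)
        assert np.all(amps[1:] < 1e-10 * q0)

    def test_more_harmonics_reduce_reconstruction_error(self):
        # biphasic venous-like signal with content above 5 harmonics
        def venous(t):
            return (1.0 + 0.4 * np.sin(2 * np.pi * t)
                    + 0.25 * np.cos(4 * np.pi * t + 0.5)
                    + 0.12 * np.sin(12 * np.pi * t + 1.0)
                    + 0.05 * np.sin(16 * np.pi * t))
        s = sampled(venous, n=128)
        _, _, rms15 = fourier_decompose(s, n_harmonics=15)
        _, _, rms5 = fourier_decompose(s, n_harmonics=5)
        assert rms15 < rms5

    def test_too_few_samples_rejected(self):
        with pytest.raises(SamplingError):
            fourier_decompose(sampled(lambda t: 1 + 0 * t, n=16),
                              n_harmonics=15)

    def test_bandlimited_roundtrip_exact_at_sample_points(self):
        rng = np.random.default_rng(7)
        coeffs = rng.normal(size=10) + 1j * rng.normal(size=10)

        def sig(t):
            m = np.arange(1, 11)
            return 1.0 + 2 * np.real(
                np.exp(2j * np.pi * np.outer(t, m)) @ coeffs).ravel()
        s = sampled(sig, n=64)
        mean, harm, _ = fourier_decompose(s)
        recon = reconstruct_flow(mean, harm, s[:, 0], 1.0)
        assert np.max(np.abs(recon - s[:, 1])) < 1e-10 * np.max(np.abs(s[:, 1]))

    def test_nonuniform_samples_resampled(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 1, 80))
        q = 1 + 0.3 * np.sin(2 * np.pi * t)
        mean, harm, _ = fourier_decompose(np.column_stack([t, q]), period=1.0)
        assert mean == pytest.approx(1.0, abs=5e-3)
        assert 2 * np.abs(harm[0]) == pytest.approx(0.3, abs=2e-2)

    def test_periodicity_of_reconstruction(self):
        wf = FlowWaveform.from_samples(
            sampled(lambda t: 1 + 0.2 * np.sin(2 * np.pi * t)))
        for t in (0.13, 0.77):
            assert wf.q(t) == pytest.approx(wf.q(t + wf.period), rel=1e-12)

    def test_dense_mean_matches_mean_coefficient(self):
        wf = FlowWaveform.from_samples(
            sampled(lambda t: 2.0 + 0.5 * np.sin(2 * np.pi * t)
                    + 0.2 * np.cos(6 * np.pi * t)))
        t = np.arange(10_000) * wf.period / 10_000
        assert np.mean(wf.q(t)) == pytest.approx(wf.mean, rel=1e-6)

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_roundtrip_property_bandlimited(self, seed):
        rng = np.random.default_rng(seed)
        nmodes = int(rng.integers(1, 15))
        coeffs = rng.normal(size=nmodes) + 1j * rng.normal(size=nmodes)

        def sig(t):
            m = np.arange(1, nmodes + 1)
            return 5.0 + 2 * np.real(
                np.exp(2j * np.pi * np.outer(np.atleast_1d(t), m)) @ coeffs
            ).ravel()
        s = sampled(sig, n=64)
        mean, harm, rms = fourier_decompose(s)
        assert mean == pytest.approx(5.0, rel=1e-10)
        assert rms < 1e-10 * (1 + np.max(np.abs(s[:, 1])))


class TestPlugInlet:
    def test_velocity_is_flow_over_area(self):
        tube = straight_tube(0.010, 0.04)
        grid = voxelize(tube, 0.00125)
        port = grid.port("IN")
        vel = plug_inlet_velocity(1e-5, port)
        assert vel == pytest.approx(1e-5 / port.area, rel=1e-14)
        # summed discrete flux equals Q to machine precision
        assert vel * port.n_faces * grid.dx ** 2 == pytest.approx(1e-5,
                                                                  rel=1e-14)

    def test_zero_flow_closes_inlet(self):
        grid = voxelize(straight_tube(0.010, 0.04), 0.00125)
        assert plug_inlet_velocity(0.0, grid.port("IN")) == 0.0

    def test_missing_port_errors(self):
        from fontanflow.errors import ConfigurationError
        with pytest.raises(ConfigurationError):
            plug_inlet_velocity(1e-5, None)


class TestOutletModels:
    def test_apc_factor_cases(self):
        assert apc_factor(1.5, 1.0) == pytest.approx(1.5)
        assert apc_factor(1.0, 1.0) == pytest.approx(1.0)
        assert apc_factor(2.4, 1.2) == pytest.approx(2.0)
        with pytest.raises(InvalidInputError):
            apc_factor(1.0, 0.0)

    def test_effective_resistance_scales_linearly(self):
        m = OutletModel(resistance=1e7, apc_factor=1.3)
        assert m.effective_resistance == pytest.approx(1.3e7)
        assert OutletModel(2e7, 1.3).effective_resistance == pytest.approx(
            2 * m.effective_resistance)
        assert OutletModel(1e7, 2.6).effective_resistance == pytest.approx(
            2 * m.effective_resistance)

    def test_baffle_pressure_drop_linear(self):
        assert baffle_pressure_drop(1e7, 1e-5) == pytest.approx(100.0)
        assert baffle_pressure_drop(1e7, 0.0) == 0.0
        assert baffle_pressure_drop(3.3e7, 2e-5) == pytest.approx(
            2 * baffle_pressure_drop(3.3e7, 1e-5))

    def test_divider_cases(self):
        assert predict_split_0d(1e8, 1e8) == pytest.approx(50.0)
        assert predict_split_0d(3e8, 1e8) == pytest.approx(25.0)
        assert predict_split_0d(1.5e8, 1.0e8) == pytest.approx(40.0)
        with pytest.raises(InvalidInputError):
            predict_split_0d(-1.0, 1.0)

    @given(st.floats(min_value=1e4, max_value=1e12),
           st.floats(min_value=1e4, max_value=1e12),
           st.floats(min_value=1e-8, max_value=1e8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_divider_invariant_to_common_scaling(self, rl, rr, scale):
        a = predict_split_0d(rl, rr)
        b = predict_split_0d(rl * scale, rr * scale)
        assert a == pytest.approx(b, rel=1e-9)
        assert 0.0 < a < 100.0


class TestWaveformCsv:
    def test_roundtrip_and_lmin_conversion(self, tmp_path):
        wf = FlowWaveform.from_samples(
            sampled(lambda t: 1e-5 * (1 + 0.3 * np.sin(2 * np.pi * t))))
        p = tmp_path / "wf.csv"
        write_waveform_csv(str(p), wf)
        back = read_waveform_csv(str(p))
        assert back.q_avg == pytest.approx(wf.q_avg, rel=1e-6)

        p2 = tmp_path / "lmin.csv"
        with open(p2, "w") as fh:
            fh.write("time_s,flow_lmin\n")
            for i in range(40):
                fh.write(f"{i/40},{1.2}\n")
        wf2 = read_waveform_csv(str(p2), period=1.0)
        assert wf2.q_avg == pytest.approx(1.2 / 60000.0, rel=1e-9)

    def test_missing_flow_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_s,velocity\n0,1\n0.5,1\n")
        with pytest.raises(InvalidInputError):
            read_waveform_csv(str(p))
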