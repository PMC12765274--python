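"""WURST envelope, chirp phase, adiabaticity and flip-angle math."""

import numpy as np
import pytest

from chirpsifter.pulse_shapes import (
    ChirpPulse,
    PI_HALF_QCRIT,
    ResonatorProfile,
    amplitude_for_qcrit,
    apply_transfer_correction,
    export_waveform,
    flip_angle,
    instantaneous_frequency,
    phase_function,
    qcrit,
    qcrit_for_flip,
    sample_waveform,
    time_bandwidth_product,
    wurst_envelope,
)


class TestEnvelope:
    def test_center_is_full_amplitude(self, pi_pulse):
        assert wurst_envelope(pi_pulse, 0.0) == 1.0

    def test_truncation_endpoints_are_zero(self, pi_pulse):
        assert wurst_envelope(pi_pulse, -50.0) == pytest.approx(0.0, abs=1e-12)
        assert wurst_envelope(pi_pulse, 50.0) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_duration_closed_form(self):
        # 1 - sin(pi/4)^16 = 1 - 2^-8
        p = ChirpPulse(tp=100.0, sweep=500.0, nu1=20.0, n=16)
        assert wurst_envelope(p, 25.0) == pytest.approx(0.99609375, abs=1e-12)

    def test_outside_support_raises(self, pi_pulse):
        with pytest.raises(ValueError, match="support"):
            wurst_envelope(pi_pulse, 51.0)


class TestInstantaneousFrequency:
    def test_zero_at_sweep_center(self, pi_pulse):
        assert instantaneous_frequency(pi_pulse, 0.0) == 0.0

    def test_endpoint_is_half_sweep(self, pi_pulse):
        assert instantaneous_frequency(pi_pulse, 50.0) == pytest.approx(250.0)
        assert instantaneous_frequency(pi_pulse, -50.0) == pytest.approx(-250.0)

    def test_slope_is_sweep_rate(self, pi_pulse):
        t = np.linspace(-50, 50, 11)
        f = instantaneous_frequency(pi_pulse, t)
        slope = np.polyfit(t, f, 1)[0]
        assert slope == pytest.approx(500.0 / 100.0, rel=1e-12)

    def test_down_sweep_negates(self, pi_pulse):
        down = pi_pulse.conjugate()
        assert instantaneous_frequency(down, 30.0) == pytest.approx(
            -instantaneous_frequency(pi_pulse, 30.0)
        )


class TestPhaseFunction:
    def test_zero_sweep_limit_is_constant(self):
        # quadratic coefficient scales with SW; tiny SW -> nearly flat phase
        p = ChirpPulse(tp=100.0, sweep=1e-9, nu1=10.0)
        t = np.linspace(-50, 50, 7)
        assert np.allclose(phase_function(p, t), 0.0, atol=1e-9)

    def test_quadratic_coefficient(self, pi_pulse):
        t = np.linspace(-50, 50, 101)
        coeff = np.polyfit(t, phase_function(pi_pulse, t), 2)[0]
        assert coeff == pytest.approx(np.pi * 500.0 / 100.0 * 1e-3, rel=1e-9)

    def test_even_in_time(self, pi_pulse):
        t = np.linspace(0, 50, 20)
        assert np.allclose(
            phase_function(pi_pulse, t), phase_function(pi_pulse, -t)
        )

    def test_matches_numerical_integration(self, pi_pulse):
        # phase = integral of the instantaneous angular frequency, zero at 0
        t = np.linspace(-50.0, 50.0, 10001)
        dphi = 2e-3 * np.pi * instantaneous_frequency(pi_pulse, t)
        from scipy.integrate import cumulative_trapezoid

        num = cumulative_trapezoid(dphi, t, initial=0.0)
        num -= num[t.size // 2]
        assert np.max(np.abs(num - phase_function(pi_pulse, t))) < 1e-9


class TestAdiabaticity:
    def test_two_pi_pitfall_pin(self):
        # the classic unit check: 18.7 MHz, 100 ns, 500 MHz -> ~0.44
        assert round(qcrit(18.7, 100.0, 500.0), 2) == 0.44

    def test_quadratic_in_amplitude(self):
        assert qcrit(20.0, 100.0, 500.0) == pytest.approx(
            4.0 * qcrit(10.0, 100.0, 500.0)
        )

    def test_amplitude_roundtrip(self):
        nu1 = amplitude_for_qcrit(0.4413, 100.0, 500.0)
        assert 18.5 < nu1 < 19.0
        assert qcrit(nu1, 100.0, 500.0) == pytest.approx(0.4413, abs=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            qcrit(-1.0, 100.0, 500.0)
        with pytest.raises(ValueError):
            amplitude_for_qcrit(0.44, 0.0, 500.0)

    @pytest.mark.parametrize(
        "tp,sw,expected", [(100.0, 500.0, 50.0), (200.0, 500.0, 100.0)]
    )
    def test_tbp_values(self, tp, sw, expected):
        assert time_bandwidth_product(tp, sw) == pytest.approx(expected)

    def test_tbp_scaling_invariance(self):
        assert time_bandwidth_product(100.0, 500.0) == pytest.approx(
            time_bandwidth_product(300.0, 500.0 / 3.0)
        )


class TestFlipAngle:
    def test_limits(self):
        assert flip_angle(0.0) == pytest.approx(0.0)
        assert flip_angle(10.0) == pytest.approx(np.pi, abs=0.01)

    def test_pi_half_at_critical_value(self):
        assert flip_angle(PI_HALF_QCRIT) == pytest.approx(np.pi / 2, abs=1e-12)
        assert round(PI_HALF_QCRIT, 2) == 0.44

    def test_strictly_monotone(self):
        q = np.linspace(0.0, 20.0, 1000)
        assert np.all(np.diff(flip_angle(q)) > 0)

    def test_inverse_roundtrip(self):
        for beta in (0.3, np.pi / 2, 2.5):
            assert flip_angle(qcrit_for_flip(beta)) == pytest.approx(
                beta, abs=1e-12
            )
        assert qcrit_for_flip(0.0) == 0.0

    def test_full_inversion_unreachable(self):
        with pytest.raises(ValueError):
            qcrit_for_flip(np.pi)
        with pytest.raises(ValueError):
            flip_angle(-0.1)


class TestWaveform:
    def test_grid_and_peak(self, pi_pulse):
        wf = sample_waveform(pi_pulse)
        assert wf.times[0] == pytest.approx(-50.0)
        assert wf.times[-1] == pytest.approx(50.0)
        assert np.abs(wf.samples).max() == pytest.approx(
            pi_pulse.omega1_max, rel=1e-12
        )

    def test_zero_amplitude_pulse(self):
        p = ChirpPulse(tp=100.0, sweep=500.0, nu1=0.0)
        wf = sample_waveform(p)
        assert np.all(wf.samples == 0)

    def test_phase_matches_closed_form(self, pi_pulse):
        wf = sample_waveform(pi_pulse)
        inner = slice(2, -2)  # endpoints have zero amplitude, phase undefined
        got = np.unwrap(np.angle(wf.samples))[inner]
        want = phase_function(pi_pulse, wf.times[inner])
        got -= got[got.size // 2] - want[want.size // 2]
        assert np.max(np.abs(got - want)) < 1e-9

    def test_down_sweep_is_conjugate(self, pi_pulse):
        up = sample_waveform(pi_pulse)
        down = sample_waveform(pi_pulse.conjugate())
        assert np.allclose(down.samples, np.conj(up.samples))
        assert np.allclose(np.abs(down.samples), np.abs(up.samples))

    def test_undersampling_rejected(self, pi_pulse):
        with pytest.raises(ValueError, match="dt"):
            sample_waveform(pi_pulse, dt=1.0)

    def test_export_roundtrip(self, pi_pulse, tmp_path):
        wf = sample_waveform(pi_pulse, dt=0.15)
        path = tmp_path / "wf.txt"
        export_waveform(wf, path)
        data = np.loadtxt(path)
        nu = data[:, 1] + 1j * data[:, 2]
        assert np.allclose(nu * 2e6 * np.pi, wf.samples, atol=1e-6)


class TestTransferCorrection:
    def _profile(self, dip_at_edge=1.0):
        f = np.linspace(-300, 300, 121)
        resp = np.ones_like(f)
        if dip_at_edge != 1.0:
            resp = 1.0 - (1.0 - dip_at_edge) * (f / 300.0) ** 2
        return ResonatorProfile(f, resp)

    def test_flat_profile_is_identity(self, pi_pulse):
        wf = sample_waveform(pi_pulse)
        out = apply_transfer_correction(wf, pi_pulse, self._profile())
        assert np.allclose(out.samples, wf.samples)

    def test_half_response_doubles_before_rescale(self, pi_pulse):
        # response 0.5 at the up-sweep band edge boosts the late samples;
        # after rescaling the peak equals omega1_max again
        f = np.linspace(-300, 300, 121)
        resp = np.where(f > 200, 0.5, 1.0)
        wf = sample_waveform(pi_pulse)
        out = apply_transfer_correction(wf, pi_pulse, ResonatorProfile(f, resp))
        ratio = np.abs(out.samples) / np.maximum(np.abs(wf.samples), 1e-30)
        late = instantaneous_frequency(pi_pulse, wf.times) > 210
        early = np.abs(instantaneous_frequency(pi_pulse, wf.times)) < 100
        assert np.median(ratio[late]) == pytest.approx(
            2.0 * np.median(ratio[early]), rel=1e-6
        )
        assert np.abs(out.samples).max() == pytest.approx(
            pi_pulse.omega1_max, rel=1e-12
        )

    def test_phase_untouched(self, pi_pulse):
        wf = sample_waveform(pi_pulse)
        out = apply_transfer_correction(
            wf, pi_pulse, self._profile(dip_at_edge=0.5)
        )
        sel = np.abs(wf.samples) > 0
        assert np.allclose(
            np.angle(out.samples[sel]), np.angle(wf.samples[sel])
        )

    def test_deep_notch_rejected(self, pi_pulse):
        f = np.linspace(-300, 300, 121)
        resp = np.where(np.abs(f) < 20, 0.01, 1.0)
        wf = sample_waveform(pi_pulse)
        with pytest.raises(ValueError, match="floor"):
            apply_transfer_correction(wf, pi_pulse, ResonatorProfile(f, resp))

    def test_profile_must_cover_band(self, pi_pulse):
        f = np.linspace(-100, 100, 41)
        wf = sample_waveform(pi_pulse)
        with pytest.raises(ValueError, match="sweep"):
            apply_transfer_correction(
                wf, pi_pulse, ResonatorProfile(f, np.ones(41))
            )

    def test_profile_file_roundtrip(self, tmp_path):
        prof = self._profile(dip_at_edge=0.6)
        path = tmp_path / "prof.txt"
        prof.to_file(path)
        back = ResonatorProfile.from_file(path)
        assert np.allclose(back.freqs, prof.freqs)
        assert np.allclose(back.response, prof.response)


def test_chirp_pulse_validation():
    with pytest.raises(ValueError):
        ChirpPulse(tp=-1.0, sweep=500.0, nu1=10.0)
    with pytest.raises(ValueError):
        ChirpPulse(tp=100.0, sweep=500.0, nu1=10.0, sign=0)
    with pytest.raises(ValueError):
        ChirpPulse(tp=100.0, sweep=500.0, nu1=10.0, n=0.5)
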