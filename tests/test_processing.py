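"""2D processing pipeline: echo FT, profile correction, background
division, dipolar FT and Tikhonov inversion."""

import numpy as np
import pytest

from chirpsifter.dipolar_sifter import (
    SpinPairModel,
    dipolar_kernel,
    field_stepped_spectra,
    simulate_sifter_2d,
    synth_dataset,
)
from chirpsifter.processing_2d import (
    EchoTransient,
    ExcitationProfile,
    background_correct,
    dipolar_ft_2d,
    echo_ft,
    excitation_profile_from_field_steps,
    tikhonov_distance,
)

TIMES = np.arange(0, 4096, 16.0)


class TestEchoFT:
    def test_pure_cosine_gives_single_line(self):
        t = np.arange(0, 512, 1.0)
        tr = EchoTransient(times=t, signal=np.exp(2j * np.pi * 40e-3 * t),
                           center=256.0)
        freqs, spec = echo_ft(tr)
        assert freqs[np.argmax(np.abs(spec))] == pytest.approx(40.0, abs=2.0)

    def test_shift_theorem_removes_phase_ramp(self):
        t = np.arange(0, 512, 1.0)
        echo = np.exp(-((t - 300.0) / 40.0) ** 2).astype(complex)
        freqs, spec = echo_ft(EchoTransient(times=t, signal=echo))
        # properly re-centered: spectrum is real and positive at the peak
        band = np.abs(freqs) < 5
        assert np.all(spec.real[band] > 0)
        assert np.max(np.abs(spec.imag[band])) < 0.05 * np.max(spec.real)

    def test_truncated_echo_rejected(self):
        t = np.arange(0, 512, 1.0)
        sig = np.exp(-((t - 30.0) / 10.0) ** 2).astype(complex)
        with pytest.raises(ValueError, match="edge"):
            echo_ft(EchoTransient(times=t, signal=sig))

    def test_roundtrip_spectrum_from_time_signal(self):
        # FT of a synthetic echo built from a known spectrum recovers it
        offsets = np.linspace(-100, 100, 201)
        spec = np.exp(-((offsets - 10) / 35.0) ** 2)
        t = np.arange(0, 1024, 1.0)
        center = 512.0
        sig = spec @ np.exp(
            2j * np.pi * offsets[:, None] * 1e-3 * (t - center)[None, :]
        )
        freqs, out = echo_ft(EchoTransient(times=t, signal=sig, center=center))
        got = np.interp(offsets, freqs, out.real)
        got /= got.max()
        rms = np.sqrt(np.mean((got - spec / spec.max()) ** 2))
        assert rms < 0.01


class TestExcitationProfile:
    def test_uniform_sensitivity_recovers_flat(self):
        offsets = np.linspace(-120, 120, 97)
        spec = np.exp(-(offsets / 40.0) ** 2)
        shifts = np.linspace(-80, 80, 9)
        stepped = field_stepped_spectra(spec, offsets, np.ones_like(offsets),
                                        shifts)
        prof = excitation_profile_from_field_steps(stepped, offsets, shifts)
        assert np.allclose(prof.sensitivity, 1.0, atol=1e-9)

    def test_imposed_shape_recovered(self):
        offsets = np.linspace(-120, 120, 241)
        spec = np.exp(-(offsets / 40.0) ** 2)
        true = 0.5 + 0.5 * np.exp(-(offsets / 70.0) ** 2)
        shifts = np.linspace(-90, 90, 25)
        stepped = field_stepped_spectra(spec, offsets, true, shifts)
        prof = excitation_profile_from_field_steps(stepped, offsets, shifts)
        got = prof(offsets[np.abs(offsets) <= 90])
        want = true[np.abs(offsets) <= 90] / true.max()
        assert np.sqrt(np.mean((got - want) ** 2)) < 0.02

    def test_division_restores_spectral_shape(self):
        offsets = np.linspace(-120, 120, 241)
        spec = np.exp(-(offsets / 40.0) ** 2)
        true = 0.6 + 0.4 * np.cos(offsets / 120.0)
        shifts = np.linspace(-90, 90, 19)
        stepped = field_stepped_spectra(spec, offsets, true, shifts)
        prof = excitation_profile_from_field_steps(stepped, offsets, shifts)
        sel = np.abs(offsets) <= 90
        distorted = spec * true / true.max()
        restored = distorted[sel] / prof(offsets[sel])
        assert np.sqrt(np.mean((restored - spec[sel]) ** 2)) < 0.02

    def test_too_few_steps_rejected(self):
        with pytest.raises(ValueError, match="5"):
            excitation_profile_from_field_steps([np.ones(3)] * 3,
                                                np.arange(3.0),
                                                [0.0, 1.0, 2.0])

    def test_tracked_point_must_stay_in_band(self):
        offsets = np.linspace(-10, 10, 21)
        with pytest.raises(ValueError, match="band"):
            excitation_profile_from_field_steps(
                [np.ones(21)] * 6, offsets, [-30, -20, -5, 0, 5, 20]
            )


class TestBackgroundCorrect:
    def test_identity_when_flat(self):
        # damped modulation on a flat unit background: nothing to correct
        y = 1.0 + 0.3 * np.cos(2 * np.pi * 2e-3 * TIMES) * np.exp(
            -((TIMES / 800.0) ** 2)
        )
        corr, k = background_correct(y, TIMES, np.ones_like(TIMES))
        assert k == pytest.approx(0.0, abs=0.01)
        assert np.allclose(corr, y, rtol=0.02)

    def test_exact_for_known_envelope_and_rate(self):
        ff = 0.5 + 0.5 * dipolar_kernel(TIMES, np.array([3.5]))[:, 0]
        env = np.exp(-((TIMES * 1e-3) / 6.0) ** 2)
        k_true = 0.12
        trace = ff * env * np.exp(-k_true * TIMES * 1e-3)
        corr, k = background_correct(trace, TIMES, env)
        assert k == pytest.approx(k_true, abs=0.03)
        # corrected trace oscillates like the form factor, tail near 1
        assert np.corrcoef(corr, ff)[0, 1] > 0.98
        assert np.mean(corr[-int(corr.size * 0.2):]) == pytest.approx(
            1.0, abs=0.05
        )

    def test_modulation_free_trace_becomes_flat_one(self):
        env = np.exp(-((TIMES * 1e-3) / 5.0) ** 2)
        trace = 0.8 * env * np.exp(-0.08 * TIMES * 1e-3)
        corr, _ = background_correct(trace, TIMES, env)
        assert np.allclose(corr, 1.0, atol=1e-6)

    def test_nonpositive_sidre_rejected(self):
        sidre = np.ones_like(TIMES)
        sidre[5] = 0.0
        with pytest.raises(ValueError, match="positive"):
            background_correct(np.ones_like(TIMES), TIMES, sidre)


class TestDipolarFT2D:
    def test_single_frequency_column(self):
        m = SpinPairModel.collinear(3.5)
        ds = synth_dataset(m, TIMES, lam=0.6, noise=0.0, seed=0,
                           n_orient=900)
        out = dipolar_ft_2d(ds)
        i0 = int(np.argmin(np.abs(ds.offsets)))
        nu = out.dominant_frequency(i0, f_min=0.3)
        assert nu == pytest.approx(52.04 / 3.5**3, rel=0.08)

    def test_edge_to_center_dispersion_factor_2(self):
        m = SpinPairModel.collinear(3.5)
        ds = synth_dataset(m, TIMES, lam=0.6, noise=0.0, seed=0,
                           n_orient=2000)
        out = dipolar_ft_2d(ds)
        cols = np.where(~out.excluded)[0]
        center = cols[np.argmin(np.abs(ds.offsets[cols]))]
        edges = (cols[0], cols[-1])
        f_c = out.dominant_frequency(center, f_min=0.3)
        f_e = max(out.dominant_frequency(e, f_min=0.3) for e in edges)
        assert f_e / f_c == pytest.approx(2.0, rel=0.1)

    def test_weak_columns_excluded(self):
        m = SpinPairModel.collinear(3.5)
        ds = synth_dataset(m, TIMES, noise=0.0, seed=0, n_orient=900)
        out = dipolar_ft_2d(ds, snr_floor=0.05)
        assert out.excluded.any() and not out.excluded.all()
        assert np.all(out.matrix[out.excluded] == 0)

    def test_heatmap_normalized_and_squared(self):
        m = SpinPairModel.collinear(3.5)
        ds = synth_dataset(m, TIMES[:256], noise=0.0, seed=0, n_orient=900)
        out = dipolar_ft_2d(ds)
        hm = out.heatmap()
        live = ~out.excluded
        assert np.allclose(hm[live].max(axis=1), 1.0)
        assert np.all(hm <= 1.0)


class TestTikhonov:
    def test_single_distance_recovery(self):
        K = dipolar_kernel(TIMES, np.array([3.5]))[:, 0]
        F = 0.4 + 0.6 * K
        r = np.arange(2.0, 5.0001, 0.05)
        dist = tikhonov_distance(TIMES, F, r)
        assert abs(dist.peak - 3.5) <= 0.05
        assert np.all(dist.density >= 0)
        assert np.trapezoid(dist.density, r) == pytest.approx(1.0)

    def test_two_component_mixture_resolved(self):
        r = np.arange(2.0, 5.0001, 0.05)
        K = dipolar_kernel(TIMES, np.array([3.0, 3.8]))
        F = 0.3 + 0.35 * K[:, 0] + 0.35 * K[:, 1]
        rng = np.random.default_rng(5)
        F = F + rng.normal(0, 0.3 / 50.0, F.shape)  # SNR ~ 50 on depth 0.7
        dist = tikhonov_distance(TIMES, F, r)
        dens = dist.density
        peaks = [
            i for i in range(1, r.size - 1)
            if dens[i] > dens[i - 1] and dens[i] > dens[i + 1]
            and dens[i] > 0.2 * dens.max()
        ]
        pk = sorted(r[i] for i in peaks)
        assert any(abs(p - 3.0) < 0.15 for p in pk)
        assert any(abs(p - 3.8) < 0.15 for p in pk)

    def test_huge_alpha_gives_maximally_smooth_density(self):
        # the second-difference penalty drives the curvature to zero
        K = dipolar_kernel(TIMES[:128], np.array([3.5]))[:, 0]
        r = np.arange(2.5, 4.5001, 0.1)
        dist = tikhonov_distance(TIMES[:128], 0.5 + 0.5 * K, r, alpha=1e4)
        curv = np.abs(np.diff(dist.density, 2))
        sharp = tikhonov_distance(TIMES[:128], 0.5 + 0.5 * K, r, alpha=1e-4)
        curv_sharp = np.abs(np.diff(sharp.density, 2))
        assert curv.max() < 1e-3 * max(curv_sharp.max(), 1e-9)

    def test_gcv_also_recovers(self):
        K = dipolar_kernel(TIMES[:192], np.array([3.2]))[:, 0]
        r = np.arange(2.0, 4.5001, 0.1)
        dist = tikhonov_distance(TIMES[:192], 0.5 + 0.5 * K, r, alpha="gcv")
        assert abs(dist.peak - 3.2) <= 0.1


def test_full_synthetic_pipeline_recovers_inputs():
    """synth_dataset -> profile correction + background + Tikhonov gets the
    spectrum and the distance back."""
    m = SpinPairModel.collinear(3.5)
    ideal = simulate_sifter_2d(m, TIMES, n_orient=1200, lam=0.5)
    true_spec = ideal.spectrum
    prof = 0.5 + 0.5 * np.exp(-(ideal.offsets / 80.0) ** 2)
    ds = synth_dataset(m, TIMES, lam=0.5, k_bg=0.1, env_tau=6.0,
                       noise=0.005, seed=11, profile=prof, n_orient=1200)

    shifts = np.linspace(-100, 80, 13)
    stepped = field_stepped_spectra(true_spec, ds.offsets, prof, shifts)
    ep = excitation_profile_from_field_steps(stepped, ds.offsets, shifts)
    corrected = ds.spectrum / np.clip(ep(ds.offsets), 1e-3, None)
    corrected *= true_spec.max() / corrected.max()
    rms = np.sqrt(np.mean((corrected - true_spec) ** 2)) / true_spec.max()
    assert rms < 0.02

    trace = ds.signal.sum(axis=0)
    corr, _ = background_correct(trace, TIMES, ds.sidre)
    r = np.arange(2.0, 5.0001, 0.05)
    dist = tikhonov_distance(TIMES, corr, r)
    assert abs(dist.peak - 3.5) <= 0.05


def test_excitation_profile_validation():
    with pytest.raises(ValueError, match="positive"):
        ExcitationProfile(np.arange(3.0), np.array([1.0, 0.0, 0.5]))
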