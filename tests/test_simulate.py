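"""Synthetic-signal generators: construction rules and determinism."""

import numpy as np
import pytest
from scipy import signal as sps

from emipac.simulate import (AMParams, BurstModelParams, GaussianTrainParams,
                             MultimodalParams, am_envelope,
                             gaussian_spike_sigma, gen_amplitude_modulated,
                             gen_coupled_bursts, gen_filtered_noise_hf,
                             gen_gaussian_train, gen_multimodal,
                             gen_pink_noise, gen_random_bursts,
                             multimodal_envelope)


def _count_sine_cycles(f_p, duration, fs):
    """Brute-force cycle count from zero crossings of the clean sine."""
    t = np.arange(int(round(duration * fs))) / fs
    s = np.sin(2 * np.pi * f_p * t)
    upward = np.sum((s[:-1] < 0) & (s[1:] >= 0))
    return upward


@pytest.mark.parametrize("gen,params", [
    (gen_coupled_bursts, BurstModelParams()),
    (gen_random_bursts, BurstModelParams(filling=0.5)),
    (gen_amplitude_modulated, AMParams()),
    (gen_multimodal, MultimodalParams(n_modes=2)),
    (gen_filtered_noise_hf, None),
])
def test_generators_are_pure_functions_of_seed(gen, params):
    if params is None:
        a, b = gen(0.1, seed=5), gen(0.1, seed=5)
        c = gen(0.1, seed=6)
    else:
        a, b = gen(params, seed=5), gen(params, seed=5)
        c = gen(params, seed=6)
    np.testing.assert_array_equal(a.samples, b.samples)
    assert not np.array_equal(a.samples, c.samples)


class TestCoupledBursts:
    def test_default_length_and_rate(self):
        x = gen_coupled_bursts(BurstModelParams(), seed=0)
        assert x.n == 5120
        assert x.fs == 512.0

    def test_pure_sine_when_bursts_and_noise_off(self):
        p = BurstModelParams(amplitudes_ratio=0.0, noise_level=0.0)
        x = gen_coupled_bursts(p, seed=0)
        assert np.max(np.abs(x.samples)) == pytest.approx(1.0, abs=1e-3)
        t = x.times
        np.testing.assert_allclose(x.samples, np.sin(2 * np.pi * 6 * t),
                                   atol=1e-12)

    def test_full_filling_burst_count_matches_cycle_count(self):
        p = BurstModelParams(noise_level=0.0, filling=1.0)
        x = gen_coupled_bursts(p, seed=0)
        clean = np.sin(2 * np.pi * p.f_p * x.times)
        residual = x.samples - clean
        # count burst envelopes via peaks of the rectified residual
        env = np.abs(sps.hilbert(residual))
        peaks, _ = sps.find_peaks(env, height=0.05, distance=30)
        cycles = _count_sine_cycles(p.f_p, p.duration, p.fs)
        assert abs(len(peaks) - cycles) <= 1

    @pytest.mark.parametrize("filling", [0.3, 0.7])
    def test_partial_filling_burst_count(self, filling):
        p = BurstModelParams(noise_level=0.0, filling=filling)
        x = gen_coupled_bursts(p, seed=3)
        residual = x.samples - np.sin(2 * np.pi * p.f_p * x.times)
        env = np.abs(sps.hilbert(residual))
        peaks, _ = sps.find_peaks(env, height=0.05, distance=30)
        expected = round(filling * _count_sine_cycles(p.f_p, p.duration,
                                                      p.fs))
        assert abs(len(peaks) - expected) <= 1

    def test_invalid_filling_rejected(self):
        with pytest.raises(ValueError):
            BurstModelParams(filling=1.5)


class TestRandomBursts:
    def test_burst_phases_are_circularly_uniform(self):
        p = BurstModelParams(noise_level=0.0, duration=60.0)
        x = gen_random_bursts(p, seed=9)
        residual = x.samples - np.sin(2 * np.pi * p.f_p * x.times)
        env = np.abs(sps.hilbert(residual))
        peaks, _ = sps.find_peaks(env, height=0.05, distance=30)
        phases = 2 * np.pi * p.f_p * x.times[peaks]
        resultant = np.abs(np.mean(np.exp(1j * phases)))
        assert resultant < 0.15  # -> 0 as duration grows

    def test_total_burst_energy_matches_coupled_model(self):
        # same atom count as the coupled model; energy is additive even when
        # randomly placed atoms overlap
        p = BurstModelParams(noise_level=0.0)
        energies = []
        for gen in (gen_coupled_bursts, gen_random_bursts):
            x = gen(p, seed=4)
            residual = x.samples - np.sin(2 * np.pi * p.f_p * x.times)
            energies.append(np.sum(residual ** 2))
        assert energies[1] == pytest.approx(energies[0], rel=0.25)


class TestAmplitudeModulation:
    def test_chi_one_gives_constant_envelope(self):
        p = AMParams(chi=1.0)
        t = np.arange(100) / p.fs
        env = am_envelope(p, t)
        np.testing.assert_allclose(env, p.a_fa)

    def test_chi_zero_envelope_spans_zero_to_max(self):
        p = AMParams(chi=0.0, a_noise=0.0)
        t = np.arange(51200) / p.fs
        env = am_envelope(p, t)
        assert env.min() == pytest.approx(0.0, abs=1e-6)
        assert env.max() == pytest.approx(p.a_fa, abs=1e-6)

    def test_envelope_extreme_ratio_equals_chi(self):
        # Hilbert envelope of the noiseless fast component
        p = AMParams(chi=0.1, a_noise=0.0, a_fp=0.0)
        x = gen_amplitude_modulated(p, seed=0)
        env = np.abs(sps.hilbert(x.samples))[500:-500]
        assert env.min() / env.max() == pytest.approx(0.1, rel=0.05)

    def test_envelope_identity_against_closed_form(self):
        p = AMParams(chi=0.1, a_noise=0.0, a_fp=0.0)
        x = gen_amplitude_modulated(p, seed=0)
        hilbert_env = np.abs(sps.hilbert(x.samples))[500:-500]
        analytic = am_envelope(p, x.times)[500:-500]
        rms = np.sqrt(np.mean((hilbert_env - analytic) ** 2))
        assert rms / np.sqrt(np.mean(analytic ** 2)) < 0.02

    def test_chi_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            AMParams(chi=1.2)


class TestMultimodal:
    def test_each_mode_normalised_to_unit_interval(self):
        p = MultimodalParams(n_modes=1, chi=0.0)
        t = np.arange(5120) / p.fs
        env = multimodal_envelope(p, t) / p.a_fa
        assert env.min() == pytest.approx(0.0, abs=1e-9)
        assert env.max() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n_modes,expected_maxima", [(1, 1), (3, 3)])
    def test_phase_histogram_modality(self, n_modes, expected_maxima):
        # brute-force binning of the noiseless envelope over slow phase
        p = MultimodalParams(n_modes=n_modes)
        t = np.arange(51200) / p.fs
        env = multimodal_envelope(p, t)
        phase = (2 * np.pi * p.f_p * t - np.pi / 2) % (2 * np.pi)
        bins = np.floor(phase / (2 * np.pi) * 18).astype(int)
        hist = np.array([env[bins == b].mean() for b in range(18)])
        n_max = sum(hist[b] > hist[(b - 1) % 18]
                    and hist[b] > hist[(b + 1) % 18] for b in range(18))
        assert n_max == expected_maxima

    def test_requires_at_least_one_mode(self):
        with pytest.raises(ValueError):
            MultimodalParams(n_modes=0)


class TestFilteredNoise:
    def test_fast_component_max_is_exactly_rescaled(self):
        x = gen_filtered_noise_hf(0.0, seed=2)
        hf = x.samples - np.sin(2 * np.pi * 6.0 * x.times)
        assert np.max(np.abs(hf)) == pytest.approx(0.1, abs=1e-9)

    def test_spectrum_has_peaks_only_at_slow_and_fast_bands(self):
        x = gen_filtered_noise_hf(0.0, seed=2)
        f, p = sps.periodogram(x.samples, fs=x.fs)
        strong = f[p > p.max() * 1e-4]
        assert np.all((strong < 10) | ((strong > 70) & (strong < 85)))

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            gen_filtered_noise_hf(0.1, seed=0, duration=0.0)


class TestGaussianTrain:
    def test_periodic_spike_count(self):
        p = GaussianTrainParams()
        bg = gen_pink_noise(10000, 1000.0, seed=1)
        x = gen_gaussian_train(p, bg, seed=2)
        # spikes are ~5 SD of background; count prominent peaks
        peaks, _ = sps.find_peaks(x.samples, height=2.5 * bg.samples.std(),
                                  distance=50)
        assert abs(len(peaks) - 100) <= 10

    def test_spike_sigma_fwhm_conversion(self):
        assert gaussian_spike_sigma(0.015) == pytest.approx(0.00637, abs=5e-5)

    def test_spike_height_before_filtering(self):
        p = GaussianTrainParams(amplitude_sd=5.0)
        bg = gen_pink_noise(10000, 1000.0, seed=3)
        x = gen_gaussian_train(p, bg, seed=4)
        # band-limited filtering attenuates only mildly at 15 ms FWHM
        assert x.samples.max() > 3.0 * bg.samples.std()

    def test_short_background_rejected(self):
        p = GaussianTrainParams()
        bg = gen_pink_noise(2000, 1000.0, seed=5)
        with pytest.raises(ValueError):
            gen_gaussian_train(p, bg, seed=6)


class TestPinkNoise:
    def test_psd_slope_is_minus_one(self):
        psds = []
        for s in range(100):
            x = gen_pink_noise(4096, 512.0, seed=s)
            f, p = sps.periodogram(x.samples, fs=512.0)
            psds.append(p)
        mean_psd = np.mean(psds, axis=0)
        band = (f >= 1) & (f <= 100)
        slope = np.polyfit(np.log(f[band]), np.log(mean_psd[band]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_zero_mean(self):
        x = gen_pink_noise(8192, 512.0, seed=0)
        assert abs(x.samples.mean()) < 3 * x.samples.std() / np.sqrt(x.n)

    def test_rejects_empty_request(self):
        with pytest.raises(ValueError):
            gen_pink_noise(0, 512.0, seed=0)
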