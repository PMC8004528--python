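"""The eMI pipeline: screening, phase identification, averaging,
surrogates, comodulogram construction and spectra."""

import numpy as np
import pytest
from scipy import signal as sps

from emipac import (ComodulogramGrid, InsufficientCyclesError, TimeSeries,
                    average_sections, extract_low_freq, find_cycle_maxima,
                    morlet_energy, run_emi, screen_phase_frequencies,
                    section_spectra, surrogate_maps, trim_edges)
from emipac.emi import phase_distributions
from emipac.simulate import (BurstModelParams, gen_coupled_bursts,
                             gen_pink_noise, gen_random_bursts)

FP_GRID = np.arange(2.0, 10.5, 1.0)


class TestScreen:
    def test_pink_noise_alone_is_rarely_significant(self):
        # expected significant fraction ~5% of f_p bins across realisations
        fractions = []
        for s in range(30):
            x = gen_pink_noise(5120, 512.0, seed=3000 + s)
            scr = screen_phase_frequencies(x, FP_GRID, n_pink=100, seed=1)
            fractions.append(scr.significant.mean())
        assert np.mean(fractions) < 0.15

    def test_strong_sine_in_pink_noise_is_significant(self):
        x = gen_pink_noise(5120, 512.0, seed=4)
        t = x.times
        spiked = x.with_samples(x.samples + 2.0 * np.sin(2 * np.pi * 6 * t))
        scr = screen_phase_frequencies(spiked, FP_GRID, n_pink=100, seed=1)
        assert scr.significant[FP_GRID.tolist().index(6.0)]

    def test_ratio_near_one_for_featureless_spectrum(self):
        x = gen_pink_noise(20480, 512.0, seed=5)
        scr = screen_phase_frequencies(x, FP_GRID, n_pink=50, seed=1)
        assert np.median(scr.ratio) == pytest.approx(1.0, abs=0.5)


class TestLowFreqExtraction:
    def test_in_band_sine_preserved(self):
        fs = 512.0
        t = np.arange(int(10 * fs)) / fs
        x = TimeSeries(np.sin(2 * np.pi * 6 * t), fs)
        y = extract_low_freq(x, 6.0, 1.0)
        # narrow-band transients decay within ~2 s; check the middle third
        assert np.max(np.abs(y.samples[1700:3400])) == pytest.approx(
            1.0, rel=0.05)

    def test_zero_phase_no_lag(self):
        fs = 512.0
        t = np.arange(int(10 * fs)) / fs
        x = TimeSeries(np.sin(2 * np.pi * 6 * t), fs)
        y = extract_low_freq(x, 6.0, 1.0)
        lags = sps.correlation_lags(x.n, x.n)
        xc = sps.correlate(y.samples, x.samples)
        assert lags[np.argmax(xc)] == 0

    def test_dc_removed(self):
        x = TimeSeries(np.full(5120, 3.0), 512.0)
        y = extract_low_freq(x, 6.0, 1.0)
        assert np.max(np.abs(y.samples)) < 1e-6

    def test_invalid_band_rejected(self):
        x = TimeSeries(np.ones(5120), 512.0)
        with pytest.raises(ValueError):
            extract_low_freq(x, 0.4, 1.0)


class TestCycleMaxima:
    def _clean_sine(self, duration=10.0, f_p=6.0, fs=512.0):
        t = np.arange(int(duration * fs)) / fs
        return TimeSeries(np.sin(2 * np.pi * f_p * t), fs)

    def test_clean_sine_maxima_spacing_and_selections(self):
        s = self._clean_sine()
        cm = find_cycle_maxima(s, 6.0)
        spacing = np.diff(cm.indices)
        assert np.all(np.abs(spacing - 512 / 6) <= 1)
        # one-cycle windows: nearly every interior maximum is kept
        assert cm.n_max_a >= 0.9 * cm.indices.size
        # three-cycle windows: every third maximum
        assert cm.n_max_b == pytest.approx(cm.indices.size / 3, abs=2)

    def test_low_prominence_ripples_discarded(self):
        s = self._clean_sine()
        ripple = 0.001 * np.sin(2 * np.pi * 200 * s.times)
        cm_clean = find_cycle_maxima(s, 6.0)
        cm_ripple = find_cycle_maxima(s.with_samples(s.samples + ripple), 6.0)
        assert cm_ripple.indices.size == cm_clean.indices.size

    def test_short_signal_abandoned(self):
        s = self._clean_sine(duration=0.4)
        with pytest.raises(InsufficientCyclesError):
            find_cycle_maxima(s, 6.0)

    def test_window_lengths_are_odd(self):
        cm = find_cycle_maxima(self._clean_sine(), 6.0)
        assert cm.len_a % 2 == 1 and cm.len_b % 2 == 1


@pytest.fixture(scope="module")
def averaging_inputs():
    x = gen_coupled_bursts(BurstModelParams(noise_level=0.05), seed=55)
    freqs = np.arange(40.0, 125.0, 5.0)
    e = trim_edges(morlet_energy(x, freqs, w=5.0))
    offset = int(round(x.fs * 5.0 / freqs.min()))
    s_fp = extract_low_freq(x, 6.0, 1.0)
    cm = find_cycle_maxima(s_fp, 6.0)
    return x, e, offset, s_fp, cm


class TestAveraging:
    def test_constant_map_average_is_identity(self, averaging_inputs):
        x, e, offset, s_fp, cm = averaging_inputs
        const = type(e)(energy=np.full_like(e.energy, 2.5),
                        times=e.times, freqs=e.freqs, w=e.w, fs=e.fs)
        sec = average_sections(const, s_fp, x, cm, offset)
        np.testing.assert_allclose(sec.m_a, 2.5)

    def test_averaged_slow_trace_is_one_centred_cycle(self, averaging_inputs):
        x, e, offset, s_fp, cm = averaging_inputs
        sec = average_sections(e, s_fp, x, cm, offset)
        # peak of the averaged filtered trace sits at the window centre
        assert abs(np.argmax(sec.sp_a) - (cm.len_a - 1) // 2) <= 1
        assert sec.sp_a.size == cm.len_a

    def test_coupled_bursts_map_peaks_once_per_cycle(self, averaging_inputs):
        x, e, offset, s_fp, cm = averaging_inputs
        sec = average_sections(e, s_fp, x, cm, offset)
        row = sec.m_a[np.argmin(np.abs(e.freqs - 75.0))]
        peaks, _ = sps.find_peaks(row, height=row.max() * 0.5)
        assert len(peaks) == 1

    def test_phase_at_window_centre_is_near_zero(self, averaging_inputs):
        x, e, offset, s_fp, cm = averaging_inputs
        sec = average_sections(e, s_fp, x, cm, offset)
        assert abs(sec.phase_a[(cm.len_a - 1) // 2]) < 0.3


class TestSurrogateMaps:
    def test_reproducible_with_seed(self, averaging_inputs):
        x, e, offset, s_fp, cm = averaging_inputs
        a = surrogate_maps(e, cm, offset, 5, np.random.default_rng(3))
        b = surrogate_maps(e, cm, offset, 5, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_energy_preserved_under_jitter(self, averaging_inputs):
        x, e, offset, s_fp, cm = averaging_inputs
        sec = average_sections(e, s_fp, x, cm, offset)
        ens = surrogate_maps(e, cm, offset, 40, np.random.default_rng(4))
        assert ens.mean() == pytest.approx(sec.m_a.mean(), rel=0.05)

    def test_uncoupled_map_within_surrogate_envelope(self):
        x = gen_random_bursts(BurstModelParams(), seed=66)
        freqs = np.arange(40.0, 125.0, 5.0)
        e = trim_edges(morlet_energy(x, freqs, w=5.0))
        offset = int(round(x.fs * 5.0 / freqs.min()))
        s_fp = extract_low_freq(x, 6.0, 1.0)
        cm = find_cycle_maxima(s_fp, 6.0)
        sec = average_sections(e, s_fp, x, cm, offset)
        ens = surrogate_maps(e, cm, offset, 100, np.random.default_rng(5))
        lo = np.quantile(ens, 0.005, axis=0)
        hi = np.quantile(ens, 0.995, axis=0)
        inside = (sec.m_a >= lo) & (sec.m_a <= hi)
        assert inside.mean() > 0.9


class TestComodulogramConstruction:
    def test_centered_surrogate_mean_is_zero(self, coupled_emi_result):
        import warnings as _warnings
        surr = coupled_emi_result.surrogate_values
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            centered_mean = np.nanmean(surr, axis=0)
        valid = ~np.isnan(centered_mean)
        assert np.allclose(centered_mean[valid], 0.0, atol=1e-12)

    def test_global_maximum_at_simulated_pair(self, coupled_emi_result):
        f_p, f_a = coupled_emi_result.comodulogram.argmax_pair()
        assert abs(f_p - 6.0) <= 1.0
        assert abs(f_a - 77.0) <= 10.0

    def test_abandoned_phase_frequencies_are_nan_columns(
            self, coupled_emi_result):
        vals = coupled_emi_result.comodulogram.values
        grid = coupled_emi_result.grid
        for f_p, _reason in coupled_emi_result.abandoned.items():
            i = int(np.argmin(np.abs(grid.f_p - f_p)))
            assert np.all(np.isnan(vals[i]))

    def test_significant_columns_confined_near_simulated_f_p(
            self, coupled_emi_result):
        grid = coupled_emi_result.grid
        sig_fp = {float(grid.f_p[i])
                  for i, j in np.argwhere(coupled_emi_result.mask)}
        assert sig_fp and sig_fp <= {5.0, 6.0, 7.0}

    def test_deterministic_rerun(self, coupled_signal, reduced_grid,
                                 coupled_emi_result):
        res2 = run_emi(coupled_signal, reduced_grid, n_surr=60, seed=11)
        np.testing.assert_array_equal(res2.comodulogram.values,
                                      coupled_emi_result.comodulogram.values)
        np.testing.assert_array_equal(res2.mask, coupled_emi_result.mask)


class TestPhaseDistributions:
    def test_distributions_sum_to_one(self, coupled_emi_result):
        p = coupled_emi_result.phase_dist
        sums = p.sum(axis=-1)
        valid = ~np.isnan(sums)
        assert np.allclose(sums[valid], 1.0, atol=1e-9)

    def test_modal_bin_matches_burst_phase(self, coupled_emi_result):
        # bursts sit on the slow-oscillation peak -> analytic phase 0
        grid = coupled_emi_result.grid
        i, j = grid.nearest_pair_index(6.0, 77.0)
        p = coupled_emi_result.phase_dist[i, j]
        modal = np.argmax(p)
        centers = -np.pi + (np.arange(18) + 0.5) * 2 * np.pi / 18
        assert abs(centers[modal]) < 2 * np.pi / 18 + 1e-9


class TestSectionSpectra:
    def test_spectra_unit_normalised(self, coupled_emi_result):
        for spec in coupled_emi_result.spectra.values():
            assert spec.avg_spectrum.sum() == pytest.approx(1.0)
            assert spec.spectrum_of_avg.sum() == pytest.approx(1.0)

    def test_synchronised_bursts_survive_averaging(self, coupled_emi_result):
        spec = coupled_emi_result.spectra[6.0]
        k = np.argmin(np.abs(spec.freqs - 77.0))
        sl = slice(max(k - 2, 0), k + 3)
        assert spec.spectrum_of_avg[sl].max() >= spec.avg_spectrum[sl].max()

    @staticmethod
    def _raw_retention(gen, seed):
        """Raw (unnormalised) power at 77 Hz retained by averaging:
        periodogram of the averaged sections over the mean of per-section
        periodograms."""
        x = gen(BurstModelParams(noise_level=0.02), seed=seed)
        s_fp = extract_low_freq(x, 6.0, 1.0)
        cm = find_cycle_maxima(s_fp, 6.0)
        half = (cm.len_b - 1) // 2
        secs = np.array([x.samples[c - half:c + half + 1]
                         for c in cm.selection_b])
        freqs, _ = sps.periodogram(secs[0], fs=x.fs, window="blackmanharris")
        per_section = np.mean([sps.periodogram(s, fs=x.fs,
                                               window="blackmanharris")[1]
                               for s in secs], axis=0)
        of_average = sps.periodogram(secs.mean(axis=0), fs=x.fs,
                                     window="blackmanharris")[1]
        band = (freqs >= 72) & (freqs <= 82)
        return of_average[band].max() / per_section[band].max()

    def test_random_phase_bursts_suppressed_by_averaging(self):
        """Incoherent bursts lose ~1/N of their power in the averaged
        signal, phase-locked bursts survive."""
        coupled = np.mean([self._raw_retention(gen_coupled_bursts, s)
                           for s in (77, 78, 79)])
        random_ = np.mean([self._raw_retention(gen_random_bursts, s)
                           for s in (77, 78, 79)])
        assert random_ < 0.5
        assert coupled > 3.0 * random_


def test_amplitude_scale_invariance_of_significance(coupled_signal,
                                                    reduced_grid,
                                                    coupled_emi_result):
    """Multiplying the input by a positive constant leaves the significance
    mask unchanged."""
    scaled = coupled_signal.with_samples(3.7 * coupled_signal.samples)
    res = run_emi(scaled, reduced_grid, n_surr=60, seed=11)
    np.testing.assert_array_equal(res.mask, coupled_emi_result.mask)
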