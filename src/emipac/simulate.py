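"""Synthetic test signals for validating phase-amplitude coupling estimators.

Seven signal families are provided:

* coupled oscillatory bursts — a slow sine with Gabor bursts of a fast
  oscillation locked to a fixed phase of every (or a fraction of) slow cycle;
* amplitude-modulated sine — a fast carrier whose envelope follows the slow
  sine (the classic sinusoidal-modulation construction);
* multimodal coupling — the fast amplitude is augmented at one, two or three
  distinct phases of the slow cycle;
* random oscillatory bursts — the no-coupling counterpart of the burst model
  (burst centres uniform in time, independent of slow phase);
* narrowband filtered noise — a slow sine plus band-limited Gaussian noise
  around the fast frequency, no phase coupling;
* periodic / non-periodic trains of Gaussian spikes on a 1/f background —
  non-sinusoidal waveforms that create spurious (waveform-dependent) coupling;
* pink (1/f) noise — the spectral background model used both for the
  slow-frequency screening null and as the spike-train background.

Every generator is a pure function of its parameters and an integer seed:
repeated calls return identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .timeseries import TimeSeries

__all__ = [
    "BurstModelParams",
    "AMParams",
    "MultimodalParams",
    "GaussianTrainParams",
    "gen_coupled_bursts",
    "gen_random_bursts",
    "gen_amplitude_modulated",
    "gen_multimodal",
    "gen_filtered_noise_hf",
    "gen_gaussian_train",
    "gen_pink_noise",
]

DEFAULT_MODE_PHASES = (4 * np.pi / 5, 3 * np.pi / 2, np.pi / 10)


@dataclass(frozen=True)
class BurstModelParams:
    """Parameters of the (coupled or random) oscillatory-burst model.

    ``burst_phase`` is the phase of the slow sine (argument of ``sin``) at
    which burst centres are placed; the default pi/2 puts them on the peaks
    of the slow oscillation.
    """

    f_p: float = 6.0
    f_a: float = 77.0
    amplitudes_ratio: float = 0.1
    noise_level: float = 0.1
    duration: float = 10.0
    filling: float = 1.0
    gabor_sigma: float = 0.01
    burst_phase: float = np.pi / 2
    fs: float = 512.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.filling <= 1.0:
            raise ValueError("filling must lie in [0, 1]")
        if self.amplitudes_ratio < 0:
            raise ValueError("amplitudes_ratio must be >= 0")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")


@dataclass(frozen=True)
class AMParams:
    """Parameters of the amplitude-modulation model.

    ``chi`` is the fraction of the fast amplitude that is *not* modulated by
    the slow phase; the depth of modulation is ``1 - chi``.
    """

    chi: float = 0.1
    a_fa: float = 0.1
    a_fp: float = 1.0
    a_noise: float = 0.1
    f_p: float = 6.0
    f_a: float = 77.0
    fs: float = 512.0
    duration: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.chi <= 1.0:
            raise ValueError("chi must lie in [0, 1]")
        if self.a_noise < 0 or self.a_fa < 0:
            raise ValueError("amplitudes must be >= 0")

    @property
    def depth_of_modulation(self) -> float:
        return 1.0 - self.chi


@dataclass(frozen=True)
class MultimodalParams:
    """Parameters of the multimodal-coupling model.

    Each mode is a Gaussian bump of the fast amplitude over the slow phase,
    realised through a phase-lagged sawtooth wave passed through a normal
    density and min-max normalised to [0, 1].
    """

    n_modes: int = 1
    mode_phases: tuple = DEFAULT_MODE_PHASES
    gaussian_variance: float = 0.01  # i.e. sigma = 0.1 on the sawtooth scale
    chi: float = 0.1
    a_fa: float = 0.1
    a_fp: float = 1.0
    a_noise: float = 0.1
    f_p: float = 6.0
    f_a: float = 77.0
    fs: float = 512.0
    duration: float = 10.0

    def __post_init__(self) -> None:
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        if self.n_modes > len(self.mode_phases):
            raise ValueError("not enough mode_phases for n_modes")
        if not 0.0 <= self.chi <= 1.0:
            raise ValueError("chi must lie in [0, 1]")


@dataclass(frozen=True)
class GaussianTrainParams:
    """Parameters of the Gaussian spike-train models.

    The periodic variant draws inter-spike intervals uniformly from
    ``mean_interval +/- interval_jitter`` (100 +/- 20 ms by default, which
    concentrates spectral power near 10 Hz).  The non-periodic variant
    scatters ``n_events`` spikes uniformly over the signal on a 1 ms lattice.
    Spike height is ``amplitude_sd`` standard deviations of the background.
    """

    periodic: bool = True
    mean_interval: float = 0.1
    interval_jitter: float = 0.02
    n_events: int = 100
    fwhm: float = 0.015
    amplitude_sd: float = 5.0
    fs: float = 1000.0
    duration: float = 10.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude_sd <= 0:
            raise ValueError("amplitude_sd must be positive")


def _n_samples(duration: float, fs: float) -> int:
    n = int(round(duration * fs))
    if n <= 0:
        raise ValueError("requested signal has zero length")
    return n


def _gabor_bursts(t, centers, f_a, sigma, amplitude):
    """Sum of Gabor atoms (Gaussian-windowed fast cosines) at given centres.

    Atoms extending past either end of the time grid are truncated by
    construction (evaluated only on the grid).
    """
    out = np.zeros_like(t)
    half = 5.0 * sigma  # beyond 5 sigma the atom is numerically zero
    fs = 1.0 / (t[1] - t[0]) if t.size > 1 else 1.0
    for c in centers:
        i0 = max(0, int(np.floor((c - half) * fs)))
        i1 = min(t.size, int(np.ceil((c + half) * fs)) + 1)
        if i1 <= i0:
            continue
        tau = t[i0:i1] - c
        out[i0:i1] += amplitude * np.exp(-0.5 * (tau / sigma) ** 2) * np.cos(
            2 * np.pi * f_a * tau
        )
    return out


def _burst_cycle_centers(p: BurstModelParams) -> np.ndarray:
    """Centre times of bursts for every complete slow cycle.

    The k-th centre sits at slow phase ``burst_phase`` of cycle k, i.e. at
    ``(burst_phase / 2pi + k) / f_p`` seconds.
    """
    phase_frac = (p.burst_phase / (2 * np.pi)) % 1.0
    k = np.arange(int(np.floor(p.duration * p.f_p)))
    centers = (phase_frac + k) / p.f_p
    return centers[centers < p.duration]


def gen_coupled_bursts(params: BurstModelParams, seed: int) -> TimeSeries:
    """Slow sine with phase-locked Gabor bursts of a fast oscillation.

    A unit-amplitude sine at ``f_p`` carries Gabor atoms (carrier ``f_a``,
    envelope sigma ``gabor_sigma``, peak ``amplitudes_ratio``) centred on
    phase ``burst_phase`` of a fraction ``filling`` of its cycles, plus white
    Gaussian noise of standard deviation ``noise_level``.
    """
    rng = np.random.default_rng(seed)
    n = _n_samples(params.duration, params.fs)
    t = np.arange(n) / params.fs
    centers = _burst_cycle_centers(params)
    if params.filling < 1.0:
        keep = int(round(params.filling * centers.size))
        centers = np.sort(rng.choice(centers, size=keep, replace=False))
    slow = np.sin(2 * np.pi * params.f_p * t)
    bursts = _gabor_bursts(t, centers, params.f_a, params.gabor_sigma,
                           params.amplitudes_ratio)
    noise = params.noise_level * rng.standard_normal(n)
    return TimeSeries(slow + bursts + noise, params.fs)


def gen_random_bursts(params: BurstModelParams, seed: int) -> TimeSeries:
    """No-coupling counterpart of :func:`gen_coupled_bursts`.

    The same number of Gabor atoms is used, but their centres are drawn
    uniformly over the signal duration, independent of the slow phase.
    """
    rng = np.random.default_rng(seed)
    n = _n_samples(params.duration, params.fs)
    t = np.arange(n) / params.fs
    n_bursts = int(round(params.filling * _burst_cycle_centers(params).size))
    centers = np.sort(rng.uniform(0.0, params.duration, size=n_bursts))
    slow = np.sin(2 * np.pi * params.f_p * t)
    bursts = _gabor_bursts(t, centers, params.f_a, params.gabor_sigma,
                           params.amplitudes_ratio)
    noise = params.noise_level * rng.standard_normal(n)
    return TimeSeries(slow + bursts + noise, params.fs)


def am_envelope(params: AMParams, t: np.ndarray) -> np.ndarray:
    """Instantaneous fast-oscillation amplitude of the AM model.

    ``a_fa * ((1 - chi) * sin(2 pi f_p t) + 1 + chi) / 2`` — ranges from
    ``a_fa * chi`` (slow-sine trough) to ``a_fa`` (slow-sine peak).
    """
    return params.a_fa * ((1 - params.chi) * np.sin(2 * np.pi * params.f_p * t)
                          + 1 + params.chi) / 2


def gen_amplitude_modulated(params: AMParams, seed: int) -> TimeSeries:
    """Fast sine with envelope tied to the slow phase, plus slow sine + noise."""
    rng = np.random.default_rng(seed)
    n = _n_samples(params.duration, params.fs)
    t = np.arange(n) / params.fs
    env = am_envelope(params, t)
    s = (env * np.sin(2 * np.pi * params.f_a * t)
         + params.a_fp * np.sin(2 * np.pi * params.f_p * t)
         + params.a_noise * rng.standard_normal(n))
    return TimeSeries(s, params.fs)


def multimodal_envelope(params: MultimodalParams, t: np.ndarray) -> np.ndarray:
    """Fast-amplitude envelope with one bump per coupling mode.

    Each mode m is a phase-lagged sawtooth of frequency ``f_p`` passed
    through a zero-mean normal density (variance ``gaussian_variance``) and
    min-max normalised to [0, 1], so every mode contributes a bump peaking
    at its own slow phase.
    """
    var = params.gaussian_variance
    total = np.zeros_like(t)
    for m in range(params.n_modes):
        phi = params.mode_phases[m]
        # sawtooth crosses zero (mid-rise) where the density peaks; the lag
        # places that peak at analytic slow-sine phase phi.
        lag = np.pi / 2 - phi + np.pi
        sw = sps.sawtooth(2 * np.pi * params.f_p * t + lag)
        g = np.exp(-sw ** 2 / (2 * var))
        g = (g - g.min()) / (g.max() - g.min())
        total += g
    return params.a_fa * ((1 - params.chi) * total + params.chi)


def gen_multimodal(params: MultimodalParams, seed: int) -> TimeSeries:
    """Fast sine coupled with up to three distinct phases of the slow cycle."""
    rng = np.random.default_rng(seed)
    n = _n_samples(params.duration, params.fs)
    t = np.arange(n) / params.fs
    env = multimodal_envelope(params, t)
    s = (env * np.sin(2 * np.pi * params.f_a * t)
         + params.a_fp * np.sin(2 * np.pi * params.f_p * t)
         + params.a_noise * rng.standard_normal(n))
    return TimeSeries(s, params.fs)


def gen_filtered_noise_hf(noise_level: float, seed: int,
                          duration: float = 10.0, fs: float = 512.0,
                          band=(76.0, 78.0)) -> TimeSeries:
    """Slow sine plus narrowband fast noise: no-coupling AM counterpart.

    White Gaussian noise is band-passed (Butterworth order 2, zero phase)
    around the fast frequency and rescaled so its maximum absolute value is
    exactly 0.1, then added to a unit 6 Hz sine and white noise of SD
    ``noise_level``.
    """
    rng = np.random.default_rng(seed)
    n = _n_samples(duration, fs)
    t = np.arange(n) / fs
    sos = sps.butter(2, band, btype="bandpass", fs=fs, output="sos")
    hf = sps.sosfiltfilt(sos, rng.standard_normal(n))
    hf *= 0.1 / np.max(np.abs(hf))
    slow = np.sin(2 * np.pi * 6.0 * t)
    noise = noise_level * rng.standard_normal(n)
    return TimeSeries(slow + hf + noise, fs)


def gaussian_spike_sigma(fwhm: float) -> float:
    """Standard deviation of a Gaussian with the given full width at half max."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gen_gaussian_train(params: GaussianTrainParams, background: TimeSeries,
                       seed: int) -> TimeSeries:
    """Gaussian spike train superimposed on a no-coupling background.

    Spikes (FWHM ``fwhm`` seconds, height ``amplitude_sd`` times the
    background SD) are placed either quasi-periodically or uniformly at
    random, added to the background, band-limited with zero-phase Butterworth
    filters (highpass 1 Hz, lowpass 250 Hz, both order 2), and a fragment of
    ``duration`` seconds is extracted.
    """
    if abs(background.fs - params.fs) > 1e-9:
        raise ValueError("background sampling rate must match params.fs")
    if background.duration < params.duration:
        raise ValueError("background shorter than the requested duration")
    rng = np.random.default_rng(seed)
    t = background.times
    total = background.duration
    if params.periodic:
        events = []
        pos = rng.uniform(0.0, params.mean_interval)
        while pos < total:
            events.append(pos)
            pos += rng.uniform(params.mean_interval - params.interval_jitter,
                               params.mean_interval + params.interval_jitter)
        events = np.asarray(events)
    else:
        # uniform event times on a 1 ms lattice
        lattice = np.arange(0.0, total, 0.001)
        events = np.sort(rng.choice(lattice, size=params.n_events,
                                    replace=False))
    sigma = gaussian_spike_sigma(params.fwhm)
    amplitude = params.amplitude_sd * np.std(background.samples)
    spikes = np.zeros_like(t)
    half = 5.0 * sigma
    for c in events:
        i0 = max(0, int(np.floor((c - half) * params.fs)))
        i1 = min(t.size, int(np.ceil((c + half) * params.fs)) + 1)
        tau = t[i0:i1] - c
        spikes[i0:i1] += amplitude * np.exp(-0.5 * (tau / sigma) ** 2)
    raw = background.samples + spikes
    sos_hp = sps.butter(2, 1.0, btype="highpass", fs=params.fs, output="sos")
    sos_lp = sps.butter(2, min(250.0, 0.45 * params.fs), btype="lowpass",
                        fs=params.fs, output="sos")
    filtered = sps.sosfiltfilt(sos_lp, sps.sosfiltfilt(sos_hp, raw))
    out = TimeSeries(filtered, params.fs)
    return out.slice_seconds(0.0, params.duration)


def gen_pink_noise(n_samples: int, fs: float, seed: int) -> TimeSeries:
    """Zero-mean 1/f noise of unit standard deviation.

    Synthesised by shaping white Gaussian noise in the frequency domain with
    a 1/sqrt(f) amplitude mask (DC removed) and inverting the FFT, which
    gives a power spectral density proportional to 1/f across the band.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = np.zeros_like(freqs)
    mask[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * mask, n=n_samples)
    pink -= pink.mean()
    sd = pink.std()
    if sd > 0:
        pink /= sd
    return TimeSeries(pink, fs)
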