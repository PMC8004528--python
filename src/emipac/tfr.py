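"""Morlet-wavelet time-frequency energy maps.

The energy density is

    E(t, f) = sqrt(2 sqrt(pi) f / w) | integral s(u) g(u - t; f, w)
                                       exp(i 2 pi f (u - t)) du |^2

where g is a Gaussian envelope of standard deviation w / (2 pi f) seconds
and w is the (unitless) wavenumber controlling the time-frequency
resolution trade-off: the frequency-domain envelope has standard deviation
f / w, so resolution in frequency degrades linearly with f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .timeseries import TimeSeries

__all__ = ["TFMap", "morlet_energy", "trim_edges", "wavelet_fwhm_freq"]

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class TFMap:
    """Energy density on a time x frequency grid.

    ``energy`` has shape (n_freqs, n_times) in squared amplitude units;
    ``times`` is the time axis in seconds (uniform at the signal's sampling
    rate); ``freqs`` the analysed frequencies in Hz; ``w`` the wavenumber.
    """

    energy: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    w: float
    fs: float


def morlet_energy(x: TimeSeries, freqs, w: float = 5.0) -> TFMap:
    """Continuous-wavelet energy map of the signal, by FFT convolution.

    Zero padding is used at the boundaries; the edge-trimming step removes
    more than the wavelet half-support at the lowest frequency, so retained
    values are unaffected by the padding choice.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= x.fs / 2):
        raise ValueError("analysis frequencies must lie below Nyquist "
                         f"({x.fs / 2:.1f} Hz)")
    if np.any(freqs <= 0):
        raise ValueError("analysis frequencies must be positive")
    dt = 1.0 / x.fs
    energy = np.empty((freqs.size, x.n))
    for k, f in enumerate(freqs):
        sigma_t = w / (2 * np.pi * f)
        half = int(np.ceil(x.fs * w / f))  # ~ 2 pi sigma_t, generous support
        tau = np.arange(-half, half + 1) * dt
        kernel = np.exp(-0.5 * (tau / sigma_t) ** 2) * np.exp(
            1j * 2 * np.pi * f * tau) * dt
        conv = sps.fftconvolve(x.samples, kernel[::-1], mode="same")
        energy[k] = np.sqrt(2 * np.sqrt(np.pi) * f / w) * np.abs(conv) ** 2
    return TFMap(energy=energy, times=x.times.copy(), freqs=freqs, w=w,
                 fs=x.fs)


def trim_edges(m: TFMap) -> TFMap:
    """Cut off the edge-effect region: w / min(freqs) seconds at each end."""
    cut = int(round(m.fs * m.w / m.freqs.min()))
    if m.times.size <= 2 * cut:
        raise ValueError("map too short to trim the edge-effect regions")
    sl = slice(cut, m.times.size - cut)
    return TFMap(energy=m.energy[:, sl], times=m.times[sl], freqs=m.freqs,
                 w=m.w, fs=m.fs)


def wavelet_fwhm_freq(f: float, w: float) -> float:
    """Frequency-domain FWHM of the wavelet envelope at frequency f.

    The time-domain Gaussian has std w / (2 pi f), hence the frequency-domain
    std is f / w and the FWHM is 2 sqrt(2 ln 2) f / w.
    """
    if f <= 0 or w <= 0:
        raise ValueError("f and w must be positive")
    return _FWHM_FACTOR * f / w
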