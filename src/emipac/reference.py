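"""Reference phase-amplitude coupling estimators: dPAC and Modulation Index.

Both estimators work on a composite series of the instantaneous phase of a
slow oscillation and the instantaneous amplitude of a fast oscillation,
extracted by zero-phase FIR band-pass filtering and the Hilbert transform.

dPAC is a normalised mean-vector-length statistic bounded in [0, 1]:

    dPAC = (1/sqrt(N)) |sum_t A(t) exp(i Phi(t))| / sqrt(sum_t A(t)^2)

The Modulation Index measures the Kullback-Leibler divergence of the
distribution of mean fast amplitude over J slow-phase bins from uniformity,
normalised by log(J) so MI lies in [0, 1].

Surrogate comodulograms replace the slow phase with the phase of band-pass
filtered white Gaussian noise (same filters), leaving the amplitude series
untouched, which preserves the spectral content of the fast band while
destroying any phase-amplitude dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .timeseries import TimeSeries

__all__ = [
    "ComodulogramGrid",
    "PhaseAmpSeries",
    "Comodulogram",
    "fir_bandpass_two_way",
    "analytic_phase_amp",
    "dpac",
    "mi",
    "reference_comodulogram",
    "reference_surrogates",
    "reference_analysis",
]


@dataclass(frozen=True)
class ComodulogramGrid:
    """Frequency grid of a comodulogram.

    ``f_p``: frequencies for phase (Hz); ``f_a``: frequencies for amplitude
    (Hz); ``delta_f_p``: bandwidth of the slow-frequency filter (Hz).
    """

    f_p: np.ndarray
    f_a: np.ndarray
    delta_f_p: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "f_p", np.asarray(self.f_p, dtype=float))
        object.__setattr__(self, "f_a", np.asarray(self.f_a, dtype=float))
        for name, v in (("f_p", self.f_p), ("f_a", self.f_a)):
            if v.ndim != 1 or v.size == 0 or np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} must be a strictly increasing vector")
        if self.f_p.max() >= self.f_a.min():
            raise ValueError("phase frequencies must lie below amplitude "
                             "frequencies")
        if self.delta_f_p <= 0:
            raise ValueError("delta_f_p must be positive")

    def nearest_pair_index(self, f_p: float, f_a: float) -> tuple[int, int]:
        return (int(np.argmin(np.abs(self.f_p - f_p))),
                int(np.argmin(np.abs(self.f_a - f_a))))


@dataclass(frozen=True)
class PhaseAmpSeries:
    """Instantaneous phase (radians, [-pi, pi]) and nonnegative amplitude."""

    phase: np.ndarray
    amplitude: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if len(self.phase) != len(self.amplitude):
            raise ValueError("phase and amplitude must have equal length")
        if np.any(np.asarray(self.amplitude) < 0):
            raise ValueError("amplitude must be nonnegative")


@dataclass
class Comodulogram:
    """Coupling values on a (f_p, f_a) grid, row-indexed by f_p."""

    values: np.ndarray
    method: str
    grid: ComodulogramGrid

    def argmax_pair(self) -> tuple[float, float]:
        """(f_p, f_a) of the global maximum, NaN entries ignored."""
        flat = np.nanargmax(self.values)
        i, j = np.unravel_index(flat, self.values.shape)
        return float(self.grid.f_p[i]), float(self.grid.f_a[j])


def _fir_coefficients(band: tuple[float, float], fs: float,
                      n_samples: int | None = None) -> np.ndarray:
    """Least-squares linear-phase band-pass FIR.

    Order = number of samples in three cycles of the band's low edge, with
    15% relative transition bands, mirroring the classic two-way
    least-squares EEG filter design.  For signals too short to support that
    order the order is capped at a third of the signal length (the sweep
    over very short signals needs this; detection stays calibrated because
    surrogates use the identical filter).
    """
    lo, hi = band
    nyq = fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} outside (0, {nyq}) Hz")
    order = int(3 * fs / lo)
    if n_samples is not None and order > n_samples // 3 - 2:
        order = n_samples // 3 - 2
        if order < 8:
            raise ValueError(
                f"signal of {n_samples} samples too short to filter "
                f"band {band} Hz")
    if order % 2:
        order += 1  # firls needs an even order (odd tap count)
    trans = 0.15
    edges = [0.0, (1 - trans) * lo, lo, hi, min((1 + trans) * hi, nyq), nyq]
    # guard against collapsing upper transition at high bands
    if edges[4] <= edges[3]:
        edges[4] = (edges[3] + nyq) / 2
    desired = [0, 0, 1, 1, 0, 0]
    taps = sps.firls(order + 1, edges, desired, fs=fs)
    # unit passband gain at the band centre (least-squares designs with
    # wide don't-care transitions can overshoot by several percent)
    center = (lo + hi) / 2
    gain = np.abs(np.sum(taps * np.exp(-2j * np.pi * center / fs
                                       * np.arange(taps.size))))
    return taps / gain


def _filtfilt(taps: np.ndarray, data: np.ndarray, axis: int = -1):
    padlen = min(3 * len(taps), data.shape[axis] - 1)
    return sps.filtfilt(taps, [1.0], data, axis=axis, padlen=padlen)


def fir_bandpass_two_way(x: TimeSeries, band: tuple[float, float]) -> TimeSeries:
    """Zero-phase (forward-backward) least-squares FIR band-pass filter."""
    taps = _fir_coefficients(band, x.fs, x.n)
    return x.with_samples(_filtfilt(taps, x.samples))


def analytic_phase_amp(x: TimeSeries) -> PhaseAmpSeries:
    """Instantaneous phase and amplitude via the analytic signal."""
    analytic = sps.hilbert(x.samples)
    return PhaseAmpSeries(phase=np.angle(analytic),
                          amplitude=np.abs(analytic), fs=x.fs)


def dpac(pa: PhaseAmpSeries) -> float:
    """Normalised mean-vector-length coupling statistic in [0, 1]."""
    a = np.asarray(pa.amplitude, dtype=float)
    denom = np.sqrt(np.sum(a ** 2))
    if denom == 0:
        raise ValueError("dPAC undefined for an all-zero amplitude series")
    num = np.abs(np.sum(a * np.exp(1j * np.asarray(pa.phase))))
    return float(num / (np.sqrt(a.size) * denom))


def _phase_bins(phase: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign phases in [-pi, pi] to bins 0..n_bins-1."""
    idx = np.floor((np.asarray(phase) + np.pi) / (2 * np.pi) * n_bins)
    return np.clip(idx, 0, n_bins - 1).astype(np.intp)


def binned_amplitude_distribution(phase: np.ndarray, amplitude: np.ndarray,
                                  n_bins: int = 18) -> np.ndarray:
    """Normalised mean amplitude per phase bin (sums to one).

    Empty bins contribute zero mean amplitude (the 0*log 0 limit convention
    applies downstream).
    """
    idx = _phase_bins(phase, n_bins)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=amplitude, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    total = means.sum()
    if total == 0:
        raise ValueError("all-zero amplitude series")
    return means / total


def mi_from_distribution(p: np.ndarray) -> float:
    """KL-based Modulation Index of a normalised phase-bin distribution."""
    p = np.asarray(p, dtype=float)
    j = p.size
    nz = p[p > 0]
    return float((np.log(j) + np.sum(nz * np.log(nz))) / np.log(j))


def mi(pa: PhaseAmpSeries, n_bins: int = 18) -> float:
    """Modulation Index: KL distance of the amplitude-over-phase-bin
    distribution from uniform, normalised to [0, 1]."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p = binned_amplitude_distribution(pa.phase, pa.amplitude, n_bins)
    return mi_from_distribution(p)


def _mi_many(phase: np.ndarray, amplitudes: np.ndarray,
             n_bins: int) -> np.ndarray:
    """MI of one phase series against each row of an amplitude matrix."""
    idx = _phase_bins(phase, n_bins)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    out = np.empty(amplitudes.shape[0])
    logj = np.log(n_bins)
    for r in range(amplitudes.shape[0]):
        sums = np.bincount(idx, weights=amplitudes[r], minlength=n_bins)
        means = np.divide(sums, counts, out=np.zeros(n_bins),
                          where=counts > 0)
        p = means / means.sum()
        nz = p[p > 0]
        out[r] = (logj + np.sum(nz * np.log(nz))) / logj
    return out


def _dpac_many(phase: np.ndarray, amplitudes: np.ndarray) -> np.ndarray:
    """dPAC of one phase series against each row of an amplitude matrix."""
    vec = np.exp(1j * phase)
    num = np.abs(amplitudes @ vec)
    denom = np.sqrt(np.sum(amplitudes ** 2, axis=1))
    return num / (np.sqrt(phase.size) * denom)


def _amplitude_matrix(x: TimeSeries, grid: ComodulogramGrid) -> np.ndarray:
    """Hilbert amplitude of the signal filtered around each f_a.

    The fast band extends twice the maximal phase frequency on each side of
    f_a, wide enough to capture the modulation side bands even when the
    coupling is multimodal (side bands at multiples of f_p).
    """
    half = 2.0 * grid.f_p.max()
    rows = []
    for f_a in grid.f_a:
        lo, hi = f_a - half, f_a + half
        if hi >= x.fs / 2:
            raise ValueError(
                f"amplitude band {lo:.1f}-{hi:.1f} Hz for f_a={f_a} Hz "
                f"exceeds the Nyquist frequency {x.fs / 2:.1f} Hz"
            )
        if lo <= 0:
            raise ValueError(
                f"amplitude band {lo:.1f}-{hi:.1f} Hz for f_a={f_a} Hz "
                f"reaches below 0 Hz; the lowest f_a must exceed twice the "
                f"maximal phase frequency ({half:.1f} Hz)"
            )
        filt = fir_bandpass_two_way(x, (lo, hi))
        rows.append(np.abs(sps.hilbert(filt.samples)))
    return np.asarray(rows)


def _phase_series(x: TimeSeries, grid: ComodulogramGrid) -> list[np.ndarray]:
    phases = []
    for f_p in grid.f_p:
        band = (f_p - grid.delta_f_p / 2, f_p + grid.delta_f_p / 2)
        filt = fir_bandpass_two_way(x, band)
        phases.append(np.angle(sps.hilbert(filt.samples)))
    return phases


def _edge_slice(n: int, fs: float) -> slice:
    """Discard the first and last second (filter edge effects)."""
    k = int(round(fs))
    if n <= 2 * k:
        raise ValueError("signal must be longer than 2 s for dPAC")
    return slice(k, n - k)


def _measure_matrix(phases, amplitudes, method: str, sl: slice,
                    n_bins: int) -> np.ndarray:
    values = np.empty((len(phases), amplitudes.shape[0]))
    amp = amplitudes[:, sl]
    for i, ph in enumerate(phases):
        if method == "mi":
            values[i] = _mi_many(ph[sl], amp, n_bins)
        else:
            values[i] = _dpac_many(ph[sl], amp)
    return values


def reference_comodulogram(x: TimeSeries, grid: ComodulogramGrid,
                           method: str = "mi",
                           n_bins: int = 18) -> Comodulogram:
    """Full comodulogram with the dPAC or MI estimator.

    dPAC discards the first and last second after filtering; MI uses the
    whole filtered series.
    """
    if method not in ("mi", "dpac"):
        raise ValueError("method must be 'mi' or 'dpac'")
    amplitudes = _amplitude_matrix(x, grid)
    phases = _phase_series(x, grid)
    sl = _edge_slice(x.n, x.fs) if method == "dpac" else slice(None)
    values = _measure_matrix(phases, amplitudes, method, sl, n_bins)
    return Comodulogram(values=values, method=method, grid=grid)


# Bank of surrogate phases, reusable across realisations that share a
# configuration (the phases depend only on the filters and the seed, not on
# the analysed data).
_PHASE_BANK: dict = {}


def surrogate_phase_bank(n: int, fs: float, grid: ComodulogramGrid,
                         n_surr: int, seed: int) -> np.ndarray:
    """Phases of band-pass filtered white noise, shape (n_surr, n_fp, n)."""
    key = (n, round(fs, 6), tuple(np.round(grid.f_p, 6)),
           round(grid.delta_f_p, 6), n_surr, seed)
    if key not in _PHASE_BANK:
        rng = np.random.default_rng(seed)
        bank = np.empty((n_surr, grid.f_p.size, n))
        for i, f_p in enumerate(grid.f_p):
            band = (f_p - grid.delta_f_p / 2, f_p + grid.delta_f_p / 2)
            taps = _fir_coefficients(band, fs, n)
            noise = rng.standard_normal((n_surr, n))
            filt = _filtfilt(taps, noise, axis=1)
            bank[:, i, :] = np.angle(sps.hilbert(filt, axis=1))
        _PHASE_BANK.clear()  # keep at most one configuration resident
        _PHASE_BANK[key] = bank
    return _PHASE_BANK[key]


def reference_surrogates(x: TimeSeries, grid: ComodulogramGrid, method: str,
                         n_surr: int, seed: int,
                         n_bins: int = 18) -> list[Comodulogram]:
    """Surrogate comodulograms with noise-derived phases.

    The amplitude series is identical to the original analysis; only the
    phase is replaced, per surrogate, by the phase of filtered white noise.
    """
    amplitudes = _amplitude_matrix(x, grid)
    sl = _edge_slice(x.n, x.fs) if method == "dpac" else slice(None)
    bank = surrogate_phase_bank(x.n, x.fs, grid, n_surr, seed)
    out = []
    for s in range(n_surr):
        phases = [bank[s, i] for i in range(grid.f_p.size)]
        values = _measure_matrix(phases, amplitudes, method, sl, n_bins)
        out.append(Comodulogram(values=values, method=method, grid=grid))
    return out


def pair_analysis(x: TimeSeries, grid: ComodulogramGrid, method: str,
                  n_surr: int, seed: int, pair: tuple[float, float],
                  n_bins: int = 18):
    """Coupling value and surrogate distribution at one pre-specified pair.

    When the coupled pair is known in advance (as in simulation sweeps) no
    multiple-comparison correction is needed; the value is tested against
    the surrogate distribution of that pair alone.  Returns
    ``(value, surrogate_values)`` with ``surrogate_values`` of length
    ``n_surr``.  Filters are identical to the full comodulogram (the
    amplitude band half-width still derives from the full phase grid).
    """
    if method not in ("mi", "dpac"):
        raise ValueError("method must be 'mi' or 'dpac'")
    i, j = grid.nearest_pair_index(*pair)
    f_p, f_a = float(grid.f_p[i]), float(grid.f_a[j])
    half = 2.0 * grid.f_p.max()
    amp = np.abs(sps.hilbert(
        fir_bandpass_two_way(x, (f_a - half, f_a + half)).samples))
    band = (f_p - grid.delta_f_p / 2, f_p + grid.delta_f_p / 2)
    phase = np.angle(sps.hilbert(fir_bandpass_two_way(x, band).samples))
    sl = _edge_slice(x.n, x.fs) if method == "dpac" else slice(None)
    amp_m = amp[np.newaxis, sl]
    measure = _mi_many if method == "mi" else _dpac_many
    args = (n_bins,) if method == "mi" else ()
    value = float(measure(phase[sl], amp_m, *args)[0])
    sub = ComodulogramGrid(f_p=np.asarray([f_p]),
                           f_a=np.asarray([f_a]),
                           delta_f_p=grid.delta_f_p)
    bank = surrogate_phase_bank(x.n, x.fs, sub, n_surr, seed)
    surr = np.array([float(measure(bank[s, 0, sl], amp_m, *args)[0])
                     for s in range(n_surr)])
    return value, surr


def reference_analysis(x: TimeSeries, grid: ComodulogramGrid, method: str,
                       n_surr: int, seed: int, n_bins: int = 18):
    """Comodulogram plus surrogate stack, sharing the filtered amplitudes.

    Returns ``(Comodulogram, ndarray of shape (n_surr, n_fp, n_fa))``.
    """
    if method not in ("mi", "dpac"):
        raise ValueError("method must be 'mi' or 'dpac'")
    amplitudes = _amplitude_matrix(x, grid)
    phases = _phase_series(x, grid)
    sl = _edge_slice(x.n, x.fs) if method == "dpac" else slice(None)
    values = _measure_matrix(phases, amplitudes, method, sl, n_bins)
    bank = surrogate_phase_bank(x.n, x.fs, grid, n_surr, seed)
    surr = np.empty((n_surr, grid.f_p.size, grid.f_a.size))
    for s in range(n_surr):
        surr[s] = _measure_matrix([bank[s, i] for i in range(grid.f_p.size)],
                                  amplitudes, method, sl, n_bins)
    return Comodulogram(values=values, method=method, grid=grid), surr
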