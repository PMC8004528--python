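"""The extended modulation index (eMI) pipeline.

The eMI estimates phase-amplitude coupling from cycle-locked averages of a
Morlet-wavelet energy map rather than from Hilbert envelopes of band-pass
filtered data.  The stages are:

1. *Screening*: only phase frequencies whose Welch spectrum stands out
   against a smooth background (relative to a pink-noise null) are analysed.
2. *Phase identification*: the slow oscillation is extracted with a
   zero-phase Butterworth filter; its prominent cycle maxima define section
   centres.  Path A uses one-cycle sections (coupling measurement); path B
   uses three-cycle sections (auxiliary diagnostics).
3. *Averaging*: one-cycle sections of the energy map are averaged into
   M_A(t, f); the averaged filtered trace SP_A supplies the phase via its
   analytic signal.  Path B produces M_B, SP_B and the averaged raw signal
   S_B.
4. *Surrogates*: section centres are jittered by up to half a slow period
   and sections are randomly stretched/squeezed by 0.9-1.1 before averaging,
   preserving the time-frequency content while destroying phase locking.
5. *Comodulogram*: the modulation index of the averaged map row against the
   averaged phase, centred per frequency pair by the mean surrogate value so
   that extreme-value statistics are comparable across pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal as sps

from . import labeling as _labeling
from .reference import (Comodulogram, ComodulogramGrid,
                        binned_amplitude_distribution, mi_from_distribution)
from .simulate import gen_pink_noise
from .stats import SignificanceResult, bin_threshold_filter, \
    extreme_value_threshold
from .tfr import TFMap, morlet_energy, trim_edges
from .timeseries import TimeSeries

__all__ = [
    "InsufficientCyclesError",
    "LowFreqScreen",
    "CycleMaxima",
    "AveragedSections",
    "SectionSpectra",
    "EMIResult",
    "screen_phase_frequencies",
    "extract_low_freq",
    "find_cycle_maxima",
    "average_sections",
    "surrogate_maps",
    "emi_comodulogram",
    "phase_distributions",
    "section_spectra",
    "run_emi",
]


_log = logging.getLogger(__name__)


class InsufficientCyclesError(ValueError):
    """Fewer than three usable slow-oscillation cycles: f_p abandoned."""


# ---------------------------------------------------------------------------
# Screening of phase frequencies


@dataclass
class LowFreqScreen:
    f_p: np.ndarray
    ratio: np.ndarray
    threshold: np.ndarray
    significant: np.ndarray


def _welch_psd(samples: np.ndarray, fs: float, f_p_min: float):
    """Welch PSD with >= 4 cycles of the slowest phase frequency per segment."""
    seg_seconds = max(2.0, 4.0 / f_p_min)
    nperseg = min(samples.size, int(round(fs * seg_seconds)))
    return sps.welch(samples, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, detrend="constant")


def _background(freqs: np.ndarray, psd: np.ndarray) -> np.ndarray:
    """Smooth background: piecewise-cubic interpolation through the PSD's
    local minima (endpoints appended as anchors).

    With fewer than two interior minima the background falls back to the
    straight line through the endpoints (in log power).
    """
    logp = np.log(np.maximum(psd, np.finfo(float).tiny))
    interior = sps.argrelmin(psd)[0]
    anchors = np.unique(np.concatenate(([0], interior, [psd.size - 1])))
    if interior.size < 2:
        _log.debug("fewer than two spectral minima in band; falling back "
                   "to a linear background through the endpoints")
        bg = np.interp(freqs, freqs[[0, -1]], logp[[0, -1]])
    else:
        bg = interpolate.PchipInterpolator(freqs[anchors], logp[anchors])(freqs)
    return np.exp(bg)


def _spectrum_ratio(samples: np.ndarray, fs: float,
                    f_p_grid: np.ndarray) -> np.ndarray:
    """Spectrum-to-background ratio evaluated at the phase frequencies."""
    freqs, psd = _welch_psd(samples, fs, float(f_p_grid.min()))
    cap = min(fs / 2, 3.0 * float(f_p_grid.max()))
    band = freqs <= cap
    bg = _background(freqs[band], psd[band])
    ratio = psd[band] / bg
    return np.interp(f_p_grid, freqs[band], ratio)


_PINK_THRESHOLD_CACHE: dict = {}


def _pink_ratio_threshold(n: int, fs: float, f_p_grid: np.ndarray,
                          n_pink: int, pct: float, seed: int) -> np.ndarray:
    """Percentile of the pink-noise spectrum-to-background ratio per f_p.

    Depends only on the configuration, not on the analysed data, so it is
    cached across calls that share signal length and grid.
    """
    key = (n, round(fs, 6), tuple(np.round(f_p_grid, 6)), n_pink,
           round(pct, 6), seed)
    if key not in _PINK_THRESHOLD_CACHE:
        ratios = np.empty((n_pink, f_p_grid.size))
        for r in range(n_pink):
            pink = gen_pink_noise(n, fs, seed=int((seed * 100003 + r)
                                                  % (2 ** 31)))
            ratios[r] = _spectrum_ratio(pink.samples, fs, f_p_grid)
        if len(_PINK_THRESHOLD_CACHE) > 4:
            _PINK_THRESHOLD_CACHE.clear()
        _PINK_THRESHOLD_CACHE[key] = np.percentile(ratios, pct, axis=0)
    return _PINK_THRESHOLD_CACHE[key]


def screen_phase_frequencies(x: TimeSeries, f_p_grid, n_pink: int = 200,
                             pct: float = 95.0, seed: int = 0) -> LowFreqScreen:
    """Mark phase frequencies whose spectrum stands out against 1/f noise.

    A frequency is significant when the signal's spectrum-to-background
    ratio exceeds the ``pct`` percentile of the same ratio computed over
    ``n_pink`` pink-noise realisations of equal length.
    """
    f_p_grid = np.asarray(f_p_grid, dtype=float)
    ratio = _spectrum_ratio(x.samples, x.fs, f_p_grid)
    threshold = _pink_ratio_threshold(x.n, x.fs, f_p_grid, n_pink, pct, seed)
    return LowFreqScreen(f_p=f_p_grid, ratio=ratio, threshold=threshold,
                         significant=ratio > threshold)


# ---------------------------------------------------------------------------
# Phase identification


def extract_low_freq(x: TimeSeries, f_p: float,
                     delta_f_p: float) -> TimeSeries:
    """Zero-phase 4th-order Butterworth band-pass around f_p."""
    band = (f_p - delta_f_p / 2, f_p + delta_f_p / 2)
    if band[0] <= 0 or band[1] >= x.fs / 2:
        raise ValueError(f"band {band} Hz outside (0, {x.fs / 2}) Hz")
    sos = sps.butter(4, band, btype="bandpass", fs=x.fs, output="sos")
    return x.with_samples(sps.sosfiltfilt(sos, x.samples))


def _window_samples(fs: float, cycles: float, f_p: float) -> int:
    """Section length in samples, forced odd to centre on the maximum."""
    n = int(round(fs * cycles / f_p))
    return n if n % 2 else n + 1


@dataclass
class CycleMaxima:
    """Retained maxima of the filtered slow oscillation and the
    non-overlapping subsets used for one-cycle (A) and three-cycle (B)
    sections."""

    indices: np.ndarray          # sample indices of retained maxima
    prominences: np.ndarray
    selection_a: np.ndarray      # subset for one-cycle windows
    selection_b: np.ndarray      # subset for three-cycle windows
    len_a: int                   # window length (samples, odd)
    len_b: int
    f_p: float
    fs: float

    @property
    def n_max_a(self) -> int:
        return self.selection_a.size

    @property
    def n_max_b(self) -> int:
        return self.selection_b.size


def _greedy_nonoverlap(centers: np.ndarray, window: int) -> np.ndarray:
    """Beginning with the first maximum, keep each next centre whose window
    does not overlap the previously kept one.

    Adjacent windows may share their single boundary sample: the odd-forced
    window is one sample longer than the cycle span, and demanding strict
    disjointness would skip every k-th cycle of a perfectly regular
    oscillation.
    """
    kept = []
    last = -np.inf
    for c in centers:
        if c - last >= window - 1:
            kept.append(c)
            last = c
    return np.asarray(kept, dtype=np.intp)


def find_cycle_maxima(s_fp: TimeSeries, f_p: float) -> CycleMaxima:
    """Locate prominent maxima of the filtered slow oscillation.

    Maxima with prominence below 5% of the median prominence are dropped, as
    are maxima within 1.5 cycles of either end (so three-cycle sections stay
    inside the signal).  Raises :class:`InsufficientCyclesError` when fewer
    than three non-overlapping sections remain on either path.
    """
    peaks, props = sps.find_peaks(s_fp.samples, prominence=0.0)
    if peaks.size == 0:
        raise InsufficientCyclesError(f"no maxima found at f_p={f_p} Hz")
    prom = props["prominences"]
    keep = prom >= 0.05 * np.median(prom)
    peaks, prom = peaks[keep], prom[keep]
    margin = 1.5 / f_p
    t = peaks / s_fp.fs
    inside = (t >= margin) & (t <= s_fp.duration - margin)
    peaks, prom = peaks[inside], prom[inside]
    len_a = _window_samples(s_fp.fs, 1.0, f_p)
    len_b = _window_samples(s_fp.fs, 3.0, f_p)
    sel_a = _greedy_nonoverlap(peaks, len_a)
    sel_b = _greedy_nonoverlap(peaks, len_b)
    if sel_a.size < 3 or sel_b.size < 3:
        raise InsufficientCyclesError(
            f"insufficient cycles at f_p={f_p} Hz "
            f"(A: {sel_a.size}, B: {sel_b.size})")
    return CycleMaxima(indices=peaks, prominences=prom, selection_a=sel_a,
                       selection_b=sel_b, len_a=len_a, len_b=len_b,
                       f_p=f_p, fs=s_fp.fs)


# ---------------------------------------------------------------------------
# Cycle-locked averaging


@dataclass
class AveragedSections:
    """Cycle-locked averages for one phase frequency.

    Path A (one slow cycle): averaged map ``m_a`` (n_freqs x len_a),
    averaged filtered trace ``sp_a`` and its analytic phase ``phase_a``.
    Path B (three cycles): averaged map ``m_b``, filtered average ``sp_b``
    and raw-signal average ``s_b``.
    """

    m_a: np.ndarray
    sp_a: np.ndarray
    phase_a: np.ndarray
    m_b: np.ndarray
    sp_b: np.ndarray
    s_b: np.ndarray
    n_used_a: int
    n_used_b: int
    f_p: float
    fs: float


def _map_sections(energy: np.ndarray, centers: np.ndarray, half: int,
                  offset: int):
    """Average map sections centred on ``centers`` (signal indices);
    sections falling outside the trimmed map are dropped."""
    n_map = energy.shape[1]
    sections = []
    used = []
    for c in centers:
        lo = c - offset - half
        hi = c - offset + half + 1
        if lo < 0 or hi > n_map:
            continue
        sections.append(energy[:, lo:hi])
        used.append(c)
    if not sections:
        return None, np.asarray(used)
    return np.mean(sections, axis=0), np.asarray(used)


def _signal_sections(samples: np.ndarray, centers: np.ndarray,
                     half: int) -> np.ndarray:
    secs = [samples[c - half:c + half + 1] for c in centers
            if c - half >= 0 and c + half + 1 <= samples.size]
    return np.mean(secs, axis=0)


def average_sections(e_trimmed: TFMap, s_fp: TimeSeries, x: TimeSeries,
                     cm: CycleMaxima, map_offset: int) -> AveragedSections:
    """Average one- and three-cycle sections of map and signals.

    ``map_offset`` is the number of samples removed from the start of the
    energy map by edge trimming; map sections whose window exceeds the
    trimmed extent are dropped (the signal sections are unaffected, since
    the edge-exclusion rule keeps them inside the signal).
    """
    half_a = (cm.len_a - 1) // 2
    half_b = (cm.len_b - 1) // 2
    m_a, used_a = _map_sections(e_trimmed.energy, cm.selection_a, half_a,
                                map_offset)
    m_b, used_b = _map_sections(e_trimmed.energy, cm.selection_b, half_b,
                                map_offset)
    if m_a is None or used_a.size < 3 or m_b is None or used_b.size < 3:
        raise InsufficientCyclesError(
            f"insufficient sections within the trimmed map at "
            f"f_p={cm.f_p} Hz")
    sp_a = _signal_sections(s_fp.samples, used_a, half_a)
    sp_b = _signal_sections(s_fp.samples, used_b, half_b)
    s_b = _signal_sections(x.samples, used_b, half_b)
    phase_a = np.angle(sps.hilbert(sp_a))
    return AveragedSections(m_a=m_a, sp_a=sp_a, phase_a=phase_a, m_b=m_b,
                            sp_b=sp_b, s_b=s_b, n_used_a=used_a.size,
                            n_used_b=used_b.size, f_p=cm.f_p, fs=cm.fs)


# ---------------------------------------------------------------------------
# Surrogate averaged maps


def surrogate_maps(e_trimmed: TFMap, cm: CycleMaxima, map_offset: int,
                   n_surr: int, rng: np.random.Generator) -> np.ndarray:
    """Ensemble of averaged maps with jittered, stretched section centres.

    Each repetition displaces every section centre by a uniform shift of up
    to half a slow period and rescales the section's time axis by an
    independent factor from U(0.9, 1.1) (resampled back to the one-cycle
    sample count by linear interpolation), then averages.  Returns an array
    of shape ``(n_surr, n_freqs, len_a)``.
    """
    energy = e_trimmed.energy
    n_map = energy.shape[1]
    half = (cm.len_a - 1) // 2
    centers = cm.selection_a.astype(float) - map_offset
    rel = np.arange(cm.len_a) - half
    max_shift = cm.fs / (2 * cm.f_p)
    out = np.empty((n_surr, energy.shape[0], cm.len_a))
    for s in range(n_surr):
        acc = np.zeros((energy.shape[0], cm.len_a))
        count = 0
        for c in centers:
            coords = None
            for _ in range(10):
                shift = rng.uniform(-max_shift, max_shift)
                factor = rng.uniform(0.9, 1.1)
                cand = c + shift + factor * rel
                if cand[0] >= 0 and cand[-1] <= n_map - 1:
                    coords = cand
                    break
            if coords is None:
                continue  # persistent out-of-range: skip this maximum
            # nearest-neighbour resampling: linear interpolation would
            # low-pass the energy rows and bias surrogate MI downward
            idx = np.clip(np.rint(coords).astype(np.intp), 0, n_map - 1)
            acc += energy[:, idx]
            count += 1
        out[s] = acc / max(count, 1)
    return out


# ---------------------------------------------------------------------------
# Comodulogram, phase distributions, spectra


def _row_distributions(phase: np.ndarray, rows: np.ndarray,
                       n_bins: int) -> np.ndarray:
    """Phase-bin distribution of each map row against a common phase."""
    out = np.empty((rows.shape[0], n_bins))
    for r in range(rows.shape[0]):
        out[r] = binned_amplitude_distribution(phase, rows[r], n_bins)
    return out


def emi_comodulogram(sections: dict, surrogates: dict,
                     grid: ComodulogramGrid, n_bins: int = 18):
    """Centred MI comodulogram plus the centred surrogate stack.

    ``sections`` maps f_p -> :class:`AveragedSections` for the analysed
    phase frequencies; ``surrogates`` maps f_p -> surrogate map ensemble.
    Abandoned phase frequencies appear as NaN columns.  Both original and
    surrogate values are centred by the per-pair surrogate mean, which makes
    values comparable across pairs (required by the extreme-value
    statistic); centred values may be negative.
    """
    n_surr = next(iter(surrogates.values())).shape[0] if surrogates else 0
    values = np.full((grid.f_p.size, grid.f_a.size), np.nan)
    surr = np.full((n_surr, grid.f_p.size, grid.f_a.size), np.nan)
    for i, f_p in enumerate(grid.f_p):
        if f_p not in sections:
            continue
        sec = sections[f_p]
        p_orig = _row_distributions(sec.phase_a, sec.m_a, n_bins)
        values[i] = [mi_from_distribution(p) for p in p_orig]
        ens = surrogates[f_p]
        for s in range(n_surr):
            p_s = _row_distributions(sec.phase_a, ens[s], n_bins)
            surr[s, i] = [mi_from_distribution(p) for p in p_s]
        center = surr[:, i, :].mean(axis=0)
        values[i] -= center
        surr[:, i, :] -= center
    return Comodulogram(values=values, method="emi", grid=grid), surr


def phase_distributions(sections: dict, surrogates: dict,
                        grid: ComodulogramGrid, n_bins: int = 18,
                        p_pc: float = 95.0):
    """Per-pair phase-bin distributions and surrogate bin thresholds.

    Returns ``(P, th)`` with ``P`` of shape (n_fp, n_fa, n_bins) (each
    distribution sums to one) and ``th`` of shape (n_fp, n_fa): the p_pc
    percentile of the distribution over surrogates of the maximal surrogate
    bin value.
    """
    p = np.full((grid.f_p.size, grid.f_a.size, n_bins), np.nan)
    th = np.full((grid.f_p.size, grid.f_a.size), np.nan)
    for i, f_p in enumerate(grid.f_p):
        if f_p not in sections:
            continue
        sec = sections[f_p]
        p[i] = _row_distributions(sec.phase_a, sec.m_a, n_bins)
        ens = surrogates[f_p]
        maxima = np.empty((ens.shape[0], grid.f_a.size))
        for s in range(ens.shape[0]):
            maxima[s] = _row_distributions(sec.phase_a, ens[s],
                                           n_bins).max(axis=1)
        th[i] = np.percentile(maxima, p_pc, axis=0)
    return p, th


@dataclass
class SectionSpectra:
    """Average of per-section periodograms (``avg_spectrum``) and
    periodogram of the averaged raw signal (``spectrum_of_avg``), both
    restricted to the amplitude-frequency range and normalised to unit
    total power."""

    freqs: np.ndarray
    avg_spectrum: np.ndarray
    spectrum_of_avg: np.ndarray


def _bh_periodogram(samples: np.ndarray, fs: float):
    return sps.periodogram(samples, fs=fs, window="blackmanharris",
                           detrend=False)


def section_spectra(x: TimeSeries, cm: CycleMaxima, s_b: np.ndarray,
                    f_a_range: tuple[float, float]) -> SectionSpectra:
    """Blackman-Harris periodograms of three-cycle sections and their
    average.

    Synchronised fast activity survives the raw-signal averaging and shows
    as a peak in the spectrum of the average; unsynchronised activity
    averages out and is visible only in the average spectrum.
    """
    half = (cm.len_b - 1) // 2
    spectra = []
    for c in cm.selection_b:
        if c - half < 0 or c + half + 1 > x.n:
            continue
        freqs, psd = _bh_periodogram(x.samples[c - half:c + half + 1], x.fs)
        spectra.append(psd)
    avg = np.mean(spectra, axis=0)
    freqs, soa = _bh_periodogram(s_b, x.fs)
    band = (freqs >= f_a_range[0]) & (freqs <= f_a_range[1])
    freqs = freqs[band]
    avg = avg[band]
    soa = soa[band]

    def _norm(v):
        tot = v.sum()
        return v / tot if tot > 0 else v

    return SectionSpectra(freqs=freqs, avg_spectrum=_norm(avg),
                          spectrum_of_avg=_norm(soa))


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class EMIResult:
    """Complete output of one eMI analysis."""

    grid: ComodulogramGrid
    w: float
    comodulogram: Comodulogram
    surrogate_values: np.ndarray
    significance: SignificanceResult
    mask: np.ndarray                 # after the phase-bin rejection rule
    phase_dist: np.ndarray           # (n_fp, n_fa, n_bins)
    bin_threshold: np.ndarray        # (n_fp, n_fa)
    regions: list
    screen: LowFreqScreen | None
    sections: dict
    spectra: dict
    abandoned: dict
    seed: int

    def significant_pair(self, f_p: float, f_a: float) -> bool:
        i, j = self.grid.nearest_pair_index(f_p, f_a)
        return bool(self.mask[i, j])


def run_emi(x: TimeSeries, grid: ComodulogramGrid, w: float = 5.0,
            n_surr: int = 200, p_c: float = 95.0, p_pc: float = 95.0,
            n_bins: int = 18, n_pink: int = 200, seed: int = 0,
            screen: bool = True, screen_seed: int | None = None) -> EMIResult:
    """Run the full eMI analysis of a single signal.

    Parameters follow the published defaults: wavenumber ``w`` = 5, 200
    surrogate repetitions, 95th-percentile thresholds for both the
    comodulogram extreme-value statistic (``p_c``) and the per-pair phase-bin
    threshold (``p_pc``), 18 phase bins.  ``seed`` governs every source of
    randomness.  ``screen_seed`` optionally fixes the seed of the pink-noise
    screening null separately, so that batch analyses of equally long
    signals can share the cached null distribution.
    """
    scr = None
    if screen:
        scr = screen_phase_frequencies(
            x, grid.f_p, n_pink=n_pink,
            seed=seed if screen_seed is None else screen_seed)
        candidates = grid.f_p[scr.significant]
    else:
        candidates = grid.f_p
    e_full = morlet_energy(x, grid.f_a, w)
    e_trim = trim_edges(e_full)
    map_offset = int(round(x.fs * w / grid.f_a.min()))
    sections: dict = {}
    surrogates: dict = {}
    spectra: dict = {}
    abandoned: dict = {}
    for f_p in grid.f_p:
        if f_p not in candidates:
            abandoned[float(f_p)] = "not significant"
            continue
        try:
            s_fp = extract_low_freq(x, f_p, grid.delta_f_p)
            cm = find_cycle_maxima(s_fp, f_p)
            sec = average_sections(e_trim, s_fp, x, cm, map_offset)
        except InsufficientCyclesError as err:
            abandoned[float(f_p)] = str(err)
            continue
        i_fp = int(np.argmin(np.abs(grid.f_p - f_p)))
        rng = np.random.default_rng([seed, i_fp])
        ens = surrogate_maps(e_trim, cm, map_offset, n_surr, rng)
        sections[f_p] = sec
        surrogates[f_p] = ens
        spectra[f_p] = section_spectra(
            x, cm, sec.s_b, (float(grid.f_a.min()), float(grid.f_a.max())))
    comod, surr = emi_comodulogram(sections, surrogates, grid, n_bins)
    if surr.size == 0:
        surr = np.full((n_surr, grid.f_p.size, grid.f_a.size), np.nan)
    p_dist, th = phase_distributions(sections, surrogates, grid, n_bins,
                                     p_pc)
    if sections:
        sig = extreme_value_threshold(comod.values, surr, p_c)
        with np.errstate(invalid="ignore"):
            mask = bin_threshold_filter(sig.mask, np.nan_to_num(p_dist),
                                        np.nan_to_num(th, nan=np.inf))
    else:
        sig = SignificanceResult(threshold=np.nan,
                                 p_vals=np.full(comod.values.shape, np.nan),
                                 mask=np.zeros(comod.values.shape, bool),
                                 p_c=p_c)
        mask = sig.mask
    regions = _labeling.label_comodulogram(mask, comod, spectra, grid, w,
                                           p_dist)
    return EMIResult(grid=grid, w=w, comodulogram=comod,
                     surrogate_values=surr, significance=sig, mask=mask,
                     phase_dist=p_dist, bin_threshold=th, regions=regions,
                     screen=scr, sections=sections, spectra=spectra,
                     abandoned=abandoned, seed=seed)
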