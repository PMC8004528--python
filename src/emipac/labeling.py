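"""Coupling-region extraction and the Reliable/Ambiguous origin heuristic.

A statistically significant coupling is *Reliable* when the comodulogram
maximum is congruent with a proper peak of the fast-frequency spectrum —
i.e. the detected modulation corresponds to a genuine oscillation rather
than to harmonics of a non-sinusoidal waveform.  Otherwise it is
*Ambiguous*.  The decision is made per phase-frequency column of each
8-connected significant region:

1. find the region's strongest amplitude frequency in that column
   (``f_a_max``); a maximum sitting on the lower edge of the analysed
   amplitude range is undecidable and yields Ambiguous with a warning;
2. convert the wavelet's frequency resolution at ``f_a_max`` into a
   congruence window ``f_a_max +/- FWHM/2``;
3. search for a spectral peak in the union of the region's frequency span
   and the congruence window, choosing between the average spectrum and the
   spectrum of the averaged signal by which one dominates over that range;
4. only proper peaks (descending slopes on both sides) count; a maximum on
   a rising slope yields Ambiguous;
5. the column is Reliable iff the peak falls inside the congruence window.

A region is Reliable when at least one of its columns is.  Finally, if the
base region of an (approximate) harmonic series of phase frequencies is
Ambiguous, the label propagates to all its harmonics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .tfr import wavelet_fwhm_freq

__all__ = [
    "CouplingRegion",
    "extract_regions",
    "choose_spectrum",
    "find_spectral_peak",
    "assign_label",
    "propagate_harmonics",
    "region_phase_histogram",
    "label_comodulogram",
]

RELIABLE = "Reliable"
AMBIGUOUS = "Ambiguous"


@dataclass
class CouplingRegion:
    """One connected patch of significant (f_p, f_a) pairs."""

    cells: np.ndarray               # (k, 2) array of (i_fp, i_fa) indices
    region_id: int
    label: str | None = None
    column_labels: dict = field(default_factory=dict)  # f_p -> label (audit)
    phase_histogram: np.ndarray | None = None

    @property
    def f_p_indices(self) -> np.ndarray:
        return np.unique(self.cells[:, 0])

    @property
    def f_a_indices(self) -> np.ndarray:
        return np.unique(self.cells[:, 1])

    def centroid_f_p(self, grid) -> float:
        return float(np.mean(grid.f_p[self.cells[:, 0]]))


def extract_regions(mask: np.ndarray) -> list[CouplingRegion]:
    """8-connected components of the significance mask.

    Regions are ordered deterministically by (min f_p index, min f_a index).
    """
    structure = np.ones((3, 3), dtype=int)
    labeled, n = ndimage.label(mask, structure=structure)
    regions = []
    for lab in range(1, n + 1):
        cells = np.argwhere(labeled == lab)
        regions.append(cells)
    regions.sort(key=lambda c: (int(c[:, 0].min()), int(c[:, 1].min())))
    return [CouplingRegion(cells=c, region_id=i)
            for i, c in enumerate(regions)]


def choose_spectrum(avg_spectrum: np.ndarray, spectrum_of_avg: np.ndarray,
                    in_range: np.ndarray) -> str:
    """Pick the spectrum with the more pronounced content over a range.

    For each spectrum, sum its power at range frequencies where it exceeds
    the other; the larger sum wins.  Ties go to the average spectrum.
    """
    a = avg_spectrum[in_range]
    s = spectrum_of_avg[in_range]
    sum_a = a[a > s].sum()
    sum_s = s[s > a].sum()
    return "SA" if sum_s > sum_a else "AS"


def find_spectral_peak(spectrum: np.ndarray, freqs: np.ndarray,
                       in_range: np.ndarray) -> float | None:
    """Frequency of the maximal power within a range, if it is a proper peak.

    The candidate must be a local maximum of the *full* spectrum with
    strictly lower neighbours on both sides; a maximum on a rising slope (or
    at the spectrum boundary) returns None.  Ties break toward the lower
    frequency.
    """
    idx_range = np.flatnonzero(in_range)
    if idx_range.size == 0:
        return None
    k = idx_range[np.argmax(spectrum[idx_range])]
    if k == 0 or k == spectrum.size - 1:
        return None
    if spectrum[k] > spectrum[k - 1] and spectrum[k] > spectrum[k + 1]:
        return float(freqs[k])
    return None


def assign_label(region: CouplingRegion, comod_values: np.ndarray,
                 spectra: dict, grid, w: float) -> CouplingRegion:
    """Apply the congruence heuristic to each phase-frequency column.

    ``spectra`` maps f_p -> :class:`~emipac.emi.SectionSpectra`.  The region
    label is Reliable iff at least one column is Reliable; per-column labels
    are kept for audit.
    """
    any_reliable = False
    for i_fp in region.f_p_indices:
        f_p = float(grid.f_p[i_fp])
        cols = region.cells[region.cells[:, 0] == i_fp, 1]
        vals = comod_values[i_fp, cols]
        j_max = cols[int(np.argmax(vals))]
        f_a_max = float(grid.f_a[j_max])
        if j_max == 0:
            warnings.warn(
                f"comodulogram maximum at the lower edge of the amplitude "
                f"range for f_p={f_p} Hz: coupling origin is uncertain")
            region.column_labels[f_p] = AMBIGUOUS
            continue
        width = wavelet_fwhm_freq(f_a_max, w)
        window = (f_a_max - width / 2, f_a_max + width / 2)
        span = (float(grid.f_a[cols.min()]), float(grid.f_a[cols.max()]))
        spec = spectra.get(f_p)
        if spec is None:
            region.column_labels[f_p] = AMBIGUOUS
            continue
        freqs = spec.freqs
        in_range = ((freqs >= span[0]) & (freqs <= span[1])) | (
            (freqs >= window[0]) & (freqs <= window[1]))
        tag = choose_spectrum(spec.avg_spectrum, spec.spectrum_of_avg,
                              in_range)
        chosen = spec.spectrum_of_avg if tag == "SA" else spec.avg_spectrum
        peak = find_spectral_peak(chosen, freqs, in_range)
        if peak is not None and window[0] <= peak <= window[1]:
            region.column_labels[f_p] = RELIABLE
            any_reliable = True
        else:
            region.column_labels[f_p] = AMBIGUOUS
    region.label = RELIABLE if any_reliable else AMBIGUOUS
    return region


def propagate_harmonics(regions: list[CouplingRegion], grid,
                        tol: float | None = None) -> list[CouplingRegion]:
    """Propagate Ambiguous labels from a base frequency to its harmonics.

    Regions whose centroid phase frequency is an approximate integer
    multiple (within ``tol``, default the grid's delta_f_p) of an Ambiguous
    region's centroid are relabelled Ambiguous.  The relabelling is
    monotone: Reliable regions never gain reliability from it.
    """
    if tol is None:
        tol = grid.delta_f_p
    centroids = [r.centroid_f_p(grid) for r in regions]
    changed = True
    while changed:  # chains: a newly ambiguous harmonic can itself be a base
        changed = False
        for b, base in enumerate(regions):
            if base.label != AMBIGUOUS:
                continue
            for h, harm in enumerate(regions):
                if h == b or harm.label == AMBIGUOUS:
                    continue
                ratio = centroids[h] / centroids[b]
                k = round(ratio)
                # strictly within tol: e.g. 13 Hz is not a harmonic of 6 Hz
                # at tol = 1 (13 is on, not inside, the 12 +/- 1 boundary)
                if k >= 2 and abs(centroids[h] - k * centroids[b]) < tol:
                    harm.label = AMBIGUOUS
                    changed = True
    return regions


def region_phase_histogram(region: CouplingRegion,
                           phase_dist: np.ndarray) -> np.ndarray:
    """Mean phase-bin distribution over the region's member pairs.

    ``phase_dist`` has shape (n_fp, n_fa, n_bins); the result sums to one.
    """
    rows = phase_dist[region.cells[:, 0], region.cells[:, 1]]
    return rows.sum(axis=0) / region.cells.shape[0]


def label_comodulogram(mask: np.ndarray, comod, spectra: dict, grid,
                       w: float, phase_dist: np.ndarray
                       ) -> list[CouplingRegion]:
    """Extract, label and annotate all significant regions."""
    regions = extract_regions(mask)
    for region in regions:
        assign_label(region, comod.values, spectra, grid, w)
        if phase_dist is not None:
            region.phase_histogram = region_phase_histogram(region,
                                                            phase_dist)
    return propagate_harmonics(regions, grid)
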