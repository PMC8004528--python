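"""Utilitarian plots: comodulogram with region outlines, polar phase
histograms, and the per-frequency auxiliary view (averaged map, averaged
signals, section spectra)."""

from __future__ import annotations

import numpy as np

from .emi import EMIResult
from .labeling import RELIABLE


def plot_comodulogram(result: EMIResult, ax=None):
    """Significant coupling strength over the (f_p, f_a) plane.

    Reliable regions are drawn in colour, Ambiguous ones in grey, each
    region outlined.  Returns the axes.
    """
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    grid = result.grid
    vals = np.where(result.mask, result.comodulogram.values, np.nan)
    extent = (grid.f_p[0], grid.f_p[-1], grid.f_a[0], grid.f_a[-1])
    reliable = np.full_like(vals, np.nan)
    ambiguous = np.full_like(vals, np.nan)
    for region in result.regions:
        target = reliable if region.label == RELIABLE else ambiguous
        target[region.cells[:, 0], region.cells[:, 1]] = \
            vals[region.cells[:, 0], region.cells[:, 1]]
    ax.imshow(ambiguous.T, origin="lower", aspect="auto", extent=extent,
              cmap="Greys")
    ax.imshow(reliable.T, origin="lower", aspect="auto", extent=extent,
              cmap="viridis")
    ax.set_xlabel("frequency for phase (Hz)")
    ax.set_ylabel("frequency for amplitude (Hz)")
    return ax


def plot_phase_histograms(result: EMIResult, ax=None):
    """Polar histogram of the phase distribution of each region."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    n_bins = result.phase_dist.shape[-1]
    centers = -np.pi + (np.arange(n_bins) + 0.5) * 2 * np.pi / n_bins
    for region in result.regions:
        if region.phase_histogram is None:
            continue
        ax.plot(np.append(centers, centers[0]),
                np.append(region.phase_histogram,
                          region.phase_histogram[0]),
                label=f"region {region.region_id} ({region.label})")
    ax.legend(loc="upper right", fontsize="small")
    return ax


def plot_auxiliary(result: EMIResult, f_p: float, fig=None):
    """Three-cycle averaged map, averaged signals, and the two spectra for
    one phase frequency — the view used to judge a coupling's origin."""
    import matplotlib.pyplot as plt
    sec = result.sections[f_p]
    spec = result.spectra[f_p]
    if fig is None:
        fig = plt.figure(figsize=(8, 5))
    gs = fig.add_gridspec(2, 2, width_ratios=(3, 1), height_ratios=(2, 1))
    ax_map = fig.add_subplot(gs[0, 0])
    t = (np.arange(sec.m_b.shape[1]) - sec.m_b.shape[1] // 2) / sec.fs
    ax_map.pcolormesh(t, result.grid.f_a, sec.m_b, shading="auto")
    ax_map.set_ylabel("f (Hz)")
    ax_sig = fig.add_subplot(gs[1, 0], sharex=ax_map)
    ax_sig.plot(t, sec.s_b, color="darkcyan", label="averaged signal")
    ax_sig.plot(t, sec.sp_b, color="black", label="slow oscillation")
    ax_sig.set_xlabel("time from cycle maximum (s)")
    ax_sig.legend(fontsize="small")
    ax_spec = fig.add_subplot(gs[0, 1], sharey=ax_map)
    ax_spec.plot(spec.avg_spectrum, spec.freqs, color="black",
                 label="average spectrum")
    ax_spec.plot(spec.spectrum_of_avg, spec.freqs, color="darkcyan",
                 label="spectrum of average")
    ax_spec.legend(fontsize="x-small")
    fig.suptitle(f"f_p = {f_p:g} Hz")
    return fig
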