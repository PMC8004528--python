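"""Significance machinery for comodulograms.

Family-wise control uses extreme-value statistics: the maximum of each
surrogate comodulogram forms a null distribution of extremes, and original
values exceeding its p_C-th percentile are declared significant.  Each value
also receives an empirical percentile within the extreme distribution
(P_vals), which converts to a p-value for pooling several epochs under
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["SignificanceResult", "extreme_value_threshold",
           "bin_threshold_filter", "fdr_combine"]


@dataclass
class SignificanceResult:
    threshold: float
    p_vals: np.ndarray  # empirical percentile of each value, in [0, 100]
    mask: np.ndarray
    p_c: float


def extreme_value_threshold(values: np.ndarray,
                            surrogate_values: np.ndarray,
                            p_c: float = 95.0) -> SignificanceResult:
    """Threshold original values against the surrogate-maxima distribution.

    Parameters
    ----------
    values : ndarray
        Original comodulogram (NaN marks abandoned cells).
    surrogate_values : ndarray
        Surrogate comodulograms stacked on the first axis, shape
        ``(n_surr, ...)`` matching ``values`` elsewhere.
    p_c : float
        Percentile of the extreme distribution used as threshold.

    The percentile uses linear interpolation between order statistics.
    Empirical percentiles are floored so that the implied p-value is never
    below 1/(n_surr + 1).
    """
    n_surr = surrogate_values.shape[0]
    if n_surr < 20:
        raise ValueError("at least 20 surrogates are required for a stable "
                         "95th-percentile threshold")
    flat = surrogate_values.reshape(n_surr, -1)
    if np.all(np.isnan(flat)):
        maxima = np.full(n_surr, np.nan)
    else:
        maxima = np.nanmax(flat, axis=1)
    threshold = float(np.percentile(maxima, p_c, method="linear"))
    mask = np.zeros_like(values, dtype=bool)
    valid = ~np.isnan(values)
    mask[valid] = values[valid] > threshold
    # empirical percentile of each value within the maxima distribution
    sorted_max = np.sort(maxima)
    ranks = np.searchsorted(sorted_max, values, side="right")
    p_vals = 100.0 * ranks / n_surr
    ceiling = 100.0 * (1.0 - 1.0 / (n_surr + 1))
    p_vals = np.minimum(p_vals, ceiling)
    p_vals[~valid] = np.nan
    return SignificanceResult(threshold=threshold, p_vals=p_vals, mask=mask,
                              p_c=p_c)


def bin_threshold_filter(mask: np.ndarray, p: np.ndarray,
                         th: np.ndarray) -> np.ndarray:
    """Reject pairs whose phase-bin distribution never exceeds its threshold.

    ``p`` holds the normalised mean amplitude per phase bin for each pair
    (shape ``mask.shape + (n_bins,)``), ``th`` the per-pair surrogate-derived
    bin threshold (same shape or broadcastable).  A pair is kept iff some
    bin exceeds its threshold.  The filter is idempotent.
    """
    if p.shape[:mask.ndim] != mask.shape:
        raise ValueError("phase-distribution shape does not match mask")
    th = np.asarray(th)
    if th.ndim == p.ndim - 1:
        th = th[..., np.newaxis]  # one threshold shared by all bins of a pair
    exceeds = np.any(p > th, axis=-1)
    return mask & exceeds


def fdr_combine(p_vals_per_epoch: list[np.ndarray], q: float = 0.05,
                n_surr: int | None = None) -> list[np.ndarray]:
    """Benjamini-Hochberg FDR across epochs of comodulogram P_vals.

    ``p_vals_per_epoch`` holds empirical percentiles (0-100) as produced by
    :func:`extreme_value_threshold`; they are converted to p-values
    ``1 - P/100``, floored at ``1/(n_surr + 1)`` when ``n_surr`` is given,
    pooled across all epochs and pairs, and tested at level ``q``.  Returns
    one boolean mask per epoch; NaN entries are never significant.
    """
    pooled = []
    shapes = []
    for pv in p_vals_per_epoch:
        pv = np.asarray(pv, dtype=float)
        shapes.append(pv.shape)
        p = 1.0 - pv / 100.0
        if n_surr is not None:
            p = np.maximum(p, 1.0 / (n_surr + 1))
        pooled.append(p.ravel())
    flat = np.concatenate(pooled)
    valid = ~np.isnan(flat)
    reject = np.zeros(flat.size, dtype=bool)
    if valid.any():
        reject[valid] = multipletests(flat[valid], alpha=q,
                                      method="fdr_bh")[0]
    masks = []
    start = 0
    for shape in shapes:
        size = int(np.prod(shape))
        masks.append(reject[start:start + size].reshape(shape))
        start += size
    return masks
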