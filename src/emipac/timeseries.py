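"""Uniformly sampled single-channel time series, the universal input type."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled voltage trace.

    Parameters
    ----------
    samples : ndarray
        Signal values in arbitrary units (e.g. microvolts).
    fs : float
        Sampling rate in Hz. Must be positive.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size == 0:
            raise ValueError("samples must be non-empty")
        if not np.isfinite(samples).all():
            raise ValueError("samples contain NaN or infinite values")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray) -> "TimeSeries":
        return TimeSeries(samples=samples, fs=self.fs)

    def slice_seconds(self, start: float, stop: float) -> "TimeSeries":
        """Extract the fragment between ``start`` and ``stop`` seconds."""
        i0 = int(round(start * self.fs))
        i1 = int(round(stop * self.fs))
        if i0 < 0 or i1 > self.n or i1 <= i0:
            raise ValueError(
                f"requested fragment [{start}, {stop}] s outside signal of "
                f"duration {self.duration:.3f} s"
            )
        return TimeSeries(samples=self.samples[i0:i1], fs=self.fs)
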