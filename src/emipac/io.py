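"""Readers, writers, epoching and analysis configuration."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .emi import EMIResult
from .timeseries import TimeSeries

__all__ = ["AnalysisConfig", "read_timeseries", "write_timeseries_csv",
           "write_results", "epoch_splitter"]


@dataclass
class AnalysisConfig:
    """Serializable description of one analysis run."""

    method: str = "emi"
    f_p_start: float = 1.0
    f_p_stop: float = 12.0
    f_p_step: float = 0.5
    f_a_start: float = 20.0
    f_a_stop: float = 200.0
    f_a_step: float = 2.0
    delta_f_p: float = 1.0
    w: float = 5.0
    n_bins: int = 18
    n_surr: int = 200
    p_c: float = 95.0
    p_pc: float = 95.0
    fdr_q: float = 0.05
    epoch_s: float | None = None
    seed: int = 0
    input_path: str | None = None
    input_format: str | None = None

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def grid(self):
        from .reference import ComodulogramGrid
        eps = 1e-9
        return ComodulogramGrid(
            f_p=np.arange(self.f_p_start, self.f_p_stop + eps, self.f_p_step),
            f_a=np.arange(self.f_a_start, self.f_a_stop + eps, self.f_a_step),
            delta_f_p=self.delta_f_p)


def _read_csv(path, fs: float | None) -> TimeSeries:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as err:
        raise ValueError(f"malformed CSV {path}: {err}") from err
    if df.shape[1] >= 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        v = df.iloc[:, 1].to_numpy(dtype=float)
        dt = np.diff(t)
        if dt.size == 0:
            raise ValueError(f"{path}: need at least two samples")
        if np.any(np.abs(dt - dt.mean()) > 1e-6 * max(dt.mean(), 1e-12)):
            raise ValueError(f"{path}: time column is not uniformly sampled")
        return TimeSeries(v, 1.0 / dt.mean())
    if fs is None:
        raise ValueError(f"{path} has a single column; sampling rate "
                         "must be supplied")
    return TimeSeries(df.iloc[:, 0].to_numpy(dtype=float), fs)


def _read_edf(path, channel) -> TimeSeries:
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("EDF reading requires the optional 'mne' "
                          "dependency") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channel is None:
        channel = raw.ch_names[0]
    elif isinstance(channel, int):
        channel = raw.ch_names[channel]
    if channel not in raw.ch_names:
        raise ValueError(f"channel '{channel}' not found in {path}; "
                         f"available: {raw.ch_names}")
    data = raw.get_data(picks=[channel])[0]
    return TimeSeries(data, float(raw.info["sfreq"]))


def read_timeseries(path, fmt: str | None = None, fs: float | None = None,
                    channel=None) -> TimeSeries:
    """Read a single-channel time series from CSV, NPY or EDF.

    CSV may have (time_s, value) columns or a single value column with
    ``fs`` given explicitly.  For EDF, ``channel`` selects by label or
    index (first channel by default).
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return _read_csv(path, fs)
    if fmt == "npy":
        if fs is None:
            raise ValueError("sampling rate must be supplied for NPY input")
        return TimeSeries(np.load(path).astype(float).ravel(), fs)
    if fmt == "edf":
        return _read_edf(path, channel)
    raise ValueError(f"unknown input format '{fmt}' "
                     "(expected csv, npy or edf)")


def write_timeseries_csv(x: TimeSeries, path,
                         params: dict | None = None) -> None:
    """Two-column (time_s, value) CSV, with an optional JSON sidecar of
    generator parameters."""
    pd.DataFrame({"time_s": x.times, "value": x.samples}).to_csv(
        path, index=False)
    if params is not None:
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(json.dumps(params, indent=2, default=float))


def write_results(result: EMIResult, path,
                  config: AnalysisConfig | None = None) -> None:
    """Write a complete eMI result bundle to HDF5.

    Layout: /comodulogram, /mask, /pvals, /phase_dist, /bin_threshold,
    /grid/{f_p,f_a}, /regions (table), /per_fp/<f_p>/{m_a,m_b,sp_a,sp_b,
    s_b,phase_a,as,sa,spec_freqs}; root attributes carry the configuration,
    seed and package version.
    """
    with h5py.File(path, "w") as h5:
        h5.create_dataset("comodulogram", data=result.comodulogram.values)
        h5.create_dataset("mask", data=result.mask)
        h5.create_dataset("pvals", data=result.significance.p_vals)
        h5.create_dataset("phase_dist", data=result.phase_dist)
        h5.create_dataset("bin_threshold", data=result.bin_threshold)
        g = h5.create_group("grid")
        g.create_dataset("f_p", data=result.grid.f_p)
        g.create_dataset("f_a", data=result.grid.f_a)
        reg = h5.create_group("regions")
        for r in result.regions:
            rg = reg.create_group(str(r.region_id))
            rg.create_dataset("cells", data=r.cells)
            rg.attrs["label"] = r.label or ""
            if r.phase_histogram is not None:
                rg.create_dataset("phase_histogram", data=r.phase_histogram)
        per = h5.create_group("per_fp")
        for f_p, sec in result.sections.items():
            sg = per.create_group(f"{f_p:g}")
            sg.create_dataset("m_a", data=sec.m_a)
            sg.create_dataset("m_b", data=sec.m_b)
            sg.create_dataset("sp_a", data=sec.sp_a)
            sg.create_dataset("sp_b", data=sec.sp_b)
            sg.create_dataset("s_b", data=sec.s_b)
            sg.create_dataset("phase_a", data=sec.phase_a)
            spec = result.spectra[f_p]
            sg.create_dataset("as", data=spec.avg_spectrum)
            sg.create_dataset("sa", data=spec.spectrum_of_avg)
            sg.create_dataset("spec_freqs", data=spec.freqs)
        h5.attrs["version"] = __version__
        h5.attrs["seed"] = result.seed
        h5.attrs["w"] = result.w
        h5.attrs["threshold"] = result.significance.threshold
        h5.attrs["abandoned"] = json.dumps(result.abandoned)
        if config is not None:
            h5.attrs["config"] = json.dumps(asdict(config))


def epoch_splitter(x: TimeSeries, epoch_s: float,
                   z_reject: float | None = 5.0) -> list[TimeSeries]:
    """Split into contiguous non-overlapping epochs, rejecting artefacts.

    A trailing partial epoch is discarded.  An epoch is rejected when any
    sample deviates from the whole-signal mean by more than ``z_reject``
    whole-signal standard deviations (a simple amplitude criterion).
    """
    n_epoch = int(round(epoch_s * x.fs))
    if n_epoch <= 0 or n_epoch > x.n:
        raise ValueError("epoch length must be positive and at most the "
                         "signal duration")
    mu, sd = x.samples.mean(), x.samples.std()
    epochs = []
    for start in range(0, x.n - n_epoch + 1, n_epoch):
        seg = x.samples[start:start + n_epoch]
        if z_reject is not None and sd > 0 and np.any(
                np.abs(seg - mu) > z_reject * sd):
            continue
        epochs.append(TimeSeries(seg, x.fs))
    return epochs
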