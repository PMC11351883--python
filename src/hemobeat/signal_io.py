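"""Reading, writing and pre-filtering of synchronized multichannel records.

A recording session holds four synchronized 1 kHz channels — ECG (mV), PCG
(chest-wall acoustics, arbitrary units), PPG (femoral optical pulse,
arbitrary units) and, for catheterized sessions, left-ventricular blood
pressure (LVBP, mmHg) — plus subject/record/dose metadata.  Two container
formats are supported: long-format CSV (one column per channel, canonical
test-fixture format) and HDF5 (one dataset per channel under ``/channels``
with root attributes).

Pre-filtering is zero-phase (forward-backward Butterworth) so no channel is
delayed relative to the others: PCG is band-passed to 30-200 Hz, ECG to
0.5-40 Hz, PPG to 0.5-20 Hz.  LVBP is low-passed at 20 Hz only: the absolute
pressure level and its slow drug-driven excursion are exactly what the
beat-wise labels are extracted from, so the DC component must survive
filtering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "CHANNELS",
    "DEFAULT_FILTERS",
    "FilterSpec",
    "MultichannelRecord",
    "UnsupportedFormatError",
    "bandpass_zero_phase",
    "load_record",
    "preprocess_record",
    "write_record",
]

#: Channel names in canonical order.
CHANNELS = ("ecg", "pcg", "ppg", "lvbp")


class UnsupportedFormatError(ValueError):
    """Raised for file formats this build does not read or write."""


@dataclass(frozen=True)
class FilterSpec:
    """Pre-filter description for one channel.

    ``passband_low == 0`` denotes a pure low-pass (used for LVBP, whose
    absolute level carries the pressure calibration).  The filter family and
    order are not dictated by the acquisition protocol; a 4th-order
    Butterworth applied forward-backward (effective 8th order, zero phase)
    is the standard biosignal choice.
    """

    channel: str
    passband_low: float
    passband_high: float
    order: int = 4
    design: str = "butter"

    def __post_init__(self) -> None:
        if not 0 <= self.passband_low < self.passband_high:
            raise ValueError(
                f"invalid passband [{self.passband_low}, {self.passband_high}]"
            )


DEFAULT_FILTERS: dict[str, FilterSpec] = {
    "ecg": FilterSpec("ecg", 0.5, 40.0),
    "pcg": FilterSpec("pcg", 30.0, 200.0),
    "ppg": FilterSpec("ppg", 0.5, 20.0),
    "lvbp": FilterSpec("lvbp", 0.0, 20.0),
}


@dataclass
class MultichannelRecord:
    """One continuous recording session of synchronized 1 kHz channels.

    LVBP is optional: inference-only data carry PCG/PPG (and usually ECG)
    without the invasive pressure channel.
    """

    record_id: str
    subject_id: str
    fs: float
    ecg: np.ndarray
    pcg: np.ndarray
    ppg: np.ndarray
    lvbp: np.ndarray | None = None
    dose: float | None = None
    filters_applied: dict[str, FilterSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for name in CHANNELS:
            x = getattr(self, name)
            if x is not None:
                setattr(self, name, np.asarray(x, dtype=float))
        lengths = {name: len(getattr(self, name)) for name in self.present_channels}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel length mismatch: {lengths}")
        if self.n_samples < 1:
            raise ValueError("record must contain at least one sample")

    @property
    def present_channels(self) -> tuple[str, ...]:
        return tuple(c for c in CHANNELS if getattr(self, c) is not None)

    @property
    def has_lvbp(self) -> bool:
        return self.lvbp is not None

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(name)
        x = getattr(self, name)
        if x is None:
            raise KeyError(f"channel {name!r} not present in record {self.record_id}")
        return x

    def replace(self, **kwargs) -> "MultichannelRecord":
        return dataclasses.replace(self, **kwargs)


def bandpass_zero_phase(
    x: np.ndarray,
    fs: float,
    low: float,
    high: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth filter (forward-backward, ``sosfiltfilt``).

    ``low == 0`` gives a low-pass; ``high >= fs/2`` gives a high-pass.
    Forward-backward application squares the magnitude response (effective
    order ``2*order``) and cancels the phase, so the output is not delayed —
    essential when beat-locked features are compared across channels.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    if not 0 <= low < high:
        raise ValueError(f"invalid band [{low}, {high}]")
    if low >= nyq:
        raise ValueError(f"band edge {low} Hz not below Nyquist {nyq} Hz")
    if low == 0 and high >= nyq:
        return x.copy()
    if low == 0:
        sos = sps.butter(order, high / nyq, btype="lowpass", output="sos")
    elif high >= nyq:
        sos = sps.butter(order, low / nyq, btype="highpass", output="sos")
    else:
        sos = sps.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")
    # sosfiltfilt pads by odd reflection; require enough samples for the
    # startup transient of the squared filter.
    if x.size <= 3 * (2 * order + 1):
        raise ValueError(f"signal of {x.size} samples too short for order-{order} zero-phase filter")
    return sps.sosfiltfilt(sos, x)


def resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling between (rational) sampling rates."""
    if fs_in == fs_out:
        return np.asarray(x, dtype=float)
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return sps.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator)


def preprocess_record(
    record: MultichannelRecord,
    filters: dict[str, FilterSpec] | None = None,
    target_fs: float = 1000.0,
) -> MultichannelRecord:
    """Apply the per-channel zero-phase pre-filters to a record.

    If the record was sampled at a rate other than ``target_fs`` it is first
    polyphase-resampled, because the model input window is defined in samples
    at 1 kHz.  The applied :class:`FilterSpec` objects are recorded on the
    returned copy; absent optional channels are skipped silently.
    """
    filters = dict(DEFAULT_FILTERS if filters is None else filters)
    updates: dict[str, np.ndarray] = {}
    fs = record.fs
    for name in record.present_channels:
        x = record.channel(name)
        if fs != target_fs:
            x = resample_to(x, fs, target_fs)
        spec = filters[name]
        updates[name] = bandpass_zero_phase(
            x, target_fs, spec.passband_low, spec.passband_high, spec.order
        )
    applied = {name: filters[name] for name in record.present_channels}
    return record.replace(fs=target_fs, filters_applied=applied, **updates)


# ---------------------------------------------------------------------------
# File formats


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in {".h5", ".hdf5", ".hdf"}:
        return "hdf5"
    raise UnsupportedFormatError(f"cannot infer format from suffix {suffix!r}")


def load_record(
    path: str | Path,
    format_name: str | None = None,
    fs: float = 1000.0,
    record_id: str | None = None,
    subject_id: str | None = None,
) -> MultichannelRecord:
    """Read a multichannel record from CSV or HDF5.

    CSV carries no metadata, so ``fs``/``record_id``/``subject_id`` may be
    supplied (the record id defaults to the file stem).  HDF5 stores them as
    root attributes.  Channel columns of unequal length (trailing NaNs in a
    ragged CSV) raise a length-mismatch error; a missing ``lvbp`` column is
    tolerated and flagged via :attr:`MultichannelRecord.has_lvbp`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_name or _infer_format(path)
    if fmt == "csv":
        df = pd.read_csv(path)
        missing = {"ecg", "pcg", "ppg"} - set(df.columns)
        if missing:
            raise ValueError(f"CSV {path} missing required channels {sorted(missing)}")
        channels: dict[str, np.ndarray | None] = {}
        lengths = {}
        for name in CHANNELS:
            if name in df.columns:
                col = df[name].to_numpy(dtype=float)
                valid = ~np.isnan(col)
                col = col[: valid.nonzero()[0][-1] + 1] if valid.any() else col[:0]
                channels[name] = col
                lengths[name] = len(col)
            else:
                channels[name] = None
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel length mismatch in {path}: {lengths}")
        return MultichannelRecord(
            record_id=record_id or path.stem,
            subject_id=subject_id or "unknown",
            fs=fs,
            ecg=channels["ecg"],
            pcg=channels["pcg"],
            ppg=channels["ppg"],
            lvbp=channels["lvbp"],
        )
    if fmt == "hdf5":
        with h5py.File(path, "r") as f:
            grp = f["channels"]
            channels = {
                name: np.asarray(grp[name], dtype=float) if name in grp else None
                for name in CHANNELS
            }
            attrs = dict(f.attrs)
        lengths = {k: len(v) for k, v in channels.items() if v is not None}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel length mismatch in {path}: {lengths}")
        dose = attrs.get("dose")
        return MultichannelRecord(
            record_id=record_id or str(attrs.get("record_id", path.stem)),
            subject_id=subject_id or str(attrs.get("subject_id", "unknown")),
            fs=float(attrs.get("fs", fs)),
            ecg=channels["ecg"],
            pcg=channels["pcg"],
            ppg=channels["ppg"],
            lvbp=channels["lvbp"],
            dose=float(dose) if dose is not None and not np.isnan(float(dose)) else None,
        )
    if fmt == "wfdb":
        raise UnsupportedFormatError(
            "WFDB reading is not available in this build; convert to CSV or HDF5"
        )
    raise UnsupportedFormatError(f"unknown format {fmt!r}")


def write_record(record: MultichannelRecord, path: str | Path, format_name: str | None = None) -> Path:
    """Write a record as CSV (``t,ecg,pcg,ppg,lvbp``) or HDF5."""
    path = Path(path)
    fmt = format_name or _infer_format(path)
    if fmt == "csv":
        data = {"t": np.arange(record.n_samples) / record.fs}
        for name in CHANNELS:
            x = getattr(record, name)
            if x is not None:
                data[name] = x
        pd.DataFrame(data).to_csv(path, index=False)
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            grp = f.create_group("channels")
            for name in record.present_channels:
                grp.create_dataset(name, data=record.channel(name))
            f.attrs["fs"] = record.fs
            f.attrs["record_id"] = record.record_id
            f.attrs["subject_id"] = record.subject_id
            f.attrs["dose"] = record.dose if record.dose is not None else np.nan
    elif fmt == "wfdb":
        raise UnsupportedFormatError(
            "WFDB writing is not available in this build; use CSV or HDF5"
        )
    else:
        raise UnsupportedFormatError(f"unknown format {fmt!r}")
    return path
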