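"""Scalp EEG containers, readers/writers, referencing and preprocessing.

The analysis chain expects ~5 min of resting-state EEG on the 19-channel
10-20 montage.  Preprocessing reproduces the conventional offline chain:
common-average reference, zero-phase 2-44 Hz bandpass, resampling to 128 Hz.

Recordings live in microvolts.  Supported on-disk formats are EDF (16-bit)
and delimited text with a header row of channel labels plus a ``# fs:``
comment line carrying the sampling rate.
"""

from __future__ import annotations

import datetime as _dt
import io
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal

#: Canonical 19-channel 10-20 montage (modern nomenclature).
MONTAGE_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)

#: Legacy 10-20 names mapped onto the modern ones.
CHANNEL_ALIASES: dict[str, str] = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

_CANONICAL_LOWER = {name.lower(): name for name in MONTAGE_1020}
_ALIAS_LOWER = {k.lower(): v for k, v in CHANNEL_ALIASES.items()}


def canonical_label(label: str) -> str:
    """Map a raw channel label to its canonical 10-20 name.

    Strips common prefixes/suffixes such as ``EEG Fp1-REF`` and resolves
    legacy aliases (T3->T7 etc.).  Raises ``KeyError`` for unknown labels.
    """
    raw = label.strip()
    token = raw
    if token.lower().startswith("eeg"):
        token = token[3:].strip(" :_-")
    token = token.split("-")[0].strip()
    low = token.lower()
    if low in _CANONICAL_LOWER:
        return _CANONICAL_LOWER[low]
    if low in _ALIAS_LOWER:
        return _ALIAS_LOWER[low]
    raise KeyError(f"unknown channel label {label!r}")


@dataclass
class EEGRecording:
    """Multichannel scalp EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = MONTAGE_1020
    reference: str = "original"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_labels)} channel labels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.reference not in ("original", "common_average"):
            raise ValueError(f"unknown reference state {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy())


def _validate_montage(labels: list[str]) -> tuple[str, ...]:
    mapped = []
    unmapped = []
    for lab in labels:
        try:
            mapped.append(canonical_label(lab))
        except KeyError:
            unmapped.append(lab)
    if unmapped:
        raise ValueError(f"unmapped channel labels: {unmapped}")
    missing = [name for name in MONTAGE_1020 if name not in mapped]
    if missing:
        raise ValueError(f"recording is missing montage channels: {missing}")
    return tuple(mapped)


def read_recording(path: str | Path, format: str | None = None,
                   fs: float | None = None, require_montage: bool = True) -> EEGRecording:
    """Read an EEG recording from EDF or delimited text.

    Parameters
    ----------
    path : file to read.  Format is inferred from the suffix unless given.
    format : "edf" or "csv".
    fs : sampling rate override; required for text files without a
        ``# fs:`` comment line.
    require_montage : if True (default), the file must contain exactly the
        19-channel 10-20 montage; labels are mapped to canonical names.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        rec = _read_edf(path)
    elif format == "csv":
        rec = _read_csv(path, fs=fs)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'edf' or 'csv')")
    if require_montage:
        labels = _validate_montage(list(rec.channel_labels))
        order = [labels.index(name) for name in MONTAGE_1020]
        rec = EEGRecording(rec.data[order], rec.fs, MONTAGE_1020, rec.reference)
    return rec


def _read_edf(path: Path) -> EEGRecording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne loads volts
    return EEGRecording(data_uv, float(raw.info["sfreq"]), tuple(raw.ch_names))


def _read_csv(path: Path, fs: float | None) -> EEGRecording:
    import pandas as pd

    header_fs = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "fs" in first:
                header_fs = float(first.split(":")[-1].strip())
            text = fh.read()
        else:
            text = first + fh.read()
    if fs is None:
        fs = header_fs
    if fs is None:
        raise ValueError("sampling rate not found in file; pass fs=")
    df = pd.read_csv(io.StringIO(text))
    if df.shape[0] == 0:
        raise ValueError(f"truncated or empty file: {path}")
    return EEGRecording(df.to_numpy().T, float(fs), tuple(str(c) for c in df.columns))


def write_csv(rec: EEGRecording, path: str | Path, float_fmt: str = "%.6f") -> None:
    """Write a recording as delimited text (samples x channels, label header)."""
    import pandas as pd

    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs: {rec.fs:g}\n")
        pd.DataFrame(rec.data.T, columns=list(rec.channel_labels)).to_csv(
            fh, index=False, float_format=float_fmt
        )


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF.

    Minimal EDF writer: one-second data records, per-channel physical
    scaling over the full 16-bit digital range, physical unit microvolts.
    The sample count must be a whole number of 1 s records (the tail is
    truncated with a warning otherwise).
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_rec = rec.n_samples // spr
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF record (1 s)")
    if n_rec * spr != rec.n_samples:
        warnings.warn("truncating recording to a whole number of 1 s EDF records")
    data = rec.data[:, : n_rec * spr]
    nch = rec.n_channels

    # round the physical range up to 2 decimals so the 8-char header field
    # holds it exactly; the digital scaling must use the written value
    phys_max = np.ceil(np.maximum(np.abs(data).max(axis=1), 1e-2) * 100) / 100
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.rint((data - phys_min[:, None]) * scale[:, None]) + dig_min, dig_min, dig_max
    ).astype("<i2")

    def pad(value: str, width: int) -> bytes:
        b = value.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("Startdate X X X X", 80),
        pad(now.strftime("%d.%m.%y"), 8),
        pad(now.strftime("%H.%M.%S"), 8),
        pad(str(256 * (1 + nch)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),
        pad(str(nch), 4),
    ])
    fields = [
        b"".join(pad(lab, 16) for lab in rec.channel_labels),
        b"".join(pad("AgAgCl electrode", 80) for _ in range(nch)),
        b"".join(pad("uV", 8) for _ in range(nch)),
        b"".join(pad(f"{phys_min[i]:.2f}", 8) for i in range(nch)),
        b"".join(pad(f"{phys_max[i]:.2f}", 8) for i in range(nch)),
        b"".join(pad(str(dig_min), 8) for _ in range(nch)),
        b"".join(pad(str(dig_max), 8) for _ in range(nch)),
        b"".join(pad("", 80) for _ in range(nch)),
        b"".join(pad(str(spr), 8) for _ in range(nch)),
        b"".join(pad("", 32) for _ in range(nch)),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(f)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def common_average_reference(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the common average (per-sample channel mean removed).

    Raises if the recording is already common-average referenced; the
    transform is idempotent numerically but re-applying it usually signals
    a pipeline wiring error.
    """
    if rec.reference == "common_average":
        raise ValueError("recording is already common-average referenced")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return EEGRecording(data, rec.fs, rec.channel_labels, reference="common_average")


def bandpass_sos(lo: float, hi: float, fs: float, order: int = 4):
    """Butterworth bandpass in second-order sections, for zero-phase use."""
    nyq = fs / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz is at or above Nyquist ({nyq} Hz)")
    return signal.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def bandpass_filter(x: np.ndarray, lo: float, hi: float, fs: float,
                    order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth bandpass."""
    sos = bandpass_sos(lo, hi, fs, order)
    return signal.sosfiltfilt(sos, x, axis=axis)


def preprocess(rec: EEGRecording, lo: float = 2.0, hi: float = 44.0,
               fs_target: float = 128.0, order: int = 16) -> EEGRecording:
    """Zero-phase 2-44 Hz bandpass followed by resampling to 128 Hz.

    The default filter order is steep (16th-order Butterworth, applied
    forward and backward) because the analysis band ends at 44 Hz while
    mains interference sits at 50 Hz; the input rate must satisfy
    fs >= 2*hi, and upsampling is refused.
    """
    if rec.fs < 2 * hi:
        raise ValueError(f"input rate {rec.fs} Hz too low for a {hi} Hz band edge")
    if fs_target > rec.fs:
        raise ValueError("fs_target exceeds the recording rate; upsampling is not supported")
    filtered = bandpass_filter(rec.data, lo, hi, rec.fs, order=order)
    if fs_target == rec.fs:
        out = filtered
    else:
        frac = Fraction(fs_target / rec.fs).limit_denominator(1000)
        out = signal.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    return EEGRecording(out, fs_target, rec.channel_labels, rec.reference)
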