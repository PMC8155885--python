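"""Recording / event-table I/O, filtering, band splitting and epoching.

A Recording is a channels x samples amplitude matrix (microvolts) with a
sampling rate and ordered 10/20-system channel labels.  The conditioning
chain is: zero-phase band-pass 0.5-50 Hz plus a 60 Hz notch (power-line),
then per-band zero-phase band-pass filters for the five clinical bands.
Independent-component artifact removal is deliberately a pre-processing
hook outside this package: inputs are assumed artifact-cleaned.

Epochs are cut per question: epoch (t, q) spans [onset(t,q), onset of the
next question), half-open on 0-based sample indices, so epochs tile each
trial exactly.  The fourth question's epoch closes at the next trial's
first onset (or the end of the recording for the final trial).
"""

from __future__ import annotations

import csv as _csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import BoundsError, FormatError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BANDS",
    "Recording",
    "EventTable",
    "Epoch",
    "read_recording",
    "write_recording_csv",
    "bandpass_notch",
    "band_split",
    "epoch_recording",
]

#: Clinical band edges in Hz; gamma is capped at 50 Hz by the low-pass.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

#: Maximum allowed response time (s); slower responses are flagged missing.
RESPONSE_WINDOW_S = 3.0


@dataclass
class Recording:
    """Multichannel EEG segment: data is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be > 0, got {self.fs}")
        if len(self.channel_names) != self.data.shape[0]:
            raise FormatError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise FormatError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]


@dataclass
class EventTable:
    """Per-question onsets and response times.

    Wraps a tidy frame with columns trial, question (1..4), onset_s and
    rt_s.  Onsets must be strictly increasing within each trial;
    responses outside (0, 3] s are flagged missing (NaN) rather than
    dropped, so trial indexing is preserved.
    """

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("trial", "question", "onset_s", "rt_s")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise FormatError(f"event table missing columns {missing}")
        df = self.df.sort_values(["trial", "question"]).reset_index(drop=True)
        for trial, grp in df.groupby("trial"):
            onsets = grp["onset_s"].to_numpy()
            if not np.all(np.diff(onsets) > 0):
                raise FormatError(f"onsets not strictly increasing in trial {trial}")
        bad = (df["rt_s"] <= 0) | (df["rt_s"] > RESPONSE_WINDOW_S)
        if bad.any():
            logger.info("flagging %d response times outside (0, %g] s as missing",
                        int(bad.sum()), RESPONSE_WINDOW_S)
            df.loc[bad, "rt_s"] = np.nan
        self.df = df

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @property
    def trials(self) -> list[int]:
        return sorted(self.df["trial"].unique())

    def onset(self, trial: int, question: int) -> float:
        sel = self.df[(self.df["trial"] == trial) & (self.df["question"] == question)]
        if sel.empty:
            raise BoundsError(f"no onset for trial {trial} question {question}")
        return float(sel["onset_s"].iloc[0])


@dataclass
class Epoch:
    """One question's samples for one channel in one band."""

    samples: np.ndarray
    fs: float
    trial: int
    question: int
    channel: str
    band: str = "broadband"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()

    def __len__(self) -> int:
        return self.samples.size


def read_recording(path: str | Path, format: str | None = None,
                   fs: float = 1000.0) -> Recording:
    """Read a Recording from EDF or CSV.

    CSV dialect: a header row of channel names followed by one row of
    samples per channel, in header order; ``fs`` must be supplied (CSV
    carries no rate).  EDF is read through MNE and carries its own rate;
    amplitudes are converted to microvolts.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        import mne  # deferred: slow import, EDF-only dependency

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        rec = Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))
    elif format == "csv":
        with open(path, newline="") as fh:
            rows = list(_csv.reader(fh))
        if len(rows) < 2:
            raise FormatError(f"{path}: need a header row and one row per channel")
        names = [c.strip() for c in rows[0]]
        if len(rows) - 1 != len(names):
            raise FormatError(
                f"{path}: header names {len(names)} channels but file has "
                f"{len(rows) - 1} data rows"
            )
        lengths = {len(r) for r in rows[1:]}
        if len(lengths) != 1:
            raise FormatError(f"{path}: ragged rows with lengths {sorted(lengths)}")
        try:
            data = np.array(rows[1:], dtype=float)
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric sample value ({exc})") from None
        rec = Recording(data, fs, names)
    else:
        raise ParameterError(f"unknown format {format!r}")
    logger.info("read %s: %d channels, %d samples at %g Hz",
                path.name, rec.n_channels, rec.n_samples, rec.fs)
    return rec


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write the CSV dialect read_recording expects."""
    with open(path, "w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(rec.channel_names)
        for row in rec.data:
            writer.writerow([f"{v:.6g}" for v in row])


def _butter_sos(low: float, high: float, fs: float, order: int = 4):
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_notch(rec: Recording, low: float = 0.5, high: float = 50.0,
                   notch: float | None = 60.0) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass plus a Q=30 notch.

    Zero-phase (forward-backward) filtering preserves epoch timing.  The
    high-pass edge removes DC drift; the notch suppresses power-line
    interference.  Returns a filtered copy with identical dimensions.
    """
    nyq = rec.fs / 2
    if not (0 < low < high):
        raise ParameterError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ParameterError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    data = signal.sosfiltfilt(_butter_sos(low, high, rec.fs), rec.data, axis=1)
    if notch is not None:
        if notch >= nyq:
            raise ParameterError(f"notch {notch} Hz >= Nyquist {nyq} Hz")
        b, a = signal.iirnotch(notch, Q=30.0, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=1)
    return Recording(data, rec.fs, list(rec.channel_names))


def band_split(rec: Recording,
               bands: dict[str, tuple[float, float] | None] | None = None
               ) -> dict[str, Recording]:
    """Split a Recording into one filtered copy per frequency band.

    ``bands`` maps band name to (low, high) edges in Hz; a value of None
    requests a broadband passthrough (unfiltered copy).  Defaults to the
    five clinical bands.
    """
    if bands is None:
        bands = dict(DEFAULT_BANDS)
    nyq = rec.fs / 2
    out: dict[str, Recording] = {}
    for name, edges in bands.items():
        if edges is None:
            out[name] = Recording(rec.data.copy(), rec.fs, list(rec.channel_names))
            continue
        low, high = edges
        if not (0 < low < high < nyq):
            raise ParameterError(
                f"band {name!r} edges ({low}, {high}) Hz outside (0, {nyq}) Hz"
            )
        data = signal.sosfiltfilt(_butter_sos(low, high, rec.fs), rec.data, axis=1)
        out[name] = Recording(data, rec.fs, list(rec.channel_names))
    return out


def epoch_recording(rec: Recording, events: EventTable,
                    band: str = "broadband") -> list[Epoch]:
    """Cut per-question epochs from a Recording.

    Epoch (t, q) spans sample indices [round(onset(t,q)*fs),
    round(onset_next*fs)) where onset_next is the next question's onset,
    the next trial's first onset for q = 4, or the recording end for the
    final question.  Four epochs per trial per channel.
    """
    df = events.df
    onsets = df[["trial", "question", "onset_s"]].to_numpy()
    order = np.lexsort((onsets[:, 1], onsets[:, 0]))
    onsets = onsets[order]
    n = rec.n_samples
    epochs: list[Epoch] = []
    for i, (trial, question, onset_s) in enumerate(onsets):
        start = int(round(onset_s * rec.fs))
        if i + 1 < len(onsets):
            end = int(round(onsets[i + 1, 2] * rec.fs))
        else:
            end = n
        if start >= n or end > n:
            raise BoundsError(
                f"trial {int(trial)} question {int(question)} at {onset_s:g} s "
                f"exceeds recording of {rec.duration_s:g} s"
            )
        for ch_idx, ch in enumerate(rec.channel_names):
            epochs.append(Epoch(rec.data[ch_idx, start:end], rec.fs,
                                int(trial), int(question), ch, band))
    return epochs
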