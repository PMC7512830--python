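"""Input/output and analysis configuration.

EEG recordings come in either as EDF files or as delimited numeric matrices
(rows = channels, columns = samples).  Event tables are tab-separated files
with columns ``time_s``, ``label`` and ``source``.  All times are seconds
from the first sample of the recording (t = 0); no wall-clock timestamps are
kept anywhere in the pipeline.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "EventTable",
    "AnalysisConfig",
    "read_eeg",
    "read_events",
    "write_events",
    "write_eeg_csv",
]

EVENT_SOURCES = ("subjective", "objective")

#: Electrode labels of the 19-channel International 10-20 dry-electrode montage.
TEN_TWENTY_19 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "C3", "Cz",
    "C4", "T4", "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
]


@dataclass
class EEGRecording:
    """A multichannel recording: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    fs: float
    channels: list
    t0: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        n_ch, n_s = self.data.shape
        if n_ch < 2:
            raise ValueError(f"fewer than 2 channels (got {n_ch})")
        if n_s < 1:
            raise ValueError("recording has no samples")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive (got {self.fs})")
        self.channels = [str(c) for c in self.channels]
        if len(self.channels) != n_ch:
            raise ValueError(
                f"{len(self.channels)} channel labels for {n_ch} channels"
            )
        if len(set(self.channels)) != n_ch:
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from the start of the recording."""
        return self.t0 + np.arange(self.n_samples) / self.fs


class EventTable:
    """Recorded events: time (s from recording start), label and source.

    ``source`` distinguishes self-reported ("subjective") from
    observer-recorded ("objective") events.  Rows are kept sorted by time.
    """

    COLUMNS = ["time_s", "label", "source"]

    def __init__(self, rows: Optional[pd.DataFrame] = None):
        if rows is None:
            rows = pd.DataFrame(columns=self.COLUMNS)
        df = pd.DataFrame(rows, columns=self.COLUMNS).copy()
        df["time_s"] = df["time_s"].astype(float)
        df["label"] = df["label"].astype(str)
        df["source"] = df["source"].astype(str)
        bad = ~df["source"].isin(EVENT_SOURCES)
        if bad.any():
            raise ValueError(
                f"unknown event source(s): {sorted(df.loc[bad, 'source'].unique())}; "
                f"expected one of {EVENT_SOURCES}"
            )
        if (df["time_s"] < 0).any():
            raise ValueError("event times must be non-negative")
        self.df = df.sort_values("time_s", kind="stable").reset_index(drop=True)

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "EventTable":
        return cls(pd.DataFrame(records, columns=cls.COLUMNS))

    @property
    def times(self) -> np.ndarray:
        return self.df["time_s"].to_numpy()

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventTable) and self.df.equals(other.df)

    def shifted(self, delta_s: float) -> "EventTable":
        df = self.df.copy()
        df["time_s"] = df["time_s"] + delta_s
        return EventTable(df)


@dataclass
class AnalysisConfig:
    """Parameters of the network-entropy pipeline.

    ``sl_samples`` is the sliding-window shift SL in samples; the window
    length is ``window_mult * sl_samples``.  When ``sl_samples`` is None it
    resolves to one second of data (round(fs)), which puts the entropy
    series on a 1 Hz grid.  ``binarize_step`` is the threshold decrement of
    the connectedness-based binarization, refined by factors of ten down to
    ``binarize_min_step`` when too coarse.  The wavelet settings control the
    time-frequency transform of the entropy series.
    """

    sl_samples: Optional[int] = None
    window_mult: int = 10
    binarize_step: float = 0.01
    binarize_min_step: float = 1e-4
    wavelet_name: str = "dmey"
    n_scales: int = 1024
    band_max_hz: float = 0.5
    band_interest_hz: Tuple[float, float] = (0.0, 0.1)
    detect_percentile: float = 90.0
    seed: Optional[int] = None
    # variant switches (defaults follow the method as published)
    pearson: bool = False            # mean-centered correlation instead of raw
    keep_dc: bool = False            # skip mean removal before the CWT
    centerline: str = "centroid"     # "centroid" | "midpoint"
    envelope_band: str = "interest"  # "interest" | "full"
    threshold_abs: bool = False      # artifact rule on |C| instead of signed C
    min_freq_hz: Optional[float] = None  # low end of the CWT frequency grid

    def __post_init__(self):
        if self.sl_samples is not None and self.sl_samples < 1:
            raise ValueError("sl_samples must be >= 1")
        if self.window_mult < 1:
            raise ValueError("window_mult must be >= 1")
        if not (0 < self.binarize_min_step <= self.binarize_step <= 1):
            raise ValueError("require 0 < binarize_min_step <= binarize_step <= 1")
        if not (0 < self.detect_percentile < 100):
            raise ValueError("detect_percentile must lie in (0, 100)")
        if self.centerline not in ("centroid", "midpoint"):
            raise ValueError("centerline must be 'centroid' or 'midpoint'")
        if self.envelope_band not in ("interest", "full"):
            raise ValueError("envelope_band must be 'interest' or 'full'")

    def resolve_sl(self, fs: float) -> int:
        """SL in samples; defaults to one second of data at rate ``fs``."""
        if self.sl_samples is not None:
            return int(self.sl_samples)
        return int(round(fs))

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# readers / writers


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    try:
        return csv.Sniffer().sniff(first, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def _read_delimited(path: Path, fs_hint: Optional[float]) -> EEGRecording:
    if fs_hint is None:
        raise ValueError(
            "delimited EEG input requires the sampling rate (fs_hint)"
        )
    delim = _sniff_delimiter(path)
    try:
        data = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    labels = [f"ch{i}" for i in range(data.shape[0])]
    if data.shape[0] == 19:
        labels = list(TEN_TWENTY_19)
    return EEGRecording(data=data, fs=float(fs_hint), channels=labels)


def _read_edf(path: Path) -> EEGRecording:
    import mne  # deferred: slow import, EDF-only dependency

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    extras = (raw._raw_extras or [{}])[0]
    n_samps = extras.get("n_samps")
    if n_samps is not None:
        sel = extras.get("sel", range(len(n_samps)))
        rates = {int(n_samps[i]) for i in sel}
        if len(rates) > 1:
            raise ValueError(
                f"EDF {path} mixes per-channel sampling rates: {sorted(rates)}"
            )
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(data=data, fs=fs, channels=list(raw.ch_names))


def read_eeg(path, fs_hint: Optional[float] = None) -> EEGRecording:
    """Read an EEG recording from an EDF file or a delimited matrix.

    Delimited files hold one channel per row; they carry no rate metadata,
    so ``fs_hint`` (Hz) is required for them and ignored for EDF.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    return _read_delimited(path, fs_hint)


def write_eeg_csv(rec: EEGRecording, path) -> None:
    """Dump a recording as a comma-delimited channels x samples matrix."""
    np.savetxt(path, rec.data, delimiter=",")


def read_events(path) -> EventTable:
    """Read a tab-separated event table (columns time_s, label, source)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(EventTable.COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table {path} lacks column(s): {sorted(missing)}")
    return EventTable(df)


def write_events(events: EventTable, path) -> None:
    events.df.to_csv(path, sep="\t", index=False)
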