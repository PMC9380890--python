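"""Reading and writing of recordings, session manifests and event tables.

Traces are stored as one-column CSV files (optional single header line),
one file per channel, with sampling metadata carried by a session manifest
(YAML or JSON).  Times are seconds from recording start, 0-based; event
intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SignalTrace",
    "Epoch",
    "SessionManifest",
    "EVENT_COLUMNS",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
    "make_event_table",
    "slice_trace",
]

EPOCH_LABELS = ("quiet", "bar_biting", "feeding")

#: canonical event-table column order (deterministic on disk)
EVENT_COLUMNS = ["onset", "offset", "peak_time", "peak_amplitude", "auc", "channel"]


@dataclass
class SignalTrace:
    """A uniformly sampled single-channel time series.

    Parameters
    ----------
    samples:
        1-D float array; volts for EMG, grams for the force channel.
    fs:
        Sampling rate in Hz (> 0).
    t0:
        Time of the first sample, seconds from recording start.
    channel:
        ``"emg"`` or ``"force"`` (free label otherwise).
    units:
        Unit string carried through processing (``"V"``, ``"g"``, ...).
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    channel: str = "emg"
    units: str = "V"
    #: derived traces (e.g. a NaN-padded moving average) may opt out of the
    #: finiteness check; loaded data never does
    allow_nan: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        if not self.allow_nan and not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValueError(f"non-finite sample at index {bad}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        """Time of the last sample relative to the first, (n - 1) / fs."""
        return (self.samples.size - 1) / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, units: str | None = None) -> "SignalTrace":
        """New trace sharing this trace's sampling metadata."""
        return SignalTrace(
            samples=samples,
            fs=self.fs,
            t0=self.t0,
            channel=self.channel,
            units=self.units if units is None else units,
        )


@dataclass
class Epoch:
    label: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise ValueError(f"unknown epoch label {self.label!r}; expected one of {EPOCH_LABELS}")
        if not self.end > self.start:
            raise ValueError(f"epoch end must exceed start ({self.start} .. {self.end})")


@dataclass
class SessionManifest:
    """Sampling metadata and epoch annotations for one recording session."""

    subject_id: str
    fs: float
    channels: dict = field(default_factory=dict)  # label -> file path
    units: dict = field(default_factory=dict)     # label -> unit string
    genotype: str = ""
    epochs: list = field(default_factory=list)    # list[Epoch]

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("manifest fs must be > 0")
        self.epochs = [e if isinstance(e, Epoch) else Epoch(**e) for e in self.epochs]

    def epochs_labeled(self, label: str) -> list:
        return [e for e in self.epochs if e.label == label]

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "genotype": self.genotype,
            "fs": self.fs,
            "channels": dict(self.channels),
            "units": dict(self.units),
            "epochs": [{"label": e.label, "start": e.start, "end": e.end} for e in self.epochs],
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SessionManifest":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls(**data)


def read_trace(
    path: str | Path,
    fs: float,
    channel: str = "emg",
    units: str = "V",
    t0: float = 0.0,
) -> SignalTrace:
    """Read a one-column CSV trace.

    A single non-numeric first line is treated as a header.  Any other
    non-numeric or non-finite value is a hard error naming the offending
    row (1-based, counting the header if present); malformed input is
    never silently repaired.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(str(path))
    if not fs > 0:
        raise ValueError("fs must be > 0")
    raw = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)[0]
    raw = raw.str.strip()
    offset = 1  # 1-based row numbers in error messages
    values = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
    if raw.size and not np.isfinite(values[0]) and _is_header(raw.iloc[0]):
        raw = raw.iloc[1:]
        values = values[1:]
        offset = 2
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        row = int(bad[0]) + offset
        raise ValueError(f"non-numeric or non-finite value {raw.iloc[int(bad[0])]!r} at row {row} of {path.name}")
    return SignalTrace(samples=values, fs=fs, t0=t0, channel=channel, units=units)


def _is_header(token: str) -> bool:
    try:
        float(token)
        return False
    except ValueError:
        return token.lower() not in ("nan", "inf", "-inf", "+inf")


def write_trace(trace: SignalTrace, path: str | Path, header: str | None = None) -> None:
    """Write a trace as one-column CSV at full float precision."""
    path = Path(path)
    hdr = f"{header}\n" if header else ""
    with open(path, "w") as fh:
        fh.write(hdr)
        np.savetxt(fh, trace.samples, fmt="%.17g")


def make_event_table(rows: Sequence[dict] | None = None, channel: str = "emg") -> pd.DataFrame:
    """Build an event table with the canonical column order, sorted by onset."""
    if not rows:
        return pd.DataFrame(columns=EVENT_COLUMNS).astype(
            {c: float for c in EVENT_COLUMNS if c != "channel"} | {"channel": object}
        )
    df = pd.DataFrame(list(rows))
    if "channel" not in df:
        df["channel"] = channel
    df = df[EVENT_COLUMNS].sort_values("onset", kind="stable").reset_index(drop=True)
    _validate_events(df)
    return df


def _validate_events(df: pd.DataFrame) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    if len(df) and not (df["onset"].to_numpy() < df["offset"].to_numpy()).all():
        raise ValueError("every event must satisfy onset < offset")
    if len(df) and not (np.diff(df["onset"].to_numpy()) >= 0).all():
        raise ValueError("event table must be sorted by onset")


def write_events(table: pd.DataFrame, path: str | Path) -> None:
    """Write an event table CSV: deterministic column order, times to 1 ns."""
    _validate_events(table)
    out = table[EVENT_COLUMNS].copy()
    out.to_csv(path, index=False, float_format="%.9f")


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) == 0:
        return make_event_table()
    _validate_events(df)
    return df[EVENT_COLUMNS]


def slice_trace(trace: SignalTrace, start: float, end: float) -> SignalTrace:
    """Return the samples with times in ``[start, end)`` as a new trace.

    ``t0`` of the slice is the absolute time of its first sample, so event
    times detected on a slice remain session times.
    """
    i0 = int(np.ceil(round((start - trace.t0) * trace.fs, 9)))
    i1 = int(np.ceil(round((end - trace.t0) * trace.fs, 9)))
    i0 = max(i0, 0)
    i1 = min(i1, len(trace))
    if i1 <= i0:
        raise ValueError(f"window [{start}, {end}) lies outside the trace")
    return SignalTrace(
        samples=trace.samples[i0:i1].copy(),
        fs=trace.fs,
        t0=trace.t0 + i0 / trace.fs,
        channel=trace.channel,
        units=trace.units,
    )
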