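"""Double-threshold event detection and burst/bite metrics.

An event is a maximal run of envelope samples *strictly* above the
amplitude threshold (quiet-period mean + k * SD) that lasts at least the
minimum duration (default 10 ms).  Ties at the threshold break toward
non-detection.  Runs separated by a gap no longer than ``merge_gap`` are
merged first (off by default).  Per-event metrics are the peak amplitude,
peak time and the trapezoidal area under the raw envelope over
``[onset, offset)`` — "muscle activity" on the EMG channel, "bite energy"
on the force channel.

Mastication sequences are maximal runs of >= 5 consecutive bursts whose
successive peak-to-peak intervals stay within ``max_cycle_gap``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SignalTrace, make_event_table

__all__ = [
    "DetectionParams",
    "QuietStats",
    "MasticationSequence",
    "SessionSummary",
    "quiet_stats",
    "detect_events",
    "detect_bites",
    "select_sequences",
    "summarize_session",
]


@dataclass
class DetectionParams:
    """Double-threshold detector parameters.

    k_sd:
        SD multiplier for the amplitude threshold (default 2).
    min_duration:
        Minimum event duration in seconds (default 0.010).
    merge_gap:
        Sub-threshold gaps up to this length (s) are bridged before the
        duration test; 0 disables merging.
    baseline_subtract:
        If True, subtract the amplitude threshold before integrating the
        area under the curve (default off: raw envelope is integrated).
    """

    k_sd: float = 2.0
    min_duration: float = 0.010
    merge_gap: float = 0.0
    baseline_subtract: bool = False

    def __post_init__(self) -> None:
        if not self.k_sd > 0:
            raise ValueError("k_sd must be > 0")
        if not self.min_duration > 0:
            raise ValueError("min_duration must be > 0")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclass
class QuietStats:
    mean: float
    sd: float
    window: tuple[float, float]

    def threshold(self, k_sd: float) -> float:
        return self.mean + k_sd * self.sd


def quiet_stats(
    trace: SignalTrace,
    window: tuple[float, float] | str = "auto",
    auto_window: float = 1.0,
    auto_stride: float = 0.1,
    min_window: float = 0.5,
) -> QuietStats:
    """Mean and SD of the envelope over the quiet (baseline) period.

    ``window`` is an absolute ``(start, end)`` time pair, or ``"auto"``:
    the 1-s sliding window (0.1-s stride) of minimum RMS is used, which
    finds the quietest stretch without an annotation.
    """
    if window == "auto":
        w = int(round(auto_window * trace.fs))
        stride = max(1, int(round(auto_stride * trace.fs)))
        if len(trace) < w:
            raise ValueError("recording shorter than the auto quiet window")
        sq = np.concatenate([[0.0], np.cumsum(trace.samples**2)])
        starts = np.arange(0, len(trace) - w + 1, stride)
        rms = (sq[starts + w] - sq[starts]) / w
        i0 = int(starts[np.argmin(rms)])
        seg = trace.samples[i0 : i0 + w]
        window = (trace.t0 + i0 / trace.fs, trace.t0 + (i0 + w) / trace.fs)
    else:
        start, end = window
        i0 = max(0, int(np.ceil(round((start - trace.t0) * trace.fs, 9))))
        i1 = min(len(trace), int(np.ceil(round((end - trace.t0) * trace.fs, 9))))
        seg = trace.samples[i0:i1]
        if seg.size < min_window * trace.fs:
            raise ValueError(f"quiet window shorter than {min_window} s of samples")
    return QuietStats(mean=float(np.mean(seg)), sd=float(np.std(seg)), window=tuple(window))


def _supra_runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, stop_exclusive) index pairs."""
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts = edges[0::2]
    stops = edges[1::2]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_events(
    envelope: SignalTrace,
    params: DetectionParams,
    quiet: QuietStats,
    channel: str | None = None,
) -> pd.DataFrame:
    """Double-threshold detection on an envelope trace.

    Returns an event table (one row per kept run) with absolute times.
    An empty table is a valid result when nothing crosses the threshold.
    """
    thr = quiet.threshold(params.k_sd)
    x = envelope.samples
    fs = envelope.fs
    runs = _supra_runs(x > thr)

    if params.merge_gap > 0 and len(runs) > 1:
        merged = [runs[0]]
        max_gap = params.merge_gap * fs + 1e-9
        for s, e in runs[1:]:
            ps, pe = merged[-1]
            if s - pe <= max_gap:
                merged[-1] = (ps, e)
            else:
                merged.append((s, e))
        runs = merged

    min_samples = params.min_duration * fs - 1e-9
    rows = []
    for s, e in runs:
        if (e - s) < min_samples:
            continue
        seg = x[s:e]
        ipk = int(np.argmax(seg))
        base = thr if params.baseline_subtract else 0.0
        auc = float(np.trapezoid(seg - base, dx=1.0 / fs))
        rows.append(
            {
                "onset": envelope.t0 + s / fs,
                "offset": envelope.t0 + e / fs,
                "peak_time": envelope.t0 + (s + ipk) / fs,
                "peak_amplitude": float(seg[ipk]),
                "auc": auc,
            }
        )
    return make_event_table(rows, channel=channel or envelope.channel)


def detect_bites(
    smoothed_force: SignalTrace,
    params: DetectionParams,
    quiet: QuietStats,
) -> pd.DataFrame:
    """Detect bites on the smoothed force channel.

    Identical detection contract; ``peak_amplitude`` is the bite force in
    grams and ``auc`` the bite energy in gram-seconds.
    """
    return detect_events(smoothed_force, params, quiet, channel="force")


@dataclass
class MasticationSequence:
    """A run of >= n_min consecutive chew cycles."""

    events: pd.DataFrame
    interpeak_intervals: np.ndarray

    @property
    def n_cycles(self) -> int:
        return len(self.events)


def select_sequences(
    burst_table: pd.DataFrame,
    n_min: int = 5,
    max_cycle_gap: float = 0.4,
) -> list[MasticationSequence]:
    """Partition bursts into maximal runs of consecutive chew cycles.

    Successive bursts belong to the same run when their peak-to-peak
    interval is <= ``max_cycle_gap`` (default 0.4 s, about twice a typical
    murine chew cycle).  Runs with fewer than ``n_min`` (default 5) cycles
    are discarded.
    """
    if len(burst_table) == 0:
        return []
    peaks = burst_table["peak_time"].to_numpy()
    if not (np.diff(peaks) >= 0).all():
        raise ValueError("burst table must be sorted by time")
    breaks = np.flatnonzero(np.diff(peaks) > max_cycle_gap) + 1
    out = []
    for chunk in np.split(np.arange(len(peaks)), breaks):
        if chunk.size >= n_min:
            ev = burst_table.iloc[chunk].reset_index(drop=True)
            out.append(
                MasticationSequence(
                    events=ev,
                    interpeak_intervals=np.diff(ev["peak_time"].to_numpy()),
                )
            )
    return out


@dataclass
class SessionSummary:
    """Per-session burst/bite metrics.

    Burst means are computed over sequence-member bursts only (>= 5
    consecutive cycles); bite statistics cover all detected bites.
    Histograms use fixed left-closed bins from zero: 50-g bins for force,
    10-g*s bins for energy.  Means with no qualifying events are NaN,
    never zero.
    """

    n_bites: int
    max_force: float
    max_energy: float
    n_force_above: int
    n_energy_above: int
    force_threshold: float
    energy_threshold: float
    force_bin_edges: np.ndarray
    force_histogram: np.ndarray
    energy_bin_edges: np.ndarray
    energy_histogram: np.ndarray
    n_sequence_bursts: int
    mean_burst_duration: float
    mean_burst_amplitude: float
    mean_interpeak_interval: float
    mean_muscle_activity: float

    def to_dict(self) -> dict:
        d = {
            "n_bites": self.n_bites,
            "max_force": self.max_force,
            "max_energy": self.max_energy,
            "n_force_above": self.n_force_above,
            "n_energy_above": self.n_energy_above,
            "force_threshold": self.force_threshold,
            "energy_threshold": self.energy_threshold,
            "force_bin_edges": self.force_bin_edges.tolist(),
            "force_histogram": self.force_histogram.tolist(),
            "energy_bin_edges": self.energy_bin_edges.tolist(),
            "energy_histogram": self.energy_histogram.tolist(),
            "n_sequence_bursts": self.n_sequence_bursts,
            "mean_burst_duration": self.mean_burst_duration,
            "mean_burst_amplitude": self.mean_burst_amplitude,
            "mean_interpeak_interval": self.mean_interpeak_interval,
            "mean_muscle_activity": self.mean_muscle_activity,
        }
        return d


def _fixed_histogram(values: np.ndarray, width: float) -> tuple[np.ndarray, np.ndarray]:
    if values.size == 0:
        edges = np.array([0.0, width])
    else:
        top = width * (np.floor(values.max() / width) + 2)
        edges = np.arange(0.0, top + width / 2, width)
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts


def summarize_session(
    burst_table: pd.DataFrame,
    bite_table: pd.DataFrame,
    sequences: list[MasticationSequence],
    force_bin: float = 50.0,
    energy_bin: float = 10.0,
    force_threshold: float = 400.0,
    energy_threshold: float = 50.0,
) -> SessionSummary:
    forces = bite_table["peak_amplitude"].to_numpy(dtype=float)
    energies = bite_table["auc"].to_numpy(dtype=float)
    f_edges, f_counts = _fixed_histogram(forces, force_bin)
    e_edges, e_counts = _fixed_histogram(energies, energy_bin)

    if sequences:
        seq_events = pd.concat([s.events for s in sequences], ignore_index=True)
        ipis = np.concatenate([s.interpeak_intervals for s in sequences])
        mean_dur = float(np.mean(seq_events["offset"] - seq_events["onset"]))
        mean_amp = float(np.mean(seq_events["peak_amplitude"]))
        mean_ipi = float(np.mean(ipis))
        mean_act = float(np.mean(seq_events["auc"]))
        n_seq = len(seq_events)
    else:
        mean_dur = mean_amp = mean_ipi = mean_act = float("nan")
        n_seq = 0

    return SessionSummary(
        n_bites=len(bite_table),
        max_force=float(forces.max()) if forces.size else float("nan"),
        max_energy=float(energies.max()) if energies.size else float("nan"),
        n_force_above=int((forces > force_threshold).sum()),
        n_energy_above=int((energies > energy_threshold).sum()),
        force_threshold=force_threshold,
        energy_threshold=energy_threshold,
        force_bin_edges=f_edges,
        force_histogram=f_counts,
        energy_bin_edges=e_edges,
        energy_histogram=e_counts,
        n_sequence_bursts=n_seq,
        mean_burst_duration=mean_dur,
        mean_burst_amplitude=mean_amp,
        mean_interpeak_interval=mean_ipi,
        mean_muscle_activity=mean_act,
    )
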