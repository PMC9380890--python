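"""Offline emulation of the closed-loop reward controller.

During recording the force channel was averaged over a trailing 1-s
window; whenever that moving average exceeded 30 (grams averaged over the
1-s window, printed as g/s), the acquisition computer triggered the
syringe pump.  This module reproduces that rule offline so session
structure can be validated.  Retrigger behaviour of the original system
is unknown, so both knobs are explicit: a trigger re-arms only after the
average has dropped back to or below the threshold (hysteresis), and no
two triggers may be closer than the refractory period (default equal to
the window).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SignalTrace

__all__ = ["RewardRule", "moving_average", "reward_triggers"]


@dataclass
class RewardRule:
    window: float = 1.0      # s
    threshold: float = 30.0  # trailing-window mean force, g (paper prints g/s)
    refractory: float | None = None  # s; defaults to the window

    def __post_init__(self) -> None:
        if not self.window > 0:
            raise ValueError("window must be > 0")
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")
        if self.refractory is None:
            self.refractory = self.window
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")


def moving_average(force_trace: SignalTrace, window: float = 1.0) -> SignalTrace:
    """Causal trailing-window mean of the force channel.

    The output has the input's length; the first ``window`` worth of
    samples (where no full trailing window exists) is NaN-padded, so the
    average at sample n covers samples n-w+1 .. n.
    """
    w = int(round(window * force_trace.fs))
    if len(force_trace) < w:
        raise ValueError("trace shorter than the averaging window")
    x = force_trace.samples
    c = np.concatenate([[0.0], np.cumsum(x)])
    out = np.full(x.size, np.nan)
    out[w - 1 :] = (c[w:] - c[:-w]) / w
    return SignalTrace(out, fs=force_trace.fs, t0=force_trace.t0,
                       channel=force_trace.channel, units=force_trace.units,
                       allow_nan=True)


def reward_triggers(force_trace: SignalTrace, rule: RewardRule) -> np.ndarray:
    """Times at which the reward rule fires.

    A trigger fires the first time the moving average strictly exceeds the
    threshold.  A later trigger requires the average to have dropped to
    <= threshold in between (hysteresis) and the refractory period to have
    elapsed; within one supra-threshold excursion it fires at the first
    sample where the refractory has elapsed.
    """
    ma = moving_average(force_trace, rule.window).samples
    above = ma > rule.threshold  # NaN compares False
    if not above.any():
        return np.array([])
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    t = force_trace.t0 + np.arange(ma.size) / force_trace.fs
    triggers: list[float] = []
    last = -np.inf
    for s, e in zip(edges[0::2], edges[1::2]):
        earliest = last + rule.refractory
        if t[s] >= earliest:
            triggers.append(t[s])
            last = t[s]
        else:
            # refractory may elapse while still above threshold
            j = s + int(np.ceil(round((earliest - t[s]) * force_trace.fs, 9)))
            if j < e:
                triggers.append(t[j])
                last = t[j]
    return np.asarray(triggers)
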