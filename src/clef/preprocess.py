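"""EMG and force preprocessing: first-order DC removal, rectification,
leaky integration and smoothing.

All filters are single-pole recursions with coefficient
``alpha = exp(-dt / tau)``:

* running mean     ``m[n] = alpha * m[n-1] + (1 - alpha) * x[n]``, ``m[0] = x[0]``
* low-pass (unit DC gain) uses the same recursion on the output.

"DC remove (time constant tau)" subtracts the running mean; "integrate" and
"smooth" are the unit-DC-gain low-pass.  Initialising at ``x[0]`` rather
than 0 avoids a spurious onset transient that the double-threshold event
detector would otherwise pick up.  Every filter is causal and
length-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import SignalTrace

__all__ = [
    "FilterSpec",
    "remove_dc",
    "rectify",
    "integrate_leaky",
    "smooth_force",
    "envelope",
    "bandpass",
]


@dataclass
class FilterSpec:
    """Time constants (seconds) of the preprocessing chain.

    Defaults: DC removal 5 ms, leaky integration 10 ms, force smoothing
    5 ms.  The 15-1,000 Hz acquisition bandwidth is treated as a property
    of the recording and is not re-applied by default (see ``bandpass``).
    """

    tau_dc: float = 0.005
    tau_int: float = 0.010
    tau_smooth: float = 0.005

    def __post_init__(self) -> None:
        for name in ("tau_dc", "tau_int", "tau_smooth"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0 seconds")


def _check(trace: SignalTrace, tau: float) -> None:
    if len(trace) < 2:
        raise ValueError("trace must contain at least 2 samples for filtering")
    if not tau > 0:
        raise ValueError(f"time constant must be > 0, got {tau}")


def _running_mean(x: np.ndarray, fs: float, tau: float) -> np.ndarray:
    # y[n] = a*y[n-1] + (1-a)*x[n], y[0] = x[0], via lfilter with matched state
    a = float(np.exp(-1.0 / (fs * tau)))
    zi = np.array([a * x[0]])
    y, _ = sps.lfilter([1.0 - a], [1.0, -a], x, zi=zi)
    return y


def remove_dc(trace: SignalTrace, tau_dc: float = 0.005) -> SignalTrace:
    """Subtract a single-pole exponential running mean (high-pass)."""
    _check(trace, tau_dc)
    return trace.with_samples(trace.samples - _running_mean(trace.samples, trace.fs, tau_dc))


def rectify(trace: SignalTrace) -> SignalTrace:
    """Full-wave rectification (elementwise absolute value); idempotent."""
    return trace.with_samples(np.abs(trace.samples))


def integrate_leaky(trace: SignalTrace, tau_int: float = 0.010) -> SignalTrace:
    """Unit-DC-gain first-order low-pass; the envelope used downstream."""
    _check(trace, tau_int)
    return trace.with_samples(_running_mean(trace.samples, trace.fs, tau_int))


def smooth_force(trace: SignalTrace, tau_smooth: float = 0.005) -> SignalTrace:
    """Smooth the force channel; identical contract to :func:`integrate_leaky`."""
    return integrate_leaky(trace, tau_smooth)


def envelope(trace: SignalTrace, spec: FilterSpec | None = None) -> SignalTrace:
    """Rectified-integrated EMG envelope: integrate(rectify(remove_dc(x)))."""
    spec = spec or FilterSpec()
    return integrate_leaky(rectify(remove_dc(trace, spec.tau_dc)), spec.tau_int)


def bandpass(trace: SignalTrace, lo: float = 15.0, hi: float = 1000.0, order: int = 4) -> SignalTrace:
    """Optional causal Butterworth band-pass (off by default in the chain)."""
    nyq = trace.fs / 2.0
    hi = min(hi, 0.95 * nyq)
    if not 0 < lo < hi:
        raise ValueError(f"invalid band [{lo}, {hi}] Hz at fs={trace.fs}")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=trace.fs, output="sos")
    return trace.with_samples(sps.sosfilt(sos, trace.samples))
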