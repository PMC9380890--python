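"""CLEF calibration: correlative electromyography and force myography.

During bar biting, EMG bursts and transducer bites are recorded
simultaneously, so each bite can be paired with its burst and the
per-subject force-activity and energy-activity laws fitted:

    F(u) = a * exp(b * u)        (bite force, grams)
    E(u) = c * u + d             (bite energy, gram-seconds)

where u is the burst's muscle activity (envelope area under the curve).
During natural feeding the transducer sees nothing, so the fitted curves
estimate the bite force and energy applied to food from the mean feeding
muscle activity alone.

The exponential fit is nonlinear least squares on the original scale,
initialised from the log-linear regression ln F = ln a + b u; the energy
fit is ordinary least squares with intercept.  R^2 is always computed on
the original scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PairingResult",
    "ClefModel",
    "FeedingEstimate",
    "pair_bursts_with_bites",
    "fit_force_model",
    "fit_energy_model",
    "fit_clef",
    "estimate_feeding",
]

MIN_PAIRS = 5


@dataclass
class PairingResult:
    """Burst-bite pairs plus the events that found no partner."""

    pairs: pd.DataFrame  # columns: activity, force, energy, pair_time
    n_unpaired_bursts: int
    n_unpaired_bites: int

    def __len__(self) -> int:
        return len(self.pairs)


def pair_bursts_with_bites(
    burst_table: pd.DataFrame,
    bite_table: pd.DataFrame,
    max_lag: float = 0.1,
) -> PairingResult:
    """Pair each bite with the nearest-in-time unused EMG burst.

    Bites are processed in time order; a bite takes the free burst whose
    peak time is nearest its own, provided the lag is <= ``max_lag``
    (default 0.1 s).  Each burst is used at most once; unpaired events on
    either side are dropped and counted.
    """
    cols = ["activity", "force", "energy", "pair_time"]
    if len(burst_table) == 0 or len(bite_table) == 0:
        return PairingResult(pd.DataFrame(columns=cols), len(burst_table), len(bite_table))

    burst_peaks = burst_table["peak_time"].to_numpy()
    used = np.zeros(len(burst_peaks), dtype=bool)
    rows = []
    n_unpaired_bites = 0
    for _, bite in bite_table.sort_values("peak_time").iterrows():
        lags = np.abs(burst_peaks - bite["peak_time"])
        lags[used] = np.inf
        j = int(np.argmin(lags))
        if lags[j] <= max_lag:
            used[j] = True
            rows.append(
                {
                    "activity": burst_table.iloc[j]["auc"],
                    "force": bite["peak_amplitude"],
                    "energy": bite["auc"],
                    "pair_time": bite["peak_time"],
                }
            )
        else:
            n_unpaired_bites += 1
    pairs = pd.DataFrame(rows, columns=cols)
    return PairingResult(pairs, int((~used).sum()), n_unpaired_bites)


def _check_pairs(u: np.ndarray, n_min: int = MIN_PAIRS) -> None:
    if u.size < n_min:
        raise ValueError(f"need at least {n_min} calibration pairs, got {u.size}")
    if np.ptp(u) == 0:
        raise ValueError("activity has no spread")


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res < 1e-20 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_force_model(pairs: pd.DataFrame, scale: str = "log") -> tuple[float, float, float]:
    """Fit F = a * exp(b * u); returns (a, b, r2) with r2 on the original scale.

    ``scale="log"`` (default) solves the least-squares problem on the log
    scale, ln F = ln a + b u — the maximum-likelihood weighting when the
    force noise is multiplicative, which bite-force data are.
    ``scale="linear"`` instead refines by unweighted nonlinear least
    squares on the original scale (log-linear initialisation); that
    variant lets the largest forces dominate and is kept for sensitivity
    analysis.
    """
    u = pairs["activity"].to_numpy(dtype=float)
    f = pairs["force"].to_numpy(dtype=float)
    _check_pairs(u)
    if not (f > 0).all():
        raise ValueError("all forces must be > 0 for the exponential fit")
    lin = stats.linregress(u, np.log(f))
    a, b = float(np.exp(lin.intercept)), float(lin.slope)
    if scale == "linear":
        popt, _ = optimize.curve_fit(
            lambda x, aa, bb: aa * np.exp(bb * x), u, f, p0=[a, b], maxfev=20000
        )
        a, b = float(popt[0]), float(popt[1])
    elif scale != "log":
        raise ValueError("scale must be 'log' or 'linear'")
    return a, b, _r2(f, a * np.exp(b * u))


def fit_energy_model(pairs: pd.DataFrame) -> tuple[float, float, float]:
    """Fit E = c * u + d by OLS; returns (c, d, r2)."""
    u = pairs["activity"].to_numpy(dtype=float)
    e = pairs["energy"].to_numpy(dtype=float)
    _check_pairs(u)
    lin = stats.linregress(u, e)
    c, d = float(lin.slope), float(lin.intercept)
    return c, d, _r2(e, c * u + d)


@dataclass
class ClefModel:
    """Per-subject fitted force-activity and energy-activity calibration."""

    a: float
    b: float
    c: float
    d: float
    r2_force: float
    r2_energy: float
    n_pairs: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("force amplitude a must be > 0")

    def predict_force(self, u: float | np.ndarray):
        return self.a * np.exp(self.b * np.asarray(u, dtype=float))

    def predict_energy(self, u: float | np.ndarray):
        return self.c * np.asarray(u, dtype=float) + self.d

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "r2_force": self.r2_force,
            "r2_energy": self.r2_energy,
            "n_pairs": self.n_pairs,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ClefModel":
        return cls(**json.loads(Path(path).read_text()))


def fit_clef(pairs: pd.DataFrame, subject_id: str = "", scale: str = "log") -> ClefModel:
    """Fit both calibration curves from one set of burst-bite pairs."""
    a, b, r2f = fit_force_model(pairs, scale=scale)
    c, d, r2e = fit_energy_model(pairs)
    return ClefModel(
        a=a, b=b, c=c, d=d, r2_force=r2f, r2_energy=r2e,
        n_pairs=len(pairs), subject_id=subject_id,
    )


@dataclass
class FeedingEstimate:
    """Estimated bite force/energy applied to food, from EMG alone."""

    mean_activity: float
    est_force: float
    est_energy: float
    n_bursts: int
    extrapolation_warning: bool = False


def estimate_feeding(
    model: ClefModel,
    feeding_burst_table: pd.DataFrame,
    per_burst: bool = False,
) -> FeedingEstimate:
    """Plug the mean feeding muscle activity into the fitted curves.

    By default the mean activity is computed first and mapped through the
    curves once (the scatter-plot arrowhead construction); ``per_burst``
    instead averages per-burst predictions.  A negative energy estimate
    is flagged as extrapolation but still returned.
    """
    if len(feeding_burst_table) == 0:
        raise ValueError("need at least one feeding burst")
    u = feeding_burst_table["auc"].to_numpy(dtype=float)
    u_bar = float(np.mean(u))
    if per_burst:
        est_force = float(np.mean(model.predict_force(u)))
        est_energy = float(np.mean(model.predict_energy(u)))
    else:
        est_force = float(model.predict_force(u_bar))
        est_energy = float(model.predict_energy(u_bar))
    return FeedingEstimate(
        mean_activity=u_bar,
        est_force=est_force,
        est_energy=est_energy,
        n_bursts=len(feeding_burst_table),
        extrapolation_warning=bool(est_energy < 0),
    )
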