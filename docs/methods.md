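# Methods

## Signal model and preprocessing

All filters are causal single-pole recursions with
`alpha = exp(-dt/tau)`:

* running mean `m[n] = alpha·m[n-1] + (1-alpha)·x[n]`, `m[0] = x[0]`;
  **DC removal** subtracts it (first-order high-pass, τ_dc = 5 ms).
* **leaky integration** and **force smoothing** apply the same recursion
  to the signal itself (unit-DC-gain low-pass; τ_int = 10 ms,
  τ_smooth = 5 ms).

The EMG envelope is `integrate(rectify(remove_dc(x)))`. Initialising
every recursion at `x[0]` rather than 0 avoids a spurious onset
transient that the event detector would register. The time constants are
the standard settings for masseter work and are exposed in `FilterSpec`.
Acquisition bandwidth (15–1,000 Hz) is treated as a property of the
recording; an optional causal Butterworth band-pass exists but is off by
default. The 20 kHz acquisition rate is the I/O default; analyses in the
test battery run at 2 kHz, which oversamples the 10-ms envelope dynamics
~20-fold and changes no detection decision — a problem-size choice,
stated wherever it is used.

A consequence worth knowing: smoothing attenuates the *peak* of a pulse
while preserving its area. A raised-cosine pulse of duration d keeps its
mean through the τ = 5 ms low-pass but its cosine component is scaled by
`1/sqrt(1+(2πτ/d)^2)`, so a 50-ms bite reads ~8% lower at the peak than
the physical pulse. Calibration and estimation are both performed on
smoothed-scale forces, so the bias cancels from CLEF estimates but not
from absolute peak-force readings.

## Event detection

The detector implements the classic two-criterion rule: amplitude
(envelope strictly above `quiet mean + k·SD`, k = 2) and duration
(≥ 10 ms). Ties at the threshold break toward non-detection. The quiet
statistics come from an annotated quiet epoch, or automatically from the
1-s sliding window (0.1-s stride) of minimum RMS. Sub-threshold gaps can
be bridged (`merge_gap`), but merging is off by default since nothing in
the measurement motivates a particular gap. The area under the curve is
the trapezoidal integral of the raw envelope over `[onset, offset)`;
baseline subtraction is available behind a flag and off by default.
Detection intervals are half-open in seconds from recording start.

Note that with a mean + 2 SD threshold, isolated ≥ 10-ms noise
excursions occasionally qualify as events (≈1–2% of detections on
synthetic sessions); validation therefore matches events to ground truth
by peak time rather than by count.

Mastication sequences are maximal runs of bursts whose successive
peak-to-peak intervals are ≤ `max_cycle_gap` (default 0.4 s — roughly
twice a murine chew cycle; the value is a documented choice, not a
measured constant) with ≥ 5 cycles. Burst means (duration, amplitude,
interpeak interval, muscle activity) are computed over sequence-member
bursts only; bite statistics cover all detected bites. Histograms use
fixed left-closed bins from zero (50 g force, 10 g·s energy); empty-input
means are NaN, never zero.

## CLEF calibration

Each bite (force channel) is paired with the nearest-in-time free EMG
burst within 0.1 s, greedily in time order — simultaneity is the only
pairing information the measurement offers. With ≥ 5 pairs and
non-degenerate activity, two curves are fitted:

* `F(u) = a·exp(b·u)` — estimated by least squares on the log scale,
  `ln F = ln a + b·u`. Bite-force noise is multiplicative (constant
  coefficient of variation), for which the log scale is the
  maximum-likelihood weighting; unweighted least squares on the original
  scale lets the few largest bites dominate and, combined with the ~10%
  intrinsic noise of envelope-area estimates, produces a systematic tilt
  of (a, b). The original-scale refinement is retained as
  `fit_force_model(..., scale="linear")` for sensitivity analysis. R² is
  always reported on the original scale.
* `E(u) = c·u + d` — ordinary least squares with intercept.

Feeding estimates plug the **mean** feeding activity ū (over
sequence-member bursts) into the fitted curves. This plug-in construction
estimates `F(ū)`, the force at the mean activity — not the mean of
per-burst forces `E[F(u)]`, which exceeds it for a convex F (Jensen's
inequality; ~50% at the synthetic generator's default activity spread).
The per-burst average is available via `per_burst=True`. Validation
against synthetic ground truth therefore targets `a·exp(b·ū_true)`; the
generator also logs the per-burst latent forces for anyone preferring
the other convention. A negative energy estimate is flagged as
extrapolation and still returned.

## Closed-loop reward emulation

The rule is a trailing 1-s moving average of the force channel (NaN
where no full window exists) with a trigger when it strictly exceeds 30
(grams averaged over the window; the "g/s" of the original printout is
numerically identical for a 1-s window). The original system's retrigger
behaviour is unknown, so both knobs are explicit: hysteresis (the
average must return to ≤ threshold before re-arming) and a refractory
period (default = window). Trigger count is monotone non-increasing in
threshold for bout-like forces whose moving average is unimodal per
bout; a threshold that splits one excursion into two can in principle
increase the count, so the monotonicity property is only claimed for
that class.

## Synthetic sessions

A generated session mirrors a recording's structure: a quiet epoch, a
bar-biting epoch (EMG bursts with simultaneous force pulses), and a
feeding epoch (rhythmic burst runs of ≥ 5 cycles, **no** transducer
force — food, not bar, is bitten; the latent `a·exp(b·u)` is logged).
The EMG is a unit-variance Gaussian carrier band-passed to 15–1,000 Hz,
amplitude-modulated by raised-cosine pulses. Pulse amplitude is set to
`u / (g_dc · sqrt(2/π) · d/2)` so the measured envelope area tracks the
drawn activity: `sqrt(2/π)` is the rectification gain of a Gaussian
carrier, `d/2` the unit-peak raised-cosine area, and `g_dc` (≈0.98) the
analytic RMS gain of the DC-removal high-pass over the carrier band.
Residual scale bias of the measured activity is ~3% (modulation spreads
carrier energy below the band edge), plus ~10% per-burst measurement
noise — both intrinsic to envelope-area estimation, not generator
artifacts.

Defaults, chosen once as the study conditions the generator emulates:
chew interval 0.15 ± 0.02 s (the 5–10 Hz murine masticatory rhythm),
burst duration 0.05 ± 0.005 s, per-burst activity lognormal(ln 4, 0.55)
capped at 14 (motor-pool saturation; with the default law this spans
bite forces up to several hundred grams, matching the range such
transducers report), force-law a = 3 g, b = 0.4, 10% multiplicative
force noise, 1-g transducer baseline noise, 3-ms EMG-to-force lag
jitter, 200 bar bites per session (a 30-min session's scale). Cohorts
are drawn around a template with lognormal between-subject variability
(CV 15% on a, 5% on b, 8% on chew interval — set so that cohort
contrasts at n = 7 attain the significance levels such experiments
report; b gets the small CV because its exponential leverage on mean
force is ~10×). The "AD-like" effect scales a by 0.6 and the chew
interval by 1.2. All randomness flows from a single integer seed; the
same seed reproduces a byte-identical session.

What the generator does **not** emulate: motor-unit structure, licking
and grooming artifacts, electrode drift and motion artifacts,
within-session fatigue, and any video-synchronised behaviour. Passing
tests therefore demonstrate correctness of the analysis chain under the
stated signal model, not robustness to every artifact of real
recordings.

## Numerical choices

* Duration threshold compared in samples with a 1e-9 guard, so a 10-ms
  excursion at any integer-sample rate is kept and a 9-ms one rejected.
* Event AUC uses the trapezoid rule at the native sampling step.
* Quiet-window and slice boundaries round at 1e-9 s before truncation to
  avoid float-boundary off-by-ones.
* `ttest_unpaired` returns t = 0, p = 1 when both groups are constant
  and equal (scipy yields NaN there). Bonferroni's multiplier counts
  only testable bins; bins all-zero in both groups are flagged
  untestable.
* Zero-spread activity or < 5 pairs abort a CLEF fit with an error
  rather than returning a degenerate model; R² of a zero-variance target
  is 1 for a perfect fit and −∞ otherwise.

## Known limitations

* The incisor-measured force-activity law is applied to molar chewing
  unchanged; incisor-to-molar transfer is out of scope.
* The plug-in feeding estimate inherits the Jensen gap described above;
  comparisons between groups are unaffected (both use the same
  construction), absolute feeding forces are conservative.
* Original-scale peak forces read ~8% low through the 5-ms smoother for
  50-ms bites (see above).
* The detector's false-positive rate is that of a mean + 2 SD threshold;
  it is not an artifact-rejection system.
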