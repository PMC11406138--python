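"""AP detection and action-potential biomarker extraction.

Implements the eight calibration biomarkers used to compare models with
patch-clamp recordings of human DRG neurons — threshold voltage, peak
voltage, maximum/minimum voltage-time gradient, full width at threshold,
after-hyperpolarisation time constant, resting membrane potential and
rheobase — plus AP half width and mean firing rate.

Conventions (applied uniformly, and configurable where noted):

* APs are detected as upward crossings of a fixed detection level
  (0 mV by default), separated by a return below that level.
* Any biomarker that cannot be measured is returned as NaN and flagged
  invalid; it is never silently zero.
* Level crossings for the width measures are linearly interpolated
  between samples to reduce sampling-rate quantisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .trace import Trace

__all__ = ["AP_DETECTION_LEVEL", "BIOMARKER_COLUMNS", "APEvent", "BiomarkerSet",
           "detect_aps", "threshold_voltage", "peak_and_slopes", "full_width",
           "half_width", "ahp_tau", "resting_membrane_potential",
           "firing_rate", "compute_biomarkers"]

AP_DETECTION_LEVEL = 0.0  # mV, upward-crossing level for AP detection
GRADIENT_THRESHOLD = 5.0  # mV/ms, threshold-voltage and AHP-window rule
AHP_MAX_WINDOW = 50.0  # ms
AHP_MIN_SAMPLES = 10

BIOMARKER_COLUMNS = [
    "threshold_voltage", "peak_voltage", "slope_max", "slope_min",
    "full_width", "ahp_tau", "rmp", "rheobase", "half_width", "firing_rate",
]


@dataclass(frozen=True)
class APEvent:
    """One detected action potential, as sample indices into a trace."""

    onset_index: int  # first sample at/above the detection level
    peak_index: int
    end_index: int  # first sample back below the detection level
    peak_voltage: float

    def __post_init__(self):
        if not (self.onset_index <= self.peak_index <= self.end_index):
            raise ValueError("require onset <= peak <= end")


@dataclass
class BiomarkerSet:
    """The calibration biomarkers for one model.

    Units: voltages mV, slopes mV/ms, widths and tau ms, rheobase pA,
    firing rate AP/s.  Unmeasurable fields are NaN; see :attr:`valid`.
    """

    threshold_voltage: float = math.nan
    peak_voltage: float = math.nan
    slope_max: float = math.nan
    slope_min: float = math.nan
    full_width: float = math.nan
    ahp_tau: float = math.nan
    rmp: float = math.nan
    rheobase: float = math.nan
    half_width: float = math.nan
    firing_rate: float = math.nan

    @property
    def valid(self) -> Dict[str, bool]:
        return {f.name: not math.isnan(getattr(self, f.name)) for f in fields(self)}

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in BIOMARKER_COLUMNS}


# ---------------------------------------------------------------------------
# AP detection and window helpers
# ---------------------------------------------------------------------------

def detect_aps(trace: Trace, level: float = AP_DETECTION_LEVEL) -> List[APEvent]:
    """Segment a trace into APs at upward crossings of ``level``.

    An event opens at a sample where the voltage reaches ``level`` from
    below and closes at the first later sample back below ``level`` (or the
    final sample).  Events are returned in time order.
    """
    v = trace.v
    above = v >= level
    events: List[APEvent] = []
    i = 1
    n = v.size
    while i < n:
        if above[i] and not above[i - 1]:
            onset = i
            j = onset
            while j < n and above[j]:
                j += 1
            end = j if j < n else n - 1
            seg = v[onset:end + 1]
            peak = onset + int(np.argmax(seg))
            events.append(APEvent(onset_index=onset, peak_index=peak,
                                  end_index=end, peak_voltage=float(v[peak])))
            i = end + 1
        else:
            i += 1
    return events


def _event_bounds(trace: Trace, events: List[APEvent], index: int) -> Tuple[int, int]:
    """Exclusive analysis window around event ``index``.

    Runs from the previous event's end (or the trace start) to the next
    event's onset (or the trace end).
    """
    lo = events[index - 1].end_index if index > 0 else 0
    hi = events[index + 1].onset_index if index + 1 < len(events) else len(trace)
    return lo, hi


def _upstroke_start(trace: Trace, event: APEvent, lo: int) -> int:
    """Sample index of the pre-upstroke voltage minimum."""
    seg = trace.v[lo:event.onset_index + 1]
    return lo + int(np.argmin(seg)) if seg.size else event.onset_index


def _gradient(trace: Trace) -> np.ndarray:
    """Centered-difference voltage-time gradient, mV/ms."""
    return np.gradient(trace.v, trace.dt)


def _cross_up_time(t, v, i, level) -> float:
    """Linearly interpolated time of the upward crossing between i-1 and i."""
    v0, v1 = v[i - 1], v[i]
    if v1 == v0:
        return float(t[i])
    return float(t[i - 1] + (level - v0) / (v1 - v0) * (t[i] - t[i - 1]))


def _cross_down_time(t, v, j, level) -> float:
    """Interpolated time of the downward crossing between j-1 and j."""
    v0, v1 = v[j - 1], v[j]
    if v1 == v0:
        return float(t[j])
    return float(t[j - 1] + (v0 - level) / (v0 - v1) * (t[j] - t[j - 1]))


# ---------------------------------------------------------------------------
# Individual biomarkers
# ---------------------------------------------------------------------------

def threshold_voltage(ramp_trace: Trace,
                      gradient_threshold: float = GRADIENT_THRESHOLD,
                      level: float = AP_DETECTION_LEVEL) -> float:
    """Voltage where dV/dt first surpasses ``gradient_threshold`` (mV/ms).

    Measured on the upstroke of the first AP of a ramp-stimulus trace,
    following the convention of ramp-based threshold measurements in DRG
    recordings.  NaN if the trace contains no AP or the gradient never
    surpasses the threshold on the upstroke.
    """
    events = detect_aps(ramp_trace, level=level)
    if not events:
        return math.nan
    ev = events[0]
    lo, _ = _event_bounds(ramp_trace, events, 0)
    start = _upstroke_start(ramp_trace, ev, lo)
    grad = _gradient(ramp_trace)
    for i in range(start, ev.peak_index + 1):
        if grad[i] > gradient_threshold:
            return float(ramp_trace.v[i])
    return math.nan


def peak_and_slopes(event: APEvent, trace: Trace,
                    bounds: Optional[Tuple[int, int]] = None
                    ) -> Tuple[float, float, float]:
    """(peak mV, slope_max mV/ms, slope_min mV/ms) for one AP.

    Slopes are extrema of the discrete gradient over the AP window, which
    extends from the pre-upstroke minimum to the post-AP trough so the full
    upstroke and downstroke are included.
    """
    lo, hi = bounds if bounds is not None else (0, len(trace))
    start = _upstroke_start(trace, event, lo)
    after = trace.v[event.end_index:hi]
    stop = event.end_index + int(np.argmin(after)) if after.size else event.end_index
    if stop <= start:
        return float(event.peak_voltage), math.nan, math.nan
    grad = _gradient(trace)[start:stop + 1]
    return float(event.peak_voltage), float(np.max(grad)), float(np.min(grad))


def full_width(event: APEvent, trace: Trace, threshold: float,
               bounds: Optional[Tuple[int, int]] = None) -> float:
    """AP width (ms) at the threshold voltage.

    Time between the first upward crossing of ``threshold`` and the first
    subsequent downward crossing, linearly interpolated between samples.
    NaN if the threshold is never crossed in both directions (e.g. the
    threshold lies above the peak).
    """
    if math.isnan(threshold) or threshold >= event.peak_voltage:
        return math.nan
    lo, hi = bounds if bounds is not None else (0, len(trace))
    t, v = trace.t, trace.v
    up = None
    for i in range(max(lo + 1, 1), hi):
        if v[i - 1] < threshold <= v[i]:
            up = i
            break
    if up is None:
        return math.nan
    for j in range(up + 1, hi):
        if v[j - 1] >= threshold > v[j]:
            return _cross_down_time(t, v, j, threshold) - _cross_up_time(t, v, up, threshold)
    return math.nan


def half_width(event: APEvent, trace: Trace, threshold: float,
               bounds: Optional[Tuple[int, int]] = None) -> float:
    """Longest continuous period (ms) above halfway between threshold and peak."""
    if math.isnan(threshold) or threshold >= event.peak_voltage:
        return math.nan
    level = 0.5 * (threshold + event.peak_voltage)
    lo, hi = bounds if bounds is not None else (0, len(trace))
    t, v = trace.t, trace.v
    mask = v[lo:hi] >= level
    if not mask.any():
        return math.nan
    # runs of consecutive samples at/above the level
    idx = np.flatnonzero(mask)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    best = 0.0
    for s, e in zip(starts, ends):
        a, b = lo + idx[s], lo + idx[e]
        t_start = _cross_up_time(t, v, a, level) if a > lo else float(t[a])
        t_end = _cross_down_time(t, v, b + 1, level) if b + 1 < hi else float(t[b])
        best = max(best, t_end - t_start)
    return best


def ahp_tau(trace: Trace, event: APEvent,
            gradient_threshold: float = GRADIENT_THRESHOLD,
            max_window: float = AHP_MAX_WINDOW,
            bounds: Optional[Tuple[int, int]] = None) -> float:
    """After-hyperpolarisation time constant (ms).

    Fits A*exp(-t/tau) + c to the voltage from the post-peak minimum up to
    the point where the gradient exceeds ``gradient_threshold`` mV/ms or
    ``max_window`` ms have elapsed, whichever comes first.  The time origin
    is at the post-peak minimum.  NaN for degenerate windows or fits.
    """
    lo, hi = bounds if bounds is not None else (0, len(trace))
    t, v = trace.t, trace.v
    hi = min(hi, len(trace))
    if event.peak_index >= hi - 1:
        return math.nan
    seg = v[event.peak_index:hi]
    m = event.peak_index + int(np.argmin(seg))
    grad = _gradient(trace)
    end = m
    for i in range(m + 1, hi):
        if grad[i] > gradient_threshold or (t[i] - t[m]) > max_window:
            break
        end = i
    if end - m + 1 < AHP_MIN_SAMPLES:
        return math.nan
    tt = t[m:end + 1] - t[m]
    vv = v[m:end + 1]
    if float(np.ptp(vv)) < 1e-9:
        return math.nan
    p0 = (float(vv[0] - vv[-1]), max(float(tt[-1]) / 5.0, trace.dt), float(vv[-1]))

    def model(x, a, tau, c):
        return a * np.exp(-x / tau) + c

    try:
        with np.errstate(over="ignore", invalid="ignore"):
            popt, _ = curve_fit(model, tt, vv, p0=p0, maxfev=5000)
    except (RuntimeError, ValueError):
        return math.nan
    tau = float(popt[1])
    return tau if tau > 0 else math.nan


def resting_membrane_potential(quiescent_trace: Trace) -> float:
    """Minimum voltage over the final 10% of a zero-stimulus simulation.

    The number of samples in the tail is ``floor(n / 10)``, with a minimum
    of one sample.
    """
    n = len(quiescent_trace)
    k = max(1, n // 10)
    return float(np.min(quiescent_trace.v[n - k:]))


def firing_rate(trace: Trace, protocol=None,
                level: float = AP_DETECTION_LEVEL) -> float:
    """Mean APs per second during the step stimulus window.

    Counts APs whose peak falls inside [delay, delay + duration] and divides
    by the stimulus duration in seconds.
    """
    if protocol is None:
        protocol = trace.protocol
    if protocol is None:
        raise ValueError("firing_rate requires the stimulus protocol")
    events = detect_aps(trace, level=level)
    t0, t1 = protocol.delay, protocol.delay + protocol.duration
    count = sum(1 for ev in events if t0 <= trace.t[ev.peak_index] <= t1)
    return count / (protocol.duration / 1000.0)


# ---------------------------------------------------------------------------
# Full biomarker set
# ---------------------------------------------------------------------------

def compute_biomarkers(step_trace: Optional[Trace], ramp_trace: Optional[Trace],
                       quiescent_trace: Trace,
                       rheobase: Optional[float],
                       level: float = AP_DETECTION_LEVEL) -> BiomarkerSet:
    """Assemble the full biomarker set for one model.

    Threshold voltage comes from the ramp trace; peak, slopes, widths, AHP
    tau and firing rate from the *first* AP of the at-rheobase step trace
    (widths use the ramp-derived threshold); resting membrane potential from
    the quiescent trace.  A missing trace or undetectable AP leaves the
    dependent fields NaN.
    """
    bset = BiomarkerSet()
    bset.rmp = resting_membrane_potential(quiescent_trace)
    bset.rheobase = math.nan if rheobase is None else float(rheobase)
    if ramp_trace is not None:
        bset.threshold_voltage = threshold_voltage(ramp_trace, level=level)
    if step_trace is None:
        return bset
    events = detect_aps(step_trace, level=level)
    if step_trace.protocol is not None:
        bset.firing_rate = firing_rate(step_trace, level=level)
    if not events:
        return bset
    ev = events[0]
    bounds = _event_bounds(step_trace, events, 0)
    bset.peak_voltage, bset.slope_max, bset.slope_min = peak_and_slopes(
        ev, step_trace, bounds=bounds)
    bset.full_width = full_width(ev, step_trace, bset.threshold_voltage, bounds=bounds)
    bset.half_width = half_width(ev, step_trace, bset.threshold_voltage, bounds=bounds)
    bset.ahp_tau = ahp_tau(step_trace, ev, bounds=bounds)
    return bset
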