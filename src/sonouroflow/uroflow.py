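"""Uroflowmetry ground truth: flowrate from weight traces, voiding metrics and
the three-group bladder-emptying pattern labels.

The volume flowrate follows from mass conservation, V(t) = dW/dt / rho, with
W the collected urine weight (g) and rho the urine density (g/mL, default 1).
Flow curves are summarized by the standard clinical quantities (voided volume,
voiding time, Qmax, Qavg, interruptions) and assigned one of three patterns:

* **A** -- healthy: bell-shaped curve, Qmax > 15 mL/s, no interruptions;
* **B** -- staccato / fluctuating (LUTS or impaired detrusor contractility):
  Qmax < 10 mL/s typical, multi-peaked but never fully interrupted;
* **C** -- interrupted (obstruction): Qmax < 5 mL/s, flow broken by zero-flow
  gaps, prolonged voiding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

LABELS = ("A", "B", "C")


class NoVoidError(ValueError):
    """Raised when a flow curve never exceeds the voiding flow threshold."""


@dataclass
class WeightTrace:
    """Collected urine weight vs time from a load cell."""

    times: np.ndarray
    weight: np.ndarray  # grams
    density: float = 1.0  # g/mL

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if self.times.size != self.weight.size:
            raise ValueError("times and weight must have equal lengths")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.density <= 0:
            raise ValueError("density must be > 0")

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.weight]),
            delimiter=",",
            header="time_s,weight_g",
            comments="",
        )

    @classmethod
    def from_csv(cls, path, density: float = 1.0) -> "WeightTrace":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, 0], arr[:, 1], density)


@dataclass
class FlowrateCurve:
    """Volume flowrate (mL/s) vs time."""

    times: np.ndarray
    flowrate: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flowrate = np.asarray(self.flowrate, dtype=float)
        if self.times.size != self.flowrate.size:
            raise ValueError("times and flowrate must have equal lengths")
        if not np.all(np.isfinite(self.flowrate)):
            raise ValueError("flowrate must be finite")
        if np.any(self.flowrate < 0):
            raise ValueError("flowrate must be nonnegative")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times))) if self.times.size > 1 else 0.0

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.flowrate]),
            delimiter=",",
            header="time_s,flowrate_ml_s",
            comments="",
        )

    @classmethod
    def from_csv(cls, path) -> "FlowrateCurve":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, 0], arr[:, 1])


@dataclass
class VoidingMetrics:
    """Clinical summary of one voiding event.

    ``q_avg`` is voided volume / voiding time (first to last threshold
    crossing).  ``q_avg_flowing`` excludes sub-threshold pauses from the
    denominator; both definitions are exposed because clinical devices differ.
    """

    voided_volume: float  # mL
    voiding_time: float  # s
    q_max: float  # mL/s
    q_avg: float  # mL/s
    n_interruptions: int
    flow_time: float = 0.0  # s above threshold
    q_avg_flowing: float = 0.0  # mL/s, volume / flow_time

    def as_dict(self) -> dict:
        return {
            "voided_volume_ml": self.voided_volume,
            "voiding_time_s": self.voiding_time,
            "q_max_ml_s": self.q_max,
            "q_avg_ml_s": self.q_avg,
            "n_interruptions": self.n_interruptions,
            "flow_time_s": self.flow_time,
            "q_avg_flowing_ml_s": self.q_avg_flowing,
        }


@dataclass
class PatternLabel:
    """Assigned bladder-emptying pattern with the metrics it was based on."""

    label: str  # "A", "B" or "C"
    basis: VoidingMetrics = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")


@dataclass
class LabelThresholds:
    """Decision thresholds of the three-group rule (mL/s unless noted).

    Curves with Qmax between ``q_weak`` and ``q_bell`` are assigned A when
    bell-shaped and B otherwise (the clinical rule leaves this band open).
    """

    q_bell: float = 15.0  # A requires Qmax above this
    q_weak: float = 10.0  # typical staccato Qmax upper bound (informational)
    q_low: float = 5.0  # C when Qmax below this
    q_interrupted: float = 7.5  # C when interrupted and Qmax below this
    flow_threshold: float = 0.5  # voiding-span detection floor, mL/s
    rel_threshold: float = 0.1  # span threshold also scales with Qmax
    min_gap: float = 1.0  # s; sub-threshold gaps at least this long count


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x.copy()
    kernel = np.ones(n) / n
    pad = n // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad : pad + x.size]


def flowrate_from_weight(wt: WeightTrace, smoothing: float = 0.5) -> FlowrateCurve:
    """Flowrate V(t) = dW/dt / rho from a weight trace.

    The weight is smoothed with a moving average of ``smoothing`` seconds
    (load-cell traces are noisy), differentiated with central differences and
    negative excursions are clipped to zero.
    """
    if wt.times.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    dt = float(np.median(np.diff(wt.times)))
    n = max(int(round(smoothing / dt)), 1)
    w = _moving_average(wt.weight, n)
    v = np.gradient(w, wt.times) / wt.density
    return FlowrateCurve(wt.times.copy(), np.maximum(v, 0.0))


def _subthreshold_gaps(times, flow, thr, i0, i1, min_gap):
    """Count maximal sub-threshold runs lasting >= min_gap strictly inside the
    voiding span [i0, i1] (span endpoints are above threshold, so every run
    is interior by construction)."""
    below = flow[i0 : i1 + 1] <= thr
    t = times[i0 : i1 + 1]
    dt = float(np.median(np.diff(times))) if times.size > 1 else 1.0
    count = 0
    run_start = None
    for k in range(below.size):
        if below[k] and run_start is None:
            run_start = k
        if run_start is not None and (not below[k] or k == below.size - 1):
            end = k - 1 if not below[k] else k
            if t[end] - t[run_start] + dt >= min_gap:
                count += 1
            run_start = None
    return count


def voiding_metrics(
    fc: FlowrateCurve,
    flow_threshold: float = 0.5,
    min_gap: float = 1.0,
    rel_threshold: float = 0.1,
) -> VoidingMetrics:
    """Clinical voiding metrics of a flow curve.

    The voiding span runs from the first to the last crossing of the span
    threshold max(``flow_threshold``, ``rel_threshold`` * Qmax) -- the
    relative term keeps span and interruption detection robust to bounded
    additive noise (e.g. augmentation, sensor noise) that scales with the
    curve amplitude.  Voided volume is the trapezoid integral of the whole
    curve; interruptions are maximal sub-threshold gaps of at least
    ``min_gap`` seconds strictly inside the voiding span.
    """
    if fc.times.size == 0:
        raise ValueError("empty flow curve")
    flow_threshold = max(flow_threshold, rel_threshold * float(fc.flowrate.max()))
    above = fc.flowrate > flow_threshold
    if not np.any(above):
        raise NoVoidError(f"flow never exceeds {flow_threshold} mL/s")
    idx = np.flatnonzero(above)
    i0, i1 = int(idx[0]), int(idx[-1])
    dt = fc.dt if fc.dt > 0 else 1.0
    voiding_time = float(fc.times[i1] - fc.times[i0])
    if voiding_time <= 0:
        voiding_time = dt
    volume = float(np.trapezoid(fc.flowrate, fc.times))
    q_max = float(fc.flowrate.max())
    q_avg = volume / voiding_time
    n_int = _subthreshold_gaps(fc.times, fc.flowrate, flow_threshold, i0, i1, min_gap)
    flow_time = float(above[i0 : i1 + 1].sum() * dt)
    return VoidingMetrics(
        voided_volume=volume,
        voiding_time=voiding_time,
        q_max=q_max,
        q_avg=q_avg,
        n_interruptions=n_int,
        flow_time=flow_time,
        q_avg_flowing=volume / flow_time if flow_time > 0 else 0.0,
    )


def is_bell_shaped(fc: FlowrateCurve, thresholds: LabelThresholds | None = None) -> bool:
    """Operational bell-shape test: after 1-s smoothing the curve has a single
    dominant peak (no second peak above half maximum with prominence above
    20% of the maximum) and no sub-threshold gap inside the voiding span."""
    thr = thresholds or LabelThresholds()
    dt = fc.dt if fc.dt > 0 else 1.0
    n = max(int(round(1.0 / dt)), 1)
    smooth = _moving_average(fc.flowrate, n)
    vmax = smooth.max()
    if vmax <= 0:
        return False
    peaks, _ = sps.find_peaks(smooth, height=0.5 * vmax, prominence=0.2 * vmax)
    n_peaks = peaks.size
    if n_peaks == 0:  # plateau or boundary maximum
        n_peaks = 1
    try:
        m = voiding_metrics(fc, thr.flow_threshold, thr.min_gap, thr.rel_threshold)
    except NoVoidError:
        return False
    return n_peaks == 1 and m.n_interruptions == 0


def label_pattern(fc: FlowrateCurve, thresholds: LabelThresholds | None = None) -> PatternLabel:
    """Assign the three-group bladder-emptying pattern label.

    * A when Qmax > 15 mL/s with no interruptions and a bell-shaped envelope;
    * C when Qmax < 5 mL/s, or the flow is interrupted with Qmax < 7.5 mL/s;
    * B otherwise (staccato / fluctuating weak stream).

    Deterministic given the curve.
    """
    thr = thresholds or LabelThresholds()
    m = voiding_metrics(fc, thr.flow_threshold, thr.min_gap, thr.rel_threshold)
    if m.q_max > thr.q_bell and m.n_interruptions == 0 and is_bell_shaped(fc, thr):
        return PatternLabel("A", m)
    if m.q_max < thr.q_low or (m.n_interruptions >= 1 and m.q_max < thr.q_interrupted):
        return PatternLabel("C", m)
    return PatternLabel("B", m)
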