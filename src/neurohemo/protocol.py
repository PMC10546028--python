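"""Block-protocol timelines, response summaries and phenotype rules.

The three stimulus protocols are block designs:

* VFT  — verbal fluency task: 30 s baseline, 60 s task, 70 s recovery (160 s).
* HCT  — high-level cognition task: same timing as VFT.
* VBH  — voluntary breath holding: baseline up to the recorded breath_start,
  task from breath_start to breath_end (subject-dependent), then recovery.

Hemodynamic series are segmented into half-open [start, start+duration)
epochs; each segment contributes descriptive statistics (means, OLS slopes,
fluctuation index, nadir/peak landmarks) and the summaries feed rule-based
phenotype labels for the oxygenation and flow axes. All rule thresholds are
explicit configuration; margins to each rule boundary are always reported so
threshold sensitivity is inspectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .preprocess import FilterSpec, apply_bandpass

__all__ = [
    "Segment",
    "ProtocolTimeline",
    "build_timeline",
    "segment_indices",
    "SignalSummary",
    "ResponseSummary",
    "summarize_response",
    "Thresholds",
    "classify_oxygenation",
    "classify_flow",
]

PROTOCOLS = ("VFT", "HCT", "VBH")
SEGMENT_LABELS = ("baseline", "task", "recovery")


@dataclass(frozen=True)
class Segment:
    label: str
    start_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class ProtocolTimeline:
    """Ordered, contiguous baseline/task/recovery segments starting at 0."""

    protocol: str
    segments: tuple[Segment, ...]
    events: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        if not self.segments:
            raise ValueError("timeline needs at least one segment")
        cursor = 0.0
        for seg in self.segments:
            if seg.label not in SEGMENT_LABELS:
                raise ValueError(f"unknown segment label {seg.label!r}")
            if seg.duration_s <= 0:
                raise ValueError(f"segment {seg.label!r} has nonpositive duration")
            if abs(seg.start_s - cursor) > 1e-9:
                raise ValueError("segments must be contiguous and start at 0")
            cursor = seg.end_s
        for name, t in self.events.items():
            if not 0 <= t <= self.total_duration_s:
                raise ValueError(f"event {name!r} at {t} s lies outside the timeline")

    @property
    def total_duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    def segment(self, label: str) -> Segment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(label)

    @property
    def baseline_window(self) -> tuple[float, float]:
        seg = self.segment("baseline")
        return (seg.start_s, seg.end_s)

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "segments": [
                {"label": s.label, "start_s": s.start_s, "duration_s": s.duration_s}
                for s in self.segments
            ],
            "events": dict(self.events),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProtocolTimeline":
        raw = json.loads(Path(path).read_text())
        return cls(
            raw["protocol"],
            tuple(
                Segment(s["label"], float(s["start_s"]), float(s["duration_s"]))
                for s in raw["segments"]
            ),
            raw.get("events", {}),
        )


def build_timeline(
    protocol: str,
    baseline_s: float = 30.0,
    task_s: float = 60.0,
    recovery_s: float = 70.0,
    events: Mapping[str, float] | None = None,
) -> ProtocolTimeline:
    """Standard block timeline; VBH derives its task from breath events.

    VFT/HCT default to the study protocol 30 + 60 + 70 = 160 s. VBH requires
    ``events`` with ``breath_start`` and ``breath_end``; the baseline runs to
    breath_start, the task is the recorded hold, recovery follows.
    """
    events = dict(events or {})
    if protocol == "VBH":
        if "breath_start" not in events or "breath_end" not in events:
            raise ValueError("VBH timeline requires breath_start/breath_end events")
        t_start, t_end = events["breath_start"], events["breath_end"]
        if not 0 < t_start < t_end:
            raise ValueError("breath events must satisfy 0 < start < end")
        segments = (
            Segment("baseline", 0.0, t_start),
            Segment("task", t_start, t_end - t_start),
            Segment("recovery", t_end, recovery_s),
        )
    else:
        segments = (
            Segment("baseline", 0.0, baseline_s),
            Segment("task", baseline_s, task_s),
            Segment("recovery", baseline_s + task_s, recovery_s),
        )
    return ProtocolTimeline(protocol, segments, events)


def segment_indices(
    time: np.ndarray, timeline: ProtocolTimeline
) -> dict[str, np.ndarray]:
    """Assign samples to segments via half-open [start, end) intervals.

    Boundary samples belong to the later segment; the assignment over the
    timeline's span is a partition (disjoint and exhaustive).
    """
    time = np.asarray(time, dtype=float)
    if time[-1] < timeline.total_duration_s - 1e-9 - (time[1] - time[0]):
        raise ValueError(
            f"series ends at {time[-1]:g} s but the timeline spans "
            f"{timeline.total_duration_s:g} s"
        )
    out: dict[str, np.ndarray] = {}
    for seg in timeline.segments:
        out[seg.label] = np.flatnonzero((time >= seg.start_s) & (time < seg.end_s))
    return out


@dataclass
class SignalSummary:
    """Descriptive task-response features for one signal."""

    baseline_mean: float
    task_delta: float
    task_slope: float
    recovery_delta: float
    overshoot: bool
    fluctuation_index: float
    task_nadir_depth: float
    task_nadir_time_s: float
    posttask_peak_height: float
    posttask_peak_time_s: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ResponseSummary:
    """Per-signal summaries for one protocol run."""

    protocol: str
    signals: dict[str, SignalSummary]

    def __getitem__(self, key: str) -> SignalSummary:
        return self.signals[key]

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "signals": {k: v.to_dict() for k, v in self.signals.items()},
        }


def _ols_slope(t: np.ndarray, x: np.ndarray) -> float:
    t = t - t.mean()
    denom = float(np.sum(t * t))
    return float(np.sum(t * x) / denom) if denom > 0 else 0.0


def _band_sd(
    x: np.ndarray, fs: float, band: tuple[float, float], idx: np.ndarray
) -> float:
    spec = FilterSpec(order=3, low_cut_hz=band[0], high_cut_hz=band[1])
    try:
        filtered = apply_bandpass(x, fs, spec)
    except ValueError:
        return float("nan")
    return float(np.std(filtered[idx]))


def summarize_response(
    signals: Mapping[str, np.ndarray],
    time: np.ndarray,
    timeline: ProtocolTimeline,
    fluctuation_band: tuple[float, float] = (0.05, 0.2),
    fluctuation_guard_s: float = 5.0,
    min_segment_samples: int = 10,
) -> ResponseSummary:
    """Segment each signal and compute the response features.

    ``task_delta``/``recovery_delta`` are segment means minus the baseline
    mean; slopes are within-segment OLS (descriptive only). The fluctuation
    index is the SD of the 0.05–0.2 Hz component during task divided by the
    same-band SD during baseline (0/0 guarded to 0); a ``fluctuation_guard_s``
    margin at each segment edge is excluded from the band SDs so that sharp
    task-locked transients in neighbouring segments cannot leak across the
    boundary through the non-causal band filter. Nadir/peak landmarks
    (used for the breath-hold dip-and-hyperemia call) are depths/heights
    relative to the baseline mean: nadir over the task, peak from task end
    onward.
    """
    time = np.asarray(time, dtype=float)
    fs = 1.0 / float(time[1] - time[0])
    idx = segment_indices(time, timeline)
    for label, ii in idx.items():
        if ii.size < min_segment_samples:
            raise ValueError(
                f"segment {label!r} has {ii.size} samples "
                f"(< {min_segment_samples})"
            )
    task_end = timeline.segment("task").end_s
    post_idx = np.flatnonzero(
        (time >= task_end) & (time < timeline.total_duration_s)
    )
    out: dict[str, SignalSummary] = {}
    for name, x in signals.items():
        x = np.asarray(x, dtype=float)
        base = float(np.mean(x[idx["baseline"]]))
        task = x[idx["task"]]
        rec = x[idx["recovery"]]
        task_delta = float(np.mean(task)) - base
        rec_delta = float(np.mean(rec)) - base
        guard = int(round(fluctuation_guard_s * fs))

        def _trim(ii: np.ndarray) -> np.ndarray:
            return ii[guard:-guard] if ii.size > 2 * guard + 2 else ii

        sd_task = _band_sd(x, fs, fluctuation_band, _trim(idx["task"]))
        sd_base = _band_sd(x, fs, fluctuation_band, _trim(idx["baseline"]))
        if not np.isfinite(sd_task) or not np.isfinite(sd_base) or sd_base == 0:
            fluct = 0.0 if (sd_task == 0 or not np.isfinite(sd_task)) else float("inf")
        else:
            fluct = sd_task / sd_base
        nadir_i = int(np.argmin(task))
        peak_i = int(np.argmax(x[post_idx])) if post_idx.size else 0
        out[name] = SignalSummary(
            baseline_mean=base,
            task_delta=task_delta,
            task_slope=_ols_slope(time[idx["task"]], task),
            recovery_delta=rec_delta,
            overshoot=bool(task_delta < 0 and np.max(rec) > base),
            fluctuation_index=float(fluct),
            task_nadir_depth=float(np.min(task)) - base,
            task_nadir_time_s=float(time[idx["task"]][nadir_i]),
            posttask_peak_height=(
                float(np.max(x[post_idx])) - base if post_idx.size else 0.0
            ),
            posttask_peak_time_s=(
                float(time[post_idx][peak_i]) if post_idx.size else float("nan")
            ),
        )
    return ResponseSummary(timeline.protocol, out)


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for the phenotype rules (all configurable).

    theta_um: activation/ischemia amplitude (uM); theta_prime_um: secondary
    chromophore amplitude (uM); theta_blunted_um: blunted ceiling (uM);
    theta_flow_pct: rCBF change floor (% of baseline); theta_fluct:
    fluctuation-index floor for flow instability.
    """

    theta_um: float = 0.2
    theta_prime_um: float = 0.1
    theta_blunted_um: float = 0.1
    theta_flow_pct: float = 5.0
    theta_fluct: float = 2.0


OXY_LABELS = (
    "typical_activation",
    "blunted",
    "task_ischemia",
    "hypoxia_typical",
    "hypoxia_atypical",
    "unclassified",
)
FLOW_LABELS = (
    "stable",
    "task_increase",
    "task_decrease_recover",
    "flow_instability",
    "vbh_dip_hyperemia",
)


def classify_oxygenation(
    summary: ResponseSummary,
    task: str | None = None,
    thresholds: Thresholds | None = None,
) -> tuple[str, dict]:
    """Rule-based oxygenation phenotype with rule margins.

    Cognitive tasks (VFT/HCT): typical_activation when dHbO2 rises above
    theta and dHb falls below -theta'; task_ischemia when both fall below
    -theta; blunted when both amplitudes stay inside the blunted ceiling.
    Breath hold (VBH): hypoxia_typical when dHbO2 falls and dHb rises;
    blunted inside the ceiling; anything else is hypoxia_atypical.
    """
    task = task or summary.protocol
    thr = thresholds or Thresholds()
    d_o = summary["dHbO2"].task_delta
    d_h = summary["dHb"].task_delta
    margins = {
        "task_delta_dHbO2_uM": d_o,
        "task_delta_dHb_uM": d_h,
        "typical_activation": min(d_o - thr.theta_um, -d_h - thr.theta_prime_um),
        "task_ischemia": min(-d_o - thr.theta_um, -d_h - thr.theta_um),
        "blunted": thr.theta_blunted_um - max(abs(d_o), abs(d_h)),
        "hypoxia_typical": min(-d_o - thr.theta_um, d_h - thr.theta_prime_um),
    }
    if task == "VBH":
        if d_o < -thr.theta_um and d_h > thr.theta_prime_um:
            label = "hypoxia_typical"
        elif max(abs(d_o), abs(d_h)) < thr.theta_blunted_um:
            label = "blunted"
        else:
            label = "hypoxia_atypical"
    else:
        if d_o > thr.theta_um and d_h < -thr.theta_prime_um:
            label = "typical_activation"
        elif d_o < -thr.theta_um and d_h < -thr.theta_um:
            label = "task_ischemia"
        elif max(abs(d_o), abs(d_h)) < thr.theta_blunted_um:
            label = "blunted"
        else:
            label = "unclassified"
    return label, margins


def classify_flow(
    summary: ResponseSummary,
    task: str | None = None,
    thresholds: Thresholds | None = None,
    signal: str = "rCBF",
) -> tuple[str, dict]:
    """Rule-based flow phenotype with rule margins.

    flow_instability dominates (fluctuation index above theta_fluct); for
    VBH a task-period nadir below baseline followed by a post-task peak
    above baseline is the dip-and-hyperemia signature; otherwise small task
    deltas are stable and larger ones are classified by sign (a negative
    delta that returns toward baseline is task_decrease_recover).
    """
    task = task or summary.protocol
    thr = thresholds or Thresholds()
    s = summary[signal]
    margins = {
        "task_delta_pct": s.task_delta,
        "fluctuation_index": s.fluctuation_index,
        "flow_instability": s.fluctuation_index - thr.theta_fluct,
        "stable": thr.theta_flow_pct - abs(s.task_delta),
        "vbh_dip_hyperemia": min(
            -s.task_nadir_depth - thr.theta_flow_pct,
            s.posttask_peak_height - thr.theta_flow_pct,
        ),
    }
    if s.fluctuation_index > thr.theta_fluct:
        return "flow_instability", margins
    if (
        task == "VBH"
        and s.task_nadir_depth < -thr.theta_flow_pct
        and s.posttask_peak_height > thr.theta_flow_pct
    ):
        return "vbh_dip_hyperemia", margins
    if abs(s.task_delta) < thr.theta_flow_pct:
        return "stable", margins
    if s.task_delta > 0:
        return "task_increase", margins
    return "task_decrease_recover", margins
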