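"""Event-averaged single-soma activity profiles and their four-class
peak-timing classification.

Each annotated soma's ΔF/F is averaged over all usable wave windows
([−8 s, 8 s] around the trigger).  The averaged trace is classified against
the wave-propagation interval — the span between peak activity in the
leading and trailing abdominal segments (A8 → A1 for forward waves,
A1 → A8 for backward waves):

* class 1 — peak activity before wave propagation,
* class 2 — peak during propagation,
* class 3 — peak after propagation,
* class 4 — two activity peaks separated by a phase of quiescence
  (the intervening minimum is reduced by ≥ 50% relative to both peaks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import UndefinedPeakError
from .timing_map import SOMA_WINDOW, select_triggered_events
from .wave_detection import RoiSet, TraceMatrix, WaveEvent, extract_roi_traces

logger = logging.getLogger(__name__)

DIP_FRACTION = 0.5
PEAK_PROMINENCE_FRACTION = 0.05  # of the trace range; suppresses noise peaks


@dataclass
class PropagationInterval:
    """Wave-propagation span, marked by the leading and trailing abdominal
    segment peaks (seconds relative to the trigger)."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_start > self.t_end:
            raise ValueError("t_start must be <= t_end")

    def contains(self, t: float) -> bool:
        return self.t_start <= t <= self.t_end


@dataclass
class SomaProfile:
    label: str
    region: str
    mean_trace: np.ndarray
    sem_trace: np.ndarray
    offsets_s: np.ndarray
    class_forward: int | None = None
    class_backward: int | None = None

    def normalized_trace(self) -> np.ndarray:
        """Display normalization: divide by the trace maximum."""
        peak = self.mean_trace.max()
        return self.mean_trace / peak if peak > 0 else self.mean_trace.copy()


def propagation_interval(
    segment_traces: TraceMatrix,
    event: WaveEvent,
    half_window_s: float = -SOMA_WINDOW[0],
) -> PropagationInterval:
    """Per-event propagation span from A1/A8 peak times.

    Forward waves run posterior→anterior, so the interval starts at the A8
    peak and ends at the A1 peak; backward waves are reversed.  Peaks are
    argmax of ΔF/F inside the event window.  A flat segment trace has no
    defined peak and raises.
    """
    segs = segment_traces
    if "A1" not in segs.labels or "A8" not in segs.labels:
        segs = segment_traces.segment_traces()
    times = segs.times()
    sel = (times >= event.time - half_window_s) & (times <= event.time + half_window_s)
    if sel.sum() < 2:
        raise UndefinedPeakError("event window contains too few frames")
    tsub = times[sel]
    peaks = {}
    for seg in ("A1", "A8"):
        y = segs.trace(seg)[sel]
        if np.ptp(y) == 0:
            raise UndefinedPeakError(f"flat {seg} trace in event window")
        peaks[seg] = float(tsub[np.argmax(y)])
    if event.direction == "forward":
        t0, t1 = peaks["A8"], peaks["A1"]
    else:
        t0, t1 = peaks["A1"], peaks["A8"]
    if t0 > t1:  # noisy contradiction of the direction rule; keep span valid
        logger.warning(
            "segment peak order contradicts %s direction at t=%.1f s",
            event.direction,
            event.time,
        )
        t0, t1 = t1, t0
    return PropagationInterval(t_start=t0, t_end=t1)


def classify_soma(
    mean_trace: np.ndarray,
    offsets_s: np.ndarray,
    interval: PropagationInterval,
    dip_fraction: float = DIP_FRACTION,
    prominence_fraction: float = PEAK_PROMINENCE_FRACTION,
) -> int | None:
    """Classify an event-averaged soma trace into classes 1–4.

    Class 4 requires two local maxima whose intervening minimum is at most
    ``(1 − dip_fraction)`` times *each* flanking peak; otherwise the class is
    1/2/3 according to whether the global peak precedes, falls inside, or
    follows the propagation interval.  An all-constant trace is
    unclassifiable (returns None).
    """
    y = np.asarray(mean_trace, dtype=float)
    rng = np.ptp(y)
    if rng == 0:
        return None
    peaks, _ = find_peaks(y, prominence=prominence_fraction * rng)
    for i in range(len(peaks) - 1):
        for j in range(i + 1, len(peaks)):
            pi, pj = peaks[i], peaks[j]
            trough = y[pi : pj + 1].min()
            lim = 1.0 - dip_fraction
            if trough <= lim * y[pi] and trough <= lim * y[pj]:
                return 4
    t_peak = float(offsets_s[np.argmax(y)])
    if t_peak < interval.t_start:
        return 1
    if t_peak > interval.t_end:
        return 3
    return 2


def _mean_interval(
    segment_traces: TraceMatrix, events: list[WaveEvent]
) -> PropagationInterval:
    """Average per-event propagation interval, relative to the trigger."""
    starts, ends = [], []
    for e in events:
        iv = propagation_interval(segment_traces, e)
        starts.append(iv.t_start - e.time)
        ends.append(iv.t_end - e.time)
    return PropagationInterval(float(np.mean(starts)), float(np.mean(ends)))


def profile_all_somata(
    dff,
    soma_rois: RoiSet,
    events: list[WaveEvent],
    segment_traces: TraceMatrix,
    regions: dict[str, str] | None = None,
    window: tuple[float, float] = SOMA_WINDOW,
    dip_fraction: float = DIP_FRACTION,
) -> tuple[list[SomaProfile], pd.DataFrame]:
    """Profile every annotated soma across both wave directions.

    Returns per-soma profiles (event-averaged trace, SEM, class per
    direction) and a summary table of class fractions per region and
    direction, including the fraction of somata with the same class in both
    directions.
    """
    regions = regions or {}
    dt = dff.frame_interval
    pre = int(round(-window[0] / dt))
    post = int(round(window[1] / dt))
    Tw = pre + post + 1
    offsets = (np.arange(Tw) - pre) * dt

    soma_traces = extract_roi_traces(dff, soma_rois)

    by_direction: dict[str, dict] = {}
    for direction in ("forward", "backward"):
        usable = select_triggered_events(
            events, direction, window, dff.n_frames, dt
        )
        if not usable:
            logger.warning("no usable %s events; skipping direction", direction)
            continue
        frames = [int(round(e.time / dt)) for e in usable]
        windows = np.stack(
            [soma_traces.data[:, f - pre : f - pre + Tw] for f in frames], axis=0
        )  # (n_events, n_somata, Tw)
        mean = windows.mean(axis=0)
        sem = windows.std(axis=0, ddof=0) / np.sqrt(len(usable))
        interval = _mean_interval(segment_traces, usable)
        by_direction[direction] = {
            "mean": mean,
            "sem": sem,
            "interval": interval,
        }

    profiles: list[SomaProfile] = []
    for i, label in enumerate(soma_traces.labels):
        fwd = by_direction.get("forward")
        bwd = by_direction.get("backward")
        base = fwd or bwd
        if base is None:
            raise UndefinedPeakError("no usable events in either direction")
        prof = SomaProfile(
            label=label,
            region=regions.get(label, "unknown"),
            mean_trace=base["mean"][i],
            sem_trace=base["sem"][i],
            offsets_s=offsets,
        )
        if fwd is not None:
            prof.class_forward = classify_soma(
                fwd["mean"][i], offsets, fwd["interval"], dip_fraction
            )
        if bwd is not None:
            prof.class_backward = classify_soma(
                bwd["mean"][i], offsets, bwd["interval"], dip_fraction
            )
        profiles.append(prof)

    rows = []
    for region in sorted({p.region for p in profiles}):
        sub = [p for p in profiles if p.region == region]
        for direction, attr in (("forward", "class_forward"), ("backward", "class_backward")):
            classes = [getattr(p, attr) for p in sub if getattr(p, attr) is not None]
            if not classes:
                continue
            for c in (1, 2, 3, 4):
                rows.append(
                    {
                        "region": region,
                        "direction": direction,
                        "class": c,
                        "fraction": classes.count(c) / len(classes),
                        "n": len(classes),
                    }
                )
    both = [
        p
        for p in profiles
        if p.class_forward is not None and p.class_backward is not None
    ]
    conserved = (
        sum(p.class_forward == p.class_backward for p in both) / len(both)
        if both
        else float("nan")
    )
    summary = pd.DataFrame(rows)
    summary.attrs["conserved_fraction"] = conserved
    return profiles, summary


def save_profiles(profiles: list[SomaProfile], csv_path, h5_path=None) -> None:
    pd.DataFrame(
        [
            {
                "label": p.label,
                "region": p.region,
                "class_fwd": p.class_forward,
                "class_bwd": p.class_backward,
            }
            for p in profiles
        ]
    ).to_csv(csv_path, index=False)
    if h5_path is not None:
        with h5py.File(h5_path, "w") as f:
            for p in profiles:
                g = f.create_group(p.label)
                g.create_dataset("mean_trace", data=p.mean_trace)
                g.create_dataset("sem_trace", data=p.sem_trace)
                g.create_dataset("offsets_s", data=p.offsets_s)
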