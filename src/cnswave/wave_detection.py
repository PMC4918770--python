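"""Detection and classification of fictive forward and backward locomotor
waves from abdominal hemisegment ΔF/F traces.

The ventral nerve cord is read out through 16 3D ROIs (hemisegments
A1L…A8R).  After z-scoring, removal of the across-segment mean and
left/right averaging, the 8 × T trace matrix is embedded in 2D with a
singular value decomposition.  In that plane a locomotor wave is a rotation
away from and back toward the origin; forward and backward waves rotate in
opposite directions.  Events are therefore detected as local peaks of the
trajectory amplitude r_t = sqrt(v1_t² + v2_t²) and classified by the sign of
the slope of the unwrapped phase θ_t = atan2(v2_t, v1_t).

Because SVD component signs are arbitrary, the slope-sign → direction
mapping is calibrated per recording from segment peak order inside detected
events: a wave whose activity peaks posterior-first (A8 before A1) is a
forward (anterior-progressing) wave.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError
from .volume_io import VolumeSeries

logger = logging.getLogger(__name__)

HEMISEGMENT_LABELS = tuple(
    f"A{i}{side}" for i in range(1, 9) for side in ("L", "R")
)
SEGMENT_LABELS = tuple(f"A{i}" for i in range(1, 9))

AMP_THRESHOLD = 0.04
SLOPE_THRESHOLD = 0.125  # radians / s
MIN_SEPARATION_S = 3.0
SLOPE_WINDOW_S = 2.0
SKIP_S = 120.0


# ---------------------------------------------------------------------------
# ROI containers and trace extraction
# ---------------------------------------------------------------------------

@dataclass
class RoiSet:
    """Named 3D voxel sets; hemisegments are labelled A1L…A8R."""

    rois: dict[str, np.ndarray]  # label -> (n, 3) int voxel coordinates

    def __post_init__(self) -> None:
        clean = {}
        for label, vox in self.rois.items():
            arr = np.asarray(vox, dtype=np.intp)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
                raise ValueError(f"ROI {label!r} must be a non-empty (n, 3) array")
            clean[label] = arr
        self.rois = clean

    @property
    def labels(self) -> list[str]:
        return list(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    @classmethod
    def from_label_volume(
        cls, labels: np.ndarray, label_map: dict[int, str]
    ) -> "RoiSet":
        rois = {}
        for value, name in label_map.items():
            coords = np.argwhere(labels == value)
            if coords.size:
                rois[name] = coords
        return cls(rois)

    @classmethod
    def from_json(cls, path) -> "RoiSet":
        with open(path) as f:
            payload = json.load(f)
        return cls({k: np.asarray(v) for k, v in payload.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump({k: v.tolist() for k, v in self.rois.items()}, f)


@dataclass
class TraceMatrix:
    """ROI × time ΔF/F values."""

    data: np.ndarray  # (n_rois, T)
    labels: list[str]
    frame_interval: float
    t_start: float = 0.0  # absolute time of column 0, seconds

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.labels):
            raise ValueError("label count does not match trace count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_frames) * self.frame_interval

    def trace(self, label: str) -> np.ndarray:
        try:
            return self.data[self.labels.index(label)]
        except ValueError:
            raise SchemaError(f"missing ROI label {label!r}") from None

    def segment_traces(self) -> "TraceMatrix":
        """Left/right-averaged abdominal segment traces A1…A8."""
        rows = []
        for seg in SEGMENT_LABELS:
            rows.append(0.5 * (self.trace(f"{seg}L") + self.trace(f"{seg}R")))
        return TraceMatrix(
            np.array(rows), list(SEGMENT_LABELS), self.frame_interval, self.t_start
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels, columns=self.times())


def extract_roi_traces(
    dff: VolumeSeries, rois: RoiSet, chunk_frames: int = 200
) -> TraceMatrix:
    """Spatially average ΔF/F over each ROI's voxel set, per timepoint.

    Accepts any series exposing ``spatial_shape``/``n_frames``/``time_slice``;
    recordings without a memory-resident array are consumed in time chunks.
    """
    shape = dff.spatial_shape
    for label, vox in rois.rois.items():
        if (vox < 0).any() or (vox >= np.asarray(shape)).any():
            raise IndexError(f"ROI {label!r} has voxels outside the volume")
    traces = np.empty((len(rois), dff.n_frames))
    for start in range(0, dff.n_frames, chunk_frames):
        stop = min(start + chunk_frames, dff.n_frames)
        block = dff.time_slice(start, stop)
        for i, vox in enumerate(rois.rois.values()):
            traces[i, start:stop] = block[vox[:, 0], vox[:, 1], vox[:, 2], :].mean(
                axis=0
            )
    return TraceMatrix(traces, rois.labels, dff.frame_interval)


# ---------------------------------------------------------------------------
# trace preprocessing and 2D embedding
# ---------------------------------------------------------------------------

@dataclass
class PreprocessedTraces:
    """8 × T matrix of z-scored, mean-removed, left/right-averaged traces."""

    X: np.ndarray
    frame_interval: float
    t_start: float

    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.X.shape[1]) * self.frame_interval


def _zscore(row: np.ndarray) -> np.ndarray:
    sd = row.std()
    if sd == 0:
        return np.zeros_like(row)  # zero-variance trace defined as all-zero
    return (row - row.mean()) / sd


def preprocess_traces(traces: TraceMatrix, skip: float = SKIP_S) -> PreprocessedTraces:
    """Standardize the 16 hemisegment traces for wave detection.

    In order: the first ``skip`` seconds are dropped (start-of-recording
    non-stationarity), each of the 16 traces is z-scored, the across-trace
    mean is subtracted (removing the CNS-wide activity envelope so relative
    segment differences dominate), and left/right partners are averaged,
    leaving 8 rows ordered A1…A8.
    """
    for label in HEMISEGMENT_LABELS:
        if label not in traces.labels:
            raise SchemaError(f"missing hemisegment label {label!r}")
    n_skip = int(round(skip / traces.frame_interval))
    if n_skip >= traces.n_frames:
        raise ValueError("recording shorter than the skipped prefix")
    hemis = np.array([traces.trace(l)[n_skip:] for l in HEMISEGMENT_LABELS])
    z = np.array([_zscore(row) for row in hemis])
    z = z - z.mean(axis=0, keepdims=True)
    X = 0.5 * (z[0::2] + z[1::2])  # average A_kL with A_kR
    return PreprocessedTraces(
        X=X,
        frame_interval=traces.frame_interval,
        t_start=traces.t_start + n_skip * traces.frame_interval,
    )


@dataclass
class Embedding:
    """2D SVD embedding of the segment trace matrix with polar features."""

    v1: np.ndarray
    v2: np.ndarray
    singular_values: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray  # unwrapped, radians
    frame_interval: float
    t_start: float

    def times(self) -> np.ndarray:
        return self.t_start + np.arange(len(self.amplitude)) * self.frame_interval


def embed(pre: PreprocessedTraces) -> Embedding:
    """X = U S Vᵀ; the first two right singular vectors span the wave plane.

    Amplitude r_t = sqrt(v1_t² + v2_t²), phase θ_t = atan2(v2_t, v1_t)
    unwrapped by removing jumps greater than π.  Component signs are made
    deterministic (largest-|U| entry positive); the arbitrary overall
    orientation is resolved downstream by direction calibration.
    """
    X = pre.X
    if X.shape[1] < X.shape[0]:
        raise ValueError("need at least as many timepoints as segments")
    if not np.any(X):
        n = X.shape[1]
        zero = np.zeros(n)
        return Embedding(
            zero, zero.copy(), np.zeros(min(X.shape)), zero.copy(), zero.copy(),
            pre.frame_interval, pre.t_start,
        )
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for k in range(2):
        pivot = np.argmax(np.abs(U[:, k]))
        if U[pivot, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k] = -Vt[k]
    v1, v2 = Vt[0], Vt[1]
    amplitude = np.hypot(v1, v2)
    phase = np.unwrap(np.arctan2(v2, v1))
    return Embedding(v1, v2, S, amplitude, phase, pre.frame_interval, pre.t_start)


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

@dataclass
class WaveEvent:
    """A detected locomotor wave."""

    time: float  # seconds, amplitude-peak time
    direction: str  # "forward" | "backward"
    amplitude: float
    phase_slope: float  # radians / second


def _local_maxima(r: np.ndarray) -> np.ndarray:
    """Indices strictly greater than both neighbours (endpoints excluded)."""
    return np.flatnonzero((r[1:-1] > r[:-2]) & (r[1:-1] > r[2:])) + 1


def _greedy_separate(
    candidates: np.ndarray, amplitudes: np.ndarray, min_sep_frames: float
) -> list[int]:
    """Keep peaks in descending amplitude order, enforcing min separation."""
    order = np.argsort(amplitudes)[::-1]
    kept: list[int] = []
    for k in order:
        idx = candidates[k]
        if all(abs(idx - candidates[j]) >= min_sep_frames for j in kept):
            kept.append(k)
    return sorted(candidates[k] for k in kept)


def _phase_slope(
    phase: np.ndarray, peak: int, half_win_frames: int, frame_interval: float
) -> float:
    lo = max(0, peak - half_win_frames)
    hi = min(len(phase), peak + half_win_frames + 1)
    t = np.arange(lo, hi) * frame_interval
    y = phase[lo:hi]
    if len(t) < 2:
        return 0.0
    return float(np.polyfit(t, y, 1)[0])


def _segment_peak_order(
    segment_traces: TraceMatrix, t_event: float, half_window_s: float
) -> float:
    """Slope of segment peak time vs segment index inside the event window.

    Negative slope means the posterior segments (larger index) peak first,
    i.e. an anterior-progressing (forward) wave.
    """
    times = segment_traces.times()
    sel = (times >= t_event - half_window_s) & (times <= t_event + half_window_s)
    if sel.sum() < 3:
        return 0.0
    sub = segment_traces.data[:, sel]
    tsub = times[sel]
    peak_times = tsub[np.argmax(sub, axis=1)]
    seg_idx = np.arange(1, 9)
    return float(np.polyfit(seg_idx, peak_times, 1)[0])


def detect_waves(
    e: Embedding,
    amp_thresh: float = AMP_THRESHOLD,
    slope_thresh: float = SLOPE_THRESHOLD,
    min_sep: float = MIN_SEPARATION_S,
    slope_win: float = SLOPE_WINDOW_S,
    segment_traces: TraceMatrix | None = None,
    calibration_half_window_s: float = 10.0,
) -> list[WaveEvent]:
    """Detect locomotor waves as amplitude peaks with a coherent phase ramp.

    Candidate peaks are strict local maxima of the amplitude above
    ``amp_thresh``; peaks closer than ``min_sep`` are pruned greedily by
    descending amplitude.  Each surviving peak is assigned the least-squares
    slope of the unwrapped phase over a ``slope_win``-second window centred
    on it; peaks whose |slope| does not exceed ``slope_thresh`` are
    discarded.  The two slope-sign classes are mapped to forward/backward by
    the majority of segment peak orders inside the events (forward =
    posterior-to-anterior progression); without ``segment_traces`` the
    positive-slope class is labelled forward by convention.
    """
    if amp_thresh <= 0 or slope_thresh <= 0:
        raise ValueError("thresholds must be > 0")
    r = e.amplitude
    candidates = _local_maxima(r)
    candidates = candidates[r[candidates] > amp_thresh]
    if candidates.size == 0:
        return []
    min_sep_frames = min_sep / e.frame_interval
    kept = _greedy_separate(candidates, r[candidates], min_sep_frames)
    half_win = int(round(0.5 * slope_win / e.frame_interval))
    events: list[tuple[int, float]] = []
    for idx in kept:
        slope = _phase_slope(e.phase, idx, half_win, e.frame_interval)
        if abs(slope) > slope_thresh:
            events.append((idx, slope))
    if not events:
        return []

    times = e.times()
    sign_to_dir = {1: "forward", -1: "backward"}
    if segment_traces is not None:
        votes: dict[int, list[float]] = {1: [], -1: []}
        for idx, slope in events:
            order = _segment_peak_order(
                segment_traces, times[idx], calibration_half_window_s
            )
            if order != 0.0:
                votes[1 if slope > 0 else -1].append(order)
        # negative peak-order slope (posterior first) marks a forward wave
        pos_votes = votes[1]
        neg_votes = votes[-1]
        if pos_votes or neg_votes:
            pos_forward = np.mean([o < 0 for o in pos_votes]) if pos_votes else None
            neg_forward = np.mean([o < 0 for o in neg_votes]) if neg_votes else None
            if pos_forward is None:
                pos_forward = 1.0 - neg_forward
            if neg_forward is None:
                neg_forward = 1.0 - pos_forward
            if pos_forward >= neg_forward:
                sign_to_dir = {1: "forward", -1: "backward"}
            else:
                sign_to_dir = {1: "backward", -1: "forward"}

    return [
        WaveEvent(
            time=float(times[idx]),
            direction=sign_to_dir[1 if slope > 0 else -1],
            amplitude=float(r[idx]),
            phase_slope=slope,
        )
        for idx, slope in events
    ]


def detect_fictive_waves(
    traces: TraceMatrix,
    skip: float = SKIP_S,
    amp_thresh: float = AMP_THRESHOLD,
    slope_thresh: float = SLOPE_THRESHOLD,
    min_sep: float = MIN_SEPARATION_S,
    slope_win: float = SLOPE_WINDOW_S,
) -> list[WaveEvent]:
    """Full detection pipeline: preprocess → embed → detect + calibrate."""
    pre = preprocess_traces(traces, skip=skip)
    emb = embed(pre)
    segs = traces.segment_traces()
    return detect_waves(
        emb,
        amp_thresh=amp_thresh,
        slope_thresh=slope_thresh,
        min_sep=min_sep,
        slope_win=slope_win,
        segment_traces=segs,
    )


# ---------------------------------------------------------------------------
# evaluation against annotations and wave statistics
# ---------------------------------------------------------------------------

def evaluate_detection(
    detected: list[WaveEvent],
    annotated: list[tuple[float, str]],
    match_tol: float = 3.0,
) -> tuple[float, float]:
    """Hit and false-alarm rates against manual annotations.

    Detected and annotated events are matched greedily one-to-one by
    smallest time difference, requiring the same direction and |Δt| ≤
    ``match_tol``.  Returns (hit_rate, false_alarm_rate) as fractions; the
    hit rate is NaN when no annotations are given.
    """
    if match_tol <= 0:
        raise ValueError("match_tol must be > 0")
    if not annotated:
        return float("nan"), (0.0 if not detected else 1.0)
    pairs = []
    for i, ev in enumerate(detected):
        for j, (t, d) in enumerate(annotated):
            if ev.direction == d and abs(ev.time - t) <= match_tol:
                pairs.append((abs(ev.time - t), i, j))
    pairs.sort()
    used_d: set[int] = set()
    used_a: set[int] = set()
    for _, i, j in pairs:
        if i in used_d or j in used_a:
            continue
        used_d.add(i)
        used_a.add(j)
    hit = len(used_a) / len(annotated)
    fa = 0.0 if not detected else (len(detected) - len(used_d)) / len(detected)
    return hit, fa


# half-width of the window used to locate A1/A8 peaks around an event; wide
# enough for the longest waves of each direction, narrow enough to exclude
# neighbouring events
DURATION_WINDOW_S = {"forward": 11.5, "backward": 6.5}


def wave_statistics(
    events: list[WaveEvent],
    traces: TraceMatrix,
    analysed_duration_s: float | None = None,
    duration_half_window_s: float | dict[str, float] | None = None,
) -> dict[str, dict]:
    """Per-direction wave frequency (mHz) and duration statistics.

    Frequency is event count over the analysed recording length.  Duration
    of one wave is |peak(A1) − peak(A8)| of the left/right-averaged segment
    ΔF/F inside the event window.
    """
    if analysed_duration_s is None:
        analysed_duration_s = traces.n_frames * traces.frame_interval
    if duration_half_window_s is None:
        duration_half_window_s = DURATION_WINDOW_S
    segs = traces.segment_traces()
    times = segs.times()
    out: dict[str, dict] = {}
    for direction in ("forward", "backward"):
        half = (
            duration_half_window_s[direction]
            if isinstance(duration_half_window_s, dict)
            else duration_half_window_s
        )
        evs = [e for e in events if e.direction == direction]
        durations = []
        for e in evs:
            sel = (times >= e.time - half) & (times <= e.time + half)
            if sel.sum() < 2:
                continue
            tsub = times[sel]
            a1 = tsub[np.argmax(segs.trace("A1")[sel])]
            a8 = tsub[np.argmax(segs.trace("A8")[sel])]
            durations.append(abs(a1 - a8))
        durations = np.asarray(durations)
        out[direction] = {
            "count": len(evs),
            "frequency_mhz": 1000.0 * len(evs) / analysed_duration_s,
            "duration_mean_s": float(durations.mean()) if durations.size else float("nan"),
            "duration_sd_s": float(durations.std(ddof=1)) if durations.size > 1 else float("nan"),
            "durations_s": durations,
        }
    return out


def events_to_frame(events: list[WaveEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "time_s": e.time,
                "direction": e.direction,
                "amplitude": e.amplitude,
                "phase_slope": e.phase_slope,
            }
            for e in events
        ]
    )
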