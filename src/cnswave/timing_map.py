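"""Voxel-wise activity-timing maps from event-triggered statistics.

For every voxel, the ΔF/F traces triggered on N detected locomotor waves
(each of length T frames) are summarized by their per-offset mean μ_t and
population variance v_t, accumulated online (Welford) so arbitrarily many
events fit in constant memory.  Two nested models are then fit by least
squares:

* a *rectangular* (time-locked) model — level λ1 inside a box window
  w(τ) = [τ−r, τ+r] and λ0 ≤ λ1 outside it;
* a *flat* model — a single level λ.

Because the optimal λ's for a given τ are window means, the optimal box
centre τ* is simply the peak of the convolution of μ_t with a box filter of
length 2r+1, and the mean-squared errors decompose into variance plus
mean-deviation terms:

    E_time = (1/T) [ Σ_t v_t + Σ_{t∈w}(μ_t−λ1)² + Σ_{t∉w}(μ_t−λ0)² ]
    E_flat = (1/T) [ Σ_t v_t + Σ_t (μ_t−λ)² ]

The per-voxel map reports τ* (when activity rises during the event window)
and the RMSE improvement sqrt(E_flat) − sqrt(E_time) ("information gain",
how strongly the voxel is time-locked to the event).  Under the λ0 ≤ λ1
constraint the box-filter argmax is exactly the constrained least-squares
optimum: the windowed-mean objective is monotone in the windowed sum on the
feasible side, and every infeasible centre collapses to the flat fit.

A paired exact sign test compares per-event peak times between two regions
(e.g. dorsal versus ventral neuropil).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np
from scipy import stats as sstats

from .errors import EmptyStatsError
from .wave_detection import WaveEvent

logger = logging.getLogger(__name__)

# triggered-window extents, seconds relative to the wave event
FORWARD_WINDOW = (-10.0, 10.0)
BACKWARD_WINDOW = (-6.0, 2.0)
SOMA_WINDOW = (-8.0, 8.0)


@dataclass
class TriggeredStats:
    """Streaming per-offset mean/variance of event-triggered traces.

    ``mean`` and ``m2`` have shape ``leading_shape + (T,)`` where the leading
    shape is the voxel grid (or empty for a single trace).  The variance
    divisor is N (population), which makes the least-squares error
    decomposition exact.
    """

    n: int
    mean: np.ndarray
    m2: np.ndarray
    window: tuple[float, float]
    frame_interval: float

    @property
    def T(self) -> int:
        return self.mean.shape[-1]

    @property
    def pre_frames(self) -> int:
        return int(round(-self.window[0] / self.frame_interval))

    @property
    def var(self) -> np.ndarray:
        return self.m2 / self.n

    def offsets_s(self) -> np.ndarray:
        """Window offsets in seconds relative to the trigger."""
        return (np.arange(self.T) - self.pre_frames) * self.frame_interval

    @property
    def sem(self) -> np.ndarray:
        return np.sqrt(self.var / self.n)


def _welford_init(shape: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    return np.zeros(shape), np.zeros(shape)


def select_triggered_events(
    events: list[WaveEvent],
    direction: str | None,
    window: tuple[float, float],
    n_frames: int,
    frame_interval: float,
) -> list[WaveEvent]:
    """Events of one direction whose windows fit in-bounds and do not overlap.

    Events whose window would run past the recording bounds are discarded,
    as are events whose window overlaps a neighbouring selected-direction
    event's window (both members of an overlapping pair are dropped, so the
    retained triggered windows are disjoint).
    """
    evs = sorted(
        (e for e in events if direction is None or e.direction == direction),
        key=lambda e: e.time,
    )
    span = window[1] - window[0]
    keep = []
    for i, e in enumerate(evs):
        f0 = int(round(e.time / frame_interval)) + int(round(window[0] / frame_interval))
        f1 = f0 + int(round(span / frame_interval))
        if f0 < 0 or f1 >= n_frames:
            logger.info("event at %.1f s discarded: window out of bounds", e.time)
            continue
        prev_ok = i == 0 or (e.time - evs[i - 1].time) >= span
        next_ok = i == len(evs) - 1 or (evs[i + 1].time - e.time) >= span
        if not (prev_ok and next_ok):
            logger.info("event at %.1f s discarded: window overlap", e.time)
            continue
        keep.append(e)
    return keep


def accumulate_triggered(
    series,
    events: list[WaveEvent],
    direction: str | None = None,
    window: tuple[float, float] = FORWARD_WINDOW,
) -> TriggeredStats:
    """Accumulate per-voxel triggered mean/variance over usable events.

    ``series`` needs ``n_frames``, ``frame_interval``, ``spatial_shape`` and
    ``time_slice(start, stop)`` — satisfied by
    :class:`~cnswave.volume_io.VolumeSeries` and by lazily rendered phantom
    series, so recordings never need to be memory-resident.
    """
    dt = series.frame_interval
    pre = int(round(-window[0] / dt))
    post = int(round(window[1] / dt))
    T = pre + post + 1
    usable = select_triggered_events(
        events, direction, window, series.n_frames, dt
    )
    if not usable:
        raise EmptyStatsError("no usable triggered events")
    shape = tuple(series.spatial_shape) + (T,)
    mean, m2 = _welford_init(shape)
    n = 0
    for e in usable:
        f = int(round(e.time / dt))
        x = np.asarray(series.time_slice(f - pre, f - pre + T), dtype=float)
        n += 1
        delta = x - mean
        mean += delta / n
        m2 += delta * (x - mean)
    return TriggeredStats(n=n, mean=mean, m2=m2, window=window, frame_interval=dt)


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

@dataclass
class TimeFit:
    """Per-voxel rectangular-model fit.

    ``tau`` is the optimal box centre as a 0-based frame offset within the
    triggered window; ``collapsed`` flags voxels where the best box was a dip
    (λ1 < λ0) and the fit fell back to the flat model.
    """

    tau: np.ndarray
    radius: int
    lambda0: np.ndarray
    lambda1: np.ndarray
    E_time: np.ndarray
    collapsed: np.ndarray


def fit_flat_model(stats: TriggeredStats) -> tuple[np.ndarray, np.ndarray]:
    """Flat-model level and error: λ = mean_t μ_t, E_flat = total variance."""
    mu = stats.mean
    lam = mu.mean(axis=-1)
    E_flat = stats.var.mean(axis=-1) + ((mu - lam[..., None]) ** 2).mean(axis=-1)
    return lam, E_flat


def fit_time_model(stats: TriggeredStats, radius: int) -> TimeFit:
    """Constrained least-squares fit of the rectangular model.

    τ* is the argmax of the (2r+1)-box-filtered mean trace over centres
    where the full window fits (ties → smallest index); λ1/λ0 are the means
    inside/outside w(τ*).  When λ1 < λ0 the voxel collapses to the flat fit
    (λ0 = λ1 = overall mean, zero gain).
    """
    T = stats.T
    W = 2 * radius + 1
    if T < W:
        raise ValueError(f"window of {W} frames does not fit in T={T}")
    mu = stats.mean
    lead = mu.shape[:-1]
    mu2d = mu.reshape(-1, T)
    var2d = stats.var.reshape(-1, T)

    csum = np.concatenate(
        [np.zeros((mu2d.shape[0], 1)), np.cumsum(mu2d, axis=1)], axis=1
    )
    csum2 = np.concatenate(
        [np.zeros((mu2d.shape[0], 1)), np.cumsum(mu2d**2, axis=1)], axis=1
    )
    # windowed sums for every valid centre tau in [radius, T-1-radius]
    win_sums = csum[:, W:] - csum[:, : T - W + 1]  # shape (M, T-W+1)
    best = np.argmax(win_sums, axis=1)  # first index on ties
    tau = best + radius
    rows = np.arange(mu2d.shape[0])
    s_in = win_sums[rows, best]
    s2_in = csum2[rows, best + W] - csum2[rows, best]
    total = csum[:, -1]
    total2 = csum2[:, -1]
    lam1 = s_in / W
    n_out = T - W
    if n_out > 0:
        lam0 = (total - s_in) / n_out
    else:
        lam0 = lam1.copy()
    sse_in = s2_in - W * lam1**2
    sse_out = (total2 - s2_in) - n_out * lam0**2 if n_out > 0 else np.zeros_like(s2_in)
    E_time = (var2d.sum(axis=1) + sse_in + sse_out) / T

    lam_flat = total / T
    E_flat = (var2d.sum(axis=1) + total2 - T * lam_flat**2) / T
    collapsed = lam1 < lam0
    lam0 = np.where(collapsed, lam_flat, lam0)
    lam1 = np.where(collapsed, lam_flat, lam1)
    E_time = np.where(collapsed, E_flat, E_time)
    # collapsed voxels have no preferred centre; the tie rule (smallest
    # valid index) keeps the fit identical to exhaustive least squares
    tau = np.where(collapsed, radius, tau)
    # guard against negative rounding in the sum-of-squares differences
    E_time = np.maximum(E_time, 0.0)

    return TimeFit(
        tau=tau.reshape(lead),
        radius=radius,
        lambda0=lam0.reshape(lead),
        lambda1=lam1.reshape(lead),
        E_time=E_time.reshape(lead),
        collapsed=collapsed.reshape(lead),
    )


@dataclass
class TimingMap:
    """Per-voxel timing (τ* in seconds relative to trigger), RMSE gain and
    fit levels."""

    tau_s: np.ndarray
    gain: np.ndarray
    lambda0: np.ndarray
    lambda1: np.ndarray
    radius: int
    window: tuple[float, float]
    frame_interval: float
    n_events: int
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("tau_s", "gain", "lambda0", "lambda1"):
                d = f.create_dataset(name, data=getattr(self, name))
                d.attrs["voxel_size"] = self.voxel_size
            f.attrs["radius"] = self.radius
            f.attrs["window"] = self.window
            f.attrs["frame_interval"] = self.frame_interval
            f.attrs["n_events"] = self.n_events


def build_timing_map(
    series,
    events: list[WaveEvent],
    direction: str | None = None,
    window: tuple[float, float] = FORWARD_WINDOW,
    radius: int | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> TimingMap:
    """Whole-volume timing map: triggered stats → per-voxel fits → gain.

    ``radius`` defaults to one second's worth of frames.  The gain map
    sqrt(E_flat) − sqrt(E_time) is non-negative because the rectangular
    family nests the flat model.
    """
    stats = accumulate_triggered(series, events, direction, window)
    if radius is None:
        radius = max(1, int(round(1.0 / series.frame_interval)))
    fit = fit_time_model(stats, radius)
    _, E_flat = fit_flat_model(stats)
    gain = np.sqrt(E_flat) - np.sqrt(fit.E_time)
    gain = np.maximum(gain, 0.0)
    tau_s = (fit.tau - stats.pre_frames) * stats.frame_interval
    return TimingMap(
        tau_s=tau_s,
        gain=gain,
        lambda0=fit.lambda0,
        lambda1=fit.lambda1,
        radius=radius,
        window=window,
        frame_interval=stats.frame_interval,
        n_events=stats.n,
        voxel_size=voxel_size or getattr(series, "voxel_size", (1.0, 1.0, 1.0)),
    )


def compare_peak_timing(
    peaksA: np.ndarray, peaksB: np.ndarray
) -> tuple[int, float]:
    """Two-sided exact sign test on paired per-event peak times.

    Returns the number of events where A peaks earlier than B and the exact
    binomial two-sided p-value; ties are dropped.  With all pairs tied the
    p-value is NaN (undefined).
    """
    a = np.asarray(peaksA, dtype=float)
    b = np.asarray(peaksB, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired observations required")
    diffs = b - a
    diffs = diffs[diffs != 0]
    n = diffs.size
    if n == 0:
        return 0, float("nan")
    k = int((diffs > 0).sum())
    p = sstats.binomtest(k, n, 0.5).pvalue
    return k, float(p)
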