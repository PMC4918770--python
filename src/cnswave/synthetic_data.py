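"""Ground-truthed CNS phantoms for exercising the whole pipeline.

The phantom emulates an isolated larval CNS explant imaged from two opposing
cameras: a ventral nerve cord of eight bilateral abdominal segment pairs
(A1 anterior … A8 posterior), two brain lobes and a suboesophageal ganglion
(SOG), all connected through a neuropil core so the specimen is a single
connected component.  A stochastic schedule of forward (posterior→anterior)
and backward (anterior→posterior) locomotor waves drives per-voxel boxcar
activity convolved with a GCaMP-like rise/decay kernel; rendering adds
per-voxel Gaussian noise, per-view depth attenuation, optional global drift,
and mirrors view B along the detection axis.

Default wave statistics follow the embedded-preparation values measured for
fictive crawling: durations 9.3 ± 3.7 s (forward) and 4.7 ± 1.1 s
(backward), frequencies 9.5 and 15.5 mHz.  Scripted somata in brain/SOG
reproduce the four peak-timing activity classes.

Everything derives deterministically from ``PhantomConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats as sstats

from .errors import DegenerateInputError
from .volume_io import ForegroundModel, VolumeSeries, path_lengths
from .wave_detection import RoiSet, TraceMatrix, WaveEvent

logger = logging.getLogger(__name__)


@dataclass
class PhantomConfig:
    """Study conditions for the synthetic CNS recording."""

    shape: tuple[int, int, int] = (160, 64, 32)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 6.0)  # micrometres
    frame_rate: float = 5.0  # Hz
    duration: float = 600.0  # seconds
    n_segments: int = 8
    forward_duration_mean: float = 9.3
    forward_duration_sd: float = 3.7
    backward_duration_mean: float = 4.7
    backward_duration_sd: float = 1.1
    forward_rate_mhz: float = 9.5
    backward_rate_mhz: float = 15.5
    n_forward: int | None = None  # fixed event counts override the rates
    n_backward: int | None = None
    schedule_start_s: float | None = None
    refractory_s: float = 20.0  # >= the largest triggered-window span
    amplitude: float = 1.0  # peak ΔF/F of a typical wave
    dwell_fraction: float = 0.5  # per-segment active time as fraction of duration
    recruit_floor: float = 0.2  # relative drive of the leading segment
    recruit_exponent: float = 2.0  # recruitment growth along the path
    vigor_timescale_s: float = 4.0  # short waves are proportionally stronger
    backward_amplitude_factor: float = 1.35  # backward waves are more vigorous
    noise_sd: float = 0.1  # per-voxel, ΔF/F units
    baseline: float = 100.0  # resting fluorescence, counts
    rise_s: float = 0.2  # GCaMP-like kinetics
    decay_s: float = 1.8
    attenuation_length_um: float = 60.0
    drift_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_somata: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.forward_rate_mhz < 0 or self.backward_rate_mhz < 0:
            raise ValueError("rates must be >= 0")
        if self.forward_duration_mean <= 0 or self.backward_duration_mean <= 0:
            raise ValueError("durations must be > 0")

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class SimEvent:
    time: float  # wave midpoint, seconds
    direction: str
    duration: float  # seconds, A8↔A1 propagation span


@dataclass
class GroundTruth:
    """Everything the renderer consumed, for downstream evaluation."""

    events: list[SimEvent]
    drift: np.ndarray  # (n_frames, 3) cumulative voxel shifts
    soma_classes: dict[str, tuple[int, int]]  # label -> (forward, backward)
    config: PhantomConfig

    def annotations(self, t_min: float = 0.0) -> list[tuple[float, str]]:
        """(time, direction) pairs usable as manual-annotation stand-ins."""
        return [(e.time, e.direction) for e in self.events if e.time >= t_min]

    def wave_events(self, t_min: float = 0.0) -> list[WaveEvent]:
        return [
            WaveEvent(time=e.time, direction=e.direction, amplitude=1.0, phase_slope=0.0)
            for e in self.events
            if e.time >= t_min
        ]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class Phantom:
    labels: np.ndarray  # int volume; 0 background
    rois: RoiSet
    fg: ForegroundModel
    label_map: dict[int, str]
    soma_regions: dict[str, str]
    segment_x: dict[str, tuple[int, int]]  # segment -> inclusive x range
    vnc_y: dict[str, tuple[int, int]]  # side -> inclusive y range
    config: PhantomConfig

    @property
    def x_c1(self) -> float:
        x0, x1 = self.segment_x["A1"]
        return 0.5 * (x0 + x1)

    @property
    def x_c8(self) -> float:
        x0, x1 = self.segment_x["A8"]
        return 0.5 * (x0 + x1)

    def vnc_mask(self) -> np.ndarray:
        m = np.zeros(self.labels.shape, dtype=bool)
        for value, name in self.label_map.items():
            if name.startswith("A"):
                m |= self.labels == value
        return m


def make_phantom(cfg: PhantomConfig) -> Phantom:
    """Build the CNS-like label geometry, hemisegment ROIs and foreground.

    Proportions follow the default 160 × 64 × 32 grid and scale with the
    requested shape; shapes too small to hold eight segment pairs raise.
    """
    nx, ny, nz = cfg.shape
    if nx < 80 or ny < 32 or nz < 16:
        raise DegenerateInputError(f"shape {cfg.shape} too small for the CNS layout")
    sx, sy, sz = nx / 160.0, ny / 64.0, nz / 32.0
    labels = np.zeros(cfg.shape, dtype=np.int16)
    label_map: dict[int, str] = {}

    def box(x0, x1, y0, y1, z0, z1):
        return (
            slice(int(round(x0 * sx)), int(round(x1 * sx)) + 1),
            slice(int(round(y0 * sy)), int(round(y1 * sy)) + 1),
            slice(int(round(z0 * sz)), int(round(z1 * sz)) + 1),
        )

    # neuropil core connecting brain, SOG and the segment blocks
    NEUROPIL, BRAIN, SOG = 19, 17, 18
    labels[box(30, 141, 28, 35, 12, 19)] = NEUROPIL
    label_map[NEUROPIL] = "neuropil"

    xx, yy, zz = np.mgrid[0:nx, 0:ny, 0:nz]
    for cx, cy, cz in ((24, 20, 16), (24, 44, 16)):
        r = 11.0
        sphere = (
            ((xx - cx * sx) / (r * sx)) ** 2
            + ((yy - cy * sy) / (r * sy)) ** 2
            + ((zz - cz * sz) / (r * sz)) ** 2
        ) <= 1.0
        labels[sphere] = BRAIN
    label_map[BRAIN] = "brain"
    labels[box(30, 49, 24, 39, 10, 21)] = SOG
    label_map[SOG] = "SOG"

    segment_x: dict[str, tuple[int, int]] = {}
    vnc_y = {"L": (int(round(22 * sy)), int(round(27 * sy))),
             "R": (int(round(36 * sy)), int(round(41 * sy)))}
    z0, z1 = int(round(10 * sz)), int(round(21 * sz))
    value = 1
    for k in range(1, 9):
        x0 = int(round((52 + 11 * (k - 1)) * sx))
        x1 = int(round((52 + 11 * (k - 1) + 9) * sx))
        segment_x[f"A{k}"] = (x0, x1)
        for side in ("L", "R"):
            y0, y1 = vnc_y[side]
            labels[x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1] = value
            label_map[value] = f"A{k}{side}"
            value += 1

    # scripted somata: small spheres inside brain/SOG, away from each other
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    soma_regions: dict[str, str] = {}
    host = (labels == BRAIN) | (labels == SOG)
    eroded = ndimage.binary_erosion(host, iterations=2)
    candidates = np.argwhere(eroded)
    if len(candidates) == 0:
        raise DegenerateInputError("brain/SOG too small to host somata")
    placed: list[np.ndarray] = []
    chosen: list[tuple[np.ndarray, str]] = []
    for separation in (5, 3, 2, 1):  # relax spacing on small grids
        placed.clear()
        chosen.clear()
        guard = 0
        while len(chosen) < cfg.n_somata and guard < 20000:
            guard += 1
            c = candidates[rng.integers(len(candidates))]
            if any(np.abs(c - p).max() <= separation for p in placed):
                continue
            region = "SOG" if labels[tuple(c)] == SOG else "brain"
            placed.append(c)
            chosen.append((c, region))
        if len(chosen) == cfg.n_somata:
            break
    if len(chosen) < cfg.n_somata:
        raise DegenerateInputError("could not place all somata")
    soma_value = 100
    for i, (c, region) in enumerate(chosen):
        sphere = (
            (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + ((zz - c[2]) * 2) ** 2
        ) <= 4.0
        name = f"soma_{i:02d}"
        labels[sphere & host] = soma_value
        label_map[soma_value] = name
        soma_regions[name] = region
        soma_value += 1

    rois = RoiSet.from_label_volume(labels, label_map)
    mask = labels > 0
    fg = ForegroundModel(
        mask=mask,
        path_length={
            "A": path_lengths(mask, 2, cfg.voxel_size, reverse=False),
            "B": path_lengths(mask, 2, cfg.voxel_size, reverse=True),
        },
        detection_axis=2,
    )
    return Phantom(
        labels=labels,
        rois=rois,
        fg=fg,
        label_map=label_map,
        soma_regions=soma_regions,
        segment_x=segment_x,
        vnc_y=vnc_y,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# event schedule
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, n):
    """Durations are normal, truncated at ±2 SD and never below 2 s — a
    locomotor wave cannot sweep eight segments in under a couple of seconds.
    The symmetric truncation preserves the configured mean."""
    if sd == 0 or n == 0:
        return np.full(n, mean)
    lo = max(2.0, mean - 2 * sd)
    hi = mean + 2 * sd
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sstats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_schedule(cfg: PhantomConfig) -> GroundTruth:
    """Draw the wave schedule: renewal event times with a refractory gap.

    With rates configured, inter-event intervals per direction are a
    refractory gap plus an exponential tail whose mean preserves the
    configured rate; the merged stream drops events violating the global
    gap.  With fixed counts (``n_forward``/``n_backward``), events alternate
    direction and are jittered around even spacing while honouring the gap,
    which guarantees the requested counts — the variant used when a study
    needs an exact number of triggered windows.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    start = cfg.refractory_s if cfg.schedule_start_s is None else cfg.schedule_start_s
    end = cfg.duration - cfg.refractory_s
    raw: list[tuple[float, str]] = []

    if cfg.n_forward is not None or cfg.n_backward is not None:
        nf = cfg.n_forward or 0
        nb = cfg.n_backward or 0
        n = nf + nb
        if n > 0:
            if n == 1:
                times = np.array([(start + end) / 2])
            else:
                spacing = (end - start) / (n - 1)
                if spacing < cfg.refractory_s:
                    raise DegenerateInputError(
                        "recording too short for the requested event count"
                    )
                jitter = 0.5 * (spacing - cfg.refractory_s)
                times = start + spacing * np.arange(n) + rng.uniform(
                    -jitter, jitter, size=n
                )
            dirs = ["forward"] * nf + ["backward"] * nb
            order = rng.permutation(n)
            dirs = [dirs[j] for j in order]
            raw = list(zip(times, dirs))
    else:
        # one merged renewal stream at the combined rate (refractory gap plus
        # an exponential tail whose mean preserves the configured total
        # rate), with directions drawn by their rate ratio — so each
        # direction's expected count matches its configured frequency
        total = cfg.forward_rate_mhz + cfg.backward_rate_mhz
        if total > 0:
            mean_iv = 1000.0 / total
            tail = max(mean_iv - cfg.refractory_s, 1e-3)
            p_forward = cfg.forward_rate_mhz / total
            t = start + rng.exponential(tail)
            while t < end:
                d = "forward" if rng.random() < p_forward else "backward"
                raw.append((t, d))
                t += cfg.refractory_s + rng.exponential(tail)

    raw.sort()
    nf = sum(d == "forward" for _, d in raw)
    nb = len(raw) - nf
    durf = _truncated_normal(rng, cfg.forward_duration_mean, cfg.forward_duration_sd, nf)
    durb = _truncated_normal(rng, cfg.backward_duration_mean, cfg.backward_duration_sd, nb)
    fi, bi = 0, 0
    events = []
    for t, d in raw:
        if d == "forward":
            dur = durf[fi]
            fi += 1
        else:
            dur = durb[bi]
            bi += 1
        events.append(SimEvent(time=float(t), direction=d, duration=float(dur)))

    drift = np.outer(np.arange(cfg.n_frames), np.asarray(cfg.drift_per_frame, float))
    soma_classes = {
        f"soma_{i:02d}": ((i % 4) + 1, ((i // 4) % 4) + 1)
        for i in range(cfg.n_somata)
    }
    return GroundTruth(events=events, drift=drift, soma_classes=soma_classes, config=cfg)


# ---------------------------------------------------------------------------
# forward model (activity and fluorescence)
# ---------------------------------------------------------------------------

def _kinetic_kernel(cfg: PhantomConfig, dt: float) -> np.ndarray:
    """Difference-of-exponentials indicator kernel, truncated at 1e-3."""
    t_max = cfg.decay_s * np.log(1e3) + cfg.rise_s
    t = np.arange(0.0, t_max, dt)
    k = np.exp(-t / cfg.decay_s) - np.exp(-t / cfg.rise_s)
    return k


def _event_response(cfg: PhantomConfig, duration: float, dt: float) -> np.ndarray:
    """Normalized single-voxel ΔF/F response to one wave passing through.

    The drive is a raised-cosine burst whose dwell is a fixed fraction of
    the wave duration (adjacent segments are co-active, as in recorded
    average waves), convolved with the indicator kernel and normalized to
    unit peak.
    """
    dwell = _dwell_s(cfg, duration, dt)
    n = max(1, int(round(dwell / dt)))
    env = np.hanning(n + 2)[1:-1]
    resp = np.convolve(env, _kinetic_kernel(cfg, dt))
    peak = resp.max()
    return resp / peak if peak > 0 else resp


def _dwell_s(cfg: PhantomConfig, duration: float, dt: float) -> float:
    return max(duration * cfg.dwell_fraction, 2 * dt)


def _event_amplitude(cfg: PhantomConfig, e: SimEvent) -> float:
    """Peak ΔF/F of one wave: shorter waves are proportionally stronger
    (vigour grows with propagation speed) and backward waves are more
    vigorous than forward waves, so both wave modes carry comparable energy
    in the population trajectory."""
    vigor = np.sqrt((e.duration + cfg.vigor_timescale_s) / e.duration)
    base = cfg.amplitude * vigor
    if e.direction == "backward":
        base *= cfg.backward_amplitude_factor
    return float(base)


def _recruit_gain(cfg: PhantomConfig, frac: np.ndarray) -> np.ndarray:
    """Relative drive as a function of position along the propagation path
    (0 = leading segment, 1 = trailing): activity is recruited progressively
    as the wave travels, so each wave grows toward its terminal segment."""
    return cfg.recruit_floor + (1.0 - cfg.recruit_floor) * frac**cfg.recruit_exponent


def activation_offset(
    x: np.ndarray | float, direction: str, duration: float, phantom: Phantom
) -> np.ndarray | float:
    """Activation-midpoint offset (s) of column x relative to the wave midpoint.

    Forward waves start at A8 (offset −duration/2) and end at A1
    (+duration/2); backward waves are reversed.  The interior segments
    A2–A7 are interpolated linearly between the A8 and A1 segment centres;
    the terminal segments activate as units at the endpoints (the wave
    ignites in, and terminates by recruiting, a whole segment), so their
    ROI-averaged peak times are exactly the scheduled endpoints.
    """
    x8, x1 = phantom.x_c8, phantom.x_c1
    x_arr = np.asarray(x, dtype=float)
    frac = np.clip((x8 - x_arr) / (x8 - x1), 0.0, 1.0)
    a1_lo, a1_hi = phantom.segment_x["A1"]
    a8_lo, a8_hi = phantom.segment_x["A8"]
    frac = np.where((x_arr >= a1_lo) & (x_arr <= a1_hi), 1.0, frac)
    frac = np.where((x_arr >= a8_lo) & (x_arr <= a8_hi), 0.0, frac)
    if direction == "backward":
        frac = 1.0 - frac
    return duration * (frac - 0.5)


def column_traces(
    phantom: Phantom, truth: GroundTruth, cfg: PhantomConfig
) -> np.ndarray:
    """Noise-free ΔF/F trace per x-column of the nerve cord, shape (nx, T).

    Activation onsets are quantized to the frame grid; every voxel sharing an
    x-column carries the same trace (the wave front is a plane normal to the
    anterior–posterior axis).
    """
    dt = cfg.frame_interval
    T = cfg.n_frames
    nx = cfg.shape[0]
    C = np.zeros((nx, T))
    x_lo = phantom.segment_x["A1"][0]
    x_hi = phantom.segment_x["A8"][1]
    cols = np.arange(x_lo, x_hi + 1)
    for e in truth.events:
        resp = _event_amplitude(cfg, e) * _event_response(cfg, e.duration, dt)
        dwell = _dwell_s(cfg, e.duration, dt)
        offs = np.asarray(activation_offset(cols, e.direction, e.duration, phantom))
        gains = _recruit_gain(cfg, offs / e.duration + 0.5)
        onset_frames = np.round((e.time + offs - dwell / 2) / dt).astype(int)
        for x, f0, g in zip(cols, onset_frames, gains):
            a = max(f0, 0)
            b = min(f0 + len(resp), T)
            if b > a:
                C[x, a:b] += g * resp[a - f0 : b - f0]
    return C


def expected_column_peak_offsets(
    phantom: Phantom,
    truth: GroundTruth,
    cfg: PhantomConfig,
    direction: str,
    events: list[SimEvent] | None = None,
    box_radius: int | None = None,
) -> dict[int, float]:
    """Scheduled per-column fluorescence-peak offsets (s relative to trigger).

    Replays the noise-free forward model per event and averages the response
    argmax offsets — the timing a perfect estimator should recover.  The
    indicator kernel's group delay is part of this expectation because the
    timing statistic measures when *fluorescence* rises.  When the estimate
    being evaluated is a box-window centre, pass its ``box_radius`` so the
    expectation is the peak of the box-filtered response (for an asymmetric
    indicator response the optimal box centre sits slightly after the raw
    peak).
    """
    dt = cfg.frame_interval
    evs = [e for e in (events or truth.events) if e.direction == direction]
    x_lo = phantom.segment_x["A1"][0]
    x_hi = phantom.segment_x["A8"][1]
    cols = np.arange(x_lo, x_hi + 1)
    acc = {int(x): [] for x in cols}
    for e in evs:
        resp = _event_response(cfg, e.duration, dt)
        if box_radius:
            w = 2 * box_radius + 1
            filt = np.convolve(resp, np.ones(w) / w, mode="full")
            ia = int(np.argmax(filt)) - box_radius
        else:
            ia = int(np.argmax(resp))
        dwell = _dwell_s(cfg, e.duration, dt)
        offs = np.asarray(activation_offset(cols, e.direction, e.duration, phantom))
        onset_frames = np.round((e.time + offs - dwell / 2) / dt).astype(int)
        for x, f0 in zip(cols, onset_frames):
            acc[int(x)].append((f0 + ia) * dt - e.time)
    return {x: float(np.mean(v)) for x, v in acc.items() if v}


def _event_interval_rel(cfg: PhantomConfig, e: SimEvent) -> tuple[float, float]:
    """Propagation interval endpoints relative to the event time, in
    fluorescence-peak terms (A8/A1 response peaks)."""
    dt = cfg.frame_interval
    resp = _event_response(cfg, e.duration, dt)
    delta = np.argmax(resp) * dt - _dwell_s(cfg, e.duration, dt) / 2
    return -e.duration / 2 + delta, e.duration / 2 + delta


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def soma_traces(
    phantom: Phantom, truth: GroundTruth, cfg: PhantomConfig
) -> tuple[list[str], np.ndarray]:
    """Noise-free ΔF/F traces for the scripted somata, shape (n_somata, T).

    Per event, each soma expresses its scripted peak-timing class relative to
    that event's propagation interval: class 1 peaks before the interval,
    class 2 at its centre, class 3 after it, and class 4 shows two peaks
    flanking a quiescent phase (trough well below half of both peaks).
    """
    dt = cfg.frame_interval
    t = np.arange(cfg.n_frames) * dt
    names = sorted(truth.soma_classes)
    out = np.zeros((len(names), cfg.n_frames))
    for e in truth.events:
        t0, t1 = _event_interval_rel(cfg, e)
        t0 += e.time
        t1 += e.time
        mid = 0.5 * (t0 + t1)
        sel = (t >= e.time - 12.0) & (t <= e.time + 12.0)
        ts = t[sel]
        for i, name in enumerate(names):
            cls = truth.soma_classes[name][0 if e.direction == "forward" else 1]
            # single-peak classes use broad bumps so that averaging over
            # events with variable durations stays unimodal
            if cls == 1:
                y = _gauss(ts, t0 - 2.5, 1.5)
            elif cls == 2:
                y = _gauss(ts, mid, 1.5)
            elif cls == 3:
                y = _gauss(ts, t1 + 2.5, 1.5)
            else:
                half = max(2.0, (t1 - t0) / 2)
                y = _gauss(ts, mid - half, 0.8) + _gauss(ts, mid + half, 0.8)
            out[i, sel] += cfg.amplitude * y
    return names, out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _scatter_dff(
    phantom: Phantom,
    C: np.ndarray,
    soma_names: list[str],
    S: np.ndarray,
    frames: slice,
) -> np.ndarray:
    """Assemble the ΔF/F volume for a frame range from column/soma traces."""
    nf = frames.stop - frames.start
    out = np.zeros(phantom.labels.shape + (nf,), dtype=np.float32)
    vnc = phantom.vnc_mask()
    xs = np.argwhere(vnc)[:, 0]
    out[vnc] = C[xs, frames].astype(np.float32)
    for name, trace in zip(soma_names, S):
        value = next(v for v, n in phantom.label_map.items() if n == name)
        out[phantom.labels == value] = trace[frames].astype(np.float32)
    return out


def render(
    phantom: Phantom, truth: GroundTruth, cfg: PhantomConfig
) -> tuple[VolumeSeries, VolumeSeries, VolumeSeries]:
    """Render the two camera views and the noise-free ΔF/F ground truth.

    F = F0·(1 + ΔF/F) inside the specimen; each view is attenuated by
    exp(−path/attenuation_length) along its detection path, Gaussian noise of
    ``noise_sd`` ΔF/F units is added, global drift is applied, and view B is
    mirrored along the detection axis.  Intended for modest phantom sizes;
    long recordings are consumed through :class:`LazyDffSeries` and
    :func:`simulate_roi_traces` instead.
    """
    dt = cfg.frame_interval
    T = cfg.n_frames
    C = column_traces(phantom, truth, cfg)
    names, S = soma_traces(phantom, truth, cfg)
    dff = _scatter_dff(phantom, C, names, S, slice(0, T))

    mask = phantom.fg.mask
    f0 = np.where(mask, cfg.baseline, 0.0).astype(np.float32)
    attA = np.where(
        mask, np.exp(-np.nan_to_num(phantom.fg.path_length["A"]) / cfg.attenuation_length_um), 1.0
    ).astype(np.float32)
    attB = np.where(
        mask, np.exp(-np.nan_to_num(phantom.fg.path_length["B"]) / cfg.attenuation_length_um), 1.0
    ).astype(np.float32)

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 37]))
    views = []
    for att, tag in ((attA, "A"), (attB, "B")):
        F = att[..., None] * f0[..., None] * (1.0 + dff)
        if cfg.noise_sd > 0:
            F = F + att[..., None] * f0[..., None] * cfg.noise_sd * rng.standard_normal(
                F.shape, dtype=np.float32
            )
        if np.any(truth.drift):
            for ti in range(T):
                shift = truth.drift[ti]
                if np.any(shift):
                    F[..., ti] = ndimage.shift(
                        F[..., ti], shift, order=1, mode="constant", cval=0.0
                    )
        np.maximum(F, 0.0, out=F)
        views.append(F)
    viewA = VolumeSeries(views[0], cfg.voxel_size, dt, view_id="A")
    viewB = VolumeSeries(
        np.flip(views[1], axis=2).copy(), cfg.voxel_size, dt, view_id="B"
    )
    dff_truth = VolumeSeries(dff, cfg.voxel_size, dt, view_id="truth")
    return viewA, viewB, dff_truth


class LazyDffSeries:
    """Frame-on-demand noisy ΔF/F phantom recording.

    Provides the same access surface as a memory-resident
    :class:`~cnswave.volume_io.VolumeSeries` (``spatial_shape``,
    ``n_frames``, ``frame_interval``, ``time_slice``) but materializes only
    the requested frames, so event-triggered accumulation over long
    recordings stays within a small memory footprint.  Noise is seeded per
    absolute frame index, making the recording deterministic regardless of
    the access pattern.
    """

    def __init__(self, phantom: Phantom, truth: GroundTruth, cfg: PhantomConfig):
        self.phantom = phantom
        self.truth = truth
        self.cfg = cfg
        self._C = column_traces(phantom, truth, cfg)
        names, S = soma_traces(phantom, truth, cfg)
        self._soma_names = names
        self._S = S
        self._vnc = phantom.vnc_mask()
        self._xs = np.argwhere(self._vnc)[:, 0]
        self._soma_masks = [
            phantom.labels == next(v for v, n in phantom.label_map.items() if n == name)
            for name in names
        ]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.cfg.shape

    @property
    def n_frames(self) -> int:
        return self.cfg.n_frames

    @property
    def frame_interval(self) -> float:
        return self.cfg.frame_interval

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.cfg.voxel_size

    def time_slice(self, start: int, stop: int) -> np.ndarray:
        nf = stop - start
        out = np.zeros(self.cfg.shape + (nf,), dtype=np.float32)
        out[self._vnc] = self._C[self._xs, start:stop].astype(np.float32)
        for m, trace in zip(self._soma_masks, self._S):
            out[m] = trace[start:stop].astype(np.float32)
        if self.cfg.noise_sd > 0:
            for i, f in enumerate(range(start, stop)):
                rng = np.random.default_rng(
                    np.random.SeedSequence([self.cfg.seed, 41, f])
                )
                out[..., i] += self.cfg.noise_sd * rng.standard_normal(
                    self.cfg.shape, dtype=np.float32
                )
        return out


def simulate_roi_traces(
    phantom: Phantom, truth: GroundTruth, cfg: PhantomConfig
) -> TraceMatrix:
    """ΔF/F traces of all phantom ROIs, with noise at the ROI level.

    Equivalent to rendering the full noisy recording and spatially averaging
    within each ROI: the ROI mean of independent per-voxel Gaussian noise is
    Gaussian with SD ``noise_sd/sqrt(n_voxels)``, so the average is drawn
    directly.  This keeps hour-long phantom recordings tractable for the
    trace-level detection pipeline.
    """
    C = column_traces(phantom, truth, cfg)
    names, S = soma_traces(phantom, truth, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 53]))
    rows = []
    labels = []
    for label, vox in phantom.rois.rois.items():
        if label in names:
            trace = S[names.index(label)].copy()
        elif label.startswith("A") and label[-1] in "LR":
            trace = C[vox[:, 0], :].mean(axis=0)
        else:
            trace = np.zeros(cfg.n_frames)
        if cfg.noise_sd > 0:
            trace = trace + cfg.noise_sd / np.sqrt(len(vox)) * rng.standard_normal(
                cfg.n_frames
            )
        rows.append(trace)
        labels.append(label)
    return TraceMatrix(np.array(rows), labels, cfg.frame_interval)


def default_detection_phantom(seed: int = 0, noise_sd: float = 0.1) -> PhantomConfig:
    """Conditions for ground-truth wave-detection evaluation: 20 forward and
    20 backward scheduled waves with non-overlapping triggered windows,
    scheduled after the detector's 120 s warm-up prefix."""
    return PhantomConfig(
        duration=1100.0,
        n_forward=20,
        n_backward=20,
        schedule_start_s=140.0,
        noise_sd=noise_sd,
        seed=seed,
    )
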