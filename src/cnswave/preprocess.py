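"""Two-view registration and fusion, time-lapse drift correction,
sliding-percentile baseline estimation and ΔF/F computation.

The two detection arms image the specimen from opposite sides of the
detection axis, so view B is first mirrored, then rigidly aligned to view A
(translation via masked phase correlation with subpixel refinement, optional
in-plane rotation via grid search).  Fusion trusts, per voxel, the view with
the shorter detection path through tissue; ties are averaged.

Specimen drift over the time-lapse is compensated by registering every stack
to the stack acquired at the temporal midpoint of the recording
(translation-only by default).

The fluorescence baseline F0 is a sliding-window percentile per voxel
(25th percentile for one-photon recordings, 10th for two-photon, window of
70 timepoints), and ΔF/F = (F − F0) / max(F0, eps).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .volume_io import ForegroundModel, VolumeSeries

logger = logging.getLogger(__name__)

PERCENTILE_ONE_PHOTON = 25.0
PERCENTILE_TWO_PHOTON = 10.0
BASELINE_WINDOW = 70


@dataclass
class RigidTransform:
    """Rigid map from view-B coordinates into the view-A frame.

    ``flip_axis`` mirrors B along the detection axis before rotation and
    translation are applied (the two cameras face each other, so the raw
    stacks are mirror images).  After the flip is factored out the rotation
    has determinant +1.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    flip_axis: int | None = None

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.isclose(abs(np.linalg.det(self.rotation)), 1.0, atol=1e-6):
            raise ValueError("rotation must be orthonormal")

    @property
    def rotation_angle_deg(self) -> float:
        """In-plane (x-y) rotation angle in degrees."""
        return float(np.degrees(np.arctan2(self.rotation[1, 0], self.rotation[0, 0])))

    def apply_to_stack(self, stack: np.ndarray, order: int = 1) -> np.ndarray:
        """Resample a single 3D stack of view B into the view-A frame."""
        out = stack
        if self.flip_axis is not None:
            out = np.flip(out, axis=self.flip_axis)
        angle = self.rotation_angle_deg
        if abs(angle) > 1e-9:
            centre = (np.array(out.shape, dtype=float) - 1) / 2
            # rotate about the volume centre in the x-y plane
            out = ndimage.rotate(
                out, -angle, axes=(0, 1), reshape=False, order=order, mode="constant"
            )
            del centre
        if np.any(np.abs(self.translation) > 1e-12):
            out = _shift_stack(out, self.translation, order=order)
        return out

    def apply(self, series: VolumeSeries, order: int = 1) -> VolumeSeries:
        frames = [
            self.apply_to_stack(series.data[..., t], order=order)
            for t in range(series.n_frames)
        ]
        return series.with_data(np.stack(frames, axis=-1))

    def invert(self) -> "RigidTransform":
        if self.flip_axis is not None:
            raise ValueError("cannot invert a transform with an embedded flip")
        return RigidTransform(
            rotation=self.rotation.T,
            translation=-self.rotation.T @ self.translation,
        )


def _shift_stack(stack: np.ndarray, shift: np.ndarray, order: int = 1) -> np.ndarray:
    """Integer shifts via roll (exact); fractional shifts via interpolation."""
    shift = np.asarray(shift, dtype=float)
    if np.allclose(shift, np.round(shift), atol=1e-9):
        ishift = np.round(shift).astype(int)
        out = np.roll(stack, ishift, axis=(0, 1, 2))
        # zero the wrapped-in margins
        for ax, s in enumerate(ishift):
            if s > 0:
                sl = [slice(None)] * 3
                sl[ax] = slice(0, s)
                out[tuple(sl)] = 0
            elif s < 0:
                sl = [slice(None)] * 3
                sl[ax] = slice(stack.shape[ax] + s, None)
                out[tuple(sl)] = 0
        return out
    return ndimage.shift(stack, shift, order=order, mode="constant", cval=0.0)


def _reference_stack(series: VolumeSeries) -> np.ndarray:
    """Time-mean stack used as the registration target (robust to activity)."""
    return series.data.mean(axis=3)


def _rotate_xy(stack: np.ndarray, angle_deg: float) -> np.ndarray:
    if abs(angle_deg) < 1e-12:
        return stack
    return ndimage.rotate(
        stack, angle_deg, axes=(0, 1), reshape=False, order=1, mode="constant"
    )


def _envelope_ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized correlation over the full stacks.

    Opposing-camera views have complementary depth attenuation, so their
    intensities are anti-correlated *inside* the specimen; what registration
    must align is the specimen envelope against the dark background, which
    the full-frame correlation rewards.
    """
    av = a.ravel() - a.mean()
    bv = b.ravel() - b.mean()
    denom = np.sqrt((av * av).sum() * (bv * bv).sum())
    if denom == 0:
        return 0.0
    return float((av * bv).sum() / denom)


def register_views(
    viewA: VolumeSeries,
    viewB: VolumeSeries,
    fgA: ForegroundModel,
    flip_axis: int | None = None,
    max_rotation_deg: float = 0.0,
    rotation_step_deg: float = 0.25,
    upsample: int = 20,
    metric_floor: float = 0.05,
) -> RigidTransform:
    """Estimate the rigid transform aligning view B onto view A.

    View B is mirrored along ``flip_axis`` (default: the foreground model's
    detection axis), then translation is estimated by phase correlation on
    foreground voxels with subpixel refinement.  If ``max_rotation_deg > 0``
    an in-plane rotation is grid-searched (coarse-to-fine) before the final
    translation estimate.  If the registration does not improve the
    foreground correlation by at least ``metric_floor`` over the unaligned
    flip, a warning is emitted and identity-after-flip is returned.
    """
    if viewA.spatial_shape != viewB.spatial_shape:
        raise ValueError("views must share a spatial shape")
    if not fgA.mask.any():
        raise ValueError("foreground is empty")
    axis = fgA.detection_axis if flip_axis is None else flip_axis
    refA = _reference_stack(viewA)
    refB = np.flip(_reference_stack(viewB), axis=axis)
    mask = fgA.mask

    # the specimen dominates the field (background ~ 0), so phase correlation
    # runs on the raw stacks; the foreground mask is used for scoring only —
    # masking the moving stack in place would anchor the correlation at zero
    best_angle = 0.0
    if max_rotation_deg > 0:
        step = rotation_step_deg
        lo, hi = -max_rotation_deg, max_rotation_deg
        for _ in range(3):  # coarse-to-fine refinement
            angles = np.arange(lo, hi + step / 2, step)
            scores = []
            for ang in angles:
                rb = _rotate_xy(refB, ang)
                shift, _, _ = phase_cross_correlation(refA, rb, upsample_factor=1)
                aligned = _shift_stack(rb, shift)
                scores.append(_envelope_ncc(refA, aligned))
            k = int(np.argmax(scores))
            best_angle = float(angles[k])
            lo, hi = best_angle - step, best_angle + step
            step /= 4

    rb = _rotate_xy(refB, best_angle)
    shift, _, _ = phase_cross_correlation(refA, rb, upsample_factor=upsample)
    aligned = _shift_stack(rb, shift)
    score_before = _envelope_ncc(refA, refB)
    score_after = _envelope_ncc(refA, aligned)
    logger.info(
        "register_views: angle=%.3f deg shift=%s ncc %.4f -> %.4f",
        best_angle,
        np.round(shift, 3),
        score_before,
        score_after,
    )
    if score_after < score_before - 1e-9 or score_after < metric_floor:
        warnings.warn(
            "registration metric improvement below floor; returning "
            "identity-after-flip"
        )
        return RigidTransform(flip_axis=axis)
    c, s = np.cos(np.radians(-best_angle)), np.sin(np.radians(-best_angle))
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return RigidTransform(rotation=rot, translation=np.asarray(shift), flip_axis=axis)


def fuse_views(
    viewA: VolumeSeries,
    viewB: VolumeSeries,
    transform: RigidTransform,
    fg: ForegroundModel,
    views: tuple[str, str] = ("A", "B"),
) -> VolumeSeries:
    """Blend two registered views, trusting the shorter detection path.

    Per voxel the output takes the value from the view whose detection path
    through tissue is shorter; exact ties (and voxels outside the foreground,
    where no path is defined) are averaged.
    """
    for v in views:
        if v not in fg.path_length:
            raise ValueError(f"missing path_length for view {v!r}")
    alignedB = transform.apply(viewB)
    pA = fg.path_length[views[0]]
    pB = fg.path_length[views[1]]
    useA = pA < pB
    useB = pB < pA
    out = 0.5 * (viewA.data.astype(float) + alignedB.data.astype(float))
    out[useA] = viewA.data[useA]
    out[useB] = alignedB.data[useB]
    return VolumeSeries(
        data=out,
        voxel_size=viewA.voxel_size,
        frame_interval=viewA.frame_interval,
        view_id="fused",
    )


def correct_drift(
    series: VolumeSeries,
    fg: ForegroundModel | None = None,
    upsample: int = 10,
) -> tuple[VolumeSeries, pd.DataFrame]:
    """Register every stack to the temporal-midpoint stack (translation only).

    Returns the corrected series and the per-timepoint shift table
    (columns t, dx, dy, dz; the shift that was *applied* to each stack).
    All-zero stacks cannot be registered; they inherit the shift of the
    previous timepoint and are flagged in the log.
    """
    if series.n_frames < 3:
        raise ValueError("drift correction needs >= 3 timepoints")
    mid = series.n_frames // 2
    ref = series.data[..., mid].astype(float)
    shifts = np.zeros((series.n_frames, 3))
    frames = np.empty_like(series.data, dtype=float)
    last = np.zeros(3)
    for t in range(series.n_frames):
        stack = series.data[..., t].astype(float)
        if not np.any(stack):
            logger.warning("all-zero stack at t=%d; carrying forward shift", t)
            shift = last
        else:
            shift, _, _ = phase_cross_correlation(
                ref, stack, upsample_factor=upsample
            )
            last = shift
        shifts[t] = shift
        frames[..., t] = _shift_stack(stack, shift)
    table = pd.DataFrame(shifts, columns=["dx", "dy", "dz"])
    table.insert(0, "t", np.arange(series.n_frames))
    return series.with_data(frames), table


@dataclass
class BaselineSeries:
    """Sliding-percentile baseline F0 with its defining parameters."""

    data: np.ndarray
    percentile: float
    window: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)


def compute_baseline(
    series: VolumeSeries,
    percentile: float = PERCENTILE_ONE_PHOTON,
    window: int = BASELINE_WINDOW,
) -> BaselineSeries:
    """Per-voxel sliding-window percentile baseline.

    F0(·, t) is the given percentile (linear interpolation between order
    statistics) of the intensities in the window centred on t; windows shrink
    at the recording edges so the baseline is defined for every timepoint.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    T = series.n_frames
    if window > T:
        warnings.warn(f"baseline window {window} > recording length {T}; clamped")
        window = T
    half_before = window // 2
    half_after = window - half_before  # exclusive upper bound offset
    out = np.empty(series.shape, dtype=float)
    for t in range(T):
        lo = max(0, t - half_before)
        hi = min(T, t + half_after)
        out[..., t] = np.percentile(series.data[..., lo:hi], percentile, axis=3)
    return BaselineSeries(data=out, percentile=percentile, window=window)


def compute_dff(
    series: VolumeSeries, baseline: BaselineSeries, eps: float = 1.0
) -> VolumeSeries:
    """ΔF/F = (F − F0) / max(F0, eps); finite everywhere by construction."""
    if baseline.data.shape != series.shape:
        raise ValueError("baseline shape does not match series")
    denom = np.maximum(baseline.data, eps)
    dff = (series.data - baseline.data) / denom
    return series.with_data(dff)
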