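"""Volumetric time-series data model, file I/O, specimen foreground modelling
and a block-based lossless foreground-compression container.

The in-memory carrier is :class:`VolumeSeries`, a 4D ``(x, y, z, t)`` array
with voxel spacing (micrometres) and frame interval (seconds).  Raw
fluorescence and the derived ΔF/F representation both travel in this type.

The compression container stores only blocks that intersect the specimen
foreground; background voxels decode to 0.  Losslessness is guaranteed for
every foreground voxel (bit-exact round trip), mirroring the strategy of
discarding background voxels of light-sheet recordings and compressing the
detected specimen volume only.
"""

from __future__ import annotations

import io
import logging
import struct
import warnings
import zlib
from dataclasses import dataclass, field

import h5py
import numpy as np
import tifffile
from scipy import ndimage

from .errors import DegenerateInputError, IntegrityError, VolumeFormatError

logger = logging.getLogger(__name__)

DEFAULT_VOXEL_SIZE = (1.0, 1.0, 1.0)
DEFAULT_FRAME_INTERVAL = 0.2  # seconds; 5 Hz volumetric rate

_MAGIC = b"CNSWBLK1"
_CODEC_ZLIB = 1
_CODECS = {_CODEC_ZLIB: "zlib"}


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class VolumeSeries:
    """A 4D fluorescence (or ΔF/F) record.

    Parameters
    ----------
    data
        Array of shape ``(x, y, z, t)``; x is the fastest-varying storage
        axis.  Raw intensities are non-negative; ΔF/F values may be negative.
    voxel_size
        Micrometres per voxel along (x, y, z).
    frame_interval
        Seconds between consecutive volumes.
    view_id
        Identifier of the camera view ("A"/"B" for the two opposing
        detection arms, "fused" after multi-view fusion).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    view_id: str = "A"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise VolumeFormatError(
                f"expected 4D (x,y,z,t) data, got {self.data.ndim}D"
            )
        if min(self.data.shape) < 1:
            raise VolumeFormatError("all dimensions must be >= 1")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be > 0")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("intensities must be finite")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def frame_rate(self) -> float:
        return 1.0 / self.frame_interval

    def times(self) -> np.ndarray:
        """Frame times in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.frame_interval

    def time_slice(self, start: int, stop: int) -> np.ndarray:
        """Return frames ``start:stop`` as an ``(x, y, z, nf)`` array."""
        return self.data[..., start:stop]

    def with_data(self, data: np.ndarray, view_id: str | None = None) -> "VolumeSeries":
        return VolumeSeries(
            data=data,
            voxel_size=self.voxel_size,
            frame_interval=self.frame_interval,
            view_id=self.view_id if view_id is None else view_id,
        )


@dataclass
class ForegroundModel:
    """Specimen mask plus per-view detection-path-length fields.

    ``path_length[view]`` holds, for every foreground voxel, the distance in
    micrometres from that voxel to the specimen surface along the view's
    detection axis; voxels outside the mask carry NaN.
    """

    mask: np.ndarray
    path_length: dict[str, np.ndarray] = field(default_factory=dict)
    detection_axis: int = 2

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")

    def foreground_fraction(self) -> float:
        return float(self.mask.mean())


def path_lengths(
    mask: np.ndarray,
    axis: int,
    voxel_size: tuple[float, float, float],
    reverse: bool = False,
) -> np.ndarray:
    """Cumulative tissue depth along a detection axis.

    For each line of sight, the first foreground voxel hit by the camera has
    path length 0; each further foreground voxel adds one voxel spacing.
    Background voxels are NaN.  ``reverse=True`` places the camera on the
    far side of ``axis``.
    """
    m = np.asarray(mask, dtype=bool)
    step = float(voxel_size[axis])
    if reverse:
        m = np.flip(m, axis=axis)
    depth = (np.cumsum(m, axis=axis) - 1) * step
    out = np.where(m, depth, np.nan)
    if reverse:
        out = np.flip(out, axis=axis)
    return out


def detect_foreground(
    series: VolumeSeries,
    rel_threshold: float = 0.04,
    close_radius: int = 2,
    margin: int = 3,
    detection_axis: int = 2,
    views: tuple[str, str] = ("A", "B"),
) -> ForegroundModel:
    """Model the specimen geometry from a raw recording.

    A time-median projection is thresholded at ``rel_threshold`` times its
    mean intensity; the largest connected component is morphologically closed
    (radius ``close_radius``) and dilated by ``margin`` voxels.  Per-view
    detection path lengths are then computed along ``detection_axis`` with
    the two cameras on opposite sides.
    """
    if rel_threshold <= 0:
        raise ValueError("rel_threshold must be > 0")
    med = np.median(series.data, axis=3)
    thresh = rel_threshold * float(med.mean())
    raw = med > thresh
    if not raw.any():
        raise DegenerateInputError("empty foreground after thresholding")
    labels, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
        raw = labels == (1 + int(np.argmax(sizes)))
    if close_radius > 0:
        struct = _ball(close_radius)
        raw = ndimage.binary_closing(raw, structure=struct)
    if margin > 0:
        raw = ndimage.binary_dilation(raw, structure=_ball(1), iterations=margin)
    # morphology can merge but never split the single component; keep largest
    labels, n = ndimage.label(raw)
    if n > 1:  # pragma: no cover - defensive
        sizes = ndimage.sum_labels(raw, labels, index=np.arange(1, n + 1))
        raw = labels == (1 + int(np.argmax(sizes)))
    pl = {
        views[0]: path_lengths(raw, detection_axis, series.voxel_size, reverse=False),
        views[1]: path_lengths(raw, detection_axis, series.voxel_size, reverse=True),
    }
    return ForegroundModel(mask=raw, path_length=pl, detection_axis=detection_axis)


def _ball(radius: int) -> np.ndarray:
    z, y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1, -radius : radius + 1]
    return x * x + y * y + z * z <= radius * radius


# ---------------------------------------------------------------------------
# block-compressed container
# ---------------------------------------------------------------------------

@dataclass
class BlockCompressedVolume:
    """In-memory block-compressed representation of a masked 4D volume.

    Blocks tile the spatial axes (half-open 0-based ranges, x fastest in
    storage order); each stored block holds all timepoints of its spatial
    extent, deflate-compressed, with a crc32 of the uncompressed bytes.
    Blocks entirely outside the foreground mask are omitted and decode to 0.
    """

    shape: tuple[int, int, int, int]
    block_size: tuple[int, int, int]
    dtype: np.dtype
    codec: int
    index: dict[tuple[int, int, int], tuple[int, int, int]]  # (offset, length, crc32)
    payload: bytes
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    view_id: str = "A"
    version: int = 1

    def nbytes(self) -> int:
        """Total container size: header + index table + payload."""
        header = 8 + 2 + 4 * 4 + 4 * 3 + 2 + 2 + 8 + 8 * 3 + 8 + 32
        index = 30 * len(self.index)
        return header + index + len(self.payload)


def compress_blocks(
    series: VolumeSeries,
    fg: ForegroundModel,
    block_size: tuple[int, int, int] = (64, 64, 8),
    level: int = 6,
) -> BlockCompressedVolume:
    """Losslessly compress the foreground of a recording, block by block.

    Background voxels inside retained blocks are zeroed before encoding, so
    the lossless guarantee applies to foreground voxels; every background
    voxel decodes to 0.
    """
    if fg.mask.shape != series.spatial_shape:
        raise ValueError("foreground mask shape does not match series")
    bs = []
    for ax in range(3):
        b = int(block_size[ax])
        if b > series.spatial_shape[ax]:
            warnings.warn(
                f"block_size[{ax}]={b} larger than volume; clamped to "
                f"{series.spatial_shape[ax]}"
            )
            b = series.spatial_shape[ax]
        if b < 1:
            raise ValueError("block_size must be >= 1")
        bs.append(b)
    bs = tuple(bs)

    nx, ny, nz, _ = series.shape
    index: dict[tuple[int, int, int], tuple[int, int, int]] = {}
    buf = io.BytesIO()
    for bx in range(0, nx, bs[0]):
        for by in range(0, ny, bs[1]):
            for bz in range(0, nz, bs[2]):
                sl = (
                    slice(bx, min(bx + bs[0], nx)),
                    slice(by, min(by + bs[1], ny)),
                    slice(bz, min(bz + bs[2], nz)),
                )
                msub = fg.mask[sl]
                if not msub.any():
                    continue
                sub = np.ascontiguousarray(series.data[sl])
                sub = np.where(msub[..., None], sub, 0).astype(series.data.dtype)
                raw = sub.tobytes()
                comp = zlib.compress(raw, level)
                index[(bx // bs[0], by // bs[1], bz // bs[2])] = (
                    buf.tell(),
                    len(comp),
                    zlib.crc32(raw),
                )
                buf.write(comp)
    return BlockCompressedVolume(
        shape=series.shape,
        block_size=bs,
        dtype=series.data.dtype,
        codec=_CODEC_ZLIB,
        index=index,
        payload=buf.getvalue(),
        voxel_size=series.voxel_size,
        frame_interval=series.frame_interval,
        view_id=series.view_id,
    )


def decompress_blocks(bc: BlockCompressedVolume) -> VolumeSeries:
    """Inverse of :func:`compress_blocks`; omitted blocks decode to zeros."""
    if bc.version != 1:
        raise IntegrityError(f"unsupported container version {bc.version}")
    if bc.codec not in _CODECS:
        raise IntegrityError(f"unknown codec id {bc.codec}")
    out = np.zeros(bc.shape, dtype=bc.dtype)
    nx, ny, nz, nt = bc.shape
    bsx, bsy, bsz = bc.block_size
    for (ix, iy, iz), (offset, length, crc) in bc.index.items():
        comp = bc.payload[offset : offset + length]
        raw = zlib.decompress(comp)
        if zlib.crc32(raw) != crc:
            raise IntegrityError(f"checksum mismatch in block ({ix}, {iy}, {iz})")
        x0, y0, z0 = ix * bsx, iy * bsy, iz * bsz
        shp = (
            min(bsx, nx - x0),
            min(bsy, ny - y0),
            min(bsz, nz - z0),
            nt,
        )
        out[x0 : x0 + shp[0], y0 : y0 + shp[1], z0 : z0 + shp[2], :] = np.frombuffer(
            raw, dtype=bc.dtype
        ).reshape(shp)
    return VolumeSeries(
        data=out,
        voxel_size=bc.voxel_size,
        frame_interval=bc.frame_interval,
        view_id=bc.view_id,
    )


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def write_series(series: VolumeSeries, path, format: str | None = None) -> None:
    fmt = format or _infer_format(str(path))
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            d = f.create_dataset("data", data=series.data)
            d.attrs["voxel_size"] = series.voxel_size
            d.attrs["frame_interval"] = series.frame_interval
            d.attrs["view_id"] = series.view_id
    elif fmt == "tiff":
        # stored as (t, z, y, x) pages; metadata in the ImageJ-style header
        arr = np.moveaxis(series.data, (0, 1, 2, 3), (3, 2, 1, 0))
        tifffile.imwrite(
            str(path),
            arr,
            photometric="minisblack",
            metadata={
                "axes": "TZYX",
                "voxel_size": list(series.voxel_size),
                "frame_interval": series.frame_interval,
                "view_id": series.view_id,
            },
        )
    elif fmt == "blockfile":
        raise ValueError("use write_blockfile for the block container")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_series(
    path,
    format: str | None = None,
    default_voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    default_frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> VolumeSeries:
    """Read a 4D recording from TIFF, HDF5 or the block container.

    Missing voxel-size / frame-interval metadata is filled from the supplied
    defaults with a logged warning.
    """
    fmt = format or _infer_format(str(path))
    if fmt == "hdf5":
        try:
            with h5py.File(path, "r") as f:
                d = f["data"]
                if d.ndim != 4:
                    raise VolumeFormatError(f"dataset is {d.ndim}D, expected 4D")
                data = d[()]
                vs = d.attrs.get("voxel_size")
                fi = d.attrs.get("frame_interval")
                view = d.attrs.get("view_id", "A")
        except OSError as exc:
            raise IOError(f"unreadable HDF5 file {path}: {exc}") from exc
        if vs is None:
            logger.warning("voxel_size missing in %s; using default", path)
            vs = default_voxel_size
        if fi is None:
            logger.warning("frame_interval missing in %s; using default", path)
            fi = default_frame_interval
        return VolumeSeries(data, tuple(float(v) for v in vs), float(fi), str(view))
    if fmt == "tiff":
        try:
            with tifffile.TiffFile(str(path)) as tf:
                arr = tf.asarray()
                meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        except (tifffile.TiffFileError, ValueError, OSError) as exc:
            raise IOError(f"unreadable TIFF file {path}: {exc}") from exc
        if arr.ndim == 3:  # single timepoint written as z-stack
            arr = arr[None]
        if arr.ndim != 4:
            raise VolumeFormatError(f"TIFF holds {arr.ndim}D data, expected 3D+time")
        data = np.moveaxis(arr, (0, 1, 2, 3), (3, 2, 1, 0))
        vs = meta.get("voxel_size")
        fi = meta.get("frame_interval")
        if vs is None:
            logger.warning("voxel_size missing in %s; using default", path)
            vs = default_voxel_size
        if fi is None:
            logger.warning("frame_interval missing in %s; using default", path)
            fi = default_frame_interval
        return VolumeSeries(
            np.ascontiguousarray(data),
            tuple(float(v) for v in vs),
            float(fi),
            str(meta.get("view_id", "A")),
        )
    if fmt == "blockfile":
        return decompress_blocks(read_blockfile(path))
    raise ValueError(f"unknown format {fmt!r}")


def _infer_format(path: str) -> str:
    p = path.lower()
    if p.endswith((".h5", ".hdf5")):
        return "hdf5"
    if p.endswith((".tif", ".tiff")):
        return "tiff"
    if p.endswith((".cbv", ".blk")):
        return "blockfile"
    raise ValueError(f"cannot infer format from {path!r}")


_DTYPE_CODES = {
    np.dtype("uint8"): 0,
    np.dtype("uint16"): 1,
    np.dtype("int16"): 2,
    np.dtype("int32"): 3,
    np.dtype("float32"): 4,
    np.dtype("float64"): 5,
    np.dtype("int64"): 6,
    np.dtype("uint32"): 7,
}
_DTYPE_FROM_CODE = {v: k for k, v in _DTYPE_CODES.items()}

# header: magic(8) version(H) shape(4I) block(3I) dtype(H) codec(H) nblocks(Q)
# voxel(3d) frame_interval(d) view_id(32s); index entries: 3I Q I I
_HEADER = struct.Struct("<8sH4I3IHHQ3dd32s")
_ENTRY = struct.Struct("<3IQII")


def write_blockfile(bc: BlockCompressedVolume, path) -> None:
    """Serialize the block container to its documented binary layout."""
    code = _DTYPE_CODES.get(np.dtype(bc.dtype))
    if code is None:
        raise ValueError(f"unsupported dtype {bc.dtype}")
    with open(path, "wb") as f:
        f.write(
            _HEADER.pack(
                _MAGIC,
                bc.version,
                *bc.shape,
                *bc.block_size,
                code,
                bc.codec,
                len(bc.index),
                *bc.voxel_size,
                bc.frame_interval,
                bc.view_id.encode()[:32].ljust(32, b"\0"),
            )
        )
        for (ix, iy, iz), (offset, length, crc) in sorted(bc.index.items()):
            f.write(_ENTRY.pack(ix, iy, iz, offset, length, crc))
        f.write(bc.payload)


def read_blockfile(path) -> BlockCompressedVolume:
    with open(path, "rb") as f:
        head = f.read(_HEADER.size)
        if len(head) < _HEADER.size:
            raise IOError(f"truncated block file {path}")
        fields = _HEADER.unpack(head)
        magic, version = fields[0], fields[1]
        if magic != _MAGIC:
            raise IntegrityError(f"bad magic in {path}")
        shape = tuple(fields[2:6])
        block = tuple(fields[6:9])
        dcode, codec, nblocks = fields[9], fields[10], fields[11]
        voxel = tuple(fields[12:15])
        fi = fields[15]
        view = fields[16].rstrip(b"\0").decode()
        if dcode not in _DTYPE_FROM_CODE:
            raise IntegrityError(f"unknown dtype code {dcode}")
        index: dict[tuple[int, int, int], tuple[int, int, int]] = {}
        for _ in range(nblocks):
            ix, iy, iz, offset, length, crc = _ENTRY.unpack(f.read(_ENTRY.size))
            index[(ix, iy, iz)] = (offset, length, crc)
        payload = f.read()
    return BlockCompressedVolume(
        shape=shape,
        block_size=block,
        dtype=_DTYPE_FROM_CODE[dcode],
        codec=codec,
        index=index,
        payload=payload,
        voxel_size=voxel,
        frame_interval=fi,
        view_id=view,
        version=version,
    )


def save_foreground(fg: ForegroundModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mask", data=fg.mask)
        f.attrs["detection_axis"] = fg.detection_axis
        for view, pl in fg.path_length.items():
            f.create_dataset(f"path_length/{view}", data=pl)


def load_foreground(path) -> ForegroundModel:
    with h5py.File(path, "r") as f:
        mask = f["mask"][()]
        axis = int(f.attrs.get("detection_axis", 2))
        pl = {}
        if "path_length" in f:
            for view in f["path_length"]:
                pl[view] = f["path_length"][view][()]
    return ForegroundModel(mask=mask, path_length=pl, detection_axis=axis)
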