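"""Reading and writing image stacks, height maps, masks and projections.

In-memory convention: stacks are numpy arrays indexed ``(channel, z, y, x)``,
with z index 0 the stack-entry side (nearest the objective, i.e. the outer
leaf surface for stacks acquired down through the abaxial epidermis).
All other modules assume this axis order.

Stacks written by this module use tifffile's "shaped" TIFF layout, which
stores the array shape, dtype and a JSON metadata block in the page
description; re-reading recovers the voxel data bit-exactly for integer
dtypes and at 32-bit float precision for derived images. Externally produced
files (ImageJ hyperstacks, OME-TIFF) are read through tifffile's series/axes
machinery and normalised to the canonical axis order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import tifffile

from .errors import StackReadError

logger = logging.getLogger(__name__)

_DEFAULT_VOXEL_SIZE = (1.0, 1.0, 1.0)


@dataclass
class ImageStack:
    """A multi-channel 3-D intensity stack.

    Parameters
    ----------
    voxels : ndarray, shape (n_channels, nz, ny, nx)
        Non-negative, finite intensities.
    channel_names : list of str
        One label per channel.
    voxel_size_um : (dz, dy, dx)
        Voxel size in micrometres; strictly positive.
    """

    voxels: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    voxel_size_um: tuple[float, float, float] = _DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 3:
            self.voxels = self.voxels[np.newaxis]
        if self.voxels.ndim != 4:
            raise ValueError(
                f"stack must be (channel, z, y, x); got ndim={self.voxels.ndim}"
            )
        if self.voxels.size == 0:
            raise ValueError("empty stack: all of nz, ny, nx must be >= 1")
        if np.issubdtype(self.voxels.dtype, np.floating):
            if not np.all(np.isfinite(self.voxels)):
                raise ValueError("stack intensities must be finite")
        if self.voxels.min() < 0:
            raise ValueError("stack intensities must be >= 0")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.voxels.shape[0])]
        if len(self.channel_names) != self.voxels.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.voxels.shape[0]} channels"
            )
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)  # type: ignore[assignment]
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel_size_um must be three strictly positive values")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def nz(self) -> int:
        return self.voxels.shape[1]

    @property
    def ny(self) -> int:
        return self.voxels.shape[2]

    @property
    def nx(self) -> int:
        return self.voxels.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def channel(self, index: int) -> np.ndarray:
        return self.voxels[index]

    def flip_z(self) -> "ImageStack":
        """Return a copy with the z axis reversed (for stacks acquired bottom-up)."""
        return ImageStack(
            self.voxels[:, ::-1].copy(), list(self.channel_names), self.voxel_size_um
        )


@dataclass
class HeightMap:
    """Per-(y, x) surface z-coordinate with a validity mask.

    Heights are real-valued in slice units; sub-slice values arise only from
    regularisation. ``nz`` records the z extent of the source stack so later
    stages can clip to [0, nz-1].
    """

    height: np.ndarray
    valid: np.ndarray
    nz: Optional[int] = None

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, dtype=np.float32)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.height.ndim != 2 or self.height.shape != self.valid.shape:
            raise ValueError("height and valid must be matching 2-D arrays")
        vh = self.height[self.valid]
        if vh.size and not np.all(np.isfinite(vh)):
            raise ValueError("valid heights must be finite")
        if self.nz is not None:
            self.nz = int(self.nz)
            if vh.size and (vh.min() < 0 or vh.max() > self.nz - 1):
                raise ValueError("valid heights must lie in [0, nz-1]")

    @property
    def all_valid(self) -> bool:
        return bool(self.valid.all())


def _axes_to_czyx(arr: np.ndarray, axes: str) -> np.ndarray:
    """Reorder an array with tifffile axis labels into (C, Z, Y, X)."""
    axes = axes.upper()
    arr = np.asarray(arr)
    # Treat samples (S, e.g. RGB) and time (T) of length 1 as squeezable;
    # anything longer is ambiguous for a confocal stack reader.
    for label in ("T", "S", "Q", "I"):
        while label in axes:
            i = axes.index(label)
            if arr.shape[i] != 1 and label in ("T", "S"):
                raise StackReadError(
                    f"cannot interpret axis {label!r} of length {arr.shape[i]}"
                )
            if arr.shape[i] == 1:
                arr = np.squeeze(arr, axis=i)
                axes = axes[:i] + axes[i + 1 :]
            else:
                # tifffile uses Q/I for unknown axes; map the first to Z, rest to C
                axes = axes[:i] + ("Z" if "Z" not in axes else "C") + axes[i + 1 :]
    for label in "CZ":
        if label not in axes:
            arr = arr[np.newaxis]
            axes = label + axes
    if sorted(axes) != ["C", "X", "Y", "Z"] or arr.ndim != 4:
        raise StackReadError(f"cannot normalise axes {axes!r} to CZYX")
    order = [axes.index(l) for l in "CZYX"]
    return np.transpose(arr, order)


def _voxel_size_from_tiff(tf: tifffile.TiffFile) -> Optional[tuple[float, float, float]]:
    dz = dy = dx = None
    if tf.imagej_metadata:
        dz = tf.imagej_metadata.get("spacing")
    page = tf.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        if xres[0] and yres[0]:
            dx = xres[1] / xres[0]
            dy = yres[1] / yres[0]
    except KeyError:
        pass
    if dz is not None and dy is not None and dx is not None:
        return float(dz), float(dy), float(dx)
    return None


def read_stack(path, channel_axis_hint: Optional[str] = None) -> ImageStack:
    """Read a single- or multi-page TIFF into an :class:`ImageStack`.

    Parameters
    ----------
    path
        Path to a TIFF file.
    channel_axis_hint
        Optional axes string (e.g. ``"ZCYX"``) overriding the axis labels
        recorded in the file, for files whose metadata is wrong or missing.

    Raises
    ------
    StackReadError
        Unreadable/corrupt file, or axes that cannot be resolved to CZYX.
    """
    path = Path(path)
    try:
        tf = tifffile.TiffFile(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise StackReadError(f"cannot read TIFF {path}: {exc}") from exc
    with tf:
        series = tf.series[0]
        arr = series.asarray()
        if channel_axis_hint and len(channel_axis_hint) != arr.ndim:
            raise StackReadError(
                f"axis hint {channel_axis_hint!r} has {len(channel_axis_hint)} labels "
                f"but {path} holds a {arr.ndim}-D array of shape {arr.shape}"
            )
        axes = channel_axis_hint or series.axes
        meta: dict = {}
        if tf.shaped_metadata:
            meta = dict(tf.shaped_metadata[0])
            axes = channel_axis_hint or meta.get("axes", axes)
        voxels = _axes_to_czyx(arr, axes)
        voxel_size = None
        if "voxel_size_um" in meta:
            voxel_size = tuple(float(v) for v in meta["voxel_size_um"])
        if voxel_size is None:
            voxel_size = _voxel_size_from_tiff(tf)
        if voxel_size is None:
            logger.warning(
                "no voxel-size metadata in %s; defaulting to (1, 1, 1) um", path
            )
            voxel_size = _DEFAULT_VOXEL_SIZE
        names = meta.get("channel_names") or [f"ch{i}" for i in range(voxels.shape[0])]
    return ImageStack(voxels, list(names), voxel_size)  # type: ignore[arg-type]


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF that :func:`read_stack` round-trips.

    Integer dtypes are preserved bit-exactly; float data is written as given
    (derived images in this package are float32 by convention).
    """
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.voxels,
        metadata={
            "axes": "CZYX",
            "voxel_size_um": list(stack.voxel_size_um),
            "channel_names": list(stack.channel_names),
        },
    )


def write_heightmap(hm: HeightMap, path) -> None:
    """Write a height map: page 0 = heights (NaN at invalid), page 1 = validity."""
    height = hm.height.astype(np.float32).copy()
    height[~hm.valid] = np.nan
    pages = np.stack([height, hm.valid.astype(np.float32)])
    tifffile.imwrite(
        Path(path),
        pages,
        metadata={"leafpeel_kind": "heightmap", "nz": hm.nz},
    )


def read_heightmap(path) -> HeightMap:
    path = Path(path)
    try:
        tf = tifffile.TiffFile(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise StackReadError(f"cannot read height map {path}: {exc}") from exc
    with tf:
        pages = tf.series[0].asarray()
        meta = dict(tf.shaped_metadata[0]) if tf.shaped_metadata else {}
    if pages.ndim != 3 or pages.shape[0] != 2:
        raise StackReadError(f"{path} is not a 2-page height map file")
    valid = pages[1] > 0.5
    height = pages[0].copy()
    height[~valid] = 0.0  # NaN codes never leak into the valid set
    return HeightMap(height, valid, nz=meta.get("nz"))


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean (z, y, x) mask as an 8-bit 0/255 multi-page TIFF."""
    tifffile.imwrite(
        Path(path),
        (np.asarray(mask, dtype=bool).astype(np.uint8) * 255),
        metadata={"leafpeel_kind": "mask"},
    )


def read_mask(path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    return np.asarray(arr) > 127


def write_projection(pixels: np.ndarray, path) -> None:
    """Write a per-channel 2-D projection as a 32-bit float TIFF."""
    arr = np.asarray(pixels, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    tifffile.imwrite(Path(path), arr, metadata={"leafpeel_kind": "projection"})


def export_png(pixels: np.ndarray, path, vmin: Optional[float] = None,
               vmax: Optional[float] = None) -> None:
    """Export a single-channel image as an 8-bit PNG with explicit scaling.

    Display only; quantification always uses the float TIFFs.
    """
    from PIL import Image

    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("PNG export takes a single 2-D channel")
    lo = float(arr.min()) if vmin is None else float(vmin)
    hi = float(arr.max()) if vmax is None else float(vmax)
    if hi <= lo:
        scaled = np.zeros_like(arr)
    else:
        scaled = np.clip((arr - lo) / (hi - lo), 0.0, 1.0)
    Image.fromarray((scaled * 255).round().astype(np.uint8)).save(Path(path))
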