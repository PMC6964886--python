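"""Layer peeling: select voxels a given offset and depth below the surface,
render Z projections of the peeled layer, and quantify per-channel signal.

A layer is the half-open slab ``h + offset <= z < h + offset + depth`` below
the column height ``h``. Half-open intervals mean adjacent layers — e.g. an
epidermis layer and the mesophyll layer starting where it ends — tile each
column with no shared voxel, so signal is never double-counted. Fractional
bounds (micrometre units, smoothed heights) are intersected with integer
slices by ``ceil(lower) <= z < ceil(upper)``; out-of-bounds parts of the slab
clip silently to the stack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyLayerError
from .stack_io import HeightMap, ImageStack

logger = logging.getLogger(__name__)


@dataclass
class PeelSpec:
    """Offset and depth of a layer below the surface.

    ``offset`` is the distance from the surface to the top of the layer and
    ``depth`` the layer thickness, both in ``units`` ("slices" or "um").
    Micrometre specs are converted with the stack's axial voxel size dz.
    """

    offset: float
    depth: float
    units: str = "slices"

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")
        if self.units not in ("slices", "um"):
            raise ValueError(f"units must be 'slices' or 'um', got {self.units!r}")

    def in_slices(self, dz_um: Optional[float] = None) -> tuple[float, float]:
        """Return (offset, depth) converted to slice units."""
        if self.units == "slices":
            return float(self.offset), float(self.depth)
        if dz_um is None or dz_um <= 0:
            raise ValueError("micrometre units require a positive axial voxel size")
        return float(self.offset) / dz_um, float(self.depth) / dz_um


@dataclass
class LayerMask:
    """Boolean voxel selection, one contiguous z run (possibly empty) per column."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be (z, y, x)")

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


@dataclass
class ProjectionImage:
    """2-D per-channel rendering of a peeled layer."""

    pixels: np.ndarray  # (channel, y, x)
    method: str


@dataclass
class LayerStats:
    channel: int
    voxel_count: int
    total_intensity: float
    mean_intensity: float


def make_layer_mask(
    stack_shape: Sequence[int],
    hm: HeightMap,
    spec: PeelSpec,
    voxel_size_um: Optional[Sequence[float]] = None,
) -> LayerMask:
    """Build the boolean voxel mask of a layer below a height map.

    Parameters
    ----------
    stack_shape : (nz, ny, nx)
    hm : fully valid height map matching (ny, nx)
    spec : offset/depth of the layer
    voxel_size_um : (dz, dy, dx), required only for micrometre specs
    """
    nz, ny, nx = (int(s) for s in stack_shape)
    if hm.height.shape != (ny, nx):
        raise ValueError(
            f"height map shape {hm.height.shape} does not match (ny, nx)=({ny}, {nx})"
        )
    if not hm.all_valid:
        raise ValueError("height map has invalid entries; run fill_gaps first")
    dz = float(voxel_size_um[0]) if voxel_size_um is not None else None
    offset, depth = spec.in_slices(dz)

    lower = hm.height.astype(np.float64) + offset
    upper = lower + depth
    lo = np.ceil(lower)
    hi = np.ceil(upper)
    if (lo >= nz).any() or (hi <= 0).any():
        logger.info("layer extends beyond stack bounds in some columns; clipping")
    z = np.arange(nz, dtype=np.float64)[:, np.newaxis, np.newaxis]
    return LayerMask((z >= lo[np.newaxis]) & (z < hi[np.newaxis]))


def full_mask(stack_shape: Sequence[int]) -> LayerMask:
    """Mask selecting every voxel (classic unsegmented projection)."""
    return LayerMask(np.ones(tuple(int(s) for s in stack_shape), dtype=bool))


def peel(stack: ImageStack, mask: LayerMask) -> ImageStack:
    """Zero every voxel outside the mask, all channels; dtype preserved."""
    if mask.mask.shape != stack.spatial_shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} != stack spatial shape {stack.spatial_shape}"
        )
    peeled = stack.voxels * mask.mask[np.newaxis].astype(stack.voxels.dtype)
    return ImageStack(peeled, list(stack.channel_names), stack.voxel_size_um)


def project(stack: ImageStack, mask: LayerMask, method: str = "sum") -> ProjectionImage:
    """Project the masked voxels along z.

    ``sum`` accumulates in int64 (integer input) or float64, so totals are
    exact for integer stacks; ``max`` takes the per-column maximum, 0 where
    the mask selects nothing.
    """
    if mask.mask.shape != stack.spatial_shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} != stack spatial shape {stack.spatial_shape}"
        )
    if method not in ("sum", "max"):
        raise ValueError(f"unknown projection method {method!r}")
    m = mask.mask[np.newaxis]
    if method == "sum":
        acc = np.int64 if np.issubdtype(stack.voxels.dtype, np.integer) else np.float64
        pixels = np.where(m, stack.voxels, 0).sum(axis=1, dtype=acc)
    else:
        pixels = np.where(m, stack.voxels, 0).max(axis=1)
    return ProjectionImage(pixels, method)


def quantify_layer(stack: ImageStack, mask: LayerMask, channel: int) -> LayerStats:
    """Voxel count, total and mean intensity of one channel inside the mask.

    Raises
    ------
    EmptyLayerError
        If the mask selects no voxel — never a silent 0/0.
    """
    if not 0 <= channel < stack.n_channels:
        raise ValueError(f"channel {channel} not in stack of {stack.n_channels}")
    if mask.mask.shape != stack.spatial_shape:
        raise ValueError("mask shape does not match stack")
    selected = stack.channel(channel)[mask.mask]
    if selected.size == 0:
        raise EmptyLayerError("empty layer: mask selects no voxels")
    total = float(selected.sum(dtype=np.float64))
    return LayerStats(
        channel=channel,
        voxel_count=int(selected.size),
        total_intensity=total,
        mean_intensity=total / selected.size,
    )


def layer_stats_frame(stack: ImageStack, mask: LayerMask,
                      layer_name: str = "layer") -> pd.DataFrame:
    """Per-channel layer statistics as a tidy table (one row per channel)."""
    rows = []
    for c in range(stack.n_channels):
        s = quantify_layer(stack, mask, c)
        rows.append(
            {
                "layer": layer_name,
                "channel": c,
                "channel_name": stack.channel_names[c],
                "voxel_count": s.voxel_count,
                "total_intensity": s.total_intensity,
                "mean_intensity": s.mean_intensity,
            }
        )
    return pd.DataFrame(rows)
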