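"""Contoured-surface detection: turn a membrane-marker channel into a height map.

The leaf surface is found per (y, x) column as the first z (scanning from the
stack-entry side, z = 0) at which the optionally pre-smoothed marker intensity
stays at or above a threshold for ``min_run`` consecutive slices. Columns with
no qualifying run are marked invalid; :func:`fill_gaps` fills them from the
nearest valid column and :func:`regularize` median-filters and Gaussian-smooths
the map into the smooth contoured surface the peeling step assumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import DetectionError
from .stack_io import HeightMap, ImageStack

Sigma3 = Union[float, tuple[float, float, float]]


@dataclass
class SurfaceParams:
    """Parameters of the surface-detection stage.

    Attributes
    ----------
    channel : int
        Index of the marker channel used for detection.
    pre_smooth_sigma_vox : float or (sz, sy, sx)
        3-D Gaussian sigma in voxels applied to the marker channel before
        thresholding. The default smooths laterally (1 px) and only mildly
        axially (0.5 slices): heavy axial smoothing blurs the surface edge
        symmetrically and shifts the detected crossing up the column.
    threshold : float or "otsu"
        Fixed intensity threshold, or Otsu's threshold resolved once globally
        on the pre-smoothed marker channel.
    min_run : int
        Consecutive above-threshold slices required to accept a crossing;
        rejects single-voxel noise spikes.
    map_median_radius : int
        Height-map median-filter radius in pixels (0 disables).
    map_smooth_sigma_px : float
        Height-map Gaussian sigma in pixels (0 disables).
    """

    channel: int = 0
    pre_smooth_sigma_vox: Sigma3 = (0.5, 1.0, 1.0)
    threshold: Union[float, str] = "otsu"
    min_run: int = 2
    map_median_radius: int = 2
    map_smooth_sigma_px: float = 2.0

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if any(s < 0 for s in self.sigma3) or self.map_smooth_sigma_px < 0:
            raise ValueError("sigmas must be >= 0")
        if self.map_median_radius < 0:
            raise ValueError("map_median_radius must be >= 0")
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ValueError(f"threshold must be a number or 'otsu', got {self.threshold!r}")

    @property
    def sigma3(self) -> tuple[float, float, float]:
        s = self.pre_smooth_sigma_vox
        if np.isscalar(s):
            return (float(s), float(s), float(s))  # type: ignore[arg-type]
        sz, sy, sx = s  # type: ignore[misc]
        return (float(sz), float(sy), float(sx))


def _preprocess(stack: ImageStack, params: SurfaceParams) -> np.ndarray:
    if not 0 <= params.channel < stack.n_channels:
        raise ValueError(f"channel {params.channel} not in stack of {stack.n_channels}")
    marker = stack.channel(params.channel).astype(np.float32)
    if any(s > 0 for s in params.sigma3):
        marker = ndi.gaussian_filter(marker, sigma=params.sigma3)
    return marker


def resolve_threshold(stack: ImageStack, params: SurfaceParams) -> float:
    """Resolve the detection threshold (fixed value or global Otsu)."""
    return _resolve_threshold(stack, _preprocess(stack, params), params)


def _resolve_threshold(stack: ImageStack, marker: np.ndarray,
                       params: SurfaceParams) -> float:
    if params.threshold == "otsu":
        if marker.max() == marker.min():
            raise DetectionError("no surface contrast: marker channel is constant")
        return float(threshold_otsu(marker))
    thr = float(params.threshold)  # type: ignore[arg-type]
    raw = stack.channel(params.channel)
    if not raw.min() <= thr <= raw.max():
        raise ValueError(
            f"fixed threshold {thr} outside intensity range "
            f"[{raw.min()}, {raw.max()}]"
        )
    return thr


def detect_surface(stack: ImageStack, params: SurfaceParams = SurfaceParams()) -> HeightMap:
    """Detect the surface crossing in every (y, x) column.

    Returns a :class:`HeightMap` whose heights are the integer crossing
    slices; columns with no run of ``min_run`` consecutive above-threshold
    slices are invalid. Deterministic: identical stack and parameters give
    an identical map.
    """
    if stack.nz < params.min_run:
        raise ValueError(f"stack has {stack.nz} slices < min_run={params.min_run}")
    marker = _preprocess(stack, params)
    thr = _resolve_threshold(stack, marker, params)

    above = marker >= thr
    # run_ok[z] = above[z] & above[z+1] & ... & above[z+min_run-1]
    run_ok = above[: stack.nz - params.min_run + 1].copy()
    for k in range(1, params.min_run):
        run_ok &= above[k : stack.nz - params.min_run + 1 + k]
    valid = run_ok.any(axis=0)
    height = np.argmax(run_ok, axis=0).astype(np.float32)
    height[~valid] = 0.0
    return HeightMap(height, valid, nz=stack.nz)


def fill_gaps(hm: HeightMap) -> HeightMap:
    """Fill invalid columns with the height of the nearest valid column.

    Nearest is Euclidean in (y, x); valid entries are returned unchanged.

    Raises
    ------
    DetectionError
        If the map has no valid entry at all.
    """
    if not hm.valid.any():
        raise DetectionError("no surface found: height map has zero valid entries")
    if hm.all_valid:
        return HeightMap(hm.height.copy(), hm.valid.copy(), nz=hm.nz)
    _, (iy, ix) = ndi.distance_transform_edt(~hm.valid, return_indices=True)
    filled = hm.height[iy, ix].astype(np.float32)
    return HeightMap(filled, np.ones_like(hm.valid, dtype=bool), nz=hm.nz)


def regularize(hm: HeightMap, params: SurfaceParams = SurfaceParams()) -> HeightMap:
    """Median-filter then Gaussian-smooth a fully valid height map.

    Radius 0 and sigma 0 are exact identities. Output heights are clipped to
    [0, nz-1] when the map records its source nz. Both filters use reflecting
    boundaries, so the output range never exceeds the input range.
    """
    if not hm.all_valid:
        raise ValueError("regularize requires a fully valid height map; run fill_gaps")
    height = hm.height.astype(np.float32)
    if params.map_median_radius > 0:
        height = ndi.median_filter(height, size=2 * params.map_median_radius + 1)
    if params.map_smooth_sigma_px > 0:
        height = ndi.gaussian_filter(height, sigma=params.map_smooth_sigma_px)
    if hm.nz is not None:
        height = np.clip(height, 0.0, hm.nz - 1)
    return HeightMap(height, np.ones_like(hm.valid, dtype=bool), nz=hm.nz)


def extract_surface(stack: ImageStack, params: SurfaceParams = SurfaceParams()) -> HeightMap:
    """Full surface chain: detect, fill gaps, regularise."""
    return regularize(fill_gaps(detect_surface(stack, params)), params)
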