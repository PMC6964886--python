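"""Ground-truthed synthetic confocal leaf phantoms and tabular fixtures.

The stack phantom emulates imaging down through the abaxial epidermis into
the mesophyll: a smooth contoured surface, a bright membrane-marker shell at
the surface with a sparse Voronoi cell-wall texture inside the tissue
(channel 0), and a reporter channel (channel 1) that is homogeneous within
each tissue layer — epidermis directly under the surface, then an optional
gap, then mesophyll down to the stack bottom. Exact ground truth (analytic
surface, first-tissue slice, per-voxel layer labels) is returned alongside,
so every pipeline stage can be scored without real acquisitions.

All generators are bit-reproducible: one seed governs everything, with
per-purpose child streams spawned deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.spatial import cKDTree

from .peeler import PeelSpec
from .phenoquant import DEFAULT_ROI_AREA_MM2, CountRecord, CtRecord
from .stack_io import HeightMap, ImageStack

BACKGROUND, EPIDERMIS, MESOPHYLL = 0, 1, 2


@dataclass
class PhantomSpec:
    """Parameters of a two-tissue leaf phantom.

    The surface model gives the analytic depth h(y, x) of the outer leaf
    surface in slices from the stack-entry side; tissue occupies z >= h.
    ``surface_shell_slices`` is the axial extent of the bright outer-membrane
    shell (2 slices by default, the apparent thickness of a membrane at
    typical confocal z-steps, and enough to satisfy run-based detection).
    """

    shape: tuple[int, int, int] = (30, 256, 256)  # (nz, ny, nx)
    surface_model: str = "flat"
    base_depth: float = 5.0
    tilt: tuple[float, float] = (0.0, 0.02)  # slices per pixel in (y, x)
    amplitude: float = 3.0
    period: float = 64.0
    bump_center: Optional[tuple[float, float]] = None  # (y, x); default image centre
    bump_width: float = 32.0
    epidermis_thickness_slices: int = 4
    mesophyll_gap_slices: int = 1
    mesophyll_thickness_slices: Optional[int] = None  # None = to stack bottom
    surface_shell_slices: int = 2
    marker_intensity: float = 100.0
    reporter_means: tuple[float, float] = (80.0, 40.0)
    noise_sigma: float = 5.0
    poisson: bool = False
    cell_diameter_px: float = 16.0
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.surface_model not in ("flat", "plane", "sine", "bump"):
            raise ValueError(f"unknown surface model {self.surface_model!r}")
        if self.epidermis_thickness_slices <= 0:
            raise ValueError("epidermis_thickness_slices must be > 0")
        if self.mesophyll_gap_slices < 0 or self.surface_shell_slices < 1:
            raise ValueError("gap must be >= 0 and shell >= 1 slices")
        if self.marker_intensity <= 0 or self.noise_sigma < 0:
            raise ValueError("marker_intensity must be > 0 and noise_sigma >= 0")
        if any(m < 0 for m in self.reporter_means):
            raise ValueError("reporter means must be >= 0")

    def height_truth(self) -> np.ndarray:
        """Analytic surface depth h(y, x) in slices (float64)."""
        _, ny, nx = self.shape
        yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
        if self.surface_model == "flat":
            h = np.full((ny, nx), float(self.base_depth))
        elif self.surface_model == "plane":
            ty, tx = self.tilt
            h = self.base_depth + ty * yy + tx * xx
        elif self.surface_model == "sine":
            h = self.base_depth + self.amplitude * np.sin(
                2 * np.pi * xx / self.period
            ) * np.cos(2 * np.pi * yy / self.period)
        else:  # bump
            cy, cx = self.bump_center or ((ny - 1) / 2.0, (nx - 1) / 2.0)
            h = self.base_depth + self.amplitude * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * self.bump_width**2)
            )
        return h


@dataclass
class PhantomTruth:
    """Exact ground truth of a generated phantom."""

    height_truth: np.ndarray  # analytic surface, float
    surface_slice: np.ndarray  # first tissue slice per column, int (= ceil(height))
    layer_labels: np.ndarray  # per-voxel {0 background, 1 epidermis, 2 mesophyll}
    spec: PhantomSpec

    def heightmap(self) -> HeightMap:
        """Ground-truth surface as a fully valid HeightMap (slice grid)."""
        return HeightMap(
            self.surface_slice.astype(np.float32),
            np.ones(self.surface_slice.shape, dtype=bool),
            nz=self.spec.shape[0],
        )


def epidermis_peel_spec(spec: PhantomSpec) -> PeelSpec:
    """PeelSpec selecting exactly the phantom's epidermis layer."""
    return PeelSpec(offset=0, depth=spec.epidermis_thickness_slices, units="slices")


def mesophyll_peel_spec(spec: PhantomSpec) -> PeelSpec:
    """PeelSpec selecting the phantom's mesophyll layer (clips at stack bottom)."""
    offset = spec.epidermis_thickness_slices + spec.mesophyll_gap_slices
    depth = spec.mesophyll_thickness_slices or spec.shape[0]
    return PeelSpec(offset=offset, depth=depth, units="slices")


def _voronoi_walls(ny: int, nx: int, cell_diameter_px: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Boolean (y, x) map of boundaries between random Voronoi cells."""
    n_cells = max(2, int(round(ny * nx / cell_diameter_px**2)))
    seeds = rng.uniform([0, 0], [ny, nx], size=(n_cells, 2))
    yy, xx = np.mgrid[0:ny, 0:nx]
    _, labels = cKDTree(seeds).query(np.column_stack([yy.ravel(), xx.ravel()]))
    lab = labels.reshape(ny, nx)
    walls = np.zeros((ny, nx), dtype=bool)
    walls[:, 1:] |= lab[:, 1:] != lab[:, :-1]
    walls[1:, :] |= lab[1:, :] != lab[:-1, :]
    return walls


def simulate_stack(spec: PhantomSpec) -> tuple[ImageStack, PhantomTruth]:
    """Generate a two-channel leaf phantom and its exact ground truth.

    Channel 0 ("membrane"): marker_intensity on the surface shell and on
    Voronoi cell walls within the tissue, 0 in background. Channel 1
    ("reporter"): reporter_means[0] inside the epidermis label,
    reporter_means[1] inside the mesophyll label. Additive Gaussian noise of
    sigma ``noise_sigma`` (clipped at 0) on both channels, or Poisson shot
    noise on the clean signal when ``poisson`` is set. Identical spec and
    seed give bit-identical output.
    """
    nz, ny, nx = spec.shape
    h = spec.height_truth()
    if h.min() < 1 or h.max() > nz - 2:
        raise ValueError(
            f"surface range [{h.min():.2f}, {h.max():.2f}] leaves < 1 slice of "
            f"margin inside the {nz}-slice stack"
        )
    zsurf = np.ceil(h).astype(np.int64)

    z = np.arange(nz)[:, np.newaxis, np.newaxis]
    t = spec.epidermis_thickness_slices
    gap = spec.mesophyll_gap_slices
    meso_top = zsurf + t + gap
    meso_bot = meso_top + (spec.mesophyll_thickness_slices or nz)
    labels = np.zeros((nz, ny, nx), dtype=np.uint8)
    labels[(z >= zsurf) & (z < zsurf + t)] = EPIDERMIS
    labels[(z >= meso_top) & (z < meso_bot)] = MESOPHYLL

    ss = np.random.SeedSequence(spec.seed)
    rng_walls, rng_marker, rng_reporter = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )

    shell = (z >= zsurf) & (z < zsurf + spec.surface_shell_slices)
    walls2d = _voronoi_walls(ny, nx, spec.cell_diameter_px, rng_walls)
    marker = np.where(
        shell | (walls2d[np.newaxis] & (labels > 0)), spec.marker_intensity, 0.0
    )

    epi_mean, meso_mean = spec.reporter_means
    reporter = np.zeros((nz, ny, nx), dtype=np.float64)
    reporter[labels == EPIDERMIS] = epi_mean
    reporter[labels == MESOPHYLL] = meso_mean

    if spec.poisson:
        marker = rng_marker.poisson(marker).astype(np.float64)
        reporter = rng_reporter.poisson(reporter).astype(np.float64)
    elif spec.noise_sigma > 0:
        marker = marker + rng_marker.normal(0, spec.noise_sigma, marker.shape)
        reporter = reporter + rng_reporter.normal(0, spec.noise_sigma, reporter.shape)
    marker = np.clip(marker, 0, None)
    reporter = np.clip(reporter, 0, None)

    stack = ImageStack(
        np.stack([marker, reporter]).astype(np.float32),
        ["membrane", "reporter"],
        spec.voxel_size_um,
    )
    return stack, PhantomTruth(h, zsurf, labels, spec)


def simulate_counts(
    n_samples: int,
    si_true: float,
    cells_per_roi: int,
    seed: int = 0,
    roi_area_mm2: float = DEFAULT_ROI_AREA_MM2,
) -> list[CountRecord]:
    """Binomial stomatal-count fixtures at a true stomatal index (percent).

    Each sample draws stomata ~ Binomial(cells_per_roi, si_true/100); the
    remaining cells are non-stomatal epidermal cells.
    """
    if not 0 <= si_true <= 100:
        raise ValueError("si_true must be a percentage in [0, 100]")
    if cells_per_roi < 1 or n_samples < 1:
        raise ValueError("cells_per_roi and n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    stomata = rng.binomial(cells_per_roi, si_true / 100.0, size=n_samples)
    return [
        CountRecord(
            sample_id=f"s{i:04d}",
            stomata=int(s),
            epidermal_cells=int(cells_per_roi - s),
            roi_area_mm2=roi_area_mm2,
        )
        for i, s in enumerate(stomata)
    ]


def simulate_ct(
    fold_changes: Mapping[str, float],
    base_ct: float = 25.0,
    replicate_sigma: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    gene: str = "target",
    reference_gene: str = "UBC21",
) -> list[CtRecord]:
    """qPCR Ct fixtures whose 2^-ddCt analysis recovers ``fold_changes``.

    ``fold_changes`` maps condition name -> true fold change relative to the
    calibrator (include the calibrator itself with fold 1). Target Ct =
    base_ct - log2(fold) + noise; reference Ct = base_ct + noise, noise
    iid N(0, replicate_sigma^2) per measurement.
    """
    if not fold_changes:
        raise ValueError("fold_changes must name at least one condition")
    for cond, f in fold_changes.items():
        if not f > 0:
            raise ValueError(f"fold change for {cond!r} must be > 0, got {f}")
    rng = np.random.default_rng(seed)
    records: list[CtRecord] = []
    for cond, fold in fold_changes.items():
        for i in range(n_replicates):
            sample = f"{cond}_r{i}"
            ct_t = base_ct - np.log2(fold) + rng.normal(0, replicate_sigma)
            ct_r = base_ct + rng.normal(0, replicate_sigma)
            records.append(CtRecord(sample, cond, gene, float(ct_t), reference_gene))
            records.append(CtRecord(sample, cond, reference_gene, float(ct_r), reference_gene))
    return records
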