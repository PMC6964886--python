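# Methods

## The problem

Confocal Z-stacks of young leaves are acquired down through the abaxial
epidermis into the mesophyll. The leaf surface is curved, so any fixed
z-slice mixes tissues: a slice that shows epidermis at the centre of the
field shows background at its edges and mesophyll elsewhere. To compare a
reporter's signal between the epidermis and the mesophyll, the stack must be
resampled relative to the *contoured surface*, not the image grid. leafpeel
does this in three stages: (1) detect the surface in a plasma-membrane
marker channel and regularise it into a height map `h(y, x)`; (2) select the
voxel slab `h + offset <= z < h + offset + depth` ("peeling"); (3) render
Z-sum projections of the peeled slab and quantify per-channel signal in it.

## Surface detection

The marker channel is optionally pre-smoothed with an anisotropic 3-D
Gaussian, a global threshold is fixed (a user value or Otsu's method on the
smoothed channel), and each (y, x) column is scanned from z = 0 (the
stack-entry side, nearest the objective) for the first z at which the
intensity stays at or above the threshold for `min_run` consecutive slices.
That z — an integer slice index — is the column's height; columns with no
qualifying run are invalid.

Parameter defaults and rationale:

| parameter              | default         | why |
|------------------------|-----------------|-----|
| `pre_smooth_sigma_vox` | (0.5, 1.0, 1.0) | Lateral smoothing (sigma 1 px) suppresses shot noise; the axial sigma is kept small (0.5 slices) because axial blurring moves the apparent onset of a thin bright shell up the column and biases every height by up to a slice. For noiseless or very clean data set it to 0: detection is then exact. |
| `threshold`            | `"otsu"`        | Resolved once globally; per-column thresholds are unstable in dark columns. Requires genuine foreground/background contrast — a constant channel raises a detection error. |
| `min_run`              | 2               | One-voxel noise spikes above threshold are rejected; two consecutive slices is the shortest run a real membrane shell produces at typical z-steps. |
| `map_median_radius`    | 2 px            | Removes isolated column failures (dust, speckle) from the height map. |
| `map_smooth_sigma_px`  | 2 px            | The biological surface is smooth at the cell scale; this suppresses the 1-slice staircase quantisation of integer crossings. |

Invalid columns are filled with the height of the nearest valid column
(Euclidean distance in the image plane, computed by a distance transform;
when several valid pixels are equidistant the transform's deterministic
choice is used — fill values are always the height of *some* nearest valid
pixel). Regularisation applies a median filter then Gaussian smoothing, both
with reflecting boundaries, so the output height range never exceeds the
input range; results are clipped to [0, nz-1].

Detection is deliberately slice-quantised: sub-slice heights arise only from
regularisation, never from interpolating the crossing. This keeps the
detection contract trivial to reason about (monotone in the threshold,
exact on noiseless step profiles for any threshold strictly between
background and signal).

## Peeling geometry

A layer is the half-open slab `[h + offset, h + offset + depth)` in
continuous z, intersected with integer slices by
`ceil(lower) <= z < ceil(upper)`. Consequences, all load-bearing:

- **Tiling.** Layers `(0, d1)` and `(d1, d2)` are disjoint and their union
  is `(0, d1 + d2)` for every height map and every (possibly fractional)
  d1, d2 — an epidermis/mesophyll split never double-counts a voxel and
  never drops one.
- **Clipping.** Slabs extending past the stack clip silently (logged);
  deep offsets near the stack bottom are routine, not errors.
- **Units.** Offsets/depths are in slices by default; micrometre specs are
  converted with the axial voxel size dz from the stack metadata.

Peeling zero-fills outside the mask (not NaN) so that sum projections remain
well defined. Sum projections accumulate in int64 for integer stacks and
float64 otherwise, so the total intensity of a sum projection equals the
masked voxel total exactly for integer data. Quantification of an empty
layer raises an error rather than returning 0/0.

## Quantification formulas

- Stomatal index `SI = 100 * S / (S + E)` with S stomata and E non-stomatal
  epidermal cells in the ROI; the percentage of epidermal cells that are
  stomata. Invariant under double-counting the same field.
- Stomatal density `SD = S / area_mm2`; the conventional counting window is
  400 um x 400 um = 0.16 mm².
- Relative expression by 2^-ddCt: per sample dCt = Ct_target - Ct_reference
  (reference gene, e.g. UBC21 or UBQ10, measured in the same sample); dCt is
  averaged arithmetically over replicate samples within a condition (the
  standard practice; averaging fold-changes instead would up-weight
  outliers on the linear scale), ddCt is taken against a calibrator
  condition, and expression is 2^-ddCt with amplification efficiency fixed
  at 2 (no efficiency calibration). The calibrator maps to exactly 1.0.
- Dual luciferase: firefly / Renilla, the co-transfected Renilla signal
  normalising transfection efficiency; zero Renilla is an input error.

Hypothesis tests on these quantities (Welch's t-test, one-way ANOVA,
Holm-Sidak) are thin pass-throughs to scipy/statsmodels and carry no logic
of their own.

## The synthetic phantom

`simulate_stack` builds the minimum structure that makes threshold-based
surface detection nontrivial but well-posed: an analytic surface h(y, x)
(flat, tilted plane, 2-D sine, or Gaussian bump), tissue at z >= h, a
membrane-marker shell `surface_shell_slices` thick (default 2 slices, the
apparent axial extent of a membrane at typical confocal z-steps — and the
minimum that supports run-based detection with `min_run = 2`) plus a sparse
Voronoi cell-wall texture inside the tissue, and a reporter channel that is
homogeneous per layer (defaults 80 in the epidermis, 40 in the mesophyll,
emulating an epidermis-enriched reporter). Noise is additive Gaussian
(default sigma 5 = 5% of the default marker intensity 100) clipped at zero,
with an optional Poisson shot-noise mode. Default geometry: 30 slices of
256 x 256, surface 5 slices deep, 4-slice epidermis, 1-slice gap, mesophyll
to the stack bottom.

Ground truth is exact by construction and returned alongside: the analytic
height, the integer first-tissue slice `surface_slice = ceil(h)`, and
per-voxel layer labels. Because detection is slice-quantised, recovered
heights are scored against `surface_slice`; the analytic height is provided
for geometric analyses.

What the phantom does **not** emulate — and therefore what passing tests do
not establish about real acquisitions: a realistic PSF, depth-dependent
attenuation and scattering, anisotropic voxels with refractive-index
mismatch, autofluorescence gradients, or surfaces with overhangs (a height
map is single-valued by construction). Real stacks with strong axial
attenuation may need a lower fixed threshold or per-stack inspection of the
detected map.

Reproducibility: one integer seed governs all randomness; per-purpose child
generators are spawned deterministically from it, so identical specs give
bit-identical stacks.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run on phantoms of 256 x 256 x 30
(surface recovery, layer quantification; the sizes at which the detection
defaults are characterised) and on 16 x 16 x 12 stacks for exhaustive
brute-force checks of mask geometry, with 20 noise realisations for surface
RMSE, 500 samples for the stomatal-index estimator and 200 seeds for the
ddCt fold-change estimator — sizes at which the Monte-Carlo standard errors
are an order of magnitude below the tolerances being checked.

## Known limitations

- Single-surface assumption: one crossing per column; folded or detached
  tissue above the true surface will capture the detector.
- Thin layers inherit surface error: a residual height error of e slices
  mixes roughly e/depth of a neighbouring layer (or background) into the
  slab, so means over few-slice layers on curved surfaces should be read
  together with the surface RMSE.
- Global threshold: strong lateral illumination gradients can bias heights;
  there is no adaptive/per-region thresholding.
- No efficiency-calibrated qPCR model and no multi-reference geometric-mean
  normalisation; the ddCt implementation is the classic fixed-efficiency
  method.
- Proprietary microscope formats (OIB/OIF, CZI) are out of scope; convert
  to TIFF first.
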