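# leafpeel

Surface-guided tissue-layer peeling and quantification for plant confocal
Z-stacks.

Confocal stacks of young leaves are acquired down through the curved abaxial
epidermis into the mesophyll, so no fixed z-slice corresponds to one tissue.
leafpeel segments the contoured leaf surface from a plasma-membrane marker
channel into a height map `h(y, x)`, extracts the voxel slab a user-defined
*offset* and *depth* below that surface,

```
layer(y, x) = { z : h(y, x) + offset <= z < h(y, x) + offset + depth }
```

renders Z-sum projections of the peeled slab, and reports per-channel layer
statistics — so epidermis and mesophyll signal (e.g. a transcription-factor
reporter such as HY5-CFP over a wave_138Y membrane marker) can be rendered
and compared separately. Layers are half-open, so an epidermis slab and the
mesophyll slab that starts where it ends tile each column exactly, with no
voxel counted twice.

It also implements the quantification formulas that accompany this kind of
imaging in stomatal-development work:

- stomatal index `SI = 100 · S / (S + E)` (percent of epidermal cells that
  are stomata) and stomatal density `SD = S / mm²`,
- relative gene expression by the 2^−ΔΔCt method against a reference gene
  (UBC21/UBQ10) and a calibrator condition,
- dual-luciferase normalisation (firefly / Renilla),

plus a ground-truthed synthetic phantom generator so the whole pipeline is
testable without any real acquisition.

Intended users: plant cell biologists quantifying layer-resolved reporter
signal from standard TIFF exports, and anyone needing a scriptable,
reproducible alternative to interactive surface-projection tools.

## Worked example

Simulate a phantom leaf (default geometry: flat surface 5 slices deep,
4-slice epidermis with reporter mean 80, mesophyll with reporter mean 40,
Gaussian noise σ = 5), recover the surface, peel both layers and quantify:

```python
import numpy as np
import leafpeel as lp
from leafpeel.synthetic import epidermis_peel_spec, mesophyll_peel_spec

spec = lp.PhantomSpec(seed=7)
stack, truth = lp.simulate_stack(spec)

hm = lp.extract_surface(stack, lp.SurfaceParams())   # detect → fill → regularise
rmse = np.sqrt(np.mean((hm.height - truth.surface_slice) ** 2))
print(f"surface RMSE: {rmse:.3f} slices")

for name, pspec in [("epidermis", epidermis_peel_spec(spec)),
                    ("mesophyll", mesophyll_peel_spec(spec))]:
    mask = lp.make_layer_mask(stack.spatial_shape, hm, pspec, stack.voxel_size_um)
    stats = lp.quantify_layer(stack, mask, channel=1)
    print(f"{name}: mean reporter intensity {stats.mean_intensity:.2f} "
          f"over {stats.voxel_count} voxels")
```

Output:

```
surface RMSE: 0.000 slices
epidermis: mean reporter intensity 80.00 over 262144 voxels
mesophyll: mean reporter intensity 40.00 over 1310720 voxels
```

Despite σ = 5 noise on both channels, the flat surface is recovered exactly
and the peeled-layer means match the generating truth (80, 40) — the
separation that makes a per-layer comparison of reporter signal meaningful.
On the curved sine phantom at the same noise level the surface is recovered
to about a third of a slice (run `surface_model="sine"` above to see it),
and that residual error leaks a few background voxels into the thin
epidermal slab, biasing its mean — which is why thin-layer means should
always be read together with the surface RMSE.

The same workflow from the shell:

```bash
leafpeel simulate --seed 7 --surface-model sine --out phantom.tif
leafpeel pipeline phantom.tif --outdir run/      # surface + both layers + CSV
leafpeel phenostats counts.csv --kind counts --out si_sd.csv
leafpeel phenostats ct.csv --kind ddct --calibrator control --out rel_expr.csv
```

`pipeline` writes the height map, peeled stacks, masks, sum projections and
`layer_stats.csv`, plus a JSON run record (resolved config, version, input
checksums) for every output. Formula quick-reference: `stomatal_index(10, 40)
→ 20.0`, `stomatal_density(24, 0.16) → 150.0 /mm²`, one extra target cycle →
`2^−1 = 0.5` relative expression, `luciferase_ratio(1000, 500) → 2.0`.

See `docs/methods.md` for the detection rule, the peeling geometry and its
invariants, parameter defaults, and what the phantom does and does not
emulate.

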