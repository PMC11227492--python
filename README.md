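# elastomap

Analysis pipeline for multiparametric MRI of preclinical brain tumors,
centred on magnetic resonance elastography (MRE).  It reconstructs
viscoelasticity maps from raw wrapped wave-phase images, fits diffusion
metrics (ADC, FA) from DWI, quantifies tumor stiffness heterogeneity and
its relation to myeloid-marker maps, and classifies volumetric treatment
response with ROC-based biomarker discrimination — everything exercisable
end-to-end on synthetic phantoms and cohorts with known ground truth, so no
animal data is required.

Intended users: preclinical imaging groups analysing murine glioma models
under therapy (e.g. immunotherapy), and anyone who needs a tested,
self-contained single-frequency MRE inversion chain.

## The reconstruction chain

A mechanical shaker drives shear waves (here 900 Hz) into the brain; the MR
sequence encodes the tissue displacement into image phase at four wave-phase
offsets per encoding direction.  The pipeline follows the standard algebraic
inversion:

1. **Unwrap** each 2-D slice of wrapped phase (reliability-sorted unwrapping).
2. **Align** slices by removing per-slice 2π offsets.
3. **First harmonic**: 4-point Fourier transform over the wave-phase offsets,
   `U(x) = (2/N) Σⱼ φ(x, φⱼ) e^{-iφⱼ}`, converted to displacement `u` via the
   encoding efficiency.
4. **Curl** `q = ∇×u` removes compressional wave contributions.
5. **Helmholtz inversion** under local homogeneity: per voxel, the complex
   shear modulus solves `ρω²q = -G*∇²q`, combined across the three curl
   components by complex least squares.
6. **Scalar maps**: stiffness `|G*| = √(G_d² + G_l²)` and phase angle
   `Y = (2/π)·atan(G_l/G_d)`, where `G_d`/`G_l` are the storage and loss
   moduli.  `Y = 0` is purely elastic, `Y = 1` purely viscous.

Downstream, elastograms are segmented into stiffness bands relative to
healthy brain (low < 4.5 kPa, intermediate 4.5–6.5 kPa, high > 6.5 kPa), and
the marker-positive volume percentage per band is computed against
co-registered microscopy-derived masks.  Tumor response is called from
longitudinal volumetry (PD ≥ +40 %, PR ≤ −65 %, SD between), and per-week
biomarkers are compared between groups by empirical ROC analysis with
rank-statistic AUC, Wilson score intervals for sensitivity/specificity and
Youden-index optimal criteria.

## Worked example

```python
import numpy as np
from elastomap import *

grid = VoxelGrid((32, 32, 32), (0.3, 0.3, 0.3))          # 300 um isotropic
phantom = make_phantom(grid, 5000 + 1500j,               # healthy background
                       [(Sphere((15.5, 15.5, 14.0), 6.0), 3770 + 1200j)])
field = solve_wavefield(phantom, 900.0)                  # 900 Hz shear waves
series = encode_phase_series(field, EncodingModel(), seed=1)
modulus = reconstruct(series, rho=1000.0)
gstar, y = modulus_maps(modulus)

tumor = LabeledVolume(grid, (phantom.labels == 1).astype(np.uint8), "mask")
stats = region_stats({"gstar_pa": gstar, "phase_angle": y}, tumor)
print(f"tumor volume: {stats.volume_mm3:.2f} mm^3 ({stats.voxel_count} voxels)")
print(f"tumor |G*|:   {stats.stats['gstar_pa']['median'] / 1000:.2f} kPa (median)")
print(f"tumor Y:      {stats.stats['phase_angle']['median']:.3f} (median)")
bands = stiffness_bands(gstar, tumor)
print("band voxels (low/intermediate/high):", bands.counts)
```

prints

```
tumor volume: 23.98 mm^3 (888 voxels)
tumor |G*|:   3.96 kPa (median)
tumor Y:      0.196 (median)
band voxels (low/intermediate/high): (832, 56, 0)
```

The spherical "tumor" was built at `G* = 3770 + 1200i` Pa, i.e.
`|G*| = 3.96` kPa and `Y = 0.196`: the full chain — forward wave solve,
motion encoding with wrapping, unwrapping, 4-point transform, curl and
Helmholtz inversion — recovers both to the printed precision, and nearly the
whole tumor falls into the "low" stiffness band, as it should for a lesion
softer than the 4.5 kPa threshold.

A command-line interface mirrors the library:
`elastomap simulate|reconstruct|diffusion|quantify|respond --help`.

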