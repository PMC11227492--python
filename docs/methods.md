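# Methods

## Scope and model

`elastomap` implements the single-frequency algebraic MRE inversion for
small-animal brain imaging together with its surrounding analysis: diffusion
tensor metrics, region quantification, and treatment-response statistics.
The physical model is a linear viscoelastic solid probed by time-harmonic
shear waves: each displacement component is assumed to satisfy the local
Helmholtz relation `ρω²u + G*∇²u = 0` with a voxelwise complex shear modulus
`G* = G_d + iG_l` (local homogeneity: spatial gradients of `G*` are
neglected).  Compressional contributions are suppressed by inverting the
curl of the displacement rather than the displacement itself.  No rheological
model (Voigt, springpot) is fitted: at a single vibration frequency the
direct `G_d`/`G_l` estimate is the natural output.

Conventions fixed throughout: time factor `e^{+iωt}`; lengths in mm
internally, SI (metres) inside the inversion so moduli come out in Pa
(reported in kPa); displacement in µm; density ρ = 1000 kg/m³ by default
(soft tissue ≈ water; ρ only scales `|G*|`); vibration frequency 900 Hz by
default; axis order (x, y, z) with z the slice axis.

## Reconstruction chain — numerical choices

- **Unwrapping**: per-slice 2-D reliability-sorted (quality-guided)
  unwrapping (`skimage.restoration.unwrap_phase`).  Valid when true in-slice
  phase gradients stay below π per voxel — satisfied by the default encoding
  (efficiency 0.3 rad/µm, amplitudes ≤ ~10 µm) at ≥ 5 voxels per wavelength.
- **Slice alignment**: adjacent-slice median differences estimate per-slice
  constants; by default only their integer-multiple-of-2π part is removed,
  because that is the only ambiguity per-slice unwrapping can introduce —
  genuine inter-slice wave structure must survive.  Full constant-bias
  removal is available (`remove_bias=True`).  Each (offset, direction)
  volume is finally recentred so its median lies in (−π, π]; a constant that
  is consistent across offsets cancels exactly in the 4-point transform.
- **First harmonic**: uniform 4-point temporal DFT on the phase domain,
  `U = (2/N) Σⱼ φⱼ e^{-iφⱼ}` (so `a·cosφ + b·sinφ → a − ib`).  Operating on
  phase rather than complex exponentials is exact in the motion-encoded
  regime where phase is linear in displacement.  The displacement vector is
  assembled by (pseudo)inverting the encoding-direction matrix; rank
  deficiency is an error.
- **Curl**: second-order central differences (one-voxel rim invalid).
- **Laplacian**: 7-point central second differences.  The same stencil is
  used by the forward solver and the inversion, deliberately: a solved field
  satisfies the inverse problem's discrete equation to round-off, so
  end-to-end phantom tests isolate the chain's algebra from discretization
  error.  For analytic (continuum) fields the stencil's `O((kh)²/12)`
  dispersion bounds the recovery error; at 0.1 mm spacing and 5 kPa this is
  ≈ 0.5 %, at the 0.3 mm acquisition spacing ≈ 5 %.
- **Inversion**: complex least squares across the three curl components,
  `G* = −ρω² Σ_c (∇²q_c)* q_c / Σ_c |∇²q_c|²` — noise-optimal under i.i.d.
  Gaussian residuals and identical to the per-component ratio in noiseless
  data.  Voxels with `‖∇²q‖` below 1e-6 × its 95th percentile (wave nodes)
  are masked, as are two rim voxels where the stacked stencils do not fit.
- **Scalar maps**: `|G*| = √(G_d² + G_l²)`; `Y = (2/π)·atan2(G_l, G_d)`,
  giving the limit `Y = 1` at `G_d = 0, G_l > 0` and a masked (NaN) value
  when both vanish.  Negative `G_d` (possible under heavy noise) yields
  `Y > 1` and flags a voxel as unphysical rather than clipping silently.
- **Smoothing**: none by default.  Optional Gaussian pre-smoothing of the
  complex displacement (σ in voxels) is exposed for noisy data; with phase
  noise σ = 0.05 rad at 0.3 mm spacing, 1-voxel smoothing keeps the median
  `|G*|` error under 15 % (asserted loosely in the suite).

## Forward simulation (synthetic_data)

The generator produces every pipeline input with known ground truth:

- **Phantoms**: piecewise-constant `G*` with sphere/box inclusions and
  region labels; defaults echo the study conditions (≈ 5 kPa healthy brain,
  ≈ 3.8–4.6 kPa tumors, 2 vs 5 kPa bimodal late-stage configurations).
- **Wave fields**: either exact analytic plane waves `A e^{ik·x}` with
  `k = ω√(ρ/G*)` (root chosen with Im k ≥ 0, decaying along propagation), or
  a finite-difference frequency-domain scalar Helmholtz solve per component
  (7-point stencil, direct sparse LU, MMD ordering).  A Dirichlet source
  drives the z = 0 face; the other five faces carry a quadratic "sponge"
  ramp that raises the local loss modulus to emulate absorbing boundaries.
  Vector coupling and mode conversion are neglected — sufficient to test an
  inversion that itself assumes component-wise Helmholtz behaviour, and an
  acknowledged departure from full elastodynamics.
- **Motion encoding**: raw phase = efficiency · Re{(u·d) e^{iφⱼ}} +
  per-slice polynomial background + optional constant slice offsets +
  Gaussian noise, wrapped to [−π, π).  Offsets default to (0, π/2, π, 3π/2)
  — uniform sampling is required for the exact 4-point DFT.  The encoding
  efficiency (0.3 rad/µm) is an arbitrary documented constant, not matched
  to any scanner's motion-encoding gradients.
- **DWI**: `S_i = S0·exp(−b dᵢᵀD dᵢ)` at b = 1500 s/mm², 30 quasi-uniform
  (Fibonacci) directions, additive Gaussian noise only.
- **Cohorts**: per-group weekly means follow the reported study values
  (tumor volume, `|G*|`, Y, ADC, FA for a vehicle-control and a treated
  group of 11 and 9 animals).  Dispersion is not reported per week, so the
  generator fixes field-realistic defaults once: volumes lognormal with
  CV 0.35 (tumor volumes are positive and right-skewed), `|G*|` SD 500 Pa,
  Y truncated-normal SD 0.05 on [0, 1], ADC SD 0.08×10⁻³ mm²/s, FA SD 0.03.
  Zero-SD specs reproduce the means exactly, which the tests exploit.
- **Marker maps**: within each stiffness band, a requested percentage of
  voxels (nearest-voxel rounding) is marked positive uniformly at random.
  Note the convention difference, kept deliberately: the generator's
  fraction is per band, while `marker_fraction_by_band` reports percentages
  of the total tumor volume (the reporting convention); a per-band
  normalized variant sits behind `per_band=True`.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: anatomy, susceptibility/motion artifacts, Rician
magnitude noise, imperfect co-registration, scanner-specific encoding, and
full elastodynamic wave physics.  Parameter recovery here demonstrates the
correctness of the chain's algebra and its discretization behaviour, not
in vivo accuracy.

## Quantification choices

- Stiffness bands: low `< 4.5 kPa`, intermediate `4.5–6.5 kPa` (both
  boundaries closed into the intermediate band — the only reading consistent
  with "< 4.5", "4.5–6.5", "> 6.5"), high `> 6.5 kPa`; all restricted to
  tumor − exclusion; NaN (invalid) elastogram voxels leave the partition
  domain.  The partition property (band counts sum to the domain) is
  guaranteed and property-tested.
- The exclusion mask (damaged tissue: cracks, holes) is user-supplied or
  threshold-derived; there is no automatic damage detection.
- Contralateral reference ROI: mirror across the mid-sagittal plane
  (configurable axis/midline), clip to brain, make disjoint from tumor, then
  deterministically grow (distance-ordered dilation) or peel
  (shallowest-first) to the tumor's exact voxel count.
- `|G*|` histograms: 0.25 kPa default bins, frequencies normalized to 1,
  modes = local maxima with prominence ≥ 0.1 × peak frequency.
- Microscopy preprocessing: 5×5×5 block-average downsampling (edge blocks
  average available voxels; global mean preserved for divisible shapes), ITK
  adaptive histogram equalization (radius 5×5×5, α = 0.3, β = 0.3 defaults;
  flat volumes returned unchanged since equalizing a degenerate histogram is
  undefined), and simple threshold segmentation.  Whether the original
  AHE corresponds exactly to the ITK power-law formulation cannot be
  verified; the parameters are honoured and the formulation documented.

## Response statistics

- PD/SD/PR thresholds are boundary-inclusive exactly as printed
  (PD ≥ +40 %, PR ≤ −65 %, SD the open interval); classification is
  scale-invariant; subjects with missing weeks are flagged, never dropped.
  Cohort percentages round half-to-even (5/9, 2/9, 2/9 → 56/22/22).
- ROC: AUC is the tie-corrected two-sample rank statistic (equal to the
  trapezoid rule); cutoffs at midpoints between adjacent observed values;
  sensitivity/specificity CIs by the Wilson score interval; the AUC CI by
  Hanley–McNeil.  The "Wilson/Brown" label of common statistics software is
  ambiguous for the AUC specifically, so the Hanley–McNeil choice is a
  documented deviation rather than a guessed equivalence.  Youden-optimal
  criteria are reported as "< c" / "> c" with ties broken toward higher
  sensitivity, then smaller |c|; the direction is auto-oriented so
  AUC ≥ 0.5 unless fixed.  ROC uses raw week-specific values (consistent
  with absolute kPa/mm³ criteria), and no multiplicity adjustment is applied
  here — group-level inferential testing is out of scope.

## Problem sizes

Forward solves use 32³ grids at 0.3 mm (the acquisition resolution, ≈ 8
voxels per wavelength at 5 kPa), chosen as the smallest domain that leaves a
sponge-free interior of several wavelengths; analytic plane-wave checks use
0.1 mm grids where stencil dispersion is below 1 %.  Direct sparse LU on a
32³ complex system factors in ≈ 15–20 s; one factorization serves all three
displacement components.

## Known limitations

Single-frequency only; isotropic, locally homogeneous viscoelasticity; no
poroelastic or anisotropic models; no in vivo artifact correction; no
registration estimation (inputs are assumed co-registered); the in-house
reconstructions behind the original study may include undocumented
smoothing or regularization, so exact numeric equivalence with its
elastograms is not claimable — the package claims correctness against its
own stated chain and analytic oracles instead.
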