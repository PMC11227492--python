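"""Synthetic inputs with known ground truth for every pipeline stage.

This module is first-class simulation code, not a test fixture: it produces
viscoelastic phantoms, time-harmonic shear-wave displacement fields (either
analytic plane waves or a finite-difference frequency-domain Helmholtz solve),
motion-encoded wrapped phase series, mono-exponential DWI signals from known
diffusion tensors, longitudinal tumor-volume cohorts, and stiffness-band-
dependent marker masks.

Conventions: time factor e^{+i omega t}; vibration frequency defaults to
900 Hz; density defaults to 1000 kg/m^3 (soft tissue ~ water); lengths in mm,
moduli in Pa, displacements in um.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import stats

from . import _stencils
from .geometry import LabeledVolume, VoxelGrid, wrap_phase
from .mre import (
    DEFAULT_DENSITY,
    DEFAULT_FREQUENCY_HZ,
    DisplacementField,
    WavePhaseSeries,
)

__all__ = [
    "Phantom",
    "Sphere",
    "Box",
    "PlaneWaveSpec",
    "EncodingModel",
    "CohortSpec",
    "make_phantom",
    "plane_wave_field",
    "solve_wavefield",
    "encode_phase_series",
    "fibonacci_directions",
    "simulate_dwi",
    "simulate_cohort",
    "simulate_marker_map",
]


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Sphere:
    """Spherical inclusion in voxel coordinates."""

    center: Tuple[float, float, float]
    radius: float

    def mask(self, grid: VoxelGrid) -> np.ndarray:
        idx = np.indices(grid.shape)
        r2 = sum((idx[a] - self.center[a]) ** 2 for a in range(3))
        return r2 <= self.radius**2

    def inside(self, grid: VoxelGrid) -> bool:
        return all(
            self.center[a] - self.radius >= -0.5 and self.center[a] + self.radius <= grid.shape[a] - 0.5
            for a in range(3)
        )


@dataclass(frozen=True)
class Box:
    """Axis-aligned box inclusion, half-open voxel index ranges [lo, hi)."""

    lo: Tuple[int, int, int]
    hi: Tuple[int, int, int]

    def mask(self, grid: VoxelGrid) -> np.ndarray:
        m = np.zeros(grid.shape, dtype=bool)
        m[self.lo[0] : self.hi[0], self.lo[1] : self.hi[1], self.lo[2] : self.hi[2]] = True
        return m

    def inside(self, grid: VoxelGrid) -> bool:
        return all(0 <= self.lo[a] and self.hi[a] <= grid.shape[a] for a in range(3))


@dataclass
class Phantom:
    """Voxelwise ground-truth complex shear modulus plus region labels.

    ``G`` is Gd + i*Gl in Pa; invariants Gd > 0, Gl >= 0, rho > 0.  Label 0 is
    background; inclusion i carries label i + 1.
    """

    grid: VoxelGrid
    G: np.ndarray
    rho: float = DEFAULT_DENSITY
    labels: np.ndarray = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=complex)
        if self.G.shape != tuple(self.grid.shape):
            raise ValueError("modulus array shape must equal grid shape")
        if np.any(self.G.real <= 0):
            raise ValueError("storage modulus Gd must be > 0 everywhere")
        if np.any(self.G.imag < 0):
            raise ValueError("loss modulus Gl must be >= 0 everywhere")
        if self.rho <= 0:
            raise ValueError("density must be > 0")
        if self.labels is None:
            self.labels = np.zeros(self.grid.shape, dtype=np.int32)

    def region_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def make_phantom(
    grid: VoxelGrid,
    background_G: complex,
    inclusions: Sequence[Tuple[object, complex]] = (),
    rho: float = DEFAULT_DENSITY,
) -> Phantom:
    """Piecewise-constant viscoelastic phantom.

    ``inclusions`` is a list of ``(shape, G)`` pairs (:class:`Sphere` or
    :class:`Box`); later inclusions overwrite earlier ones where they overlap.
    """
    if complex(background_G).real <= 0:
        raise ValueError("background storage modulus must be > 0")
    G = np.full(grid.shape, complex(background_G), dtype=complex)
    labels = np.zeros(grid.shape, dtype=np.int32)
    for i, (shape_spec, g_val) in enumerate(inclusions):
        if complex(g_val).real <= 0:
            raise ValueError(f"inclusion {i}: storage modulus must be > 0")
        if not shape_spec.inside(grid):
            raise ValueError(f"inclusion {i} does not lie inside the grid")
        m = shape_spec.mask(grid)
        G[m] = complex(g_val)
        labels[m] = i + 1
    return Phantom(grid=grid, G=G, rho=rho, labels=labels)


# ---------------------------------------------------------------------------
# wave fields
# ---------------------------------------------------------------------------


def shear_wavenumber(rho: float, G: complex, frequency_hz: float) -> complex:
    """Complex shear wavenumber k (rad/m) with Im(k) >= 0 (decaying wave).

    k^2 = rho * omega^2 / G; of the two roots, the one decaying along the
    propagation direction under the e^{+i omega t} convention is returned.
    """
    omega = 2.0 * np.pi * frequency_hz
    k = omega * np.sqrt(rho / complex(G))
    if k.imag < 0:
        k = -k
    return k


@dataclass(frozen=True)
class PlaneWaveSpec:
    """Analytic shear plane wave: amplitude vector (um), unit propagation
    direction, vibration frequency (Hz)."""

    amplitude: Tuple[complex, complex, complex] = (5.0, 0.0, 0.0)
    direction: Tuple[float, float, float] = (0.0, 0.0, 1.0)
    frequency_hz: float = DEFAULT_FREQUENCY_HZ

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be > 0")
        d = np.asarray(self.direction, dtype=float)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-6):
            raise ValueError("propagation direction must be a unit vector")


def plane_wave_field(
    grid: VoxelGrid,
    spec: PlaneWaveSpec,
    rho: float = DEFAULT_DENSITY,
    G: complex = 5000 + 1500j,
) -> DisplacementField:
    """u(x) = A exp(i k d.x) satisfying the homogeneous Helmholtz relation
    rho omega^2 u + G laplacian(u) = 0 exactly for the given (rho, G, f)."""
    k = shear_wavenumber(rho, G, spec.frequency_hz)  # rad/m
    ax = grid.axes_mm()
    x, y, z = np.meshgrid(*ax, indexing="ij")
    d = np.asarray(spec.direction, dtype=float)
    proj_m = (d[0] * x + d[1] * y + d[2] * z) * 1e-3
    carrier = np.exp(1j * k * proj_m)
    amp = np.asarray(spec.amplitude, dtype=complex)
    u = amp[:, None, None, None] * carrier[None, ...]
    return DisplacementField(grid=grid, u=u, frequency_hz=spec.frequency_hz, rho=rho)


def _sponge_profile(grid: VoxelGrid, width: int, strength: float) -> np.ndarray:
    """Quadratic damping ramp near all faces except the source face z = 0."""
    s = np.zeros(grid.shape)
    if width <= 0:
        return s
    nx, ny, nz = grid.shape
    idx = np.indices(grid.shape).astype(float)
    for ax, n in ((0, nx), (1, ny), (2, nz)):
        lo = np.clip((width - idx[ax]) / width, 0.0, 1.0)
        hi = np.clip((idx[ax] - (n - 1 - width)) / width, 0.0, 1.0)
        ramp = hi**2 if ax == 2 else np.maximum(lo, hi) ** 2
        s = np.maximum(s, ramp)
    return strength * s


def solve_wavefield(
    phantom: Phantom,
    frequency_hz: float = DEFAULT_FREQUENCY_HZ,
    source: Optional[np.ndarray] = None,
    sponge_width: int = 5,
    sponge_strength: float = 2.0,
) -> DisplacementField:
    """Finite-difference frequency-domain scalar Helmholtz solve per component.

    Each displacement component obeys  rho omega^2 u + G(x) laplacian(u) = 0
    on interior voxels (local-homogeneity form, matching the assumption of the
    downstream inversion; vector coupling is neglected).  A Dirichlet source
    drives the z = 0 face; the five remaining faces carry a quadratic damping
    ("sponge") layer that raises the local loss modulus to emulate absorbing
    boundaries.  The discretised operator reuses the exact 7-point stencil of
    the inversion, so interior voxels outside the sponge satisfy the inverse
    problem's equation to round-off.

    Parameters
    ----------
    source
        Complex array of shape (3, nx, ny) with the displacement (um) imposed
        on the z = 0 face; defaults to a uniform in-plane shear polarization
        (5, 2, 0) um.
    """
    if frequency_hz <= 0:
        raise ValueError("frequency must be > 0 (singular system at f = 0)")
    grid = phantom.grid
    nx, ny, nz = grid.shape
    if nz < 3:
        raise ValueError("need at least 3 slices along the propagation axis")
    if source is None:
        source = np.zeros((3, nx, ny), dtype=complex)
        source[0] = 5.0
        source[1] = 2.0
    source = np.asarray(source, dtype=complex)
    if source.shape != (3, nx, ny):
        raise ValueError("source must have shape (3, nx, ny)")

    omega = 2.0 * np.pi * frequency_hz
    sponge = _sponge_profile(grid, sponge_width, sponge_strength)
    g_eff = phantom.G * (1.0 + 1j * sponge)

    spacing_m = [s * 1e-3 for s in grid.spacing]
    lap = _stencils.laplacian_matrix(grid.shape, spacing_m)
    n_vox = nx * ny * nz
    a_full = sp.diags(np.full(n_vox, phantom.rho * omega**2, dtype=complex)) + sp.diags(
        g_eff.ravel()
    ) @ lap
    a_full = a_full.tocsr()

    known = np.zeros(grid.shape, dtype=bool)
    known[:, :, 0] = True
    known_flat = known.ravel()
    unknown_flat = ~known_flat
    a_uu = a_full[unknown_flat][:, unknown_flat].tocsc()
    a_uk = a_full[unknown_flat][:, known_flat].tocsc()
    # structurally symmetric pattern: MMD_AT_PLUS_A halves factorization time
    lu = spla.splu(a_uu, permc_spec="MMD_AT_PLUS_A")

    u = np.empty((3,) + tuple(grid.shape), dtype=complex)
    for c in range(3):
        u_known = np.zeros(np.count_nonzero(known_flat), dtype=complex)
        u_known[:] = source[c].ravel()
        rhs = -a_uk @ u_known
        sol = lu.solve(rhs)
        vol = np.empty(n_vox, dtype=complex)
        vol[known_flat] = u_known
        vol[unknown_flat] = sol
        u[c] = vol.reshape(grid.shape)
    return DisplacementField(grid=grid, u=u, frequency_hz=frequency_hz, rho=phantom.rho)


# ---------------------------------------------------------------------------
# motion encoding
# ---------------------------------------------------------------------------


@dataclass
class EncodingModel:
    """Motion-encoding model: wave-phase offsets, encoding directions, rad/um
    efficiency, optional per-slice background phase and Gaussian phase noise.

    ``background_coeffs`` (nz, 3) adds ``c0 + c1*X + c2*Y`` per slice with X,
    Y the voxel coordinates normalized to [-1, 1]; ``slice_offsets`` (nz,)
    adds a constant per slice.  Both are identical across offsets and
    directions (static field contributions) and therefore cancel in the
    4-point transform once slices are aligned.
    """

    offsets: Tuple[float, ...] = (0.0, np.pi / 2, np.pi, 3 * np.pi / 2)
    directions: np.ndarray = dc_field(default_factory=lambda: np.eye(3))
    efficiency_rad_per_um: float = 0.3
    background_coeffs: Optional[np.ndarray] = None
    slice_offsets: Optional[np.ndarray] = None
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if len(self.offsets) < 4:
            raise ValueError("at least 4 wave-phase offsets are required")
        if np.linalg.matrix_rank(self.directions) < min(3, self.directions.shape[0]):
            raise ValueError("encoding directions must be linearly independent")
        if self.efficiency_rad_per_um <= 0:
            raise ValueError("encoding efficiency must be > 0")

    def background_volume(self, grid: VoxelGrid) -> np.ndarray:
        nx, ny, nz = grid.shape
        bg = np.zeros(grid.shape)
        if self.background_coeffs is not None:
            coeffs = np.asarray(self.background_coeffs, dtype=float)
            if coeffs.shape != (nz, 3):
                raise ValueError("background_coeffs must have shape (nz, 3)")
            xn = np.linspace(-1, 1, nx)[:, None] if nx > 1 else np.zeros((1, 1))
            yn = np.linspace(-1, 1, ny)[None, :] if ny > 1 else np.zeros((1, 1))
            for k in range(nz):
                c0, c1, c2 = coeffs[k]
                bg[:, :, k] += c0 + c1 * xn + c2 * yn
        if self.slice_offsets is not None:
            so = np.asarray(self.slice_offsets, dtype=float)
            if so.shape != (nz,):
                raise ValueError("slice_offsets must have shape (nz,)")
            bg += so[None, None, :]
        return bg


def encode_phase_series(
    field: DisplacementField,
    model: EncodingModel,
    seed: Optional[int] = None,
    return_raw: bool = False,
):
    """Motion-encode a displacement field into a wrapped MRE phase series.

    For direction d and offset phi_j the raw phase is

        efficiency * Re{ (u . d) e^{i phi_j} } + background(x) + noise,

    wrapped into [-pi, pi).  ``seed`` makes the additive Gaussian phase noise
    reproducible.  With ``return_raw=True`` the pre-wrap phase is returned as
    well (useful for validating unwrapping against ground truth).
    """
    rng = np.random.default_rng(seed)
    grid = field.grid
    dirs = model.directions
    offsets = np.asarray(model.offsets, dtype=float)
    bg = model.background_volume(grid)

    raw = np.empty((offsets.size, dirs.shape[0]) + tuple(grid.shape))
    for d in range(dirs.shape[0]):
        ud = np.tensordot(dirs[d], field.u, axes=(0, 0))  # complex, um
        for j, phi in enumerate(offsets):
            signal = model.efficiency_rad_per_um * np.real(ud * np.exp(1j * phi))
            raw[j, d] = signal + bg
    if model.noise_sigma > 0:
        raw = raw + rng.normal(0.0, model.noise_sigma, size=raw.shape)
    series = WavePhaseSeries(
        grid=grid,
        phases=wrap_phase(raw),
        offsets=offsets,
        directions=dirs,
        frequency_hz=field.frequency_hz,
        efficiency_rad_per_um=model.efficiency_rad_per_um,
        wrapped=True,
    )
    if return_raw:
        return series, raw
    return series


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------


def fibonacci_directions(n: int = 30) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors on the sphere (n, 3)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    d = np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )
    return d / np.linalg.norm(d, axis=1, keepdims=True)


def simulate_dwi(
    grid: VoxelGrid,
    tensors: np.ndarray,
    b: float = 1500.0,
    directions: Optional[np.ndarray] = None,
    S0: float | np.ndarray = 1.0,
    noise_sigma: float = 0.0,
    seed: Optional[int] = None,
):
    """Mono-exponential DWI signals from a known diffusion-tensor field.

    ``tensors`` is (nx, ny, nz, 3, 3) in mm^2/s (symmetric PSD); the signal in
    direction d_i is  S_i = S0 * exp(-b d_i^T D d_i) + noise.  Defaults follow
    the acquisition this package targets: b = 1500 s/mm^2, 30 directions.
    Returns a :class:`elastomap.diffusion.DWIDataset`.
    """
    from .diffusion import DWIDataset

    rng = np.random.default_rng(seed)
    if directions is None:
        directions = fibonacci_directions(30)
    directions = np.asarray(directions, dtype=float)
    tensors = np.asarray(tensors, dtype=float)
    if tensors.shape != tuple(grid.shape) + (3, 3):
        raise ValueError("tensors must have shape grid.shape + (3, 3)")
    if not np.allclose(tensors, np.swapaxes(tensors, -1, -2), atol=1e-12):
        raise ValueError("diffusion tensors must be symmetric")
    evals = np.linalg.eigvalsh(tensors)
    if np.min(evals) < -1e-12:
        raise ValueError("diffusion tensors must be positive semi-definite")

    s0_vol = np.broadcast_to(np.asarray(S0, dtype=float), grid.shape).copy()
    # quadratic form d^T D d for every voxel and direction
    qf = np.einsum("id,...de,ie->i...", directions, tensors, directions)
    signals = s0_vol[None, ...] * np.exp(-b * qf)
    if noise_sigma > 0:
        signals = signals + rng.normal(0.0, noise_sigma, size=signals.shape)
        signals = np.clip(signals, 0.0, None)
    return DWIDataset(grid=grid, S0=s0_vol, signals=signals, b=b, directions=directions)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Reported group means driving the default cohort generator.  Volumes in
#: mm^3, |G*| in Pa, ADC in mm^2/s; weeks 2 (baseline), 3 (effector phase)
#: and 4 (clearing phase).
GL261_GROUP_MEANS = {
    "vehicle": {
        "volume_mm3": {2: 9.77, 3: 24.27, 4: 60.02},
        "gstar_pa": {2: 4600.0, 3: 5620.0, 4: 5340.0},
        "phase_angle": {2: 0.35, 3: 0.32, 4: 0.30},
        "adc_mm2_s": {2: 0.74e-3, 3: 0.84e-3, 4: 0.86e-3},
        "fa": {2: 0.16, 3: 0.18, 4: 0.18},
    },
    "treated": {
        "volume_mm3": {2: 8.74, 3: 11.07, 4: 5.56},
        "gstar_pa": {2: 4290.0, 3: 3770.0, 4: 4000.0},
        "phase_angle": {2: 0.31, 3: 0.32, 4: 0.32},
        "adc_mm2_s": {2: 0.79e-3, 3: 0.85e-3, 4: 0.78e-3},
        "fa": {2: 0.16, 3: 0.14, 4: 0.18},
    },
}

#: Field-realistic default dispersions (see docs/methods.md).  Volume spread
#: is a coefficient of variation (lognormal); the rest are absolute SDs.
DEFAULT_COHORT_SDS = {
    "volume_cv": 0.35,
    "gstar_pa": 500.0,
    "phase_angle": 0.05,
    "adc_mm2_s": 0.08e-3,
    "fa": 0.03,
}

DEFAULT_GROUP_SIZES = {"vehicle": 11, "treated": 9}


@dataclass
class CohortSpec:
    """Per-group, per-week sampling specification for a synthetic cohort.

    ``means[group][param][week]`` are arithmetic means; ``sds`` mirrors the
    structure (for volumes the entry is a coefficient of variation).  Tumor
    volumes are drawn lognormally (positive, right-skewed, exact mean/SD
    moment match); the phase angle is a normal truncated to [0, 1]; the other
    parameters are normals truncated at zero.  Zero SD reproduces the means
    exactly.
    """

    group_sizes: Dict[str, int] = dc_field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    means: Dict[str, Dict[str, Dict[int, float]]] = dc_field(
        default_factory=lambda: {g: {p: dict(w) for p, w in ps.items()} for g, ps in GL261_GROUP_MEANS.items()}
    )
    sds: Dict[str, float] = dc_field(default_factory=lambda: dict(DEFAULT_COHORT_SDS))
    seed: int = 0

    def __post_init__(self) -> None:
        for g, params in self.means.items():
            for p, weeks in params.items():
                for w, m in weeks.items():
                    if p == "phase_angle":
                        if not 0.0 <= m <= 1.0:
                            raise ValueError(f"phase-angle mean out of [0,1]: {g}/{w}: {m}")
                    elif m <= 0:
                        raise ValueError(f"non-positive mean for {g}/{p}/{w}: {m}")
        if any(s < 0 for s in self.sds.values()):
            raise ValueError("SDs must be >= 0")


def _lognormal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _truncated_normal(rng, mean: float, sd: float, lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(spec: Optional[CohortSpec] = None) -> pd.DataFrame:
    """Synthetic longitudinal cohort table.

    One row per subject and week with columns ``subject_id, group, week,
    volume_mm3, gstar_pa, phase_angle, adc_mm2_s, fa``.  Bit-reproducible
    under ``spec.seed``.
    """
    spec = spec if spec is not None else CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rows: List[dict] = []
    for group in sorted(spec.group_sizes):
        n = spec.group_sizes[group]
        params = spec.means[group]
        weeks = sorted(next(iter(params.values())).keys())
        draws: Dict[str, Dict[int, np.ndarray]] = {}
        for p in sorted(params):
            draws[p] = {}
            for w in weeks:
                m = params[p][w]
                if p == "volume_mm3":
                    sd = spec.sds.get("volume_cv", 0.0) * m
                    draws[p][w] = _lognormal(rng, m, sd, n)
                elif p == "phase_angle":
                    draws[p][w] = _truncated_normal(rng, m, spec.sds.get(p, 0.0), 0.0, 1.0, n)
                else:
                    draws[p][w] = _truncated_normal(rng, m, spec.sds.get(p, 0.0), 0.0, np.inf, n)
        for i in range(n):
            sid = f"{group}_{i + 1:02d}"
            for w in weeks:
                row = {"subject_id": sid, "group": group, "week": w}
                for p in sorted(params):
                    row[p] = draws[p][w][i]
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marker maps
# ---------------------------------------------------------------------------


def simulate_marker_map(bands, fractions, seed: Optional[int] = None) -> LabeledVolume:
    """Marker-positive mask whose abundance depends on stiffness band.

    ``fractions`` are percentages (low, intermediate, high) of each band's
    voxel count to mark positive, e.g. the reported myeloid-marker pattern
    (8.78, 1.78, 0.15)%.  Voxels are chosen uniformly at random within each
    band; counts round to the nearest voxel.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (3,):
        raise ValueError("fractions must be (low, intermediate, high)")
    if np.any(fractions < 0) or np.any(fractions > 100):
        raise ValueError("fractions must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    marker = np.zeros(bands.grid.shape, dtype=np.uint8)
    for frac, band_mask in zip(fractions, (bands.low, bands.intermediate, bands.high)):
        idx = np.argwhere(band_mask.astype(bool))
        n_pos = int(np.rint(frac / 100.0 * len(idx)))
        if n_pos > 0:
            chosen = idx[rng.choice(len(idx), size=n_pos, replace=False)]
            marker[tuple(chosen.T)] = 1
    return LabeledVolume(grid=bands.grid, values=marker, kind="marker")
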