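"""MR elastography reconstruction: wrapped phase series -> viscoelasticity maps.

The chain mirrors the standard single-frequency algebraic inversion used in
preclinical brain MRE:

1. per-slice 2-D phase unwrapping (reliability-sorted),
2. inter-slice alignment (removal of per-slice 2*pi offsets),
3. temporal first-harmonic extraction by a 4-point Fourier transform over the
   acquired wave-phase offsets,
4. curl of the displacement field to suppress compressional contributions,
5. voxelwise Helmholtz inversion  rho * omega^2 * q = -G* * laplacian(q)
   solved jointly over the three curl components by complex least squares,
6. the scalar maps  |G*| = sqrt(Gd^2 + Gl^2)  and  Y = (2/pi) atan(Gl/Gd).

Gd (storage modulus) and Gl (loss modulus) are the real and imaginary parts
of the complex shear modulus G*; Y = 0 is a purely elastic material and
Y = 1 a purely viscous one.  The time convention is e^{+i omega t}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from skimage.restoration import unwrap_phase as _unwrap_2d

from . import _stencils
from .geometry import LabeledVolume, VoxelGrid, wrap_phase

__all__ = [
    "WavePhaseSeries",
    "DisplacementField",
    "CurlField",
    "ComplexModulusMap",
    "unwrap_slices",
    "align_slices",
    "first_harmonic",
    "curl",
    "helmholtz_invert",
    "modulus_maps",
    "reconstruct",
]

DEFAULT_FREQUENCY_HZ = 900.0
DEFAULT_DENSITY = 1000.0  # kg/m^3, soft tissue ~ water


class ReconstructionError(RuntimeError):
    """Raised when an inversion produces no valid voxels."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class WavePhaseSeries:
    """Wrapped MRE phase images over wave-phase offsets x encoding directions.

    ``phases`` has shape ``(n_offsets, n_directions, nx, ny, nz)`` with values
    in ``[-pi, pi)`` (radians) unless ``wrapped=False`` (intermediate products
    of the unwrap/align steps).
    """

    grid: VoxelGrid
    phases: np.ndarray
    offsets: np.ndarray
    directions: np.ndarray
    frequency_hz: float = DEFAULT_FREQUENCY_HZ
    efficiency_rad_per_um: float = 1.0
    wrapped: bool = True

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if self.frequency_hz <= 0:
            raise ValueError("vibration frequency must be > 0")
        if self.offsets.size < 4:
            raise ValueError("at least 4 wave-phase offsets are required")
        expected = (self.offsets.size, self.directions.shape[0]) + tuple(self.grid.shape)
        if self.phases.shape != expected:
            raise ValueError(
                f"phase array shape {self.phases.shape} != expected {expected}"
            )
        if self.wrapped:
            if np.nanmin(self.phases) < -np.pi - 1e-9 or np.nanmax(self.phases) >= np.pi + 1e-9:
                raise ValueError("wrapped phase values must lie in [-pi, pi)")

    @property
    def n_offsets(self) -> int:
        return self.offsets.size

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]


@dataclass
class DisplacementField:
    """Complex first-harmonic displacement, 3 components per voxel (um)."""

    grid: VoxelGrid
    u: np.ndarray  # (3, nx, ny, nz) complex
    frequency_hz: float
    rho: float = DEFAULT_DENSITY

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=complex)
        if self.u.shape != (3,) + tuple(self.grid.shape):
            raise ValueError("displacement array must have shape (3, nx, ny, nz)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")
        if self.frequency_hz <= 0 or self.rho <= 0:
            raise ValueError("frequency and density must be positive")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi * self.frequency_hz


@dataclass
class CurlField:
    """Curl q = rot(u) of the displacement field; compression-free shear part."""

    grid: VoxelGrid
    q: np.ndarray  # (3, nx, ny, nz) complex, units um/mm
    valid: np.ndarray  # bool, stencil-interior voxels
    frequency_hz: float
    rho: float

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=complex)
        self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class ComplexModulusMap:
    """Voxelwise complex shear modulus: storage Gd, loss Gl (both Pa)."""

    grid: VoxelGrid
    Gd: np.ndarray
    Gl: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.Gd = np.asarray(self.Gd, dtype=float)
        self.Gl = np.asarray(self.Gl, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def gstar_pa(self) -> np.ndarray:
        """|G*| = sqrt(Gd^2 + Gl^2), pascal."""
        return np.hypot(self.Gd, self.Gl)

    @property
    def phase_angle(self) -> np.ndarray:
        """Y = (2/pi) atan(Gl/Gd); masked (NaN) where Gd = Gl = 0."""
        y = (2.0 / np.pi) * np.arctan2(self.Gl, self.Gd)
        both_zero = (self.Gd == 0) & (self.Gl == 0)
        return np.where(both_zero, np.nan, y)


# ---------------------------------------------------------------------------
# reconstruction chain
# ---------------------------------------------------------------------------


def unwrap_slices(series: WavePhaseSeries) -> WavePhaseSeries:
    """Unwrap each 2-D slice of every (offset, direction) phase image.

    Uses the reliability-sorted (quality-guided) 2-D unwrapper.  The result
    differs from the true phase by a per-slice integer multiple of 2*pi
    whenever the true in-slice gradients stay below pi per voxel.
    """
    out = np.empty_like(series.phases)
    nz = series.grid.shape[2]
    for j in range(series.n_offsets):
        for d in range(series.n_directions):
            for k in range(nz):
                sl = series.phases[j, d, :, :, k]
                if np.all(np.isnan(sl)):
                    raise ValueError(f"slice {k} of offset {j}, direction {d} is all-NaN")
                out[j, d, :, :, k] = np.asarray(_unwrap_2d(sl))
    return WavePhaseSeries(
        grid=series.grid,
        phases=out,
        offsets=series.offsets,
        directions=series.directions,
        frequency_hz=series.frequency_hz,
        efficiency_rad_per_um=series.efficiency_rad_per_um,
        wrapped=False,
    )


def align_slices(series: WavePhaseSeries, remove_bias: bool = False) -> WavePhaseSeries:
    """Remove per-slice constant offsets left over from per-slice unwrapping.

    Adjacent-slice median differences estimate the per-slice constants; by
    default only the integer-multiple-of-2*pi part is removed (that is the
    only ambiguity 2-D unwrapping introduces), so genuine inter-slice
    structure of the wave field is preserved.  ``remove_bias=True`` removes
    the full estimated constant instead.  Slice 0 is the reference.  Each
    volume is finally recentred so its median lies in ``(-pi, pi]``, removing
    the volume-global 2*pi ambiguity (a constant per volume cancels in the
    subsequent 4-point transform only once it is consistent across offsets).
    """
    phases = series.phases.copy()
    nz = series.grid.shape[2]
    two_pi = 2.0 * np.pi
    for j in range(series.n_offsets):
        for d in range(series.n_directions):
            vol = phases[j, d]
            if nz >= 2:
                cum = 0.0
                for k in range(1, nz):
                    step = np.median(vol[:, :, k] - vol[:, :, k - 1])
                    cum += step
                    correction = cum if remove_bias else two_pi * np.round(cum / two_pi)
                    vol[:, :, k] -= correction
                    cum -= correction
            med = np.median(vol)
            vol -= two_pi * np.round(med / two_pi)
    return WavePhaseSeries(
        grid=series.grid,
        phases=phases,
        offsets=series.offsets,
        directions=series.directions,
        frequency_hz=series.frequency_hz,
        efficiency_rad_per_um=series.efficiency_rad_per_um,
        wrapped=False,
    )


def first_harmonic(series: WavePhaseSeries, rho: float = DEFAULT_DENSITY) -> DisplacementField:
    """Extract the complex first harmonic by the 4-point Fourier transform.

    For each encoding direction d the temporal DFT over the uniformly spaced
    wave-phase offsets ``phi_j`` is

        U_d(x) = (2/N) * sum_j phase(x, phi_j, d) * exp(-i phi_j),

    so a signal ``a cos(phi) + b sin(phi)`` returns ``a - i b`` (e^{+i omega t}
    convention).  The displacement vector is then assembled by solving the
    (direction . u) system — exact for orthonormal directions, least squares
    otherwise — and converted from phase to um via the encoding efficiency.
    """
    if series.n_offsets < 4:
        raise ValueError("first_harmonic requires at least 4 offsets")
    phi = series.offsets
    spacing_check = np.diff(np.sort(phi))
    if not np.allclose(spacing_check, spacing_check[0], atol=1e-9):
        raise ValueError("wave-phase offsets must uniformly sample one period")
    n = series.n_offsets
    weights = np.exp(-1j * phi) * (2.0 / n)
    # (offsets, dirs, x, y, z) . (offsets,) -> (dirs, x, y, z)
    proj = np.tensordot(weights, series.phases, axes=(0, 0))

    d_mat = series.directions
    if np.linalg.matrix_rank(d_mat) < min(3, d_mat.shape[0]):
        raise ValueError("encoding direction set is rank deficient")
    if d_mat.shape[0] < 3:
        raise ValueError("3 independent encoding directions are needed for a vector field")
    pinv = np.linalg.pinv(d_mat)  # (3, n_dirs)
    u = np.tensordot(pinv, proj, axes=(1, 0)) / series.efficiency_rad_per_um
    return DisplacementField(grid=series.grid, u=u, frequency_hz=series.frequency_hz, rho=rho)


def curl(field: DisplacementField) -> CurlField:
    """Compression-wave removal: central-difference curl of the displacement."""
    if min(field.grid.shape) < 3:
        raise ValueError("curl requires at least 3 voxels per axis")
    q = _stencils.curl(field.u, field.grid.spacing)
    valid = _stencils.laplacian_valid_mask(field.grid.shape)
    return CurlField(
        grid=field.grid, q=q, valid=valid, frequency_hz=field.frequency_hz, rho=field.rho
    )


def helmholtz_invert(
    curl_field: CurlField,
    rho: Optional[float] = None,
    frequency_hz: Optional[float] = None,
    validity_floor: float = 1e-6,
) -> ComplexModulusMap:
    """Algebraic Helmholtz inversion of the curl field.

    Solves  rho * omega^2 * q_c = -G* * laplacian(q_c)  jointly over the three
    curl components by complex least squares:

        G* = -rho * omega^2 * sum_c conj(L q_c) q_c / sum_c |L q_c|^2 .

    The Laplacian is evaluated in SI units (spacing converted mm -> m) so G*
    comes out in pascal.  Voxels whose Laplacian magnitude falls below
    ``validity_floor`` times its 95th percentile (wave nodes) are masked, as
    is everything outside the stencil-interior region.
    """
    rho = curl_field.rho if rho is None else rho
    f = curl_field.frequency_hz if frequency_hz is None else frequency_hz
    if rho <= 0 or f <= 0:
        raise ValueError("density and frequency must be positive")
    omega = 2.0 * np.pi * f
    spacing_m = [s * 1e-3 for s in curl_field.grid.spacing]

    num = np.zeros(curl_field.grid.shape, dtype=complex)
    den = np.zeros(curl_field.grid.shape, dtype=float)
    for c in range(3):
        lap = _stencils.laplacian(curl_field.q[c], spacing_m)
        num += np.conj(lap) * curl_field.q[c]
        den += np.abs(lap) ** 2

    # the Laplacian consumes curl values one voxel out; require those to be
    # central-difference-accurate as well
    from scipy.ndimage import binary_erosion

    valid = binary_erosion(curl_field.valid) & _stencils.laplacian_valid_mask(
        curl_field.grid.shape
    )
    norm = np.sqrt(den)
    if np.any(valid):
        floor = validity_floor * np.percentile(norm[valid], 95.0)
        valid &= norm > floor
    if not np.any(valid):
        raise ReconstructionError(
            "Helmholtz inversion produced no valid voxels "
            f"(grid {curl_field.grid.shape}, floor {validity_floor:g})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        g = -rho * omega**2 * num / den
    g[~valid] = np.nan
    return ComplexModulusMap(
        grid=curl_field.grid, Gd=np.real(g), Gl=np.imag(g), valid=valid
    )


def modulus_maps(modulus: ComplexModulusMap) -> Tuple[LabeledVolume, LabeledVolume]:
    """Scalar elastogram pair (|G*| in Pa, phase angle Y) from Gd/Gl.

    |G*| = sqrt(Gd^2 + Gl^2);  Y = (2/pi) atan(Gl/Gd) with the limiting value
    Y = 1 when Gd = 0 and Gl > 0, and masked (NaN) when both vanish.
    """
    gstar = modulus.gstar_pa
    y = modulus.phase_angle
    gstar = np.where(modulus.valid, gstar, np.nan)
    y = np.where(modulus.valid, y, np.nan)
    return (
        LabeledVolume(grid=modulus.grid, values=gstar, kind="modulus"),
        LabeledVolume(grid=modulus.grid, values=y, kind="scalar"),
    )


def reconstruct(
    series: WavePhaseSeries,
    rho: float = DEFAULT_DENSITY,
    validity_floor: float = 1e-6,
    presmooth_sigma_vox: float = 0.0,
) -> ComplexModulusMap:
    """Full chain: unwrap -> align -> first harmonic -> curl -> inversion.

    ``presmooth_sigma_vox`` optionally Gaussian-smooths the complex
    displacement before the curl (off by default; no smoothing is part of the
    canonical chain).
    """
    unwrapped = unwrap_slices(series)
    aligned = align_slices(unwrapped)
    field = first_harmonic(aligned, rho=rho)
    if presmooth_sigma_vox > 0:
        from scipy.ndimage import gaussian_filter

        sm = np.empty_like(field.u)
        for c in range(3):
            sm[c] = gaussian_filter(field.u[c].real, presmooth_sigma_vox) + 1j * gaussian_filter(
                field.u[c].imag, presmooth_sigma_vox
            )
        field = DisplacementField(
            grid=field.grid, u=sm, frequency_hz=field.frequency_hz, rho=field.rho
        )
    q = curl(field)
    return helmholtz_invert(q, validity_floor=validity_floor)
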