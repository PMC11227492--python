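"""ADC and diffusion-tensor / FA mapping from DWI series.

The mono-exponential model is used throughout:  S_i = S0 exp(-b d_i^T D d_i).
ADC is the per-direction average of log-ratios (the simplest estimator
consistent with a single-shell acquisition); FA follows the standard tensor
eigenvalue formula with population-variance normalization,

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import LabeledVolume, VoxelGrid

__all__ = ["DWIDataset", "DiffusionMaps", "fit_adc", "fit_tensor_fa"]


@dataclass
class DWIDataset:
    """Single-shell diffusion acquisition: S0 volume, weighted volumes
    ``signals[(i, x, y, z)]``, b-value (s/mm^2) and unit gradient directions."""

    grid: VoxelGrid
    S0: np.ndarray
    signals: np.ndarray
    b: float
    directions: np.ndarray

    def __post_init__(self) -> None:
        self.S0 = np.asarray(self.S0, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if self.b <= 0:
            raise ValueError("b-value must be > 0")
        if self.S0.shape != tuple(self.grid.shape):
            raise ValueError("S0 shape must equal grid shape")
        if self.signals.shape != (self.directions.shape[0],) + tuple(self.grid.shape):
            raise ValueError("signals must have shape (n_directions, nx, ny, nz)")
        if np.nanmin(self.signals) < 0 or np.nanmin(self.S0) < 0:
            raise ValueError("signals must be non-negative")
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gradient directions must be unit vectors")

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]


@dataclass
class DiffusionMaps:
    """Tensor-derived maps: ADC (mm^2/s), FA, sorted eigenvalues, validity."""

    grid: VoxelGrid
    adc: np.ndarray
    fa: np.ndarray
    evals: np.ndarray  # (..., 3), lambda1 >= lambda2 >= lambda3
    valid: np.ndarray
    clipped: np.ndarray  # voxels where negative eigenvalues were clipped to 0


def fit_adc(dwi: DWIDataset) -> LabeledVolume:
    """Apparent diffusion coefficient: mean over directions of ln(S0/S_i)/b.

    Voxels with any non-positive S_i or S0 are masked (NaN).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log(dwi.S0[None, ...] / dwi.signals) / dwi.b
    bad = (dwi.signals <= 0).any(axis=0) | (dwi.S0 <= 0)
    adc = ratio.mean(axis=0)
    adc[bad] = np.nan
    return LabeledVolume(grid=dwi.grid, values=adc, kind="scalar")


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from (..., 3) eigenvalues; 0 where all vanish."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.sqrt(((evals - mean) ** 2).sum(axis=-1))
    den = np.sqrt((evals**2).sum(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def fit_tensor_fa(dwi: DWIDataset) -> DiffusionMaps:
    """Log-linear least-squares diffusion-tensor fit and FA map.

    Solves  ln(S_i/S0) = -b d_i^T D d_i  for the six unique tensor elements,
    eigendecomposes, clips negative eigenvalues to zero (voxel flagged) and
    evaluates FA.  Requires >= 6 non-collinear directions.
    """
    d = dwi.directions
    if d.shape[0] < 6:
        raise ValueError("tensor fit needs at least 6 directions")
    design = np.column_stack(
        [
            d[:, 0] ** 2,
            d[:, 1] ** 2,
            d[:, 2] ** 2,
            2 * d[:, 0] * d[:, 1],
            2 * d[:, 0] * d[:, 2],
            2 * d[:, 1] * d[:, 2],
        ]
    )
    if np.linalg.matrix_rank(design) < 6:
        raise ValueError("direction set is rank deficient for a tensor fit")

    shape = tuple(dwi.grid.shape)
    good = (dwi.signals > 0).all(axis=0) & (dwi.S0 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = -np.log(dwi.signals / dwi.S0[None, ...]) / dwi.b  # (ndir, ...)
    y_flat = y.reshape(dwi.n_directions, -1)
    y_flat = np.where(np.isfinite(y_flat), y_flat, 0.0)
    coeffs, *_ = np.linalg.lstsq(design, y_flat, rcond=None)  # (6, nvox)

    dxx, dyy, dzz, dxy, dxz, dyz = coeffs
    tensors = np.empty((y_flat.shape[1], 3, 3))
    tensors[:, 0, 0] = dxx
    tensors[:, 1, 1] = dyy
    tensors[:, 2, 2] = dzz
    tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
    tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
    tensors[:, 1, 2] = tensors[:, 2, 1] = dyz
    evals = np.linalg.eigvalsh(tensors)[:, ::-1]  # descending

    clipped = (evals < 0).any(axis=-1)
    evals = np.clip(evals, 0.0, None)
    fa = fa_from_eigenvalues(evals)
    adc = evals.mean(axis=-1)

    adc = adc.reshape(shape)
    fa = fa.reshape(shape)
    evals = evals.reshape(shape + (3,))
    clipped = clipped.reshape(shape)
    valid = good
    adc = np.where(valid, adc, np.nan)
    fa = np.where(valid, fa, np.nan)
    return DiffusionMaps(
        grid=dwi.grid, adc=adc, fa=fa, evals=evals, valid=valid, clipped=clipped & valid
    )
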