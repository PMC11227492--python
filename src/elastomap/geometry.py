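"""Voxel-grid geometry and labeled volumes shared by every pipeline stage.

All lengths are millimetres, stiffness is pascal internally (reported in kPa),
and angular frequency is rad/s.  The in-memory axis order is fixed as
``(x, y, z)`` with ``z`` the slice axis: phase unwrapping and inter-slice
alignment are per-slice operations and need an unambiguous slice axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = ["VoxelGrid", "LabeledVolume", "VOLUME_KINDS", "wrap_phase"]

#: Recognised per-voxel value semantics.
VOLUME_KINDS = (
    "magnitude",
    "wrapped_phase",
    "modulus",
    "mask",
    "marker",
    "scalar",
)


def wrap_phase(values: np.ndarray) -> np.ndarray:
    """Wrap angles into the half-open interval ``[-pi, pi)``."""
    return np.mod(np.asarray(values) + np.pi, 2.0 * np.pi) - np.pi


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3-D sampling grid.

    Parameters
    ----------
    shape
        Number of voxels along (x, y, z); every entry >= 1.
    spacing
        Voxel edge length in mm along each axis; strictly positive.
    origin
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    axis_order
        Convention tag; the package always uses ``"xyz"`` with z = slice axis.
    """

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = "xyz"

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValueError("shape, spacing and origin must be length-3")
        if any(n < 1 for n in shape):
            raise ValueError(f"grid shape must be >= 1 on every axis, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"grid spacing must be > 0 on every axis, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world (mm) affine (diagonal, this convention)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_coords(self, index) -> np.ndarray:
        """World coordinates (mm) of one or more voxel indices."""
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        return np.squeeze(idx * np.asarray(self.spacing) + np.asarray(self.origin))

    def axes_mm(self):
        """Per-axis coordinate vectors (mm) of voxel centres."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )


@dataclass
class LabeledVolume:
    """A scalar (or complex) per-voxel volume plus its grid and semantics.

    Invariants enforced at construction: value array shape equals
    ``grid.shape``; a ``mask`` contains only {0, 1}; ``wrapped_phase`` values
    lie in ``[-pi, pi)``.
    """

    grid: VoxelGrid
    values: np.ndarray
    kind: str = "scalar"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.kind not in VOLUME_KINDS:
            raise ValueError(f"unknown volume kind {self.kind!r}; expected one of {VOLUME_KINDS}")
        if tuple(self.values.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"value array shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )
        if self.kind == "mask" or self.kind == "marker":
            uniq = np.unique(self.values)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError(
                    f"{self.kind} volume must contain only {{0, 1}}, found values {uniq[:8]}"
                )
            self.values = self.values.astype(np.uint8)
        elif self.kind == "wrapped_phase":
            vals = np.asarray(self.values, dtype=float)
            # tolerate float round-off exactly at +pi from I/O round trips
            vals = np.where(np.isclose(vals, np.pi), -np.pi, vals)
            if np.nanmin(vals) < -np.pi - 1e-9 or np.nanmax(vals) >= np.pi:
                raise ValueError("wrapped_phase values must lie in [-pi, pi)")
            self.values = vals

    @property
    def mask_indices(self) -> np.ndarray:
        if self.kind not in ("mask", "marker"):
            raise ValueError("mask_indices only defined for mask/marker volumes")
        return np.argwhere(self.values > 0)

    def astype_bool(self) -> np.ndarray:
        return self.values.astype(bool)
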