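"""Shared finite-difference stencils.

The forward wave solver and the Helmholtz inversion must discretise the
Laplacian identically: the 7-point second-difference below is used both to
assemble the sparse forward operator and, as an array operation, inside the
inversion.  Only interior voxels (one-voxel rim excluded per application of a
stencil) are trustworthy.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "laplacian",
    "laplacian_valid_mask",
    "curl",
    "laplacian_matrix",
]


def laplacian(vol: np.ndarray, spacing) -> np.ndarray:
    """7-point Laplacian of a 3-D (possibly complex) array.

    ``spacing`` is per-axis step length; the result carries units of
    ``vol / spacing**2``.  Boundary voxels use zero ghost values and are not
    meaningful — mask them with :func:`laplacian_valid_mask`.
    """
    vol = np.asarray(vol)
    out = np.zeros_like(vol)
    for ax in range(3):
        h2 = float(spacing[ax]) ** 2
        plus = np.roll(vol, -1, axis=ax)
        minus = np.roll(vol, 1, axis=ax)
        out = out + (plus + minus - 2.0 * vol) / h2
    return out


def laplacian_valid_mask(shape) -> np.ndarray:
    """Interior mask: one-voxel rim excluded on every face."""
    m = np.zeros(shape, dtype=bool)
    m[1:-1, 1:-1, 1:-1] = True
    return m


def curl(u: np.ndarray, spacing) -> np.ndarray:
    """Central-difference curl of a 3-component field ``u[(c, x, y, z)]``.

    Uses second-order central differences in the interior (numpy.gradient);
    the one-voxel rim falls back to one-sided differences and must be masked
    by the caller.
    """
    u = np.asarray(u)
    if u.ndim != 4 or u.shape[0] != 3:
        raise ValueError("curl expects an array of shape (3, nx, ny, nz)")
    sx, sy, sz = (float(s) for s in spacing)
    dux = np.gradient(u[0], sx, sy, sz)
    duy = np.gradient(u[1], sx, sy, sz)
    duz = np.gradient(u[2], sx, sy, sz)
    qx = duz[1] - duy[2]
    qy = dux[2] - duz[0]
    qz = duy[0] - dux[1]
    return np.stack([qx, qy, qz])


def laplacian_matrix(shape, spacing) -> sp.csr_matrix:
    """Sparse 7-point Laplacian on the full grid with zero-Dirichlet ghosts.

    Row/column ordering is C order of ``shape``; coefficients match
    :func:`laplacian` exactly so that a field solved with this operator
    satisfies the array-stencil equation at interior voxels to round-off.
    """

    def second_diff(n: int, h: float) -> sp.csr_matrix:
        main = -2.0 * np.ones(n)
        off = np.ones(n - 1)
        return sp.diags([off, main, off], [-1, 0, 1], format="csr") / (h * h)

    nx, ny, nz = (int(n) for n in shape)
    hx, hy, hz = (float(s) for s in spacing)
    ix, iy, iz = sp.identity(nx), sp.identity(ny), sp.identity(nz)
    lap = (
        sp.kron(sp.kron(second_diff(nx, hx), iy), iz)
        + sp.kron(sp.kron(ix, second_diff(ny, hy)), iz)
        + sp.kron(sp.kron(ix, iy), second_diff(nz, hz))
    )
    return lap.tocsr()
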