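"""On-disk formats: NIfTI volumes, cohort CSV tables, YAML run configs.

All volumes go through NIfTI-1.  On read, images are reoriented to the
package's internal (x, y, z) convention (closest canonical / RAS) and the
grid (spacing in mm, origin = world coordinate of voxel (0,0,0) centre) is
populated from the header.  Complex volumes are stored as paired real/imag
scalar files for portability.  Masks with values outside {0, 1} are rejected
rather than binarized — silent coercion hides registration errors.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .geometry import LabeledVolume, VoxelGrid
from .mre import WavePhaseSeries
from .response import VolumeTrajectory

__all__ = [
    "read_volume",
    "write_volume",
    "read_complex_volume",
    "write_complex_volume",
    "read_cohort_table",
    "write_cohort_table",
    "save_phase_series",
    "load_phase_series",
    "load_config",
]


class VolumeFormatError(ValueError):
    """Header/data inconsistency or kind-validation failure on read."""


def read_volume(path, expected_kind: str = "scalar") -> LabeledVolume:
    """Read a NIfTI volume into a :class:`LabeledVolume`.

    The image is reoriented to closest-canonical axes so that in-memory axis
    order is (x, y, z) with z the slice axis; spacing (mm) and origin come
    from the reoriented affine.  ``expected_kind`` drives validation (e.g. a
    mask must contain only {0, 1}).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    grid = VoxelGrid(shape=data.shape, spacing=tuple(float(z) for z in zooms), origin=tuple(float(o) for o in origin))
    if expected_kind in ("mask", "marker"):
        uniq = np.unique(data)
        if not np.isin(uniq, (0, 1)).all():
            raise VolumeFormatError(
                f"{path}: requested a {expected_kind} but found values outside {{0, 1}}"
            )
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float64)
    try:
        return LabeledVolume(grid=grid, values=data, kind=expected_kind)
    except ValueError as exc:
        raise VolumeFormatError(f"{path}: {exc}") from exc


def write_volume(vol: LabeledVolume, path) -> Path:
    """Write a :class:`LabeledVolume` as NIfTI-1; returns the path.

    Integer kinds (mask/marker) are stored as uint8 and round-trip bitwise;
    scalar kinds round-trip to float precision.
    """
    path = Path(path)
    if not os.access(path.parent if path.parent != Path("") else Path("."), os.W_OK):
        raise IOError(f"directory not writable: {path.parent}")
    if vol.kind in ("mask", "marker"):
        data = vol.values.astype(np.uint8)
    else:
        data = vol.values.astype(np.float64)
    img = nib.Nifti1Image(data, vol.grid.affine)
    img.header.set_zooms(vol.grid.spacing)
    nib.save(img, str(path))
    return path


def write_complex_volume(grid: VoxelGrid, values: np.ndarray, prefix) -> Tuple[Path, Path]:
    """Store a complex volume as ``<prefix>_real.nii.gz`` + ``<prefix>_imag.nii.gz``."""
    prefix = Path(prefix)
    values = np.asarray(values, dtype=complex)
    real = write_volume(LabeledVolume(grid=grid, values=values.real, kind="scalar"),
                        prefix.with_name(prefix.name + "_real.nii.gz"))
    imag = write_volume(LabeledVolume(grid=grid, values=values.imag, kind="scalar"),
                        prefix.with_name(prefix.name + "_imag.nii.gz"))
    return real, imag


def read_complex_volume(prefix) -> LabeledVolume:
    """Reassemble a complex volume written by :func:`write_complex_volume`."""
    prefix = Path(prefix)
    real = read_volume(prefix.with_name(prefix.name + "_real.nii.gz"))
    imag = read_volume(prefix.with_name(prefix.name + "_imag.nii.gz"))
    return LabeledVolume(grid=real.grid, values=real.values + 1j * imag.values, kind="scalar")


REQUIRED_COHORT_COLUMNS = ("subject_id", "group", "week", "volume_mm3")


def read_cohort_table(path) -> List[VolumeTrajectory]:
    """Read per-subject longitudinal tumor volumes from CSV.

    Requires columns subject_id, group, week, volume_mm3 (UTF-8, header row).
    One trajectory per subject, weeks sorted ascending; missing weeks are
    permitted (``VolumeTrajectory.missing_weeks`` records them).  Duplicate
    (subject, week) rows and negative volumes are validation errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing_cols = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    if df.duplicated(subset=["subject_id", "week"]).any():
        dup = df[df.duplicated(subset=["subject_id", "week"], keep=False)]
        raise ValueError(f"{path}: duplicate (subject, week) rows:\n{dup}")
    if (df["volume_mm3"] < 0).any():
        raise ValueError(f"{path}: negative tumor volumes present")
    out: List[VolumeTrajectory] = []
    for sid, sub in df.groupby("subject_id", sort=True):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise ValueError(f"{path}: subject {sid} appears in multiple groups")
        out.append(
            VolumeTrajectory(
                subject_id=str(sid),
                group=str(groups[0]),
                volumes={int(w): float(v) for w, v in zip(sub["week"], sub["volume_mm3"])},
            )
        )
    return out


def write_cohort_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def save_phase_series(series: WavePhaseSeries, prefix) -> Tuple[Path, Path]:
    """Write a wave-phase series as a 4-D NIfTI plus a YAML sidecar.

    Volume t of the 4-D file is (offset j, direction d) with
    ``t = d * n_offsets + j``; the sidecar records offsets, directions,
    vibration frequency and encoding efficiency.
    """
    prefix = Path(prefix)
    n_off, n_dir = series.n_offsets, series.n_directions
    vols = np.stack(
        [series.phases[j, d] for d in range(n_dir) for j in range(n_off)], axis=-1
    )
    img = nib.Nifti1Image(vols.astype(np.float64), series.grid.affine)
    nii_path = prefix.with_name(prefix.name + "_phase.nii.gz")
    nib.save(img, str(nii_path))
    meta = {
        "offsets_rad": [float(o) for o in series.offsets],
        "directions": [[float(x) for x in row] for row in series.directions],
        "frequency_hz": float(series.frequency_hz),
        "efficiency_rad_per_um": float(series.efficiency_rad_per_um),
        "spacing_mm": [float(s) for s in series.grid.spacing],
        "origin_mm": [float(o) for o in series.grid.origin],
    }
    yaml_path = prefix.with_name(prefix.name + "_phase.yaml")
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(meta, fh)
    return nii_path, yaml_path


def load_phase_series(prefix) -> WavePhaseSeries:
    """Read a series written by :func:`save_phase_series`."""
    prefix = Path(prefix)
    nii_path = prefix.with_name(prefix.name + "_phase.nii.gz")
    yaml_path = prefix.with_name(prefix.name + "_phase.yaml")
    with open(yaml_path) as fh:
        meta = yaml.safe_load(fh)
    img = nib.load(str(nii_path))
    vols = np.asanyarray(img.dataobj).astype(np.float64)
    offsets = np.asarray(meta["offsets_rad"], dtype=float)
    directions = np.asarray(meta["directions"], dtype=float)
    n_off, n_dir = offsets.size, directions.shape[0]
    if vols.shape[-1] != n_off * n_dir:
        raise VolumeFormatError(
            f"{nii_path}: {vols.shape[-1]} volumes != offsets*directions = {n_off * n_dir}"
        )
    grid = VoxelGrid(
        shape=vols.shape[:3],
        spacing=tuple(meta["spacing_mm"]),
        origin=tuple(meta.get("origin_mm", (0.0, 0.0, 0.0))),
    )
    phases = np.empty((n_off, n_dir) + vols.shape[:3])
    for d in range(n_dir):
        for j in range(n_off):
            phases[j, d] = vols[..., d * n_off + j]
    return WavePhaseSeries(
        grid=grid,
        phases=phases,
        offsets=offsets,
        directions=directions,
        frequency_hz=float(meta["frequency_hz"]),
        efficiency_rad_per_um=float(meta["efficiency_rad_per_um"]),
    )


def load_config(path) -> Dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg
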