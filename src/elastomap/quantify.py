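"""Region-based quantification of parameter maps.

Covers tumor volumetry and ROI statistics, the contralateral equal-volume
reference region, |G*| frequency-distribution histograms, stiffness-band
segmentation of elastograms (low < 4.5 kPa, intermediate 4.5-6.5 kPa,
high > 6.5 kPa relative to healthy brain), marker-fraction-per-band analysis,
and the microscopy preprocessing steps (block-average downsampling, adaptive
histogram equalization, threshold segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy.ndimage import binary_dilation, distance_transform_edt
from scipy.signal import find_peaks

from .geometry import LabeledVolume, VoxelGrid

__all__ = [
    "RegionStats",
    "StiffnessBands",
    "MarkerFractionResult",
    "HistogramResult",
    "region_stats",
    "contralateral_roi",
    "gstar_histogram",
    "stiffness_bands",
    "marker_fraction_by_band",
    "bin_downsample",
    "ahe_filter",
    "threshold_segment",
]

#: Stiffness-band thresholds (Pa): healthy murine brain parenchyma sits
#: between these, so "low" is softer and "high" stiffer than healthy tissue.
T_LOW_PA = 4500.0
T_HIGH_PA = 6500.0


@dataclass
class RegionStats:
    """Summary of one region: voxel count, volume, per-map statistics.

    ``stats[name]`` holds mean/sd/median/n_valid computed over the
    intersection of the region mask with each map's finite (valid) voxels.
    SD uses ddof=1 (sample SD), reported as 0 for a single voxel.
    """

    region_id: str
    voxel_count: int
    volume_mm3: float
    stats: Dict[str, Dict[str, float]] = field(default_factory=dict)


@dataclass
class StiffnessBands:
    """Low/intermediate/high stiffness masks partitioning tumor - exclusion."""

    grid: VoxelGrid
    low: np.ndarray
    intermediate: np.ndarray
    high: np.ndarray
    t_low_pa: float = T_LOW_PA
    t_high_pa: float = T_HIGH_PA
    exclusion: Optional[np.ndarray] = None

    @property
    def counts(self) -> Tuple[int, int, int]:
        return (
            int(self.low.sum()),
            int(self.intermediate.sum()),
            int(self.high.sum()),
        )


@dataclass
class MarkerFractionResult:
    """Marker-positive volume percentage per stiffness band.

    By default percentages are normalized by the total (tumor - exclusion)
    volume, so their sum is the overall marker-positive fraction (<= 100%).
    """

    percent: Dict[str, float]
    marker_voxels: Dict[str, int]
    band_voxels: Dict[str, int]
    total_voxels: int
    normalization: str = "tumor"


@dataclass
class HistogramResult:
    """Normalized |G*| frequency distribution and its modes (kPa)."""

    bin_edges_kpa: np.ndarray
    frequency: np.ndarray
    modes_kpa: np.ndarray
    counts: np.ndarray


def _as_array(vol) -> np.ndarray:
    return vol.values if isinstance(vol, LabeledVolume) else np.asarray(vol)


def region_stats(
    maps: Mapping[str, LabeledVolume],
    mask: LabeledVolume,
    region_id: str = "tumor",
) -> RegionStats:
    """Mean/SD/median of each supplied map over a region mask.

    Volume is voxel count times voxel volume (mm^3).  Statistics are computed
    only where the map is finite (its validity mask); an empty intersection
    for every map is an error.
    """
    m = mask.astype_bool()
    count = int(m.sum())
    if count == 0:
        raise ValueError("region mask is empty")
    out = RegionStats(
        region_id=region_id,
        voxel_count=count,
        volume_mm3=count * mask.grid.voxel_volume_mm3,
    )
    any_valid = False
    for name, vol in maps.items():
        if tuple(_as_array(vol).shape) != tuple(m.shape):
            raise ValueError(f"map {name!r} does not share the mask's grid shape")
        vals = np.asarray(_as_array(vol), dtype=float)[m]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            out.stats[name] = {"mean": np.nan, "sd": np.nan, "median": np.nan, "n_valid": 0}
            continue
        any_valid = True
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        out.stats[name] = {
            "mean": float(np.mean(vals)),
            "sd": sd,
            "median": float(np.median(vals)),
            "n_valid": int(vals.size),
        }
    if maps and not any_valid:
        raise ValueError("no map has valid voxels inside the region mask")
    return out


def _mirror_mask(mask: np.ndarray, axis: int, midline: Optional[float]) -> np.ndarray:
    """Reflect a mask across a midline plane along ``axis``.

    ``midline`` is the (possibly fractional) voxel coordinate of the plane;
    None means the grid centre, where reflection is a pure flip.
    """
    n = mask.shape[axis]
    if midline is None:
        return np.flip(mask, axis=axis)
    out = np.zeros_like(mask)
    idx = np.arange(n)
    target = np.rint(2.0 * midline - idx).astype(int)
    ok = (target >= 0) & (target < n)
    src = [slice(None)] * mask.ndim
    dst = [slice(None)] * mask.ndim
    for i, t in zip(idx[ok], target[ok]):
        src[axis] = i
        dst[axis] = t
        out[tuple(dst)] |= mask[tuple(src)]
    return out


def contralateral_roi(
    tumor_mask: LabeledVolume,
    brain_mask: LabeledVolume,
    axis: int = 0,
    midline: Optional[float] = None,
) -> LabeledVolume:
    """Equal-volume reference region in the contralateral hemisphere.

    The tumor mask is mirrored across the mid-sagittal plane (default: the
    grid centre plane along ``axis``), clipped to the brain and made disjoint
    from the tumor, then morphologically adjusted — deterministic peeling or
    dilation ordered by Euclidean distance — until its voxel count equals the
    tumor's exactly.
    """
    tumor = tumor_mask.astype_bool()
    brain = brain_mask.astype_bool()
    target = int(tumor.sum())
    if target == 0:
        raise ValueError("tumor mask is empty")
    allowed = brain & ~tumor
    if int(allowed.sum()) < target:
        raise ValueError(
            f"insufficient contralateral brain: need {target} voxels, "
            f"only {int(allowed.sum())} available"
        )
    roi = _mirror_mask(tumor, axis, midline) & allowed
    if not roi.any():
        raise ValueError("mirrored tumor does not intersect the brain mask")

    while int(roi.sum()) < target:
        ring = binary_dilation(roi) & allowed & ~roi
        if not ring.any():
            raise ValueError("cannot grow contralateral ROI to the tumor volume")
        need = target - int(roi.sum())
        # distance to current ROI orders candidates; lexicographic tie-break
        dist = distance_transform_edt(~roi)
        cand = np.argwhere(ring)
        order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], dist[tuple(cand.T)]))
        for j in order[:need]:
            roi[tuple(cand[j])] = True
    if int(roi.sum()) > target:
        # peel shallowest voxels first (smallest inside-distance)
        excess = int(roi.sum()) - target
        depth = distance_transform_edt(roi)
        vox = np.argwhere(roi)
        order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0], depth[tuple(vox.T)]))
        for j in order[:excess]:
            roi[tuple(vox[j])] = False
    return LabeledVolume(grid=tumor_mask.grid, values=roi.astype(np.uint8), kind="mask")


def gstar_histogram(
    gstar_pa: LabeledVolume,
    mask: LabeledVolume,
    bin_width_kpa: float = 0.25,
    prominence_frac: float = 0.1,
) -> HistogramResult:
    """Normalized |G*| frequency distribution inside a mask, with modes.

    Modes are local maxima of the frequency curve whose prominence exceeds
    ``prominence_frac`` times the peak frequency.  Bin width and mode
    locations are in kPa.
    """
    m = mask.astype_bool()
    vals = np.asarray(_as_array(gstar_pa), dtype=float)[m] / 1000.0  # kPa
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid |G*| values inside the mask")
    lo = np.floor(vals.min() / bin_width_kpa) * bin_width_kpa
    hi = np.ceil(vals.max() / bin_width_kpa) * bin_width_kpa
    n_bins = max(1, int(np.rint((hi - lo) / bin_width_kpa)))
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, lo + n_bins * bin_width_kpa))
    freq = counts / counts.sum()
    padded = np.concatenate([[0.0], freq, [0.0]])
    peaks, _ = find_peaks(padded, prominence=prominence_frac * freq.max())
    centers = (edges[:-1] + edges[1:]) / 2.0
    modes = centers[peaks - 1]
    return HistogramResult(bin_edges_kpa=edges, frequency=freq, modes_kpa=modes, counts=counts)


def stiffness_bands(
    gstar_pa: LabeledVolume,
    tumor_mask: LabeledVolume,
    exclusion_mask: Optional[LabeledVolume] = None,
    t_low_pa: float = T_LOW_PA,
    t_high_pa: float = T_HIGH_PA,
) -> StiffnessBands:
    """Segment a tumor into low / intermediate / high stiffness bands.

    low: |G*| < t_low;  intermediate: t_low <= |G*| <= t_high (both boundary
    values closed into the intermediate band);  high: |G*| > t_high.  All
    restricted to (tumor - exclusion); NaN voxels in the elastogram are
    assigned to no band and dropped from the partition domain.
    """
    if not t_low_pa < t_high_pa:
        raise ValueError("t_low must be < t_high")
    g = np.asarray(_as_array(gstar_pa), dtype=float)
    tumor = tumor_mask.astype_bool()
    excl = exclusion_mask.astype_bool() if exclusion_mask is not None else np.zeros_like(tumor)
    domain = tumor & ~excl & np.isfinite(g)
    low = domain & (g < t_low_pa)
    inter = domain & (g >= t_low_pa) & (g <= t_high_pa)
    high = domain & (g > t_high_pa)
    return StiffnessBands(
        grid=tumor_mask.grid,
        low=low,
        intermediate=inter,
        high=high,
        t_low_pa=t_low_pa,
        t_high_pa=t_high_pa,
        exclusion=excl,
    )


def marker_fraction_by_band(
    marker_mask: LabeledVolume,
    bands: StiffnessBands,
    tumor_mask: LabeledVolume,
    per_band: bool = False,
) -> MarkerFractionResult:
    """Marker-positive volume percentage per stiffness band.

    Default normalization is the total (tumor - exclusion) volume — the
    reported convention; ``per_band=True`` normalizes by each band's own
    volume instead (sensitivity analysis).
    """
    marker = marker_mask.astype_bool()
    tumor = tumor_mask.astype_bool()
    excl = bands.exclusion if bands.exclusion is not None else np.zeros_like(tumor)
    domain = tumor & ~np.asarray(excl, dtype=bool)
    total = int(domain.sum())
    if total == 0:
        raise ValueError("tumor (minus exclusion) is empty")
    percent: Dict[str, float] = {}
    marker_vox: Dict[str, int] = {}
    band_vox: Dict[str, int] = {}
    for name, band in (("low", bands.low), ("intermediate", bands.intermediate), ("high", bands.high)):
        nb = int(band.sum())
        nm = int((marker & band).sum())
        band_vox[name] = nb
        marker_vox[name] = nm
        denom = nb if per_band else total
        percent[name] = 100.0 * nm / denom if denom > 0 else 0.0
    return MarkerFractionResult(
        percent=percent,
        marker_voxels=marker_vox,
        band_voxels=band_vox,
        total_voxels=total,
        normalization="band" if per_band else "tumor",
    )


def bin_downsample(vol: LabeledVolume, factors=(5, 5, 5)) -> LabeledVolume:
    """Block-average downsampling (shrink factor per axis, bin method: average).

    Each output voxel is the mean of its factor-block; edge blocks average
    over the voxels actually available.  Spacing multiplies by the factors;
    the origin moves to the centre of the first block.
    """
    factors = tuple(int(f) for f in factors)
    if any(f < 1 for f in factors):
        raise ValueError("factors must be >= 1")
    data = np.asarray(_as_array(vol), dtype=float)
    from skimage.measure import block_reduce

    sums = block_reduce(data, factors, np.sum, cval=0.0)
    ones = block_reduce(np.ones_like(data), factors, np.sum, cval=0.0)
    out = sums / ones
    g = vol.grid
    new_grid = VoxelGrid(
        shape=out.shape,
        spacing=tuple(s * f for s, f in zip(g.spacing, factors)),
        origin=tuple(o + (f - 1) / 2.0 * s for o, s, f in zip(g.origin, g.spacing, factors)),
        axis_order=g.axis_order,
    )
    kind = vol.kind if vol.kind not in ("mask", "marker", "wrapped_phase") else "scalar"
    return LabeledVolume(grid=new_grid, values=out, kind=kind)


def ahe_filter(
    vol: LabeledVolume,
    radius=(5, 5, 5),
    alpha: float = 0.3,
    beta: float = 0.3,
) -> LabeledVolume:
    """Adaptive histogram equalization (ITK alpha/beta power-law family).

    ``alpha`` interpolates between classic AHE (0) and unsharp masking (1);
    ``beta`` controls the mean shift, with the (alpha=1, beta=1) limit being
    the identity.  Deterministic; output values stay within the input range.
    A flat (zero-range) volume is returned unchanged — the equalization of a
    degenerate histogram is undefined and identity is the only continuous
    choice.
    """
    import SimpleITK as sitk

    data = np.asarray(_as_array(vol), dtype=float)
    if np.ptp(data) == 0:
        return LabeledVolume(grid=vol.grid, values=data.copy(), kind="scalar")
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    f = sitk.AdaptiveHistogramEqualizationImageFilter()
    f.SetRadius([int(r) for r in radius])
    f.SetAlpha(float(alpha))
    f.SetBeta(float(beta))
    out = sitk.GetArrayFromImage(f.Execute(img))
    out = np.transpose(out, (2, 1, 0))
    return LabeledVolume(grid=vol.grid, values=out, kind="scalar")


def threshold_segment(vol: LabeledVolume, threshold: float, above: bool = True) -> LabeledVolume:
    """Binary threshold segmentation; ``above=True`` keeps values >= threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    data = np.asarray(_as_array(vol), dtype=float)
    mask = data >= threshold if above else data < threshold
    mask &= np.isfinite(data)
    return LabeledVolume(grid=vol.grid, values=mask.astype(np.uint8), kind="mask")
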