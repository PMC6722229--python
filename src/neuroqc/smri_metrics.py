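"""Structural (sMRI / CT) quality-control metrics.

Eight metric families: mean slice intensity, SNR, SVNR, CNR, CVNR, TCTV,
smoothness (FWHM by the variance-of-derivatives method) and centre of mass,
plus the odd/even slice intensity difference used for phantom scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, SegmentationError, ValidationError
from .head_partition import (
    HeadPartition,
    TissueStats,
    extract_brain_mask,
    partition_head_background,
    segment_tissues,
    tissue_stats,
)
from .volume_io import Volume3D

LN2 = math.log(2.0)

#: metric name -> quality direction ("lower-is-worse" means low values flag bad)
DIRECTIONALITY = {
    "snr": "lower-is-worse",
    "svnr": "higher-is-worse",
    "cnr": "lower-is-worse",
    "cvnr": "higher-is-worse",
    "tctv": "lower-is-worse",
    "fwhm": "higher-is-worse",
    "com": "higher-is-worse",
}


@dataclass
class FWHMResult:
    per_axis_mm: tuple[float | None, float | None, float | None]
    magnitude: float | None
    resolvable_elements: float | None
    unresolved_axes: tuple[int, ...] = ()


@dataclass
class CoMResult:
    centroid_mm: tuple[float, float, float]
    offset_mm: tuple[float, float, float]
    magnitude: float


@dataclass
class StructuralMetrics:
    """Per-scan structural QC record; unavailable metrics carry flags."""

    msi: np.ndarray | None = None
    snr: float | None = None
    svnr: float | None = None
    cnr: float | None = None
    cvnr: float | None = None
    tctv: float | None = None
    fwhm: FWHMResult | None = None
    com: CoMResult | None = None
    odd_even_diff: float | None = None
    stats: TissueStats | None = None
    flags: dict = field(default_factory=dict)

    def scalar_dict(self) -> dict:
        out = {
            "snr": self.snr,
            "svnr": self.svnr,
            "cnr": self.cnr,
            "cvnr": self.cvnr,
            "tctv": self.tctv,
            "fwhm": None if self.fwhm is None else self.fwhm.magnitude,
            "com": None if self.com is None else self.com.magnitude,
        }
        return out


def mean_slice_intensity(vol: Volume3D, slice_axis: int | None = None) -> np.ndarray:
    """Vector of per-slice mean intensities along the slice axis."""
    axis = vol.slice_axis if slice_axis is None else slice_axis
    other = tuple(a for a in range(3) if a != axis)
    return vol.values.mean(axis=other)


def odd_even_slice_difference(vol: Volume3D, slice_axis: int | None = None) -> float:
    """mean(MSI of odd-index slices) - mean(MSI of even-index slices), 0-based."""
    msi = mean_slice_intensity(vol, slice_axis)
    if msi.size < 2:
        raise ValidationError("odd/even difference requires >= 2 slices")
    return float(msi[1::2].mean() - msi[0::2].mean())


def compute_snr(stats: TissueStats) -> float | None:
    """Mean head signal over background SD; lower values indicate poorer quality."""
    if stats.mu_head is None or stats.sigma_background is None:
        return None
    if stats.sigma_background == 0:
        stats.flags["snr"] = "background SD is zero; SNR undefined"
        return None
    return stats.mu_head / stats.sigma_background


def compute_svnr(stats: TissueStats) -> float | None:
    """Head intensity variance over background variance; higher is worse."""
    if stats.var_head is None or stats.var_background is None:
        return None
    if stats.var_background == 0:
        stats.flags["svnr"] = "background variance is zero; SVNR undefined"
        return None
    return stats.var_head / stats.var_background


def compute_cnr(stats: TissueStats) -> float | None:
    """|mu_GM - mu_WM| over background SD; lower is worse."""
    if stats.mu_gm is None or stats.mu_wm is None or stats.sigma_background is None:
        return None
    if stats.sigma_background == 0:
        stats.flags["cnr"] = "background SD is zero; CNR undefined"
        return None
    return abs(stats.mu_gm - stats.mu_wm) / stats.sigma_background


def compute_cvnr(stats: TissueStats) -> float | None:
    """|sigma_GM - sigma_WM| over background SD (SD analogue of CNR)."""
    if stats.sigma_gm is None or stats.sigma_wm is None or stats.sigma_background is None:
        return None
    if stats.sigma_background == 0:
        stats.flags["cvnr"] = "background SD is zero; CVNR undefined"
        return None
    return abs(stats.sigma_gm - stats.sigma_wm) / stats.sigma_background


def compute_tctv(stats: TissueStats) -> float | None:
    """|mu_GM - mu_WM| over the quadrature-pooled GM/WM SD; smaller is worse."""
    if None in (stats.mu_gm, stats.mu_wm, stats.sigma_gm, stats.sigma_wm):
        return None
    pooled = math.hypot(stats.sigma_gm, stats.sigma_wm)
    if pooled == 0:
        if stats.mu_gm == stats.mu_wm:
            stats.flags["tctv"] = "0/0: zero contrast and zero tissue variance"
            return None
        stats.flags["tctv"] = "zero tissue variance; TCTV infinite"
        return None
    return abs(stats.mu_gm - stats.mu_wm) / pooled


def estimate_fwhm(vol: Volume3D, brain_mask: np.ndarray,
                  min_voxels: int = 1000,
                  resel_convention: str = "geometric-mean") -> FWHMResult:
    """Per-axis smoothness by the variance-of-derivatives construction.

    For each axis ``a``::

        r_a = 1 - var(forward differences within the mask) / (2 var(masked values))
        FWHM_a = voxel_size_a * sqrt(-2 ln 2 / ln r_a)

    Axes with r outside (0, 1), or an estimate below the voxel size, are
    clamped to the voxel size and flagged unresolved.  ``resolvable_elements``
    divides the brain voxel count by the geometric mean of the three per-axis
    FWHMs (set ``resel_convention="product"`` for the conventional resel
    count).
    """
    mask = np.asarray(brain_mask, dtype=bool)
    n = int(mask.sum())
    if n < min_voxels:
        raise ValidationError(f"brain mask has {n} voxels; FWHM needs >= {min_voxels}")
    values = vol.values
    var_all = float(values[mask].var(ddof=0))
    if var_all == 0:
        raise DegenerateInputError("zero intensity variance in the brain mask")
    per_axis: list[float | None] = []
    unresolved: list[int] = []
    for axis in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        pair_mask = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
        diffs = (values[tuple(sl_hi)] - values[tuple(sl_lo)])[pair_mask]
        dx = vol.voxel_size[axis]
        if diffs.size < 2:
            per_axis.append(None)
            unresolved.append(axis)
            continue
        r = 1.0 - float(diffs.var(ddof=0)) / (2.0 * var_all)
        if r <= 0.0 or r >= 1.0:
            per_axis.append(dx)
            unresolved.append(axis)
            continue
        fwhm = dx * math.sqrt(-2.0 * LN2 / math.log(r))
        if fwhm < dx:
            fwhm = dx
            unresolved.append(axis)
        per_axis.append(fwhm)
    if any(f is None for f in per_axis):
        return FWHMResult(tuple(per_axis), None, None, tuple(unresolved))
    magnitude = math.sqrt(sum(f**2 for f in per_axis))
    if resel_convention == "geometric-mean":
        denom = math.prod(per_axis) ** (1.0 / 3.0)
    elif resel_convention == "product":
        denom = math.prod(per_axis)
    else:
        raise ValidationError(f"unknown resel convention {resel_convention!r}")
    return FWHMResult(tuple(per_axis), magnitude, n / denom, tuple(unresolved))


def center_of_mass(vol: Volume3D, mask: np.ndarray) -> CoMResult:
    """Unweighted centroid of mask voxels in mm, plus offset from grid centre.

    The centroid is the mean of voxel coordinates (not intensity weighted);
    the offset form is acquisition-size invariant and is what auto-QC uses.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("centre of mass of an empty mask")
    idx = np.argwhere(mask)
    centroid = idx.mean(axis=0) * np.asarray(vol.voxel_size)
    offset = centroid - vol.grid_center_mm()
    return CoMResult(
        centroid_mm=tuple(float(c) for c in centroid),
        offset_mm=tuple(float(o) for o in offset),
        magnitude=float(np.linalg.norm(offset)),
    )


def intensity_center_of_mass(vol: Volume3D) -> CoMResult:
    """Intensity-weighted centroid of the whole frame, in mm.

    Used for frame-to-frame CoM tracking in 4D series, where a fixed-mask
    centroid could not move with the content.
    """
    from scipy import ndimage

    total = vol.values.sum()
    if total <= 0:
        raise ValidationError("non-positive total intensity; CoM undefined")
    centroid = np.asarray(ndimage.center_of_mass(vol.values)) * np.asarray(vol.voxel_size)
    offset = centroid - vol.grid_center_mm()
    return CoMResult(centroid_mm=tuple(float(c) for c in centroid),
                     offset_mm=tuple(float(o) for o in offset),
                     magnitude=float(np.linalg.norm(offset)))


def structural_report(vol: Volume3D,
                      profile: str = "t1",
                      background_fraction: float = 0.10,
                      external_brain_mask: np.ndarray | None = None,
                      class_order=None,
                      fwhm_min_voxels: int = 1000,
                      seed: int = 0) -> StructuralMetrics:
    """Full structural pipeline: partition, brain mask, segmentation, metrics.

    ``profile`` controls which metric families apply: the ``ct`` profile skips
    tissue segmentation (CNR/CVNR/TCTV flagged unavailable); ``phantom`` adds
    the odd/even slice difference.
    """
    from .head_partition import CSF, GM, WM

    if class_order is None:
        class_order = (WM, GM, CSF) if profile in ("t2", "flair") else (CSF, GM, WM)
    report = StructuralMetrics()
    report.msi = mean_slice_intensity(vol)
    if profile == "phantom":
        report.odd_even_diff = odd_even_slice_difference(vol)
    try:
        partition = partition_head_background(vol, background_fraction)
    except DegenerateInputError as exc:
        report.flags["partition"] = str(exc)
        return report
    try:
        partition = extract_brain_mask(vol, partition, external_mask=external_brain_mask)
    except SegmentationError as exc:
        report.flags["brain_mask"] = str(exc)
    labels = None
    if profile not in ("ct",) and partition.brain_mask is not None:
        labels = segment_tissues(vol, partition.brain_mask,
                                 class_order=tuple(class_order), seed=seed)
        if labels.degenerate:
            report.flags["segmentation"] = "degenerate: <3 intensity modes in brain"
    elif profile == "ct":
        report.flags["segmentation"] = "not requested for CT profile"
    stats = tissue_stats(vol, partition, labels)
    report.stats = stats
    report.snr = compute_snr(stats)
    report.svnr = compute_svnr(stats)
    report.cnr = compute_cnr(stats)
    report.cvnr = compute_cvnr(stats)
    report.tctv = compute_tctv(stats)
    if partition.brain_mask is not None:
        try:
            report.fwhm = estimate_fwhm(vol, partition.brain_mask, min_voxels=fwhm_min_voxels)
        except (ValidationError, DegenerateInputError) as exc:
            report.flags["fwhm"] = str(exc)
        report.com = center_of_mass(vol, partition.brain_mask)
    else:
        report.flags.setdefault("fwhm", "no brain mask")
        report.flags.setdefault("com", "no brain mask")
    report.flags.update(stats.flags)
    return report
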