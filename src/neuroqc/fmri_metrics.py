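"""Functional (4D) quality-control metrics.

Scalar metrics: framewise displacement (FD) and DVARS with their threshold
counts, and temporal SNR.  Plotted quantities: per-frame MSI, velocity,
outlier fraction, CoM change, FWHM, spectrum statistics, per-slice variation
and SFNR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .errors import DegenerateInputError, ValidationError
from .head_partition import partition_head_background, extract_brain_mask
from .rigid import RegistrationResult, register_rigid
from .smri_metrics import (
    FWHMResult,
    estimate_fwhm,
    intensity_center_of_mass,
    mean_slice_intensity,
)
from .volume_io import Series4D, Volume3D

FD_THRESHOLD_MM = 0.5
DVARS_THRESHOLD = 50.0
HEAD_RADIUS_MM = 50.0


@dataclass
class RigidParams:
    """Per-frame rigid motion parameters relative to the first frame."""

    translations: np.ndarray  # (n_frames, 3) mm
    rotations: np.ndarray     # (n_frames, 3) radians
    missing: np.ndarray       # (n_frames,) bool: optimiser failure flags

    def __post_init__(self):
        self.translations = np.asarray(self.translations, dtype=float)
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (self.translations.shape == self.rotations.shape
                and self.translations.shape[1] == 3
                and self.missing.shape == (self.translations.shape[0],)):
            raise ValidationError("inconsistent rigid parameter arrays")

    @property
    def n_frames(self) -> int:
        return self.translations.shape[0]


@dataclass
class FunctionalMetrics:
    fd: np.ndarray | None = None
    max_fd: float | None = None
    n_fd_gt: int | None = None
    fd_threshold: float = FD_THRESHOLD_MM
    dvars: np.ndarray | None = None
    max_dvars: float | None = None
    min_dvars: float | None = None
    n_dvars_gt: int | None = None
    dvars_threshold: float = DVARS_THRESHOLD
    avg_tsnr: float | None = None
    tsnr_map: np.ndarray | None = None
    median_sfnr: float | None = None
    sfnr_map: np.ndarray | None = None
    motion: RigidParams | None = None
    outlier_fraction: np.ndarray | None = None
    velocity: np.ndarray | None = None
    spectrum_mean: float | None = None
    spectrum_max: float | None = None
    spectrum: tuple[np.ndarray, np.ndarray] | None = None  # (freqs, magnitudes)
    frame_msi: np.ndarray | None = None
    frame_com_offset: np.ndarray | None = None
    frame_fwhm: np.ndarray | None = None
    slice_variation: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    def scalar_dict(self) -> dict:
        return {
            "max_fd": self.max_fd,
            "n_fd_gt": self.n_fd_gt,
            "avg_tsnr": self.avg_tsnr,
            "max_dvars": self.max_dvars,
            "min_dvars": self.min_dvars,
            "n_dvars_gt": self.n_dvars_gt,
        }


def default_brain_mask(series: Series4D, external_mask: np.ndarray | None = None) -> np.ndarray:
    """Brain mask from the temporal-mean volume (or an external bypass)."""
    mean_vol = Volume3D(series.values.mean(axis=3), series.voxel_size,
                        slice_axis=series.slice_axis)
    partition = partition_head_background(mean_vol)
    partition = extract_brain_mask(mean_vol, partition, external_mask=external_mask)
    return partition.brain_mask


def estimate_motion(series: Series4D, brain_mask: np.ndarray | None = None,
                    reference_frame: int = 0) -> RigidParams:
    """Rigid realignment of every frame to the reference frame.

    Normalised-correlation cost, CoM initialisation, two-level multiresolution
    Powell search.  Frames where the optimiser fails are flagged missing.
    """
    n = series.n_frames
    translations = np.zeros((n, 3))
    rotations = np.zeros((n, 3))
    missing = np.zeros(n, dtype=bool)
    reference = series.values[..., reference_frame]
    for t in range(n):
        if t == reference_frame:
            continue
        try:
            res: RegistrationResult = register_rigid(series.values[..., t], reference,
                                                     series.voxel_size)
        except Exception:
            missing[t] = True
            continue
        translations[t] = res.translation
        rotations[t] = res.rotation
    return RigidParams(translations, rotations, missing)


def framewise_displacement(params: RigidParams,
                           head_radius: float = HEAD_RADIUS_MM,
                           threshold: float = FD_THRESHOLD_MM,
                           mode: str = "frame-to-frame"):
    """Power-style FD: sum of absolute parameter changes, rotations as arc length.

    ``mode="frame-to-frame"`` (default) differences consecutive frames;
    ``mode="to-first"`` differences each frame against the reference.
    Returns (fd vector, max, count above threshold).  FD at the first frame
    is 0 by construction; junctions with missing parameters are NaN.
    """
    t = params.translations
    r = params.rotations
    if mode == "frame-to-frame":
        dt = np.diff(t, axis=0)
        dr = np.diff(r, axis=0)
    elif mode == "to-first":
        dt = t[1:] - t[0]
        dr = r[1:] - r[0]
    else:
        raise ValidationError(f"unknown FD mode {mode!r}")
    fd = np.zeros(params.n_frames)
    fd[1:] = np.abs(dt).sum(axis=1) + head_radius * np.abs(dr).sum(axis=1)
    if params.missing.any():
        bad = np.where(params.missing)[0]
        for b in bad:
            fd[max(b, 1):min(b + 2, fd.size)] = np.nan
    valid = fd[np.isfinite(fd)]
    max_fd = float(valid.max()) if valid.size else None
    count = int(np.sum(valid > threshold))
    return fd, max_fd, count


def compute_dvars(series: Series4D, brain_mask: np.ndarray,
                  normalize: str | None = "median-1000",
                  threshold: float = DVARS_THRESHOLD):
    """Root-mean-square frame-to-frame signal change within the mask.

    With ``normalize="median-1000"`` intensities are rescaled so the median
    within-mask intensity of the temporal-mean volume is 1000 (a DVARS of 50
    then means 5% signal change); pass ``None`` to use raw units.
    Returns (dvars vector, max, min, count above threshold); element 0 is 0
    by construction.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty brain mask for DVARS")
    data = series.values[mask, :]  # (n_voxels, n_frames)
    if normalize == "median-1000":
        med = np.median(data.mean(axis=1))
        if med <= 0:
            raise DegenerateInputError("non-positive median intensity; cannot normalise")
        data = data * (1000.0 / med)
    elif normalize is not None:
        raise ValidationError(f"unknown DVARS normalisation {normalize!r}")
    diffs = np.diff(data, axis=1)
    dvars = np.zeros(series.n_frames)
    dvars[1:] = np.sqrt(np.mean(diffs**2, axis=0))
    tail = dvars[1:]
    return dvars, float(tail.max()), float(tail.min()), int(np.sum(tail > threshold))


def temporal_snr(series: Series4D, brain_mask: np.ndarray):
    """Per-voxel temporal mean / temporal SD and its within-mask average.

    Zero-SD voxels are excluded from the average; the excluded count is
    returned.  Returns (tsnr map over the mask as a 3D grid with NaN outside,
    average, n_excluded).
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty brain mask for tSNR")
    if series.n_frames < 10:
        warnings.warn("temporal SNR on < 10 frames is unstable", stacklevel=2)
    data = series.values[mask, :]
    mean = data.mean(axis=1)
    sd = data.std(axis=1, ddof=0)
    valid = sd > 0
    tsnr_vals = np.full(mean.shape, np.nan)
    tsnr_vals[valid] = mean[valid] / sd[valid]
    tsnr_map = np.full(series.shape, np.nan)
    tsnr_map[mask] = tsnr_vals
    avg = float(tsnr_vals[valid].mean()) if valid.any() else None
    return tsnr_map, avg, int((~valid).sum())


def _detrend_residuals(data: np.ndarray, order: int = 2) -> np.ndarray:
    """Residuals after per-voxel polynomial detrend; data is (n_voxels, n_frames)."""
    n = data.shape[1]
    x = np.linspace(-1.0, 1.0, n)
    design = np.vander(x, order + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, data.T, rcond=None)
    return data - (design @ coef).T


def compute_sfnr(series: Series4D, brain_mask: np.ndarray, detrend_order: int = 2):
    """Signal-to-fluctuation-noise ratio: mean over SD of detrended residuals.

    Returns (sfnr map with NaN outside the mask, median over valid voxels,
    n_excluded).
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty brain mask for SFNR")
    if series.n_frames < detrend_order + 2:
        raise ValidationError("too few frames for polynomial detrending")
    data = series.values[mask, :]
    resid = _detrend_residuals(data, order=detrend_order)
    mean = data.mean(axis=1)
    noise_sd = resid.std(axis=1, ddof=0)
    valid = noise_sd > 1e-12 * np.maximum(np.abs(mean), 1.0)
    sfnr_vals = np.full(mean.shape, np.nan)
    sfnr_vals[valid] = mean[valid] / noise_sd[valid]
    sfnr_map = np.full(series.shape, np.nan)
    sfnr_map[mask] = sfnr_vals
    median = float(np.median(sfnr_vals[valid])) if valid.any() else None
    return sfnr_map, median, int((~valid).sum())


def outlier_fraction(series: Series4D, brain_mask: np.ndarray,
                     alpha: float = 0.001) -> np.ndarray:
    """Per-frame share of mask voxels deviating beyond an alpha-level threshold.

    Per voxel the trend is the temporal median; the deviation threshold is
    ``z(1 - alpha/2) * sqrt(pi/2) * mean(|residual|)`` — the sqrt(pi/2) factor
    converts the mean absolute deviation of a Gaussian to its SD, so a pure
    noise series yields a fraction close to alpha.  Zero-deviation voxels are
    excluded.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty brain mask for outlier counting")
    data = series.values[mask, :]
    trend = np.median(data, axis=1, keepdims=True)
    resid = data - trend
    mad = np.abs(resid).mean(axis=1)
    valid = mad > 0
    if not valid.any():
        return np.zeros(series.n_frames)
    z = sstats.norm.ppf(1.0 - alpha / 2.0)
    thr = z * math.sqrt(math.pi / 2.0) * mad[valid]
    exceed = np.abs(resid[valid, :]) > thr[:, None]
    return exceed.mean(axis=0)


def velocity(series: Series4D) -> np.ndarray:
    """Volume-mean running difference per frame; 0 at the first frame."""
    means = series.values.mean(axis=(0, 1, 2))
    v = np.zeros(series.n_frames)
    v[1:] = np.diff(means)
    return v


def spectrum_stats(series: Series4D, brain_mask: np.ndarray):
    """Magnitude spectrum of the mean within-mask signal (DC excluded).

    Returns (freqs, magnitudes, mean, max).  Frequencies are Hz when the
    frame interval is known, otherwise cycles/frame (with a warning).
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty brain mask for spectrum")
    signal = series.values[mask, :].mean(axis=0)
    tr = series.frame_interval
    if tr is None:
        warnings.warn("frame interval unknown; frequencies are cycles/frame", stacklevel=2)
        tr = 1.0
    spectrum = np.abs(np.fft.rfft(signal))[1:]
    freqs = np.fft.rfftfreq(signal.size, d=tr)[1:]
    return freqs, spectrum, float(spectrum.mean()), float(spectrum.max())


def per_frame_descriptors(series: Series4D, brain_mask: np.ndarray,
                          fwhm_min_voxels: int = 1000):
    """Frame-wise MSI, CoM offsets and FWHM triples, plus per-slice variation.

    Reuses the structural operators on every frame; the CoM is the
    intensity-weighted frame centroid (a fixed-mask centroid could not track
    content motion).  Slice variation is the SD over time of each slice's
    mean intensity.
    Returns (msi (n,), com_offsets (n, 3), fwhm (n, 3), slice_variation (n_slices,)).
    """
    mask = np.asarray(brain_mask, dtype=bool)
    n = series.n_frames
    msi = np.empty(n)
    com = np.empty((n, 3))
    fwhm = np.full((n, 3), np.nan)
    slice_msi = []
    for t in range(n):
        frame = series.frame(t)
        msi[t] = frame.values.mean()
        com[t] = intensity_center_of_mass(frame).offset_mm
        slice_msi.append(mean_slice_intensity(frame))
        try:
            res: FWHMResult = estimate_fwhm(frame, mask, min_voxels=fwhm_min_voxels)
            fwhm[t] = [f if f is not None else np.nan for f in res.per_axis_mm]
        except (ValidationError, DegenerateInputError):
            pass
    slice_variation = np.stack(slice_msi, axis=1).std(axis=1, ddof=0)
    return msi, com, fwhm, slice_variation


def functional_report(series: Series4D,
                      external_brain_mask: np.ndarray | None = None,
                      fd_threshold: float = FD_THRESHOLD_MM,
                      dvars_threshold: float = DVARS_THRESHOLD,
                      head_radius: float = HEAD_RADIUS_MM,
                      motion_params: RigidParams | None = None,
                      run_motion: bool = True,
                      fwhm_min_voxels: int = 1000) -> FunctionalMetrics:
    """Full functional pipeline: mask, motion, all scalar and plotted metrics.

    Pre-computed motion parameters can be injected via ``motion_params``
    (e.g. simulation ground truth); otherwise rigid realignment runs unless
    ``run_motion`` is false.
    """
    report = FunctionalMetrics(fd_threshold=fd_threshold, dvars_threshold=dvars_threshold)
    try:
        mask = default_brain_mask(series, external_mask=external_brain_mask)
    except Exception as exc:
        report.flags["brain_mask"] = str(exc)
        return report
    if motion_params is not None:
        report.motion = motion_params
    elif run_motion:
        report.motion = estimate_motion(series, mask)
    if report.motion is not None:
        report.fd, report.max_fd, report.n_fd_gt = framewise_displacement(
            report.motion, head_radius=head_radius, threshold=fd_threshold)
    else:
        report.flags["fd"] = "motion estimation skipped"
    report.dvars, report.max_dvars, report.min_dvars, report.n_dvars_gt = compute_dvars(
        series, mask, threshold=dvars_threshold)
    report.tsnr_map, report.avg_tsnr, n_excluded = temporal_snr(series, mask)
    if n_excluded:
        report.flags["tsnr"] = f"{n_excluded} zero-SD voxel(s) excluded"
    if series.n_frames >= 4:
        report.sfnr_map, report.median_sfnr, _ = compute_sfnr(series, mask)
    report.outlier_fraction = outlier_fraction(series, mask)
    report.velocity = velocity(series)
    freqs, spectrum, smean, smax = spectrum_stats(series, mask)
    report.spectrum = (freqs, spectrum)
    report.spectrum_mean, report.spectrum_max = smean, smax
    (report.frame_msi, report.frame_com_offset,
     report.frame_fwhm, report.slice_variation) = per_frame_descriptors(
        series, mask, fwhm_min_voxels=fwhm_min_voxels)
    return report
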