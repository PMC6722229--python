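"""Diffusion-weighted QC: per-gradient vectors, histograms, slice report and
tensor-derived FA/MD/ADC maps.

The tensor fit is unweighted log-linear least squares per voxel; the head and
background masks are derived from the b=0 frame with the structural partition
operator and reused for every gradient volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError
from .head_partition import HeadPartition, extract_brain_mask, partition_head_background
from .smri_metrics import intensity_center_of_mass
from .volume_io import GradientScheme, Series4D, Volume3D


@dataclass
class GradientHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    mean: float
    sd: float
    minimum: float
    maximum: float
    median: float
    q25: float
    q75: float


@dataclass
class DiffusionMetrics:
    msi: np.ndarray | None = None                 # per gradient volume
    snr: np.ndarray | None = None                 # per gradient volume
    com_displacement: np.ndarray | None = None    # (n_gradients, 3) mm about the mean
    histograms: list[GradientHistogram] | None = None
    slice_report: pd.DataFrame | None = None
    b0_map: np.ndarray | None = None
    fa_map: np.ndarray | None = None
    md_map: np.ndarray | None = None
    adc_map: np.ndarray | None = None
    n_negative_eigenvalue_voxels: int = 0
    flags: dict = field(default_factory=dict)


def b0_partition(series: Series4D, scheme: GradientScheme,
                 external_brain_mask: np.ndarray | None = None) -> HeadPartition:
    """Head/background/brain partition computed on the mean b=0 frame."""
    b0 = series.values[..., scheme.b0_mask].mean(axis=3)
    vol = Volume3D(b0, series.voxel_size, slice_axis=series.slice_axis)
    partition = partition_head_background(vol)
    return extract_brain_mask(vol, partition, external_mask=external_brain_mask)


def per_gradient_metrics(series: Series4D, scheme: GradientScheme,
                         partition: HeadPartition):
    """MSI, SNR and CoM displacement for each gradient-direction volume.

    SNR reuses the structural definition frame-wise with the b0-derived
    partition; the CoM displacement is each frame's intensity-weighted
    centroid minus the mean centroid over frames (so it sums to zero per
    axis).
    """
    if len(scheme) != series.n_frames:
        raise ValidationError("gradient scheme length does not match the series")
    n = series.n_frames
    msi = np.empty(n)
    snr = np.full(n, np.nan)
    com = np.empty((n, 3))
    bg = partition.background_mask
    head = partition.head_mask
    for t in range(n):
        frame = series.values[..., t]
        msi[t] = frame.mean()
        s_bg = float(frame[bg].std(ddof=0)) if bg.any() else 0.0
        if s_bg > 0:
            snr[t] = float(frame[head].mean()) / s_bg
        com[t] = np.asarray(intensity_center_of_mass(series.frame(t)).centroid_mm)
    com_displacement = com - com.mean(axis=0, keepdims=True)
    return msi, snr, com_displacement


def gradient_histograms(series: Series4D, scheme: GradientScheme,
                        head_mask: np.ndarray, n_bins: int = 100) -> list[GradientHistogram]:
    """Within-head-mask intensity histogram + descriptive stats per volume."""
    mask = np.asarray(head_mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty head mask for gradient histograms")
    out = []
    for t in range(series.n_frames):
        vals = series.values[..., t][mask]
        lo, hi = float(vals.min()), float(vals.max())
        if lo == hi:
            edges = np.linspace(lo - 0.5, hi + 0.5, n_bins + 1)
        else:
            edges = np.linspace(lo, hi, n_bins + 1)
        counts, edges = np.histogram(vals, bins=edges)
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        out.append(GradientHistogram(
            bin_edges=edges, counts=counts,
            mean=float(vals.mean()), sd=float(vals.std(ddof=0)),
            minimum=lo, maximum=hi,
            median=float(med), q25=float(q25), q75=float(q75)))
    return out


def slice_report(series: Series4D, scheme: GradientScheme,
                 slice_axis: int | None = None) -> pd.DataFrame:
    """One row per (gradient volume, slice): n_voxels, mean, SD, min, max."""
    if len(scheme) != series.n_frames:
        raise ValidationError("gradient scheme length does not match the series")
    axis = series.slice_axis if slice_axis is None else slice_axis
    rows = []
    for t in range(series.n_frames):
        frame = np.moveaxis(series.values[..., t], axis, 0)
        for k in range(frame.shape[0]):
            sl = frame[k]
            rows.append({
                "gradient": t, "slice": k, "n_voxels": int(sl.size),
                "mean": float(sl.mean()), "sd": float(sl.std(ddof=0)),
                "min": float(sl.min()), "max": float(sl.max()),
            })
    return pd.DataFrame(rows)


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    dwi = ~scheme.b0_mask
    b = scheme.b_values[dwi]
    g = scheme.directions[dwi]
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack([
        b * gx * gx, b * gy * gy, b * gz * gz,
        2 * b * gx * gy, 2 * b * gx * gz, 2 * b * gy * gz,
    ])


def fit_tensor(series: Series4D, scheme: GradientScheme, brain_mask: np.ndarray,
               condition_limit: float = 1e6):
    """Log-linear least-squares tensor fit; returns a :class:`DiffusionMetrics`
    carrying b0/FA/MD/ADC maps (NaN outside the mask or where the signal is
    non-positive).

    Per voxel: solve ``-ln(S_g / S_0) = b g^T D g`` for the six unique tensor
    entries, eigendecompose, then MD = mean eigenvalue and
    FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||.  The ADC map averages the
    per-gradient apparent coefficients ``-ln(S_g/S_0)/b``.  Voxels with any
    negative eigenvalue are counted but not silently clipped.
    """
    if len(scheme) != series.n_frames:
        raise ValidationError("gradient scheme length does not match the series")
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty brain mask for tensor fitting")
    dwi = ~scheme.b0_mask
    if dwi.sum() < 6:
        raise ValidationError("tensor fit requires >= 6 diffusion-weighted volumes")
    X = _design_matrix(scheme)
    cond = np.linalg.cond(X)
    if cond > condition_limit:
        raise DegenerateInputError(
            f"gradient directions are (nearly) collinear: design condition number {cond:.3g}")

    s0 = series.values[..., scheme.b0_mask].mean(axis=3)
    signals = series.values[..., dwi][mask, :]           # (n_voxels, n_dwi)
    s0_masked = s0[mask]
    b = scheme.b_values[dwi]

    valid = (s0_masked > 0) & np.all(signals > 0, axis=1)
    y = -np.log(signals[valid] / s0_masked[valid, None])  # (n_valid, n_dwi)
    coef, *_ = np.linalg.lstsq(X, y.T, rcond=None)        # (6, n_valid)
    dxx, dyy, dzz, dxy, dxz, dyz = coef
    tensors = np.empty((coef.shape[1], 3, 3))
    tensors[:, 0, 0] = dxx
    tensors[:, 1, 1] = dyy
    tensors[:, 2, 2] = dzz
    tensors[:, 0, 1] = tensors[:, 1, 0] = dxy
    tensors[:, 0, 2] = tensors[:, 2, 0] = dxz
    tensors[:, 1, 2] = tensors[:, 2, 1] = dyz
    eigvals = np.linalg.eigvalsh(tensors)                 # ascending, (n_valid, 3)
    md = eigvals.mean(axis=1)
    dev = eigvals - md[:, None]
    norm = np.linalg.norm(eigvals, axis=1)
    fa = np.zeros(md.shape)
    nz = norm > 0
    fa[nz] = np.sqrt(1.5) * np.linalg.norm(dev[nz], axis=1) / norm[nz]
    n_negative = int(np.any(eigvals < 0, axis=1).sum())

    adc_per_grad = y / b[None, :]
    adc = adc_per_grad.mean(axis=1)

    def to_map(vals):
        grid = np.full(series.shape, np.nan)
        inner = np.full(mask.sum(), np.nan)
        inner[valid] = vals
        grid[mask] = inner
        return grid

    result = DiffusionMetrics(
        b0_map=s0, fa_map=to_map(fa), md_map=to_map(md), adc_map=to_map(adc),
        n_negative_eigenvalue_voxels=n_negative)
    n_invalid = int((~valid).sum())
    if n_invalid:
        result.flags["signal"] = f"{n_invalid} voxel(s) with non-positive signal skipped"
    return result


def diffusion_report(series: Series4D, scheme: GradientScheme,
                     external_brain_mask: np.ndarray | None = None,
                     n_bins: int = 100) -> DiffusionMetrics:
    """Full diffusion pipeline: b0 partition, per-gradient vectors, histograms,
    slice report and the tensor-derived maps."""
    partition = b0_partition(series, scheme, external_brain_mask=external_brain_mask)
    msi, snr, com_disp = per_gradient_metrics(series, scheme, partition)
    report = fit_tensor(series, scheme, partition.brain_mask)
    report.msi = msi
    report.snr = snr
    report.com_displacement = com_disp
    report.histograms = gradient_histograms(series, scheme, partition.head_mask, n_bins=n_bins)
    report.slice_report = slice_report(series, scheme)
    return report
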