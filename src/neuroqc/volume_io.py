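"""NIfTI input/output and the internal voxel-grid image model.

All metric code consumes :class:`Volume3D` / :class:`Series4D` rather than
nibabel objects directly, so that geometry invariants (positive voxel sizes,
finite intensities, non-degenerate grids) are checked exactly once, at load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import GradientSchemeError, ValidationError

MIN_AXIS_LEN = 8

__all__ = [
    "Volume3D",
    "Series4D",
    "GradientScheme",
    "read_volume",
    "read_series",
    "read_gradients",
    "write_volume",
    "write_series",
]


def _check_grid(values: np.ndarray, voxel_size, ndim: int) -> None:
    if values.ndim != ndim:
        raise ValidationError(f"expected {ndim}D data, got {values.ndim}D")
    if any(s < MIN_AXIS_LEN for s in values.shape[:3]):
        raise ValidationError(
            f"grid must have >= {MIN_AXIS_LEN} voxels per spatial axis, got {values.shape[:3]}"
        )
    n_bad = int(np.size(values) - np.isfinite(values).sum())
    if n_bad:
        raise ValidationError(f"{n_bad} non-finite voxel(s) in input")
    vs = np.asarray(voxel_size, dtype=float)
    if vs.shape != (3,) or not np.all(np.isfinite(vs)) or np.any(vs <= 0):
        raise ValidationError(f"voxel sizes must be three positive finite numbers, got {voxel_size}")


@dataclass(frozen=True)
class Volume3D:
    """A 3D scalar grid with physical voxel spacing.

    Parameters
    ----------
    values
        3D array of intensities; must be finite.
    voxel_size
        (x, y, z) spacing in millimetres.
    axis_order
        Stored-index to anatomical-axis mapping, informational.
    slice_axis
        Index of the acquisition slice dimension (default: third stored axis).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    axis_order: tuple[str, str, str] = ("x", "y", "z")
    slice_axis: int = 2

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        _check_grid(values, self.voxel_size, ndim=3)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        if self.slice_axis not in (0, 1, 2):
            raise ValidationError("slice_axis must be 0, 1 or 2")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def grid_center_mm(self) -> np.ndarray:
        """Physical coordinates of the grid centre (0-based index * voxel size)."""
        return (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.voxel_size)


@dataclass(frozen=True)
class Series4D:
    """An ordered stack of 3D frames sharing one grid.

    ``values`` is stored (x, y, z, t).  ``frame_interval`` is the repetition
    time in seconds, or ``None`` for series without a meaningful TR (DWI).
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    frame_interval: float | None = None
    slice_axis: int = 2

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        _check_grid(values, self.voxel_size, ndim=4)
        if values.shape[3] < 2:
            raise ValidationError("series requires >= 2 frames")
        if self.frame_interval is not None and not (
            np.isfinite(self.frame_interval) and self.frame_interval > 0
        ):
            raise ValidationError(f"frame_interval must be positive, got {self.frame_interval}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    def frame(self, t: int) -> Volume3D:
        return Volume3D(self.values[..., t], self.voxel_size, slice_axis=self.slice_axis)

    def frames(self):
        return [self.frame(t) for t in range(self.n_frames)]


@dataclass(frozen=True)
class GradientScheme:
    """Per-frame diffusion weighting: b-values (s/mm^2) and unit directions."""

    b_values: np.ndarray
    directions: np.ndarray
    b0_tolerance: float = 50.0

    def __post_init__(self):
        b = np.atleast_1d(np.asarray(self.b_values, dtype=float))
        g = np.asarray(self.directions, dtype=float)
        if g.shape != (b.size, 3):
            raise GradientSchemeError(
                f"directions shape {g.shape} does not match {b.size} b-values"
            )
        if not np.all(np.isfinite(b)) or not np.all(np.isfinite(g)):
            raise GradientSchemeError("non-finite entries in gradient table")
        if not np.any(b <= self.b0_tolerance):
            raise GradientSchemeError("no b=0 reference volume in the gradient table")
        dwi = b > self.b0_tolerance
        norms = np.linalg.norm(g[dwi], axis=1)
        bad = np.abs(norms - 1.0) > 1e-3
        if np.any(bad):
            raise GradientSchemeError(
                f"{int(bad.sum())} diffusion direction(s) are not unit vectors "
                f"(norms {norms[bad][:5]})"
            )
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)

    def __len__(self) -> int:
        return self.b_values.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b_values <= self.b0_tolerance


def _load_nifti(path):
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel message passthrough
        raise ValidationError(f"cannot read NIfTI file {path}: {exc}") from exc
    return img


def read_volume(path) -> Volume3D:
    """Read a 3D NIfTI file (optionally gzipped) into a :class:`Volume3D`."""
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume, got {data.ndim}D data")
    zooms = img.header.get_zooms()[:3]
    return Volume3D(data.astype(np.float64), tuple(float(z) for z in zooms))


def read_series(path) -> Series4D:
    """Read a 4D NIfTI file into a :class:`Series4D`; TR from the header when set."""
    img = _load_nifti(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        if data.ndim == 3:
            raise ValidationError(f"{path}: series requires >= 2 frames, got a 3D volume")
        raise ValidationError(f"{path}: expected 4D data, got {data.ndim}D")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    return Series4D(data.astype(np.float64), tuple(float(z) for z in zooms[:3]), frame_interval=tr)


def read_mask(path, reference: Volume3D | Series4D | None = None) -> np.ndarray:
    """Read a binary mask NIfTI and return a boolean grid."""
    img = _load_nifti(path)
    data = np.squeeze(np.asanyarray(img.dataobj))
    if data.ndim != 3:
        raise ValidationError(f"{path}: mask must be 3D")
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValidationError(f"{path}: mask must be binary 0/1, found values {uniq[:5]}")
    mask = data.astype(bool)
    if reference is not None and mask.shape != reference.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match image grid {reference.shape}"
        )
    return mask


def _affine(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def write_volume(vol: Volume3D, path, dtype=np.float64) -> None:
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=dtype), _affine(vol.voxel_size))
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def write_series(series: Series4D, path, dtype=np.float64) -> None:
    img = nib.Nifti1Image(np.asarray(series.values, dtype=dtype), _affine(series.voxel_size))
    tr = series.frame_interval if series.frame_interval is not None else 0.0
    img.header.set_zooms(series.voxel_size + (tr,))
    if series.frame_interval is not None:
        img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, voxel_size, path) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_size))
    nib.save(img, str(path))


def read_gradients(bval_path, bvec_path, n_frames: int | None = None,
                   b0_tolerance: float = 50.0) -> GradientScheme:
    """Parse FSL-dialect bval/bvec text files into a :class:`GradientScheme`.

    bvals: a single whitespace-separated row.  bvecs: three rows (x, y, z),
    one column per frame.
    """
    b = np.loadtxt(str(bval_path), dtype=float)
    b = np.atleast_1d(b)
    if b.ndim != 1:
        raise GradientSchemeError(f"{bval_path}: expected a single row of b-values")
    g = np.loadtxt(str(bvec_path), dtype=float)
    g = np.atleast_2d(g)
    if g.shape[0] != 3:
        raise GradientSchemeError(f"{bvec_path}: expected three rows (x, y, z), got {g.shape[0]}")
    if g.shape[1] != b.size:
        raise GradientSchemeError(
            f"bvec column count {g.shape[1]} does not match {b.size} b-values"
        )
    if n_frames is not None and b.size != n_frames:
        raise GradientSchemeError(
            f"gradient table has {b.size} entries but the series has {n_frames} frames"
        )
    return GradientScheme(b, g.T, b0_tolerance=b0_tolerance)
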