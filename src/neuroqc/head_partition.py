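"""Background/head split, brain extraction and tissue labelling.

These masks supply the numerators and denominators of the SNR/CNR metric
family.  Brain extraction is deliberately simple (Otsu threshold within the
head, largest connected component, closing + hole fill) and an externally
supplied mask always takes precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from sklearn.cluster import KMeans

from .errors import DegenerateInputError, SegmentationError, ValidationError
from .volume_io import Volume3D

CSF, GM, WM = 1, 2, 3
_CLASS_NAMES = {CSF: "CSF", GM: "GM", WM: "WM"}

# 26-connectivity structuring element
_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class HeadPartition:
    """Disjoint background/head masks plus an optional brain mask."""

    head_mask: np.ndarray
    background_mask: np.ndarray
    brain_mask: np.ndarray | None = None

    def __post_init__(self):
        h = np.asarray(self.head_mask, dtype=bool)
        b = np.asarray(self.background_mask, dtype=bool)
        if h.shape != b.shape:
            raise ValidationError("head and background masks must share one grid")
        if np.any(h & b) or not np.all(h | b):
            raise ValidationError("head and background must partition the grid")
        object.__setattr__(self, "head_mask", h)
        object.__setattr__(self, "background_mask", b)
        if self.brain_mask is not None:
            br = np.asarray(self.brain_mask, dtype=bool)
            if br.shape != h.shape:
                raise ValidationError("brain mask grid mismatch")
            if np.any(br & ~h):
                raise ValidationError("brain mask must be contained in the head mask")
            object.__setattr__(self, "brain_mask", br)

    def with_brain(self, brain_mask: np.ndarray) -> "HeadPartition":
        return HeadPartition(self.head_mask, self.background_mask, brain_mask)


@dataclass(frozen=True)
class TissueLabels:
    """CSF/GM/WM label grid defined inside the brain mask (0 elsewhere)."""

    labels: np.ndarray
    degenerate: bool = False

    def mask(self, cls: int) -> np.ndarray:
        return self.labels == cls


@dataclass
class TissueStats:
    """Intensity statistics per region/class (population SD convention)."""

    mu_head: float | None = None
    sigma_head: float | None = None
    var_head: float | None = None
    sigma_background: float | None = None
    var_background: float | None = None
    mu_gm: float | None = None
    mu_wm: float | None = None
    mu_csf: float | None = None
    sigma_gm: float | None = None
    sigma_wm: float | None = None
    sigma_csf: float | None = None
    n_brain_voxels: int = 0
    flags: dict = field(default_factory=dict)


def partition_head_background(vol: Volume3D, background_fraction: float = 0.10) -> HeadPartition:
    """Split the grid at the ``background_fraction`` intensity quantile.

    Background = voxels at or below the quantile (linear-interpolation sample
    quantile); head = the complement.
    """
    if not 0 < background_fraction < 0.5:
        raise ValidationError("background_fraction must lie in (0, 0.5)")
    values = vol.values
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise DegenerateInputError("constant image: background/head split undefined")
    q = float(np.quantile(values, background_fraction))
    if q >= vmax:
        # quantile collapsed onto the maximum; fall back to strict inequality
        background = values < q
    else:
        background = values <= q
    return HeadPartition(head_mask=~background, background_mask=background)


def extract_brain_mask(vol: Volume3D, partition: HeadPartition,
                       external_mask: np.ndarray | None = None) -> HeadPartition:
    """Attach a brain mask: external bypass, or Otsu-within-head extraction.

    The automatic route thresholds head voxels with Otsu, keeps the largest
    26-connected component, then applies one binary closing and a hole fill.
    """
    if external_mask is not None:
        mask = np.asarray(external_mask, dtype=bool)
        if mask.shape != vol.shape:
            raise ValidationError("external brain mask grid mismatch")
        if not mask.any():
            raise SegmentationError("external brain mask is empty")
        return partition.with_brain(mask)
    head = partition.head_mask
    if not head.any():
        raise SegmentationError("head mask empty; cannot extract brain")
    head_vals = vol.values[head]
    if head_vals.min() == head_vals.max():
        raise SegmentationError(
            "head intensities are constant; supply an external brain mask"
        )
    thr = threshold_otsu(head_vals)
    candidate = head & (vol.values > thr)
    if not candidate.any():
        raise SegmentationError("no voxels above the Otsu threshold; supply an external mask")
    labelled, n = ndimage.label(candidate, structure=_STRUCT26)
    sizes = ndimage.sum_labels(np.ones_like(labelled), labelled, index=np.arange(1, n + 1))
    brain = labelled == (1 + int(np.argmax(sizes)))
    brain = ndimage.binary_closing(brain, structure=_STRUCT26)
    brain = ndimage.binary_fill_holes(brain)
    brain &= head
    if not brain.any():
        raise SegmentationError("brain extraction produced an empty mask")
    return partition.with_brain(brain)


def segment_tissues(vol: Volume3D, brain_mask: np.ndarray,
                    class_order: tuple[int, int, int] = (CSF, GM, WM),
                    seed: int = 0) -> TissueLabels:
    """Three-class 1-D intensity clustering (k-means, 20 restarts) in the brain.

    Cluster means are sorted ascending and assigned ``class_order`` — the
    default CSF < GM < WM matches T1-like contrast; pass a different order for
    T2/FLAIR sequences.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise SegmentationError("brain mask is empty")
    intensities = vol.values[brain_mask]
    labels = np.zeros(vol.shape, dtype=np.int8)
    if np.unique(intensities).size < 3:
        return TissueLabels(labels=labels, degenerate=True)
    km = KMeans(n_clusters=3, n_init=20, random_state=seed)
    assign = km.fit_predict(intensities.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    remap = np.empty(3, dtype=np.int8)
    for rank, cluster in enumerate(order):
        remap[cluster] = class_order[rank]
    labels[brain_mask] = remap[assign]
    return TissueLabels(labels=labels, degenerate=False)


def _pop_stats(values: np.ndarray) -> tuple[float, float]:
    return float(values.mean()), float(values.std(ddof=0))


def tissue_stats(vol: Volume3D, partition: HeadPartition,
                 labels: TissueLabels | None = None) -> TissueStats:
    """Per-region/per-class means and population SDs over the exact mask voxels."""
    stats = TissueStats()
    v = vol.values
    if partition.head_mask.any():
        stats.mu_head, stats.sigma_head = _pop_stats(v[partition.head_mask])
        stats.var_head = stats.sigma_head**2
    else:
        stats.flags["head"] = "empty head mask"
    if partition.background_mask.any():
        _, stats.sigma_background = _pop_stats(v[partition.background_mask])
        stats.var_background = stats.sigma_background**2
    else:
        stats.flags["background"] = "empty background mask"
    if partition.brain_mask is not None:
        stats.n_brain_voxels = int(partition.brain_mask.sum())
    if labels is not None and not labels.degenerate:
        for cls, mu_attr, sd_attr in ((CSF, "mu_csf", "sigma_csf"),
                                      (GM, "mu_gm", "sigma_gm"),
                                      (WM, "mu_wm", "sigma_wm")):
            mask = labels.mask(cls)
            if mask.any():
                mu, sd = _pop_stats(v[mask])
                setattr(stats, mu_attr, mu)
                setattr(stats, sd_attr, sd)
            else:
                stats.flags[_CLASS_NAMES[cls]] = "empty class"
    elif labels is not None:
        stats.flags["tissues"] = "segmentation degenerate (<3 intensity modes)"
    return stats
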