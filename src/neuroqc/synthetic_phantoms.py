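"""Ground-truth-known synthetic phantoms for every metric family.

Structural phantoms are nested ellipsoids (head shell, CSF, GM, WM) on a
uniform background; functional series add rigid motion events, polynomial
drift and intensity spikes; diffusion series are generated from per-
compartment tensors via the mono-exponential signal model.  All generators
are fully deterministic given the spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .head_partition import CSF, GM, WM, TissueLabels
from .volume_io import GradientScheme, Series4D, Volume3D

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: classic six-direction diffusion scheme (unit vectors)
SIX_DIRECTIONS = np.array([
    [1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1], [0, 1, 1], [0, 1, -1],
], dtype=float) / math.sqrt(2.0)


@dataclass(frozen=True)
class MotionEvent:
    frame: int
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SpikeEvent:
    frame: int
    voxel_fraction: float
    amplitude_mads: float


@dataclass
class PhantomSpec:
    """Parametric description of a synthetic scan with retrievable truth."""

    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    # compartment semi-axes as fractions of the half grid extent (nested)
    head_fraction: float = 0.92
    brain_fraction: float = 0.75   # CSF outer boundary == brain
    gm_fraction: float = 0.60
    wm_fraction: float = 0.38
    # intensities
    background_intensity: float = 0.0
    head_intensity: float = 45.0
    csf_intensity: float = 30.0
    gm_intensity: float = 70.0
    wm_intensity: float = 110.0
    # degradations
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"     # gaussian | rician
    smooth_fwhm_mm: float = 0.0
    bias_order: int = 0
    bias_amplitude: float = 0.0
    ghost_fraction: float = 0.0
    ghost_axis: int = 1
    ringing_keep_fraction: float = 1.0   # <1 truncates k-space
    # 4D parameters
    n_frames: int = 2
    frame_interval: float = 2.0
    motion_events: tuple[MotionEvent, ...] = ()
    drift_coefficients: tuple[float, ...] = ()
    spike_events: tuple[SpikeEvent, ...] = ()
    # diffusion: per-compartment diagonal tensors, mm^2/s
    tensor_field: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        fr = (self.wm_fraction, self.gm_fraction, self.brain_fraction, self.head_fraction)
        if not all(0 < a < b for a, b in zip(fr, fr[1:])):
            raise ValidationError("compartments must be strictly nested: WM < GM < CSF < head")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")


def _ellipsoid_mask(shape, voxel_size, center_mm, semi_axes_mm) -> np.ndarray:
    coords = np.meshgrid(*[np.arange(n) * v for n, v in zip(shape, voxel_size)],
                         indexing="ij")
    acc = np.zeros(shape)
    for x, c, a in zip(coords, center_mm, semi_axes_mm):
        acc += ((x - c) / a) ** 2
    return acc <= 1.0


def compartment_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Nested boolean masks: head, brain (CSF boundary), gm, wm."""
    half = np.asarray(spec.shape) * np.asarray(spec.voxel_size) / 2.0
    center = ((np.asarray(spec.shape) - 1) / 2.0 * np.asarray(spec.voxel_size)
              + np.asarray(spec.center_offset_mm))
    out = {}
    for name, frac in (("head", spec.head_fraction), ("brain", spec.brain_fraction),
                       ("gm", spec.gm_fraction), ("wm", spec.wm_fraction)):
        out[name] = _ellipsoid_mask(spec.shape, spec.voxel_size, center, half * frac)
    return out


def truth_labels(masks: dict[str, np.ndarray]) -> TissueLabels:
    labels = np.zeros(masks["brain"].shape, dtype=np.int8)
    labels[masks["brain"]] = CSF
    labels[masks["gm"]] = GM
    labels[masks["wm"]] = WM
    return TissueLabels(labels=labels)


def _base_image(spec: PhantomSpec, masks: dict[str, np.ndarray]) -> np.ndarray:
    img = np.full(spec.shape, spec.background_intensity, dtype=float)
    img[masks["head"]] = spec.head_intensity
    img[masks["brain"]] = spec.csf_intensity
    img[masks["gm"]] = spec.gm_intensity
    img[masks["wm"]] = spec.wm_intensity
    return img


def _apply_bias(img: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.bias_order <= 0 or spec.bias_amplitude == 0:
        return img
    grids = np.meshgrid(*[np.linspace(-1, 1, n) for n in spec.shape], indexing="ij")
    r = np.sqrt(sum(g**2 for g in grids) / 3.0)
    return img * (1.0 + spec.bias_amplitude * r**spec.bias_order)


def _apply_ghost(img: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.ghost_fraction == 0:
        return img
    shift = img.shape[spec.ghost_axis] // 2
    return img + spec.ghost_fraction * np.roll(img, shift, axis=spec.ghost_axis)


def _apply_ringing(img: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.ringing_keep_fraction >= 1.0:
        return img
    k = np.fft.fftn(img)
    keep = [max(2, int(round(n * spec.ringing_keep_fraction)) // 2) for n in img.shape]
    mask = np.zeros(img.shape, dtype=bool)
    sl = tuple(np.abs(np.fft.fftfreq(n) * n) < kk for n, kk in zip(img.shape, keep))
    mask = sl[0][:, None, None] & sl[1][None, :, None] & sl[2][None, None, :]
    return np.real(np.fft.ifftn(k * mask))


def _apply_smoothing(img: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    if spec.smooth_fwhm_mm <= 0:
        return img
    sigma_vox = [spec.smooth_fwhm_mm * FWHM_TO_SIGMA / v for v in spec.voxel_size]
    return ndimage.gaussian_filter(img, sigma=sigma_vox)


def _apply_noise(img: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.noise_sigma == 0:
        return img
    if spec.noise_model == "gaussian":
        return img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    real = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    imag = rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.sqrt(real**2 + imag**2)


def make_structural(spec: PhantomSpec) -> tuple[Volume3D, dict]:
    """Structural phantom + ground truth (masks, labels, generative means)."""
    rng = np.random.default_rng(spec.seed)
    masks = compartment_masks(spec)
    img = _base_image(spec, masks)
    img = _apply_bias(img, spec)
    img = _apply_ghost(img, spec)
    img = _apply_ringing(img, spec)
    img = _apply_smoothing(img, spec)
    img = _apply_noise(img, spec, rng)
    vol = Volume3D(img, spec.voxel_size)
    truth = {
        "head_mask": masks["head"],
        "brain_mask": masks["brain"],
        "background_mask": ~masks["head"],
        "labels": truth_labels(masks),
        "class_means": {"CSF": spec.csf_intensity, "GM": spec.gm_intensity,
                        "WM": spec.wm_intensity},
        "noise_sigma": spec.noise_sigma,
    }
    return vol, truth


def _analytic_frame(spec: PhantomSpec, translation, rotation,
                    edge_mm: float = 1.0) -> np.ndarray:
    """Render the phantom at a given pose by transforming the geometry.

    Ellipsoid compartments are evaluated at inverse-mapped coordinates with a
    soft edge profile of width ``edge_mm``, so frames at different poses have
    identical blur characteristics (no resampling interpolation) and the pose
    is recoverable to sub-voxel precision.
    """
    from .rigid import rotation_matrix

    shape = spec.shape
    vs = np.asarray(spec.voxel_size, dtype=float)
    half = np.asarray(shape) * vs / 2.0
    grid_c = (np.asarray(shape) - 1) / 2.0 * vs
    center = grid_c + np.asarray(spec.center_offset_mm)
    coords = np.stack(np.meshgrid(*[np.arange(n) * v for n, v in zip(shape, vs)],
                                  indexing="ij"))
    R = rotation_matrix(*rotation)
    w = coords - (grid_c + np.asarray(translation))[:, None, None, None]
    w0 = np.einsum("ji,jxyz->ixyz", R, w) + grid_c[:, None, None, None]
    img = np.full(shape, spec.background_intensity, dtype=float)
    layers = (
        (spec.head_fraction, spec.head_intensity),
        (spec.brain_fraction, spec.csf_intensity),
        (spec.gm_fraction, spec.gm_intensity),
        (spec.wm_fraction, spec.wm_intensity),
    )
    for frac, intensity in layers:
        axes = half * frac
        q = np.sqrt(sum(((w0[i] - center[i]) / axes[i]) ** 2 for i in range(3)))
        # signed distance to the boundary, approximated via the mean radius
        d = (1.0 - q) * axes.mean()
        weight = np.clip(0.5 + d / edge_mm, 0.0, 1.0)
        img = img * (1.0 - weight) + intensity * weight
    return img


def _pose_schedule(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Absolute per-frame pose: each event sets the pose from its frame onward."""
    t = np.zeros((spec.n_frames, 3))
    r = np.zeros((spec.n_frames, 3))
    for ev in sorted(spec.motion_events, key=lambda e: e.frame):
        if not 0 <= ev.frame < spec.n_frames:
            raise ValidationError(f"motion event frame {ev.frame} out of range")
        t[ev.frame:] = ev.translation_mm
        r[ev.frame:] = np.deg2rad(ev.rotation_deg)
    return t, r


def make_functional(spec: PhantomSpec) -> tuple[Series4D, dict]:
    """Functional series: moved base phantom + drift + spikes + noise.

    Ground truth carries the per-frame translations (mm) and rotations
    (radians) along with the compartment masks of the unmoved base phantom.
    """
    if spec.n_frames < 2:
        raise ValidationError("functional phantom needs >= 2 frames")
    rng = np.random.default_rng(spec.seed)
    masks = compartment_masks(spec)
    translations, rotations = _pose_schedule(spec)
    pose_cache: dict[tuple, np.ndarray] = {}

    def rendered(t_vec, r_vec) -> np.ndarray:
        key = tuple(np.round(np.concatenate([t_vec, r_vec]), 9))
        if key not in pose_cache:
            frame = _analytic_frame(spec, t_vec, r_vec)
            frame = _apply_bias(frame, spec)
            pose_cache[key] = _apply_smoothing(frame, spec)
        return pose_cache[key]
    x = np.arange(spec.n_frames, dtype=float)
    x = x / max(spec.n_frames - 1, 1)
    drift = (np.polynomial.polynomial.polyval(x, np.asarray(spec.drift_coefficients))
             if spec.drift_coefficients else np.zeros(spec.n_frames))
    frames = np.empty(spec.shape + (spec.n_frames,))
    mad_scale = spec.noise_sigma if spec.noise_sigma > 0 else 1.0
    spike_lookup: dict[int, list[SpikeEvent]] = {}
    for ev in spec.spike_events:
        spike_lookup.setdefault(ev.frame, []).append(ev)
    brain_idx = np.argwhere(masks["brain"])
    for t in range(spec.n_frames):
        frame = rendered(translations[t], rotations[t]).copy()
        frame = frame + drift[t]
        for ev in spike_lookup.get(t, ()):
            n_spiked = int(round(ev.voxel_fraction * brain_idx.shape[0]))
            chosen = brain_idx[rng.choice(brain_idx.shape[0], size=n_spiked, replace=False)]
            frame[tuple(chosen.T)] += ev.amplitude_mads * mad_scale
        frames[..., t] = _apply_noise(frame, spec, rng)
    series = Series4D(frames, spec.voxel_size, frame_interval=spec.frame_interval)
    truth = {
        "translations": translations,
        "rotations": rotations,
        "brain_mask": masks["brain"],
        "head_mask": masks["head"],
        "drift": drift,
        "noise_sigma": spec.noise_sigma,
    }
    return series, truth


DEFAULT_TENSORS = {
    "background": np.zeros(3),
    "head": np.array([0.7, 0.7, 0.7]) * 1e-3,
    "csf": np.array([3.0, 3.0, 3.0]) * 1e-3,
    "gm": np.array([0.9, 0.9, 0.9]) * 1e-3,
    "wm": np.array([1.7, 0.3, 0.3]) * 1e-3,
}


def make_gradient_scheme(n_b0: int = 1, b_value: float = 1000.0,
                         directions: np.ndarray | None = None) -> GradientScheme:
    """A b0 + n-direction scheme (default: the classic six directions)."""
    if directions is None:
        directions = SIX_DIRECTIONS
    n_dwi = directions.shape[0]
    b = np.concatenate([np.zeros(n_b0), np.full(n_dwi, b_value)])
    g = np.vstack([np.zeros((n_b0, 3)), directions])
    return GradientScheme(b, g)


def _tensor_matrix(entry) -> np.ndarray:
    arr = np.asarray(entry, dtype=float)
    if arr.shape == (3,):
        return np.diag(arr)
    if arr.shape == (3, 3):
        return arr
    raise ValidationError("tensor entries must be length-3 diagonals or 3x3 matrices")


def make_diffusion(spec: PhantomSpec, scheme: GradientScheme) -> tuple[Series4D, dict]:
    """Diffusion series from per-compartment tensors: S = S0 exp(-b g^T D g)."""
    rng = np.random.default_rng(spec.seed)
    masks = compartment_masks(spec)
    tensors = dict(DEFAULT_TENSORS)
    tensors.update(spec.tensor_field)
    # compartment -> (mask, S0): painted outside-in so inner compartments win
    regions = [
        ("head", masks["head"] & ~masks["brain"], spec.head_intensity),
        ("csf", masks["brain"] & ~masks["gm"], spec.csf_intensity),
        ("gm", masks["gm"] & ~masks["wm"], spec.gm_intensity),
        ("wm", masks["wm"], spec.wm_intensity),
    ]
    n = len(scheme)
    frames = np.zeros(spec.shape + (n,))
    tensor_grid = np.zeros(spec.shape + (3, 3))
    for t in range(n):
        b = scheme.b_values[t]
        g = scheme.directions[t]
        frame = np.full(spec.shape, spec.background_intensity, dtype=float)
        for name, mask, s0 in regions:
            D = _tensor_matrix(tensors[name])
            atten = math.exp(-b * float(g @ D @ g)) if b > 0 else 1.0
            frame[mask] = s0 * atten
            if t == 0:
                tensor_grid[mask] = D
        frames[..., t] = _apply_noise(frame, spec, rng)
    series = Series4D(frames, spec.voxel_size, frame_interval=None)
    truth = {
        "tensor_grid": tensor_grid,
        "tensors": {name: _tensor_matrix(tensors[name]) for name, _, _ in regions},
        "brain_mask": masks["brain"],
        "head_mask": masks["head"],
        "wm_mask": masks["wm"],
        "gm_mask": masks["gm"] & ~masks["wm"],
    }
    return series, truth


#: heavy artifact recipe used for "bad" scans in the reference population
def _degrade(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    return replace(
        spec,
        noise_sigma=max(spec.noise_sigma, 2.0) * 4.0,
        smooth_fwhm_mm=max(spec.smooth_fwhm_mm, 4.0),
        ghost_fraction=0.3,
        center_offset_mm=tuple(np.asarray(spec.center_offset_mm)
                               + rng.uniform(4.0, 7.0, size=3) * rng.choice([-1, 1], size=3)),
    )


def make_reference_population(n: int, base_spec: PhantomSpec | None = None,
                              artifact_prevalence: float = 0.2, seed: int = 0,
                              metric_fn=None):
    """Simulated reference population: metric table + good/bad truth labels.

    ``round(prevalence * n)`` scans receive the heavy-artifact recipe and are
    labelled bad.  ``metric_fn`` maps a Volume3D to a dict of scalar metrics;
    the default runs the structural report and extracts its scalar block.
    Returns ``(pandas.DataFrame, labels)`` with ``labels[i] = True`` for bad.
    """
    import pandas as pd

    from .smri_metrics import structural_report

    if base_spec is None:
        base_spec = PhantomSpec(noise_sigma=2.0)
    if metric_fn is None:
        def metric_fn(vol):
            return structural_report(vol).scalar_dict()
    rng = np.random.default_rng(seed)
    n_bad = int(round(artifact_prevalence * n))
    bad_idx = set(rng.choice(n, size=n_bad, replace=False).tolist())
    rows, labels = [], []
    for i in range(n):
        jitter = replace(
            base_spec,
            seed=seed * 100003 + i,
            noise_sigma=base_spec.noise_sigma * float(rng.uniform(0.8, 1.2)),
            center_offset_mm=tuple(rng.uniform(-1.0, 1.0, size=3)),
            gm_intensity=base_spec.gm_intensity * float(rng.uniform(0.97, 1.03)),
        )
        is_bad = i in bad_idx
        if is_bad:
            jitter = _degrade(jitter, rng)
        vol, _ = make_structural(jitter)
        rows.append(metric_fn(vol))
        labels.append(is_bad)
    return pd.DataFrame(rows), np.asarray(labels, dtype=bool)
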