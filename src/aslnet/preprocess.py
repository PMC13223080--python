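"""Automated ROI extraction and feature-channel engineering for perfusion volumes.

The pipeline is fully automatic: the tumour region is approximated by the
centroid of the brightest 0.01% of voxels, a 70 mm cube is extracted around
it, a per-scan background threshold ``vf`` is estimated from small
low-intensity uniform subregions, and four aligned channels are built:

0. raw perfusion signal,
1. global robust standardisation by foreground median and MAD,
2. local standardisation within 15 mm tiles,
3. ``log1p`` of the background-shifted signal.

Augmentation (axis flips, +/-10 degree rotations, elastic deformation,
Rician noise) applies identical geometric transforms to every channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "AslVolume", "RoiCube", "FeatureStack", "AugmentPolicy",
    "extract_roi", "estimate_background_threshold", "mad_standardize",
    "local_standardize", "log_transform", "build_feature_stack",
    "add_rician_noise", "augment_sample", "flip_stack", "rotate_stack",
    "elastic_deform_stack", "save_volume", "load_volume", "CHANNEL_NAMES",
]

CHANNEL_NAMES = ("raw", "mad", "local", "log")


@dataclass
class AslVolume:
    """A 3-D scalar perfusion field with voxel spacing and world affine."""

    intensities: np.ndarray
    voxel_mm: float = 1.0
    affine: np.ndarray | None = None
    patient_id: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.voxel_mm <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.affine is None:
            self.affine = np.diag([self.voxel_mm] * 3 + [1.0])


@dataclass
class RoiCube:
    """A cube extracted around the bright-voxel centroid of a scan."""

    intensities: np.ndarray
    centroid_voxel: tuple[int, int, int]
    voxel_mm: float = 1.0
    background_threshold: float | None = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        s = self.intensities.shape
        if len(s) != 3 or len(set(s)) != 1:
            raise ValueError("ROI cube must be a cube")

    @property
    def side(self) -> int:
        return self.intensities.shape[0]


@dataclass
class FeatureStack:
    """Four aligned channels (raw, MAD-standardised, local, log), channels-last."""

    channels: np.ndarray
    background_threshold: float | None = None

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 4 or self.channels.shape[-1] != 4:
            raise ValueError("feature stack must have shape (S, S, S, 4)")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("feature stack must be finite")


@dataclass
class AugmentPolicy:
    """Random augmentation configuration."""

    flip_prob: tuple[float, float, float] = (0.5, 0.5, 0.5)
    rotation_max_deg: float = 10.0
    elastic_spacing: int = 15
    elastic_sd: float = 2.0
    rician_sigma: float = 0.0
    enable_flip: bool = True
    enable_rotation: bool = True
    enable_elastic: bool = True
    enable_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.rotation_max_deg < 0:
            raise ValueError("rotation_max_deg must be >= 0")
        if any(not 0.0 <= p <= 1.0 for p in self.flip_prob):
            raise ValueError("flip probabilities must be in [0, 1]")
        if self.rician_sigma < 0:
            raise ValueError("rician_sigma must be >= 0")


# ---------------------------------------------------------------------------
# ROI extraction


def extract_roi(volume: AslVolume, top_fraction: float = 1e-4,
                cube_mm: float = 70.0, presmooth_sigma_mm: float | None = None,
                resample_to_mm: float | None = None) -> RoiCube:
    """Centroid-of-brightest-voxels ROI.

    Selects the ``ceil(top_fraction * n_voxels)`` brightest voxels (all ties
    at the cut included), takes their unweighted voxel centroid rounded to
    the nearest voxel, and extracts a cube of ``cube_mm`` per side centred
    there, shifted minimally to stay inside the grid.
    """
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must be in (0, 1)")
    x = volume.intensities
    voxel_mm = volume.voxel_mm
    if resample_to_mm is not None and not math.isclose(resample_to_mm, voxel_mm):
        x = ndimage.zoom(x, voxel_mm / resample_to_mm, order=1)
        voxel_mm = resample_to_mm
    if presmooth_sigma_mm:
        x = ndimage.gaussian_filter(x, presmooth_sigma_mm / voxel_mm)

    side = int(round(cube_mm / voxel_mm))
    if any(side > n for n in x.shape):
        raise ValueError(
            f"ROI cube of {side} voxels does not fit inside grid {x.shape}")

    k = math.ceil(top_fraction * x.size)
    flat = x.ravel()
    threshold = np.partition(flat, x.size - k)[x.size - k]
    mask = x >= threshold
    if mask.all():
        # k-th order statistic hit the background floor: restrict to voxels
        # strictly above it so the tied set stays a bright set
        mask = x > threshold
    if mask.all() or not mask.any():
        raise ValueError(
            "volume is constant: no distinct brightest-voxel set exists")
    coords = np.argwhere(mask)
    centroid = np.rint(coords.mean(axis=0)).astype(int)

    start = np.clip(centroid - side // 2, 0, np.array(x.shape) - side)
    cube = x[start[0]:start[0] + side,
             start[1]:start[1] + side,
             start[2]:start[2] + side]
    return RoiCube(intensities=cube.copy(), centroid_voxel=tuple(int(c) for c in centroid),
                   voxel_mm=voxel_mm)


def _window_stats(x: np.ndarray, w: int):
    """Mean and variance of every w^3 window fully inside x (corner-anchored)."""
    pad = np.zeros(tuple(n + 1 for n in x.shape))
    pad[1:, 1:, 1:] = x
    s1 = pad.cumsum(0).cumsum(1).cumsum(2)
    pad[1:, 1:, 1:] = np.square(x, dtype=np.float64)
    s2 = pad.cumsum(0).cumsum(1).cumsum(2)

    def box(s):
        return (s[w:, w:, w:] - s[:-w, w:, w:] - s[w:, :-w, w:] - s[w:, w:, :-w]
                + s[:-w, :-w, w:] + s[:-w, w:, :-w] + s[w:, :-w, :-w]
                - s[:-w, :-w, :-w])

    nw = w ** 3
    mean = box(s1) / nw
    var = np.maximum(box(s2) / nw - mean ** 2, 0.0)
    return mean, var


def estimate_background_threshold(roi: RoiCube | np.ndarray,
                                  subregion_fraction: float = 0.005) -> float:
    """Per-scan background threshold ``vf``.

    Scans every cubic subregion covering ~``subregion_fraction`` of the
    volume, scores each by mean + standard deviation (low and uniform wins),
    and returns the maximum intensity inside the best-scoring subregion.
    Voxels <= vf are treated as background by the channel statistics.
    """
    x = roi.intensities if isinstance(roi, RoiCube) else np.asarray(roi)
    if not np.all(np.isfinite(x)):
        raise ValueError("ROI must be finite")
    w = max(2, int(round(min(x.shape) * subregion_fraction ** (1.0 / 3.0))))
    w = min(w, min(x.shape))
    mean, var = _window_stats(x.astype(np.float64), w)
    score = mean + np.sqrt(var)
    origin = np.unravel_index(int(np.argmin(score)), score.shape)
    block = x[origin[0]:origin[0] + w,
              origin[1]:origin[1] + w,
              origin[2]:origin[2] + w]
    return float(block.max())


def _eps_for(values: np.ndarray) -> float:
    scale = float(np.abs(values).max()) if values.size else 0.0
    return 1e-6 * (scale if scale > 0 else 1.0)


def mad_standardize(roi: RoiCube | np.ndarray, vf: float) -> np.ndarray:
    """Background-free robust standardisation ``(x - median) / (MAD + eps)``.

    Median and MAD are computed over foreground voxels (> vf) only; the map
    is applied to all voxels.  Raw MAD, no consistency constant.
    """
    x = roi.intensities if isinstance(roi, RoiCube) else np.asarray(roi)
    fg = x[x > vf]
    if fg.size == 0:
        raise ValueError("no foreground voxels above the background threshold")
    m = float(np.median(fg))
    mad = float(np.median(np.abs(fg - m)))
    return ((x - m) / (mad + _eps_for(fg))).astype(np.float32)


def local_standardize(roi: RoiCube | np.ndarray, window_mm: float = 15.0,
                      voxel_mm: float | None = None) -> np.ndarray:
    """Standardise each non-overlapping ~15 mm tile by its own mean and sd.

    Edge tiles are truncated to fit the cube.
    """
    if isinstance(roi, RoiCube):
        x = roi.intensities
        voxel_mm = roi.voxel_mm if voxel_mm is None else voxel_mm
    else:
        x = np.asarray(roi)
        voxel_mm = 1.0 if voxel_mm is None else voxel_mm
    w = int(round(window_mm / voxel_mm))
    if w > min(x.shape):
        raise ValueError(
            f"local window of {w} voxels exceeds cube side {min(x.shape)}")
    out = np.empty_like(x, dtype=np.float32)
    for i0 in range(0, x.shape[0], w):
        for j0 in range(0, x.shape[1], w):
            for k0 in range(0, x.shape[2], w):
                tile = x[i0:i0 + w, j0:j0 + w, k0:k0 + w]
                sd = float(tile.std())
                out[i0:i0 + w, j0:j0 + w, k0:k0 + w] = \
                    (tile - tile.mean()) / (sd + _eps_for(tile))
    return out


def log_transform(roi: RoiCube | np.ndarray, vf: float) -> np.ndarray:
    """``log(1 + max(x - vf, 0))``: zero on background, monotone above it."""
    x = roi.intensities if isinstance(roi, RoiCube) else np.asarray(roi)
    return np.log1p(np.maximum(x - vf, 0.0)).astype(np.float32)


def build_feature_stack(roi: RoiCube, window_mm: float = 15.0) -> FeatureStack:
    """Assemble the 4-channel model input in the fixed order raw/MAD/local/log."""
    vf = roi.background_threshold
    if vf is None:
        vf = estimate_background_threshold(roi)
    x = roi.intensities
    if np.any(x > vf):
        mad_ch = mad_standardize(x, vf)
    else:
        mad_ch = np.zeros_like(x)  # fully-background (constant) cube
    channels = np.stack([
        x,
        mad_ch,
        local_standardize(x, window_mm, roi.voxel_mm),
        log_transform(x, vf),
    ], axis=-1)
    return FeatureStack(channels=channels, background_threshold=float(vf))


# ---------------------------------------------------------------------------
# noise and augmentation


def add_rician_noise(field: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    """Rician-corrupt a non-negative field: sqrt((x + n1)^2 + n2^2)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    x = np.asarray(field, dtype=np.float64)
    if sigma == 0:
        return np.abs(x).astype(field.dtype if hasattr(field, "dtype") else np.float32)
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, x.shape)
    n2 = rng.normal(0.0, sigma, x.shape)
    return np.sqrt((x + n1) ** 2 + n2 ** 2).astype(np.float32)


def flip_stack(channels: np.ndarray, axis: int) -> np.ndarray:
    """Flip all channels along one spatial axis (0, 1 or 2)."""
    if axis not in (0, 1, 2):
        raise ValueError("flip axis must be a spatial axis 0, 1 or 2")
    return np.flip(channels, axis=axis).copy()

def rotate_stack(channels: np.ndarray, angle_deg: float,
                 axes: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Rotate all channels identically in one spatial plane (linear interp)."""
    return ndimage.rotate(channels, angle_deg, axes=axes, reshape=False,
                          order=1, mode="nearest").astype(np.float32)


def elastic_deform_stack(channels: np.ndarray, spacing: int, sd: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Smooth random displacement field from a coarse control grid."""
    spatial = channels.shape[:3]
    ctrl = tuple(max(2, -(-n // spacing) + 1) for n in spatial)
    coords = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in spatial],
                         indexing="ij")
    disp = []
    for d in range(3):
        coarse = rng.normal(0.0, sd, ctrl)
        fine = ndimage.zoom(coarse, [n / c for n, c in zip(spatial, ctrl)],
                            order=3)
        disp.append(fine[:spatial[0], :spatial[1], :spatial[2]])
    warped = np.empty_like(channels, dtype=np.float32)
    sample_at = [coords[d] + disp[d] for d in range(3)]
    for c in range(channels.shape[-1]):
        warped[..., c] = ndimage.map_coordinates(
            channels[..., c], sample_at, order=1, mode="nearest")
    return warped


_ROTATION_PLANES = ((0, 1), (0, 2), (1, 2))


def augment_sample(stack: FeatureStack, policy: AugmentPolicy) -> FeatureStack:
    """Randomly flip, rotate, elastically deform and Rician-corrupt a stack.

    All channels receive identical geometric transforms; the draw sequence
    is fully determined by ``policy.seed``.
    """
    rng = np.random.default_rng(policy.seed)
    ch = stack.channels
    if policy.enable_flip:
        for axis, p in enumerate(policy.flip_prob):
            if rng.random() < p:
                ch = flip_stack(ch, axis)
    if policy.enable_rotation and policy.rotation_max_deg > 0:
        angle = rng.uniform(-policy.rotation_max_deg, policy.rotation_max_deg)
        plane = _ROTATION_PLANES[rng.integers(len(_ROTATION_PLANES))]
        ch = rotate_stack(ch, float(angle), plane)
    if policy.enable_elastic:
        ch = elastic_deform_stack(ch, policy.elastic_spacing, policy.elastic_sd, rng)
    if policy.enable_noise and policy.rician_sigma > 0:
        noise_seed = int(rng.integers(2 ** 31))
        ch = add_rician_noise(ch, policy.rician_sigma, noise_seed)
    return FeatureStack(channels=np.ascontiguousarray(ch, dtype=np.float32),
                        background_threshold=stack.background_threshold)


# ---------------------------------------------------------------------------
# NIfTI I/O


def save_volume(volume: AslVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.intensities.astype(np.float32), volume.affine)
    nib.save(img, str(path))


def load_volume(path: str | Path, patient_id: str = "") -> AslVolume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    voxel_mm = float(img.header.get_zooms()[0])
    return AslVolume(intensities=data, voxel_mm=voxel_mm,
                     affine=np.asarray(img.affine), patient_id=patient_id or Path(path).stem)
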