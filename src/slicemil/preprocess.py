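"""Volume-to-sequence preprocessing.

The pipeline is fixed as: mask -> VOI crop -> HU windowing -> resize to the
target shape -> 3-channel adjacent-slice stacking. Windowing maps the HU
interval [center - width/2, center + width/2] linearly onto [0, 1] and
clips outside it; the default window (width 700, center 100) gives soft
tissue mid-gray and aerated lung black. Resizing is trilinear with
align-corners sampling, so equal source and target shapes are an identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic import VolumeRecord

__all__ = [
    "BoundingBox3D",
    "WindowSpec",
    "ProcessedSequence",
    "AugmentConfig",
    "compute_voi",
    "crop",
    "window_normalize",
    "standardize",
    "resample_slice_labels",
    "stack_adjacent",
    "preprocess_record",
    "augment",
]


@dataclass(frozen=True)
class BoundingBox3D:
    lo: tuple[int, int, int]  # inclusive
    hi: tuple[int, int, int]  # exclusive

    def __post_init__(self):
        if any(l >= h for l, h in zip(self.lo, self.hi)):
            raise ValueError("bounding box must have lo < hi componentwise")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))


@dataclass(frozen=True)
class WindowSpec:
    width: float = 700.0
    center: float = 100.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")


@dataclass
class ProcessedSequence:
    """Fixed-depth stack of normalized 3-channel slice images."""

    exam_id: str
    frames: np.ndarray  # (D, 3, H, W), values in [0, 1]
    slice_labels: np.ndarray  # (D,)
    source_depth: int
    exam_label: int
    subtype: str = "negative"

    @property
    def depth(self) -> int:
        return self.frames.shape[0]


def compute_voi(mask: np.ndarray) -> BoundingBox3D:
    """Tightest axis-aligned box containing all mask-true voxels."""
    if not mask.any():
        raise ValueError("no volume of interest: mask is empty")
    coords = np.argwhere(mask > 0)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    return BoundingBox3D(tuple(int(v) for v in lo), tuple(int(v) for v in hi))


def crop(volume: np.ndarray, box: BoundingBox3D) -> np.ndarray:
    sl = tuple(slice(l, h) for l, h in zip(box.lo, box.hi))
    return volume[sl]


def window_normalize(volume: np.ndarray, spec: WindowSpec = WindowSpec()) -> np.ndarray:
    lo = spec.center - spec.width / 2.0
    return np.clip((np.asarray(volume, dtype=np.float64) - lo) / spec.width, 0.0, 1.0)


def _nearest_source_slice(source_depth: int, target_depth: int) -> np.ndarray:
    """For each target slice, the nearest source slice under align-corners
    mapping (ties resolved to the lower index)."""
    positions = np.linspace(0, source_depth - 1, target_depth)
    src = np.arange(source_depth)
    return np.array([int(np.argmin(np.abs(src - p))) for p in positions])


def resample_slice_labels(slice_labels: np.ndarray, target_depth: int) -> np.ndarray:
    nearest = _nearest_source_slice(len(slice_labels), target_depth)
    return np.asarray(slice_labels)[nearest].astype(np.int8)


def standardize(
    volume: np.ndarray,
    slice_labels: np.ndarray,
    target_shape: tuple[int, int, int] = (184, 256, 256),
) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear resize to `target_shape`; labels follow the nearest source
    slice, so any positive source slice keeps at least one positive target
    slice whenever target depth >= 1."""
    if volume.shape[0] < 2:
        raise ValueError("source depth must be >= 2")
    if len(slice_labels) != volume.shape[0]:
        raise ValueError("slice_labels length must equal source depth")
    if volume.shape == tuple(target_shape):
        return np.asarray(volume, dtype=np.float64), np.asarray(
            slice_labels, dtype=np.int8
        )
    grids = np.meshgrid(
        *[np.linspace(0, s - 1, t) for s, t in zip(volume.shape, target_shape)],
        indexing="ij",
    )
    resized = ndimage.map_coordinates(
        np.asarray(volume, dtype=np.float64), np.stack(grids), order=1, mode="nearest"
    )
    return resized, resample_slice_labels(slice_labels, target_shape[0])


def stack_adjacent(volume: np.ndarray) -> np.ndarray:
    """(D, H, W) -> (D, 3, H, W) with channels (i-1, i, i+1), edges replicated."""
    if volume.shape[0] < 1:
        raise ValueError("need at least one slice")
    d = volume.shape[0]
    prev_idx = np.maximum(np.arange(d) - 1, 0)
    next_idx = np.minimum(np.arange(d) + 1, d - 1)
    return np.stack([volume[prev_idx], volume, volume[next_idx]], axis=1)


def preprocess_record(
    record: VolumeRecord,
    window: WindowSpec = WindowSpec(),
    target_shape: tuple[int, int, int] = (184, 256, 256),
) -> ProcessedSequence:
    """Full pipeline: VOI crop -> window -> standardize -> 3-channel stack."""
    box = compute_voi(record.mask)
    vol = crop(record.volume, box)
    labels = record.slice_labels[box.lo[0] : box.hi[0]]
    vol = window_normalize(vol, window)
    vol, labels = standardize(vol, labels, target_shape)
    frames = stack_adjacent(vol)
    return ProcessedSequence(
        exam_id=record.exam_id,
        frames=frames.astype(np.float32),
        slice_labels=labels,
        source_depth=int(record.volume.shape[0]),
        exam_label=int(record.exam_label),
        subtype=record.subtype,
    )


@dataclass(frozen=True)
class AugmentConfig:
    """Stochastic training augmentations; all probabilities 0 = identity.

    The geometric transforms (rotation, flip) use one draw per exam applied
    to every frame; intensity transforms re-clip to [0, 1].
    """

    rotate_prob: float = 0.0
    rotate_max_deg: float = 10.0
    flip_prob: float = 0.0
    brightness_prob: float = 0.0
    brightness_max: float = 0.10
    contrast_max: float = 0.10
    noise_prob: float = 0.0
    noise_var: float = 0.004
    blur_prob: float = 0.0
    blur_sigma: float = 0.7


def augment(
    sequence: ProcessedSequence, cfg: AugmentConfig, rng: np.random.Generator
) -> ProcessedSequence:
    frames = np.asarray(sequence.frames, dtype=np.float64)
    if rng.random() < cfg.rotate_prob:
        angle = rng.uniform(0.0, cfg.rotate_max_deg)
        frames = ndimage.rotate(
            frames, angle, axes=(-2, -1), reshape=False, order=1, mode="nearest"
        )
    if rng.random() < cfg.flip_prob:
        frames = frames[..., ::-1]
    if rng.random() < cfg.brightness_prob:
        shift = rng.uniform(-cfg.brightness_max, cfg.brightness_max)
        scale = 1.0 + rng.uniform(-cfg.contrast_max, cfg.contrast_max)
        frames = (frames - 0.5) * scale + 0.5 + shift
    if rng.random() < cfg.blur_prob:
        frames = ndimage.gaussian_filter(
            frames, sigma=(0, 0, cfg.blur_sigma, cfg.blur_sigma)
        )
    if rng.random() < cfg.noise_prob:
        frames = frames + rng.normal(0.0, np.sqrt(cfg.noise_var), size=frames.shape)
    frames = np.clip(frames, 0.0, 1.0)
    return ProcessedSequence(
        exam_id=sequence.exam_id,
        frames=frames.astype(np.float32),
        slice_labels=sequence.slice_labels.copy(),
        source_depth=sequence.source_depth,
        exam_label=sequence.exam_label,
        subtype=sequence.subtype,
    )
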