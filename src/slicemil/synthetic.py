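"""Synthetic phantom cohorts for exam-level lesion classification.

Each phantom exam is a 3D Hounsfield-unit volume containing a two-ellipsoid
"lung" mask. Positive exams carry one or more spherical hyperdense lesions
inside the mask: *central* lesions are large spheres placed in the central
third of the in-plane mask extent (spanning many slices), *peripheral*
lesions are small spheres near the mask boundary (spanning few slices).
A slice is labeled positive iff at least one lesion voxel lies on it, and an
exam is positive iff at least one of its slices is — the same consistency
rule the cohort validator enforces downstream.

Default label structure mirrors a CT pulmonary-angiography screening cohort:
roughly 30% positive exams, lesions occupying a few percent of slices, with
a minority of positives being large central lesions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .util import round_half_up

__all__ = [
    "PhantomConfig",
    "VolumeRecord",
    "generate_cohort",
    "inject_lesion",
    "inject_vessel",
    "lung_mask",
    "write_cohort",
    "read_cohort",
]

SUBTYPES = ("negative", "central", "peripheral")


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings; defaults define the desk-scale study conditions."""

    n_exams: int = 60
    prevalence: float = 0.30
    central_fraction: float = 0.20
    volume_shape: tuple[int, int, int] = (32, 64, 64)
    hu_background: float = 40.0
    hu_lung: float = -800.0
    hu_lesion: float = 100.0
    noise_sd: float = 20.0
    central_lesion_radius: int = 6
    peripheral_lesion_radius: int = 2
    lesions_per_exam: tuple[int, int] = (1, 3)
    hu_vessel: float = 300.0
    vessels_per_exam: tuple[int, int] = (0, 0)
    vessel_radius: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must be in [0, 1]")
        if not (0.0 <= self.central_fraction <= 1.0):
            raise ValueError("central_fraction must be in [0, 1]")
        if self.central_lesion_radius < 1 or self.peripheral_lesion_radius < 1:
            raise ValueError("lesion radii must be >= 1")
        if self.volume_shape[0] < 3:
            raise ValueError("depth must be >= 3")
        r_min = min(self.central_lesion_radius, self.peripheral_lesion_radius)
        if any(dim < 3 * r_min for dim in self.volume_shape):
            raise ValueError(
                f"degenerate shape {self.volume_shape}: every dimension must be "
                f">= 3x the smallest lesion radius ({r_min})"
            )
        lo, hi = self.lesions_per_exam
        if lo < 1 or hi < lo:
            raise ValueError("lesions_per_exam must be a nonempty range with min >= 1")
        v_lo, v_hi = self.vessels_per_exam
        if v_lo < 0 or v_hi < v_lo:
            raise ValueError("vessels_per_exam must be a nonnegative range")


@dataclass
class VolumeRecord:
    """One exam: HU volume, organ mask, per-slice labels, exam label."""

    exam_id: str
    volume: np.ndarray
    mask: np.ndarray
    slice_labels: np.ndarray
    exam_label: int
    subtype: str = "negative"

    def validate(self):
        if self.volume.shape != self.mask.shape:
            raise ValueError(f"{self.exam_id}: volume/mask shape mismatch")
        if len(self.slice_labels) != self.volume.shape[0]:
            raise ValueError(f"{self.exam_id}: slice_labels length != depth")
        if not self.mask.any():
            raise ValueError(f"{self.exam_id}: empty mask")
        if self.subtype not in SUBTYPES:
            raise ValueError(f"{self.exam_id}: unknown subtype {self.subtype!r}")

    @property
    def consistent(self) -> bool:
        return int(self.exam_label) == int(self.slice_labels.max(initial=0))


def lung_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Two axis-aligned ellipsoids standing in for the left and right lungs."""
    d, h, w = shape
    z, y, x = np.ogrid[:d, :h, :w]
    cz, cy = (d - 1) / 2.0, (h - 1) / 2.0
    rz, ry, rx = 0.45 * d, 0.38 * h, 0.17 * w
    mask = np.zeros(shape, dtype=np.uint8)
    for cx in (0.28 * (w - 1), 0.72 * (w - 1)):
        dist = ((z - cz) / rz) ** 2 + ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2
        mask |= (dist <= 1.0).astype(np.uint8)
    return mask


def _candidate_centers(mask: np.ndarray, subtype: str, radius: int) -> np.ndarray:
    """Voxel coordinates where a lesion of the given subtype may be centred."""
    coords = np.argwhere(mask > 0)
    ys, xs = coords[:, 1], coords[:, 2]
    y_lo, y_hi = ys.min(), ys.max()
    x_lo, x_hi = xs.min(), xs.max()
    if subtype == "central":
        # central third of the in-plane mask bounding box
        y_third = (y_hi - y_lo + 1) / 3.0
        x_third = (x_hi - x_lo + 1) / 3.0
        keep = (
            (ys >= y_lo + y_third)
            & (ys < y_hi + 1 - y_third)
            & (xs >= x_lo + x_third)
            & (xs < x_hi + 1 - x_third)
        )
    elif subtype == "peripheral":
        from scipy.ndimage import distance_transform_edt

        # near the boundary, but with the sphere (mostly) inside the mask so
        # a "lesion" is never a near-invisible one-voxel sliver
        dist = distance_transform_edt(mask)
        d = dist[tuple(coords.T)]
        keep = (d >= radius) & (d <= radius + 2)
    else:
        raise ValueError(f"cannot inject lesion of subtype {subtype!r}")
    return coords[keep]


def inject_lesion(
    record: VolumeRecord,
    subtype: str,
    rng: np.random.Generator,
    config: PhantomConfig,
    max_retries: int = 50,
) -> VolumeRecord:
    """Write one spherical lesion of `subtype` into the record, in place.

    The sphere is intersected with the mask; slices receiving at least one
    lesion voxel are marked positive and the exam label is updated.
    """
    if not record.mask.any():
        raise ValueError("cannot inject a lesion into an empty mask")
    radius = (
        config.central_lesion_radius
        if subtype == "central"
        else config.peripheral_lesion_radius
    )
    candidates = _candidate_centers(record.mask, subtype, radius)
    d, h, w = record.volume.shape
    z, y, x = np.ogrid[:d, :h, :w]
    for _ in range(max_retries):
        cz, cy, cx = candidates[rng.integers(len(candidates))]
        sphere = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= radius**2
        lesion = sphere & (record.mask > 0)
        if lesion.any():
            record.volume[lesion] = config.hu_lesion
            hit = np.where(lesion.any(axis=(1, 2)))[0]
            record.slice_labels[hit] = 1
            record.exam_label = 1
            record.subtype = subtype
            return record
    raise RuntimeError(f"no in-mask placement found after {max_retries} retries")


def inject_vessel(
    record: VolumeRecord, rng: np.random.Generator, config: PhantomConfig
) -> VolumeRecord:
    """Write one benign vessel (hyperdense z-axis tube, unlabeled) through
    the lung.

    Vessels appear in positive and negative exams alike and run continuously
    along z, the way contrast-filled vessels thread through real lungs;
    lesions by contrast are compact spheres that appear and vanish within a
    few slices. Telling the two apart requires exactly the local slice
    context the model is given — which is what makes exam-level labels
    ambiguous on their own.
    """
    from scipy.ndimage import distance_transform_edt

    radius = config.vessel_radius
    # pick an in-plane position with interior clearance on the mid slice
    mid = record.mask.shape[0] // 2
    dist2d = distance_transform_edt(record.mask[mid])
    coords = np.argwhere(dist2d >= radius)
    if len(coords) == 0:
        coords = np.argwhere(record.mask[mid] > 0)
    cy, cx = coords[rng.integers(len(coords))]
    h, w = record.volume.shape[1:]
    y, x = np.ogrid[:h, :w]
    disk = (y - cy) ** 2 + (x - cx) ** 2 <= radius**2
    tube = disk[None, :, :] & (record.mask > 0)
    record.volume[tube] = config.hu_vessel
    return record


def generate_cohort(config: PhantomConfig) -> list[VolumeRecord]:
    """Generate a deterministic phantom cohort.

    Exactly round(n_exams x prevalence) exams are positive; of those, the
    first round(n_pos x central_fraction) by assignment order carry central
    lesions and the rest peripheral. Each exam draws from its own RNG
    substream keyed by (seed, exam index), so a record is reproducible
    independently of cohort size.
    """
    n = config.n_exams
    n_pos = round_half_up(n * config.prevalence)
    n_central = round_half_up(n_pos * config.central_fraction)
    assign_rng = np.random.default_rng([config.seed, n])
    order = assign_rng.permutation(n)
    subtype_of = {}
    for rank, idx in enumerate(order):
        if rank < n_central:
            subtype_of[idx] = "central"
        elif rank < n_pos:
            subtype_of[idx] = "peripheral"
        else:
            subtype_of[idx] = "negative"

    mask = lung_mask(config.volume_shape)
    depth = config.volume_shape[0]
    records = []
    for i in range(n):
        rng = np.random.default_rng([config.seed, i])
        volume = np.full(config.volume_shape, config.hu_background, dtype=np.float32)
        volume[mask > 0] = config.hu_lung
        record = VolumeRecord(
            exam_id=f"exam_{i:04d}",
            volume=volume,
            mask=mask.copy(),
            slice_labels=np.zeros(depth, dtype=np.int8),
            exam_label=0,
        )
        v_lo, v_hi = config.vessels_per_exam
        n_vessels = int(rng.integers(v_lo, v_hi + 1)) if v_hi > 0 else 0
        for _ in range(n_vessels):
            inject_vessel(record, rng, config)
        subtype = subtype_of[i]
        if subtype != "negative":
            lo, hi = config.lesions_per_exam
            for _ in range(int(rng.integers(lo, hi + 1))):
                inject_lesion(record, subtype, rng, config)
        record.volume += rng.normal(0.0, config.noise_sd, size=config.volume_shape)
        record.validate()
        records.append(record)
    return records


def shifted_config(config: PhantomConfig, seed_offset: int = 1000) -> PhantomConfig:
    """A domain-shifted variant used as an external-validation cohort:
    different noise level and lesion contrast, same label structure."""
    return replace(
        config,
        noise_sd=config.noise_sd * 1.5,
        hu_lesion=config.hu_lesion - 20.0,
        seed=config.seed + seed_offset,
    )


# --------------------------------------------------------------------- I/O

_AFFINE = np.eye(4)


def write_cohort(records: list[VolumeRecord], directory: str | Path) -> dict:
    """Write one NIfTI volume + mask per exam, a label CSV, and a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    manifest = {"exams": []}
    for rec in records:
        rec.validate()
        vol_name = f"{rec.exam_id}_volume.nii.gz"
        mask_name = f"{rec.exam_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(rec.volume.astype(np.float32), _AFFINE), directory / vol_name)
        nib.save(nib.Nifti1Image(rec.mask.astype(np.uint8), _AFFINE), directory / mask_name)
        for idx, lab in enumerate(rec.slice_labels):
            rows.append(
                {
                    "exam_id": rec.exam_id,
                    "slice_index": idx,
                    "slice_label": int(lab),
                    "exam_label": int(rec.exam_label),
                    "subtype": rec.subtype,
                }
            )
        manifest["exams"].append(
            {
                "exam_id": rec.exam_id,
                "volume": vol_name,
                "mask": mask_name,
                "depth": int(rec.volume.shape[0]),
            }
        )
    pd.DataFrame(rows).to_csv(directory / "labels.csv", index=False)
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_cohort(directory: str | Path) -> list[VolumeRecord]:
    """Read a cohort written by `write_cohort`.

    Structural problems (missing files, volume/mask shape mismatch, CSV slice
    count differing from volume depth) raise; label *consistency* is the
    business of `supervision.validate_labels`, which flags offending exams.
    """
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    labels = pd.read_csv(directory / "labels.csv")
    records = []
    for entry in manifest["exams"]:
        vol_path = directory / entry["volume"]
        mask_path = directory / entry["mask"]
        if not vol_path.exists() or not mask_path.exists():
            raise FileNotFoundError(f"missing files for {entry['exam_id']}")
        volume = np.asarray(nib.load(vol_path).dataobj, dtype=np.float32)
        mask = np.asarray(nib.load(mask_path).dataobj, dtype=np.uint8)
        if volume.shape != mask.shape:
            raise ValueError(f"{entry['exam_id']}: volume/mask shape mismatch")
        sub = labels[labels.exam_id == entry["exam_id"]].sort_values("slice_index")
        if len(sub) != volume.shape[0]:
            raise ValueError(
                f"{entry['exam_id']}: CSV slice count {len(sub)} != depth {volume.shape[0]}"
            )
        records.append(
            VolumeRecord(
                exam_id=entry["exam_id"],
                volume=volume,
                mask=mask,
                slice_labels=sub.slice_label.to_numpy().astype(np.int8),
                exam_label=int(sub.exam_label.iloc[0]),
                subtype=str(sub.subtype.iloc[0]),
            )
        )
    return records
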