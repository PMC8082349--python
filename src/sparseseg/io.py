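"""Subjects, masks, NIfTI round-tripping and cohort manifests.

A *subject* is one patient's co-registered stack of up to four MRI channels
on a common voxel grid.  The post-contrast T1-weighted channel (T1c) is the
primary channel and is always present; the secondary channels (T1w, T2w,
FLAIR) may be absent, in which case they are materialized as zero-filled
volumes of the common shape and flagged unavailable.  Volumes are used on
their on-disk voxel lattice; no reorientation or resampling is performed —
inputs are assumed pre-registered.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

CHANNEL_NAMES: tuple[str, ...] = ("T1c", "T1w", "T2w", "FLAIR")
PRIMARY_CHANNEL = "T1c"
SECONDARY_CHANNELS: tuple[str, ...] = ("T1w", "T2w", "FLAIR")

#: relative tolerance when comparing voxel spacings across files of one subject
SPACING_RTOL = 1e-4


@dataclasses.dataclass
class SegmentationMask:
    """Binary 3D label volume (1 = tumor core) with its voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        vals = np.unique(self.voxels)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be binary, got {vals[:10]}")
        self.voxels = self.voxels.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * float(np.prod(self.spacing))


@dataclasses.dataclass
class Subject:
    """One patient's channel stack plus availability flags and masks.

    channels
        ``(4, D, H, W)`` float array in the fixed order (T1c, T1w, T2w, FLAIR).
    available
        boolean flags per channel; an unavailable channel is identically zero.
    brain_mask
        binary support of the head/brain (the whitening domain).
    mask
        optional binary tumor-core ground truth, a subset of ``brain_mask``.
    """

    subject_id: str
    channels: np.ndarray
    available: np.ndarray
    spacing: tuple[float, float, float]
    brain_mask: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float32)
        self.available = np.asarray(self.available, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.brain_mask = np.asarray(self.brain_mask, dtype=np.uint8)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=np.uint8)
        self.validate()

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.channels.shape[1:])

    def validate(self) -> None:
        if self.channels.ndim != 4 or self.channels.shape[0] != len(CHANNEL_NAMES):
            raise ValueError(f"channels must be (4, D, H, W), got {self.channels.shape}")
        if self.available.shape != (len(CHANNEL_NAMES),):
            raise ValueError("available must have one flag per channel")
        if not self.available[0]:
            raise ValueError("primary channel (T1c) must be available")
        if self.brain_mask.shape != self.shape:
            raise ValueError("brain_mask shape mismatch")
        for i, ok in enumerate(self.available):
            if not ok and np.abs(self.channels[i]).max() > 0:
                raise ValueError(
                    f"channel {CHANNEL_NAMES[i]} flagged unavailable but non-zero")
        if self.mask is not None:
            if self.mask.shape != self.shape:
                raise ValueError("mask shape mismatch")
            if np.any(self.mask > self.brain_mask):
                raise ValueError("tumor mask must be contained in brain_mask")

    def copy(self) -> "Subject":
        return Subject(
            subject_id=self.subject_id,
            channels=self.channels.copy(),
            available=self.available.copy(),
            spacing=self.spacing,
            brain_mask=self.brain_mask.copy(),
            mask=None if self.mask is None else self.mask.copy(),
        )


def _load_volume(path: Path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, img.affine


def read_subject(channel_paths: dict, mask_path=None, subject_id: str = "") -> Subject:
    """Assemble a Subject from per-channel NIfTI paths.

    ``channel_paths`` maps channel names to paths; missing or ``None`` entries
    for secondary channels yield zero-filled volumes flagged unavailable.  The
    primary channel must be present.  All provided files must share the grid
    shape exactly and the spacing to within ``SPACING_RTOL``.
    """
    paths = {c: channel_paths.get(c) for c in CHANNEL_NAMES}
    if not paths[PRIMARY_CHANNEL]:
        raise FileNotFoundError("primary channel (T1c) is required but missing")

    primary, spacing, _ = _load_volume(Path(paths[PRIMARY_CHANNEL]))
    shape = primary.shape
    channels = np.zeros((len(CHANNEL_NAMES),) + shape, dtype=np.float32)
    available = np.zeros(len(CHANNEL_NAMES), dtype=bool)
    channels[0] = primary
    available[0] = True

    problems = []
    for i, name in enumerate(CHANNEL_NAMES[1:], start=1):
        p = paths[name]
        if not p:
            continue
        data, sp, _ = _load_volume(Path(p))
        if data.shape != shape:
            problems.append(f"{p}: shape {data.shape} != primary {shape}")
            continue
        if not np.allclose(sp, spacing, rtol=SPACING_RTOL, atol=0):
            problems.append(f"{p}: spacing {sp} != primary {spacing}")
            continue
        channels[i] = data
        available[i] = True
    if problems:
        raise ValueError("grid mismatch:\n" + "\n".join(problems))

    mask = None
    brain = None
    if mask_path:
        mdata, msp, _ = _load_volume(Path(mask_path))
        if mdata.shape != shape:
            raise ValueError(f"{mask_path}: mask shape {mdata.shape} != {shape}")
        if not np.allclose(msp, spacing, rtol=SPACING_RTOL, atol=0):
            raise ValueError(f"{mask_path}: mask spacing {msp} != {spacing}")
        mask = (mdata > 0).astype(np.uint8)
    # brain support: union of non-zero voxels over available channels
    brain = (np.abs(channels[available]).max(axis=0) > 0).astype(np.uint8)
    if mask is not None:
        brain = np.maximum(brain, mask)
    return Subject(subject_id=subject_id, channels=channels, available=available,
                   spacing=spacing, brain_mask=brain, mask=mask)


def write_mask(mask: SegmentationMask, path) -> None:
    """Write a binary mask as uint8 NIfTI; round-trips bit-identically."""
    affine = np.diag(list(mask.spacing) + [1.0])
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_mask(path) -> SegmentationMask:
    data, spacing, _ = _load_volume(Path(path))
    return SegmentationMask(voxels=(data > 0).astype(np.uint8), spacing=spacing)


def write_volume(volume: np.ndarray, spacing, path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


MANIFEST_COLUMNS = ["subject_id", "split"] + [f"path_{c}" for c in CHANNEL_NAMES] + ["path_mask"]


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def load_split(manifest: pd.DataFrame, split: str, root=None) -> list[Subject]:
    """Read every subject of a manifest split, resolving paths against root."""
    root = Path(root) if root is not None else Path(".")

    def resolve(cell: str):
        return None if cell == "" else str(root / cell)

    subjects = []
    for _, row in manifest[manifest["split"] == split].iterrows():
        channel_paths = {c: resolve(row[f"path_{c}"]) for c in CHANNEL_NAMES}
        subjects.append(read_subject(channel_paths, mask_path=resolve(row["path_mask"]),
                                     subject_id=row["subject_id"]))
    return subjects
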