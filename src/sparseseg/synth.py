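"""Seeded multi-channel 3D phantom cohorts with missing-sequence patterns.

Each phantom subject is an ellipsoidal "brain" of mid-gray tissue containing
a randomly placed, randomly deformed tumor core made of an enhancing rim
around a necrotic center.  The four channels render the same latent geometry
with different contrasts, mimicking the partial redundancy of clinical MRI:

==========  ==============================================================
channel     appearance (arbitrary units, tissue baseline 100)
==========  ==============================================================
T1c         bright enhancing rim (160), dark necrotic core (60)
T1w         whole core dark (70)
T2w         whole core bright (150)
FLAIR       whole core bright (170) plus a bright halo around it (140)
==========  ==============================================================

Because every channel's tumor signal is a deterministic function of the same
latent core, a network can in principle recover the core from any channel
subset that includes T1c — the property that makes missing-sequence
robustness learnable at all.  A smooth multiplicative bias field and
additive Gaussian noise are applied per channel; background outside the
brain stays exactly zero, as in skull-stripped MRI.  Missingness is drawn
per subject: with probability ``missing_fraction`` one non-empty subset of
secondary channels (weighted toward T2w-only, then T2w+FLAIR, echoing the
frequencies reported for multi-hospital glioblastoma cohorts) is zero-filled
and flagged unavailable.

All randomness flows from ``(config.seed, subject_seed)`` so cohorts are
reproducible file-by-file.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import (CHANNEL_NAMES, SECONDARY_CHANNELS, Subject, write_manifest,
                 write_volume, write_mask, SegmentationMask)

#: default distribution over non-empty missing secondary-channel subsets
DEFAULT_MISSING_WEIGHTS: dict[tuple[str, ...], float] = {
    ("T2w",): 0.50,
    ("T2w", "FLAIR"): 0.25,
    ("FLAIR",): 0.10,
    ("T1w",): 0.10,
    ("T1w", "T2w"): 0.03,
    ("T1w", "FLAIR"): 0.01,
    ("T1w", "T2w", "FLAIR"): 0.01,
}

# appearance model: tissue baseline and per-channel region intensities
TISSUE = 100.0
# FLAIR carries the strongest whole-core contrast by design; T1w/T2w are
# weakly informative and T1c encodes the core through its rim + dark center,
# so the core is recoverable without FLAIR but only by pooling harder cues.
INTENSITY = {
    "T1c": {"tissue": TISSUE, "rim": 160.0, "necrosis": 60.0},
    "T1w": {"tissue": TISSUE, "core": 80.0},
    "T2w": {"tissue": TISSUE, "core": 125.0},
    "FLAIR": {"tissue": TISSUE, "core": 170.0, "halo": 140.0},
}
#: reference tumor-tissue contrast (T1c rim vs tissue) used to scale noise
CONTRAST = 60.0


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sd: float = 0.5           # additive noise, fraction of CONTRAST
    bias_amplitude: float = 0.2     # multiplicative bias field, +/- fraction
    tumor_radius_range: tuple[float, float] = (5.0, 9.0)  # mm
    deform_amplitude: float = 0.15  # radial deformation, fraction of radius
    rim_thickness: float = 2.0      # mm
    halo_thickness: float = 2.0     # mm
    missing_fraction: float = 0.5
    missing_pattern_weights: Optional[dict] = None
    seed: int = 0

    def __post_init__(self):
        if min(self.shape) < 16:
            raise ValueError("shape must be >= 16 per axis")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing_fraction must be in [0, 1]")
        w = self.weights()
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError("missing_pattern_weights must sum to 1")

    def weights(self) -> dict[tuple[str, ...], float]:
        if self.missing_pattern_weights is None:
            return dict(DEFAULT_MISSING_WEIGHTS)
        return {tuple(k.split("+")) if isinstance(k, str) else tuple(k): v
                for k, v in self.missing_pattern_weights.items()}


def _smooth_field(rng: np.random.Generator, shape, sigma_frac: float = 0.25):
    """Smooth zero-mean random field normalized to peak amplitude 1."""
    field = rng.standard_normal(shape)
    field = ndimage.gaussian_filter(field, sigma=[s * sigma_frac for s in shape])
    peak = np.abs(field).max()
    return field / peak if peak > 0 else field


def _coords_mm(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def generate_subject(config: PhantomConfig, subject_seed: int,
                     subject_id: Optional[str] = None,
                     force_complete: bool = False,
                     max_attempts: int = 50) -> Subject:
    """Generate one phantom subject; deterministic in ``(config, subject_seed)``."""
    rng = np.random.default_rng([config.seed, subject_seed])
    shape, spacing = config.shape, config.spacing
    zz, yy, xx = _coords_mm(shape, spacing)
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    center_brain = extent / 2.0
    semi = extent * 0.42
    brain = (((zz - center_brain[0]) / semi[0]) ** 2
             + ((yy - center_brain[1]) / semi[1]) ** 2
             + ((xx - center_brain[2]) / semi[2]) ** 2) <= 1.0

    # place a deformed spherical core fully inside the brain
    core = rim = necrosis = halo = None
    for _ in range(max_attempts):
        r = rng.uniform(*config.tumor_radius_range)
        lo = r + config.halo_thickness + 1.0
        if np.any(lo >= semi):
            continue  # tumor too large for this brain at this radius draw
        c = np.array([rng.uniform(cb - sa + lo, cb + sa - lo)
                      for cb, sa in zip(center_brain, semi)])
        deform = _smooth_field(rng, shape, sigma_frac=0.15) * config.deform_amplitude
        dist = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
        core_cand = dist <= r * (1.0 + deform)
        halo_cand = dist <= (r * (1.0 + deform) + config.halo_thickness)
        if core_cand.sum() < 8 or np.any(halo_cand & ~brain):
            continue
        # keep the component containing the center; reject fragmented draws
        lbl, n_comp = ndimage.label(core_cand)
        ci = tuple(np.round(c / np.array(spacing)).astype(int))
        if lbl[ci] == 0:
            continue
        core_cand = lbl == lbl[ci]
        necro_cand = dist <= (r * (1.0 + deform) - config.rim_thickness)
        necro_cand &= core_cand
        core, necrosis, halo = core_cand, necro_cand, halo_cand
        rim = core & ~necrosis
        break
    if core is None:
        raise RuntimeError(
            f"could not place tumor inside brain after {max_attempts} attempts "
            f"(radius range {config.tumor_radius_range} mm, brain semi-axes {semi} mm)")

    channels = np.zeros((len(CHANNEL_NAMES),) + tuple(shape), dtype=np.float32)
    for i, name in enumerate(CHANNEL_NAMES):
        vol = np.where(brain, INTENSITY[name]["tissue"], 0.0)
        if name == "T1c":
            vol = np.where(rim, INTENSITY[name]["rim"], vol)
            vol = np.where(necrosis, INTENSITY[name]["necrosis"], vol)
        elif name == "FLAIR":
            vol = np.where(halo & brain & ~core, INTENSITY[name]["halo"], vol)
            vol = np.where(core, INTENSITY[name]["core"], vol)
        else:
            vol = np.where(core, INTENSITY[name]["core"], vol)
        bias = 1.0 + config.bias_amplitude * _smooth_field(rng, shape)
        vol = vol * bias
        if config.noise_sd > 0:
            vol = vol + rng.standard_normal(shape) * config.noise_sd * CONTRAST
        channels[i] = np.where(brain, vol, 0.0)

    available = np.ones(len(CHANNEL_NAMES), dtype=bool)
    if not force_complete and rng.random() < config.missing_fraction:
        weights = config.weights()
        patterns = list(weights.keys())
        probs = np.array([weights[p] for p in patterns])
        chosen = patterns[rng.choice(len(patterns), p=probs / probs.sum())]
        for name in chosen:
            idx = CHANNEL_NAMES.index(name)
            channels[idx] = 0.0
            available[idx] = False

    return Subject(
        subject_id=subject_id or f"phantom-{subject_seed:05d}",
        channels=channels,
        available=available,
        spacing=spacing,
        brain_mask=brain.astype(np.uint8),
        mask=core.astype(np.uint8),
    )


def generate_cohort_subjects(config: PhantomConfig, n: int, start_seed: int = 0,
                             force_complete: bool = False,
                             id_prefix: str = "phantom") -> list[Subject]:
    """Generate ``n`` in-memory subjects with consecutive derived seeds."""
    return [generate_subject(config, start_seed + i,
                             subject_id=f"{id_prefix}-{start_seed + i:05d}",
                             force_complete=force_complete)
            for i in range(n)]


def generate_cohort(config: PhantomConfig, n_train: int, n_val: int, n_test: int,
                    out_dir, complete_test: bool = True) -> pd.DataFrame:
    """Write a phantom cohort (NIfTI files + manifest CSV) to ``out_dir``.

    Splits are disjoint by construction (consecutive subject seeds).  With
    ``complete_test`` every test subject has all four channels, mirroring an
    evaluation set on which every missing pattern can be simulated.
    """
    for n in (n_train, n_val, n_test):
        if n < 1:
            raise ValueError("each split needs at least one subject")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    seed = 0
    for split, n, force in (("train", n_train, False), ("val", n_val, False),
                            ("test", n_test, complete_test)):
        for s in generate_cohort_subjects(config, n, start_seed=seed,
                                          force_complete=force):
            row = {"subject_id": s.subject_id, "split": split}
            for i, name in enumerate(CHANNEL_NAMES):
                if s.available[i]:
                    rel = f"{s.subject_id}_{name}.nii.gz"
                    write_volume(s.channels[i], s.spacing, out_dir / rel)
                    row[f"path_{name}"] = rel
                else:
                    row[f"path_{name}"] = ""
            rel = f"{s.subject_id}_mask.nii.gz"
            write_mask(SegmentationMask(s.mask, s.spacing), out_dir / rel)
            row["path_mask"] = rel
            rows.append(row)
        seed += n
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
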