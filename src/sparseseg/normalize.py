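"""Histogram normalization and whitening that leave missing channels alone.

Intensity standardization follows the percentile-landmark scheme of Nyúl and
Udupa: per channel, landmark percentiles {1, 10, 20, ..., 90, 99} of the
foreground (brain-mask) intensities are pooled over the training subjects to
define a standard scale; at normalization time a subject's own landmarks are
mapped piecewise-linearly onto that scale, after which the channel is
whitened to zero mean and unit variance over the brain mask.

The one adjustment that matters for missing-sequence robustness: a channel
flagged unavailable (an all-zero volume standing in for a missing scan)
passes through both steps bit-exactly unchanged.  Because available channels
are whitened to mean zero over the brain, an all-zero missing channel enters
the network at the mean intensity of the available data.  Missing-channel
detection uses the ``available`` flag only — never intensity heuristics — so
a legitimately dark but present channel is never misclassified.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import CHANNEL_NAMES, Subject

#: percentile grid for the landmark mapping
LANDMARK_PERCENTILES = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0,
                        60.0, 70.0, 80.0, 90.0, 99.0)


@dataclasses.dataclass
class HistogramModel:
    """Per-channel landmark intensities on the pooled training scale."""

    landmarks: dict[str, np.ndarray]
    percentiles: tuple[float, ...] = LANDMARK_PERCENTILES

    def __post_init__(self):
        for name, lm in self.landmarks.items():
            lm = np.asarray(lm, dtype=float)
            if lm.shape != (len(self.percentiles),):
                raise ValueError(f"{name}: {lm.shape} landmarks for "
                                 f"{len(self.percentiles)} percentiles")
            if not np.all(np.diff(lm) > 0):
                raise ValueError(
                    f"landmarks for channel {name} are not strictly increasing "
                    f"(degenerate intensity distribution): {lm}")
            self.landmarks[name] = lm

    def to_json(self, path) -> None:
        payload = {"percentiles": list(self.percentiles),
                   "landmarks": {k: v.tolist() for k, v in self.landmarks.items()}}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "HistogramModel":
        payload = json.loads(Path(path).read_text())
        return cls(landmarks={k: np.asarray(v) for k, v in payload["landmarks"].items()},
                   percentiles=tuple(payload["percentiles"]))


def fit_histogram_model(subjects: Sequence[Subject],
                        percentiles=LANDMARK_PERCENTILES) -> HistogramModel:
    """Fit landmark percentiles from pooled foreground intensities.

    Only channels with ``available=True`` contribute; each channel must be
    available in at least one subject.  Pooling is over the concatenated
    brain-mask voxels of all contributing subjects, so the result does not
    depend on subject order.
    """
    if not subjects:
        raise ValueError("need at least one subject")
    landmarks = {}
    for i, name in enumerate(CHANNEL_NAMES):
        pools = [s.channels[i][s.brain_mask > 0]
                 for s in subjects if s.available[i]]
        if not pools:
            raise ValueError(f"channel {name} is available in zero subjects")
        pooled = np.concatenate(pools)
        # empirical-CDF quantile: invariant under duplicating the pool
        landmarks[name] = np.percentile(pooled, percentiles, method="inverted_cdf")
    return HistogramModel(landmarks=landmarks, percentiles=tuple(percentiles))


def _map_landmarks(vol: np.ndarray, fg: np.ndarray, target: np.ndarray,
                   percentiles) -> np.ndarray:
    src = np.percentile(vol[fg], percentiles)
    if not np.all(np.diff(src) > 0):
        raise ValueError("degenerate channel: landmark percentiles are not "
                         f"strictly increasing ({src})")
    # piecewise-linear, extrapolating the end segments linearly
    out = np.interp(vol, src, target)
    below = vol < src[0]
    above = vol > src[-1]
    slope_lo = (target[1] - target[0]) / (src[1] - src[0])
    slope_hi = (target[-1] - target[-2]) / (src[-1] - src[-2])
    out[below] = target[0] + (vol[below] - src[0]) * slope_lo
    out[above] = target[-1] + (vol[above] - src[-1]) * slope_hi
    return out


def normalize_subject(subject: Subject, model: HistogramModel) -> Subject:
    """Landmark-map then whiten available channels; missing channels pass through.

    Whitening statistics are computed over the brain mask so background air
    does not dominate.  Unavailable channels are returned exactly all-zero.
    """
    if set(model.landmarks) != set(CHANNEL_NAMES):
        raise ValueError(f"model channels {sorted(model.landmarks)} do not match "
                         f"subject channels {sorted(CHANNEL_NAMES)}")
    out = subject.copy()
    fg = subject.brain_mask > 0
    for i, name in enumerate(CHANNEL_NAMES):
        if not subject.available[i]:
            continue  # zero-filled missing channel: unaffected, bit-exact
        mapped = _map_landmarks(subject.channels[i].astype(np.float64), fg,
                                model.landmarks[name], model.percentiles)
        mu = mapped[fg].mean()
        sd = mapped[fg].std()
        if sd == 0:
            raise ValueError(f"channel {name}: zero variance over brain mask")
        out.channels[i] = ((mapped - mu) / sd).astype(np.float32)
    return out


def normalize_cohort(subjects: Sequence[Subject],
                     model: HistogramModel) -> list[Subject]:
    return [normalize_subject(s, model) for s in subjects]
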