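"""Synthetic stimulus images with controlled RMS contrast and luminance.

The experimental images were photographs whose contrast and luminance were
adjusted to fixed RMS values per factor level (contrast 34% vs 50%,
luminance 34% vs 51%). Here each condition gets a smooth random texture
adjusted to the same targets, so that image-computable feature models
(GIST, HMAX) see the same low-level statistics structure as the design
prescribes.

Definitions used throughout the package (the source experiment does not
publish its formulas, so these are package conventions):

* RMS luminance: ``sqrt(mean(I**2))`` of intensities in [0, 1], in percent
  of full scale.
* RMS contrast: ``std(I) / mean(I)`` in percent — the relative (Michelson-
  family) RMS contrast. Expressing contrast relative to the mean keeps all
  four contrast x luminance cells simultaneously realizable within [0, 1];
  an absolute-scale SD of 50% together with an RMS luminance of 51% would
  force a binary image with mean 0.10, which no in-range image can attain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import Design

#: Per-level targets in percent, keyed by (factor, level).
CONTRAST_TARGETS = {"low": 34.0, "high": 50.0}
LUMINANCE_TARGETS = {"low": 34.0, "high": 51.0}

#: Tolerance (percentage points) within which achieved statistics must land.
RMS_TOLERANCE_PP = 0.5


def rms_luminance(image: np.ndarray) -> float:
    """Root-mean-square luminance in percent of full scale."""
    return 100.0 * float(np.sqrt(np.mean(np.square(image))))


def rms_contrast(image: np.ndarray) -> float:
    """Relative RMS contrast, std/mean, in percent."""
    mean = float(np.mean(image))
    if mean == 0:
        raise ValueError("RMS contrast undefined for an all-zero image")
    return 100.0 * float(np.std(image)) / mean


@dataclass
class ImageSet:
    """Per-condition grayscale stimulus images with achieved RMS statistics."""

    images: np.ndarray  # conditions x side x side, intensities in [0, 1]
    condition_ids: np.ndarray
    stats: pd.DataFrame  # condition_id, target/achieved contrast & luminance

    @property
    def side(self) -> int:
        return self.images.shape[1]

    def image_for(self, condition_id: int) -> np.ndarray:
        idx = int(np.flatnonzero(self.condition_ids == condition_id)[0])
        return self.images[idx]

    def stats_to_csv(self, path) -> None:
        self.stats.to_csv(path, index=False)


def _target_moments(contrast_pct: float, luminance_pct: float) -> tuple[float, float]:
    """Mean and SD (fractions of full scale) matching both RMS targets.

    rms^2 = mu^2 + sigma^2 and sigma = c * mu give mu = rms / sqrt(1 + c^2).
    """
    c = contrast_pct / 100.0
    rms = luminance_pct / 100.0
    mu = rms / np.sqrt(1.0 + c * c)
    return mu, c * mu


def _texture(rng: np.random.Generator, side: int, smooth_px: float = 4.0) -> np.ndarray:
    """Smooth standardized random texture, soft-clipped to suppress tails."""
    raw = ndimage.gaussian_filter(rng.standard_normal((side, side)), smooth_px)
    raw = (raw - raw.mean()) / raw.std()
    squashed = np.tanh(raw / 2.0)  # bounded in (-1, 1)
    return (squashed - squashed.mean()) / squashed.std()


def _adjust(texture: np.ndarray, mu: float, sigma: float, max_iter: int = 50) -> np.ndarray:
    """Affinely map texture to mean mu / SD sigma, re-projecting after clipping."""
    x = texture
    image = mu + sigma * x
    for _ in range(max_iter):
        clipped = np.clip(image, 0.0, 1.0)
        if np.allclose(clipped, image):
            return clipped
        x = (clipped - clipped.mean()) / clipped.std()
        image = mu + sigma * x
    return np.clip(image, 0.0, 1.0)


def generate_images(design: Design, side: int = 128, seed: int = 0) -> ImageSet:
    """Generate one textured image per condition, adjusted to its RMS targets.

    Determinism: the same ``seed`` yields bit-identical pixels. If clipping
    to [0, 1] prevents reaching a target within 0.5 percentage points, a
    warning reports the achieved value; the image is still returned.
    """
    if side < 32:
        raise ValueError(f"side must be >= 32, got {side}")
    rng = np.random.default_rng(seed)
    images = np.empty((design.n_conditions, side, side))
    rows = []
    for idx, row in design.table.iterrows():
        c_target = CONTRAST_TARGETS[row["contrast"]]
        l_target = LUMINANCE_TARGETS[row["luminance"]]
        mu, sigma = _target_moments(c_target, l_target)
        image = _adjust(_texture(rng, side), mu, sigma)
        images[idx] = image
        c_ach, l_ach = rms_contrast(image), rms_luminance(image)
        if abs(c_ach - c_target) > RMS_TOLERANCE_PP or abs(l_ach - l_target) > RMS_TOLERANCE_PP:
            warnings.warn(
                f"condition {row['condition_id']}: achieved RMS contrast "
                f"{c_ach:.2f}% / luminance {l_ach:.2f}% "
                f"(targets {c_target:.0f}% / {l_target:.0f}%) after clipping"
            )
        rows.append(
            {
                "condition_id": row["condition_id"],
                "target_contrast": c_target,
                "achieved_contrast": c_ach,
                "target_luminance": l_target,
                "achieved_luminance": l_ach,
            }
        )
    return ImageSet(
        images=images,
        condition_ids=design.condition_ids.to_numpy(),
        stats=pd.DataFrame(rows),
    )
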