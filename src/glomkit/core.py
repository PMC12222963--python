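"""Shared domain types and coordinate conventions.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``; windows are half-open
  ``[lo, hi)`` rectangles;
* every raster carries an ``mpp`` (microns per pixel) so geometry can be
  reported in physical units;
* a multi-class mask is stored as a single integer label grid where 0 is
  background and ``1..5`` index the five glomerular lesion classes.  The
  5-channel binary representation exists only at the model boundary and is
  produced by :func:`mask_to_channels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from PIL import Image


class LesionClass(Enum):
    """The five glomerular lesion categories.

    Background is deliberately *not* a member: it is the absence of any
    class label (0 in a label grid).
    """

    NL = 0
    GS = 1
    SS = 2
    CR = 3
    ISC = 4

    @property
    def index(self) -> int:
        return self.value

    @property
    def label(self) -> int:
        """Value used for this class in a label grid (index + 1)."""
        return self.value + 1

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]

    @classmethod
    def from_label(cls, label: int) -> "LesionClass":
        if not 1 <= label <= 5:
            raise ValueError(f"label {label} is not a lesion-class label (1..5)")
        return cls(label - 1)


_DISPLAY_NAMES = {
    LesionClass.NL: "no lesion",
    LesionClass.GS: "global sclerosis",
    LesionClass.SS: "segmental sclerosis",
    LesionClass.CR: "crescent",
    LesionClass.ISC: "ischemic change",
}

N_CLASSES = 5
CLASS_CODES = [c.name for c in LesionClass]

#: Working resolution every slide is resampled to before tiling (um/px).
#: "10x" on a 0.25 um/px scanner is a 4x downsample; 0.21 um/px scans land
#: at the same physical resolution so features are scanner-independent.
WORKING_MPP = 1.0


@dataclass
class SlideRaster:
    """An RGB biopsy raster with micron-per-pixel metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    mpp: float
    slide_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("raster must have positive dimensions")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class MultiClassMask:
    """Hard labels on a raster grid: 0 = background, 1..5 = lesion class."""

    labels: np.ndarray  # (H, W) integer
    mpp: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > N_CLASSES):
            raise ValueError("mask labels must lie in {0..5}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def support(self) -> np.ndarray:
        """Boolean union of all class channels (non-background pixels)."""
        return self.labels > 0


@dataclass
class ProbabilityMap:
    """Per-pixel per-class probabilities; channels are independent
    (no normalisation across channels is assumed)."""

    probs: np.ndarray  # (H, W, 5) float
    mpp: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 3 or self.probs.shape[2] != N_CLASSES:
            raise ValueError("probs must be (H, W, 5)")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")
        if self.probs.size and (self.probs.min() < -1e-6 or self.probs.max() > 1 + 1e-6):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape[:2]


@dataclass
class GlomerulusInstance:
    """One separated glomerulus on a slide.

    ``pixels`` is an (N, 2) array of (row, col) coordinates; pixel sets of
    distinct instances on one slide are disjoint.
    """

    instance_id: int
    lesion: LesionClass
    pixels: np.ndarray
    confidence: float = 1.0
    bounding_box: tuple[int, int, int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2 or len(self.pixels) == 0:
            raise ValueError("pixels must be a non-empty (N, 2) array")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        if self.bounding_box is None:
            r, c = self.pixels[:, 0], self.pixels[:, 1]
            self.bounding_box = (int(r.min()), int(c.min()), int(r.max()) + 1, int(c.max()) + 1)

    @property
    def area_px(self) -> int:
        return len(self.pixels)

    def flat_indices(self, width: int) -> np.ndarray:
        """Raveled pixel indices on a grid of the given width (for fast
        intersection tests)."""
        return self.pixels[:, 0].astype(np.int64) * width + self.pixels[:, 1]


def mask_to_channels(mask: MultiClassMask) -> np.ndarray:
    """Expand a label grid to the 5-channel binary form.

    Channel ``c`` is 1 exactly where ``labels == c + 1``; channels are
    pairwise disjoint by construction and their union is the
    non-background support.
    """
    out = np.zeros((N_CLASSES,) + mask.shape, dtype=bool)
    for cls in LesionClass:
        out[cls.index] = mask.labels == cls.label
    return out


def channels_to_mask(channels: np.ndarray, mpp: float) -> MultiClassMask:
    """Collapse 5 binary channels back to a label grid.

    Raises if any pixel is set in more than one channel.
    """
    channels = np.asarray(channels).astype(bool)
    if channels.ndim != 3 or channels.shape[0] != N_CLASSES:
        raise ValueError("channels must be (5, H, W)")
    if (channels.sum(axis=0) > 1).any():
        raise ValueError("channels overlap: a pixel carries more than one class")
    labels = np.zeros(channels.shape[1:], dtype=np.uint8)
    for cls in LesionClass:
        labels[channels[cls.index]] = cls.label
    return MultiClassMask(labels, mpp)


def resample_to_working_resolution(slide: SlideRaster, target_mpp: float = WORKING_MPP) -> SlideRaster:
    """Area-average downscale a raster to a coarser resolution.

    Upsampling is refused (it would invent information).  Output
    dimensions are ``floor(dim * mpp / target_mpp)``; the result carries
    exactly ``target_mpp``.
    """
    if target_mpp < slide.mpp:
        raise ValueError(
            f"cannot upsample: slide at {slide.mpp} um/px, requested {target_mpp} um/px"
        )
    if target_mpp == slide.mpp:
        return slide
    scale = slide.mpp / target_mpp
    h = int(np.floor(slide.pixels.shape[0] * scale))
    w = int(np.floor(slide.pixels.shape[1] * scale))
    if h < 1 or w < 1:
        raise ValueError("target resolution collapses the raster to zero size")
    img = Image.fromarray(np.ascontiguousarray(slide.pixels.astype(np.uint8)))
    out = np.asarray(img.resize((w, h), resample=Image.Resampling.BOX))
    return SlideRaster(out, target_mpp, slide.slide_id)


def resample_mask(mask: MultiClassMask, target_mpp: float) -> MultiClassMask:
    """Nearest-label downscale of a label grid (annotation companion to
    :func:`resample_to_working_resolution`)."""
    if target_mpp < mask.mpp:
        raise ValueError("cannot upsample a mask")
    if target_mpp == mask.mpp:
        return mask
    scale = mask.mpp / target_mpp
    h = int(np.floor(mask.labels.shape[0] * scale))
    w = int(np.floor(mask.labels.shape[1] * scale))
    img = Image.fromarray(mask.labels.astype(np.uint8), mode="L")
    out = np.asarray(img.resize((w, h), resample=Image.Resampling.NEAREST))
    return MultiClassMask(out, target_mpp)
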