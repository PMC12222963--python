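"""Patch grid, patch sampling, test-time augmentation and stitching.

A slide is covered by 512x512 windows at 50% overlap (stride 256); the
final row/column window is clamped so its far edge coincides with the
slide edge, which may duplicate coverage but never pads with invented
tissue.  Patch predictions are stitched back by per-pixel arithmetic
mean over every window covering the pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import MultiClassMask, N_CLASSES, ProbabilityMap


@dataclass(frozen=True)
class TilingConfig:
    patch_size: int = 512
    overlap: float = 0.5
    working_mpp: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must lie in [0, 1)")
        stride = self.patch_size * (1.0 - self.overlap)
        if stride <= 0 or abs(stride - round(stride)) > 1e-9:
            raise ValueError("patch_size * (1 - overlap) must be a positive integer")

    @property
    def stride(self) -> int:
        return int(round(self.patch_size * (1.0 - self.overlap)))


@dataclass(frozen=True)
class PatchRef:
    """One half-open window [row0, row1) x [col0, col1) on a slide."""

    slide_id: str
    row0: int
    col0: int
    row1: int
    col1: int

    @property
    def origin(self) -> tuple[int, int]:
        return (self.row0, self.col0)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row1 - self.row0, self.col1 - self.col0)

    def crop(self, array: np.ndarray) -> np.ndarray:
        return array[self.row0 : self.row1, self.col0 : self.col1]


def _axis_origins(size: int, patch: int, stride: int) -> list[int]:
    if size <= patch:
        return [0]
    origins = list(range(0, size - patch + 1, stride))
    if origins[-1] + patch < size:
        origins.append(size - patch)
    return origins


def enumerate_patches(
    slide_shape: tuple[int, int], config: TilingConfig, slide_id: str = ""
) -> list[PatchRef]:
    """Row-major sliding-window grid covering the whole slide.

    Windows start at multiples of the stride; a final clamped position is
    appended per axis so the last window's far edge equals the slide
    edge.  Slides smaller than the patch yield a single clamped window.
    """
    h, w = slide_shape
    if h < 1 or w < 1:
        raise ValueError("slide dimensions must be >= 1")
    p, s = config.patch_size, config.stride
    return [
        PatchRef(slide_id, r, c, min(r + p, h), min(c + p, w))
        for r in _axis_origins(h, p, s)
        for c in _axis_origins(w, p, s)
    ]


def filter_glomerular_patches(patches: Sequence[PatchRef], mask: MultiClassMask) -> list[PatchRef]:
    """Discard patches whose window contains no glomerular pixel."""
    support = mask.support
    return [p for p in patches if p.crop(support).any()]


@dataclass
class SamplerConfig:
    """Combined under/over-sampling to counter lesion-class imbalance.

    Patches containing only no-lesion glomeruli are independently kept
    with ``undersample_keep_prob``; a patch containing any minority class
    is replicated by the max oversample factor over the classes present.
    """

    undersample_keep_prob: float = 0.5
    oversample_factors: dict = field(
        default_factory=lambda: {"GS": 2, "SS": 4, "CR": 8, "ISC": 8}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.undersample_keep_prob <= 1.0:
            raise ValueError("undersample_keep_prob must lie in (0, 1]")
        if any(v < 1 for v in self.oversample_factors.values()):
            raise ValueError("oversample factors must be >= 1")


_MINORITY_LABELS = {"GS": 2, "SS": 3, "CR": 4, "ISC": 5}


def balance_patches(
    patches: Sequence[PatchRef], mask: MultiClassMask, sampler: SamplerConfig
) -> list[PatchRef]:
    """Apply under/over-sampling; deterministic under the sampler seed.

    Oversampling only replicates and undersampling never touches a
    lesion-containing patch, so the set of distinct lesioned patches is
    preserved.
    """
    rng = np.random.default_rng(np.random.SeedSequence([sampler.seed, 0xBA]))
    out: list[PatchRef] = []
    for p in patches:
        window = p.crop(mask.labels)
        present = set(np.unique(window)) - {0}
        minority = [
            code for code, lab in _MINORITY_LABELS.items() if lab in present
        ]
        if minority:
            factor = max(sampler.oversample_factors.get(c, 1) for c in minority)
            out.extend([p] * int(factor))
        elif present:  # NL-only patch
            if rng.random() < sampler.undersample_keep_prob:
                out.append(p)
        else:  # no glomerular pixels at all: kept as-is (pre-filtering is upstream)
            out.append(p)
    return out


# ---------------------------------------------------------------------------
# test-time augmentation
# ---------------------------------------------------------------------------

# geometric variants: (name, forward, inverse), acting on (H, W, C) arrays
_GEOMETRIC = {
    "identity": (lambda a: a, lambda a: a),
    "hflip": (lambda a: a[:, ::-1], lambda a: a[:, ::-1]),
    "vflip": (lambda a: a[::-1, :], lambda a: a[::-1, :]),
    "rot90": (lambda a: np.rot90(a, 1), lambda a: np.rot90(a, -1)),
    "rot180": (lambda a: np.rot90(a, 2), lambda a: np.rot90(a, -2)),
    "rot270": (lambda a: np.rot90(a, 3), lambda a: np.rot90(a, -3)),
}

#: Default TTA set: the six geometric variants at native intensity plus
#: two intensity-multiplied identity variants (x0.9, x1.1) -- flip,
#: rotation and multiply families with mean fusion.
DEFAULT_TTA: tuple[tuple[str, float], ...] = (
    ("identity", 1.0),
    ("hflip", 1.0),
    ("vflip", 1.0),
    ("rot90", 1.0),
    ("rot180", 1.0),
    ("rot270", 1.0),
    ("identity", 0.9),
    ("identity", 1.1),
)


def tta_predict(
    patch_pixels: np.ndarray,
    predictor: Callable[[np.ndarray, PatchRef | None], np.ndarray],
    ref: PatchRef | None = None,
    tta_set: Sequence[tuple[str, float]] = DEFAULT_TTA,
) -> np.ndarray:
    """Mean-fused test-time augmentation for one patch.

    Each variant applies a geometric transform and an intensity multiply
    to the patch, runs the predictor, inverts the geometric transform on
    the output, and the per-pixel per-channel mean over variants is
    returned.  Raises if the predictor output shape disagrees with the
    input.
    """
    h, w = patch_pixels.shape[:2]
    acc = np.zeros((h, w, N_CLASSES), dtype=np.float64)
    for name, mult in tta_set:
        fwd, inv = _GEOMETRIC[name]
        pixels = fwd(patch_pixels)
        if mult != 1.0:
            pixels = np.clip(pixels.astype(np.float64) * mult, 0, 255).astype(patch_pixels.dtype)
        probs = np.asarray(predictor(pixels, ref))
        expect = pixels.shape[:2] + (N_CLASSES,)
        if probs.shape != expect:
            raise ValueError(f"predictor returned shape {probs.shape}, expected {expect}")
        acc += inv(probs)
    return (acc / len(tta_set)).astype(np.float32)


def stitch(
    patch_maps: Sequence[tuple[PatchRef, np.ndarray]],
    slide_shape: tuple[int, int],
    mpp: float = 1.0,
) -> ProbabilityMap:
    """Aggregate patch predictions to a slide-level probability map.

    Per-pixel per-channel arithmetic mean over every window covering the
    pixel; pixels covered by no window are 0.
    """
    h, w = slide_shape
    acc = np.zeros((h, w, N_CLASSES), dtype=np.float64)
    cover = np.zeros((h, w, 1), dtype=np.float64)
    for ref, probs in patch_maps:
        probs = np.asarray(probs)
        if ref.row1 > h or ref.col1 > w or ref.row0 < 0 or ref.col0 < 0:
            raise ValueError(f"patch window {ref} outside slide bounds {slide_shape}")
        if probs.shape != ref.shape + (N_CLASSES,):
            raise ValueError("probability map shape disagrees with its window")
        acc[ref.row0 : ref.row1, ref.col0 : ref.col1] += probs
        cover[ref.row0 : ref.row1, ref.col0 : ref.col1] += 1.0
    out = np.divide(acc, cover, out=np.zeros_like(acc), where=cover > 0)
    return ProbabilityMap(out.astype(np.float32), mpp)


def harden(probmap: ProbabilityMap, threshold: float = 0.5) -> MultiClassMask:
    """Threshold a probability map to hard labels.

    A pixel gets the argmax channel when the max channel probability is
    at least ``threshold``, else background; argmax ties break to the
    lowest class index (numpy argmax convention).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    best = probmap.probs.argmax(axis=2)
    peak = probmap.probs.max(axis=2)
    labels = np.where(peak >= threshold, best + 1, 0).astype(np.uint8)
    return MultiClassMask(labels, probmap.mpp)


def predict_slide(
    slide_pixels: np.ndarray,
    predictor: Callable[[np.ndarray, PatchRef | None], np.ndarray],
    config: TilingConfig = TilingConfig(),
    slide_id: str = "",
    use_tta: bool = False,
    mpp: float = 1.0,
) -> ProbabilityMap:
    """Tile a slide, run the predictor per patch (optionally with TTA)
    and stitch the results back to a slide-level probability map."""
    patches = enumerate_patches(slide_pixels.shape[:2], config, slide_id)
    maps = []
    for ref in patches:
        pixels = ref.crop(slide_pixels)
        if use_tta:
            probs = tta_predict(pixels, predictor, ref)
        else:
            probs = np.asarray(predictor(pixels, ref))
            if probs.shape != ref.shape + (N_CLASSES,):
                raise ValueError("predictor output shape disagrees with patch window")
        maps.append((ref, probs))
    return stitch(maps, slide_pixels.shape[:2], mpp=mpp)
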