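"""Pluggable patch-predictor contract and reference predictors.

The trained segmentation network is replaced by a contract: a predictor
is a callable ``(patch_pixels, patch_ref) -> (h, w, 5) probabilities``.
Two reference implementations ship with the package so the pipeline runs
end-to-end without trained weights:

* :func:`oracle_predictor` -- emits (optionally corrupted) one-hot
  probabilities read from a ground-truth mask.  It is window-addressed:
  the ``patch_ref`` locates the patch on the slide, and the pixel
  content is ignored.
* :func:`threshold_predictor` -- a colour-distance model driven purely
  by pixel content, exercising the contract the way a real network
  would.

Adapter hook: any user model can participate by wrapping its forward
pass in a callable of the same signature (ignore ``patch_ref`` for
stateless pixel models).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import LesionClass, MultiClassMask, N_CLASSES
from .tiling import PatchRef


@dataclass
class OracleCorruption:
    """Controlled degradation of the ground-truth oracle.

    boundary_shift_px erodes (negative) or dilates (positive) every
    instance's support; class_confusion_rate flips each instance's class
    to a uniformly random other class; prob_noise_sd adds clipped
    Gaussian noise to the emitted probabilities.
    """

    boundary_shift_px: int = 0
    class_confusion_rate: float = 0.0
    prob_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.class_confusion_rate < 1.0:
            raise ValueError("class_confusion_rate must lie in [0, 1)")
        if self.prob_noise_sd < 0:
            raise ValueError("prob_noise_sd must be >= 0")


def corrupt_mask(mask: MultiClassMask, corruption: OracleCorruption) -> MultiClassMask:
    """Apply instance-level class confusion and boundary shift to a mask."""
    rng = np.random.default_rng(np.random.SeedSequence([corruption.seed, 0xC7]))
    comp, n = ndi.label(mask.support, structure=np.ones((3, 3), dtype=bool))
    labels = np.zeros_like(mask.labels)
    struct = ndi.generate_binary_structure(2, 2)
    for i in range(1, n + 1):
        region = comp == i
        vals, counts = np.unique(mask.labels[region], return_counts=True)
        keep = vals > 0
        cls_label = int(vals[keep][counts[keep].argmax()])
        if corruption.class_confusion_rate > 0 and rng.random() < corruption.class_confusion_rate:
            others = [l for l in range(1, N_CLASSES + 1) if l != cls_label]
            cls_label = int(rng.choice(others))
        if corruption.boundary_shift_px < 0:
            region = ndi.binary_erosion(
                region, structure=struct, iterations=-corruption.boundary_shift_px
            )
        elif corruption.boundary_shift_px > 0:
            region = ndi.binary_dilation(
                region, structure=struct, iterations=corruption.boundary_shift_px
            )
        labels[region] = cls_label
    return MultiClassMask(labels, mask.mpp)


def oracle_predictor(mask: MultiClassMask, corruption: OracleCorruption | None = None):
    """Stand-in for a trained network: reads (corrupted) ground truth.

    Returns a predictor callable.  The corrupted mask is computed once at
    slide level so overlapping patches agree; per-patch probability noise
    is seeded by the window origin, making the predictor a deterministic
    pure function of ``(patch, ref)``.
    """
    corruption = corruption or OracleCorruption()
    corrupted = (
        corrupt_mask(mask, corruption)
        if (corruption.boundary_shift_px or corruption.class_confusion_rate)
        else mask
    )
    h, w = mask.shape

    def predict(patch_pixels: np.ndarray, ref: PatchRef | None) -> np.ndarray:
        if ref is None:
            raise ValueError("the oracle predictor is window-addressed and needs a PatchRef")
        if ref.row1 > h or ref.col1 > w or ref.row0 < 0 or ref.col0 < 0:
            raise ValueError(f"window {ref} outside the oracle mask of shape {(h, w)}")
        window = ref.crop(corrupted.labels)
        probs = np.zeros(window.shape + (N_CLASSES,), dtype=np.float32)
        for cls in LesionClass:
            probs[window == cls.label, cls.index] = 1.0
        if corruption.prob_noise_sd > 0:
            rng = np.random.default_rng(
                np.random.SeedSequence([corruption.seed, 0x0E, ref.row0, ref.col0])
            )
            probs = np.clip(
                probs + rng.normal(0.0, corruption.prob_noise_sd, probs.shape), 0.0, 1.0
            ).astype(np.float32)
        return probs

    return predict


def threshold_predictor(class_colors: np.ndarray | None = None, tolerance: float = 60.0):
    """Colour-distance baseline predictor.

    The probability for class c decreases linearly from 1 at the class
    reference colour to 0 at RGB distance ``tolerance``.  Defaults to the
    colours the synthetic generator renders at its default contrast.
    """
    if class_colors is None:
        from .synthetic import rendered_class_colors

        class_colors = rendered_class_colors()
    colors = np.asarray(class_colors, dtype=float)
    if colors.shape != (N_CLASSES, 3):
        raise ValueError("class_colors must be (5, 3)")
    if len(np.unique(colors, axis=0)) != N_CLASSES:
        raise ValueError("class colours must be distinct")

    def predict(patch_pixels: np.ndarray, ref: PatchRef | None = None) -> np.ndarray:
        px = patch_pixels.astype(float)
        dists = np.linalg.norm(px[:, :, None, :] - colors[None, None, :, :], axis=3)
        return np.clip(1.0 - dists / tolerance, 0.0, 1.0).astype(np.float32)

    return predict


def constant_predictor(value: float):
    """Predictor emitting a constant probability everywhere (testing aid)."""

    def predict(patch_pixels: np.ndarray, ref: PatchRef | None = None) -> np.ndarray:
        return np.full(patch_pixels.shape[:2] + (N_CLASSES,), value, dtype=np.float32)

    return predict
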