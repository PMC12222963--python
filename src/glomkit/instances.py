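"""Instance separation of merged glomerulus segments.

Closely located glomeruli are often segmented as one connected region.
Separation runs marker-controlled watershed on the Euclidean
distance-to-background transform of the union support across classes:
glomerulus centres appear as local maxima of the distance map (minima of
its negation, on which the watershed floods), one marker per glomerulus.

Markers are depth-filtered (h-maxima) and distance-filtered so shallow
noise peaks inside a single glomerulus do not split it; regions below a
minimum area are merged into their largest neighbour or dropped when
isolated.  Class is re-assigned per region by majority ground label,
because merged neighbours may differ in lesion class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .core import GlomerulusInstance, LesionClass, MultiClassMask, ProbabilityMap

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class SeparationConfig:
    """Defaults tuned on the synthetic suite; all config-exposed.

    min_marker_distance_px (~um at working resolution) suppresses marker
    pairs closer than a plausible glomerulus radius;
    marker_depth_px is the h-maxima depth below which a secondary peak is
    considered noise rather than a second glomerulus.
    """

    min_marker_distance_px: int = 15
    min_instance_area_px: int = 300
    smoothing_sigma_px: float = 2.0
    marker_depth_px: float = 1.0

    def __post_init__(self) -> None:
        if self.min_marker_distance_px < 1 or self.min_instance_area_px < 1:
            raise ValueError("marker distance and min area must be >= 1")
        if self.smoothing_sigma_px < 0:
            raise ValueError("smoothing sigma must be >= 0")


def _select_markers(dist: np.ndarray, support: np.ndarray, config: SeparationConfig) -> np.ndarray:
    """Marker image: depth-filtered maxima of the distance map, greedily
    suppressed within min_marker_distance, at least one per component."""
    if config.marker_depth_px > 0:
        peaks = h_maxima(dist, config.marker_depth_px) & support
    else:
        maxed = ndi.maximum_filter(dist, size=3)
        peaks = (dist >= maxed) & support
    peak_lab, n_peaks = ndi.label(peaks, structure=_EIGHT)
    comp, n_comp = ndi.label(support, structure=_EIGHT)

    centers: list[tuple[float, float]] = []
    values: list[float] = []
    if n_peaks:
        centroids = ndi.center_of_mass(peaks, peak_lab, range(1, n_peaks + 1))
        maxima = ndi.maximum(dist, peak_lab, range(1, n_peaks + 1))
        centers = [tuple(c) for c in centroids]
        values = list(np.atleast_1d(maxima))

    # every connected component needs at least one marker
    have = set()
    for c in centers:
        have.add(comp[int(round(c[0])), int(round(c[1]))])
    for i in range(1, n_comp + 1):
        if i in have:
            continue
        masked = np.where(comp == i, dist, -1.0)
        r, c = np.unravel_index(int(masked.argmax()), masked.shape)
        centers.append((float(r), float(c)))
        values.append(float(dist[r, c]))

    # non-maximum suppression by marker value within the distance radius
    order = sorted(range(len(centers)), key=lambda i: (-values[i], centers[i]))
    kept: list[tuple[float, float]] = []
    markers = np.zeros(dist.shape, dtype=np.int32)
    next_id = 1
    min_d2 = float(config.min_marker_distance_px) ** 2
    for i in order:
        r, c = centers[i]
        if any((r - kr) ** 2 + (c - kc) ** 2 < min_d2 for kr, kc in kept):
            continue
        kept.append((r, c))
        markers[int(round(r)), int(round(c))] = next_id
        next_id += 1
    return markers


def _merge_small_regions(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Merge regions smaller than min_area into their largest adjacent
    region (within the same component); drop isolated small regions."""
    labels = labels.copy()
    while True:
        ids, areas = np.unique(labels[labels > 0], return_counts=True)
        small = ids[areas < min_area]
        if len(small) == 0:
            return labels
        area_of = dict(zip(ids.tolist(), areas.tolist()))
        changed = False
        for sid in small:
            region = labels == sid
            ring = ndi.binary_dilation(region, structure=_EIGHT) & ~region
            neighbors = np.unique(labels[ring])
            neighbors = neighbors[neighbors > 0]
            if len(neighbors) == 0:
                labels[region] = 0  # isolated fragment: dropped
            else:
                target = max(neighbors, key=lambda n: area_of.get(int(n), 0))
                labels[region] = target
            changed = True
        if not changed:
            return labels


def separate_instances(
    mask: MultiClassMask,
    probmap: ProbabilityMap | None = None,
    config: SeparationConfig = SeparationConfig(),
) -> list[GlomerulusInstance]:
    """Split the mask's union support into distinct glomerulus instances.

    Pipeline: distance-to-background transform on the union support ->
    optional Gaussian smoothing -> depth- and distance-filtered maxima as
    markers -> watershed on the negated distance map constrained to the
    support -> small-region merge -> per-region majority class and mean
    winning-channel confidence.

    The returned pixel sets are pairwise disjoint and partition the
    support minus dropped fragments.
    """
    if probmap is not None and probmap.shape != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} and probability map shape {probmap.shape} differ"
        )
    support = mask.support
    if not support.any():
        return []
    dist = ndi.distance_transform_edt(support)
    if config.smoothing_sigma_px > 0:
        dist = ndi.gaussian_filter(dist, config.smoothing_sigma_px)
    markers = _select_markers(dist, support, config)
    labels = watershed(-dist, markers, mask=support, connectivity=2)
    labels = _merge_small_regions(labels, config.min_instance_area_px)

    instances: list[GlomerulusInstance] = []
    out_id = 0
    for rid in np.unique(labels[labels > 0]):
        region = labels == rid
        vals, counts = np.unique(mask.labels[region], return_counts=True)
        keep = vals > 0
        if not keep.any():
            continue
        cls_label = int(vals[keep][counts[keep].argmax()])
        lesion = LesionClass.from_label(cls_label)
        if probmap is not None:
            confidence = float(probmap.probs[..., lesion.index][region].mean())
            confidence = min(max(confidence, 0.0), 1.0)
        else:
            confidence = 1.0
        pixels = np.argwhere(region)
        out_id += 1
        instances.append(
            GlomerulusInstance(
                instance_id=out_id, lesion=lesion, pixels=pixels, confidence=confidence
            )
        )
    return instances


def instances_from_label_map(
    label_map: np.ndarray,
    mask: MultiClassMask,
    probmap: ProbabilityMap | None = None,
) -> list[GlomerulusInstance]:
    """Build instances from a known instance label map (e.g. a synthetic
    manifest), bypassing watershed.  Used for ground-truth instances."""
    instances: list[GlomerulusInstance] = []
    objects = ndi.find_objects(label_map)
    out_id = 0
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        region = label_map[sl] == i
        if not region.any():
            continue
        vals, counts = np.unique(mask.labels[sl][region], return_counts=True)
        keep = vals > 0
        if not keep.any():
            continue
        lesion = LesionClass.from_label(int(vals[keep][counts[keep].argmax()]))
        pixels = np.argwhere(region)
        pixels[:, 0] += sl[0].start
        pixels[:, 1] += sl[1].start
        if probmap is not None:
            conf = float(
                probmap.probs[pixels[:, 0], pixels[:, 1], lesion.index].mean()
            )
            conf = min(max(conf, 0.0), 1.0)
        else:
            conf = 1.0
        out_id += 1
        instances.append(
            GlomerulusInstance(instance_id=out_id, lesion=lesion, pixels=pixels, confidence=conf)
        )
    return instances


def count_instances_by_class(instances: list[GlomerulusInstance]) -> np.ndarray:
    """Per-class instance counts as a 5-vector (sums to len(instances))."""
    counts = np.zeros(5, dtype=int)
    for inst in instances:
        counts[inst.lesion.index] += 1
    return counts
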