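"""Object- and pixel-level segmentation metrics.

* instance matching under the >= 50% ground-truth-coverage rule
  (coverage = |P intersect G| / |G|, not IoU; an IoU flag is available
  for comparison studies);
* per-class average precision with all-point interpolation over the
  pooled cross-slide confidence ranking;
* per-class Dice similarity, micro-aggregated over pixels across slides;
* ground-truth-count-weighted averages;
* percentile bootstrap confidence intervals resampling slides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import GlomerulusInstance, LesionClass, MultiClassMask


@dataclass(frozen=True)
class MatchConfig:
    coverage_threshold: float = 0.5
    require_class_match: bool = True
    use_iou: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage_threshold <= 1.0:
            raise ValueError("coverage_threshold must lie in (0, 1]")


@dataclass
class MatchResult:
    """One prediction's fate after matching (gt_id is None for FP)."""

    pred_id: int
    lesion: LesionClass
    confidence: float
    gt_id: int | None
    is_tp: bool
    coverage: float


def _coverage(pred: GlomerulusInstance, gt: GlomerulusInstance, width: int, use_iou: bool) -> float:
    p = pred.flat_indices(width)
    g = gt.flat_indices(width)
    inter = len(np.intersect1d(p, g, assume_unique=True))
    if use_iou:
        union = len(p) + len(g) - inter
        return inter / union if union else 0.0
    return inter / len(g)


def match_instances(
    pred_instances: Sequence[GlomerulusInstance],
    gt_instances: Sequence[GlomerulusInstance],
    config: MatchConfig = MatchConfig(),
    grid_width: int = 1 << 20,
) -> tuple[list[MatchResult], list[int]]:
    """Greedy confidence-ordered matching of predictions to ground truth.

    Predictions are visited in descending confidence (ties broken by
    instance id); each claims the unclaimed ground-truth instance with
    the largest coverage among those at or above the threshold (and of
    the same class when required).  Returns per-prediction results and
    the ids of unmatched ground truths (false negatives).
    """
    order = sorted(pred_instances, key=lambda p: (-p.confidence, p.instance_id))
    claimed: set[int] = set()
    results: list[MatchResult] = []
    for pred in order:
        best_cov, best_gt = 0.0, None
        for gt in gt_instances:
            if gt.instance_id in claimed:
                continue
            if config.require_class_match and gt.lesion != pred.lesion:
                continue
            cov = _coverage(pred, gt, grid_width, config.use_iou)
            if cov >= config.coverage_threshold and (
                cov > best_cov or (cov == best_cov and best_gt is not None and gt.instance_id < best_gt)
            ):
                best_cov, best_gt = cov, gt.instance_id
        if best_gt is not None:
            claimed.add(best_gt)
            results.append(
                MatchResult(pred.instance_id, pred.lesion, pred.confidence, best_gt, True, best_cov)
            )
        else:
            results.append(
                MatchResult(pred.instance_id, pred.lesion, pred.confidence, None, False, 0.0)
            )
    missed = [g.instance_id for g in gt_instances if g.instance_id not in claimed]
    return results, missed


def optimal_match_count(
    pred_instances: Sequence[GlomerulusInstance],
    gt_instances: Sequence[GlomerulusInstance],
    config: MatchConfig = MatchConfig(),
    grid_width: int = 1 << 20,
) -> int:
    """Maximum achievable TP count by exhaustive assignment (oracle for
    small scenes; exponential in the number of predictions)."""
    eligible: list[list[int]] = []
    for pred in pred_instances:
        opts = []
        for j, gt in enumerate(gt_instances):
            if config.require_class_match and gt.lesion != pred.lesion:
                continue
            if _coverage(pred, gt, grid_width, config.use_iou) >= config.coverage_threshold:
                opts.append(j)
        eligible.append(opts)

    best = 0

    def recurse(i: int, used: set[int], count: int) -> None:
        nonlocal best
        if count + (len(eligible) - i) <= best:
            return
        if i == len(eligible):
            best = max(best, count)
            return
        for j in eligible[i]:
            if j not in used:
                used.add(j)
                recurse(i + 1, used, count + 1)
                used.remove(j)
        recurse(i + 1, used, count)

    recurse(0, set(), 0)
    return best


@dataclass
class PRCurve:
    recalls: np.ndarray
    precisions: np.ndarray
    ap: float


def average_precision(
    match_results: Sequence[Sequence[MatchResult]],
    n_gt: int,
    lesion: LesionClass,
) -> PRCurve | None:
    """Pooled cross-slide average precision for one class.

    All predictions of the class are pooled across slides, ranked by
    descending confidence, and the precision/recall sweep is integrated
    with all-point interpolation: AP = sum (r_i - r_{i-1}) p_i.  Returns
    None (metric undefined) when the class has no ground truth.
    """
    if n_gt == 0:
        return None
    pooled = [
        (res.confidence, slide_idx, res.pred_id, res.is_tp)
        for slide_idx, slide in enumerate(match_results)
        for res in slide
        if res.lesion == lesion
    ]
    pooled.sort(key=lambda t: (-t[0], t[1], t[2]))
    tp = np.cumsum([1 if hit else 0 for *_rest, hit in pooled]) if pooled else np.array([])
    if len(pooled) == 0:
        return PRCurve(np.array([0.0]), np.array([0.0]), 0.0)
    ranks = np.arange(1, len(pooled) + 1)
    precisions = tp / ranks
    recalls = tp / n_gt
    prev = np.concatenate([[0.0], recalls[:-1]])
    ap = float(((recalls - prev) * precisions).sum())
    return PRCurve(recalls, precisions, ap)


def dice_per_class(
    pred_masks: Sequence[MultiClassMask],
    gt_masks: Sequence[MultiClassMask],
    lesion: LesionClass,
) -> float | None:
    """Micro-aggregated Dice 2|P^G| / (|P|+|G|) over all slides' pixels.

    None when neither masks contain the class (undefined).
    """
    inter = total = 0
    for pred, gt in zip(pred_masks, gt_masks, strict=True):
        if pred.shape != gt.shape:
            raise ValueError("prediction/ground-truth mask shapes differ")
        p = pred.labels == lesion.label
        g = gt.labels == lesion.label
        inter += int((p & g).sum())
        total += int(p.sum()) + int(g.sum())
    if total == 0:
        return None
    return 2.0 * inter / total


def weighted_average(
    per_class_values: Sequence[float | None], per_class_counts: Sequence[float]
) -> float:
    """Ground-truth-count-weighted mean; missing (None) classes are
    excluded together with their counts."""
    num = den = 0.0
    for v, n in zip(per_class_values, per_class_counts, strict=True):
        if v is None:
            continue
        if n < 0:
            raise ValueError("counts must be non-negative")
        num += v * n
        den += n
    if den == 0:
        raise ValueError("all counts are zero")
    return num / den


def bootstrap_ci(
    metric_fn: Callable[[list], float],
    resample_units: Sequence,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval resampling whole units (slides).

    Replicates on which the metric is undefined (raises or returns NaN)
    are redrawn, up to 10B attempts.
    """
    if len(resample_units) < 2:
        raise ValueError("need at least 2 resample units")
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB5]))
    n = len(resample_units)
    stats: list[float] = []
    attempts = 0
    while len(stats) < B:
        attempts += 1
        if attempts > 10 * B:
            raise RuntimeError("metric undefined on too many bootstrap replicates")
        idx = rng.integers(0, n, size=n)
        try:
            value = metric_fn([resample_units[i] for i in idx])
        except (ValueError, ZeroDivisionError):
            continue
        if value is None or not np.isfinite(value):
            continue
        stats.append(float(value))
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class EvalReport:
    """Per-class and weighted AP/DSC with bootstrap CIs (Table layout)."""

    per_class_ap: dict
    per_class_dsc: dict
    per_class_ci_ap: dict
    per_class_ci_dsc: dict
    gt_counts: dict
    weighted_ap: float
    weighted_dsc: float
    weighted_ap_ci: tuple[float, float]
    weighted_dsc_ci: tuple[float, float]

    def to_rows(self) -> list[dict]:
        rows = []
        for cls in LesionClass:
            code = cls.name
            rows.append(
                {
                    "class": code,
                    "n_gt": self.gt_counts[code],
                    "ap": self.per_class_ap[code],
                    "ap_ci_lo": self.per_class_ci_ap[code][0],
                    "ap_ci_hi": self.per_class_ci_ap[code][1],
                    "dsc": self.per_class_dsc[code],
                    "dsc_ci_lo": self.per_class_ci_dsc[code][0],
                    "dsc_ci_hi": self.per_class_ci_dsc[code][1],
                }
            )
        rows.append(
            {
                "class": "weighted_average",
                "n_gt": sum(self.gt_counts.values()),
                "ap": self.weighted_ap,
                "ap_ci_lo": self.weighted_ap_ci[0],
                "ap_ci_hi": self.weighted_ap_ci[1],
                "dsc": self.weighted_dsc,
                "dsc_ci_lo": self.weighted_dsc_ci[0],
                "dsc_ci_hi": self.weighted_dsc_ci[1],
            }
        )
        return rows


def _pooled_ap_by_class(slides: list[dict]) -> dict:
    out = {}
    for cls in LesionClass:
        n_gt = sum(s["gt_counts"][cls.name] for s in slides)
        curve = average_precision([s["matches"] for s in slides], n_gt, cls)
        out[cls.name] = None if curve is None else curve.ap
    return out


def _pooled_dsc_by_class(slides: list[dict]) -> dict:
    return {
        cls.name: dice_per_class(
            [s["pred_mask"] for s in slides], [s["gt_mask"] for s in slides], cls
        )
        for cls in LesionClass
    }


def evaluate_slides(
    slides: list[dict],
    match_config: MatchConfig = MatchConfig(),
    B: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Full evaluation over a list of per-slide dicts with keys
    ``pred_instances``, ``gt_instances``, ``pred_mask``, ``gt_mask``.

    Matching runs once per slide; AP and DSC are pooled across slides;
    95% CIs come from percentile bootstrap over slides.
    """
    from .instances import count_instances_by_class

    units = []
    for s in slides:
        matches, _ = match_instances(s["pred_instances"], s["gt_instances"], match_config)
        counts = count_instances_by_class(s["gt_instances"])
        units.append(
            {
                "matches": matches,
                "gt_counts": {cls.name: int(counts[cls.index]) for cls in LesionClass},
                "pred_mask": s["pred_mask"],
                "gt_mask": s["gt_mask"],
            }
        )

    ap = _pooled_ap_by_class(units)
    dsc = _pooled_dsc_by_class(units)
    gt_counts = {
        cls.name: sum(u["gt_counts"][cls.name] for u in units) for cls in LesionClass
    }
    counts_vec = [gt_counts[cls.name] for cls in LesionClass]
    w_ap = weighted_average([ap[c.name] for c in LesionClass], counts_vec)
    w_dsc = weighted_average([dsc[c.name] for c in LesionClass], counts_vec)

    ci_ap, ci_dsc = {}, {}
    for i, cls in enumerate(LesionClass):
        if ap[cls.name] is None:
            ci_ap[cls.name] = (float("nan"), float("nan"))
        else:
            ci_ap[cls.name] = bootstrap_ci(
                lambda ss, c=cls: _pooled_ap_by_class(ss)[c.name], units, B=B, seed=seed + i
            )
        if dsc[cls.name] is None:
            ci_dsc[cls.name] = (float("nan"), float("nan"))
        else:
            ci_dsc[cls.name] = bootstrap_ci(
                lambda ss, c=cls: _pooled_dsc_by_class(ss)[c.name],
                units,
                B=B,
                seed=seed + 10 + i,
            )

    def _weighted(ss: list[dict], fn) -> float:
        vals = fn(ss)
        cnts = [sum(s["gt_counts"][c.name] for s in ss) for c in LesionClass]
        return weighted_average([vals[c.name] for c in LesionClass], cnts)

    w_ap_ci = bootstrap_ci(lambda ss: _weighted(ss, _pooled_ap_by_class), units, B=B, seed=seed + 20)
    w_dsc_ci = bootstrap_ci(lambda ss: _weighted(ss, _pooled_dsc_by_class), units, B=B, seed=seed + 21)

    return EvalReport(
        per_class_ap=ap,
        per_class_dsc=dsc,
        per_class_ci_ap=ci_ap,
        per_class_ci_dsc=ci_dsc,
        gt_counts=gt_counts,
        weighted_ap=w_ap,
        weighted_dsc=w_dsc,
        weighted_ap_ci=w_ap_ci,
        weighted_dsc_ci=w_dsc_ci,
    )
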