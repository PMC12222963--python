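"""Synthetic slides, masks and clinical cohorts.

The generator stands in for PAS-stained biopsy rasters: an elliptical
tissue core containing blob glomeruli of five lesion classes at realistic
prevalences, a matched ground-truth label mask, and a per-patient clinical
table whose binary kidney-outcome depends on the slide's global-sclerosis
burden through a logistic model.

Glomeruli are ellipses with low-frequency radial noise, so boundaries are
smooth and analytic shape expectations (eccentricity, roundness) remain
checkable.  Each lesion class gets a distinct mean colour in the raster,
so a simple colour-threshold predictor can succeed; this emulates the
stain contrast that makes lesions recognisable, not PAS texture itself.

All randomness flows from a single integer seed through spawned
`numpy` generators; the same seed gives bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import expit

from .core import CLASS_CODES, LesionClass, MultiClassMask, SlideRaster

# Lesion-class prevalences of a typical annotated training cohort
# (no lesion dominates; ischemic change is rarest).
DEFAULT_CLASS_WEIGHTS = (0.7063, 0.2012, 0.0585, 0.0186, 0.0154)

# Distinct mean colours per class (lesion colour-coding convention:
# red / green / blue / yellow / cyan), blended toward tissue pink by
# 1 - texture_contrast.
_CLASS_COLORS = np.array(
    [
        [200, 100, 110],  # NL
        [110, 180, 110],  # GS
        [110, 120, 200],  # SS
        [205, 190, 90],   # CR
        [100, 190, 195],  # ISC
    ],
    dtype=float,
)
_TISSUE_COLOR = np.array([228, 205, 215], dtype=float)
_SLIDE_BG = np.array([244, 244, 244], dtype=float)


@dataclass
class SyntheticSlideSpec:
    """Parameters of one synthetic slide at 1.0 um/px.

    Defaults emulate a biopsy core: ~18 glomeruli of 35-75 um mean radius
    inside an elliptical tissue region, class mix at cohort prevalences,
    and a small fraction of deliberately touching pairs whose mask support
    merges (the situation watershed separation exists for).
    """

    width: int = 1536
    height: int = 1536
    n_glomeruli: int = 18
    class_weights: tuple[float, ...] = DEFAULT_CLASS_WEIGHTS
    radius_range: tuple[float, float] = (35.0, 75.0)
    overlap_fraction: float = 0.1
    texture_contrast: float = 0.8
    noise_sd: float = 6.0
    #: touching pairs are placed with centre separation at least this
    #: multiple of the pair's mean radius
    min_pair_separation_factor: float = 1.2
    #: between-slide lesion-burden heterogeneity: per-slide class weights
    #: are drawn from Dirichlet(concentration x class_weights), whose
    #: mean is class_weights.  The default reproduces the large
    #: between-slide spread of lesion count ratios seen in real cohorts
    #: (GS count-ratio sd ~0.2); None disables the jitter (every slide
    #: samples classes i.i.d. from class_weights).
    class_weight_concentration: float | None = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.class_weights, dtype=float)
        if w.shape != (5,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("class_weights must be 5 non-negative values summing to 1")
        if self.radius_range[0] < 10.0:
            raise ValueError("minimum glomerulus radius must be >= 10 um")
        if self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius_range must be (min, max) with min <= max")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.n_glomeruli < 0:
            raise ValueError("n_glomeruli must be non-negative")


@dataclass
class SlideManifest:
    """Ground truth for one generated slide.

    ``instances`` has one row per glomerulus (slide_id, instance_id,
    lesion, center_row, center_col, mean_radius_um, area_px, merged_pair);
    ``label_map`` assigns every glomerular pixel its instance id (1-based,
    0 = background) and partitions the mask support.
    """

    slide_id: str
    instances: pd.DataFrame
    label_map: np.ndarray

    def class_counts(self) -> np.ndarray:
        counts = np.zeros(5, dtype=int)
        for code, n in self.instances["lesion"].value_counts().items():
            counts[LesionClass[code].index] = n
        return counts


def rendered_class_colors(texture_contrast: float = 0.8) -> np.ndarray:
    """Mean RGB each lesion class is rendered with at the given contrast
    (the reference colours a colour-threshold predictor should use)."""
    return texture_contrast * _CLASS_COLORS + (1 - texture_contrast) * _TISSUE_COLOR


def tissue_ellipse(height: int, width: int) -> np.ndarray:
    """Boolean elliptical 'tissue core' centred in the slide."""
    rr, cc = np.ogrid[:height, :width]
    a, b = 0.45 * height, 0.45 * width
    return ((rr - height / 2) / a) ** 2 + ((cc - width / 2) / b) ** 2 <= 1.0


def _blob_geometry(rng: np.random.Generator, radius_range: tuple[float, float]):
    r0 = rng.uniform(*radius_range)
    q = rng.uniform(0.70, 0.95)          # minor/major axis ratio
    a, b = r0 / math.sqrt(q), r0 * math.sqrt(q)
    theta = rng.uniform(0.0, math.pi)
    amps = rng.uniform(0.0, 0.05, size=3)    # radial harmonics k = 2, 3, 4
    phases = rng.uniform(0.0, 2 * math.pi, size=3)
    return r0, a, b, theta, amps, phases


def _paint_blob(label_map, norm_map, idx, center, a, b, theta, amps, phases, tissue):
    """Rasterise one noisy ellipse; contested pixels go to the instance
    whose normalised elliptical radius is smaller (nearest-centre rule)."""
    h, w = label_map.shape
    rmax = max(a, b) * 1.10
    r0 = max(int(center[0] - rmax), 0)
    r1 = min(int(center[0] + rmax) + 2, h)
    c0 = max(int(center[1] - rmax), 0)
    c1 = min(int(center[1] + rmax) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return 0
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - center[0]
    dx = cc - center[1]
    ct, st = math.cos(theta), math.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    rho = np.hypot(u, v)
    ang = np.arctan2(v, u)
    boundary = np.ones_like(rho)
    for k, (amp, ph) in enumerate(zip(amps, phases), start=2):
        boundary += amp * np.cos(k * ang + ph)
    norm = rho / boundary
    inside = (norm <= 1.0) & tissue[r0:r1, c0:c1]
    take = inside & (norm < norm_map[r0:r1, c0:c1])
    label_map[r0:r1, c0:c1][take] = idx
    norm_map[r0:r1, c0:c1][take] = norm[take]
    return int(inside.sum())


def generate_slide(spec: SyntheticSlideSpec) -> tuple[SlideRaster, MultiClassMask, SlideManifest]:
    """Generate one slide: RGB raster, ground-truth mask, and manifest.

    A fraction ``overlap_fraction`` of glomeruli is placed to touch a
    previously placed neighbour (centre separation between
    ``min_pair_separation_factor`` x mean pair radius and just under the
    sum of radii), producing merged components in the mask support.  The
    remainder are placed with clear margins.

    Raises ``RuntimeError`` naming the achievable count when placement
    fails after bounded retries.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x51]))
    h, w = spec.height, spec.width
    tissue = tissue_ellipse(h, w)
    label_map = np.zeros((h, w), dtype=np.int32)
    norm_map = np.full((h, w), np.inf, dtype=np.float32)
    weights = np.asarray(spec.class_weights, dtype=float)
    if spec.class_weight_concentration is not None:
        alive = weights > 0
        jitter = rng.dirichlet(spec.class_weight_concentration * weights[alive])
        weights = np.zeros_like(weights)
        weights[alive] = jitter

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    rows = []
    merged_flags: list[bool] = []
    cy, cx = h / 2.0, w / 2.0
    ea, eb = 0.45 * h, 0.45 * w

    for i in range(spec.n_glomeruli):
        class_idx = int(rng.choice(5, p=weights))
        r0, a, b, theta, amps, phases = _blob_geometry(rng, spec.radius_range)
        want_pair = bool(centers) and rng.random() < spec.overlap_fraction
        if want_pair:
            # a touching pair stays identifiable (two distance-map peaks)
            # only when the partners are round-ish, comparable in size and
            # not chained onto an already-merged instance
            hosts = [k for k in range(len(centers)) if not merged_flags[k]]
            if hosts:
                j = int(rng.choice(hosts))
                r0 = float(
                    np.clip(radii[j] * rng.uniform(0.85, 1.18), *spec.radius_range)
                )
                q = rng.uniform(0.85, 0.95)
                a, b = r0 / math.sqrt(q), r0 * math.sqrt(q)
                amps = rng.uniform(0.0, 0.03, size=3)
            else:
                want_pair = False
        placed = False
        for _attempt in range(300):
            if want_pair:
                mean_r = 0.5 * (r0 + radii[j])
                lo = spec.min_pair_separation_factor * mean_r
                hi = 0.96 * (r0 + radii[j])
                if lo >= hi:
                    want_pair = False
                    continue
                d = rng.uniform(lo, hi)
                phi = rng.uniform(0.0, 2 * math.pi)
                cand = (centers[j][0] + d * math.sin(phi), centers[j][1] + d * math.cos(phi))
                clear_of = [k for k in range(len(centers)) if k != j]
            else:
                cand = (rng.uniform(0, h), rng.uniform(0, w))
                clear_of = list(range(len(centers)))
            # keep the whole blob inside the tissue core
            if ((cand[0] - cy) / ea) ** 2 + ((cand[1] - cx) / eb) ** 2 > (1 - 1.25 * r0 / min(ea, eb)) ** 2:
                continue
            ok = all(
                math.hypot(cand[0] - centers[k][0], cand[1] - centers[k][1])
                > r0 + radii[k] + 4.0
                for k in clear_of
            )
            if not ok:
                continue
            _paint_blob(label_map, norm_map, i + 1, cand, a, b, theta, amps, phases, tissue)
            centers.append(cand)
            radii.append(r0)
            merged_flags.append(want_pair)
            if want_pair:
                merged_flags[j] = True
            rows.append(
                {
                    "instance_id": i + 1,
                    "lesion": CLASS_CODES[class_idx],
                    "center_row": cand[0],
                    "center_col": cand[1],
                    "mean_radius_um": r0,
                }
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place glomerulus {i + 1}/{spec.n_glomeruli}; "
                f"achievable count is {len(centers)}"
            )

    slide_id = f"synthetic_{spec.seed:08d}"
    areas = np.bincount(label_map.ravel(), minlength=spec.n_glomeruli + 1)
    for row in rows:
        row["slide_id"] = slide_id
        row["area_px"] = int(areas[row["instance_id"]])
        row["merged_pair"] = bool(merged_flags[row["instance_id"] - 1])

    # class labels from the instance map
    lut = np.zeros(spec.n_glomeruli + 1, dtype=np.uint8)
    for row in rows:
        lut[row["instance_id"]] = LesionClass[row["lesion"]].label
    labels = lut[label_map]
    mask = MultiClassMask(labels, mpp=1.0)

    # raster: background, tissue, class-coloured blobs, Gaussian noise
    img = np.empty((h, w, 3), dtype=float)
    img[:] = _SLIDE_BG
    img[tissue] = _TISSUE_COLOR
    for cls in LesionClass:
        sel = labels == cls.label
        if sel.any():
            color = spec.texture_contrast * _CLASS_COLORS[cls.index] + (
                1 - spec.texture_contrast
            ) * _TISSUE_COLOR
            img[sel] = color
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    raster = SlideRaster(np.clip(img, 0, 255).astype(np.uint8), mpp=1.0, slide_id=slide_id)

    columns = [
        "slide_id",
        "instance_id",
        "lesion",
        "center_row",
        "center_col",
        "mean_radius_um",
        "area_px",
        "merged_pair",
    ]
    instances = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(columns=columns)
    manifest = SlideManifest(slide_id=slide_id, instances=instances, label_map=label_map)
    return raster, mask, manifest


def merged_component_count(mask: MultiClassMask) -> int:
    """Number of 8-connected components in the mask's union support."""
    _, n = ndi.label(mask.support, structure=np.ones((3, 3), dtype=bool))
    return n


# ---------------------------------------------------------------------------
# clinical cohort
# ---------------------------------------------------------------------------

#: Table-1-like marginal distributions of the clinical variables
#: (mean, sd) for continuous ones, event probability for flags.
DEFAULT_CLINICAL_MEANS = {
    "age": 34.0,
    "bmi": 22.4,
    "baseline_egfr": 93.9,
    "upcr": 1.93,
    "creatinine": 1.26,
    "sbp": 118.5,
    "dbp": 72.9,
    "hemoglobin": 12.9,
}
DEFAULT_CLINICAL_SDS = {
    "age": 19.0,
    "bmi": 3.9,
    "baseline_egfr": 46.2,
    "upcr": 2.59,
    "creatinine": 1.30,
    "sbp": 14.0,
    "dbp": 11.3,
    "hemoglobin": 1.9,
}
DEFAULT_FLAG_RATES = {
    "sex_male": 0.548,
    "diabetes": 0.042,
    "hypertension": 0.356,
    "isd": 0.107,
    "rasb": 0.495,
}
# Oxford MEST-C score marginals (score value -> probability)
DEFAULT_OXFORD = {
    "oxford_m": {0: 0.569, 1: 0.431},
    "oxford_e": {0: 0.802, 1: 0.198},
    "oxford_s": {0: 0.396, 1: 0.604},
    "oxford_t": {0: 0.760, 1: 0.162, 2: 0.078},
    "oxford_c": {0: 0.852, 1: 0.136, 2: 0.012},
}


@dataclass
class SyntheticCohortSpec:
    """Parameters of the clinical cohort generator.

    The outcome event (sustained eGFR halving or end-stage kidney
    disease within follow-up) is Bernoulli with log-odds
    ``event_base_logodds + beta_gs_ratio * GS_count_ratio``; the default
    base rate lands near the ~18% adverse-outcome prevalence of an
    internal IgAN cohort.
    """

    n_patients: int = 100
    event_base_logodds: float = -1.9
    beta_gs_ratio: float = 2.0
    clinical_means: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_MEANS))
    clinical_sds: dict = field(default_factory=lambda: dict(DEFAULT_CLINICAL_SDS))
    flag_rates: dict = field(default_factory=lambda: dict(DEFAULT_FLAG_RATES))
    followup_months_range: tuple[float, float] = (12.0, 120.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        lo, hi = self.followup_months_range
        if not (0 < lo <= hi):
            raise ValueError("followup_months_range must be positive and ordered")


@dataclass
class CohortTable:
    """Per-patient clinical variables plus the follow-up eGFR series.

    ``patients`` carries one row per patient including the ground-truth
    event indicator (``event_true``) and its generative probability
    (``true_event_prob``) for oracle checks; ``followup`` is a long table
    (patient_id, months, egfr, krt_flag) with one point per 6 months.
    """

    patients: pd.DataFrame
    followup: pd.DataFrame


def generate_cohort(spec: SyntheticCohortSpec, slide_features: pd.DataFrame) -> CohortTable:
    """Draw a clinical cohort joined 1:1 to slide feature vectors.

    ``slide_features`` must have one row per patient with at least
    ``slide_id`` and ``GS_count_ratio`` columns (the output of
    :func:`glomkit.morphometry.cohort_feature_table`).  Clinical
    variables are independent of outcome; the event depends only on the
    GS count ratio.  The eGFR trajectory is piecewise linear with one
    point per 6 months and crosses 50% of baseline iff the event fired.
    """
    if len(slide_features) != spec.n_patients:
        raise ValueError(
            f"need one slide feature vector per patient: got {len(slide_features)} "
            f"for {spec.n_patients} patients"
        )
    if "GS_count_ratio" not in slide_features.columns:
        raise ValueError("slide_features must contain a GS_count_ratio column")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0]))
    n = spec.n_patients
    m, s = spec.clinical_means, spec.clinical_sds

    pat = pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "slide_id": slide_features["slide_id"].to_numpy(),
        }
    )
    pat["age"] = np.clip(rng.normal(m["age"], s["age"], n), 18, 85).round(1)
    pat["sex_male"] = (rng.random(n) < spec.flag_rates["sex_male"]).astype(int)
    pat["bmi"] = np.clip(rng.normal(m["bmi"], s["bmi"], n), 14, 45).round(1)
    pat["baseline_egfr"] = np.clip(rng.normal(m["baseline_egfr"], s["baseline_egfr"], n), 20, 160).round(1)
    pat["upcr"] = np.clip(rng.normal(m["upcr"], s["upcr"], n), 0.05, 15).round(2)
    pat["creatinine"] = np.clip(rng.normal(m["creatinine"], s["creatinine"], n), 0.4, 8).round(2)
    pat["sbp"] = np.clip(rng.normal(m["sbp"], s["sbp"], n), 85, 200).round(0)
    pat["dbp"] = np.clip(rng.normal(m["dbp"], s["dbp"], n), 45, 130).round(0)
    pat["map"] = ((pat["sbp"] + 2 * pat["dbp"]) / 3).round(1)
    pat["hemoglobin"] = np.clip(rng.normal(m["hemoglobin"], s["hemoglobin"], n), 6, 19).round(1)
    for flag in ("diabetes", "hypertension", "isd", "rasb"):
        pat[flag] = (rng.random(n) < spec.flag_rates[flag]).astype(int)
    for col, dist in DEFAULT_OXFORD.items():
        vals = np.array(list(dist.keys()))
        probs = np.array(list(dist.values()), dtype=float)
        pat[col] = rng.choice(vals, size=n, p=probs / probs.sum())

    gs_ratio = slide_features["GS_count_ratio"].to_numpy(dtype=float)
    pat["gs_count_ratio"] = gs_ratio
    logit = spec.event_base_logodds + spec.beta_gs_ratio * gs_ratio
    p_event = expit(logit)
    pat["true_event_prob"] = p_event
    event = rng.random(n) < p_event
    pat["event_true"] = event.astype(int)

    lo, hi = spec.followup_months_range
    fu_end = rng.uniform(lo, hi, n)
    pat["followup_end_months"] = fu_end.round(1)

    fu_rows = []
    for i in range(n):
        base = float(pat.loc[i, "baseline_egfr"])
        end = float(fu_end[i])
        times = np.arange(6.0, end + 1e-9, 6.0)
        if len(times) == 0 or times[-1] < end - 1e-9:
            times = np.append(times, end)
        if event[i]:
            t_evt = rng.uniform(6.0, end)
            # linear decline crossing 45% of baseline at t_evt, then flat low
            frac = np.where(
                times <= t_evt, 1.0 - 0.55 * times / t_evt, 0.45 - 0.02 * (times - t_evt)
            )
            egfr = np.maximum(base * frac, 6.0)
        else:
            # mild decline, bounded strictly above both event thresholds
            slope = rng.uniform(0.0, 0.25)
            egfr = base * (1.0 - slope * times / max(end, 1.0))
            egfr += rng.normal(0.0, 1.5, size=len(times))
            egfr = np.maximum(egfr, max(0.56 * base, 16.0))
        krt = egfr < 10.0
        for t, e, k in zip(times, egfr, krt):
            fu_rows.append(
                {
                    "patient_id": pat.loc[i, "patient_id"],
                    "months": round(float(t), 2),
                    "egfr": round(float(e), 2),
                    "krt_flag": bool(k),
                }
            )
    followup = pd.DataFrame(fu_rows, columns=["patient_id", "months", "egfr", "krt_flag"])
    return CohortTable(patients=pat, followup=followup)


def bayes_auc(event_probs: np.ndarray) -> float:
    """Closed-form expected AUC of the Bayes-optimal score.

    Given the sampled per-subject event probabilities ``p_i`` (which are a
    monotone function of the generative risk score), the expected AUC of
    any score monotone in ``p`` is

        sum_{i != j} p_i (1 - p_j) [ 1(p_i > p_j) + 1/2 1(p_i = p_j) ]
        / sum_{i != j} p_i (1 - p_j).

    This upper-bounds (in expectation) the test AUC of any fitted model.
    """
    p = np.asarray(event_probs, dtype=float)
    P = p[:, None]
    Q = p[None, :]
    w = P * (1 - Q)
    num = (w * (P > Q)).sum() + 0.5 * (w * (P == Q)).sum()
    den = w.sum()
    # remove the i == j diagonal (ties with weight p_i (1 - p_i))
    diag = (p * (1 - p)).sum()
    num -= 0.5 * diag
    den -= diag
    if den <= 0:
        raise ValueError("degenerate probabilities: no discordant mass")
    return float(num / den)
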