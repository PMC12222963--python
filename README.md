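# glomkit

Quantitative glomerular morphology for IgA nephropathy (IgAN) biopsy
slides: the computational pipeline that surrounds a multi-class
glomerulus segmentation model, for digital-pathology and nephrology
researchers who want lesion-specific morphometry and prognostic
modelling without re-implementing the plumbing.

Kidney biopsies stained with PAS are scanned to whole-slide rasters;
each glomerulus belongs to one of five lesion classes — no lesion (NL),
global sclerosis (GS), segmental sclerosis (SS), crescent (CR),
ischemic change (ISC).  Given per-pixel class probabilities from any
segmentation model, `glomkit` provides:

* **Tiling and stitching** — 512 x 512 sliding windows at 50% overlap,
  empty-patch filtering, class-balancing sampler, test-time
  augmentation, and mean-fused aggregation back to a slide-level
  probability map.
* **Instance separation** — marker-controlled watershed on the distance
  transform splits touching glomeruli into distinct instances.
* **Morphometry** — per-glomerulus area, axis lengths, compactness
  P²/(4πA), eccentricity √(1 − (b/a)²), solidity, roundness 4A/(πa²),
  aggregated per lesion class into a 41-feature slide vector.
* **Evaluation** — object-level average precision under the ≥50%
  ground-truth-coverage true-positive rule, per-class Dice 2|P∩G|/(|P|+|G|),
  count-weighted averages, slide-resampling bootstrap CIs.
* **Prognosis** — binary kidney-outcome labels (eGFR halving, eGFR < 15,
  or kidney replacement therapy), five feature sets (image, clinical,
  their union, IIgAN-PT variables, and image+IIgAN-PT), three classifier
  families (XGBoost, random forest, logistic regression), AUC with
  DeLong confidence intervals and DeLong tests between models.
* **Synthetic data** — a seeded generator producing slides, masks,
  ground-truth manifests and clinical cohorts with the statistical
  structure above, so the whole pipeline runs and is tested without any
  real data.

The segmentation network itself is *not* included: predictors plug in
through a one-function contract, and two reference predictors (a
ground-truth oracle with controllable corruption, and a colour-threshold
baseline) ship with the package.

## Worked example

```python
from glomkit.synthetic import SyntheticSlideSpec, generate_slide, tissue_ellipse
from glomkit.instances import separate_instances, count_instances_by_class
from glomkit.morphometry import aggregate_slide

spec = SyntheticSlideSpec(width=512, height=512, n_glomeruli=8,
                          radius_range=(20, 36), overlap_fraction=0.3, seed=11)
raster, mask, manifest = generate_slide(spec)

instances = separate_instances(mask)
print("instances recovered:", len(instances), "of", len(manifest.instances))
print("per-class counts   :", count_instances_by_class(instances))

vec = aggregate_slide(instances, tissue_ellipse(512, 512), mask.mpp, manifest.slide_id)
print("GS count ratio     :", round(vec["GS_count_ratio"], 3))
print("NL mean major axis :", round(vec["NL_mean_major_axis_um"], 1), "um")
print("glomeruli / tissue :", round(vec["glom_area_over_tissue"], 3))
```

prints

```
instances recovered: 8 of 8
per-class counts   : [2 5 1 0 0]
GS count ratio     : 0.625
NL mean major axis : 63.3 um
glomeruli / tissue : 0.12
```

The slide contained eight glomeruli, some deliberately touching;
watershed separation recovered all eight as distinct instances.  Five
are globally sclerotic, so the GS count ratio — the strongest prognostic
image feature — is 0.625; glomeruli occupy 12% of the tissue core.

## Command line

A thin CLI chains the stages on synthetic or on-disk data:

```bash
glomkit all --seed 5 --out runs/demo \
    --set slides.n_slides=12 --set slides.width=512 --set slides.height=512
```

writes slides/masks (PNG), manifests and cohorts (CSV), stitched
predictions, separated instances, the 41-feature table, an evaluation
report mirroring the per-class AP/DSC table layout, and the prognostic
model grid.  Identical config + seed reproduces every CSV byte for
byte; `run_manifest.json` records the config hash, seed and version.

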