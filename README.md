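# temquant

Quantification of neuron–glia ultrastructure in transmission electron
micrographs: morphometry of the contact between sensory neuron somata and
their satellite glial cell (SGC) sheath, and a two-stage deep-learning
detector for ~50 nm vesicular profiles in SGC cytoplasm, with per-cell
vesicle density and group statistics.

It is written for studies that compare genotypes (e.g. wild-type vs *Fmr1*
knockout) on two phenotypes: (1) pathological micron-scale gaps along the
neuron–SGC contact surface, where the normal separation is only tens of
nanometres, and (2) elevated vesicle density in the glial cytoplasm.
Because suitable raw micrographs are rarely shareable, the package includes
a synthetic-scene generator with complete ground truth, so every stage of
the pipeline is testable end to end without any data download.

## What it computes

**Morphometry** (per neuron, from traced membrane contours):

- *Gap profile*: distances d(s) from points sampled uniformly by arc length
  on the neuron membrane to the nearest point of the SGC inner membrane.
- *Three largest gaps* at distinct locations (local maxima separated by a
  configurable angular exclusion, default 20°), a binary **gap flag**
  (1 iff max gap ≥ threshold, default 0.25 µm), **Feret diameter** (maximum
  caliper), **area** (shoelace), and **circularity** = major/minor axis
  ratio of the second-moment ellipse (1 = circle, > 1 = elliptic).

**Vesicle detection** (two stages, both small CNNs trained here):

1. a patch classifier (vesicle vs background) scanned across the image;
   Grad-CAM maps of positive patches are stitched into an image-level
   localization map whose connected regions become ROIs;
2. a fully-convolutional segmenter labels vesicle pixels inside each ROI;
   connected components become vesicle instances with equivalent diameter
   2·√(A/π)·(nm/px).

**Density and statistics** (per cell / per group): DBSCAN clustering of
centroids, convex-hull area of the vesicle set (the smallest convex set
containing all vesicles), density = count / hull area, a "detectable
vesicles" flag (count ≥ 3), then a 2×2 Pearson chi-square test on the
detectable proportion and a two-sample Kolmogorov–Smirnov test on the
density distributions, with group summaries as mean ± SEM.

## Worked example

Morphometry of one synthetic knockout-like scene:

```python
from temquant import synthesize_scene, ko_like_params
from temquant.morphometry import Contour, measure_neuron

params = ko_like_params(seed=2)                  # 2–4 gap sectors, 0.5–2 µm
_, truth = synthesize_scene(params, render=False)
rec = measure_neuron(Contour(truth.neuron_contour, truth.nm_per_px),
                     Contour(truth.sgc_inner_contour, truth.nm_per_px),
                     neuron_id="ko1")
print(rec)
```

prints

```
MorphometryRecord(neuron_id='ko1', gap_flag=1,
    gap_distances_um=(1.671, 1.436, 1.195),
    diameter_um=20.049004125768757, area_um2=251.4250639343809,
    circularity=1.2542788342448787, gap_threshold_um=0.25,
    distinct_gaps=True)
```

The three reported gaps are the depths of three of the four injected
sectors (deepest 1.641 µm plus the 30 nm baseline), the soma measures
~20 µm across with a mildly elliptic outline — and the neuron is flagged
as having obvious distant glia.

A group contrast on detectable-vesicle counts:

```python
from temquant.density_stats import chi_square_2x2
c = chi_square_2x2([[20, 5], [5, 20]])
print(c.statistic, c.p_value)      # 18.0 2.2090496998585475e-05
```

The full pipeline (synthesis → training → detection → morphometry →
statistics) runs from one config:

```sh
temquant pipeline --out runs/demo --seed 1
```

and writes `morpho.csv`, `detections.json`, `profiles.csv`,
`comparisons.csv`, `summary.json` plus a manifest with seeds and output
hashes; a rerun with the same config and seed reproduces all CSV/JSON
outputs bit-for-bit.

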