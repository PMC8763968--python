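# Methods

## Synthetic scene model

No public micrographs accompany the kind of study this package targets, so
all validation runs on synthetic scenes with exact ground truth.  Two
generators are provided.

**Whole neuron–SGC units** (`synthesize_scene`).  The soma boundary is an
ellipse (default semi-axes 10 × 8 µm, in the range of sensory neuron somata)
modulated by a smooth low-order radial wobble (default ±2%, Fourier modes
2–4) so it is only roughly elliptic.  The SGC inner membrane is the neuron
contour offset along the neuron's *outward normal* by

    g(θ) = g₀ + Σᵢ dᵢ · cos²(π·Δθᵢ / wᵢ)   within sector i, else g₀,

where g₀ is the baseline gap (default 30 nm — the normal separation is a
few tens of nm) and each sector i has angular width wᵢ and depth dᵢ.  The
normal offset is the load-bearing choice: at a sector peak the gap gradient
along the contour vanishes and the offset is perpendicular to the membrane,
so the nearest-point distance from the neuron to the SGC membrane equals
g₀ + dᵢ *exactly*; injected depths are therefore recoverable to sub-pixel
precision (measured error ≈ 0.01 px at 2,048 contour vertices).  Sector
widths scale with depth (w ≥ 5·d/r radians) so that the sector floor, not
its side walls, is the nearest membrane — without this, a deep narrow
"well" reports its wall distance and no generator can be recovered
faithfully.  The SGC outer membrane adds the sheath thickness (default
0.5 µm) along the same normals.

**High-resolution cytoplasm fields** (`synthesize_vesicle_field`).  Vesicle
counting in practice images small cytoplasm regions at high magnification,
not whole somata; fields default to 256 px = 1.28 µm squares at 5 nm/px.
Vesicle profiles are a homogeneous Poisson process: count ~
Poisson(density × area), positions uniform (inset by one vesicle radius),
diameters normal with mean 50 nm, SD 5 nm, truncated at ±3 SD (the
literature gives only "~50 nm").  Each vesicle renders as a dark membrane
ring with a lighter lumen.

Rendering adds region grey levels (extracellular, neuron, cytoplasm,
membranes), Gaussian-smoothed cytoplasm texture, a low-frequency
illumination gradient, and additive Gaussian noise (default SD 8 of 255),
then quantizes to 8-bit.  These constants are stand-ins: no raw-image
properties (bit depth, magnification, noise spectrum) were available to
match.  Identical parameters and seed give bit-identical images and truth.

**Presets.**  "WT-like": no gap sectors, vesicle density 20/µm².
"KO-like": 2–4 sectors with depths drawn in 0.5–2 µm, density 40/µm²
(2× WT).  The 2× ratio mirrors the qualitative direction of the phenotype;
the absolute densities are this package's choice, made on two grounds:
~50 nm profiles at 20–40/µm² cover 4–8% of the cytoplasm area (a visually
dense but realistic secretory cytoplasm), and a convex-hull density
estimate needs tens of points per field to mean anything (see *Density*
below).

## Morphometry

Inputs are polygon contours (traced or ground truth).  The gap profile
samples 720 points (0.5° steps) uniformly by arc length on the neuron
contour and takes each point's distance to the SGC-inner polyline.  The
three reported gaps are the three largest local maxima of the circular
profile separated by at least 20° (greedy selection in descending order);
if fewer than three separated maxima exist the remainder is padded from
the global order and the record is flagged.  The exclusion implements
"three measurements at the largest visible gaps" as distinct locations.
A neuron is flagged 1 ("obvious distant glia") iff its largest gap reaches
the threshold, default 0.25 µm — an operational cutoff for a criterion
that is inherently qualitative; the threshold is part of every output
record.  The boundary case (gap exactly at threshold) counts as flagged.

Diameter is the maximum caliper (Feret) distance, computed on convex-hull
vertices.  Area is the shoelace formula on the polygon, orientation
independent.  Circularity is the square root of the ratio of the principal
eigenvalues of the region's central second-moment tensor, evaluated by
exact polygon integrals (Green's theorem) — equivalently, the axis ratio
of the best-fit ellipse.  This is rotation-stable and recovers the exact
axis ratio for analytic ellipses; note it reports 1.0 for any shape with
equal principal moments (e.g. a square).  A min/max-caliper definition
would behave differently there; the second-moment definition was chosen
because it is the standard "fit ellipse" axis ratio of image-analysis
practice.

## Two-stage vesicle detector

Both stages are small CNNs implemented in `temquant._minicnn`, a
self-contained float32 numpy stack (im2col convolution, ReLU, 2×2 max
pool, nearest-neighbour upsampling, global average pooling, dense layers,
softmax cross-entropy, Adam) with hand-derived backpropagation — verified
against finite differences in the test suite.  This keeps the pipeline
free of any deep-learning framework and makes Grad-CAM a first-class
operation on the same computational graph.

Training patches are 32×32; positives place a ground-truth vesicle
anywhere within ±10 px of the patch centre (not only at the middle) — the
scanned detector must recognise vesicles far off a tile's centre, and
without this jitter, vesicles straddling tile borders are missed at coarse
scan strides.  Negatives come from windows containing no vesicle.

**Stage 1 — patch classifier.**  32×32 patches (160 nm field at 5 nm/px,
about three vesicle diameters), architecture conv8–pool–conv16–pool–conv32
–GAP–dense(2).  Training: mini-batch 25, at most 500 epochs, Adam 1e-3,
augmentation capped at ±10% isotropic resizing plus horizontal reflection,
20% stratified validation split.  Early stopping when validation accuracy
has not improved by ≥ 1e-4 for 20 epochs; the best-epoch weights are kept.

**Stage 2 — pixel segmenter.**  Fully convolutional encoder–decoder
(conv8, pool, conv16, conv16, conv8, 2× upsample, conv(2) at full
resolution); mini-batch 100, at most 1,000 epochs, augmentation limited to
±5% resizing, reflection and a ±2 px pixel shift (small objects tolerate
little augmentation before labels and images decohere).  Validation
accuracy is per-pixel.  An alternative blob-classifier reading of stage 2
is not provided; segmentation subsumes it here because instance masks are
needed for diameters anyway.

**Grad-CAM.**  For class c, channel weights are the spatial mean of
∂(logit c)/∂A over the last convolutional feature maps A; the map is
ReLU(Σ wₖAₖ), bilinearly upsampled to patch size and max-normalized to
[0, 1] (an all-zero map is valid when no class evidence exists).  The test
suite checks the closed form on a linear conv–GAP–dense network and, on
trained models, that mean map mass inside true vesicle masks exceeds the
mass outside.

**Scan → ROIs → instances.**  The image is tiled with overlapping patches
(stride = patch/2 by default); tiles whose vesicle probability reaches the
ROI threshold (default 0.5) contribute their Grad-CAM maps to a stitched
map, averaged over contributing tiles; connected regions above the
threshold, padded by 8 px, become ROIs.  Stage 2 labels pixels inside each
ROI; components ≥ 15 px become instances (suppressing sub-vesicle
fragments; a 50 nm disk is ~78 px); instances from overlapping ROIs are
deduplicated by centroid distance < 5 px (one vesicle radius).  Equivalent
diameter is 2·√(area/π)·(nm/px).

On the default synthetic conditions this recovers counts with regression
slope ≈ 0.97 against truth across densities 1–5/µm² and mean diameter
≈ 51.6 nm.

## Density and group statistics

Vesicle centroids are clustered with DBSCAN (eps 200 nm, minPts 3 —
config-exposed; no algorithm or parameters are canonical for this step).
The density denominator is the convex-hull area of **all** detected
vesicles ("the smallest convex set that contains all the vesicles");
a largest-cluster mode is selectable, in which case the numerator is that
cluster's own count.  Hulls need ≥ 3 non-collinear points; degenerate
hulls mark the density undefined rather than raising.  A cell has
"detectable vesicles" iff count ≥ 3 (the minimum for a hull) — the
criterion is undefined in the source protocol and is config-exposed.

The convex hull of n uniform points underestimates the occupied region by
a factor ≈ 1 − v/n (v = hull vertices; ≈ (8/3)·ln n for a square field),
so raw hull densities are biased high at small n — severely below ~20
points, ~15% at n ≈ 80.  This is why the preset densities put tens of
vesicles in a field, and why an optional Ripley–Rasson-corrected area
estimator (hull area / (1 − v/n)) is provided; the default reports the
raw hull density for protocol fidelity.  Group *comparisons* are
unaffected in direction because both groups share the bias.

Comparisons: Pearson chi-square on the 2×2 detectable-by-group table
(df = 1, no Yates correction by default; available by flag) and the
two-sample KS statistic D = sup|ECDF₁ − ECDF₂| with the exact null
distribution when n₁·n₂ ≤ 10⁴ and the asymptotic Kolmogorov distribution
otherwise (both via scipy.stats; the tests cross-check the exact p against
full permutation enumeration).  Summaries report mean ± SEM (SD/√n,
ddof = 1; a single-observation group reports SEM 0 and is flagged).  No
multiple-testing correction is applied (one test per question).  Under the
presets (20 cells/group, 2× density) the KS test rejects at p < 0.05 in
≥ 90% of 50 replicate simulated experiments.

## Reproducibility and problem sizes

One global seed drives scene synthesis, dataset splits, augmentation and
weight initialization through independent `numpy` Generator streams; all
pipeline CSV/JSON outputs are bit-for-bit reproducible under a fixed seed
(model training is reproducible up to the BLAS reduction order of the host,
recorded per run in the manifest).  Default problem sizes — 2,000-patch
training sets, 40 training fields of 512 px, 20 scenes or fields per
condition in recovery experiments, 50 replicates in power checks — are the
package's desk-scale choices; they keep the full suite in the tens of
minutes on a single CPU core while leaving every estimate comfortably
inside its tolerance.

## What the synthetic benchmarks do and do not show

The generator reproduces the geometry and first-order photometry of the
target micrographs, not their physics: no electron-optical point-spread,
no section-thickness effects, no organelles other than vesicles, no
membrane-adjacent clutter, and vesicle contrast is idealized.  Passing
recovery tests therefore demonstrates that the pipeline is correct and
self-consistent (it measures what the scene contains), not that the
trained networks would transfer to real TEM data — on real data the
networks must be retrained on hand-labeled patches, and the morphometry
operates on hand-traced contours exactly as it does on ground truth here.
The two headline validation accuracies are scaled-down analogues computed
on synthetic patches, at the training regimes stated, not reproductions of
any laboratory dataset.
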