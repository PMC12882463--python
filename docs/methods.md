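# Methods

This note documents the models, procedures and design choices behind
`cuscuta_hsi`, a pipeline for pixel-level discrimination of parasitic
dodder (*Cuscuta* spp.) from host plants in hyperspectral line-scan
imagery, and the synthetic scene generator that stands in for camera
data throughout the test suite.

## Problem setting

Dodders are leafless, winding stem parasites with reduced chlorophyll
and relatively elevated carotenoids. In a VNIR/SWIR hyperspectral cube
every pixel carries a reflectance spectrum, and the task decomposes
into: (1) converting raw counts to reflectance and denoising spectra,
(2) separating plant pixels from a dark-cloth background, (3) labelling
plant pixels semi-supervised (one species per cropped image), (4)
splitting pixels into train/validation/test without spatial leakage,
(5) training pixel classifiers for the binary host/parasite and the
five-class species task, and (6) shrinking the spectral feature set to
the bands that matter.

## Cube model and geometry

A cube is `(lines, samples, bands)` float64 in memory, float32 on disk
in an ENVI-style header+binary pair (BSQ/BIL/BIP all accepted and
normalized on read). Coordinates are 0-based with half-open ranges.
Bands are always addressed by 0-based index into a calibration table of
center wavelengths; the shipped VNIR (186 bands, 407–995 nm) and SWIR
(288 bands, 950–2518 nm) profiles are **synthetic stand-ins**: monotone
piecewise-linear tables anchored exactly at the published index →
wavelength pairs (VNIR band 64 → 620.29 nm, band 121 → 827.09 nm; SWIR
band 27 → 1098.07 nm, band 136 → 1655.20 nm), because the true
per-band tables are not linearly spaced and are not computable from the
range endpoints. Wavelengths are always looked up from the profile,
never derived analytically.

Line-scan geometry: the along-track pixel footprint is belt speed ×
exposure (102 mm/s × 4.8 ms = 0.4896 ≈ 0.49 mm VNIR; × 5.9 ms =
0.6018 ≈ 0.6 mm SWIR); cross-track is field of view / spatial pixels.
The SWIR cross-track figure cannot be reconciled with a shared 300 mm
field of view, so the helper is provided without asserting a reference
value for SWIR.

## Synthetic scenes

The generator emulates the features the pipeline depends on, not leaf
optics. Each class endmember is

```
R(λ) = baseline
       − chl_depth   · G(λ; 662 nm, chl_width)       (chlorophyll a)
       − car_depth   · G(λ; 470 nm, car_width)        (carotenoids, 400–515 nm)
       − w1450 · G(λ; 1450 nm, ·) − w1950 · G(λ; 1950 nm, ·)   (water)
       + red_edge_height · sigmoid((λ − red_edge_center)/red_edge_width)
```

clipped to [0, 1], with Gaussians `G` and a logistic red edge. These
parametric shapes are the simplest forms reproducing the qualitative
mean-reflectance morphology of green vegetation: strong visible
absorption, a steep rise between ~680 and 750 nm, and SWIR water wells.
The five default classes (host plus *C. campestris*, *C. platyloba*,
*C. monogyna*, *C. reflexa*) differ chiefly in red-edge position
(702–733 nm) and pigment depths, arranged so that the two subgenus
pairs (*campestris*/*platyloba*, *monogyna*/*reflexa*) are spectrally
adjacent, mirroring the within-subgenus similarity of the real species.
All five defaults have noise-free NDVI (bands 121/64) above 0.81, the
cloth background (flat 0.05 baseline) has NDVI ≈ 0; these margins are
what makes the 0.75 threshold meaningful on the phantom.

Spatially, stems are sinusoidal winding paths of configurable width
(default 2 px, 3 stems per class on a 96×96 scene), one species per
scene to mirror per-species cropping. Infection scenes overlay parasite
stems on host stems; contact pixels keep the parasite label, are
flagged, and receive the convex mixture `0.5·host + 0.5·parasite` — a
modelling choice, since only a "shifted spectrum" at infection sites is
reported, with no mixing model. The forward model finishes with a
multiplicative illumination ramp across the scan (default ±5%) and
per-band additive Gaussian noise (default SD 0.01 reflectance). One
seeded generator drives each scene; a fixed seed reproduces the cube
bit-exactly.

What the phantom does *not* model: mixed border pixels (other than
infection sites), specular highlights, shadowing, 3-D architecture,
radiometric sensor effects, spectral autocorrelation of noise. Passing
tests therefore demonstrate that the pipeline's machinery is correct
and recovers known structure under realistic noise — not that the real
images' accuracies are reproduced; those depend on data that is not
deposited.

A second generator, `planted_band_dataset`, produces featureless
Gaussian spectra (60 bands, SD 0.15 around 0.5) where exactly five
planted bands carry class offsets (±0.15 by a fixed sign pattern over
four classes). The shift is calibrated so no single band solves the
task and dropping any planted band measurably lowers macro F1 —
the regime a band selector must operate in to be worth testing.

## Preprocessing

Order is fixed: flat-field → smoothing → (segmentation) → scaling.

* **Flat field**: `(raw − dark)/(white − dark)` per spatial sample and
  band, the white/dark cubes averaged along-track; entries with
  `white ≤ dark` are undefined, set to 0 and counted in a warning.
* **Savitzky–Golay**: window 13, degree 3, applied along the spectral
  axis only (scipy's `savgol_filter`, `mode="interp"`): spectrum ends
  are the evaluation of the least-squares polynomial fitted to the
  terminal window, so no reflectance is invented beyond the sensor
  range. The filter is validated against an independent sliding-window
  polynomial fit to 1e-10.
* **Min–max scaling** is fitted on the training split only and
  persisted as plain text. Constant bands map to 0 (logged); data
  outside the training range is *not* clipped, so out-of-range inputs
  stay visible downstream. The scaler records the calibration profile
  it was fitted under and refuses application across profiles, keeping
  it specific to one experimental setup.

Segmentation runs on smoothed, *un-normalized* reflectance: the
normalized-difference indices are invariant to per-pixel illumination
gain but not to a per-band affine map, so scaling before segmentation
would distort the indices. Only classifier inputs are scaled.

## Segmentation

NDVI `(NIR−red)/(NIR+red)` with bands 121/64 and a strict threshold of
0.75 is the VNIR method; boundary pixels count as background
(conservative reading of a lower cut). For SWIR, NDWI with bands
27/136 followed by 1-D k-means, labelling the cluster with the highest
mean NDWI as plant — clustering-based methods need an automatic
plant-cluster rule in an unattended pipeline, and water-rich tissue has
the highest NDWI. `0/0` pixels get index 0 by convention.

The comparison methods are implemented in full: Euclidean k-means
(Lloyd iterations from k-means++ seeding, 10 seeded restarts keeping
the best within-cluster sum of squares, per-iteration WCSS trace
exposed), X-means (recursive 2-way centroid splits accepted when the
spherical-Gaussian BIC of the two-component model beats the parent,
bounded by the user's k range), and LVQ1 (prototypes moved toward
same-class samples and away from others under a linearly decaying
learning rate; supervision comes from a small seeded label set, which
plain plant/background use requires).

## Splitting

Pixels from one image — or from spatially linked tiles of one image —
never span subsets. Tiles are grid cells of configurable size; "close
spatial proximity" is 8-neighborhood adjacency within an image, merged
by union-find when proximity linking is on. Allocation is greedy and
reproducible: per class, groups are shuffled under the seed, ordered
largest first, and each goes to the subset furthest below its 60/20/20
pixel target, after every subset has one group of the class. A class
whose group count is below the number of subsets is a stratification
error naming the class. Exact per-class fractions are not enforceable
at group granularity and are only reported; with 200 groups the
achieved fractions land within 2 points of target.

## Classification

Macro-averaged F1 is the selection objective everywhere: parasite
pixels outnumber host roughly 2:1 and plain accuracy rewards majority
classes. Class order is fixed alphabetically for reproducible confusion
matrices; evaluation reports are checked for internal consistency
(accuracy = trace/total, macro F1 = unweighted mean of per-class F1)
against a brute-force tally in the tests.

* **Random Forest** (scikit-learn): tuned defaults 313 trees/depth 50
  (binary) and 176/29 (multiclass), square-root features per split,
  minimum leaf 1, no bootstrap. Depth ~20–25 is known to suffice; a
  documented shallow profile exposes that alternative.
* **Neural network**: two hidden layers, 384/128 with dropout 0.0/0.4
  and learning rate 1.97e-4 (binary); 384/256, 0.1/0.4, 2.1e-4
  (multiclass). Activation (ReLU), optimizer (Adam), epochs (100),
  batch size (1024) and early stopping (patience 10 on validation
  macro F1, best weights restored) are package decisions — the tuned
  sources state only widths, dropout and learning rate. The network is
  implemented directly on numpy so dropout placement and the macro-F1
  stopping rule follow the stated architecture exactly and runs are
  single-threaded deterministic under one seed.
* **Tuning** is seeded random search (budget default 50 trials) over a
  user-supplied space, argmax validation macro F1, full trial log kept.
* **Binary task** pools all four parasite species into one class
  without rebalancing.
* **Infection retraining**: infection-site pixels appended to the
  training table (provenance retained) reduce misclassification at
  host/parasite contact sites; the paired evaluation in the tests
  fixes seeds and holds out half the infection pixels.

Classification maps paint masked pixels with the predicted class code
(0 reserved for background) and render to false color with per-class
tallies.

## Band selection

Both reducers read the validation split only; the test split is wrapped
in a guard object that raises on any access during selection and is
read exactly once, by the final retrain-and-evaluate step.

* **LIME + elbow**: per explained pixel, spectra are perturbed with
  per-band Gaussian noise (scaled by the band SD of the reference
  table), the classifier's probability for the pixel's predicted class
  is fitted by a ridge surrogate with RBF-kernel sample weights
  (width 0.75·√bands), and absolute surrogate weights are averaged over
  pixels (defaults: 200 pixels × 1000 perturbations). The "elbow" is
  operationalized as *smallest k within tolerance*: retrain on each
  top-k prefix and return the smallest k whose validation macro F1 is
  within 0.01 of the full-feature model — no curvature criterion is
  given by the source method, and this rule is monotone and auditable.
* **Genetic algorithm**: individuals are band-inclusion bit patterns;
  fitness is validation macro F1 of a model trained on the subset.
  Population 30, per-bit mutation 0.05, 2 elites, uniform crossover,
  fitness-proportional parent selection — conventional defaults, all
  configurable and logged. The stopping target is the full-feature
  validation score computed *before* the search; the generation cap is
  50. Empty individuals are repaired by activating one random band;
  fitness is cached by bit pattern so duplicates cost nothing. With at
  least one elite the best-fitness trace is non-decreasing.

## Pipeline and determinism

`run_pipeline` executes simulate → preprocess → segment → split →
normalize → train → select-bands → predict from one YAML-serializable
configuration. A single global seed derives per-stage seeds by hashing
the stage name, so stages rerun in isolation reproduce themselves; two
identical runs produce identical metrics (exact for the deterministic
stages, and in practice bit-identical for the model metrics under
single-threaded execution). Every stage persists its outputs and the
manifest records parameters, seeds, outputs and timings; a failing
stage aborts with its name, leaving completed intermediates on disk.

## Problem sizes used in validation

The shipped validation suite uses scaled synthetic conditions chosen to
exercise each property well inside a desktop budget: 20 noisy 64×64
scenes for segmentation recovery; 100 seeded splits of 200 groups for
split integrity; a ~50k-pixel five-class dataset (96×96 scenes, eight
stems each) for classifier recovery; 1500/700-pixel planted-band tables
for the selectors with a 30-tree fitness forest; and a reduced
end-to-end configuration for the determinism check. These sizes are
package choices, documented here so they can be scaled up freely.

## Known limitations

* The synthetic endmembers are calibrated to qualitative spectral
  statements, not digitized reflectance curves; absolute reflectance
  levels (e.g. the near-saturated SWIR plateau of the phantom's
  vegetation) are not physical.
* Real-image headline numbers (accuracies, confusion matrices,
  per-class pixel counts) are out of scope: the imagery is not public.
* No morphological post-processing of masks, no spatial-context
  classifiers, no scatter-correction alternatives (SNV/MSC).
* X-means uses a spherical-Gaussian BIC; elongated clusters may
  over-split.
* The LIME surrogate perturbs bands independently; strongly correlated
  neighboring bands share credit and their individual ranks are less
  stable than their group's.
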