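# Methods

## Problem and pipeline

Proximal dental caries appear on bitewing radiographs as radiolucent
(locally darker) regions inside enamel and dentin.  `carieseg` implements a
two-network detection pipeline:

1. **U-CS**, a binary U-Net, produces a per-pixel caries probability map.
2. **U-SS**, a 7-class U-Net, segments anatomical structures (background,
   enamel, dentin, pulp, metal restoration, tooth-colored restoration,
   gutta-percha).
3. The caries map is thresholded (strictly greater than the operating
   threshold, default 0.55), connected components ("blobs") are extracted,
   and every blob that shares no pixel with the predicted enamel-or-dentin
   support is eliminated as a false detection — caries cannot exist outside
   mineralized tooth tissue.

Detections are scored at the component level: a blob is a hit when it covers
at least a fraction θ (default 0.1) of a ground-truth lesion.  TP counts
lesions with at least one qualifying blob, FP blobs qualifying for none, FN
lesions left uncovered.  Matching is many-to-many: no one-to-one assignment
is performed, since a single blob may legitimately span two adjacent lesions
and annotators may split what the detector merges.  The overlap denominator
is the ground-truth lesion area (a recall-oriented reading of the hit
criterion); intersection-over-union is available via
`match_components(..., denominator="iou")`.

Cross-validation results are pooled by summing TP/FP/FN over folds and
computing precision/recall/F1 once on the pooled counts, never by averaging
per-fold percentages — the two differ whenever folds carry unequal lesion
counts (this is asserted by a counterexample test).

## Network and training

Both segmenters share one architecture family: a five-level U-Net, two 3×3
convolutions + ReLU per level, 2×2 max pooling down, 2×2 transposed
convolution up with skip concatenation, a final 1×1 projection, softmax over
classes.  Convolutions are zero-padded so the probability map covers the
full input frame; the original valid-convolution U-Net crops instead, and
this full-frame choice is a deliberate simplification that keeps masks and
maps on one grid.

The reference configuration takes 572×572 inputs with base width 64 and Adam
at learning rate 1e-5.  The **desk-scale profile** used by the test suite
and the acceptance script is 96×96 inputs, base width 8, Adam at 1e-3, ≤30
epochs, batch size 4.  At this scale 1e-5 cannot descend meaningfully within
tens of epochs, so the profile raises the rate; the full-scale default keeps
1e-5.  The conv-net core is a compact CPU implementation (numpy, im2col +
BLAS); a forward+backward pass on one 96×96 image costs ≈65 ms on one core,
so a full training run is minutes, not hours.

**Epoch selection.**  After every epoch the mean per-pixel misclassification
rate on the (never augmented) validation set is recorded; the returned model
carries the parameters of the epoch minimizing it.

**Penalty loss.**  Images whose ground-truth caries mask is empty contribute
an extra term λ · mean(p_caries) — λ times the mean predicted caries
probability over all pixels — added to the pixelwise cross-entropy.  λ = 0
recovers plain cross-entropy; the default is λ = 1.  This is the simplest
differentiable way to charge predicted caries on caries-free radiographs and
is what makes a caries-free training subset informative for a detector.  On
caries-free inputs the loss is non-decreasing in λ for fixed predictions
(property-tested).  No other class reweighting is applied.

**Curriculum.**  `train_curriculum` trains U-CS three times on accumulating
subsets — structures+caries (`d_a`), +caries-only (`d_b`), +caries-free
(`d_c`) — mirroring how annotation cost shapes real archives.  U-SS trains
on `d_a` alone, the only subset with structure labels.

**Augmentation.**  The joint pass samples one geometric transform (flips,
rotation, anisotropic width scaling, isotropic zoom, coarse-lattice elastic
deformation) and applies it identically to image and masks — bilinear for
the image, nearest-neighbor for masks so labels never blend — plus a
multiplicative intensity jitter on the image only.  Width scaling is
horizontal-only, deliberately distinct from isotropic zoom.  The mask-only
pass (random disk dilation + elastic warp of the caries mask) emulates
annotator boundary inconsistency.  Magnitudes are package choices (the
defaults are mild: ±8% gain, ±6° rotation, ±6% scales, ≈0.7 px coarse
elastic std) — no published values exist for them.  Augmentation is applied
to training folds only.

## Threshold calibration

`sweep_threshold` evaluates all 99 candidates 0.01 … 0.99 (step 0.01) by
running the full binarize → extract → refine → component-F1(θ=0.1) chain on
validation images, pooling counts across images, and selecting the
F1-maximizing candidate; ties resolve to the lowest threshold (sensitivity
preference).  The agreement statistic is the pipeline's own evaluation
metric, a package decision.  Note the threshold test is strict (`>`), so a
candidate exactly equal to a noise plateau already excludes it; the selected
value on the two-plateau construction is the lowest grid point at or above
the noise level, which an independent brute-force argmax confirms.  The
default operating point 0.55 is a value calibrated this way on clinical
data; any particular selection is a property of the dataset it was swept
on, and the package reproduces the procedure, not a fixed value.

## Phantoms

The generator renders a row of posterior crowns as layered superellipses:
enamel shell, dentin body, pulp core, over soft-tissue background, with mean
intensities ordered enamel (≈3350) > dentin (≈2400) > pulp (≈1250) >
background (≈550) on the 12-bit scale.  Optional occlusal restorations
(metal ≈4000 / tooth-colored ≈2850) replace crown tissue, and gutta-percha
strips (≈3800) fill pulp canals.  Lesions are discs seeded at proximal
surface points, intersected with that tooth's enamel∪dentin and reduced to
the connected component at the entry point; they darken the tissue
multiplicatively (factor ≈0.55) before a Gaussian PSF blur (σ 0.7 px) and
additive Gaussian noise (σ 60 DN) are applied.  Lesion depth is controlled
along the inward ray: the achieved penetration is re-measured on the pixel
grid as (reach − enamel thickness)/dentin thickness and mapped to severity
by thirds of the dentin — initial ≤ 1/3, moderate ≤ 2/3, extensive beyond,
boundaries closed on the left class, enamel-only lesions initial.

Dataset sizes default to 149/105/50/50 for the four subsets
(structures+caries, caries-only, caries-free, held-out), scalable down for
tests; the desk-scale experiments use 96×96 two-tooth phantoms with 1–2
lesions per image and severity mix (0.45, 0.35, 0.20).

What the phantoms do **not** model: real anatomical shape variation,
overlapping proximal surfaces, cervical burnout, scatter, device-specific
noise spectra, primary teeth, and caries-type-specific geometry (occlusal /
root / secondary lesions are all rendered as generic radiolucent blobs).
Passing tests therefore demonstrate that the pipeline's machinery —
training, fusion, refinement, calibration, scoring — works as specified, not
that clinical accuracy at any level is achieved on real radiographs.

## Cross-validation folds

`plan_folds` shuffles ids with a seeded generator and deals them round-robin
into six folds (sizes differ by ≤1; with a remainder, the leading folds in
shuffle order take it).  Round r tests fold r, validates on fold (r+1) mod
6, and trains on the remaining four — the 4:1:1 ratio, with every fold
serving as the test fold exactly once across the six rounds.

## Reader study

Readers tag lesion regions on the held-out set before and after seeing the
model's detections.  Scoring is lesion-level with an any-overlap rule: a
consensus lesion counts as detected as soon as any tagged region shares one
pixel with it, regardless of overlap ratio.  Sensitivity = detected/total
lesions; PPV = tagged regions hitting some lesion / total tagged; F1 is the
harmonic mean on the percent scale.  The before-vs-after F1 difference is
assessed by a seeded bootstrap (default 1000 resamples) resampling
*radiographs* — the cluster unit, since lesions within an image are
dependent — with a percentile 95% CI and a two-sided bootstrap p-value.
Synthetic readers for testing are built by deleting a stated fraction of
consensus lesions (30% before, 10% after) and jittering kept outlines
without breaking overlap, so expected sensitivities (70% / 90%) and the
expected F1 change follow in closed form and can be checked against the
bootstrap interval.  GEE-style hypothesis testing of sensitivity/PPV is out
of scope; the per-radiograph count table the analysis produces is what such
a model would consume.

## Numerical choices and degenerate inputs

* Binarization is strict (`probability > threshold`); a pixel exactly at
  the threshold is negative.
* Blob connectivity defaults to 8 (lesions are blobby); 4 is available.
  Blob ordering is by top-left pixel then area, making outputs reproducible.
* Argmax label ties fall to the lowest class index (background).
* Probability maps are renormalized after bilinear upsampling back to
  native resolution so per-pixel probabilities stay on the simplex (±1e-5).
* Metrics with zero denominators are reported absent (`None`), never as 0;
  all-zero count tables raise a dedicated signal; F1 with precision = recall
  = 0 is reported 0 with a `f1_defined = False` flag.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); generation, training, augmentation,
  bootstrap and fold planning are deterministic given (inputs, seed).

## Problem sizes used by the automated runs

The test suite and the acceptance script train at the desk-scale profile:
60 phantoms (48 train / 12 validation) for the main models, 16 held-out
phantoms for detection scoring, 8 caries-free held-outs for false-positive
counting, 36-phantom/10-epoch paired runs (3 seeds) for the λ comparison,
20-image consensus sets for the reader analysis.  These sizes are the
package's own choice of a configuration that demonstrates every mechanism
at interactive runtimes; all of them scale up through the public
configuration objects.

## Known limitations

* The CPU conv-net core is single-threaded apart from BLAS and does not
  target GPU-scale replication of the reference 572×572 configuration.
* The penalty-loss functional form is one reasonable realization of
  "penalize predicted caries on caries-free images"; alternatives (e.g.
  hinge on blob count) were not explored.
* Phantom realism is intentionally minimal (see above); reported phantom
  metrics say nothing quantitative about clinical performance.
* Checkpoints store raw float32 parameters; no quantization or pruning.
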