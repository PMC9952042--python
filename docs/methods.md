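# Methods

## The enhancement model

A screening mammogram contains two broad tissue populations: darker fatty
(non-dense) tissue and brighter fibroglandular (dense) tissue.  Masses most
often overlap the dense tissue, where their contrast margin is smallest, so
a detector benefits from a preprocessing step that suppresses the fatty
background while preserving the ordering and range of the dense/mass
intensities.

The core operation is a **lower-cap linear stretch**.  For an image `I`
normalized to [0, 1]:

1. compute Otsu's threshold `t` of the intensity histogram (restricted to
   the breast mask by default, so air does not dominate the histogram);
2. form the lower cap `L = α · t` with a factor `α ∈ [1.0, 1.9]`;
3. map linearly `[L, U] → [0, U]` with `U = max(I)`, clipping below:
   `out = clip((I − L)/(U − L), 0, 1) · U`.

Pixels at or below the cap become exactly 0; pixels above it keep their rank
order, and the brightest pixel is unchanged (the upper limit of the
adjustment equals the original image's maximum).  The map is monotone, so
dense-region structure survives while the fatty background collapses.

**Factor selection.**  Images are split into the clinical density groups —
non-dense (ACR 1–2) vs dense (ACR 3–4) — and a single factor per group is
chosen as the argmin of the group-mean reference-less quality score over the
grid α = 1.0, 1.1, …, 1.9 (step 0.1, configurable).  Ties break toward the
smaller factor, so outputs are deterministic.  A factor that wipes out all
image structure (degenerate feature statistics) receives an infinite score
and can never win.

The multiplicative reading `L = α·t` and the 0.1 grid step are design
choices; both the algebraic role of the factor and the grid are exposed in
configuration.  Group-mean aggregation is the default; the aggregate is
injectable.

## Reference-less quality scoring

The scorer contract is a callable `image → float`, lower = better.  Two
backends exist:

* **pretrained-model** — canonical BRISQUE maps 36 natural-scene-statistics
  features to a differential mean opinion score with an SVR trained on the
  LIVE database.  Those trained weights are not redistributable, so this
  backend accepts a user-supplied callable wrapping any standard BRISQUE
  implementation.
* **naturalness-fallback** (default) — self-contained proxy.  The 36
  features are the standard BRISQUE set: MSCN coefficients
  `(I − μ)/(σ + C)` (Gaussian 7×7 window, σ = 7/6, C = 1 on the 0–255
  scale) fitted with a generalized Gaussian (moment matching on the
  gamma-ratio lookup over shape 0.2–10), plus asymmetric-GGD fits of the
  four orientation products, at two dyadic scales.  The score is the RMS
  z-score of these features against a pristine corpus — 12 low-noise seeded
  phantoms generated at first use.  A diagonal covariance is used because a
  full 36×36 covariance is rank-deficient for any small corpus.

The fallback is a monotone distortion proxy (verified against additive
noise and blur orderings), **not** canonical BRISQUE: its absolute values
are not comparable with published BRISQUE scores, and score parity with any
published table is out of scope.

## The phantom generator

Real mammogram datasets are access-restricted, so every stage is exercised
on synthetic phantoms that emulate the *structure* of a mammogram, not its
anatomy:

* breast region: half-ellipse anchored at the left (chest-wall) edge;
* air background ≈ 0.02; fatty tissue around mean 0.35; dense tissue around
  mean 0.65, with gentle Gaussian-correlated texture;
* dense region: a smoothed random field thresholded at the in-breast
  quantile, which pins the dense-area fraction to the ACR target
  (1 → 0.10, 2 → 0.30, 3 → 0.55, 4 → 0.80 by default — a convention chosen
  to straddle the non-dense/dense split, not a calibrated population value);
* masses: benign = Gaussian-smoothed disc; malignant = star polygon with
  8–14 spikes of random length, lightly smoothed.  Both are brighter than
  their local background by a contrast δ (default 0.12, deliberately low so
  masses on dense tissue are genuinely low-contrast).  A mass placed "on
  dense" is centered in an eroded core of the dense region (with adaptive
  back-off when the blobs are small), so its local background really is
  dense tissue;
* additive Gaussian noise (σ default 0.02), clipping to [0, 1];
* ground truth: breast/dense/per-mass masks, tight bounding boxes, labels.

Intensity means, texture amplitude and smoothing scales are free parameters
of the generator, chosen once to look mammogram-like at 128×128; they are
not calibrated against any dataset.  Consequently, passing tests demonstrate
the *mechanics and direction* of the method (background suppression, edge
contrast, feature separation) on controlled inputs — they do not certify
performance on clinical images.

Augmentation is purely geometric (rotation 30–300°, Bernoulli(0.5)
horizontal flip, scale 1.0–1.3, identical transforms for image, masks and
boxes, boxes recomputed as tight boxes of the transformed masks); hue,
contrast, brightness and saturation are never altered.

Detector output for the evaluation stage comes from `simulate_detections`:
ground-truth boxes jittered in position/size with confidence correlated
with localization quality, plus occasional misses and low-confidence false
positives.  It is labelled synthetic detector output; no detector is trained
or shipped.

## Measurement suite

* **MSE** `(1/mn)Σ|f−g|²` on normalized intensities; **mean intensity**
  with the 3-channel convention `Σ(R+G+B)/(3n)` so grayscale and replicated
  RGB agree.
* **GLCM** (default 8 levels, offset (0, 1), asymmetric): uniform
  quantization `k = floor(x·levels)` clipped to the top bin; masked pairs
  require both endpoints in-mask.  Contrast, correlation, energy,
  homogeneity from the normalized matrix, with μ/σ from its marginals.
  Homogeneity uses the standard `1 + |i−j|` denominator; the raw `i−j`
  variant (singular on the diagonal) is selectable but never default.
  Correlation of a constant image is reported as NaN with a flag, never a
  silent 0.
* **Edge probe**: 3×3 diagonal kernel `[[1,1,0],[1,0,−1],[0,−1,−1]]`
  applied as zero-padded stride-2 cross-correlation (no kernel flip — the
  deep-learning convention it emulates), 2×2 max pooling, and
  `Δ = max(mass cells) − max(background cells)` with pooled cells assigned
  by their receptive-field centers (any-overlap assignment selectable).
  Responses are reported on the 0–255 scale.  On phantoms, Δ is typically
  *negative* before enhancement (the dense-tissue boundary out-edges the
  mass) and positive after — the probe quantifies exactly the overlap
  problem the enhancement addresses.
* **Detection metrics**: PASCAL-style greedy matching (confidence-descending,
  one-to-one, IoU ≥ 0.5, confidence ≥ 0.5).  Two readings of mAP are always
  reported: the area under the all-point-interpolated PR curve (headline)
  and the literal precision ratio TP/(TP+FP) at the fixed thresholds.
  Detection rate = % images with ≥ 1 true positive; CS accuracy = mean
  confidence of the best true positive per detected image (per-box
  averaging selectable).
* **Segmentation metrics**: pixel confusion counts → per-class IoU, mean
  IoU, accuracy `(TP+TN)/(TP+FP+FN+TN)`.
* **ROC-AUC** via the rank statistic (midrank ties).

## Mass classification

Inside a (detected or ground-truth) box, the mass is segmented with a
classical stand-in for a learned segmenter: Otsu threshold of the crop,
connected component containing the box centre, morphological closing
(radius 2).  A constant crop is resolved against the ring of pixels just
outside the box: brighter than the surroundings → the whole box is mass;
otherwise an error.

Six features per mass: the four GLCM statistics restricted to the mass
pixels, the mean intensity over the mask, and **circularity**
`4π·Area/Perimeter²` (the isoperimetric quotient, 1 for a disc; the
alternative constant placement `4·Area/(π·Perimeter²)` is selectable).
The perimeter is the marching-squares contour length after smoothing the
closed contour with a circular moving average (window 7).  The smoothing
matters: the raw staircased contour overestimates a disc's perimeter by
about 6% (circularity ≈ 0.90) and is not rotation-stable on resampled
masks; the smoothed estimator puts discs at ≈ 1.00 with < 1% rotation
deviation while leaving spiculated shapes clearly below (≈ 0.3–0.7).
Raw-contour and Crofton estimators remain available.

The classifier is a weighted k-NN: k = 10, Euclidean distance on
standardized features, inverse-distance vote (an exact-match neighbor
dominates), stratified 5-fold cross-validation with a recorded seed.
Optional preprocessing: a chi-square filter (features quartile-binned
against the label; keep χ² ≥ 1.0; never returns an empty set — the
top-scoring feature is kept as a fallback) or PCA on standardized features
(sign convention: each component's largest-magnitude loading is positive).

## Numerical conventions

* Boxes are 0-based, half-open `(x, y, w, h)`; all CSV/JSON writers share
  this convention.
* Otsu threshold = bin center of a 256-bin histogram on [0, 1]; ties break
  to the lowest threshold.  Factor ties break to the smallest factor.
* Images are written as 16-bit PNG (lossless on [0, 1] at that depth);
  masks as 8-bit PNG; reports as JSON with values rounded to 10 decimals
  for byte-stable reruns.
* Every random path flows from an explicit integer seed through
  `numpy.random.default_rng`; cohort items get child seeds drawn once from
  the cohort seed.

## Evaluation sizes and limitations

The bundled evaluation (`scripts/acceptance.py`) uses a 60-phantom cohort
(balanced ACR mix, 128×128, one mass each) for the enhancement, detection
and segmentation blocks, and a 200-phantom cohort for the benign/malignant
experiment; these sizes give stable estimates while keeping the whole
script in the tens of seconds on one CPU.

Known limitations: phantoms carry no anatomical texture (vessels, ducts,
pectoral muscle is only emulated for the removal test); the pectoral
heuristic is a corner-anchored stand-in, and callers with real MLO data
should supply a pectoral mask; the fallback quality score is a proxy; the
detector is simulated; and the classification experiment measures
separability of the generator's benign/malignant shape model, not clinical
discrimination.
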