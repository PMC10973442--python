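# Methods

## Model

The classifier is fully unsupervised: texture features are extracted per
image, the feature vectors are clustered into two groups, and only then —
for evaluation — are the clusters aligned to the ground-truth classes.
Labels are never visible to the clustering stage (the pipeline passes the
feature matrix alone).

### Texture features

An input image is converted to gray with the ITU-R 601 luma weights
(0.299 R + 0.587 G + 0.114 B, Pillow's `convert("L")`), resized to a
`resolution × resolution` square with bilinear interpolation, and
uniformly quantized from [0, 255] into `n_levels` bins
(`level = intensity · n_levels // 256`, monotone by construction).

The gray-level co-occurrence matrix counts ordered pixel pairs at
displacement (distance *d*, angle *θ*); the four canonical angles use
offsets (row, col) = (0, d), (−d, d), (−d, 0), (−d, −d) for 0°, 45°, 90°,
135°. All four statistics (ASM, CON, IDM, COR) — and the optional Shannon
entropy, reported in bits — are computed on the **normalized** table so
values are comparable across image sizes. COR uses the marginal means and
standard deviations of the normalized table; when a marginal standard
deviation is zero (a constant image) COR is undefined, and the feature
extractor substitutes 0 with a `RuntimeWarning` so batch runs survive
degenerate inputs.

Defaults, and why:

| parameter | default | rationale |
|---|---|---|
| `n_levels` | 8 | keeps an 8×8 GLCM dense even at the 40-px working resolution |
| `distance` | 1 px | standard practice for fine texture |
| `angles` | 0°, 45°, 90°, 135°, averaged | one rotation-robust value per image; symmetric counting |
| `symmetric` | true | pair order carries no information for texture |
| `resolution` | 40 px | the smallest of the four standard test resolutions; cheapest and (on the sweep schema) not worse than larger ones |

With symmetric counting and four-angle averaging the feature vector is
invariant to image transposition (a tested property).

Tamura coarseness (optional, off by default): for window exponents
k = 0..4 (window side 2^k, capped by the image size) the image is
mean-filtered, absolute horizontal/vertical differences of the filtered
image are taken at offset max(1, 2^(k−1)) with edge-clamped indexing, each
pixel selects the k with the largest difference (ties toward the smallest
k, so a constant image scores exactly 1.0), and the image score is the
mean of 2^k_best. The max(1, ·) offset makes k = 0 well defined; the
deterministic tie-break and edge clamping make the statistic reproducible
bit-for-bit.

### The UDLM clusterer

Each particle's position is the concatenation of two candidate centers in
feature space; fitness is the sum over points of the Euclidean distance to
the nearer center. The algorithm keeps only personal bests and the global
best: per iteration each particle draws one uniformly random distinct
neighbor, the pair is ordered by personal-best value (worse = role *i*,
better = role *j*; an exact tie gives role *i* to the particle whose turn
it is), both Gaussian candidates are evaluated, a candidate replaces its
owner's personal best only on strict improvement, and the global best is
refreshed after every evaluation. Consequences, all tested:

* the gbest history is non-increasing for every seed;
* a fully converged pair (p_i = p_j = g) is a fixed point (all sds are 0
  and a Gaussian with zero sd returns its mean exactly);
* runs are bit-reproducible from the seed (one `numpy` Generator drives
  initialization and all draws, consumed in a fixed order).

Initialization scatters particles uniformly in the per-feature data range
(replicated for both centers); no clamping is applied after the Gaussian
step, since the learning rule itself contracts toward the data as the
swarm converges. Defaults `pop_size = 30`, `max_iter = 200` converge on
all shipped fixtures in well under a second; with a single particle the
pair degenerates to (self, self) and the run is a graceful no-op rather
than an error.

Design choices that were genuinely open: the acceptance rule (strict
improvement of the owner's personal best, position identified with the
personal best) is the simplest scheme consistent with a recorded-best
memory; neighbor selection is global-uniform (no topology); both pair
members are updated each pairing with an immediate (asynchronous) gbest
refresh. The clusterer is strictly two-center by design.

### Feature scaling

Before clustering, features are min-max scaled to [0, 1] per column by
default. CON is unbounded while ASM/IDM/COR live in unit-scale ranges, so
unscaled Euclidean distances would be dominated by contrast alone;
`feature_scaling: none` (strict literalism) and `zscore` are available.

### Evaluation

Malignant is the positive class. ACC, PRE, SPE, F1 follow the usual
confusion-matrix definitions (reported as percentages, rounded to 2
decimals for display; raw fractions are kept internally). Sensitivity is
TP/(TP+FN); a published variant with TP+TN in the denominator is
internally inconsistent with any report where SEN ≠ SPE and is therefore
not used (the discrepancy is noted in the `metrics` module docstring).

Cluster-to-class alignment tries both possible mappings and keeps the more
accurate one (tie → identity). The ROC score for the unsupervised model is
the margin `dist(x, benign center) − dist(x, malignant center)`;
thresholding it at 0 reproduces the hard nearest-center assignment, and
for a hard classifier the two-segment ROC integrates to
AUC = (SEN + SPE)/2 — an identity the test suite checks in rational
arithmetic for balanced classes. The supervised RF/SVM controls use
library-default hyperparameters (recorded verbatim in the run report), a
stratified 80/20 split, and the same hard-classifier AUC convention; the
UDLM clusters all samples presented, since the split exists to protect the
supervised fits only.

## Synthetic fixtures: what they do and do not show

`make_texture_dataset` emulates exactly one property of real
histopathology images — two classes separated by texture *scale*. Class
"benign" images are Gaussian noise fields blurred with sigma
`smooth_kernel = 8` px; class "malignant" uses `rough_kernel = 0` (raw
noise, sd 40 around mid-gray); every image is contrast-stretched to the
full 8-bit range so classes differ in coarseness/contrast only, not in
brightness (and so blurred fields do not quantize to constants, which
would degenerate COR). Defaults are 50 images/class at 40 px. The fixture
is *designed* separable — the rough class has higher CON by construction —
so passing tests demonstrate that the pipeline recovers a separation that
exists; they say nothing about stain variation, nuclei morphology,
subtype heterogeneity, class imbalance, or any other property of real
tumor images. Accuracy on the fixture (typically 100%) must not be read
as an expectation for clinical data.

`make_feature_blobs` samples two isotropic Gaussian clouds (default 100
points/class, 4-D, sd 1, centers 10σ apart along the diagonal) and returns
the true centers, enabling exact recovery assertions: the swarm's centers
are compared against the per-blob sample means (tolerance 0.5σ) and its
objective against converged Lloyd's k-means (k = 2, 10 restarts) as an
independent oracle.

## Numerical choices and degenerate inputs

* GLCM probabilities are validated to sum to 1 within 1e-8 before any
  statistic is computed; unnormalized tables raise a contract error.
* Tie-breaks are all deterministic: nearest-center assignment ties go to
  cluster 0, alignment ties to the identity mapping, Tamura window ties to
  the smallest window, pair-ordering ties to the first-selected particle.
* Min-max scaling maps zero-spread columns to 0 instead of dividing by 0.
* Empty images, empty folders, single-class inputs to the baselines, and
  one-class ROC inputs raise typed errors; single-class inputs to the
  unsupervised pipeline still produce assignments, with metrics skipped
  and a warning recorded.
* Artifacts are written temp-then-rename with SHA-256 content hashes in
  `manifest.json`, so determinism can be checked byte-for-byte.

## Problem sizes

The shipped tests and the acceptance script run at the fixture scale
chosen for the package: 100 images at 40 px for the end-to-end path, 200
4-D points for the blob recovery panel, GLCM oracle comparisons on images
up to 6×6 with up to 4 gray levels (exhaustive over all binary images up
to 3×3), feature-range checks on 1000 random small images, and swarm
monotonicity across 50 seeds. The full suite completes in well under a
minute on one CPU.

## Known limitations

* Strictly two classes; the eight BreakHis-style subtypes are ingested as
  metadata only.
* The GLCM feature set is the four-statistic vector (plus optional ENT and
  coarseness); the remaining Haralick statistics are out of scope.
* The swarm optimizer is stochastic; while every shipped fixture converges
  to the k-means-quality optimum on every tested seed, no global-optimum
  guarantee exists for adversarial data.
* Published per-resolution accuracies on the real BreakHis corpus are not
  reproducible without that corpus and are not claimed by this package's
  tests; the synthetic fixture defines its own acceptance surface.
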