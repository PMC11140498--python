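# Methods

## Problem and approach

`nsseg` studies whether self-training with unlabeled data improves the
out-of-distribution (OOD) generalization of a lesion detection and
segmentation model, using a fully synthetic head-phantom benchmark so the
whole experiment runs on one CPU in minutes and is bit-reproducible.

The workflow is the noisy-student scheme:

1. a **teacher** is trained on a small pixel-labeled corpus (site A);
2. the teacher predicts every image of a large unlabeled corpus (site B);
3. images are **ranked** by predicted lesion probability and only the top
   C% (default C = 10) are declared pseudo-positive; their probability
   maps are **trinarized** — pixels above K_pos = 0.7 positive, below
   K_neg = 0.3 negative, in between *ignore* (no loss) — while all other
   images get all-negative masks;
4. a **student**, initialized from the teacher's weights, trains on
   minibatches mixing labeled and pseudo-labeled data 0.6 : 0.4, with
   input noise (contrast and head-geometry augmentation);
5. teacher (= labeled-only baseline) and student are compared on an OOD
   test site (site C) with exam-level ROC AUC, pooled Dice and pixel
   average precision, and with a paired-bootstrap comparison machinery
   (1000 resamples, KS normality check, Z = Δ/σ, percentile CIs).

Two Oracle benchmarks bound what pseudo-labels could achieve: the
image-label Oracle supervises unlabeled images with their true image
labels through the classification branch only (whole images as patches);
the pixel Oracle keeps the teacher's pseudo masks but resets them to
all-negative wherever the true image label is negative.

## The synthetic study

Each examination is an ordered stack of 64×64 images: an elliptical
"head" of smoothly textured tissue on a dark background. Lesions are
bright discs (the contrast polarity of acute blood on CT) with
per-lesion intensity offsets drawn from a range, so conspicuity spans
faint to obvious. Images may also carry **artifact speckle clusters**:
small bright dots near the head periphery that are *not* lesions and
never enter the reference mask. Artifacts are the false-positive bait
that gives the ranker its purpose.

Three "institutions" differ in appearance (`DomainSpec`):

| parameter | site A (labeled) | site B (unlabeled) | site C (OOD test) |
|---|---|---|---|
| contrast gamma | 1.0 | 1.30 | 1.70 |
| noise SD | 0.04 | 0.07 | 0.11 |
| tissue mean | 0.45 | 0.50 | 0.57 |
| aspect jitter | 0.90–1.10 | 0.75–1.05 | 0.62–0.98 |
| lesion offset | 0.12–0.30 | 0.11–0.26 | 0.10–0.22 |
| lesion radius (px) | 2.5–5.5 | 2.2–5.0 | 2.0–4.5 |
| artifact rate | 0.12 | 0.35 | 0.50 |

Site B sits between A and C, emulating a broad multi-scanner corpus;
site C extrapolates beyond B (darker reconstruction, more noise,
squashed heads, fainter and smaller lesions, heavy artifact burden).
The default splits are 40 labeled exams (26.9% positive), 100 unlabeled
exams of 4 images (400 images, 40% positive exams), 20 validation exams
and 60 OOD exams (41.8% positive). Everything is generated from
`numpy.random.Generator` seed chains; identical config + seed gives
bit-identical corpora.

What the generator does **not** emulate: 3D anatomy, skull/bone, HU
calibration, lesion subtypes with distinct textures, slice-to-slice
correlation, and reader disagreement. Passing tests on these phantoms
therefore demonstrate that the *pipeline mechanics* (ranking,
trinarization, masked losses, mixing, bootstrap inference) behave as
specified, and what the self-training scheme does *at desk scale* — not
that the clinical effect sizes transfer.

## Model

A deliberately small dual-branch patch network, written directly in
numpy with hand-derived backpropagation:

* input: 2 channels — raw intensity and a high-pass residual (raw minus
  a sigma-4 Gaussian blur). The residual gives the small receptive field
  a brightness-normalized view, without which global gamma shifts (and
  the contrast augmentation itself) are unlearnable at this scale;
* trunk: conv3×3 (2→8) → leaky ReLU → 2× average pool → conv3×3 (8→16)
  → leaky ReLU → nearest upsample → skip-concat (24 channels);
* segmentation branch: 1×1 conv → sigmoid per-pixel probability map;
* classification branch: global average pool of the bottleneck → linear
  → sigmoid patch probability.

Final layers start at zero, so an untrained model outputs 0.5
everywhere. Training minimizes, per minibatch, the mean over samples of
the masked pixel binary cross-entropy (mean over non-ignore pixels; a
fully ignored patch contributes zero) plus λ (default 1) times the
classification cross-entropy, with patch labels derived from the mask
patch ("any positive pixel"; ignore pixels are not positive evidence).

Optimization: Adam (lr 0.04 for the defaults), cosine decay to lr/10,
global gradient-norm clipping at 5, leaky-ReLU slope 0.1. These choices
were made for stability: plain ReLU at comparable learning rates
intermittently collapsed to constant outputs (dead first-layer units).
Training draws random crops (default 32×32, batch 16, 40 steps/epoch,
45 epochs); inference tiles a deterministic grid and averages overlaps.

Exam scores: per-image probability defaults to the maximum of the
classification output and the pixel maximum (`max_both`), with the exam
score the maximum over images. The experiment runner instead scores
exams with the classification branch alone (`class`): on artifact-heavy
OOD negatives the pixel-max rule saturates near 1.0, which makes the
exam AUC depend on ties among saturated scores. The ranker likewise uses
the classification branch, whose global pooling naturally ranks small
artifact speckles below true lesions (pseudo-positive purity 36–39/40
versus 25–32/40 under the pixel-max rule).

## Statistical machinery

Model comparisons use paired bootstrap: each replicate resamples unit
indices (exams or images) with replacement and applies the *same*
indices to both models; Δ = metric(B) − metric(A) is recorded per
replicate. σ is the SD of the bootstrap Δ; the test statistic is
Z = Δ_full / σ with Δ_full computed on the unresampled set (the
conventional bootstrap-SE test; the bootstrap-mean Δ is also reported);
p = 2·Φ(−|Z|); the 95% CI is the 2.5th/97.5th percentile of the Δ
values. Normality of the Δ distribution is checked with a one-sample KS
test of the sample-standardized values against N(0,1); because mean and
SD are estimated from the sample this p-value is anti-conservative
(the Lilliefors caveat) — it gates a warning, never the test itself.
Replicates whose resample leaves a single reference class are redrawn
and counted. A paired t-test (df = n−1) covers test–retest designs;
zero-variance differences raise rather than return a misleading p.

Numerical conventions: Dice of two empty masks is 1 (correct negatives
are rewarded; this matters only if a bootstrap set has no positive
pixels); Dice over an image set is pooled (one global overlap), with
binarization threshold 0.5; pixel AP is the non-interpolated
precision-at-each-positive form over the pooled descending ranking;
ranking ties keep original order (stable sort); the ranker count is
floor(C/100·N); probabilities exactly at K_pos or K_neg are ignored
(strict inequalities); probabilities are clipped at 1e−7 inside
cross-entropies.

## What the desk-scale experiment shows — and what it cannot

The ranker-direction result reproduces: across seeds, the student
trained on ranked pseudo-labels scores a higher mean OOD exam AUC than
the ablation student trained with the ranker removed (every image
trinarized as positive), which reinforces the teacher's artifact false
positives exactly as the full-scale study describes.

The headline student-over-baseline direction does **not** reproduce
consistently at this scale, and the package's own Oracle benchmarks show
why this is a scale limit rather than a pseudo-label defect: even
training with *perfect* unlabeled image labels (image-label and pixel
Oracle modes) fails to beat the labeled-only baseline on the OOD split.
A ~1.3k-parameter network trained on 160 labeled images is already
capacity-saturated, so additional (even perfectly labeled) data from a
different domain buys little, while the extra optimization drifts the
pixel-probability calibration downward — pooled Dice at a fixed 0.5
threshold is particularly sensitive to that drift. The published effect
rests on a ~10⁷-parameter backbone, 25 000 unlabeled exams and
600-epoch training, where the baseline is far from its capacity ceiling.
We report the directional comparison honestly rather than tune the
benchmark until it flatters the method.

## Known limitations

* 2D phantoms with geometric lesions; no anatomy, no subtype structure.
* The probability calibration of the desk-scale network is coarse; the
  pooled-Dice operating threshold (0.5) is configurable but not tuned
  per model.
* The KS normality check inherits the Lilliefors caveat (documented
  above).
* One teacher→student generation only (iterated self-training is out of
  scope), and the human-in-the-loop inspection that chose C in the
  original workflow is replaced by a config parameter with default 10.
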