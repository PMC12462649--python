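# Methods

## Model and assumptions

The classifier assigns one binary label per patient from a pair of
co-registered 3D volumes (metabolic PET channel, anatomical MRI
channel) or from either channel alone. Its central assumptions are:

* volumes are co-registered upstream and share one voxel grid;
* a positive case contains at least one focal region whose PET uptake
  exceeds its surroundings, somewhere below the brain;
* the brain — the global PET maximum in a disease-free head-and-neck
  stack — occupies the most superior slices, so depth position carries
  prior information (exploited by the weighted aggregation rule);
* intensity scales are uninformative across patients (scanner- and
  tracer-dependent), so every volume is min-max scaled per channel per
  case before the network sees it.

The network is an entry 3×3×3 convolution (+BN+ReLU) followed by two
stages of residual + attention blocks at 64 and 128 filters, global
average pooling, dense(512, ReLU) and a sigmoid unit. Choices the
architecture description leaves open were fixed as follows: spatial
downsampling happens by a stride-2 first convolution at each residual
stage (with a 1×1×1 stride-2 projection on the skip path); the
attention block's two parallel 1×1×1 convolutions are merged by
element-wise addition (concatenation + re-projection is available via
`ModelConfig(attention_merge="concat")`); batch normalisation appears
inside residual blocks as well as the entry block (switchable with
`bn_in_residual`); the classification head is dense(512, ReLU) →
dense(1, sigmoid). Global average pooling makes the trunk
depth-agnostic; anything deeper than ~8 slices survives the two
stride-2 stages.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `stage_filters` | (64, 128) | channel widths of the two stages; (8, 16) in the scaled-down study |
| `focal_gamma`, `focal_alpha` | 2.0, 0.25 | focal BCE: −α(1−p)^γ log p for positives, −(1−α)p^γ log(1−p) for negatives; the canonical values, since the loss description fixes none |
| `lr0`, `decay_rate`, `decay_steps` | 1e-4, 0.96, 100000 | Adam schedule lr0·rate^(step/steps), continuous (not staircased) |
| `depth_window` | 32 slices | training crop; positives get a window extended symmetrically from the centremost mask slice and clamped at the boundaries (the tumour is contained, not centred), negatives a uniformly random window seeded per (global seed, case id) |
| `window`, `stride` | 32, 16 | sliding-window inference geometry |
| `tail_policy` | `end_aligned` | appends a final window flush with the inferior end when the stride grid stops short; `floor` keeps only stride multiples. With 48–50-slice stacks the two policies differ exactly at depths 49–50, where `end_aligned` yields a third window — the only reading under which average and median aggregation can disagree at those depths. Both are kept. |

Probabilities are clipped to [1e-7, 1−1e-7] before the loss so the log
terms stay finite.

## Threshold selection

Each fold's decision threshold is chosen on its validation scores only,
from the midpoints of adjacent sorted unique scores, maximising
min(sensitivity, specificity); ties break toward higher sensitivity,
then lower threshold (a screening-oriented choice). Youden's J is
available as an alternative criterion. The selector is verified against
an exhaustive sweep in the tests. The ensemble threshold is the
arithmetic mean of the five fold thresholds.

## Aggregation rules

For window scores p₁…p_W ordered superior → inferior: average = mean,
median = sample median, weighted = Σ wᵢpᵢ with wᵢ = i / Σⱼ j (a linear
ramp that discounts the brain-containing top of the stack; other ramps
can be plugged in), majority = positive iff strictly more than W/2
windows score at or above the threshold — so an even split is negative,
and the rule yields no continuous score and hence no ROC/AUC. Member
probabilities are averaged per window before aggregation; for the
average rule this is mathematically identical to aggregating members
separately, for median and majority it is not (the per-window mean was
chosen for simplicity and determinism).

## Synthetic phantoms

The generator emulates the statistical skeleton of head-and-neck FDG
PET/MRI: a smooth PET background (mean ≈ 1 arbitrary unit, ±20 %
low-pass structure), a brain analogue at 5× background filling the top
quarter of the stack (in-plane ellipse), Gaussian noise with
intensity-proportional variance (sd = noise_sd·√intensity, a seedable
stand-in for Poisson-like count noise), and, in positives, one
ellipsoidal hot-spot whose mean uptake is `tumour_contrast`× background
at a uniformly random position strictly below the brain. The MRI
channel is low-pass texture under one of several contrast archetypes
(emulating mixed T1 / fat-suppressed T1 / T2 acquisitions) with a
multiplicative tumour signature of 2.0 by default — visible but weak,
so classifier skill should order PET > MRI, mirroring the modality
ordering observed clinically. Intensities carry no SUV calibration:
the pipeline min-max scales per volume regardless.

What the phantoms do **not** model: anatomy (organs, air/bone
interfaces), attenuation and partial-volume effects, multi-focal or
infiltrative disease, necrotic (photopenic) tumour cores, and
inter-scanner intensity distribution shifts beyond the contrast
archetypes. Passing tests on phantoms therefore demonstrates that the
pipeline's mechanics — preprocessing, optimisation, ensembling, window
aggregation, attention mapping — behave as specified on data satisfying
the model's assumptions; they say nothing about clinical accuracy.

## Scaled-down study

The end-to-end learnability and localization checks run a reduced
version of the full design: 32×32×16 phantoms with an easy hot-spot
(contrast 6), stage filters (8, 16), 200 training phantoms (160/40
train/validation split for best-epoch and threshold selection), 100
held-out test phantoms, 10 epochs, batch 8. Two deliberate departures
from the full-size defaults, chosen for the short schedule: lr0 = 1e-3
(1e-4 is tuned to a schedule two orders of magnitude longer) and no
augmentation (the homogeneous phantom population gains nothing from the
5× copy expansion; the expansion itself is tested separately). On these
conditions the PET-channel model reaches held-out AUC ≈ 0.99 and the
Grad-CAM per-slice argmax falls within the tumour slice range ± 2 on
~100 % of true positives; the weak-MRI channel stays near chance at
this resolution, giving the expected PET > MRI ordering. Localization
quality depends on convergence — models trained on substantially fewer
cases or epochs classify well before they localize well, drifting
attention to the brain analogue.

## Numerical choices

* All network arithmetic is float32; convolutions are evaluated as
  im2col matrix products (one BLAS call per layer) with a pointwise
  fast path for 1×1×1 kernels.
* Batch normalisation: momentum 0.9, eps 1e-5; inference uses running
  statistics, so outputs are independent of batch composition.
* Initialisation is He-normal, seeded; equal seeds give byte-identical
  parameters, and all randomness (phantoms, fold shuffles, window
  choices, batch order) derives from named seeds.
* Min-max scaling of a constant volume returns zeros with a warning
  rather than raising (robust to masked or cropped regions).
* Mask resampling is nearest-neighbour; if coarse resampling would
  erase a small mask entirely, its centroid voxel is preserved so the
  label/mask invariant survives.
* Positive counts in generated datasets round half away from zero, as
  does 2-decimal report rounding (0.725 → 0.73); internal computation
  is never rounded.
* Fold summaries take the unweighted mean/median of per-fold metrics,
  not pooled counts — the two differ in the third decimal and only the
  former reproduces the reference fold-table summaries.
* Stratified folds deal each class into near-equal parts with the
  per-class remainder staggered by class rank across folds; with
  101+101 cases and k = 5 this yields fold sizes 41/41/40/40/40 with
  positives 21/20/20/20/20 and negatives 20/21/20/20/20, consistent
  with the reference fold counts (a naive first-fold remainder rule
  would give 42/40/40/40/40).
* Grad-CAM maps are normalised per volume (not per slice), merged
  across overlapping windows by voxelwise maximum, and upsampled
  trilinearly; an all-zero map stays all-zero.

## Known limitations

* The numpy engine is CPU-bound and intended for the reduced problem
  sizes; full-size (64, 128)-filter training on 64×64×32 volumes is
  orders of magnitude slower than a GPU framework.
* The attention mechanism is channel-wise only (1×1×1); no spatial
  attention is modelled.
* Grad-CAM at the final attention stage has a z-resolution of a quarter
  of the input depth before upsampling, which bounds how sharply the
  per-slice profile can localize.
* The balanced-criterion threshold assumes both classes are present in
  every validation fold; degenerate folds raise rather than guess.
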