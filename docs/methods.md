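# Methods

## The problem

Clinical pain assessment from video raises an obvious privacy problem:
faces identify patients. The pipeline implemented here works entirely on
3D face *landmarks* — a fixed-topology point cloud (478 points in the
dense face-mesh layout, 83 in the sparser expert-annotated layout) that
preserves facial geometry while discarding identity-revealing texture.
From landmark sequences it (1) detects the presence of 8 facial action
units (AUs 5, 6, 8, 9, 10, 12, 14, 18 of the Facial Action Coding System),
(2) regresses the 0–5 FACS intensity of 5 AUs (6, 10, 12, 14, 17), and
(3) classifies ~20 s segments as pain vs. non-pain from the AU time
series.

## Models

**AU detector / intensity estimator.** A frame's landmarks are
similarity-Procrustes-normalized to a canonical template (centroid to the
origin, mean point-to-centroid distance matched, least-squares rotation
without reflection) and flattened to a 3·Ns vector. Both heads share one
architecture: input 3·Ns → 128 ReLU units → output layer. Detection uses
8 logistic outputs with per-unit binary cross-entropy (the standard
multi-label treatment; the source architecture states no output
activation, and F1-based evaluation makes the logistic/BCE choice
natural). Intensity uses 5 linear outputs with mean squared error,
matching RMSE reporting; predictions are clamped to [0, 5] and may be
rounded half-away-from-zero to discrete levels. Optimization is
mini-batch Adam (β₁ = 0.9, β₂ = 0.999), batch 64, learning rate 0.01, up
to 500 epochs, no early stopping by default (a patience option exists but
is off). Normalization is applied uniformly to both topologies; the
source pipeline is silent on coordinate preprocessing, and pose
invariance is the reason for adopting it.

**Pain classifiers.** AU vector sequences are cut into fixed-length
windows (flagship length 350 frames ≈ 14 s at 25 fps; stride = window
length, with one extra right-aligned window when the uncovered tail is at
least half a window; shorter segments are right-zero-padded under a mask).
The Transformer encoder linearly projects each AU vector to d = 1024,
adds fixed sinusoidal positional encodings, and applies 2 post-norm
encoder blocks with 4-head self-attention; padded positions are masked
out of attention. The classification head is a 1-hidden-layer MLP (256
units, dropout 0.1) on the representation of the last *non-padded* frame,
with a single logistic output; the hard label is round(probability). The
LSTM baseline stacks 2 layers (hidden 512, forget-gate bias 1) and feeds
the hidden state at the last non-padded frame to the same head. Training:
Adam, batch 16, up to 150 epochs; learning rates 10⁻⁵ (Transformer) and
10⁻³ (LSTM). Segment-level decisions are a majority vote over the
segment's windows, ties resolved toward pain (the clinically conservative
direction).

All networks are implemented in numpy with hand-written backprop; the
test suite verifies every analytic gradient against central finite
differences (tolerance 1e-5) and the attention forward pass against a
brute-force softmax computation (1e-6).

## The synthetic-data generator

Real FACS-annotated pain elicitation data is access-restricted, so a
forward simulator provides ground truth for every stage. It emulates a
study of 140 subjects, each contributing 1 pain segment and 3 non-pain
segments (happiness, embarrassment, fear), ~20 s at 25 fps — the pain :
other frame ratio is therefore ≈ 1 : 3.

* **Template**: a bilaterally symmetric face-like point cloud (dome over
  an oval) with landmark density concentrated around eyes, brows, nose
  and mouth. The left/right index pairing (mirror map) is known by
  construction and doubles as the horizontal-flip permutation.
* **Deformation basis**: each simulated AU owns a smooth random 3D
  displacement field windowed by a Gaussian region mask centred on the
  AU's facial region (cheek raiser near the cheeks, lip-corner puller at
  the mouth corners, …), mirror-symmetrized. Fields of AUs sharing a
  region are Gram–Schmidt-orthogonalized so that pairwise cosine
  similarity stays below 0.3 — AUs remain statistically identifiable.
  Fields have unit RMS over their support; the global gain (0.15 of the
  template scale at intensity 5) sets deformation amplitude.
* **Activation timecourses**: class-associated AUs (pain: 4, 6, 7, 9, 17,
  18, 23, 24; happiness: 6, 7, 12, 25, 26; fear: 1, 2, 4, 5, 7, 20, 25;
  embarrassment, absent from the standard prototype table, is modelled as
  a controlled smile 6, 12, 24) fire smooth onset–apex–offset pulses with
  duration-proportional counts (Poisson, ~0.15 pulses/s) and apex
  intensities skewed toward low FACS levels. Class-neutral top-present
  AUs (8, 10, 14) fire background pulses in every class; all other AUs
  fire rare low-amplitude distractors. Per-frame intensity change is
  bounded by 1.0 (slope-capped ramps plus a smoothing guard).
* **Rendering**: frameₜ = Poseₜ(subject_template + Σₖ (Iₜₖ/5)·gain·fieldₖ)
  + Gaussian noise. Subject variation enters as a smooth shape
  perturbation (sd 0.02 of template scale) and an expressiveness factor
  (sd 0.10, clipped to [0.75, 1.25]) that scales the activation trace
  itself — labels are derived *after* this scaling, so ground truth
  always describes the rendered motion, as a human FACS coder would
  label it. Pose jitter is a smoothed random walk (±2° per axis, ±0.01
  translation). Presence labels follow the FACS convention intensity ≥ 1.

What the simulator does **not** emulate: landmark-extractor failure modes
(occlusion, tracking drift), nonlinear or coupled muscle actions,
demographic appearance variation, asymmetric (unilateral) AUs, and
correlated sensor noise. Passing recovery tests therefore demonstrates
that the pipeline's estimators are correct and well-conditioned on data
matching their generative assumptions — not that real-world F1 levels
would match.

## Augmentation

Image-side augmentations are mapped to landmark space: horizontal flip =
x-negation + mirror-map permutation (labels unchanged; the label schema
is bilateral); rotation (±15°); cropping = framing jitter (translation
±0.05, scale 0.9–1.1), since removing landmarks is impossible when the
network consumes all 3·Ns inputs; linear distortion = a shear matrix
(±0.1 off-diagonal). One transform is sampled per segment to preserve
temporal coherence. Because Procrustes normalization cancels rotation and
framing jitter, shear and flip carry the diversity on the normalized
pathway; transforms are applied before normalization. Rare-AU
oversampling duplicates the frames positive for a target AU (4 transformed
copies per positive by default) in the *training split only* — augmenting
a split tagged `test` raises an error rather than silently leaking.

## Evaluation protocol

Cross-validation is always subject-independent: subjects are randomly
partitioned into k balanced folds (3 for frame-wise AU tasks, 10 for pain
at full scale), and every fold's train/test subject sets are asserted
disjoint at run time. Detection reports per-AU F1 averaged over folds and
the unweighted mean across AUs (the AVG column is re-derived from its row
cells on emit and must agree within 0.005). Intensity reports per-AU
RMSE/MAE. Pain reports per-fold accuracy/F1 plus a confusion matrix
summed over folds, from which aggregate accuracy/F1 are recomputed.
Precision/recall with empty denominators are 0 by default (a flag yields
NaN instead). Percentages are printed to 2 decimals, half-up.

## Desk-scale study sizes

The flagship configuration (478-point topology, 140 subjects, 20 s
segments, 350-frame windows, d = 1024) is exposed as the default config
but is not what the test suite runs. The recovery studies use sizes
chosen for single-CPU tractability while keeping the protocols intact:

* AU detection/intensity recovery: 100 subjects, 83-point topology,
  noise sd 0.005, every 4th frame, 60 epochs, 67/33 subject split.
* Pain recovery: 30 subjects, 10 s segments, subject-independent 3-fold
  CV, 250-frame exact-fit windows, Transformer d = 64 (4 heads, 2
  layers, feed-forward 128) at learning rate 10⁻³ for 25 epochs, LSTM
  hidden 64 for 15 epochs. The higher learning rate follows the
  reduced model and data size; at the flagship scale the stated 10⁻⁵/10⁻³
  rates apply.
* Oversampling study: 12 subjects with two AUs made artificially rare
  (class-firing probability × 0.15), 4 transformed copies per positive
  frame.

## Numerical choices and degenerate inputs

Float64 throughout. Procrustes rejects frames whose points all coincide;
reflections are excluded by determinant correction. Masked attention uses
−10³⁰ pre-softmax so padded keys get exactly zero weight after
normalization. Intensity ties (x.5) round half away from zero. Windows
shorter than 10 frames are skipped with a warning. Seeds fan out from one
global seed through CRC32-salted `SeedSequence`s; every simulation,
shuffle and initialization is reproducible from the global seed alone.

## Known limitations

The AU detector is frame-wise and ignores temporal context; the
pipeline compensates in the temporal pain stage. The simulator's
linear AU→displacement model makes intensity regression easier than on
real faces. The 83-point and 478-point topologies here are synthetic
stand-ins with the right cardinalities and symmetry, not the actual
layouts of those products. All-AU ground-truth mode feeds binary
presences (not intensities) for the 34 simulated AUs.
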