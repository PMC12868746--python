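# Methods

## Overview

`topoeeg` implements a topological forecasting pipeline for multi-channel
EEG. Each recording is decomposed into the five canonical frequency bands,
cut into consecutive non-overlapping 4-s windows, and each window is turned
into a *high-order persistence image* (PI): a fixed-resolution vectorization
of the window's Vietoris–Rips persistence diagram restricted to homology
dimensions ≥ 1 (loops and voids rather than connected components). A
generator built from two graph-attention layers, an LSTM over the flattened
pixel sequence and a sigmoid FC head predicts the PI of the *next* window;
a two-layer FC discriminator drives adversarial refinement. Evaluation uses
AUC, mean average precision (MAP) and mean absolute error (MAE). A separate
CNN regressor maps PIs to clinical severity scores; its per-sample outputs
after a fixed training budget are the *image-quality coefficients* whose
per-band Pearson correlations with PANSS scores the package tabulates.

Real clinical EEG of this kind is not publicly available, so the package
ships a synthetic cohort generator that makes every stage executable and
testable end-to-end.

## Synthetic EEG cohorts

Each subject's recording is a sum over the five bands of an
amplitude-modulated sinusoid at the band-centre frequency (random phase per
channel, slow 0.1–0.4 Hz AM) plus band-passed Gaussian noise at half the
carrier RMS, plus broadband white noise (`noise_sd`, default 2 in the same
arbitrary microvolt-scale units). Band amplitude means default to a rough
1/f profile (Delta 20, Theta 10, Alpha 15, Beta 5, Gamma 3). Subjects vary
by a log-normal amplitude jitter (σ = 0.2 in log space), which keeps
amplitudes positive and gives regression targets a non-degenerate predictor.
The patient/control contrast is a per-band relative amplitude shift
(`band_effect_sizes`); the default contrast (+40% Theta and Gamma in
patients) mirrors the bands that carry the clinical signal in this model
family. This is a *stand-in* class contrast: nothing here is a claim about
schizophrenia electrophysiology — no volume conduction, no dipole sources,
no artifacts (blinks, EMG), no inter-channel covariance structure beyond
shared band content. Passing tests therefore demonstrate that the machinery
detects planted band-structure differences, not that it detects disease.

Clinical scores are planted as
`PANSS_total = intercept + slope · θ_amp + N(0, noise_sd)` with the
subject's drawn Theta amplitude as the signal property (defaults: intercept
60, slope 1.5, noise 5 — putting totals near the 74 ± 11 range typical of
stabilized patients); positive/negative subscales are fixed fractions of
the total with their own noise. With `noise_sd = 0` the relation is exact;
with `slope = 0` scores are independent of the signal.

Sampling rate defaults to 250 Hz (a 4-s window is 1000 samples) and the
synthetic channel count to 8; both are config knobs — the analysis collapses
channels to their mean before embedding (a single named channel can be
selected instead), so channel count mostly affects noise averaging.

## Preprocessing

Band-pass filtering is zero-phase order-4 Butterworth (forward–backward via
`sosfiltfilt`); a broadband 1–50 Hz pre-filter with 50 Hz notch is available
and off by default for synthetic data (which contains no mains or drift).
Windows are consecutive, non-overlapping, trailing remainder dropped;
cropping uses half-open sample intervals `[start·fs, end·fs)`.

## Topological featurization

Each window's collapsed series is Takens-embedded (defaults: dimension 3,
delay 4 samples; an average-mutual-information delay selector is provided),
optionally subsampled to a point cap, and fed to a Vietoris–Rips persistence
computation over Z/2:

- simplices up to one dimension above the requested homology are enumerated
  with diameters below the cloud's *enclosing radius* (min over points of
  max distance), beyond which the complex is a cone and contributes nothing;
- the boundary matrix is reduced with columns stored as big-integer
  bitmasks, making column addition a single word-parallel XOR;
- zero-persistence pairs are discarded; unpaired creators get infinite
  death.

`brute_force_persistence` is an intentionally independent oracle for clouds
of ≤ 12 points: full untruncated filtration, set-based naive reduction. The
test suite asserts feature-for-feature equality between the two on random
clouds, and both against hand-derived cases (unit square: one H1 feature
born at 1, dead at √2; octahedron: one H2 feature born at √2, dead at 2).

Persistence images place a persistence-weighted Gaussian (σ defaulting to
5% of the persistence-axis range) at each finite (birth, persistence) point
of the selected homology dimensions, evaluated at pixel centres, then
min-max normalize to [0, 1] — the generator's sigmoid output lives in
[0, 1], so its targets must too. Axis ranges are pooled over the cohort's
diagrams per band and frozen, so images are comparable across windows and
subjects. Pre-normalization the map is additive in the diagram.

Cost note: Rips complexity grows steeply with cloud size (the H2 filtration
holds O(n⁴) simplices). The library default caps clouds at 200 points with
H1 + H2; the desk-scale configuration used by tests, the CLI default and
the acceptance script uses 40-point clouds, H1 only, and 20 × 20 images.
Those are the problem sizes all reported desk-scale numbers refer to.

## Model

A PI becomes a graph with one node per pixel (row-major, matching the
flatten order), 8-neighbourhood grid edges plus self-loops; structure never
depends on pixel values. The generator runs:

1. GAT layer 1, K = 8 heads, per-head width 8. Attention logits are
   additive (`a_dst·Wh_i + a_src·Wh_j`), LeakyReLU slope 0.2, softmax over
   each node's in-neighbourhood; aggregation *averages* the heads (the
   formulation is printed that way; a concatenating variant is deliberately
   not provided). ELU activation. Dropout (default 0.6) on layer-1 input
   features and attention coefficients during training.
2. GAT layer 2, single head, back to one feature per node. The grid shape
   is conserved through both layers (100 × 100 stays 100 × 100).
3. Row-major flatten to an (R², 1) sequence — 10,000 × 1 at full
   resolution — consumed scalar-by-scalar by an LSTM with hidden size 5;
   the last hidden state summarizes the image.
4. FC 5 → R² with sigmoid, reshaped back to R × R.

The discriminator is FC(R² → 32) + ReLU + FC(32 → 1) + sigmoid
(`Y_d = Sigmoid(W_d·V_d + b_d)` per layer); its hidden width is a free
choice, 32 by default.

All layers are NumPy with hand-derived backpropagation. The test suite
checks every parameter family of every model variant against centred finite
differences at 1e-4 relative tolerance (with an absolute floor of 1e-3 on
the comparison scale, below which the finite difference itself has no
significant digits).

Ablation variants share the training harness: *GAT-only* replaces the
LSTM+FC stack with a shared per-node affine map + sigmoid (keeping its
parameter count below the full model's, which a dense R² → R² head would
not); *LSTM-only* feeds the raw flattened pixels to the LSTM.

## Training

RMSprop throughout (the classical running-mean-of-squares form,
α = 0.99). Pretraining minimizes pixelwise BCE between predicted and target
images at lr 0.01. Joint training alternates at lr 0.001: the discriminator
takes a BCE step on real targets (label 1) versus generated images
(label 0); the generator then minimizes adversarial BCE toward label 1 plus
`recon_weight` (default 1) times reconstruction BCE. Batch size 32. Splits
are at subject level (80/20 with 10% of training subjects as validation),
which prevents temporally adjacent windows of one subject straddling the
train/test boundary.

Two GAT dropout rates appear in the source material for this architecture
family (0.6 with the architecture description, 0.5 with the experimental
setup); the package exposes one key, default 0.6.

*Gradient balance.* On desk-scale pair counts an unconstrained
discriminator separates real from generated images within a few epochs,
after which the generator's adversarial term grows without bound. The
package therefore trains the discriminator at a reduced rate
(`disc_lr_scale`, default 0.1 of the joint learning rate) and skips its
update whenever its batch loss is already below `disc_loss_floor` (default
1.0, against the 2·log 2 ≈ 1.39 chance level) — a standard balancing rule.
The regime in which both loss curves show the expected declining trend over
the first 100 joint epochs is early joint training from scratch: the
generator's reconstruction descent dominates its curve while the slowed
discriminator descends smoothly toward the floor. A converged (pretrained)
generator instead leaves only the adversarial see-saw, in which one curve's
fall is the other's rise.

## Evaluation

MAE is the mean absolute pixel difference. The primary AUC/MAP protocol is
pixelwise: each target image binarized at the classification threshold
(default 0.4) provides labels, the predicted intensities provide scores;
AP (step-interpolated area under the precision–recall curve) and AUC
(Mann–Whitney with half-credit for ties) are averaged over images, with
degenerate all-positive/all-negative targets excluded. This protocol needs
nothing beyond the images themselves and uses the printed threshold; a
subject-level protocol is provided separately: a subject's score is the
generator's mean reconstruction BCE over the subject's window pairs.
Sequences with richer, more variable topology are intrinsically harder to
forecast, and in the synthetic cohorts the amplitude-elevated patient class
is exactly that class, so the patient label is the positive class for this
score. Under identical class distributions the subject AUC sits at chance;
under a large planted band-amplitude effect (3× the analysis band in
patients) it exceeds 0.8 at desk scale.

## Ablation study conditions

The planted "spatial + temporal" sequences used to compare the three
generator variants are Gaussian blobs at one of four discrete horizontal
stations, advancing one station per frame, under heavy iid pixel noise
(σ = 0.35 against unit signal). The design targets each module's
distinctive capability: the blob is smooth, so neighbourhood aggregation
raises per-pixel SNR before the LSTM's sequential readout (whose effective
integration window is limited by forget-gate decay, so it cannot average
the noise away on its own), while re-rendering the *next* station is a
global nonlinear map that a per-node head cannot express. Desk-scale
ablation runs disable GAT dropout: a 0.6 rate is calibrated to
hundred-subject cohorts and swamps ~50-pair training sets. Under these
conditions the full generator's mean test MAE over 5 seeds is below both
ablations'.

## Image-quality coefficients

The quality coefficient is defined operationally, mirroring its source: the
per-sample prediction of a score-supervised CNN regressor (two 3×3
conv + max-pool blocks, 16/32 channels by default, dense head) after a
fixed Adam budget (500 rounds by default; desk-scale runs use 40–100).
Targets are z-scored internally — Adam's step size would otherwise never
bridge the ~74-point PANSS offset — and predictions are mapped back.
Correlations are Pearson with two-sided p via the t transform, reported per
band and clinical variable without multiple-testing correction (a
Benjamini–Hochberg helper is deliberately out of scope; the tabulated cells
are raw p-values). Note the in-sample character of the coefficient: it is a
trained model's output on its own training samples, which is how it is
defined, not an oversight.

## Reproducibility and numerics

Every stage draws from named substreams of one global seed
(`substream_rng(seed, *labels)`, CRC-32-hashed labels into a PCG64 seed
sequence), so cohorts, splits, dropout masks, shuffles and subsampling are
bit-reproducible and order-independent. Degenerate inputs are defined
rather than accidental: empty diagrams give zero images; all-zero images
stay zero under min-max normalization; ties in ranking metrics get half
credit (AUC) or stable-rank treatment (AP); zero-variance inputs to the
correlation raise an error; a diverging loss aborts training with a
diagnostic rather than propagating NaNs.

## Known limitations

- The synthetic EEG is oscillators-plus-noise; none of the reported
  desk-scale numbers transfer to clinical data.
- Full-scale Rips (200-point clouds, H1+H2, per window, per band, per
  subject) is computationally serious in pure NumPy; the implementation is
  exact but intended for desk-scale studies, not batch processing of large
  cohorts.
- The LSTM consumes pixels in raster order; a temporal variant across
  windows is a natural extension and is not implemented.
- The subject-classification direction (patients = harder to forecast) is a
  property of the synthetic contrast, not a clinical claim.
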