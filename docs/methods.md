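# Methods

## Problem and model

`vidspo2` estimates peripheral oxygen saturation (SpO2, percent) from
plain RGB video of skin regions.  The physical signal is tiny: each
heartbeat modulates skin color by roughly 1% of the DC reflectance, and
the ratio between the red- and blue-channel pulsatile fractions encodes
SpO2 through the classical ratio-of-ratios law

    SpO2 = A − B · (AC_R/DC_R) / (AC_B/DC_B),

because oxygenated and deoxygenated hemoglobin absorb red and blue light
differently.  The pipeline has three learned parts:

1. **rPPG backbone.** A 3-D convolutional network maps a `(3, T, S, S)`
   clip to a `(6, T)` multi-channel remote-photoplethysmography (rPPG)
   time series: per-clip channel standardization; a `1×5×5` convolution;
   two blocks of two `3×3×3` convolutions with temporal dilation 2;
   average pooling that halves the temporal axis once and reduces the
   spatial axes to 16×16; a further dilated block; linear temporal
   interpolation back to length T; a final `3×3×3` convolution; a global
   spatial average; and a `3×3×3` output convolution to 6 channels.
   Reference channel widths are 32/64 for a 128×128 input.  Smaller
   square inputs (64/32/16/8) skip spatial pooling stages adaptively so
   the pre-pooling feature map is at most 16×16; a `width_mult` scales
   the channel widths for CPU-scale experiments.  Every convolution but
   the last is followed by normalization and ReLU.

2. **PSD-contrastive pre-training (stage 1)** needs no labels.  Each
   training tuple holds a face clip `x_a` and hand clip `x_b` from the
   first half of a window, a *pseudo clip* `x_c` made by freezing one
   chromatically jittered frame of `x_a` (so it carries no pulse), and
   the face during the second half `x_d` (where rotation may occur).
   All clips — and the four quadrant sub-ROIs of face and hand — pass
   through the shared backbone; outputs are compared as band-limited
   (0.5–4 Hz), L1-normalized power spectra, which discard phase and
   amplitude.  The positive loss averages squared PSD distances over all
   ordered pairs of quadrant spectra (divided by 16·N²) plus the
   whole-clip terms |f_a−f_b|² and |f_a−f_d|²; the negative loss is
   −mean |f_a−f_c|².  Stage 2 fine-tunes with the cosine loss
   L_s = 2 − cos(y_a, ỹ1) − cos(y_d, ỹ2) against contact-PPG references.

3. **SpO2 head (stage 3).** A deep branch (1-D CNN → bidirectional LSTM
   → linear → sigmoid, so Mout1 ∈ [0,1]) and a manual branch: the MFAM
   (manual-feature attention module) turns the six handcrafted features
   C_w = per-channel pixel means and variances of the ROI clip into
   softmax attention weights and outputs the attention-weighted feature
   sum Mout2.  The fusion SpO2 = k1·Mout1 + k2·Mout2 enforces
   k1 + k2 = 100 *structurally*: one parameter θ defines
   k1 = 100·sigmoid(θ), k2 = 100 − k1, initialized at the 50/50 split.
   During stage 3 the backbone is frozen; training minimizes MSE on the
   percent scale.

The published training schedule is lr 1e-3/300 epochs (stage 1),
1e-4/200 (stage 2), 5e-3/50 (stage 3); the package keeps these learning
rates and treats epoch counts as profile-dependent.

### What the deep head actually sees

Every learned path in the backbone normalizes amplitude away (input
standardization, per-channel instance norms, PSD normalization) — which
is exactly right for pulse *timing* but removes the amplitude-ratio
information that carries SpO2.  The head therefore receives, alongside
the `6×T` rPPG series:

* `3×T` relative photometric traces, `100·(m_c(t)/mean − 1)`, of the ROI;
* six window-level summary scalars: per-channel AC amplitudes (RMS of
  the linearly detrended relative traces) and their three pairwise
  log-ratios — the classical camera-oximetry ratio features.  They are
  z-scored with training-set statistics stored on the model.

Without this path the head provably cannot out-perform a constant
predictor from normalized inputs alone; with it, the SpO2 dependence is
nearly linear in the log-ratio features.

### Interpretation choices

* The printed MFAM formula sums a softmax and is identically one; the
  implemented Mout2 is the attention-weighted feature sum, which matches
  the module's stated role and satisfies "equal features in, that value
  out".  σ features are variances (not standard deviations), following
  the accompanying prose.
* k1 is the weight of the deep branch per the fusion equation (the
  surrounding prose swaps the labels; the trained trajectory and the
  conclusion both indicate the deep branch dominates).
* The per-sample whole-clip terms of the positive loss carry no batch
  index in the printed equation; they are averaged over the batch.
* Backbone normalization is instance norm (per sample, per channel)
  rather than batch norm: deterministic at any batch size, no running
  statistics, exact for batch-of-one inference.
* The reference is single-channel while the backbone emits six; the
  supervised cosine loss reduces predictions by the channel mean, the
  symmetric choice.

## Synthetic data generator

The generator renders face and hand clips whose skin region (a filled
ellipse / rounded rectangle over a textured background) carries

* a cardiac oscillation at the configured heart rate with a second
  harmonic at 30% amplitude, modulating each channel by its pulsatile
  fraction α_c: α_B = 0.8% and α_G = 1.2% are fixed, α_R varies with the
  target SpO2 via the ratio-of-ratios law with A = 110, B = 13
  (constants chosen so the 93–100% range maps to plausible red/blue
  ratios of ≈0.77–1.31);
* multiplicative global lighting drift at 0.1 Hz (below the 0.5 Hz
  analysis band, so the cardiac band-pass removes it);
* optional in-plane rotation of the face (a slow sinusoidal angle
  trajectory), emulating head motion;
* static multiplicative skin texture (0.5% default) and per-pixel
  Gaussian sensor noise (σ = 0.003 default).

Structural randomness (texture, phases) is driven by a separate
`structure_seed`, so different noise seeds leave the deterministic scene
unchanged.  `invert_ratio_of_ratios` applies the calibration law in
reverse from detrended channel-mean traces and recovers configured
traces within 0.5% MAE on clean scenes — the generator's
self-consistency oracle.

What the generator does **not** emulate: melanin and physiology-resolved
optics, facial geometry and landmarks, out-of-plane pose, specular
highlights, compression artifacts, or realistic skin texture.  Passing
tests therefore demonstrate that the pipeline recovers the encoded
signal under the stated nuisances (noise, drift, rotation), not clinical
accuracy on real skin.

Synthetic cohorts give each participant an individual heart rate
(60–90 bpm), baseline SpO2 (95–99%), and a breath-hold-like desaturation
dip (1.5–3.5% deep), so a predict-the-global-mean baseline is
meaningfully imperfect both between and within subjects.

## Evaluation protocol

Evaluation is leave-one-participant-out on the SpO2 stage.  Following
the original protocol — where contrastive pre-training and rPPG
fine-tuning use *separate* corpora from the oximetry dataset — stages
1–2 train once on an auxiliary synthetic cohort that contains none of
the evaluation subjects; each fold then trains only the SpO2 stage on
its five training subjects.  No test-subject frames enter any training
stage of their fold.  End-to-end ablation arms (no pre-training) train
from scratch within each fold.  Per-fold MAE/RMSE/Pearson are aggregated
as median and IQR.  Ablation arms: a generic backbone+LSTM baseline,
the backbone+CNN-BiLSTM variant, baseline+contrastive, baseline+MFAM,
and the full model — all on identical folds and seeds.

## Numerical and engineering choices

* **numpy autodiff backend.** The networks run on an in-repo
  reverse-mode autodiff kernel over numpy, with direct numba-JIT conv3d
  kernels (4-way output-channel blocking; cross-checked against a pure
  numpy matmul formulation in the tests), a fused instance-norm(+ReLU)
  primitive, and glibc allocator tuning.  float32 for network state,
  float64 wherever loss values are compared against oracles.
* **Optimization.** Adam throughout.  Stages 3/e2e use β₂ = 0.99 — the
  50/50 fusion init produces initial residuals of tens of percent, and a
  long second-moment memory would throttle steps long after the offset
  is fixed — and a ×25 learning-rate multiplier on the single fusion
  gate parameter, whose useful range (several logits across a 0–100
  scale) is far wider than that of ordinary weights.  The deep head's
  output bias initializes the sigmoid at 96.5%, the middle of the
  measurement range.
* **Augmentation.** SpO2-stage batches apply random circular time shifts
  plus small additive noise to the head's time-series inputs.  Labels
  and amplitude summaries are shift-invariant, so this suppresses
  memorization of individual windows without touching the signal.
* **FIR band-pass.** Windowed-sinc, order 4·rate/f_low (241 taps at
  30 Hz), applied forward–backward.  Zero-phase edge transients last
  about one filter length; amplitude assertions therefore exclude 8–9 s
  at each end, and label preparation caps the order at one third of the
  reference length for short recordings.
* **PSD.** A single Hann-windowed periodogram over the analysis window
  (not Welch), restricted to 0.5–4 Hz and L1-normalized — maximal
  frequency resolution for 1–2 s windows.  The differentiable variant
  used inside the losses adds a 1e-8 floor before normalization so
  pulse-free pseudo clips yield finite, near-uniform spectra.
* **Degenerate inputs.** Constant signals are rejected for
  normalization/cosine similarity; all-zero spectra are rejected;
  detection failures name the frame; boxes are clipped to frame bounds
  with a warning.

## Desk-scale profile

CPU-scale experiments use 16×16 ROIs (8×8 quadrants), width_mult 0.25,
16 s subjects, T = 60-frame windows at 30 fps, an auxiliary cohort of
8 subjects (one window each) with 20+20 pre-training epochs, 250 SpO2
epochs (the frozen-backbone stage is cheap, and the gate needs the
steps), and 10 end-to-end epochs for the ablation arms.  These sizes
were fixed by flop budgeting for a single CPU core; the full-scale
profile (128×128, reference widths, published epoch counts) is the
documented default of the model classes themselves.

## Known limitations

* The optical model is a two-term linear calibration; real skin spectra,
  motion blur and sensor pipelines are far richer.
* Quadrant sub-ROIs at desk scale are 8×8 pixels; spatial-similarity
  pre-training at that size is a weaker signal than at full resolution.
* The MFAM branch's weighted feature sum lives on the feature scale
  (≤ max C_w ≈ 0.8), so the fusion gate must, and does, learn to weight
  the deep branch heavily; this mirrors the published trained split
  (87/13) but means the manual branch mostly refines offsets.
* Pearson correlations on short test traces (8 windows per subject) are
  noisy; medians across folds are the reliable summary.
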