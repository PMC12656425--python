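# Methods

This note documents the models and procedures implemented in voxfuse, the
defaults and why they were chosen, the numerical decisions that matter, and
what the synthetic-data experiments do and do not demonstrate.

## Synthetic phonation model

Sustained phonation is emulated cycle by cycle. Cycle *i* lasts
`T_i = (1/f0) · max(N(1, jitter_rel), 0.2)` seconds and contains
`A_i · Σ_{k=1..K} (1/k) · sin(2πk t / T_i)` with
`A_i = max(N(1, shimmer_rel), 0.05)` and `K = 10` harmonics. The 1/k
roll-off gives a sawtooth-like vowel proxy whose cycle boundary is an
upward zero crossing with maximal slope — an unambiguous landmark for
cycle marking. White Gaussian noise is scaled over the voiced region so
the harmonic-to-noise power ratio equals `hnr_db` exactly by construction.
The realized per-cycle periods and amplitudes, the noise RMS and the
voiced interval are recorded as ground truth; applying the jitter/shimmer
formulas directly to these sequences defines the oracle values that the
extraction-recovery tests compare against.

Defaults: `f0 = 150 Hz`, 1 s duration, 16 kHz. Cohort class profiles are
directionally consistent with Parkinsonian dysphonia — PD:
`jitter_rel = 0.02, shimmer_rel = 0.06, hnr_db = 12`; control:
`0.005, 0.02, 22` — and are toolkit defaults, not literature estimates.
Subjects carry a multiplicative log-normal random effect
(`subject_sigma = 0.15` on perturbation parameters, 1.5 dB on HNR), and the
synthetic embedding block is a pair of unit-covariance Gaussians at a
configurable Mahalanobis separation (default 3.0) plus a within-subject
offset. Cohorts can be generated as full audio or directly in feature
space; feature-space generation maps the perturbation parameters to the
feature columns through the folded-normal expectation
`E|ΔT|/T = σ·√2·√(2/π)` so the two modes are statistically consistent.

What the generator does **not** emulate: glottal-source/vocal-tract
physiology, formant structure, conversational speech, recording-channel
variation, or the correlation structure of real clinical features. Passing
recovery and learning tests on this data shows the estimators and the
training machinery are correct, not that any accuracy level transfers to
clinical recordings.

## Preprocessing

Resampling is polyphase band-limited (`scipy.signal.resample_poly`) with a
rational factor; VAD uses 30 ms frames at a 10 ms hop, marking frames whose
RMS energy exceeds the loudest frame by more than −40 dB, merging adjacent
active frames and discarding runs shorter than 3 frames. Spectral gating
estimates a per-bin noise floor from the lowest-energy decile of STFT
frames and applies the soft gain
`clip((|Z| − thr) / (1.5·thr), 0, 1)` with
`thr = floor_mean + 1.5·floor_std`; gains never exceed 1, so gating cannot
add energy. The estimator presumes stationary noise observable in the
quiet frames (pauses); a recording with no pauses has no observable noise
floor, and a stationary tone is then indistinguishable from noise. The
gate is off by default for sustained phonation and intended for
conversational audio. Duration fitting standardizes the pre-pad region to
zero mean / unit variance and zero-pads or truncates at the tail to 30 s.

## Biomarker extraction

Pitch analysis uses 40 ms frames (10 ms hop, at least two maximum periods
per frame). The frame autocorrelation is computed by FFT and oversampled
8× in lag by zero-padding the power spectrum — exact band-limited
interpolation — then corrected for the rectangular taper `(1 − τ/N)`.
Voicing requires a normalized peak ≥ 0.3 within the 50–500 Hz lag band.
Lag selection is octave-robust: among near-maximum values (≥ 0.9 of the
peak) the first contiguous run is taken, since integer multiples of the
true period score equally high.

Cycle marks are placed at the upward zero crossing preceding each waveform
peak, with linear sub-sample interpolation. The choice is deliberate: a
marker at any fixed nonzero phase of the cycle mixes adjacent periods
(`mark_i = start_i + φ·T_i` implies
`mark_{i+1} − mark_i = (1−φ)T_i + φT_{i+1}`) and deflates jitter by up to
~20% at φ = 0.25, whereas the zero crossing sits at φ = 0 and recovers the
realized periods directly. Per-cycle amplitudes are peak-to-peak between
consecutive marks.

Jitter and shimmer follow the formulas in the README; RAP/PPQ5/APQ3 use
the standard Praat/MDVP moving-average conventions. HNR is computed per
voiced frame as `10·log10(R/(1−R))` at the frame's pitch-period lag
(fractional, clamped to (0,1)) and averaged in dB. Note that HNR measures
*total* aperiodicity: injected jitter/shimmer lower it below the
additive-noise level, which is physically correct behaviour for this
measure. MFCCs use a 26-filter triangular mel bank (HTK mel scale),
512-point FFT, 25 ms/10 ms framing, an energy floor of 1e-10 before the
log, and the cosine transform
`MFCC_k = Σ log(S_n) cos(πk/M(n−½))` averaged over frames.

The default 22-entry extraction schema is Fo/Fhi/Flo, jitter (%, abs, RAP,
PPQ5), shimmer (local, dB, APQ3), HNR, and MFCC 1–11. The published UCI
Parkinson's column set (which includes measures such as RPDE, DFA, PPE
that have no agreed closed-form definition) is accepted schema-driven for
CSV parsing but not computed from audio. Z-score standardization uses the
population (divide-by-N) standard deviation, fitted on training rows only;
constant features map to 0 with a logged warning.

## Neural components

Both networks run on a small in-package reverse-mode autodiff engine
(float64 numpy). The speech encoder is a strided 1-D convolution stack
(default widths 10/8/8/8, strides 5/4/4/4 — cumulative stride 320, i.e.
~50 tokens/s at 16 kHz) followed by pre-norm transformer blocks; the
default hidden size is 768 to honour the architecture family it emulates,
while experiments and tests use d = 32. The projection head is a 2-layer
MLP (d → d → 128); its output is used only inside the contrastive loss —
the downstream embedding is the un-projected temporal mean pool.
Temperature τ starts at 0.07 and is learned on the log scale. Positive
pairs are two independent draws of the augmentation chain
time-mask → additive noise (SNR 25–30 dB) → circular shift (±5%), each
applied with probability 0.5 in that fixed order; a mask never covers more
than half the utterance so a view always retains content. The pretraining
interface consumes plain waveform lists — there is no label field to read.

The fusion classifier: Block A is
`BN(Drop(ReLU(Dense₂(Drop(ReLU(Dense₁(x)))))))` plus a **learned linear
skip projection** (input and output widths differ, so an identity skip is
unavailable). Block B reshapes the hidden vector into S = 8 tokens of
512/S dims (4 heads, FFN width 256, pre-norm, dropout) with a whole-block
residual; zeroing its weights reduces it exactly to the identity, which
the wiring tests exploit. The head is 512 → 128 → 2 with ReLU, BN,
dropout 0.5 and a softmax; the loss is 2-class categorical cross-entropy
with a 1e-12 floor inside the log (for a 2-way softmax this coincides with
binary cross-entropy).

## Training and evaluation

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with L2 weight decay 1e-4, batch
size 32, cosine-annealed learning rate from η_max = 1e-4 to η_min = 1e-6
over T = 100 epochs, early stopping on validation loss (patience 10,
absolute improvement threshold 1e-5), keeping the minimum-validation-loss
checkpoint. Biomarker training rows are re-augmented each epoch with
Gaussian noise of sd = 5% of each feature's training-set range.

Desk-scale experiments (the test suite and examples) keep the same
optimizer and schedule shape but use η_max = 1e-3, η_min = 1e-5 and 40–60
epochs with a 64-unit classifier: the full-scale rate is tuned for
fine-tuning a large pretrained encoder, while the small from-scratch
numpy model needs a proportionally larger step to converge in the same
number of passes.

Splits are subject-wise 70/15/15 by default, stratified at the subject
level by each subject's majority label so every set sees both classes
whenever the cohort allows it; a sample-level stratified 80/20 mode exists
for protocol parity but is not leakage-free and is never the default.
Cross-validation folds are subject-wise and label-stratified; each fold's
training subjects are re-split internally (85/15) to drive early stopping.
Metrics come from the 2×2 confusion matrix; AUC is the trapezoidal area
under the ROC with the midpoint tie convention (a constant score yields
exactly 0.5). The ablation grid runs named configurations — full,
drop-biomarkers, drop-embeddings, no-batch-norm, no-dropout, late-fusion
voting (two unimodal networks, averaged probabilities), and a logistic
baseline on biomarkers — under one shared split and seed.

## Attribution

MDI importance fits a `RandomForestClassifier` (500 trees, Gini,
unlimited depth, fixed seed) on one feature block and reports normalized
`feature_importances_`. Shapley values use Monte-Carlo permutation
sampling: each draw picks a random permutation and a random background
row, walks the permutation replacing background coordinates with the
sample's, and credits each feature with the change in model output. Per
draw the credits telescope to `f(x) − f(b)`, so the averaged attributions
satisfy local accuracy exactly against the mean background prediction;
the residual is reported anyway as a numerical check. The default
background is ≤ 100 training rows. The two methods are deliberately kept
distinct: MDI is a fast global ranking, Shapley a per-prediction
explanation; they answer different questions and are never merged.

## Numerical and design decisions

- Everything runs in float64; finite-difference gradient checks hold to
  ~1e-6 relative where gradients are resolvable.
- Autocorrelation oversampling by spectrum zero-padding was chosen over
  parabolic peak interpolation because the parabola's curvature error is
  amplified ~400× when mapped through `R ↦ 10·log10(R/(1−R))` near R = 1.
- Perturbation quotients snap to exactly 0 on constant windows to avoid
  floating-point residue breaking the "zero on perfectly periodic input"
  property.
- The greedy subject assignment guarantees per-label sample counts within
  one subject's worth of the targets; empty sets are repaired by moving a
  subject from the largest set.
- Checkpoints are single-file `.npz` archives embedding the architecture
  configuration; loading validates shapes before accepting weights.
- All randomness flows from one global seed through named substreams
  (`SeedSequence([seed, crc32(name)])`), so any module's draws are
  reproducible in isolation.

## Known limitations

- The synthetic vowel proxy has no formant structure; MFCC features
  therefore carry little class signal in synthetic cohorts (they are
  class-neutral by construction in feature-space mode).
- Autocorrelation HNR saturates for very clean signals (R → 1) and is
  biased low in the presence of strong jitter; both are properties of the
  measure, not implementation artifacts.
- The contrastive encoder at desk scale learns augmentation invariance,
  not phonetics; its embeddings separate synthetic cohorts only because
  the cohort generator plants a separable embedding block.
- No calibration of predicted probabilities beyond confidence reporting;
  the confidence-distribution overlap mass is descriptive, not a
  calibrated risk.
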