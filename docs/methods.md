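# Methods

`ppgbp` estimates systolic and diastolic arterial pressure (SBP/DBP, mmHg)
from 3-second windows of photoplethysmogram (PPG), using a 1-D residual
convolutional network with a multi-scale stem and squeeze-and-excitation
(SE) channel attention, trained with the Huber loss. This note records the
model, the choices that were genuinely open, and what the synthetic study
does and does not demonstrate.

## Signal model and synthetic data

Real training data for this problem are paired PPG and invasive arterial
blood pressure (ABP) waveforms sampled at 125 Hz. The built-in simulator
stands in for such recordings so the full pipeline is testable offline.

Each cardiac cycle is a sum of two Gaussian lobes on the beat's local time
axis: a systolic peak (relative position 0.16 of the period) and a dicrotic
lobe whose amplitude is `dicrotic_strength` (default 0.4). Beat-to-beat
period jitter (±3% by default) makes the train quasi-periodic. The ABP
channel is the same pulse train affinely rescaled per beat so each beat's
maximum/minimum equals that beat's SBP/DBP exactly; the PPG channel
additionally carries baseline drift (0.1 Hz sinusoid), powerline
interference (50 Hz, above the filter pass-band by design) and white noise.

Blood pressure is coupled to pulse *morphology*, not amplitude, because
per-segment Min–Max normalisation destroys absolute scale:

- systolic lobe width `sigma_s = 0.055 + 0.045·(180 − SBP)/90` (fraction of
  the period) — strictly decreasing in SBP;
- dicrotic lobe position `t_d = 0.36 + 0.24·(DBP − 50)/40` and width
  `sigma_d = 0.07 + 0.07·(DBP − 50)/40` — strictly increasing in DBP.

The ramps span the physiologic design range (SBP 90–180, DBP 50–90 mmHg,
pulse pressure ≥ 20) and extrapolate linearly outside it, so monotonicity
is global. Heart rate is drawn per record from 55–85 bpm. Two BP presets
exist: `uniform` (SBP ~ U[90, 180], DBP ~ U[50, 90]) and `skewed`
(gamma-tailed, mimicking the right-skewed pressure histograms of ICU
cohorts).

What the simulator does **not** emulate: hemodynamic (Windkessel) wave
physics, pathology-specific morphology, motion artifacts, sensor coupling
changes, or between-subject morphology variation unrelated to pressure.
The BP-from-shape mapping is clean and deterministic by construction, so a
network that recovers it demonstrates that the pipeline and optimizer work
end to end — it says nothing about accuracy on clinical data.

## Conditioning chain

Fixed stage order: filter → segment → extract references → screen →
normalize/derive (asserted via per-segment provenance trails).

1. **Band-pass filter**: 4th-order Butterworth, 0.5–8 Hz, applied to the
   PPG only. Zero-phase (forward–backward) filtering is the default
   because phase distortion would bias the derivative channels; a causal
   single-pass mode is retained. Zero-phase squares the magnitude
   response (doubling attenuation in dB); tests use the single-pass
   analytic response as the bound.
2. **Segmentation**: 3-s windows (375 samples at 125 Hz), stride equal to
   the window by default (the stride is configurable; nothing in the
   pipeline depends on overlap). ABP windows are cut at identical offsets
   and are never filtered or normalised, so labels stay in mmHg.
3. **Reference extraction**: SBP = mean of detected per-beat ABP maxima,
   DBP = mean of per-beat minima. Peak detection uses a minimum peak
   distance of one period at 180 bpm and a prominence of half the window
   range — the half-range prominence keeps dicrotic peaks out of the beat
   count. Fewer than two detected beats falls back to the global
   max/min; a flat window (< 1 mmHg range) yields NaN references, which
   the screening stage turns into a BP-range failure rather than an
   exception.
4. **Quality screening** (a segment is kept iff all rules pass):
   reference SBP ≤ 180 mmHg **and** DBP ≥ 50 mmHg (read as: exclusion
   when either bound is violated); PPG skewness ≥ 0 (third standardized
   moment with population, divide-by-N statistics); autocorrelation SQI
   ≥ 0.6. The SQI is the maximum mean-removed Pearson autocorrelation
   over beat-period lags spanning 30–150 bpm, with the lag search capped
   at `len(x) − 32` so a 3-s window is always valid (the nominal 30-bpm
   lag of 250 samples leaves 125 overlapping samples). Every rule outcome
   is recorded per segment, so kept + per-rule failures always reconcile.
5. **Channels**: channel 0 is the Min–Max-normalised PPG; the velocity
   (VPG) and acceleration (APG) channels are successive first differences,
   right-padded by repeating the last difference and independently
   re-normalised to [0, 1]. Differencing after normalisation guarantees
   the stated input range for all three channels; the edge-replicate pad
   keeps a linear ramp's VPG exactly constant, which is then rejected as
   degenerate. Min–Max degeneracy uses a relative tolerance of 1e-9 so
   rounding-floor ranges count as constant.

## Architecture

`MSAResNet` is a 1-D adaptation of a 34-layer residual network (all
convolutions, pooling and global averaging act along time; the inputs are
3×375 channel stacks):

- **Multi-scale stem (MSFE)**: four parallel stride-2 branches — regular
  convolutions with kernels 3/5/7 plus a large-kernel-13 branch realised
  as a depthwise convolution followed by a pointwise (kernel-1) mixing
  convolution (3·13 + 3·16 = 87 weights vs 624 for a full kernel-13
  convolution). Same-padding keeps all branch lengths equal; outputs are
  concatenated (4×16 = 64 channels) and reshaped by a kernel-1
  convolution.
- **Stages**: [3, 4, 6, 3] residual blocks at widths [64, 128, 256, 512],
  stride 2 at each stage entry after the first; a max pool (3/2, pad 1)
  follows the stem. Each block is conv–BN–ReLU–conv–BN with an SE module
  (reduction 16) applied to the residual branch before the shortcut
  addition, and a projection (kernel-1 conv + BN) shortcut where stride
  or width changes. SE sits in every block.
- **Head**: global average pool → fully connected layer with two outputs,
  predicting SBP and DBP jointly in mmHg.

Choices that were open and how they were settled: batch normalisation +
ReLU after every convolution (required for trainability at this depth);
bias-free convolutions wherever a batch norm follows (its shift subsumes
the bias); SE reduction 16 and residual-branch placement (the standard
SE-ResNet arrangement); stem stride 2 + max pool mirroring the classic
ResNet stem. A `width_multiplier` scales every channel count so the
desk-scale quarter-width model exercises the identical code path.

The network and its training loop are implemented as a self-contained
numpy engine (`ppgbp.nn`) with explicit forward/backward passes; every
layer's analytic gradient is verified against central finite differences
to ~1e-7 in the test suite.

## Training

Loss: Huber with δ = 1 mmHg (quadratic below δ, linear above; continuous
first derivative at the knee), averaged over samples and both targets,
with error convention `reference − predicted`. MSE and MAE are provided
for the loss-ablation experiment. Optimizer: SGD with classical momentum
0.9 and weight decay 0 by default, learning rate on a single cosine cycle
`lr = eta_min + 0.5(lr0 − eta_min)(1 + cos(π·epoch/total))`. Splits are
7:1:2 (train/validation/test) over segments by default, floor-sized and
seeded; a record-unit split is available because segment-level splitting
leaks subjects across partitions. The best checkpoint is the lowest mean
of SBP and DBP validation MAE (restored after the last epoch). Training
aborts with a diagnostic if the loss becomes non-finite. Everything is
bit-reproducible given the seed.

Two hyperparameter regimes:

- **Reference protocol** (the `TrainConfig` defaults): batch 1024,
  lr0 = 0.001, 120 epochs — sized for ~50k segments.
- **Desk scale** (`MSAResNetRegressor.small_defaults()`): quarter width,
  batch 64, lr0 = 0.05, 20 epochs, output-head bias initialised at the
  training-label means. With labels in mmHg and δ = 1 the Huber loss is
  almost everywhere in its linear regime, so per-sample gradients are
  bounded by ~1; a 20-epoch run on 2,000 segments therefore needs the
  larger step size, and starting the head at the marginal predictor
  removes the long bias walk to the ~130/75 mmHg operating point.

Problem sizes used by the scaled experiments (tests and
`scripts/acceptance.py`): 700 clean 10-s records → 2,000 segments, 400
held out for testing; the loss-ablation run uses 800 segments, 10 epochs,
lr 0.02 and 5% gross label outliers (±40–80 mmHg). On this synthetic
study the quarter-width model reaches held-out MAE of roughly 1–2 mmHg
(SBP) and below 1 mmHg (DBP) — far below a constant-mean predictor
(~22/10 mmHg) — and the Huber-trained model's clean-test MAE does not
exceed the MSE-trained counterpart's under label outliers. These numbers
characterise the noise-free simulator, not clinical performance.

## Evaluation

- `error_stats`: ME, SD, MAE with `error = reference − predicted`. SD is
  the sample standard deviation of the errors about their mean (ddof = 1),
  the standard device-evaluation usage; an `sd_as_printed` switch computes
  `sqrt(Σe²/(m−1))` without mean-centering for compatibility with reports
  that define it that way.
- AAMI verdict: pass iff |ME| ≤ 5 mmHg and SD ≤ 8 mmHg, bounds inclusive
  (boundary behaviour is unobservable in practice; inclusivity is
  declared).
- BHS grade: cumulative percentages of |error| ≤ 5/10/15 mmHg; grade A
  requires 60/85/95, B 50/75/90, C 40/65/85 simultaneously (≥), else D
  (the protocol's below-C verdict).
- Bland–Altman: mean difference and 95% limits of agreement
  (mean ± 1.96·SD of the differences), plus the fraction of differences
  inside the limits.
- Correlation: Pearson product-moment (regression scatter plots are
  linear, so Pearson is the natural choice).

## Pipeline and reproducibility

`run_all` chains simulate → preprocess → train → evaluate from one
validated YAML mapping (unknown keys rejected before any compute). A
single global seed fans out to per-stage sub-seeds via
`numpy.random.SeedSequence([global_seed, stage_index])`; per-record
sub-seeds spawn from the dataset seed the same way. Every artifact is
listed in a manifest with its SHA-256 hash and dependency chain.

## Known limitations

- The simulator's BP-morphology coupling is injective and noise-free at
  the defaults used for the learning-recovery study; real PPG-BP coupling
  is confounded by subject physiology, and segment-level splits further
  flatter the result. The record-unit split option exists for the honest
  variant.
- The window-length precondition "within half a sample of an integer" is
  vacuous at 125 Hz (any window rounds); windows are rounded to the
  nearest sample count.
- The reference-extraction prominence (half the window range) assumes the
  dicrotic wave stays below half the pulse pressure; extreme
  `dicrotic_strength` values near 1 could be miscounted.
- Training is CPU-bound numpy; the full-width, batch-1024, 120-epoch
  protocol is expressible but not practical here — the quarter-width
  configuration is the supported desk-scale model.
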