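# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `nirsbreath`, and what the test suite does and does not
establish.

## Signals and windows

A recording is a 4-channel series of hemodynamic concentration changes
(PD1-O₂Hb, PD1-HHb, PD2-O₂Hb, PD2-HHb; two photodetector depths) sampled at
120 Hz. The sampling rate is metadata only — no resampling is performed.
Classifier inputs are 384-sample crops (~3.2 s). The windowing stride is
configurable with a default of 32 samples: dense enough to multiply the
training set, coarse enough to keep desk-scale runs tractable (the original
acquisition protocol does not pin a stride, and published window totals do
not disambiguate it). Splits are always by participant, never by window;
the split constructor rejects any overlap, and the augmentation-statistics
API takes a `forbid_participants` guard so held-out subjects can never leak
into training statistics.

## Impulse filtering

Wearable NIRS electronics produce voltage-transient spikes. Per channel, the
forward difference d[t] = x[t+1] − x[t] is computed once; samples whose
difference leaves the interval mean ± z·STD are flagged, with z the two-sided
normal quantile of the configured coverage (z = 1.6449 at the default 90%).
Choices made where the procedure is underdetermined:

* the *later* sample x[t+1] of an outlying difference is flagged — an impulse
  onset manifests in the forward difference into the corrupted sample;
* statistics are computed in a single pass (no re-estimation after removal);
* `delete` mode removes the cross-channel union of flagged indices so
  channels stay aligned; `interpolate` mode patches each channel from its own
  nearest clean neighbours and preserves length, which windowing prefers.

On a pure Gaussian random walk ~10% of samples are flagged by construction;
the filter is meant for signals whose derivative is dominated by smooth
respiratory structure, where the flagged set concentrates on true transients.

## Synthetic cohort

The generator exists so that every downstream stage is testable without the
original recordings. Each channel is

    DC offset + linear drift + skewed breathing oscillation
    + cardiac ripple + white noise + Poisson impulse artifacts

with one trait draw per participant (DC level, amplitude factor, waveform
skew, drift sign, cardiac rate) shared across that person's recordings, and
channel-specific gains giving the deeper photodetector a larger response and
the HHb channels a negative (anticorrelated) respiratory gain. Class
definitions: slow = 10 breaths/min and rapid = 30 breaths/min (paced tasks,
small ±0.5–1 bpm pacing jitter); normal spans the physiological resting range
12–20 breaths/min, deliberately bordering the slow class so the task is
learnable but not trivial; breath-hold is a near-flat trace with a slow
monotone drift. The skewed oscillation sin(θ + s·sinθ) models unequal
inspiration/expiration durations without moving the fundamental frequency.

Amplitude defaults (oscillation 0.25–1.0 units × participant factor 0.6–1.4,
DC ±0.5, noise SD 0.02, cardiac 0.04) are chosen so per-window peak-to-peak
amplitudes span roughly 0.4–2.3 concentration units; dataset-statistics-driven
scale factors then land in the same order-one range as published augmentation
examples, and the literal scale-interval reading (below) behaves sensibly.

What the generator does **not** emulate: motion artifacts, baseline shifts
from sensor re-seating, breath-to-breath rate variability within a task,
Mayer waves, or realistic hemodynamic response dynamics (no Windkessel or
Beer–Lambert modelling). Passing desk-scale tests therefore demonstrates
correct implementation and the qualitative value of the architecture and
augmentation — not clinical performance on real recordings.

## Augmentation

For a training dataset D and window I (statistics per channel by default):

* scale: I·γ, γ ~ U[min_D ptp(d), max_D ptp(d)] — the literal reading of the
  published interval, used as the default. A `ratio` mode dividing by ptp(I)
  is also provided: it keeps the *scaled* window's peak-to-peak inside the
  dataset range and guarantees the subsequent offset interval cannot invert.
* offset: I+β, β ~ U[min_D min(d) − min(I), max_D max(d) − max(I)], sampled
  *after* scaling (matching the operator nesting); this keeps the shifted
  window inside the dataset's amplitude envelope. If scaling pushed the
  window's range beyond the envelope the interval inverts; β is then clamped
  to 0 and logged.
* flip: joint time reversal of all channels with probability ½.

Uniform sampling within the intervals is the maximum-entropy choice; the
source material states the intervals but not a distribution. Augmentation is
applied on the fly per training batch and never to held-out data.

## Architecture

Both streams are built from pre-activation bottleneck units (BN → ReLU →
conv ×3, kernel 1/3/1; the optional stride or transposed upsampling sits on
the first convolution; shortcut = identity, or a learned 1×1 (transposed)
projection applied to the first pre-activation output when shape changes).
Stage tables (channels as c1,c2,c3 triples):

| part | stages |
|---|---|
| encoder | stem 7×1,16 /4 → stem 7×1,16 /3 → 5×(16,16,64) → 5×(32,32,128) /2 |
| decoder | 5×(128,32,32) ↑2 → 5×(64,16,16) → t-stem 5×1,16 ↑3 → t-stem 7×1,4 ↑4 |
| classifier | stems as encoder → 22×(16,16,64) → 11×(32,32,128) /2 → fusion → 11×(32,32,128) → 22×(64,64,256) /2 → BN-ReLU → global average pool (256) → FC → 4 |

The classifier has 201 weight layers (2 stems + 3·66 block convolutions +
1 FC; projections and normalizations are not counted, the usual residual-
network naming). The single-stream ablation drops the autoencoder and runs
stage 3 unstrided; its 264-layer variant distributes 21 extra units over
stages 2–5 proportionally (29/15/14/29, largest-remainder rounding).

**Fusion axis.** The encoder's 128×16 output joins the classifier's 128×16
stage-3 output. Two readings are implemented. The *channel* reading (default)
stacks to 256×16 and leaves stage 4 unstrided; it reproduces the published
complexity budget — 1.50 M parameters and 16.43 M multiply-accumulates per
window on the inference path, against published figures of 1.53 M and 16.4 M —
and is most consistent with the budget's margin. The *time* reading appends
to 128×32 with a strided stage 4, matching the published per-stage temporal
extents. The two are identical from stage 5 onward; both are tested.

**Counting conventions.** Convolutions keep their bias terms even where a
normalization follows (the bias is then functionally inert, but it is the
common default of mainstream frameworks and the convention under which the
parameter budget reconciles; it contributes ~1% of parameters). One
multiply-accumulate = one FLOP; transposed convolutions are charged one MAC
per kernel tap per *input* position (their true cost), projections, pooling
adds and the FC layer are all included. The published budget matches the
inference path (encoder + classifier); decoder-inclusive summaries
(1.63 M / 20.2 M) are available via `include_decoder=True`. Every count is
computed twice — from the built layer objects and from a closed-form walk of
the declarative stage table — and the test suite requires exact agreement.

**Desk-scale variants.** `width_scale` multiplies all channel counts and
`depth_scale` all unit counts (each floored at 1). Geometry (stage extents,
fusion compatibility, decoder output shape) is preserved under scaling and
property-tested.

## Training

Two phases, SGD with momentum 0.9, batch 128, learning rate ÷10 every 30
epochs (all configurable):

1. **Autoencoder pre-training** minimizes the reconstruction loss alone
   (initial rate 0.1); the resulting weights initialize the two-stream
   model's autoencoder.
2. **Joint training** minimizes L_R + α·L_C with α = 10 (initial rate 0.01)
   over *both* streams — the encoder is not frozen, since the coupled
   objective trains it further; a freeze is possible by passing the
   autoencoder parameter group to a separate optimizer.

**Loss scaling.** L_R is defined as the mean over windows of the *summed*
squared error — ~1536× the elementwise mean. Gradient magnitudes at that
scale are incompatible with the standard learning-rate regime above (SGD
diverges), so the optimizer minimizes the elementwise-mean form by default
(`recon_reduction="mean"`; same minimizer, rescaled gradients) and histories
report L_R in the definitional units. The definitional form is available via
`recon_reduction="sum"` with correspondingly smaller rates.

Cross-entropy uses mean reduction; weight decay defaults to 0; batches are
reshuffled every epoch and the last incomplete batch is kept. α is constant
from epoch 0. Divergence (non-finite loss) aborts with a diagnostic rather
than continuing. Runs are deterministic under a fixed seed up to
floating-point reduction order; the CLI fans one global seed into per-stage
seeds through a fixed affine map so stages are independently reproducible.

Desk-scale problem sizes used by the test suite (chosen to exercise the full
protocol in minutes on one CPU): a 14-participant cohort with an 11/3 split,
90 s per task, stride 128, a ¼-width 1/10-depth model, 10 pre-training and
60 joint epochs (rate decayed every 25) for the learning check — the second
decay step is what stabilizes the held-out accuracy across training seeds —
and a deliberately small 6-participant
15 s cohort for the augmentation ablation; a ½-width model and 30 epochs for
the pre-training check. The ablation uses 5 seeded repeats and compares mean
held-out accuracy, mirroring the repeated-from-scratch evaluation format
(mean / sample STD with n−1 / best).

## Evaluation

Accuracy is 100 × correct/total. Confusion matrices are row-normalized by
true class in the fixed order (normal, hold, slow, rapid); rows without test
support are all-zero and flagged rather than NaN. With equal class support
the diagonal mean equals accuracy/100, an identity the tests exploit.

## Known limitations

* The NumPy engine is single-threaded NumPy/BLAS; full-size 140-epoch
  training is out of its intended scope (the full model builds and runs
  forward in well under a second, which the complexity checks use).
* Impulse statistics are estimated in one pass; recordings dominated by
  artifacts (most samples corrupted) are rejected rather than cleaned.
* The synthetic cohort's difficulty is not calibrated to the real task;
  absolute accuracies on it do not transfer to real recordings.
* The literal scale-interval reading can produce inverted offset intervals
  for extreme windows (clamped to identity); `ratio` mode avoids this
  entirely.
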