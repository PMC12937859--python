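# Methods

## Problem setting

Implanted brain–computer interfaces record continuously, but motor intent
is sparse: most of the day the cortex near the electrode is doing nothing
the decoder cares about. Streaming full-precision local field potentials
(LFPs) — 12 bit at 2 kHz, 24 kbps per channel — through a wireless link
wastes the implant's power budget on silence. `lfpgate` implements a
hierarchical gating pipeline that decides, every 16 ms, whether the
current data deserves transmission and full-precision decoding, and
quantifies the resulting data-volume reduction.

## The state model

Continuous neural activity is discretized into four states:

* **S0 — distinct rest.** LFP amplitude near the background noise floor.
  The majority of the session.
* **S1 — indistinguishable rest.** No motor intent, but high-amplitude
  interference (EMG, blinks, non-motor fluctuations) that exceeds any
  simple amplitude threshold while lacking pre-movement temporal
  structure.
* **S2 — transition.** The preparation span of length `T_pre` tracing
  back from each movement-trigger event (`t_release`); the climb from
  resting baseline toward the active burst.
* **S3 — fully active.** Movement execution, from `t_release` to the end
  of the trial.

Ground-truth S3 and S2 come from behavioral events; the S0/S1 split is
*defined by* the silence detector — S1 is exactly the rest that fools the
hardware gate. Event-based labels take priority (S3 > S2 > S1/S0). A
window belongs to an interval iff its last sample falls in the half-open
interval `[start, end)`: decisions are stamped causally at window end.
`T_pre` defaults to four analysis windows (4 × 512 ms = 2.048 s) and is
configurable.

## Level 1: the silence detector

Signal strength over a trailing window of `Tw` samples of the virtual
channel `x_vc`:

    E[n] = sum_{k=n-Tw+1}^{n} |x_vc[k]|

This windowed mean-absolute-value (MAV) needs only rectification and
addition — no multipliers — which is why it can run at nanowatt power
next to the electrode. `Tw` defaults to 32 samples at 2 kHz (16 ms), the
pipeline's decision cadence.

The threshold `Vth` is the lower 3% quantile of the strength distribution
during confirmed-active (S3) epochs, taken as the `ceil(q·n)`-th order
statistic without interpolation. Calibrating on the *active* distribution
rather than the noise floor makes the gate a high-recall brain switch: by
construction at least 97% of distinct active strengths exceed `Vth`. Ties
at the threshold transmit (`E >= Vth` wakes the next stage). A window
below threshold is S0 and nothing downstream sees it.

The module also implements the three comparison strength features used to
rank detectors at a fixed 3% active miss rate — per-window median absolute
deviation (MAD), winsorized average (WA, computed on the rectified window
with 5%/95% limits; on the signed zero-mean signal a winsorized mean would
measure level, not strength), and the mean Teager energy operator
ψ[n] = x[n]² − x[n−1]·x[n+1] (NEO, boundary samples dropped) — and a
bit-accurate integer model of the hardware datapath (absolute-value
accumulate and compare). The accumulator must be at least
`input_bits + ceil(log2(Tw))` wide, which makes overflow impossible at
all-rail input; under that invariant the integer decisions equal the
floating-point ones exactly.

## Level 2: the DualGRU cascade

Windows that pass the gate reach a two-stage classifier:

* **GRU1 (screen)** consumes the 6-bit / 1 kHz stream and separates Rest
  from Potential-Active at an operating point chosen for high recall:
  `theta1` is the largest threshold whose recall on a calibration split
  meets the 97% floor (equivalently the `ceil(0.97·n_pos)`-th largest
  positive score), maximizing precision subject to that floor.
* **GRU2 (confirm)** re-examines only GRU1-passing windows on the
  12-bit / 2 kHz stream at threshold `theta2` (default 0.5). Its training
  negatives are the negatives GRU1 passes — its job is GRU1's false
  positives, so it trains on exactly those hard examples (falling back to
  all negatives if GRU1 passes none, to keep training two-class).

The decision chain is strictly monotone: ACTIVE ⊆ Potential-Active ⊆
gate-open, for every threshold setting.

Both stages are single-layer, 32-unit GRUs with a logistic head —
deliberately tiny, matching the nanowatt-class deployment intent — and are
implemented directly in NumPy with hand-derived backpropagation-through-
time (verified against finite differences in the test suite). Each 512 ms
window is presented as 32 frames of 16 ms (16 samples at 1 kHz, 32 at
2 kHz), one frame per decision step: the recurrence then spans the
decision cadence rather than thousands of raw samples, keeping BPTT short
and well-conditioned. Frames are code-normalized and multiplied by an
input gain that maps the stream's background noise to roughly unit
variance; the noise sigma is estimated as `median(|codes|)/0.6745`, the
robust estimator conventional in neural-signal thresholding. The gain is
stored with the model so training and inference agree.

### Training recipe

Adam at learning rate 3e-4, at most 300 epochs, minibatches of 64,
class-weighted binary cross-entropy (weights inverse to prevalence —
active windows are sparse), early stopping with patience 20 monitoring
validation F1 and restoring the best weights. All randomness flows from
explicit seeds; identical seeds give bit-identical models.

### Cross-validation

Five trial-blocked folds: consecutive windows overlap by 96.9%
(512 ms field of view, 16 ms stride), so window-random folds would leak
nearly identical data between train and test. Every window between one
trial's end and the next belongs to that trial's block. Within the
training folds a seeded 20% of blocks is held out for early stopping and
operating-point calibration. Training thins the window set to a 64 ms
stride (factor 4); evaluation always uses the full 16 ms stride.

Cross-validation scores the *model cascade* (screen at `theta1`, confirm
at `theta2`) over all windows, Active (S2∪S3) vs Rest (S0∪S1). The
hardware gate is excluded from this metric deliberately: in the system's
own labeling a below-threshold window *is* S0, so including the gate would
conflate the detector's calibrated 3% miss with the classifier's errors.
The full chain including the gate is evaluated separately by the
deployment decision trace and its throughput accounting. Fold spread is
reported as the sample standard deviation, `sqrt(sum (x_i - x̄)² / (n-1))`
with n = 5.

## Preprocessing

The virtual channel is the arithmetic mean of N = 4 spatially adjacent
electrodes (adjacent LFP channels are highly correlated with negligible
phase lag, so plain averaging raises SNR without beamforming), averaged in
full precision and then quantized. Decimation uses a zero-phase FIR
low-pass (`firwin` + `filtfilt`, cutoff 0.4·fs_out) — a Chebyshev IIR's
passband ripple, squared by forward–backward filtering, can exceed 1%
amplitude error on in-band oscillations, and phase distortion would shift
the oscillatory features the classifier keys on. The 1 kHz stream is
derived from the 2 kHz stream by the same path so both stages see
time-aligned windows. The quantizer is signed mid-tread with
Δ = 2·FS/2^bits, saturating at the rails; its representable span is the
two's-complement asymmetric `[-FS, FS-Δ]`. Full scale is calibrated to
the 0.1/99.9 amplitude percentiles of the calibration segment so a single
artifact cannot waste the code range.

## The synthetic generator

`generate_session` emulates the *state semantics*, not cortical
biophysics: S0 is Gaussian noise (default sd 5 µV); S1 adds randomly
timed 100–300 ms broadband bursts at 5–10× the noise floor with soft
edges; S3 is a sustained beta + high-gamma mixture (22 Hz at 20 µV, 80 Hz
at 15 µV — the bands carrying motor intent) until trial end; S2 ramps the
oscillation envelope linearly over `T_pre` into the burst. The envelope
starts at 0.25 of the active amplitude rather than zero: the transition
state must be detectable at the window level from its onset for
window-level labels to be learnable, emulating the measurable band-power
rise at movement preparation. Trials are laid out so the requested S2/S3
occupancies are met by construction; S1 bursts fill a sample budget.
Channels share the oscillation/artifact signal plus a configurable
fraction (default 0.8) of common noise. Defaults: 2 kHz, 4 channels,
occupancies S1/S2/S3 = 0.15/0.10/0.12 (S0 the remainder, ~63%, matching
the premise that valid command windows occupy well under a third of the
day).

What the generator does **not** emulate — and therefore what passing tests
do not show about real recordings: 1/f background spectra, nonstationary
noise floors, behavioral variability in burst morphology and timing,
imperfect event annotations, electrode drift, or any dataset-specific
interception/F1 value. Published real-data figures depend on the actual
recordings and channel/threshold choices; this package reproduces the
*protocols* (fixed-miss interception ranking, recall-floor operating
points, occupancy arithmetic) and verifies them on data whose ground truth
is known exactly.

## Throughput accounting

With the gate shutting a fraction `s0` of the session and a fraction
`low` of the remaining windows handled at the low-resolution
configuration (screened rest plus windows whose escalation GRU2 rejected),
and the low-res stream `b` = 1 − (6·1000)/(12·2000) = 75% cheaper than
full resolution:

    occupancy       = s0 + (1 - s0)·low
    total_reduction = s0 + b·low·(1 - s0)

against the 24 kbps/channel full-precision reference. The per-window bit
ledger charges 0 bits to gated windows, the low-res step cost (96 bits per
16 ms) to screened windows, and low + high (96 + 384 bits) to escalated
windows. The reduction formula charges a confirmed-active step the
full-rate cost alone — in sustained active phases the system streams
high-res continuously rather than dual streams per window — so the ledger
and the formula agree up to the low-res prefix of active windows.

## Problem sizes and numerical choices

The acceptance-scale evaluation uses a 300 s default-configuration
session: ~18 700 windows, 15 trials, five folds. Cross-validation of both
stages completes in a few minutes on one CPU; unit tests use 10–60 s
sessions. Other conventions: quantile thresholds are lower order
statistics (hardware-realizable, makes the 97% exceedance property
exact); `E = Vth` transmits; windows are trailing/causal with
`n_windows = floor((n - win)/stride) + 1`; NEO windows drop the two
boundary samples; all-zero streams get unit input gain; AUC in
cross-validation uses the combined score `p1·p2`.

## Known limitations

* The GRU implementation is CPU NumPy: fine for 32-unit models at desk
  scale, not for large architectures. The `MODEL_REGISTRY` hook lets
  alternative sequence classifiers (with the same `fit`/`predict_proba`
  surface) run through the training and cross-validation harness.
* Only single-layer GRUs; `layers > 1` is rejected explicitly.
* The fixed-point model covers the detector datapath (mux–accumulate–
  compare), not the GRU arithmetic: the cascade runs in float, as it does
  on the edge side of the deployment boundary.
* The quantile-threshold gate is amplitude-based and inherits the known
  sensitivity to low-frequency artifacts; the S1 state and GRU1 exist
  precisely to absorb that weakness, but gating quality on real artifacts
  depends on data this package does not model.
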