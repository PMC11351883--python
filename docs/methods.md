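# Methods

## Problem and approach

`hemobeat` estimates four intraventricular hemodynamic parameters on a
beat-by-beat basis from two non-invasive body-surface signals — the
phonocardiogram (PCG) and the femoral photoplethysmogram (PPG):

* **SBP** — peak systolic left-ventricular (LV) pressure, mmHg;
* **DBP** — minimum LV pressure in the diastolic phase, mmHg (an
  intraventricular minimum, which can be negative relative to transducer
  calibration — not cuff diastolic pressure);
* **MRR** (LV +dP/dt_max) — maximum rate of LV pressure rise, mmHg/s, an
  index of contractility;
* **MRD** (LV −dP/dt_max) — maximum rate of LV pressure decline
  (the derivative minimum), mmHg/s, an index of relaxation capacity.

The physiological rationale: the first heart sound's amplitude rises
approximately linearly with the rate of LV pressure rise, the second heart
sound reflects the deceleration at semilunar valve closure, and the PPG
pulse's transit delay and amplitude track systolic pressure and pulse
pressure. A regression network can therefore read these parameters off the
(PCG, PPG) pair of a single cardiac cycle.

## Pipeline

1. **Pre-filtering** (`signal_io`). Zero-phase (forward-backward)
   4th-order Butterworth filters per channel: PCG 30–200 Hz, ECG
   0.5–40 Hz, PPG 0.5–20 Hz. LVBP is low-passed at 20 Hz *without* the
   0.5 Hz high-pass: the absolute pressure level and its slow drug-driven
   excursion are precisely what the beat labels are extracted from, and a
   zero-phase high-pass would remove both. Forward-backward application
   doubles the effective order and cancels phase, so beat-locked features
   stay aligned across channels. Records not sampled at 1 kHz are
   polyphase-resampled first, because the model input window is defined in
   samples at 1 kHz.

2. **R-wave detection** (`segmentation.detect_r_peaks`). The
   Pan–Tompkins algorithm in its classical stages: 5–15 Hz band-pass,
   five-point derivative, squaring, 150 ms moving-window integration,
   adaptive dual signal/noise thresholds with a search-back at half
   threshold when a beat is overdue (1.66× the running R-R average), a
   200 ms refractory period, and refinement of each fiducial to the ECG
   maximum within ±50 ms. Departure from the classical on-line recursion:
   the running signal/noise estimates are initialized from the quartiles
   of all integrator peak heights rather than the first two seconds, so a
   single large artifact cannot dominate the starting threshold; and
   candidates within 100 ms of the record edges are ignored (filtfilt
   transients).

3. **Segmentation and quality screening**. Cycles are the half-open
   sample intervals `[R_k, R_{k+1})` (0-based); the trailing partial beat
   is discarded. Quality gating is template correlation: per channel a
   running template (exponentially weighted mean of accepted,
   length-normalized cycles, update weight 0.1) is correlated with each
   new cycle, and the cycle score is the minimum over PCG and PPG. The
   PCG is correlated through its analytic-signal *envelope*: heart-sound
   bursts are narrowband, and a sub-millisecond carrier-phase shift
   between morphologically identical beats would otherwise destroy the
   correlation. Cycles also fail on flat-line variance, rail clipping
   (≥1% of samples at the extreme), or R-R outside 250–1500 ms. The
   default acceptance threshold is 0.8. On simulated data with 5% of
   beats corrupted by high-amplitude bursts, this gate rejects all
   corrupted beats and no clean ones.

4. **Label extraction** (`labels`). Per cycle: SBP = maximum pressure;
   DBP = minimum over the samples at/after the systolic peak ("end of the
   systolic stroke" is read as the pressure maximum — consistent with the
   reported SBP magnitudes — and "diastolic phase" as everything after
   it); MRR/MRD = extrema of the central-difference derivative scaled by
   the sampling rate. No extra smoothing: the pressure channel is already
   low-passed at 20 Hz.

5. **Spike repair**. Per record and per parameter, beat-to-beat
   differences exceeding 3 robust sigmas (median/MAD·1.4826) from the
   median difference mark candidate beats; an up-then-down pair of
   abnormal differences is consumed as one spike. A candidate is
   confirmed only if the beat value deviates from the interpolation of
   its non-candidate neighbours by the same threshold, which makes the
   rule idempotent and spares genuine trends. Confirmed beats are
   replaced by linear interpolation of the nearest unflagged neighbours.
   The robust sigma (rather than the plain SD of the differences) is
   deliberate: an isolated spike inflates the plain SD enough to mask
   itself on short records. A constant-step sequence (zero MAD) flags
   nothing.

6. **Windowing**. Accepted cycles become fixed 1000-sample × 2-channel
   inputs (PCG channel 0, PPG channel 1), zero-padded at the tail. Cycles
   longer than 1 s cannot fit the window; they are excluded with a
   warning by default (`long_cycle_policy="exclude"`) rather than
   truncated, which would cut diastolic content. Truncation is available
   as a config option.

## The regression network

Input `(batch, 1000, 2)`; targets are the scaled 4-vectors
(SBP/50, DBP/10, MRR/2000, MRD/1000), fixed divisors that equalize the
four contributions to the MSE loss; predictions are inverse-scaled back
to physical units.

Six residual 1-D convolutional blocks: the main branch is
[BN → ReLU (omitted at the start of block 1)] → Conv1D → BN → ReLU →
Dropout(0.2) → Conv1D(stride *s*); the shortcut is MaxPool(*s*), with a
1×1 projection convolution where the channel count changes (block 5,
32→64 — the projection keeps the additive shortcut well-defined). All
convolutions use kernel length 16; kernel numbers are
(32, 32, 32, 32, 64, 64); *s* = 2 in blocks 1, 3, 5 and 1 elsewhere, so
the temporal length falls 1000 → 125 (factor 8). A bidirectional GRU
(32 units per direction) consumes the 125×64 sequence; its summary
feature is the concatenation of the forward and backward final hidden
states (64-dim; temporal mean pooling is selectable), followed by BN,
LeakyReLU (α = 0.01) and a 4-cell dense layer.

Training: MSE on scaled targets, Adam at learning rate 0.001 (plain SGD
selectable), default batch size 64 and 200 epochs; the retained weights
are those of the epoch with minimum validation loss. One integer seed
controls weight initialization, dropout and shuffling, making runs
bit-reproducible on a fixed BLAS.

The layers (convolution via per-tap batched GEMMs, batch norm, GRU with
explicit backpropagation through time, pooling, dropout, dense) are
implemented directly on NumPy in `hemobeat.nn`; every backward pass is
verified against central-difference numerical gradients in the test
suite. Float32 is used throughout training.

## Evaluation schemes

Splits are always at the **record** level — neighbouring beats are nearly
identical, so cycle-level splits would leak test information into
training.

* **Scheme I (within subject)**: the subject's records are shuffled into
  5 near-equal test subsets; per fold, the remaining records are split
  3:1 into train/validation. Every record is tested exactly once.
* **Scheme II (cross subject)**: train on all other subjects' records;
  the target subject's records are halved into validation/test and the
  halves are swapped for a second pass.
* **Calibrated scheme II**: identical, except `n_cal` (default 1) target
  validation records move into the training set; test sets are unchanged
  so results are directly comparable.

Metrics per parameter: ME (mean error), MAE, SD of the mean-removed
errors (N−1 denominator), Pearson CC with its t-test p-value (N−2 df)
and a Fisher-z 95% confidence interval. Fold aggregation is the
unweighted mean of per-fold metrics.

## Synthetic study data

The generator emulates an epinephrine-bolus protocol on an anesthetized
subject: a ~10 s resting plateau, then a double-exponential excursion
(rise τ 6 s, decay τ 10 s) whose magnitude scales with dose (0.5/1/2
units/kg → multipliers 0.55/0.75/1.0), returning to baseline within the
record. Defaults for the primary subject: baseline SBP 130 mmHg, DBP
5 mmHg, MRR 2000 mmHg/s, MRD −2000 mmHg/s, HR 100 bpm; peak deltas at
full dose +115, −32, +5800, −2900 and +35% HR. Beat-to-beat AR(1)
variability is small relative to the excursions, and all parameters are
clipped to the observed total ranges (SBP [77, 272] mmHg, DBP [−47, 20]
mmHg, MRR [106, 9181] mmHg/s, MRD [−5896, −70] mmHg/s).

Waveform kernels are minimal but physiologically shaped, and chosen so
that (a) QRS detection fires, (b) the labels are exactly recoverable from
the pressure trace, and (c) the PCG/PPG morphology carries the label
information the network must learn:

* **LV pressure**: raised-cosine upstroke from end-diastolic pressure
  (DBP + 12 mmHg) to SBP whose peak slope equals MRR exactly
  (T_rise = π·ΔP/(2·MRR)), a short flat plateau at SBP, a raised-cosine
  downstroke to DBP with peak slope MRD, and a smoothstep diastolic
  refill. Infeasible label combinations raise an error: a systole that
  cannot fit inside the R-R interval, a rise or fall faster than 15 ms
  (an isovolumic-phase floor that also keeps the peak slope well
  resolved on the 1 kHz grid), or a diastolic refill so short that its
  slope would rival a small MRR and masquerade as the beat's +dP/dt
  maximum. The feasible-label sampler rejection-samples within the total
  ranges subject to these constraints (jointly uniform sampling over the
  four ranges is physically impossible — a tiny MRR cannot produce a
  large pulse pressure within one beat).
* **PCG**: S1 and S2 as Gaussian-modulated sinusoids (50/70 Hz, σ 12/10
  ms) at the upstroke midpoint and end-systole; S1 amplitude =
  a₁·MRR + b₁, S2 amplitude = a₂·|MRD| + b₂.
* **PPG**: a raised-cosine pulse delayed by a transit time decreasing
  linearly with SBP (280 ms − 0.6 ms/mmHg·SBP), amplitude proportional
  to pulse pressure, a small dicrotic bump, and a baseline offset
  proportional to DBP (giving DBP a direct morphological cue, as the
  diastolic blood-volume level plausibly provides).
* **ECG**: a narrow biphasic R spike at each beat onset plus a low T
  wave — sufficient for the detector, with no P-wave or QT modelling.

White noise is added per channel (default SNR 25 dB for ECG/PCG/PPG,
45 dB for the catheter pressure); a configurable fraction of beats
(default 2%) is overwritten with high-amplitude artifact bursts and
flagged, to exercise quality screening. Between records the acoustic and
optical sensors are "re-seated": per-record lognormal jitter (sigma 0.10)
on the S1/S2 and PPG gain couplings, a few hertz of heart-sound carrier
shift and a few milliseconds of transit-delay offset. This inter-record
variability is what makes a single calibration record an incomplete
description of a subject, as it is in practice. A second subject profile
(`PROFILE_B`) creates a controlled domain shift: its waveforms *look*
like the primary subject's (same heart-sound frequencies, overlapping
heart-rate and pressure ranges) but the couplings conflict —
weaker/offset S1 and S2 amplitude laws, a flatter and shorter
transit-delay law, weaker pulse-pressure gain, and an opposite-sign DBP
baseline coupling. Because the inputs are not trivially separable by
subject, a single network cannot satisfy both mappings at once: plain
cross-subject transfer genuinely degrades, and one calibration record
(outnumbered by the source subject's beats) recovers only part of the
gap — the mechanism by which individual differences resist one-shot
calibration in real cross-subject studies.

**What passing tests show — and do not show.** The synthetic data make
the label information present, stationary and low-noise by construction;
real chest acoustics and optical pulses carry motion artifacts,
sensor-placement variability, respiratory modulation and
subject-specific nonlinearities that this generator does not model.
Passing the end-to-end tests demonstrates that the pipeline and network
are wired correctly and can extract such relationships when they exist;
it does not establish clinical estimation accuracy.

## Problem sizes used in tests and the acceptance script

Experiments are scaled down from a multi-minute, ~300–570-beats-per-record
protocol to keep single-CPU runs practical, as the package's own choice of
test conditions: records of 40 s (~70 beats), 8 records for the primary
subject and 5 for the second, 16 training epochs at batch 16 for the
scheme runs (instead of the default 200 epochs at batch 64), and 5
records for the QRS benchmark (~350 beats at 20 dB ECG SNR). The
within-subject five-fold run, the cross-subject run and the calibrated
run each train one network per fold/pass from scratch.

## Numerical and design notes

* BN statistics in evaluation mode use running estimates (momentum 0.1);
  training batches of fewer than 2 samples are skipped.
* The GRU uses the candidate-gate formulation in which the reset gate
  multiplies the *hidden* projection (separate hidden bias), gate order
  (reset, update, candidate); recurrent weights are orthogonally
  initialized per gate, input weights Glorot-uniform.
* Checkpoint selection is strictly `argmin` of the per-epoch validation
  loss; ties resolve to the earliest epoch.
* `compute_metrics` flags CC as undefined (`None`) for constant series
  instead of emitting NaN; error statistics are still reported.
* The spike-repair rule operates per record, not globally: the bolus
  protocol makes between-record level differences physiological, not
  artifactual.
* Known limitations: no arrhythmia handling (a single R-R gate only), no
  P/T-wave delineation, heart rates below 60 bpm are excluded by the 1 s
  window policy, and the WFDB container format is not read — CSV and
  HDF5 are the supported interchange formats.
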