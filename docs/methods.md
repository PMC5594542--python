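# Methods

## Study design being simulated

The package reproduces, in simulation, a five-session single-hand
motor-imagery experiment with three force-load conditions:

| session | trials | tasks | trial timeline |
|---|---|---|---|
| 1-3 | 2 blocks × 10 (5 high + 5 low, shuffled) | motor execution then motor imagery at the cued load | cue 2 s → execution 6 s → rest 4 s → imagery 6 s → rest 4 s |
| 4 | 30 relaxed | relaxed "imagery" | cue 2 s → imagery 6 s → rest 4 s |
| 5 | 4 blocks × 12 (4 per class, shuffled) | online three-class imagery | cue 2 s → imagery 6 s → rest 4 s |

A two-class (high vs low) decoder is trained on session 1 and refitted
after sessions 2 and 3 on the accumulated imagery data; the three-class
decoder is trained on sessions 1-4; session 5 is decoded trial by trial
with the frozen three-class decoder and a feedback event is logged per
trial. Simulated subjects do not adapt to feedback: the human learning
trend across sessions 1-3 is a cognitive phenomenon outside the model,
so between-session comparisons here exercise the reporting machinery,
not a learning effect.

## Generative model

Each channel carries, in microvolts:

* **1/f background** — spectrally shaped Gaussian noise with exponent 1
  (configurable), std `noise_amplitude` = 1 µV.
* **Oscillatory sources** — band-limited Gaussian processes in the mu
  (8-13 Hz) and beta (14-30 Hz) bands from a focal source at C3
  (std `osc_amplitude` = 3 µV at the focus; beta at 0.5× mu) and a
  mirror source at C4 at 30% gain. Source-to-channel weights decay as
  exp(−rank/3) over the channel's rank-distance from the focus in a
  generated 2-D 10-20 layout.
* **ERD** — during execution and imagery segments the sources are
  multiplied by (1 − depth), ramped over 300 ms at segment edges.
  Depths: high 0.5, low 0.25, relaxed 0 (beta depth = 1.2× mu depth,
  capped at 1).
* **Line interference** — a 0.5 µV 50 Hz component with random phase
  per channel, removed again by a zero-phase notch at the acquisition
  stage, mirroring a recording chain with a hardware notch.
* **EMG channel** — 20-450 Hz noise (2 µV) plus bursts (40 µV for high,
  0.6× for low) strictly inside motor-execution segments.

Two variability terms make the classes overlap the way real
motor-imagery data do (without them the synthetic task is close to
perfectly separable, which no human cohort shows):

* **per-trial oscillation gain** — lognormal, σ = 0.1 on the log scale,
  applied across the whole trial (baseline included);
* **per-segment ERD-depth jitter** — multiplicative lognormal,
  σ = 0.2, so a zero depth stays exactly zero and null configurations
  remain exact nulls.

The two sigmas were fixed once, by simulating a small pilot cohort on
seeds disjoint from any reported run and choosing the values at which
per-subject online accuracy falls in the range multi-class
motor-imagery cohorts report (roughly 0.70-0.85 against a 1/3 chance
level) with non-degenerate, ordered confusions. They are study-design
constants, not fitting targets.

All noise and source series are normalized **analytically** (by the
theoretical std of the shaping filter), not by the realized std of the
session. Empirical per-session normalization would stamp each session
with a reproducible amplitude fingerprint; since the relaxed class is
recorded in its own session, a classifier can exploit such a fingerprint
and beat chance even when all ERD depths are equal. With deterministic
scales, sessions are exchangeable under the null and the chance-level
calibration holds.

Every random draw flows from an integer seed; a session's stream is
derived from (seed, session-id), so subjects are reproducible
bit-for-bit and sessions are mutually independent.

## Decoding chain

* Channel selection drops the mastoid (M1, M2) and ocular (HEO, VEO)
  leads and the EMG channel, leaving 60 scalp channels in input order.
* Downsampling 1000 → 200 Hz uses a polyphase FIR anti-alias filter
  (line-padded edges); the ratio must be an integer.
* Band-pass 8-30 Hz: 4th-order Butterworth, applied forward-backward
  (zero phase) so ERD onsets are not delayed. The order and the
  zero-phase choice are package choices; only the band is given by the
  protocol.
* CAR subtracts the instantaneous mean across the retained channels.
  Processing order is downsample → band-pass → CAR; filtering and CAR
  commute on linear signals, so the order is a convention, and both
  orders are available through the stage functions.
* Classification epochs cover the full imagery segment [0, 6) s
  (half-open, 0-based samples, times relative to imagery onset).

CSP uses per-trial covariances normalized by their trace (suppressing
global amplitude scaling) and solves the generalized eigenproblem
against the composite covariance; eigenvalues are clipped to [0, 1] and
filters are sign-fixed (largest coefficient positive) for deterministic
output. `n_pairs` = 3 filters are kept from each end of the spectrum
(the conventional 2-4 range; 2 are used in reduced test studies with
19 channels). Multi-class decomposition is one-vs-rest in sorted label
order (a pairwise scheme is available behind a flag). CAR makes the
channel-space covariance exactly rank-deficient; a scalar shrinkage
toward the identity (γ = 1e-5, with a warning) regularizes the
composite matrix when its condition number exceeds 1e10.

The classifier is a linear SVM (C = 1, no probability calibration,
no feature scaling beyond the CSP log-variance normalization);
multi-class decisions take the one-vs-rest argmax with lowest-index
tie-breaking. Cross-validated accuracies use stratified 5-fold CV with
CSP refitted inside each fold (no leakage). Three-class training uses
the cue labels of sessions 1-4.

## ERSP

Per trial, power is estimated with a 256-sample Hanning STFT (75%
overlap by default; the protocol fixes only the window length). Trial
powers are averaged **before** the dB conversion, then the mean baseline
dB level over [-2, 0] s is subtracted per frequency. Only STFT frames
whose window lies entirely inside the baseline interval define the
reference, so post-onset power cannot leak into it; those frames average
exactly 0 dB by construction. A multiplicative amplitude attenuation
`a` of an oscillation therefore reads out as 20·log10(a) dB. At 200 Hz
a 256-sample window spans 1.28 s (≈0.78 Hz resolution), adequate for
the 8-30 Hz summary band. Paired difference topographies keep only
channels whose across-subject paired t-test is significant (α = 0.05);
zero-variance differences are reported as t = 0, p = 1.

## EMG screen

The EMG trace is notched at 50 Hz and band-passed 5-500 Hz (upper edge
clipped to 0.49·fs when the rate is exactly 1 kHz); per-trial IEMG is
the sum of rectified samples, kept at the native 1 kHz. Task conditions
are compared to relaxed trials by position-paired t-tests (unequal
counts truncate to the shorter list). The screen passes when execution
conditions differ and imagery conditions do not.

## What the simulation does and does not show

Passing tests demonstrate that the pipeline is correct and that the
protocol is feasible *given* load-graded ERD of the configured depth:
graded depths are recovered as ordered ERSP, human-cohort-level decoding
accuracy, and force-ordered confusions, while null configurations are
chance-calibrated. The generator does not model eye blinks or movement
artifacts, electrode impedance drift, inter-subject anatomical
variability, non-stationarity across sessions, or feedback-driven
learning — so simulated accuracies say nothing about any individual
human subject, only about the method's behavior under the stated
signal model. Absolute ERD magnitudes (dB) are set for detectability,
not matched to any particular dataset.

## Problem sizes and numerics

Default study: 60 + 4 EEG channels + 1 EMG at 1 kHz, five sessions
(~2250 s of signal per subject); cohort analyses use 20 subjects.
Reduced studies used in parts of the test suite keep the identical
statistical structure on a 19-channel sensorimotor montage at 200 Hz.
Recordings are generated in float32 (≈7 significant digits, far below
the 1 µV noise floor) and analysed in float64. Degenerate inputs fail
loudly: empty epoch windows, single-channel CAR, non-integer decimation
ratios, missing classes, unpaired comparisons and truncated containers
all raise typed exceptions.

## Serialization

Recordings, epochs and decoders round-trip through `.npz` containers
with CSV event sidecars and JSON metadata. EDF files can be read via
`mne` (optional extra); EDF writing is not supported. Pipeline runs
write their resolved YAML configuration and a file manifest next to
their outputs, so any artifact is reproducible from (config, seeds).
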