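# mfload

Simulation and decoding toolkit for **multi-force-load motor-imagery
brain-computer interfaces**: can the *imagined force* of a single hand —
clenching hard (30% MVC), lightly (10% MVC), or not at all — drive a
three-command BCI?

Imagining a hand movement attenuates the sensorimotor mu (8-13 Hz) and
beta (14-30 Hz) rhythms over the contralateral motor cortex
(event-related desynchronization, ERD), and the attenuation deepens with
the imagined force load. `mfload` packages everything needed to study
that effect end to end without access to human recordings:

* a **synthetic EEG+EMG generator** producing five-session experiments
  (64-channel 10-20 montage + one forearm EMG lead, 1 kHz) with
  load-graded ERD focused at C3, a weaker mirror source at C4, 1/f
  background, line interference, and EMG bursts only during overt
  motor execution;
* the **decoding chain**: 60-channel selection, 1000→200 Hz
  downsampling, zero-phase 8-30 Hz Butterworth band-pass, common average
  reference (CAR), common spatial patterns (two-class and one-vs-rest
  multi-class CSP), and a linear SVM with the session-wise protocol
  (two-class after session 1, updated after sessions 2-3, three-class
  from sessions 1-4);
* a **simulated online session** (48 trials, feedback log, output
  distribution / confusion matrix);
* **ERSP analysis** (256-point Hanning STFT, dB baseline normalization,
  band means, topographies, paired-t difference maps);
* an **IEMG muscle-activity screen** verifying imagery is EMG-silent.

The core statistic behind the decoder is CSP: for class covariances
Σ_a, Σ_b (per-trial, trace-normalized, averaged), spatial filters *w*
solve Σ_a w = λ(Σ_a + Σ_b)w with λ ∈ [0, 1]; filters from both ends of
the spectrum yield normalized log-variance features
f_j = log(var_j / Σ_k var_k). ERSP is the trial-averaged STFT power
ERSP(f, t) = (1/n) Σ_k |F_k(f, t)|², expressed in dB relative to the
mean pre-onset baseline power per frequency. IEMG is Σ_i |x_i| over a
trial.

## Worked example

`python examples/02_decode_force_loads.py` runs the complete protocol
for one simulated subject and prints:

```
Per-session decoding accuracy (subject seed 0):
  session 1 (offline CV, 2-class):   75.0%
  session 2 (online, 2-class):       90.0%
  session 3 (online, 2-class):       85.0%
  session 5 (online, 3-class):       72.9%
  chance level (3 classes):          33%

Session-5 output distribution (rows = intended, cols = decoded):
                high       low   relaxed
      high      1.00      0.00      0.00
       low      0.38      0.44      0.19
   relaxed      0.00      0.25      0.75
```

Session 1 is the offline cross-validated high-vs-low accuracy; sessions
2-3 are decoded online with the decoder available at the time; session 5
is the online three-class run (chance level 33%). The confusion matrix
rows are the intended classes: misclassified 'high' trials land on
'low', not on 'relaxed' — the three tasks are ordered along a force-load
axis rather than scattered.

The scripts in `examples/` walk through each capability (generation and
ERD inspection, decoding, ERSP maps, the EMG screen, cohort summaries);
each prints the numbers it computes and a line on what they mean. A thin
CLI mirrors the stages (`mfload simulate|preprocess|train|online|ersp|
emg|pipeline`).

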