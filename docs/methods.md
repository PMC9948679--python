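# Methods

This note records the models, conventions and numerical choices behind
`reflexloop`, and what the simulator does and does not emulate.

## Background-level pipeline

Background EMG level is the mean rectified value of the high-pass-filtered
signal in a trailing sliding window. The published protocol this engine
follows does not fix the filter family, cutoff or window length, so the
package declares defaults rather than reconstructing unpublished values:

| parameter | default | why |
|---|---|---|
| high-pass | 2nd-order Butterworth, 10 Hz, causal | removes DC/motion artifact without touching the 20–250 Hz surface-EMG band |
| window | 200 ms trailing | responsive feedback while smoothing over single motor-unit bursts |
| sample rate | 2 kHz | 0.5 ms resolution on 6–45 ms response latencies |
| amplifier gain | 500 (divided out) | signals held in mV at the skin so thresholds stay physiological |
| processing block | 20 ms | all timing tolerances quantize to one block |

Both filter and moving sum carry `lfilter` state between blocks, so
block-wise (streaming) processing agrees with single-shot processing to
better than 1e-9 mV on any partition (the IIR stage is bit-exact; the FIR
moving sum differs by a few 1e-14 from summation-order effects). Frames
earlier than one full window are averaged over the samples available so
far.

## Trigger gating

The gate fires at the end of the first frame at which (a) both muscles
have stayed inside their configured ranges — inclusive bounds, blank
bounds unbounded — continuously for the hold duration (default 2 s), and
(b) the minimum inter-stimulus interval (default 5 s; stimulus-test mode
3 s, with the range contingency waived) has elapsed. Two declared
conventions where the behaviour was genuinely open:

* the in-range timer resets to zero at every stimulus, so each trial
  requires a fresh hold (prevents double-triggering right after the
  interval expires);
* no per-trial timeout is enforced.

`run_gate` evaluates whole traces with an integer-frame run-length scan
for speed; the frame-by-frame `step` state machine is the behavioural
reference, and property tests assert the two agree on random in-range
masks. A 1e-9 s slack absorbs float accumulation when comparing elapsed
time against hold/interval, so "2 s at 2 kHz" means exactly 4000 frames.

## Response quantification

Epochs span 50 ms before to 100 ms after stimulus onset (soleus M-wave
~6–25 ms, H-reflex ~25–50 ms). Analysis windows are half-open `[start,
end)` in ms, mapped to frames by `floor(start*fs/1000) ..
floor(end*fs/1000)-1`; defaults are reference = [6, 23) ms and target =
[28, 45) ms, meant to be adjusted per participant and persisted. The
stimulus artifact is excluded simply by starting windows after 0 ms; no
blanking is applied. Sizes are peak-to-peak (max − min) or mean rectified
amplitude of the windowed segment.

## Distributions, criteria, stability

* Percentiles use linear interpolation between order statistics
  (numpy's `"linear"` method), so thresholds are bit-reproducible.
* Down-conditioning: success ⇔ size ≤ P-th percentile of the defining
  sample; up-conditioning: success ⇔ size ≥ (100−P)-th percentile;
  default P = 66. Ties at the threshold count as success (deterministic
  and participant-favourable). P = 100 is allowed as the degenerate
  all-successful boundary.
* Recruitment sweeps pool consecutive trials (default 4, matching an
  intensity step every four trials); `M_max`/`H_max` are the maxima of
  the pooled reference/target sizes.
* M-wave constancy: a run is flagged when its mean reference size
  deviates from nominal by more than ±15 % (the protocol only demands
  "roughly constant"; 15 % is a declared default).
* Histogram binning (Freedman–Diaconis) is display-only.

## The virtual participant

The simulator emulates the *conditions* of a conditioning study, not a
motoneuron pool:

* **Background EMG**: Gaussian white noise band-passed 20–250 Hz and
  scaled so its expected mean rectified value equals the drive (the
  half-normal mean E|X| = σ√(2/π) gives the scale factor analytically).
  The drive relaxes Ornstein–Uhlenbeck-style (τ = 0.5 s, relative SD 0.2)
  toward the midpoint of the configured target range, so 2 s holds
  succeed most of the time and occasional range exits occur.
* **Recruitment**: M(I) is a logistic (midpoint 30 mA, slope 0.25/mA,
  `M_max` 8 mV); H(I) is a logistic rise (midpoint 15 mA, slope 0.5/mA,
  `H_max` 3 mV) times a logistic collision suppression (midpoint 35 mA,
  slope 0.4/mA), times the excitability state. These functional forms are
  modeling choices that reproduce the qualitative shapes (M rises then
  saturates, H rises then falls); with the defaults the H peak (~26 mA)
  reaches ≈ 97 % of `H_max`, and the default conditioning intensity of
  24 mA elicits a near-maximal H-reflex with a clearly visible M-wave.
* **Evoked waveforms**: Hann-windowed single-cycle biphasic templates
  (9 ms for M at 8 ms latency, 12 ms for H at 30 ms latency), calibrated
  so the injected peak-to-peak equals the programmed amplitude exactly —
  with all noise off, the full pipeline recovers programmed amplitudes to
  machine precision.
* **Trial-to-trial noise**: multiplicative Gaussian, default SD 15 % of
  amplitude (real per-trial H-reflex variance is unpublished; this is a
  declared assumption). Parameter-recovery checks use 2 % SD with
  4-trial pooling, the regime in which recruitment extrema are expected
  to be recoverable to a few percent.
* **Plasticity**: each rewarded trial multiplies the excitability by
  1 ∓ r (r = plasticity rate, 0 by default; 0.01 in the conditioning
  demonstrations), clipped to [0.2, 2.0]. This is a phenomenological
  stand-in for operant reflex change, not a mechanism.

What it does **not** emulate: electrode lift-off and impedance drift,
stimulus artifact bleed into the reference window, non-stationary or
correlated EMG spectra, fatigue, posture shifts, or quantitative clinical
effect sizes. Passing tests therefore demonstrate the correctness of the
engine's logic and measurement chain under controlled conditions, not
performance on real recordings.

In the closed loop the gate operates on the background trace of the
ongoing-EMG signal; evoked templates are added afterwards at the gated
times. Under default timing this cannot change any gating decision (the
150 ms epoch is far shorter than the fresh 2 s hold plus 5 s interval
required after each stimulus), and it keeps simulation O(run length).

## Problem sizes and runtime choices

Simulated studies in the tests are scaled to what the checks need:
trigger-timing runs use a handful of trials; parameter recovery uses 20
seeded full sweeps (21 intensities × 4 trials); the directional
conditioning comparison uses 20 seeds × two arms of a scaled session
(20 control + 75 training trials at 1 kHz, recruitment-curve runs
omitted) — large enough for a decisive paired one-sided test, since the
programmed effect (≈ 20–40 % reflex reduction) dwarfs the SE of a 75-trial
run mean (≈ 2 %).

## Persistence

Run containers are HDF5 (float64 signals, event arrays, per-trial table,
JSON-encoded config snapshot) with a human-readable JSON sidecar; the
round trip is bit-exact. File names follow
`YYYYMMDD-HHMM_<ID>_<MODE><NN>` (date-time, participant id, mode code
ST/VC/RC/CT/TT, sequential run number); the delimiter layout is a
declared convention, and writing over an existing run file is a hard
error. All timestamps come from an injectable clock, so session logic is
deterministic under test.
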