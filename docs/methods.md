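# Methods

`radarhrv` implements a complete processing chain from Six-Port radar
baseband signals to heart rate variability (HRV) indices, together with a
forward simulator that generates radar recordings with known ground truth.
This note documents the models, the parameters that matter, and the design
choices made where the problem left the design open.

## Signal model and demodulation

A continuous-wave 24 GHz Six-Port interferometer superimposes the
transmitted reference and the wave reflected off the chest under four
static phase shifts (0°, 90°, 180°, 270°). After diode power detection the
four baseband channels B3…B6 form two differential pairs that are the
quadrature components of a complex signal

    Z = I + jQ = (B5 − B6) + j(B3 − B4).

A change Δx in the radar–chest distance changes the round-trip path by
2Δx, so the phase of Z rotates by 2π per λ/2 of displacement:

    Δx = Δφ/(2π) · λ/2,   Δφ = unwrap(arg Z),

with λ = c/24 GHz ≈ 12.49 mm. The implementation (`radarhrv.sixport`):

* **Phase unwrapping** uses standard 2π-jump unwrapping. Respiration moves
  the chest by millimetres, i.e. several λ/4, so multi-wrap recovery is a
  requirement, not an edge case.
* **Magnitude floor.** Where |Z| falls below 10⁻⁶ of the record median the
  phase of a near-zero complex number is meaningless; such samples hold
  the previous phase. If more than half the record is below the floor,
  demodulation is refused (`LowSignalError`).
* **DC removal** before forming I and Q is optional (off for simulated
  data, recommended for recorded files). Ideal differential pairs cancel
  detector offsets exactly; real detectors may not. No further I/Q
  imbalance correction is applied.
* **Clipping detection** counts samples lying exactly on the rails (known
  rails, or each channel's min/max plateau as estimate). The default flag
  threshold is a rail fraction of 0.01: a clipped record invalidates phase
  demodulation and must be excluded, not silently processed. Flagged
  subjects are reported `excluded` by the pipeline.

## Synchronisation

Two devices (radar and reference) record the same binary Gold-code
watermark at nominally different rates. Alignment solves two parameters
(`radarhrv.sync`):

* **Resampling factor** — the clock-rate ratio, found by maximising the
  peak normalised cross-correlation of the first sequence against the
  second resampled by the candidate factor. The objective's basin is only
  ~one chip of accumulated drift wide, so the search is multi-resolution:
  short central slices of the second sequence (decimated for speed) give a
  wide capture range, longer slices narrow it, and a bounded scalar
  minimisation polishes to 10⁻⁶. Linear-interpolation resampling is used
  throughout (estimation and tests alike, so no method-mismatch bias).
* **Latency** — the argmax of the full cross-correlation once both
  sequences share a rate; positive latency means the second record's
  content starts later. Because any residual factor error turns into a
  linear lag drift along the record, `solve_sync` refines the global
  estimate by measuring the local lag in an early and a late window
  (sub-sample peak interpolation) and extrapolating to the record start,
  where the latency is defined.

Gold codes are generated as the XOR of a preferred pair of maximal-length
LFSR sequences (degree 10, taps x¹⁰+x³+1 and x¹⁰+x⁸+x³+x²+1, length 1023);
primitivity is verified by the balance property. The default chip rate of
the simulated watermark is 25 chips/s: the code repeats cyclically, so the
latency is only identifiable modulo one code period, and 1023/25 ≈ 40.9 s
disambiguates lags within ±15 s through the larger overlap of the true
alignment. Alignment requires at least 10 s of overlap and targets
2000 Hz.

## Heart-sound features

The heart sounds are micro-vibrations (tens of µm) riding on millimetre
respiration and sub-millimetre pulse waves. `radarhrv.features` isolates
them with a zero-phase 4th-order Butterworth band-pass, default
**16–80 Hz** (standard phonocardiography band; configurable). Four
per-frame features at a **50 Hz feature rate** (20 ms frames — resolving
the 60–120 ms S1/S2 durations and well inside the 75 ms scoring
tolerance):

1. **Homomorphic envelope**: exp(LP(log(|analytic(y)| + ε))), 1st-order
   zero-phase low-pass at 8 Hz, ε = 10⁻¹².
2. **Hilbert envelope**: |analytic(y)|.
3. **PSD envelope**: mean short-time spectral power in the heart-sound
   band (50 ms Hann frames, 20 ms hop).
4. **Heart rate**: argmax of the normalised autocorrelation of the
   homomorphic envelope within lags equivalent to 40–135 bpm, computed
   per non-overlapping 10 s window and broadcast to its frames. Peaks
   below 0.25 of the zero-lag value are flagged unreliable (periodic
   envelopes score above ~0.35; broadband noise below ~0.2).

Envelope features are z-normalised per record; the raw bpm estimate is
kept alongside for the HSMM's duration prior.

## HSMM segmentation

The four cardiac states follow the fixed cycle
S1 → systole → S2 → diastole. `radarhrv.hsmm` models:

* **Emissions**: one multivariate Gaussian per state over the four
  features (covariance regularised by 10⁻⁶·I). The cited phonocardiogram
  segmentation literature uses logistic-regression emissions; Gaussians
  have fewer moving parts and the same interface, and parameter recovery
  is testable directly.
* **Sojourns**: discretised Gaussians over frames, truncated at ±3σ
  (σ floored at 0.5 frames). S1 and S2 durations are heart-rate
  independent (~100 ms, ~80 ms); systole and diastole means scale with the
  cycle period 60/HR. Training fits S1/S2 in seconds and SYS/DIA as
  fractions of the local period implied by the track's HR estimate; edge
  runs truncated by record boundaries are excluded.
* **Decoding**: duration-explicit Viterbi maximising
  Σ frame emissions + Σ segment duration log-pmfs + log ¼ (uniform initial
  state), over all legal cyclic segmentations; edge segments score with
  the same truncated pmf as interior ones, which keeps the objective
  well-defined and lets exhaustive enumeration serve as an oracle on toy
  instances. Ties resolve toward the shorter sojourn (deterministic).
  The decoder requires the a-priori heart rate to lie in 40–135 bpm and
  surfaces an explicit error outside it — the known weakness of
  duration-prior segmentation at extreme rates.

## Bidirectional LSTM segmentation

`radarhrv.lstm` implements the network directly on numpy arrays: two
bidirectional LSTM layers (400 and 200 hidden units per direction in the
full configuration), dropout 0.2 after each recurrent layer, then a dense
softmax over the four states. Training: Adam, 50 epochs, batch size 64,
learning rate 0.001 dropping ×0.1 every 20 epochs, class-weighted
cross-entropy (S1/S2 frames are rare against diastole; unweighted loss
collapses to the majority class on short runs), sequences chunked into
10 s windows for batching. The optimiser and the loss weighting are
design choices — community defaults for recurrent sequence labelling —
while the architecture, dropout, epochs, batch size and learning-rate
schedule are fixed by the method being implemented.

Everything (initialisation, shuffling, dropout masks) draws from one
seeded generator, so training is bit-reproducible given the seed under
single-threaded BLAS.

A reduced **desk tier** (`LstmConfig.desk()`: 64/32 units, 10 epochs,
2.5 s windows) keeps CPU-only runs in minutes. The shorter windows matter:
with the fixed batch size of 64, small simulated cohorts would otherwise
provide only one or two gradient updates per epoch.

The raw argmax path need not respect the cardiac cycle. `repair_cycle`
projects the per-frame posteriors onto the nearest legal cyclic path with
a first-order Viterbi whose only transitions are "stay" or "advance to the
cyclic successor"; advance probabilities are 1/expected sojourn (0.10,
0.21, 0.08, 0.55 s at rest). This removes isolated label flips and makes
S1 onsets well-defined.

## Beat evaluation

A beat reference point is the onset of the first heart sound (first S1
frame of each cycle). Matching against reference beats is one-to-one with
tolerance 75 ms — half the recognised 150 ms tolerance for R-peak
detection. Among matchings with maximal true-positive count the one with
minimal total |Δt| is selected; since both lists are sorted and
admissibility is an interval condition, a non-crossing dynamic programme
finds the optimum (greedy nearest-neighbour can undercount TPs in crowded
regions; an exhaustive-search oracle enforces optimality in the tests).
Scores: sensitivity TP/(TP+FN), precision TP/(TP+FP),
F1 = 2TP/(2TP+FP+FN) (the harmonic mean of sensitivity and precision),
accuracy TP/(TP+FP+FN).

**Sub-frame refinement.** Segmentation localises each S1 onset only to one
20 ms feature frame; that quantisation is broadband noise in the RR series
and measurably inflates spectral HRV indices. Refinement runs in two
stages, both enabled by default in the pipeline:

1. `refine_beats` moves each beat to the parabolic-interpolated maximum of
   the smoothed heart-sound envelope near the coarse time (~7 ms jitter
   down to ~3 ms on simulated data);
2. `refine_beats_waveform` builds the record's mean S1 waveform template
   and aligns every beat to it by local cross-correlation, searched only
   within ±8 ms — under a quarter of the ~30 Hz carrier period, so the
   correlation cannot slip to a neighbouring carrier cycle (which is why
   the envelope stage must run first). Consistent alignment to one common
   template brings the jitter below a millisecond on clean signals.

The final times are shifted back by half the mean detected S1 sojourn to
approximate onsets; a shift common to all beats cancels in the RR
intervals either way.

## HRV analysis

From beat times (`radarhrv.hrv`):

* **RR sequence**: interval i ends at beat i+1.
* **Artefact filter**: an interval deviating more than 20% from the
  running median of the last 5 accepted intervals is an artefact. An
  interval ≈2× the median (missed beat) is split in two; two adjacent
  flagged intervals summing to ≈1× the median (false detection) are
  merged; anything else is flagged invalid and excluded. More than 30%
  flagged marks the sequence low-quality. The 20%/5-interval thresholds
  are this package's instantiation of running-median artefact filtering;
  both are configurable. Corrected (split/merged) intervals do enter the
  spectra; unresolvable ones never do.
* **Triangular index (TRI)**: total valid interval count divided by the
  modal bin count of the interval histogram, bins aligned to multiples of
  1/128 s (the conventional discrete grid for geometric HRV measures).
  Identical intervals give TRI = 1; k equally filled bins give TRI = k.
* **Spectral indices**: valid (time, interval) pairs are linearly
  interpolated onto a uniform 4 Hz grid (community standard rate), the
  first `window` seconds (90 s in the cold-pressor protocol) are
  standardised to zero mean and unit variance, Hann-tapered, zero-padded
  to the next power of two and Fourier-transformed. Band powers are sums
  of squared magnitudes over LF = [0.04, 0.15) Hz and HF = [0.15, 0.4) Hz.
  The Hann taper is a deliberate choice: with a rectangular window a pure
  in-band tone leaks a few percent of its power into the neighbouring
  band, which would make band-purity guarantees impossible. Powers are
  reported on the standardised-signal scale; absolute ms² powers are out
  of scope. Normalised units: hf_norm = 100·HF/(LF+HF) (and symmetrically
  LF), lf_hf_ratio = LF/HF.
* **Windowed analysis** evaluates the indices per named scenario window
  (Baseline/Response/Recovery of 90 s each in the cold-pressor layout);
  heart rate is 60/mean valid interval; windows with fewer than 30 valid
  intervals are flagged low-confidence. Resting-style analyses use the
  same machinery over the full segment.
* **Agreement**: Pearson r, Bland–Altman mean difference with limits of
  agreement mean ± 1.96 sd, and relative error mean(|a−b|/b)·100 across
  subjects.

## The simulator — what it emulates and what it does not

`radarhrv.simulate` generates the full causal chain with ground truth:

1. **Tachogram**: RR(t) = mean_rr + 0.03·sin(2π·0.1 Hz·t) +
   s(t)·0.05·sin(2π·0.25 Hz·t) + N(0, 5 ms) — an LF (baroreflex-like)
   rhythm, an HF rhythm at the respiratory rate (respiratory sinus
   arrhythmia), and white jitter. s(t) scales the HF coupling per scenario
   window; halving it emulates vagal withdrawal during a cold-pressor
   Response (the "negative" reaction), raising it the opposite reaction.
2. **Displacement**: 3 mm respiration at 0.25 Hz + a 0.4 mm raised-cosine
   pulse bump per beat + Gaussian-windowed tone bursts for S1 (30 µm,
   30 Hz, 100 ms, at the beat time) and S2 (20 µm, 35 Hz, 80 ms, at
   beat + 0.35·RR). Amplitudes are the orders of magnitude reported in
   radar vital-signs work; all configurable. Per-sample state labels mark
   burst supports, systole between them, diastole elsewhere.
3. **Baseband**: the exact inverse of the demodulation model — phase
   2π·2x/λ + φ₀, differential pairs split around a common detector bias,
   additive white Gaussian detector noise (default σ = 0.01 of the unit
   detector amplitude — "moderate" noise), optional rail clipping.
4. **Cohorts**: per-subject seeds derived from a master seed by fixed
   offsets; mean RR spread over 57–80 bpm; a `CohortPlan` assigns each
   subject's Response-window HF scaling (default 3 negative / 3 positive
   reactors), with the cold-pressor layout 10 s lead-in + 90 s Baseline +
   60 s pause + 90 s Response + 60 s pause + 90 s Recovery.

Not emulated: electromagnetic propagation, body-movement artefacts
(flagged-segment handling is exercised through clipping instead),
beat-morphology variability, detector nonlinearity, multipath. Passing
closed-loop tests therefore demonstrates the correctness of the
algorithms under the stated signal model, not clinical performance on
human recordings.

## Problem sizes in tests and the acceptance script

Simulated studies are sized for a single CPU: HSMM train/test uses six
2-minute subjects (train on five, test the sixth); the LSTM
leave-one-subject-out cross-validation uses six 3-minute subjects at
moderate noise with the desk-tier configuration; the end-to-end cohort
uses six subjects with the full ~7-minute cold-pressor layout and HSMM
segmentation (the LSTM path is exercised by the LOSOCV study). The
synchronisation study uses twenty 60 s sequence pairs with factors in
[0.9, 1.1] and lags in ±10 s.

## Known limitations

* The latency is reported as an integer sample count at the target rate;
  sub-sample residuals (≤ ~1 sample at 2000 Hz) remain.
* The HSMM's heart-rate prior is a single scalar per decoded track;
  records with strong within-track rate drift should be decoded in
  windows.
* The artefact filter's split/merge rules assume isolated corruptions;
  bursts of consecutive artefacts are flagged-excluded rather than
  repaired.
* The numpy LSTM trains on CPU only and is sized accordingly; the
  full-scale 400/200 configuration is provided and functional but slow
  off-desk.
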