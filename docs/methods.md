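# Methods

`oprars` implements a hearing-aid fitting chain in which per-channel
insertion gains and compression thresholds of a simulated five-channel
aid are tuned by seeded genetic random search, with candidate settings
scored on hearing-loss-simulated speech by a pluggable intelligibility
objective. This note records the models, the parameters that matter, the
numerical choices, and the limits of what the synthetic pipeline shows.

## Processing chain

For one candidate setting the chain is:

1. **Baseline prescription.** An audiogram (11 audiometric frequencies,
   125 Hz–8 kHz) is mapped to two insertion-gain functions, IGSP65 and
   IGSP85 (gains for 65- and 85-dB-SPL speech), by a registered
   prescription rule. The default rule is a deliberately simple linear
   stand-in, IGSP65 = 0.45·HL and IGSP85 = 0.30·HL capped at 55 dB: it is
   monotone in loss, compressive (IGSP85 < IGSP65), and exercises every
   downstream constraint with realistic magnitudes. Real prescriptions
   from commercial fitting software can be supplied through the
   `external` rule as a CSV table; nothing downstream depends on the
   rule's internals.
2. **Search offsets.** A candidate is ten numbers: one gain offset per
   channel (±10 dB in 0.1-dB steps, applied to both IGSP65 and IGSP85 of
   every frequency in the channel) and one compression threshold per
   channel (20–50 dB SPL in 1-dB steps). The five channels span
   100–700, 700–1400, 1400–2800, 2800–5600 and 5600–8000 Hz; each
   channel's "center" is the geometric mean of its edges snapped to the
   nearest audiometric frequency.
3. **Compression-ratio bounds.** At each channel center the two-level
   gains imply a compression ratio CR = 20 / (20 + IG85 − IG65). The
   ratio is forced into [1, 10] by repeated 0.5-dB corrections (CR < 0:
   raise IG85; 0 ≤ CR < 1: raise IG65; CR > 10: lower IG65), re-checking
   after every step. A zero denominator (infinite CR) is handled by the
   CR > 10 rule, which the three-case rule set does not itself cover.
   The correction found at the center is applied to the whole channel so
   within-channel gain shape is preserved.
4. **SII equalization.** A uniform offset in 0.1-dB quanta shifts all
   gains until the candidate's Speech Intelligibility Index matches the
   baseline prescription's as closely as possible (first non-improving
   step is reverted). This stops the search from trading audibility for
   spectral shape, since the scoring metric is level-normalized. One
   final bounds pass guards the rare cap interaction. The SII inside
   this loop is evaluated from the long-term octave spectrum of the
   clean tokens plus the candidate's IG65 interpolated at band centers;
   a uniform gain shift is then an exact spectrum shift, which makes the
   0.1-dB loop cheap and exactly monotone in the shift.
5. **Hearing-aid simulation.** Zero-phase brick-wall band split at the
   channel edges (channels tile the 0.1–8 kHz band exactly, so their sum
   reconstructs the band-limited input); per channel a slow main
   compressor followed by a fast output limiter. Static curve:
   out = in + G below CT and out = CT + G + (in − CT)/CR above, with G
   anchored so a 65-dB-SPL input receives exactly IGSP65. Attack/release
   times are 200/2000, 100/1500, 100/1200, 100/1000, 100/1000 ms for
   channels 1–5; the limiter (unspecified by any prescription rule) uses
   conventional values CT 100 dB SPL, CR 10, 5/50 ms, configurable.
6. **Hearing-loss simulation.** Threshold elevation and loudness
   recruitment: per band the envelope level L (dB SPL) maps to
   (L − HL)·C/(C − HL) with ceiling C = 100 dB SPL, i.e. envelope
   expansion with exponent C/(C − HL); fine structure is preserved.
   Loss of frequency selectivity is intentionally not simulated. A band
   whose loss reaches the ceiling cannot be expanded and is treated as
   dead (silenced) by the scoring objectives; the public `simulate_loss`
   raises instead, because silently zeroing a band is the objective's
   semantics, not the simulator's.
7. **Scoring.** The surrogate metric correlates the short-time (32-ms)
   log band energies of the processed token with the clean token's as
   one joint (band × frame) pattern, after clipping both at the
   normal-hearing audibility floor (0 dB SPL band level); each pattern
   is centered by its global mean only, and a negative correlation clips
   to zero, giving a per-token value in [0, 1]. A token is "recognized"
   when its metric reaches the threshold θ (default 0.5); the score is
   the recognized percentage (granularity 100/N for N tokens) and the
   mean metric over recognized tokens breaks score ties. Two details
   carry the physics: global (not per-band) mean removal models a
   recognizer front-end that normalizes overall level but remains
   sensitive to spectral shape — per-band normalization would make the
   metric blind to channel gain balance, and repetitions of the search
   would not converge to similar gain functions; and the audibility
   clipping matters because recruitment is an affine map of the dB
   envelope, so an unclipped correlation would be blind to it and
   amplification could never help. An adapter contract (WAV files +
   manifest in, CSV verdicts out) lets an external ASR system replace
   the surrogate, restoring a true top-5 lexicon rule.

## Calibration

Unit RMS is defined as 100 dB SPL. Fixture tokens are scaled to
65 dB SPL long-term. Level detectors smooth signal *power* with separate
attack/release one-pole stages, preceded by a 2-ms symmetric stage that
removes the 2f ripple of narrowband inputs; for steady tones the
detector reads the RMS level exactly, so static-curve measurements are
RMS-referred without crest-factor corrections.

## Search algorithms

All three optimizers run four deterministic sequential "threads" with
independent seeded substreams ("parallel" is an execution detail, not a
semantic one), perturb parameters uniformly within ±Δ, round to the
parameter grid, clip to the global ranges, and accept a candidate only
if it scores strictly higher, or ties with a strictly higher likelihood
(otherwise the incumbent is restored — rollback). Exact likelihood ties
keep the incumbent; among simultaneous thread challengers the lowest
thread index wins.

* **GEN1** — threads are fully independent; every iteration perturbs all
  ten parameters. Δ decays by a constant per-iteration decrement from
  half the search range to the parameter stepsize over the budget
  (750 iterations), and is floored at the stepsize so the "during the
  final iteration" and "after the final decrement" readings coincide.
  Each thread's random initialization is its own baseline and is not
  counted against the budget. The best thread wins at the end.
* **GEN2** — channels are tuned in order 1→5, 150 iterations each, all
  threads resynchronized to the cross-thread best every iteration;
  previously tuned channels stay frozen, untuned channels sit at the
  baseline (offset 0, CT 35 dB SPL — the midpoint of the range). Δ
  shrinks linearly to zero as (N − i − 1)/N of the half-range, indexed
  by the *global* iteration counter i ∈ 1..750 (consistent with the
  fixed denominator), and each channel phase opens with one full-range
  random draw per thread, not counted against the budget.
* **GEN3** — first 250 iterations tune all five CTs with gain offsets
  pinned to the baseline prescription, then 500 iterations tune all
  offsets with CTs frozen at their phase-1 best; synchronization and
  decay as in GEN2.

The searched grid has (200 offsets × 30 thresholds) = 6000 settings per
channel, 6000⁵ ≈ 7.78 × 10¹⁸ configurations over five channels — the
scale that motivates random search over exhaustive enumeration.

## Fast objective evaluation

A search evaluates thousands of candidates against one fixed token set,
so the candidate-independent work is hoisted: per token the channel band
signals and the detector level trajectories (main compressor, limiter,
recruitment envelope) of the *clean* signal are computed once. A
candidate then only applies its gain trajectory in the dB domain:
because compressor gains vary slowly relative to the detector time
constants, the detector level of a processed signal is the clean level
shifted by the running gain (quasi-static approximation). The
recruitment stage reuses the five hearing-aid channels as its band
scheme and the metric's band decomposition is those same channels, so an
entire evaluation is vectorized per-channel arithmetic with no FFTs.

Validation: against an exact per-channel reference (identical structure,
detectors smoothing the actually modulated signals), per-token metric
differences stay below 0.01–0.02. The literal resynthesis composition
(`amplify` then `simulate_loss` on the summed waveform, octave-band
recruitment) differs more for severe losses — gain-modulation sidebands
leak across brick-wall band edges and recruitment slopes up to 6 amplify
the leakage — so the channel-wise evaluation is a structural design
choice of the objective, documented rather than hidden: both paths
implement the same physics, they differ in where band decomposition
happens.

## Synthetic fixtures

* **Audiograms** (`synth_audiogram`): sloping-loss profiles for severity
  levels 4–7, built from fixed base profiles (PTA roughly 33, 43, 56 and
  70 dB HL) with a seeded ±4-dB overall shift and ±10 % slope scaling;
  `jitter` adds independent per-frequency noise (dB SD) to emulate the
  more erratic shape of individual clinical audiograms. Deterministic
  per (severity, seed); monotone non-decreasing when jitter is 0.
* **Tokens** (`generate_tokens`): 0.4–0.8-s two-syllable items — a
  sawtooth glottal source with declining f0 (100–140 Hz), three per-
  syllable formant resonators, a 2–6-kHz noise burst at the second-
  syllable onset — band-limited to 0.08–7.9 kHz and calibrated to
  65 dB SPL. They are distinct (pairwise metric < 1) but are not words;
  anything requiring lexical content needs the external-ASR adapter.

What passing tests on these fixtures shows: the constraint pipeline,
simulators and optimizers behave as specified, the chain is end-to-end
reproducible from a seed, and independent repetitions converge on
similar gain functions. What they cannot show: recognition of real
speech by a real recognizer, listener benefit, or the absolute scores a
trained ASR system would produce.

## Numerical choices and degenerate inputs

* Missing audiogram thresholds are completed by a degree-3 least-squares
  polynomial in log2(frequency) (audiometric convention; a linear-Hz
  cubic extrapolates badly at 125 Hz), clamped to [−10, 120] dB HL; at
  least 4 present values are required.
* CR feasibility is tested on the denominator (2 ≤ 20 + IG85 − IG65 ≤ 20)
  with a 1e-9 tolerance to avoid float chatter at the boundaries.
* The SII equalizer's offset is rounded to an exact 0.1-dB multiple; the
  loop is capped at 2000 steps (never reached in practice). Offsets may
  push effective gains past the ±10-dB search range; this is permitted
  and flagged in the provenance record.
* Digital silence yields −inf band levels, audibility 0, metric 0.
* Problem sizes in the shipped experiment defaults are desk-scale by
  design: 75 iterations, 50 tokens, 16 kHz for batch runs (the
  documented full budget remains 750); the unit suite uses 6–12 tokens.

## Known limitations

* The default prescription rule is a stand-in, not CAM2/NAL/DSL; gains
  are plausible but not clinically prescriptive.
* The surrogate metric is a STOI-flavoured envelope correlation, not a
  recognizer; its threshold rule replaces a top-5 lexicon decision.
* No microphone/receiver transfer functions, venting, feedback, or
  speech-in-noise conditions; one presentation level (65 dB SPL).
* Recruitment uses a fixed 100-dB-SPL ceiling; losses at or above it are
  scored as dead bands.
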