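# oprars

Hearing-aid fitting by seeded genetic random search over a simulated
aid and a simulated impaired ear.

Prescription rules (CAM2, NAL-NL2, DSL-v5, …) give a patient an initial
hearing-aid setting; the fine-tuning that follows is limited by how many
settings a human listener can be tested on. `oprars` replaces the
listener with a processing chain — five-channel dynamic-range-compression
hearing-aid simulator, loudness-recruitment hearing-loss simulator, and a
speech-intelligibility objective — and lets a random-search optimizer
audition thousands of candidate settings for one audiogram. It is aimed
at researchers in computational audiology who want a fully seeded,
self-contained testbed for fitting-by-optimization experiments.

## The model in brief

A candidate setting is ten numbers: per channel (100–700, 700–1400,
1400–2800, 2800–5600, 5600–8000 Hz) one insertion-gain offset
ΔIG ∈ [−10, +10] dB (step 0.1 dB, applied to the baseline prescription's
IGSP65 and IGSP85) and one compression threshold CT ∈ [20, 50] dB SPL
(step 1 dB) — a grid of (200·30)⁵ ≈ 7.78 × 10¹⁸ configurations.
Each candidate is made physically and clinically admissible before
scoring:

* the per-channel compression ratio
  `CR = (85 − 65) / (85 + IG85 − (65 + IG65)) = 20 / (20 + IG85 − IG65)`
  is forced into [1, 10] by repeated 0.5-dB gain corrections;
* a uniform 0.1-dB-quantized gain shift equalizes the candidate's Speech
  Intelligibility Index (ANSI-style octave-band audibility) to the
  baseline prescription's, so the level-normalized objective cannot
  starve the listener of audibility.

Three optimizers share rollback acceptance (keep a candidate only if its
score — or, on a score tie, its continuous likelihood — strictly
improves) and four seeded search threads:

* **GEN1** perturbs all ten parameters each iteration, with the search
  half-range Δ decaying linearly from half the range to the parameter
  stepsize over 750 iterations (Δᵢ₊₁ = Δᵢ − (Δ₀ − step)/750);
* **GEN2** tunes one channel at a time (150 iterations each), threads
  synchronized to the cross-thread best, Δᵢ = (750 − i − 1)·half-range/750
  on the global iteration index;
* **GEN3** tunes all CTs for 250 iterations (gains pinned to baseline),
  then all gain offsets for 500.

Scoring uses matched clean/processed speech tokens: short-time log band
energies, clipped at the audibility floor, are correlated as one
(band × frame) pattern per token; tokens above a threshold count as
recognized, giving a percent score with 100/N granularity plus the mean
metric as tie-breaking likelihood. An adapter contract lets an external
ASR system stand in for the surrogate metric.

## Worked example

```python
from oprars import (ChannelBank, HAConfiguration, baseline_prescription,
                    gen1_run, pta, synth_audiogram)
from oprars.workbench import SurrogateChainObjective, generate_tokens

a = synth_audiogram(severity=6, seed=7)      # sloping moderate-severe loss
print(f"PTA: {pta(a):.1f} dB HL")
bank = ChannelBank()
baseline = baseline_prescription(a, bank)    # stand-in linear rule
tokens = generate_tokens(50, seed=42)        # 50 speech-like tokens @ 65 dB SPL

objective = SurrogateChainObjective(tokens, a, baseline, bank)
print(objective(HAConfiguration()))          # unsearched baseline setting
state = gen1_run(objective, budget=75, seed=42)
best = objective.resolve(state.best_config)
print(state.best_result, best.ct_db_spl, best.dig)
```

Output (abridged):

```
PTA: 50.6 dB HL
baseline:  score 100.0 %, likelihood 0.9308
optimized: score 100.0 %, likelihood 0.9769
CTs (dB SPL):    [44.0, 50.0, 45.0, 28.0, 44.0]
IG offsets (dB): [9.8, 0.7, -4.0, -8.6, -9.7]
```

Both settings recognize all 50 tokens (scores saturate near ceiling, as
expected for speech in quiet), so the continuous likelihood carries the
comparison: the searched setting raises the mean clean/processed
envelope-pattern correlation from 0.931 to 0.977 — it reshapes gains
across channels (here: more low-frequency, less high-frequency gain than
the baseline rule) while the SII equalizer holds overall audibility at
the baseline's level.

The same run from the shell:

```
oprars audiogram --severity 6 --seed 7 --out a.csv
oprars fit --audiogram a.csv --algorithm gen1 --iterations 75 --seed 42 --out settings.json
oprars amplify --in speech.wav --config settings.json --out aided.wav
oprars degrade --in aided.wav --audiogram a.csv --out perceived.wav
```

Batch experiments (audiogram sets × repetitions, with run logs and a
summary CSV) run through `oprars experiment --config exp.yaml` or
`oprars.workbench.run_experiment`; `compare_repetitions` reports the
per-audiogram Pearson correlation between the gain functions of two
repetitions and per-channel |ΔCT| — the package's reproducibility
analysis.

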