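# fatiguewave

Wavelet Rényi-entropy analysis of prefrontal EEG as a marker of
accumulating mental fatigue, together with the synthetic cohort
simulator and repeated-measures statistics needed to validate it end to
end.

## The problem

Prolonged cognitive workload builds up mental fatigue, but self-report
scales (e.g. the Stanford Sleepiness Scale) and reaction-time tasks are
coarse and noisy at small sample sizes. Resting-state EEG over the
prefrontal cortex offers an objective alternative: as fatigue
accumulates, the distribution of signal power across the classical
δ/θ/α/β rhythms flattens, and that flattening can be summarized by a
single entropy number per session.

`fatiguewave` is written for researchers who want to compute this marker
from multi-channel resting-state EEG (CSV or EDF), run the accompanying
oddball reaction-time and self-report analyses, and test the whole chain
against simulated cohorts with known ground truth.

## The marker

Each recording is band-pass filtered to 3–30 Hz, z-scored per channel
over the session, decimated to a 62.5 Hz analysis rate, and cut into 8-s
windows with 50 % overlap. Every window is decomposed with a 4-level
Daubechies-4 discrete wavelet transform, whose detail levels 1–4 then
cover ≈ 15.6–31.2 / 7.8–15.6 / 3.9–7.8 / 2.0–3.9 Hz — approximately the
β, α, θ and δ bands. Per level *j*, coefficients with
|w| > mean(|w_j|) + 2·std(|w_j|) are halved (in-band denoising), the band
energy is E_j = Σ_k w_j(k)², and the relative energies
p_j = E_j / Σ_j E_j form a probability-like band profile. The marker is
the normalized order-2 Rényi entropy

    RE = ln(Σ_j p_j²) / (1 − 2) / ln 4  ∈ [0, 1],

which is 1 for a flat profile and 0 when a single band holds all the
power. The session value is the mean across windows. Inference across
sessions uses within-subject (repeated-measures) ANOVA with the
Greenhouse-Geisser correction applied to every effect, LSD post-hoc
pairwise tests, and Pearson correlations against prior sleep.

## Worked example

Simulate the default cohort (nine subjects, six sessions from `Day1` to
`Day5`, 4-channel forehead EEG at 250 Hz) shortened to 60-s recordings,
and run the full pipeline:

```python
import fatiguewave as fw
from fatiguewave.io import PipelineConfig

cfg = PipelineConfig(seed=11, cohort={"duration_s": 60.0})
res = fw.run_pipeline(cfg)
print(res.summary.query("metric == 'entropy'").to_string(index=False))
```

```
 metric session     mean       sd
entropy    Day1 0.830113 0.053096
entropy    Day2 0.841296 0.036043
entropy    Day3 0.831044 0.035517
entropy   Day4A 0.861354 0.054476
entropy   Day4B 0.866044 0.037639
entropy    Day5 0.895359 0.028193
```

The session means rise as the programmed band profiles flatten — little
change over the first three days, then a clear climb through the
sleep-deprivation sessions (`Day4A`, `Day4B`, `Day5`). The absolute
level sits above the programmed trajectory because wavelet band leakage
and the 1/f background both push measured profiles toward flat (see
`docs/methods.md`). The timepoint effect on the `Fp1h` channel,

```
F(2.493, 19.943) = 21.022, p = 4.83e-06, eps = 0.499
```

is strongly significant after Greenhouse-Geisser correction, and the
pooled correlation of the marker with prior sleep duration is negative
(`r = −0.40, n = 54`): less sleep, flatter spectrum, higher entropy.

The same chain is available from a shell:

```sh
fatiguewave run --seed 11 --out results/        # full in-memory chain
fatiguewave simulate --seed 11 --out cohort/    # write signals/logs/metadata
fatiguewave extract --signals cohort/signals --out tables/
fatiguewave behav --events cohort/events --out tables/
fatiguewave stats --tables tables/ --out tables/
fatiguewave report --tables tables/ --out tables/
```

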