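# marchphys

Wearable-physiology analysis of loaded long-distance marches.

Prolonged load carriage is one of the most demanding routine tasks in
military service. Given per-minute wearable streams — heart rate (HR) from a
chest ECG belt, body core temperature (BCT) from an ingestible telemetry
pill, hip-accelerometer counts, and step frequency — `marchphys`
reconstructs each soldier's energetic and recovery profile over a march and
compares cardiorespiratory-fitness groups. It is written for exercise and
occupational physiologists analysing field monitoring campaigns, and ships a
synthetic-cohort generator with known ground truth so the whole pipeline can
be validated without access to raw field data.

## What it computes

**Fitness.** VO2peak is predicted from the peak velocity of a progressive
endurance run (start 8.5 km·h⁻¹, +0.5 km·h⁻¹ every 200 m):

    VO2peak [mL·kg⁻¹·min⁻¹] = 2.309 · v_peak [km·h⁻¹] + 16.549

and the cohort is split into lower/middle/higher thirds (LT/MT/HT).

**Segmentation.** Streams are processed in 1-minute intervals. A minute with
step frequency > 1 Hz is marching; ≤ 1 Hz is a break. Maximal same-state
runs form activity segments (short blips are debounced); a break's onset is
the minute step frequency dropped below 1 Hz.

**Energetics.** Physical-activity energy expenditure per minute, from heart
rate above rest (HRaR = HR − supine resting HR), in kcal·min⁻¹:

    marching:  PAEE = (HRaR · 0.7810 − 15.9337) / 4.1868
    break:     PAEE = (HRaR · 0.4840 + H-Acc[cpm] · 0.0010 − 4.7964) / 4.1868

Resting energy expenditure uses the Mifflin–St Jeor men's equation
(10·W + 6.25·H − 5·A + 5 kcal·day⁻¹) prorated over the protocol window;
TEE = ΣPAEE + prorated REE; energy deficit = intake − TEE. Work rate is
classified on Howley's occupational scale ("very heavy" above
7.5 kcal·min⁻¹).

**Recovery.** Slow-phase HR and BCT recovery across the third break: value
at the last marching minute minus value at the tenth break minute.

**Statistics.** Each outcome is screened per group with Shapiro–Wilk; normal
outcomes get one-way ANOVA with Bonferroni pairwise t tests, the rest
Kruskal–Wallis with Dunn–Bonferroni. Dropout-by-tertile uses an r×c Fisher
exact test (full enumeration, Monte-Carlo fallback).

## Worked example

```python
import marchphys as mp

dataset = mp.generate_dataset(seed=1)     # 55 soldiers, 475-min march, 4 breaks
result = mp.analyze_dataset(dataset)
df = result.per_soldier
print(df.groupby("tertile")[["paee", "tee", "intake", "deficit", "pct_replaced"]].median().round(0))
```

prints

```
           paee     tee  intake  deficit  pct_replaced
tertile
HT       4172.0  4762.0  1699.0  -3083.0          36.0
LT       4135.0  4701.0  1027.0  -3647.0          22.0
MT       4146.0  4733.0  1245.0  -3486.0          26.0
```

Every group expends ~4,700 kcal but eats back only a fraction of it — the
least fit third replaces 22% of its TEE, the fittest 36% — leaving deficits
of 3,000–3,700 kcal. The cohort's median work rate (~8.8 kcal·min⁻¹)
classifies the march as a "very heavy" occupational task.

The `examples/` scripts walk through each capability (cohort simulation,
energy budgets, break recovery, group statistics), and a thin CLI wraps the
pipeline:

```bash
marchphys simulate --out data/ --seed 1
marchphys analyze --data data/ --out report/
```

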