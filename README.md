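# gaitcontext

Contextualised analysis of real-world walking from wearable gait events and
smartphone GPS, aimed at studies of people with Parkinson's (PwP) and
older-adult controls. Week-long free-living recordings tell us *how much* and
*how fast* people walk, but not *where*: walking down a hallway and walking to
the shops are different behaviours. `gaitcontext` labels every walking bout
indoor or outdoor from GPS stay points and a land-use map, aggregates digital
mobility outcomes (DMOs) by context, characterises each person's
walking-speed distribution by its number of Gaussian modes, and runs the
accompanying statistical comparisons — together with a fully seeded synthetic
cohort generator so every stage can be validated against planted ground
truth.

## What it computes

**Walking bouts.** Stride-level gait events (start, duration, length) are
filtered (duration in [0.2, 3.0] s, length > 0.15 m) and split into bouts
wherever the inter-stride break exceeds 3 s; bouts with fewer than 3 gait
cycles are discarded. Bouts are classed by duration: >10 s, 10–30 s, >30 s,
>60 s.

**Indoor/outdoor context.** Stay points are detected where GPS fixes remain
within a 20 m radius for over 2 min (a data gap counts toward the dwell when
its flanking fixes are within 10 m — the receiver stops reporting when
stationary). Stay points are clustered into stay regions with HDBSCAN,
regions inherit an indoor probability from the land-use polygon they fall in
(building → 0.9, urban/park/forest → 0.1, none → 0.5), and each bout gets the
time-weighted mean probability over its interval: indoor if p > 0.5, outdoor
if p < 0.5, unknown when evidence covers less than half the bout.

**Walking-speed modes.** Per participant and bout-duration class, the stride
speed distribution is fitted with univariate Gaussian mixtures for K = 1..9
and two variance families (pooled and per-component) by EM, and the number of
modes is chosen by the Bayesian Information Criterion,

    BIC(K) = -2 log L + p log n,   p = 2K (equal) or 3K − 1 (varying),

minimised over the table, ties broken toward smaller K. A resampling utility
re-estimates modes at fixed per-day stride counts (2,500 / 5,000 / 7,500 /
10,000) via linear interpolation of each day's speed sequence.

**Statistics.** Within-cohort Gaussian GLMs of each DMO on location
(adjusted for sex, age, height), cohort × location interaction models,
Fisher's exact test on mode-count contingency tables (exact 2×2 enumeration;
seeded fixed-margin Monte Carlo for larger tables), and proportional-odds
ordinal regression of the mode count on clinical predictors (LEDD,
MDS-UPDRS II/III, ...) with backward elimination at p > 0.05 and
Nagelkerke's R².

## Worked example

```python
import gaitcontext as gc

cfg = gc.RunConfig(
    out_dir="demo_run", seed=3,
    cohort=gc.CohortSpec(n_pwp=3, n_control=3, n_days=3,
                         bouts_per_day_mean=60),
)
out = gc.run_pipeline(cfg)

import pandas as pd
modes = pd.read_csv(out / "modes.csv")
print(modes[["participant_id", "duration_class", "selected_k"]].head(6))
```

prints (seed 3):

```
  participant_id duration_class  selected_k
0         CTL001          >10 s           2
1         CTL001        10–30 s           2
2         CTL001          >30 s           2
3         CTL002          >10 s           3
4         CTL002        10–30 s           3
5         CTL002          >30 s           3
```

`selected_k` is the BIC-chosen number of walking-speed modes for that
participant in that bout-duration class — here CTL001 was planted with a
2-mode speed distribution and CTL002 with 3 modes
(see `demo_run/ground_truth.json`), and both are recovered in every class.
At this miniature scale (3 participants per cohort) some GLM outcomes emit
"singular design" warnings and are skipped; they fit normally at study
scale. `demo_run/` also contains `bouts.csv` (with indoor/outdoor
labels and indoor probabilities), `dmo_daily.csv` / `dmo_participant.csv`
(steps/day, walking minutes, bout counts, speed, cadence, stride length and
duration, per context stratum), `results.csv` (GLM and ordinal-model
estimates) and `manifest.json` (full configuration for reproduction).

The same pipeline is available from the shell:

```sh
gaitcontext simulate --out demo_run --seed 3 --n-pwp 3 --n-control 3 --n-days 3
gaitcontext report demo_run
```

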