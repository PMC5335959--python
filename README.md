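# routinescore

Non-intrusive monitoring of a household's daily routine from appliance
switch-on events, aimed at ambient-assisted-living use: detecting when an
elderly person's activity pattern deviates from their learned routine using
nothing but smart-meter data disaggregated to appliance level (NILM).

The only observable is the timestamp at which a manually operated appliance
is switched on. Switch-on instants require human activity (an appliance left
running does not), so their pattern over the day and the week is a proxy for
activities of daily living. The package learns each household's routine,
scores every test day's *normality* with an explicit uncertainty band, and
flags deviations — gradual deterioration (e.g. declining cooking activity),
absences, and acute anomalies.

## The model

The frame of discernment is Ω = {h₁ (normal pattern), h₂ (abnormal
pattern)}, with h₃ = h₁ ∪ h₂ carrying ignorance. Training bins events per
(appliance, weekday, intra-day interval) and estimates the presence
probability

> P(Tᵢ) = (# training days of that weekday with ≥ 1 event in Tᵢ) / (# training days of that weekday)

At test time each (appliance, interval) observation becomes a basic belief
assignment weighted by two certainty constants (defaults C₀ = 0.9, C₁ = 0.1):

| | m(h₁) | m(h₂) | m(h₃) |
|---|---|---|---|
| event observed | P·C₀ | (1−P)·C₀ | 1−C₀ |
| no event | (1−P)·C₁ | P·C₁ | 1−C₁ |

i.e. an observed switch-on leaves 10 % uncertainty, an absent one 90 % —
human behaviour is non-deterministic, so silence is weak evidence of
anything. Dempster's rule of combination,

> (m₁ ⊕ m₂)(A) = 1/(1−K) · Σ_{B∩C=A≠∅} m₁(B) m₂(C),  K = Σ_{B∩C=∅} m₁(B) m₂(C),

fuses the per-appliance BBAs within each observation window (default 6 h)
and then the window masses over the day. The daily belief/plausibility pair
[bel(h₁), pl(h₁)] bounds the probability that the day followed the normal
routine; a threshold θ classifies each day as NORMAL (θ ≤ bel), ABNORMAL
(θ ≥ pl), or INDETERMINATE (inside the band — the evidence does not
suffice, which is how inactivity is muffled instead of raising alarms).

A Gaussian-mixture union-probability baseline (per-appliance, per-weekday
time-of-day mixtures selected by BIC; daily score 1 − ∏ₐ(1 − pₐ)) is
included for comparison, together with a seeded synthetic-household
generator with injectable deterioration / absence / acute / recovery
scenarios, so the whole pipeline is testable without external datasets.

## Worked example

```python
import warnings
from datetime import timedelta
from routinescore import *

profile = preset_profiles()["pensioner_small"]
onset = SimulationConfig(120, 100, 7).first_test_date + timedelta(days=50)
config = SimulationConfig(n_train_days=120, n_test_days=100, seed=7, scenarios=(
    Scenario(ScenarioKind.DETERIORATION,
             appliances=("cooker", "kettle", "microwave", "toaster"),
             onset=onset, intensity=0.3),
))
log = filter_relevant(generate_log(profile, config))
train, test = split_train_test(log, 120 / 220)
table = train_usage_table(train, interval_hours=6)
daily, _ = score_period(test, table, ScoringConfig(threshold=0.5))
```

prints (first and last three test days, plus summary):

```
trained P(kettle | Monday, 06:00-12:00) = 0.889
2015-05-05  bel=0.962  pl=0.962  NORMAL
2015-05-06  bel=0.987  pl=0.987  NORMAL
2015-05-07  bel=0.980  pl=0.980  NORMAL
2015-08-10  bel=0.812  pl=0.823  NORMAL
2015-08-11  bel=0.915  pl=0.924  NORMAL
2015-08-12  bel=0.786  pl=0.788  NORMAL
median daily bel(h1): 0.969 before onset -> 0.838 after
2 of 100 test days classified ABNORMAL
```

The trained kettle probability recovers the generator's 0.85 morning habit;
after the injected cooking deterioration begins, the median daily belief in
a normal pattern drops from 0.969 to 0.838 and occasional days cross the
threshold. The narrow [bel, pl] bands show how accumulating a whole day's
evidence shrinks ignorance relative to any single 6-hour window.

The same pipeline is available from the shell:

```bash
routinescore simulate --preset pensioner_small --train-days 120 --test-days 100 \
    --seed 7 --events-out events.csv --registry-out registry.csv
routinescore train --events events.csv --registry registry.csv --out table.csv
routinescore score --events events.csv --registry registry.csv \
    --table table.csv --out scores.csv --gmm
```

## Layout

- `src/routinescore/dst.py` — mass functions, Dempster's rule, belief/plausibility
- `src/routinescore/events.py` — event CSV + power-channel I/O, edge detection, filtering, chronological split
- `src/routinescore/bba.py` — usage-probability training and BBA weighing
- `src/routinescore/scoring.py` — window/day fusion, classification, score CSV
- `src/routinescore/gmm.py` — Gaussian-mixture union-probability baseline
- `src/routinescore/simulate.py` — synthetic households and anomaly scenarios
- `src/routinescore/cli.py` — `routinescore` command-line tool

See `docs/methods.md` for modeling details, parameter choices and known
limitations.
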