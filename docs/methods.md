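# Methods

## Problem and observables

The package scores the day-to-day *normality* of a household's routine
using only appliance-level switch-on events, the kind of stream a NILM
(non-intrusive load monitoring) system produces from a single smart meter.
Only manually operated appliances with a repetitive pattern carry
information about human activity; continuously or automatically cycling
loads (fridge, freezer) are excluded via a per-appliance `relevant` flag in
the registry. Durations of use are deliberately ignored: an appliance left
running implies no activity, whereas switching one on does. Events are
timezone-naive local timestamps at minute resolution; days are half-open
`[00:00, 24:00)`, and daylight-saving clock changes are not corrected (the
source logs are local-time recordings — a documented caveat, not a bug).

When only raw power channels are available, switch-on events are extracted
as rising edges through a watt threshold (default 10 W) after the channel
has been below it for a debounce period (default 5 min). These defaults are
this package's choice — event detection is usually delegated to the NILM
layer, and no canonical threshold exists for it here.

## Evidence model

The frame of discernment is {h₁ = normal pattern, h₂ = abnormal pattern};
the third focal element h₃ = h₁ ∪ h₂ carries ignorance. The implementation
hard-codes these three focal elements rather than offering a general
power-set engine: every mass function in this method lives on exactly this
frame, and a general engine would add surface without coverage.

**Training.** Events are binned by (appliance, weekday, intra-day
interval). The usage probability of a bin is the fraction of training days
of that weekday on which the appliance fired at least once inside the
interval. Presence counting (not raw occurrence counting) keeps the
estimate a probability even when an appliance fires several times per
interval; correspondingly, several events in one bin contribute a single
event-branch BBA at scoring time. Appliances never seen in training keep
all-zero rows; optional add-one (Laplace) smoothing is available behind a
flag but off by default, because a hard zero is what makes unexpected
activity maximally informative.

**Weighing.** With usage probability P and certainty constants C₀
(event observed) and C₁ (no event):

- event: m(h₁) = P·C₀, m(h₂) = (1−P)·C₀, m(h₃) = 1−C₀
- no event: m(h₁) = (1−P)·C₁, m(h₂) = P·C₁, m(h₃) = 1−C₁

Both branches sum to one algebraically. Defaults C₀ = 0.9, C₁ = 0.1: an
observed switch-on leaves 10 % uncertainty, an absent one 90 %, encoding
that human behaviour is non-deterministic and silence is weak evidence.
The no-event branch is mirrored (missing a habitual usage is *weak
abnormal* evidence, using an unhabitual slot is *strong abnormal*
evidence through the event branch).

**One deliberate boundary choice.** A bin with trained P = 0 and no event
contributes nothing (a vacuous mass) instead of the formula's
(C₁, 0, 1−C₁). Read literally, the no-event branch at P = 0 awards weak
*normal* evidence for silence in a bin the appliance never used; since a
realistic routine is sparse (most of the 7 × 4 × N_appliances bins are
empty), a completely inactive day would then accumulate bel(h₁) ≈ 0.8 and
classify NORMAL — the opposite of the intended behaviour, where inactivity
is muffled into indeterminacy. Treating "nothing expected, nothing seen"
as *no information* is the standard evidential-reasoning stance (a sensor
with nothing to say emits the vacuous mass) and restores the intended
behaviour: on an empty day only habitual bins speak, each weakly abnormal,
so belief stays low while plausibility stays high and the day lands in the
indeterminate band. An event in a P = 0 bin still yields maximal abnormal
evidence m(h₂) = C₀.

**Fusion.** Dempster's rule with conflict renormalization combines the
per-appliance BBAs of each observation window (default 6 h, so four
windows per day), and the window masses are then fused over the day. By
associativity, fusing windows-then-day equals fusing all appliance masses
jointly, so the decomposition is presentational. The fold is implemented
pairwise; tests cross-check it against a brute-force single-pass 3^N
enumeration. Total conflict (K = 1) is only reachable when both operands
have zero ignorance, which cannot happen while C₀, C₁ < 1; the error is
raised (naming the fusion step) rather than silently clamped. Masses are
renormalized after each combination to absorb floating-point drift, and
the pairwise cross-terms are grouped so combination is bit-exact
commutative.

**Classification.** The daily [bel(h₁), pl(h₁)] interval is compared with
a threshold θ: NORMAL if θ ≤ bel, ABNORMAL if θ ≥ pl, INDETERMINATE
otherwise. θ is user-set (default 0.5); the thresholds used on real
deployments are empirical and never published, so a calibration helper
sweeps θ over the training period's self-scores and returns the largest θ
whose false-alarm (ABNORMAL) rate stays within a budget. Display values
are truncated (not rounded) to two decimals, matching the convention of
the canonical worked example; internal arithmetic is full precision.

## The union-probability baseline

The comparison model fits, per (appliance, weekday), a 1-D Gaussian
mixture over time-of-day (component count by BIC over 1..3, ties toward
fewer components; variance floored at (6 min)² because event times have
minute resolution and narrower spikes only let BIC overfit duplicate
timestamps), plus a usage prevalence. The per-appliance day score is a
reconstruction — the original is published only in outline:

- events present: pₐ = mixture density at the best-matching event time,
  normalized by the mixture's peak density (∈ [0,1]; habitual-time events
  score 1);
- no events: pₐ = 1 − prevalence (the probability of a no-use day);
- events present but the cell has no mixture (fewer than two training
  events): pₐ = prevalence.

The daily score is the union 1 − ∏ₐ(1 − pₐ) over all relevant appliances
(whether the original unions over appliances or over events is not
recoverable; per-appliance is implemented). Time-of-day is linear on
[0, 24) with no circular wrap — household appliances rarely straddle
midnight, a documented limitation. The union rule's known failure mode is
saturation: one appliance with a strict routine drives the score to 1 and
masks anomalies everywhere else. The evidence-fusion scorer does not share
this failure mode, and the test suite demonstrates the contrast.

## Synthetic households

Real reference datasets are external, so the generator produces event logs
with the statistical structure the method assumes: per-(appliance,
weekday, interval) presence probabilities, truncated-Gaussian event times
within each interval (the fusion scorer only uses presence, but the
mixture baseline needs realistic times), multi-month spans, and seeded
determinism (same seed → byte-identical CSV).

Two presets are provided. `pensioner_small` is a single-pensioner home
with six relevant appliances plus a non-relevant cycling fridge; the
kettle follows the canonical peaked shape (presence 0.85 in the morning
interval, 0.6 in the evening one), laundry runs Mondays and Thursdays,
giving the weekday dependence the model exploits. `family_large` is a
20-appliance family home with a dense, strict routine, including a boiler
fired like clockwork morning and evening. Probabilities were fixed once
from the canonical shapes; they are study conditions, not tuning knobs.

Scenarios perturb presence probabilities over a date window:
DETERIORATION ramps a multiplier linearly from 1 down to `intensity`
(default ramp 21 days — the simplest monotone model of a gradual
multi-week decline), ABSENCE forces 0, ACUTE applies the multiplier on
single days, RECOVERY ramps back up to 1. At most one scenario may touch
a given appliance on a given day; overlaps raise an error rather than
guessing a composition.

The masked-anomaly case (`generate_masked_anomaly_log`) models the
saturation stress test: the boiler keeps its strict schedule while the
rest of the household's routine collapses — kettle, microwave and
television fire at odd night hours (presence 0.5) and everything else
goes silent for two weeks. Pure absence of all non-strict appliances is
*not* sufficient: two daily boiler events at P̂ = 1 contribute a
multiplicative normal-evidence factor (~10²) that outweighs the ~30 weak
no-event abnormal masses of a silent day. Off-schedule events, each
committing C₀ = 0.9 to h₂, are what real disrupted routines produce and
what tips the fused evidence abnormal; the union baseline stays saturated
above 0.95 either way.

What the generator does **not** emulate: watt-level power traces (only a
square-wave writer for testing edge detection), appliance durations,
correlated appliance usage (events are independent across appliances given
the routine), seasonal drift, or NILM disaggregation errors. Passing tests
therefore show the method behaves as designed under its own assumptions,
not that it survives the noise of a real disaggregator.

## Numerical and design notes

- Mass invariants: non-negative, sum to 1 within 1e−9; combination
  equality checks in tests use 1e−12 absolute tolerance.
- Chronological train/test split on whole calendar days,
  ⌊fraction × n_days⌋ train days (ε-guarded against float artefacts such
  as floor((120/220)·220) = 119); earlier days train because routines
  drift and the starting routine is the reference.
- Daily fusion includes fully-vacuous windows — they are neutral elements,
  so inclusion is harmless and simplifies bookkeeping.
- The daily uncertainty band is never wider than the narrowest window band
  in all tested configurations (empirically swept; accumulated evidence
  narrows ignorance).
- Mixture fits are seeded; determinism is asserted in tests.
- The relevance heuristic (`suggest_auto_cyclers`: events on > 90 % of
  days and median inter-event gap < 2 h) only *suggests* fridge-like
  cyclers; relevance remains a manual registry decision, and the heuristic
  is applied nowhere by default.

## Problem sizes used in tests

Simulation-backed tests use 120 train + 100 test days (the deterioration,
absence and masked-anomaly runs), 500 simulated weeks for
usage-probability recovery (every bin within 0.05 of generator truth), and
n = 200 single-cluster draws for mixture-mean recovery (within 0.15 h).
These sizes give stable seeded statistics while keeping the default test
run fast.

## Known limitations

- Single-household model; no cross-household pooling or priors.
- No long-term trend tests on the score series (change-point detection is
  out of scope; trends are inspected visually or downstream).
- The no-wrap time-of-day treatment penalizes routines genuinely
  straddling midnight.
- DST clock changes shift one hour of events twice a year.
- The union baseline is a reconstruction; absolute union values should not
  be compared against other implementations, only its qualitative
  behaviour.
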