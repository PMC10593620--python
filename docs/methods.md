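# Methods

## Scope and data model

The package analyses epoch-level passive-infrared (PIR) activity traces:
one value per 10 s epoch, the percent of the epoch with detected motion,
per singly-housed animal under a 12:12 light–dark cycle. Missing epochs
are always explicit (NaN in memory, empty field in CSV); nothing is ever
imputed silently. All derived quantities state their missing-data policy
below.

Zeitgeber time (ZT) is hours since lights-on; an epoch is in the light
phase iff ZT ∈ [0, 12). A treatment day runs lights-on to lights-on, so
each day contains its light phase followed by its dark phase and the daily
injection (~ZT 11.5) precedes that day's dark phase; the dark phase
reported for day *d* is therefore the one that began after day *d*'s
injection. Baseline calendar days carry labels ≤ 0 and are averaged into
the "day 0" reference during table assembly ("baseline collapse");
treatment days are 1..12 (dosing) and 13 onward (discontinuation) under
the default 4 + 12 + 13-day calendar. Timestamps are naive local clock
times; constant-condition laboratory housing is assumed (no DST handling).

Partial epochs at trace start/end are truncated to whole epochs by the
reader; whole-day metrics (actograms, IS/IV) use complete days only.

## Sleep scoring

Immobility is `activity ≤ θ` with default θ = 0: any PIR detection within
an epoch marks it mobile. θ is exposed for sensitivity analyses because
the original acquisition systems differ in noise floor; 0 is the faithful
default for percent-time-active data. A sleep bout is a maximal immobility
run of duration ≥ τ, default τ = 40 s (4 epochs), the EEG-validated
behavioural criterion for mice. Durations are whole epochs; τ must be a
multiple of the epoch length (no sub-epoch interpolation). Missing epochs
break immobility runs — a bout cannot span unobserved time, which is
conservative and can only underestimate sleep.

Bouts are attributed to the phase and day of their **onset** (each bout
counted exactly once; consistent with latency semantics). Epoch-level
quantities (percent asleep per hour/phase) attribute by epoch, so a bout
spanning a boundary contributes its overlap to each side. Bout-duration
bins are left-inclusive on integer seconds: ≤ 60 s, (60, 600], (600,
3600], > 3600 s; a 60 s bout is "≤ 1 min". Bin percentages are of the
phase's bout count and are undefined (NaN, 0/0) for phases with no bouts.

Sleep latency for a day is the time from lights-on to the first bout
onset at or after lights-on, 0 if a bout spans lights-on, and missing if
the light phase contains no bout.

## Circadian statistics

On hourly bins (the package's default and only tested bin width for these
statistics, exposed as a parameter):

* `IS = [N Σ_h (x̄_h − x̄)²] / [p Σ_i (x_i − x̄)²]` with p = 24 bins/day and
  N observed samples. For iid noise over d days, IS is exactly the
  between-hours ANOVA variance ratio with mean (p − 1)/(N − 1) ≈ 1/d; for
  any day-periodic series IS = 1.
* `IV = [N Σ (x_i − x_{i−1})²] / [(N − 1) Σ (x_i − x̄)²]`, pairs taken
  across day boundaries. Closed forms used as oracles: IV = 4 for an
  alternating two-level series (even N); IV → 2(1 − cos(2π/24)) ≈ 0.0681
  for an hourly-sampled 24 h sinusoid.

Missing hours are excluded from all sums; IV pairs spanning a missing hour
are dropped and the (N − 1) pair count generalises to the number of valid
pairs; both metrics report `n_hours_used`. Zero-variance series yield NaN
(undefined), never 0. Period-restricted IS/IV (baseline / dosing /
discontinuation) use only the whole days of that period. Both statistics
are affine-invariant, so they are insensitive to sensor gain/offset.

Actogram matrices hold one row per whole day and one column per
within-day bin (bin width must divide 24 h); double-plotting appends day
d + 1 to the right of day d with the final row's right half empty.

## The synthetic cohort generator

The generator exists so every stage of the pipeline can be verified
against exact expectations; it emulates the statistical structure the
analysis assumes, not mouse physiology.

Two-state alternating renewal process per animal, 10 s resolution:

* **Wake → sleep**: per-epoch hazard h, one value per phase (defaults
  h_light = 0.03, h_dark = 0.01 per epoch, i.e. mean wake runs of ~333 s
  and ~1000 s), giving geometric wake runs with mean Δ/h seconds.
* **Sleep bouts**: drawn at onset from a phase-specific two-component
  lognormal mixture, discretised as k = ⌈D/Δ⌉ epochs. Defaults: a brief
  component (median 25 s, σ = 0.7, weight 0.5 light / 0.6 dark) that
  deliberately places mass *below* the 40 s threshold — the scorer, not
  the generator, decides what counts as sleep — and a consolidated
  component (median 12 min light / 6 min dark). Sleeping epochs have
  activity exactly 0.
* **Wake activity**: truncated normal (σ = 6) around a circadian mean
  profile — light baseline 5 %, dark baseline 28 %, Gaussian bumps at
  ZT 13 (+38) and ZT 22.5 (+28) for the early- and late-dark activity
  peaks typical of C57BL/6 mice — clipped to [0.5, 100], so an awake
  epoch can never read 0 and masquerade as immobility.
* **Injection/handling**: a daily window (default ZT 11.5–12.0) forces
  wakefulness (ongoing bouts are truncated, none can start) and adds a
  +45 burst to the activity mean, reproducing the injection-time activity
  spike.
* **Treatment effects** are step functions per study period applied to the
  dark phase: an activity multiplier, a sleep-hazard multiplier, and
  bout-duration scale multipliers. The scale can act on the whole mixture
  (`bout_scale_multiplier`) or per component: lengthening only the
  consolidated component enriches the 10–60 min bin (drug-on
  consolidation), while lengthening only the brief component moves mass
  from ≤ 1 min into 1–10 min without touching the long bins (post-drug
  de-fragmentation). A uniform scale on both components cannot produce the
  latter signature — it drains the 1–10 min bin into 10–60 min faster than
  it refills from ≤ 1 min (verified on the exact bin masses) — which is
  why the per-component knobs exist.

Default treated-group effects (the study conditions; the control group is
effect-free): dosing — dark activity × 0.55, dark hazard × 1.8, long-bout
scale × 1.5; discontinuation — dark hazard × 0.85 with brief-bout scale
× 2.2, i.e. fewer, longer brief bouts at nearly unchanged total dark sleep
(sleep de-fragmentation after drug withdrawal). The study gives no
quantitative effect sizes, so these are chosen once for clear qualitative
structure at n = 12/group and documented here; they are not fit to data.

Determinism: per-animal seeds are a stable hash of (master seed,
animal id) (`seed·1 000 003 + crc32(id) mod 2³¹−1`), so cohorts are
reproducible animal-by-animal and invariant to cohort ordering.

**Ground truth.** With bout-length pmf p_k (computed exactly from the
mixture CDF on the Δ grid) and per-epoch hazard h, renewal theory gives
expected scored percent-asleep `100 · E[k; k ≥ τ/Δ] / (E[k] + 1/h)` (bouts
below threshold score as wake), and expected bin shares as the pmf mass in
each bin conditioned on k ≥ τ/Δ. These are exact for a homogeneous phase;
phase boundaries (a bout drawn in one phase spilling into the next) and
the injection window introduce errors well under 1 percentage point over a
12 h phase, which is why cohort-scale recovery is tested at 3 points
(sleep) and 5 points (bin shares).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no ultradian or homeostatic (Process-S) sleep
regulation, no REM/NREM substructure, no sensor artefacts other than
missingness, no inter-animal parameter heterogeneity (animals differ only
by seed), step rather than pharmacokinetic treatment onsets, and no
free-running (DD) conditions.

## Pipeline and inference

`summarize_cohort` emits one tidy row per (animal, day, window, metric)
with a coverage flag; exclusions — explicit (animal, day, window) records,
e.g. a final light phase truncated by cull, or figure-level outlier
removals — are applied before baseline collapse, so an excluded baseline
day also drops out of the day-0 mean. No automatic outlier rule is
implemented because no reproducible rule exists; exclusions are always an
explicit user list. Variable-length follow-up (e.g. a 7-day first cohort)
simply yields missing later days.

Formal inference on these tables (mixed-effects models,
Geisser–Greenhouse-corrected ANOVA, post-hoc tests) is deliberately out of
scope — those are routine in statsmodels/R. The built-in check is a
two-sided permutation test on the difference of group means with
`p = (1 + #{|T_perm| ≥ |T_obs|}) / (1 + n_perm)`, which is never anti-
conservative, is reproducible given a seed, and is calibrated in the test
suite (type-I rate at α = 0.05 over 1,000 simulated null cohorts, n =
6/group, 2-day calendar, 199 permutations — sizes chosen to make a
thousand-replicate calibration routine on a laptop).

## Numerical choices

* Bin and threshold comparisons are exact on integer seconds (no float
  ties possible).
* Percent-asleep/active denominators count non-missing epochs only; an
  hour with zero observed epochs is missing, and windows report the
  fraction of usable hours as `coverage` rather than failing.
* IS/IV need ≥ 2 full days; zero variance → NaN.
* Permutation test adds 1e-15 slack to the |T_perm| ≥ |T_obs| comparison
  so exact ties under relabelling count as extreme (conservative).
* CSV round-trips use `%.17g` formatting and round-trip float parsing, so
  write → read is bit-exact, which the determinism guarantees rely on.

## Problem sizes used in the checks

The shipped verification runs use the full study geometry where it
matters — 24 animals × 29 days × 8,640 epochs (≈ 6·10⁶ epochs) for
recovery, bin conservation and study-shape checks — and scaled-down
geometries where only calibration is at stake (null cohorts of 12 animals
× 2 days for the type-I rate; 1,000 random sequences up to 10⁴ epochs for
the scorer oracle). These sizes are the package's own defaults and are
stated in the relevant test/docstrings.
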