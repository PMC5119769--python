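# Methods

## Generative model

One synthetic participant is a session of CT, IT and NT trials in
uniformly random order — 64/64/32 for the ABV-style task, 20/20/20 for the
TL-BS-style task. Each trial's RT is an independent draw from
Normal(μ, σ) where μ depends on the trial's type and its bias subset and σ
is the group's RT standard deviation. Start values are μ = 600 ms,
σ = 30 ms for every type. Drawing per trial after ordering is
distributionally identical to drawing each homogeneous batch at once and
scattering it over the matching positions, so the generator needs no
batch-then-relocate step.

A *static* bias b is implied by CT mean 600 − b/2 and IT mean 600 + b/2.
A *dynamic* bias splits the session into n consecutive subsets whose bias
alternates +m, −m, +m, … around the 600 ms midpoint. Subset lengths divide
a switch base evenly, the last subset absorbing leftovers; the base is all
160 positions for the ABV task and the 40 CT+IT trials for the TL-BS task
(NT trials inherit the surrounding regime). The two bases are the only
placement rule consistent with both layouts' stated switch positions
(e.g. three ABV subsets end at trials 53/106/160; eight TL-BS subsets
switch after every 5th CT/IT trial). NT means stay at the session mean; in
the mean- and SD-manipulating series NT follows the CT/IT manipulation so
the whole session shifts together — NT trials never enter any index, so
this choice only keeps overall-RT-based filtering uniform.

## Outlier exclusion

Filters set inclusion flags and never alter data. Both methods run two
single-shot passes: absolute bounds first (150–2000 ms for ABV-style,
200–1500 ms for TL-BS-style; strict inequalities), then an SD gate on the
survivors — more than 2 sample SDs from the trial type's own mean for the
ABV method (per-type, as that method prescribes), more than 3 sample SDs
from the pooled mean for the TL-BS method. The gate is not iterated. A
group with fewer than two survivors skips its gate with a logged warning.

The traditional BI is computed over trials passing the absolute bounds
only; the SD gates are treated as part of the ABV/TL-BS methodologies and
apply to those indices alone. This is deliberate: a gate whose thresholds
are estimated from the same few dozen trials it censors *inflates* the
sampling variance of the surviving mean (simulation: dataset-level BI SD
rises from ≈5.3 to ≈5.9 ms under the per-type 2-SD gate at σ = 30), so
applying it to BI would distort the reference index the variability
measures are compared against.

## Indices

* `traditional_bi` — mean included-IT RT minus mean included-CT RT;
  undefined (NaN) if either type has no included trials.
* `bin_bias_series` / `abv` — eight bins of 20 *original* positions (bin
  membership ignores exclusions); ABV = sample SD (n−1) of the eight bin
  BIs over the mean RT of all included CT+IT trials. Any bin lacking
  included CT or IT trials makes ABV NaN; the formula is deliberately not
  rescued with seven bins. Under start values this happens in ≈0.03% of
  datasets (random ordering occasionally packs a bin with NT trials).
* `pair_trials` — each included CT/IT anchor pairs with the nearest
  included opposite-type trial within 5 positions (distance counted over
  all session positions, NT included; ties to the earlier trial — a
  deterministic convention, the method's description does not fix one).
  A mutually nearest CT/IT pair contributes two points, one per anchor.
* `tlbs_summary` — mean/peak of strictly positive and strictly negative
  point values (exactly 0 when a sign is absent — a meaningful "no
  excursion" observation, not missing data; zero values count as neither
  sign), plus TL-BS variability: the mean Euclidean step
  `sqrt(Δposition² + Δvalue²)` between consecutive points. The superseded
  mean-absolute-difference formulation is available via
  `method="absolute"` but is not used anywhere by default.

## Simulation engine

Five series, 10 runs each, change group vs control group (control at
start values): mean +20 ms/run; SD +2 ms/run; static bias +3 ms/run;
switch count = run number at amplitude 20 (control constant +20); and
amplitude 20 + 3(run−1) at four subsets (control amplitude 20). Each run
simulates studies of 26 + 26 participants; per index the groups are
compared with a two-sided Welch t-test (Satterthwaite df, α = .05, no
multiple-testing correction) and the run outcome is the percentage of
studies with p < .05. NaN index values are dropped per group before
testing; a study with fewer than two defined values in a group yields an
undefined test, which leaves the percentage's denominator.

Seeding: a root seed spawns one `numpy` `SeedSequence` child per run and
one grandchild per study, so every cell is independently reproducible.

Default scale is the full 1000 studies per run (a run takes ~10 s on one
CPU); `--studies 200` gives a fast mode whose percentages carry ≈3× the
Monte-Carlo error. Property and recovery tests in the suite use 150–4000
datasets or 200 studies per condition, sized so that three standard errors
resolve the effect under test.

## What the generator does and does not emulate

Real dot-probe RT data are right-skewed, serially dependent, and
heterogeneous across participants; this generator is deliberately "tidy" —
normal, i.i.d. within trial type, identical parameters within a group.
That isolates exactly one question: which *distributional* features each
index responds to. Passing tests therefore certify the indices'
sensitivity map under controlled conditions, not their behaviour on
empirical data.

## Known limitations

* Figure-style smoothed TL-BS time-series plots are out of scope.
* The trial-level CSV entry point accepts real data in the documented
  schema but assumes the session matches one of the two fixed layouts.
* Percentages at 1000 studies carry binomial noise (SE ≈ 1.5 points near
  50%); comparisons tighter than ±3 SE are not meaningful at that scale.
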