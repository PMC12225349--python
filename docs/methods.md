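# Methods

This note documents the models, rules and numerical conventions behind
`cprvent`, and what the synthetic-data tests do and do not demonstrate.

## Setting

A resuscitation test is a two-minute run of the adult 30:2 protocol
(cycles of 30 chest compressions and 2 bag-mask ventilations) preceded by
5 initial rescue breaths, the sequence used for drowning victims. Tests
are performed by rescuer pairs on an instrumented manikin at three
exposure levels: T0 (untrained), T1 (after one training session), T2
(after two). The manikin logs compressions (depth mm, instantaneous rate
min⁻¹, per-compression correctness flags) and ventilations (insufflation
time, recorded in integer milliseconds; volume in mL; an "effective"
capture flag). Only effective ventilations enter any analysis sample;
excluded events are tallied, never silently dropped.

## Ventilation classification

Each effective ventilation is coloured by its joint (volume, insufflation
time) position:

* **green** — volume in [500, 600] mL *and* time in [0.85, 1.15] s;
* **red** — volume < 400 mL, volume > 700 mL, time < 0.55 s, or
  time > 1.45 s;
* **amber** — everything else (inside the wide box, outside the green one).

All interval bounds are closed. The red conditions are strict
inequalities, so a value exactly on a wide-box boundary is amber; green
bounds are inclusive for symmetry. Because the green box is nested in
the amber box (a validated invariant of `ClassificationThresholds`), the
rules partition the plane; evaluation order is green, then red, else
amber. Times are stored as integer milliseconds and divided by 1000
exactly at the comparison boundary, so threshold comparisons never see
accumulated float error. The bands are deliberately configuration data
(JSON) rather than constants: they are convention-based tolerances around
the guideline targets (500–600 mL; ≈ 1 s insufflation), not physical
constants, and alternative bands should be explorable without code
changes.

## Session metrics

Per-session variables: mean compression depth and rate; number of
effective ventilations; percent effective; mean volume and mean
insufflation time over effective ventilations; and the composite scores

* compression quality `CC_q` = mean of (% correct depth, % correct
  recoil, % correct rate);
* ventilation quality `V_q` = % of effective ventilations classified
  green (0 when the session has none — a deliberate convention so an
  all-ineffective session scores 0 rather than erroring);
* CPR quality = (`CC_q` + `V_q`) / 2, exactly.

"Correct rate" is ambiguous between a per-compression judgement and a
session-level one, so both are implemented: the default scores each
compression's instantaneous rate against the guideline band
[100, 120] min⁻¹ (consistent with the per-compression depth and recoil
components); `rate_mode="session-mean"` scores 100 if the session's mean
rate is in band, else 0. Neither is asserted to be what any particular
device reports.

**No-flow time** is the session duration minus the union of
compression-occupancy intervals, where a compression at instantaneous
rate *r* occupies 60/*r* s; overlapping intervals are merged before
summing. It is reported both in seconds and as % of duration, because
the two conventions coexist in practice. Note that under this strict
definition the ventilation interludes of a 30:2 protocol count as
no-flow, so values near 30–35% are expected for a protocol-faithful
session; device-reported "no-flow" figures that exclude planned
ventilation pauses will be much smaller and are not comparable.

Group summaries report the median and IQR (Q1–Q3) per variable per test,
using linear-interpolation quartiles (numpy's default percentile rule);
fixing the convention makes reported IQRs exactly reproducible.

## Repeated-measures comparisons

The unit of analysis defaults to the rescuer pair (CPR is performed in
pairs; the pair is the independent replicate), with a participant-level
switch for data recorded per participant. For each variable the three
exposure columns are tested for normality with Shapiro–Wilk at α = 0.05
(a standard choice at these sample sizes); constant columns, which make
the test degenerate, route nonparametric.

* **Parametric route:** one-way repeated-measures ANOVA (statsmodels
  `AnovaRM`), then pairwise paired *t* tests with Bonferroni correction
  (p × 3 capped at 1) and Cohen's *d* for paired data,
  |mean Δ| / sd(Δ) with the n−1 sd. Zero-spread differences make *d*
  undefined and are flagged rather than given a value.
* **Nonparametric route:** Friedman test on within-subject ranks
  (tie-corrected χ² approximation), then pairwise Wilcoxon signed-rank
  tests using the normal approximation with Pratt zero handling — chosen
  because it is deterministic and remains defined under the heavy ties
  that percentage-valued scores produce at n = 5 pairs. The Wilcoxon
  *z* feeds Rosenthal's *r* = |z|/√N.

Rosenthal's N defaults to the total observation count across the two
related samples (2 × pairs), the common formulation; `rosenthal_n="n"`
switches to N = pairs, since the literature uses both. Effect magnitudes
are labelled < 0.2 trivial, 0.2–0.5 small, 0.5–0.8 moderate, 0.8–1.3
large, ≥ 1.3 very large (lower bound inclusive).

For very small designs an exact Friedman p-value is available by
enumerating all (k!)ⁿ equally likely within-subject orderings (n ≤ 6 at
k = 3); it is the enumerative counterpart of the χ² approximation and is
cross-checked in the tests against an independent brute-force oracle.
The χ² approximation is slightly conservative at n = 10 (empirical null
rejection ≈ 0.042 at α = 0.05) and accurate by n = 30; the calibration
tests therefore check the parametric route at n = 10 (the F test is
exact under normality) and the Friedman route at n = 30. Sphericity
corrections (Greenhouse–Geisser) are intentionally out of scope.

## Case-control contingency analysis

Category counts per exposure level form three 3×2 tables (green-vs-amber,
green-vs-red, amber-vs-red). For each:

* Pearson χ² **without** continuity correction, df = (r−1)(c−1). No
  Yates correction is applied anywhere: Cramér's V is defined from the
  uncorrected statistic, and the corrected statistic would understate
  the association at these sample sizes. Tables with any expected count
  below 5 are flagged, not rejected; a zero marginal makes the statistic
  undefined and raises.
* Cramér's V = √(χ² / (N·(min(r,c)−1))), labelled 0.1–0.3 small, 0.3–0.5
  medium, ≥ 0.5 large; values below 0.1 fall outside the named bands and
  are labelled "negligible" rather than rounded up to small.
* Pairwise decomposition into the three 2×2 exposure contrasts, with
  significance declared when the **raw** p falls below the
  Bonferroni-adjusted threshold 0.05/3 ≈ 0.0167 (threshold form rather
  than p-multiplication; both the raw p and the verdict are reported).
* Odds ratios by the cross-product (a·d)/(b·c) with Woolf (log-normal)
  95% CIs, exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)). When any cell is zero,
  the Haldane–Anscombe +0.5 correction is applied to **all** cells and
  flagged; a fully zero row or column leaves the OR undefined. The
  reference orientation (default: lowest exposure and second category in
  the denominator, i.e. odds of the healthier category relative to the
  untrained state) is recorded in the output rather than left implicit.

Report rendering rounds V to 2 decimals and percentages to 0, matching
conventional display precision; JSON outputs keep full precision.

## Synthetic-data generator

The simulator stands in for device exports, which are proprietary; it
generates data with the statistical structure the analysis assumes, not
a physiological model of airway or rescuer.

**Marginals.** Volumes, insufflation times, compression rates and depths
are drawn independently per event from lognormal distributions
parameterised by a median and IQR: μ = ln(median),
σ = ln(Q3/Q1)/(2·z₀.₇₅) with z₀.₇₅ ≈ 0.6745. This fit reproduces the
target median exactly and the quartile ratio Q3/Q1 exactly; the IQR
itself is matched distributionally. Lognormals were chosen because the
quantities are positive and right-skewed (untrained squeezes produce a
long fast-and-large tail). Volume–time independence is an explicit
simplification — no joint distribution is published for such data — and
a between-pair random effect (lognormal-scale shift, default sd 0) is
the only dependence knob.

**Built-in exposure profiles** encode the typical evolution across a
ventilation-focused training programme: T0 median volume 639 mL
(IQR 593–717) with insufflation time 0.48 s (0.41–0.59) — fast, deep
squeezes; T1 452 mL (317–519) at 0.91 s (0.73–1.21); T2 531 mL (488–618)
at 0.94 s (0.82–1.03) — near-guideline squeezes. Compression rates fall
from median 122 to 113 min⁻¹ and depths stay in the low 50s mm.
Effectiveness probability defaults to 1.0 (effective capture is the norm
on a well-sealed manikin); recoil-correctness probability is 0.5
untrained and 0.85 trained, a plausible training effect that gives the
compression-quality score room to improve.

**Timeline.** The clock starts at 0: five initial breaths (each
occupying its insufflation time plus a 1.5 s inter-breath gap), then
cycles of 30 compressions (each occupying one beat, 60/rate s), a 2.0 s
hands-off transition pause, and 2 breaths. An event is emitted only if
it finishes within the 120 s duration; generation stops at the first
event that does not fit. The gap and pause constants follow from the
timeline algebra: with the T0 profile a cycle takes ≈ 20.7 s, so five
full cycles fit after the 10 s initial phase (modal 15 ventilations),
while the slower trained profiles fit four (modal 13) — reproducing the
characteristic drop in ventilation count as squeezes lengthen. These are
tuning constants of the generator, documented here, not measurements.

**Reproducibility.** One study seed fans out to per-session substreams
via `SeedSequence([seed, crc32(pair_id|test_id)])`, so any session can
be regenerated independently of generation order and the event CSV is
byte-identical across reruns.

**What the synthetic tests show — and don't.** Passing tests demonstrate
that the pipeline's arithmetic, rules and statistics behave as specified
on data with the assumed structure (independent lognormal marginals,
exact protocol compliance, no fatigue or drift within a session, no
volume–time correlation). They do not validate the lognormal assumption
against real manikin exports, nor the independence assumptions; analyses
of real data should treat those as open questions. Published
summary-level inputs (category counts) are analysed directly and do not
depend on the generator.

## Problem sizes and tolerances

The test and acceptance runs use: exact-enumeration oracles at n ≤ 5
subjects (6ⁿ orderings / 2ⁿ sign flips); 2000 null replicates for type-I
calibration with a 3σ binomial band (± 0.0146 around 0.05); 10⁴ events
per exposure profile for median recovery at 2% relative tolerance; and
200 seeded study replicates for the dose-response ordering check
(green share T0 < T2, required in ≥ 95%). Cramér's V reproduction from
summary counts is checked at 2 decimal places, the precision at which
such effect sizes are conventionally reported.

## Known limitations

* Volumes are recorded by observer checklist in the motivating setting;
  the event model treats them as exact mL values and models no
  measurement error.
* The classification thresholds are convention-based tolerances, not
  validated clinical cut-points; conclusions change with the bands, which
  is why they are configuration.
* Odds ratios from published 2×2 counts are reported by the standard
  cross-product formula only; no small-sample exact (conditional) OR is
  implemented.
* The simulator models neither rescuer fatigue, role swaps within a
  pair, nor any within-session learning; each event is exchangeable
  within its session.
* With the default zero between-pair variance, session-level medians are
  tighter across pairs than real cohorts would show; raise
  `StudyDesign.between_pair_sd` to emulate realistic between-pair spread.
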