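# cprvent

Quality analysis of **bag-mask ventilations** delivered during simulated
cardiopulmonary resuscitation (CPR), for resuscitation-training researchers
working with instrumented manikins.

Lifeguards and other first responders who treat drowning victims must
deliver high-quality rescue ventilations, and current guidance emphasises a
slow bag squeeze (insufflation time ≈ 1 s) at least as much as the delivered
volume. Training manikins log every ventilation (volume in mL, insufflation
time in ms) and every chest compression (depth, rate, correctness flags),
but most analyses look at volume only. `cprvent` implements a pipeline that
evaluates volume and insufflation time **jointly**:

* **Three-tier classification.** Each effective ventilation with volume
  $V$ (mL) and insufflation time $t$ (s) is coloured

  $$
  \text{green} \iff V \in [500, 600] \wedge t \in [0.85, 1.15], \qquad
  \text{red} \iff V < 400 \lor V > 700 \lor t < 0.55 \lor t > 1.45,
  $$

  and amber otherwise (inside the wide tolerance box, outside the green
  one). The bands are configuration data (`thresholds.json`), not code.
* **Composite quality scores.**
  $CC_q = (\%\text{depth ok} + \%\text{recoil ok} + \%\text{rate ok})/3$,
  $V_q = \%\text{green ventilations}$, and
  $CPR_q = (CC_q + V_q)/2$.
* **Repeated-measures comparisons** of session variables across three
  exposure levels (T0 = untrained, T1 = after one training session,
  T2 = after two), on the same rescuer pairs: Shapiro–Wilk-routed
  RM-ANOVA/paired *t* (Cohen's *d*) or Friedman/Wilcoxon signed-rank
  (Rosenthal's $r = |z|/\sqrt{N}$), all with Bonferroni correction.
* **Case-control contingency analysis** of category counts against
  exposure: Pearson $\chi^2$ (no continuity correction), Cramér's
  $V = \sqrt{\chi^2 / (N(\min(r,c)-1))}$ with magnitude labels, pairwise
  2×2 decomposition at the Bonferroni-adjusted threshold $p < 0.0167$,
  and cross-product odds ratios with Woolf 95% CIs (Haldane–Anscombe
  correction for zero cells).
* **A synthetic session simulator** that generates two-minute 30:2
  sessions (five initial rescue breaths, then cycles of 30 compressions +
  2 ventilations) with event values drawn from lognormal distributions
  fitted to median/IQR summaries — so the whole pipeline is testable
  without any proprietary device export.

## Worked example

Analyse the built-in study sample — 381 effective ventilations from 10
lifeguard students in 5 pairs, classified at three exposure levels:

```python
from cprvent.datasets import lifeguard_ventilation_counts
from cprvent.casecontrol import case_control_all

for pair, res in case_control_all(lifeguard_ventilation_counts()).items():
    print(f"{pair[0]} vs {pair[1]}: chi2={res.chi2.statistic:.2f}, "
          f"p={res.chi2.p:.3g}, V={res.cramers_v:.2f} ({res.v_label})")
    for pw in res.pairwise:
        star = "*" if pw.significant else ""
        print(f"  {pw.exposures[0]} vs {pw.exposures[1]}: "
              f"p={pw.chi2.p:.3g}{star}, V={pw.cramers_v:.2f}")
```

prints

```
green vs amber: chi2=10.46, p=0.00534, V=0.24 (Small)
  T0 vs T1: p=0.12, V=0.17
  T0 vs T2: p=0.00946*, V=0.24
  T1 vs T2: p=0.0271, V=0.18
green vs red: chi2=69.74, p=7.17e-16, V=0.55 (Large)
  T0 vs T1: p=0.000173*, V=0.28
  T0 vs T2: p=3.09e-16*, V=0.61
  T1 vs T2: p=4.98e-05*, V=0.39
amber vs red: chi2=87.05, p=1.25e-19, V=0.50 (Medium)
  T0 vs T1: p=3.91e-10*, V=0.40
  T0 vs T2: p=4.29e-20*, V=0.58
  T1 vs T2: p=0.00242*, V=0.21
```

Read: before training no ventilation was green; after two sessions the
association between exposure and achieving a green rather than red
ventilation is large ($V = 0.61$ for T0 vs T2), and every pairwise
green-vs-red and amber-vs-red contrast is significant at the adjusted
threshold (`*` marks $p < 0.0167$).

The same pipeline runs from the shell on simulated or recorded event
files:

```bash
cprvent analyze --seed 7 --out results/run   # simulate + full analysis
cprvent simulate --seed 7 --out results/sim  # events.csv + truth.json only
cprvent casecontrol --counts counts.csv --out results/cc
```

`analyze` writes an audit-ready bundle: `events.csv`, per-event
`classification.csv`, `summary.csv` ("median (Q1–Q3)" per test),
`comparisons.json`, `case_control.json`, a rendered `report.md` and a
`metadata.json` sidecar with the seed and all switches. Re-running with
the same seed reproduces every file byte-for-byte.

## Layout

| Module | Responsibility |
|---|---|
| `cprvent.events` | event data model, CSV dialect, contingency-table I/O |
| `cprvent.classify` | green/amber/red rules, configurable thresholds |
| `cprvent.metrics` | per-session metrics, composite scores, group summaries |
| `cprvent.repeated` | normality-routed repeated-measures machinery |
| `cprvent.casecontrol` | χ², Cramér's V, pairwise decomposition, odds ratios |
| `cprvent.simulate` | lognormal-from-median/IQR fits, 30:2 timeline simulator |
| `cprvent.cli` / `cprvent.report` | command-line pipeline and markdown reports |

See `docs/methods.md` for the statistical and modelling choices in detail.
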