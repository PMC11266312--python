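# pulsesv

Stroke-volume (SV) estimation from arterial pressure: a registry of 22
published prediction formulae, the statistical machinery to validate them
against beat-by-beat reference measurements, and a synthetic hemodynamic
data generator for end-to-end testing.

## The problem

Workers in hot environments accumulate cardiovascular strain that is best
indexed by cardiac output (CO = SV × HR) or the cardiac index (CO/BSA), but
measuring SV requires clinical equipment. A century of physiology offers a
way around this: regression formulae that predict SV from quantities a cuff
can provide — pulse pressure (PP = SAP − DAP), diastolic pressure, age —
or from simple anthropometry (weight, height, body surface area). The bulk
of these are Starr-family equations of the form

```
SV = a + b·PP − c·DAP − d·age        (mL; pressures in mmHg, age in years)
```

plus power-law anthropometric fits (de Simone), linear anthropometric fits
(Skrabal), a CO regression converted through heart rate (Lu), and a
pressure → aortic-volume-factor lookup (Remington). This package collects
all 22 formulae with their printed coefficients and applicability limits
(the de Simone equations only apply below BMI 25.25 kg/m²) and implements
the model-selection pipeline used to decide which formula to trust for
upright workers in the heat:

1. **Cleaning** — measured SV restricted to the plausible 61–145 mL window,
   then arterial pressures filtered at ±2 SD within subject × posture ×
   condition groups (single pass, sample SD).
2. **Four metrics per formula and stratum** — Pearson r between measured
   and predicted SV; Hedges g (pooled-SD standardized mean difference, with
   small-sample correction); the sum of squared residuals
   SSR = Σ(observed − predicted)²; and the mean bias. Bland–Altman limits
   of agreement (bias ± 1.96·SD of the differences) for the winner.
3. **Rank aggregation** — each formula receives a competition rank per
   metric (|r| descending; |g|, SSR, |bias| ascending; ties share the best
   rank) and the total score is the sum of the four ranks; the lowest total
   wins. Rankings are produced for the nine posture × ambient-temperature
   cells (supine/60° head-up tilt/both × thermoneutral/hot/both).

A matched-pairs power module reproduces the cohort-design arithmetic
(pooled effect size dz = |m₁−m₂|/√((s₁²+s₂²)/2); exact noncentral-t power;
minimum n), and a beat-level synthetic generator emulates the study design
(7 young males, 9 days, daily supine + 60° tilt tests, 25.4 °C vs 35.4 °C
work shifts) with a controllable pressure↔SV coupling, so the entire
pipeline is testable without access to raw physiological recordings.

## Worked example

```python
from pulsesv import (
    load_registry, pooled_effect_size, min_sample_size, paired_t_power,
    simulate_study, ProtocolConfig, stratified_report,
)
from pulsesv.io import attach_subjects
from pulsesv.preprocessing import clean

dz = pooled_effect_size(123, 28, 87, 14)
print(f"pooled effect size dz = {dz:.2f}")
print(f"power at n=7 pairs    = {paired_t_power(7, dz):.3f}")
print(f"minimum n (two-tailed) = {min_sample_size(dz)}")

registry = load_registry()
participants, obs, truth = simulate_study(
    seed=1, protocol=ProtocolConfig(beats_per_phase=200)
)
cleaned, report = clean(attach_subjects(obs, participants))
print(f"cleaned {report.n_retained}/{report.n_input} beats "
      f"(SV window removed {report.n_removed_sv_range}, "
      f"BP outliers {report.n_removed_bp_outlier})")
tables = stratified_report(cleaned, registry)
best = tables["both|both"].best
print(f"best formula (all data): {best['formula_id']} "
      f"(total score {best['total_score']}, r={best['r']:.2f}, "
      f"SSR={best['ssr']:.0f}, bias={best['bias']:.2f} mL, n={best['n']})")
```

prints

```
pooled effect size dz = 1.63
power at n=7 pairs    = 0.945
minimum n (two-tailed) = 8
cleaned 20403/25200 beats (SV window removed 3224, BP outliers 1573)
best formula (all data): starr54_eq72 (total score 4, r=0.65, SSR=1732265, bias=0.18 mL, n=20403)
```

The two summarised SV measurement methods (123 ± 28 vs 87 ± 14 mL) pool to
a standardized difference of 1.63; at that effect size a two-tailed paired
t-test reaches 94.5% power with 7 pairs and crosses 95% at 8. The synthetic
study generates pressures from the Starr 1954 equation 72 with noise
calibrated so the combined-data validation correlation is ≈0.65; the
pipeline then correctly identifies that equation as the best-ranked
predictor, with a near-zero bias, on 20,403 retained beats.

The same pipeline is available from a shell:

```bash
pulsesv simulate --seed 1 --out-dir sim
pulsesv validate --observations sim/observations.csv --out sim/cleaned.csv
pulsesv report --observations sim/observations.csv \
               --participants sim/participants.csv --out-dir sim/report
pulsesv power --mean1 123 --sd1 28 --mean2 87 --sd2 14
```

`report` writes one ranking CSV/JSON per stratum, a best-formula summary, a
Bland–Altman plot for the overall winner, and a log with the fully resolved
configuration.

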