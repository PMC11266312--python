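# Methods

This note records the statistical model behind `pulsesv`, the defaults and
their rationale, the numerical choices, and what the synthetic-data tests
do and do not demonstrate.

## 1. The formula registry

All 22 formulae are shipped in `src/pulsesv/data/formulae.yaml`, each with
the equation string exactly as printed in its source next to the structured
interpretation this package evaluates. Interpretation decisions that were
genuinely open:

* **Composite entries (Grollman, Warren, Liljestrand, Cathcart).** The
  printed strings concatenate a scale factor with the intercept of a Starr
  base equation (e.g. `0.4593+0.54PP−0.47DP−0.61age+43` reads as
  0.45·(93 + 0.54PP − 0.47DP − 0.61age) + 43). These four are stored as
  scale/offset transforms of the corresponding base equation; the raw
  string is retained alongside.
* **Starr equations 62/63/64.** The trailing `+k·PP` fragments are read as
  part of the diastolic bracket, −0.57·(DAP + k·PP). Under this reading
  equation 62 is algebraically identical to 59b, and 64 differs from 59b
  by the constant −0.01 — consistent with their near-identical published
  validation metrics. These identities are enforced by tests.
* **Jackson.** 0.5·SAP − 1.09·DAP ≡ 0.5·PP − 0.59·DAP, so Jackson's
  nomogram equation is an exact duplicate of Starr equation 71 (also
  test-enforced).
* **Height units.** de Simone's height^2.04 takes metres (≈80 mL at
  1.80 m); Skrabal's 1.19·height − 112 takes centimetres (≈102 mL at
  180 cm). The unit is stored per formula.
* **Lu.** The printed string is read as a cardiac-output regression in
  L/min (6.963 + 0.446 − 0.037·age + 0.013·weight) converted to SV as
  1000·CO/HR. The multiplicand of the orphaned 0.446 term is not
  recoverable from the printed source; it is kept as an additive constant.
* **Remington.** Implemented as SV = (VF(SAP) − VF(DAP)) × BSA with VF a
  user-supplied strictly increasing pressure → volume-factor table,
  linearly interpolated. No published table values are shipped, so the
  entry is skipped (with a note) unless a table is provided, and it is
  excluded from default ranking runs.
* **Applicability.** The three de Simone formulae were fitted in a
  normal-weight population and are marked inapplicable above
  BMI 25.25 kg/m²; predictions for such subjects are skipped with a
  reason, never silently computed.

Body surface area defaults to DuBois–DuBois
(0.007184·H_cm^0.725·W^0.425), with Mosteller (√(H_cm·W/3600)) selectable;
both round to 2.0 m² at the cohort-mean anthropometry.

## 2. Cleaning

Two filters run in a fixed order:

1. **SV plausibility window**: measured SV outside [61, 145] mL (inclusive
   bounds) is attributed to movement artifact and removed.
2. **Pressure outliers**: a record is removed when its SAP *or* DAP
   deviates from its group mean by more than k = 2 sample SDs (ddof = 1).
   Group statistics are computed once, on the data as it stands — no
   re-iteration after removals. The default grouping is
   subject × posture × condition; pooling across postures would purge
   genuine orthostatic pressure shifts as outliers. `global` and
   `per_subject` groupings are selectable. Groups with fewer than three
   records pass through untouched and are counted.

Every input record lands in exactly one of retained / removed-by-SV /
removed-by-BP, and the cleaning report carries all three counts.

## 3. Validation metrics and ranking

For each formula and stratum, on the aligned (measured, predicted) pairs:

* **r** — Pearson correlation (undefined for constant series; such
  formulae rank last on r and are flagged);
* **g** — |mean(x) − mean(y)| / s_pooled with
  s_pooled = √((s_x² + s_y²)/2), times the small-sample correction
  J = 1 − 3/(4(2n−2) − 1). The pooled-SD construction mirrors the
  effect-size arithmetic of the power module; an uncorrected Cohen d is
  selectable. Reported positive.
* **SSR** — Σ(observed − predicted)², in mL²;
* **bias** — mean(observed − predicted), signed; ranking uses |bias|.

Ranks are *competition* ranks (ties share the minimum rank): with several
algebraically duplicate formulae in the registry, exact ties are the norm,
and competition ranking lets a formula tied for the best correlation still
rank 1. The total score is rank_r + rank_g + rank_ssr + rank_bias; rows are
ordered by ascending total score.

SSR is a sum, so it is comparable only between formulae evaluated on the
identical record set. Formulae with applicability exclusions are ranked on
their reduced n (reported per row), but `min_ssr_formula` — used by the
parameter-recovery analyses — restricts the SSR comparison to formulae at
the full stratum n by default.

Bland–Altman limits of agreement use bias ± 1.96·SD of the paired
differences (sample SD). An optional helper expresses the limits relative
to a reference mean SV; this is an interpretation provided for descriptive
use and takes no part in ranking.

## 4. Power analysis

Matched-pairs design, exact noncentral-t computation: at n pairs and
standardized effect dz, power = P(T′ > t_crit) (+ P(T′ < −t_crit) for two
tails) with T′ noncentral t at df = n − 1 and noncentrality dz·√n. The
lower-tail term is negligible at moderate effects but is included for
exactness. `min_sample_size` returns the smallest integer n whose power
reaches the target.

At the package's worked effect size dz = 1.63 (pooling 123 ± 28 against
87 ± 14 mL), the two-tailed boundary sits just past seven pairs: power(7)
= 0.9454, power(8) = 0.9749, so the integer two-tailed requirement at 95%
power is 8 (continuous solution 7.12; one-tailed requirement 6). Tails are
configurable and default to two; the implementation agrees with a direct
quadrature of the noncentral-t density and with statsmodels' `TTestPower`
to ~1e-10.

## 5. The synthetic study generator

The generator emulates a heat-strain tilt-test protocol: 7 subjects
(anthropometry drawn from normals: age 21.5 ± 1.2 y resample-truncated to
19–23; height 1.80 ± 0.056 m; weight 81.5 ± 14.5 kg), 9 days — work-shift
ambience thermoneutral (25.4 °C) on days 1–3 and 7–9, hot (35.4 °C) on days
4–6 — and two daily 10-min postural phases (supine, then 60° head-up
tilt) of beat-by-beat records (default 600 beats/phase).

Per beat, with stratum = posture × condition:

* measured SV ~ N(μ_s, σ_s) with the four stratum (μ_s, σ_s) defaulting to
  study-shaped values (supine 83.45 ± 12.56 / 86.24 ± 16.87 mL
  thermoneutral/hot; tilt 69.77 ± 6.28 / 69.51 ± 6.76 mL). A per-subject
  random effect accounts for a *fraction* of each stratum SD (default 0.5,
  variance-split), so configured stratum totals are preserved exactly —
  an absolute between-subject SD cannot be reconciled with tilt-stratum
  SDs of ~6.5 mL.
* DAP ~ N(70, 8) supine, N(75, 8) tilted — conventional placeholder
  levels; no cohort pressure summaries exist to emulate, and the pipeline's
  behaviour depends on the coupling structure, not these levels.
* HR ~ N(65, 8) baseline, +15 bpm when tilted, plus thermal cardiac
  reactivity on hot days: 33 bpm per °C of core-temperature elevation
  (default offset 0.3 °C).
* PP is obtained by inverting the generating formula (default Starr
  eq. 72, flattened to SV = A + B·PP + C·DAP + D·age) at a *coupled*
  SV value, then perturbed: PP = (SV_c − A − C·DAP − D·age)/B + ε,
  ε ~ N(0, σ_pp), where SV_c = anchor + κ·(SV − anchor) and the anchor is
  the protocol-weighted mean SV. SAP = DAP + PP.

**Why the coupling slope κ.** With κ = 1 (exact inversion) the formula's
predictions carry *more* spread than the measured SV, and once the noise is
large enough to bring the validation r down to realistic levels (~0.65),
any down-scaled formula in the registry beats the generating formula on
SSR — mean-square-error shrinkage, not a pipeline defect. Real beat data
show the opposite geometry (predictions *less* dispersed than
measurements), which requires κ < 1. Writing the prediction as
κ·(measured deviation) + independent noise U, the generating formula is its
own minimum-MSE predictor — the premise of any parameter-recovery test —
exactly when U = κ(1 − κ)·Var(SV), which forces r² = κ. The default
κ = 0.42 therefore corresponds to the target validation correlation
r ≈ 0.65; at κ = 1 and σ_pp = 0 the generator degenerates to exact
inversion (r = 1, SSR = 0), which the tests also exercise.

**Noise calibration.** `calibrate_noise_for_target_r` bisects σ_pp until
the simulated combined-data r (measured vs generating-formula prediction,
after default cleaning) matches the target within ±0.008. Each candidate
σ_pp is evaluated on the same small set of simulation seeds (common random
numbers, averaged over 8 replicates), which keeps the simulated r monotone
in σ_pp and damps cohort-to-cohort luck. Because subject-level effects
never average out under a fixed cohort, "large n" simulations grow the
cohort with the requested size (~216 beats per subject; 24 subjects at
n = 5000) — the only regime in which the calibration target is
well-defined. The default σ_pp = 12.0 mmHg is the calibrated output for
r = 0.65 at the default generating formula.

**Artifact injection** corrupts a ledgered subset of records: SV values
moved strictly outside the plausibility window (targets rows currently
inside it, so the window filter removes exactly the ledgered rows), and
SAP shifted +8 within-group SDs (the ±2 SD rule removes these along with
whatever genuine tail beats it would have removed anyway — exact
ledger-to-removal matching is asserted for the deterministic SV window
only).

**What the generator does not emulate**: arterial waveforms, beat-to-beat
autocorrelation, circadian or day-order drift, heat-induced hypotension,
measurement drift between calibrations, and non-Gaussian SV tails. Passing
recovery tests therefore demonstrate that the pipeline's statistics,
filters and ranking are correct and self-consistent — not that any formula
is valid on real physiological data.

## 6. Numerical and engineering choices

* All randomness flows through a single `numpy.random.default_rng` (PCG64)
  per entry point, seeded explicitly; identical seeds give identical output
  across platforms. Derived seeds stay below 2³¹.
* Truncation is by resampling, not clipping, preserving distribution shape
  near bounds; invariant-violating beats (non-positive PP after noise,
  out-of-range HR) are redrawn jointly.
* Metric computations are vectorised but tested against pure-Python loop
  oracles to 1e-9 on 10⁴ pairs.
* Empty strata are omitted from reports with a warning rather than raising;
  zero applicable pairs propagate as explicit empty arrays.
* Undefined metrics (constant series, zero pooled SD) become NaN/inf,
  rank last, and flag the row — never silent exceptions.
* Problem sizes in the test-suite and acceptance script (200 beats/phase,
  50 recovery seeds, 20 calibration seeds at n = 5000) were chosen to give
  stable rates at interactive runtimes; the full default protocol
  (600 beats/phase, 75,600 beats) runs in well under a second.

## 7. Known limitations

* The Lu interpretation (orphaned 0.446 constant) and the Remington
  BSA-multiplication reading are best-effort reconstructions of garbled
  printed sources; both are isolated behind configuration.
* The registry takes coefficients as printed; no re-derivation from the
  original regression data is attempted.
* Stratified rankings on only 7 subjects are sensitive to cohort-level
  offsets of a few mL; algebraic near-duplicates (eq. 71/Jackson, offset
  ≈1.5 mL from eq. 72) can legitimately swap places with the generating
  formula in individual runs, which is why recovery is asserted for the
  equivalence class.
* The ±2 SD pressure rule removes ~4–5% of perfectly clean Gaussian beats
  by construction; it is applied because it is part of the validated
  procedure, not because it is optimal.
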