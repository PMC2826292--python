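# Methods

## The advisory algorithm

The advisor is a deterministic function of one decision point's inputs
(last potassium, last creatinine, age, weight, sex, 6-hour diuresis, renal
replacement therapy, infusion history) and a configuration object. All
constants live in `AdvisorConfig` with clinically motivated defaults.

**Renal assessment.** Creatinine clearance is estimated with
Cockcroft–Gault, `(140 − age)·weight / (72·creatinine[mg/dL])`, times 0.85
for women; creatinine enters in μmol/L and is converted at 88.4 μmol/L per
mg/dL. The nurse-entered 6-hour diuresis is divided by 6 to mL/h. The
potassium clearance fraction is `min(1, GFR/100, diuresis/60)`, plus 0.5 on
hemofiltration; combining the two linear components with a minimum is the
conservative choice (the most impaired signal wins). Renal impairment —
GFR < 30 mL/min or diuresis < 30 mL/h, strict inequalities — lowers both
target bounds by 0.2 mmol/L and widens the notification window. Missing
creatinine falls back to a diuresis-only assessment and vice versa; with no
renal data at all the advisor assumes normal clearance and logs a warning.

**Dosing.** The target range (3.8–4.5 mmol/L) is inclusive at both ends;
classification uses strict inequalities. Hypokalemia is dosed from a
sliding scale, linear through the anchors (2.0 mmol/L, 20 mmol/h) and
(3.5 mmol/L, 6 mmol/h), clamped at 20 below K = 2.0 and extended with the
same slope between 3.5 and the target lower bound — with only two anchors
printed, linearity is the minimal assumption. Normokalemia is dosed by
exponential smoothing of the time-weighted mean infusion rate over the last
8 h (or since admission, whichever is shorter; gaps count as zero):
`(1 − λ)·mean + λ·4f` with λ = 0.25. This satisfies both requirements on
the within-range rule — it advises (approximately) the recent mean, and
iterating it converges geometrically to the clearance-matched rate 4·f,
which is an exact fixed point. The smoothed value is kept exact inside the
operation; rounding to the 0.5 mmol/h pump resolution (a 1 mmol/mL solution,
so rates map 1:1 to mL/h) is applied once when the advice is emitted.
Rounding inside the iteration instead would make every pump-grid point in
[3, 5] mmol/h a fixed point of the within-range map and destroy the printed
limits, which is why the emission point carries the rounding. Hyperkalemia
always advises rate 0; the advisor deliberately gives no further
hyperkalemia treatment advice. The within-range advice is not capped at the
12 mmol/h alert threshold — the alert, not a clamp, is the safety mechanism.

**Scheduling.** The next-measurement table is 1 h after a marked-abnormal
alert, 2 h out of range, 4 h in range; it is a design choice of this
package, calibrated so a stable patient is sampled about six times a day,
and fully overridable.

## The virtual patient

Plasma potassium `C` in a single compartment of volume `V` follows

    dC/dt = (R + B + H·(C_set − C) − CL0·f·C) / V,

with pump infusion `R`, endogenous input `B`, transcellular buffering `H`
toward a set point `C_set`, and renal elimination `CL0·f·C`. The closed-form
steady state is `C* = (R + B + H·C_set)/(H + CL0·f)`. Defaults
(V = 15 L, CL0 = 16/7 L/h, H = 1 L/h, B = 7.3 mmol/h, C_set = 4.2 mmol/L)
are solved so that a normal-clearance patient sits at exactly 4.2 mmol/L on
a 2.3 mmol/h infusion — a typical clinical mean rate — and drifts to
3.5 mmol/L untreated; renal failure (small f) produces hyperkalemic
accumulation. Note one deliberate tension: the advisor's clearance-matched
maintenance rate 4·f slightly overshoots what this virtual physiology needs
(C* at R = 4, f = 1 is ≈ 4.72 mmol/L), so a closed-loop normal patient
cycles near the top of the target range rather than parking exactly at 4f;
the advisory convergence itself is exact and is tested as such.

Integration is Euler–Maruyama with dt = 0.05 h and additive process noise
(default 0.15 mmol/L·h^−1/2); the state is floored at 0.5 mmol/L.
Measurements add Gaussian analyzer noise (default SD 0.05 mmol/L) and are
reported at the 0.1 mmol/L point-of-care resolution. Each patient consumes
a named RNG stream spawned from the master seed, so runs are reproducible
patient-by-patient and under any execution order.

`make_cohort` samples heterogeneous patients: admission potassium
Normal(4.0, 0.4) truncated to [2.0, 6.5] mmol/L; ~11% renally impaired
(low GFR and oliguria, consistent with observed acute-kidney-injury rates
near 10–12%), of whom ~45% are on renal replacement therapy (~5% of the
cohort); ages, weights and sex mix typical of an adult surgical ICU.
Covariates (creatinine, diuresis) are generated to be exactly consistent
with the sampled clearance fraction through the advisor's own renal model.
Impaired patients receive a reduced endogenous potassium input (emulating
dietary restriction); without it an f = 0.1 patient's untreated steady
state would be ≈ 9.4 mmol/L, which no real cohort exhibits. Cohort
composition depends only on (n, seed), so both arms of a comparison run on
the identical cohort.

**Physician emulator.** The pre-protocol baseline revises the prescription
only at the daily 08:00 ward-clock review (each patient gets a random
admission clock hour, so the review phase varies across the cohort) or,
after a one-hour consult delay, when a measurement falls below 3.0 or above
5.5 mmol/L. Its dose choice is a coarse sliding scale rounded to 2 mmol/h
for hypokalemia, 2 mmol/h maintenance in range, zero above 5.0 mmol/L;
measurements run every 4 h. This emulator is a plausibility baseline for
daily-review physician practice, not a validated reconstruction of any
unit's behaviour — quantitative gaps between its statistics and any
published cohort are expected; only the direction of the computer-versus-
physician contrast is meaningful.

What the simulator does **not** model: acid-base and insulin effects on
transcellular shifts, administration-route kinetics, magnesium, evolving
renal function, discharge/censoring, or outcome. Passing closed-loop tests
therefore demonstrates the control logic and its direction of effect, not
clinical performance on real patients.

## Evaluation

Each patient's potassium curve is the linear interpolant of their
measurements; prevalence of hypo-/hyperkalemia (< 3.5 / > 5.0 mmol/L;
marked hyperkalemia > 6.0) is the time in range divided by the stay, with
segment threshold crossings solved analytically (an exact computation,
cross-checked in tests against one-second resampling of the curve). When
explicit admission/discharge times are absent, the span from first to last
measurement stands in for the stay; single-measurement patients are
excluded from prevalence and counted. Incidence is the pooled fraction of
individual measurements out of range, excluding the first 8 h after
admission; thresholds are strict, so values exactly at 3.5 or 5.0 are in
range. Pooled counting (rather than averaging per-patient fractions) is
used because it matches the count arithmetic that odds ratios on
measurement totals imply.

Odds ratios are `[p1/(1−p1)]/[p2/(1−p2)]` — the point estimate depends only
on the proportions — with Woolf (log-normal) 95% intervals whose standard
error uses cell counts reconstructed as round(p·n); a Haldane +0.5
correction (with a warning) handles empty cells. The interval is centered
on the point estimate so it always brackets it. Chi-square on the pooled
out-of-range counts is computed without Yates correction by default (counts
are large; configurable), Mann-Whitney U compares per-patient prevalence
distributions, and kurtosis of those distributions flags whether medians
with IQRs, rather than means with SDs, are the appropriate presentation.
Percentile bands (5/25/50/75/95 by default) evaluate every curve covering a
grid time and use the linear-interpolation percentile definition; band
monotonicity in the percentile order is guaranteed.

## Problem sizes and numerical choices

The closed-loop test cohorts are 100 patients × 5 days per arm (and smaller
in unit smoke tests), chosen as the smallest scale at which the arm
contrast is unambiguous across seeds while a two-arm comparison still runs
in about a second. Zero-noise steady-state checks run 10 time constants
(τ = V/(H + CL0·f) ≈ 4.6 h) and require agreement with the closed-form
fixed point within 1e-3 mmol/L; dt-halving must perturb a 48 h zero-noise
trajectory by less than 1e-3 mmol/L. Hour-valued interval arithmetic inside
the simulator uses integer step indices (dt divides all scheduling
intervals), avoiding floating-point drift in event times. CSV writers use
fixed decimal formatting and LF endings so identical inputs produce
byte-identical files.

## Known limitations

* The advisor encodes one unit's protocol constants; deployment elsewhere
  requires local review of targets, scales and alert thresholds. It is a
  research implementation, not a medical device.
* The hypokalemia sliding-scale dose is not scaled by the clearance
  fraction; safety in renal failure relies on the lowered target, the
  widened alert window and the high-rate alert.
* The physician emulator and the kinetic model are intentionally simple;
  absolute prevalence/incidence levels from simulation should not be read
  as predictions for any real cohort.
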