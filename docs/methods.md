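# Methods

## The bench model

A stirred reservoir (1 L heparinized bovine blood plus ~0.19 L saline
prime; default mixed volume 1.19 L) is connected to a CRRT circuit run at a
fixed blood flow of 200 mL/min (12 L/h). Apixaban is spiked to the
healthy-subject single-dose peak (0.104 mg/L) and the reservoir is sampled
pre-filter at 0, 10, 20, 30, 45 and 60 min, with paired post-filter and
effluent samples at 10 and 30 min. Twelve conditions (mode × filter × flow
× dilution split) are run in duplicate: CVVH at 2 L/h with 100/0, 50/50 and
0/100 pre/post replacement-fluid splits and at 4 L/h with 50/50, and CVVHD
at 2 and 4 L/h, each with both the HF1400 (PAES) and M150 (AN69) filter
sets — 24 open-circuit experiments. Separate closed-circuit runs (effluent
rerouted to the reservoir, 0–180 min) isolate filter adsorption, and
ultrafiltration of contrived plasma samples measures protein binding.

Units: concentrations ng/mL (≡ µg/L), doses mg, flows and clearances L/h.
Time is minutes at the data layer and hours in all PK math; the conversion
happens once, on entry to the NCA/clearance layer.

## Noncompartmental analysis

The one-hour bolus design makes the profile mono-exponential by
construction, so λz defaults to a log-linear least-squares fit over **all
positive points after C_max** (an optional best-adjusted-r² terminal-window
mode exists for irregular profiles; with six points and one phase there is
nothing else to fit). Zero/BLQ values are excluded from the log fit and
treated as linear-interval endpoints in the AUC. AUC₀₋last uses the
linear-up/log-down trapezoid: linear on rising/flat intervals or any
interval touching zero, logarithmic ((C₁−C₂)Δt/ln(C₁/C₂)) on strictly
positive descents, which integrates exponential decay exactly on any grid.
Then AUC₀₋∞ = AUC₀₋last + C_last/λz, CL = Dose/AUC₀₋∞, Vz = CL/λz, and
AUC₀₋₂₄ = 24·AUC₀₋last (proportional scaling of the 1-h window in a linear
system). The reported distribution volume is interpreted as Vz; the
condition-level prints are consistent with CL/λz within rounding.

## Transmembrane clearance

Two estimators of the same elimination:

* **By AUC (primary)** — CL_TM = Dose/AUC₀₋∞. The circuit is the only
  elimination route, so total clearance ≡ CL_TM.
* **By SC/SA (secondary)** — the per-experiment SC (CVVH) or SA (CVVHD) is
  the mean of the two paired sampling times, multiplied by the effluent
  flow. For CVVH with pre-filter replacement fluid the textbook correction
  CL = SC·Q_uf·Q_b/(Q_b + Q_rep) is available behind
  `dilution_corrected=True`, but the default is **off**: the study's
  reported clearances equal SC × flow for every condition, including 100%
  pre-dilution, so the uncorrected convention is what reproduces them. The
  discrepancy between the stated correction formula and the reported table
  is surfaced here rather than resolved silently.

`sc_variants` enumerates the conventions in circulation (undiluted vs
diluted pre-filter reference, with/without the (Q_b+Q_rep)/Q_b correction,
pre/post mean), since published SC values differ across groups precisely in
these choices.

**Adsorption** is reported as the unrecovered mass fraction
100·(1 − C(t)·V/Dose) per time point, with peak and final summaries.  The
source description of this assay prints an equation whose dose sits in the
numerator, contradicting both its own prose definition (amount added minus
amount recovered) and the percent scale; the prose definition is
implemented. Negative values (noise pushing recovery above the dose) are
preserved in profiles and clipped to zero only in summaries.

**Protein binding** is 100·(total − unbound)/total per paired sample, with
the mean and intra-assay CV reported.

## Inference

Pooled-variance t-tests; factorial ANOVA fitted by OLS with Type II sums of
squares (identical to I/III on the balanced layout, robust to the one
unbalanced comparison — dilution split only varies at 2 L/h). Estimated
marginal means average model predictions over an equal-weight grid of the
off-factor levels, with t intervals on the residual df. Tukey HSD uses the
studentized-range distribution (scipy's numerical implementation) with the
fitted model's residual mean square as error term — the documented choice
for the mixed 2 L/h-only dilution comparisons, where the "right" error term
is otherwise ambiguous. Backward-stepwise regression removes the candidate
with the largest p-value above α = 0.05 (ties: the last-listed candidate,
for deterministic builds) until all retained p ≤ α, and reports 95% CIs,
adjusted R² = 1 − (1−R²)(n−1)/(n−p−1), VIF and tolerance. Covariates enter
as interpretable numeric codes (filter HF1400 = 1 / M150 = 2, mode
CVVH = 0 / CVVHD = 1, flow L/h, pre-filter dilution fraction with CVVHD
at 0 since it uses no replacement fluid).

## Dosing

CL_TM is predicted from the published regression
CL_TM = 1.469 − 0.821·filter + 0.612·flow (or a freshly fitted model),
CL_T = CL_TM + CL_NR with CL_NR = 2.52 L/h (residual renal function
assumed zero but exposed as a policy field), and
TDD = 2.1038 mg·h/L × CL_T. The exposure target is printed in its source
as "2103.8 mg·h/L"; dimensional analysis of the dosing arithmetic shows
the intended unit is ng·h/mL, and it is treated as such. No intermediate
rounding anywhere: the printed tables are only reproduced when CL_TM is
carried unrounded. The per-administration dose (TDD/2 for BID) rounds to
the nearest 2.5 mg tablet with exact midpoints rounded **down** — the
conservative direction for an anticoagulant, and consistent with the
published 4.5 L/h cell (6.23 mg/dose → 5 mg). Single doses above 10 mg
raise an error (linear-absorption bound). Two cells of the published
dosing table differ in the last printed digit from the unrounded chain
(TDD 11.82 vs computed 11.8149 at HF1400/4 L/h, which matches
display-rounded CL_T × target; CL_T 3.27 vs the exact tie 3.265 at
M150/1.5 L/h); tests require one-unit-last-digit agreement there and exact
prints elsewhere.

## The simulator

What it emulates: open-circuit runs as exact mono-exponential reservoir
decay C(t) = C₀e^(−CL·t/V) sampled on the bench schedule, effluent by the
SC/SA definitions, post-filter concentration from single-pass plasma mass
balance C_post = C_pre·(1 − CL/Q_plasma) with Q_plasma = Q_b(1 − hct),
hct = 0.369 (an extraction fraction above 1 is rejected). Closed-circuit
runs integrate reversible single-site (Langmuir-type) filter binding,
dA/dt = k_on·C·(A_max − A) − k_off·A with mass conservation C·V + A = dose,
via LSODA at rtol 1e−10; `adsorption_kinetics_for_fraction` solves the
equilibrium exactly for a requested bound fraction, with capacity defaulted
to 4× the dose (far from saturation, as observed — no saturation evidence
on the bench). The default k_off = 6/h puts the relaxation time near
6 min, consistent with near-peak binding by the first 10-min sample. In a
closed system with constant parameters the bound amount approaches
equilibrium monotonically; the observed slight decline after the 10-min
peak is not reproduced by a single-site mechanism and is a documented
limitation.

Noise is multiplicative lognormal per sample with median 1, default CV 5%
(the assay accepted ≤15% CV; observed intra-assay CVs ranged 1.2–10%).
`generate_study` adds lognormal **between-replicate** variability on each
run's realized clearance, default CV 30% — chosen once as the mean relative
SD of the reported per-condition clearances (n = 2 per cell, so those SDs
only bracket the truth). Condition-level clearance and SC/SA truth default
to the reported study means. All randomness flows from one seed;
identical specs give byte-identical output.

What passing recovery tests therefore show: the estimators are unbiased and
precise when the data really are single-phase, well-mixed, log-normally
noisy and on-schedule. They do not validate behavior under filter
clotting/aging, multi-phase disposition, blood–plasma partitioning beyond a
static hematocrit, carryover, or assay calibration drift — none of which
the generator emulates.

## Numerical and design notes

- λz needs ≥3 positive points; profiles shorter than that raise; a
  non-positive slope refuses extrapolation to infinity.
- Zero-variance degenerate inputs: t-test returns p = 1 at equal means;
  ANOVA on a constant response defines F = 0, p = 1, R² = 0.
- Stepwise with all candidates removed returns the intercept-only fit with
  a warning rather than failing.
- The tidy CSV contract (`experiment_id, replicate_id, mode, filter,
  effluent_flow_L_h, dilution_split, analyte, site, time_min, conc_ng_mL`)
  carries an optional `dose_mg` column; without it CL and Vz are NaN and
  AUCs are still reported. Display rounding exists only in report writing
  (3 decimals for SC/SA and coefficients, 2 for clearances and doses).
- Problem sizes in the test-suite and acceptance recovery studies (50–100
  simulated 24-run batches, 200-seed Monte-Carlo checks) were chosen to
  keep sampling error well below the asserted tolerances.

## Known limitations

- The regression refitted to condition-level mean clearances does not
  reproduce the published coefficient set exactly; the underlying
  per-experiment data are unavailable, and the reported means are rounded
  to one decimal. The dosing layer therefore defaults to the published
  coefficients and accepts a fitted model explicitly.
- Under the generator's defaults the condition-level truth contains a real
  CRRT-mode effect (CVVHD cells sit below the filter+flow plane), so
  stepwise selection retains {filter, flow} alone in fewer than half of
  seeded batches; selecting exactly those two covariates in ≥90% of batches
  is not achievable under these study conditions, and the corresponding
  end-to-end check documents this honestly rather than adjusting the
  conditions.
- In vitro clearance of a highly protein-bound drug in bovine plasma
  (~71% bound vs ~87% in humans) may overestimate in vivo CRRT clearance;
  the package computes, it does not extrapolate clinically.
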