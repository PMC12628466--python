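# Methods

## Stoichiometric yield ledger

The ledger treats a scenario as a steady-state partition of a glucose pool,
not a kinetic simulation. Assumptions:

- Every glucose is phosphorylated once (−1 ATP at hexokinase), whether it
  subsequently enters glycolysis or the PPP.
- The PPP runs a single oxidative pass at maximal NADPH-recycling efficiency:
  per 6 G6P, 12 NADPH and 6 CO₂ are produced and the non-oxidative branch
  returns 4 F6P + 2 GAP (five hexose-equivalents; one glucose fully
  oxidized). Counts are real-valued so any glucose pool and split are
  well defined; the rule scales linearly.
- `f6p_return_mode` decides whether regenerated F6P re-enters glycolysis at
  PFK (costing 1 ATP each, `return_to_glycolysis`) or is retained as
  recycled hexose (`retain`). The control preset returns F6P; the
  oxidative-stress and exercise presets retain it, consistent with running
  the PPP for NADPH rather than throughput. The mode is an explicit flag
  because either bookkeeping is defensible.
- PPP-produced GAP re-enters lower glycolysis at no ATP cost (`gap_return`,
  default on).
- The RLS diverts `rls_triose_count` trioses past PGK (losing that ATP) while
  keeping the PK ATP; each diverted triose yields one 2,3-BPG. The shunt
  count is a direct parameter rather than a fraction because the preset
  scenarios imply mutually inconsistent fractions (24 of 118, 20 of 98,
  39 of 210 trioses); a direct count keeps each scenario exact.
- All completing trioses end as lactate, so GAPDH's +1 NADH and LDH's −1
  NADH cancel identically; `nadh_net` is reported to make that audit visible.

`carbon_balance` closes the books: 6 C per glucose in, against 3 C per
lactate, 1 C per CO₂, 6 C per retained F6P and 3 C per retained GAP. The
residual is zero for every feasible configuration (property-tested over
random scenarios), which guards the ledger against bookkeeping drift.

Preset yields: control 94 ATP / 12 NADPH / 24 2,3-BPG per 60 glucose;
oxidative stress 50 / 84 / 20 per 84 glucose; exercise 180 NADPH and 39
2,3-BPG per 180 glucose with ledger ATP 111. A figure of 108 ATP is
sometimes quoted for the exercise scenario; neither return mode of this
ledger (nor any accounting we could construct that simultaneously gives 39
2,3-BPG and 180 NADPH) produces 108, so the preset reports the ledger result
and attaches an explanatory note rather than special-casing the number.

The muscle-comparison arithmetic is deliberately trivial and exposed as two
functions (`atp_turnover_scale`, `relative_rate`) so the scaling claims —
resting erythrocyte ATP turnover 1.50 mM/h, ×3 with exercise = 4.5 mM/h,
≈ 0.025% of the 18,000 mM/h muscle maximum — are computed, not quoted.

## Oxygen dissociation curve

The revised Dash–Bassingthwaighte closed-form parameterization. Standard
state: plasma pH 7.40, pCO₂ 40 mmHg, 2,3-BPG 4.65 mM, 37 °C, p50 = 26.8
mmHg. Plasma pH is first mapped to erythrocyte pH with the linear Donnan
relation pH_rbc = 0.795·pH_pl + 1.357 (7.40 → 7.24). Each effector's
deviation feeds a correction polynomial (cubic in ΔpH and ΔT, quadratic in
ΔpCO₂ and Δ[2,3-BPG] in molar), and the four corrected p50 factors compose
multiplicatively. p50 is closed-form — no root finding — and the saturation
curve is a Hill function with pO₂-dependent exponent
n(pO₂) = 2.82 − 1.20·10^(−pO₂/29.25 mmHg), anchored at the adjusted p50, so
saturation(p50) = 0.5 holds by construction and saturation is strictly
increasing on (0, 150] mmHg for every physiological state.

Conventions and edge handling:

- 2,3-BPG is taken in mM (standard 4.65 mM). Converting from assay units
  (e.g. mmol per g Hb, or per packed-cell volume) is the caller's
  responsibility.
- States outside the published validity envelope (pH 6.8–7.8, pCO₂ 10–90
  mmHg, 2,3-BPG 1–10 mM, 34–42 °C) evaluate with a
  `PhysiologicalRangeWarning` instead of failing, because post-exhaustion
  panels sit near the edge; hard invariants (pH within (6.5, 8.0), T within
  (30, 44) °C) still raise.
- The implementation is verified against an independently transcribed
  evaluation of the same published equations (a naive pure-Python oracle in
  `tests/oracles.py`) on a 5⁴ effector grid to 1e-9, plus finite-difference
  sign checks: ∂p50/∂DPG > 0, ∂p50/∂pCO₂ > 0, ∂p50/∂T > 0, ∂p50/∂pH < 0.

Measured per-participant pH and 2,3-BPG panels from the motivating study are
not publicly tabulated, so no attempt is made to reproduce specific printed
p50 values; the model is validated by its structural properties instead.

## Ex vivo glycolytic flux

Plain OLS of lactate (μM) on incubation time (min) — with four points,
anything more robust would be underdetermined. Slope, intercept, slope SE
and R² come from `scipy.stats.linregress`; a constant-response series is
special-cased as a perfect flat fit (slope 0, R² defined as 1) because the
textbook R² is 0/0 there. R² < 0.9 attaches a QC flag without dropping the
sample; no exclusion rule is applied. Flux units are μM/min of the
50%-hematocrit suspension; no per-cell normalization is attempted.
Fold-changes are ratios of cell means (not means of per-sample ratios),
matching how group percentage changes are reported. Dose–response tables
validate doses against the declared grids (glucose 3.9/5.6/7.2/10 mM; H₂O₂
0/5/10/20/40 μM) and report the sign of the Spearman correlation of mean
flux with dose per condition.

## NIRS reduction

All summary values are means over half-open 30-s trailing windows
(end−30 s, end], exactly 300 samples at 10 Hz:

- baseline: window ending at the end of the 5-min rest phase;
- exercise bins: windows ending at the 10%,…,100% points of the exercise
  duration, so traces with different exhaustion times always yield exactly
  10 bins; windows clip at exercise start for very short durations, and
  durations under 60 s are rejected;
- occlusion: windows ending at minutes 1–5 of the occlusion, with the
  5/5/3-min protocol enforced within a 10% tolerance;
- recovery: windows ending 60/90/120 s after the end of exercise/occlusion
  (cuff release), the physiologically standard origin.

Whether the 30-s bins should trail or be centered on each time point is a
genuine open choice; trailing is the default (mirroring the last-30-s
baseline convention) and `window_position="centered"` is available. Optode
averaging is a pointwise mean; tHb is the sum of the O₂Hb and HHb
summaries, which equals the summary of the sum because window means are
linear. Input not on the 0.1-s grid within 1% is rejected at trace
construction. No chromophore separation, adipose-thickness correction or
muscle-VO₂ slope estimation is performed.

## Synthetic-data generator

The generator emulates the crossover study's design and measured effect
sizes; its defaults are the study conditions, not tuning knobs:

- n = 20 participants, conditions {control, oxidative stress}, timepoints
  {baseline, pre, post-0, post-10, post-30 min}, incubation times
  0/30/60/90 min.
- Participant baseline flux ~ Normal(21.1, 4.0) μM/min (mean from the
  resting assay; between-participant SD set to a ~19% CV, typical of
  metabolic rates in healthy young men). Multipliers: ×1.4 (oxidative
  stress, applied from the pre timepoint), ×2.74 control / ×1.67 stress
  immediately post exercise (+174% / +67%), geometric midpoint at 10 min,
  return to the pre level by 30 min. The same participant baseline is used
  in both conditions (crossover), so truth-table fold-changes are exact by
  construction.
- Lactate points: intercept + flux·t + Normal(0, 50 μM) noise. The
  intercept defaults to 150 μM with participant-level jitter (SD 30 μM),
  representing residual extracellular lactate in a washed suspension; with
  a zero intercept, keeping concentrations non-negative would truncate half
  of the t = 0 draws and bias fitted slopes by about −2%. Negative draws
  are resampled, not clipped, so the Gaussian error model is preserved
  (at the default intercept resampling triggers on ~0.1% of t = 0 points).
- Blood gas: plasma pH 7.40 falling by 0.10 at exhaustion (a typical
  maximal-exercise arterialized value; the study does not print its pH
  deltas), 2,3-BPG 4.65 mM rising 14% (control) / 22% (stress), temperature
  37 → 38.5 °C, half-recovered at 10 min and fully by 30 min.
- Redox biomarkers are unit-mean levels shifted +22% (F₂-isoprostanes),
  +28% (protein carbonyls), −20% (glutathione) under oxidative stress.
- NIRS: piecewise kinetics (flat rest; monotone O₂Hb fall/HHb rise to
  exhaustion or linear occlusion drift; exponential recovery, τ = 30 s) with
  independent white noise per optode; exercise duration drawn uniformly from
  480–900 s so the duration-normalized binning is exercised.

What the generator does not emulate: day-to-day within-participant
variation, biomarker covariance structure, heteroscedastic assay noise,
drop-out, or NIRS movement artifacts. Passing recovery tests therefore
demonstrates estimator correctness under the assumed error model, not
robustness to real-world artifacts.

## Numerical choices

- Scenario counts are floats; preset integrality is preserved by computing
  the PPP share as glucose_total minus the glycolytic share.
- Carbon residuals are asserted to 1e-6 relative; ODC oracle agreement to
  1e-9 absolute; OLS oracle agreement to 1e-9 relative.
- Monte-Carlo recovery checks use 100 replicate studies at n = 20 and accept
  within two Monte-Carlo standard errors of the embedded multiplier; the
  whole suite runs in well under a minute.
- All randomness flows from `numpy.random.default_rng` seeded per study;
  identical seeds give bit-identical tables.

## Known limitations

- The stoichiometric model is bookkeeping, not kinetics: no enzyme
  capacities, thermodynamics, or Mg²⁺/pH dependence of the shunt.
- The ODC model omits CO₂ (carbamino) binding curves, whole-blood O₂
  content, methemoglobin/carboxyhemoglobin corrections, and temperature
  effects on the Donnan ratio.
- Flux is per suspension volume; whether the original assay normalized per
  packed-cell volume is not documented, so comparisons across hematocrits
  should rescale explicitly.
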