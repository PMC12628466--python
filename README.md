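# erythroflux

Analysis tools for erythrocyte glycolytic and redox metabolism in exercise
physiology. Erythrocytes rely exclusively on glycolysis for ATP, generate
NADPH through the pentose phosphate pathway (PPP), and tune hemoglobin's
oxygen affinity through 2,3-bisphosphoglycerate (2,3-BPG) made in the
Rapoport–Luebering shunt (RLS). This package models how those pathways
repartition under oxidative stress and acute exercise, and how the resulting
effector changes shift the hemoglobin oxygen dissociation curve (ODC) — for
exercise physiologists and red-cell biochemists working with ex vivo flux
assays, blood-gas panels and muscle NIRS.

## What it computes

**Stoichiometric yield ledger** (`erythroflux.stoichiometry`). For a scenario
that routes a glucose pool between glycolysis and a single-pass PPP operating
at maximal NADPH-recycling efficiency (per 6 G6P: 12 NADPH, 6 CO₂, five
hexose-equivalents regenerated as 4 F6P + 2 GAP, one glucose fully oxidized),
with a chosen number of trioses diverted through the RLS, the ledger counts

- ATP: −1/glucose at hexokinase, −1/F6P at phosphofructokinase, +1 per
  non-shunt triose at phosphoglycerate kinase, +1 per triose at pyruvate
  kinase;
- NADPH: 2 per G6P entering the PPP; 2,3-BPG: 1 per shunt triose;
- NADH: +1 at GAPDH and −1 at lactate dehydrogenase per triose, netting to 0
  when all trioses end as lactate; a full carbon balance audit.

Named presets: `control` (60 glucose, 90/10 split, 24 shunt trioses →
94 ATP / 12 NADPH / 24 2,3-BPG), `oxidative_stress` (84 glucose, 50/50,
regenerated F6P retained, 20 shunt trioses → 50 / 84 / 20), `exercise`
(180 glucose, 50/50 → 180 NADPH; ledger ATP 111, with a flagged note — see
`docs/methods.md`).

**Ex vivo glycolytic flux** (`erythroflux.flux`). Flux is the OLS slope
(μM/min) of extracellular lactate against incubation time (0/30/60/90 min,
50%-hematocrit suspension), with SE, R², QC flags, condition × timepoint
summaries, fold-changes, and glucose / H₂O₂ dose–response tables with
Spearman trend diagnostics.

**ODC and p50** (`erythroflux.odc`). The revised Dash–Bassingthwaighte
closed-form model: p50 = 26.8 mmHg at the standard state (plasma pH 7.40,
pCO₂ 40 mmHg, 2,3-BPG 4.65 mM, 37 °C), shifted by correction polynomials in
each effector's deviation and composed multiplicatively; saturation is a Hill
curve with a pO₂-dependent exponent anchored at p50, so S(p50) = ½ exactly.

**NIRS reduction** (`erythroflux.nirs`). 10 Hz O₂Hb/HHb traces are reduced to
optode means, a last-30-s-of-rest baseline, ten 30-s bins at 10%…100% of the
exercise duration, minute-wise occlusion values (5/5/3-min protocol), and
recovery points 60/90/120 s after cuff release or exhaustion; tHb = O₂Hb+HHb
throughout.

**Synthetic study** (`erythroflux.synthetic`). A seeded generator for a
20-participant two-condition crossover (baseline/pre/post-0/10/30 min) with
known ground truth: resting flux ≈ 21 μM/min, ×1.4 under oxidative stress,
×2.74 (control) / ×1.67 (stress) immediately post exercise, blood-gas and
biomarker shifts, and NIRS kinetics — so every stage is testable without any
data download.

## Worked example

```python
import numpy as np
from erythroflux import synthetic, flux, odc, stoichiometry

study = synthetic.generate_study(synthetic.StudyDesign(n_participants=20, rng_seed=1))
slopes = {}
for series in study.lactate_series():
    key = (series.meta["condition"], series.meta["timepoint"])
    slopes.setdefault(key, []).append(flux.estimate_flux(series).slope)

ctl_pre = np.mean(slopes[("control", "pre")])
os_pre = np.mean(slopes[("oxidative_stress", "pre")])
ctl_post = np.mean(slopes[("control", "post0")])
print(f"control pre flux:   {ctl_pre:.1f} uM/min")
print(f"stress  pre flux:   {os_pre:.1f} uM/min  (x{os_pre/ctl_pre:.2f})")
print(f"control post flux:  {ctl_post:.1f} uM/min  (+{flux.percent_change(ctl_pre, ctl_post):.0f}%)")

rest = odc.BloodGasState(ph=7.40, dpg=4.65, temp=37.0)
post = odc.BloodGasState(ph=7.30, dpg=4.65 * 1.14, temp=38.5)
shift = odc.delta_p50(rest, post)
print(f"p50 rest {odc.p50_adjusted(rest):.2f} -> exercise {odc.p50_adjusted(post):.2f} mmHg "
      f"({shift.label}, +{shift.delta_mmHg:.2f})")

s = stoichiometry.preset("control")
print(f"control scenario: {s.atp_net:.0f} ATP, {s.nadph:.0f} NADPH, {s.bpg23:.0f} 2,3-BPG per 60 glucose")
```

prints

```
control pre flux:   21.3 uM/min
stress  pre flux:   30.0 uM/min  (x1.41)
control post flux:  58.2 uM/min  (+174%)
p50 rest 26.80 -> exercise 31.92 mmHg (right shift, +5.12)
control scenario: 94 ATP, 12 NADPH, 24 2,3-BPG per 60 glucose
```

The fitted group means recover the generator's embedded multipliers (1.4
under oxidative stress, 2.74 post-exercise) to within sampling noise; the
post-exercise effector state (pH −0.10, 2,3-BPG +14%, 38.5 °C) right-shifts
the ODC by ~5 mmHg, favouring oxygen release to working muscle.

## Command line

```bash
erythroflux simulate --n 20 --seed 1 --out data/      # lactate/bloodgas/biomarkers/truth CSVs
erythroflux flux --lactate data/lactate.csv --out flux.csv
erythroflux flux-dose --lactate doses.csv --challenge h2o2 --out dose.csv
erythroflux stoich --preset control                   # yield ledger as JSON
erythroflux odc --bloodgas data/bloodgas.csv --out p50.csv
erythroflux run --seed 1 --out report.json            # full pipeline report
```

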