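# snedds-screen

Adaptive ternary mixture-design screening for self-nanoemulsifying drug
delivery systems (SNEDDS).

A SNEDDS is an anhydrous preconcentrate — an oil/lipid, a surfactant (or
surfactant blend) and a co-solvent — that spontaneously forms a
nanoemulsion when dispersed in aqueous media, carrying a poorly
water-soluble drug into solution. Finding the excipient ratio that yields
a *good* nanoemulsion (droplet size < 50 nm, polydispersity index
PDI < 0.15, transmittance > 99% vs water) classically means preparing the
whole ternary composition grid in 10% increments: 66 mixtures. This
package implements a far cheaper adaptive strategy for formulation
scientists:

1. **Stage 1** — prepare the center point of the ternary diagram
   (sample 1, equal parts of each component) and the six vertices of a
   hexagon mapped around it (samples 2–7).
2. **DAOI** — score each mixture with a desirability function (geometric
   mean of size/PDI/transmittance ramps) and locate the *designated area
   of interest*: the desirability-weighted centroid of the top-scoring
   samples.
3. **Refinement** — place a parallelogram (4 mixtures, samples 8–11) or a
   trapezoid with extra points along its parallel sides (up to 7 mixtures,
   samples 8–14) into the DAOI and prepare those; stop at the first stage
   containing a specification-passing mixture.

The result: 11–14 experiments instead of ~50–66.

Around the screening loop the package provides the supporting mixture
bookkeeping and statistics:

- **Drug load** per the campaign equation
  `load [%] = f · mean(c_s) · 0.1`, with `c_s` the saturation
  solubilities (mg/g) of the drug in the individual components and `f` a
  drug-specific safety factor; blend expansion from a simplex point to the
  full mass-percent formulation; encapsulation efficiency; solubility
  ranking and pairwise miscibility filtering of excipient candidates.
- **Scheffé-style mixture regression** of each response on main (x_i),
  interaction (x_i·x_j) and quadratic (x_i²) terms, with t-based
  confidence intervals, interval-excludes-zero significance flags,
  observed-vs-predicted diagnostics, externally studentized outlier
  flagging, worst-case imputation of mixtures that never emulsified, and
  contour grids over the simplex for plotting.
- A **synthetic response-surface simulator** (quadratic droplet-size bowl,
  logistic transmittance, ordinal emulsification grade, failure region)
  so the entire closed loop is testable without a laboratory.

## Worked example

```python
from snedds_screen import (run_screening, ScreeningConfig, scenario_preset,
                           observe, drug_load, expand_blend, TernaryPoint,
                           BlendComponent)

scn = scenario_preset("celecoxib_like")
cfg = ScreeningConfig(figure_kind=scn.figure_kind, extras=scn.extras)
result = run_screening(lambda p: observe(scn.surface, p, seed=1), cfg)
print(result.n_experiments, result.winner, result.stop_reason)
```

prints `11 8 spec_met`: the campaign consumed 11 mixture preparations
(7 stage-1 + 4 parallelogram) and sample 8 — the mixture at
42.98/29.06/27.96 mass % of the three axes — passed every specification
(size 23.9 nm, PDI 0.09, transmittance 100.0%, grade I).

Formulation bookkeeping, using the bundled synthetic solubility table for
a fenofibrate-style campaign (f = 0.5):

```python
load = drug_load(f=0.5, solubilities=[30.0, 120.0, 150.0, 116.8])  # 5.21 %
blend = BlendComponent(("Tween 80", "d-TPGS"), (5, 1))
form = expand_blend(TernaryPoint(0.20, 0.10, 0.70),
                    ["Miglyol 812", "Brij 35", blend], "fenofibrate", load)
```

yields the full composition `Miglyol 812 18.96 / Brij 35 9.48 /
Tween 80 55.29 / d-TPGS 11.06 / fenofibrate 5.21` mass %, conserving mass
to 100.00.

## Command line

`snedds-screen` exposes the same loop as subcommands — `plan-init`,
`simulate`, `plan-refine`, `evaluate`, `select`, `fit`, `contour`,
`run-sim`, `report` — exchanging CSV tables keyed by `sample_id`:

```sh
snedds-screen plan-init --out stage1.csv
snedds-screen simulate --scenario celecoxib_like --seed 1 \
    --design stage1.csv --out responses1.csv
snedds-screen plan-refine --requests stage1.csv \
    --responses responses1.csv --out stage2.csv
```

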