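# eflow

Hydrologic alteration and its ecological consequences, reach by reach.

Environmental-flow management needs to know *how much* a stream's flow
regime has been altered by dams, withdrawals and urbanization, and *at what
level of alteration* native biodiversity starts to decline. `eflow`
implements an end-to-end pipeline for exactly that question, aimed at
ecohydrologists and water managers working in the ELOHA (Ecological Limits
of Hydrologic Alteration) tradition:

1. **Hydrologic indices** — a 41-index suite of daily-streamflow statistics
   (magnitude MA/ML/MH, duration DL/DH, frequency FL/FH, Colwell timing
   TA1/TA2, rate-of-change RA) computed from screened records with at least
   15 complete water years (≤ 30 missing days per year).
2. **Alteration at gauges** — per-index alteration as the capped
   proportional departure from expected reference conditions,

   `a = min(|(O − E)/E|, 1) ∈ [0, 1]`,

   where E comes from ensemble-of-trees models fit on reference gauges'
   natural covariates (or a class envelope for indices those models handle
   poorly). Two cumulative indices summarise multivariate change: a
   **seasonality index** (cumulative proportional deviation of the 12 mean
   monthly flows) and the **HAI**, the eigenvalue-weighted sum of a gauge's
   significant principal-component score excursions outside its hydrologic
   class's reference envelope (component significance by the broken-stick
   rule); both are min–max rescaled within each ecohydrologic region.
3. **Extrapolation to ungauged reaches** — one random forest per metric and
   scope (whole network, or per region) maps 50 disturbance/natural
   covariates to alteration, validated by out-of-bag AUC against two binary
   controls (reference vs non-reference; alteration above/below 0.5) with
   min–max-scaled permutation variable importance.
4. **Flow–ecology tipping points** — linear quantile regressions
   (τ = 0.50/0.75/0.95) of fish-richness residuals on alteration, fit per
   HUC-4 watershed with region-mean fallback; the alteration `T = −β₀/β₁`
   where the fitted bound crosses zero is the tipping point. Comparing each
   reach's alteration to its thresholds gives a binary exceedance vector
   whose mean is the probability of fish-biodiversity loss.
5. **Compounded uncertainty** — alteration widened by model OOB error,
   thresholds re-derived at slopes β₁ ∓ SE, yielding lower/upper loss
   probabilities and cumulative exceedance curves with an uncertainty band.

A first-class synthetic generator produces gauge networks, class-specific
reference flow regimes, disturbance-perturbed flows, linked covariates and
wedge-shaped fish responses with a **known tipping point**, so every stage
is testable against ground truth.

## Worked example

Recovering a biodiversity tipping point from a synthetic wedge
(`examples/04_fish_tipping_points.py`): 500 survey sites with alteration
uniform on [0, 1], richness residuals bounded above by an envelope that is
0 up to the true tipping point 0.40 and falls to −5 species at full
alteration:

```
tau=0.50: residual = +1.67 -8.18 x HA  (slope SE 0.13)  -> tipping point 0.204 in [0.201, 0.207]
tau=0.95: residual = +3.33 -10.33 x HA  (slope SE 0.01)  -> tipping point 0.323 in [0.322, 0.323]
```

The τ = 0.95 regression tracks the wedge's upper envelope, so its zero
crossing (0.32) estimates the alteration beyond which the first native
species is expected to be lost — within 0.1 of the true 0.40. The median
line runs through the scatter and crosses earlier, as it should.

Extrapolating alteration to ungauged reaches
(`examples/03_reach_extrapolation.py`, 60 gauges / 80 reaches):

```
out-of-bag validation, whole-network models:
  AUC (reference vs non-reference) mean 0.974
  AUC (alteration > 0.5 control)   mean 0.871
  OOB MSE mean                     0.0297
```

AUC near 1 means the disturbance covariates almost perfectly rank disturbed
above reference sites out-of-bag; predictions are clipped to the [0, 1]
alteration scale.

The other examples cover the index engine (`01`), gauge-level alteration
and the HAI (`02`), and the full pipeline with uncertainty bands (`05`).

## Command line

Each pipeline stage is a subcommand over a shared artifact directory:

```sh
eflow run   --seed 1 --out artifacts/          # everything, synth -> uncertainty
eflow synth --seed 1 --out artifacts/          # or stage by stage
eflow metrics --out artifacts/
eflow model --scope regional --out artifacts/
```

Configuration is a YAML file (`--config cfg.yml`) validated against the
`RunConfig` schema; every output CSV gets a `.manifest.yml` column
dictionary, and identical config + seed reproduces every table byte for
byte.

## Layout

```
src/eflow/        synthetic, series, metrics, alteration, models,
                  ecology, uncertainty, io, config, pipeline, cli
examples/         one short narrative script per capability
tests/            pytest suite with brute-force oracles
docs/methods.md   models, assumptions, parameter choices, limitations
```
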