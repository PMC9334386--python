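# Methods

This note records the models behind each pipeline stage, the defaults that
matter and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical conventions a user re-deriving results will
want to know.

## Record screening and calendars

Daily discharge records are screened to water years (Oct 1 – Sep 30,
labelled by the ending calendar year; configurable) with at most 30 missing
days; a gauge needs at least 15 such years. Fifteen years is the
conventional minimum for stabilising inter-annual variance in flow indices;
the 30-day allowance bounds the bias of computing statistics on slightly
incomplete years. Feb 29 is dropped everywhere so every year has 365 days,
which keeps rolling windows and generated series aligned; the pipeline does
not control for climate non-stationarity between reference and disturbed
periods of record.

## The hydrologic index engine

Forty-one indices spanning the five facets of the natural flow regime.
Conventions the index definitions leave open were fixed as follows:

* **Rolling extremes (DL1–5 / DH1–5)** — trailing 1/3/7/30/90-day windows
  fully contained in one water year; annual minima/maxima of the window
  means, averaged over years. Years shorter than a window (after gap
  trimming) are skipped for that window only.
* **Pulse thresholds** — 25th/75th percentiles of all daily flows in the
  screened record (standard IHA practice); an event is a maximal run of
  consecutive days strictly beyond the threshold. Flood thresholds for
  FH6/FH7 are 3× and 7× the median daily flow. DL16/DH15 are the mean over
  years of the median within-year event duration; counts (FL1, FH1, FH6,
  FH7, DL18, RA8) are prorated to 365 days when a retained year has gaps.
* **Colwell constancy/predictability (TA1/TA2)** — contingency matrix of
  calendar month × flow state of the monthly mean flow; 11 logarithmically
  spaced states between the record's positive minimum and maximum, zero
  months in a reserved 12th state, natural-log entropies, denominator
  log(12). State edges derive from the record itself, so rescaling all
  flows by a constant leaves TA1/TA2 unchanged. Both are exactly 1 for a
  constant record. Plug-in entropies are biased at small cell counts; at
  typical record lengths this inflates predictability by a few hundredths.
* **Rates (RA1/RA3/RA8)** — day-over-day differences within water years;
  RA3 is stored as a positive magnitude (fall rate); reversals are sign
  changes between consecutive non-zero differences (zero differences are
  transparent). A record with no rises (falls) reports RA1 (RA3) = 0.
* Missing days inside retained years are excluded from means and
  percentiles, not imputed.

The engine is verified against independent brute-force oracles: exhaustive
window scans for DL/DH, a literal run-length scanner for all pulse metrics,
and entropy formulas applied to hand-built contingency matrices.

## Alteration calculus

Per-index alteration is `min(|(O − E)/E|, 1)`; the cap makes every index a
[0, 1] "likelihood of alteration" and deliberately discards how far beyond
100% a departure goes. Reference gauges are set to 0 by definition. E = 0
conventions (O = 0 → 0; O > 0 → 1) keep the ratio defined for
intermittent-stream indices and are logged whenever triggered.

Expected conditions E at non-reference gauges come from one
random-forest regression per index, fit on reference gauges' *natural*
covariates only (basin size, climate, natural cover). Indices for which
such models are unreliable — by default the flow-timing indices TA1/TA2 —
instead use the central 90% interval (5th–95th percentile) of reference
values within the gauge's hydrologic class: observed values inside the
interval score 0, outside it the capped distance to the nearest bound.
"90th percent confidence interval" is interpreted as this empirical central
interval; no distributional estimator is assumed.

The **seasonality index** sums the twelve monthly proportional deviations.
The default uses absolute deviations, because a literal signed sum lets
opposite-sign seasonal shifts (e.g. a rotated hydrograph) cancel to zero
alteration; a `seasonality_signed` flag restores the literal signed form.

The **HAI** measures multivariate departure from the class-typical flow
regime: all indices are min–max scaled to [0, 1], centred, and decomposed
by PCA fit on reference and non-reference gauges jointly. The number of
significant components k comes from the broken-stick rule (observed
variance proportion must strictly exceed the null proportion
`b_j = (1/p) Σ_{i=j..p} 1/i`, stopping at the first failure; k is floored
at 1 so the index is defined). Per hydrologic class, the central 90%
interval of *reference* scores on each significant component forms an
envelope (a_i, b_i); a gauge's HAI is `Σ |S_i − nearest violated bound| ×
V_i` over components whose score falls outside, V_i the eigenvalue.
Envelope percentiles are computed before the regional rescaling. Loadings
follow a fixed sign convention (largest-|loading| entry positive) so refits
are bit-reproducible. Seasonality and HAI are min–max rescaled within each
ecohydrologic region (rank-preserving; a constant region maps to zeros with
a warning).

## Forest models and reach extrapolation

One random-forest *regression* per metric × scope predicts the [0, 1]
alteration response from the 50 covariates, with predictions clipped to
[0, 1]. A classification mode on the binarised (> 0.5) response exists for
comparison; regression is the default because continuous alteration values
carry no trials count that would justify a strict binomial likelihood.
Defaults: 200 trees, scikit-learn's standard bootstrap (≈ 1/3 OOB),
minimum 20 gauges per scope (smaller strata are skipped with a logged
reason). Validation uses OOB predictions: rank-based AUC (midrank ties)
against the reference/non-reference control and against the high/low
(0.5) alteration control; either measure is reported as undefined — not
zero — when its control has a single class. Variable importance is
forest-level permutation importance (rise in MSE when one column is
permuted), min–max scaled to [0, 1] within a bundle; by default it is
computed for whole-network models only, since it is the slow part and the
regional bundles' AUC/MSE do not depend on it. Under the regional scope
policy a reach uses its region's model and falls back to the whole-network
model when the region was skipped.

## Flow–ecology fits and loss probability

Linear quantile regressions of richness residual on alteration (τ = 0.50,
0.75, 0.95) per metric × HUC-4, minimum 30 observations, constant-gradient
cells skipped; the cumulative HAI is excluded from ecological fitting.
Slope standard errors use the asymptotic iid-kernel estimate; fits whose SE
comes back undefined get degenerate (zero-width) threshold bounds rather
than dropping out, so the metric set behind the probability bounds always
matches the point estimate. HUC-4s without fits inherit the unweighted
region-mean coefficients (SEs pooled as root-mean-square). Linearity is
assumed because only slope/intercept coefficients and their SEs are
propagated downstream.

Tipping point: `T = −β₀/β₁` clipped to [0, 1] for a declining bound;
β₀ ≤ 0 means species are already lost at zero alteration (T = 0); a
non-declining bound with β₀ ≥ 0 never crosses zero, so the threshold is
undefined and the metric is excluded from that subregion's exceedance
vector (absence of evidence, not evidence of safety). Exceedance uses ≥
(the boundary counts as loss). The loss probability is the mean of the
defined binary responses; a reach with no defined metric reports a missing
value, never 0. Richness deltas (β₀ + β₁·HA per metric) are summarised as
the median and minimum across metrics.

## Uncertainty propagation

Alteration bounds add/subtract each model's OOB MSE (clipped to [0, 1]).
MSE is used literally by default even though it is not in alteration units;
`use_rmse_bounds` switches to RMSE. The error follows each prediction's
scope tag. Threshold bounds re-derive the crossing at slopes β₁ ∓ SE; a
shallow slope β₁ + SE ≥ 0 sends the upper bound to 1 (the crossing escapes
the unit interval).

The probability bounds pair the widened quantities *ordering-consistently*:
the lower bound counts a metric only when loss is certain under every error
scenario (HA_lower ≥ T_upper), the upper bound when loss is possible under
some scenario (HA_upper ≥ T_lower); this guarantees
p_lower ≤ p ≤ p_upper for every reach and τ. A `literal_bound_rule` mode
applies the opposite pairing (lower fires when T_lower ≥ HA_upper, upper
when T_upper ≥ HA_lower) for fidelity with formulations that print the
inequalities that way; that pairing can invert the ordering and is flagged
in logs and output metadata. Cumulative exceedance curves report, for each
probability level q, the (optionally length-weighted) proportion of reaches
with p ≥ q, for the point estimate and both bounds.

## The synthetic generator

The generator reproduces the *statistical structure* the analysis assumes,
with known ground truth:

* **Reference flows** — per hydrologic class: seasonal sinusoid (amplitude
  0.3–0.6, class-specific phase) scaled by drainage area at 0.05 cfs/km²
  specific runoff, multiplicative lognormal daily noise (σ = 0.25, mean-1),
  Poisson storm pulses (0.03/day, exponential peaks, e-folding recession
  ≈ 2.2 days); the last class is intermittent (dry-season floor at zero).
  With noise and storms disabled the discrete-sum mean equals the sinusoid
  mean exactly, giving a closed-form MA1.
* **Disturbance operators** — seasonal rotation (whole months), dam
  regulation (moving-average blending up to a 30-day window plus a
  minimum-release floor at intensity × half the median flow — dampens
  peaks and CV, raises low flows), withdrawal (multiplicative, so MA1
  scales exactly), urban flashiness (extra storm spikes with ≈ 0.7-day
  recession — raises rise rates and high-pulse counts). A zero profile is
  the identity. Ground-truth alteration for tests is *computed* by running
  the index engine on paired reference/disturbed series.
* **Covariates** — the 8 field-standard predictor groups (urbanization 14,
  agriculture 10, dams 6, power 6, dischargers 5, disturbance indices 3,
  basin/climate 3, natural cover 3 = 50 columns). Disturbance groups are
  strictly monotone power transforms of the true driving intensity with
  Gaussian noise (default σ = 0.1) added before the transform; natural
  columns depend only on drainage area and class.
* **Fish responses** — richness residuals drawn uniformly between a lower
  wedge bound and an upper envelope U(HA) that is 0 up to the true tipping
  point and declines linearly to −max_loss at HA = 1. Uniform noise keeps
  the fitted upper-quantile bound analytically predictable. The wedge depth
  defaults to 2 species: with uniform noise the conditional 95th percentile
  sits 0.05 × depth below the envelope, and a deep wedge pushes the fitted
  intercept below zero, collapsing the derived threshold to 0; 2 species
  keeps the τ = 0.95 recovery within ±0.1 of the truth at 500 sites while
  still allowing low residuals everywhere.
* Defaults of the full synthetic study: 200 gauges (40% reference), 1,000
  reaches, 4 regions × 2 HUC-4s, 3 classes, 15-year records, tipping point
  0.4, max loss 5 species. These sizes keep a complete run to a few minutes
  on one core while leaving every stratum populated.

What the generator does **not** emulate: spatial autocorrelation and flow
routing, rainfall-runoff physics, climate non-stationarity, correlated
disturbance regimes (pressures are drawn independently), site-to-site
heterogeneity in the fish wedge (residuals above the envelope never occur),
and measurement error in discharge. Passing tests therefore demonstrate
the *machinery* — index arithmetic, model plumbing, uncertainty ordering,
reproducibility — under the stated statistical assumptions, not predictive
skill on real gauge networks.

A known consequence of these study conditions: model-predicted alteration
at reaches concentrates below the 0.4 tipping point, the wedge is weakly
expressed in the survey sample, τ = 0.95 intercepts come out slightly
negative, and most fitted thresholds collapse to 0 — so reach loss
probabilities saturate near 1 even though the true loss below the tipping
point is zero. This is the compounded-error regime the uncertainty stage
exists to expose; the dedicated wedge-recovery test (uniform driver)
isolates the quantile machinery under well-expressed conditions.

## Numerical and reproducibility conventions

All randomness derives from one seed through fixed per-stage seed
sequences, so any stage re-run standalone from the written CSVs reproduces
the in-memory run. Tables are written with 17 significant digits and read
back with round-trip float parsing — restarted stages see bit-identical
inputs (forest splits are sensitive to 1-ulp differences). PCA sign and
broken-stick tie conventions are fixed (a proportion exactly on the null
expectation is not significant). Identical config + seed yields
byte-identical artifacts.

## Known limitations

Slope SEs from the iid-kernel assume homoscedastic errors, which the wedge
violates by construction; bootstrap SEs would be wider. The HAI depends on
the metric set and class assignment supplied; it is not comparable across
runs with different metric sets. Regional min–max scaling makes seasonality
and HAI values relative within a region, not absolute measures — a
lightly-disturbed region's worst gauge still scores 1. Reach predictions
from regional models carry regional scaling biases; whole-network scope is
preferable for cross-region comparisons.
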