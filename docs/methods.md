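# Methods

This note documents the models and procedures implemented in `compoundhaz`,
the assumptions behind them, the defaults that matter, and what the synthetic
validation studies do and do not demonstrate.

## Problem setting

The package analyses county-level emergency-department (ED) surveillance of
child and adolescent psychiatric visits (mood/affective disorders and
suicide-related presentations) during warm-season (May–September) climate
hazards. Three hazards are considered per county-day: heatwave, drought, and
their compound co-occurrence. The pipeline answers three questions:

1. *Where* is psychiatric ED risk spatially concentrated during each hazard
   (Bernoulli spatial scan)?
2. Do the two hazards *interact* — is the compound effect more or less than
   the sum/product of the individual effects (RERI, synergy index,
   multiplicative ratio)?
3. *Which* household and community characteristics predict residence in a
   high-risk cluster (MARS variable importance)?

Real ED line lists of this kind are restricted, so the package ships a
synthetic-data generator with planted ground truth; every downstream stage is
validated against what was planted.

## Exposure definitions

**Heatwave.** A day-of-year climatology is built per county from daily mean
temperature: for each calendar day, the 90th and 95th percentiles of all
temperatures inside a centered 31-day window pooled across the climatology
years (default 2000–2015 in the synthetic system). The threshold for May 1
therefore pools April 15–May 15 of every climatology year. A heatwave event
begins on the first of 3 consecutive days strictly above t90 and ends on the
last above-threshold day followed by 3 consecutive days at or below t90 (or
by the series end). All days between start and end count as heatwave days,
including short sub-threshold dips — an event is terminated only by a 3-day
break.

Numerical conventions, fixed for reproducibility where the underlying
definitions are silent: percentiles interpolate linearly between order
statistics; exceedance is strict (`>`); February 29 is dropped before
day-of-year indexing (the warm-season analysis never touches it, and it
simplifies the cyclic window); gaps in a series are treated as
below-threshold days and logged.

A degenerate consequence of these conventions worth knowing: on a perfectly
noise-free seasonal cosine, the 2–3 days at the annual peak exceed the 90th
percentile of their own windows (the center day of the warmest window is by
construction above its window's 4th-largest value), producing one exact-tie
"event" per year at the peak. Any realistic noise removes the ties; the test
suite pins this behaviour down rather than pretending it away.

**EHF (excess heat factor).** For day *i*, with the forward three-day mean
T3 = mean(T_i, T_i+1, T_i+2):

    ehi_sig  = T3 − t95(doy_i)          [°C]
    ehi_accl = T3 − mean(T_{i−30..i−1}) [°C]
    ehf      = ehi_sig · max(1, ehi_accl) [°C²]

The three-day window is forward-looking, per the metric's published
formulation; days without a full 30-day history are skipped. A heatwave
event is *high-intensity* when any of its days has EHF at or above the
county's 85th percentile of positive climatological EHF values (ties count
as high). Counties with no positive climatological EHF have an undefined
severity threshold; their events are kept low-intensity and logged. The
high-intensity flag drives the sensitivity hazards `heatwave_high` and
`compound_high`.

**Drought.** Weekly categories on the ordinal roster None, D0–D4 (D1 =
moderate drought; the implemented roster follows the actual monitoring
convention, whose top category is D4). An episode begins the first week at
D1 or worse and ends at the last ≥D1 week followed by 3 consecutive None/D0
weeks (or series end); single sub-D1 dip weeks do not terminate an episode.
Every day of every week inside an episode is a drought day. Weeks are
Tuesday-anchored (the release convention of the drought monitor),
represented by their start date.

**Compound.** A compound day is a heatwave day that is also a drought day in
the same county. Event-level bookkeeping keeps multiple heatwaves inside one
drought as separate compound spells.

## Bernoulli spatial scan

Visits are aggregated per county into cases (event-day visits) and controls
(non-event-day visits) for one hazard × outcome. Candidate windows are
nested prefixes of counties ordered by elliptic distance from each county
centroid, over the standard grid of ellipse shapes {1, 1.5, 2, 3, 4, 5}
(axis ratios) with {1, 4, 6, 9, 12, 15} orientations respectively; shape 1
is the circular scan. Windows are capped by default at 25% of the total
observations (the scan convention); a `cap_on="cases"` switch caps at 25% of
cases instead (the literal reading of the source method). Windows reducing
to the same county set are deduplicated; equal-LLR ties break by smaller
window size, then lexicographic member ids.

The one-sided Bernoulli log-likelihood ratio for a window with c of n points
inside, out of C cases among N points, is the closed form given in
`scan.bernoulli_llr`, zero unless the inside rate exceeds the outside rate,
with 0·ln 0 = 0. Inference: 999 Monte Carlo replicates redistribute the C
case labels uniformly over the N fixed points (a multivariate hypergeometric
draw over counties — exactly a label permutation aggregated to counties),
and p = (1 + #{replicate max LLR ≥ observed})/(1 + 999), so the smallest
attainable p is 1/1000. Secondary clusters are the next-best windows sharing
no county with a better-ranked reported cluster. Reported clusters (p <
0.05, RR > 1) are pruned: member counties whose own single-county RR is
below 1 are removed and the cluster's c, n and RR recomputed, while LLR and
p stand on the originally detected window — pruning trims non-elevated
neighbours, it does not re-test. Cluster RR is (c/E)/((C−c)/(C−E)) with
E = nC/N.

Distances are planar (km). The synthetic lattice is already planar; real
coordinates must be projected to an equal-area CRS upstream.

**Caveat on the Bernoulli null.** The scan tests *spatially uniform case
probability*. When counties differ in how often they are exposed (more
drought weeks → mechanically more event-day visits), that is a genuine
violation of this null even with no risk effect, and the scan will flag it.
The synthetic system therefore models weather as predominantly regional (see
below); analyses of real data share this property and should interpret
drought-scan clusters with county exposure frequency in mind.

## Interaction measures

From the pruned primary-cluster relative risks of the three scans for one
outcome — RR10 (heatwave alone), RR01 (drought alone), RR11 (compound):

* RERI = RR11 − RR10 − RR01 + 1 (0 under exact additivity; < 0 = less than
  additivity);
* Synergy index S = (RR11 − 1)/((RR10 − 1) + (RR01 − 1)) (1 under exact
  additivity; undefined and explicitly flagged when the denominator is 0);
* Multiplicative ratio = RR11/(RR10·RR01) (1 under exact multiplicativity).

Values are reported at two decimals; full precision is retained internally.
If any hazard lacks a significant primary cluster the interaction record
carries an explicit `estimable: false` flag with the missing hazards —
never a silent omission. Confidence intervals for these measures are out of
scope.

## Community covariates and ICE

The Index of Concentration at the Extremes is ICE = (A − P)/T ∈ [−1, 1]
for advantaged count A, deprived count P, total T: 1 means the whole
population is in the privileged group, −1 the deprived group. The module
takes pre-tabulated A/P/T counts per variant (racial, economic,
racialized-economic) rather than encoding census table codes — the formula
stays testable and the data contract explicit. All three variants are kept
as columns; the racialized-economic variant enters the models as
`residential_segregation` by default (configurable).

The predictor roster mirrors community-resilience-style variables:
proportions (age 65+, HS graduation, no vehicle, overcrowding ≥1.51
occupants/room, low English proficiency, no health coverage, broadband,
homeowner/rental vacancy, veterans, Hispanic or Latino), a housing-unit
count, residential segregation, and greenspace per person (m²/person =
green area / population). Proportions are validated to [0, 1] and missing
counties fail the join loudly.

## MARS variable importance

County outcome counts in high-risk cluster counties are modeled as Poisson
with a hinge-basis log-linear mean. The forward pass greedily adds the
reflected hinge pair max(0, x−t)/max(0, t−x) minimizing Poisson deviance
(fit by IRLS), with knots at all distinct observed predictor values —
counties are few, so no minspan/endspan thinning. Degree is 1 (additive) by
default, matching the per-variable hinge-set structure of the reported
importance tables. The backward pass deletes terms one at a time, keeping
the subset minimizing

    GCV = deviance / (n · (1 − M_eff/n)²),  M_eff = M + penalty·(M−1)/2.

The default penalty is 3. With exhaustive knot search the best spurious
candidate on pure noise reduces deviance by roughly 2·log(#candidates)
regardless of n; at penalty 2 such terms survive pruning in most replicates,
at penalty 3 the pruned noise model is intercept-only about half the time
and carries essentially no structure otherwise (gcv_r2 < 0.25). Even so, a
perfectly clean intercept-only outcome on noise cannot be guaranteed — a
known property of exhaustive-knot MARS, shared by the standard R
implementation.

GCV R² = 1 − GCV/GCV_null (intercept-only GCV). Being deviance-based, its
ceiling is set by the irreducible Poisson noise (1 − n/dev_null), so it
approaches 1 only for strong signals.

Variable importance: drop all of a variable's basis functions, refit the
coefficients, record the GCV increase; normalize so the top variable scores
100 (clipped at 0). The `bases` column counts basis functions per variable.
Importance is GCV-based (the reporting convention of the SAS procedure is
not documented; this choice is fixed and stated).

Rows are partitioned into random train/test/validation thirds when there are
at least 30 of them: selection uses the training third's GCV, the held-out
thirds are reported as out-of-sample deviance only. With fewer counties the
thirds would be too small to mean anything and the model fits all rows. The
response default is cluster-counties-only (matching the high-risk-cluster
framing); a config option models every county and adds a cluster-membership
indicator predictor. No population offset is used by default (configurable).

## Synthetic data generator

The generator emulates the study conditions: 20 counties on a 5×4 lattice at
30 km spacing; 16 climatology years (2000–2015) plus 4 analysis years
(2016–2019); warm season May–September; two outcomes.

* **Temperature** = seasonal cosine (mean 21 °C, amplitude 8 °C, peak
  mid-July) + AR(1) anomalies (ρ = 0.7, sd 3 °C — typical of daily-mean
  anomalies) + hot spells (Poisson rate 1.5 per warm season, +6 °C for
  3 + Poisson(2) days). Heat is synoptic-scale: the anomaly mixes a
  region-wide AR(1) series (variance share 0.9, about the inter-county
  daily-anomaly correlation within one state) with a county-specific
  remainder, and hot spells hit all counties on the same days. Spells occur
  in climatology years too, so thresholds reflect them.
* **Drought** = first-order Markov chain per county over None, D0–D4 with a
  persistent default transition matrix (drought ≈ a third of the stationary
  mass); regional coherence via a shared weekly transition draw used with
  probability 0.8 (each county's marginal law is exactly the chain). An
  optional coupling suppresses wetter transitions the week after a hot
  spell (off by default).
* **Visits**: per county-day and outcome, Poisson(baseline × RR) with
  baseline 0.5 visits/county-day/outcome and RR = 3 on hazard-flagged days
  inside a planted compact 2×2 county block (RR = 1 elsewhere). Rows carry
  date, county, outcome, and demographic fields with configurable
  marginals. Off-season days generate no visits.
* **Covariates**: truncated-normal marginals per roster column, with
  configured mean shifts in planted counties (default: overcrowding +0.05,
  greenspace −120 m²/person); ICE inputs are generated as consistent
  advantaged/deprived/total counts. Out-of-bound values are clipped with a
  warning.

All generators are pure functions of (config, seed) via fixed-code
sub-streams, so each input regenerates independently and reproducibly.

**What the generator does not emulate:** realistic geography or population
weights, distance-decaying spatial correlation (regional + independent
components only), seasonality of visit rates, demographic structure in risk,
reporting artifacts, or county-varying baseline rates. Passing tests
therefore demonstrate the *machinery* — detection rules, scan inference,
interaction arithmetic, importance ranking — under controlled conditions,
not that real compound-hazard effects are of any particular size.

## Validation studies (`compoundhaz.studies`)

* **Null calibration**: 200 visit replicates with RR = 1 over one fixed
  exposure calendar; expected case total ≈ 60 (the baseline rate is derived
  from the calendar's event-day count). The study sets the regional weather
  share to 1.0 so event-day frequency is spatially constant and the scan's
  null holds *exactly*; the primary-cluster p-value is then conservative-to-
  nominal (measured fraction p ≤ 0.05 ≈ 0.03–0.07). Under the generator
  default of 0.9 the residual county-level exposure heterogeneity is a true
  mild null violation and raises the rate to ≈ 0.10 — a property of the
  problem, not of the implementation (under an exact Bernoulli null the
  scan rejects at 0.050).
* **Planted recovery**: 50 replicates, RR = 3 on heatwave days, baseline
  0.5, ≥100 event county-days; the pruned primary cluster attains Jaccard
  ≥ 0.6 with the planted block in ≥80% of replicates (measured ≈ 100%).
* **MARS recovery**: 20 replicates at 100 counties; two covariates drive a
  Poisson response (log-linear, ±1 per sd) and the other 12 roster columns
  are pure noise; the two drivers occupy the top-2 importance rows in ≥90%
  of replicates, the first at exactly 100.
* **Exceedance**: by construction of the percentile climatology, each county
  exceeds t90 on ≈10% (±2 points) of climatology days.

Problem sizes (20 counties, 4 analysis years, 999 permutations, 200/50/20
replicates) are the package's chosen study conditions; they keep a full
validation run within a few minutes on one CPU.

## Known limitations

* The scan is purely spatial (no space-time scan), Bernoulli-only, without
  covariate adjustment or Gumbel-approximated p-values.
* Interaction measures come without confidence intervals.
* MARS importance has no uncertainty quantification; with ~20 counties the
  cluster-counties-only response cannot support a meaningful model and the
  pipeline reports intercept-only fits honestly rather than inventing
  structure.
* Drought categories are taken as given; no drought index computation.
* Gridded-to-county temperature aggregation is upstream of this package.
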