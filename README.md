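# compoundhaz

County-level analysis of child and adolescent psychiatric emergency-department
(ED) visits during compound heatwave–drought events.

Concurrent heat and drought may burden mental health more than either hazard
alone, but county-day surveillance of this question needs several pieces of
machinery assembled consistently: climate exposure calendars, spatial cluster
detection on event-day versus non-event-day visits, interaction measures, and
a ranking of the community characteristics that predict high-risk places.
`compoundhaz` implements that pipeline end to end for epidemiologists and
climate-health researchers, together with a synthetic surveillance generator
with planted ground truth, so every stage is testable without restricted
patient data.

## What it computes

**Exposure calendars.** Per county-day flags for three hazards over the warm
season (May–September):

* *heatwave* — an event starts after 3 consecutive days with daily mean
  temperature above the day-of-year 90th percentile t90 (centered 31-day
  window pooled over the climatology years) and ends after 3 consecutive days
  at or below it;
* *drought* — weekly monitor categories; an episode runs from the first week
  at D1 (moderate) or worse to the last ≥D1 week followed by 3 None/D0 weeks,
  every day of every episode week flagged;
* *compound* — a heatwave day that is also a drought day.

A high-intensity sensitivity flag uses the excess heat factor
EHF = (T₃ − t95) · max(1, T₃ − T̄₃₀) [°C²], where T₃ is the forward 3-day
mean and T̄₃₀ the prior 30-day mean; events containing a day with EHF at or
above the county's 85th percentile of positive climatological EHF are
high-intensity.

**Bernoulli spatial scan.** Visits aggregate per county into cases (event-day
visits) and controls (non-event-day visits). Elliptical windows (shapes
1–5, circles included, capped at 25% of observations) are scored with the
one-sided Bernoulli log-likelihood ratio; inference uses 999 label
permutations (p = (1 + #{max ≥ obs})/1000); reported clusters are pruned of
member counties with single-county RR < 1.

**Interaction.** From the primary-cluster relative risks RR₁₀ (heatwave),
RR₀₁ (drought), RR₁₁ (compound):
RERI = RR₁₁ − RR₁₀ − RR₀₁ + 1, synergy index
S = (RR₁₁ − 1)/((RR₁₀ − 1) + (RR₀₁ − 1)), and the multiplicative ratio
RR₁₁/(RR₁₀·RR₀₁).

**Determinants.** Multivariate adaptive regression splines (MARS) with a
Poisson deviance lack-of-fit model county outcome counts in high-risk
clusters on a roster of community covariates (including the Index of
Concentration at the Extremes, ICE = (A − P)/T, and greenspace per person);
forward hinge growth, GCV backward pruning, and a per-variable importance
table normalized so the top variable scores 100.

See `docs/methods.md` for assumptions, defaults, and known limitations.

## Worked example

A self-contained synthetic run (20 counties, 2016–2019 warm seasons, a
planted 2×2 county block whose visit rate triples on compound days):

```bash
compoundhaz demo --out demo_run --seed 1
```

prints the interaction records, e.g. for mood disorders:

```json
{
 "mood": {
  "estimable": true,
  "rr10": 1.6457, "rr01": 1.7579, "rr11": 2.6604,
  "reri": 0.26, "synergy": 1.18, "multiplicative_ratio": 0.92,
  "additive_direction": "greater than additivity",
  "multiplicative_direction": "negative multiplicative interaction"
 }
}
```

Here the compound primary-cluster RR (2.66) exceeds additivity of the two
single-hazard RRs (RERI 0.26 > 0, S 1.18 > 1) but falls short of their
product (ratio 0.92 < 1). When any hazard lacks a significant primary
cluster the record says `"estimable": false` with the missing hazards listed
rather than silently omitting values.

`demo_run/clusters_table2.csv` holds the per-hazard cluster summaries; the
first rows from the run above:

```
hazard,outcome,rank,cases,llr,n_counties,p_value,rr
compound,mood,1,32,10.110,2,0.002,2.660
drought,mood,1,556,104.959,3,0.001,1.758
heatwave,mood,1,145,11.858,5,0.001,1.646
```

The compound primary cluster (p = 0.002, RR = 2.66) consists of two counties
from the planted block. Per-stage commands (`exposure`, `scan`, `interact`,
`mars`, `all`) operate on the same CSV schemas; `compoundhaz --help` lists
them.

Library use mirrors the CLI:

```python
from compoundhaz import RiskTriple, reri, synergy_index, multiplicative_ratio

t = RiskTriple(rr10=1.29, rr01=6.32, rr11=3.39)
print(round(reri(t), 2),                  # -3.22
      round(synergy_index(t), 2),         # 0.43
      round(multiplicative_ratio(t), 2))  # 0.42
```

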