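# mrdsurvey

Mark-recapture distance sampling (MRDS) abundance estimation for
double-observer aerial line-transect surveys, built around the 2014
springtime on-ice survey of the Kane Basin polar bear (*Ursus maritimus*)
subpopulation.

## The problem and the model

Line-transect distance sampling estimates density from the perpendicular
distances of detected animal clusters, via a detection function g(y) with
g(0) = 1. For aerial surveys of bears on sea ice the textbook assumption
that detection *on* the line is certain does not hold, so two observer
teams (front and rear seats) act as capture occasions: each team's
detection probability for cluster *i* follows

```
logit(p_i,pos) = b0_pos + b1 d_i [+ b2 x_i]
```

with position-specific intercepts, a shared distance slope, and at most one
extra covariate (distance², cluster size, activity, ice structure,
visibility, cloud cover, a 75 m rear-seat blind-spot dummy, or a
position-specific slope) — nine candidate models ranked by AICc. The
probability that at least one team sees a cluster on the line is

```
p0* = 1 - (1 - pF,0)(1 - pR,0),
```

estimated from the conditional (detected-by-at-least-one) multinomial
likelihood over capture histories. Distance-sampling detection functions
(uniform key with cosine/polynomial adjustments, hazard-rate, half-normal)
are fit to the exact distances by maximum likelihood with forward AIC
adjustment selection, giving the mean in-strip detection probability
p_d = ∫g/w. Average detectability is p_a = p0* · p_d, and stratified
abundance follows a Horvitz–Thompson estimator

```
C_S = Σ_k c_k / p_a,   C_Total = Σ_k (A_k / a_k) c_k / p_a,   N = C_Total · g
```

with a_k = 2 w L_k the strip area, g the mean cluster size, and a variance
that adds a delta-method detection component to a systematic
encounter-rate component (the "S2" estimator pairing adjacent transects),
propagated to N and summarized by lognormal intervals. Point estimates are
model-averaged with Akaike weights, including model-selection variance.

## Worked example

`examples/abundance_from_published_tables.py` runs the model-averaging and
planning arithmetic on the survey's published per-model rows:

```
p0* = 0.953 (SE 0.056) x pd = 0.571 (SE 0.151) -> pa = 0.544 (SE 0.147)
N (all 4 models) = 190 bears (SE 75; CV 0.39; 95% CI 90-399)
N (hazard-rate excluded) = 165 bears (SE 40; CV 0.24; 95% CI 103-264)
extrapolated to 27214 km2 of unsampled polynya ice: ~46 bears (95% CI 8-270)
reaching CV 25% from 39% needs 2.4x the survey effort (precision improves as 1/sqrt(n)).
```

Read: roughly 95% of clusters sitting on the transect line were seen by at
least one team, but barely half of the clusters inside the 1400 m strip
were detectable at all, so the 28 observed clusters scale up to about 190
bears — with the wide interval driven mostly by uncertainty in the
detection function. The other examples fit each stage on reconstructed or
simulated data:

- `examples/binned_sightings.py` — rebuild and re-bin the double-observer
  sighting table,
- `examples/fit_double_observer.py` — the nine-model mark-recapture set
  and model-averaged p0*,
- `examples/fit_detection_functions.py` — the four detection functions
  with AIC adjustment selection,
- `examples/simulate_and_recover.py` — synthetic surveys with known truth
  and CI coverage of the full pipeline.

A thin CLI mirrors the library (`survey validate / summarize / fit-mr /
fit-ds / estimate / simulate / run`), driven by a YAML config naming the
observation/transect CSVs and stratum areas.

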