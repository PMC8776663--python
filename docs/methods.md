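# Methods

## Detection model

The package treats a cluster of bears (an adult female with cubs, a pair of
adults, a lone bear) as the sampling unit, because detections within a
cluster are correlated. Detection is factored into two stages that are
estimated from different aspects of the data and multiplied:

1. **Mark-recapture stage (p0\*)** — two observer teams search
   independently, so the capture histories of detected clusters (front
   only / rear only / both) identify each team's detection probability.
   Each team's probability follows a logistic model in perpendicular
   distance with position-specific intercepts and a shared slope,
   optionally plus one extra covariate. The likelihood is the
   independent-observer ("io") conditional multinomial: conditioning on
   detection by at least one team removes the unobserved never-detected
   class, and P(10) + P(01) + P(11) = 1 per cluster by construction. The
   line-intercept summary is p0\* = 1 − (1 − pF,0)(1 − pR,0).
2. **Distance-sampling stage (p_d)** — a conventional detection function
   g(y) on the exact (continuous) distances, normalized to g(0) = 1, with
   mean in-strip detection probability p_d = ∫₀ʷ g / w.

Average detectability p_a = p0\*·p_d combines the stages, with the
delta-method variance var(p_a) = (p0\*)² var(p_d) + (p_d)² var(p0\*). This
mirrors the point-independence idea: the mark-recapture stage calibrates
the intercept of detectability at y = 0, the distance stage carries its
shape.

### Candidate sets and model averaging

The mark-recapture candidate set contains nine models: the base
(intercepts + distance) plus one of distance², cluster size, activity,
rough ice, poor visibility, cloud cover, a rear-seat blind-spot dummy
(coded 1 within 75 m of the line for the rear team), or a
position-specific distance slope. Models are ranked by AICc with n = the
number of detected clusters. A one-parameter addition whose AICc lands
within 2 units of the nested base model while its coefficient's |z| < 1.28
is flagged as an uninformative parameter and excluded from model
averaging; averaging otherwise uses models with ΔAICc < 4, weights
renormalized over the averaged subset, and the unconditional SE
Σ wᵢ √(vᵢ + (θᵢ − θ̄)²) that adds model-selection spread.

The distance-sampling candidate set holds the four standard shapes:
uniform key with cosine adjustments, uniform with even simple-polynomial
adjustments, hazard-rate 1 − exp(−(y/σ)^(−b)), and half-normal
exp(−y²/2σ²); Hermite adjustments are available for the half-normal key.
Adjustment series are expansions in y/w (cosine orders start at 1 for the
uniform key and 2 otherwise; polynomial powers 2, 4, …; Hermite orders
4, 6, …), rescaled so g(0) = 1. Forward selection adds one term at a time
and keeps it only when AIC improves by at least 2 — a term that cannot
beat its own parameter penalty by a full ranking unit is treated as
uninformative, the same screen used in the mark-recapture set. (Plain
strict-decrease selection is available via `min_aic_gain=0`.) Cluster size
as a log-linear scale covariate is implemented but off by default; in the
motivating survey it never improved AIC.

### Reporting line intercepts under covariate models

When the extra term is a covariate, pF,0 and pR,0 are reported as the
simple mean over detected clusters of the per-cluster probability at
distance 0 with that cluster's own covariate value, and p0\* as the mean of
the per-cluster 1 − (1 − pF,0,i)(1 − pR,0,i) (which is below the value
obtained by plugging the mean pF,0 and pR,0 into the formula, by
convexity). An inverse-p\* (Horvitz–Thompson) weighting of the same
per-cluster quantities is available via `p0_weighting="ht"`; the simple
mean is the default because the weighting used in the motivating analysis
is not documented. The blind-spot dummy is set to 0 when reporting
intercepts, so the rear intercept describes detection on the line outside
the blind spot and the dummy coefficient carries the reduction.

## Abundance and variance

Strata share a single p_a and mean cluster size (with one detection in the
low-density stratum there is nothing to estimate separately); only
encounter rates differ. Per stratum, a_k = 2 w L_k with w in km converts
effort to strip area, and C_Total scales the Horvitz–Thompson count by
A_k/a_k. Variance on the cluster scale is an exact sum of:

- **detection**: Σ (A_k/a_k)² (c_k/p_a²)² var(p_a);
- **encounter**: the among-transect "S2" estimator for systematic designs —
  transects sorted by design order form non-overlapping adjacent pairs
  (the trailing transect joins the last pair when the count is odd), each
  group contributes a length-weighted variance of n/L, groups combine with
  (L_h/L)² weights, and the rate variance is scaled to the count by L² and
  to C_Total by ((A/a)/p_a)², treating the detection correction as a
  constant since its uncertainty is already in the detection component.

Total abundance is N = C_Total · ĝ with
var(N) = C_Total² var(ĝ) + ĝ² var(C_Total), ĝ the arithmetic mean cluster
size (SE = SD/√n). Intervals assume lognormality:
(N/C, N·C) with C = exp(z √ln(1 + CV²)) and z = 1.96 at 95%. The
per-stratum density (bears per 1000 km²) carries the same decomposition,
and the low-density stratum's density can be projected onto unsurveyed
areas with its CV carried over. Survey planning uses the 1/√n law:
reaching a target CV requires (CV_now/CV_target)² times the effort.

### Goodness of fit

The mark-recapture fit is checked with a Pearson χ² on per-observer
seen/missed tables by distance bin, using conditional expected
probabilities pF/p\* and pR/p\*. Each bin's total is fixed, so a bin
contributes one free cell; adjacent bins pool until both expected cells
reach 2, and df = pooled bins (front + rear) − k. Null simulations show
the statistic's mean tracks this df. The distance-sampling fit is checked
with the one-sample Cramér–von Mises statistic on the fitted distance CDF;
its standard asymptotic p-value is exact when the comparison CDF is fixed
and conservative when the same data estimated the parameters.

## Synthetic surveys

The generator emulates the motivating design as its default: two strata
(nearshore high-density ice, ~18 870 km² at 8 bears/1000 km² with 6 km
transect spacing; offshore pack, ~9 110 km² at 1.7 bears/1000 km² at
18 km), truncation w = 1400 m, cluster sizes drawn from the observed
composition 13:9:6 for sizes 1:2:3 (mean 1.75), and binary sighting
covariates at plausible rates (rough ice 0.5, moving 0.3, poor visibility
0.2). Each stratum is laid out as a square with systematic east–west
transects; clusters arrive by a Poisson process inside the surveyed strips
only (clusters beyond w cannot enter any estimator and are not
materialized), with distances uniform on [0, w] by construction.

Detection composes an availability curve g(y) (default half-normal,
σ = 800 m, chosen so in-strip detectability sits near 0.6 as in the
motivating survey) with independent front/rear logistic detection given
availability (intercepts 1.66 and 0.98, i.e. pF,0 ≈ 0.84 and pR,0 ≈ 0.73;
shared slope −1 per km). Because availability cancels from the conditional
capture-history likelihood, the mark-recapture stage recovers the
logistic parameters, while the distance stage absorbs the product
g(y)·p\*(y)/p\*(0); p_a = p0\*·p_d then estimates the true mean detection
probability, so the full pipeline is consistent and its CI coverage can be
tested against known truth. What the generator does *not* emulate: spatial
density gradients and clumping beyond Poisson, responsive movement,
observer heterogeneity within a team, measurement error in distances, and
ferry legs — passing recovery tests therefore demonstrate internal
consistency of the estimator under the stated design, not robustness to
those field realities.

The replicate study (`recovery_study`) reruns generate → fit → estimate
per seeded replicate and reports relative bias, empirical CV, RMSE and 95%
CI coverage. Test and acceptance runs use 50–200 replicates with ~25
detected clusters each and single-detection-function pipelines
(half-normal), sizes chosen to keep the whole suite comfortably
interactive while leaving Monte-Carlo error on coverage near one
percentage point.

## Numerical choices

- Distances enter the mark-recapture linear predictor in km (coefficients
  reported per km; `coef_distance_per_m` rescales); detection-function
  scales are optimized as log(σ/w) and the hazard power as log(b − 1), so
  p_d is exactly invariant to rescaling distances and w together.
- Optimization is multistart quasi-Newton (BFGS; Nelder–Mead warm start
  for detection functions) from the null model plus jittered starts with
  the tightest practical tolerances (gtol 1e-8); ties break toward lower
  AICc, then fewer parameters. Covariance matrices come from the inverse
  observed information (numerical Hessian), and derived SEs (p0\*, p_d)
  from numerically differentiated delta-method gradients.
- ∫g is evaluated by adaptive quadrature (relative error ≤ 1e-8) with a
  fixed 2049-point Simpson grid as deterministic fallback; g ≥ 0 is
  enforced on a fixed grid through a penalty (monotonicity deliberately is
  not, matching standard practice).
- Degenerate inputs are refused loudly: empty datasets, a covariate model
  on data without (or with constant) covariates, all-identical distances,
  single-transect strata for the S2 estimator, capture histories with no
  front-only or no rear-only detections (flagged non-identifiable rather
  than silently estimated at a boundary).
- Pipeline JSON output is rounded to six significant digits so identical
  inputs reproduce byte-identical files; all simulation randomness flows
  from one integer seed.

## Known limitations

- With ~28 clusters the detection function is weakly identified; the
  hazard-rate shape in particular can drift toward implausibly low p_d
  with a huge CV, which is why the averaging-with-exclusion path exists.
- The bin-midpoint fixture reconstructed from published binned counts
  reproduces frequency tables exactly but only approximates
  continuous-distance fits; covariate models cannot be refit from it.
- The lognormal interval uses the standard z-based factor; interval
  variants based on t-quantiles with estimated degrees of freedom would
  widen small-sample intervals and are not implemented.
- Model-averaged abundance is computed by averaging per-model abundance
  rows (each already using the model-averaged p0\*), matching the
  motivating analysis; averaging p_d first and estimating once gives
  slightly different (also defensible) numbers.
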