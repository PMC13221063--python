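# Methods

## The suitability model

The package treats habitat quality for a specialist stream fish as a
product of independent unimodal responses to environmental parameters.
Each parameter gets a Gaussian curve `S(x) = exp(−(x−μ)²/2σ²)` with `μ`
and `σ` estimated as **frequency-weighted moments**, the weights being
fish abundance: a count of *w* fish at value *x* is treated as *w*
replicate observations of preferred conditions. This is the biased
(`Σw`-denominator) estimator; an unbiased reliability-weight variant is
available via `weighted_gaussian_fit(..., unbiased=True)` for users who
read abundance as precision rather than replication. Fitting demands at
least two distinct positively-weighted values; a zero-variance input
raises `DegenerateNicheError` rather than silently producing a delta
function.

Evaluation clamps *x* to the observed `[low, high]` range of the fitting
data by default, so the curve is never extrapolated beyond sampled
conditions; raw evaluation (`clamp=False`) exists for plotting. The
reported *optimal range* of a parameter is `μ ± σ` intersected with the
observed bounds — the interval where suitability exceeds `exp(−1/2) ≈
0.61`. This convention is an assumption of the package; it is consistent
with preferred-range intervals whose midpoint and half-width recover the
fitted moments exactly (e.g. a dissolved-oxygen optimum of 6.42–8.66 mg/L
with μ = 7.54, σ = 1.12).

**Substrate texture** is folded into the same 0–1 framework through a
pedotransfer step: saturated hydraulic conductivity from the Cosby (1984)
sand/clay regression (`log₁₀ Ks = −0.6 + 0.0126·sand% − 0.0064·clay%`,
coefficients pinned as module constants so the choice is auditable),
log-normalised across the site set to `(log v − log v_min)/(log v_max −
log v_min)` and floored at 10⁻³. The floor is load-bearing: the site at
the normalisation minimum would otherwise score 0 and annihilate the
geometric mean. Gravel is excluded and the sand/silt/clay fines
renormalised; only the fines enter the regression. The score is relative
to the site set being analysed, which is why it needs ≥ 2 sites and why
leave-one-out validation excludes it by default.

The composite **HSI** is the geometric mean of per-parameter scores,
computed in log space. Strictly positive inputs are a hard precondition:
a zero must be floored upstream deliberately, never averaged away
silently. Classification into five zones (Unsuitable … Highly Suitable)
uses the 20/40/60/80th percentiles of the HSI distribution itself (linear
interpolation between order statistics, pinned in config), with
left-closed intervals and a both-sides-closed top class — so a degenerate
all-equal distribution lands every site in the top class. Explicit
threshold overrides and the named preset `"hajar"` (0.47/0.51/0.59/0.75,
the published twelve-wadi survey classification) bypass the percentile
computation; the bundled survey table keeps its published labels
alongside, because two of its printed labels (K2, AW1) are inconsistent
with its printed intervals and both readings should stay reproducible.

## Diversity and the trade-off statistics

Shannon entropy uses the natural logarithm and Gini–Simpson (`1 − Σp²`)
is the Simpson form; both conventions back-solve the bundled survey table
to integer species richness (3–4 species per site), which is how they
were identified. Pielou evenness `H/ln S_obs` is **undefined** (NaN) for
monocultures rather than 0 — a monoculture is not "maximally uneven".
Bray–Curtis dissimilarity delegates to `scipy.spatial.distance`.

Correlations between HSI and diversity metrics are Pearson r with a
two-sided t-based p-value and a **percentile bootstrap CI** (default 1000
iterations) resampling whole sites, i.e. paired (x, y) rows — the unit of
observation is the site, not the individual value. A BCa variant is
available behind `method="bca"`. Degenerate resamples (zero variance) are
excluded from the CI rather than propagating NaN. The percentile CI is
mildly anticonservative below n ≈ 50; the coverage property test
therefore runs at n = 100 per trial, where the estimator is in its
validity regime.

## Validation battery

All confusion-matrix metrics come from the four counts; any metric with a
zero denominator is returned as NaN with a reason string, never as a
silent 0. The identities `TSS = sens + spec − 1` and `balanced accuracy =
(TSS+1)/2` are property-tested over random counts. The prevalence
mismatch flag raises when predicted and observed prevalence differ by
more than 10 percentage points. AUC is the Mann–Whitney U estimate (ties
half). Threshold selection scans candidate cuts at midpoints of
consecutive sorted unique scores plus {0, 1}; ties in the objective break
toward the **lower** threshold. The calibration ratio is
`(q−1)/(q+1)` with `q` the presence/background mean-suitability ratio.

The continuous Boyce index slides 10 overlapping windows (width 20% of
the score range by default) across suitability, computes the
predicted-to-expected frequency ratio P/E per window, drops windows with
zero expected frequency, and reports the Spearman correlation (average
ranks) of P/E against window midpoints. Note the null distribution of
this statistic is wide — ranks of ten near-equal ratios — so null checks
must average over replicates rather than read a single seed.

LOOCV of an unsupervised index needs a reference: the package scores
transfer against the **full-data HSI** (self-consistency), the only
well-defined reading. A failing fold (e.g. degenerate re-fit) is flagged
in the report and excluded from the summaries, never silently skipped.
R² = 1 − SS_res/SS_tot may be negative when transfer is worse than
predicting the mean.

## Extrapolation screening

MESS similarity per variable follows the percentile construction with *f*
the percentage of reference values **strictly below** the point (ties
count above; the alternative convention would shift boundary cells, so
the choice is pinned). The point score is the minimum over variables,
tagged with the most dissimilar variable. Classes: strong (< −10),
moderate (−10 ≤ MESS < 0, closed at −10), analog (≥ 0). A zero-width
reference range scores 100 on it and a −1000 sentinel off it. NODATA
(NaN) propagates through MESS, replicate CV (sample SD / mean, cells with
mean 0 excluded from the reported fraction), and the equal-interval
classifier (0.25/0.5/0.75 bounds, left-closed, top-closed).

## Conservation gap accounting

High-suitability habitat is the ≥ 90th-percentile mask of valid cells
(percentile configurable). Protection rate is a cell-count ratio times a
constant user-supplied cell area — equal-area grids are assumed; there is
no geodesic reprojection. Fold increases (`target/rate`) are reported raw
and nearest-integer rounded, as such figures are usually quoted. Wadi
density classes use km/km² bounds with medium as the closed interval
[0.0004, 0.0008]. Two easily-conflated readings of "percent of wadis
protected" are computed and labelled separately: the within-class
protection rate (protected streams ÷ streams in the class, compared
against the 50/30/10% tier targets) and the composition of the protected
network (class share of all protected streams, which sums to 100%).

## The synthetic generator

`wadihsi.synthetic` emulates a small arid-mountain stream survey.
Defaults are fixed study conditions, not tuning knobs:

- **Parameter envelopes** are realistic field ranges for Hajar Mountain
  wadis (depth 25–84 cm, width 2.5–11.5 m, velocity 0.01–0.4 m/s,
  temperature 28–31.6 °C, pH 7.9–8.6, EC 696–2610 µS/cm, TDS 351–1331
  mg/L, salinity 0.33–1.33 ppt, DO 5.8–10.4 mg/L, BOD 2.84–4.36 mg/L,
  turbidity 1.1–22 NTU); values are drawn uniformly within them.
- **True optima and widths** sit at the midpoint/half-width of published
  preferred ranges for *Aphaniops* killifish (e.g. DO μ = 7.54, σ = 1.12
  mg/L).
- **Abundance** is `17,708 × Π exp(−z²/2)` (the survey's maximum count,
  attained by a hypothetical site at every optimum) with multiplicative
  lognormal noise (σ_log = 0.3) and a floor of 1 fish after rounding.
  Because eleven independent Gaussian factors multiply, off-optimum sites
  have realistically small counts and between-site variation is large.
- **Community structure** encodes a specialisation–dominance trade-off:
  the specialist's expected share rises from 1/S at suitability 0 to a
  cap of 0.995 (kept below 1 so Shannon stays defined) as `h^γ` with
  γ = 3; the remainder splits evenly over S − 1 = 3 generalists, jittered
  by a symmetric Dirichlet when noise is on, and counts are multinomial
  (1000 individuals/site). Shannon entropy of the expected composition is
  non-increasing in h by construction, which is what makes the negative
  HSI–diversity correlation reproducible (negative in ≥ 95% of seeded
  replicates).
- **Grids** are smoothed Gaussian fields: suitability through the normal
  CDF (covers all four equal-interval classes), the protected mask by
  thresholding an independent field at its (1 − pa_fraction) quantile
  (default 5.6%, a realistic national protected-area share), density
  scaled to wadi-network magnitudes (≤ 1.2 × 10⁻³ km/km²).
- **Prediction sets**: background uniform on [0, 1/(1+s)], presence its
  mirror image — exchangeable at separation s = 0 (AUC ½), disjoint for
  s > 1 (AUC 1), monotone in between.

Everything flows from one explicit seed through `numpy.random.default_rng`;
no global RNG state. The generator emits one pooled season per site; it
does not simulate quarterly revisit structure, climate layers, hydrology,
or spatial autocorrelation among sites — so passing tests demonstrate the
*statistical machinery* is correct under the assumed response model, not
that real wadi data satisfy that model.

## Problem sizes and numerical choices

The test suite and the acceptance script run the bundled twelve-site
table exactly as published; synthetic checks use 12–200 sites, 40–50×50
grids, 500-trial coverage runs at n = 100 and 1000 bootstrap resamples —
sizes chosen to estimate each property well while keeping the whole suite
fast. Geometric means are computed in log space; percentile computations
use linear interpolation throughout; Spearman ties get average ranks;
threshold ties break low; all class intervals are left-closed with a
closed top.

## Known limitations

- The Gaussian-response assumption cannot express skewed or bimodal
  niches, and the abundance-weighted σ shrinks a few percent below the
  generating width when sampling concentrates near the optimum (the
  recovery tests compare against the analytic weighted-moment limit for
  exactly this reason).
- The texture score is relative to the analysed site set, so HSI values
  are not comparable across site sets that were normalised separately.
- LOOCV self-consistency measures transferability of the index, not
  predictive skill against independent observations.
- Gap areas assume equal-area cells; no vector GIS or per-reserve
  attribution.
- The bundled survey table stores values at published (3-decimal)
  precision; statistics recomputed from it can differ from full-precision
  originals in the third decimal (the HSI–evenness correlation computes
  to −0.590 from the rounded pairs).
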