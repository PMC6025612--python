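# Methods

## Scope and model

`pitchrisk` assesses excess lifetime cancer risk from dermal contact with
arsenic-contaminated topsoil on an irrigated sports ground. The dose model
is the USEPA soil-dermal-contact pathway:

    ADI  = C · AF · ABS · CF · SA · EV · EF · ED / (BW · AT)
    Risk = ADI · SF

All parameters enter multiplicatively (BW and AT as divisors), so risk is
monotone in each of them. Two consequences are used throughout: (i)
evaluating at all-minima / all-maxima parameter vectors yields rigorous
deterministic bounds on any Monte Carlo draw whose marginals are supported
inside those ranges (asserted as an invariant of every fit), and (ii) risk
is invariant to multiplying C by k while dividing AF by k, which the test
suite uses as a structural check.

Non-carcinogenic hazard, ingestion and inhalation pathways, and
age-stratified exposure are out of scope.

### Parameters

| symbol | meaning | default / admissible range | units |
|---|---|---|---|
| C | soil arsenic (aqua-regia-recoverable total As) | 13.14–591.31 (site survey) | mg/kg |
| SF | dermal slope factor (oral SF ÷ GI absorption 0.41) | 3.66 | (mg·kg⁻¹·day⁻¹)⁻¹ |
| AF | soil-to-skin adherence | 0.01–0.08 | mg/cm² |
| ABS | dermal absorption fraction for As | 0.03 | – |
| CF | mass conversion | 10⁻⁶ | kg/mg |
| SA | exposed skin area (clothing-dependent) | 3300–5700 | cm² |
| EV | games per visit | 1–3 | events/day |
| EF | visits per year | 3–80 | days/yr |
| ED | years of membership | 0.083–13 | yr |
| BW | adult body weight | 74.8 | kg |
| AT | carcinogen averaging time (70 yr) | 25,550 | days |

AT is sometimes tabulated with units written as "days/yr"; it is implemented
as days (70 × 365), which makes ADI a per-day dose as the equation requires.

### Monte Carlo

Site-specific parameters are propagated as **empirical distributions**
(resampling observations with replacement) rather than fitted parametric
laws, since soil concentrations and questionnaire responses are generally
right-skewed and non-normal. Default 10,000 iterations, one seeded
`numpy.random.Generator` stream per run. Parameters are drawn
independently by default; `DermalRiskModel.from_tables(..., joint=True)`
instead resamples whole questionnaire records, preserving within-respondent
correlation between SA, EV, EF and ED — arguably closer to "using the
original data distributions", offered as an option because the standard
formulation treats marginals independently.

`fit()` reports deterministic bounds computed against the published
admissible ranges (widened if data extend beyond them), i.e. the
methodology's best/worst cases; `monte_carlo_risk` alone bounds against the
supplied distributions' supports. Summaries round to 2 significant figures
(the reporting convention for risk); raw values are retained in JSON
output. Classification reports both the strict 10⁻⁶ rule and the
10⁻⁶–10⁻⁴ tolerated band, plus whole orders of magnitude above 10⁻⁶.

## Spatial interpolation

IDW with default power p = 2, all-samples neighbourhood and 5 m cells
(configurable: k-nearest or radius neighbourhoods). These defaults are the
common convention; survey reports that name IDW rarely state the GIS
parameters used, so no attempt is made to reproduce any particular
published map pixel-wise — leave-one-out cross-validation (`cross_validate_idw`)
is provided to choose p objectively. A cell centre within the snap
tolerance (10⁻⁶ m) of a sample takes the sample's value exactly, which both
implements IDW's exactness property and avoids the division-by-zero
singularity. Two distinct samples at one location are an error: QA
duplicates must be reconciled (averaged) first. Cell-centre evaluation;
NODATA −9999 per the ESRI ASCII convention; grids are written as ESRI
ASCII (human-diffable, 6 significant digits) rather than binary GeoTIFF.
Coordinates are planar projected metres throughout; no CRS handling.

## Soil statistics

- **Quartiles.** Outer-fence screening is Tukey's rule (fence = Q₃ + 3·IQR),
  so the default quartile convention is the median-split: sort, split into
  exclusive halves at the median, take each half's median (for 1..9 this
  gives 2.5/7.5). The interpolated convention (`"linear"`, numpy's default;
  3/7 for 1..9) is available because printed quartiles from surveys cannot
  be re-derived without raw data and conventions differ.
- **Flagging** uses strict `>` at the fence: a value exactly on the fence is
  retained.
- **Mean updates.** `mean_after_removal(n, mean, removed) = (n·mean −
  removed)/(n−1)` updates printed aggregate means when an outlier is
  excluded without access to raw data.
- **Group comparison.** Welch's unequal-variance t on untransformed values
  by default; a permutation test on the difference of means is provided for
  the skewed case. Zero-variance equal-mean groups return p = 1 by
  convention.
- **Mass loading.** load (kg/yr) = conc × flow × duration × events/week ×
  weeks/yr × 10⁻⁶, linear in every factor; cumulative = load × years. With
  the default regime (7.63 L/s, 30 min, twice a week, 52 wk/yr) the load is
  9.50 kg/yr at 6.65 mg/L but 8.57 kg/yr at a nominal 6.0 mg/L — the water
  concentration dominates, so both are exposed rather than one being
  presented as canonical. Note 9.5 × 13 yr = 123.5 kg; the cumulative
  operation reports exactly this product.
- "Twice a week" is interpreted as 104 irrigation events per year for the
  whole irrigated complex.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* of an irrigated-site
arsenic survey, so that passing tests demonstrate the pipeline's behaviour
on realistically structured data — not that any real site's values are
recovered:

- **Geometry.** A 250 × 188 m (47,000 m²) site; three half-hectare pitches
  (IA); the remainder NIA; a 20 × 20 m restricted farm plot inside the NIA.
  Planar metres, y north, no geodesy.
- **Design.** Stratified sampling with fixed per-zone counts (23 IA + 16
  NIA primaries by default) drawn from a candidate lattice, so zone counts
  are design constants, not random outcomes. QA duplicates at every 5th
  location are re-measurements with 5% CV multiplicative noise, averaged
  before analysis (how real duplicates were reconciled is rarely reported;
  averaging is this package's convention).
- **Concentrations.** Lognormal per zone, moment-matched to (mean, sd) =
  (138.1, 82.9) IA and (59.5, 37.7) NIA mg/kg — the minimal positive
  right-skewed law consistent with reported moments — truncated by
  resampling at mean + 3.5 sd so that, in the default dataset, only the
  injected extreme (591.31 mg/kg, placed at the farm-plot centroid) crosses
  the combined-set outer fence. Truncation biases zone means low by ~3%,
  well inside the 10% recovery tolerance verified at 100× sample size.
  Under an unlucky seed a legitimate upper-tail draw can still cross the
  fence (the fence itself is random); real surveys behave the same way, and
  the uniqueness property is asserted for the default seed.
- **Depth cores.** Exponential decay C(z) = C₀·exp(−kz) with multiplicative
  noise (CV 10%), k = ln(5)/10 per cm by default so the 0–10 cm band is ~5×
  the 10–20 cm band; six contiguous 10 cm bands to 60 cm (a hard maximum —
  deeper requests error). Only monotone decline is empirically grounded;
  the exponential form is a modelling choice.
- **Questionnaire.** 179 respondents. Clothing ensembles (sleeves × bottoms
  × socks, 8 categories) map to SA via fixed per-region increments — base
  3300 cm² (head, neck, hands) plus forearms 1200, thighs/knees 1000, ankle
  band 200 — anchored so the extreme ensembles hit 3300 and 5700 cm²
  exactly; the intermediate mapping is a documented convention
  approximating adult body-part proportions, not survey-derived. Games per
  visit ∈ {1, 2, 3} (55/30/15%); visits/yr a three-part mixture (occasional
  3–30, weekly regulars ≈ N(52, 6), intensive 61–80) bounded by [3, 80];
  membership duration 0.083 + 12.917·Beta(0.7, 1.6) yr, right-skewed with
  support spanning [1 month, 13 yr] (the club's age).
- **Water.** Channel and faucet locations, 3 replicates each, As ~ N(6.7,
  1.6) and N(6.6, 0.2) mg/L truncated positive, with typical alkaline,
  oxidising, brackish physicochemistry.
- **Determinism.** One master seed; sub-generators derive child streams via
  `SeedSequence.spawn`, so a fixed seed reproduces every table
  byte-for-byte.

Not emulated: any real site's geometry or raw data; spatial
autocorrelation within zones (draws are i.i.d. given the zone, so the
synthetic IDW maps are rougher than real ones); correlation between
questionnaire items; seasonal exposure variation. Tests passing on this
data therefore validate the *computations*, not field realism.

Known arithmetic tension carried from typical survey reporting: 39 primary
locations with every-5th duplicates cannot produce 77 surface samples; the
duplicate policy is a parameter (default every-5th → 46 surface rows)
rather than a hard-coded total.

## Numerical choices and degenerate inputs

- IDW: convexity (min ≤ value ≤ max of samples) and oracle equivalence
  against direct summation at ≤10 points / ≤100 cells (rtol 1e-10) are
  tested properties; a radius neighbourhood that captures no sample yields
  NaN for that cell.
- Quartiles need n ≥ 2; fencing needs n ≥ 4; mean removal n ≥ 2; group
  comparison n ≥ 2 per group; leave-one-out CV n ≥ 3.
- Validation errors name the offending parameter, zone, or 1-based CSV row.
- Empirical distributions must be non-empty; probability vectors must sum
  to 1 within 1e-9.

## Problem sizes

Default analyses run at the survey's natural sizes (39 soil samples, 179
respondents, 10,000 Monte Carlo iterations, ~1,900-cell rasters). The
statistical-power check uses 1,000 replicates of the two-zone comparison at
n = 23/15, and distributional recovery is verified at 100× the survey size
— sizes at which every check completes in seconds on one core while the
Monte Carlo error of the checked quantities is far below the asserted
tolerances.
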