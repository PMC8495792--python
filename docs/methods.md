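# Methods

## The survey data model

A survey record is one quadrat in one field in one year. Quadrats are
10 × 20 m (200 m²) and carry an ordinal density state 0–5; state 0 means
*Striga* was verified absent by a whole-field walk-through, a protocol
step the loader treats as already applied by the surveyor (the data are
taken at face value; no re-derivation). Field-level density is the
unweighted arithmetic mean of the quadrat states — all quadrats cover
equal area, so no weighting is defensible — and all models operate on
log(x+1) of that mean. The natural log is used; the +1 offset handles
the many zero-density fields.

Fields resurveyed under a non-cereal (non-host) crop are kept in the
dataset but excluded from density analyses; `link_years` emits every
exclusion with a reason code (`unmatched`, `non-cereal`) so the paired
sample documents itself. Change in density is second-year minus
first-year mean state, bounded in [−5, 5].

## Covariates

**Precipitation seasonality** is the coefficient of variation of the 12
monthly totals: 100 × sd/mean with the sample (n−1) sd and the mean
*monthly* total as denominator, the standard bioclim (BIO15) convention.
A literal "ratio to annual precipitation" reading would divide by the
annual sum instead; this is available as `denominator="annual_total"`
(values 12× smaller) but is not the default. The CV is invariant to
rescaling all months and to month order; it is 0 iff all months are
equal and undefined (an error) for an all-zero year.

**Nearest-neighbour density** uses the haversine great-circle distance
(sphere radius 6,371 km) within the same survey year only; distance ties
break to the lexicographically smaller field id so results are
deterministic. Only the single nearest field is used, not an average of
several.

## The composite management score

Indicator extraction from a 3-season rotation follows fixed counting
rules: fallow inclusion is a 0/1 flag; cereal years count seasons whose
main crop contains a cereal constituent (so a mixed `maize/manioc`
season counts); legume years count seasons with a legume as main *or*
companion crop, with *Mimosa diplotricha* treated as a legume and no
distinction between legume species; crop diversity counts distinct
constituent crops across mains and companions, with distinct rice
varieties as distinct crops and fallow contributing as a land-use
category. Fallow-in-diversity is configurable but on by default — with
three seasons, the observed diversity range 1–5 is only attainable if
companions and fallow contribute.

The score is the dot product of the indicators with coefficients from
one joint OLS fit of log1p density on all four indicators; the intercept
is estimated but never enters the score (the published worked totals
confirm a pure weighted sum). Scoring uses the fixed default
coefficients; refitting on a run's own data is an explicit opt-in
(`RunConfig.refit_coefficients`), because a monitoring index should not
silently re-weight itself per dataset.

The change regression is simple OLS of Δ density on the score with an F
test of the slope at (1, n−2) df, refusing constant scores.

## Sequential (type I) ANOVA

Each predictor is tested in its own three-term model, terms entering in
the fixed order Year → Effect → Year×Effect; the interaction enters
last to respect marginality. Term SS is the residual-SS drop when the
term joins the growing model; numerator df are design-rank increments
(robust to aliased levels); every F uses the full model's residual mean
square, so all three terms share one residual df. Factors are
treatment-coded with the first observed level as reference — irrelevant
to type I SS, fixed for reproducible coefficients. Design matrices are
built directly and solved with least squares; the test suite
cross-checks the decomposition against an independent nested-OLS oracle
(statsmodels `anova_lm`, type 1) to 1e-8 and verifies SS conservation
(term SS + residual SS = total SS) on every fit.

Missing predictor values are dropped per model, not listwise across the
battery, so per-model n and residual df vary between predictors — the
behaviour a mixed-provenance survey table produces. Predictors with
fewer than two observed levels are skipped with a logged warning, never
fatally. Continuous predictors enter linearly; no smoothers, no mixed
models, no ordinal-response models for the 0–5 scale, and no
multiple-testing correction are applied. Collinearity between two
climate predictors is screened with VIF = 1/(1−R²) from the OLS of one
on the other; heavily collinear pairs are reported in separate models
only.

## Synthetic landscapes

The generator emulates the study design, not any particular dataset:

* **Layout** — `n_fields` (default 220) split ~4:1 over two transects at
  1 km spacing, alternating road sides (~110 m lateral offset).
* **Climate** — along each transect, seasonality amplitude and mean
  temperature rise while altitude falls, all nearly linear in position
  with small noise; this makes seasonality CV and temperature strongly
  collinear (r > 0.8), reproducing the screening problem the battery
  must handle. Monthly precipitation is a cosine seasonal profile scaled
  to an annual total of 1,100–1,900 mm.
* **Rotations** — the surveyed (middle) season is always a cereal (rice
  0.6 / maize 0.4, the second-crop marginals of the reference transition
  counts); the preceding season is drawn from the row-normalised
  (backward) reference counts and the following season from the
  column-normalised (forward) counts, with uniform fallback for empty
  rows/columns. Companion crops: legume with p = 0.2, manioc with
  p = 0.15 per survey season.
* **Latent density** — first-year latent log1p density = baseline (1.8)
  + variety effect + legume-history effect (−0.4) + climate terms
  (+0.05 per CV point, −0.003 per m altitude, on centred covariates)
  + ρ·(previous field's latent deviation) + N(0, σ). The spatial term is
  one sweep along the transect ordering (ρ = 0.3), which produces
  neighbour correlation without solving a simultaneous spatial system —
  a documented simplification. Second-year latent = first-year latent
  + year effect (−0.3) + γ·score + N(0, σ). σ defaults to 0.7, sized so
  the spread of between-year changes matches field observations
  (roughly ±2–3 density states). Variety effects span −0.8 (resistant
  NERICA-10) to +0.4 (susceptible B22).
* **Observation model** — each quadrat adds N(0, 0.4) to the field
  latent and is discretised through plant-count thresholds (0.5, 5, 20,
  50, 150 per 200 m²): the state is the number of thresholds strictly
  below exp(latent)−1. The thresholds are fixture defaults on a
  plausible count scale, not estimates of the field protocol's
  narrative band definitions. Non-host resurveyed fields have 4
  subtracted from their latent before discretisation, so they read ~0,
  matching the observation that almost no non-cereal field carries
  emerged *Striga*; such fields are excluded from density analyses
  anyway.

### Sign convention and attenuation

γ (`mgmt_gamma`) is defined as the slope of the *latent* between-year
change on the composite score. Because all score coefficients are
negative, the field observation "higher score → larger density
increase" corresponds to γ > 0; the default −0.5 exercises the
recovery machinery at a known magnitude, and the direction property is
tested as sign(fitted slope) = sign(γ) for both signs.

The ordinal observation scale is not affine in the latent: the
thresholds are unevenly spaced in log1p units and states clamp at 0 and
5, so the regression of observed state-scale change on the score
recovers roughly 75–80% of the latent-scale γ (measured ≈ −0.39 at
γ = −0.5). Parameter-recovery tests therefore regress on the latent
ground-truth table the generator returns for exactly that purpose; the
observable-scale regression is checked for direction and significance,
not magnitude. This mirrors the real-data situation, where the ordinal
scale measures relative, not absolute, change.

### What passing tests do and do not show

The generator draws all noise as independent Gaussians, makes climate
gradients linear, ties rotations to a stationary transition process and
uses a single nearest-neighbour coupling sweep. Real survey data have
spatially structured non-Gaussian noise, observer effects, non-linear
(e.g. hump-shaped altitude) responses and temporally varying rotation
behaviour. Recovery of γ, the indicator coefficients and the null
calibration therefore validate the *estimators* under the assumed model,
not the assumptions themselves.

## Numerical and design choices

* Problem sizes in the stochastic test batteries: 100 seeds × 300-field
  landscapes for γ recovery; 50 × n = 1,000 indicator tables (σ = 0.1)
  for coefficient bias (< 5% of each effect, achieved ≤ 1.2%); 2,000
  replicates of n = 40 for null calibration (empirical rate must lie in
  [0.035, 0.065]); 200 replicates for 2-SE coverage with a 99.9%
  binomial lower bound as pass mark. All batteries are fixed-seed and
  deterministic.
* Degenerate inputs fail loudly: all-zero rainfall, constant predictors,
  saturated models, single-level factors, rank-deficient indicator
  matrices (the offending columns are named), unknown crop labels
  (listed), rotations shorter than three seasons for scoring.
* CSV round-trips are exact for integer fields and tolerance-free in
  practice for reals (pandas writes full precision; the round-trip test
  compares frames exactly).
* The reference transition counts total 281 rotations; their published
  dominance shares (44.5% cereal→cereal; 15% continuous maize; 10%
  continuous rice; 19% maize↔rice) are reproduced by `rotation_fraction`
  after the same rounding.
* The scoring worked examples reproduce the published totals for the
  four internally consistent reference rows to 5 decimal places; one
  published example row is arithmetically inconsistent (its printed
  total does not equal the sum of its printed components) and is not
  used.

## Known limitations

* The ordinal-scale attenuation above means state-scale effect sizes are
  conservative relative to latent effects; users comparing γ-like
  quantities across datasets should do so on a common scale.
* No spatial statistics beyond the nearest-neighbour covariate (no
  Moran's I, no kriging); no Markov projection of rotations; no
  seedbank dynamics (emerged plants only); no GIS export.
* The optional loader path expects the package's canonical long CSV; it
  does not auto-detect foreign schemas.
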