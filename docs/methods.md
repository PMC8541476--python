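# Methods

## The ICE regression and its assumptions

An interspecies correlation estimation (ICE) model relates the acute
sensitivities of two soil species by ordinary least squares on the log10
scale:

    log10(predicted SMAV) = a · log10(surrogate SMAV) + b

with one point per chemical tested in both species at the same endpoint
type (LC50 or mortality LOEC), both axes in log10 mg/kg dry soil.  The fit
assumes a linear log–log relation with homoscedastic Gaussian residuals and
an error-free predictor.  The second assumption is knowingly violated —
surrogate SMAVs are measurements too — which attenuates the fitted slope
toward zero; see the generator notes below.  Logarithms are base 10
throughout.

Because simple least squares is symmetric in its second moments, the two
directed fits of a species pair satisfy exact identities: both directions
share R² and p-value, the slopes multiply to R², and the MSEs stand in the
same ratio as the slopes (both equal the ratio of sample variances of the
two axes).  The test suite asserts these to 1e−9 or better; they also serve
as integrity checks on any published-style model table.

Conventions where the choice was genuinely open:

- **MSE** is the residual mean square SSE/(n−2).  Any constant-df
  convention leaves the reciprocity ratio identity intact; the residual
  mean square is the standard regression error estimate.
- **Model p-value** is the two-sided t-test of slope = 0 on n−2 df,
  identical to the regression F-test in simple regression, which reproduces
  the p-value symmetry between fit directions.
- **Exact collinearity** (SSE = 0): R² is reported as 1, MSE as 0, and the
  p-value as the smallest representable positive float, since the t
  statistic diverges.  The detection threshold is SSE ≤ 1e−14·max(SST, 1).
- **Degenerate inputs**: fewer than 3 paired chemicals or zero variance in
  the surrogate raise typed errors rather than returning a fit.

## Curation

Records are filtered in a fixed order: unit convertibility → acute
duration/endpoint filter → minimum-chemicals rule → SMAV computation.  The
duration rule is exact-match per taxon group (default 1 day for nematodes,
14 days for earthworms and springtails; potworms and woodlice also default
to 14 d, a configurable judgment since no standard duration is established
for them).  Non-standard durations such as 2-day contact tests are excluded
as not comparable to soil exposure.  A species must have data for at least
3 distinct chemicals per endpoint type, counted on acute-qualifying data,
or all its records are dropped.  SMAVs are geometric means per species ×
chemical × endpoint; life stages are pooled and no soil-property
standardization (pH, organic matter, clay) is attempted.  LC50 and LOEC
streams never mix from the SMAV stage onward.

The supported unit dialect (mg/kg, g/kg, µg/g, ng/g, µg/kg, ppm, ppb, with
ppm read as mg/kg dry soil) is itself a documented judgment: soil-toxicity
sources rarely state which units required conversion, so the table covers
the common dry-mass spellings and refuses anything aqueous, where a
soil-mass equivalent would require exposure-media assumptions.

Chemical identity is matched by hyphen-normalized CAS number when present,
else by lower-cased, whitespace-collapsed name.  Chemical forms are never
merged: distinct salts of one metal are distinct chemicals.  Binomials are
canonicalized case-insensitively with a small spelling-variant table (the
literature prints, e.g., both *Eudrilus eugeniae* and *Eudrilus euganiae*).

## Cross-validation and the fold-difference statistic

Only significant models (p < α, default 0.05) with at least 4 points are
cross-validated; eligibility is decided once on the full-data model, and
the leave-one-out refits are not re-tested for significance.  Each of the n
chemicals is held out in turn, the model refit on the remaining n−1 points,
and the held-out SMAV predicted and back-transformed to mg/kg before
scoring.  The fold difference is max(predicted/actual, actual/predicted),
always ≥ 1; "within 5-fold" is inclusive (≤ 5.0), consistent with the
framing of 5-fold as the span of interlaboratory variation.  The procedure
contains no randomness.

Group summaries average per-model success rates with equal weight by
default; a prediction-weighted (hold-out-count) option exists because
neither convention is canonical.  Pairs are classified within-taxa when
both species share an order and across-taxa when their phyla differ.

## Synthetic-data generator

The generator emulates exactly the structure the regression assumes, plus
the violations real data bring.  Each chemical c draws a latent log10
potency x_c ~ Normal(μ, τ²); species s responds with true log10 SMAV
α_s + β_s·x_c + ε, ε ~ Normal(0, σ_s²).  Each species covers a Bernoulli
fraction of the chemicals (independent thinning, so a pair's shared
fraction is the product of coverages), each covered cell emits one or more
replicate records with lognormal replicate noise, and records can be spread
over the supported unit dialect with durations chosen so default curation
retains them.  One seeded generator drives all draws; identical
(config, seed) reproduces tables byte-for-byte.

Defaults describe a realistic two-earthworm acute study: potencies centred
at 100 mg/kg (μ = 2) spanning about two orders of magnitude (τ = 1), and
species residual sd σ = 0.2 log10 units, on the order of replicate
variability in acute soil assays.

Because noise sits on both axes, the expected OLS slope of B on A is the
attenuated value β_A·β_B·τ² / (β_A²·τ² + σ_A²), not the naive ratio
β_B/β_A; recovery tests target the attenuated value, with bands frozen from
an independent Monte Carlo oracle of the sampling distribution.  The
generator is rank-1 by construction (one shared potency factor), the
simplest structure consistent with relatedness-driven correlation; it does
not mimic chemical classes, modes of action, censored values, or
soil-property effects.  Passing tests therefore demonstrate correctness of
the statistical machinery under the stated model, not robustness to every
pathology of knowledgebase exports.

## Problem sizes and numerical choices

Statistical suites use two-species studies of 30 chemicals with 100–200
seed replicates — large enough that the attenuated-slope band (half-width
0.0077 around 0.769) and the noise-monotonicity ordering of within-5-fold
means over σ ∈ {0, 0.1, 0.3, 0.6} are sharp, while the whole suite runs in
seconds.  At the highest noise level a few seeds yield non-significant
models; these are excluded from the seed-averaged success means by the same
eligibility gate the pipeline itself applies.  Presentation rounding
(coefficients to 2 decimals, p-values to 3 significant figures, success
rates to 2 decimals) is applied only at the table-formatting boundary;
internal values are never rounded.

## Known limitations

- The regression carries no prediction or confidence intervals; the
  within-5-fold LOOCV rate is the only accuracy statement.
- Attenuation from measurement error in the surrogate is documented but not
  corrected (no errors-in-variables estimator).
- Taxonomy for the within-/across-taxa split comes from the input records'
  phylum/class/order columns; inconsistent annotations will misclassify
  pairs.
- The duration filter is an exact match; windowed matching (e.g. 7–14 d
  exposures) must be expressed through configuration.
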