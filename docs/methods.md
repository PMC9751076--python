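# Methods

## Scope and data model

`divstab` analyses long-format species-level biomass tables
(plot × year × species, g/m²) from sown-richness-gradient grassland
experiments. The default design emulates a classical long-term layout: a
60-species pool in four functional groups (12 legumes, 16 grasses, 20
tall herbs, 12 small herbs), mixtures sown at 1/2/4/8/16 species with 16
random distinct compositions per level — 14 at richness 16, where a
mono-functional-group mixture of either 12-species group cannot be
assembled — spread evenly over 4 spatial blocks, plus one small
monoculture-reference plot per pool species. That yields 78 mixture/main
plots and 60 monoculture references. (Published descriptions of such
experiments sometimes count fewer main plots after later abandonments;
the builder follows the replication rules, and any real design can be
supplied as a CSV instead.) Spring and summer harvests are summed per
year on read.

## Synthetic experiment generator

The generator is first-class, tested code: it defines the conditions all
recovery tests run under. Species biomass is multiplicative log-normal,

    biomass_ijt = (m0_i/N) · exp(−max(d0 − d1·log2 N, 0)·t)
                · exp(sel_link·z_i·1[N>1]) · exp(u_t + v_it + ε_ijt),

with per-species lognormal baselines m0_i, a common year effect u_t, a
species-specific year deviation v_it shared across plots, independent
residual noise ε, and optional dropout (biomass set to 0) exercising the
monoculture-failure path. Choices and rationale:

- **Multiplicative log-normal noise** keeps biomass positive and makes
  CVs comparable across richness levels; no specific noise model is
  implied by the field data, this is the simplest one with those
  properties.
- **v_it shared across plots** means a species has one "good year"
  everywhere — precisely what makes monoculture-based relative yields
  informative about mixtures, and what generates asynchrony against the
  shared year signal u_t.
- **Richness-dependent decline** max(d0 − d1·log2 N, 0) makes
  monocultures decline fastest; with d1 > 0, RYT of an N-species plot at
  year t equals exp((d(1) − d(N))·t) in the noise-free limit, so
  complementarity strengthens with community age — the temporal structure
  the slope and path modules are tested on.
- **sel_link** couples a species' baseline productivity to its mixture
  dominance via the standardized log-baseline z_i, producing a positive
  selection effect without complementarity.

Default magnitudes (the field data imply none; chosen once as realistic
for temperate grassland and not revisited): m0 lognormal with log-mean
6.0 (≈ 400 g/m²) and log-SD 0.5; d0 = 0.06/yr so monocultures lose ≈ 6%
per year; d1 = 0.015 per log2-richness unit so a 16-species mixture is
roughly flat; σ_year = 0.2, σ_species-year = 0.3, σ_resid = 0.2 on the
log scale; dropout 2%/species-year in the full scenario. Presets:
`null` (no diversity effects, noise only), `complementarity_growth`,
`asynchrony`, `selection`, and `jena_like` (all channels, 17 years).

Note one degeneracy relevant to testing: synchrony θ is scale-invariant,
so independent noise of *any* amplitude produces the same asynchrony
structure. Species-year deviations raise asynchrony only relative to a
shared year effect; the asynchrony recovery tests therefore keep
σ_year > 0 in both arms of the contrast.

What the generator does **not** emulate: spatial autocorrelation within
blocks, temporally autocorrelated year effects, species interactions
beyond the dominance coupling, mechanistic soil feedback, or directed
extinction dynamics. Passing recovery tests therefore shows the pipeline
recovers known structure of this class, not that real data meet these
assumptions.

## Additive partition

RY_i = O_i/M_i, RYT = ΣRY_i, NE = ΣO_i − ΣM_i/N,
CE = (RYT − 1)(ΣM_i/N), SE = (N−1)·cov(M_i, RY_i − 1/N). The covariance
uses the sample convention Σ(x−x̄)(y−ȳ)/(N−1), so (N−1)·cov is the raw
cross-product sum and NE = CE + SE holds identically — this is asserted
to 1e-9 on every record. Conventions:

- **M_i** is the mean annual biomass over the species' monoculture
  plots in that year; a species with M_i = 0 (failed monoculture) is
  excluded from that plot-year's partition and N is decremented, so the
  additive identity is preserved on the used species set. NE is computed
  over the same used set.
- **O_i = 0 is kept** (RY_i = 0): failure in the mixture is information,
  failure in the monoculture is a missing denominator.
- **N_used < 2** leaves CE/SE undefined; the record is emitted with a
  reason code rather than dropped silently.
- **Windowed partition** sums O_i and M_i over the window years first and
  applies the identical formulas; under constant biomass a w-year window
  reproduces w × the annual effects, while alternating dominance turns
  yearly selection into multi-year complementarity.
- **Outlier rule**: per effect column, values outside
  Q1 − m·IQR … Q3 + m·IQR are flagged (not removed), m = 6 by default
  and configurable. Quartiles use linear interpolation; other quartile
  conventions shift fences by at most a fraction of one IQR and are
  covered by a tolerance test. Fences are pooled over years by default.
- **Community relative yield** is plot ANPP divided by the mean ANPP of
  all monoculture plots in the same year.

## Stability, synchrony, windows

Sample (n−1) standard deviations throughout; θ = σ_net/Σσ_i (the
square-root-of-squares form printed in the literature is algebraically
identical for non-negative arguments), asynchrony = 1 − θ,
CV_pop = Σσ_i/μ_net, stability = μ_net/σ_net. The identity
CV_net = θ·CV_pop is asserted at machine precision on every emitted
record. One definitional conflict in the source literature — "CV_net =
μ_net/σ_net", the *inverse* of the conventional CV — is resolved in
favour of the standard definition (cv_net = σ/μ) with stability as its
inverse, which matches every downstream use.

Sown-but-never-recorded species contribute constant-zero series
(σ_i = 0), leaving θ unchanged; an "observed species only" mode is
available. Monocultures have θ ≡ 1 and CV_pop = CV_net by construction.

Rolling windows of width w over n years give n − w + 1 windows (13
five-year and 15 three-year windows over 17 years). The non-overlapping
subset takes the maximal count k = n // w, spread evenly so the first
window starts at the first year and the last ends at the final year —
for 17 years and width 5: years 1–5, 7–11, 13–17, matching the published
three-window layout (which skips two years rather than packing at
stride 5).

## Slopes and identities

Per year, OLS fits of √ANPP, log community-RY, NE, CE, SE and log RYT on
log sown richness (outlier-flagged records excluded); per window, fits of
log μ_net, log σ_net, log CV_net⁻¹, log asynchrony, log CV_pop⁻¹ and
log θ⁻¹ on log richness, restricted to the common plot set on which all
six are positive and finite (monocultures drop out via asynchrony = 0).
On a common set, linearity of least squares makes
b_CVnet⁻¹ = b_mean − b_SD and b_CVnet⁻¹ = b_θ⁻¹ + b_CVpop⁻¹ exact; both
gaps are computed and asserted. The conventional asynchrony slope uses
log(1 − θ), which cannot satisfy the sum identity exactly — both it and
the exact log θ⁻¹ variant are reported, and the gap between the two
decompositions is emitted rather than hidden.

Absolute-effect slopes (NE/CE/SE, g/m² per log-richness unit) are
additionally divided by the year's grand-mean ANPP, since a constant
absolute slope over declining productivity is a *strengthening* relative
effect. Trends are OLS of slope on time (linear or log), two-sided
t-tests, no multiple-testing correction. Mixed-effects structure (block
and plot random effects, AR(1) residuals) is deliberately replaced by
per-time cross-sectional OLS plus trend-on-slopes: the quantities of
interest are the slopes themselves, and this keeps every step exactly
decomposable. √ANPP fits are scale-dependent (documented); all log-log
slopes are invariant to biomass rescaling.

## Path analysis

The recursive model (richness → CE, SE, ANPP; CE/SE/ANPP/richness →
population stability; richness/CE/SE → asynchrony; asynchrony +
population stability → community stability; CE↔SE and
asynchrony↔population-stability residuals free) is estimated
equation-wise: each endogenous node regressed on its parents by OLS on
standardized data. For an acyclic system whose free residual covariances
involve only terminal disturbances, these point estimates coincide with
full-information SEM estimates; a test verifies that Wright-style implied
correlations (computed recursively along directed paths) reproduce
observed richness correlations within 0.02 on data generated from the
model itself. No direct richness → community-stability edge is included:
stability is fully mediated by its two components.

Transforms before standardization: log for community stability,
population stability and windowed ANPP; windowed CE is min-max scaled to
[ε, 1] with ε = 1e-3 then log-transformed (the clamp handles the zero
minimum; ε is the package's choice where the literature is silent); SE
and asynchrony enter untransformed; richness as log. Global ML fit
indices (χ², RMSEA) and RMSEA-driven data pruning are out of scope;
extreme windowed CE/SE values are handled by the same quartile-fence
filter as the annual effects, a general procedure rather than a
dataset-specific pruning loop.

Inference is nonparametric bootstrap over rows (plots), re-standardizing
within each replicate; indirect effects are per-replicate products of
chain coefficients, so their CIs propagate the joint uncertainty.
Between-window comparisons require disjoint (plot, year) observations —
the same plots in non-overlapping windows qualify, overlapping windows
are rejected — and use the difference of the two independent bootstrap
distributions, with compact-letter groupings at α = 0.05, unadjusted.
Fewer than 10 usable rows, zero-variance nodes, and collinear parent
sets (condition number > 1e8) are hard errors.

## Numerical and degenerate-input conventions

- Quartiles: linear interpolation (numpy default).
- σ totals of exactly 0 (all species constant) and μ_net = 0 flag the
  record rather than emit infinities.
- Windows require width ≥ 2 (temporal variance undefined below).
- Bootstrap p-values are 2·min(P(b ≤ 0), P(b ≥ 0)), capped at 1;
  fixed seeds make every bootstrap exactly reproducible.
- Degenerate bootstrap resamples (a zero-variance column) are redrawn
  once; with n ≥ 10 continuous rows this is vanishingly rare.

## Problem sizes used in tests and the acceptance script

Recovery experiments use the full default design (138 plots, 17 years):
20 replicate simulations for the sign tests of the CE-slope trend and
the richness–asynchrony slope, 20 replicate datasets (n = 500) for
bootstrap-CI coverage of a known path chain, and 100 null replicates for
the type-I error of the trend test (reported against the ≤ 10/100 upper
binomial bound at the nominal 5%). These sizes give the sign tests power
near 1 under the preset effect sizes while keeping the whole suite quick
to run.

## Known limitations

- Per-year OLS ignores block structure and temporal autocorrelation of
  residuals; slope standard errors are cross-sectional only. Trend
  p-values treat yearly slope estimates as independent, which shared
  year effects violate mildly.
- Equation-wise estimation provides no global goodness-of-fit statistic;
  the implied-correlation check is a consistency diagnostic, not a fit
  index.
- The windowed CE min-max transform depends on the sample minimum and
  maximum, so standardized CE coefficients are comparable within, not
  across, windows.
- The generator's independence assumptions (see above) mean recovery
  results bound what the pipeline can do under its own model, not under
  field conditions.
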