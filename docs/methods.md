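# Methods

`foodwebkit` implements the analysis chain used in multi-year food-web
disturbance monitoring: invertebrate prey availability and fish diet
samples are converted to numeric and energetic assemblage matrices,
summarized with univariate metrics, compared with permutational
multivariate statistics, and contrasted through an energy-based prey
selectivity index. This note records the models, the defaults and why,
the numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Data model

Inputs are tidy CSV tables (UTF-8, comma, header row, `""` = missing):
a taxon catalog (rank path class→species, aquatic/terrestrial origin,
life stage), sample events (section, season, period, habitat, gear,
sampling effort), observations (one row per taxon per sample, with
optional body measurements in mm), and fish records for diet data.
Referential integrity is enforced at load: every observation must
resolve to a known taxon, sample, and (for diets) fish, and gear fixes
the effort unit (benthic/fallout per m², drift per m³, diets per fish).
Taxa identified only to a coarse rank (partially digested prey) keep
their own column when matrices are built at a finer rank, flagged
`unresolved`, rather than being discarded or guessed downward. How such
items should count toward numeric density is genuinely ambiguous in
field practice; they are counted and flagged, not reweighted.

## Energetics

Dry mass follows the standard invertebrate length–mass power law
`DM = a·L^b` (mg, L in mm), and energy is `DM × ED` with ED in J per mg
dry mass. Coefficients are user-supplied per rank-path prefix and life
stage; lookup returns the most specific matching entry and falls back
species→genus→family→order→class, preferring the exact life stage at
each level before stage-unspecific entries. The fallback is
deterministic under row permutation (entries are canonically sorted).
Energy densities quoted per wet mass are supported through the percent
dry mass column (`wet = DM / pDM`); the default pathway is per dry
mass, since sources differ and neither convention can be asserted in
general.

Unmeasured individuals (digestion makes full measurement of diet items
impossible) are imputed by a chain: mean energy of measured conspecifics
in the same sample, then the taxon mean across the data set, then the
Order mean, then a per-taxon default carried by the conversion table.
A taxon with no measured individuals anywhere and no default is an
error, not a silent zero.

Reported units follow the field convention: No·m⁻³ and J·m⁻³ for drift,
No·m⁻² and kJ·m⁻² for areal estuary gears, kJ per stomach for diets.

## Univariate metrics and tests

Per sample: numeric density, energy density, taxa richness at the finest
identified level, and the percentage of terrestrial-origin individuals
(or energy). Group summaries are unweighted means ± sample SD (n−1);
singleton groups report SD as missing. Headline declines are
`100·(1 − during/pre)`, positive = decline, rounded to whole percent
for reporting; the quantity is undefined for a non-positive baseline.

ANOVA is fixed-factor only (one-way, or two-way crossed with
interaction, Type III via sum contrasts), delegated to statsmodels OLS,
with Tukey HSD on significant terms and a compact letter display derived
from the full pairwise rejection matrix. Response transformations
(`none`, `log10(x+c)`, `arcsine-sqrt`) are explicit configuration, not
hard-coded per metric, because the appropriate variance-stabilizing
choice is data-dependent.

## Resemblance

Bray-Curtis similarity `100·(1 − Σ|x₁−x₂| / Σ(x₁+x₂))` on
power-transformed abundances (square root for drift, fourth root
otherwise, balancing common and rare taxa). A dummy species with raw
abundance 0.1 is added to every sample *before* transformation, so
pairs of empty samples are defined (similarity 100) instead of 0/0;
adding it after transformation is a one-flag change. Bray-Curtis is a
semi-metric — the triangle inequality is deliberately not asserted
anywhere.

Diet–availability overlap standardizes both assemblages to row-relative
abundance before comparison, because counts per stomach and densities
per m² or m³ are not on commensurable scales; only composition is.

Group centroids are computed in principal-coordinate space. Because
Bray-Curtis is non-Euclidean, the Gower-centered matrix is carried as
signed coordinate blocks (positive and negative eigenvalue axes);
squared centroid distances subtract the negative-block component and
are clamped at zero before the square root (the standard corrected
treatment of "imaginary" axes).

## Permutational statistics

All permutation machinery is implemented in this package (scikit-bio is
used only as an independent cross-check in the test suite).

**PERMANOVA.** With `G = −½ J D² J` and a hat matrix `H` (intercept
included), the SS explained is `tr(H G)`. Type III partial SS for a
term is the trace reduction between the full model and the model
omitting that term's sum-coded columns. Significance uses Freedman–Lane
permutation of reduced-model residuals, performed in the PCoA
coordinate blocks so that non-Euclidean structure is preserved exactly.
The P estimator counts the observed statistic, `(b+1)/(m+1)`; ties in
the permuted statistic count as ≥. Exhaustive enumeration of all row
permutations is available for small n and matches the random-permutation
estimator in the limit. In the Euclidean one-way univariate limit the
pseudo-F equals the classical ANOVA F to machine precision — this is a
standing regression test.

**ECV** (component of variation for a fixed term) is the signed square
root of `(MS_term − MS_res)/q`, with `q = N / (number of level
combinations of the term's factors)` — the balanced expected-mean-square
coefficient, with average cell size standing in for unbalanced designs.
The signed root (negative when MS_term < MS_res) follows the convention
of the reference software's output tables. The residual line reports
`sqrt(MS_res)`.

**Pairwise tests** report `pseudo-t = sqrt(F)` of the two-group one-way
test. The number of distinct relabelings is `C(n₁+n₂, n₁)`; below 40
the exact permutation distribution is enumerated and a Monte Carlo P is
reported, flagged, from a Pearson-III (shifted gamma) fit to the first
three moments of the permutation F distribution (normal fallback for
non-positive skew). Family-wise control is Bonferroni:
`α / n_comparisons` (0.05/6 ≈ 0.0083 for four periods).

**ANOSIM.** Clarke's `R = (r̄_between − r̄_within) / (n(n−1)/4)` with
mid-ranks for ties; P by label permutation. R lies in [−1, 1] by
construction with this denominator.

**SIMPER.** Per taxon j, the mean over between-group pairs of
`100·|x₁ⱼ−x₂ⱼ| / Σₖ(x₁ₖ+x₂ₖ)`; contributions sum exactly to the average
between-group dissimilarity (asserted to 1e-9 in tests). Rows at or
above 2% of the total are flagged for reporting.

**nMDS.** Kruskal stress-1 minimized by alternating isotonic regression
(disparities fit to configuration distances in dissimilarity rank
order, ties pooled — sklearn's isotonic solver) with Guttman/SMACOF
updates. The first start is the metric PCoA configuration, the rest
random; the best configuration ever visited is kept, so the reported
stress never exceeds the stress of any start. Configurations are
centered, principal-axis rotated, and sign-fixed for determinism.
`nmds_scree` seeds each dimensionality with the previous solution
padded by a zero column, guaranteeing stress is non-increasing in k.
Stress above 0.2 is flagged as an untrustworthy 2-D picture.

## Selectivity (IRI)

Per prey Order within a section × season × period group:
`IRI = F·(N + J)` with F the frequency-of-occurrence percentage, N the
numerical percentage, and J the energetic percentage (energy replacing
the classical volume term); %IRI is normalized to sum to 100 within the
group. F for diets is counted over individual stomachs (the diet-study
convention) with empty stomachs excluded from the denominator by
default; F for the environment is counted over site sample events. Both
choices are switchable, since either convention is defensible.

Selectivity coordinates are `(log₁₀ env %IRI, log₁₀ diet %IRI)`;
contributions under 0.1% are plotted at the axis floor −2, and Orders
absent from environmental sampling (plankton, fish prey) are excluded.
Points above the 1:1 line (with configurable tolerance ε, default
exact) are classified selected; below, avoided.

## Synthetic data

The generator emulates the monitoring design the analysis assumes:
impacted sections (LE, ME) and an unimpacted reference (TR), two
seasons, a pre-disturbance period plus three disturbance years, 8 drift
events per cell of roughly 30 m³ each. Per-taxon baselines are
log-normal (σ = 1) around totals of 9 aquatic and 0.9 terrestrial
individuals·m⁻³ — a strong aquatic majority with a ~10% terrestrial
fringe, typical of undisturbed drift. Counts are Poisson in
`effort × density × factor`; the default factors impose an 85%/96%/50%
aquatic decline in LE across the three disturbance years with 2–2.5×
terrestrial enrichment in the first two, and mild effects in ME — the
qualitative pattern the analysis is designed to detect. Diets draw a
negative-binomial number of prey per stomach (mean ≈ 15, shape 3, ~5%
empty stomachs) composed multinomially as availability × per-Order
weight. Ground truth is always emitted (and written to a JSON sidecar)
so tests recover it rather than re-derive it.

What the generator does **not** emulate: spatial autocorrelation among
sites, seasonal phenology of emergence, gear selectivity and mesh bias,
taxonomic misidentification, and day-to-day flow-driven variation in
drift. Passing recovery tests therefore demonstrate that the estimators
are consistent and calibrated under the assumed sampling model, not
that field data meet that model.

## Problem sizes and numerical choices

The test and acceptance workloads use deliberately modest sizes chosen
to make the statistical checks sharp: type-I calibration uses 500 null
data sets of 12 samples with 199 permutations (the `(b+1)/(m+1)`
estimator is exactly unbiased at nominal 0.05 there), decline recovery
averages 60–100 replicate simulations, exhaustive-permutation checks
use n = 6 (720 relabelings), and brute-force rank oracles go to n = 10.
Default `n_perm` for analyses is 9999. Eigenvalues below `1e-9 × max`
are treated as zero in PCoA; permutation-F ties use a relative 1e-12
guard; nMDS converges at stress change below 1e-9.

## Known limitations

- Only fixed-factor designs: no nested or random effects, no
  dispersion (PERMDISP) test.
- The Monte Carlo small-sample P is a moment-matched approximation; the
  reference implementation's exact algorithm is unpublished, so small-n
  Monte Carlo P values are comparable but not identical to it.
- Unbalanced-design ECV uses the average-cell-size coefficient; it is an
  approximation flagged as such.
- Length–mass regressions are consumed, not fitted; fitting new
  coefficients from specimens is out of scope.
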