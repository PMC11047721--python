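# Methods

## Pairwise partition of β diversity

All statistics are incidence-based: abundance input is binarized on read,
because every downstream quantity depends only on the pair counts
`(a, b, c)` — species shared, unique to the first site, unique to the
second. For each unordered pair, total dissimilarity is Sørensen
`βsor = (b+c)/(2a+b+c)`; the turnover component is Simpson
`βsim = min(b,c)/(a+min(b,c))`, which ignores richness differences; the
nestedness-resultant component is the difference `βsne = βsor − βsim`,
computed from its direct product form and cross-checked against the
difference to 1e-12 on every evaluation. Pairs involving an empty site are
undefined (a = min(b,c) = 0) and are refused: surveys are first passed
through an explicit, logged empty-site exclusion, mirroring field practice
where transects with no captures are dropped before analysis.

Survey-level summaries are means and sample SDs (n−1) over the n(n−1)/2
pairs. `βratio = βsne/βsor` is computed per pair and then averaged — the
per-pair distribution is what gives the ratio a spread — with the
ratio-of-means reported alongside. Pairs with βsor = 0 (identical
assemblages) are excluded from ratio statistics with a warning and a
count; means below 0.5 classify the survey as turnover-dominated,
otherwise nestedness-dominated.

## Explanatory distances and variable screening

Geographic distance is the haversine great-circle distance on a sphere of
radius 6 378 137 m (the geospatial-library convention), carried in metres.
Elevational distance is |Δelevation| in metres. Environmental distance is
the Euclidean distance over variables z-scored to mean 0 and sample SD 1.
The substrate composition is four proportion columns (sand, gravel, rock,
humus); the pooled environmental distance uses their standardized values,
and the substrate's own predictor matrix is the Euclidean distance between
raw proportion vectors (a dominant-category 0/1 mismatch is available by
configuration).

Before pooling, variables (plus elevation) are screened: Shapiro–Wilk
normality p-values are reported but drive no action, and Spearman rank
correlations flag pairs with |ρ| at or above a threshold (default 0.7;
chosen because a rank correlation that high makes two predictors
statistically interchangeable at these sample sizes, and a montane survey
typically flags the water-temperature/elevation pair near |ρ| ≈ 0.8).
Within a flagged pair the variable lower on a priority list (default:
elevation first, then column order) is removed; flagged pairs are resolved
in order of decreasing |ρ|, so the outcome is deterministic.

## Inference on distance matrices

Matrices are unfolded to their n(n−1)/2 lower-triangle entries in one
fixed ordering shared package-wide (identical to scipy's condensed order).
The Mantel statistic is the Pearson correlation of two unfolded matrices;
its null distribution is built by relabeling the sites of one matrix —
permuting rows and columns together, never entries independently — because
entries sharing a site are dependent. The p-value uses the add-one
estimator `p = (1 + #{r* ≥ r}) / (n_perm + 1)` (never exactly zero);
ties count as extreme. Defaults: 9999 permutations, one-sided "greater"
tail (the distance-decay alternative; two-sided available). For n ≤ 7 an
exact mode enumerates all n! relabelings and reports the exact tail
probability; tests verify Monte-Carlo/exact agreement and the test's
type-I error calibration. Distance-decay OLS fits are descriptive; their
classical t-test p is reported with an explicit pseudo-replication flag,
and significance statements belong to the Mantel/MRM permutation tests.

MRM regresses one unfolded dissimilarity matrix on several unfolded,
z-scored predictor matrices by OLS with intercept. The response matrix is
permuted (predictors fixed; permuting all predictors jointly is
distributionally identical and shares the implementation); p(R²) is
upper-tailed, p(b) two-tailed on |b|. Hierarchical partitioning fits all
2^k predictor subsets (k ≤ 16; k = 13 means 8192 small regressions,
well under a second at n = 15) and computes each predictor's independent
contribution with the subset-size weights equivalent to averaging
incremental R² over all k! orderings; the joint contribution is the
remainder of the univariate R². Two identities — ΣI = full-model R² and
I_k + J_k = univariate R²_k — are asserted on every run. Negative I
(suppressors) is reported as-is with a warning, and percentage scaling
uses the signed sum.

Every stochastic stage draws from an independent child of one master seed
(`numpy.random.SeedSequence.spawn`), so results are reproducible and
invariant to stage order or predictor order.

## The synthetic scenario generator

No field data ship with the package, so the generator produces surveys
with the statistical structure the chain is meant to detect, and returns
the planted structure as a first-class truth record. The default
("Emei-like") configuration is 18 transects evenly spaced from 485 to
2865 m along a jittered ~30 km arc (so geographic and elevational
distances correlate without coinciding), 19 species, three forced-empty
transects, and a water-temperature column calibrated by noise-scale search
to a target Spearman |ρ| of 0.81 with elevation.

The environment table holds 12 microhabitat variables. Nine load
moderately on elevation (|ρ| ≈ 0.55, deliberately below the screening
threshold) and on a shared site-quality factor (loading 0.45), with the
rest idiosyncratic: montane streams get narrower, shallower, faster,
colder, better oxygenated, and nutrient- and algae-poorer upslope. pH is
pure noise; substrate is a 4-part Dirichlet composition that coarsens
upslope.

Species occupancy is deterministic niche membership XOR symmetric
Bernoulli flips (default flip probability 0.02 — merged multi-year
incidence surveys have low presence/absence error; tests of regime
classification also use 0.05). The niche axis is
`g = elevation + 800 m × (signed microhabitat composite)`: composition
responds to the habitat a transect actually offers, not to elevation per
se, which is what lets the pooled environmental distance predict
dissimilarity beyond its elevation trend. Regimes:

- **turnover** — staggered optima with equal breadth (default 700 m) on a
  lattice extended one breadth past both gradient ends; the two edge
  species tolerate everything beyond the ends, so no site falls outside
  every niche. When the optima lattice aligns with the site lattice and
  the composite weight is zero, every site has identical richness and
  every pair has b = c, making βsne exactly zero — the noise-free
  turnover benchmark.
- **nested** — all species share the low-gradient optimum with strictly
  nested reaches ordered by site suitability, so every pair is a subset
  pair and βratio is exactly 1 at zero noise.
- **mixed** (default) — half turnover, half nested, with the nested half
  kept rare (reaches ≤ n/2) so nestedness is the minor share of total
  dissimilarity, as in sparse stream faunas; the nested suitability order
  is elevation plus independent 1000 m jitter, so which sites lose species
  first tracks elevation only loosely and the nestedness component is not
  itself distance-structured.
- **neutral** — i.i.d. Bernoulli occupancy, for null calibration.

What the generator does *not* emulate: real species identities or
abundances, detection covariates, spatial autocorrelation beyond the
one-dimensional arc, peaked (mid-elevation) richness profiles, or
phylogenetic structure. Passing tests therefore demonstrate that the
chain's machinery is correct and that it recovers structure of the planted
kind at realistic sizes — not that any particular field system behaves
this way.

## Numerical and design notes

- Sample sizes in tests and the acceptance script are the study-scale
  defaults: 15–18 sites (105–153 pairs), 19 species, 9999 permutations for
  single headline runs, 199 permutations inside repeated-calibration loops
  (the add-one estimator keeps the nominal level exact at 199).
- The partition identity tolerance is 1e-12; hierarchical-partitioning
  identities are asserted at 1e-8; standardization at 1e-10.
- Degenerate inputs are first-class: constant distance matrices are
  refused where a statistic is undefined, and the pipeline records `None`
  (NaN in tables) for cells whose response matrix has zero variance — a
  perfectly nested community has an identically-zero turnover matrix.
- z-scored ("signed") matrices are carried by the same container as plain
  distances with an explicit flag, so downstream stages can enforce
  non-negativity where it matters.
- The hierarchical-partitioning predictor cap is 16 (65 536 subset fits),
  deliberately above the 13 predictors the full analysis uses.
- Known limitations: Mantel and MRM permutation tests inherit the usual
  caveats under strong spatial autocorrelation (inflated type-I error for
  autocorrelated responses); distance-decay OLS on pairs is
  pseudo-replicated by construction; the screening rule is a hard
  threshold, not model selection.
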