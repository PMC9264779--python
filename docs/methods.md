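# Methods

This note documents the statistical machinery implemented in `fishdiv`,
the conventions chosen where the methods literature leaves latitude, and
what the synthetic test system does and does not establish about real data.

## Data model

A **checklist** is a table of species with a six-rank lineage
(phylum, class, order, family, genus, species) and optional 0/1 flag
columns. Validation enforces a tree-shaped taxonomy: each genus maps to
exactly one family, each family to one order, each order to one class,
each class to one phylum. Flags are free-form columns, so new categories
(e.g. *migratory*) need no schema change. An **occurrence matrix** is a
wide binary table (rows = species, columns = sites); a site with zero
presences is rejected by default because every downstream statistic is
undefined for it. **Site attributes** are numeric, non-negative drivers;
missing cells are allowed and propagated (never imputed), because real
driver tables have gaps. Site ordering is taken from the occurrence file
and preserved in every output, which makes runs deterministic.

## G-F indices

`D_G` is the Shannon entropy (natural log) of the genus partition of an
assemblage; `D_F` sums each family's entropy of species over genera; the
standardized index is `D_GF = 1 − D_G/D_F`, defined as 0 when `D_F = 0`.
Natural logarithms are used throughout — this is the convention under
which the published pool arithmetic (1 − 4.43/14.74 = 0.70) reproduces.
The indices are presence-only; abundance never enters. `D_GF` usually
falls in [0, 1] but is *not* clamped: a species-poor assemblage whose
families are mostly monogeneric can have `D_F < D_G` and hence a negative
contrast, which is informative (it flags exactly the situation where
within-family structure is too thin to support the comparison). Tables
are reported at 2 decimals; full precision is kept internally.

## Taxonomic distinctness

Pairs of species are weighted by the number of ranks ascended to their
lowest shared rank. The default weights are the published three-decimal
values 16.667 / 33.333 / 50.000 / 66.667 / 83.333 (same genus … same
phylum), used verbatim rather than as exact multiples of 100/6, so that a
congeneric pair scores exactly 16.667. The rank relation "same order but
not the same family" takes 50.000, the arithmetic mid-step consistent
with equal step lengths. Species pairs in different phyla (possible,
since the data model retains phylum) take 100. `PathWeightScheme.from_step`
builds exact-multiple schemes for users who prefer them.

`Δ⁺` is the mean pair weight; `Λ⁺` is the *population* variance of pair
weights about `Δ⁺` (divide by the pair count, not pair count − 1). Both
need at least two species.

The randomization funnel draws, for each subset size *m*, `n_draws`
(default 10,000) uniform subsets *without replacement* from the master
checklist — the standard scheme — and records the mean, SD, and empirical
2.5/97.5 percentiles of both statistics. Percentile limits are used
rather than normal-theory ones. Funnels are computed marginally per
statistic. Subset sums are evaluated through indicator-matrix products
(`Z W Zᵀ` diagonals), so a full funnel over a 380-species pool costs a
few seconds. `Δ⁺` is exactly unbiased under uniform subsetting (each pair
is equally likely); the test suite verifies this by exhaustive
enumeration of all C(8, m) subsets of an 8-species pool, to 1e-10.

Site classification interpolates the limits linearly between computed
sizes and uses **closed** intervals: a value exactly on a limit is
"within" (a relative tolerance of 1e-9 absorbs floating-point noise at
the collapse point m = S, where both limits equal the master value).
Sites with fewer than two species are reported unclassifiable.

## Beta-diversity partitioning

Pairwise components follow the additive turnover/nestedness split of
total Sørensen and Jaccard dissimilarity (see the formulas in the module
docstring). 0/0 forms — comparisons of identical assemblages — return 0.
The additivity identities and the ordering
`β_sim ≤ β_sor ≤ β_jac` are asserted property-style on random pair
counts at 1e-12.

The multiple-site statistics use the pair-sum generalization
(`Σmin`, `Σmax` of the asymmetric exclusive counts and the pooled-core
term `ΣS_i − S_T`); for n = 2 they reduce algebraically to the pairwise
formulas, which the tests check. A per-site summary reports, for each
site, the mean ± sample SD (n−1) of its n−1 pairwise values per
component — the shape of a per-basin similarity table. Because the
multi-site statistics are single numbers, a spread is attached by
resampling random site subsets (default 100 subsets of size n−2, seeded);
this is documented as an approximation, not an estimator with known
sampling theory. The Sørensen-family multi-site split is cross-checked
against an independent R implementation (vegan's `nestedbetasor`) in the
test suite.

## Community structure

Similarities are 1 − dissimilarity for Jaccard, Sørensen, or Bray–Curtis;
on binary data Bray–Curtis equals Sørensen similarity (the optional
log1p transform only matters for abundance inputs, where it is applied
before the Bray–Curtis comparison; on 0/1 data it is a no-op by
algebra). Clustering is agglomerative (group-average/UPGMA or complete
linkage) on 1 − similarity via scipy. Sites are sorted lexicographically
before linkage, so the tree and the group labels are invariant to input
column order; scipy's deterministic merge order resolves ties. The
default pipeline configuration is Jaccard + group average; Bray–Curtis +
complete ("furthest neighbour") is available through flags because survey
practice varies — both configurations are first-class and the choice is
surfaced, not silently resolved. `cut_at(t)` returns the connected
components merged at dissimilarity ≤ 1 − t, numbered by first site in
label order. Newick export uses ultrametric midpoint branch lengths
(child depth = merge height / 2), so tree distances equal cophenetic
dissimilarities exactly; round-trips are verified against scikit-bio's
parser.

## Mantel tests

Driver distances are |x_i − x_j|; sites missing a driver value are
dropped for that driver only (pairwise-complete testing), and exclusions
are logged and collected into the run manifest. The Mantel statistic is
the Spearman correlation of lower-triangle vectors; the null distribution
comes from jointly permuting rows and columns of one matrix — the
standard simultaneous-relabeling scheme. p-values use the add-one rule,
so p ≥ 1/(n_perm + 1) and is never 0. The default alternative is
one-tailed "greater" (do geographic differences *increase* compositional
dissimilarity?); two-sided and "less" are flags. Permutations are
vectorized (gather + row-wise ranking), so 1000 null calibrations at 999
permutations run in seconds; the suite checks the empirical type-I error
is 0.05 ± 0.02 and the null p-value distribution passes a KS uniformity
check.

The partial test uses the rank-based first-order partial correlation
`r_ab·c = (r_ab − r_ac r_bc)/√((1−r_ac²)(1−r_bc²))`, permuting the first
matrix and recomputing the statistic. When the control is rank-identical
to an input, numerator and denominator vanish together — the association
is fully explained — and the statistic is defined as 0; a vanishing
denominator with residual signal raises an error (with rank transforms
this is a numerical guard, since |r_bc| = 1 forces rank identity and
hence a zero numerator). No multiple-testing correction is applied
across the component × driver grid; raw p-values are reported and the
grid size is visible in the output table.

## Synthetic study system

The generator emulates a checklist survey over sub-basins on a
northwest→southeast gradient:

- **Taxonomy**: truncated-geometric partition of species among genera
  (shape 0.35; a few large genera, many monotypic), then genera among
  families, families among orders, orders among classes; totals are hit
  exactly at every rank. The 12-site preset forces one radiation of ≥ 30
  congeners, mimicking a cave-adapted clade, because such a clade is the
  main stress on the skew-sensitivity of `D_G`.
- **Occurrences**: per-site richness targets interpolate monotonically
  between the richness extremes. *Nested* mode ranks species once and
  gives site k the top r_k — a strict chain with zero turnover by
  construction. *Turnover* mode gives each species a contiguous window of
  sites, built from per-site window start/end counts so richness targets
  are met exactly; extra species beyond the richest site's count become
  single-boundary splits that raise replacement without disturbing
  richness. *Mixed(θ)* assigns a θ-fraction of species (and of each
  site's richness target) to the turnover construction and the rest to
  the nested one.
- **Preset**: 380 species / 158 genera / 43 families / 17 orders over 12
  sites with richness 185 → 18, mixed assembly at θ = 0.75. θ was
  calibrated once by simulation: the turnover share of multi-site
  dissimilarity grows with θ and is already ≈ 0.84 at θ = 0.75 because
  the steep richness gradient itself generates replacement structure, so
  0.75 is the admissible value closest to the replacement-dominated
  regime being emulated, and it is fixed. The preset ships with a
  published table of per-sub-basin drivers (length, area, gradient,
  precipitation, temperature, runoff, altitude — one area cell missing,
  which exercises the pairwise-complete Mantel path). Endemic flags go to
  single-site species; cave/threatened/alien flags are drawn at the pool
  fractions 83/380, 49/380, 18/380.

Regime-recovery tests check the decomposition against the generator:
strict nested chains give multi-site turnover exactly 0; pure-turnover
data give a turnover share ≥ 0.9 (tested at a mild richness gradient,
30–90 species per site — a steep gradient necessarily adds a nestedness
component, since richness differences are what nestedness measures); the
mixed preset gives turnover > nestedness in both families.

**What the synthetic system does not show.** Windows on a 1-D gradient
cannot mimic karst-driven spatial structure (disjoint underground
refugia), taxonomy names are arbitrary, and flag assignment (other than
endemism) is random rather than phylogenetically clustered, whereas real
cave lineages concentrate in few genera. Passing tests therefore
establish the correctness and calibration of the statistics, not any
biological claim about a particular fauna.

## Numerical and reporting conventions

- Tables round at 2 decimals (indices) or 4–6 (matrices); internal
  computation is double precision throughout.
- All randomness flows from `numpy.random.default_rng`; the pipeline
  derives stage seeds from the master seed via `SeedSequence`, records
  them in the manifest, and produces byte-identical outputs for equal
  seeds.
- Funnel default 10,000 draws; Mantel default 9999 permutations;
  multi-site resampling default 100 subsets of size n−2. Test and
  example runs use smaller draws where the check is structural rather
  than distributional.

## Known limitations

- Abundance-weighted distinctness (Δ, Λ) and abundance-based beta
  decompositions are out of scope; everything is presence-only.
- The multi-site ±SD via subset resampling has no exact sampling
  interpretation; treat it as a stability diagnostic.
- No synonym resolution or name validation against external taxonomic
  databases; the checklist is trusted after structural validation.
- The order-level percentage conventions in historical survey reports
  vary (denominators sometimes count native species only); this package
  always uses the total species count of the supplied checklist and says
  so in the output header.
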