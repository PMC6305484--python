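# Methods

This note records the statistical definitions, parameter defaults and
numerical choices implemented in `spoilcom`, and the rationale for each.

## Study design and data model

The analysis targets a two-factor field design: stations are classified by
**substrate** (ST = coal-mine spoil tip, PE = peripheral native soil) and
**vegetation cover** (B = bare, M = meadow, S = shrub, T = tree).  The
default synthetic design has 81 stations (ST 37 / PE 44; per-cover cell
counts ST {B 11, M 9, S 3, T 14} and PE {B 5, M 23, S 5, T 11}) with five
soil-core replicates per station.  Replicates are pooled by summation to
station level before any analysis; all tests operate on stations, the
independent sampling units.

Two standard filters are applied after pooling:

- species whose grand total is **below 10 individuals** are removed
  (singletons and near-singletons carry no distributional information for
  IndVal or binomial tests);
- stations with **fewer than 2 individuals** are removed (their
  presence/absence distances to all other stations are degenerate, and
  Bray-Curtis is undefined for an all-zero row).

Both thresholds are strict (`< 10`, `< 2`) and configurable.

## Distances and ordination

Bray-Curtis dissimilarity is computed with `scipy.spatial.distance.pdist`;
the Sorensen dissimilarity is Bray-Curtis on the presence/absence
transform.  NMDS uses `sklearn.manifold.smacof(metric=False)` restarted
from `n_starts = 100` random configurations (run seed for start *r* is
derived as `seed * 100_003 + r`, so runs are independent but fully
reproducible).  Stress is recomputed by our own Kruskal stress-1

    stress = sqrt( sum (d_hat - d_conf)^2 / sum d_conf^2 )

with the monotone regression fitted by `sklearn.isotonic.IsotonicRegression`
under the **primary** approach to ties (tied dissimilarities are ordered by
their fitted values first, so ties are free to untie).  Numerical choices:

- SMACOF convergence `eps = 1e-12`, `max_iter = 500`.  The sklearn default
  `eps` stops far from the optimum on exactly embeddable data (observed
  stress ~7e-4 where 0 is attainable); at 1e-12 the same cases reach
  stress below 2e-6 at negligible extra cost.
- A solution is reported `converged` when two independent starts agree to
  `1e-6` in stress and `1e-3` in Procrustes residual; otherwise the best
  of all starts is returned with `converged = False` (stress is still
  valid — convergence is a diagnostic, not a gate).
- Stress above 0.3 triggers a warning (a configuration that poor is
  conventionally considered close to arbitrary).

Configurations are compared with `scipy.spatial.procrustes` plus a
row-permutation test of the Procrustes `m^2` statistic.

## PERMANOVA

For n stations in a groups with squared distances `d_ij^2`:

    SS_T = (1/n) * sum_{i<j} d_ij^2
    SS_W = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    pseudo-F = ((SS_T - SS_W)/(a-1)) / (SS_W/(n-a))

The p-value comes from free permutation of group labels with the add-one
rule, `p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`; the default
`n_perm = 200` follows common practice for screening many strata and gives
a minimum attainable p of 1/201 ~ 0.005.  Substrate effects are tested
overall and within each cover stage; cover effects within each substrate.
Strata in which any group has fewer than 2 stations are reported as
skipped rather than tested.  Implementation is our own (vectorized
per-group block sums); `scikit-bio`'s PERMANOVA is used in the test suite
as an independent oracle only.

## Indicator values and species classification

For species *i* and group *j*: specificity `A_ij` uses the **total
abundance** denominator (individuals of *i* in *j* over individuals of *i*
everywhere; the per-group-mean variant is available behind
`denominator="group_mean"`), fidelity `B_ij` is the occupied fraction of
the group's stations, and `IndVal_ij = 100 * A_ij * B_ij`.  Significance
permutes station labels (default 999 permutations, add-one rule) with the
species' maximum IndVal over groups as the statistic.

Species without a significant IndVal are assigned a preferred habitat by
an exact two-sided binomial test (`scipy.stats.binomtest`): the favored
group maximizes the observed/expected abundance ratio, successes are the
individuals found there, and the null probability is that group's share of
stations — so unbalanced designs are corrected for.

Two decision trees qualify each species at `alpha = 0.05`:

- **substrate**: significant IndVal for ST -> *pioneer* (if found in ST
  only) or *stenoecious*; significant IndVal for PE -> *colonizing*;
  otherwise a significant binomial preference -> *opportunist* for the
  favored substrate; no signal -> *euryecious*.
- **cover**: significant IndVal for one cover -> *exclusive*; otherwise a
  significant binomial preference -> *elective* when the species occurs in
  exactly two covers, *preferring* when in more; no signal (including the
  edge case of a species present in a single cover without significance)
  -> *indifferent*.

The cover tree uses its own permutation seed (`seed + 1`) so the two trees
are independent but jointly reproducible.

## Rank tests on soil variables

Soil variables (5 granulometric fractions, nitrogen, organic matter, pH,
C/N) are compared ST vs. PE with Mann-Whitney U
(`scipy.stats.mannwhitneyu`): the **exact** null distribution when
`n1 + n2 <= 20` and there are no ties, the normal approximation with tie
and continuity corrections otherwise; an all-equal degenerate input
returns p = 1 with a warning.  Comparisons are run overall and within each
cover stage.

## Diversity profiles

Hill numbers `qD = (sum p_s^q)^(1/(1-q))` are evaluated on the grid
q = 0 to 4 in steps of 0.25; orders within 1e-9 of 1 are routed to the
analytic limit `exp(H)` to avoid the 0/0 exponent.  Group profiles pool
all stations of a group into one assemblage before profiling (the
alternative, per-station profiles, is behind `pooled=False`); pooling is
the default because the cover cells are too unbalanced for per-station
averages to be comparable.  Profile comparison declares dominance only
when one profile is above the other at **every** grid order (tolerance
1e-12); otherwise the crossing intervals are reported.

## Synthetic community generator

Counts for species *s* at a replicate of station *u* are negative binomial
with mean `mu_s * e_s(substrate(u)) * f_s(cover(u))` and dispersion `k_s`
(parameterized as `rng.negative_binomial(k, k/(k+m))`).  Optional
per-(substrate, cover) cell overrides allow interactions — the shipped
fixture uses them to fade the substrate contrast under tree cover,
emulating convergence of assemblages in closed vegetation.  A small leak
probability (0.01) plants single stray individuals in structurally zero
cells, so exclusivity is realistic rather than absolute.  What the
generator does **not** emulate: spatial autocorrelation between
neighboring stations, temporal variation between sampling campaigns, and
species interactions; all counts are conditionally independent given the
design.

Pools: `default_pool` (39 species, scaled to ~12.5k individuals, with a
rare tail near the filtering threshold), `strong_effect_pool` (planted
effects >= 10x with floor mean 5, used for recovery validation),
`null_pool` (no structure, used for type-I calibration), `fixture_pool`
(the demonstration survey: richer peripheral fauna, substrate specialists,
tree-cover convergence).  Soil variables are truncated-normal draws per
substrate with the five granulometric fractions renormalized to
1000 g/kg, three samples per station.

## Problem sizes and budgets

Defaults are sized for interactive use: the full pipeline on the
81-station fixture (100-start NMDS, 7 PERMANOVAs at 200 permutations,
999-permutation IndVal for both trees) runs in about half a minute; the
shipped demonstration config uses 25 NMDS starts.  The validation suite
calibrates type-I error on 500 simulated null datasets and recovers
planted specialists across 20 simulated surveys within a few minutes.

## Limitations

- PERMANOVA with free permutation tests the marginal effect per stratum;
  no restricted/blocked permutation scheme is implemented.
- The binomial preference test conditions on total abundance and ignores
  overdispersion, so it is anticonservative for strongly clumped species —
  which is why it is only consulted when the (permutation-based) IndVal
  test is not significant.
- NMDS convergence across random starts is a heuristic; for small n the
  stress surface can have symmetric minima that never agree to 1e-6, in
  which case the best solution is still returned.
- Profile dominance is evaluated on the q grid, not symbolically; a
  crossing entirely inside one grid step (0.25) would be missed.
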