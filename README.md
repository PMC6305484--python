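# spoilcom — community assembly of soil microarthropods on coal-mine spoil tips

`spoilcom` is an analysis toolkit for a classic question in restoration
ecology: when mining waste is dumped into spoil tips and left to
revegetate, do the soil animal communities that assemble on the spoil
converge on those of the surrounding native soils, or does the substrate
keep its own fauna?  The package implements the full analytical chain used
in field studies of springtail (Collembola) assemblages sampled on
spoil-tip versus peripheral stations across a vegetation-succession
gradient (bare ground, meadow, shrub, tree cover):

- **Community data handling** — station x species count matrices with
  replicate soil cores pooled per station, rare-species and sparse-station
  filters, presence/absence conversion (`spoilcom.community_data`).
- **Ordination** — Bray-Curtis and Sorensen distances, non-metric
  multidimensional scaling (NMDS) with multi-start optimization and
  Kruskal stress-1, Procrustes comparison of configurations
  (`spoilcom.ordination`).
- **Community-level tests** — permutational MANOVA (PERMANOVA) on any
  distance matrix, overall and within strata; Mann-Whitney U comparisons
  of soil variables (`spoilcom.community_tests`).
- **Indicator species analysis** — Dufrene-Legendre indicator values
  (IndVal) with permutation significance, exact binomial habitat-preference
  tests, and the two decision trees that qualify every species with respect
  to substrate (pioneer / stenoecious / colonizing / opportunist /
  euryecious) and vegetation cover (exclusive / elective / preferring /
  indifferent) (`spoilcom.indicator`).
- **Diversity profiles** — Hill numbers of any order q and profile
  dominance comparisons (`spoilcom.diversity`).
- **Synthetic surveys** — a negative-binomial community generator over the
  81-station two-factor design, with planted species archetypes and known
  truth labels, used for validation and as a shipped demonstration dataset
  (`spoilcom.synthetic`).
- **Pipeline and CLI** — a configurable end-to-end analysis
  (`spoilcom.pipeline`, `spoilcom report`) plus subcommands for each stage
  (`spoilcom simulate|ordinate|permanova|indval|classify|diversity|soils`).

## The statistics in brief

For species *i* and station group *j*, the indicator value combines
specificity and fidelity:

```
A_ij   = N_individuals(i, j) / N_individuals(i, all groups)
B_ij   = N_stations(i, j)    / N_stations(j)
IndVal = 100 * A_ij * B_ij
```

IndVal is 100 exactly when a species occurs in every station of one group
and nowhere else.  Significance is assessed by permuting station labels
(999 permutations, add-one rule).  Habitat preference of non-indicator
species uses an exact two-sided binomial test of the individuals found in
the favored habitat against that habitat's share of stations.  Community
structure is tested by PERMANOVA: with total sum of squared distances
`SS_T = (1/n) * sum_{i<j} d_ij^2` partitioned into within- and
between-group parts, `pseudo-F = (SS_A/(a-1)) / (SS_W/(n-a))` is compared
to its free-permutation null.  Diversity uses Hill numbers
`qD = (sum_s p_s^q)^(1/(1-q))`, whose profile over q makes "more diverse"
a partial order: one assemblage dominates another only if its profile is
above at every order.

## Worked example

The numbered scripts under `analysis/` run the complete study on the
shipped fixed-seed demonstration survey (81 stations = 37 spoil-tip + 44
peripheral, four cover stages, five soil cores per station):

```
python analysis/01_simulate_survey.py
python analysis/02_ordination.py
python analysis/03_community_structure.py
python analysis/04_indicator_species.py
python analysis/05_diversity.py
python analysis/06_soils.py
```

Step 1 reports the filtered dataset — `stations: 81  species kept: 25`,
`individuals after filtering: 14687`.  Step 2 finds a well-resolved
two-dimensional ordination, `NMDS stress (Kruskal stress-1): 0.0266`.
Step 3 recovers the planted structure — a strong substrate effect that
disappears under tree cover, where the generator plants converged
communities:

```
substrate_overall        F =   90.21  R2 = 0.533  p = 0.0050 **
substrate_within_B       F =   40.74  R2 = 0.744  p = 0.0050 **
substrate_within_M       F =  114.84  R2 = 0.793  p = 0.0050 **
substrate_within_S       F =   52.67  R2 = 0.898  p = 0.0149 *
substrate_within_T       F =    1.65  R2 = 0.067  p = 0.1393 NS
cover_within_PE          F =   70.56  R2 = 0.841  p = 0.0050 **
cover_within_ST          F =    7.38  R2 = 0.401  p = 0.0050 **
```

Step 4 classifies the 25 species —
`substrate qualifications: {'stenoecious': 16, 'pioneer': 5, 'euryecious': 4}`
and
`cover qualifications: {'exclusive': 16, 'preferring': 5, 'indifferent': 4}`
— and step 5 shows the peripheral native-soil assemblage is unambiguously
more diverse than the spoil-tip one (`PE: expH = 18.66, invSimpson = 16.15`
vs. `ST: expH = 9.72, invSimpson = 5.84`; `PE vs ST -> A_dominates`, i.e.
the PE profile is above the ST profile at every order q).  Step 6 confirms
the planted soil contrast: the spoil substrate is much coarser (coarse
sand 480 vs. 160 g/kg, p < 1e-37) while pH does not differ (p = 0.40).

The same pipeline runs in one shot with
`spoilcom report --config <config.yaml> --out <dir>` or from Python via
`spoilcom.pipeline.run_full_analysis(fixture_config())`.

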