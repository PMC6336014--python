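# germfda

Functional data analysis of seed germination time courses, built for studies
of **physical seed dormancy** (water-impermeable seed coats) screened under
alternating temperature regimes. Given daily cumulative imbibition counts
per accession, the package fits penalized B-spline germination curves,
classifies accessions into dormancy categories, tests spatially corrected
associations with the environment of origin, partitions explained variation
between environment and space, compares ecological niches between dormancy
groups, and relates dormancy to seed-coat traits.

## Who it is for

Seed biologists and ecologists running germination screens of georeferenced
wild accessions (the design it targets: ~100 accessions, 25 seeds x 2
replicas, scored daily for 28 days under two day/night regimes, 25/15 °C and
35/15 °C), who want a reproducible pipeline from raw daily counts to
dormancy classes, environmental association tests and niche overlap — plus a
synthetic-study generator so every stage is testable without any data
download.

## The model

**Germination curves.** The cumulative count of imbibed seeds for one
accession is treated as discrete observations of a non-decreasing function
of time, the *absolute germination distribution function* (AGDF)
`s(t)` on `[0, 28]` days. `s` is a degree-4 spline on equispaced knots
(interior knots every 2 days → an 18-dimensional B-spline basis), fitted by
penalized least squares

```
min_c  Σ_i (y_i − s(t_i))²  +  λ ∫ (s′(t))² dt ,   s(t) = Σ_j c_j B_j(t)
```

with a `(0, 0)` anchor (seeds start ungerminated) and λ chosen by
generalized cross-validation. The coefficient vector `c` is a multivariate
descriptor of the whole germination pattern — final fraction *and* speed —
which single numbers (final %, LT50, MGT, CV; all also provided) cannot
separate. The area under the AGDF (composite trapezoid) aggregates both.

**Dormancy classes.** Accessions are clustered by UPGMA on Euclidean
distances between descriptors (B-spline coefficients per treatment; the
`(AUC₂₅, AUC₃₅)` pair for combined treatments) and clusters are labelled
non-dormant (N), temperature-responsive (R) or dormant (D) from their mean
final germination under the two regimes.

**Space and environment.** Moran's I correlograms over ten equal-frequency
distance classes (largest excluded, randomization p, Bonferroni global
verdict) test spatial structure; Dutilleul's modified t-test corrects
axis–environment correlations for shared spatial autocorrelation via an
effective sample size; PCNM spatial eigenvectors and redundancy analysis
(RDA) with Ezekiel-adjusted R², forward selection (999-permutation tests,
FDR adjustment) and pure/shared variance partitioning quantify how much of
the germination pattern environment and space explain.

**Niches and traits.** Suitability surfaces per dormancy group (built-in
climate-envelope baseline, or any externally produced raster) are compared
with Schoener's D and Hellinger I over a 300-km background buffer, with
Warren-style equivalency permutation tests. Seed-coat thickness is compared
across categories by Kruskal–Wallis; dormancy category (ordered D < R < N)
is regressed on seed morphology by proportional-odds ordinal logistic
regression with AIC ranking; the soluble/insoluble proanthocyanidin ratio is
analysed by AN(C)OVA with total PA as covariate, including the custom
D+R vs N contrast.

## Worked example

Simulate a complete synthetic study (97 accessions in three latent classes,
spatially structured environment with one class-linked field, class-linked
traits), then run the chain:

```bash
germfda simulate --seed 1 --out sim97
germfda fit sim97/germination.csv --out descriptors.csv
germfda classify descriptors.csv --out classes.csv
germfda ordinate descriptors.csv --out scores.csv
```

which prints

```
wrote synthetic study (97 accessions) to sim97
fitted 97 accessions -> descriptors.csv
classified 97 accessions -> classes.csv
PC1 84.3%  PC2 14.2% of total variation
```

`classes.csv` recovers the generating split exactly at this seed — 28 N, 40
R, 29 D — and PC1 of the B-spline coefficient matrix (84.3% of variation) is
the *germination responsivity* axis ordering accessions from dormant to
non-dormant. `germfda partition`, `germfda niche`, `germfda traits` and
`germfda run-all` continue the chain; the same functionality is available as
a library (`germfda.fit_agdf`, `germfda.run_full_analysis`, ...), with the
fit-shaped components exposed as scikit-learn-style estimators
(`PenalizedBSpline`, `UnstandardizedPCA`, `RDA`, `ProportionalOddsModel`,
`ClimateEnvelopeModel`).

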