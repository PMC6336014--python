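# Methods

This note records the models and procedures germfda implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Germination curve model

Daily cumulative imbibed-seed counts `y_i` at days `t_i = 1..28` are
smoothed into an absolute germination distribution function (AGDF), a
degree-4 spline `s(t) = Σ_j c_j B_j(t)` on a clamped B-spline basis,
minimizing

    Σ_i (y_i − s(t_i))² + λ ∫₀²⁸ (s′(t))² dt .

Choices:

- **Knots.** Equispaced interior knots every 2 days on `[0, 28]` (14
  spans), giving an 18-dimensional basis: enough resolution for the
  fastest imbibition fronts observed at daily scoring, few enough that the
  normal system stays well-conditioned with 29 observations. Both spacing
  and an explicit knot vector are configurable.
- **Penalty.** First-derivative L2 norm for germination curves: the AGDF
  itself should be flat where nothing happens, and the penalty's null
  space (constants) matches a finished or never-starting curve. The
  scatterplot smoother (`smooth_regression`, used for responsivity ~
  environment fits) uses a second-derivative penalty instead, whose null
  space is the straight line — so infinite smoothing recovers the
  ordinary least-squares line, the natural degenerate limit for a
  regression smooth.
- **λ.** Generalized cross-validation over a 33-point log grid
  `10⁻⁴..10⁴` by default; a fixed λ override exists for exact
  reproducibility of a published fit.
- **Anchor.** A `(0, 0)` pseudo-observation is prepended: seeds start
  ungerminated, and the anchor gives every accession the same integration
  domain for AUC comparisons.
- **Monotonicity.** The AGDF is non-decreasing in principle but the fit is
  unconstrained; a diagnostic warns when the fitted derivative dips below
  −0.02 × seeds_total on a 0.1-day grid, and an isotonic (running-maximum)
  adjustment of evaluations is available before integration. An
  unconstrained fit keeps the estimator linear in the data (used by the
  linearity property test) and preserves the interpretation of B-spline
  coefficients as local curve level.
- **Replicates.** The two replicas are summed into one series per
  accession × treatment (doubling `seeds_total`); per-replicate mode is
  available.
- **Degenerate inputs.** All-zero counts give exactly zero coefficients
  (the normal equations' right side vanishes); constant series are
  reproduced exactly (zero residual, zero penalty). Fits with fewer than
  two distinct times are rejected. Near λ = 0 the solve applies one step
  of iterative refinement because the normal equations become
  ill-conditioned.

Classical indices: final fraction; AUC by composite trapezoid of the
piecewise-linear interpolant anchored at `(0, 0)`; LT50 as the linearly
interpolated first crossing of half the final count (the observation day
itself when the level is hit exactly); MGT as the increment-weighted mean
germination day; CV = 100/MGT. All three time-based indices are NaN (not
zero) when nothing germinated.

## Dormancy classification

UPGMA (average linkage) on Euclidean distances; per-treatment analyses use
the B-spline coefficient vectors, the combined analysis the
`(AUC₂₅, AUC₃₅)` pair. scipy's linkage provides the agglomeration (its tie
handling is deterministic for a fixed input order; accession ids are sorted
upstream). Cutting the tree into `k` clusters, each cluster is labelled
from its mean final germination: N when both regime means ≥ 0.80, D when
the 35/15 mean < 0.40, R otherwise. The dormant cutoff sits mid-gap
between the dormant response level (dormant groups germinate up to
~20–28% at 35/15) and the released level of responsive groups (~60–80%):
placing the boundary at 0.20 itself — on top of the dormant class's own
response level — would bisect that class, which is exactly what the
end-to-end recovery tests showed before the cutoff was moved. Both
thresholds are configurable. Finer cuts (`subgroup_k`) reproduce
subgroup-style labels (N1, N2, …) as secondary annotations.

## Spatial statistics

- **Distances.** Spherical haversine, Earth radius 6371.0088 km. Adequate
  at 5-km buffer and continental class-width scales; no ellipsoid, no
  projections.
- **Distance classes.** Ten classes with equal pair counts (quantile
  boundaries — hence unequal widths), largest class excluded from
  testing; equal-width and explicit-boundary overrides exist.
- **Moran's I.** Binary within-class weights; randomization p-values (999
  permutations, two-sided around E[I] = −1/(n−1)) rather than the normal
  approximation, because n ≈ 100 and the rest of the pipeline is
  permutation-based anyway. The correlogram is globally significant when
  any tested class beats the Bonferroni level α/(tested classes).
- **Dutilleul's modified t.** The Pearson correlation is unchanged; its
  df are replaced by an effective sample size
  `n̂ = 1 + tr(B Rx B) tr(B Ry B) / tr(B Rx B Ry B)` (B the centering
  projector), which is n when both processes are white. Rx and Ry are
  estimated two ways from the same distance-class correlogram: (a) binned —
  every pair gets its class's Moran's I, bias-corrected by +1/(n−1) and
  clipped to [−1, 1]; (b) profiled — an exponential decay `exp(−d/φ)` with
  φ chosen by weighted least squares against the binned correlogram,
  modelling the centering offset (an empirical correlogram estimates the
  correlation minus its pair-weighted mean, which is why binned estimates
  can never average positive and systematically under-correct under
  strong, uniformly positive autocorrelation); the identity wins when it
  fits better. The smaller of the two effective sample sizes is used.
  The acceptance suite verifies the resulting operating characteristics:
  type-I error at or below 0.08 under a shared exponential-covariance null
  with range half the domain extent — where the classical t-test is
  grossly liberal — and mean n̂ within 10% of n for white noise.
- **PCNM.** Truncation at the longest minimum-spanning-tree edge (keeps
  the neighbour graph connected); larger distances replaced by 4× the
  truncation (the originating convention); double-centered PCoA;
  eigenvectors with positive eigenvalues returned in decreasing-eigenvalue
  order with a largest-entry-positive sign rule.
- **Buffer extraction.** Mean of unmasked cell centers within a great-circle
  radius (default 5 km), errors on empty buffers and out-of-extent points.

## Ordination and variance partitioning

Collinearity pruning removes, while any pair has |r| ≥ 0.90, the member of
the worst pair with the larger mean absolute correlation to everything
else (constants first), logging each removal. PCA of the (horizontally
concatenated, both-treatment) B-spline coefficient matrix is
covariance-based — centered, never scaled, since the coefficients share
units — with a deterministic sign rule; the pipeline additionally orients
PC1 to correlate positively with mean final germination so "responsivity"
always increases toward non-dormancy.

RDA is multivariate least squares followed by SVD of the fitted values;
explained variation uses Ezekiel's adjustment
`1 − (1 − R²)(n − 1)/(n − p − 1)`. Partial effects residualize both Y and
X on the covariates; partial adjusted R² is computed as semipartial
differences of Ezekiel-adjusted values, and the two-set partition is
pure(X1) = adj(X1∪X2) − adj(X2), shared = adj(X1) + adj(X2) − adj(X1∪X2)
(an algebraic identity ties the three to adj(X1∪X2) exactly; the shared
fraction is reported untested, as it is not permutable). Permutation tests
permute rows of the — already residualized, Freedman–Lane style — response
(999 draws; p = (1 + #{F* ≥ F})/1000). Forward selection uses double
stopping: a candidate must pass its conditional permutation test at
α = 0.05, and once the cumulative adjusted R² reaches the full-candidate
model's adjusted R², no further variable is added (the crossing variable
itself, being significant, is kept — a full model padded with noise
candidates can have a *lower* adjusted R² than one strong predictor, so
rejecting the crossing variable would discard genuine signal).
Benjamini–Hochberg FDR is applied to selection p-values.

## Niche overlap

Suitability surfaces are normalized to probability surfaces over the
background (cells within 300 km of any group occurrence);
`D = 1 − ½ Σ|p₁ − p₂|` and `I = 1 − ½ Σ(√p₁ − √p₂)²`. The built-in model
is a transparent climate envelope: per variable, suitability 1 inside the
central 5th–95th percentile envelope of values at the occurrences,
tapering linearly to 0 at the observed min/max; cell suitability is the
product over variables. It is deliberately simple — the scientific content
here is the overlap and equivalency testing, and the model slot accepts
externally produced suitability rasters (e.g. from a maximum-entropy
model) through the same interface. The equivalency test pools both groups'
occurrences, repartitions at random preserving sizes, refits and
recomputes D and I (default 100 replicates; one-sided: observed overlap
below the null signals non-equivalent niches). A group whose envelope
admits no cell has an empty predicted niche and overlap 0 by convention.
D ≤ I is not asserted anywhere — it is not a theorem.

## Trait statistics

Kruskal–Wallis with tie correction on testa thickness; 95% CIs of medians
by the distribution-free binomial order-statistic method. Proportional-odds
ordinal logistic regression (category ordered D < R < N, increasing
germination propensity) fit by ML through statsmodels' OrderedModel; with
two levels it collapses to binary logistic regression; AIC ranks the
one-covariate models against the multiple model; non-convergence (e.g.
complete separation) is flagged, never silent. The PA analysis fits
`ratio ~ category + centered covariate` in cell-means coding, so the
category coefficients are the least-squares means at the covariate grand
mean; type-III F tests; custom contrasts (D+R vs N) are Wald F tests on
those LS means, verified in the suite against the nested-model F. The
covariate-free ANOVA variant is reported alongside.

## Synthetic-data generator

The generator reproduces the statistical structure the analysis assumes,
at the emulated study's design scale — 97 accessions split 28 N / 40 R /
29 D, 25 seeds × 2 replicas × 28 days × two regimes. (The emulated
design's printed group sizes sum to one more than its accession count; the
responsive group absorbs the discrepancy.)

- **Germination.** Each seed is independently "willing" with a class- and
  regime-specific probability — N (0.92, 0.95), R (0.15, 0.75),
  D (0.15, 0.20) for (25/15, 35/15), matching the printed group means —
  jittered per accession by a 0.35-SD logit-normal; willing seeds draw a
  log-normal imbibition day (class medians 5–14 d, log-SD 0.35; right-
  skewed, positive support; any two-parameter positive distribution could
  be slotted in) censored at 28 d.
- **Landscape.** Accession coordinates from a clustered point process
  (8 cluster centers, 2° spread) over a Mediterranean-scale extent; six
  environmental fields as Gaussian processes with exponential covariance
  (range 500 km) sampled jointly at accession points and on a 24×36 export
  raster. One field (the "BIO7 analog", temperature annual range) drives
  class membership through an ordered latent score — link strength 2.0 ×
  the standardized field plus logistic noise, class sizes held fixed, with
  dormant accessions at the low end (small annual range), and strength 0
  decoupling classes from the environment entirely.
- **Traits.** Log-normal testa thickness with class medians 138/140/84 µm
  (D/R/N; N with the larger spread), truncated-normal total PA with class
  means 2.18/1.87/1.77 mg g⁻¹ on the printed 1.21–4.70 range, soluble
  fraction uniform on 94–99% (insoluble is the exact remainder), and
  morphology linked to class only through a slightly larger
  length-to-width ratio in N.

What it does **not** emulate: realistic climate values or units, spatially
varying sampling intensity, measurement error in coordinates, temporal
(chilling, after-ripening) dormancy dynamics, non-exponential spatial
covariances, or any genetic structure. Passing end-to-end tests therefore
demonstrates that the pipeline recovers the latent structure it assumes —
not that real germination screens satisfy those assumptions.

## Problem sizes in the test and acceptance runs

The suites run the study at its native scale (97 accessions) for single-
study checks; replicate-based calibration uses 100 replicate studies for
forward-selection recovery, 500 simulations for the Dutilleul level, 200
for randomization-p uniformity and white-noise effective n, 50
meta-replicates for equivalency calibration, and n = 500 for ordinal
parameter recovery. The acceptance script uses 25 replicate studies for
the selection-rate figure and 499 permutations inside the single-study
pipeline; all random draws descend from the one `--seed`.

## Known limitations

- The envelope niche model ignores variable interactions and presence
  density; it is a baseline, not a replacement for a fitted niche model.
- Ezekiel-based semipartial adjustments are slightly biased for small n
  (the shared fraction of two orthogonal sets is negative by an exact
  algebraic amount that vanishes as n grows); a permutation-calibrated
  adjustment would remove this at substantial cost.
- The Dutilleul correction's profiled estimator assumes a monotone
  (exponential-family) decay; strongly non-monotone spatial correlation
  (e.g. periodic structure) would fall back to the binned estimate alone.
- GCV occasionally undersmooths scatterplot fits; the regression F-test
  compensates with an inflated reference df and is approximate, as such
  tests are in GAM practice.
- LT50 reports the first crossing only; multi-phase germination curves
  with plateaus can make it unstable between adjacent days.
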