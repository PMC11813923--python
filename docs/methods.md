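# Methods

This note documents the statistical models megaenv implements, the
choices made where the methodology leaves room, and what the synthetic
data generator does and does not emulate.

## Augmented p-rep designs

A trial is specified by its grid (rows x columns) and the counts of
unreplicated entries, duplicated checks and six-fold standards; the fill
condition `singles + 2*checks + 6*standards + masked = rows*cols` is
enforced.  Plot positions are a uniform random permutation of the usable
cells under the trial seed.  We deliberately do not optimize the layout
(no A-/D-optimality search): partial-replication spatial balance is a
diagnostic for the analyst, not a constraint, and the mixed model
absorbs row/column effects.  Trials whose plot count falls short of the
grid (139/138/137 plots on a 14x10 field) are modelled by masking
randomly chosen cells and reducing the entry count accordingly; how such
trials were physically arranged is generally not documented, so masking
is this package's convention.

Connectivity of a trial series is the graph on trials with an edge
wherever two trials share a genotype.  A disconnected series makes
cross-trial genotype contrasts non-identifiable; the fitting routine
warns rather than refuses, because variance components remain estimable.

## Synthetic MET generator

Plot values are drawn from the same model the analysis assumes:

    y = mu_j + G_i + GE_ij + r_row + c_col + eps

* `mu_j = mu + E_j`, `E_j ~ N(0, env_sd^2)`.  Environment main effects
  are fixed in the analysis, so `env_sd` only sets realistic spread;
  the default is twice the interaction sd because location and season
  move trait means far more than any genotype does.
* `G_i ~ N(0, var_g)` plus an additive botanical-type shift for
  genotypes with an assigned type.  Default shifts are the seed-size
  class effects estimated for the faba bean collection (paucijuga
  reference intercepts; minor/equina/major shifts), including the
  non-significant ones.
* `GE_ij = sqrt(var_ge) (c lam_{i,m(j)} + eta_ij) / sqrt(c^2+1)` with a
  loading `lam` per genotype and mega-environment group and unstructured
  noise `eta`; `c` (`crossover_strength`) moves interaction variance
  from noise into a repeatable group crossover without changing
  Var(GE) = var_ge.  This is the planted structure the which-won-where
  analysis is meant to detect.
* Row and column effects each get `var_rc / 2`, splitting the pooled
  "row and column" component equally, since only the pooled value is
  normally reported.
* Residual `eps ~ N(0, var_e)`; an optional drop rate removes plots to
  emulate field loss (default 0).

Default per-trait variances and grand means are the multi-trial REML
estimates and typical environment means of the reference collection
(e.g. flowering time 16.7 / 9.91 / 2.19 / 10.6).  Simulated values are
truncated to the biologically admissible range — heights, counts and
lengths cannot be negative, pods per flower lies in [0, 1] — with a
small positive floor (1% of the grand mean) for strictly positive
traits so ideotype-folding stays defined, as it is for real field data.
The truncation is far in the tails for every default trait, so it does
not measurably distort the calibrated variances.

What the generator does **not** emulate: spatial autocorrelation beyond
iid row/column effects, non-Gaussian measurement error, trait-trait
genetic correlations (each trait draws independent genotype effects, so
cross-trait analyses see only the botanical-type-induced correlation),
year-to-year carryover, and missing-not-at-random field loss.  Passing
tests therefore demonstrate correctness of the estimators under the
stated model, not robustness to these real-data complications.

## REML engine

The mixed model `y = Xb + sum_k Z_k u_k + e` with iid blocks is fitted
on the observation scale: `V(theta) = s2_e I + sum_k s2_k K_k` with
`K_k = Z_k Z_k'` precomputed, one Cholesky of V per likelihood
evaluation (n is a few thousand at most, so dense algebra beats sparse
machinery here).  Optimization is average-information REML: score and AI
matrix from the standard P-matrix identities, step-halving on the REML
log-likelihood, components clamped at `1e-8` of the total variance
(reported as boundary / exactly zero), convergence at `1e-8` on the
criterion with a log-scale gradient check.  A Nelder-Mead fallback on
log-variances covers pathological starts.  The engine was validated
three ways: against expected-mean-squares closed forms on balanced data
(agreement to ~1e-13), against lme4's REML on an unbalanced p-rep series
(components and log-likelihood to ~5 decimals), and by a 200-replicate
parameter-recovery study (below).

BLUPs are `u_hat = s2 Z' P y`; the prediction-error variance matrix of
the genotype block gives `vblup` as the exact mean over all genotype
pairs of Var(BLUP_i - BLUP_j) (no pair sampling; the collection sizes
here make the exact average cheap).  Generalized heritability
`H2 = 1 - vblup/(2 var_g)` is clamped to [0, 1] with a flag.  Fixed
effects get Satterthwaite-type degrees of freedom via a delta-method
propagation of the AI covariance; p-values can differ in the third
decimal from other df approximations.

Row/column effects and the trial term: whether rows/columns are fixed
or random, and trial fixed, is often left implicit in MET reports.  We
take trial fixed (its variance is not of genetic interest and the
environments are purposively chosen) and rows/columns within trial
random, which is also what keeps the row+column variance reportable.

## Parameter-recovery study

200 simulations of nine 7x10 p-rep trials (44 singles, 10 duplicated
checks, 1 six-fold standard; 150 genotypes rotating through the entry
slots) at the flowering-time component set.  The mean REML estimate of
each component lands within 10% of its generating value; this is the
package's standing calibration check.  The trial size was chosen so the
suite completes in a few minutes at one fit per ~0.5 s; the estimator
itself is size-agnostic.

## GGE biplot

Environment-centering `M_ij = Y_ij - mu_j` follows the model equation;
figure-style alternatives (double centering, unit-variance scaling) are
deliberately not implemented.  The two-way table is built from
model-based predictions `mu_j + G_i + GE_ij`, which are complete even
when a genotype missed a trial; cells filled this way are flagged.
Singular axes are oriented so each axis's largest-magnitude environment
loading is positive — a pure reporting convention; all winners and
rankings are invariant to sign flips, and numerically zero singular
values are truncated to exactly zero so degenerate geometry is detected
reliably.

Which-won-where: the convex hull of rank-2 genotype coordinates
(monotone chain, deterministic tie-breaks), sector boundaries at the
outward normals of the hull edges (the normal fan), environments
assigned by angle with boundary ties going to the counterclockwise
sector.  By construction the sector winner equals the exhaustive rank-2
argmax `argmax_i alpha~_i . gamma~_j`, which the tests verify against a
brute-force oracle.  Mega-environments: locations are grouped only when
every location has at least two year-instances and all of a location's
instances share one winning genotype; any deviation returns a single
mega-environment.  This all-instances rule is strict by design — a
repeatability claim should not survive a counterexample year.

Mean-vs-stability: the average-environment axis (AEA) is the normalized
mean of environment rank-2 coordinates; mean performance is the signed
projection of a genotype on it, instability the orthogonal distance,
and the ideal genotype sits on the AEA at the maximal observed
projection.  For a per-mega-environment assessment the model is
refitted on the subset of environments rather than sliced from the full
fit, so the axes reflect the subset's own interaction structure.

## Mega-environment recovery study

100 seeded simulations of a crossover-dominated MET: 40 genotypes, four
locations x two years in two planted groups, six replicates per
genotype per trial, `var_ge = 100` against `var_g = 2` and
`crossover_strength = 50`.  The planted truth is the partition implied
by the structured loadings themselves (group-level winners computed
from the drawn effects): if both groups happen to draw the same top
genotype, the true structure *is* one mega-environment, and the
detector is scored against that, not against the group labels.  The
detected partition matches the planted one in >= 95% of runs; residual
failures are near-ties between a group's top two loadings at the noise
floor.

## MTSI chain

* Ideotype transform `Y = I ± |X - I|` with the branch chosen by the
  position of the target in the observed range; the direction of merit
  after transformation follows from the branch.  Non-positive
  transformed values are an error naming the genotypes (they would
  poison the rescaling), never silently clamped.
* WAASB uses symmetric-scaled scores (`lambda^0.5 u`) over **all**
  nonzero SVD axes of the interaction BLUP matrix, weighted by each
  axis's share of interaction variance.  An all-zero interaction matrix
  yields WAASB = 0 everywhere with a degeneracy warning, and the
  pipeline then assigns every genotype full stability marks rather than
  failing on a constant column.
* Rescaling is the linear 0-100 map with (a, b) = (100, 0) or (0, 100)
  by direction of merit; WAASBY is the (70, 30) weighted mean by
  default.
* Factor analysis of the WAASBY matrix: principal-component extraction
  from the correlation matrix, retention at eigenvalue >= 1 (never
  fewer than one factor), varimax rotation, regression-method scores
  `F = Z R^-1 A`.  The ideotype is the all-100 row pushed through the
  identical standardization and scoring — an interpretation we flag,
  since "canonical loadings" are defined operationally here.
* MTSI is the Euclidean distance to the ideotype scores; selection
  keeps `round_half_up(SI * n)` genotypes.  Half-up rounding reproduces
  both reference counts (27 of 179, 33 of 220); ceiling would too, and
  the choice is recorded here precisely because the data cannot
  distinguish them.
* Per-mega-environment runs refit everything — including the SVD behind
  WAASB — on the subset of trials, consistent with reporting per-ME
  variance shares.

## Summaries

Descriptive statistics are per environment and trait (mean, sd, se,
CV%, min, max, range) with single-observation and zero-mean flags.
Correlations are pairwise-complete Pearson with t-based p-values and an
alpha = 0.01 display mask.  Clustering is complete-linkage on Euclidean
distances of the standardized BLUP matrix (scipy's deterministic
implementation; ties are measure-zero on continuous BLUPs); cluster
diameter is the mean pairwise within-cluster distance and inter-cluster
distance the mean pairwise between-cluster distance.  PCA is
correlation-matrix based by default.  Transitional botanical types
merge into the first-named main type (equina-major -> equina,
major-equina -> major, equina-minor -> equina, minor-paucijuga ->
minor); the merge direction is a convention, configurable in one map.

## Known limitations

* No spatial correlation models (AR1xAR1) or multivariate mixed models;
  each trait is analyzed independently.
* The factor-analysis scoring of the ideotype, the transitional-type
  merge direction, and the masked-cell handling of reduced trials are
  documented conventions, not uniquely determined by the methodology.
* The REML engine is dense and targets datasets up to a few thousand
  plots; it is not meant for genomic-scale random effects.
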