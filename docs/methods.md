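# Methods

## Scope and shape

`histgp` implements a two-stage genomic prediction analysis for multi-year
breeding data. Stage one reduces plot-level alpha-lattice trials to genotype
BLUEs per year × selection environment; stage two fits genomic models on
those BLUEs and evaluates them by forward validation — training only on
years strictly before each target year, which is how the models would be
used in practice. The model layer is organized as scikit-learn-style
estimators (`GBLUPRegressor`, `GxYRegressor`) over precomputed kernels, so
they compose with sklearn tooling; the surrounding pipeline stages are
plain functions over pandas tables.

## Stage one: BLUEs and heritability

The plot model has genotype fixed (cell-means coding) and trial,
replication-within-trial and block-within-replication random, residuals iid
within a year × environment. Variance components are estimated by REML
profiled over the variance ratios λ_k = σ²_k/σ²_ε: for each candidate λ the
sparse mixed-model equations are factorized once (scipy `splu`), giving the
restricted log-likelihood through the determinant identity
log|V| + log|X′V⁻¹X| = n log σ²_ε + Σ_k q_k log σ²_k + log|C|; Nelder–Mead
minimizes over log λ (tolerance 1e-8, bounded ratios, at most a few hundred
evaluations). With the genotype block diagonal this stays fast with a
thousand fixed genotype effects, which is why the engine is written here
rather than delegated to a general mixed-model package; a dense brute-force
restricted-likelihood optimizer serves as the independent cross-check in the
test suite. BLUE standard errors come from the fixed-effect block of the
inverted coefficient matrix. Factors with a single level are dropped from
the random part (their variance is unidentifiable). Heritability refits the
same model with genotype random and reports the entry-mean ratio
H² = σ²_g/(σ²_g + σ²_ε/r), clamped to [0, 1]; r defaults to the median
plot count per genotype. A zero-variance response yields NaN (undefined),
deliberately distinct from H² = 0.

Stage two consumes the BLUEs unweighted; their standard errors are reported
but not propagated. Checks are kept in stage one — they are the only
genotypes linking subtrials — and flagged downstream.

## Genomic layer

Markers are biallelic dosages in {0, 1, 2} with missing calls. QC removes
markers with minor-allele frequency strictly below 5% or missingness
strictly above 50% (both configurable); imputation is by column mean, a
deliberate simplification of haplotype-based imputation appropriate for the
synthetic data this package targets. The relationship matrix is VanRaden
method 1 with allele frequencies taken from the full supplied matrix
(training and target cohorts together — one G across all years), and a
1e-8 ridge ahead of any factorization. Genetic distances between cohorts
are mean pairwise Euclidean distances on raw dosage rows (centering is
available but changes nothing for complete data, since row shifts cancel in
differences). PCA of the column-centered dosage matrix uses a full SVD.

## Stage two: GBLUP and the genotype-by-year model

Both models are Bayesian with conjugate Gibbs updates and scaled-inverse-χ²
priors: degrees of freedom 5, scales set by the usual variance-partition
heuristic (R² = 0.5 per kernel against the sample variance of the response,
divided by the kernel's mean diagonal). Chains default to 12,000 iterations,
2,000 burn-in, thinning 5.

GBLUP is sampled in the eigenbasis of G: with an orthonormal design and
homoscedastic residuals the eigen-coefficients are conditionally
independent, so each iteration is a vectorized joint draw.

The multi-year model adds a year main effect (iid), an optional iid line
effect (on by default — it absorbs non-genomic line variance), the genomic
main effect over records, and the interaction term whose covariance is the
genomic kernel masked to same-year pairs (the Hadamard product of
record-level genomic and year-incidence kernels). Residual variances are
per-year by default. Two sampling regimes coexist:

- the interaction kernel is block-diagonal by year and residuals are
  constant within a year, so each year-block gets an exact vectorized joint
  update in its own eigenbasis;
- the genomic main effect spans years with heteroscedastic residuals, where
  no diagonal update exists; it uses a systematic-scan single-site Gibbs
  sweep over eigen-coefficients (numba-compiled, O(records × rank) per
  iteration), updating the running residual in place.

Eigendecompositions are truncated at 99.99% of spectral mass (and a 1e-10
relative eigenvalue floor) after a 1e-8 ridge.

Prediction for genotypes without phenotypes flows through the relationship
matrix: ĝ_new = G_new,obs G_obs,obs⁻¹ ĝ_obs. For a future, unobserved year
the year and interaction effects have prior mean zero, so a new-year GEBV
is the genomic main term alone — the only prediction consistent with the
independence assumptions of the interaction term. `solve_mme` implements
the exact multi-kernel BLUP at fixed variance components and anchors the
sampler tests (kernel-BLUP equals marker ridge regression with penalty
λ = c σ²_ε/σ²_g; sampler posterior means track the exact solution at the
posterior-mean variances).

## Validation design

For each environment and target year, window k trains on the k immediately
preceding years: k = 1 with GBLUP (a single year cannot identify year or
interaction effects), k ≥ 2 with the G×Y model. Accuracy is Pearson's r
between GEBVs and target-year BLUEs over the scored intersection;
`(1 − r²)/√(n − 3)` approximates its standard error. Checks phenotyped in
both training and target years are excluded from scoring by default (they
are not unphenotyped candidates; scoring them would flatter accuracy) —
switchable, with the excluded ids logged. Every grid cell runs on its own
deterministic substream of the master seed, so cells are reproducible in
isolation, and failed cells are recorded rather than aborting the run.

The distance analysis trains on each single year strictly before a target,
scores the target, attaches the mean training–target genetic distance, and
regresses accuracy on distance per (environment, target year), with a
pooled-per-environment regression also available. Single-target regressions
have few points and wobble — as they do on real data — so the pooled
correlation is the steadier per-program statistic and is what the shipped
experiments report.

## The synthetic breeding program

The generator mimics a stage-2 yield-testing program: each year a cohort of
new candidate lines plus a fixed set of checks, phenotyped in subtrials of
60 entries (54 candidates + 6 checks repeated in every subtrial), 2
replications of 12 incomplete blocks × 5 plots, with trial, rep and block
effects and heterogeneous per-year residual noise. Defaults describe a
10-year, 1,080-candidate program; the shipped experiments use a scaled
8-year × 432-candidate analogue.

Genetics: candidate cohorts are produced by crossing within a rolling pool
of 64 parents. Pool membership survives year-to-year with probability
0.5^(1/halflife) (halflife 2 years by default), so cohorts Δ years apart
share roughly 0.5^(Δ/halflife) of their parents — this is the relatedness
decay the validation feeds on. Retired slots are refilled half from the
latest cohort (tying generations together, and putting some parents' own
records into deeper training windows) and half by novel introductions drawn
from an external donor pool whose allele frequencies random-walk across
years (variance 0.05·p(1−p) per year), so distant cohorts diverge
systematically — mean inter-cohort distance grows monotonically with the
year gap. Meiosis is one crossover per chromosome at a uniform position; no
genetic map is modeled. The `unrelated_cohorts` switch replaces all of this
with fresh equilibrium draws every year — the negative control in which
nothing but the shared checks links years.

Causal architecture: the n_qtl causal loci are simulated alongside the
marker panel on the same chromosomes but are *excluded from it*; markers
tag QTL only through cosegregation and realized relatedness, as with a real
genotyping panel. This matters for the negative control: were causal loci
inside the panel, marker-effect transfer would create accuracy between
unrelated cohorts and the control would not be flat. QTL effects are drawn
once and scaled so the founder variance of breeding values equals σ²_g.
Interaction deviations are drawn per year with covariance σ²_Yg·G over the
year's cohort, independent across years, matching the stage-two model's
assumption; year effects are iid.

Default variances (t/ha² around a mean yield of 5 t/ha): σ²_g = 0.35,
σ²_Yg = 0.30, σ²_year = 0.40, σ²_line = 0.05, residuals rising from 0.9 to
1.5 across years (heterogeneous, as the stage-two model assumes; no
published per-year values exist, so these are chosen once as plausible for
yield trials spanning stress and optimal regimes). They imply an entry-mean
H² around 0.3 and single-year forward accuracies around 0.1–0.25 — the
regime reported for grain yield. All randomness flows from one master seed
through named substreams (CRC-tagged SeedSequence), so each stage is
independently reproducible.

What the generator does *not* emulate: selection response (parents are
recycled at random, untruncated), sequencing error and real missingness
patterns, linkage-disequilibrium calibration to any real genome, spatial
field trends beyond the lattice factors, and multi-environment genetic
correlation structure (environments share the same genetic truth). Passing
tests therefore demonstrate that the estimators are correct and that the
pipeline detects relatedness-driven phenomena it should detect — not that
any particular real program will show gains of a particular size.

## Experiment sizes and chain lengths

The shipped experiments (tests and `scripts/acceptance.py`) use: 8 years ×
432 candidates × 1,000 markers for the forward-validation and distance
studies (window gains over 5 programs; distance regressions pooled over the
last 3 target years; unrelated control over windows k ∈ {1, 2, 4}); 3 years
× 300 lines for the variance-component recovery (chains 6,000/1,000); 500
genotypes × 2 reps × 50 replicates for heritability recovery. Validation
and distance grids use shortened chains (2,500 iterations, 500 burn-in):
posterior-mean point predictions stabilize far earlier than variance
components, and accuracy is invariant to the residual scaling those longer
chains refine. The variance-recovery experiment simulates directly from the
stage-two model's own assumptions (g ~ N(0, σ²_g G)) — the correct target
for validating a sampler — and fits with the line effect off, since nothing
in that simulation generates iid line variance.

## Numerical choices and degenerate inputs

Ridge 1e-8 on kernels before factorization; PSD tolerance −1e-6 relative on
the smallest eigenvalue; REML ratios bounded in [e⁻³⁰, e³⁰]; a flat
likelihood surface at the boundary is accepted as converged. Constant
responses collapse the samplers gracefully (variances shrink toward their
floored prior scales, predictions constant); constant accuracy or distance
vectors raise explicit degenerate-input errors in the regression step
rather than returning meaningless correlations. Correlations require ≥ 3
shared ids; the SE approximation requires n ≥ 4.

## Known limitations

Stage-one BLUE standard errors are not carried into stage two (unweighted
two-stage analysis). The G×Y model predicts nothing year-specific for
future years by construction. The single-site sweep makes the G×Y sampler's
cost quadratic in window size; windows beyond ~3,000 records warrant longer
chains and patience. Check handling in scoring, trial fixed-vs-random, and
raw-vs-centered distance coding are judgment calls on questions the
two-stage literature leaves open; each is a documented switch.
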