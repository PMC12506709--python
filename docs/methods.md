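# Methods

This note documents the statistical machinery behind `sireval`: the models,
the estimation algorithms and their numerical choices, what the simulator
does and does not emulate, and the known limitations.

## Pedigree relationship algebra

The numerator relationship matrix `A` is built by the tabular method
(`a_ij = ½(a_j,s(i) + a_j,d(i))`, `a_ii = 1 + ½ a_s(i),d(i)`, unknown
parents contributing zero); it is only materialized densely on demand —
the pipeline works with the sparse inverse throughout.  `A⁻¹` is assembled
directly from the pedigree by Henderson's rules, with Mendelian-sampling
variances `d_i = ½ − ¼(F_s + F_d)` (¾ − ¼F with one known parent, 1 with
none).  Inbreeding coefficients come from Meuwissen–Luo-style ancestor
tracing: each parent's genome-contribution row of the `A = T D T'`
decomposition is expanded lazily toward its ancestors in descending
pedigree order, and `F_i = ½ Σ_k T_sk T_dk D_k`.  This reproduces
`diag(A) − 1` exactly (property-tested on random pedigrees) without ever
forming `A`.

Unknown parents are treated as unrelated, non-inbred founders; there are
no unknown-parent groups, because the data this package targets carry no
grouping information.  Pedigree validation inserts missing parent rows as
founders, sorts parents before offspring (Kahn's algorithm, ties broken by
input position so the order is reproducible), and reports a named animal
on any cycle.

## Mixed-model equations and BLUP

Fixed effects use reference coding: an intercept plus all non-first levels
of each factor, which keeps the fixed block full rank for connected data;
aliased levels are detected by pivoted QR and reported by name.  Two-way
interaction cells with fewer than 2 records receive no parameter (they are
absorbed into the residual) — sparse single-record cells cannot separate
an interaction effect from their own residual.

The MME are assembled sparsely and solved by sparse LU with one iterative
refinement step; solutions satisfy the equations to a residual below
`1e-8·‖rhs‖`.  Prediction-error variances come from the diagonal of the
inverse coefficient matrix: densely for systems up to 2,000 equations,
otherwise by one unit-vector solve per requested animal against the LU
factors (by default the animals with recorded progeny, i.e. the bulls
under evaluation).  This is the accuracy bottleneck for very large
evaluations and is deliberate: the package targets desk-scale progeny
tests (tens of sires, thousands of daughters).

Reliability is `1 − PEV/σ²_A`, clamped to [0, 1] (clamping matters only
when sampling noise in the variance components makes PEV marginally exceed
σ²_A); accuracy is its square root, and PTA is EBV/2.  Animals without
records or relatives get EBV 0 and reliability 0.

## EM-REML in the rotated (marginal) basis

The restricted likelihood of the animal model depends on the pedigree only
through the relationship matrix among *recorded* animals, `A_rec`:
unrecorded ancestors are integrated out of the marginal distribution of
`y`.  `sireval` therefore estimates variance components in the marginal
model `y = Xb + g + e`, `g ~ N(0, A_rec σ²_A)`.  With the
eigendecomposition `A_rec = U D U'`, the rotated data `U'y` have
independent components of variance `d_i σ²_A + σ²_E`, and one EM-REML
iteration costs O(n p²) instead of one dense inverse of the full MME.  The
updates are the classical EM fixed-point updates

```
σ²_k ← σ²_k + (σ²_k² / n) · (y'P M_k P y − tr(P M_k)),   M_A = A_rec, M_E = I
```

with `P` the REML projection; the restricted log-likelihood is
non-decreasing along the sequence and is asserted so at every iteration.
The EM fixed point equals the REML maximizer (verified in tests against
direct maximization of the restricted likelihood, and against the
half-sib ANOVA estimator on balanced designs).  The eigendecomposition can
be precomputed once and shared across traits and simulation replicates
with identical record sets.

Defaults: convergence when the maximum relative parameter change drops
below `1e-8`, at most 5,000 iterations.  Plain EM needs a few thousand
iterations on realistic half-sib designs — each costing only O(n) here, so
the default cap is generous rather than tight.  Non-convergence is flagged
on the result, never raised.  A variance heading for zero is held at a
floor of `1e-8` of the initial phenotypic variance and flagged as a
boundary estimate, which keeps `h²` defined.

Standard errors come from the numerically differentiated observed
information (central differences on the restricted log-likelihood at
convergence; steps of 1e-4 relative); SEs of `h²`, `r_g` and `r_p` follow
by the delta method.  Near a boundary (e.g. `r_g → 1`) the information
matrix can be numerically singular, in which case SEs are reported as NaN
rather than fabricated.

The bivariate fit stacks two traits with 2×2 genetic (`G₀`) and residual
(`R₀`) blocks per rotated observation and applies the matrix form of the
same EM update,

```
G₀ ← G₀ + (1/n) G₀ [Σ_i d_i ((Py)_i (Py)_i' − P_ii)] G₀
```

(likewise for `R₀` with unit weights).  Updates leaving the PSD cone are
projected back by an eigenvalue floor and flagged.  Rows missing either
trait are dropped (complete-case pairing).  Phenotypic correlations use
`P₀ = G₀ + R₀` componentwise.  Trait pairs are fitted pairwise; a full
8-trait multivariate REML is out of scope — it is unstable at this data
scale and is not needed for the index, whose inputs are the (co)variance
matrices themselves.

## Fixed-effects layer

The outlier screen removes records more than two sample standard
deviations from their group mean, in a single pass with mean and SD taken
from the unfiltered group, separately per trait within genotype grade.  On
Gaussian data this removes ≈ 4.6% (the two-tail mass beyond 2 SD).
Descriptives report N, min, max, mean, `SE = SD/√N` and `CV% = 100·SD/mean`.

LS-means are classical: the fitted-model prediction at a factor level,
averaging the other factors' levels with *equal* weights (not observed
frequencies).  SEs use the linear-combination variance rule on the OLS
coefficient covariance; the omnibus test is the F-test that all
non-reference coefficients of the factor vanish.  Pairwise separation uses
Tukey–Kramer studentized-range p-values on LS-mean differences, and the
compact letter display is produced by the insert-and-absorb algorithm, so
two levels share a letter exactly when their pairwise p ≥ α.

## Selection index

`b = P⁻¹ G a` with no normalization; a non-positive-definite `P` is an
error reporting the smallest eigenvalue.  EBVs are standardized across the
candidate bulls with the population-SD convention (ddof = 0; a sample-SD
flag exists).  "Lower is better" traits are handled entirely through the
sign of the supplied economic values — the code never flips signs itself.
The top `ceil(fraction · n)` bulls are selected (so 20% of 51 bulls is
11), with ties broken by ascending bull identifier for deterministic
reports.  The index is linear in `a`, and rankings are invariant to
positive rescaling of the weight vector — both property-tested.

## The simulator

`synthetic_data` generates the study conditions end to end: sire founders
allocated to genotype grades, one unrelated dam per daughter (paternal
half-sibs; a shared-dam policy producing full sibs is available but off by
default, since field recording of dams is typically absent), and daughter
phenotypes `μ + grade + parity + location + BV + e`.  Breeding values are
drawn `N(0, G)` for founders and transmitted as mid-parent average plus a
Mendelian deviation of covariance `½G(1 − (F_s + F_d)/2)`, which
reproduces `A` exactly; a single RNG stream with a documented draw order
(per-animal BV normals in pedigree order, then parity, location, residual
draws) makes output bit-identical for a fixed seed.

The shipped preset mirrors a crossbred HF × Local progeny test: 51 sires
(8/12/31 in the 50%, 62.5% and 75% HF grades), 4,319 daughters with family
sizes from 7 to 628 (a deterministic right-skewed exponential profile,
pinned at both extremes), trait means per grade, additive and residual
variances giving heritabilities 0.09–0.33, and published genetic and
phenotypic correlation matrices.  The residual covariance is derived as
`E = P − G`; because published correlations are estimated pairwise, `E`
can fail to be PSD, in which case it is projected to the nearest PSD
matrix (eigenvalue floor).  Parity (3 levels) and location (6 levels)
effects are deterministic symmetric spreads of 0.2 and 0.3 phenotypic SDs
— large enough that ignoring them would visibly bias the evaluation, small
enough to stay realistic for managed herds.

What the simulator does *not* emulate: selection or assortative mating
(parents are drawn at random), genomic marker data, maternal or permanent
environmental effects, repeated lactations per daughter, year/season
trends, heterogeneous residual variances across herds, or non-Gaussian
trait distributions (SPC is simulated as Gaussian although it is a count).
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the stated model, not robustness to these real-data
features.

## Problem sizes and numerical choices

Recovery tests run 20 replicates of a 50-sire × 80-daughter design
(4,000 records) for single-trait heritability and 10 replicates at the
same size for bivariate correlation, sharing one eigendecomposition across
replicates; these sizes give Monte-Carlo error comfortably inside the
±0.05 recovery bands while keeping the suite fast.  The full shipped
design (51 sires, 4,319 daughters, 8 traits) is exercised by the
acceptance script, which reports single-realization estimates — with only
51 sire families the sampling SE of an h² estimate is roughly 0.05–0.08,
so individual traits scatter around their generating values accordingly,
while structural quantities (selection counts, accuracy ordering, filter
fraction) are stable.

Other numeric choices: PSD validation tolerance `1e-8` relative;
MME refinement threshold `1e-8·‖rhs‖`; EM monotonicity assertion slack
`1e-6` relative (floating-point noise near convergence); dense-PEV
threshold 2,000 equations; variance floor `1e-8` of phenotypic variance.

## Known limitations

- No multi-trait MME, maternal effects, repeated records or genomic
  relationships.
- PEV by explicit (or per-animal) inversion limits very large evaluations.
- Pairwise bivariate correlations need not assemble into a jointly PSD
  8-trait matrix — the same caveat that applies to any pairwise-estimated
  correlation table.
- The economic-value vector is taken as given; deriving it from profit
  functions is out of scope.
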