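# Methods

## The model

Each record is one fitness assay of a single F1 individual from the
cross dam *i* × sire *j* (*i* = *j* marks an inbred self), of known sex,
in one replicate block, with fitness measured as a count of F2
offspring.  The response is `log(fitness + 1)`; the offset is needed
because zero counts occur, and it is the package's single largest
reproduction risk for absolute variance-component magnitudes (ratios
and correlations are insensitive to it).

The full sexed model has fixed effects {intercept, block, inbreeding
b1, sex S, S×b1} and random inheritance classes
{a, b2, c, b3, d} × {unsexed, S×}.  Incidence coding, for strain k on a
record with dam i, sire j:

| term | coding |
| --- | --- |
| a | `[k==i] + [k==j]` (2 on selfs) |
| c | `[k==i] − [k==j]` (0 on selfs) |
| b2 | `[k∈{i,j}]` on outcross rows, 0 on selfs |
| b3 | pair indicator over unordered outcross pairs, projected orthogonal to the strain-margin space |
| d | signed pair indicator (+1 if i<j, −1 if i>j), projected orthogonal to the strain-difference margins |
| S×q | the q incidence × sex contrast (+1 female, −1 male) |

The projection for b3/d is deliberate: Hayman's b3 is the *residual*
symmetric interaction after additive and parent-specific dominance
margins, and d the residual reciprocal interaction after the maternal
margins.  With raw pair indicators, a reduced model containing only b3
would absorb essentially all pooled family structure into the b3 BLUPs,
and the SSDR residualization below would destroy exactly the additive
and dominance variation it is supposed to preserve.  The projected
coding keeps the published level counts (n(n−1)/2 pairs; 120 at n=16)
while confining b3/d to interaction deviations.

The sex contrast is +1 female / −1 male, so a positive S×q BLUP is
female-beneficial and the SA rotation reads q_SA = (q_F − q_M)/√2.

## Unconstrained REML

The restricted log-likelihood is maximised directly in
θ = (σ²_a, …, σ²_ε) with no positivity transform, subject only to
V = Σ_q σ²_q Z_q Z_qᵀ + σ²_ε I staying positive definite.  This is what
allows negative component estimates, which the classical diallel
literature reports and interprets as "not different from zero"; a
log- or squared-parameterization cannot produce them.

Numerics: all likelihood work is reduced to q×q space (q = total
random levels, 560 for the full sexed 16×16 model) through the Woodbury
identity and the matrix determinant lemma, with Z′Z, Z′[y X] and
[y X]′[y X] precomputed.  Positive definiteness is monitored through
the eigenvalues of R G R′ where Z′Z = R′R; outside the cone the
objective returns a large penalty with a gradient pointing back along
the violated eigendirection.  The optimiser is L-BFGS-B with the
analytic REML gradient
∂ℓ/∂θ_k = −½[tr(P V̇_k) − (Py)ᵀ V̇_k (Py)]; the generic divergence of
the objective at the cone boundary acts as a natural barrier.  Starting
values split the OLS residual variance 90/10 between ε and the random
terms.  Standard errors come from the observed information matrix
(central differences of the analytic gradient at the optimum); fixed
effects are GLS at the optimum with Wald F tests on denominator df
n − rank(X).  Aliased fixed columns are dropped by rank-revealing QR.
Convergence status and the final log-likelihood are reported on every
fit; non-convergence is flagged, never silent.

BLUPs are u_q = σ²_q Z_qᵀ V⁻¹(y − Xβ̂).  Terms with negative variance
estimates have no valid prediction: `extract_blups` refuses them, and
the residualization skips them (contribution zero) while reporting the
skip.

## Geometry

BLUP vectors are variance-standardized by the sample standard deviation
(n−1 denominator) *without centering* — BLUPs are centred near zero by
construction, and not recentering keeps the rotation an exact
involution.  Pair-level classes (b3, d) are collapsed to strain means
over the n−1 pairs containing each strain before any geometry; for the
antisymmetric d class this collapse is convention-dependent and is
flagged as such.  Angles use unit-norm vectors with the inner product
clamped to [−1, 1]; they are reported in degrees.  A class is excluded
from the report (with the reason) when any needed component — q or S×q
in the full model, q in either sex-specific model — is negative.

## The SSDR statistic

Residuals are taken from y = μ + x + b₃ + ε (plus a in the conservative
variant), fitted by the same REML machinery on the same log response;
they are not variance-standardized.  Family means are tabulated per sex
from these residuals, pooling replicates across blocks unweighted
(block effects were removed with the fixed part, so pooling is
unbiased).  For strain k and one sex,

σ_P,r(k) = ½[cov(r_dam, P) + cov(r_sire, P)],

where r_dam = {z̄(k,j)}, r_sire = {z̄(j,k)} over partners j ≠ k and
P = {z̄(j,j)}; sample covariances with n−1 denominators; a partner
enters a side only if both its outcross mean and its self mean exist
(the design's missing families drop pairwise, never imputed); each side
requires ≥ 3 usable partners.  V_r is the variance of the pooled
outcross means.  The cross-sex Pearson correlation of the 16 per-strain
values carries a Fisher-z 95% CI (tanh(atanh r ± 1.96/√(n−3))) and a
two-sided t p-value on n−2 df; Spearman's ρ is the Pearson correlation
of the ranks, with a t-approximation p-value (an exact permutation p
would differ slightly at n = 16 and is not attempted).  Datasets
without all parental selfs, or with fewer than 6 strains, are refused —
the statistic is undefined or meaningless there.

The Wr–Vr diagnostic regresses σ_P,r on V_r by OLS across strains.  Per
locus the theoretical slope is exactly 1 whatever the dominance level
(the two genotype classes of the focal strain differ by
Δcov = 2α·Δslope·v and ΔV_r = (s₁²−s₀²)v with s₁+s₀ = 2α); summing
loci makes it approximate, and under *pure* additivity the points
coincide and the regression is degenerate — the diagnostic errors on
zero V_r variance rather than reporting a meaningless slope.

## The generator

`SimulationConfig` defaults emulate a two-block 16×16 diallel fitness
experiment at realistic scale: ~3 replicate assays per family × sex ×
block with 6% record-level missingness (~2,900 records), baseline
fitness ~40 offspring (μ0 = log 40), residual sd 0.3 on the log scale,
20 SA loci (opposite-sign effects, full dominance reversal,
Beta(6,2)-concentrated h in the favoured sex), 20 SC loci, and 16
strain-private recessive load loci (Exp(0.5) penalties, doubled in
males) producing strong, male-biased inbreeding depression.  μ0 and
σ_e are calibration choices — no empirical per-assay count moments were
available to set them.  Per-sex effect magnitudes are drawn
independently (antagonism and concordance constrain only the signs);
`sex_symmetric_magnitudes=True` restores exact mirror symmetry.
Observed fitness is max(0, round(exp(latent))), making the count
nature of the data and the log-transform decision downstream
meaningful.  One seed drives a `SeedSequence`; stages (genomes/effects,
noise, missingness) use spawned child streams so each is independently
reproducible.

What the generator does *not* emulate: linkage, X/Y-linked loci (the
organism has X/Y sex determination but the inheritance classes modelled
are autosomal), explicit epistatic generative terms (only what the exp
link induces), sex-specific residual variances (real data showed ~5×
male residual variance; the model fits a single ε, and so does the
generator), and overdominance (h is confined to [0, 1]).  Passing tests
therefore show the machinery recovers architectures of this idealised
family, not that real data meet these assumptions.

### Stated oracle conditions

Two frozen configurations back the sign-recovery checks:

* `high_signal_reversal`: 12 SA loci of large effect (α scale 0.30,
  h ~ Beta(20,1) in the favoured sex, exact reversal in the other),
  sex-symmetric magnitudes, 2 replicates, no missingness.  Few loci of
  large effect is also the architecture the variance-partitioning
  pattern (dominance ≫ additive) points to.  Under these conditions the
  cross-sex σ_P,r rank correlation is negative in ≥ 90% of seeded runs.
* `concordant_control`: 30 SC loci, shared dominance, sex-symmetric
  magnitudes, 4 replicates — the statistic's median across seeds is
  positive, confirming the negative result is specific to reversal.

The residualized statistic has a genuine subtlety these conditions
respect: the b3 removal subtracts the *sex-pooled* interaction
deviations, so the surviving reversal signal rides on the sexed
interaction and on retained margins.  Strongly sex-asymmetric effect
magnitudes weaken it, and worlds with heavy SA additive variance but
concordant dominance can push the statistic negative — the conservative
SC-additive-removed variant exists precisely to guard that reading.

## Problem sizes

Tests and the acceptance script run the full sexed model (560 random
levels, ~2,900 records) a handful of times and the two-component
residualization models dozens of times; sign-recovery uses 50 seeds in
the suite and 30 in the script, with the 4-strain solver-oracle
fixtures at 64 records.  These sizes were chosen to keep a complete
desk run in minutes while leaving every Monte-Carlo margin comfortably
away from its threshold.

## Known limitations

* Absolute variance-component magnitudes depend on the log offset and
  on the exact FDIALLEL-internal incidence constraints, which the
  source procedure does not print; level counts and all correlation/
  rank-based results are robust to both.
* Negative-variance terms are skipped (not subtracted) in
  residualization; on datasets where b3 itself comes out negative the
  SSDR residuals equal the fixed-part residuals.
* The Spearman p-value uses the t approximation; at n = 16 an exact
  permutation p differs in the third decimal.
* The Wr–Vr slope check is an across-seed average; single 16-strain
  panels fluctuate by ±0.2 through leave-one-out partner effects.
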