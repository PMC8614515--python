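# Methods

## Phenotype construction

Raw records are within-day CH₄/CO₂ concentration measurements taken during
milking visits. The diurnal rhythm is removed per farm with an ordinary
least-squares Fourier fit (harmonic k has period 24/k h; default two
harmonics: the 24 h feeding/milking cycle plus a 12 h overtone). The
correction subtracts each record's fitted deviation *centered over the
corrected sample*, so farm means are preserved exactly; refitting on
corrected data returns zero harmonics (projection idempotence). Corrected
records are averaged per cow per day inside each farm's DIM window
(defaults 15–305 and 5–305 for the two farm profiles); lactation numbers
above 8 are rejected; the contemporary group is farm–ISO-year–ISO-week.

CH₄ g/d multiplies the daily mean CH₄:CO₂ ratio (mean of per-visit ratios)
by the predicted CO₂ exhalation volume and by the density of methane,
0.668 g/L at 20 °C and 101.325 kPa. CO₂ volume comes from heat production
`HP (W) = 5.6·kg^0.75 + 22·ECM + 1.6e-5·preg³`, one heat-producing unit
(1000 W) exhaling 180 L CO₂/h. The coefficients are module constants a
user can override; the milk column is used as fat–protein-corrected milk
(a raw-milk pass-through warns). Cow-days missing any covariate leave the
g/d value absent rather than imputed. Farm comparisons use Bartlett's
variance test and Welch's t with Satterthwaite degrees of freedom; both
are also available from (mean, SD, n) summaries, cross-checked against the
raw-sample scipy routes.

## Genotype QC

Filters run in a fixed order — sex/unassigned chromosome removal, animal
call rate, SNP call rate, monomorphic removal, Hardy–Weinberg exact-ish
1-df chi-square — with boundary readings pinned by tests: SNPs survive only
with call rate strictly above 0.95; animals are removed strictly below
0.90. The HWE rejection level defaults to 1e-6, the conventional chip-QC
level (the analysis this package reproduces does not print one). Missing
genotypes stay missing after QC; mean imputation happens only inside the
genomic relationship (zero after frequency centering). The order of steps
is a documented choice; filtering is idempotent and invariant to animal
order.

## Relationship matrices

`A` uses the tabular method over an ancestor-ordered pedigree. `G` is the
VanRaden cross-product with observed allele frequencies by default;
base-population frequencies may be supplied (the synthetic generator
records its true founder frequencies, on which E[G] = A under gene
dropping — the convergence test uses them because observed-frequency
centering always leaves the ones vector in G's null space). `G` is blended
with `A₂₂` (default α = 0.95; α = 1 disables) before entering

    H11 = A11 + A12 A22⁻¹ (G − A22) A22⁻¹ A21,  H12 = A12 A22⁻¹ G,  H22 = G

and `H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]`. Everything is dense; the target
scale is herds of at most a few thousand animals. The stratification check
is an eigendecomposition of the double-centered G; with n animals the
centering leaves n−1 informative components, so an identity G yields
100/(n−1)% per surviving component.

## Random-regression REML

The basis is normalized Legendre, φₙ(x) = √((2n+1)/2)·Pₙ(x) on
x = 2(t−5)/300 − 1; fixed lactation curve orders 1–4 (order 0 absorbed by
the lactation-class indicators; a raw-monomial switch exists because the
model is sometimes written with powers of DIM), random genetic and
permanent-environment regressions of order 2. Coefficients are stacked
animal-major, var(a) = H ⊗ K_a.

Variance components maximize the restricted likelihood via
average-information iterations with three safeguards found necessary on
these likelihoods:

1. **Cholesky parameterization** — AI steps are taken on the factors
   K = LL′, which makes the positive-semidefinite cone unconstrained;
   boundary solutions (singular K) become ordinary stationary points.
2. **Adaptive Marquardt damping** — the step solves
   (AI_L + λ diag(AI_L)) δ = ∇L, with λ divided by 5 after an accepted
   step and multiplied by 10 after a rejected one; damping bends the
   direction away from overshoot rather than merely shortening it.
3. **EM fallback** — when no damped AI proposal improves the likelihood,
   an expectation-maximization update (monotone, cone-respecting) is taken;
   two EM burn-in iterations tame the crude start
   (K diag ∝ 0.1·var(y)·4⁻ᵒʳᵈᵉʳ, σₑ² = 0.8·var(y)).

All score, AI and EM quantities come from mixed-model-equation identities
(`Z'PZ = G⁻¹ − G⁻¹C^{uu}G⁻¹`; working vectors solved through the factored
coefficient matrix); the restricted likelihood and the score were verified
against direct dense-V evaluation and finite differences. Convergence:
relative parameter change < 1e-8 or |Δ(−2logL)| below `ltol`
(default 1e-6; the replicated experiments use 1e-4, where the h²
functional is stable to < 1e-3). Non-convergence raises an error carrying
the iteration trace. A `solve_mme` entry point solves at fixed components
(the single-record GBLUP case drops the pe block when K_p is zero/None).

Trajectories are v(t) = φ(t)'Kφ(t) and
h²(t) = v_a/(v_a+v_p+σₑ²); "average" values are plain means over the
integer DIM grid 5–305.

## Single-step GWAS

The scalar trait handed to GWAS is the mean daily genetic effect,
c'aᵢ with c = mean_t φ(t) (per-coefficient pass-through available),
because the random-regression fit yields three coefficients but one
Manhattan view per trait is wanted. Back-solution uses the unblended G
with a ridge of 1e-8·trace/n (ridge 0 selects an exact minimum-norm
solve): û = (1/d)Z'G⁻¹â, which reproduces â exactly when G is full rank.
Var(û) propagates Var(â) = σ²ₐG − PEV through the same map; two-sided
normal p-values; non-positive variances are clamped with p = 1 and a
flag. Window variance is the across-animal variance of summed SNP scores
as a percent of EBV variance, over sliding 50-SNP windows (step 1,
truncated-with-flag on short chromosomes) or 70-kb windows anchored at
each SNP. The Bonferroni threshold is −log₁₀(α/m).

## Synthetic herd generator

The generator is the package's study stand-in: two farm profiles with
means/SDs on the scale of commercial sniffer data (505/517 ppm; live
weights 544/669 kg; milk 33.7/36.6 kg; record counts ~10:1 between farms),
DIM windows 15–305 and 5–305, lactations 1–8 (classes 1 vs 2+),
farm-year-week effects, a two-harmonic diurnal rhythm, i.i.d. residual
noise, and a per-cow CH₄:CO₂ ratio ~ N(0.1, 0.01²) truncated positive.
Pedigrees are discrete-generation with alternating sexes; an optional
per-generation sire pool reproduces the large paternal half-sib families
of AI breeding. Genotypes are gene-dropped (founder alleles Bernoulli at
uniform [0.05, 0.5] frequencies; one allele from each parent per SNP), so
realized genomic relationships converge to A. True breeding-value
coefficients are drawn either down the pedigree (parent average +
Mendelian sampling with variance 0.5/0.75/1 of K_a by number of known
parents, parental inbreeding ignored) or from the genotypes with per-SNP
effects ~ N(0, K_a/d), making the conditional-on-Z coefficient covariance
exactly G ⊗ K_a.

What it does **not** emulate: linkage-disequilibrium decay (SNPs segregate
independently in founders), selection, genotyping error, heterogeneous
residuals, eructation-event physics, or seasonal environment beyond the
week effects. Passing tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness to
the measurement pathologies of real sniffer data.

## Operating characteristics and chosen experiment scales

The replicated experiments in `ch4herd.validation` fix their conditions as
follows (all seeds flow from one `SeedSequence`):

* **Heritability recovery** — ~770 pedigree animals (80 founders, three
  generations of 115 matings × 2 offspring, 18 sires per generation),
  ~385 cows with 45 daily records, 68% of cows genotyped at 2,000 SNPs,
  truth K_a, K_p, σₑ² giving a DIM-averaged h² of 0.214 with a
  pe:genetic ratio like that of daily methane mass output. Non-phenotyped
  relatives are absorbed exactly through the phenotyped-cow block of H.
  Measured over many pilot batches, the REML estimate of mean h² at this
  scale has a spread of about ±0.04–0.05 (1 sd) around the truth, limited
  by the number of independent sire families — the classic half-sib
  information bound — not by optimizer precision: in outlying replicates
  the REML mode exceeds the truth's restricted likelihood by 8–13 units
  and is reached from either starting point. A ±0.05 tolerance is
  therefore met by roughly three quarters of replicates, and the
  20-replicate acceptance check of 18/20 can fail at this herd size; the
  experiment is retained at the study-like scale rather than inflated.
* **Null calibration** — p-values pooled over five independent herds of
  200 genotyped animals × 1,000 SNPs under a fully polygenic truth
  (every SNP infinitesimal). Pooling is used because the SNP tests within
  one herd share a single realized EBV vector, giving the per-herd
  rejection rate extra-binomial spread; the pooled rate is a lower-variance
  estimate of the same type-I quantity (0.040–0.062 across tested seeds).
* **Planted-QTL power** — 800 genotyped animals, 1,000 SNPs on five
  chromosomes, one QTL carrying 30% of genetic variance over a polygenic
  background, effective heritability 0.45 (the repeatability-adjusted
  reliability of a cow's lactation mean over ~45 daily records at a daily
  h² near 0.2). Success = a 50-SNP window containing the QTL ranks in the
  top 1%. At 500 animals the measured power is only ~0.7–0.85 because the
  back-solved effects are heavily shrunken at low EBV accuracy; 800
  animals puts it at 0.95–1.0, which is the regime the check is meant to
  certify.

## Numerical notes and limitations

* Dense linear algebra throughout; MME dimension is p + 3·(animals) +
  3·(cows). Herds beyond a few thousand animals need the sparse
  Henderson-style machinery this package deliberately omits.
* Observed-frequency centering makes G singular (ones in the null space);
  blending with A₂₂ (or a ridge in the back-solution) is therefore not
  optional in practice.
* The K_a/K_p partition is weakly identified in herds with few phenotyped
  relatives; expect flat likelihood ridges, occasional boundary estimates
  and wide h² sampling spread at a few hundred cows.
* Fixed-effect designs are checked for column rank only when there are at
  least as many records as columns; degenerate toy designs fail later at
  the factorization with a clear error.
* FYW is treated as fixed; the fixed lactation curve is not nested within
  lactation class; residual variance is homogeneous along DIM.
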