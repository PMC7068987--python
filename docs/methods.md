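# Methods

## Scope and data model

The package analyses pedigreed, SNP-genotyped pig populations with
repeated-measure-free phenotypes: one record per animal per trait, fixed
effects of line and contemporary group, a body-weight covariate, a
common-litter random effect, and an additive-genetic random effect with
pedigree covariance. Genotypes are biallelic dosages in {0, 1, 2} on the
18 pig autosomes; after QC they are complete (mean-imputed) and
real-valued imputations are allowed downstream.

## Genotype quality control

Order of operations: (1) calls with a quality (GenCall-type) score below
the threshold are replaced by the within-breed mean dosage of the marker;
(2) samples below the call-rate floor are removed; (3) markers below the
call-rate floor are removed; (4) markers below the MAF floor, computed on
the retained samples, are removed. The order itself is a design choice —
imputing before the call-rate filters avoids double-penalising markers
that were called but with low confidence, and computing MAF last uses the
final sample set. Mean imputation (not rounding to the nearest integer
dosage) is deliberate: it preserves the marker variance structure that
mixed-model and whole-genome-regression methods rely on. MAF is
`min(p, 1-p)` with `p = mean(dosage)/2` over non-missing calls. QC is
idempotent and the report reconciles exactly with the dimension changes
(property-tested).

## Relationship matrices

**A** is built by the tabular recursion (`a_ii = 1 + 0.5 a_sd`,
`a_ij = 0.5(a_{j,s} + a_{j,d})`, unknown parents contribute 0, no genetic
groups). Inbreeding is `F_i = a_ii - 1`; the summary statistic reported is
the mean F over animals with F > 0, the convention for quoting "mean
inbreeding of inbred animals". The test suite checks the tabular result
against an independent Wright path-coefficient enumeration on random tiny
pedigrees.

**G** follows VanRaden method 1, `G = ZZ' / (2 Σ p_k(1-p_k))` with
allele frequencies from the analysed samples — the field-standard choice;
with sample frequencies the off-diagonal mean is slightly negative by
construction (row sums of Z vanish), which is the expected behaviour for
within-population summaries. Fold-level summaries average off-diagonal
pairs only within a fold; including self-relationships would inflate the
within-fold mean.

## REML animal model

Variance components are estimated by restricted maximum likelihood with
average-information (AI) updates on the linear covariance structure
`V = Σ_r θ_r K_r`. Steps that reduce the likelihood or leave the
parameter space are step-halved; if no step is accepted, a multiplicative
fixed-point update (an EM-style move, positive by construction) is taken
on the variance parameters. Variance parameters pinned at the lower floor
(1e-8 × phenotypic variance) with negative score are frozen out of the
Newton system — without this active-set handling the near-singular AI
matrix stalls the remaining parameters. Convergence is declared when the
log-likelihood stops improving by more than the tolerance (default 1e-6),
with a three-iteration stall window because AI steps can dither at
round-off level near a flat optimum; the best iterate is returned.

Univariate two-component models (no litter effect) take a fast path: one
eigendecomposition of the relationship submatrix diagonalises V, making
each iteration O(n). Bivariate fits estimate full 2×2 genetic, litter and
residual covariance matrices; blocks that leave the PSD cone are
eigenvalue-clipped with a warning (boundary estimates such as r_G = ±1
are reported as such, not hidden).

Standard errors of h², c², r_G and r_P come from the delta method on the
inverse AI matrix at the optimum. Because additive and litter variances
are weakly separable when litters are few, the results object exposes the
sampling correlation between the two estimates
(`estimate_correlation("animal", "litter")`) as an identifiability
diagnostic. The body-weight covariate is centred before fitting
(conditioning only; estimates are unchanged). The heritability identity
used for tabulated components is `σ²_p = (σ²_a + σ²_e)/(1 − c²)`,
`h² = σ²_a/σ²_p`, i.e. the phenotypic variance is reconstructed from the
additive and residual variances and the litter ratio.

## Bayes-alphabet samplers

Single-site Gibbs throughout. The inclusion indicator of each marker is
drawn from the marginalised likelihood ratio (effect integrated out);
included effects are drawn from their conditional normal. BayesB samples
a per-marker effect variance from its scaled-inverse-χ² conditional
(prior draw when the marker is excluded); BayesC/C0 share one effect
variance; BayesCπ samples π from its conjugate Beta posterior on the
zero-effect count, `π ~ Beta(#excluded+1, #included+1)`. Fixed effects
have flat priors. Hyperpriors: effect-variance scale set so the prior
mean equals `σ̂²_a / ((1−π) Σ 2p_k(1−p_k))` with ν = 4.2; residual scale
from σ̂²_e with ν = 10 — the σ̂² values being the pedigree REML estimates.
Dosages are centred by training-set allele frequencies; the litter effect
is deliberately absent from this model (fixed effects + SNPs only).
Chains are reproducible bit-for-bit given the seed (the kernel is a
compiled single-threaded loop with an explicitly seeded RNG). Default
thinning is 1; chains at the published scale (50,000 iterations, 5,000
burn-in) are supported, while tests and the demo pipeline use shorter
chains at reduced problem sizes (stated below).

The BayesC0 posterior-mean GEBVs are validated against the closed-form
mixed-model-equation (ridge/GBLUP) solution with variance ratio
`σ²_e / (σ²_a / Σ2pq)`; the two agree to r ≥ 0.98 on a 60-animal,
200-marker simulation.

## Window summaries

Windows are half-open 1-Mb bins `[k, k+1)` Mb per chromosome. For each
retained draw, the window's genomic values (centred dosages × that draw's
effects) are computed across animals; the draw-level share is the
window's empirical variance over the sum across windows, and %TGVM is 100
× the posterior mean share. Averaging draw-level ratios (rather than the
ratio of averaged variances) propagates the joint posterior uncertainty;
the alternative is available via `per_draw_ratio=False`. Draws with no
included marker have undefined shares and are skipped (counted in the
output). PPI is the fraction of retained draws with ≥ 1 nonzero-effect
marker in the window — at π = 0.99 this convention yields PPI values in
the observed 0.5–0.9 range for real QTL windows. QTL calling seeds
windows at %TGVM ≥ 4.0 (configurable — reported regions in this
literature go as low as 3.4%) and merges same-chromosome seeds within a
1-Mb gap.

## Cross-validated prediction

Folds group 5 randomly ordered sires each; daughters inherit the sire's
fold, leftover sires' daughters join the smallest folds. Fixed effects
used to adjust validation phenotypes (y*) come from the training fit of
each fold — validation records never inform their own adjustment (a
leakage-safe choice; unseen factor levels contribute zero with a
warning). The GPA denominator is always the validation breed's pedigree
h², supplied as an input, not re-estimated per fold. Between-breed runs
are a single train/validate split (hence no across-fold SD); marker
panels are intersected after per-breed QC and monomorphic-in-training
markers get zero effects. Validation dosages are centred with
training-set allele frequencies. QTL-subset prediction always trains on
ALL markers so effect estimates are conditional on the whole genome;
subsets (per-QTL, QTL union, REST with 3-Mb flanks excluded) restrict
only the prediction sum, which makes subset GEBVs exactly additive.

## Synthetic populations

The generator emulates a purebred nucleus population: discrete
generations, each dam producing one litter per generation with a single
sire (every sire serves at least one dam when dams suffice), and the
final generation's females as the phenotyped cohort. Defaults mirror the
two study populations: cohorts of ~475 (Landrace-like, 20 sires) and
~708 (Yorkshire-like, 30 sires) gilts, litter size 10, three generations;
trait variance components, means, and body-weight distributions follow
the published per-breed tables (VH/VW as correlated traits, VA = VH×VW;
`va_direct_*` presets simulate vulva area as one trait with its published
components). Desk-scale genome defaults are 2,000 markers on 5
chromosomes of 100 Mb; a full-scale run (18 autosomes, 37k markers) is a
configuration change, not a code path.

Founder haplotypes use a Gaussian-copula block-LD model: markers within a
block share a latent variable with correlation 0.6, thresholded at each
marker's target allele-frequency quantile (founder MAF uniform on
[0.05, 0.5]). Descent is by gene dropping with recombination probability
0.01 × Mb between adjacent markers (1 cM/Mb, capped at 0.5). This is
deliberately simpler than a coalescent simulator: it produces the local
LD and family structure the pipeline's assumptions require, but not
long-range LD decay profiles, selection signatures, genotyping error, or
realistic recombination maps — so passing tests demonstrate correctness
of the estimators under the assumed model, not robustness to those
real-data features.

Breeding values are a sparse-QTL component (marker effects scaled so each
QTL carries a configured share of σ²_a at its observed heterozygosity;
all QTL can be planted in one 1-Mb window, whose marker support the map
generator guarantees) plus a polygenic remainder transmitted as parent
average + Mendelian sampling with variance `0.5(1 − F̄)σ²_poly` (parental
mean inbreeding from the pedigree; inbreeding adjustments beyond this
scaling are ignored). Cross-trait genetic correlations are imposed by
drawing QTL effect vectors and polygenic deviations from the target
correlation matrix. Two QTL-effect modes exist: fixed magnitude with MVN
sign (exact variance shares — used for planted-QTL power checks) and full
MVN magnitudes (exact cross-trait correlations — used by the correlated
multi-trait presets, since sign-only coupling attenuates the realized
r_G). Litter effects are drawn independent across traits; residuals take
an optional residual correlation (presets use 0.6, mimicking the observed
phenotypic correlations).

## Problem sizes in tests

Unit and acceptance tests run at desk scale, chosen as the smallest sizes
at which each statistical claim is decided: REML oracle checks use 50
sires × 20 daughters × 20 replicates; the GBLUP-limit check 60 animals ×
200 markers × 5,000 iterations; planted-QTL window recovery 600-gilt
cohorts × 2,000 markers × 2,000-iteration chains × 10 seeds; the
between- vs within-breed contrast ~300-gilt cohorts × 800 markers × 10
seeds. The full suite completes in about two minutes on one core.

## Known limitations

- REML is dense-matrix; cohorts beyond ~5,000 records per trait would
  need sparse mixed-model equations.
- BayesB's per-marker variance update samples the variance given the
  current effect rather than integrating it out (the common Gibbs
  implementation); mixing is adequate at the tested scales.
- The generator's LD model has no population-history interpretation;
  realized LD between a planted QTL and its window-mates varies by seed,
  which is why window-level (not marker-level) recovery is the tested
  claim.
- Between-breed prediction in the synthetic world is null by
  construction when QTL are disjoint; the consistently negative
  accuracies reported for real breed pairs (opposite-phase small-effect
  QTL) are not modelled.
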