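# Methods

`hetfix` analyzes heterosis and inbreeding depression in clonally propagated
hybrid crops from pseudo-diploid SNP-array genotypes and multi-year clonal
field trials, and ships a simulator that generates data with the same
statistical structure so that every stage can be tested against known truth.
This note records the models, the defaults and why they were chosen, the
numerical decisions, and the limits of what the synthetic checks demonstrate.

## Genotype representation

Array calls on a polyploid are pseudo-diploid: three genotype classes per
biallelic marker, coded as alternate-allele dosages {0, 1, 2} with missing as
NA. All statistics in the package operate on these calls; true polyploid
allele dosage and phase are out of scope. QC follows standard array
practice: samples with call rate ≤ 0.90 are dropped first, then markers with
minor-allele frequency < 0.05 or > 10% missing calls. The MAF threshold is
read as 5% (a figure sometimes typeset as "0.05%" in array literature); it
is a configuration knob.

## Diversity and inbreeding

Observed heterozygosity is Ho_i = n_het,i / n_nonmissing,i. Two inbreeding
estimators are provided: `one_minus_H` (F = 1 − Ho), the estimator used for
headline per-individual statements on array calls, and `excess_homozygosity`
F = (O_hom − E_hom)/(m − E_hom) with E_hom = Σ_j (1 − 2 p_j q_j) over the
individual's nonmissing markers, allele frequencies taken from the analyzed
panel itself. The two agree in rank order (checked by simulation,
Spearman ρ > 0.95); `one_minus_H` is the default. Effective population size
uses one-generation heterozygosity decay, Ne = −1/(2 ln(H1/H0)); when
H1 ≥ H0 the estimator is reported non-finite with a warning. Evaluated at
the rounded published inputs (0.355, 0.313) the formula gives 3.97 where the
original analysis printed 3.91 from unrounded inputs — a ~1.5% input-rounding
discrepancy documented rather than hidden.

## Relationship matrices and PCA

The additive GRM is VanRaden method 1: K_A = WW′/(2 Σ p_j q_j) with W the
dosage matrix centred by 2p_j; missing calls are mean-imputed per marker.
The dominance matrix uses the classical mean-centred covariate (−2p², 2pq,
−2q² for dosages 0, 1, 2 with p the counted-allele frequency) and
denominator Σ(2 p_j q_j)²; a missing call imputes to the covariate's HWE
mean of zero. Monomorphic markers are excluded from both. PCA scores come
from the eigendecomposition of the centred-dosage Gram matrix (equivalent to
the SVD, cheaper when markers outnumber individuals), with the deterministic
sign convention that each component's largest-magnitude score is positive.

## Parentage forensics

Duo and trio transgression ratios count Mendelian-impossible configurations:
S_i = 1 iff offspring and candidate parent carry opposite homozygotes;
T_i = 1 iff the offspring is heterozygous while both candidate parents are
the same homozygote; TTR sums T_i + S1_i + S2_i − S1_i·S2_i over markers (the
product term prevents double counting a marker where both duos transgress).
Markers missing in any member of the duo/trio are excluded from the
denominator, so components share one marker set. True relationships score
exactly 0 on error-free genotypes; the scan's default pass/fail threshold of
0.01 tolerates realistic per-call error rates (at a 1% error rate, true-duo
DTR stays an order of magnitude below unrelated-pair levels, which sit near
the panel's mean 2p²q²). Self-duos are excluded from scans.

## The REML engine

All variance-component models are fitted by a single engine: restricted (or
full) maximum likelihood via average-information (AI) updates with EM
fallback steps and step halving, so the objective is non-decreasing across
iterations. Convergence is declared when the relative change in the
(restricted) log-likelihood falls below 1e−8 or after 200 iterations
(non-convergence is flagged and the last iterate returned); a point where
neither a damped AI step nor an EM step improves the objective is treated as
a (possibly boundary-constrained) optimum. Non-negative components are kept
off zero by a floor of 1e−8 × var(y) and reported as exact zeros when pinned
there. Two equivalent evaluation paths are used: a Woodbury-identity path
in the total random-effect dimension (fast for trial models with thousands
of plots and factor-coded effects) and a dense n × n path that also accepts
covariance terms, including sign-unconstrained ones for covariance
components. The engine is cross-checked in the test suite against the
balanced one-way ANOVA expected-mean-squares closed form and against
`lme4::lmer` on a crossed genotype/year/block design.

## Trial model, EMMs, heritability

The across-year model per trait is y = genotype + block + year +
genotype×year + residual, genotype fixed for estimated marginal means and
random for variance components. Harvest-level records are aggregated to
plot-level season totals (yield-like traits) or means (quality traits)
before modelling. With cell-means coding each genotype's fixed-effect GLS
coefficient is its EMM, averaging over the random year and block effects; in
a balanced design this equals the genotype's arithmetic plot mean (verified
to 1e−8). Contrast SEs come from the full GLS coefficient covariance;
degrees of freedom are residual-based (n − p), not Kenward–Roger.
Clone-mean broad-sense heritability is H² = σ²_G /(σ²_G + σ²_G×Y/y +
σ²_E/(r y)) with y the number of years and r the harmonic mean of realized
plots per genotype per year. Narrow-sense h² = σ²_A/(σ²_A + σ²_resid) from
a single-kernel (K_A) model on EMMs.

Genetic correlations between trait pairs use a bivariate model on
mean-centred, unit-scaled EMMs with an unstructured 2×2 additive covariance
(K_A kernel) and an unstructured 2×2 residual; after scaling, the additive
covariance is the correlation, and its p-value is the upper-tail standard
normal of the Z-ratio (estimate over the asymptotic SE from the inverse AI
matrix). Affinely identical inputs make the bivariate covariance singular
and short-circuit to the degenerate r_G = ±1; non-convergence falls back to
the correlation of per-trait additive BLUPs, flagged as such.

## Heterosis contrasts

MPH = ȳ_F1 − (ȳ_P1 + ȳ_P2)/2 and BPH = ȳ_F1 − ȳ_BP, with percentages on the
mid-/best-parent scale. The best parent of an elite×elite hybrid is the one
with the greater EMM (ties broken by ID order and flagged); for elite×exotic
hybrids the elite parent is best by definition — the exotic is a donor being
screened, not a benchmark — so BPH remains defined even when the exotic
parent could not be phenotyped, while MPH requires both parent EMMs and is
otherwise left missing. Significance uses per-contrast Wald tests at α
(default 0.05) with no multiple-testing correction across hybrids (a knob);
summary tables report, per trait and cross class, the percentage of hybrids
significantly negative / not significant / significantly positive, and the
percentage below (and significantly below) the worst parent.

A calibration subtlety: with segregating purely additive QTLs, each
individual F1 genuinely deviates from its mid-parent through Mendelian
segregation variance, so the mean MPH is zero but per-hybrid contrasts are
not null hypotheses. The machinery's type-I calibration is therefore
checked in the zero-genetic-variance limit, where the significantly-positive
MPH rate sits at α/2; under segregating additivity the package checks
mean MPH ≈ 0 instead. Because best-parent selection maximizes over noisy
parent EMMs, the BPH contrast is biased downward under the null, so its
significantly-positive rate is bounded by — not equal to — α/2.

Trait-on-heterozygosity regressions fit degree-1 and degree-2 polynomials to
EMM, MPH, or BPH; the quadratic term is tested by the exact OLS F-test, or,
when additive and dominance kernels are supplied, by a maximum-likelihood
ratio test inside the kernel mixed model (ML, not REML, because the nested
models differ in fixed effects).

## Directional dominance and the marker scan

The homozygosity-covariate model Y = μ + β·Ho (+ β₂·Ho²) + A + D + ε with
A ~ N(0, K_A σ²_A), D ~ N(0, K_D σ²_D) measures inbreeding depression per
unit homozygosity: under predominantly positive dominance deviations β is
negative for the depressed traits. Ho is centred before fitting; a constant
Ho is dropped with a warning. The degree-1 vs degree-2 comparison is a
1-df ML likelihood-ratio test.

The marker scan tests each marker's additive (dosage) effect by GLS in a
mixed model with K_A, with variance components estimated once under the null
model and reused per marker (the population-parameters-previously-determined
approximation; exact per-marker REML is available behind a flag and agrees
with the approximation to a few percent). Monomorphic markers are skipped;
the genome-wide significance threshold defaults to 5×10⁻⁸. Null p-values
are uniform (KS-checked) and a marker explaining ~20% of variance at n = 400
is recovered as the top hit essentially always — on a linkage-equilibrium
panel. In a bottlenecked population the drift LD between markers makes
single-marker attribution genuinely ambiguous, which is a property of such
data, not of the estimator.

## Single-locus generation-means theory

With genotype values (−a, d, +a) for favorable-allele dosages (0, 1, 2), the
HWE population mean is a(2p−1) + 2pq·d; the cross of two populations with
favorable frequencies p1, p2 has mid-parent heterosis d(p1−p2)²; inbreeding
a population to coefficient F costs 2pq·d·F (baseline heterosis); and
inbred-MPH (fully inbred parent means) adds d(p1q1 + p2q2). All derive from
genotype-frequency enumeration (the test suite re-derives them for random
parameter draws) and all vanish as p → 1: fixation of the favorable dominant
allele extinguishes heterosis, which is the theoretical core of the
analysis. Quantities add across independent loci, and the simulator's mean
F1 heterosis matches the multi-locus sum Σ d_j (p1j − p2j)² within sampling
error, bridging theory and simulation.

## The simulator

The generator emulates the target study design: 27 elite and 3 exotic
founders, 356 elite×elite and 113 elite×exotic F1 hybrids, 31 S1 selfs of 9
elite parents, a randomized-complete-blocks clonal trial with 3 blocks
repeated over 2 years and ~12 weekly harvests, and a filtered panel of
28,523 biallelic markers spread over 28 chromosomes. Between-group
divergence is a Balding–Nichols draw of group frequencies around shared
ancestral frequencies (uniform on [0.1, 0.9]), giving expected
Weir–Cockerham FST equal to the configured divergence (default 0.2).
Markers are unlinked by default; an optional Haldane map per chromosome
(default 1 Morgan) supports linked transmission, with heterozygous founder
sites phased uniformly at random — valid for the single-generation crosses
the package supports.

Elite founders descend from crosses among a small ancestor pool (default 4),
making them consanguineous: their hybrids lose heterozygosity at roughly
1/(2·4) per generation, which reproduces the study-scale one-generation
decay (Ne ≈ 4 for within-elite crosses, larger when outbred exotic crosses
are added). Setting `n_elite_ancestors = 0` yields unrelated HWE founders;
the FST and HWE calibration tests use that setting because they probe the
divergence machinery itself, on which bottleneck drift is a confounder.

Trait architecture: each trait has n_qtl loci with additive effects
a ~ Exponential(scale) and dominance deviations d = δ·a, δ ~ N(δ_mean, δ_sd).
δ_mean > 0 encodes directional dominance (defaults 0.8/0.7/0.5 for the
yield-like, count-like and weight-like traits; 0 for the unselected
quality trait), the prerequisite for heterosis and inbreeding depression. A
`load_fraction` (default 0.2–0.3) of QTLs model deleterious partially
recessive alleles: their δ is forced strongly positive so the unfavorable
allele is masked in heterozygotes and exposed by selfing. Two QTL placement
modes capture selection history: `qtl_elite_fixed` puts QTLs where the
favorable allele is near fixation among elites but not exotics (the
footprint that makes estimated additive effects grow when wide hybrids enter
a scan), and `qtl_balanced` restricts QTLs to markers with similar group
frequencies (an unselected trait segregating everywhere). Genotype value:
dosage 0 → −a, 1 → d, 2 → +a.

Phenotypes: plot value = μ + genetic value + block + year + G×Y + residual,
all random terms Gaussian with configured variances, stated at the
plot (aggregated) level; harvest-level records are constructed so that the
configured components are reproduced exactly after season aggregation
(totals for yield-like, means for quality-like traits). Blocks share
effects across years, matching the analysis model. One exotic founder is
left unphenotyped by default, mirroring a donor that cannot be clonally
propagated, so its hybrids exercise the BPH-only code path. Genotyping
error and missingness are injected independently per call after all
Mendelian sampling.

What the simulator does not emulate: real linkage disequilibrium structure
and selective sweeps, array intensity-clustering artifacts, subgenome
homoeology, spatial field trends, multi-generation selection, or
non-Gaussian trait distributions (fruit counts are simulated as Gaussian).
Passing the synthetic checks therefore demonstrates correctness of the
estimators and calibration of their tests under the assumed generative
model, not robustness to every failure mode of real field and array data.

## Problem sizes and determinism

Everything is deterministic given the configured seeds (verified
byte-identical pipeline outputs across reruns). The test suite and the
acceptance script run the stochastic checks at reduced but statistically
adequate sizes chosen as a deliberate scaling of the study design: REML
recovery at 300 genotypes × 2 years × 3 blocks over 50 (tests) or 20
(script) replicates; directional-dominance sign recovery at n = 400
individuals over 50/20 replicates; forensics exactness at 50 individuals ×
2,000 markers; scan calibration at n = 400 × 2,000 markers. The full
study-scale configuration (469 hybrids, 28,523 markers) is the simulator
default and runs end to end in a few minutes via `hetfix all`.
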