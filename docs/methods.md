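# Methods

## The problem and the model

Case–control GWAS data give, for each of n individuals, a disease status
y ∈ {0, 1} and L biallelic SNP genotypes coded as minor-allele counts
g ∈ {0, 1, 2}.  A pairwise interaction search asks whether any of the
L(L−1)/2 genotype *pairs* separates cases from controls beyond what single
markers do.  Testing every pair's 3×3 genotype table runs into two walls:
the multiple-testing burden of ~10^11 correlated hypotheses at genome
scale, and sparse cells that break the asymptotics of saturated-table
tests.  This package instead treats the search as ultrahigh-dimensional
variable selection in a logistic regression

    logit P(y = 1) = β0 + Σ_j β_j X_j,

where the X_j are dummy predictors built from genotype pairs, and follows
the two-step sure-independence-screening (SIS) recipe: marginal ranking of
all predictors, then penalized multiple regression on the d survivors.

## Dummy coding

Every predictor reduces a pair to a 2×2 case/control × exposed/unexposed
table, which sidesteps the sparse-cell problem and keeps effect sizes
interpretable as odds ratios.  Two codings are provided:

* **CDC (cell-wise dummy coding)** — one indicator per cell of the 3×3
  table (cell index 3·g1 + g2), nine per pair, plus three genotype
  indicators per single SNP: 9L(L−1)/2 + 3L candidates in total.  CDC
  shines when one or a few cells carry the signal (including the
  "dominance" pattern of concentrated diagonal cells between linked SNPs).
* **ADC (adaptive dummy coding)** — one indicator per pair, defined by the
  high-risk/low-risk bipartition of the nine cells that maximizes balanced
  accuracy BA = (sensitivity + specificity)/2 over all 2⁹ − 2 = 510
  nontrivial assignments, evaluated on the original data (no
  cross-validation; the penalized step is the validation).  ADC pools
  cells, so it is the more stable choice for spread-out interaction
  patterns, and it never occupies more than one ranking slot per pair.

Ties in the BA maximization resolve to the smallest mask integer.  The
blocked scan uses a closed form — keep exactly the cells with positive
case_k·n_ctrl − ctrl_k·n_case — which provably attains the enumeration
optimum including its tie-breaks; the 510-way enumeration remains in
`adc_best_partition` and the two are cross-checked in the tests.

## Ranking criteria

Each candidate's 2×2 table is scored after a continuity correction (+0.5
to all four cells *only* when a zero cell appears) by either

* the likelihood-ratio statistic G² of the table (equivalently, the LR
  test of zero slope in the univariate logistic regression on that
  indicator), or
* the two-sided Wald p-value of the log odds ratio.

The three published strategy names combine coding and criterion: LCDC
(CDC + likelihood), PCDC (CDC + p-value), PADC (ADC + p-value).  Ordering
by ascending Wald p equals ordering by descending |log OR|/SE until p
underflows double precision, where |z| is the documented fallback — the
implementation therefore ranks directly on |z|.  Remaining ties break
deterministically: pairs in row-major (i, j) order with ascending
cell/mask, then main effects.  The top d = 256 survive (the fixed choice
used throughout; `recommended_d` exposes ⌊0.25·n/ln n⌋ for reference).

The scan is blocked and never materializes all candidates: pair-cell
counts for a block of row-SNPs come from four float32 indicator-matrix
products per phenotype group (exact for integer counts below 2²⁴), the
other five cells follow from genotype margins, and a running top-d pool is
merged per block.  G² is evaluated through a lookup table of x·log x at
half-integer counts, bit-identical to the scalar formula, so the blocked
ranking equals a naive full sort exactly.

## Penalized regression step

The d surviving indicators (plus an unpenalized intercept) enter a ridge
smooth-thresholding logistic regression.  Initial coefficients β̂(0) come
from a joint ridge logistic fit with λ₂ = 1/n; if the Newton solve fails
(singular or non-finite system), λ₂ is multiplied by 10 and the fit
retried, up to 12 escalations.  For a threshold λ ≥ 0,

    δ_j = min(1, λ / β̂_j(0)²),   active set A = {j : δ_j < 1},

coefficients outside A are exactly zero, and the active ones minimize
−ℓ(β) + ½ Σ_{j∈A} [λ₂ + δ_j/(1−δ_j)] β_j², fitted by damped Newton/IRLS
(step-halving keeps the penalized objective monotone; coefficient-change
tolerance 1e−8; 100 iterations for the ridge init, 200 for path fits).
The printed source formula is ambiguous between δ = λ/β̂² and
δ = (λ/|β̂|)²; we implement the former, isolated in `st_weights`.  On the
breakpoint path used here the distinction vanishes: at λ just above the
k-th largest β̂², both readings give δ_j = β̂_k²/β̂_j² for every active j,
so all path fits are identical under either reading.

λ is tuned by the extended BIC,

    EBIC(γ) = −2 ℓ(β̂) + (ln n + 2γ ln p) · dim(β̂),   γ ∈ [0, 1],

with ℓ the *unpenalized* log-likelihood at the shrunken solution, dim the
number of nonzero non-intercept coefficients, and p the saturated
dimension *before* screening — 9L(L−1)/2 + 3L for CDC and L(L−1)/2 for
ADC (main-effect dummies are candidates under ADC but excluded from its
p, following the printed convention).  The λ candidates are the active-set
breakpoints {0} ∪ {β̂_j(0)²(1+1e−9)}: consecutive points differ exactly by
the coefficients they deactivate, so every threshold-reachable model is
visited once, each at the λ giving its mildest shrinkage, and selection is
deterministic and complete (a λ grid could only visit a subset of these
models).  EBIC ties resolve to the smaller dimension, then the larger λ.
Because the fitted path is shared, evaluating a γ grid is a cheap
re-scoring; the selected dimension is non-increasing in γ by a standard
exchange argument, which the tests assert on every run.

γ defaults to 0.6; the type-1-error study below supports γ ≈ 0.4–0.5 for
LCDC/PCDC and 0.6–0.7 for PADC as practical operating points.

## Synthetic data

`simulate_null` draws, per SNP, a MAF uniform on [0.05, 0.5] (the no-LD
null scenario's interval) and genotypes Binomial(2, MAF) independently per
individual — Hardy–Weinberg equilibrium, no linkage disequilibrium — with
the phenotype assigned by group membership (default 500/500).
`simulate_epistasis` places a causal pair at the first and last SNP,
draws causal genotypes under HWE at the model MAFs, samples disease from a
user-supplied 3×3 penetrance matrix, and fills both groups by rejection
sampling; the other SNPs are null.  The shipped example penetrance
shapes (multiplicative, threshold, XOR, heterogeneity) are synthetic
reconstructions of the classic two-locus families, not copies of any
published table.

For LD smoke tests, `simulate_null_ld` builds each haplotype from a
latent AR(1) Gaussian series thresholded at the per-SNP allele-frequency
quantile, giving locally correlated genotypes with the same marginals;
it is a qualitative stand-in (real LD maps require external marker data)
and no LD-scenario rates are claimed from it.

What the main generators do *not* emulate: realistic LD structure (real
SNP panels are locally correlated; LD inflates type-1 error of any
multiple-regression selection, so the headline null rates are the no-LD
baseline), genotyping error and missingness, covariates, and population
structure.  Passing tests therefore demonstrate correctness of the
machinery and its behavior under the stated sampling models, not
performance guarantees on real cohorts.

Each experiment replicate derives its RNG stream from
SeedSequence(seed, spawn_key=(replicate,)), so experiments are
reproducible and order-independent.

## Experiment definitions

* **Type-1 error (study-wise)**: fraction of null replicates in which the
  selected model is non-empty at a given γ — any non-intercept predictor,
  main effects included, is a false positive under the global null.
* **Power**: fraction of replicates in which a *pair* predictor (cell or
  partition) of the causal pair is selected; main-effect dummies of causal
  SNPs do not count, since they do not demonstrate interaction detection.

## Problem sizes used

The acceptance script runs the null scenario at its stated size (1000
SNPs, 500/500) with 100 replicates for LCDC and PCDC and 50 for PADC,
reporting rates at the γ values of interest; the recovery experiments use
50 SNPs, 400/400, 50 seeds.  These counts were chosen as the package's
standard verification scale; binomial-error bands quoted alongside rates
use 3·√(p(1−p)/R).

## Numerical choices and edge cases

* Genotype 0/1/2 is the minor-allele count; PLINK input counts the A1
  allele per the .bim columns (A1 = minor by convention), and missing
  genotypes (bed code 01) are a hard error naming SNP and sample.
* QC (control-based, as in the WTCCC-style filter): keep SNPs with
  control MAF > 0.05 and control HWE exact-test p ≥ 5.7e−7.  The HWE test
  is the exact conditional test on the heterozygote count.  The filter is
  idempotent; an empty result is allowed and reported.
* `balanced_accuracy` refuses tables with an empty case or control
  margin; ADC partition search operates on raw counts, with the
  continuity correction applied only to the ranking statistics.
* A ridge coefficient initialized exactly at zero is excluded (δ = 1) for
  any λ > 0, by continuity; λ = 0 activates everything with δ = 0 and
  reproduces the plain ridge fit to 1e−8.
* Reported zeros in fitted coefficient vectors are exact zeros.
* Reported per-predictor OR/CI/p in results files are the marginal
  corrected-table values; the multivariable coefficient is given
  alongside.

## Known limitations

* The joint ridge initialization at λ₂ = 1/n is weak; when the screened
  set contains strongly correlated predictors (e.g. the family of cells
  and main effects around one true interaction, or quasi-separating rare
  cells), coefficients can inflate in compensating directions and the
  β̂(0)² ordering — which fixes the nesting of all reachable active sets —
  need not place the strongest marginal signal first.  Smooth-thresholding
  then shrinks near-threshold coefficients hard, which can suppress
  detection of a genuinely planted effect at mid-range γ.  This
  multicollinearity sensitivity is a known open issue of the method
  itself; the package reports it honestly rather than quietly altering
  the procedure.
* Exact type-1-error rates at a given γ depend on which λ values the
  selection step can reach.  The breakpoint path used here dominates any
  λ grid (it sees every reachable model at mildest shrinkage), so its
  rates are an upper bound on grid-based variants of the same procedure;
  rates from such variants can sit below ours at the same γ,
  and the γ calibration should be read per-implementation.
* No LD-aware null calibration, covariates, non-binary phenotypes,
  missing-genotype handling, or iterated (ISIS-style) re-screening.
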