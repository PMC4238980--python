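# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the places where the design was genuinely open.

## QTL mapping

**Scan models.** The scan is marker regression: one test per genotyped
marker, no pseudomarker imputation. At the marker density the pipeline
targets (tens of markers per chromosome) interval mapping adds little, and
peaks are reported at marker resolution; this is a documented limitation.
Genotype enters as the three F2 classes, never as a dosage, so dominance is
not assumed away.

* *Nonparametric model* (continuous traits): Kruskal–Wallis H across the
  genotype groups on the trait ranks, with the standard tie correction,
  mapped to the LOD scale as `LOD = H / (2 ln 10)` — the usual χ²-to-LOD
  convention with 2 df. Rank statistics make the scan invariant under any
  strictly monotone transform of the trait.
* *Covariates in the nonparametric scan*: the trait is first residualized
  on the covariates (least squares, with intercept), then ranked. Classic
  nonparametric scan software does not define covariate handling; the
  residualize-then-rank rule keeps the rank machinery intact while removing
  additive covariate signal, and is recorded in the scan metadata. Age at
  death is the covariate for tumor traits; age and primary tumor burden for
  metastasis traits.
* *Binary model*: per marker, maximized logistic log-likelihoods with and
  without two genotype indicator terms, covariates in both models;
  `LOD = (ℓ_full − ℓ_null)/ln 10`, floored at 0. Complete separation is
  caught by a cap on the linear predictor (|η| ≤ 30); the capped fit is
  reported with a `separation` flag.

**Permutation significance.** Rows of the (trait, covariates) block are
permuted jointly against the genotype rows; the genome-wide threshold is
the empirical (1 − α) quantile (`method="higher"`, so α = 1 gives the
minimum) of the per-permutation maximum LOD, and the genome p of a peak is
the add-one estimator `(#{max_perm ≥ obs} + 1)/(n_perm + 1)`. Two
identities keep this exact but fast: residualize-then-rank commutes with a
joint row permutation, so nonparametric permutations reduce to permuting
the precomputed rank vector (the whole null sample is then three matrix
products); and the binary null model depends only on the jointly permuted
block, so its likelihood is permutation-invariant and only the full models
are refitted (batched Newton iterations across markers).

**Support intervals and regions.** The 2-LOD support interval scans
outward from the peak marker until the LOD first falls below peak − 2; the
interval is the bp span of the outermost contiguous markers still within
the drop, truncated at chromosome ends. Ties at the maximum resolve to the
leftmost marker. Same-chromosome intervals sharing at least one bp are
unioned into genomic regions; intervals that merely touch end-to-start+1
do not merge.

## eQTL scan

For each SNP × transcript pair, OLS of log2 expression on NOD-allele
dosage (additive 0/1/2 coding — one β per record) plus covariates. The
implementation residualizes both sides on the covariate design and uses
the partial-regression identities, vectorized over transcripts;
t = β/SE with df = n − (covariates + 2), two-sided p from the t
distribution. SNPs with missing calls fall back to per-SNP complete-case
computation; zero-variance SNPs are skipped and counted.

The low-expression filter removes transcripts whose mean (over all
samples) is below the linearly interpolated 10th percentile of the
per-transcript means; ties at the cut are retained.

Classification: different chromosomes → trans; same chromosome and
|SNP − TSS| ≤ 1 Mb (inclusive) → proximal; otherwise distal. BH FDR is
computed jointly across all tested pairs by default; a stratified mode
(proximal vs distal/trans corrected separately) is available because
standard matrix-eQTL tooling supports either convention. A p-value
prefilter can bound memory; q-values are then computed against the exact
test count, which is conservative for the stored records (dropping the
tail can only raise the step-up cumulative minimum).

## Trait correlation and nomination

Transcript membership in a QTL is by TSS position inside the 2-LOD
interval (a single consistent coordinate per transcript, the same one the
eQTL classification uses). Continuous traits: Pearson r with the df = n−2
t test. Binary traits: two-sample t-test of expression between classes,
equal-variance by default with Welch behind a flag (the choice is not
dictated by the procedure being mirrored; equal-variance is the classical
default). FDR is one family per QTL, mirroring per-QTL correlation
reporting.

A candidate is a (transcript, SNP) pair satisfying all three clauses:
TSS in interval, proximal eQTL with q < 0.05, trait correlation with
q < 0.05 for that QTL's trait. The proximal SNP itself need not lie inside
the interval — only the transcript must — with a stricter SNP-in-interval
mode behind a flag. Candidates lacking a human ortholog are dropped.
The founder-direction annotation requires a per-SNP declaration of which
founder contributed the counted allele; a single global convention cannot
reproduce mixed directions across SNPs, so the assignment is an input.

## Human-cohort validation

z-scores are (x − μ_ref)/σ_ref with σ computed over the reference set
(population ddof = 0); the reference set is all samples or, in diploid
mode, the diploid-flagged subset. Stepwise logistic regression is forward
selection on Wald p < 0.05 with backward removal at p > 0.10 after every
addition, iterated to a fixpoint — the common defaults of stepwise
implementations; the published procedure names only "stepwise", so the
thresholds and the Wald (rather than likelihood-ratio) criterion are
package choices, both configurable. Genes provoking separation are flagged
and excluded from selection rather than silently winning.

Risk and protective gene sets are unions over cohorts of genes with
OR > 1 and OR < 1; a gene appearing in both directions raises an error
rather than being resolved silently. A case is altered when z ≥ 2 for at
least one risk-set gene (boundary inclusive); survival compares altered vs
all other cases by Kaplan–Meier curves (lifelines) and the two-group
log-rank test with the hypergeometric variance over distinct event times.

## Case-case GWAS

All analyses are within cases (aggressive vs non-aggressive), so HWE QC
runs on the case cohort. The HWE test is the exact Levene–Haldane
enumeration (probabilities of all heterozygote configurations given the
allele counts, summing those no more probable than observed); the χ²(1 df)
test is available by flag. Monomorphic SNPs get p = 1 and are retained
with a flag. SNPs map to genes within a 100 kb radius of the gene span
(distance 0 inside the gene); a SNP may map to several genes.

Association is a binomial glm with logit link: outcome ~ dosage + age +
PC1 + PC2 + PC3, age continuous. Reported are OR = e^β with the 95% Wald
CI, the Wald z, the asymptotic p and the per-group minor-allele
frequencies. Permutation p-values (outcome labels shuffled across
subjects, covariates staying put, statistic |t| of the dosage term,
add-one estimator so the smallest attainable value is 1/(n_perm+1)) are
computed only for records with asymptotic p < 0.01. A separated refit
counts as a statistic larger than any finite one.

## Integration

High-priority genes = risk-set genes with ≥ 1 GWAS record at permutation
p < 0.05. The protective set never feeds the intersection (its survival
association is treated as unestablished). `pipeline_run` executes the
stages as a DAG of file-pure steps; every summary count is recomputable
from the stage TSVs.

## The synthetic-data model

The generator reproduces the study conditions: 228 F2 males; 126 tumors
with expression; human cohorts of 246 and 131 cases; a GWAS cohort of
1,172 cases. Meiosis is Haldane (no interference): adjacent-marker
recombination `c = (1 − e^(−2d/100))/2`; two independent gametes per
individual, dosage = NOD-allele count. Binary traits use a logistic link
on the same linear predictor as continuous ones (matching the binary scan
model downstream, rather than a liability threshold). Expression is
baseline + Σβ·dosage + λ·standardized trait + noise, with λ chosen to hit
a target correlation, and an 8% background tail near the array floor
(3.04 ± 0.12 log2 units) so the percentile filter has real work. The GWAS
cohort is drawn under HWE with two latent ancestry axes plus noise as the
PC covariates; no confounding is planted unless asked.

Effect sizes the source tables only bracket were fixed once at
field-typical values: cis β = 0.5 (the published candidate βs span
0.08–0.92), trait correlation target 0.4, human per-z log-odds 1.0 on each
gene's primary clinical variable, survival hazard ratio 2.5 for altered
cases, GWAS OR 1.6 at MAF 0.3. The default study plants three genes end to
end; each expression-bearing QTL spreads its effect over two adjacent
markers so the 2-LOD interval reliably spans the planted transcripts —
the broad multi-marker intervals typical of an F2 cross. Planted risk
genes also carry weaker positive effects on the non-primary clinical
variables, reflecting that aggressiveness variables are correlated
manifestations of one phenotype; without this, spurious wrong-direction
selections would occasionally trip the gene-set conflict error.

What the generator does **not** emulate: linkage disequilibrium beyond
map-distance decay, array probe effects, copy-number or somatic-mutation
structure, population stratification confounding, or informative
censoring. Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the stated model, not robustness to those
real-data complications.

## Numerical choices and scales

Permutation counts default to 10,000 in configuration; the test suite and
the acceptance script run the synthetic pipeline at 1,000 permutations per
test and the calibration suites at 200, sizes chosen to keep the full
suite in the minutes range while leaving the add-one estimator resolution
(≥ 1/1001) far below every decision threshold it feeds. Stochastic suites
run at 25–200 replicates with fixed seeds. Logistic fitting uses
statsmodels for every reported record; the in-package Newton/IRLS solver
(ridge 1e-10, |η| cap 30, tolerance 1e-10) serves only permutation inner
loops and is validated against statsmodels in the tests. BH q-values come
from statsmodels' `multipletests`. Quantiles: the permutation threshold
uses the `higher` method (slightly conservative); the expression filter
uses linear interpolation.

## Known limitations

Marker-resolution scans (no interval mapping); no multiple-QTL or
interaction models; no haplotype-block analysis; the stepwise procedure
inherits the usual instability of forward selection under collinearity;
the exact HWE p is the plain (not mid-p) estimator; Storey q-values are
not implemented (BH throughout).
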