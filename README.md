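# sysgen

Systems-genetics nomination and cross-validation of aggressive-cancer
susceptibility genes.

## The problem

Most prostate cancers run an indolent course; a small subset turns
aggressive and lethal, and germline variation is thought to modulate that
risk. A forward-genetics route to such modifiers starts in a mouse model:
map quantitative trait loci (QTLs) for aggressive-disease traits in an F2
intercross, nominate the genes inside those loci whose expression is both
genetically driven and trait-correlated, then ask whether the human
orthologs of those genes carry the same signal in patient cohorts — in
tumor expression data and in a case-case genome-wide association study
(GWAS) that contrasts aggressive against non-aggressive disease rather than
cases against controls.

`sysgen` implements that full pipeline as a tested, reusable library with a
thin CLI, plus a synthetic-data generator that plants known genetic and
expression effects so every stage can be validated offline against ground
truth.

## The method

1. **F2 QTL scan** — single-locus marker regression over an intercross of
   n = 228 males. Continuous traits use a Kruskal–Wallis rank statistic
   across the three genotype groups, reported as LOD = H / (2 ln 10);
   binary traits (e.g. distant-metastasis-free survival) use a logistic
   likelihood-ratio with two genotype indicator terms,
   LOD = (ℓ₁ − ℓ₀) / ln 10. Genome-wide significance comes from permuting
   the (trait, covariate) rows against the genotypes and taking the
   (1 − α) quantile of the per-permutation maximum LOD; confidence regions
   are 2-LOD support intervals, and overlapping intervals merge into
   distinct genomic regions.
2. **eQTL scan** — for every SNP × transcript pair, OLS of log2 expression
   on allele dosage with age and tumor-burden covariates; pairs are classed
   proximal (same chromosome, ≤ 1 Mb from the TSS), distal, or trans, with
   Benjamini–Hochberg FDR across all tests. Transcripts in the lower 10th
   percentile of mean expression are excluded first.
3. **Trait correlation** — Pearson r (continuous) or two-sample t-test
   (binary) between each in-interval transcript and the QTL trait, FDR per
   QTL.
4. **Nomination** — a transcript becomes a candidate when it lies inside a
   QTL interval, has a significant proximal eQTL, and a significant trait
   correlation; candidates without a human ortholog are dropped.
5. **Human expression validation** — per-gene z-scores
   z = (x − μ_ref)/σ_ref, stepwise logistic regression of dichotomized
   clinical variables on candidate z-scores, gene sets from the odds-ratio
   direction, and Kaplan–Meier / log-rank survival of expression-altered
   vs other cases.
6. **Case-case GWAS** — exact Hardy–Weinberg QC, SNP-to-gene assignment
   within 100 kb, logistic glm of each aggressiveness variable on dosage +
   age + PC1–3, and an add-one permutation p (10,000 label shuffles by
   default) for records with asymptotic p < 0.01.
7. **Intersection** — genes in the expression risk set with at least one
   GWAS record at permutation p < 0.05 are the high-priority susceptibility
   genes.

## Worked example

The package bundles the published evidence tables (QTL intervals, cohort
logistic-regression hits, GWAS hits) as small TSVs:

```python
import sysgen
from sysgen import datasets

qtls = datasets.load_published_qtl_intervals()        # 11 mapped QTLs
merged = sysgen.merge_qtl_regions(qtls)
print(len(merged))                                    # 9 distinct regions

logistic = datasets.load_published_logistic_results()
risk, protective = sysgen.build_gene_sets(
    [logistic[logistic.cohort == c] for c in logistic.cohort.unique()])
print(sorted(risk))       # ['CXCL14', 'ITGAX', 'LPCAT2', 'RNASEH2A', 'ZNF322']
print(sorted(protective)) # ['CCL19', 'HIST1H1A']

gwas = datasets.load_published_gwas_hits()
hp = sysgen.high_priority_genes(risk, gwas, perm_cut=0.05)
print(hp.gene.tolist())   # ['CXCL14', 'ITGAX', 'LPCAT2']
```

The 11 mapped intervals collapse to 9 genomic regions (the chromosome 8
and 13 pairs overlap and merge); five genes show risk-direction odds
ratios and two protective; three of the five risk genes also carry a
permutation-significant GWAS association — those three are the
high-priority susceptibility genes.

A full synthetic run with planted truth:

```sh
sysgen run --seed 1 --outdir out/
```

prints a summary such as

```json
{
  "high_priority_genes": ["GENE1", "GENE2", "GENE3"],
  "n_merged_regions": 3,
  "n_qtls": 3,
  "risk_set": ["GENE1", "GENE2", "GENE3"],
  ...
}
```

where `GENE1–3` are the three genes the generator planted end to end
(QTL + cis-eQTL + trait correlation in the cross; expression association
and GWAS signal in the human cohorts).

## Layout

| module | role |
| --- | --- |
| `sysgen.io_formats` | TSV/PLINK/BED readers and writers, config, logging |
| `sysgen.synthdata` | generators with planted effects + truth records |
| `sysgen.cross_qtl` | genome scans, permutation thresholds, 2-LOD intervals |
| `sysgen.eqtl_scan` | matrix eQTL scan, classification, BH FDR |
| `sysgen.trait_correlation` | in-interval expression–trait correlation |
| `sysgen.candidate_nomination` | evidence intersection, orthologs, founder alleles |
| `sysgen.human_expr` | z-scores, stepwise logistic, gene sets, KM/log-rank |
| `sysgen.gwas_case_case` | HWE QC, SNP assignment, glm, permutation p, MAF |
| `sysgen.integrate_report` | high-priority intersection, pipeline orchestration |
| `sysgen.datasets` | bundled published evidence tables |

See `docs/methods.md` for the statistical details and design choices.
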