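"""Bundled worked-example tables from the published study.

Small TSVs shipped with the package: the eleven mapped QTL support
intervals, the stepwise logistic regression hits in the two human cohorts,
the case-case GWAS association hits, and the nominated candidate genes.
They serve as inputs to the worked examples (interval merging, gene-set
construction, the high-priority intersection) and as fixtures in tests.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("sysgen.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t", **kwargs)


def load_published_qtl_intervals() -> pd.DataFrame:
    """The eleven mapped QTLs: trait, chrom, LOD, genome p, 2-LOD interval."""
    df = _load("qtl_intervals.tsv", dtype={"chrom": str})
    return df.rename(columns={"ci_start_bp": "ci_start_bp", "ci_end_bp": "ci_end_bp"})


def load_published_logistic_results() -> pd.DataFrame:
    """Cohort logistic-regression hits: gene, OR, 95% CI, p, per cohort."""
    return _load("logistic_results.tsv")


def load_published_gwas_hits() -> pd.DataFrame:
    """Case-case GWAS hits: SNP, gene, variable, OR/CI, MAFs, p, permutation p."""
    return _load("gwas_hits.tsv", dtype={"cytoband": str})


def load_published_candidates() -> pd.DataFrame:
    """Nominated candidate genes with eQTL and correlation evidence."""
    return _load("candidate_genes.tsv", dtype={"chrom": str}, na_values=["NA"],
                 keep_default_na=False)
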