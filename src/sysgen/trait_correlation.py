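"""Expression-trait correlation for transcripts inside a QTL support interval.

For each QTL, every transcript whose TSS lies inside the 2-LOD interval on
the QTL chromosome is tested against the QTL trait: Pearson correlation with
a two-sided t test (df = n - 2) for continuous traits, and a two-sample
equal-variance t test of expression between the two outcome classes for
binary traits (Welch's correction available by flag).  BH q-values are
computed within each QTL's transcript family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cross_qtl import QTLRegion
from .eqtl_scan import ExpressionMatrix, bh_fdr

logger = logging.getLogger("sysgen.trait_correlation")


def transcripts_in_region(annotation: pd.DataFrame, region: QTLRegion) -> list[str]:
    """Transcripts whose TSS falls in [ci_start_bp, ci_end_bp] on the QTL chrom."""
    sel = annotation[
        (annotation["chrom"].astype(str) == str(region.chrom))
        & (annotation["tss_bp"].astype(int) >= region.ci_start_bp)
        & (annotation["tss_bp"].astype(int) <= region.ci_end_bp)
    ]
    return sel["transcript_id"].tolist()


def correlate_transcripts_in_qtl(
    expr: ExpressionMatrix,
    region: QTLRegion,
    trait: pd.Series,
    trait_type: str,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Correlation records for all in-interval transcripts against the trait.

    Returns columns transcript_id/trait/chrom/stat/p/fdr_q/method where
    ``stat`` is Pearson's r for continuous traits and the class mean
    difference (class 1 minus class 0) for binary traits.
    """
    members = transcripts_in_region(expr.annotation, region)
    trait = trait.reindex(expr.samples)
    y = trait.to_numpy(dtype=float)
    ok = ~np.isnan(y)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 complete trait/expression pairs")
    y = y[ok]
    cols = np.asarray(expr.samples)[ok]

    rows = []
    for tid in members:
        x = expr.matrix.loc[tid, cols].to_numpy(dtype=float)
        if np.std(x) == 0:
            logger.warning("transcript %s: zero variance, correlation skipped", tid)
            continue
        if trait_type == "continuous":
            r, p = stats.pearsonr(x, y)
            stat, method = float(r), "pearson"
        elif trait_type == "binary":
            x0, x1 = x[y == 0], x[y == 1]
            if len(x0) == 0 or len(x1) == 0:
                raise ValueError("binary trait with a single class")
            res = stats.ttest_ind(x1, x0, equal_var=equal_var)
            stat, p, method = float(x1.mean() - x0.mean()), float(res.pvalue), "ttest"
        else:
            raise ValueError(f"unknown trait_type {trait_type!r}")
        rows.append(
            {"transcript_id": tid, "trait": region.trait, "chrom": region.chrom,
             "stat": stat, "p": max(p, np.finfo(float).tiny), "method": method}
        )
    out = pd.DataFrame(rows, columns=["transcript_id", "trait", "chrom",
                                      "stat", "p", "method"])
    if len(out):
        out["fdr_q"] = bh_fdr(out["p"].to_numpy())
    else:
        out["fdr_q"] = pd.Series(dtype=float)
    return out
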