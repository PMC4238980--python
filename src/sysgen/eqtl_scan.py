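"""Matrix linear-model eQTL scan with covariates and BH FDR.

For every SNP x transcript pair, expression is regressed on the NOD-allele
dosage (0/1/2, additive coding) plus covariates by OLS; the dosage beta, its
t statistic and two-sided p are reported, and Benjamini-Hochberg q-values
are computed jointly across all tested pairs (a per-class stratified mode is
available).  Each association is classified by position: ``proximal`` when
the SNP lies within 1 Mb of the transcript's TSS on the same chromosome,
``distal`` when on the same chromosome beyond the window, and ``trans`` when
on a different chromosome.

Transcripts expressed near the array background are removed first: per-
transcript means are computed across all samples and transcripts below the
lower 10th percentile of those means are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GenotypeMatrix

logger = logging.getLogger("sysgen.eqtl_scan")


@dataclass
class ExpressionMatrix:
    """Log2 expression (transcripts x samples) with positional annotation.

    ``annotation`` has columns transcript_id/chrom/tss_bp and optionally
    ortholog; it must cover every transcript in the matrix.
    """

    matrix: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not np.isfinite(self.matrix.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        ann_ids = set(self.annotation["transcript_id"])
        missing = [t for t in self.matrix.index if t not in ann_ids]
        if missing:
            raise ValueError(f"transcripts missing annotation: {missing[:5]}...")

    @property
    def transcripts(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.columns)

    def annotation_for(self, transcript_id: str) -> pd.Series:
        rows = self.annotation[self.annotation["transcript_id"] == transcript_id]
        return rows.iloc[0]


def filter_low_expression(expr: ExpressionMatrix, percentile: float = 10.0) -> ExpressionMatrix:
    """Drop transcripts whose mean expression sits below the given percentile.

    The cut is the linearly interpolated percentile of per-transcript means;
    transcripts exactly at the cut are retained.
    """
    if len(expr.matrix) < 10:
        raise ValueError("need at least 10 transcripts to compute the percentile cut")
    means = expr.matrix.mean(axis=1)
    cut = np.percentile(means.to_numpy(), percentile)  # linear interpolation
    keep = means >= cut
    dropped = int((~keep).sum())
    logger.info("low-expression filter: removed %d of %d transcripts (cut %.3f)",
                dropped, len(means), cut)
    kept = expr.matrix.loc[keep]
    ann = expr.annotation[expr.annotation["transcript_id"].isin(kept.index)]
    return ExpressionMatrix(kept, ann.reset_index(drop=True))


def classify_eqtl(
    snp_chrom: str, snp_bp: int, tss_chrom: str, tss_bp: int,
    window_bp: int = 1_000_000,
) -> str:
    """proximal (same chrom, |snp - tss| <= window), distal, or trans."""
    if str(snp_chrom) != str(tss_chrom):
        return "trans"
    if abs(int(snp_bp) - int(tss_bp)) <= window_bp:
        return "proximal"
    return "distal"


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _residualize_columns(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residual of every column of M on the design C (C includes intercept)."""
    beta, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ beta


def eqtl_matrix_scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    window_bp: int = 1_000_000,
    p_prefilter: float = 1.0,
    snp_map: pd.DataFrame | None = None,
    fdr_mode: str = "joint",
) -> pd.DataFrame:
    """OLS eQTL scan over all SNP x transcript pairs on the shared samples.

    Returns one record per stored pair with columns snp_id/snp_chrom/snp_bp/
    transcript_id/tss_chrom/tss_bp/beta/t/p/fdr_q/eclass.  ``p_prefilter``
    bounds memory by storing only pairs with p below it; FDR is still
    computed against the exact number of tests.  ``snp_map`` supplies SNP
    positions (marker_id/chrom/pos_bp); ``fdr_mode`` is "joint" (one family)
    or "stratified" (proximal vs distal/trans corrected separately).
    """
    samples = [s for s in expr.samples if s in set(geno.samples)]
    n = len(samples)
    n_cov = len(covariates.columns) if covariates is not None else 0
    if n < n_cov + 4:
        raise ValueError("too few shared samples for the model size")

    sample_pos = {s: i for i, s in enumerate(geno.samples)}
    rows = [sample_pos[s] for s in samples]
    G = geno.codes[rows]                                   # (n, m_snp)
    Y = expr.matrix.loc[:, samples].to_numpy(dtype=float).T  # (n, m_tr)
    C = np.ones((n, 1))
    if covariates is not None and n_cov:
        cov = covariates.reindex(samples).to_numpy(dtype=float)
        if np.isnan(cov).any():
            raise ValueError("missing covariate values among shared samples")
        C = np.column_stack([C, cov])
    df_resid = n - (C.shape[1] + 1)

    ann = expr.annotation.set_index("transcript_id")
    tss_chrom = ann.loc[expr.transcripts, "chrom"].astype(str).to_numpy()
    tss_bp = ann.loc[expr.transcripts, "tss_bp"].astype(int).to_numpy()
    if snp_map is not None:
        smap = snp_map.set_index("marker_id")
        snp_chrom = smap.loc[geno.markers, "chrom"].astype(str).to_numpy()
        snp_bp = smap.loc[geno.markers, "pos_bp"].astype(int).to_numpy()
    else:
        raise ValueError("snp_map with marker positions is required")

    Yr = _residualize_columns(Y, C)
    Syy = (Yr**2).sum(axis=0)                              # (m_tr,)

    records = []
    n_tests = 0
    n_skipped = 0
    has_missing = np.isnan(G).any()
    for j, snp in enumerate(geno.markers):
        gj = G[:, j]
        if has_missing and np.isnan(gj).any():
            ok = ~np.isnan(gj)
            if gj[ok].std() == 0:
                n_skipped += len(expr.transcripts)
                continue
            Cj = C[ok]
            xr = _residualize_columns(gj[ok, None], Cj)[:, 0]
            yr = _residualize_columns(Y[ok], Cj)
            dfj = ok.sum() - (C.shape[1] + 1)
            syy = (yr**2).sum(axis=0)
        else:
            if gj.std() == 0:
                n_skipped += len(expr.transcripts)
                continue
            xr = _residualize_columns(gj[:, None], C)[:, 0]
            yr, dfj, syy = Yr, df_resid, Syy
        sxx = float(xr @ xr)
        if sxx <= 0:
            n_skipped += len(expr.transcripts)
            continue
        sxy = xr @ yr                                      # (m_tr,)
        beta = sxy / sxx
        rss = np.clip(syy - beta**2 * sxx, 0.0, None)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(rss / dfj / sxx)
            t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p = 2.0 * stats.t.sf(np.abs(t), dfj)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        n_tests += len(p)
        keep = p <= p_prefilter
        for i in np.flatnonzero(keep):
            records.append(
                (snp, snp_chrom[j], snp_bp[j], expr.transcripts[i],
                 tss_chrom[i], tss_bp[i], beta[i], t[i], p[i])
            )
    if n_skipped:
        logger.info("eQTL scan: skipped %d pairs at zero-variance SNPs", n_skipped)

    out = pd.DataFrame(
        records,
        columns=["snp_id", "snp_chrom", "snp_bp", "transcript_id",
                 "tss_chrom", "tss_bp", "beta", "t", "p"],
    )
    if out.empty:
        out["fdr_q"] = pd.Series(dtype=float)
        out["eclass"] = pd.Series(dtype=str)
        return out
    out["eclass"] = [
        classify_eqtl(sc, sb, tc, tb, window_bp)
        for sc, sb, tc, tb in zip(out["snp_chrom"], out["snp_bp"],
                                  out["tss_chrom"], out["tss_bp"])
    ]
    # BH against the exact test count even when a prefilter dropped pairs;
    # losing the dropped tail from the step-up cumulative minimum can only
    # make the stored q-values larger, so the prefilter is conservative.
    def _bh_with_total(p: np.ndarray, m_total: int) -> np.ndarray:
        order = np.argsort(p, kind="mergesort")
        ranked = p[order] * m_total / (np.arange(len(p)) + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.clip(q, None, 1.0)
        out = np.empty_like(q)
        out[order] = q
        return out

    if fdr_mode == "joint":
        out["fdr_q"] = _bh_with_total(out["p"].to_numpy(), n_tests)
    elif fdr_mode == "stratified":
        out["fdr_q"] = np.nan
        prox = (out["eclass"] == "proximal").to_numpy()
        # stratified totals scale the family sizes by the stored proportions
        for strat_mask in (prox, ~prox):
            if strat_mask.any():
                m_total = int(round(n_tests * strat_mask.mean()))
                out.loc[strat_mask, "fdr_q"] = _bh_with_total(
                    out.loc[strat_mask, "p"].to_numpy(), max(m_total, strat_mask.sum())
                )
    else:
        raise ValueError(f"unknown fdr_mode {fdr_mode!r}")
    # deterministic output order regardless of sample/transcript input order
    out = out.sort_values(["snp_id", "transcript_id"], kind="mergesort")
    return out.reset_index(drop=True)


def eqtl_class_counts(records: pd.DataFrame, q_cut: float = 0.05) -> dict:
    """Counts of significant proximal/distal/trans records at an FDR cut."""
    sig = records[records["fdr_q"] < q_cut]
    counts = sig["eclass"].value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in ("proximal", "distal", "trans")}
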