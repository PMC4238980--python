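"""Candidate-gene nomination by intersecting three evidence clauses.

A transcript is nominated for a QTL iff all of:

1. its TSS lies inside the QTL's 2-LOD support interval;
2. it has at least one significant proximal eQTL (FDR < cut) — the eQTL SNP
   itself need not lie inside the interval, only the transcript must (a
   stricter SNP-in-interval mode is available);
3. its expression-trait correlation for that QTL's trait is significant
   (FDR < cut).

One candidate record is emitted per qualifying (transcript, proximal-eQTL
SNP) pair, so a transcript with two proximal eQTLs yields two rows.
Candidates are then mapped to human orthologs (those without one are
dropped) and annotated with the founder strain whose eQTL allele is
correlated with increased expression.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cross_qtl import QTLRegion
from .trait_correlation import transcripts_in_region

logger = logging.getLogger("sysgen.candidate_nomination")


def nominate_candidates(
    regions: list[QTLRegion],
    eqtls: pd.DataFrame,
    correlations: pd.DataFrame,
    annotation: pd.DataFrame,
    q_cut: float = 0.05,
    snp_in_interval: bool = False,
) -> pd.DataFrame:
    """Intersect QTL membership, proximal-eQTL and correlation evidence.

    ``correlations`` must carry trait/chrom columns identifying the QTL each
    record was computed for (one FDR family per QTL).  Returns one row per
    qualifying (transcript, SNP) pair with both evidence records attached.
    """
    prox = eqtls[(eqtls["eclass"] == "proximal") & (eqtls["fdr_q"] < q_cut)]
    rows = []
    for region in regions:
        members = set(transcripts_in_region(annotation, region))
        corr = correlations[
            (correlations["trait"] == region.trait)
            & (correlations["chrom"].astype(str) == str(region.chrom))
            & (correlations["fdr_q"] < q_cut)
        ]
        corr_by_tid = corr.set_index("transcript_id")
        for _, e in prox[prox["transcript_id"].isin(members)].iterrows():
            tid = e["transcript_id"]
            if tid not in corr_by_tid.index:
                continue
            if snp_in_interval and not (
                str(e["snp_chrom"]) == str(region.chrom)
                and region.ci_start_bp <= int(e["snp_bp"]) <= region.ci_end_bp
            ):
                continue
            c = corr_by_tid.loc[tid]
            rows.append(
                {
                    "transcript_id": tid,
                    "trait": region.trait,
                    "qtl_chrom": region.chrom,
                    "ci_start_bp": region.ci_start_bp,
                    "ci_end_bp": region.ci_end_bp,
                    "snp_id": e["snp_id"],
                    "snp_bp": int(e["snp_bp"]),
                    "eqtl_beta": float(e["beta"]),
                    "eqtl_t": float(e["t"]),
                    "eqtl_p": float(e["p"]),
                    "eqtl_fdr_q": float(e["fdr_q"]),
                    "corr_stat": float(c["stat"]),
                    "corr_p": float(c["p"]),
                    "corr_fdr_q": float(c["fdr_q"]),
                    "corr_method": c["method"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "trait", "qtl_chrom", "ci_start_bp", "ci_end_bp",
                 "snp_id", "snp_bp", "eqtl_beta", "eqtl_t", "eqtl_p", "eqtl_fdr_q",
                 "corr_stat", "corr_p", "corr_fdr_q", "corr_method"],
    )


def map_orthologs(candidates: pd.DataFrame, ortholog_table: pd.DataFrame) -> pd.DataFrame:
    """Attach human ortholog symbols; drop candidates without a direct ortholog.

    ``ortholog_table`` has columns mouse_symbol/human_symbol where a missing
    or "None" human symbol means no direct ortholog.  Candidates whose symbol
    is absent from the table are treated as ortholog-less and logged.
    """
    lut = {}
    for _, row in ortholog_table.iterrows():
        human = row["human_symbol"]
        if pd.isna(human) or str(human) == "None" or str(human) == "":
            human = None
        lut[str(row["mouse_symbol"])] = human
    out = candidates.copy()
    orthologs = []
    for tid in out["transcript_id"]:
        if tid not in lut:
            logger.warning("candidate %s absent from ortholog table; dropped", tid)
            orthologs.append(None)
        else:
            orthologs.append(lut[tid])
    out["human_ortholog"] = orthologs
    dropped = int(out["human_ortholog"].isna().sum())
    if dropped:
        logger.info("ortholog mapping: dropped %d candidate rows without ortholog",
                    dropped)
    return out[out["human_ortholog"].notna()].reset_index(drop=True)


def founder_allele_direction(beta: float, counted_allele_founder: str) -> str:
    """Founder strain whose eQTL allele correlates with increased expression.

    ``counted_allele_founder`` declares which founder contributed the counted
    allele at the SNP ("NOD/ShiLtJ" or "C57BL/6J"); dosage coding is per-SNP,
    so this assignment is a required input rather than a global convention.
    """
    if counted_allele_founder not in ("NOD/ShiLtJ", "C57BL/6J"):
        raise ValueError(f"unknown founder {counted_allele_founder!r}")
    if beta == 0 or not np.isfinite(beta):
        raise ValueError("founder direction undefined for beta == 0")
    other = "C57BL/6J" if counted_allele_founder == "NOD/ShiLtJ" else "NOD/ShiLtJ"
    return counted_allele_founder if beta > 0 else other


def annotate_founder_direction(
    candidates: pd.DataFrame, allele_assignment: dict[str, str] | None = None
) -> pd.DataFrame:
    """Add the founder-direction column; default assignment counts NOD alleles."""
    assignment = allele_assignment or {}
    out = candidates.copy()
    out["founder_direction"] = [
        founder_allele_direction(b, assignment.get(snp, "NOD/ShiLtJ"))
        for b, snp in zip(out["eqtl_beta"], out["snp_id"])
    ]
    return out
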