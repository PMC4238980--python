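"""End-to-end orchestration and the final evidence intersection.

A gene is *high priority* when it is implicated by both human evidence
streams: it sits in the risk gene set from cohort expression (odds ratio
above 1 in stepwise logistic regression) and at least one of its SNPs shows
a permutation p below the cut in the case-case GWAS.  The protective set
does not feed the intersection.

``pipeline_run`` executes the synthetic-mode pipeline stage by stage —
simulate, QTL scan, eQTL scan, trait correlation, nomination, human-cohort
expression validation, case-case GWAS, intersection — writing one TSV per
stage table plus a manifest and a summary JSON of per-stage counts.  Every
stage consumes only the outputs of earlier stages, so each is individually
re-runnable from its on-disk inputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthdata
from .candidate_nomination import (annotate_founder_direction, map_orthologs,
                                   nominate_candidates)
from .cross_qtl import (find_significant_qtls, merge_qtl_regions,
                        permutation_threshold, regions_to_frame, scan_binary,
                        scan_nonparametric)
from .eqtl_scan import (ExpressionMatrix, eqtl_class_counts, eqtl_matrix_scan,
                        filter_low_expression)
from .gwas_case_case import run_gwas
from .human_expr import (build_gene_sets, compute_zscores, dichotomize_clinical,
                         flag_altered_cases, km_logrank, stepwise_logistic)
from .io_formats import PipelineConfig, write_results
from .trait_correlation import correlate_transcripts_in_qtl

logger = logging.getLogger("sysgen.integrate_report")


def high_priority_genes(
    risk_set: set[str] | list[str],
    gwas_records: pd.DataFrame,
    perm_cut: float = 0.05,
) -> pd.DataFrame:
    """Risk-set genes with >=1 GWAS record at permutation p < perm_cut."""
    if gwas_records.empty or "perm_p" not in gwas_records.columns:
        return pd.DataFrame(columns=["gene", "n_gwas_records", "best_perm_p"])
    sig = gwas_records[gwas_records["perm_p"].notna()
                       & (gwas_records["perm_p"] < perm_cut)]
    rows = []
    for gene in sorted(set(risk_set)):
        hits = sig[sig["gene"] == gene]
        if len(hits):
            rows.append({
                "gene": gene,
                "n_gwas_records": int(len(hits)),
                "best_perm_p": float(hits["perm_p"].min()),
            })
    return pd.DataFrame(rows, columns=["gene", "n_gwas_records", "best_perm_p"])


def _stage_seed(base: int, offset: int) -> int:
    return int((base * 1_000 + offset) % (2**31 - 1))


def pipeline_run(
    config: PipelineConfig,
    outdir: str | Path | None = None,
    study: dict | None = None,
) -> dict:
    """Run the full synthetic-mode pipeline; returns the result bundle.

    ``study`` is a spec dict as produced by ``synthdata.default_study``;
    when omitted the default study conditions are used.  Stage outputs,
    the run manifest and a summary JSON are written when ``outdir`` is set.
    """
    seed = config.seed
    thr = config.thresholds
    if study is None:
        study = synthdata.default_study(seed)
    gmap = study["map"]
    trait_covs = study.get("trait_covariates", config.trait_covariates)

    # --- mouse cross -------------------------------------------------------
    geno = synthdata.simulate_f2_genotypes(study["cross"], _stage_seed(seed, 1))
    trait_data = synthdata.simulate_traits(geno, study["cross"], _stage_seed(seed, 2))
    expr_data = synthdata.simulate_expression(
        geno, study["expression"], trait_data, _stage_seed(seed, 3)
    )

    # --- QTL scans ---------------------------------------------------------
    scans, regions = {}, []
    scan_tables = []
    for trait in trait_data.traits.columns:
        cov_names = [c for c in trait_covs.get(trait, []) if c != trait]
        cov_frame = pd.DataFrame(index=geno.samples)
        for c in cov_names:
            source = (trait_data.covariates if c in trait_data.covariates.columns
                      else trait_data.traits)
            cov_frame[c] = source[c]
        cov_frame = cov_frame if len(cov_frame.columns) else None
        model = ("binary" if trait_data.trait_types[trait] == "binary"
                 else "nonparametric")
        scan_fn = scan_binary if model == "binary" else scan_nonparametric
        scan = scan_fn(geno, gmap, trait_data.traits[trait], cov_frame)
        perm = permutation_threshold(
            geno, gmap, trait_data.traits[trait], cov_frame, model,
            n_perm=config.n_perm, alpha=thr.genome_alpha,
            seed=_stage_seed(seed, 4),
        )
        found = find_significant_qtls(scan, gmap, perm)
        scans[trait] = scan
        regions.extend(found)
        t = scan.table.copy()
        t.insert(0, "trait", trait)
        t["model"] = model
        t["threshold"] = perm.threshold
        scan_tables.append(t)
    regions_df = regions_to_frame(regions)
    merged = merge_qtl_regions(regions)

    # --- eQTL scan + trait correlation ------------------------------------
    expr = ExpressionMatrix(expr_data.matrix, expr_data.annotation)
    expr = filter_low_expression(expr)
    eqtl_cov = pd.DataFrame(index=expr_data.samples)
    for c in study.get("eqtl_covariates", []):
        source = (trait_data.covariates if c in trait_data.covariates.columns
                  else trait_data.traits)
        eqtl_cov[c] = source.reindex(expr_data.samples)[c]
    snp_map = gmap.table.rename(columns={"pos_bp": "pos_bp"})
    eqtls = eqtl_matrix_scan(
        expr, geno, eqtl_cov if len(eqtl_cov.columns) else None,
        window_bp=thr.proximal_window_bp, snp_map=snp_map,
    )

    corr_frames = []
    for region in regions:
        trait_series = trait_data.traits[region.trait].reindex(expr.samples)
        corr = correlate_transcripts_in_qtl(
            expr, region, trait_series, trait_data.trait_types[region.trait]
        )
        corr_frames.append(corr)
    corr_frames = [f for f in corr_frames if len(f)]
    correlations = (pd.concat(corr_frames, ignore_index=True) if corr_frames
                    else pd.DataFrame(columns=["transcript_id", "trait", "chrom",
                                               "stat", "p", "method", "fdr_q"]))

    # --- nomination --------------------------------------------------------
    candidates = nominate_candidates(
        regions, eqtls, correlations, expr.annotation, q_cut=thr.fdr_q
    )
    ortho_table = expr_data.annotation.rename(
        columns={"transcript_id": "mouse_symbol", "ortholog": "human_symbol"}
    )[["mouse_symbol", "human_symbol"]]
    candidates = map_orthologs(candidates, ortho_table)
    if len(candidates):
        candidates = annotate_founder_direction(candidates)
    candidate_genes = sorted(set(candidates.get("human_ortholog", pd.Series(dtype=str))))

    # --- human-cohort expression validation --------------------------------
    logistic_frames, km_rows, surv_curves, flag_frames = [], [], [], []
    cohort_data: dict[str, synthdata.HumanCohortData] = {}
    for i, cohort_spec in enumerate(study["cohorts"]):
        cohort = synthdata.simulate_human_cohort(cohort_spec, _stage_seed(seed, 10 + i))
        panel = [g for g in candidate_genes if g in cohort.expression.index]
        if not panel:
            logger.warning("cohort %s: no candidate genes in panel", cohort.name)
            continue
        z = compute_zscores(cohort.expression, mode="population")
        rules = {
            v.name: {v.levels[0]: 0, v.levels[1]: 1} for v in cohort_spec.clinical
        }
        outcomes = dichotomize_clinical(cohort.clinical, rules)
        for var in outcomes.columns:
            res = stepwise_logistic(outcomes[var], z.loc[panel].T)
            t = res.table.copy()
            t.insert(0, "cohort", cohort.name)
            t.insert(1, "variable", var)
            logistic_frames.append(t)
        flags = flag_altered_cases(z, panel, z_cut=thr.z_cut)
        flag_frames.append(pd.DataFrame({
            "cohort": cohort.name, "sample": flags.index, "altered": flags.to_numpy(),
        }))
        cohort_data[cohort.name] = cohort

    logistic_frames = [f for f in logistic_frames if len(f)]
    logistic = (pd.concat(logistic_frames, ignore_index=True) if logistic_frames
                else pd.DataFrame(columns=["cohort", "variable", "gene",
                                           "odds_ratio", "ci_low", "ci_high", "p"]))
    risk_set, protective_set = build_gene_sets(
        [logistic[logistic["cohort"] == c] for c in logistic.get("cohort", pd.Series(dtype=str)).unique()]
    ) if len(logistic) else (set(), set())

    # KM survival: altered in the *risk set* vs all other cases
    for name, cohort in cohort_data.items():
        panel_risk = [g for g in risk_set if g in cohort.expression.index]
        if not panel_risk:
            continue
        z = compute_zscores(cohort.expression, mode="population")
        flags = flag_altered_cases(z, panel_risk, z_cut=thr.z_cut)
        if flags.any() and (~flags).any() and cohort.survival["event"].sum() > 0:
            km = km_logrank(cohort.survival["time_months"], cohort.survival["event"],
                            flags)
            km_rows.append({"cohort": name, "chi2": km.chi2, "logrank_p": km.p,
                            "n_altered": km.n_altered, "n_other": km.n_other})
            curves = km.curves.copy()
            curves.insert(0, "cohort", name)
            surv_curves.append(curves)
    km_table = pd.DataFrame(km_rows, columns=["cohort", "chi2", "logrank_p",
                                              "n_altered", "n_other"])

    # --- case-case GWAS ----------------------------------------------------
    gwas_data = synthdata.simulate_gwas_cohort(study["gwas"], _stage_seed(seed, 20))
    gene_intervals = study["gwas_genes"]
    gene_intervals = gene_intervals[gene_intervals["gene"].isin(candidate_genes)]
    if len(gene_intervals):
        gwas_records, manhattan = run_gwas(
            gwas_data.genotypes, gwas_data.snps, gwas_data.clinical,
            gwas_data.covariates, gene_intervals,
            radius_bp=thr.gene_radius_bp, hwe_p_cut=thr.hwe_p,
            perm_gate_p=thr.perm_gate_p, n_perm=config.n_perm,
            seed=_stage_seed(seed, 21),
        )
    else:
        gwas_records = pd.DataFrame(columns=["snp_id", "gene", "variable",
                                             "odds_ratio", "ci_low", "ci_high",
                                             "t_stat", "p", "maf_aggressive",
                                             "maf_nonaggressive", "perm_p", "flag"])
        manhattan = pd.DataFrame(columns=["variable", "chrom", "bp", "snp_id",
                                          "neg_log10_p"])

    # --- intersection ------------------------------------------------------
    high_priority = high_priority_genes(risk_set, gwas_records, perm_cut=0.05)

    summary = {
        "n_qtls": int(len(regions)),
        "n_merged_regions": int(len(merged)),
        "eqtl_counts": eqtl_class_counts(eqtls, thr.fdr_q),
        "n_candidate_rows": int(len(candidates)),
        "n_candidate_genes": int(len(candidate_genes)),
        "risk_set": sorted(risk_set),
        "protective_set": sorted(protective_set),
        "n_gwas_significant_genes": int(
            gwas_records[gwas_records["perm_p"].notna()
                         & (gwas_records["perm_p"] < 0.05)]["gene"].nunique()
        ) if len(gwas_records) else 0,
        "high_priority_genes": high_priority["gene"].tolist(),
    }
    bundle = {
        "tables": {
            "scan_curves": pd.concat(scan_tables, ignore_index=True),
            "qtl_regions": regions_df,
            "merged_regions": merged,
            "eqtl_records": eqtls,
            "correlation_records": correlations,
            "candidates": candidates,
            "logistic_results": logistic,
            "altered_flags": (pd.concat(flag_frames, ignore_index=True)
                              if flag_frames else pd.DataFrame(
                                  columns=["cohort", "sample", "altered"])),
            "survival_tests": km_table,
            "survival_curves": (pd.concat(surv_curves, ignore_index=True)
                                if surv_curves else pd.DataFrame(
                                    columns=["cohort", "group", "time", "survival"])),
            "gwas_records": gwas_records,
            "gwas_manhattan": manhattan,
            "high_priority": high_priority,
        },
        "summary": summary,
        "truth": {
            "qtl": trait_data.truth,
            "expression": expr_data.truth,
            "planted_genes": study.get("planted_genes", []),
        },
    }
    if outdir is not None:
        write_results(bundle["tables"], outdir, config=config,
                      extra_manifest={"summary": summary})
        with open(Path(outdir) / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return bundle
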