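"""Case-case GWAS of disease aggressiveness around candidate genes.

Healthy controls are omitted by design: every contrast is aggressive vs
non-aggressive disease within cases, so the analysis targets severity
rather than incidence.  The stages are: exact Hardy-Weinberg QC on the case
cohort, assignment of SNPs to candidate genes within a 100 kb radius,
covariate-adjusted logistic association (dosage + age + PC1-3), an add-one
permutation p-value for records passing the asymptotic gate p < 0.01, and
per-group minor-allele frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._fastglm import logit_fit

logger = logging.getLogger("sysgen.gwas_case_case")


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg p by full enumeration of heterozygote counts.

    Uses the Levene-Haldane conditional distribution of the heterozygote
    count given the allele counts; the p-value sums the probabilities of all
    configurations no more probable than the observed one.  Monomorphic SNPs
    return 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one subject")
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # unnormalized P(het = h | allele counts), computed by recurrence
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.zeros(len(hets))
    mid_i = len(hets) // 2
    probs[mid_i] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / ((nr-h+2)/2 * (nc-h+2)/2) ... use
    # standard ratio P(h+2)/P(h) = 4*rare_hom(h)*common_hom(h) / ((h+2)(h+1))
    n_common = 2 * n - n_rare
    for i in range(mid_i, len(hets) - 1):
        h = hets[i]
        rare_hom = (n_rare - h) // 2
        common_hom = (n_common - h) // 2
        probs[i + 1] = probs[i] * 4.0 * rare_hom * common_hom / ((h + 2.0) * (h + 1.0))
    for i in range(mid_i, 0, -1):
        h = hets[i]
        rare_hom = (n_rare - h) // 2
        common_hom = (n_common - h) // 2
        probs[i - 1] = probs[i] * h * (h - 1.0) / (4.0 * (rare_hom + 1.0) * (common_hom + 1.0))
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_ab)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_chi2_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Chi-square (1 df) Hardy-Weinberg p against p^2 / 2pq / q^2 expectation."""
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("need at least one subject")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((obs - exp) ** 2 / exp))
    return float(stats.chi2.sf(chi2, df=1))


def genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    """Counts of (hom-minor, het, hom-major) from a 0/1/2 dosage vector."""
    d = np.asarray(dosage, dtype=float)
    d = d[~np.isnan(d)]
    return int((d == 2).sum()), int((d == 1).sum()), int((d == 0).sum())


def hwe_filter(
    genotypes: pd.DataFrame, p_cut: float = 0.001, method: str = "exact"
) -> pd.DataFrame:
    """Per-SNP HWE p on the case cohort; SNPs with p < p_cut are dropped.

    Returns a frame with snp_id/hwe_p/retained/flag; monomorphic SNPs get
    p = 1 and are retained with a flag.
    """
    test = hwe_exact_p if method == "exact" else hwe_chi2_p
    if method not in ("exact", "chi2"):
        raise ValueError(f"unknown HWE method {method!r}")
    rows = []
    for snp in genotypes.columns:
        n2, n1, n0 = genotype_counts(genotypes[snp].to_numpy())
        p = test(n2, n1, n0)
        flag = "monomorphic" if (n1 == 0 and (n2 == 0 or n0 == 0)) else ""
        rows.append({"snp_id": snp, "hwe_p": p, "retained": p >= p_cut or bool(flag),
                     "flag": flag})
    out = pd.DataFrame(rows)
    n_drop = int((~out["retained"]).sum())
    if n_drop:
        logger.info("HWE filter removed %d of %d SNPs", n_drop, len(out))
    return out


# ---------------------------------------------------------------------------
# SNP-to-gene assignment
# ---------------------------------------------------------------------------


def assign_snps_to_genes(
    snps: pd.DataFrame, genes: pd.DataFrame, radius_bp: int = 100_000
) -> pd.DataFrame:
    """(snp, gene, distance) pairs for SNPs within the radius of a gene.

    ``snps`` has snp_id/chrom/bp; ``genes`` has gene/chrom/start/end
    (1-based inclusive).  Distance is 0 inside the gene, else the bp gap to
    the nearest edge; a SNP may map to several genes.
    """
    rows = []
    for _, g in genes.iterrows():
        on_chrom = snps[snps["chrom"].astype(str) == str(g["chrom"])]
        for _, s in on_chrom.iterrows():
            bp = int(s["bp"])
            if bp < int(g["start"]):
                dist = int(g["start"]) - bp
            elif bp > int(g["end"]):
                dist = bp - int(g["end"])
            else:
                dist = 0
            if dist <= radius_bp:
                rows.append({"snp_id": s["snp_id"], "gene": g["gene"],
                             "distance_bp": dist})
    return pd.DataFrame(rows, columns=["snp_id", "gene", "distance_bp"])


# ---------------------------------------------------------------------------
# Association model
# ---------------------------------------------------------------------------


@dataclass
class AssocRecord:
    snp_id: str
    gene: str
    variable: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    t_stat: float
    p: float
    maf_aggressive: float
    maf_nonaggressive: float
    perm_p: float | None = None
    flag: str = ""


def _complete_cases(outcome, dosage, covariates):
    y = np.asarray(outcome, dtype=float)
    d = np.asarray(dosage, dtype=float)
    C = covariates.to_numpy(dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(d) & ~np.isnan(C).any(axis=1)
    return y[ok], d[ok], C[ok]


def assoc_glm(
    outcome: pd.Series,
    dosage: pd.Series,
    covariates: pd.DataFrame,
    snp_id: str = "",
    gene: str = "",
    variable: str = "",
) -> AssocRecord:
    """Logistic glm of an aggressiveness outcome on dosage + age + PC1-3.

    Reports OR = exp(beta) for the dosage term with the 95% Wald CI, the
    Wald z ("t stat"), the asymptotic two-sided p, and per-group MAFs.
    Separation yields a capped fit with the record flagged.
    """
    y, d, C = _complete_cases(outcome, dosage, covariates)
    if len(set(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X = np.column_stack([np.ones(len(y)), d, C])
    flag = ""
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        beta, se = fit.params[1], fit.bse[1]
        if not np.isfinite(se) or se > 50 or np.abs(beta) > 20:
            raise ValueError("separation")
    except Exception:
        beta_v, cov, _, converged = logit_fit(X, y)
        beta, se = beta_v[1], float(np.sqrt(cov[1, 1]))
        flag = "separation"
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    p = float(2 * stats.norm.sf(abs(z)))
    maf_agg, maf_non = group_maf(pd.Series(d), pd.Series(y))
    return AssocRecord(
        snp_id=snp_id, gene=gene, variable=variable,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        t_stat=float(z), p=max(p, np.finfo(float).tiny),
        maf_aggressive=maf_agg, maf_nonaggressive=maf_non,
        flag=flag,
    )


def permutation_pvalue(
    outcome: pd.Series,
    dosage: pd.Series,
    covariates: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Add-one permutation p for the dosage |t| under outcome-label shuffles.

    Outcome labels are permuted across individuals while dosage and
    covariates stay with their subjects;
    perm_p = (#{|t_perm| >= |t_obs|} + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y, d, C = _complete_cases(outcome, dosage, covariates)
    X = np.column_stack([np.ones(len(y)), d, C])

    def stat(yv: np.ndarray) -> float:
        # separation makes the Wald ratio degenerate; a separated fit is
        # evidence stronger than any finite statistic
        b, c, _, converged = logit_fit(X, yv)
        if not converged:
            return np.inf
        se = np.sqrt(c[1, 1])
        return abs(b[1] / se) if se > 0 else np.inf

    t_obs = stat(y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if stat(rng.permutation(y)) >= t_obs:
            exceed += 1
    return (exceed + 1) / (n_perm + 1)


def group_maf(dosage: pd.Series, outcome: pd.Series) -> tuple[float, float]:
    """Counted-allele frequency in the aggressive (1) and non-aggressive (0) groups."""
    d = np.asarray(dosage, dtype=float)
    y = np.asarray(outcome, dtype=float)
    out = []
    for cls in (1.0, 0.0):
        dd = d[(y == cls) & ~np.isnan(d)]
        if len(dd) == 0:
            raise ValueError(f"outcome group {int(cls)} empty or all-missing")
        out.append(float(dd.sum() / (2 * len(dd))))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Orchestration over variables and assigned SNPs
# ---------------------------------------------------------------------------


def run_gwas(
    genotypes: pd.DataFrame,
    snps: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: pd.DataFrame,
    genes: pd.DataFrame,
    radius_bp: int = 100_000,
    hwe_p_cut: float = 0.001,
    perm_gate_p: float = 0.01,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full case-case association pass; returns (records, manhattan) tables.

    Permutation p-values are computed only for records whose asymptotic
    p < perm_gate_p, each with a seed derived from the base seed.
    """
    hwe = hwe_filter(genotypes, p_cut=hwe_p_cut)
    kept = set(hwe[hwe["retained"]]["snp_id"])
    assigned = assign_snps_to_genes(snps[snps["snp_id"].isin(kept)], genes, radius_bp)

    snp_pos = snps.set_index("snp_id")
    records: list[AssocRecord] = []
    manhattan_rows = []
    rng = np.random.default_rng(seed)
    for variable in clinical.columns:
        outcome = clinical[variable]
        if outcome.dropna().nunique() < 2:
            logger.warning("variable %s: single class, skipped", variable)
            continue
        for _, pair in assigned.iterrows():
            snp = pair["snp_id"]
            rec = assoc_glm(outcome, genotypes[snp], covariates,
                            snp_id=snp, gene=pair["gene"], variable=variable)
            if rec.p < perm_gate_p and not rec.flag:
                rec.perm_p = permutation_pvalue(
                    outcome, genotypes[snp], covariates,
                    n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
                )
            records.append(rec)
            manhattan_rows.append({
                "variable": variable,
                "chrom": str(snp_pos.loc[snp, "chrom"]),
                "bp": int(snp_pos.loc[snp, "bp"]),
                "snp_id": snp,
                "neg_log10_p": float(-np.log10(rec.p)),
            })
    rec_df = pd.DataFrame([vars(r) for r in records])
    manhattan = pd.DataFrame(manhattan_rows,
                             columns=["variable", "chrom", "bp", "snp_id",
                                      "neg_log10_p"])
    return rec_df, manhattan
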