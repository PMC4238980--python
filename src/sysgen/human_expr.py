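"""Human-cohort expression validation of candidate genes.

Expression is standardized to z-scores, z = (x - ref_mean) / ref_sd, where
the reference set is either the whole cohort (population mode) or the
diploid-flagged tumors (diploid mode).  Dichotomized clinical variables are
regressed on candidate-gene z-scores by stepwise logistic regression
(forward selection on Wald p < p_enter with backward removal at
p > p_remove).  Genes with odds ratios above/below 1 across cohorts form a
risk and a protective gene set; a case is "altered" when z >= z_cut for at
least one set member, and disease-free survival of altered vs other cases
is compared by Kaplan-Meier curves with a two-group log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

logger = logging.getLogger("sysgen.human_expr")


# ---------------------------------------------------------------------------
# z-scores
# ---------------------------------------------------------------------------


def compute_zscores(
    expr: pd.DataFrame,
    mode: str = "population",
    diploid_mask: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene z-scores of a genes x samples expression matrix.

    In population mode the reference set is all samples; in diploid mode it
    is the diploid-flagged subset (``diploid_mask`` indexed by sample).
    Genes with zero reference sd are excluded with a warning.
    """
    if mode == "population":
        ref = expr
    elif mode == "diploid":
        if diploid_mask is None:
            raise ValueError("diploid mode requires a diploid_mask")
        ref_samples = [s for s in expr.columns if bool(diploid_mask.get(s, False))]
        if not ref_samples:
            raise ValueError("diploid reference set is empty")
        ref = expr.loc[:, ref_samples]
    else:
        raise ValueError(f"unknown z-score mode {mode!r}")
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=0)
    keep = sd > 0
    for gene in expr.index[~keep]:
        logger.warning("gene %s: zero reference sd, excluded from z-scores", gene)
    z = expr.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return z


# ---------------------------------------------------------------------------
# Clinical dichotomization
# ---------------------------------------------------------------------------


def dichotomize_clinical(table: pd.DataFrame, rules: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Map clinical levels to 0/1 outcomes per variable.

    ``rules`` maps a column name to a level -> {0,1} mapping, e.g. a stage
    comparison of T2 vs T3+T4 is {"T2": 0, "T3": 1, "T4": 1}.  Unmatched or
    missing levels become NaN and drop out of downstream regressions.
    """
    out = pd.DataFrame(index=table.index)
    for var, mapping in rules.items():
        if var not in table.columns:
            raise KeyError(f"clinical variable {var!r} not in table")
        col = table[var].astype("string")
        out[var] = col.map({str(k): v for k, v in mapping.items()}).astype(float)
    return out


def gleason_rule(levels) -> dict[str, int]:
    """The <7 vs >=7 Gleason comparison over the observed numeric levels."""
    return {str(l): int(float(l) >= 7) for l in levels}


# ---------------------------------------------------------------------------
# Stepwise logistic regression
# ---------------------------------------------------------------------------


@dataclass
class StepwiseResult:
    table: pd.DataFrame          # gene, odds_ratio, ci_low, ci_high, p
    selected: list[str]
    excluded_separation: list[str]


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    return model.fit(disp=0, maxiter=100)


def stepwise_logistic(
    outcome: pd.Series,
    z_matrix: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> StepwiseResult:
    """Forward stepwise logistic regression of an outcome on gene z-scores.

    ``z_matrix`` is samples x genes.  At each step the candidate with the
    smallest Wald p enters if p < p_enter; after every addition any included
    term with p > p_remove is removed; iteration stops at a fixpoint.  Genes
    triggering (quasi-)separation are flagged and excluded from selection.
    Reported per retained gene: OR = exp(beta) with 95% Wald CI.
    """
    data = z_matrix.copy()
    data = data.loc[outcome.reindex(data.index).notna()]
    y = outcome.reindex(data.index).to_numpy(dtype=float)
    if len(set(y)) < 2:
        raise ValueError("outcome must contain both classes")

    included: list[str] = []
    excluded: list[str] = []
    while True:
        changed = False
        # forward step: best candidate by Wald p
        best_gene, best_p = None, np.inf
        for gene in data.columns:
            if gene in included or gene in excluded:
                continue
            try:
                fit = _fit_logit(y, data[included + [gene]])
            except Exception:
                excluded.append(gene)
                logger.warning("gene %s: fit failure, excluded from selection", gene)
                continue
            if not fit.mle_retvals.get("converged", True) or \
                    np.abs(fit.params).max() > 20 or np.isnan(fit.bse).any():
                excluded.append(gene)
                logger.warning("gene %s: separation flagged, excluded", gene)
                continue
            p = fit.pvalues[gene]
            if p < best_p:
                best_gene, best_p = gene, p
        if best_gene is not None and best_p < p_enter:
            included.append(best_gene)
            changed = True
        # backward step: drop any included term above p_remove
        while included:
            fit = _fit_logit(y, data[included])
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] > p_remove:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    rows = []
    if included:
        fit = _fit_logit(y, data[included])
        for gene in included:
            beta, se = fit.params[gene], fit.bse[gene]
            rows.append(
                {
                    "gene": gene,
                    "odds_ratio": float(np.exp(beta)),
                    "ci_low": float(np.exp(beta - 1.96 * se)),
                    "ci_high": float(np.exp(beta + 1.96 * se)),
                    "p": float(fit.pvalues[gene]),
                }
            )
    table = pd.DataFrame(rows, columns=["gene", "odds_ratio", "ci_low", "ci_high", "p"])
    return StepwiseResult(table, included, excluded)


# ---------------------------------------------------------------------------
# Gene sets and altered-case flags
# ---------------------------------------------------------------------------


class GeneSetConflictError(ValueError):
    """A gene shows risk direction in one cohort and protective in another."""


def build_gene_sets(results: list[pd.DataFrame]) -> tuple[set[str], set[str]]:
    """Union logistic results over cohorts into (risk, protective) gene sets.

    Genes with OR > 1 anywhere join the risk set, OR < 1 the protective set;
    a gene appearing in both directions raises GeneSetConflictError.
    """
    risk: set[str] = set()
    protective: set[str] = set()
    for res in results:
        for _, row in res.iterrows():
            if row["odds_ratio"] > 1:
                risk.add(row["gene"])
            elif row["odds_ratio"] < 1:
                protective.add(row["gene"])
    overlap = risk & protective
    if overlap:
        raise GeneSetConflictError(
            f"genes with conflicting directions across cohorts: {sorted(overlap)}"
        )
    return risk, protective


def flag_altered_cases(
    z: pd.DataFrame,
    gene_set: set[str] | list[str],
    z_cut: float = 2.0,
    direction: str = "up",
) -> pd.Series:
    """Flag cases with z >= z_cut (or <= -z_cut for direction="down") in >=1 gene."""
    genes = [g for g in gene_set if g in z.index]
    missing = set(gene_set) - set(genes)
    if missing:
        raise KeyError(f"genes absent from z-score matrix: {sorted(missing)}")
    if not genes:
        return pd.Series(False, index=z.columns)
    sub = z.loc[genes]
    if direction == "up":
        return (sub >= z_cut).any(axis=0)
    if direction == "down":
        return (sub <= -z_cut).any(axis=0)
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


@dataclass
class KMResult:
    curves: pd.DataFrame   # group, time, survival
    chi2: float
    p: float
    n_altered: int
    n_other: int


def km_logrank(
    time: pd.Series, event: pd.Series, altered: pd.Series
) -> KMResult:
    """Kaplan-Meier curves and the two-group log-rank test.

    ``altered`` is a boolean per case (altered-in-gene-set vs all others).
    The log-rank statistic uses the hypergeometric variance summed over the
    distinct event times, with ties handled by the simultaneous-event
    convention, and is referred to chi-square with 1 df.
    """
    df = pd.DataFrame({
        "time": time.astype(float),
        "event": event.astype(int),
        "altered": altered.astype(bool),
    }).dropna()
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    g1, g0 = df[df["altered"]], df[~df["altered"]]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both survival groups must be nonempty")
    if df["event"].sum() < 1:
        raise ValueError("need at least one event")

    res = logrank_test(
        g1["time"], g0["time"],
        event_observed_A=g1["event"], event_observed_B=g0["event"],
    )
    curves = []
    for label, grp in (("altered", g1), ("other", g0)):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"], label=label)
        sf = kmf.survival_function_
        curves.append(pd.DataFrame({
            "group": label,
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf[label].to_numpy(dtype=float),
        }))
    return KMResult(
        curves=pd.concat(curves, ignore_index=True),
        chi2=float(res.test_statistic),
        p=float(res.p_value),
        n_altered=len(g1),
        n_other=len(g0),
    )
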