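"""Single-locus genome scan over an F2 cross, with permutation significance.

Two scan models are provided, matching standard single-QTL practice:

* nonparametric — a Kruskal-Wallis rank statistic H across the three
  genotype groups at each marker, reported on the LOD scale as
  ``LOD = H / (2 ln 10)``.  Covariates are handled by residualizing the
  trait on them by least squares before ranking.
* binary — a logistic likelihood-ratio at each marker, with the genotype
  entering as two indicator terms (genotype-means model, so dominance is
  not assumed away) on top of any covariates;
  ``LOD = (llf_full - llf_null) / ln 10``.

Genome-wide significance comes from permutation: trait and covariate rows
are permuted jointly against the genotype rows, and the null distribution of
the genome-wide maximum LOD yields both the alpha-level threshold and the
permutation genome p of an observed peak.  Support intervals use the 2-LOD
drop rule, and overlapping intervals on a chromosome can be merged into
distinct genomic regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._fastglm import logit_fit
from .io_formats import GeneticMap, GenotypeMatrix

logger = logging.getLogger("sysgen.cross_qtl")

LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    """Per-marker LOD curve for one trait."""

    table: pd.DataFrame  # marker_id, chrom, pos_cM, pos_bp, lod, flag
    model: str           # "nonparametric" | "binary"
    trait: str
    covariates: list
    n: int


@dataclass
class QTLRegion:
    """A scan peak with its 2-LOD support interval."""

    trait: str
    chrom: str
    peak_marker: str
    peak_cM: float
    peak_lod: float
    ci_start_bp: int
    ci_end_bp: int
    genome_p: float | None = None

    def __post_init__(self) -> None:
        if self.ci_start_bp > self.ci_end_bp:
            raise ValueError("support interval start exceeds end")


def regions_to_frame(regions: list[QTLRegion]) -> pd.DataFrame:
    cols = ["trait", "chrom", "peak_marker", "peak_cM", "peak_lod",
            "genome_p", "ci_start_bp", "ci_end_bp"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in regions],
                        columns=cols)


# ---------------------------------------------------------------------------
# Shared numerics
# ---------------------------------------------------------------------------


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Least-squares residual of y on [1, covariates]."""
    y = np.asarray(y, dtype=float)
    if covariates is None or covariates.size == 0:
        return y - y.mean()
    C = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ beta


def _tie_correction(ranks: np.ndarray) -> float:
    n = len(ranks)
    _, counts = np.unique(ranks, return_counts=True)
    denom = n**3 - n
    if denom == 0:
        return 1.0
    corr = 1.0 - np.sum(counts**3 - counts) / denom
    return corr if corr > 0 else 1.0


def _kw_h_batch(ranks: np.ndarray, indicators: list[np.ndarray],
                tie_corr: float) -> np.ndarray:
    """Kruskal-Wallis H for each marker, for one or many rank vectors.

    ``ranks`` is (k, n) (k permutations) and each indicator is (n, m).
    Markers where fewer than 2 genotype groups are present get NaN.
    """
    n = ranks.shape[1]
    m = indicators[0].shape[1]
    h = np.zeros((ranks.shape[0], m))
    n_groups = np.zeros(m)
    for ind in indicators:
        ng = ind.sum(axis=0)                      # (m,)
        present = ng > 0
        n_groups += present
        rg = ranks @ ind                          # (k, m) group rank sums
        with np.errstate(divide="ignore", invalid="ignore"):
            h += np.where(present, rg**2 / np.where(ng > 0, ng, 1), 0.0)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    h /= tie_corr
    h[:, n_groups < 2] = np.nan
    return np.clip(h, 0.0, None)


def kruskal_wallis_lod(h: np.ndarray | float) -> np.ndarray | float:
    """Convert a Kruskal-Wallis H statistic to the LOD scale: H / (2 ln 10)."""
    return np.asarray(h, dtype=float) / (2.0 * LN10)


def _complete_rows(*arrays: np.ndarray) -> np.ndarray:
    mask = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        if a is None:
            continue
        a = np.asarray(a, dtype=float)
        mask &= ~np.isnan(a if a.ndim == 1 else a).any(axis=-1) if a.ndim > 1 \
            else ~np.isnan(a)
    return mask


def _align_inputs(
    geno: GenotypeMatrix,
    trait: pd.Series,
    covariates: pd.DataFrame | None,
):
    """Complete-case alignment of trait/covariates to the genotype samples."""
    trait = trait.reindex(geno.samples)
    y = trait.to_numpy(dtype=float)
    C = None
    if covariates is not None and len(covariates.columns):
        C = covariates.reindex(geno.samples).to_numpy(dtype=float)
    mask = ~np.isnan(y)
    if C is not None:
        mask &= ~np.isnan(C).any(axis=1)
    return y[mask], (C[mask] if C is not None else None), mask


# ---------------------------------------------------------------------------
# Nonparametric scan
# ---------------------------------------------------------------------------


def _genotype_indicators(G: np.ndarray) -> list[np.ndarray]:
    return [(G == g).astype(float) for g in (0.0, 1.0, 2.0)]


def scan_nonparametric(
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> ScanResult:
    """Kruskal-Wallis marker scan of a continuous trait on the LOD scale."""
    y, C, mask = _align_inputs(geno, trait, covariates)
    if len(y) < 3:
        raise ValueError("fewer than 3 complete samples")
    G = geno.codes[mask]
    resid = residualize(y, C)
    ranks = stats.rankdata(resid)

    if np.isnan(G).any():
        lods = np.empty(G.shape[1])
        for j in range(G.shape[1]):
            ok = ~np.isnan(G[:, j])
            gj, rj = G[ok, j], stats.rankdata(resid[ok])
            groups = [rj[gj == g] for g in (0, 1, 2) if (gj == g).any()]
            if len(groups) < 2:
                logger.warning("marker %s: <2 genotype groups, LOD missing",
                               geno.markers[j])
                lods[j] = np.nan
                continue
            h = stats.kruskal(*groups).statistic
            lods[j] = kruskal_wallis_lod(h)
    else:
        tie = _tie_correction(ranks)
        h = _kw_h_batch(ranks[None, :], _genotype_indicators(G), tie)[0]
        lods = kruskal_wallis_lod(h)
        for j in np.flatnonzero(np.isnan(lods)):
            logger.warning("marker %s: <2 genotype groups, LOD missing",
                           geno.markers[j])

    table = gmap.table[gmap.table["marker_id"].isin(geno.markers)].copy()
    table = table.set_index("marker_id").loc[geno.markers].reset_index()
    table["lod"] = lods
    table["flag"] = ""
    return ScanResult(table, "nonparametric", str(trait.name),
                      list(covariates.columns) if covariates is not None else [],
                      len(y))


# ---------------------------------------------------------------------------
# Binary scan
# ---------------------------------------------------------------------------


def _binary_designs(G: np.ndarray, C: np.ndarray | None) -> list[np.ndarray]:
    """Full-model design per marker: [1, het, hom-NOD, covariates]."""
    n = G.shape[0]
    ones = np.ones((n, 1))
    covs = C if C is not None else np.empty((n, 0))
    designs = []
    for j in range(G.shape[1]):
        i1 = (G[:, j] == 1.0).astype(float)
        i2 = (G[:, j] == 2.0).astype(float)
        designs.append(np.column_stack([ones, i1, i2, covs]))
    return designs


def scan_binary(
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> ScanResult:
    """Logistic likelihood-ratio marker scan of a 0/1 trait on the LOD scale."""
    y, C, mask = _align_inputs(geno, trait, covariates)
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0} or len(classes) < 2:
        raise ValueError("binary trait must contain both classes coded 0/1")
    G = geno.codes[mask]
    n = len(y)
    ones = np.ones((n, 1))
    null_X = np.column_stack([ones, C]) if C is not None else ones
    _, _, llf_null, _ = logit_fit(null_X, y)

    lods = np.empty(G.shape[1])
    flags = [""] * G.shape[1]
    for j, X in enumerate(_binary_designs(G, C)):
        gj = G[:, j]
        present = [g for g in (0.0, 1.0, 2.0) if (gj == g).any()]
        if np.isnan(gj).any():
            ok = ~np.isnan(gj)
            Xj, yj = X[ok], y[ok]
            _, _, llf_nj, _ = logit_fit(null_X[ok], yj)
            beta, _, llf_fj, conv = logit_fit(Xj, yj)
            lods[j] = max(0.0, (llf_fj - llf_nj) / LN10)
        elif len(present) < 2:
            logger.warning("marker %s: <2 genotype groups, LOD missing",
                           geno.markers[j])
            lods[j] = np.nan
            continue
        else:
            beta, _, llf_full, conv = logit_fit(X, y)
            lods[j] = max(0.0, (llf_full - llf_null) / LN10)
        if not conv:
            flags[j] = "separation"

    table = gmap.table[gmap.table["marker_id"].isin(geno.markers)].copy()
    table = table.set_index("marker_id").loc[geno.markers].reset_index()
    table["lod"] = lods
    table["flag"] = flags
    return ScanResult(table, "binary", str(trait.name),
                      list(covariates.columns) if covariates is not None else [],
                      n)


def _batched_binary_lods(
    designs: np.ndarray, y: np.ndarray, llf_null: float, maxiter: int = 25
) -> np.ndarray:
    """Genome-wide binary-scan LODs via Newton iterations batched over markers.

    ``designs`` is (m, n, p); used in the permutation loop where per-marker
    convergence flags are not needed.
    """
    m, n, p = designs.shape
    beta = np.zeros((m, p))
    eye = 1e-10 * np.eye(p)
    for _ in range(maxiter):
        eta = np.clip(np.einsum("mnp,mp->mn", designs, beta), -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = np.einsum("mnp,mn->mp", designs, y[None, :] - mu)
        hess = np.einsum("mnp,mn,mnq->mpq", designs, w, designs) + eye
        step = np.linalg.solve(hess, grad[..., None])[..., 0]
        beta += step
        if np.abs(step).max() < 1e-8:
            break
    eta = np.clip(np.einsum("mnp,mp->mn", designs, beta), -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    llf = np.sum(y[None, :] * np.log(mu + 1e-300)
                 + (1 - y[None, :]) * np.log(1 - mu + 1e-300), axis=1)
    return np.clip((llf - llf_null) / LN10, 0.0, None)


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    threshold: float
    alpha: float
    max_lods: np.ndarray
    n_perm: int

    def genome_p(self, observed_max_lod: float) -> float:
        """Add-one permutation p of an observed genome-wide peak LOD."""
        exceed = int(np.sum(self.max_lods >= observed_max_lod))
        return (exceed + 1) / (self.n_perm + 1)


def permutation_threshold(
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    trait: pd.Series,
    covariates: pd.DataFrame | None,
    model: str,
    n_perm: int,
    alpha: float,
    seed: int,
) -> PermutationResult:
    """Genome-wide LOD threshold from joint (trait, covariates) permutations.

    Rows of the trait/covariate block are permuted against the genotype rows;
    the threshold is the empirical (1 - alpha) quantile of the per-permutation
    maximum LOD over all markers.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y, C, mask = _align_inputs(geno, trait, covariates)
    G = geno.codes[mask]
    n = len(y)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])

    if model == "nonparametric":
        # residualize-then-rank commutes with a joint row permutation of
        # (trait, covariates), so permuting the precomputed rank vector is
        # exactly the joint permutation of the spec'd procedure
        resid = residualize(y, C)
        ranks = stats.rankdata(resid)
        tie = _tie_correction(ranks)
        if np.isnan(G).any():
            max_lods = np.empty(n_perm)
            for k in range(n_perm):
                rp = resid[perm_idx[k]]
                lods = []
                for j in range(G.shape[1]):
                    ok = ~np.isnan(G[:, j])
                    gj, rj = G[ok, j], stats.rankdata(rp[ok])
                    groups = [rj[gj == g] for g in (0, 1, 2) if (gj == g).any()]
                    if len(groups) >= 2:
                        lods.append(kruskal_wallis_lod(stats.kruskal(*groups).statistic))
                max_lods[k] = np.nanmax(lods)
            perm_max = max_lods
        else:
            inds = _genotype_indicators(G)
            perm_ranks = ranks[perm_idx]                   # (n_perm, n)
            h = _kw_h_batch(perm_ranks, inds, tie)         # (n_perm, m)
            perm_max = np.nanmax(kruskal_wallis_lod(h), axis=1)
    elif model == "binary":
        ones = np.ones((n, 1))
        null_X = np.column_stack([ones, C]) if C is not None else ones
        # the null model depends only on the jointly permuted (trait,
        # covariates) block, so its log-likelihood is permutation-invariant
        _, _, llf_null, _ = logit_fit(null_X, y)
        designs = np.stack(_binary_designs(G, C))          # (m, n, p)
        perm_max = np.empty(n_perm)
        n_cov = C.shape[1] if C is not None else 0
        for k in range(n_perm):
            idx = perm_idx[k]
            d = designs.copy()
            d[:, :, 0] = 1.0
            if n_cov:
                d[:, :, 3:] = np.broadcast_to(C[idx], (d.shape[0], n, n_cov))
            lods = _batched_binary_lods(d, y[idx], llf_null)
            perm_max[k] = np.nanmax(lods)
    else:
        raise ValueError(f"unknown scan model {model!r}")

    threshold = float(np.quantile(perm_max, 1.0 - alpha, method="higher"))
    return PermutationResult(threshold, alpha, perm_max, n_perm)


# ---------------------------------------------------------------------------
# Support intervals and region merging
# ---------------------------------------------------------------------------


def support_interval_2lod(
    scan: ScanResult, gmap: GeneticMap, chrom: str, drop: float = 2.0
) -> QTLRegion:
    """2-LOD support interval around the peak marker on a chromosome.

    Scans outward from the peak in both directions until the LOD first falls
    below (peak - drop); the interval is bounded by the outermost contiguous
    markers still within the drop, truncated at the chromosome ends.  Ties at
    the maximum resolve to the leftmost (smallest bp) marker.
    """
    sub = scan.table[scan.table["chrom"] == str(chrom)].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no markers on chromosome {chrom}")
    lods = sub["lod"].to_numpy()
    if np.isnan(lods).all():
        raise ValueError(f"no informative markers on chromosome {chrom}")
    peak_idx = int(np.nanargmax(lods))
    peak_lod = lods[peak_idx]
    cut = peak_lod - drop
    left = peak_idx
    while left - 1 >= 0 and not (np.isnan(lods[left - 1]) or lods[left - 1] < cut):
        left -= 1
    right = peak_idx
    n = len(lods)
    while right + 1 < n and not (np.isnan(lods[right + 1]) or lods[right + 1] < cut):
        right += 1
    return QTLRegion(
        trait=scan.trait,
        chrom=str(chrom),
        peak_marker=sub.loc[peak_idx, "marker_id"],
        peak_cM=float(sub.loc[peak_idx, "pos_cM"]),
        peak_lod=float(peak_lod),
        ci_start_bp=int(sub.loc[left, "pos_bp"]),
        ci_end_bp=int(sub.loc[right, "pos_bp"]),
    )


def find_significant_qtls(
    scan: ScanResult,
    gmap: GeneticMap,
    perm: PermutationResult,
) -> list[QTLRegion]:
    """One QTL per chromosome whose peak LOD reaches the permutation threshold."""
    regions: list[QTLRegion] = []
    for chrom in dict.fromkeys(scan.table["chrom"]):
        sub = scan.table[scan.table["chrom"] == chrom]
        if sub["lod"].isna().all():
            continue
        peak_lod = float(sub["lod"].max())
        if peak_lod >= perm.threshold:
            region = support_interval_2lod(scan, gmap, chrom)
            region.genome_p = perm.genome_p(peak_lod)
            regions.append(region)
    return regions


def merge_qtl_regions(regions: pd.DataFrame | list[QTLRegion]) -> pd.DataFrame:
    """Union same-chromosome support intervals that share at least one bp.

    Accepts a list of QTLRegion or a frame with chrom/ci_start_bp/ci_end_bp.
    Returns one row per merged genomic region with the member traits joined.
    """
    if isinstance(regions, list):
        regions = regions_to_frame(regions)
    if regions.empty:
        return pd.DataFrame(columns=["chrom", "start_bp", "end_bp", "n_qtls", "traits"])
    df = regions.sort_values(["chrom", "ci_start_bp", "ci_end_bp"]).reset_index(drop=True)
    merged: list[dict] = []
    for _, row in df.iterrows():
        if merged and merged[-1]["chrom"] == str(row["chrom"]) and \
                int(row["ci_start_bp"]) <= merged[-1]["end_bp"]:
            cur = merged[-1]
            cur["end_bp"] = max(cur["end_bp"], int(row["ci_end_bp"]))
            cur["n_qtls"] += 1
            cur["traits"].append(str(row.get("trait", "")))
        else:
            merged.append(
                {
                    "chrom": str(row["chrom"]),
                    "start_bp": int(row["ci_start_bp"]),
                    "end_bp": int(row["ci_end_bp"]),
                    "n_qtls": 1,
                    "traits": [str(row.get("trait", ""))],
                }
            )
    out = pd.DataFrame(merged)
    out["traits"] = out["traits"].map(lambda ts: ";".join(t for t in ts if t))
    return out
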