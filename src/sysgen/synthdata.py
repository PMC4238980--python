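"""Synthetic data with planted effects for every stage of the pipeline.

The generator emulates the study design end to end: an F2 intercross of 228
males genotyped on a sparse marker panel, 126 primary-tumor expression
profiles with planted cis-eQTLs and trait-correlated transcripts, two human
tumor cohorts (expression + dichotomizable clinical variables + survival),
and a case-case GWAS cohort.  Each simulator emits a *truth record* next to
its dataset; downstream recovery tests consume the truth, never re-derive it.

Meiosis uses the Haldane map function (no crossover interference): the
recombination fraction between adjacent markers d centimorgans apart is
c = (1 - exp(-2d/100)) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GeneticMap, GenotypeMatrix, ValidationError

# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class QTLEffect:
    marker_id: str
    trait: str
    a: float                      # additive effect per NOD allele (dosage - 1)
    d: float = 0.0                # dominance deviation of heterozygotes
    trait_type: str = "continuous"  # or "binary"


@dataclass
class CrossSpec:
    """An F2 intercross with planted QTL effects and an age covariate."""

    map: GeneticMap
    n_individuals: int = 228
    qtl_effects: list[QTLEffect] = field(default_factory=list)
    age_mean: float = 190.0       # age at death, days (30-week endpoint study)
    age_sd: float = 25.0
    covariate_coefs: dict = field(default_factory=dict)  # trait -> {cov: coef}
    noise_sd: dict = field(default_factory=dict)         # trait -> sd (default 1)
    binary_intercept: dict = field(default_factory=dict)  # trait -> logit intercept

    def __post_init__(self) -> None:
        known = set(self.map.marker_ids)
        for eff in self.qtl_effects:
            if eff.marker_id not in known:
                raise ValidationError(f"QTL effect marker {eff.marker_id!r} not in map")
        for trait, sd in self.noise_sd.items():
            if sd <= 0:
                raise ValidationError(f"noise sd for {trait!r} must be > 0")

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(e.trait for e in self.qtl_effects))


@dataclass
class CisEffect:
    transcript_id: str
    marker_id: str
    beta: float


@dataclass
class TraitLink:
    transcript_id: str
    trait: str
    r_target: float


@dataclass
class ExpressionSpec:
    """Tumor log2 expression with planted cis/trans eQTLs and trait links.

    ``annotation`` has columns transcript_id/chrom/tss_bp/ortholog (ortholog
    may be None).  A ``background_fraction`` of transcripts is drawn near the
    array background floor so the lower-10th-percentile filter has work to do.
    """

    annotation: pd.DataFrame
    n_samples: int = 126
    cis_effects: list[CisEffect] = field(default_factory=list)
    trans_effects: list[CisEffect] = field(default_factory=list)
    trait_links: list[TraitLink] = field(default_factory=list)
    baseline_mean: float = 7.0
    baseline_between_sd: float = 0.8   # spread of per-transcript baselines
    noise_sd: float = 0.5              # within-transcript residual sd
    background_fraction: float = 0.08
    background_mean: float = 3.04      # array background intensity floor
    background_sd: float = 0.12
    proximal_window_bp: int = 1_000_000

    def __post_init__(self) -> None:
        ann = self.annotation.set_index("transcript_id")
        for link in self.trait_links:
            if not abs(link.r_target) < 1:
                raise ValidationError("|r_target| must be < 1")
            if link.transcript_id not in ann.index:
                raise ValidationError(f"unknown transcript {link.transcript_id!r}")
        for eff in self.cis_effects:
            if eff.transcript_id not in ann.index:
                raise ValidationError(f"unknown transcript {eff.transcript_id!r}")

    def validate_cis_windows(self, gmap: GeneticMap) -> None:
        """Check that every planted cis effect is within the proximal window."""
        ann = self.annotation.set_index("transcript_id")
        for eff in self.cis_effects:
            row = gmap.marker_row(eff.marker_id)
            tss = ann.loc[eff.transcript_id]
            if str(row["chrom"]) != str(tss["chrom"]) or (
                abs(int(row["pos_bp"]) - int(tss["tss_bp"])) > self.proximal_window_bp
            ):
                raise ValidationError(
                    f"cis effect {eff.transcript_id!r}/{eff.marker_id!r} outside "
                    f"the {self.proximal_window_bp} bp proximal window"
                )


@dataclass
class ClinicalVariable:
    """A dichotomizable clinical variable with planted per-gene log-odds."""

    name: str
    gene_log_or: dict = field(default_factory=dict)  # gene -> log-odds per z unit
    intercept: float = -0.5
    levels: tuple = ("0", "1")  # labels emitted for outcome 0 / 1


@dataclass
class HumanCohortSpec:
    """A human tumor cohort: per-gene expression, clinical calls, survival."""

    name: str
    genes: list[str]
    n_cases: int = 246
    gene_mean: float = 8.0
    gene_sd: float = 1.0
    clinical: list[ClinicalVariable] = field(default_factory=list)
    risk_genes: list[str] = field(default_factory=list)  # drive the survival HR
    hazard_ratio: float = 2.5
    baseline_median_months: float = 60.0
    censoring_rate: float = 0.5
    z_cut: float = 2.0

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValidationError("hazard_ratio must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must lie in [0,1)")
        unknown = [g for g in self.risk_genes if g not in self.genes]
        if unknown:
            raise ValidationError(f"risk genes not in gene panel: {unknown}")


@dataclass
class GwasSnp:
    snp_id: str
    chrom: str
    bp: int
    maf: float
    gene: str | None = None  # nearby candidate gene, for truth bookkeeping


@dataclass
class GwasSpec:
    """Case-case GWAS cohort: aggressive vs non-aggressive prostate cancer."""

    snps: list[GwasSnp]
    n_subjects: int = 1172
    # variable name -> {snp_id: log OR per minor-allele dose}
    planted_log_or: dict = field(default_factory=dict)
    variable_intercepts: dict = field(default_factory=dict)
    age_mean: float = 62.0
    age_sd: float = 8.0
    age_log_or: float = 0.0
    pc_sd: float = 1.0

    def __post_init__(self) -> None:
        ids = {s.snp_id for s in self.snps}
        for snp in self.snps:
            if not 0 < snp.maf <= 0.5:
                raise ValidationError(f"MAF of {snp.snp_id!r} outside (0, 0.5]")
        for var, effs in self.planted_log_or.items():
            unknown = set(effs) - ids
            if unknown:
                raise ValidationError(f"planted SNPs not in panel ({var}): {unknown}")


# ---------------------------------------------------------------------------
# F2 genotypes
# ---------------------------------------------------------------------------


def haldane_recomb_fraction(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in centimorgans (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def simulate_f2_genotypes(spec: CrossSpec, seed: int) -> GenotypeMatrix:
    """Drop two independent gametes per F2 individual along the marker map.

    Each gamete starts from a fair coin at the first marker of a chromosome
    and switches parental origin between adjacent markers with the Haldane
    recombination fraction.  Dosage is the number of NOD/ShiLtJ alleles.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_individuals
    gmap = spec.map
    cols: dict[str, np.ndarray] = {}
    for chrom in gmap.chromosomes:
        sub = gmap.chrom_markers(chrom)
        m = len(sub)
        c = haldane_recomb_fraction(np.diff(sub["pos_cM"].to_numpy()))
        # 2n gametes simulated at once
        alleles = np.empty((2 * n, m), dtype=np.int8)
        alleles[:, 0] = rng.random(2 * n) < 0.5
        for j in range(1, m):
            flip = rng.random(2 * n) < c[j - 1]
            alleles[:, j] = np.where(flip, 1 - alleles[:, j - 1], alleles[:, j - 1])
        dosage = alleles[:n] + alleles[n:]
        for j, marker in enumerate(sub["marker_id"]):
            cols[marker] = dosage[:, j].astype(float)
    samples = [f"F2_{i + 1:03d}" for i in range(n)]
    codes = np.column_stack([cols[m] for m in gmap.marker_ids])
    return GenotypeMatrix(samples, gmap.marker_ids, codes)


# ---------------------------------------------------------------------------
# F2 traits
# ---------------------------------------------------------------------------


@dataclass
class TraitData:
    traits: pd.DataFrame       # samples x traits (binary traits coded 0/1)
    covariates: pd.DataFrame   # samples x covariates (age, ...)
    trait_types: dict          # trait -> "continuous" | "binary"
    truth: pd.DataFrame        # planted (marker, trait, a, d, trait_type)


def simulate_traits(geno: GenotypeMatrix, spec: CrossSpec, seed: int) -> TraitData:
    """Draw trait and covariate tables with the spec's planted QTL effects.

    Continuous traits are a sum of genotype effects, covariate terms and
    Gaussian noise.  Binary traits put the same linear predictor through a
    logistic link; a draw leaving the trait monomorphic is retried up to 10
    times before raising.
    """
    rng = np.random.default_rng(seed)
    n = len(geno.samples)
    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    covariates = pd.DataFrame({"age": age}, index=geno.samples)

    trait_types = {
        e.trait: e.trait_type for e in spec.qtl_effects
    }
    traits = pd.DataFrame(index=geno.samples)
    # continuous traits first so they can serve as covariates of binary ones
    order = sorted(trait_types, key=lambda t: trait_types[t] == "binary")
    for trait in order:
        effects = [e for e in spec.qtl_effects if e.trait == trait]
        lin = np.zeros(n)
        for eff in effects:
            dos = geno.column(eff.marker_id)
            lin += eff.a * (dos - 1.0) + eff.d * (dos == 1.0)
        for cov, coef in spec.covariate_coefs.get(trait, {}).items():
            if cov in covariates.columns:
                x = covariates[cov].to_numpy()
            elif cov in traits.columns:
                x = traits[cov].to_numpy()
            else:
                raise ValidationError(f"unknown covariate {cov!r} for trait {trait!r}")
            lin += coef * (x - x.mean()) / x.std()
        sd = spec.noise_sd.get(trait, 1.0)
        if trait_types[trait] == "continuous":
            traits[trait] = lin + rng.normal(0.0, sd, size=n)
        else:
            eta = spec.binary_intercept.get(trait, 0.0) + lin
            p = 1.0 / (1.0 + np.exp(-eta))
            for attempt in range(10):
                y = (rng.random(n) < p).astype(float)
                if 0 < y.sum() < n:
                    break
            else:
                raise ValidationError(f"binary trait {trait!r} monomorphic after 10 draws")
            traits[trait] = y

    truth = pd.DataFrame(
        [
            {
                "marker_id": e.marker_id,
                "trait": e.trait,
                "a": e.a,
                "d": e.d,
                "trait_type": e.trait_type,
            }
            for e in spec.qtl_effects
        ]
    )
    return TraitData(traits, covariates, trait_types, truth)


# ---------------------------------------------------------------------------
# Tumor expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionData:
    matrix: pd.DataFrame       # transcripts x samples, log2 intensity
    annotation: pd.DataFrame   # transcript_id, chrom, tss_bp, ortholog
    samples: list[str]
    truth: dict                # planted cis/trans/trait-link/background records


def simulate_expression(
    geno: GenotypeMatrix,
    spec: ExpressionSpec,
    trait_data: TraitData,
    seed: int,
) -> ExpressionData:
    """Simulate a log2 expression matrix over a subset of the F2 samples.

    Intensity = per-transcript baseline + sum of planted beta * dosage terms
    + lambda * standardized linked trait + Gaussian noise.  The lambda for a
    trait link is chosen so the expected sample correlation with the trait is
    the spec's r_target.  Background transcripts sit near the array floor.
    """
    rng = np.random.default_rng(seed)
    ann = spec.annotation.reset_index(drop=True)
    tids = ann["transcript_id"].tolist()
    n_tr = len(tids)

    take = min(spec.n_samples, len(geno.samples))
    sample_idx = rng.choice(len(geno.samples), size=take, replace=False)
    sample_idx.sort()
    samples = [geno.samples[i] for i in sample_idx]
    n = len(samples)

    n_bg = int(round(spec.background_fraction * n_tr))
    bg_idx = rng.choice(n_tr, size=n_bg, replace=False) if n_bg else np.array([], int)
    planted = {e.transcript_id for e in spec.cis_effects + spec.trans_effects}
    planted |= {l.transcript_id for l in spec.trait_links}
    bg_idx = np.array([i for i in bg_idx if tids[i] not in planted], dtype=int)
    is_bg = np.zeros(n_tr, dtype=bool)
    is_bg[bg_idx] = True

    baseline = rng.normal(spec.baseline_mean, spec.baseline_between_sd, size=n_tr)
    baseline[is_bg] = rng.normal(spec.background_mean, spec.background_sd, size=is_bg.sum())

    mat = np.tile(baseline[:, None], (1, n))
    noise_sd = np.full(n_tr, spec.noise_sd)
    noise_sd[is_bg] = spec.background_sd

    tr_index = {t: i for i, t in enumerate(tids)}
    for eff in spec.cis_effects + spec.trans_effects:
        dos = geno.column(eff.marker_id)[sample_idx]
        mat[tr_index[eff.transcript_id]] += eff.beta * dos
    for link in spec.trait_links:
        y = trait_data.traits.loc[samples, link.trait].to_numpy()
        z = (y - y.mean()) / y.std()
        lam = spec.noise_sd * link.r_target / np.sqrt(1.0 - link.r_target**2)
        mat[tr_index[link.transcript_id]] += lam * z
    mat += rng.normal(0.0, noise_sd[:, None], size=(n_tr, n))

    truth = {
        "cis": [vars(e) for e in spec.cis_effects],
        "trans": [vars(e) for e in spec.trans_effects],
        "trait_links": [vars(l) for l in spec.trait_links],
        "background": [tids[i] for i in bg_idx],
    }
    matrix = pd.DataFrame(mat, index=tids, columns=samples)
    return ExpressionData(matrix, ann, samples, truth)


# ---------------------------------------------------------------------------
# Human cohort
# ---------------------------------------------------------------------------


@dataclass
class HumanCohortData:
    name: str
    expression: pd.DataFrame   # genes x samples
    clinical: pd.DataFrame     # samples x clinical variables (level labels)
    survival: pd.DataFrame     # samples x [time_months, event]
    truth: dict


def simulate_human_cohort(spec: HumanCohortSpec, seed: int) -> HumanCohortData:
    """Simulate expression, dichotomous clinical calls and survival times.

    The dichotomized outcome of each clinical variable follows a logistic
    model on population z-scores with the planted per-gene log-odds.  Survival
    is exponential; cases altered in the risk-gene set (z >= z_cut for at
    least one risk gene) have their hazard multiplied by the spec's ratio.
    Censoring is an independent exponential competing time.
    """
    rng = np.random.default_rng(seed)
    n, genes = spec.n_cases, spec.genes
    samples = [f"{spec.name}_S{i + 1:03d}" for i in range(n)]
    expr = rng.normal(spec.gene_mean, spec.gene_sd, size=(len(genes), n))
    expression = pd.DataFrame(expr, index=genes, columns=samples)

    z = (expr - expr.mean(axis=1, keepdims=True)) / expr.std(axis=1, ddof=0, keepdims=True)
    zdf = pd.DataFrame(z, index=genes, columns=samples)

    clinical = pd.DataFrame(index=samples)
    for var in spec.clinical:
        eta = np.full(n, var.intercept)
        for gene, lor in var.gene_log_or.items():
            eta += lor * zdf.loc[gene].to_numpy()
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        clinical[var.name] = [var.levels[v] for v in y]

    base_rate = np.log(2.0) / spec.baseline_median_months
    altered = np.zeros(n, dtype=bool)
    for gene in spec.risk_genes:
        altered |= zdf.loc[gene].to_numpy() >= spec.z_cut
    rate = base_rate * np.where(altered, spec.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / rate)
    if spec.censoring_rate > 0:
        cens_rate = base_rate * spec.censoring_rate / (1.0 - spec.censoring_rate)
        cens_time = rng.exponential(1.0 / cens_rate, size=n)
    else:
        cens_time = np.full(n, np.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    survival = pd.DataFrame(
        {"time_months": time, "event": event}, index=samples
    )
    truth = {
        "clinical": {v.name: dict(v.gene_log_or) for v in spec.clinical},
        "risk_genes": list(spec.risk_genes),
        "hazard_ratio": spec.hazard_ratio,
        "altered_cases": [s for s, a in zip(samples, altered) if a],
    }
    return HumanCohortData(spec.name, expression, clinical, survival, truth)


# ---------------------------------------------------------------------------
# GWAS cohort
# ---------------------------------------------------------------------------


@dataclass
class GwasData:
    genotypes: pd.DataFrame    # subjects x snps, minor-allele dosage
    snps: pd.DataFrame         # snp_id, chrom, bp, maf, gene
    clinical: pd.DataFrame     # subjects x clinical variables (0/1)
    covariates: pd.DataFrame   # subjects x [age, PC1, PC2, PC3]
    truth: dict


def simulate_gwas_cohort(spec: GwasSpec, seed: int) -> GwasData:
    """Simulate a case-case GWAS cohort under Hardy-Weinberg equilibrium.

    Genotypes are binomial(2, MAF) draws per SNP.  The three PCs are two
    latent ancestry axes plus one pure-noise axis; no confounding with the
    outcome is planted.  Each aggressiveness variable is a logistic draw with
    the planted per-SNP log-ORs and an optional age term.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    subjects = [f"G{i + 1:04d}" for i in range(n)]
    snp_ids = [s.snp_id for s in spec.snps]
    geno = np.column_stack(
        [rng.binomial(2, s.maf, size=n).astype(float) for s in spec.snps]
    )
    genotypes = pd.DataFrame(geno, index=subjects, columns=snp_ids)
    snps = pd.DataFrame(
        [
            {"snp_id": s.snp_id, "chrom": s.chrom, "bp": s.bp, "maf": s.maf,
             "gene": s.gene}
            for s in spec.snps
        ]
    )

    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    ancestry = rng.normal(0.0, spec.pc_sd, size=(n, 2))
    covariates = pd.DataFrame(
        {
            "age": age,
            "PC1": ancestry[:, 0] + rng.normal(0, 0.1, n),
            "PC2": ancestry[:, 1] + rng.normal(0, 0.1, n),
            "PC3": rng.normal(0.0, spec.pc_sd, size=n),
        },
        index=subjects,
    )

    clinical = pd.DataFrame(index=subjects)
    for var, effs in spec.planted_log_or.items():
        eta = np.full(n, spec.variable_intercepts.get(var, 0.0))
        eta += spec.age_log_or * (age - spec.age_mean) / spec.age_sd
        for snp_id, lor in effs.items():
            eta += lor * genotypes[snp_id].to_numpy()
        clinical[var] = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    truth = {"planted_log_or": {v: dict(e) for v, e in spec.planted_log_or.items()}}
    return GwasData(genotypes, snps, clinical, covariates, truth)


# ---------------------------------------------------------------------------
# Default study configuration
# ---------------------------------------------------------------------------


def default_marker_map(
    n_chrom: int = 5, markers_per_chrom: int = 12, spacing_cM: float = 10.0
) -> GeneticMap:
    """A sparse evenly spaced marker panel (~1.8 Mb per cM, mouse-like)."""
    rows = []
    for c in range(1, n_chrom + 1):
        for j in range(markers_per_chrom):
            cm = j * spacing_cM
            rows.append(
                {
                    "marker_id": f"m{c}_{j + 1:02d}",
                    "chrom": str(c),
                    "pos_cM": cm,
                    "pos_bp": int(3_000_000 + cm * 1_800_000),
                }
            )
    return GeneticMap(pd.DataFrame(rows))


def default_study(seed: int = 0) -> dict:
    """The default synthetic study: specs for every pipeline input.

    Three genes are planted end to end — in a mapped QTL interval, with a
    cis-eQTL and trait correlation in the cross, a human-cohort expression
    association, and a GWAS signal — so the full pipeline has a known answer.
    """
    gmap = default_marker_map()
    # each expression-bearing QTL spreads its effect over two adjacent
    # markers, giving the broad multi-marker support intervals typical of an
    # F2 cross (the mapped intervals span tens of Mb); the planted
    # transcripts sit between the two effect markers, inside the interval
    cross = CrossSpec(
        map=gmap,
        n_individuals=228,
        qtl_effects=[
            QTLEffect("m2_05", "tumor_burden", a=0.40),
            QTLEffect("m2_06", "tumor_burden", a=0.40),
            QTLEffect("m4_03", "tumor_burden", a=0.38),
            QTLEffect("m4_04", "tumor_burden", a=0.38),
            QTLEffect("m1_07", "dmfs", a=0.9, trait_type="binary"),
        ],
        covariate_coefs={"tumor_burden": {"age": -0.2}, "dmfs": {"age": -0.2}},
        noise_sd={"tumor_burden": 1.0},
    )

    def bp_of(marker: str) -> int:
        return int(gmap.marker_row(marker)["pos_bp"])

    # transcript panel: 3 planted end-to-end genes + structured decoys + nulls
    rows = []

    def add_tx(tid, chrom, tss, ortholog):
        rows.append(
            {"transcript_id": tid, "chrom": str(chrom), "tss_bp": int(tss),
             "ortholog": ortholog}
        )

    # planted genes: within 1 Mb of a cis marker AND between the two QTL
    # effect markers so they fall inside the 2-LOD support interval
    add_tx("Tx_g1", "2", bp_of("m2_05") + 300_000, "GENE1")
    add_tx("Tx_g2", "2", bp_of("m2_06") - 400_000, "GENE2")
    add_tx("Tx_g3", "4", bp_of("m4_04") - 300_000, "GENE3")
    # decoys, each violating exactly one nomination clause:
    #   cis eQTL + trait link but outside any QTL (chr5 carries no QTL)
    add_tx("Tx_cisonly", "5", bp_of("m5_03") + 100_000, "CISONLY")
    #   in-interval + trait link but no cis eQTL
    add_tx("Tx_linkonly", "4", bp_of("m4_04") - 600_000, "LINKONLY")
    #   full evidence but no human ortholog (dropped at ortholog mapping)
    add_tx("Tx_noorth", "2", bp_of("m2_05") + 600_000, None)
    rng = np.random.default_rng(seed + 17)
    for i in range(114):
        chrom = str(rng.integers(1, 6))
        tss = int(rng.integers(3_000_000, 3_000_000 + int(110 * 1.8e6)))
        add_tx(f"Tx_null{i + 1:03d}", chrom, tss, f"NULL{i + 1:03d}")
    annotation = pd.DataFrame(rows)

    expr = ExpressionSpec(
        annotation=annotation,
        n_samples=126,
        cis_effects=[
            CisEffect("Tx_g1", "m2_05", 0.5),
            CisEffect("Tx_g2", "m2_06", 0.5),
            CisEffect("Tx_g3", "m4_04", 0.5),
            CisEffect("Tx_cisonly", "m5_03", 0.5),
            CisEffect("Tx_noorth", "m2_05", 0.5),
        ],
        trait_links=[
            TraitLink("Tx_g1", "tumor_burden", 0.4),
            TraitLink("Tx_g2", "tumor_burden", 0.4),
            TraitLink("Tx_g3", "tumor_burden", 0.4),
            TraitLink("Tx_linkonly", "tumor_burden", 0.4),
            TraitLink("Tx_noorth", "tumor_burden", 0.4),
        ],
    )
    expr.validate_cis_windows(gmap)

    human_genes = sorted(
        {o for o in annotation["ortholog"].dropna()} & (
            {"GENE1", "GENE2", "GENE3", "CISONLY", "LINKONLY"}
        )
    ) + [f"NULL{i:03d}" for i in range(1, 5)]
    cohort_a = HumanCohortSpec(
        name="cohortA",
        genes=human_genes,
        n_cases=246,
        clinical=[
            ClinicalVariable(
                "disease_free_status",
                gene_log_or={"GENE1": 1.0, "GENE2": 1.0, "GENE3": 1.0},
                intercept=-0.6,
                levels=("DiseaseFree", "Recurred"),
            ),
            # aggressiveness variables are correlated manifestations of one
            # phenotype: risk genes shift all of them, strongest the primary
            ClinicalVariable(
                "pathological_stage",
                gene_log_or={"GENE1": 0.8, "GENE2": 0.4, "GENE3": 0.4},
                intercept=-0.4,
                levels=("T2", "T3"),
            ),
        ],
        risk_genes=["GENE1", "GENE2", "GENE3"],
        hazard_ratio=2.5,
    )
    cohort_b = HumanCohortSpec(
        name="cohortB",
        genes=human_genes,
        n_cases=131,
        clinical=[
            ClinicalVariable(
                "gleason_score",
                gene_log_or={"GENE1": 1.0, "GENE2": 1.0, "GENE3": 1.0},
                intercept=-0.3,
                levels=("6", "7"),
            ),
        ],
        risk_genes=["GENE1", "GENE2", "GENE3"],
        hazard_ratio=2.5,
    )

    # human gene intervals on synthetic coordinates; two SNPs near each
    # planted gene (one associated, one null) and nulls elsewhere
    gene_rows, snp_list, planted_gwas = [], [], {}
    human_chrom = {"GENE1": "5", "GENE2": "16", "GENE3": "16",
                   "CISONLY": "9", "LINKONLY": "6",
                   "NULL001": "1", "NULL002": "2", "NULL003": "3", "NULL004": "4"}
    for i, gene in enumerate(human_genes):
        start = 10_000_000 + i * 2_000_000
        gene_rows.append(
            {"gene": gene, "chrom": human_chrom.get(gene, "1"),
             "start": start, "end": start + 50_000}
        )
        snp_a = GwasSnp(f"rs{gene}_a", human_chrom.get(gene, "1"), start + 10_000,
                        maf=0.3, gene=gene)
        snp_b = GwasSnp(f"rs{gene}_b", human_chrom.get(gene, "1"), start + 90_000,
                        maf=0.2, gene=gene)
        snp_list += [snp_a, snp_b]
    gwas_genes = pd.DataFrame(gene_rows)
    planted_gwas = {
        "pros_gleason": {"rsGENE1_a": np.log(1.6), "rsGENE2_a": np.log(1.6)},
        "pros_stage_t": {"rsGENE3_a": np.log(1.6)},
        "pros_stage": {},
        "pros_stage_n": {},
        "pros_stage_m": {},
        "pros_gleason_biop": {},
        "pros_gleason_prost": {},
    }
    gwas = GwasSpec(
        snps=snp_list,
        n_subjects=1172,
        planted_log_or=planted_gwas,
        variable_intercepts={
            "pros_gleason": -0.3, "pros_stage_t": -0.8, "pros_stage": 0.3,
            "pros_stage_n": -1.5, "pros_stage_m": -2.0,
            "pros_gleason_biop": -0.2, "pros_gleason_prost": -0.2,
        },
    )

    return {
        "map": gmap,
        "cross": cross,
        "expression": expr,
        "cohorts": [cohort_a, cohort_b],
        "gwas": gwas,
        "gwas_genes": gwas_genes,
        "trait_covariates": {"tumor_burden": ["age"], "dmfs": ["age", "tumor_burden"]},
        "eqtl_covariates": ["age", "tumor_burden"],
        "planted_genes": ["GENE1", "GENE2", "GENE3"],
    }
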