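"""Readers/writers for the on-disk formats the pipeline touches, plus config.

Canonical dialect is TSV (tab-delimited, UTF-8, '.' decimal).  PLINK-style
.ped/.map is accepted read-only for genotypes, and BED3+name for gene
intervals.  All genomic coordinates are held 1-based inclusive internally;
BED input is converted from 0-based half-open at the boundary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("sysgen")


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger once, idempotently."""
    root = logging.getLogger("sysgen")
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        root.addHandler(handler)
    root.setLevel(level.upper())


class FormatError(ValueError):
    """A file violates its declared format (bad header, bad cell, duplicate key)."""


class ValidationError(ValueError):
    """Structurally well-formed data violating a domain invariant."""


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

MAP_COLUMNS = ["marker_id", "chrom", "pos_cM", "pos_bp"]


@dataclass
class GeneticMap:
    """Marker map of an intercross panel.

    ``table`` has columns marker_id/chrom/pos_cM/pos_bp, sorted within each
    chromosome by centimorgan position, with bp jointly nondecreasing.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MAP_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"marker map missing columns: {missing}")
        t = self.table.loc[:, MAP_COLUMNS].copy()
        t["chrom"] = t["chrom"].astype(str)
        t["pos_cM"] = t["pos_cM"].astype(float)
        t["pos_bp"] = t["pos_bp"].astype(int)
        dup = t["marker_id"][t["marker_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate marker_id(s): {sorted(set(dup))}")
        if (t["pos_cM"] < 0).any():
            raise ValidationError("negative pos_cM")
        if (t["pos_bp"] < 1).any():
            raise ValidationError("pos_bp must be a positive 1-based coordinate")
        t = t.sort_values(["chrom", "pos_cM"], kind="mergesort").reset_index(drop=True)
        for chrom, grp in t.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos_bp"].to_numpy()) >= 0):
                raise ValidationError(
                    f"chromosome {chrom}: pos_bp not nondecreasing along pos_cM order"
                )
        self.table = t

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_markers(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == str(chrom)]

    def marker_row(self, marker_id: str) -> pd.Series:
        rows = self.table[self.table["marker_id"] == marker_id]
        if rows.empty:
            raise KeyError(f"marker {marker_id!r} not in map")
        return rows.iloc[0]


def read_marker_map(path: str | Path) -> GeneticMap:
    """Read a TSV marker map (header marker_id/chrom/pos_cM/pos_bp)."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str},
                     float_precision="round_trip")
    return GeneticMap(df)


def write_marker_map(gmap: GeneticMap, path: str | Path) -> None:
    """Write the canonical (sorted) TSV form of a marker map."""
    gmap.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """F2 genotype dosages: count of NOD/ShiLtJ-derived alleles per marker.

    ``codes`` is a float array of shape (n_samples, n_markers) with values in
    {0, 1, 2} and NaN for missing calls.
    """

    samples: list[str]
    markers: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.samples), len(self.markers)):
            raise ValidationError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        vals = self.codes[~np.isnan(self.codes)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = sorted(set(vals[~np.isin(vals, (0.0, 1.0, 2.0))]))
            raise ValidationError(f"genotype codes outside {{0,1,2,NA}}: {bad}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.samples, columns=self.markers)

    def column(self, marker_id: str) -> np.ndarray:
        return self.codes[:, self.markers.index(marker_id)]


def read_genotype_table(path: str | Path, gmap: GeneticMap) -> GenotypeMatrix:
    """Read a samples x markers dosage TSV, reordering columns to match the map.

    Cells must be 0/1/2 or NA (empty also accepted as missing).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    unknown = [c for c in df.columns if c not in set(gmap.marker_ids)]
    if unknown:
        raise FormatError(f"genotype columns not in marker map: {unknown}")
    codes = df.to_numpy(dtype=float)
    bad = ~(np.isnan(codes) | np.isin(codes, (0.0, 1.0, 2.0)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"illegal genotype value {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    order = [m for m in gmap.marker_ids if m in df.columns]
    df = df.loc[:, order]
    return GenotypeMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=float))


def read_ped(
    ped_path: str | Path,
    map_path: str | Path,
    nod_alleles: dict[str, str],
    gmap: GeneticMap | None = None,
) -> GenotypeMatrix:
    """Read PLINK-style .ped/.map, recoding allele pairs to NOD-allele dosage.

    ``nod_alleles`` declares, per marker, which allele letter is
    NOD/ShiLtJ-derived; '0' in the .ped denotes a missing allele.
    """
    map_df = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "marker_id", "pos_cM", "pos_bp"],
        dtype={"chrom": str, "marker_id": str},
    )
    markers = map_df["marker_id"].tolist()
    missing_assign = [m for m in markers if m not in nod_alleles]
    if missing_assign:
        raise FormatError(f"no NOD allele declared for markers: {missing_assign}")
    samples: list[str] = []
    rows: list[list[float]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(markers):
                raise FormatError(
                    f".ped line {lineno}: expected {6 + 2 * len(markers)} fields, "
                    f"got {len(fields)}"
                )
            samples.append(fields[1])
            alleles = fields[6:]
            row: list[float] = []
            for i, m in enumerate(markers):
                a, b = alleles[2 * i], alleles[2 * i + 1]
                if a == "0" or b == "0":
                    row.append(np.nan)
                else:
                    row.append(float((a == nod_alleles[m]) + (b == nod_alleles[m])))
            rows.append(row)
    gm = GenotypeMatrix(samples, markers, np.array(rows, dtype=float))
    if gmap is not None:
        order = [m for m in gmap.marker_ids if m in markers]
        idx = [markers.index(m) for m in order]
        gm = GenotypeMatrix(samples, order, gm.codes[:, idx])
    return gm


# ---------------------------------------------------------------------------
# BED gene intervals (0-based half-open on disk <-> 1-based inclusive in memory)
# ---------------------------------------------------------------------------


def read_bed_genes(path: str | Path) -> pd.DataFrame:
    """Read BED3+name gene intervals, converting to 1-based inclusive."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str, "gene": str},
    )
    if (df["end"] <= df["start"]).any():
        raise FormatError("BED interval with end <= start")
    out = df.copy()
    out["start"] = df["start"].astype(int) + 1
    out["end"] = df["end"].astype(int)
    return out.loc[:, ["gene", "chrom", "start", "end"]]


def write_bed_genes(genes: pd.DataFrame, path: str | Path) -> None:
    """Write 1-based inclusive gene intervals back to 0-based half-open BED."""
    out = genes.loc[:, ["chrom", "start", "end", "gene"]].copy()
    out["start"] = out["start"].astype(int) - 1
    out["end"] = out["end"].astype(int)
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class Thresholds:
    """Statistical constants used throughout the pipeline."""

    fdr_q: float = 0.05            # significance cut on BH q-values
    genome_alpha: float = 0.05     # genome-wide permutation significance
    proximal_window_bp: int = 1_000_000   # cis/proximal eQTL window around TSS
    gene_radius_bp: int = 100_000  # SNP-to-gene assignment radius in the GWAS
    z_cut: float = 2.0             # |z| defining an expression-altered case
    hwe_p: float = 0.001           # SNPs below this exact-HWE p are dropped
    perm_gate_p: float = 0.01      # permutation p computed only below this p

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValidationError("fdr_q must lie in (0,1)")
        if not 0 < self.genome_alpha < 1:
            raise ValidationError("genome_alpha must lie in (0,1)")
        if self.proximal_window_bp <= 0 or self.gene_radius_bp <= 0:
            raise ValidationError("window sizes must be positive")
        if self.z_cut <= 0:
            raise ValidationError("z_cut must be positive")
        if not 0 < self.hwe_p < 1 or not 0 < self.perm_gate_p < 1:
            raise ValidationError("hwe_p and perm_gate_p must lie in (0,1)")


@dataclass
class PipelineConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_perm: int = 10_000
    seed: int = 0
    paths: dict = field(default_factory=dict)
    synthetic: dict | None = None
    # covariate wiring: trait name -> list of covariate column names
    trait_covariates: dict = field(default_factory=dict)
    eqtl_covariates: list = field(default_factory=lambda: ["age", "tumor_burden"])

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# Result bundles
# ---------------------------------------------------------------------------


def write_results(
    bundle: dict[str, pd.DataFrame],
    outdir: str | Path,
    config: PipelineConfig | None = None,
    extra_manifest: dict | None = None,
) -> dict[str, Path]:
    """Write one TSV per result table plus a JSON run manifest.

    Returns the mapping of table name to file path.  Tables are written with
    a header even when empty so that every stage output is re-readable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in bundle.items():
        path = outdir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        written[name] = path
    manifest: dict = {
        "tables": {k: str(v) for k, v in written.items()},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if config is not None:
        manifest["config"] = config.to_dict()
        manifest["seed"] = config.seed
    if extra_manifest:
        manifest.update(extra_manifest)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return written
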