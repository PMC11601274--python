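"""Readers and writers for the standard formats the pipeline touches.

Dialect decisions
-----------------
* Internal coordinates are 1-based inclusive (VCF/GTF convention); BED input
  is 0-based half-open and converted at the boundary.
* Variant identity is ``(chrom, pos, frozenset of alleles)``; rsIDs are labels.
* Multi-allelic VCF records are skipped with a warning.
* The weight database follows the community PredictDB dialect: an SQLite file
  with ``weights`` and ``extra`` tables plus a gzipped text covariance file
  with lines ``GENE RSID1 RSID2 VALUE``.
"""

from __future__ import annotations

import gzip
import logging
import sqlite3
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

CELL_META_COLUMNS = ["cell_id", "individual_id", "cell_type", "n_count_total", "mito_pct"]

GWAS_DEFAULT_COLUMN_MAP = {
    "variant_id": "variant_id",
    "chromosome": "chromosome",
    "position": "position",
    "effect_allele": "effect_allele",
    "non_effect_allele": "non_effect_allele",
    "beta": "beta",
    "standard_error": "standard_error",
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class CellMatrix:
    """Sparse cell x gene count matrix with per-cell metadata.

    ``cell_meta`` is indexed by ``cell_id`` and carries ``individual_id``,
    ``cell_type``, ``n_count_total`` and ``mito_pct`` (percent, 0-100).
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        n_cells, n_genes = self.counts.shape
        if n_genes != len(self.gene_ids):
            raise FormatError(
                f"counts has {n_genes} genes but {len(self.gene_ids)} gene ids"
            )
        if n_cells != len(self.cell_ids):
            raise FormatError(
                f"counts has {n_cells} cells but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell_ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative count in cell matrix")
        missing = set(self.cell_ids) - set(self.cell_meta.index)
        if missing:
            raise FormatError(f"missing metadata for {len(missing)} barcodes")
        meta = self.cell_meta.loc[self.cell_ids]
        if (meta["n_count_total"] < 0).any():
            raise FormatError("n_count_total must be non-negative")
        if ((meta["mito_pct"] < 0) | (meta["mito_pct"] > 100)).any():
            raise FormatError("mito_pct must lie in [0, 100]")
        self.cell_meta = meta

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CellMatrix":
        idx = np.flatnonzero(np.asarray(mask))
        return CellMatrix(
            counts=self.counts[idx],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
        )


@dataclass
class GenotypePanel:
    """Individual x SNP dosage matrix with variant records.

    ``snp_records`` columns: snp_id, chrom, pos (1-based), ref_allele,
    eff_allele. Dosages count copies of ``eff_allele`` and lie in [0, 2].
    """

    dosages: np.ndarray
    snp_records: pd.DataFrame
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individual_ids), len(self.snp_records)):
            raise FormatError("dosage matrix shape does not match ids/records")
        if self.dosages.size and (
            self.dosages.min() < 0 or self.dosages.max() > 2
        ):
            raise FormatError("dosages must lie in [0, 2]")
        for col in ("ref_allele", "eff_allele"):
            bad = ~self.snp_records[col].isin(VALID_BASES)
            if bad.any():
                raise FormatError(
                    f"non single-base alleles: {self.snp_records.loc[bad, 'snp_id'].tolist()[:5]}"
                )
        self.snp_records = self.snp_records.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_records)

    def subset_snps(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            dosages=self.dosages[:, idx],
            snp_records=self.snp_records.iloc[idx].reset_index(drop=True),
            individual_ids=list(self.individual_ids),
        )


@dataclass
class GeneAnnotation:
    """Per-gene TSS annotation: gene_id, chrom, tss (1-based), strand."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "tss", "strand"}
        if not required.issubset(self.table.columns):
            raise FormatError(f"annotation missing columns {required - set(self.table.columns)}")
        if self.table["gene_id"].duplicated().any():
            raise FormatError("duplicate gene_id in annotation")
        if (self.table["tss"] < 1).any():
            raise FormatError("tss must be >= 1 (1-based)")
        if not self.table["strand"].isin(["+", "-"]).all():
            raise FormatError("strand must be + or -")
        self.table = self.table.reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    def record(self, gene_id: str) -> pd.Series:
        rows = self.table[self.table["gene_id"] == gene_id]
        if rows.empty:
            raise KeyError(f"gene {gene_id} not annotated")
        return rows.iloc[0]


@dataclass
class GWASSummary:
    """Per-variant marginal association statistics.

    Columns: variant_id, chromosome, position, effect_allele,
    non_effect_allele, beta, standard_error. ``beta`` is the marginal effect
    of each copy of ``effect_allele``; ``standard_error`` is strictly positive.
    """

    table: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if (self.table["standard_error"] <= 0).any():
            raise FormatError("standard_error must be > 0")
        if not np.isfinite(self.table["beta"]).all():
            raise FormatError("beta must be finite")
        self.table = self.table.reset_index(drop=True)

    def variant_key_index(self) -> dict[tuple, int]:
        """Map (chrom, pos, frozenset{alleles}) -> row index."""
        keys = {}
        for i, row in enumerate(self.table.itertuples(index=False)):
            key = (str(row.chromosome), int(row.position),
                   frozenset((row.effect_allele, row.non_effect_allele)))
            keys.setdefault(key, i)
        return keys


@dataclass
class LDBlockSet:
    """Approximately independent LD blocks as sorted, non-overlapping intervals.

    Internally 1-based inclusive: a block spans [start, end]. ``n_blocks`` is
    the total number of defined blocks (the universe, e.g. 1703 genome-wide).
    """

    table: pd.DataFrame  # chrom, start, end, block_id

    def __post_init__(self) -> None:
        t = self.table.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, grp in t.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (starts[1:] <= ends[:-1]).any():
                raise FormatError(f"overlapping LD blocks on {chrom}")
            if (ends < starts).any():
                raise FormatError(f"block end < start on {chrom}")
        self.table = t

    @property
    def n_blocks(self) -> int:
        return len(self.table)


@dataclass
class WeightDB:
    """PredictDB-style container of per-gene SNP predictor weights.

    ``weights`` columns: gene, rsid, varID, ref_allele, eff_allele, weight.
    ``extra`` columns: gene, genename, n_snps_in_model, cv_performance.
    ``covariances`` maps gene -> (rsid list, SNP x SNP covariance matrix).
    """

    weights: pd.DataFrame
    extra: pd.DataFrame
    covariances: dict[str, tuple[list[str], np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w_genes = set(self.weights["gene"])
        e_genes = set(self.extra["gene"])
        if not w_genes <= e_genes:
            raise FormatError("weights reference genes absent from extra table")
        counts = self.weights.groupby("gene").size()
        for gene, n in zip(self.extra["gene"], self.extra["n_snps_in_model"]):
            if counts.get(gene, 0) != n:
                raise FormatError(f"n_snps_in_model mismatch for {gene}")
        for gene, (rsids, cov) in self.covariances.items():
            cov = np.asarray(cov, float)
            if cov.shape != (len(rsids), len(rsids)):
                raise FormatError(f"covariance shape mismatch for {gene}")
            if np.abs(cov - cov.T).max(initial=0.0) > 1e-8:
                raise FormatError(f"covariance asymmetric beyond 1e-8 for {gene}")

    @property
    def genes(self) -> list[str]:
        return self.extra["gene"].tolist()

    def gene_weights(self, gene: str) -> pd.DataFrame:
        return self.weights[self.weights["gene"] == gene].reset_index(drop=True)


# ---------------------------------------------------------------------------
# cell matrices (MatrixMarket triplets + sidecar lists)
# ---------------------------------------------------------------------------


def read_cell_matrix(mtx_path, features_path, barcodes_path, meta_path) -> CellMatrix:
    """Read a cell x gene MTX triplet file with feature/barcode lists and metadata.

    The MTX file is gene x cell or cell x gene; orientation is inferred from
    the sidecar list lengths (10x convention stores genes as rows).
    """
    mat = scipy.io.mmread(str(mtx_path))
    gene_ids = [l.split("\t")[0].strip() for l in _read_lines(features_path)]
    cell_ids = [l.strip() for l in _read_lines(barcodes_path)]
    if mat.shape == (len(gene_ids), len(cell_ids)):
        mat = mat.T
    elif mat.shape != (len(cell_ids), len(gene_ids)):
        raise FormatError(
            f"MTX shape {mat.shape} does not match {len(gene_ids)} features x {len(cell_ids)} barcodes"
        )
    meta = pd.read_csv(meta_path, sep="\t", dtype={"cell_id": str, "individual_id": str})
    if "cell_id" not in meta.columns:
        raise FormatError("metadata must have a cell_id column")
    meta = meta.set_index("cell_id")
    return CellMatrix(
        counts=sp.csr_matrix(mat, dtype=np.int64),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_meta=meta,
    )


def write_cell_matrix(cm: CellMatrix, mtx_path, features_path, barcodes_path, meta_path) -> None:
    """Write a CellMatrix as gene x cell MTX with sidecar lists (10x layout)."""
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(cm.counts.T), field="integer")
    Path(features_path).write_text("".join(g + "\n" for g in cm.gene_ids))
    Path(barcodes_path).write_text("".join(c + "\n" for c in cm.cell_ids))
    meta = cm.cell_meta.copy()
    meta.index.name = "cell_id"
    meta.reset_index().to_csv(meta_path, sep="\t", index=False)


def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [l for l in fh if l.strip()]


# ---------------------------------------------------------------------------
# genotype dosages
# ---------------------------------------------------------------------------


def read_dosages(path, format_hint: str | None = None) -> GenotypePanel:
    """Read genotypes as a dosage panel from VCF (GT or DS) or a TSV table.

    The TSV dialect is one row per SNP: columns ``snp_id chrom pos ref_allele
    eff_allele`` followed by one dosage column per individual.
    """
    path = Path(path)
    fmt = format_hint or ("vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "tsv")
    if fmt == "vcf":
        return _read_vcf_dosages(path)
    return _read_tsv_dosages(path)


def _read_tsv_dosages(path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["snp_id", "chrom", "pos", "ref_allele", "eff_allele"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise FormatError(f"dosage TSV missing columns {missing}")
    indiv = [c for c in df.columns if c not in meta_cols]
    dos = df[indiv].to_numpy(float).T
    if dos.size and (dos.min() < 0 or dos.max() > 2):
        raise FormatError("dosage outside [0, 2]")
    return GenotypePanel(dosages=dos, snp_records=df[meta_cols].copy(), individual_ids=indiv)


def write_dosages(panel: GenotypePanel, path) -> None:
    df = panel.snp_records.copy()
    for j, ind in enumerate(panel.individual_ids):
        df[ind] = panel.dosages[j]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _read_vcf_dosages(path) -> GenotypePanel:
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    records, rows = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            warnings.warn(f"skipping multi-allelic record at {variant.CHROM}:{variant.POS}")
            continue
        ref, alt = variant.REF, variant.ALT[0]
        if ref not in VALID_BASES or alt not in VALID_BASES:
            warnings.warn(f"skipping non-SNV record at {variant.CHROM}:{variant.POS}")
            continue
        ds = variant.format("DS")
        if ds is not None:
            dos = np.asarray(ds, float).reshape(-1)
        else:
            # allele counting from GT; cyvcf2 gt_types: 0=hom ref,1=het,3=hom alt
            dos = np.array(
                [a + b for a, b, *_ in variant.genotypes], dtype=float
            )
        if dos.size and (np.nanmin(dos) < 0 or np.nanmax(dos) > 2):
            raise FormatError(f"dosage outside [0, 2] at {variant.CHROM}:{variant.POS}")
        records.append(
            {
                "snp_id": variant.ID or f"{variant.CHROM}_{variant.POS}_{ref}_{alt}",
                "chrom": variant.CHROM,
                "pos": variant.POS,
                "ref_allele": ref,
                "eff_allele": alt,
            }
        )
        rows.append(dos)
    snp_records = pd.DataFrame(records, columns=["snp_id", "chrom", "pos", "ref_allele", "eff_allele"])
    dosages = np.array(rows, float).T if rows else np.zeros((len(individual_ids), 0))
    return GenotypePanel(dosages=dosages, snp_records=snp_records, individual_ids=individual_ids)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def read_gene_annotation(path) -> GeneAnnotation:
    """Read a TSV gene annotation with columns gene_id, chrom, tss, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GeneAnnotation(table=df)


def write_gene_annotation(ann: GeneAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


def read_gwas(path, column_map: dict[str, str] | None = None) -> GWASSummary:
    """Read GWAS summary statistics from a TSV with a configurable column map.

    Rows with non-positive standard error or non-finite beta are dropped and
    counted; among duplicate variant keys the first row wins (with a warning).
    """
    cmap = dict(GWAS_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype={cmap["chromosome"]: str})
    missing = [src for src in cmap.values() if src not in df.columns]
    if missing:
        raise FormatError(f"GWAS file missing mapped columns {missing}")
    df = df.rename(columns={src: dst for dst, src in cmap.items()})[list(cmap)]
    n0 = len(df)
    keep = (df["standard_error"] > 0) & np.isfinite(df["beta"]) & np.isfinite(df["standard_error"])
    df = df[keep]
    dup = df.duplicated(subset=["chromosome", "position", "effect_allele", "non_effect_allele"])
    if dup.any():
        warnings.warn(f"dropping {int(dup.sum())} duplicate variant rows (keeping first)")
        df = df[~dup]
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.info("read_gwas: dropped %d invalid/duplicate rows", n_dropped)
    return GWASSummary(table=df.reset_index(drop=True), n_dropped=n_dropped)


def write_gwas(gwas: GWASSummary, path) -> None:
    gwas.table.to_csv(path, sep="\t", index=False, float_format="%.8g")


# ---------------------------------------------------------------------------
# LD blocks (BED)
# ---------------------------------------------------------------------------


def read_ld_blocks(bed_path) -> LDBlockSet:
    """Read LD blocks from BED (0-based half-open), converting to 1-based inclusive."""
    rows = []
    with open(bed_path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line {i + 1}: fewer than 3 columns")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            block_id = parts[3] if len(parts) > 3 else f"{chrom}_{start0}_{end0}"
            rows.append({"chrom": chrom, "start": start0 + 1, "end": end0, "block_id": block_id})
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "block_id"])
    return LDBlockSet(table=table)


def write_ld_blocks(blocks: LDBlockSet, bed_path) -> None:
    with open(bed_path, "w") as fh:
        for row in blocks.table.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.block_id}\n")


# ---------------------------------------------------------------------------
# weight database (PredictDB dialect)
# ---------------------------------------------------------------------------


def write_weight_db(db: WeightDB, db_path, cov_path) -> None:
    """Write a WeightDB to an SQLite file plus a gzipped covariance text file.

    Genes with zero weight rows are excluded from both tables with a warning
    (they have no predictor).
    """
    counts = db.weights.groupby("gene").size()
    keep = db.extra["gene"].map(lambda g: counts.get(g, 0) > 0)
    if (~keep).any():
        warnings.warn(f"excluding {int((~keep).sum())} genes with 0 SNPs from the database")
    extra = db.extra[keep]
    Path(db_path).unlink(missing_ok=True)
    with sqlite3.connect(db_path) as conn:
        conn.execute(
            "CREATE TABLE weights (gene TEXT, rsid TEXT, varID TEXT,"
            " ref_allele TEXT, eff_allele TEXT, weight REAL)"
        )
        conn.execute(
            "CREATE TABLE extra (gene TEXT, genename TEXT,"
            " n_snps_in_model INTEGER, cv_performance REAL)"
        )
        conn.executemany(
            "INSERT INTO weights VALUES (?,?,?,?,?,?)",
            db.weights[["gene", "rsid", "varID", "ref_allele", "eff_allele", "weight"]]
            .itertuples(index=False, name=None),
        )
        conn.executemany(
            "INSERT INTO extra VALUES (?,?,?,?)",
            extra[["gene", "genename", "n_snps_in_model", "cv_performance"]]
            .itertuples(index=False, name=None),
        )
    with gzip.open(cov_path, "wt") as fh:
        fh.write("GENE RSID1 RSID2 VALUE\n")
        for gene in extra["gene"]:
            if gene not in db.covariances:
                continue
            rsids, cov = db.covariances[gene]
            cov = np.asarray(cov, float)
            for a in range(len(rsids)):
                for b in range(a, len(rsids)):
                    fh.write(f"{gene} {rsids[a]} {rsids[b]} {cov[a, b]:.10g}\n")


def read_weight_db(db_path, cov_path) -> WeightDB:
    """Read a PredictDB-dialect SQLite weight database and covariance file."""
    with sqlite3.connect(db_path) as conn:
        weights = pd.read_sql_query("SELECT * FROM weights", conn)
        extra = pd.read_sql_query("SELECT * FROM extra", conn)
    covariances: dict[str, tuple[list[str], np.ndarray]] = {}
    entries: dict[str, dict[tuple[str, str], float]] = {}
    with gzip.open(cov_path, "rt") as fh:
        header = fh.readline()
        if not header.startswith("GENE"):
            raise FormatError("covariance file missing header")
        for line in fh:
            gene, r1, r2, val = line.split()
            entries.setdefault(gene, {})[(r1, r2)] = float(val)
    gene_rsids = weights.groupby("gene")["rsid"].apply(list).to_dict()
    for gene, pairs in entries.items():
        rsids = gene_rsids.get(gene)
        if rsids is None:
            continue
        k = len(rsids)
        idx = {r: i for i, r in enumerate(rsids)}
        cov = np.zeros((k, k))
        for (r1, r2), v in pairs.items():
            i, j = idx[r1], idx[r2]
            cov[i, j] = cov[j, i] = v
        covariances[gene] = (rsids, cov)
    return WeightDB(weights=weights, extra=extra, covariances=covariances)
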