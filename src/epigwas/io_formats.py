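"""Readers and writers for every external format the tool touches.

All validation happens here so downstream modules operate on typed objects
only. Formats: GWAS summary TSV (configurable columns), BED3+ peaks,
MatrixMarket cell-peak triplets with barcode TSV, gene models as TSV or GTF
(gene features), GMT gene sets, and the per-gene SNP annotation text format.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.stats import norm

from .types import (
    CellPeakMatrix,
    ConfigurationError,
    GeneAnnotationRecord,
    GeneModel,
    GeneSetCollection,
    GwasSummary,
    Peak,
    SnpGeneAnnotation,
    ValidationError,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

DEFAULT_GWAS_COLUMNS = {
    "snp": "SNP", "chrom": "CHR", "pos": "POS", "pval": "P",
    "z": "Z", "n": "N",  # optional: ignored when the file lacks them
}

#: smallest positive normal double; underflowed p = 0 entries are clipped here
#: (subnormals would push the normal quantile to infinity)
_P_FLOOR = float(np.finfo(float).tiny)


def zscore_from_pval(pval: np.ndarray) -> np.ndarray:
    """Unsigned z from a two-sided p-value: z = Phi^{-1}(1 - p/2) >= 0.

    Summary files without signed effects still carry association strength;
    downstream peak weights use |z| only, so the unsigned magnitude suffices.
    """
    return norm.isf(np.asarray(pval, dtype=float) / 2.0)


def read_gwas(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    sep: str = "\t",
) -> GwasSummary:
    """Read GWAS summary statistics from a delimited text file.

    ``column_map`` maps logical names (snp, chrom, pos, pval, optionally z, n)
    to column headers in the file. Rows with unparseable or out-of-range
    p-values are dropped (count logged); p = 0 is clipped to the smallest
    positive double with a warning; missing z is derived as the unsigned
    normal quantile of p.
    """
    column_map = dict(column_map or DEFAULT_GWAS_COLUMNS)
    for key in ("snp", "chrom", "pos", "pval"):
        if key not in column_map:
            raise ConfigurationError(f"column_map must name a {key!r} column")
    raw = pd.read_csv(path, sep=sep)
    missing = [
        v for k, v in column_map.items()
        if v not in raw.columns and k in ("snp", "chrom", "pos", "pval")
    ]
    if missing:
        raise ConfigurationError(
            f"columns {missing} not found in {path} (have {list(raw.columns)})"
        )
    # optional columns (z, n) are used only when present
    column_map = {k: v for k, v in column_map.items() if v in raw.columns}
    df = pd.DataFrame(
        {
            "snp": raw[column_map["snp"]].astype(str),
            "chrom": raw[column_map["chrom"]].map(normalize_chrom),
            "pos": pd.to_numeric(raw[column_map["pos"]], errors="coerce"),
            "pval": pd.to_numeric(raw[column_map["pval"]], errors="coerce"),
        }
    )
    if "z" in column_map:
        df["z"] = pd.to_numeric(raw[column_map["z"]], errors="coerce")
    if "n" in column_map:
        df["n"] = pd.to_numeric(raw[column_map["n"]], errors="coerce")

    n_zero = int((df["pval"] == 0).sum())
    if n_zero:
        logger.warning("%d p-values of 0 clipped to %.3g", n_zero, _P_FLOOR)
        df.loc[df["pval"] == 0, "pval"] = _P_FLOOR
    ok = (
        df["pos"].notna()
        & df["pval"].notna()
        & (df["pval"] > 0)
        & (df["pval"] <= 1)
        & (df["pos"] >= 1)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_gwas: dropped %d rows with bad pos/pval", n_dropped)
    df = df.loc[ok].copy()
    df["pos"] = df["pos"].astype(np.int64)
    if "z" not in df.columns or df["z"].isna().all():
        df["z"] = zscore_from_pval(df["pval"].to_numpy())
    else:
        fill = df["z"].isna()
        df.loc[fill, "z"] = zscore_from_pval(df.loc[fill, "pval"].to_numpy())
    if df["snp"].duplicated().any():
        dups = sorted(df.loc[df["snp"].duplicated(), "snp"].unique()[:10])
        raise ValidationError(f"duplicate snp ids in {path}: {dups}")
    return GwasSummary(df)


def write_gwas(gwas: GwasSummary, path: str | Path) -> None:
    cols = ["snp", "chrom", "pos", "pval", "z"] + (
        ["n"] if "n" in gwas.df.columns else []
    )
    gwas.df[cols].rename(
        columns={"snp": "SNP", "chrom": "CHR", "pos": "POS", "pval": "P", "z": "Z", "n": "N"}
    ).to_csv(path, sep="\t", index=False)


def read_peaks_bed(path: str | Path) -> list[Peak]:
    """Read peaks from a BED3+ file (0-based half-open, as on disk)."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}: line {i} has fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValidationError(
                    f"{path}: line {i}: start {start} >= end {end}"
                )
            peaks.append(Peak(normalize_chrom(chrom), start, end))
    return peaks


def write_peaks_bed(peaks: list[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


def read_barcodes(path: str | Path) -> tuple[list[str], list[str] | None]:
    """Read cell barcodes, optionally with a second cell_type column."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    barcodes = df[0].tolist()
    cell_type = df[1].tolist() if df.shape[1] > 1 else None
    return barcodes, cell_type


def read_cell_matrix(
    mtx_path: str | Path,
    peaks_bed: str | Path,
    barcodes_path: str | Path,
    orientation: str = "auto",
) -> CellPeakMatrix:
    """Assemble a CellPeakMatrix from an MTX triplet + BED + barcode TSV.

    ``orientation`` is "cells_by_peaks", "peaks_by_cells", or "auto" (infer
    from the axis lengths; ambiguous square matrices require an explicit flag).
    """
    peaks = read_peaks_bed(peaks_bed)
    barcodes, cell_type = read_barcodes(barcodes_path)
    X = sp.csr_matrix(scipy.io.mmread(mtx_path))
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValidationError(f"{mtx_path}: empty matrix")
    n_cells, n_peaks = len(barcodes), len(peaks)
    if orientation == "auto":
        if X.shape == (n_cells, n_peaks) and X.shape == (n_peaks, n_cells):
            raise ConfigurationError(
                "square matrix: orientation ambiguous, pass it explicitly"
            )
        if X.shape == (n_cells, n_peaks):
            orientation = "cells_by_peaks"
        elif X.shape == (n_peaks, n_cells):
            orientation = "peaks_by_cells"
        else:
            raise ValidationError(
                f"matrix shape {X.shape} matches neither {n_cells} cells x "
                f"{n_peaks} peaks nor its transpose"
            )
    if orientation == "peaks_by_cells":
        X = X.T.tocsr()
    if X.shape != (n_cells, n_peaks):
        raise ValidationError(
            f"matrix shape {X.shape} inconsistent with {n_cells} barcodes "
            f"and {n_peaks} peaks"
        )
    return CellPeakMatrix(X, barcodes, peaks, cell_type)


def write_cell_matrix(mat: CellPeakMatrix, outdir: str | Path, prefix: str = "") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(outdir / f"{prefix}matrix.mtx", sp.coo_matrix(mat.X))
    write_peaks_bed(mat.peaks, outdir / f"{prefix}peaks.bed")
    with open(outdir / f"{prefix}barcodes.tsv", "w") as fh:
        for i, bc in enumerate(mat.cell_ids):
            if mat.cell_type is not None:
                fh.write(f"{bc}\t{mat.cell_type[i]}\n")
            else:
                fh.write(f"{bc}\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from TSV (gene_id, chrom, start, end, strand) or GTF.

    GTF detection is by extension (.gtf); only ``gene`` features are used and
    GTF 1-based inclusive coordinates are converted to the internal 0-based
    convention.
    """
    path = Path(path)
    if path.suffix.lower() == ".gtf":
        return _read_gene_models_gtf(path)
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"{path}: gene TSV needs columns {sorted(required)}"
        )
    if "strand" not in df.columns:
        df["strand"] = "+"
    return [
        GeneModel(
            str(r.gene_id), normalize_chrom(r.chrom), int(r.start), int(r.end), r.strand
        )
        for r in df.itertuples()
    ]


def _read_gene_models_gtf(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(
                kv.strip().split(" ", 1)
                for kv in f[8].rstrip(";").split(";")
                if " " in kv.strip()
            )
            gid = attrs.get("gene_id", "").strip('"')
            if not gid:
                raise ValidationError(f"{path}: gene feature without gene_id")
            genes.append(
                GeneModel(gid, normalize_chrom(f[0]), int(f[3]) - 1, int(f[4]), f[6])
            )
    return genes


def write_gene_models(genes: list[GeneModel], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genes],
        columns=["gene_id", "chrom", "start", "end", "strand"],
    ).to_csv(path, sep="\t", index=False)


def write_gene_annot(annot: SnpGeneAnnotation, path: str | Path) -> None:
    """Write the per-gene SNP annotation: ``gene_id  chrom:start:end  snp...``.

    SNPs are deduplicated across the body/CRE provenance split and ordered by
    genomic position; genes with zero SNPs are omitted (count logged).
    """
    if not annot.genes:
        raise ValidationError("cannot write an empty annotation")
    n_empty = 0
    with open(path, "w") as fh:
        for gene_id in sorted(annot.genes):
            snps = annot.exported_snps(gene_id)
            if not snps:
                n_empty += 1
                continue
            chrom, start, end = annot.gene_loc[gene_id]
            fh.write(f"{gene_id}\t{chrom}:{start}:{end}\t" + "\t".join(snps) + "\n")
    if n_empty:
        logger.info("write_gene_annot: omitted %d genes with zero SNPs", n_empty)


def read_gene_annot(path: str | Path, gwas: GwasSummary) -> SnpGeneAnnotation:
    """Read the annotation format written by :func:`write_gene_annot`.

    The file does not record provenance, so all SNPs load as body_snps; the
    exported (union) view round-trips exactly. SNP positions are recovered
    from the accompanying GWAS summary.
    """
    pos_map = dict(zip(gwas.df["snp"], zip(gwas.df["chrom"], gwas.df["pos0"])))
    genes: dict[str, GeneAnnotationRecord] = {}
    gene_loc: dict[str, tuple[str, int, int]] = {}
    snp_pos: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}: line {i} has no SNPs")
            gene_id, loc = fields[0], fields[1]
            chrom, start, end = loc.rsplit(":", 2)
            snps = fields[2:]
            unknown = [s for s in snps if s not in pos_map]
            if unknown:
                raise ValidationError(
                    f"{path}: line {i}: SNPs absent from GWAS: {unknown[:5]}"
                )
            genes[gene_id] = GeneAnnotationRecord(body_snps=set(snps))
            gene_loc[gene_id] = (chrom, int(start), int(end))
            for s in snps:
                snp_pos[s] = pos_map[s]
    if not genes:
        raise ValidationError(f"{path}: empty annotation file")
    return SnpGeneAnnotation(genes, snp_pos, gene_loc)


def read_gene_sets(path_gmt: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path_gmt) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path_gmt}: line {i} has {len(fields)} fields (need >= 3)"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValidationError(f"{path_gmt}: duplicate set name {name!r} (line {i})")
            deduped = list(dict.fromkeys(g for g in genes if g))
            if len(deduped) < len([g for g in genes if g]):
                logger.info("set %s: duplicate genes removed", name)
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write(name + "\t" + desc + "\t" + "\t".join(genes) + "\n")


def read_links(path: str | Path):
    """Read a peak-gene link table TSV written by :func:`write_links`."""
    from .types import PeakGeneLink

    df = pd.read_csv(path, sep="\t")
    links = []
    for r in df.itertuples():
        pval = None if pd.isna(r.pval) else float(r.pval)
        links.append(
            PeakGeneLink(Peak.from_id(r.peak_id), str(r.gene_id), float(r.score), r.method, pval)
        )
    return links


def write_links(links, path: str | Path) -> None:
    pd.DataFrame(
        [
            (l.peak.peak_id, l.gene_id, l.score, l.method,
             np.nan if l.pval is None else l.pval)
            for l in links
        ],
        columns=["peak_id", "gene_id", "score", "method", "pval"],
    ).to_csv(path, sep="\t", index=False)


def read_dosages(path: str | Path):
    """Read a plain dosage TSV (individuals x SNPs, header = snp ids)."""
    from .types import GenotypePanel

    df = pd.read_csv(path, sep="\t")
    pheno = None
    if "__phenotype__" in df.columns:
        pheno = df.pop("__phenotype__").to_numpy(dtype=float)
    return GenotypePanel(df.to_numpy(dtype=float), list(df.columns), pheno)


def write_dosages(panel, path: str | Path) -> None:
    df = pd.DataFrame(panel.dosages.astype(int), columns=panel.snp_ids)
    if panel.phenotype is not None:
        df["__phenotype__"] = panel.phenotype
    df.to_csv(path, sep="\t", index=False)
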