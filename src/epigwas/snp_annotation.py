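"""SNP-to-gene annotation.

Two strategies are implemented:

* window-based (the conventional baseline): a SNP is assigned to a gene when
  it falls within ``window_bp`` of the gene body (inclusive span);
* CRE-based: gene-body SNPs plus SNPs inside distal peaks linked to the gene
  by a peak-gene link table, so noncoding variants in regulatory elements
  reach their target gene regardless of linear distance.

Also provides the comparative gene typing (type 1/2/3) and the distal-SNP
significance summary used to contrast the two strategies.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import (
    GeneAnnotationRecord,
    GeneModel,
    GwasSummary,
    Peak,
    PeakGeneLink,
    SnpGeneAnnotation,
    ValidationError,
)

logger = logging.getLogger(__name__)


def _snp_arrays(gwas: GwasSummary) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (sorted pos0, snp_id) arrays for fast interval queries."""
    out = {}
    for chrom, g in gwas.df.groupby("chrom", sort=False):
        g = g.sort_values("pos0")
        out[str(chrom)] = (g["pos0"].to_numpy(), g["snp"].to_numpy())
    return out


def _snps_in_range(
    arrays: dict[str, tuple[np.ndarray, np.ndarray]],
    chrom: str,
    lo: int,
    hi: int,
    inclusive_hi: bool,
) -> np.ndarray:
    """SNP ids with pos0 in [lo, hi) or [lo, hi] on a chromosome."""
    if chrom not in arrays:
        return np.array([], dtype=object)
    pos, ids = arrays[chrom]
    left = np.searchsorted(pos, lo, side="left")
    right = np.searchsorted(pos, hi, side="right" if inclusive_hi else "left")
    return ids[left:right]


def assign_snps_window(
    gwas: GwasSummary, gene_models: list[GeneModel], window_bp: int
) -> SnpGeneAnnotation:
    """Window-based baseline: SNP in [start - window, end + window], inclusive.

    A SNP may map to multiple genes; cre_snps stay empty.
    """
    if window_bp < 0:
        raise ValidationError("window_bp must be >= 0")
    arrays = _snp_arrays(gwas)
    genes: dict[str, GeneAnnotationRecord] = {}
    gene_loc: dict[str, tuple[str, int, int]] = {}
    snp_pos: dict[str, tuple[str, int]] = {}
    pos_map = dict(zip(gwas.df["snp"], zip(gwas.df["chrom"], gwas.df["pos0"])))
    for g in gene_models:
        lo = max(0, g.start - window_bp)
        hi = g.end + window_bp
        hits = _snps_in_range(arrays, g.chrom, lo, hi, inclusive_hi=True)
        rec = GeneAnnotationRecord(body_snps=set(hits))
        genes[g.gene_id] = rec
        gene_loc[g.gene_id] = (g.chrom, g.start, g.end)
        for s in rec.body_snps:
            snp_pos[s] = pos_map[s]
    return SnpGeneAnnotation(genes, snp_pos, gene_loc)


def assign_snps_cre(
    gwas: GwasSummary,
    gene_models: list[GeneModel],
    links: list[PeakGeneLink],
) -> SnpGeneAnnotation:
    """CRE-based annotation: gene-body SNPs plus SNPs in linked peaks.

    The exported per-gene SNP list is the deduplicated union of both parts.
    """
    known = {g.gene_id for g in gene_models}
    unknown = sorted({l.gene_id for l in links} - known)
    if unknown:
        raise ValidationError(f"links reference unknown genes: {unknown[:10]}")
    annot = assign_snps_window(gwas, gene_models, window_bp=0)
    arrays = _snp_arrays(gwas)
    pos_map = dict(zip(gwas.df["snp"], zip(gwas.df["chrom"], gwas.df["pos0"])))
    by_gene: dict[str, set[Peak]] = defaultdict(set)
    for l in links:
        by_gene[l.gene_id].add(l.peak)
    for gene_id, peaks in by_gene.items():
        rec = annot.genes[gene_id]
        for p in peaks:
            hits = _snps_in_range(arrays, p.chrom, p.start, p.end, inclusive_hi=False)
            if len(hits):
                rec.cre_snps.update(hits)
                rec.peaks.add(p)
                for s in hits:
                    annot.snp_pos[s] = pos_map[s]
            else:
                rec.peaks.add(p)
    return annot


def classify_genes(
    annot_sce: SnpGeneAnnotation, annot_window: SnpGeneAnnotation
) -> pd.DataFrame:
    """Per-gene comparative typing of the CRE annotation against the baseline.

    type1: no CRE-specific SNPs; type2: both CRE-specific and baseline SNPs;
    type3: only CRE-specific SNPs. Genes present in either annotation are
    classified; the three classes partition them.
    """
    rows = []
    for gene_id in sorted(set(annot_sce.genes) | set(annot_window.genes)):
        sce = annot_sce.snps_for(gene_id) if gene_id in annot_sce.genes else set()
        win = annot_window.snps_for(gene_id) if gene_id in annot_window.genes else set()
        specific = sce - win
        if not specific:
            gtype = "type1"
        elif win:
            gtype = "type2"
        else:
            gtype = "type3"
        rec = annot_sce.genes.get(gene_id)
        rows.append(
            {
                "gene_id": gene_id,
                "type": gtype,
                "n_body": len(rec.body_snps) if rec else 0,
                "n_cre": len(rec.cre_snps) if rec else 0,
                "n_specific": len(specific),
            }
        )
    return pd.DataFrame(rows)


def _distal_snps(annot: SnpGeneAnnotation, gwas: GwasSummary) -> set[str]:
    """SNPs assigned to at least one gene but outside every gene body span."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene_id, (chrom, start, end) in annot.gene_loc.items():
        trees[chrom].addi(start, end + 1)  # inclusive body span
    assigned = set()
    for rec in annot.genes.values():
        assigned |= rec.all_snps
    distal = set()
    for s in assigned:
        chrom, pos0 = annot.snp_pos[s]
        if not trees[chrom].overlaps(pos0, pos0 + 1):
            distal.add(s)
    return distal


def distal_snp_significance(
    annot_sce: SnpGeneAnnotation,
    annot_window: SnpGeneAnnotation,
    gwas: GwasSummary,
    quantiles: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9),
) -> pd.DataFrame:
    """Quantile table of -log10 p for SNPs assigned outside gene bodies.

    One row per (method, quantile); an empty table (with a warning) when no
    distal SNPs exist for either method.
    """
    pmap = dict(zip(gwas.df["snp"], gwas.df["pval"]))
    rows = []
    for method, annot in (("cre", annot_sce), ("window", annot_window)):
        distal = _distal_snps(annot, gwas)
        if not distal:
            continue
        nlp = -np.log10([pmap[s] for s in distal])
        for q in quantiles:
            rows.append(
                {
                    "method": method,
                    "quantile": q,
                    "neg_log10_p": float(np.quantile(nlp, q)),
                    "n_distal": len(distal),
                }
            )
    if not rows:
        logger.warning("distal_snp_significance: no distal SNPs for any method")
        return pd.DataFrame(columns=["method", "quantile", "neg_log10_p", "n_distal"])
    return pd.DataFrame(rows)
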