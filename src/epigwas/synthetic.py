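"""Synthetic data with known ground truth for every pipeline stage.

The toy genome emulates the geometry that motivates CRE-based annotation:
genes with promoter-anchor peaks, distal wired enhancer peaks 30-80 kb from
the gene body (beyond the conventional 10 kb window), GWAS SNPs both inside
and outside peaks, and causal SNPs planted exclusively in the distal wired
peaks of a few causal genes. Cell-peak counts carry a shared per-gene
activity factor across each gene's peaks (so co-accessibility is
recoverable) and an optional accessibility boost for the causal genes'
peaks in one planted cell type.

These generators emulate count statistics and genomic geometry only — no
fragment-length structure, TF footprints, batch effects, or realistic LD
beyond an AR(1) haplotype model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

from . import io_formats
from .types import (
    CellPeakMatrix,
    GeneModel,
    GenotypePanel,
    GwasSummary,
    Peak,
    ValidationError,
)

CHROM = "chr1"
GENE_SPACING = 400_000
GENE_LENGTH = 20_000
N_WIRED_PER_GENE = 3
DISTAL_MIN, DISTAL_MAX = 30_000, 80_000  # wired-peak distance from gene body
SNPS_PER_PEAK = 2
SNPS_PER_GENE_BODY = 5


@dataclass
class ToyGenomeTruth:
    """Ground truth for the toy genome: wiring, causal genes/SNPs, planting."""

    genes: list[GeneModel]
    peaks: list[Peak]
    anchor_peak: dict[str, Peak]
    wired_peaks: dict[str, list[Peak]]  # distal wired peaks per gene
    causal_genes: list[str]
    causal_snps: list[str]
    snp_df: pd.DataFrame  # snp, chrom, pos (1-based)
    planted_cell_type: str = "typeA"
    cell_types: tuple[str, ...] = ("typeA", "typeB", "typeC")

    @property
    def risk_peaks(self) -> list[Peak]:
        """Peaks belonging to causal genes (anchor + wired)."""
        out: set[Peak] = set()
        for g in self.causal_genes:
            out.add(self.anchor_peak[g])
            out.update(self.wired_peaks[g])
        return sorted(out)

    @property
    def true_links(self) -> set[tuple[str, str]]:
        """(peak_id, gene_id) pairs for the planted distal wiring."""
        return {
            (p.peak_id, g) for g, ps in self.wired_peaks.items() for p in ps
        }


def toy_genome(
    n_genes: int = 20,
    n_peaks: int = 200,
    n_snps: int = 5000,
    n_causal_genes: int = 2,
    seed: int = 0,
) -> ToyGenomeTruth:
    """Build the toy genome: gene models, peaks, SNP positions, causal wiring.

    Every gene gets a promoter anchor peak and ``N_WIRED_PER_GENE`` distal
    wired peaks 30-80 kb upstream of the gene body (hence invisible to a
    10 kb window but inside a 500 kb link window). Causal SNPs sit inside
    wired peaks of the causal genes only.
    """
    rng = np.random.default_rng(seed)
    genes, peaks = [], []
    anchor_peak: dict[str, Peak] = {}
    wired_peaks: dict[str, list[Peak]] = {}
    for i in range(n_genes):
        start = 200_000 + i * GENE_SPACING
        g = GeneModel(f"G{i:03d}", CHROM, start, start + GENE_LENGTH, "+")
        genes.append(g)
        anchor = Peak(CHROM, g.tss - 1000, g.tss + 500)
        anchor_peak[g.gene_id] = anchor
        peaks.append(anchor)
        wired = []
        dists = rng.integers(DISTAL_MIN, DISTAL_MAX, size=N_WIRED_PER_GENE)
        for d in sorted(set(int(x) for x in dists)):
            p = Peak(CHROM, g.start - d - 600, g.start - d)
            wired.append(p)
            peaks.append(p)
        wired_peaks[g.gene_id] = wired
    genome_end = 200_000 + n_genes * GENE_SPACING
    n_background = n_peaks - len(peaks)
    if n_background < 0:
        raise ValidationError("n_peaks too small for the gene layout")
    taken = {(p.start, p.end) for p in peaks}
    while n_background > 0:
        s = int(rng.integers(10_000, genome_end))
        if (s, s + 600) in taken:
            continue
        peaks.append(Peak(CHROM, s, s + 600))
        taken.add((s, s + 600))
        n_background -= 1
    peaks = sorted(set(peaks))

    # SNPs: guaranteed coverage of peaks and gene bodies, remainder uniform
    positions: list[int] = []
    for p in peaks:
        positions.extend(
            int(x) for x in rng.integers(p.start, p.end, size=SNPS_PER_PEAK)
        )
    for g in genes:
        positions.extend(
            int(x) for x in rng.integers(g.start, g.end, size=SNPS_PER_GENE_BODY)
        )
    n_rest = n_snps - len(positions)
    if n_rest < 0:
        raise ValidationError("n_snps too small to cover peaks and gene bodies")
    positions.extend(int(x) for x in rng.integers(10_000, genome_end, size=n_rest))
    order = np.argsort(positions, kind="stable")
    snp_df = pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(len(positions))],
            "chrom": CHROM,
            "pos": np.asarray(positions)[order] + 1,  # 1-based
        }
    )

    causal_genes = [genes[j].gene_id for j in
                    rng.choice(n_genes, size=n_causal_genes, replace=False)]
    causal_snps: list[str] = []
    pos0 = snp_df["pos"].to_numpy() - 1
    for g in causal_genes:
        hits: list[str] = []
        for p in wired_peaks[g]:
            inside = np.flatnonzero((pos0 >= p.start) & (pos0 < p.end))
            if len(inside):
                hits.append(str(snp_df["snp"].iloc[inside[0]]))
            if len(hits) == 2:
                break
        causal_snps.extend(hits)
    return ToyGenomeTruth(
        genes, peaks, anchor_peak, wired_peaks, causal_genes, causal_snps, snp_df
    )


# ---------------------------------------------------------------------------
# GWAS + genotype panel
# ---------------------------------------------------------------------------

def simulate_gwas(
    truth: ToyGenomeTruth,
    n_individuals: int = 2000,
    h2_per_causal: float = 0.02,
    ld_rho: float = 0.0,
    seed: int = 0,
) -> tuple[GwasSummary, GenotypePanel]:
    """Simulate genotypes, a phenotype, and per-SNP marginal summary stats.

    Haplotypes come from AR(1)-correlated latent Gaussians (pairwise
    correlation ``ld_rho`` between adjacent SNPs in position order)
    thresholded at each SNP's allele frequency; the phenotype is the sum of
    standardized causal dosages times sqrt(h2_per_causal) plus Gaussian
    noise. Marginal regressions give z and two-sided p per SNP.
    """
    if not (0 <= ld_rho < 1):
        raise ValidationError("ld_rho must be in [0, 1)")
    n_snps = len(truth.snp_df)
    total_h2 = h2_per_causal * len(truth.causal_snps)
    if not (0 <= total_h2 <= 1):
        raise ValidationError(f"total heritability {total_h2} outside [0, 1]")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.1, 0.5, size=n_snps)
    thr = norm.ppf(maf)

    def haplotypes() -> np.ndarray:
        eps = rng.standard_normal((n_individuals, n_snps))
        if ld_rho > 0:
            lat = np.empty_like(eps)
            lat[:, 0] = eps[:, 0]
            c = np.sqrt(1 - ld_rho**2)
            for j in range(1, n_snps):
                lat[:, j] = ld_rho * lat[:, j - 1] + c * eps[:, j]
        else:
            lat = eps
        return (lat < thr).astype(np.int8)

    dosage = (haplotypes() + haplotypes()).astype(np.float64)
    snp_ids = truth.snp_df["snp"].tolist()
    idx = {s: j for j, s in enumerate(snp_ids)}
    y = rng.standard_normal(n_individuals) * np.sqrt(max(1.0 - total_h2, 0.0))
    for s in truth.causal_snps:
        g = dosage[:, idx[s]]
        sd = g.std()
        if sd == 0:
            continue
        y = y + np.sqrt(h2_per_causal) * (g - g.mean()) / sd

    # marginal association per SNP
    yc = (y - y.mean()) / y.std()
    gc = dosage - dosage.mean(axis=0)
    gsd = gc.std(axis=0)
    poly = gsd > 0
    r = np.zeros(n_snps)
    r[poly] = (gc[:, poly] / gsd[poly]).T @ yc / n_individuals
    r = np.clip(r, -0.999999, 0.999999)
    z = r * np.sqrt(n_individuals - 2) / np.sqrt(1 - r**2)
    pval = 2 * norm.sf(np.abs(z))
    pval = np.clip(pval, np.nextafter(0.0, 1.0), 1.0)

    df = truth.snp_df.copy()
    df["pval"] = pval
    df["z"] = z
    df["n"] = n_individuals
    return GwasSummary(df), GenotypePanel(dosage, snp_ids, phenotype=y)


# ---------------------------------------------------------------------------
# scATAC counts
# ---------------------------------------------------------------------------

@dataclass
class _AtacParams:
    activity_sd: float = 0.8  # per-gene per-cell activity factor (log scale)
    type_effect_sd: float = 0.2  # background cell-type multipliers (log scale)
    depth_sd: float = 0.3  # per-cell depth factor (log scale)


def simulate_scatac(
    truth: ToyGenomeTruth,
    n_cells_per_type: int = 200,
    depth: float = 1000.0,
    effect_fold: float = 1.0,
    noise: float = 0.3,
    seed: int = 0,
    params: _AtacParams | None = None,
) -> CellPeakMatrix:
    """Poisson cell-peak counts with planted structure.

    Each gene's peaks (anchor + wired) share a per-cell activity factor, so
    wired peaks co-vary with their promoter anchor; the causal genes' peaks
    are ``effect_fold`` times more accessible in the planted cell type.
    Background cell-type multipliers apply to non-risk peaks only, keeping
    the planted fold change interpretable. Expected depth is calibrated from
    the base configuration, so the planted type carries its extra signal as
    extra reads.
    """
    if effect_fold < 1:
        raise ValidationError("effect_fold must be >= 1")
    if params is None:
        params = _AtacParams()
    rng = np.random.default_rng(seed)
    peaks = truth.peaks
    n_peaks = len(peaks)
    types = list(truth.cell_types)
    n_cells = n_cells_per_type * len(types)
    cell_type = [t for t in types for _ in range(n_cells_per_type)]

    peak_index = {p: j for j, p in enumerate(peaks)}
    gene_of_peak = np.full(n_peaks, -1)
    for gi, g in enumerate(truth.genes):
        for p in [truth.anchor_peak[g.gene_id]] + truth.wired_peaks[g.gene_id]:
            gene_of_peak[peak_index[p]] = gi
    risk_cols = np.array([peak_index[p] for p in truth.risk_peaks])

    base = np.exp(rng.normal(0.0, 0.5, size=n_peaks))
    type_mult = np.exp(rng.normal(0.0, params.type_effect_sd, size=(len(types), n_peaks)))
    type_mult[:, risk_cols] = 1.0  # risk peaks: planted effect only
    planted_idx = types.index(truth.planted_cell_type)

    activity = np.exp(
        params.activity_sd * rng.standard_normal((n_cells, len(truth.genes)))
    )
    depth_factor = np.exp(rng.normal(0.0, params.depth_sd, size=n_cells))

    rate = np.tile(base, (n_cells, 1))
    gene_cols = gene_of_peak >= 0
    rate[:, gene_cols] *= activity[:, gene_of_peak[gene_cols]]
    for ti in range(len(types)):
        rows = slice(ti * n_cells_per_type, (ti + 1) * n_cells_per_type)
        rate[rows] *= type_mult[ti]
    if effect_fold > 1:
        rows = slice(planted_idx * n_cells_per_type,
                     (planted_idx + 1) * n_cells_per_type)
        rate[np.ix_(np.arange(n_cells)[rows], risk_cols)] *= effect_fold
    if noise > 0:
        rate *= np.exp(rng.normal(0.0, noise, size=rate.shape))
    # calibrate expected depth from the base configuration (no planted effect)
    rate *= depth / base.sum()
    rate *= depth_factor[:, None]
    counts = rng.poisson(rate)
    X = sp.csr_matrix(counts)
    cell_ids = [f"cell{ci:04d}" for ci in range(n_cells)]
    return CellPeakMatrix(X, cell_ids, peaks, cell_type)


# ---------------------------------------------------------------------------
# multiome expression
# ---------------------------------------------------------------------------

def simulate_multiome(
    truth: ToyGenomeTruth,
    atac: CellPeakMatrix,
    link_strength: float = 0.8,
    depth: float = 20.0,
    seed: int = 0,
) -> tuple[sp.csr_matrix, list[str]]:
    """Cell x gene expression counts coupled to the wired peaks' accessibility.

    Each gene's expression rate mixes the depth-normalized summed
    accessibility of its wired (+ anchor) peaks with independent noise:
    rate ∝ link_strength * signal + (1 - link_strength); counts are Poisson.
    """
    if not (0.0 <= link_strength <= 1.0):
        raise ValidationError("link_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dense = atac.X.toarray().astype(float)
    cdepth = dense.sum(axis=1)
    cdepth[cdepth == 0] = 1.0
    dense = dense / cdepth[:, None]
    peak_index = {p: j for j, p in enumerate(atac.peaks)}
    genes = [g.gene_id for g in truth.genes]
    rates = np.empty((atac.n_cells, len(genes)))
    for gi, g in enumerate(truth.genes):
        cols = [peak_index[p] for p in
                [truth.anchor_peak[g.gene_id]] + truth.wired_peaks[g.gene_id]]
        signal = dense[:, cols].sum(axis=1)
        m = signal.mean()
        signal = signal / m if m > 0 else np.ones_like(signal)
        rates[:, gi] = link_strength * signal + (1.0 - link_strength)
    counts = rng.poisson(rates * depth)
    return sp.csr_matrix(counts), genes


# ---------------------------------------------------------------------------
# fixture export
# ---------------------------------------------------------------------------

def write_fixture(
    outdir: str | Path,
    truth: ToyGenomeTruth,
    gwas: GwasSummary,
    panel: GenotypePanel,
    atac: CellPeakMatrix,
    rna: tuple[sp.csr_matrix, list[str]] | None = None,
) -> None:
    """Write a complete fixture directory in the standard on-disk dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io_formats.write_gwas(gwas, outdir / "gwas.tsv")
    io_formats.write_dosages(panel, outdir / "panel.tsv")
    io_formats.write_gene_models(truth.genes, outdir / "genes.tsv")
    io_formats.write_cell_matrix(atac, outdir)
    if rna is not None:
        X_rna, gene_ids = rna
        import scipy.io

        scipy.io.mmwrite(outdir / "rna.mtx", sp.coo_matrix(X_rna))
        with open(outdir / "rna_genes.tsv", "w") as fh:
            fh.write("\n".join(gene_ids) + "\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "causal_genes": truth.causal_genes,
                "causal_snps": truth.causal_snps,
                "planted_cell_type": truth.planted_cell_type,
                "wired_peaks": {
                    g: [p.peak_id for p in ps]
                    for g, ps in truth.wired_peaks.items()
                },
                "anchor_peak": {
                    g: p.peak_id for g, p in truth.anchor_peak.items()
                },
            },
            fh,
            indent=1,
        )


def true_link_objects(truth: ToyGenomeTruth):
    """The planted wiring as PeakGeneLink objects (score 1, no pval)."""
    from .types import PeakGeneLink

    return [
        PeakGeneLink(p, g, 1.0, "coaccessibility")
        for g, ps in truth.wired_peaks.items()
        for p in ps
    ]
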