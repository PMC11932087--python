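"""Typed in-memory objects exchanged between pipeline stages.

Coordinate convention: every in-memory coordinate is 0-based, half-open for
peak intervals. GWAS positions arrive 1-based and are converted exactly once,
at read time (``pos0 = pos - 1``). Gene bodies are stored as 0-based
``[start, end]`` spans with *inclusive* membership for SNPs, matching the
semantics of window-based gene annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Peak",
    "GeneModel",
    "GwasSummary",
    "CellPeakMatrix",
    "GeneSetCollection",
    "PeakGeneLink",
    "MetacellAssignment",
    "SnpGeneAnnotation",
    "GenotypePanel",
    "RiskPeakSet",
    "TechVariance",
    "CellScoreResult",
    "GeneResult",
    "GeneSetResult",
    "ValidationError",
    "ConfigurationError",
    "normalize_chrom",
]


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class ConfigurationError(ValueError):
    """Caller-supplied configuration is unusable (bad column map, etc.)."""


def normalize_chrom(chrom: str) -> str:
    """Normalize chromosome names to the ``chr``-prefixed convention."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        return "chr" + c[3:]
    return "chr" + c


@dataclass(frozen=True, order=True)
class Peak:
    """An ATAC-seq peak (candidate cis-regulatory element), 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid peak interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def peak_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_id(cls, peak_id: str) -> "Peak":
        chrom, _, span = peak_id.rpartition(":")
        start, _, end = span.partition("-")
        return cls(chrom, int(start), int(end))

    def contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene body span with strand-aware TSS."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


class GwasSummary:
    """GWAS summary statistics: one record per SNP.

    Backed by a DataFrame with columns ``snp``, ``chrom`` (chr-prefixed),
    ``pos`` (1-based), ``pos0`` (0-based), ``pval`` in (0, 1], ``z`` (finite,
    non-negative when derived from p), and optional ``n``.
    """

    REQUIRED = ("snp", "chrom", "pos", "pval", "z")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"GwasSummary missing column {col!r}")
        if df["snp"].duplicated().any():
            dups = sorted(df.loc[df["snp"].duplicated(), "snp"].unique()[:10])
            raise ValidationError(f"duplicate snp ids: {dups}")
        if (df["pos"] < 1).any():
            raise ValidationError("GWAS positions must be >= 1 (1-based)")
        bad_p = ~((df["pval"] > 0) & (df["pval"] <= 1))
        if bad_p.any():
            raise ValidationError("pval outside (0, 1]")
        if not np.isfinite(df["z"]).all():
            raise ValidationError("non-finite z score")
        if "pos0" not in df.columns:
            df["pos0"] = df["pos"].astype(np.int64) - 1
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp"].to_numpy()

    def by_chrom(self) -> dict[str, pd.DataFrame]:
        return {str(c): g for c, g in self.df.groupby("chrom", sort=True)}


class CellPeakMatrix:
    """Sparse cells x peaks accessibility counts with optional cell-type labels."""

    def __init__(
        self,
        X: sp.spmatrix,
        cell_ids: list[str],
        peaks: list[Peak],
        cell_type: list[str] | None = None,
    ):
        X = sp.csr_matrix(X)
        if X.shape != (len(cell_ids), len(peaks)):
            raise ValidationError(
                f"matrix shape {X.shape} inconsistent with {len(cell_ids)} cells "
                f"and {len(peaks)} peaks"
            )
        if X.nnz and X.data.min() < 0:
            raise ValidationError("negative count in cell-peak matrix")
        if cell_type is not None and len(cell_type) != len(cell_ids):
            raise ValidationError("cell_type length mismatch")
        self.X = X
        self.cell_ids = list(cell_ids)
        self.peaks = list(peaks)
        self.cell_type = list(cell_type) if cell_type is not None else None

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.X.shape[1]

    #: fixed scale for depth normalization; a constant (rather than the
    #: matrix's own median depth) makes normalized values invariant to
    #: uniform rescaling of the counts
    TARGET_DEPTH = 1e4

    def lognorm(self, target_depth: float | None = None) -> np.ndarray:
        """Depth-normalized log1p matrix: log1p(count / depth * target)."""
        depth = np.asarray(self.X.sum(axis=1)).ravel().astype(float)
        depth[depth == 0] = 1.0
        if target_depth is None:
            target_depth = self.TARGET_DEPTH
        dense = self.X.toarray().astype(float)
        return np.log1p(dense / depth[:, None] * target_depth)


class GeneSetCollection:
    """Named gene sets (GMT semantics) with optional descriptions."""

    def __init__(
        self,
        sets: dict[str, list[str]],
        descriptions: dict[str, str] | None = None,
    ):
        for name, genes in sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate genes")
        self.sets = dict(sets)
        self.descriptions = dict(descriptions or {})

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass(frozen=True)
class PeakGeneLink:
    """A scored association between a (usually distal) peak and a gene."""

    peak: Peak
    gene_id: str
    score: float
    method: str  # "coaccessibility" | "expression_correlation"
    pval: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("coaccessibility", "expression_correlation"):
            raise ValidationError(f"unknown link method {self.method!r}")


@dataclass
class MetacellAssignment:
    """Partition of cells into metacells used to densify sparse counts."""

    labels: np.ndarray  # metacell index per cell
    sizes: np.ndarray  # cells per metacell

    @property
    def n_metacells(self) -> int:
        return len(self.sizes)


@dataclass
class GeneAnnotationRecord:
    body_snps: set[str] = field(default_factory=set)
    cre_snps: set[str] = field(default_factory=set)
    peaks: set[Peak] = field(default_factory=set)

    @property
    def all_snps(self) -> set[str]:
        return self.body_snps | self.cre_snps


class SnpGeneAnnotation:
    """Per-gene SNP sets with provenance (gene body vs linked CRE)."""

    def __init__(
        self,
        genes: dict[str, GeneAnnotationRecord],
        snp_pos: dict[str, tuple[str, int]],
        gene_loc: dict[str, tuple[str, int, int]],
    ):
        self.genes = genes
        self.snp_pos = snp_pos  # snp_id -> (chrom, pos0)
        self.gene_loc = gene_loc  # gene_id -> (chrom, start, end)

    def __len__(self) -> int:
        return len(self.genes)

    def snps_for(self, gene_id: str) -> set[str]:
        return self.genes[gene_id].all_snps

    def exported_snps(self, gene_id: str) -> list[str]:
        """Deduplicated per-gene SNP list, ordered by genomic position."""
        snps = self.genes[gene_id].all_snps
        return sorted(snps, key=lambda s: (self.snp_pos[s][0], self.snp_pos[s][1], s))

    def equals(self, other: "SnpGeneAnnotation") -> bool:
        if set(self.genes) != set(other.genes):
            return False
        return all(self.snps_for(g) == other.snps_for(g) for g in self.genes)


class GenotypePanel:
    """Reference dosage matrix (individuals x SNPs, values in {0, 1, 2})."""

    def __init__(
        self,
        dosages: np.ndarray,
        snp_ids: list[str],
        phenotype: np.ndarray | None = None,
    ):
        dosages = np.asarray(dosages)
        if dosages.ndim != 2 or dosages.shape[1] != len(snp_ids):
            raise ValidationError("dosage matrix shape inconsistent with snp_ids")
        if not np.isin(dosages, (0, 1, 2)).all():
            raise ValidationError("dosages must be in {0, 1, 2}")
        self.dosages = dosages.astype(np.float64)
        self.snp_ids = list(snp_ids)
        self._index = {s: j for j, s in enumerate(self.snp_ids)}
        if phenotype is not None:
            phenotype = np.asarray(phenotype, dtype=float)
            if phenotype.shape != (dosages.shape[0],):
                raise ValidationError("phenotype length mismatch")
        self.phenotype = phenotype

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def subset(self, snp_subset: list[str]) -> np.ndarray:
        missing = [s for s in snp_subset if s not in self._index]
        if missing:
            raise ValidationError(f"SNPs absent from panel: {missing[:10]}")
        cols = [self._index[s] for s in snp_subset]
        return self.dosages[:, cols]

    def monomorphic_mask(self, snp_subset: list[str]) -> np.ndarray:
        G = self.subset(snp_subset)
        return G.std(axis=0) == 0


@dataclass
class RiskPeakSet:
    """Peaks tied to risk genes, weighted by the max SNP |Z| under each peak."""

    peaks: list[Peak]
    weights: np.ndarray
    source_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.peaks) != len(self.weights):
            raise ValidationError("peaks and weights length mismatch")
        if len(self.peaks) != len(set(self.peaks)):
            raise ValidationError("risk peaks must be unique")
        if len(self.weights) and (
            not np.isfinite(self.weights).all() or not (self.weights > 0).any()
        ):
            raise ValidationError("weights must be finite and not all zero")

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class TechVariance:
    """Per-peak technical-variance decomposition from the mean-variance trend."""

    sigma2_tech: np.ndarray  # technical variance in log1p-normalized space
    observed_log_var: np.ndarray
    proportion_tech: np.ndarray  # in [0, 1]
    usable: np.ndarray  # peaks with sigma2_tech > 0

    def __post_init__(self) -> None:
        if np.any(self.sigma2_tech - self.observed_log_var > 1e-9):
            raise ValidationError("sigma2_tech exceeds observed log-space variance")


@dataclass
class CellScoreResult:
    """Per-cell and per-cell-type disease-relevance scores and MC p-values."""

    cell_ids: list[str]
    scores: np.ndarray  # raw S_c
    control_scores: np.ndarray  # n_cell x B raw controls
    norm_scores: np.ndarray  # cell-wise standardized S_c
    norm_control_scores: np.ndarray
    cell_pvals: np.ndarray
    celltype_stats: pd.DataFrame  # cell_type, n_cells, t, p_mc

    @property
    def B(self) -> int:
        return self.control_scores.shape[1]


@dataclass
class GeneResult:
    gene_id: str
    n_snps: int
    statistic: float
    pval: float
    mode: str  # "raw" | "summary"

    def __post_init__(self) -> None:
        if not (0 < self.pval <= 1):
            raise ValidationError(f"gene {self.gene_id}: pval {self.pval} not in (0,1]")
        if self.n_snps < 1:
            raise ValidationError(f"gene {self.gene_id}: n_snps must be >= 1")


@dataclass
class GeneSetResult:
    set_name: str
    n_genes_in_set: int
    beta: float
    se: float
    pval: float
    qval: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.pval <= 1):
            raise ValidationError(f"set {self.set_name}: pval not in (0,1]")
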