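"""Infer peak-gene links from single-cell chromatin accessibility.

Two modes:

* co-accessibility (scATAC-seq only): cells are aggregated into metacells,
  counts log-normalized, and a graphical-lasso partial-correlation matrix is
  estimated within overlapping genomic windows with a penalty that grows with
  genomic distance between peaks. Peaks co-accessible with a gene's promoter
  anchor peak above a threshold are linked to the gene. This is a simplified
  distance-penalized co-accessibility model, not a port of any published
  implementation.
* expression correlation (multiome ATAC+RNA): per gene, the Pearson
  correlation between each nearby peak's accessibility and the gene's
  expression is compared against a background of accessibility-matched peaks
  by z-test, with Benjamini-Hochberg control within gene.
"""

from __future__ import annotations

import logging
from collections import defaultdict

import numpy as np
import scipy.sparse as sp
from scipy.stats import t as t_dist
from sklearn.decomposition import TruncatedSVD
from statsmodels.stats.multitest import multipletests

from .types import (
    CellPeakMatrix,
    GeneModel,
    MetacellAssignment,
    Peak,
    PeakGeneLink,
    ValidationError,
)

logger = logging.getLogger(__name__)

PROMOTER_UP = 2000  # bp upstream of TSS, strand-aware
PROMOTER_DOWN = 100  # bp downstream of TSS
DEFAULT_WINDOW_BP = 500_000
DEFAULT_THRESHOLD = 0.1


# ---------------------------------------------------------------------------
# metacells
# ---------------------------------------------------------------------------

def tfidf_embedding(
    X: sp.spmatrix, n_components: int = 30, seed: int = 0
) -> np.ndarray:
    """TF-IDF + truncated SVD (LSI) embedding of cells; first component dropped.

    The first LSI component tracks sequencing depth and is removed, as is
    conventional for scATAC-seq.
    """
    X = sp.csr_matrix(X, dtype=float)
    depth = np.asarray(X.sum(axis=1)).ravel()
    depth[depth == 0] = 1.0
    tf = sp.diags(1.0 / depth) @ X
    ncells_with_peak = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = np.log1p(X.shape[0] / (1.0 + ncells_with_peak))
    tfidf = tf @ sp.diags(idf)
    k = min(n_components, min(X.shape) - 1)
    svd = TruncatedSVD(n_components=max(k, 2), random_state=seed)
    emb = svd.fit_transform(tfidf)
    return emb[:, 1:]


def make_metacells(X: CellPeakMatrix, k: int, seed: int = 0) -> MetacellAssignment:
    """Group cells into metacells of >= k similar cells.

    Cells are embedded by TF-IDF/SVD; in a seeded random order each unassigned
    cell seeds a metacell with its k-1 nearest unassigned neighbors; a final
    remnant smaller than k is merged into the nearest existing metacell.
    Deterministic given the seed.
    """
    n = X.n_cells
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n < k:
        raise ValidationError(f"n_cells={n} < k={k}")
    labels = np.full(n, -1, dtype=int)
    if k == 1:
        labels = np.arange(n)
        return MetacellAssignment(labels, np.ones(n, dtype=int))
    emb = tfidf_embedding(X.X, seed=seed)
    # full pairwise distances: metacell construction is run on modest cell counts
    d2 = (
        (emb**2).sum(1)[:, None] + (emb**2).sum(1)[None, :] - 2 * emb @ emb.T
    )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    next_label = 0
    for c in order:
        if labels[c] != -1:
            continue
        unassigned = np.flatnonzero(labels == -1)
        if len(unassigned) < k:
            break
        nearest = unassigned[np.argsort(d2[c, unassigned], kind="stable")[:k]]
        labels[nearest] = next_label
        next_label += 1
    remnant = np.flatnonzero(labels == -1)
    for c in remnant:
        assigned = np.flatnonzero(labels != -1)
        labels[c] = labels[assigned[np.argmin(d2[c, assigned])]]
    sizes = np.bincount(labels, minlength=next_label)
    return MetacellAssignment(labels, sizes)


def aggregate_metacells(X: CellPeakMatrix, meta: MetacellAssignment) -> np.ndarray:
    """Sum counts within metacells, depth-normalize to the median, log1p."""
    m = meta.n_metacells
    indic = sp.csr_matrix(
        (np.ones(X.n_cells), (meta.labels, np.arange(X.n_cells))),
        shape=(m, X.n_cells),
    )
    agg = np.asarray((indic @ X.X).todense(), dtype=float)
    depth = agg.sum(axis=1)
    depth[depth == 0] = 1.0
    return np.log1p(agg / depth[:, None] * np.median(depth))


# ---------------------------------------------------------------------------
# graphical lasso with an elementwise penalty matrix
# ---------------------------------------------------------------------------

def _lasso_cd(W11, s12, rho12, beta, tol, max_iter=200):
    """Coordinate descent for 0.5 b'W11 b - b's12 + sum rho|b| (in place)."""
    p = len(s12)
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            r = s12[j] - W11[j] @ beta + W11[j, j] * beta[j]
            new = np.sign(r) * max(abs(r) - rho12[j], 0.0) / W11[j, j]
            delta = max(delta, abs(new - beta[j]))
            beta[j] = new
        if delta < tol:
            break
    return beta


def glasso_penalized(S: np.ndarray, Rho: np.ndarray, tol: float = 1e-4,
                     max_iter: int = 100) -> np.ndarray:
    """Graphical lasso with a symmetric elementwise L1 penalty matrix.

    Friedman-style block coordinate descent on the covariance estimate W;
    returns the precision matrix. ``Rho`` must have a zero diagonal (the
    diagonal is never penalized here).
    """
    p = S.shape[0]
    if p == 1:
        return np.array([[1.0 / S[0, 0]]])
    S = S + 1e-6 * np.eye(p)  # ridge for numerical safety
    W = S.copy()
    B = np.zeros((p, p))  # column j holds beta for subproblem j
    idx = np.arange(p)
    scale = np.mean(np.abs(S - np.diag(np.diag(S)))) + 1e-12
    for _ in range(max_iter):
        W_old = W.copy()
        for j in range(p):
            rest = idx[idx != j]
            W11 = W[np.ix_(rest, rest)]
            beta = _lasso_cd(W11, S[rest, j], Rho[rest, j], B[rest, j].copy(),
                             tol=tol * scale)
            B[rest, j] = beta
            w12 = W11 @ beta
            W[rest, j] = w12
            W[j, rest] = w12
        if np.mean(np.abs(W - W_old)) < tol * scale:
            break
    Theta = np.zeros((p, p))
    for j in range(p):
        rest = idx[idx != j]
        denom = W[j, j] - W[rest, j] @ B[rest, j]
        Theta[j, j] = 1.0 / denom
        Theta[rest, j] = -B[rest, j] * Theta[j, j]
    Theta = (Theta + Theta.T) / 2.0
    return Theta


def partial_correlations(Theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(Theta))
    pc = -Theta / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


# ---------------------------------------------------------------------------
# co-accessibility links
# ---------------------------------------------------------------------------

def promoter_interval(gene: GeneModel, up: int = PROMOTER_UP,
                      down: int = PROMOTER_DOWN) -> tuple[int, int]:
    """Strand-aware promoter anchor interval around the TSS (half-open)."""
    if gene.strand == "+":
        return max(0, gene.tss - up), gene.tss + down
    return max(0, gene.tss - down), gene.tss + up


def _anchor_peaks(gene: GeneModel, peaks: list[Peak]) -> list[int]:
    lo, hi = promoter_interval(gene)
    return [
        j for j, p in enumerate(peaks)
        if p.chrom == gene.chrom and p.start < hi and p.end > lo
    ]


def coaccessibility_matrix(
    Xmeta: np.ndarray,
    peaks: list[Peak],
    window_bp: int,
    penalty_scale: float = 0.2,
    penalty_floor: float = 0.05,
) -> dict[tuple[int, int], float]:
    """Distance-penalized partial correlations for peak pairs within windows.

    Overlapping windows (width ``window_bp``, half-window step) tile each
    chromosome; pair estimates from multiple windows are averaged. Penalty per
    pair: ``penalty_scale * max(distance / window_bp, penalty_floor)``.
    """
    widest = max(p.end - p.start for p in peaks)
    if window_bp < widest:
        raise ValidationError(
            f"window_bp={window_bp} smaller than the widest peak ({widest} bp)"
        )
    mids = np.array([(p.start + p.end) // 2 for p in peaks])
    chroms = np.array([p.chrom for p in peaks])
    # standardized metacell profiles -> correlation-scale covariance
    Z = Xmeta - Xmeta.mean(axis=0)
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z = Z / sd
    acc: dict[tuple[int, int], list[float]] = defaultdict(list)
    half = window_bp // 2
    for chrom in np.unique(chroms):
        cidx = np.flatnonzero(chroms == chrom)
        cmids = mids[cidx]
        lo, hi = cmids.min(), cmids.max()
        starts = np.arange(lo, hi + 1, half)
        for w0 in starts:
            in_win = cidx[(cmids >= w0) & (cmids < w0 + window_bp)]
            if len(in_win) < 2:
                continue
            S = (Z[:, in_win].T @ Z[:, in_win]) / Z.shape[0]
            d = np.abs(mids[in_win][:, None] - mids[in_win][None, :])
            Rho = penalty_scale * np.maximum(d / window_bp, penalty_floor)
            np.fill_diagonal(Rho, 0.0)
            pc = partial_correlations(glasso_penalized(S, Rho))
            for a in range(len(in_win)):
                for b in range(a + 1, len(in_win)):
                    i, j = int(in_win[a]), int(in_win[b])
                    acc[(i, j)].append(float(pc[a, b]))
    return {pair: float(np.mean(v)) for pair, v in acc.items()}


def coaccessibility_links(
    X: CellPeakMatrix,
    meta: MetacellAssignment,
    gene_models: list[GeneModel],
    window_bp: int = DEFAULT_WINDOW_BP,
    threshold: float = DEFAULT_THRESHOLD,
    penalty_scale: float = 0.2,
) -> list[PeakGeneLink]:
    """Link distal peaks to genes via co-accessibility with promoter anchors."""
    if window_bp <= 0:
        raise ValidationError("window_bp must be > 0")
    if not (-1.0 <= threshold <= 1.0):
        raise ValidationError("threshold must be in [-1, 1]")
    Xmeta = aggregate_metacells(X, meta)
    coacc = coaccessibility_matrix(Xmeta, X.peaks, window_bp, penalty_scale)
    links: list[PeakGeneLink] = []
    n_no_anchor = 0
    for gene in gene_models:
        anchors = _anchor_peaks(gene, X.peaks)
        if not anchors:
            n_no_anchor += 1
            continue
        best: dict[int, float] = {}
        for a in anchors:
            for j in range(len(X.peaks)):
                if j == a:
                    continue
                pair = (min(a, j), max(a, j))
                if pair not in coacc:
                    continue
                score = coacc[pair]
                if score >= threshold:
                    best[j] = max(best.get(j, -np.inf), score)
        anchor_set = set(anchors)
        for j, score in sorted(best.items()):
            if j in anchor_set:
                continue  # never link a gene to its own anchor peak
            links.append(
                PeakGeneLink(X.peaks[j], gene.gene_id, score, "coaccessibility")
            )
    if n_no_anchor:
        logger.info("coaccessibility_links: %d genes had no promoter anchor peak",
                    n_no_anchor)
    return links


# ---------------------------------------------------------------------------
# multiome (accessibility x expression) links
# ---------------------------------------------------------------------------

def multiome_links(
    X_atac: CellPeakMatrix,
    X_rna: sp.spmatrix,
    rna_genes: list[str],
    gene_models: list[GeneModel],
    window_bp: int = DEFAULT_WINDOW_BP,
    n_background: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[PeakGeneLink]:
    """Link peaks to genes by accessibility-expression correlation.

    For each gene and each peak within ``window_bp`` of its TSS, the Pearson
    correlation between log-normalized accessibility and log-normalized
    (CP10K) expression across cells is z-tested against ``n_background``
    control peaks drawn from the same mean-accessibility decile; links with
    BH-adjusted (within gene) p <= alpha are retained.
    """
    if n_background < 1:
        raise ValidationError("n_background must be >= 1")
    X_rna = sp.csr_matrix(X_rna, dtype=float)
    if X_rna.shape[0] != X_atac.n_cells:
        raise ValidationError("ATAC and RNA cell counts differ")
    if X_rna.shape[1] != len(rna_genes):
        raise ValidationError("RNA matrix width inconsistent with gene list")
    rng = np.random.default_rng(seed)
    n = X_atac.n_cells

    A = X_atac.lognorm()
    A = A - A.mean(axis=0)
    a_sd = A.std(axis=0)
    a_sd[a_sd == 0] = 1.0
    A = A / a_sd

    rna_depth = np.asarray(X_rna.sum(axis=1)).ravel()
    rna_depth[rna_depth == 0] = 1.0
    R = np.log1p(X_rna.toarray() / rna_depth[:, None] * 1e4)

    mean_acc = np.asarray(X_atac.X.mean(axis=0)).ravel()
    deciles = np.searchsorted(
        np.quantile(mean_acc, np.linspace(0.1, 0.9, 9)), mean_acc, side="right"
    )
    gene_index = {g: j for j, g in enumerate(rna_genes)}
    mids = np.array([(p.start + p.end) // 2 for p in X_atac.peaks])
    chroms = np.array([p.chrom for p in X_atac.peaks])

    links: list[PeakGeneLink] = []
    for gene in gene_models:
        if gene.gene_id not in gene_index:
            logger.info("multiome_links: gene %s absent from RNA data", gene.gene_id)
            continue
        g = R[:, gene_index[gene.gene_id]]
        g = g - g.mean()
        g_sd = g.std()
        if g_sd == 0:
            continue
        g = g / g_sd
        r_all = A.T @ g / n  # correlation of every peak with this gene
        cand = np.flatnonzero(
            (chroms == gene.chrom) & (np.abs(mids - gene.tss) <= window_bp)
        )
        if len(cand) == 0:
            continue
        pvals, scores = [], []
        for j in cand:
            pool = np.flatnonzero(deciles == deciles[j])
            pool = pool[pool != j]
            if len(pool) < 3:  # tiny bin: fall back to all peaks
                pool = np.arange(len(X_atac.peaks))
                pool = pool[pool != j]
            bg = rng.choice(pool, size=min(n_background, len(pool)), replace=False)
            mu = float(r_all[bg].mean())
            sd = float(r_all[bg].std(ddof=1))
            # exchangeable-null spread of r_j - mu is sd * sqrt(1 + 1/n_bg)
            stat = (r_all[j] - mu) / max(sd * np.sqrt(1 + 1 / len(bg)), 1e-12)
            pvals.append(float(t_dist.sf(stat, len(bg) - 1)))
            scores.append(float(r_all[j]))
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for j, p, q, s in zip(cand, pvals, qvals, scores):
            if q <= alpha:
                links.append(
                    PeakGeneLink(
                        X_atac.peaks[j], gene.gene_id, s, "expression_correlation", p
                    )
                )
    return links
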