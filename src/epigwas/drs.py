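"""Per-cell disease relevance scoring from GWAS-weighted peak accessibility.

Given a set of risk peaks — peaks tied to disease-associated genes, each
weighted by the largest SNP |Z| underneath it — every cell receives a
disease score:

    S_c = sum_{p in P} Z_p sigma_tech,p^{-1} X'_cp / sum_{p in P} Z_p sigma_tech,p^{-1}

where X' is the log1p depth-normalized accessibility matrix and
sigma^2_tech,p the technical portion of peak p's across-cell variance,
estimated from the mean-variance trend. Significance comes from a Monte
Carlo null: B control peak sets matched to the risk peaks on mean
accessibility and variance, scored with the same formula using the control
peaks' own weights and technical variances. Cell-level p-values pool all
normalized control scores; cell-type-level p-values compare the top-5%
quantile of the type's scores against the same quantile of each control
replicate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .types import (
    CellPeakMatrix,
    CellScoreResult,
    GwasSummary,
    Peak,
    RiskPeakSet,
    SnpGeneAnnotation,
    TechVariance,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_B = 1000
CELLTYPE_QUANTILE = 0.95  # test statistic: top-5% quantile of the type's scores
MIN_CELLS_PER_TYPE = 20


# ---------------------------------------------------------------------------
# peak weights and risk-peak assembly
# ---------------------------------------------------------------------------

def peak_weights(gwas: GwasSummary, peaks: list[Peak]) -> np.ndarray:
    """Weight per peak: the largest SNP |z| located within the peak.

    Peaks containing no SNP (or only z = 0 SNPs) get weight 0; callers drop
    them from risk sets.
    """
    weights = np.zeros(len(peaks))
    by_chrom = {}
    for chrom, g in gwas.df.groupby("chrom", sort=False):
        g = g.sort_values("pos0")
        by_chrom[str(chrom)] = (g["pos0"].to_numpy(), np.abs(g["z"].to_numpy()))
    for i, p in enumerate(peaks):
        if p.chrom not in by_chrom:
            continue
        pos, absz = by_chrom[p.chrom]
        lo = np.searchsorted(pos, p.start, side="left")
        hi = np.searchsorted(pos, p.end, side="left")
        if hi > lo:
            weights[i] = absz[lo:hi].max()
    return weights


def risk_peaks_from_annotation(
    annot: SnpGeneAnnotation,
    risk_genes: list[str],
    gwas: GwasSummary,
) -> RiskPeakSet:
    """Union of peaks linked to any risk gene, weighted by max SNP |z|."""
    unknown = sorted(set(risk_genes) - set(annot.genes))
    if unknown:
        raise ValidationError(f"risk genes absent from annotation: {unknown[:10]}")
    peak_set: set[Peak] = set()
    for g in risk_genes:
        peak_set |= annot.genes[g].peaks
    if not peak_set:
        raise ValidationError(
            "no peaks are linked to the risk genes; loosen the gene-level "
            "significance threshold or check the link table"
        )
    peaks = sorted(peak_set)
    weights = peak_weights(gwas, peaks)
    keep = weights > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("risk_peaks_from_annotation: %d peaks without SNPs dropped",
                    n_dropped)
    if not keep.any():
        raise ValidationError("every candidate risk peak has zero weight")
    return RiskPeakSet(
        [p for p, k in zip(peaks, keep) if k], weights[keep], set(risk_genes)
    )


# ---------------------------------------------------------------------------
# technical-variance estimation
# ---------------------------------------------------------------------------

def _loess_quadratic(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray,
                     span: float) -> np.ndarray:
    """Local quadratic regression with tricube weights (loess, degree 2)."""
    n = len(x)
    m = max(int(np.ceil(span * n)), 5)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(len(x_eval))
    for i, x0 in enumerate(x_eval):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, min(m, n) - 1)[:m]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = ys[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        X = np.column_stack(
            [np.ones(len(idx)), xs[idx] - x0, (xs[idx] - x0) ** 2]
        )
        Wh = w[:, None] * X
        beta, *_ = np.linalg.lstsq(X.T @ Wh, Wh.T @ ys[idx], rcond=None)
        out[i] = beta[0]
    return out


def estimate_tech_variance(X: CellPeakMatrix, span: float = 0.3) -> TechVariance:
    """Decompose per-peak variance into technical and biological parts.

    Per peak, mean and variance are computed in the original (non-log) count
    space; a local quadratic trend of log10 variance on log10 mean models the
    expected technical variance at a given mean accessibility; the proportion
    of technical variance is predicted/observed clipped to [0, 1]; and
    sigma^2_tech is that proportion times the peak's variance in the
    log1p-normalized space.
    """
    dense = X.X.toarray().astype(float)
    mean_raw = dense.mean(axis=0)
    var_raw = dense.var(axis=0)
    nonzero = mean_raw > 0
    if nonzero.sum() < 50:
        raise ValidationError(
            f"only {int(nonzero.sum())} peaks with nonzero mean; "
            "need >= 50 for a stable mean-variance trend"
        )
    fit_mask = nonzero & (var_raw > 0)
    lx = np.log10(mean_raw[fit_mask])
    ly = np.log10(var_raw[fit_mask])
    pred = np.full(X.n_peaks, -np.inf)
    pred[nonzero] = _loess_quadratic(lx, ly, np.log10(mean_raw[nonzero]), span)
    pred_var = np.where(nonzero, 10.0**pred, 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        proportion = np.where(var_raw > 0, pred_var / var_raw, 1.0)
    proportion = np.clip(proportion, 0.0, 1.0)

    log_norm = X.lognorm()
    obs_log_var = log_norm.var(axis=0)
    sigma2_tech = obs_log_var * proportion
    sigma2_tech[var_raw == 0] = 0.0  # constant peaks: nothing to weight by
    usable = sigma2_tech > 0
    return TechVariance(sigma2_tech, obs_log_var, proportion, usable)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _score(Xnorm: np.ndarray, weights: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Weighted mean of normalized accessibility: w_p = Z_p / sigma_tech,p."""
    w = weights / sigma
    denom = w.sum()
    if denom <= 0:
        raise ValidationError("zero total weight in disease score denominator")
    return Xnorm @ w / denom


def disease_scores(
    X: CellPeakMatrix,
    risk: RiskPeakSet,
    tech: TechVariance,
    Xnorm: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell disease score over the risk peaks.

    Risk peaks with zero technical variance cannot be inverse-weighted and
    are dropped (count logged). ``Xnorm`` lets callers pass a precomputed
    log1p depth-normalized matrix.
    """
    if Xnorm is None:
        Xnorm = X.lognorm()
    index = {p: i for i, p in enumerate(X.peaks)}
    missing = [p for p in risk.peaks if p not in index]
    if missing:
        raise ValidationError(f"risk peaks absent from matrix: {missing[:5]}")
    cols = np.array([index[p] for p in risk.peaks])
    sigma2 = tech.sigma2_tech[cols]
    ok = sigma2 > 0
    if not ok.any():
        raise ValidationError("all risk peaks have zero technical variance")
    if (~ok).any():
        logger.info("disease_scores: %d zero-variance risk peaks dropped",
                    int((~ok).sum()))
    return _score(Xnorm[:, cols[ok]], risk.weights[ok], np.sqrt(sigma2[ok]))


# ---------------------------------------------------------------------------
# matched controls
# ---------------------------------------------------------------------------

def matched_controls(
    risk: RiskPeakSet,
    X: CellPeakMatrix,
    tech: TechVariance,
    all_weights: np.ndarray,
    B: int = DEFAULT_B,
    n_bins: int = 10,
    seed: int = 0,
    include_risk_in_pool: bool = False,
) -> np.ndarray:
    """Draw B control peak index sets matched on mean accessibility x variance.

    All peaks are binned on an ``n_bins x n_bins`` grid of mean-accessibility
    and variance quantiles (computed across all cells in count space). For
    each risk peak and each replicate, a control peak is drawn uniformly from
    the risk peak's bin; empty bins fall back to the nearest nonempty bin.
    The candidate pool excludes the risk peaks themselves (unless
    ``include_risk_in_pool``, used for null calibration) and peaks that are
    unusable for scoring (zero weight or zero technical variance).

    Returns an integer array of shape (B, n_risk_peaks) of peak column
    indices into the matrix.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    dense_mean = np.asarray(X.X.mean(axis=0)).ravel()
    dense_var = np.asarray(X.X.power(2).mean(axis=0)).ravel() - dense_mean**2
    index = {p: i for i, p in enumerate(X.peaks)}
    risk_cols = np.array([index[p] for p in risk.peaks])

    def bin_of(values: np.ndarray) -> np.ndarray:
        edges = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
        return np.searchsorted(edges, values, side="right")

    mb, vb = bin_of(dense_mean), bin_of(dense_var)
    pool_mask = (all_weights > 0) & tech.usable
    if not include_risk_in_pool:
        pool_mask[risk_cols] = False
    pool = np.flatnonzero(pool_mask)
    if len(pool) == 0:
        raise ValidationError("control candidate pool is empty")
    rng = np.random.default_rng(seed)

    by_bin: dict[tuple[int, int], np.ndarray] = {}
    for j in pool:
        by_bin.setdefault((mb[j], vb[j]), []).append(j)  # type: ignore[arg-type]
    by_bin = {k: np.asarray(v) for k, v in by_bin.items()}
    bin_keys = np.array(list(by_bin.keys()))

    n_fallback = 0
    controls = np.empty((B, len(risk_cols)), dtype=int)
    for i, col in enumerate(risk_cols):
        key = (mb[col], vb[col])
        if key in by_bin:
            cand = by_bin[key]
        else:
            n_fallback += 1
            d = np.abs(bin_keys[:, 0] - key[0]) + np.abs(bin_keys[:, 1] - key[1])
            nearest = tuple(bin_keys[np.argmin(d)])
            cand = by_bin[nearest]
        controls[:, i] = rng.choice(cand, size=B, replace=True)
    if n_fallback:
        logger.info("matched_controls: %d risk peaks used a fallback bin",
                    n_fallback)
    return controls


def control_scores(
    Xnorm: np.ndarray,
    controls: np.ndarray,
    all_weights: np.ndarray,
    tech: TechVariance,
) -> np.ndarray:
    """Score each control replicate with the control peaks' own Z and sigma.

    Returns an (n_cells, B) array.
    """
    B = controls.shape[0]
    out = np.empty((Xnorm.shape[0], B))
    sigma = np.sqrt(np.where(tech.sigma2_tech > 0, tech.sigma2_tech, np.inf))
    for b in range(B):
        cols = controls[b]
        out[:, b] = _score(Xnorm[:, cols], all_weights[cols], sigma[cols])
    return out


# ---------------------------------------------------------------------------
# Monte Carlo p-values
# ---------------------------------------------------------------------------

def normalize_scores(
    S: np.ndarray, S_ctrl: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-wise standardization against the per-cell control distribution.

    The observed score is standardized against all B controls; each control
    is standardized against the other B-1 (leave-one-out), so observed and
    control scores are both held out of their own baseline and remain
    exchangeable under the null.
    """
    B = S_ctrl.shape[1]
    mu = S_ctrl.mean(axis=1)
    sd = S_ctrl.std(axis=1)
    sd[sd == 0] = 1.0
    S_n = (S - mu) / sd
    if B < 3:
        return S_n, (S_ctrl - mu[:, None]) / sd[:, None]
    total = S_ctrl.sum(axis=1, keepdims=True)
    ss = (S_ctrl**2).sum(axis=1, keepdims=True)
    mu_loo = (total - S_ctrl) / (B - 1)
    var_loo = (ss - S_ctrl**2) / (B - 1) - mu_loo**2
    sd_loo = np.sqrt(np.clip(var_loo, 0.0, None))
    sd_loo[sd_loo == 0] = 1.0
    return S_n, (S_ctrl - mu_loo) / sd_loo


def cell_pvalues(
    S: np.ndarray, S_ctrl: np.ndarray, normalize: bool = True
) -> np.ndarray:
    """Cell-level MC p-values against the pooled control-score distribution.

    p_c = (1 + #{pooled controls >= S_c}) / (1 + n_cell * B); with
    ``normalize`` both sides are cell-wise standardized against the control
    mean/sd before pooling.
    """
    if S_ctrl.ndim != 2 or S_ctrl.shape[0] != len(S):
        raise ValidationError("S_ctrl must be n_cell x B")
    B = S_ctrl.shape[1]
    if B == 0:
        raise ValidationError("B must be >= 1")
    if normalize:
        S, S_ctrl = normalize_scores(S, S_ctrl)
    pooled = np.sort(S_ctrl.ravel())
    n_cell = len(S)
    # count of pooled controls >= S_c  ==  total - #(pooled < S_c)
    n_ge = pooled.size - np.searchsorted(pooled, S, side="left")
    return (1.0 + n_ge) / (1.0 + n_cell * B)


def celltype_pvalues(
    S: np.ndarray,
    S_ctrl: np.ndarray,
    cell_types: list[str],
    q: float = CELLTYPE_QUANTILE,
    min_cells: int = MIN_CELLS_PER_TYPE,
) -> pd.DataFrame:
    """Cell-type-level MC p-values.

    The test statistic t is the q-quantile (default top 5%) of the type's
    scores; each control replicate b yields the same quantile t_b over the
    same cells; p_mc = (1 + #{t <= t_b}) / (1 + B). Types with fewer than
    ``min_cells`` cells are skipped (logged).
    """
    cell_types = np.asarray(cell_types)
    B = S_ctrl.shape[1]
    rows = []
    for ct in pd.unique(cell_types):
        mask = cell_types == ct
        n = int(mask.sum())
        if n < min_cells:
            logger.info("cell type %s skipped: %d cells < %d", ct, n, min_cells)
            continue
        t = float(np.quantile(S[mask], q))
        t_b = np.quantile(S_ctrl[mask], q, axis=0)
        p_mc = (1.0 + int((t <= t_b).sum())) / (1.0 + B)
        rows.append({"cell_type": ct, "n_cells": n, "t": t, "p_mc": p_mc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def score_cells(
    X: CellPeakMatrix,
    risk: RiskPeakSet,
    gwas: GwasSummary,
    B: int = DEFAULT_B,
    n_bins: int = 10,
    seed: int = 0,
    normalize: bool = True,
    include_risk_in_pool: bool = False,
    tech: TechVariance | None = None,
) -> CellScoreResult:
    """Full scoring pipeline: technical variance, scores, matched-control MC
    null, cell- and cell-type-level p-values."""
    if tech is None:
        tech = estimate_tech_variance(X)
    Xnorm = X.lognorm()
    all_weights = peak_weights(gwas, X.peaks)
    index = {p: i for i, p in enumerate(X.peaks)}
    risk_cols = np.array([index[p] for p in risk.peaks])
    # align risk weights with the matrix-wide weight vector for consistency
    all_weights[risk_cols] = np.maximum(all_weights[risk_cols], risk.weights)

    usable = tech.usable[risk_cols]
    kept = RiskPeakSet(
        [p for p, u in zip(risk.peaks, usable) if u],
        risk.weights[usable],
        risk.source_genes,
    )
    S = disease_scores(X, kept, tech, Xnorm)
    controls = matched_controls(
        kept, X, tech, all_weights, B=B, n_bins=n_bins, seed=seed,
        include_risk_in_pool=include_risk_in_pool,
    )
    S_ctrl = control_scores(Xnorm, controls, all_weights, tech)
    if normalize:
        S_n, S_ctrl_n = normalize_scores(S, S_ctrl)
    else:
        S_n, S_ctrl_n = S, S_ctrl
    p_c = cell_pvalues(S, S_ctrl, normalize=normalize)
    if X.cell_type is not None:
        ct_stats = celltype_pvalues(S_n, S_ctrl_n, X.cell_type)
    else:
        ct_stats = pd.DataFrame(columns=["cell_type", "n_cells", "t", "p_mc"])
    return CellScoreResult(
        cell_ids=X.cell_ids,
        scores=S,
        control_scores=S_ctrl,
        norm_scores=S_n,
        norm_control_scores=S_ctrl_n,
        cell_pvals=p_c,
        celltype_stats=ct_stats,
    )


def cell_result_table(result: CellScoreResult, cell_types: list[str] | None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "cell_id": result.cell_ids,
            "cell_type": cell_types if cell_types is not None else "",
            "score": result.scores,
            "norm_score": result.norm_scores,
            "pval": result.cell_pvals,
        }
    )
    df["bh_q"] = multipletests(df["pval"], method="fdr_bh")[1]
    return df
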