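# Methods

`epigwas` interprets GWAS variants with single-cell epigenomic data in three
stages: (1) link candidate cis-regulatory elements (CREs, observed as
ATAC-seq peaks) to target genes, (2) aggregate SNP-level association into
gene- and gene-set-level tests over the resulting SNP-gene annotation, and
(3) score individual cells and cell types for disease relevance from the
accessibility of risk peaks. This note documents the models, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
fixtures do and do not establish.

## Coordinate conventions

Peaks are 0-based half-open (BED). GWAS positions are read 1-based and
converted once at load (`pos0 = pos - 1`); all in-memory coordinates are
0-based thereafter. A SNP lies in a peak iff `start <= pos0 < end`, and in a
gene body iff `start <= pos0 <= end` (inclusive span). Chromosome names are
normalized to the `chr`-prefixed form at read time. When a summary file
lacks signed effects, the per-SNP z is the unsigned quantile
`z = Phi^{-1}(1 - p/2) >= 0`; every downstream use of z takes magnitudes
only, so signs are never needed.

## Peak-gene links

**Co-accessibility mode (scATAC only).** Cells are embedded by TF-IDF +
truncated SVD (LSI, 30 components, first component dropped as a depth
surrogate) and grouped into metacells of at least `k` similar cells
(default `k = 5`); counts are summed per metacell, depth-normalized and
log1p-transformed. Within overlapping genomic windows (default 500 kb,
half-window step) a graphical-lasso precision matrix is estimated with an
elementwise L1 penalty that grows with genomic distance:
`rho_ij = penalty_scale * max(d_ij / window, 0.05)`, `penalty_scale = 0.2`.
Co-accessibility is the partial correlation derived from the precision
matrix, averaged when a pair appears in several windows. A gene's promoter
anchor peaks are those overlapping `[TSS - 2000, TSS + 100]` (strand-aware;
all overlapping peaks are anchors); any other peak whose co-accessibility
with an anchor reaches the threshold (default 0.1) is linked to the gene.

Why these defaults: metacells of 5 keep enough observations (n_metacells =
n_cells / 5) for the precision matrix to be estimable — partial
correlations inside a clique of strongly co-varying peaks are the
statistically hardest quantity here, and their sampling error scales as
1/sqrt(n_metacells); larger metacells denoise individual profiles but
starve the estimator of observations. The light penalty (0.2) keeps the
soft-thresholding bias on true edges small while the distance scaling still
suppresses spurious long-range edges. The block coordinate-descent
graphical lasso is written in-house because no installed library accepts an
elementwise penalty matrix. This module is a simplified distance-penalized
co-accessibility model, not a port of any published implementation, and is
flagged as such in its docstring.

**Multiome mode (ATAC + RNA).** For each gene, every peak within the window
of its TSS is scored by the Pearson correlation between log1p
depth-normalized accessibility and log1p CP10K expression across cells. The
null reference is a background of up to 200 control peaks drawn (without
replacement) from the candidate's mean-accessibility decile; the
standardized contrast `(r - mean_bg) / (sd_bg * sqrt(1 + 1/n_bg))` is
referred to a Student t with `n_bg - 1` degrees of freedom — the
finite-background analogue of a z-test, exact under exchangeability of the
candidate with its matched background. p-values are Benjamini-Hochberg
adjusted within gene; links with adjusted p <= alpha (default 0.05) are
retained with the raw correlation as score.

## SNP-gene annotation

The window-based baseline assigns a SNP to a gene iff it falls within
`window_bp` of the (inclusive) gene body; the CRE-based annotation takes
the union of gene-body SNPs and SNPs inside any peak linked to the gene.
Exports deduplicate across the two provenance classes and order SNPs by
position; with an empty link table the CRE annotation reduces exactly to
the window-0 baseline. SNPs may annotate multiple genes. The comparative
gene typing labels each gene type 1 (no CRE-specific SNPs), type 2 (both
CRE-specific and baseline SNPs) or type 3 (only CRE-specific SNPs); the
baseline window is symmetric (10 kb on both sides by default).

## Gene and gene-set tests

**Raw mode** (individual-level genotypes): the gene's standardized dosage
matrix is reduced by PCA to the smallest component count explaining 99.9%
of variance, the phenotype is regressed on those components, and the joint
F-test p-value is the gene p. With one SNP this is exactly the squared-t
single-marker test.

**Summary mode** (z-scores only): the statistic is `sum(z^2)`; under the
null with LD matrix R its distribution is `sum_i lambda_i chi2_1` with
`lambda_i` the eigenvalues of R. R is shrunk toward identity by 1%
(numerical stability on small panels), eigenvalues clipped at zero, and the
tail computed by Imhof-type numerical inversion of the characteristic
function (absolute accuracy ~1e-6, verified against an independent nested
smooth-convolution oracle), with two shortcuts: exactly-equal eigenvalues
reduce to a scaled central chi-square in closed form (this also covers the
slowly converging one-eigenvalue integrand), and integration failure falls
back to a moment-matched Satterthwaite approximation. `ld=None` declares
independent SNPs and uses the chi-square tail directly.

**Gene-set test** (competitive): gene p-values become
`z = Phi^{-1}(1 - p)` (clipped to keep z finite); z is regressed on the
set-membership indicator plus log SNP count (and optional caller
covariates); the one-sided p tests a positive membership coefficient; BH
q-values are reported across sets. Sets overlapping fewer than 10 scored
genes are skipped; a set covering every gene is a degenerate design and an
error.

**Type-1-error experiment**: per replicate, observed z-scores are permuted
across SNP positions (severing SNP-signal linkage while preserving the
marginal z distribution), gene tests are recomputed (summary mode,
independent-SNP null) and the fraction of genes below alpha recorded, with
the mean and Monte Carlo SE per annotation strategy. The rate conditioned
on one GWAS inherits that draw's z-pool variance (a 2% variance deficit in
the pool shifts a 25-SNP gene test noticeably), so calibration checks
average over independent GWAS draws and estimate the SE across draws.

## Cell and cell-type disease relevance

Risk peaks are the union of peaks linked to genes found disease-associated
at the gene level, each weighted by `Z_p`, the largest SNP |z| under the
peak (peaks without SNPs are dropped). Technical variance is estimated from
the mean-variance relationship: per-peak mean and variance in the original
count space; a local quadratic (tricube-weighted, span 0.3) fit of log10
variance on log10 mean gives the expected technical variance at a peak's
mean; the technical proportion is predicted/observed clipped to [0, 1]; and
`sigma^2_tech,p` is that proportion times the peak's variance in the log1p
depth-normalized space. The local polynomial regression is written in-house
because the spec of the trend is degree-2 local regression and the
available lowess implementation is degree-1 only. Constant peaks get
proportion 1, `sigma^2_tech = 0`, and are excluded from scoring (their
inverse weight is undefined).

Each cell's score is the weighted mean

    S_c = sum_p Z_p sigma_tech,p^-1 X'_cp / sum_p Z_p sigma_tech,p^-1

over the risk peaks, where X' is the log1p depth-normalized matrix with a
fixed scaling target of 1e4 counts. A fixed target (rather than the
matrix's own median depth) makes X', and hence every score, exactly
invariant to uniform rescaling of the counts.

**Monte Carlo null.** All peaks are binned on a 10x10 grid of
mean-accessibility x variance quantiles; for each risk peak and each of B
control replicates (default B = 1000) a control peak is drawn uniformly
from the risk peak's bin (nearest nonempty bin as fallback). Control
replicates are scored with the control peaks' own GWAS weights and their
own technical variances. The candidate pool excludes the risk peaks
themselves, preventing null contamination; calibration experiments
re-include them so that the observed set is exchangeable with the controls.

Scores are normalized cell-wise against the control distribution: the
observed score against the mean/sd of all B controls, each control against
the other B-1 (leave-one-out). Without the leave-one-out correction each
control is part of its own baseline while the observed score is not, an
O(1/B) asymmetry that measurably inflates the cell-type test at B = 100.
Cell-level p-values pool all normalized control scores:
`p_c = (1 + #{pooled controls >= S_c}) / (1 + n_cell * B)`; cell-type
p-values compare the top-5% quantile t of the type's normalized scores with
the same quantile of each control replicate:
`p_mc = (1 + #{t <= t_b}) / (1 + B)`. Quantiles use linear interpolation.
Types with fewer than 20 cells are skipped.

**Known property.** Control sets are matched on per-peak mean and variance
but not on between-peak covariance. When the risk peaks co-vary strongly
(e.g. CREs of one gene sharing a regulatory program), the observed score
has a larger between-cell spread than any control replicate, which raises
the type-level statistic in every cell type at once. The test remains
exactly calibrated when the risk set is exchangeable with the control pool,
and the planted-effect contrast (which type stands out) is unaffected; but
an absolute "this type is significant" reading should be made with this in
mind. Cell-level p-values within one run are strongly dependent for the
same reason — each replicate shares one observed-set offset — so their
calibration is a statement about rejection rates over replicate
experiments, not about within-run uniformity.

## Synthetic fixtures

The toy genome places 20 genes 400 kb apart on one chromosome, each with a
promoter anchor peak and ~3 wired distal peaks 30-80 kb upstream of the
gene body — inside the 500 kb link window but invisible to a 10 kb window
— plus background peaks (200 total) and 5000 SNPs covering peaks, gene
bodies and intergenic space. Two causal genes carry causal SNPs only inside
their wired distal peaks.

Genotypes come from AR(1)-correlated latent Gaussian haplotypes thresholded
at each SNP's allele frequency (U(0.1, 0.5)); defaults are n = 2000
individuals, per-causal-SNP h2 = 0.02 and ld_rho = 0 (independent SNPs, so
the summary test's independent-SNP null is exact). The phenotype is the sum
of standardized causal dosages times sqrt(h2) plus Gaussian noise, and
per-SNP marginal regressions give z and p. The expected causal chi-square
is 1 + n*h2 (~41 at the defaults), large enough for gene-level recovery
without saturating every test.

scATAC counts are Poisson with per-peak baselines, per-cell depth factors,
and a per-gene per-cell activity factor shared by a gene's anchor and wired
peaks — this shared factor is what makes the wiring recoverable from
co-accessibility. The causal genes' peaks are `effect_fold` times more
accessible in the planted cell type (default fold 3 in planted fixtures);
mild background cell-type multipliers apply to non-risk peaks only, keeping
the planted fold interpretable. Multiome expression mixes the wired peaks'
summed normalized accessibility with independent noise in proportion
`link_strength`.

What passing tests show: the geometry of distal annotation, the exactness
and calibration of the statistics, and end-to-end recovery of planted
signal at realistic desk-scale sizes (600 cells, 200 peaks, 5000 SNPs, 20
genes — chosen so the full suite runs in minutes on one CPU). What they do
not show: behavior under realistic chromatin biology (fragment models, TF
footprints, batch effects), realistic LD panels, or genome-scale multiple
testing burdens.

## Numerical and design decisions

- p = 0 in summary files is clipped to the smallest positive *normal*
  double before the normal quantile (subnormals push `Phi^{-1}` to
  infinity); gene p-values are clipped to [1e-300, 1].
- The graphical lasso adds a 1e-6 ridge to each window's covariance and
  converges on the mean absolute change of the covariance estimate (1e-4
  relative); per-column lasso subproblems use cyclic coordinate descent.
- Ties in promoter anchoring (TSS overlapping several peaks) keep all
  overlapping peaks as anchors; a gene is never linked to its own anchor.
- The exported annotation file stores no provenance; re-reading recovers
  the deduplicated union exactly, and the `drs` CLI command reconstructs
  per-gene peak sets by SNP-in-peak overlap against the supplied matrix.
- Monte Carlo p-values are never zero by construction (the +1 in numerator
  and denominator); their floors 1/(1 + n_cell*B) and 1/(1 + B) are exact
  and tested.
- All stochastic steps take explicit seeds and the CLI pipeline is
  byte-reproducible at a fixed seed.

## Limitations

The co-accessibility module approximates, not reproduces, dedicated
co-accessibility tools; trans links, Hi-C-informed links and eQTL-based
assignment are out of scope, as are fragment-level inputs, liftover, and
conditional gene-set analysis. The matched-control null spans accessibility
and variance but not covariance (above). Summary-mode gene tests assume the
supplied LD panel matches the GWAS population.
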