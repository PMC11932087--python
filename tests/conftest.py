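"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from epigwas import drs, snp_annotation, synthetic
from epigwas.types import CellPeakMatrix, Peak


@pytest.fixture(scope="session")
def truth():
    return synthetic.toy_genome(seed=0)


@pytest.fixture(scope="session")
def gwas_panel(truth):
    return synthetic.simulate_gwas(truth, seed=1)


@pytest.fixture(scope="session")
def gwas(gwas_panel):
    return gwas_panel[0]


@pytest.fixture(scope="session")
def panel(gwas_panel):
    return gwas_panel[1]


@pytest.fixture(scope="session")
def true_links(truth):
    return synthetic.true_link_objects(truth)


@pytest.fixture(scope="session")
def annot_cre(gwas, truth, true_links):
    return snp_annotation.assign_snps_cre(gwas, truth.genes, true_links)


@pytest.fixture(scope="session")
def annot_win10k(gwas, truth):
    return snp_annotation.assign_snps_window(gwas, truth.genes, 10_000)


@pytest.fixture(scope="session")
def atac_null(truth):
    """Null scATAC matrix: no planted cell-type effect."""
    return synthetic.simulate_scatac(truth, n_cells_per_type=100,
                                     effect_fold=1.0, seed=2)


@pytest.fixture(scope="session")
def atac_planted(truth):
    """Planted matrix: causal genes' peaks 3x more accessible in typeA."""
    return synthetic.simulate_scatac(truth, n_cells_per_type=100,
                                     effect_fold=3.0, seed=2)


@pytest.fixture()
def small_matrix():
    """Tiny dense-ish matrix for direct-formula tests."""
    rng = np.random.default_rng(0)
    peaks = [Peak("chr1", i * 1000, i * 1000 + 500) for i in range(60)]
    X = sp.csr_matrix(rng.poisson(2.0, size=(120, 60)))
    return CellPeakMatrix(X, [f"c{i}" for i in range(120)], peaks,
                          ["a"] * 60 + ["b"] * 60)


def naive_disease_scores(Xnorm, weights, sigma):
    """Independent double-loop oracle for the weighted-accessibility score."""
    n_cells, n_peaks = Xnorm.shape
    out = np.empty(n_cells)
    for c in range(n_cells):
        num = 0.0
        den = 0.0
        for p in range(n_peaks):
            w = weights[p] / sigma[p]
            num += w * Xnorm[c, p]
            den += w
        out[c] = num / den
    return out
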