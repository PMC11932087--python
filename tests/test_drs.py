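"""Disease-relevance scoring: weights, technical variance, scores, MC tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from epigwas import drs
from epigwas.types import (
    CellPeakMatrix,
    GwasSummary,
    Peak,
    RiskPeakSet,
    TechVariance,
    ValidationError,
)
from tests.conftest import naive_disease_scores


def gwas_at(positions, zvals, chrom="chr1"):
    df = pd.DataFrame(
        {
            "snp": [f"s{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,  # 1-based
            "pval": 0.5,
            "z": zvals,
        }
    )
    return GwasSummary(df)


class TestPeakWeights:
    def test_max_abs_z_within_peak(self):
        peak = Peak("chr1", 100, 200)
        gwas = gwas_at([150, 180], [1.2, -2.5])
        w = drs.peak_weights(gwas, [peak])
        assert w[0] == 2.5

    def test_no_snp_peak_gets_zero(self):
        gwas = gwas_at([500], [1.0])
        assert drs.peak_weights(gwas, [Peak("chr1", 100, 200)])[0] == 0.0

    def test_half_open_boundaries(self):
        peak = Peak("chr1", 100, 200)
        # 1-based 101 -> pos0 100 (inside); 1-based 201 -> pos0 200 (outside)
        gwas = gwas_at([101, 201], [1.0, 9.0])
        assert drs.peak_weights(gwas, [peak])[0] == 1.0


class TestRiskPeaks:
    def test_union_and_weights_match_brute_force(self, truth, gwas, annot_cre):
        risk = drs.risk_peaks_from_annotation(annot_cre, truth.causal_genes, gwas)
        expected = set()
        for g in truth.causal_genes:
            expected |= annot_cre.genes[g].peaks
        pos0 = gwas.df["pos0"].to_numpy()
        absz = np.abs(gwas.df["z"].to_numpy())
        kept = {}
        for p in expected:
            inside = (pos0 >= p.start) & (pos0 < p.end)
            w = absz[inside].max() if inside.any() else 0.0
            if w > 0:
                kept[p] = w
        assert set(risk.peaks) == set(kept)
        for p, w in zip(risk.peaks, risk.weights):
            assert w == pytest.approx(kept[p])

    def test_shared_peak_appears_once(self, gwas):
        from epigwas.types import GeneAnnotationRecord, SnpGeneAnnotation

        peak = Peak("chr1", 200_000, 201_000)
        annot = SnpGeneAnnotation(
            {
                "A": GeneAnnotationRecord(peaks={peak}),
                "B": GeneAnnotationRecord(peaks={peak}),
            },
            {},
            {"A": ("chr1", 0, 10), "B": ("chr1", 20, 30)},
        )
        risk = drs.risk_peaks_from_annotation(annot, ["A", "B"], gwas)
        assert len(risk.peaks) == 1

    def test_no_peaks_is_actionable_error(self, gwas):
        from epigwas.types import GeneAnnotationRecord, SnpGeneAnnotation

        annot = SnpGeneAnnotation(
            {"A": GeneAnnotationRecord()}, {}, {"A": ("chr1", 0, 10)}
        )
        with pytest.raises(ValidationError, match="threshold"):
            drs.risk_peaks_from_annotation(annot, ["A"], gwas)


class TestTechVariance:
    def test_poisson_peaks_mostly_technical(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.5, 8.0, 150)
        counts = rng.poisson(np.tile(base, (500, 1)))
        mat = CellPeakMatrix(
            sp.csr_matrix(counts), [f"c{i}" for i in range(500)],
            [Peak("chr1", i * 1000, i * 1000 + 500) for i in range(150)],
        )
        tech = drs.estimate_tech_variance(mat)
        assert tech.proportion_tech.mean() >= 0.8

    def test_overdispersed_peak_below_peers(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0.5, 5.0, 120)
        counts = rng.poisson(np.tile(base, (400, 1)))
        lam = base[0] * rng.gamma(0.4, 1 / 0.4, size=400)  # 10x excess variance
        counts[:, 0] = rng.poisson(lam)
        mat = CellPeakMatrix(
            sp.csr_matrix(counts), [f"c{i}" for i in range(400)],
            [Peak("chr1", i * 1000, i * 1000 + 500) for i in range(120)],
        )
        tech = drs.estimate_tech_variance(mat)
        peers = np.argsort(np.abs(base - base[0]))[1:11]
        assert tech.proportion_tech[0] < tech.proportion_tech[peers].min()

    def test_constant_peak_degenerate_case(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(2.0, size=(300, 80))
        counts[:, 0] = 3  # constant nonzero: zero observed variance
        mat = CellPeakMatrix(
            sp.csr_matrix(counts), [f"c{i}" for i in range(300)],
            [Peak("chr1", i * 1000, i * 1000 + 500) for i in range(80)],
        )
        tech = drs.estimate_tech_variance(mat)
        assert tech.proportion_tech[0] == 1.0
        assert tech.sigma2_tech[0] == 0.0
        assert not tech.usable[0]

    def test_too_few_informative_peaks_rejected(self):
        mat = CellPeakMatrix(
            sp.csr_matrix(np.ones((100, 10))), [f"c{i}" for i in range(100)],
            [Peak("chr1", i * 1000, i * 1000 + 500) for i in range(10)],
        )
        with pytest.raises(ValidationError):
            drs.estimate_tech_variance(mat)


class TestDiseaseScores:
    def _fixture(self, Xnorm_row, weights, sigma2):
        n_peaks = len(weights)
        peaks = [Peak("chr1", i * 1000, i * 1000 + 500) for i in range(n_peaks)]
        tech = TechVariance(
            sigma2_tech=np.asarray(sigma2, dtype=float),
            observed_log_var=np.asarray(sigma2, dtype=float) + 1.0,
            proportion_tech=np.ones(n_peaks),
            usable=np.asarray(sigma2) > 0,
        )
        mat = CellPeakMatrix(sp.csr_matrix(np.zeros((1, n_peaks))), ["c0"], peaks)
        risk = RiskPeakSet(peaks, np.asarray(weights, dtype=float))
        return mat, risk, tech

    def test_equal_weights_is_plain_mean(self):
        mat, risk, tech = self._fixture([2.0, 0.0], [1.0, 1.0], [1.0, 1.0])
        S = drs.disease_scores(mat, risk, tech, Xnorm=np.array([[2.0, 0.0]]))
        assert S[0] == pytest.approx(1.0)

    def test_hand_computed_weighted_mean(self):
        mat, risk, tech = self._fixture([4.0, 0.0], [3.0, 1.0], [1.0, 1.0])
        S = drs.disease_scores(mat, risk, tech, Xnorm=np.array([[4.0, 0.0]]))
        assert S[0] == pytest.approx(3.0)  # 12 / 4

    def test_weight_scale_invariance(self, atac_null, gwas, truth, annot_cre):
        tech = drs.estimate_tech_variance(atac_null)
        risk = drs.risk_peaks_from_annotation(annot_cre, truth.causal_genes, gwas)
        S1 = drs.disease_scores(atac_null, risk, tech)
        scaled = RiskPeakSet(risk.peaks, risk.weights * 7.0, risk.source_genes)
        S2 = drs.disease_scores(atac_null, scaled, tech)
        assert np.allclose(S1, S2, atol=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        Xnorm = rng.random((20, 30))
        weights = rng.random(30) + 0.1
        sigma2 = rng.random(30) + 0.1
        mat, risk, tech = self._fixture(None, weights, sigma2)
        mat = CellPeakMatrix(sp.csr_matrix(np.zeros((20, 30))),
                             [f"c{i}" for i in range(20)], mat.peaks)
        S = drs.disease_scores(mat, risk, tech, Xnorm=Xnorm)
        oracle = naive_disease_scores(Xnorm, weights, np.sqrt(sigma2))
        assert np.max(np.abs(S - oracle)) < 1e-12

    def test_score_within_row_range(self):
        rng = np.random.default_rng(5)
        Xnorm = rng.random((10, 15))
        weights = rng.random(15) + 0.1
        sigma2 = rng.random(15) + 0.1
        mat, risk, tech = self._fixture(None, weights, sigma2)
        mat = CellPeakMatrix(sp.csr_matrix(np.zeros((10, 15))),
                             [f"c{i}" for i in range(10)], mat.peaks)
        S = drs.disease_scores(mat, risk, tech, Xnorm=Xnorm)
        assert (S >= Xnorm.min(axis=1) - 1e-12).all()
        assert (S <= Xnorm.max(axis=1) + 1e-12).all()


class TestMatchedControls:
    def test_deterministic(self, atac_null, gwas, truth, annot_cre):
        tech = drs.estimate_tech_variance(atac_null)
        risk = drs.risk_peaks_from_annotation(annot_cre, truth.causal_genes, gwas)
        w = drs.peak_weights(gwas, atac_null.peaks)
        a = drs.matched_controls(risk, atac_null, tech, w, B=20, seed=5)
        b = drs.matched_controls(risk, atac_null, tech, w, B=20, seed=5)
        assert (a == b).all()

    def test_single_bin_draws_from_whole_pool(self, atac_null, gwas, truth,
                                              annot_cre):
        tech = drs.estimate_tech_variance(atac_null)
        risk = drs.risk_peaks_from_annotation(annot_cre, truth.causal_genes, gwas)
        w = drs.peak_weights(gwas, atac_null.peaks)
        ctrl = drs.matched_controls(risk, atac_null, tech, w, B=300, n_bins=1,
                                    seed=6)
        pool_size = ((w > 0) & tech.usable).sum() - len(risk)
        assert len(np.unique(ctrl)) > 0.8 * pool_size

    def test_zero_B_rejected(self, atac_null, gwas, truth, annot_cre):
        tech = drs.estimate_tech_variance(atac_null)
        risk = drs.risk_peaks_from_annotation(annot_cre, truth.causal_genes, gwas)
        w = drs.peak_weights(gwas, atac_null.peaks)
        with pytest.raises(ValidationError):
            drs.matched_controls(risk, atac_null, tech, w, B=0)


class TestMcPvalues:
    def test_cell_p_floor_and_ceiling(self):
        n_cell, B = 30, 50
        S_ctrl = np.zeros((n_cell, B))
        S_hi = np.full(n_cell, 1.0)
        p = drs.cell_pvalues(S_hi, S_ctrl, normalize=False)
        assert np.all(p == 1.0 / (1 + n_cell * B))
        S_lo = np.full(n_cell, -1.0)
        p = drs.cell_pvalues(S_lo, S_ctrl, normalize=False)
        assert np.all(p == 1.0)

    def test_celltype_p_floor_at_B19(self):
        B = 19
        n = 40
        S = np.full(n, 10.0)
        S_ctrl = np.zeros((n, B))
        out = drs.celltype_pvalues(S, S_ctrl, ["t"] * n)
        assert out["p_mc"].item() == pytest.approx(1.0 / 20)  # = 0.05

    def test_celltype_p_ceiling(self):
        S = np.full(40, -10.0)
        S_ctrl = np.zeros((40, 25))
        out = drs.celltype_pvalues(S, S_ctrl, ["t"] * 40)
        assert out["p_mc"].item() == 1.0

    def test_small_cell_type_skipped(self):
        S = np.zeros(30)
        S_ctrl = np.zeros((30, 10))
        types = ["big"] * 25 + ["tiny"] * 5
        out = drs.celltype_pvalues(S, S_ctrl, types)
        assert list(out["cell_type"]) == ["big"]

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_pvalue_bounds_always_hold(self, seed):
        rng = np.random.default_rng(seed)
        n_cell, B = rng.integers(2, 12), rng.integers(1, 9)
        S = rng.standard_normal(n_cell)
        S_ctrl = rng.standard_normal((n_cell, B))
        p = drs.cell_pvalues(S, S_ctrl)
        assert np.all(p >= 1.0 / (1 + n_cell * B) - 1e-12)
        assert np.all(p <= 1.0)
        out = drs.celltype_pvalues(S, S_ctrl, ["t"] * n_cell, min_cells=1)
        assert 1.0 / (1 + B) - 1e-12 <= out["p_mc"].item() <= 1.0


class TestScoreCells:
    def test_full_pipeline_deterministic(self, atac_planted, gwas, truth,
                                         annot_cre):
        risk = drs.risk_peaks_from_annotation(annot_cre, truth.causal_genes, gwas)
        a = drs.score_cells(atac_planted, risk, gwas, B=30, seed=9)
        b = drs.score_cells(atac_planted, risk, gwas, B=30, seed=9)
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.control_scores, b.control_scores)
        assert np.array_equal(a.cell_pvals, b.cell_pvals)
        pd.testing.assert_frame_equal(a.celltype_stats, b.celltype_stats)

    def test_planted_type_detected(self, atac_planted, gwas, truth, annot_cre):
        risk = drs.risk_peaks_from_annotation(annot_cre, truth.causal_genes, gwas)
        res = drs.score_cells(atac_planted, risk, gwas, B=100, seed=10)
        ct = res.celltype_stats.set_index("cell_type")
        assert ct["p_mc"].idxmin() == truth.planted_cell_type
        assert ct.loc[truth.planted_cell_type, "p_mc"] <= 0.05
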