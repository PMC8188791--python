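"""Matrix correction, pooling, quantile normalization and binomial
downsampling."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from umiseen import (
    CountMatrix,
    CUHistogram,
    GenePrediction,
    PooledHistogramSource,
    apply_correction,
    batch_correct,
    binomial_downsample_hist,
    build_cu_histograms,
    expected_survivors,
    make_pool_source,
    normalize_source_to_target,
    pool_histograms,
    predict_gene_counts,
    quantile_normalize,
)
from umiseen.metrics import ccc, mean_expression_profile
from umiseen.simulate import (
    GeneSpec,
    SimSpec,
    histogram_from_counts,
    simulate_dataset,
    simulate_gene,
)


def random_matrix(rng, n_genes=12, n_cells=6) -> CountMatrix:
    dense = rng.integers(0, 40, size=(n_genes, n_cells)).astype(float)
    return CountMatrix(
        sp.csr_matrix(dense),
        [f"g{i}" for i in range(n_genes)],
        [f"c{j}" for j in range(n_cells)],
    )


class TestPredictGeneCounts:
    def test_t_zero_keeps_observed(self):
        hists = {
            "a": CUHistogram("a", {1: 30, 2: 10}),
            "b": CUHistogram("b", {1: 15, 3: 8}),
        }
        preds = predict_gene_counts(hists, method="ztnb", t=0.0)
        for g, h in hists.items():
            assert preds[g].c == h.n_molecules

    def test_degenerate_genes_fall_back_flagged(self):
        hists = {"a": CUHistogram("a", {1: 5})}
        preds = predict_gene_counts(hists, method="ztnb", t=9.0)
        assert preds["a"].c == 5 and not preds["a"].applied

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown method"):
            predict_gene_counts({}, method="magic")

    def test_simulation_accuracy_for_expressed_genes(self):
        rng = np.random.default_rng(12)
        hists, truth = {}, {}
        for i in range(30):
            mu = float(np.exp(rng.uniform(np.log(0.5), np.log(8.0))))
            reads = simulate_gene(3000, mu, 1.0, rng)
            hists[f"g{i}"] = histogram_from_counts(f"g{i}", reads)
            truth[f"g{i}"] = 3000
        preds = predict_gene_counts(hists, method="ztnb", t=1e12)
        rel = [abs(preds[g].c / truth[g] - 1) for g in hists if preds[g].applied]
        assert np.mean(rel) < 0.10


class TestApplyCorrection:
    def test_scale_factor_formula(self):
        # T=100, P=200, c_g=10 -> m_g = 5
        m = CountMatrix(sp.csr_matrix(np.array([[10.0], [90.0]])), ["a", "b"], ["c0"])
        _, res = apply_correction(m, {"a": 10.0, "b": 190.0})
        assert res.per_gene.loc["a", "m"] == pytest.approx(5.0)

    def test_identity_when_predictions_equal_observed(self):
        rng = np.random.default_rng(13)
        m = random_matrix(rng)
        preds = m.gene_totals().to_dict()
        corrected, res = apply_correction(m, preds)
        assert corrected == m
        assert res.P == res.T

    def test_conservation_on_random_inputs(self):
        rng = np.random.default_rng(14)
        m = random_matrix(rng)
        preds = {g: float(v) for g, v in
                 (m.gene_totals() * rng.uniform(1.0, 4.0, m.shape[0])).items()}
        corrected, res = apply_correction(m, preds)
        assert res.per_gene["m"].sum() == pytest.approx(res.T, rel=1e-9)
        assert corrected.total_umis == pytest.approx(res.T, rel=1e-9)

    def test_prediction_below_observed_warns(self):
        m = CountMatrix(sp.csr_matrix(np.array([[10.0]])), ["a"], ["c0"])
        with pytest.warns(UserWarning, match="below"):
            apply_correction(m, {"a": 5.0})

    def test_missing_gene_rejected(self):
        m = random_matrix(np.random.default_rng(15))
        with pytest.raises(ValueError, match="no prediction"):
            apply_correction(m, {})


class TestQuantileNormalize:
    def test_identity_and_rank_mapping(self):
        v = np.array([0.3, 0.1, 0.7])
        assert quantile_normalize(v, v) == pytest.approx(v)
        assert quantile_normalize([0.2, 0.4], [0.6, 0.8]) == pytest.approx([0.6, 0.8])

    def test_order_statistics_match_target(self):
        rng = np.random.default_rng(16)
        src, tgt = rng.random(40), rng.random(40)
        out = quantile_normalize(src, tgt)
        assert np.sort(out) == pytest.approx(np.sort(tgt))
        # rank order preserved
        assert np.all(np.argsort(out) == np.argsort(src))

    def test_idempotent_against_same_target(self):
        rng = np.random.default_rng(17)
        src, tgt = rng.random(25), rng.random(30)
        once = quantile_normalize(src, tgt)
        assert quantile_normalize(once, tgt) == pytest.approx(once)


class TestPooling:
    def _source(self, did, fscm, n):
        df = pd.DataFrame(
            {"fscm": [fscm], "fdcm": [0.1], "n_umis": [n]}, index=pd.Index(["g"], name="gene")
        )
        return PooledHistogramSource(did, df, normalized=True)

    def test_weighted_mean(self):
        target = self._source("t", 0.6, 100)
        source = self._source("s", 0.8, 300)
        pooled = pool_histograms(target, [source])
        # (0.6*100 + 0.8*300) / 400 = 0.75, scaled by target n=100
        assert pooled["g"].counts[1] == pytest.approx(75.0)

    def test_identical_source_is_noop(self):
        target = self._source("t", 0.6, 100)
        pooled = pool_histograms(target, [self._source("s", 0.6, 50)])
        assert pooled["g"].counts[1] == pytest.approx(60.0)
        assert pooled["g"].counts[2] == pytest.approx(10.0)

    def test_fmcm_complement(self):
        df = pd.DataFrame(
            {"fscm": [0.6], "fdcm": [0.3], "n_umis": [100]},
            index=pd.Index(["g"], name="gene"),
        )
        target = PooledHistogramSource("t", df, normalized=True)
        pooled = pool_histograms(target, [])
        assert pooled["g"].counts[3] == pytest.approx(10.0)

    def test_gene_absent_from_sources_uses_target(self):
        target = self._source("t", 0.5, 80)
        other = PooledHistogramSource(
            "s",
            pd.DataFrame({"fscm": [0.9], "fdcm": [0.05], "n_umis": [500]},
                         index=pd.Index(["other_gene"], name="gene")),
            normalized=True,
        )
        pooled = pool_histograms(target, [other])
        assert pooled["g"].counts[1] == pytest.approx(40.0)

    def test_normalization_applied_to_raw_sources(self):
        rng = np.random.default_rng(18)
        hists = {
            f"g{i}": CUHistogram(f"g{i}", {1: int(rng.integers(20, 60)), 2: 10, 3: 5})
            for i in range(10)
        }
        target = make_pool_source("t", hists)
        source = make_pool_source("s", hists)
        normed = normalize_source_to_target(source, target)
        assert normed.normalized
        assert np.sort(normed.per_gene["fscm"]) == pytest.approx(
            np.sort(target.per_gene["fscm"])
        )


class TestBinomialDownsampling:
    def test_singletons_halved(self):
        h_new, n = binomial_downsample_hist(CUHistogram("g", {1: 100}), 0.5)
        assert n == pytest.approx(50.0)
        assert h_new.counts == {1: pytest.approx(50.0)}

    def test_doubles_split_by_binomial_pmf(self):
        h_new, n = binomial_downsample_hist(CUHistogram("g", {2: 10}), 0.5)
        assert h_new.counts[1] == pytest.approx(5.0)
        assert h_new.counts[2] == pytest.approx(2.5)
        assert n == pytest.approx(7.5)

    def test_x_one_is_identity(self):
        h = CUHistogram("g", {1: 7, 3: 2, 8: 1})
        h_new, n = binomial_downsample_hist(h, 1.0)
        assert h_new == h and n == h.n_molecules

    def test_x_out_of_range_rejected(self):
        h = CUHistogram("g", {1: 5})
        for bad in (0.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                binomial_downsample_hist(h, bad)

    def test_read_conservation_exact(self):
        h = histogram_from_counts("g", simulate_gene(5000, 3.0, 1.0, seed=19))
        for x in (0.2, 0.5, 0.9):
            h_new, _ = binomial_downsample_hist(h, x)
            assert h_new.total_reads == pytest.approx(x * h.total_reads, rel=1e-12)

    def test_composition_is_multiplicative(self):
        h = histogram_from_counts("g", simulate_gene(2000, 2.5, 0.8, seed=20))
        h12, _ = binomial_downsample_hist(binomial_downsample_hist(h, 0.6)[0], 0.5)
        h_direct, _ = binomial_downsample_hist(h, 0.3)
        for j in set(h12.counts) | set(h_direct.counts):
            assert h12.counts.get(j, 0.0) == pytest.approx(
                h_direct.counts.get(j, 0.0), rel=1e-9, abs=1e-9
            )

    def test_matches_monte_carlo_thinning(self):
        h = histogram_from_counts("g", simulate_gene(20000, 3.0, 1.0, seed=21))
        copies, counts = h.as_arrays()
        expanded = np.repeat(copies, counts.astype(int))
        rng = np.random.default_rng(22)
        survivors = np.array(
            [(rng.binomial(expanded, 0.3) > 0).sum() for _ in range(50)]
        )
        _, n_analytic = binomial_downsample_hist(h, 0.3)
        se = survivors.std(ddof=1) / np.sqrt(len(survivors))
        assert abs(n_analytic - survivors.mean()) < 3 * se

    def test_expected_survivors_closed_form_matches_full(self):
        h = histogram_from_counts("g", simulate_gene(1000, 2.0, 1.0, seed=23))
        for x in (0.1, 0.45, 1.0):
            _, n_full = binomial_downsample_hist(h, x)
            n_closed = expected_survivors({"g": h}, x)["g"]
            assert n_closed == pytest.approx(n_full, rel=1e-9)


class TestBatchCorrect:
    @staticmethod
    @pytest.fixture(scope="class")
    def depth_pair():
        rng = np.random.default_rng(24)
        genes = [
            GeneSpec(
                f"G{i:03d}",
                n_molecules=int(np.exp(rng.uniform(np.log(300), np.log(3000)))),
                nb_mean=float(np.exp(rng.uniform(np.log(0.5), np.log(16.0)))),
            )
            for i in range(60)
        ]
        deep, _ = simulate_dataset(SimSpec(genes, n_cells=30, read_fraction=1.0, seed=25))
        shallow, _ = simulate_dataset(SimSpec(genes, n_cells=30, read_fraction=0.5, seed=26))
        h_deep, m_deep = build_cu_histograms(deep)
        h_shallow, m_shallow = build_cu_histograms(shallow)
        return m_deep, h_deep, m_shallow

    def test_x_one_is_identity(self, depth_pair):
        m_deep, h_deep, m_shallow = depth_pair
        corrected, res = batch_correct(m_deep, h_deep, m_shallow, x=1.0)
        assert corrected == m_deep
        assert res.per_gene["f"].to_numpy() == pytest.approx(1.0)

    def test_correction_improves_concordance(self, depth_pair):
        m_deep, h_deep, m_shallow = depth_pair
        corrected, res = batch_correct(m_deep, h_deep, m_shallow, x="auto")
        shared = [g for g in m_deep.gene_ids if g in set(m_shallow.gene_ids)]
        prof_s = np.log2(mean_expression_profile(m_shallow).values.loc[shared] + 1)
        prof_u = np.log2(mean_expression_profile(m_deep).values.loc[shared] + 1)
        prof_c = np.log2(mean_expression_profile(corrected).values.loc[shared] + 1)
        assert ccc(prof_c, prof_s) > ccc(prof_u, prof_s)

    def test_auto_finds_depth_ratio(self, depth_pair):
        m_deep, h_deep, m_shallow = depth_pair
        _, res = batch_correct(m_deep, h_deep, m_shallow, x="auto")
        assert res.chosen_by == "ccc-grid"
        assert abs(res.x - 0.5) <= 0.1

    def test_auto_needs_shared_genes(self):
        m = CountMatrix(sp.csr_matrix(np.ones((1, 2))), ["a"], ["c0", "c1"])
        other = CountMatrix(sp.csr_matrix(np.ones((1, 2))), ["b"], ["c0", "c1"])
        with pytest.raises(ValueError, match="shared"):
            batch_correct(m, {}, other, x="auto")
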