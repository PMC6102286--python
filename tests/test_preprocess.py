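"""Delta computation, quantile normalization, PCA and PC removal."""

import numpy as np
import pandas as pd
import pytest

import statinsig as ss


def _delta(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ss.DeltaExpression(values=pd.DataFrame(arr, index=genes,
                                                  columns=samples))


class TestComputeDelta:
    def test_identical_matrices_give_zero(self):
        m = pd.DataFrame(np.arange(6.0).reshape(2, 3),
                         index=["g1", "g2"], columns=list("abc"))
        assert (ss.compute_delta(m, m).values == 0).all().all()

    def test_constant_offset(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 4)),
                         index=list("xyz"), columns=list("abcd"))
        d = ss.compute_delta(m + 1.0, m)
        assert np.allclose(d.values.to_numpy(), 1.0)

    def test_alignment_of_permuted_columns(self):
        rng = np.random.default_rng(1)
        statin = pd.DataFrame(rng.normal(size=(4, 5)),
                              index=list("gxyz"), columns=list("abcde"))
        control = pd.DataFrame(rng.normal(size=(4, 5)),
                               index=list("gxyz"), columns=list("abcde"))
        shuffled = control[list("ecabd")].loc[list("yzgx")]
        pd.testing.assert_frame_equal(
            ss.compute_delta(statin, shuffled).values,
            ss.compute_delta(statin, control).values)

    def test_index_mismatch_rejected(self):
        a = pd.DataFrame(np.ones((2, 2)), index=["g1", "g2"], columns=["a", "b"])
        b = pd.DataFrame(np.ones((2, 2)), index=["g1", "g3"], columns=["a", "b"])
        with pytest.raises(ValueError):
            ss.compute_delta(a, b)


class TestQuantileNormalize:
    def test_hand_computed_example(self):
        m = np.array([[5.0, 4.0], [2.0, 1.0], [3.0, 2.0]])
        out = ss.quantile_normalize(m)
        expected = np.array([[4.5, 4.5], [1.5, 1.5], [2.5, 2.5]])
        np.testing.assert_allclose(out, expected)

    def test_single_column_unchanged(self):
        m = np.array([[3.0], [1.0], [2.0]])
        np.testing.assert_allclose(ss.quantile_normalize(m), m)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(50, 6))
        once = ss.quantile_normalize(m)
        np.testing.assert_allclose(ss.quantile_normalize(once), once,
                                   atol=1e-9)

    def test_columns_share_value_multiset(self):
        rng = np.random.default_rng(3)
        out = ss.quantile_normalize(rng.normal(size=(40, 5)))
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-9)

    def test_column_exchangeable_and_rank_preserving(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(30, 4))
        perm = [2, 0, 3, 1]
        np.testing.assert_allclose(ss.quantile_normalize(m[:, perm]),
                                   ss.quantile_normalize(m)[:, perm])
        out = ss.quantile_normalize(m)
        for j in range(4):
            assert (np.argsort(out[:, j], kind="stable")
                    == np.argsort(m[:, j], kind="stable")).all()

    def test_ties_get_mean_of_spanned_reference(self):
        m = np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]])
        out = ss.quantile_normalize(m)
        ref = np.sort(m, axis=0).mean(axis=1)  # [5.5, 10.5, 17.5]
        np.testing.assert_allclose(out[:, 0],
                                   [(ref[0] + ref[1]) / 2,
                                    (ref[0] + ref[1]) / 2, ref[2]])


class TestBatchRegression:
    def test_single_batch_identity(self):
        d = _delta(np.random.default_rng(0).normal(size=(5, 6)))
        out = ss.regress_out_batch(d, pd.Series(["b1"] * 6,
                                                index=d.sample_ids))
        pd.testing.assert_frame_equal(out.values, d.values)
        assert out.batch_adjusted

    def test_pure_batch_offsets_removed(self):
        base = np.zeros((3, 6))
        offs = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        d = _delta(base + offs)
        batch = pd.Series(["b1"] * 3 + ["b2"] * 3, index=d.sample_ids)
        out = ss.regress_out_batch(d, batch)
        assert np.allclose(out.values.to_numpy(),
                           out.values.to_numpy()[:, :1])

    def test_residuals_orthogonal_to_batch_indicator(self):
        rng = np.random.default_rng(5)
        d = _delta(rng.normal(size=(20, 12)))
        batch = pd.Series(rng.choice(["b1", "b2", "b3"], size=12),
                          index=d.sample_ids)
        out = ss.regress_out_batch(d, batch)
        resid = out.values.to_numpy() - out.values.to_numpy().mean(
            axis=1, keepdims=True)
        for lev in ("b1", "b2", "b3"):
            ind = (batch == lev).to_numpy(dtype=float)
            ind -= ind.mean()
            assert np.abs(resid @ ind).max() < 1e-8

    def test_tiny_batch_level_rejected(self):
        d = _delta(np.ones((3, 4)) + np.arange(4.0))
        batch = pd.Series(["b1", "b1", "b1", "b2"], index=d.sample_ids)
        with pytest.raises(ValueError):
            ss.regress_out_batch(d, batch)


class TestPCA:
    def test_rank_one_spectrum(self):
        u = np.array([1.0, -2.0, 0.5, 3.0, 1.5])
        v = np.array([1.0, 2.0, -1.0, 0.5])
        pca = ss.pca_samples(_delta(np.outer(u, v)))
        assert pca.variance_explained[0] == pytest.approx(1.0)
        assert np.all(pca.variance_explained[1:] < 1e-12)

    def test_variance_shares_sum_to_one(self):
        d = _delta(np.random.default_rng(6).normal(size=(30, 8)))
        assert ss.pca_samples(d).variance_explained.sum() == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(7)
        m = rng.normal(size=(100, 20))
        d = _delta(m)
        pca = ss.pca_samples(d)
        mc = m - m.mean(axis=1, keepdims=True)
        cov = mc.T @ mc / (m.shape[0] - 1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(pca.variance_explained,
                                   (eig / eig.sum())[:len(pca.variance_explained)],
                                   atol=1e-8)

    def test_scores_orthogonal(self):
        d = _delta(np.random.default_rng(8).normal(size=(40, 10)))
        s = ss.pca_samples(d).scores.to_numpy()
        gram = s.T @ s
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() / np.abs(np.diag(gram)).max() < 1e-6


class TestSelectNPcs:
    @pytest.mark.parametrize("ve,expected", [
        ([0.10, 0.02, 0.004, 0.003], 2),
        ([0.02] * 30, 25),          # capped at 25
        ([0.004, 0.003], 0),
        ([0.005, 0.005, 0.004], 2),  # threshold is inclusive
    ])
    def test_rule(self, ve, expected):
        assert ss.select_n_pcs(ve) == expected


class TestRemovePcs:
    def test_k_zero_is_quantile_normalization_only(self):
        d = _delta(np.random.default_rng(9).normal(size=(20, 6)))
        pca = ss.pca_samples(d)
        out = ss.remove_pcs(d, pca, 0)
        pd.testing.assert_frame_equal(out.values,
                                      ss.quantile_normalize(d).values)
        assert out.n_pcs_removed == 0 and out.quantile_normalized

    def test_rank_one_killed_by_first_component(self):
        u = np.array([1.0, -2.0, 0.5, 3.0])
        v = np.array([1.0, 2.0, -1.0, 0.5, 2.5])
        d = _delta(np.outer(u, v))
        out = ss.remove_pcs(d, ss.pca_samples(d), 1, renormalize=False)
        assert np.abs(out.values.to_numpy()).max() < 1e-8

    def test_residuals_orthogonal_to_removed_scores(self):
        d = _delta(np.random.default_rng(10).normal(size=(30, 10)))
        pca = ss.pca_samples(d)
        out = ss.remove_pcs(d, pca, 3, renormalize=False)
        resid = out.values.to_numpy()
        dots = resid @ pca.scores.to_numpy()[:, :3]
        assert np.abs(dots).max() < 1e-8

    def test_removal_reduces_leading_variance_shares(self, small_delta):
        pca = ss.pca_samples(small_delta)
        k = 3
        out = ss.remove_pcs(small_delta, pca, k)
        post = ss.pca_samples(out).variance_explained
        assert np.all(post[:k] < pca.variance_explained[k - 1])

    def test_negative_k_rejected(self, small_delta):
        with pytest.raises(ValueError):
            ss.remove_pcs(small_delta, ss.pca_samples(small_delta), -1)


class TestSweep:
    def test_sweep_cardinality_and_provenance(self, small_delta):
        datasets = ss.pc_correction_sweep(small_delta, 5)
        assert len(datasets) == 5
        assert [d.n_pcs_removed for d in datasets] == [1, 2, 3, 4, 5]
        for d in datasets:
            assert list(d.gene_ids) == list(small_delta.gene_ids)
            assert list(d.sample_ids) == list(small_delta.sample_ids)
            assert d.quantile_normalized

    def test_single_step_matches_remove_pcs(self, small_delta):
        pca = ss.pca_samples(small_delta)
        sweep = ss.pc_correction_sweep(small_delta, 1, pca)
        direct = ss.remove_pcs(small_delta, pca, 1)
        pd.testing.assert_frame_equal(sweep[0].values, direct.values)


class TestDiagnostics:
    def test_covariate_equal_to_pc1(self, small_delta, small_study):
        pca = ss.pca_samples(small_delta)
        ph = small_study.phenotypes.copy()
        ph["probe"] = pca.scores.iloc[:, 0].reindex(ph.sample_id).to_numpy()
        diag = ss.pc_covariate_diagnostics(pca, ph, n_pcs=3,
                                           covariates=["probe"])
        row = diag[(diag.pc == "PC1") & (diag.covariate == "probe")]
        assert abs(row.statistic.iloc[0]) == pytest.approx(1.0)

    def test_constant_covariate_flagged(self, small_delta, small_study):
        pca = ss.pca_samples(small_delta)
        ph = small_study.phenotypes.copy()
        ph["flat"] = 1.0
        diag = ss.pc_covariate_diagnostics(pca, ph, n_pcs=2,
                                           covariates=["flat"])
        assert diag.undefined.all() and diag.p.isna().all()

    def test_null_covariate_false_positive_rate(self):
        rng = np.random.default_rng(11)
        hits = total = 0
        for _ in range(200):
            d = _delta(rng.normal(size=(80, 30)))
            pca = ss.pca_samples(d)
            ph = pd.DataFrame({"sample_id": d.sample_ids,
                               "noise": rng.normal(size=30)})
            diag = ss.pc_covariate_diagnostics(pca, ph, n_pcs=20,
                                               covariates=["noise"])
            hits += (diag.p < 0.05).sum()
            total += len(diag)
        assert 0.03 < hits / total < 0.07

    def test_correction_removes_covariate_structure(self):
        """Confounder-driven data: after removing k PCs the PCs decouple."""
        cfg = ss.SimulationConfig(n_genes=500, n_signature=5, effect_size=0.0,
                                  n_background_samples=120,
                                  covariate_confounder_corr=0.9, seed=13)
        study = ss.simulate_study(cfg)
        e = study.expression
        delta = ss.compute_delta(e.statin, e.control)
        pca = ss.pca_samples(delta)
        before = ss.pc_covariate_diagnostics(pca, study.phenotypes, n_pcs=5,
                                             covariates=["age"])
        corrected = ss.remove_pcs(delta, pca, 5)
        after = ss.pc_covariate_diagnostics(
            ss.pca_samples(corrected), study.phenotypes, n_pcs=5,
            covariates=["age"])
        assert before.statistic.abs().max() > 0.4  # structure was there
        assert after.statistic.abs().max() < 0.2   # and is gone


class TestPCCorrectorEstimator:
    def test_sklearn_roundtrip(self, small_delta):
        from sklearn.base import clone
        X = small_delta.values.to_numpy().T
        est = ss.PCCorrector(n_pcs=3)
        clone(est)  # get_params/set_params contract
        Xt = est.fit_transform(X)
        assert Xt.shape == X.shape
        assert est.n_pcs_ == 3
        direct = ss.remove_pcs(small_delta, ss.pca_samples(small_delta), 3)
        np.testing.assert_allclose(Xt, direct.values.to_numpy().T, atol=1e-8)

    def test_rule_based_selection(self, small_delta):
        est = ss.PCCorrector().fit(small_delta.values.to_numpy().T)
        assert est.n_pcs_ == ss.select_n_pcs(est.variance_explained_)

    def test_transform_requires_fitted_matrix(self, small_delta):
        X = small_delta.values.to_numpy().T
        est = ss.PCCorrector(n_pcs=2).fit(X)
        with pytest.raises(ValueError):
            est.transform(X[:10])
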