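import numpy as np
import pandas as pd
import pytest
from scipy import stats

from deepdr import model as dm
from deepdr import pretraining as pt
from deepdr.exceptions import ValidationError
from deepdr.neural_core import TrainConfig, forward, he_uniform_init


@pytest.fixture(scope="module")
def encoders():
    menc = he_uniform_init([40, 16, 8], seed=1)
    eenc = he_uniform_init([60, 16, 8], seed=2)
    return menc, eenc


class TestAssembleModel:
    def test_head_dims_chain_from_concatenated_bottlenecks(self, encoders):
        menc, eenc = encoders
        m = dm.assemble_model(menc, eenc, n_drugs=12, seed=0, head_hidden=(32, 32, 32))
        assert m.head.dims == [16, 32, 32, 32, 12]

    def test_transfer_is_copy(self, encoders):
        menc, eenc = encoders
        m = dm.assemble_model(menc, eenc, n_drugs=5, seed=0)
        np.testing.assert_array_equal(m.menc.layers[0].W, menc.layers[0].W)
        m.menc.layers[0].W += 1.0  # mutating the model must not touch the archive
        assert not np.array_equal(m.menc.layers[0].W, menc.layers[0].W)

    def test_parameter_count_matches_closed_form(self, encoders):
        menc, eenc = encoders
        m = dm.assemble_model(menc, eenc, n_drugs=7, seed=0, head_hidden=(32, 32, 32))
        def count(dims):
            return sum(fi * fo + fo for fi, fo in zip(dims, dims[1:]))
        expected = count([40, 16, 8]) + count([60, 16, 8]) + count([16, 32, 32, 32, 7])
        assert m.n_params() == expected

    def test_invalid_drug_count_rejected(self, encoders):
        with pytest.raises(ValidationError):
            dm.assemble_model(*encoders, n_drugs=0, seed=0)


class TestSplitSamples:
    def test_ten_samples_default_fractions(self):
        split = dm.split_samples([f"s{i}" for i in range(10)], seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (8, 1, 1)

    def test_deterministic_given_seed(self):
        ids = [f"s{i}" for i in range(25)]
        assert dm.split_samples(ids, seed=3) == dm.split_samples(ids, seed=3)
        assert dm.split_samples(ids, seed=3) != dm.split_samples(ids, seed=4)

    def test_622_samples_test_size(self):
        split = dm.split_samples([f"s{i}" for i in range(622)], seed=1)
        assert len(split.test) in (62, 63)
        assert len(split.train) + len(split.val) + len(split.test) == 622

    def test_disjoint_union(self):
        ids = [f"s{i}" for i in range(37)]
        split = dm.split_samples(ids, seed=5)
        assert set(split.train) | set(split.val) | set(split.test) == set(ids)
        assert not set(split.train) & set(split.test)

    def test_empty_set_after_rounding_rejected(self):
        with pytest.raises(ValidationError):
            dm.split_samples(["a", "b", "c"], seed=0)


class TestTrainPredict:
    def test_constant_targets_learned_via_bias(self, small_cohort, imputed_response):
        c = small_cohort
        const = pd.DataFrame(
            2.5, index=imputed_response.index, columns=imputed_response.columns
        )
        menc = he_uniform_init([40, 16, 8], seed=1)
        eenc = he_uniform_init([60, 16, 8], seed=2)
        m = dm.assemble_model(menc, eenc, const.shape[0], seed=3, head_hidden=(16, 16, 16))
        split = dm.split_samples(const.columns, seed=4)
        cfg = TrainConfig(max_epochs=60, learning_rate=3e-3, seed=5)
        _, report = dm.train_deepdr(m, c.mutation, c.expression, const, split, cfg)
        zero_predictor_mse = float((const.to_numpy() ** 2).mean())
        assert report.mse < zero_predictor_mse

    def test_prediction_composition_oracle(self, small_cohort, imputed_response):
        # predictions must equal head(concat(encode(M), encode(E))) recomputed
        # independently layer by layer
        c = small_cohort
        menc = he_uniform_init([40, 16, 8], seed=6)
        eenc = he_uniform_init([60, 16, 8], seed=7)
        m = dm.assemble_model(menc, eenc, 12, seed=8, head_hidden=(16, 16, 16))
        pred = dm.predict_ic50(m, c.mutation, c.expression)
        Xm = c.mutation.to_numpy(dtype=float).T
        Xe = c.expression.to_numpy(dtype=float).T
        H = np.concatenate([pt.encode(m.menc, Xm), pt.encode(m.eenc, Xe)], axis=1)
        expected = forward(m.head, H).T
        np.testing.assert_allclose(pred.to_numpy(), expected, atol=1e-10)
        assert pred.shape == (12, c.mutation.shape[1])

    def test_identical_samples_identical_predictions(self, small_cohort):
        c = small_cohort
        m = dm.assemble_model(
            he_uniform_init([40, 8], seed=0), he_uniform_init([60, 8], seed=1),
            5, seed=2, head_hidden=(8,),
        )
        M2 = pd.concat([c.mutation.iloc[:, [0]], c.mutation.iloc[:, [0]]], axis=1)
        E2 = pd.concat([c.expression.iloc[:, [0]], c.expression.iloc[:, [0]]], axis=1)
        M2.columns = E2.columns = ["a", "b"]
        pred = dm.predict_ic50(m, M2, E2)
        np.testing.assert_array_equal(pred["a"], pred["b"])

    def test_gene_mismatch_lists_missing(self, small_cohort):
        c = small_cohort
        m = dm.assemble_model(
            he_uniform_init([40, 8], seed=0), he_uniform_init([60, 8], seed=1),
            5, seed=2, head_hidden=(8,),
            mut_genes=list(c.mutation.index), expr_genes=list(c.expression.index),
        )
        with pytest.raises(ValidationError, match="lacks"):
            dm.predict_ic50(m, c.mutation.iloc[5:], c.expression)

    def test_test_rows_never_influence_parameters(self, small_cohort, imputed_response):
        # shuffling the response values of test samples must leave the trained
        # parameters identical under a fixed seed
        c = small_cohort
        split = dm.split_samples(imputed_response.columns, seed=11)
        cfg = TrainConfig(max_epochs=3, seed=12)

        def train_once(ic):
            m = dm.assemble_model(
                he_uniform_init([40, 16, 8], seed=1),
                he_uniform_init([60, 16, 8], seed=2),
                12, seed=3, head_hidden=(16, 16, 16),
            )
            m, _ = dm.train_deepdr(m, c.mutation, c.expression, ic, split, cfg)
            return m

        ic_perturbed = imputed_response.copy()
        ic_perturbed.loc[:, list(split.test)] = (
            ic_perturbed.loc[:, list(split.test)].to_numpy()[:, ::-1]
        )
        a = train_once(imputed_response)
        b = train_once(ic_perturbed)
        np.testing.assert_array_equal(a.head.layers[0].W, b.head.layers[0].W)
        np.testing.assert_array_equal(a.menc.layers[0].W, b.menc.layers[0].W)

    def test_save_load_round_trip(self, tmp_path):
        m = dm.assemble_model(
            he_uniform_init([10, 4], seed=0), he_uniform_init([12, 4], seed=1),
            3, seed=2, head_hidden=(8,), mut_genes=[f"g{i}" for i in range(10)],
        )
        dm.save_model(m, tmp_path)
        back = dm.load_model(tmp_path)
        np.testing.assert_array_equal(back.head.layers[0].W, m.head.layers[0].W)
        assert back.mut_genes == m.mut_genes


class TestComputeMetrics:
    def _random_pair(self):
        rng = np.random.default_rng(21)
        idx = [f"d{i}" for i in range(5)]
        cols = [f"s{j}" for j in range(4)]
        return (
            pd.DataFrame(rng.normal(size=(5, 4)), index=idx, columns=cols),
            pd.DataFrame(rng.normal(size=(5, 4)), index=idx, columns=cols),
        )

    def test_perfect_prediction(self):
        pred, _ = self._random_pair()
        rep = dm.compute_metrics(pred, pred.copy())
        assert rep.mse == 0
        assert np.allclose(rep.pearson, 1.0)
        assert np.allclose(rep.spearman, 1.0)

    def test_rank_reversal_gives_minus_one_spearman(self):
        pred, _ = self._random_pair()
        rep = dm.compute_metrics(pred, -pred)
        assert np.allclose(rep.spearman, -1.0)

    def test_matches_textbook_formulas(self):
        pred, truth = self._random_pair()
        rep = dm.compute_metrics(pred, truth)
        P, T = pred.to_numpy(), truth.to_numpy()
        assert rep.mse == pytest.approx(((P - T) ** 2).mean(), abs=1e-12)
        for j, col in enumerate(pred.columns):
            p, t = P[:, j], T[:, j]
            r_manual = ((p - p.mean()) * (t - t.mean())).sum() / np.sqrt(
                ((p - p.mean()) ** 2).sum() * ((t - t.mean()) ** 2).sum()
            )
            assert rep.pearson[col] == pytest.approx(r_manual, abs=1e-12)
            rp = stats.rankdata(p)
            rt = stats.rankdata(t)
            rs_manual = np.corrcoef(rp, rt)[0, 1]
            assert rep.spearman[col] == pytest.approx(rs_manual, abs=1e-12)

    def test_symmetry(self):
        pred, truth = self._random_pair()
        a = dm.compute_metrics(pred, truth)
        b = dm.compute_metrics(truth, pred)
        assert a.mse == pytest.approx(b.mse)
        pd.testing.assert_series_equal(a.pearson, b.pearson)

    def test_zero_variance_sample_reported_missing(self):
        pred = pd.DataFrame([[1.0, 1.0], [1.0, 2.0]], columns=["a", "b"])
        truth = pd.DataFrame([[1.0, 3.0], [2.0, 4.0]], columns=["a", "b"])
        rep = dm.compute_metrics(pred, truth)
        assert np.isnan(rep.pearson["a"])
        assert not np.isnan(rep.pearson["b"])


class TestPcaEncoder:
    def test_rank1_first_component_explains_everything(self):
        rng = np.random.default_rng(5)
        X = np.outer(rng.normal(size=50), rng.normal(size=20))
        proj = dm.pca_encoder(X, n_components=1)
        Z = proj.transform(X)
        recon = proj.inverse_transform(Z)
        assert np.abs(recon - X).max() < 1e-8

    def test_components_orthogonal_in_sample_covariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 10))
        Z = dm.pca_encoder(X, n_components=4).transform(X)
        cov = np.cov(Z.T)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8

    def test_reconstruction_error_equals_trailing_eigenvalues(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(80, 12))
        k = 5
        proj = dm.pca_encoder(X, n_components=k)
        recon = proj.inverse_transform(proj.transform(X))
        err = ((X - recon) ** 2).sum() / (X.shape[0] - 1)
        eig = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        assert err == pytest.approx(eig[k:].sum(), rel=1e-8)

    def test_components_beyond_rank_rejected(self):
        X = np.outer(np.arange(10.0), np.arange(6.0))  # rank 1
        with pytest.raises(ValidationError):
            dm.pca_encoder(X, n_components=3)


class TestBenchmark:
    @pytest.fixture(scope="class")
    def tiny_benchmark(self, small_cohort, imputed_response):
        c = small_cohort
        menc = he_uniform_init([40, 16, 8], seed=31)
        eenc = he_uniform_init([60, 16, 8], seed=32)
        cfg = TrainConfig(max_epochs=3, patience=3)
        return dm.run_benchmark(
            c.mutation, c.expression, imputed_response, menc, eenc,
            n_iter=1, seed=33, train_cfg=cfg, head_hidden=(16, 16, 16),
            pca_components=8,
        )

    def test_one_row_per_model(self, tiny_benchmark):
        counts = tiny_benchmark.per_iteration.groupby("model").size()
        assert set(counts.index) == set(dm.BENCHMARK_MODELS)
        assert (counts == 1).all()

    def test_medians_reproducible_from_stored_iterations(self, tiny_benchmark):
        summary = tiny_benchmark.summary()
        for model_name in dm.BENCHMARK_MODELS:
            rows = tiny_benchmark.per_iteration.query("model == @model_name")
            assert summary.loc[model_name, "median_test_mse"] == rows["test_mse"].median()

    def test_median_of_odd_count_is_middle_order_statistic(self):
        vals = pd.Series([3.0, 1.0, 2.0])
        assert vals.median() == 2.0  # convention used by BenchmarkTable

    def test_invalid_n_iter_rejected(self, small_cohort, imputed_response):
        with pytest.raises(ValidationError):
            dm.run_benchmark(
                small_cohort.mutation, small_cohort.expression, imputed_response,
                he_uniform_init([40, 8], seed=0), he_uniform_init([60, 8], seed=1),
                n_iter=0,
            )
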