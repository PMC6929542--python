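"""KNN cold-start fill, RLS scoring, and the composed DDIGIP pipeline."""

import numpy as np
import pytest

from ddigip import (
    DdigipModel,
    DdigipParams,
    DrugIndex,
    FeatureMatrix,
    InteractionMatrix,
    KernelMatrix,
    ddigip_predict,
    gip_kernel,
    knn_fill,
    pearson_similarity,
    rls_scores,
)
from ddigip.errors import InvalidParameterError

from conftest import random_interactions, random_psd_kernel


def _interactions(y):
    n = len(y)
    return InteractionMatrix(
        np.array(y, dtype=float), DrugIndex.from_ids(f"d{i}" for i in range(n)),
        binary=bool(np.isin(np.array(y), (0, 1)).all()),
    )


def _pearson_kernel(values, degenerate=None):
    n = len(values)
    return KernelMatrix(
        np.array(values, dtype=float),
        DrugIndex.from_ids(f"d{i}" for i in range(n)),
        kind="pearson",
        degenerate=degenerate,
    )


class TestKnnFill:
    def _setup(self, sims):
        """Drug 0 is new; drugs 1, 2 interact with drug 3."""
        y = _interactions(
            [[0, 0, 0, 0], [0, 0, 0, 1], [0, 0, 0, 1], [0, 1, 1, 0]]
        )
        s = np.eye(4)
        for j, v in sims.items():
            s[0, j] = s[j, 0] = v
        return y, _pearson_kernel(s)

    def test_single_neighbor_weight_cancels(self):
        y, s = self._setup({1: 0.8})
        filled = knn_fill(y, s, K=1)
        assert filled.values[0, 3] == pytest.approx(1.0)
        assert filled.values[3, 0] == pytest.approx(1.0)

    def test_weighted_average(self):
        # neighbors: sim 0.8 with y_13=1, sim 0.2 with y_23=0
        y = _interactions(
            [[0, 0, 0, 0], [0, 0, 0, 1], [0, 0, 0, 0], [0, 1, 0, 0]]
        )
        s = np.eye(4)
        s[0, 1] = s[1, 0] = 0.8
        s[0, 2] = s[2, 0] = 0.2
        # make drug 2 eligible (it needs an interaction): link it to drug 1
        y.values[1, 2] = y.values[2, 1] = 1.0
        filled = knn_fill(y, _pearson_kernel(s), K=2)
        assert filled.values[0, 3] == pytest.approx(0.8 * 1 / (0.8 + 0.2))

    def test_rows_with_interactions_unchanged(self):
        y, s = self._setup({1: 0.9, 2: 0.5})
        filled = knn_fill(y, s, K=2)
        np.testing.assert_array_equal(filled.values[1:, 1:], y.values[1:, 1:])

    def test_fewer_than_k_neighbors_warns_and_uses_all(self):
        y, s = self._setup({1: 0.9})
        with pytest.warns(UserWarning, match="eligible neighbours"):
            filled = knn_fill(y, s, K=50)
        assert filled.values[0].sum() > 0

    def test_nonpositive_denominator_leaves_row_zero(self):
        y, s = self._setup({1: -0.5, 2: -0.1, 3: -0.9})
        with pytest.warns(UserWarning, match="non-positive"):
            filled = knn_fill(y, s, K=3)
        assert filled.values[0].sum() == 0

    def test_missing_features_skip_fill(self):
        y, s = self._setup({1: 0.9})
        missing = np.array([True, False, False, False])
        with pytest.warns(UserWarning, match="missing/degenerate"):
            filled = knn_fill(y, s, K=1, feature_missing=missing)
        assert filled.values[0].sum() == 0

    def test_filled_values_convex_when_similarities_positive(self):
        rng = np.random.default_rng(3)
        y = random_interactions(rng, 15)
        y.values[0, :] = y.values[:, 0] = 0.0  # make drug 0 new
        s = np.abs(random_psd_kernel(rng, 15))
        filled = knn_fill(y, _pearson_kernel(s), K=4)
        row = filled.values[0]
        assert ((row >= 0) & (row <= 1)).all()

    def test_two_new_drugs_filled_symmetrically(self):
        y = _interactions(
            [[0] * 5, [0] * 5, [0, 0, 0, 1, 0], [0, 0, 1, 0, 1], [0, 0, 0, 1, 0]]
        )
        s = np.full((5, 5), 0.5)
        np.fill_diagonal(s, 1.0)
        filled = knn_fill(y, _pearson_kernel(s), K=2)
        np.testing.assert_allclose(filled.values, filled.values.T)
        assert (np.diag(filled.values) == 0).all()


class TestRlsScores:
    def _kernel(self, g):
        n = len(g)
        return KernelMatrix(np.array(g, dtype=float),
                            DrugIndex.from_ids(f"d{i}" for i in range(n)), kind="gip")

    def test_identity_kernel_halves_labels(self):
        rng = np.random.default_rng(0)
        y = random_interactions(rng, 6)
        g = self._kernel(np.eye(6))
        out = rls_scores(g, y, sigma=1.0)
        np.testing.assert_allclose(out.values, y.values / 2.0, atol=1e-12)

    def test_two_drug_hand_value(self, two_drug_network):
        a = np.exp(-2)
        g = self._kernel([[1.0, a], [a, 1.0]])
        out = rls_scores(g, two_drug_network, sigma=1.0)
        expected = (2 - np.exp(-4)) / (4 - np.exp(-4))
        assert out.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_zero_labels_give_zero_scores(self):
        idx = DrugIndex.from_ids(["a", "b", "c"])
        y = InteractionMatrix(np.zeros((3, 3)), idx)
        g = KernelMatrix(np.eye(3), idx, kind="gip")
        assert rls_scores(g, y, sigma=2.0).values.sum() == 0

    def test_sigma_must_be_positive(self, two_drug_network):
        g = self._kernel(np.eye(2))
        with pytest.raises(InvalidParameterError):
            rls_scores(g, two_drug_network, sigma=0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_explicit_inverse_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        g = random_psd_kernel(rng, n)
        y = random_interactions(rng, n)
        gk = KernelMatrix(g, y.drug_index, kind="gip")
        ours = rls_scores(gk, y, sigma=1.0).values
        y_hat = g @ np.linalg.inv(g + np.eye(n)) @ y.values
        oracle = (y_hat + y_hat.T) / 2.0
        np.testing.assert_allclose(ours, oracle, rtol=1e-8, atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_spectral_shrinkage(self, seed):
        """Eigenvalues of G(G+sI)^-1 lie in [0,1) so scores shrink in norm."""
        rng = np.random.default_rng(40 + seed)
        n = 12
        g = random_psd_kernel(rng, n)
        y = random_interactions(rng, n)
        gk = KernelMatrix(g, y.drug_index, kind="gip")
        out = rls_scores(gk, y, sigma=1.0).values
        eig = np.linalg.eigvalsh(g)
        shrink = eig / (eig + 1.0)
        assert (shrink >= -1e-10).all() and (shrink < 1.0).all()
        assert np.linalg.norm(out) <= np.linalg.norm(y.values) + 1e-10

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_regularization(self, seed):
        rng = np.random.default_rng(70 + seed)
        n = 10
        g = random_psd_kernel(rng, n)
        y = random_interactions(rng, n)
        gk = KernelMatrix(g, y.drug_index, kind="gip")
        norm1 = np.linalg.norm(rls_scores(gk, y, sigma=0.5).values)
        norm2 = np.linalg.norm(rls_scores(gk, y, sigma=2.0).values)
        assert norm2 <= norm1 + 1e-10


class TestDdigipPredict:
    def test_no_new_drugs_fill_is_noop(self):
        rng = np.random.default_rng(1)
        y = random_interactions(rng, 10, p=0.5)
        assert (y.degrees() > 0).all()
        feats = FeatureMatrix((rng.random((10, 20)) < 0.5).astype(float), y.drug_index)
        with_features = ddigip_predict(y, feats, DdigipParams())
        plain = rls_scores(gip_kernel(y), y, sigma=1.0)
        np.testing.assert_allclose(with_features.values, plain.values, atol=1e-12)

    def test_worked_example_end_to_end(self, two_drug_network):
        out = ddigip_predict(two_drug_network)
        expected = (2 - np.exp(-4)) / (4 - np.exp(-4))
        assert out.values[0, 1] == pytest.approx(expected, abs=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        y = random_interactions(rng, 12)
        perm = rng.permutation(12)
        y_perm = InteractionMatrix(
            y.values[np.ix_(perm, perm)],
            DrugIndex.from_ids(y.drug_index.ids[p] for p in perm),
        )
        out = ddigip_predict(y).values
        out_perm = ddigip_predict(y_perm).values
        np.testing.assert_allclose(out_perm, out[np.ix_(perm, perm)], atol=1e-10)

    def test_cold_start_uses_knn(self, synth_default):
        """A new drug gets informative scores only through the feature fill."""
        y, feats, _ = synth_default
        y2 = y.copy()
        y2.values[0, :] = y2.values[:, 0] = 0.0
        scores_knn = ddigip_predict(y2, feats, DdigipParams())
        scores_raw = ddigip_predict(y2, params=DdigipParams(knn_enabled=False))
        # with the fill, true partners of drug 0 outrank its non-partners
        from ddigip import auc_rank
        others = np.arange(y.n_drugs) != 0
        pos = scores_knn.values[0, others & (y.values[0] == 1)]
        neg = scores_knn.values[0, others & (y.values[0] == 0)]
        pos_raw = scores_raw.values[0, others & (y.values[0] == 1)]
        neg_raw = scores_raw.values[0, others & (y.values[0] == 0)]
        assert auc_rank(pos, neg) > auc_rank(pos_raw, neg_raw)


class TestModelApi:
    def test_fit_returns_results_with_summary(self, synth_default):
        y, feats, _ = synth_default
        model = DdigipModel(y, feats)
        res = model.fit()
        assert res.prediction.values.shape == (y.n_drugs, y.n_drugs)
        text = res.summary()
        assert "drugs:" in text and "sigma:" in text
        top = res.top_pairs(5)
        assert list(top.columns) == ["rank", "drug_id_1", "drug_id_2", "score"]
        assert (top["score"].diff().dropna() <= 0).all()

    def test_from_files_roundtrip(self, tmp_path, synth_default):
        from ddigip import write_edge_list
        from ddigip.cli import _write_feature_table

        y, feats, _ = synth_default
        ep = str(tmp_path / "e.tsv")
        fp = str(tmp_path / "f.tsv")
        write_edge_list(y, ep)
        _write_feature_table(feats, fp)
        model = DdigipModel.from_files(ep, fp)
        np.testing.assert_array_equal(model.interactions.values, y.values)
        np.testing.assert_array_equal(model.features.values, feats.values)

    def test_misaligned_inputs_are_aligned(self):
        idx_y = DrugIndex.from_ids(["A", "B"])
        y = InteractionMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), idx_y)
        feats = FeatureMatrix(
            np.array([[1.0, 0.0], [0.0, 1.0]]), DrugIndex.from_ids(["B", "C"])
        )
        model = DdigipModel(y, feats)
        assert model.interactions.drug_index.ids == ("A", "B", "C")
        assert model.features.missing[0]
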