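import numpy as np
import pytest

from sclstm import nn
from sclstm.io import ValidationError
from sclstm.kernel import TANH1, KernelMatrix, kernel_embedding
from sclstm.metrics import ari
from sclstm.clustering import agglomerative_from_similarity
from sclstm.siamese import (
    PairSet,
    SiameseConfig,
    TrainedPairScorer,
    _init_params,
    derive_pseudo_labels,
    embed_single_branch,
    generate_pairs,
    score_all_pairs,
    train_siamese,
)
from sclstm.synthetic import simulate_counts

from .conftest import block_similarity, fast_siamese_config, separable_spec


def block_kernel(sizes, within=0.7, between=0.05):
    M, labels = block_similarity(sizes, within, between)
    np.fill_diagonal(M, TANH1)
    M[M == 1.0] = within
    np.fill_diagonal(M, TANH1)
    return KernelMatrix(values=M, cell_ids=[f"c{i}" for i in range(len(labels))]), labels


@pytest.fixture(scope="module")
def trained_on_blocks():
    S, truth = block_kernel([10, 10])
    cfg = fast_siamese_config(seed=0, epochs=40, pairs_per_cell=8)
    pairs = generate_pairs(truth, cfg, np.random.default_rng(0))
    scorer = train_siamese(S, pairs, cfg)
    return S, truth, cfg, scorer


class TestBackprop:
    def test_lstm_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        params = nn.init_lstm_params(3, 4, rng)
        X = rng.random((5, 6, 3))
        w = rng.random(4)  # scalar loss L = sum(h_final @ w)

        h, cache = nn.lstm_forward(X, params)
        grads = nn.lstm_backward(np.tile(w, (5, 1)), cache, params)

        eps = 1e-6
        for key in ("Wx", "Wh", "b"):
            flat = params[key].ravel()
            for idx in rng.choice(flat.size, size=8, replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = float(np.sum(nn.lstm_forward(X, params)[0] @ w))
                flat[idx] = orig - eps
                lm = float(np.sum(nn.lstm_forward(X, params)[0] @ w))
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert grads[key].ravel()[idx] == pytest.approx(
                    numeric, rel=1e-5, abs=1e-8
                ), key


class TestPseudoLabels:
    def test_two_blocks_recovered(self):
        S, truth = block_kernel([6, 5])
        labels = derive_pseudo_labels(S, 2)
        assert ari(truth, labels) == 1.0

    def test_k0_n_minus_1_one_shared_pair(self):
        rng = np.random.default_rng(1)
        A = rng.random((8, 8)) * 0.5
        M = (A + A.T) / 2
        np.fill_diagonal(M, TANH1)
        S = KernelMatrix(M, [f"c{i}" for i in range(8)])
        labels = derive_pseudo_labels(S, 7)
        counts = np.bincount(labels)
        assert sorted(counts.tolist()) == [1] * 6 + [2]

    def test_permutation_equivariance(self):
        S, truth = block_kernel([5, 4, 3])
        perm = np.random.default_rng(2).permutation(12)
        Sp = KernelMatrix(S.values[np.ix_(perm, perm)],
                          [S.cell_ids[i] for i in perm])
        a = derive_pseudo_labels(S, 3)
        b = derive_pseudo_labels(Sp, 3)
        assert ari(a[perm], b) == 1.0

    def test_k0_out_of_range(self):
        S, _ = block_kernel([3, 3])
        with pytest.raises(ValueError):
            derive_pseudo_labels(S, 6)


class TestGeneratePairs:
    def test_counts_and_validity(self):
        labels = np.array(["A", "A", "B", "B"])
        cfg = fast_siamese_config(pairs_per_cell=2)
        pairs = generate_pairs(labels, cfg, np.random.default_rng(0))
        assert len(pairs) == 8
        pos = [(i, j) for i, j, y in pairs.pairs if y == 1]
        neg = [(i, j) for i, j, y in pairs.pairs if y == 0]
        assert len(pos) == 4 and len(neg) == 4
        for i, j in pos:
            assert labels[i] == labels[j] and i != j
        for i, j in neg:
            assert labels[i] != labels[j]

    def test_all_singletons_error(self):
        cfg = fast_siamese_config()
        with pytest.raises(ValidationError, match="singleton"):
            generate_pairs(np.array([0, 1, 2, 3]), cfg, np.random.default_rng(0))

    def test_one_class_error(self):
        cfg = fast_siamese_config()
        with pytest.raises(ValidationError):
            generate_pairs(np.array([1, 1, 1]), cfg, np.random.default_rng(0))

    def test_singleton_classes_skipped_for_positives(self):
        labels = np.array([0, 0, 0, 1])  # class 1 cannot give positives
        cfg = fast_siamese_config(pairs_per_cell=5)
        pairs = generate_pairs(labels, cfg, np.random.default_rng(0))
        for i, j, y in pairs.pairs:
            if y == 1:
                assert labels[i] == labels[j] == 0

    def test_deterministic_given_seed(self):
        labels = np.repeat([0, 1, 2], 5)
        cfg = fast_siamese_config(seed=5)
        a = generate_pairs(labels, cfg, np.random.default_rng(5))
        b = generate_pairs(labels, cfg, np.random.default_rng(5))
        assert a.pairs == b.pairs


class TestPairSet:
    def test_self_pair_rejected(self):
        with pytest.raises(ValidationError):
            PairSet([(1, 1, 1)])

    def test_conflicting_duplicate_rejected(self):
        with pytest.raises(ValidationError):
            PairSet([(0, 1, 1), (1, 0, 0)])

    def test_consistent_duplicate_allowed(self):
        ps = PairSet([(0, 1, 1), (1, 0, 1)])
        assert len(ps) == 2


class TestTraining:
    def test_loss_decreases_on_separable_input(self, trained_on_blocks):
        *_, scorer = trained_on_blocks
        assert scorer.epoch_losses[-1] < scorer.epoch_losses[0]

    def test_within_exceeds_between(self, trained_on_blocks):
        S, truth, _, scorer = trained_on_blocks
        M = score_all_pairs(scorer, S).values
        same = truth[:, None] == truth[None, :]
        off = ~np.eye(len(truth), dtype=bool)
        assert M[same & off].mean() > M[~same].mean()

    def test_untrained_scorer_deterministic(self):
        cfg = fast_siamese_config(seed=3)
        params = _init_params(cfg, np.random.default_rng(cfg.seed))
        scorer = TrainedPairScorer(params, cfg, n_cells=6)
        S, _ = block_kernel([3, 3])
        assert scorer.score(0, 4, S) == scorer.score(0, 4, S)

    def test_empty_pairs_error(self):
        S, _ = block_kernel([3, 3])
        with pytest.raises(ValidationError):
            train_siamese(S, PairSet([]), fast_siamese_config())

    def test_training_bit_deterministic(self):
        S, truth = block_kernel([6, 6])
        cfg = fast_siamese_config(seed=7, epochs=5)
        runs = []
        for _ in range(2):
            pairs = generate_pairs(truth, cfg, np.random.default_rng(cfg.seed))
            scorer = train_siamese(S, pairs, cfg)
            runs.append(score_all_pairs(scorer, S).values)
        np.testing.assert_array_equal(runs[0], runs[1])


class TestScoreAllPairs:
    def test_symmetric_unit_diagonal(self, trained_on_blocks):
        S, *_ , scorer = trained_on_blocks
        M = score_all_pairs(scorer, S).values
        np.testing.assert_allclose(M, M.T, atol=0)
        np.testing.assert_array_equal(np.diag(M), 1.0)
        assert M.min() >= 0.0 and M.max() <= 1.0

    def test_n2_single_off_diagonal(self):
        vals = np.array([[TANH1, 0.3], [0.3, TANH1]])
        S = KernelMatrix(vals, ["a", "b"])
        cfg = fast_siamese_config(epochs=2)
        pairs = PairSet([(0, 1, 0)])
        scorer = train_siamese(S, pairs, cfg)
        M = score_all_pairs(scorer, S).values
        assert M[0, 1] == M[1, 0]

    def test_wrong_n_rejected(self, trained_on_blocks):
        *_, scorer = trained_on_blocks
        S2, _ = block_kernel([3, 3])
        with pytest.raises(ValidationError):
            score_all_pairs(scorer, S2)


class TestSingleBranch:
    def test_embedding_shape(self, trained_on_blocks):
        S, _, cfg, scorer = trained_on_blocks
        E = embed_single_branch(scorer, S)
        assert E.shape == (S.n_cells, cfg.hidden_units)

    def test_identical_rows_identical_embeddings(self, trained_on_blocks):
        S, *_ , scorer = trained_on_blocks
        vals = S.values.copy()
        vals[1] = vals[0]
        E = scorer.embed_rows(vals)
        np.testing.assert_array_equal(E[0], E[1])


@pytest.fixture(scope="module")
def small_separable():
    X, y = simulate_counts(
        separable_spec(seed=11, k=3, n_cells=80, proportions=(0.5, 0.3, 0.2))
    )
    S = kernel_embedding(X)
    cfg = fast_siamese_config(seed=11)
    pairs = generate_pairs(derive_pseudo_labels(S, 3), cfg,
                           np.random.default_rng(11))
    scorer = train_siamese(S, pairs, cfg)
    return S, y, score_all_pairs(scorer, S)


class TestSeparationProperties:
    """Properties on a separable synthetic data set (silhouette >= 0.5)."""

    def test_margin_at_least_point_two(self, small_separable):
        S, y, M = small_separable
        same = y[:, None] == y[None, :]
        off = ~np.eye(len(y), dtype=bool)
        margin = M.values[same & off].mean() - M.values[~same].mean()
        assert margin >= 0.2

    def test_learned_matrix_no_worse_than_raw_kernel(self, small_separable):
        S, y, M = small_separable
        ari_learned = ari(y, agglomerative_from_similarity(M, 3).labels)
        ari_raw = ari(y, agglomerative_from_similarity(S, 3).labels)
        assert ari_learned >= ari_raw


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("hidden_units", 0), ("epochs", 0), ("batch_size", -1),
        ("learning_rate", 0.0), ("positive_fraction", 1.0),
        ("embed_mode", "bogus"),
    ])
    def test_bad_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            SiameseConfig(**{field: value})
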