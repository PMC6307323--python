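import numpy as np
import pytest

import genebreadth as gb
from genebreadth.errors import DomainError


def naive_lstm_forward(params, sequence):
    """Loop-per-gate scalar reference implementation (oracle)."""
    def sig(z):
        return 1.0 / (1.0 + np.exp(-z))

    H = params.hidden_dim
    h = [0.0] * H
    c = [0.0] * H
    for x_t in sequence:
        f, i, g, o = [0.0] * H, [0.0] * H, [0.0] * H, [0.0] * H
        for r in range(H):
            zf = params.b_f[r] + sum(params.W_f[r, k] * x_t[k]
                                     for k in range(len(x_t)))
            zi = params.b_i[r] + sum(params.W_i[r, k] * x_t[k]
                                     for k in range(len(x_t)))
            zg = params.b_c[r] + sum(params.W_c[r, k] * x_t[k]
                                     for k in range(len(x_t)))
            zo = params.b_o[r] + sum(params.W_o[r, k] * x_t[k]
                                     for k in range(len(x_t)))
            for s in range(H):
                zf += params.U_f[r, s] * h[s]
                zi += params.U_i[r, s] * h[s]
                zg += params.U_c[r, s] * h[s]
                zo += params.U_o[r, s] * h[s]
            f[r], i[r], g[r], o[r] = sig(zf), sig(zi), np.tanh(zg), sig(zo)
        c = [f[r] * c[r] + i[r] * g[r] for r in range(H)]
        h = [o[r] * np.tanh(c[r]) for r in range(H)]
    return np.array(h)


class TestVectorToSequence:
    @pytest.mark.parametrize("d,chunk,t,pad", [
        (10, 5, 2, 0), (7, 3, 3, 2), (1, 1, 1, 0), (32, 32, 1, 0)])
    def test_chunking_and_padding(self, d, chunk, t, pad):
        x = np.arange(1, d + 1, dtype=float)
        seq = gb.vector_to_sequence(x, chunk)
        assert seq.shape == (t, chunk)
        np.testing.assert_array_equal(seq.ravel()[:d], x)
        assert np.all(seq.ravel()[d:] == 0)
        assert seq.size - d == pad

    def test_empty_vector_error(self):
        with pytest.raises(DomainError):
            gb.vector_to_sequence([], 4)


class TestLstmForward:
    def test_zero_parameters_give_zero_state(self):
        h, d = 3, 2
        z = np.zeros
        params = gb.LstmParams(
            W_f=z((h, d)), W_i=z((h, d)), W_c=z((h, d)), W_o=z((h, d)),
            U_f=z((h, h)), U_i=z((h, h)), U_c=z((h, h)), U_o=z((h, h)),
            b_f=z(h), b_i=z(h), b_c=z(h), b_o=z(h),
            readout_w=z(h), readout_b=0.0, hidden_dim=h, chunk_size=d)
        out = gb.lstm_forward(params, np.ones((4, d)))
        np.testing.assert_array_equal(out, np.zeros(h))

    def test_hand_computed_two_steps(self):
        # hidden 2, chunk 1, T = 2; every gate checked by hand arithmetic
        ones = np.ones((2, 1))
        params = gb.LstmParams(
            W_f=0.5 * ones, W_i=0.25 * ones, W_c=1.0 * ones, W_o=0.75 * ones,
            U_f=np.zeros((2, 2)), U_i=np.zeros((2, 2)),
            U_c=np.zeros((2, 2)), U_o=np.zeros((2, 2)),
            b_f=np.zeros(2), b_i=np.zeros(2), b_c=np.zeros(2),
            b_o=np.zeros(2), readout_w=np.zeros(2), readout_b=0.0,
            hidden_dim=2, chunk_size=1)

        def sig(v):
            return 1 / (1 + np.exp(-v))

        # t=1, x=1: c1 = sig(0.25)*tanh(1); h1 = sig(0.75)*tanh(c1)
        c1 = sig(0.25) * np.tanh(1.0)
        # t=2, x=2 (U == 0, so h1 does not enter the gates)
        c2 = sig(1.0) * c1 + sig(0.5) * np.tanh(2.0)
        h2 = sig(1.5) * np.tanh(c2)
        out = gb.lstm_forward(params, np.array([[1.0], [2.0]]))
        np.testing.assert_allclose(out, [h2, h2], atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_naive_reference(self, seed):
        rng = np.random.default_rng(seed)
        h = int(rng.integers(2, 5))
        d = int(rng.integers(1, 4))
        params = gb.LstmParams.init(h, d, rng)
        seq = rng.normal(size=(int(rng.integers(1, 6)), d))
        np.testing.assert_allclose(gb.lstm_forward(params, seq),
                                   naive_lstm_forward(params, seq),
                                   atol=1e-10)

    def test_hidden_state_bounded(self):
        rng = np.random.default_rng(8)
        params = gb.LstmParams.init(4, 3, rng, scale=2.0)
        out = gb.lstm_forward(params, rng.normal(size=(6, 3)))
        assert np.all(np.abs(out) < 1.0)

    def test_cell_state_bound_grows_at_most_one_per_step(self):
        # |c_t| <= t since f, i in (0,1) and |tanh| < 1
        rng = np.random.default_rng(9)
        params = gb.LstmParams.init(3, 2, rng, scale=3.0)
        seq = rng.normal(size=(5, 2))
        h = np.zeros(3)
        c = np.zeros(3)
        sig = lambda z: 1 / (1 + np.exp(-z))
        for t, x in enumerate(seq, start=1):
            f = sig(params.W_f @ x + params.U_f @ h + params.b_f)
            i = sig(params.W_i @ x + params.U_i @ h + params.b_i)
            g = np.tanh(params.W_c @ x + params.U_c @ h + params.b_c)
            o = sig(params.W_o @ x + params.U_o @ h + params.b_o)
            c = f * c + i * g
            h = o * np.tanh(c)
            assert np.all(np.abs(c) <= t)

    def test_shape_mismatch_error(self):
        params = gb.LstmParams.init(2, 3, np.random.default_rng(0))
        with pytest.raises(DomainError):
            gb.lstm_forward(params, np.ones((2, 4)))


class TestTrainPredict:
    @pytest.mark.parametrize("engine", ["lstm", "random_forest"])
    def test_separable_training_accuracy(self, separable_data, engine):
        X, y = separable_data
        hp = {"chunk_size": 2} if engine == "lstm" else {}
        clf = gb.train(gb.ClassifierSpec(engine, seed=1, hyperparameters=hp),
                       X, y)
        assert np.mean(gb.predict(clf, X) == y) == 1.0

    @pytest.mark.parametrize("engine", ["lstm", "random_forest"])
    def test_determinism_same_seed(self, separable_data, engine):
        X, y = separable_data
        spec = gb.ClassifierSpec(engine, seed=5)
        p1 = gb.predict(gb.train(spec, X, y), X)
        p2 = gb.predict(gb.train(spec, X, y), X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_error(self):
        with pytest.raises(DomainError):
            gb.train(gb.ClassifierSpec("random_forest", seed=0),
                     np.zeros((4, 2)), np.ones(4, dtype=int))

    def test_single_row_prediction(self, separable_data):
        X, y = separable_data
        clf = gb.train(gb.ClassifierSpec("random_forest", seed=0), X, y)
        assert gb.predict(clf, X[:1]).shape == (1,)

    def test_zero_logit_counts_positive(self):
        model = gb.LstmClassifier(seed=0)
        model.params = "sentinel"
        model.decision_function = lambda X: np.array([0.0, -0.1, 0.1])
        np.testing.assert_array_equal(model.predict(None), [1, 0, 1])

    def test_column_mismatch_error(self, separable_data):
        X, y = separable_data
        clf = gb.train(gb.ClassifierSpec("random_forest", seed=0), X, y)
        with pytest.raises(DomainError):
            gb.predict(clf, X[:, :1])

    @pytest.mark.parametrize("engine", ["lstm", "random_forest"])
    def test_youden_on_well_separated_problem(self, engine):
        fm, labels = gb.generate_feature_matrix(
            300, 10, 4, shift=3.0, imbalance=4.7, seed=7)
        y = labels.y(fm.gene_ids)
        hp = {"epochs": 150} if engine == "lstm" else {}
        spec = gb.ClassifierSpec(engine, seed=11, hyperparameters=hp)
        folds = gb.kfold_assign(len(y), 10, 3, strata=y)
        rec = gb.compute_metrics(gb.cross_validate(fm.scores, y, spec, folds))
        assert rec.J > 0.8

    def test_model_container_round_trip(self, tmp_path, separable_data):
        X, y = separable_data
        clf = gb.train(gb.ClassifierSpec("random_forest", seed=0), X, y)
        path = tmp_path / "model.joblib"
        clf.save(path)
        back = gb.TrainedClassifier.load(path)
        np.testing.assert_array_equal(gb.predict(back, X), gb.predict(clf, X))
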