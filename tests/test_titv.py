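import numpy as np
import pytest

from akipredict._autodiff import sigmoid_np
from akipredict.titv import (BaselineModel, TitvConfig, TitvModel,
                             fit_baseline, fit_titv, init_titv_params,
                             titv_forward)

TINY = TitvConfig(hidden_size=4, film_hidden=4, max_epochs=50,
                  early_stop_patience=50, learning_rate=0.05, seed=0)


def _random_case(rng, T=3, F=5, config=None):
    config = config or TINY
    params = init_titv_params(T, F, config, rng)
    # randomize every trainable parameter so invariants are tested away
    # from the symmetric initialization
    for k, t in params.items():
        if t.requires_grad:
            t.data = np.asarray(t.data + rng.normal(0, 0.5, size=t.data.shape))
    X = rng.random((T, F))
    M = (rng.random((T, F)) < 0.7).astype(float)
    X = X * M
    return params, X, M


def _toy_separable(n=60, T=3, F=4, seed=0):
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 2).astype(float)
    X = rng.uniform(0.0, 0.3, size=(n, T, F))
    X[y == 1, :, 0] = rng.uniform(0.7, 1.0, size=(int(y.sum()), T))
    M = np.ones_like(X)
    return X, M, y


class TestForwardInvariants:
    def test_normalization_and_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            params, X, M = _random_case(rng)
            out = titv_forward(params, X, M, TINY)
            assert np.all(out.beta >= 0)
            assert out.beta.sum() == pytest.approx(1.0, abs=1e-6)
            assert np.all(out.alpha >= 0)
            assert out.alpha.sum() == pytest.approx(1.0, abs=1e-6)
            logit = np.log(out.risk / (1.0 - out.risk))
            assert out.contributions.sum() + out.logit_bias == pytest.approx(
                logit, abs=1e-5)

    def test_zero_input_zero_delta(self):
        rng = np.random.default_rng(1)
        params = init_titv_params(3, 5, TINY, rng)  # delta = 0, x_mean = 0
        X = np.zeros((3, 5))
        M = np.ones((3, 5))
        out = titv_forward(params, X, M, TINY)
        assert np.all(out.contributions == 0)
        assert out.risk == pytest.approx(
            float(sigmoid_np(params["bias"].data)))

    def test_feature_permutation_symmetry(self):
        rng = np.random.default_rng(2)
        params, X, M = _random_case(rng, T=3, F=5)
        out = titv_forward(params, X, M, TINY)
        perm = np.array([3, 0, 4, 1, 2])
        per_feature = ("g_base", "delta", "u_mean", "u_sd", "m_mean",
                       "m_sd", "x_mean", "w")
        for k in per_feature:
            params[k].data = params[k].data[perm]
        for d in ("f", "b"):
            params[f"Wx_{d}"].data = params[f"Wx_{d}"].data[perm]
        out_p = titv_forward(params, X[:, perm], M[:, perm], TINY)
        assert out_p.risk == pytest.approx(out.risk, abs=1e-10)
        np.testing.assert_allclose(out_p.beta, out.beta[perm], atol=1e-10)
        np.testing.assert_allclose(out_p.alpha, out.alpha[:, perm], atol=1e-10)

    def test_shape_and_nan_errors(self):
        rng = np.random.default_rng(3)
        params, X, M = _random_case(rng, T=3, F=5)
        with pytest.raises(ValueError):
            titv_forward(params, np.zeros((3, 4)), np.zeros((3, 4)), TINY)
        params["w"].data = params["w"].data * np.nan
        with pytest.raises(ValueError):
            titv_forward(params, X, M, TINY)


class TestTraining:
    def test_separable_toy_set(self):
        X, M, y = _toy_separable()
        model = fit_titv((X, M, y), (X, M, y), TINY)
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(y, model.predict_proba(X, M)) == 1.0

    def test_determinism(self):
        X, M, y = _toy_separable()
        cfg = TitvConfig(hidden_size=4, film_hidden=4, max_epochs=5, seed=3)
        m1 = fit_titv((X, M, y), (X, M, y), cfg)
        m2 = fit_titv((X, M, y), (X, M, y), cfg)
        for k in m1.params:
            assert np.array_equal(m1.params[k].data, m2.params[k].data), k

    def test_single_class_raises(self):
        X, M, y = _toy_separable()
        with pytest.raises(ValueError):
            fit_titv((X, M, np.zeros_like(y)), (X, M, y), TINY)

    def test_save_load_roundtrip(self, tmp_path):
        X, M, y = _toy_separable()
        cfg = TitvConfig(hidden_size=4, film_hidden=4, max_epochs=3, seed=1)
        model = fit_titv((X, M, y), (X, M, y), cfg, analytes=[f"f{i}"
                                                              for i in range(4)])
        path = str(tmp_path / "m.ckpt")
        model.save(path)
        loaded = TitvModel.load(path)
        np.testing.assert_array_equal(model.predict_proba(X, M),
                                      loaded.predict_proba(X, M))
        assert loaded.analytes == model.analytes
        assert loaded.config == cfg


class TestExplain:
    def test_topk_mass_and_cap(self):
        rng = np.random.default_rng(5)
        params, X, M = _random_case(rng, T=3, F=5)
        model = TitvModel(params, TINY, 3, 5,
                          analytes=[f"f{i}" for i in range(5)])
        ranked = model.explain(X, M, top_k=3 * 5)
        assert len(ranked) == 15
        assert sum(s for _, _, s in ranked) == pytest.approx(1.0, abs=1e-6)
        assert len(model.explain(X, M, top_k=999)) == 15
        scores = [s for _, _, s in ranked]
        assert scores == sorted(scores, reverse=True)


class TestBaselines:
    def test_logistic_on_separable(self):
        X, M, y = _toy_separable()
        model = fit_baseline("logistic", (X, M, y), (X, M, y), TINY)
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(y, model.predict_proba(X, M)) == 1.0

    def test_bgru_has_more_parameters(self):
        X, M, y = _toy_separable(n=20)
        cfg = TitvConfig(hidden_size=4, film_hidden=4, max_epochs=1, seed=0)
        gru = fit_baseline("gru", (X, M, y), (X, M, y), cfg)
        bgru = fit_baseline("bgru", (X, M, y), (X, M, y), cfg)
        assert bgru.n_parameters > gru.n_parameters

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            BaselineModel("mlp", TINY, 3, 4)
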