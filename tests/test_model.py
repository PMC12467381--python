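import numpy as np
import pytest

from offtarget.model import (
    InteractionModel,
    ModelConfig,
    bce_sigmoid_loss,
    classify_pair,
    dual_cross_attention,
    project_modality,
    sigmoid,
    triplet_loss,
)


def straight_line_forward(params, cfg, E1, E2):
    """Independent matrix-algebra oracle for the composed forward pass.

    Written as explicit, unshared straight-line code: three dense layers per
    modality, explicit sigmoid gate per attention head, concatenation, global
    mix, residual sum, layer normalisation, linear readout.
    """
    def relu(x):
        return np.where(x > 0, x, 0.0)

    def stack(E, w):
        h = relu(params[f"{w}.W1"].T @ E + params[f"{w}.b1"])
        h = relu(params[f"{w}.W2"].T @ h + params[f"{w}.b2"])
        return relu(params[f"{w}.W3"].T @ h + params[f"{w}.b3"])

    L1 = stack(E1, "t")
    L2 = stack(E2, "c")
    half = cfg.p // 2
    q1 = params["att.Wq1"].T @ L1
    k1 = params["att.Wk1"].T @ L1
    v1 = params["att.Wv1"].T @ L1
    q2 = params["att.Wq2"].T @ L2
    k2 = params["att.Wk2"].T @ L2
    v2 = params["att.Wv2"].T @ L2
    g1 = 1.0 / (1.0 + np.exp(-(q1 @ k2) / np.sqrt(half)))
    g2 = 1.0 / (1.0 + np.exp(-(q2 @ k1) / np.sqrt(half)))
    A = params["att.WG"].T @ np.concatenate([g1 * v2, g2 * v1])
    Ahat = L1 + L2 + A
    mu = Ahat.mean()
    var = ((Ahat - mu) ** 2).mean()
    xhat = (Ahat - mu) / np.sqrt(var + cfg.eps)
    y = xhat * params["head.alpha"] + params["head.beta"]
    return float(y @ params["head.W4"] + params["head.b4"])


@pytest.fixture()
def small_model():
    return InteractionModel(ModelConfig(d_protein=10, d_compound=14, p=8,
                                        hidden=(6, 7), seed=42))


class TestProjection:
    def test_zero_weights_give_zero_output(self, small_model):
        for k, v in small_model.params.items():
            if k.startswith(("t.", "c.")):
                small_model.params[k] = np.zeros_like(v)
        out = project_modality(np.ones(10), small_model, "t")
        assert np.array_equal(out, np.zeros(8))

    def test_outputs_nonnegative(self, small_model, rng):
        for _ in range(20):
            out = project_modality(rng.normal(size=14), small_model, "c")
            assert out.min() >= 0

    def test_shape_error(self, small_model):
        with pytest.raises(ValueError):
            small_model.forward(np.ones(11), np.ones(14))


class TestAttention:
    def test_zero_dot_product_gives_half_gate(self):
        m = InteractionModel(ModelConfig(d_protein=4, d_compound=4, p=8, seed=1))
        # make q1 orthogonal trivially: zero the query maps
        m.params["att.Wq1"] = np.zeros_like(m.params["att.Wq1"])
        m.params["att.Wq2"] = np.zeros_like(m.params["att.Wq2"])
        m.params["att.WG"] = np.eye(8)
        L1, L2 = np.ones(8), np.arange(8.0)
        A = dual_cross_attention(L1, L2, m)
        v2 = L2 @ m.params["att.Wv2"]
        v1 = L1 @ m.params["att.Wv1"]
        # gate sigmoid(0) = 0.5 in both heads
        assert np.allclose(A, np.concatenate([0.5 * v2, 0.5 * v1]))

    def test_symmetric_parameters_swap_heads(self):
        m = InteractionModel(ModelConfig(d_protein=4, d_compound=4, p=8, seed=2))
        for role in ("q", "k", "v"):
            m.params[f"att.W{role}2"] = m.params[f"att.W{role}1"].copy()
        m.params["att.WG"] = np.eye(8)
        a, b = np.arange(8.0), np.arange(8.0)[::-1].copy()
        A_ab = dual_cross_attention(a, b, m)
        A_ba = dual_cross_attention(b, a, m)
        half = 4
        assert np.allclose(A_ab[:half], A_ba[half:])
        assert np.allclose(A_ab[half:], A_ba[:half])

    def test_tokens_mode_runs_and_differs_from_gate(self):
        cfg_g = ModelConfig(d_protein=6, d_compound=6, p=16, seed=3, attention_mode="gate")
        cfg_t = ModelConfig(d_protein=6, d_compound=6, p=16, seed=3,
                            attention_mode="tokens", n_tokens=4)
        mg, mt = InteractionModel(cfg_g), InteractionModel(cfg_t)
        E1, E2 = np.ones(6), np.full(6, 0.5)
        assert mg.forward(E1, E2).shape == mt.forward(E1, E2).shape
        assert not np.allclose(mg.forward(E1, E2), mt.forward(E1, E2))


class TestClassifierHead:
    def test_identity_affine_zero_readout(self, small_model):
        small_model.params["head.alpha"] = np.ones(8)
        small_model.params["head.beta"] = np.zeros(8)
        small_model.params["head.W4"] = np.zeros(8)
        small_model.params["head.b4"] = np.zeros(())
        logit, prob = classify_pair(np.ones(8), np.ones(8), np.ones(8), small_model)
        assert logit == 0.0
        assert prob == 0.5

    def test_layernorm_standardisation_identity(self, small_model, rng):
        Ahat = rng.normal(size=(1, 8))
        _, cache = small_model._head_forward(Ahat, np.zeros((1, 8)), np.zeros((1, 8)))
        xhat = cache["xhat"]
        assert abs(xhat.mean()) < 1e-6
        assert abs(xhat.var() - 1) < 10 * small_model.config.eps


class TestOracleEquivalence:
    def test_forward_matches_straight_line_oracle(self, rng):
        """Composed forward pass vs an independent dense-algebra oracle."""
        for draw in range(100):
            cfg = ModelConfig(d_protein=6, d_compound=9, p=8, hidden=(5, 7),
                              seed=1000 + draw)
            m = InteractionModel(cfg)
            E1 = rng.normal(size=6)
            E2 = rng.normal(size=9)
            expected = straight_line_forward(m.params, cfg, E1, E2)
            got = float(m.forward(E1, E2)[0])
            assert got == pytest.approx(expected, abs=1e-5)


class TestLosses:
    def test_bce_identities(self):
        assert bce_sigmoid_loss([0.0], [1]) == pytest.approx(np.log(2), abs=1e-9)
        assert bce_sigmoid_loss([20.0], [1]) < 1e-8
        assert bce_sigmoid_loss([0.0, 0.0], [0, 1]) == pytest.approx(np.log(2), abs=1e-12)

    def test_bce_errors(self):
        with pytest.raises(ValueError):
            bce_sigmoid_loss([], [])
        with pytest.raises(ValueError):
            bce_sigmoid_loss([0.0], [0.5])

    def test_bce_extreme_logits_finite(self):
        assert np.isfinite(bce_sigmoid_loss([1000.0, -1000.0], [0, 1]))

    def test_triplet_identities(self):
        a = np.zeros(3)
        assert triplet_loss(a, a, [np.array([9.0, 0, 0])], margin=1.0) == 0.0
        assert triplet_loss(a, a, [a, a], margin=0.7) == pytest.approx(0.7)
        # per-triplet terms 0 and 0.4 average to 0.2
        p = np.array([1.0, 0, 0])  # d(a,p) = 1
        n_far = np.array([2.5, 0, 0])   # term = max(0, 1 - 2.5 + 1) = 0
        n_near = np.array([1.6, 0, 0])  # term = max(0, 1 - 1.6 + 1) = 0.4
        assert triplet_loss(a, p, [n_far, n_near], margin=1.0) == pytest.approx(0.2)

    def test_triplet_empty_negatives(self):
        with pytest.raises(ValueError):
            triplet_loss(np.zeros(2), np.zeros(2), [], margin=1.0)


class TestGradients:
    @pytest.mark.parametrize("mode", ["gate", "tokens"])
    def test_backprop_matches_finite_differences(self, mode, rng):
        """Analytic gradients of the total loss vs central differences."""
        cfg = ModelConfig(d_protein=7, d_compound=9, p=8, hidden=(6, 5),
                          attention_mode=mode, n_tokens=2, seed=3)
        m = InteractionModel(cfg)
        E1 = rng.normal(size=(4, 7))
        E2 = rng.normal(size=(4, 9))
        y = rng.integers(0, 2, 4).astype(float)
        E2n = rng.normal(size=(4, 3, 9))

        def total_loss():
            z = m.forward(E1, E2)
            bce = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
            Pa = m.project_target(E1)
            Pp = m.project_compound(E2)
            Pn = m.project_compound(E2n.reshape(-1, 9)).reshape(4, 3, -1)
            dap = np.linalg.norm(Pa - Pp, axis=1)
            dan = np.linalg.norm(Pa[:, None] - Pn, axis=2)
            return bce + float(np.maximum(0, dap[:, None] - dan + 1.0).mean())

        _, g_bce = m.bce_loss_and_grads(E1, E2, y)
        _, g_tri = m.triplet_loss_and_grads(E1, E2, E2n, margin=1.0)
        grads = {k: g_bce[k] + g_tri[k] for k in g_bce}

        checked = 0
        for name, g in grads.items():
            flat = m.params[name].reshape(-1)
            n_check = max(1, flat.size // 100)  # ~1% of parameters
            for i in rng.choice(flat.size, size=min(n_check, 5), replace=False):
                eps, old = 1e-6, flat[i]
                flat[i] = old + eps
                lp = total_loss()
                flat[i] = old - eps
                lm = total_loss()
                flat[i] = old
                fd = (lp - lm) / (2 * eps)
                ana = g.reshape(-1)[i]
                assert ana == pytest.approx(fd, rel=1e-3, abs=1e-8)
                checked += 1
        assert checked >= 15


class TestMirroredTriplet:
    def test_compound_anchor_grads_match_finite_differences(self, rng):
        """The target-decoy (compound-anchor) triplet direction backprops
        correctly through the swapped projection stacks."""
        cfg = ModelConfig(d_protein=7, d_compound=9, p=8, hidden=(6, 5), seed=4)
        m = InteractionModel(cfg)
        E2a = rng.normal(size=(3, 9))   # compound anchors
        E1p = rng.normal(size=(3, 7))   # positive targets
        E1n = rng.normal(size=(3, 2, 7))  # target decoys

        def loss():
            Pa = m.project_compound(E2a)
            Pp = m.project_target(E1p)
            Pn = m.project_target(E1n.reshape(-1, 7)).reshape(3, 2, -1)
            dap = np.linalg.norm(Pa - Pp, axis=1)
            dan = np.linalg.norm(Pa[:, None] - Pn, axis=2)
            return float(np.maximum(0, dap[:, None] - dan + 1.0).mean())

        _, grads = m.triplet_loss_and_grads(E2a, E1p, E1n, margin=1.0, anchor="c")
        for name in ("t.W1", "c.W2", "t.b3", "c.W3"):
            flat = m.params[name].reshape(-1)
            for i in rng.choice(flat.size, size=4, replace=False):
                eps, old = 1e-6, flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                fd = (lp - lm) / (2 * eps)
                assert grads[name].reshape(-1)[i] == pytest.approx(fd, rel=1e-3, abs=1e-8)


class TestPersistence:
    def test_save_load_bit_identical_predictions(self, small_model, tmp_path, rng):
        E1, E2 = rng.normal(size=(3, 10)), rng.normal(size=(3, 14))
        before = small_model.forward(E1, E2)
        path = tmp_path / "ckpt.npz"
        small_model.save(path)
        loaded = InteractionModel.load(path)
        assert np.array_equal(loaded.forward(E1, E2), before)

    def test_load_validates_shapes(self, small_model, tmp_path):
        path = tmp_path / "ckpt.npz"
        small_model.save(path)
        import json

        import numpy as np_
        data = dict(np_.load(path))
        data["t.W1"] = data["t.W1"][:, :-1]
        np_.savez(path, **data)
        with pytest.raises(ValueError, match="shape"):
            InteractionModel.load(path)

    def test_forward_deterministic(self, small_model, rng):
        E1, E2 = rng.normal(size=10), rng.normal(size=14)
        assert np.array_equal(small_model.forward(E1, E2), small_model.forward(E1, E2))
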