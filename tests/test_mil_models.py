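"""The four MIL heads: probability contracts, oracles, invariances, training."""

import numpy as np
import pytest

from cytorigin.bagio import CATEGORIES, ClinicalCovariates
from cytorigin.errors import (ConfigurationError, DataError, EmptyBagError,
                              IncompleteCovariatesError, ParameterError)
from cytorigin.mil_models import (ARCHITECTURES, AbMIL, EnsembleSpec, FeatureBag,
                                  MILConfig, ProbabilityVector, TrainConfig,
                                  TransMILCMA, build_model, embed_clinical,
                                  ensemble_predict, gated_attention, load_model,
                                  save_model, scaled_dot_attention,
                                  select_checkpoint, train_mil)
from cytorigin.mil_models import ClinicalEmbedding

COV = ClinicalCovariates(age=63, sex="male", site="hydrothorax")
TINY = MILConfig(d=8, abmil_hidden=(6, 4), attn_width=3, mb_proj=4, d_model=8, d_k=4)


def random_bag(rng, k=None, d=8):
    k = k or int(rng.integers(1, 12))
    return FeatureBag(rng.normal(size=(k, d)))


class TestProbabilityContracts:
    @pytest.mark.parametrize("arch", sorted(ARCHITECTURES))
    def test_valid_probability_vectors_on_random_bags(self, arch):
        """100 random (bag, parameter) draws each yield a distribution."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            model = build_model(arch, TINY, seed=seed)
            p = model.predict_proba(random_bag(rng), COV)
            assert (p.p >= 0).all()
            assert p.p.sum() == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("arch", ["abmil", "abmil_mb"])
    def test_exact_permutation_invariance(self, arch):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            model = build_model(arch, TINY, seed=seed)
            bag = random_bag(rng, k=7)
            perm = rng.permutation(7)
            p1 = model.predict_proba(bag, COV).p
            p2 = model.predict_proba(FeatureBag(bag.X[perm]), COV).p
            assert np.allclose(p1, p2, atol=1e-12)
            a1 = model.attention_scores(bag, COV)
            a2 = model.attention_scores(FeatureBag(bag.X[perm]), COV)
            assert np.allclose(a1[perm], a2, atol=1e-12)
            assert a1.sum() == pytest.approx(1.0, abs=1e-6)

    def test_transmil_invariant_with_shared_patch_slot(self, rng):
        # bags are unordered: the shared patch-slot position embedding keeps
        # the transformer permutation invariant
        model = build_model("transmil", TINY, seed=1)
        bag = random_bag(rng, k=6)
        perm = rng.permutation(6)
        assert np.allclose(model.predict_proba(bag, COV).p,
                           model.predict_proba(FeatureBag(bag.X[perm]), COV).p)

    def test_empty_bag_rejected(self):
        model = build_model("abmil", TINY, seed=0)
        with pytest.raises(EmptyBagError):
            model.forward(FeatureBag(np.empty((0, 8))), COV)

    def test_probability_vector_validation(self):
        with pytest.raises(ParameterError):
            ProbabilityVector(np.array([0.5, 0.5, 0.2, -0.1, -0.1]))
        pv = ProbabilityVector(np.array([0.1, 0.2, 0.3, 0.2, 0.2]))
        assert pv.p_cancer == pytest.approx(0.8)


class TestGatedAttention:
    def test_sole_instance(self):
        assert gated_attention(np.array([[2.0]]), [[1.0]], [[1.0]]) == pytest.approx([1.0])

    def test_identical_instances_uniform(self):
        H = np.ones((5, 3))
        V = U = np.eye(3)
        assert np.allclose(gated_attention(H, V, U), 0.2)

    def test_scalar_closed_form(self):
        # h1=0, h2 -> +inf with V=U=1: scores -> (0, 1), softmax = (1/(1+e), e/(1+e))
        H = np.array([[0.0], [50.0]])
        a = gated_attention(H, [[1.0]], [[1.0]])
        assert a == pytest.approx([1 / (1 + np.e), np.e / (1 + np.e)], rel=1e-9)

    def test_normalization_property(self, rng):
        for _ in range(20):
            H = rng.normal(size=(rng.integers(1, 9), 4))
            a = gated_attention(H, rng.normal(size=(3, 4)), rng.normal(size=(3, 4)),
                                branch=rng.normal(size=3))
            assert (a >= 0).all() and a.sum() == pytest.approx(1.0)

    def test_empty_bag(self):
        with pytest.raises(EmptyBagError):
            gated_attention(np.empty((0, 2)), np.eye(2), np.eye(2))


class TestScaledDotAttention:
    def test_single_token_returns_value(self, rng):
        v = rng.normal(size=(1, 4))
        out = scaled_dot_attention(rng.normal(size=(1, 4)), rng.normal(size=(1, 4)),
                                   v, d_k=4)
        assert np.allclose(out, v)

    def test_identical_keys_average_values(self, rng):
        K = np.ones((2, 4))
        V = rng.normal(size=(2, 4))
        out = scaled_dot_attention(rng.normal(size=(2, 4)), K, V, d_k=64)
        assert np.allclose(out, V.mean(axis=0))

    def test_invalid_dk(self):
        with pytest.raises(ParameterError):
            scaled_dot_attention(np.ones((1, 2)), np.ones((1, 2)), np.ones((1, 2)), 0)


class TestAbMILOracle:
    def test_two_instance_scalar_hand_evaluation(self):
        cfg = MILConfig(d=1, abmil_hidden=(1, 1), attn_width=1, mb_proj=1,
                        d_model=2, d_k=1)
        model = build_model("abmil", cfg, seed=0, use_clinical=False)
        w1, b1, w2, b2 = 1.2, 0.1, 0.8, -0.05
        v, u = 0.9, 1.1
        w3 = np.array([0.3, -0.2, 0.5, 0.0, -0.4])
        b3 = np.array([0.05, 0.0, -0.1, 0.2, 0.0])
        state = model.state_dict()
        state["fc1.weight"] = np.array([[w1]])
        state["fc1.bias"] = np.array([b1])
        state["fc2.weight"] = np.array([[w2]])
        state["fc2.bias"] = np.array([b2])
        state["v.weight"] = np.array([[v]])
        state["u.weight"] = np.array([[u]])
        state["classifier.weight"] = w3[None, :]
        state["classifier.bias"] = b3
        model.load_state_dict(state)

        x = np.array([0.7, -1.3])
        # independent scalar evaluation of the published equations
        h = np.maximum(0.0, w2 * np.maximum(0.0, w1 * x + b1) + b2)
        gate = np.tanh(v * h) * (1 / (1 + np.exp(-u * h)))
        a = np.exp(gate) / np.exp(gate).sum()
        z = (h * a).sum()
        logits = w3 * z + b3
        expected = np.exp(logits - logits.max())
        expected /= expected.sum()

        got = model.predict_proba(FeatureBag(x[:, None])).p
        assert np.allclose(got, expected, atol=1e-12)


class TestAbMILMBOracle:
    def test_scalar_toy_matches_hand_logits(self):
        cfg = MILConfig(d=1, abmil_hidden=(1, 1), attn_width=1, mb_proj=1,
                        d_model=2, d_k=1)
        model = build_model("abmil_mb", cfg, seed=0, use_clinical=False)
        w1 = 0.7
        va, ua = 1.3, 0.6
        branches = np.array([[0.5], [-0.8], [1.0], [0.0], [0.3]])
        class_w = np.array([[1.0], [0.4], [-0.6], [0.2], [0.9]])
        state = model.state_dict()
        state["proj.weight"] = np.array([[w1]])
        state["proj.bias"] = np.array([0.0])
        state["v.weight"] = np.array([[va]])
        state["u.weight"] = np.array([[ua]])
        state["branches"] = branches
        state["class_weights"] = class_w
        model.load_state_dict(state)

        x = np.array([0.4, -0.9])
        h = w1 * x
        gate = np.tanh(va * h) * (1 / (1 + np.exp(-ua * h)))
        logits = np.empty(5)
        for i in range(5):
            s = branches[i, 0] * gate
            a = np.exp(s - s.max())
            a /= a.sum()
            logits[i] = class_w[i, 0] * (a * h).sum()
        expected = np.exp(logits - logits.max())
        expected /= expected.sum()
        assert np.allclose(model.predict_proba(FeatureBag(x[:, None])).p,
                           expected, atol=1e-12)

    def test_single_patch_aggregate_is_that_patch(self, rng):
        model = build_model("abmil_mb", TINY, seed=3)
        bag = FeatureBag(rng.normal(size=(1, 8)))
        assert model.attention_scores(bag, COV) == pytest.approx([1.0])


class TestTransMIL:
    def test_token_count_is_k_plus_4(self, rng):
        model = build_model("transmil", TINY, seed=0)
        bag = random_bag(rng, k=9)
        tokens = model._tokens(bag, COV)
        assert tokens.shape == (9 + 4, TINY.d_model)

    def test_zeroed_weights_give_uniform(self, rng):
        model = build_model("transmil", TINY, seed=0)
        state = {k: np.zeros_like(v) for k, v in model.state_dict().items()}
        model.load_state_dict(state)
        p = model.predict_proba(random_bag(rng), COV).p
        assert np.allclose(p, 0.2)

    def test_heads_config(self):
        assert MILConfig(d=8, d_model=384, d_k=64).n_heads == 6
        with pytest.raises(ConfigurationError):
            MILConfig(d=8, d_model=100, d_k=64)


class TestCMA:
    def test_zeroed_cross_values_reduce_to_self_attention(self, rng):
        """With the clinical value projection zeroed, the first multimodal
        block's image-stream update equals pure self-attention, verified
        against an independent numpy evaluation."""
        cfg = MILConfig(d=5, abmil_hidden=(4, 3), attn_width=2, mb_proj=3,
                        d_model=4, d_k=4)  # single head
        model = build_model("transmil_cma", cfg, seed=2)
        block = model.mm_blocks[0]
        block.cli_qkv[2].weight.data[:] = 0.0
        block.cli_qkv[2].bias.data[:] = 0.0

        bag = FeatureBag(rng.normal(size=(3, 5)))
        from cytorigin._autodiff import Tensor

        x_img, x_cli = model._streams(bag, COV)
        out_img, _ = block(Tensor(x_img.data), Tensor(x_cli.data))

        # independent oracle: scaled-dot self-attention + layernorm + MLP
        xi = x_img.data
        def lin(layer, x):
            return x @ layer.weight.data + layer.bias.data
        q, k, v = (lin(block.img_qkv[i], xi) for i in range(3))
        attn = scaled_dot_attention(q, k, v, cfg.d_k)
        mu = attn.mean(axis=-1, keepdims=True)
        var = ((attn - mu) ** 2).mean(axis=-1, keepdims=True)
        ln = (attn - mu) / np.sqrt(var + 1e-5)
        hidden = np.maximum(0.0, lin(block.mlp_img.fc1, ln))
        expected = lin(block.mlp_img.fc2, hidden) + attn
        assert np.allclose(out_img.data, expected, atol=1e-10)

    def test_block_order_two_multimodal_then_self(self):
        model = build_model("transmil_cma", TINY, seed=0)
        assert len(model.mm_blocks) == 2
        assert model.self_block is not None

    def test_requires_complete_covariates(self, rng):
        model = build_model("transmil_cma", TINY, seed=0)
        with pytest.raises(IncompleteCovariatesError):
            model.forward(random_bag(rng), ClinicalCovariates(60, None, "ascites"))


class TestClinicalEmbedding:
    def test_additive_fusion_shape_and_identity(self, rng):
        tables = ClinicalEmbedding(8, rng)
        x_age, x_sex, x_site = embed_clinical(COV, "additive", tables)
        X = rng.normal(size=(6, 8))
        fused = X + (x_age.data + x_sex.data + x_site.data)
        assert fused.shape == X.shape
        tables.age.table.data[:] = 0
        tables.sex.table.data[:] = 0
        tables.site.table.data[:] = 0
        x_age, x_sex, x_site = embed_clinical(COV, "additive", tables)
        assert np.allclose(X + x_age.data + x_sex.data + x_site.data, X)

    def test_deterministic(self, rng):
        tables = ClinicalEmbedding(8, rng)
        a = embed_clinical(COV, "tokens", tables)
        b = embed_clinical(COV, "tokens", tables)
        assert all(np.array_equal(x.data, y.data) for x, y in zip(a, b))

    def test_incomplete_raises(self, rng):
        tables = ClinicalEmbedding(8, rng)
        with pytest.raises(IncompleteCovariatesError):
            embed_clinical(ClinicalCovariates(None, "male", "ascites"),
                           "additive", tables)


class TestGradientFlow:
    @pytest.mark.parametrize("arch", sorted(ARCHITECTURES))
    def test_cross_entropy_gradient_matches_finite_differences(self, arch, rng):
        cfg = MILConfig(d=3, abmil_hidden=(3, 2), attn_width=2, mb_proj=2,
                        d_model=4, d_k=2, ffn_hidden=3)
        model = build_model(arch, cfg, seed=4)
        bag = FeatureBag(rng.normal(size=(2, 3)))

        def loss():
            return -(model.forward(bag, COV)[2] + 1e-12).log()

        params = model.parameters()
        for p in params:
            p.grad = None
        loss().backward()
        eps = 1e-6
        for p in params:
            grad = p.grad if p.grad is not None else np.zeros_like(p.data)
            it = np.nditer(p.data, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = p.data[i]
                p.data[i] = old + eps
                hi = loss().item()
                p.data[i] = old - eps
                lo = loss().item()
                p.data[i] = old
                num = (hi - lo) / (2 * eps)
                assert abs(grad[i] - num) <= 1e-4 * (abs(num) + 1e-2)


class TestTraining:
    def test_checkpoint_selection_ignores_early_epochs(self):
        losses = [0.01] * 59 + [0.9, 0.5, 0.7]   # global minimum before epoch 60
        assert select_checkpoint(losses, select_from=60) == 61

    def test_checkpoint_selection_earliest_on_ties(self):
        losses = [1.0] * 70
        assert select_checkpoint(losses, select_from=60) == 60

    def test_deterministic_training(self, rng):
        train = [(random_bag(rng, k=4), COV, int(rng.integers(5))) for _ in range(6)]
        val = [(random_bag(rng, k=4), COV, int(rng.integers(5))) for _ in range(3)]
        logs = []
        states = []
        for _ in range(2):
            model = build_model("abmil", TINY, seed=9)
            logs.append(train_mil(model, train, val,
                                  TrainConfig(epochs=3, select_from_epoch=2), seed=9))
            states.append(model.state_dict())
        assert logs[0].val_loss == logs[1].val_loss
        assert logs[0].selected_epoch == logs[1].selected_epoch
        assert all(np.array_equal(states[0][k], states[1][k]) for k in states[0])

    def test_separable_set_reaches_high_training_accuracy(self, rng):
        # 40 bags, two planted classes far apart in feature space
        def bag_for(y):
            X = rng.normal(size=(6, 8))
            X[:3] += 3.0 * (1 if y == 0 else -1)
            return (FeatureBag(X), COV, 0 if y == 0 else 4)

        train = [bag_for(i % 2) for i in range(40)]
        val = [bag_for(i % 2) for i in range(10)]
        model = build_model("abmil", TINY, seed=2)
        train_mil(model, train, val, TrainConfig(epochs=15, lr=1e-3,
                                                 select_from_epoch=8), seed=2)
        acc = np.mean([np.argmax(model.predict_proba(b, c).p) == y
                       for b, c, y in train])
        assert acc >= 0.95

    def test_empty_split_rejected(self):
        model = build_model("abmil", TINY, seed=0)
        with pytest.raises(DataError):
            train_mil(model, [], [], TrainConfig(epochs=1))


class TestEnsemble:
    class _Const:
        categories = CATEGORIES

        def __init__(self, p):
            self._p = np.asarray(p, dtype=float)

        def predict_proba(self, bag, cov=None):
            return ProbabilityVector(self._p)

    def test_mean_of_members(self, rng):
        spec = EnsembleSpec([self._Const([1, 0, 0, 0, 0]),
                             self._Const([0, 1, 0, 0, 0])])
        out = ensemble_predict(spec, random_bag(rng), COV)
        assert np.allclose(out.p, [0.5, 0.5, 0, 0, 0])

    def test_identical_members_unchanged(self, rng):
        p = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        spec = EnsembleSpec([self._Const(p)] * 3)
        assert np.allclose(ensemble_predict(spec, random_bag(rng), COV).p, p)

    def test_category_order_mismatch_rejected(self):
        bad = self._Const([1, 0, 0, 0, 0])
        bad.categories = tuple(reversed(CATEGORIES))
        with pytest.raises(ConfigurationError):
            EnsembleSpec([self._Const([1, 0, 0, 0, 0]), bad])

    def test_member_without_covariates_dropped_with_warning(self, rng):
        cma = build_model("transmil_cma", TINY, seed=0)
        spec = EnsembleSpec([self._Const([0.2] * 5), cma])
        with pytest.warns(UserWarning, match="dropping ensemble member"):
            out = ensemble_predict(spec, random_bag(rng), cov=None)
        assert np.allclose(out.p, 0.2)

    def test_full_spec_is_twelve_members(self):
        feature_inputs = ("cyto", "histo", "cyto_histo")
        members = [build_model(a, TINY, seed=i)
                   for i, (a, _) in enumerate(
                       (a, f) for a in sorted(ARCHITECTURES) for f in feature_inputs)]
        assert len(EnsembleSpec(members).members) == 12


def test_model_round_trip(tmp_path, rng):
    model = build_model("transmil", TINY, seed=5)
    bag = random_bag(rng, k=4)
    save_model(model, tmp_path / "m.npz")
    loaded = load_model(tmp_path / "m.npz")
    assert np.allclose(model.predict_proba(bag, COV).p,
                       loaded.predict_proba(bag, COV).p)
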