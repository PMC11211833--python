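"""Sampling ops, measurement-matrix contracts, heads, and gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import protomil as pm
from protomil.autograd import Tensor
from protomil.errors import ConfigError, DimensionError
from protomil.model import _measurement_t, attention_weights
from protomil.training import cross_entropy


def identity_state(prototypes: np.ndarray, head="mean", mode="cluster", n_heads=1):
    """State whose projection and Q/K maps are identities (d3 = d1)."""
    d = prototypes.shape[1] if prototypes is not None else 2
    cfg = pm.ModelConfig(d1=d, d3=d, mlp_hidden=4, head=head,
                         prototype_mode=mode, n_heads=n_heads, seed=0)
    state = pm.init_model_state(
        cfg,
        prototypes=prototypes if mode == "cluster" else None,
        n_prototypes=None if mode == "cluster" else 2,
    )
    for name in ("fp_w", "wq_w", "wk_w"):
        state.params[name].data = np.eye(d)
    return state


class TestRandomSample:
    def test_identity_when_r_exceeds_n(self, toy_bag):
        assert pm.random_sample(toy_bag, 10, seed=0) is toy_bag

    def test_exact_subset_size_and_alignment(self, cohort8):
        bag = cohort8.bags[0]
        sub = pm.random_sample(bag, 7, seed=3)
        assert sub.n_instances == 7
        lookup = {tuple(c): i for i, c in enumerate(bag.coords)}
        idx = [lookup[tuple(c)] for c in sub.coords]
        assert len(set(idx)) == 7
        np.testing.assert_array_equal(sub.features, bag.features[idx])

    def test_deterministic_given_seed(self, cohort8):
        bag = cohort8.bags[1]
        a = pm.random_sample(bag, 5, seed=9)
        b = pm.random_sample(bag, 5, seed=9)
        assert np.array_equal(a.features, b.features)

    def test_default_grid_matches_published_sampling_sizes(self):
        assert pm.model.R_GRID == (10_000, 5_000, 2_000, 1_000, 500, 200)
        assert pm.ModelConfig().S == 500


class TestSelectorAndMining:
    def test_zero_selector_gives_zero_scores(self, toy_bag, tiny_protos):
        state = pm.init_model_state(
            pm.ModelConfig(d1=6, d3=8, mlp_hidden=4), prototypes=tiny_protos
        )
        state.params["sel_w"].data[:] = 0.0
        assert np.array_equal(
            pm.instance_scores(toy_bag.features, state), np.zeros(5)
        )

    def test_first_coordinate_selector(self, toy_bag, tiny_protos):
        state = pm.init_model_state(
            pm.ModelConfig(d1=6, d3=8, mlp_hidden=4), prototypes=tiny_protos
        )
        state.params["sel_w"].data[:] = 0.0
        state.params["sel_w"].data[0, 0] = 1.0
        np.testing.assert_allclose(
            pm.instance_scores(toy_bag.features, state), toy_bag.features[:, 0]
        )

    def test_top_k_mining_with_ties_prefers_lower_index(self, tiny_protos):
        feats = np.zeros((4, 6))
        feats[:, 0] = [0.1, 0.9, 0.5, 0.9]  # tie between 1 and 3
        bag = pm.FeatureBag(
            "t", feats, np.array([[0, 0], [256, 0], [0, 256], [256, 256]])
        )
        state = pm.init_model_state(
            pm.ModelConfig(d1=6, d3=8, mlp_hidden=4), prototypes=tiny_protos
        )
        state.params["sel_w"].data[:] = 0.0
        state.params["sel_w"].data[0, 0] = 1.0
        mined = pm.mine_instances(bag, state, 2)
        lookup = {tuple(c): i for i, c in enumerate(bag.coords)}
        assert sorted(lookup[tuple(c)] for c in mined.coords) == [1, 3]
        mined3 = pm.mine_instances(bag, state, 3)
        assert sorted(lookup[tuple(c)] for c in mined3.coords) == [1, 2, 3]

    def test_mining_identity_when_s_exceeds_n(self, toy_bag, tiny_protos):
        state = pm.init_model_state(
            pm.ModelConfig(d1=6, d3=8, mlp_hidden=4), prototypes=tiny_protos
        )
        assert pm.mine_instances(toy_bag, state, 99) is toy_bag

    def test_width_mismatch_raises(self, tiny_protos):
        state = pm.init_model_state(
            pm.ModelConfig(d1=6, d3=8, mlp_hidden=4), prototypes=tiny_protos
        )
        with pytest.raises(DimensionError):
            pm.instance_scores(np.zeros((3, 4)), state)


class TestMeasurement:
    def test_hand_cosines(self):
        protos = np.array([[1.0, 0.0], [1.0, 1.0]])
        state = identity_state(protos)
        M = pm.measurement(np.array([[0.0, 1.0]]), state)
        np.testing.assert_allclose(
            M.values, [[0.0], [1.0 / np.sqrt(2)]], atol=1e-9
        )

    def test_identical_vectors_give_cosine_one(self):
        protos = np.array([[2.0, 3.0]])
        state = identity_state(protos)
        M = pm.measurement(np.array([[2.0, 3.0], [4.0, 6.0]]), state)
        np.testing.assert_allclose(M.values, [[1.0, 1.0]], atol=1e-9)

    def test_zero_norm_instance_yields_zero(self):
        protos = np.array([[1.0, 0.0]])
        state = identity_state(protos)
        M = pm.measurement(np.array([[0.0, 0.0]]), state)
        assert M.values[0, 0] == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=8), st.integers(min_value=0, max_value=10**6))
    def test_entries_bounded(self, n, seed):
        rng = np.random.default_rng(seed)
        state = pm.init_model_state(
            pm.ModelConfig(d1=5, d3=7, mlp_hidden=4, seed=0),
            prototypes=pm.PrototypeSet(rng.standard_normal((3, 5)), [3], ["x"]),
        )
        M = pm.measurement(rng.standard_normal((n, 5)), state)
        assert (np.abs(M.values) <= 1.0).all()

    def test_positive_rescaling_invariance(self, cohort8, protos8):
        # with fresh (zero-bias) linear maps, cosine ignores instance scale
        state = pm.init_model_state(
            pm.ModelConfig(d1=8, d3=16, mlp_hidden=4, seed=0), prototypes=protos8
        )
        feats = cohort8.bags[0].features[:6].copy()
        M1 = pm.measurement(feats, state).values
        feats2 = feats.copy()
        feats2[2] *= 37.5
        M2 = pm.measurement(feats2, state).values
        np.testing.assert_allclose(M1, M2, atol=1e-9)

    def test_instance_permutation_permutes_columns_exactly(self, cohort8, protos8):
        state = pm.init_model_state(
            pm.ModelConfig(d1=8, d3=16, mlp_hidden=4, seed=0), prototypes=protos8
        )
        feats = cohort8.bags[0].features[:6]
        perm = np.array([3, 1, 5, 0, 2, 4])
        M1 = pm.measurement(feats, state).values
        M2 = pm.measurement(feats[perm], state).values
        assert np.array_equal(M1[:, perm], M2)

    def test_self_attention_mode_is_square(self):
        state = identity_state(None, mode="none")
        M = _measurement_t(Tensor(np.random.default_rng(0).standard_normal((4, 2))), state)
        assert M.shape == (4, 4)


class TestHeads:
    def test_mean_head_pools_instance_axis(self, tiny_protos):
        state = pm.init_model_state(
            pm.ModelConfig(d1=6, d3=8, mlp_hidden=4, seed=0), prototypes=tiny_protos
        )
        # make the MLP read out the pooled vector directly
        M = np.array([[0.0, 1.0], [2.0, 3.0], [0.0, 0.0], [0.0, 0.0]])
        pooled = M.mean(axis=1)
        assert np.allclose(pooled[:2], [0.5, 2.5])
        state.params["mlp_w1"].data = np.zeros((4, 4))
        state.params["mlp_w2"].data = np.zeros((4, 2))
        probs = pm.head_mean(M, state)
        np.testing.assert_allclose(probs, [0.5, 0.5])  # equal logits

    def test_probabilities_sum_to_one(self, tiny_protos):
        rng = np.random.default_rng(1)
        M = rng.uniform(-1, 1, (4, 7))
        for head in ("mean", "attention", "transformer"):
            state = pm.init_model_state(
                pm.ModelConfig(d1=6, d3=8, mlp_hidden=4, head=head, n_heads=2, seed=1),
                prototypes=tiny_protos,
            )
            fn = {"mean": pm.head_mean, "attention": pm.head_attention,
                  "transformer": pm.head_transformer}[head]
            probs = fn(M, state)
            assert probs.shape == (2,)
            assert probs.sum() == pytest.approx(1.0)
            assert (probs >= 0).all()

    @pytest.mark.parametrize("head", ["mean", "attention", "transformer"])
    def test_column_permutation_invariance(self, tiny_protos, head):
        rng = np.random.default_rng(2)
        M = rng.uniform(-1, 1, (4, 9))
        state = pm.init_model_state(
            pm.ModelConfig(d1=6, d3=8, mlp_hidden=4, head=head, n_heads=2, seed=2),
            prototypes=tiny_protos,
        )
        fn = {"mean": pm.head_mean, "attention": pm.head_attention,
              "transformer": pm.head_transformer}[head]
        a = fn(M, state)
        b = fn(M[:, rng.permutation(9)], state)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_attention_weights_contract(self, tiny_protos):
        state = pm.init_model_state(
            pm.ModelConfig(d1=6, d3=8, mlp_hidden=4, head="attention", seed=3),
            prototypes=tiny_protos,
        )
        w1 = attention_weights(np.ones((4, 1)), state)
        assert w1 == pytest.approx([1.0])  # singleton softmax
        w = attention_weights(np.random.default_rng(3).uniform(-1, 1, (4, 6)), state)
        assert w.sum() == pytest.approx(1.0, abs=1e-6)
        assert ((w > 0) & (w < 1)).all()

    def test_uniform_attention_equals_mean_pooling(self, tiny_protos):
        state = pm.init_model_state(
            pm.ModelConfig(d1=6, d3=8, mlp_hidden=4, head="attention", seed=4),
            prototypes=tiny_protos,
        )
        # zero the scorer: uniform weights -> weighted sum is the column mean
        state.params["attn_v"].data[:] = 0.0
        M = np.random.default_rng(4).uniform(-1, 1, (4, 5))
        probs_attn = pm.head_attention(M, state)
        mean_state = pm.init_model_state(
            pm.ModelConfig(d1=6, d3=8, mlp_hidden=4, head="mean", seed=4),
            prototypes=tiny_protos,
        )
        for k in ("mlp_w1", "mlp_b1", "mlp_w2", "mlp_b2"):
            mean_state.params[k].data = state.params[k].data
        np.testing.assert_allclose(probs_attn, pm.head_mean(M, mean_state), atol=1e-12)

    def test_transformer_single_column_and_head_divisibility(self, tiny_protos):
        state = pm.init_model_state(
            pm.ModelConfig(d1=6, d3=8, mlp_hidden=4, head="transformer", n_heads=2, seed=5),
            prototypes=tiny_protos,
        )
        probs = pm.head_transformer(np.array([[0.2], [0.1], [-0.3], [0.9]]), state)
        assert probs.sum() == pytest.approx(1.0)
        with pytest.raises(ConfigError):
            pm.init_model_state(
                pm.ModelConfig(d1=6, d3=8, mlp_hidden=4, head="transformer", n_heads=3),
                prototypes=tiny_protos,
            )


class TestForward:
    def test_inference_deterministic(self, toy_bag, tiny_protos):
        state = pm.init_model_state(
            pm.ModelConfig(d1=6, d3=8, mlp_hidden=4, seed=0), prototypes=tiny_protos
        )
        a = pm.forward(toy_bag, state)
        b = pm.forward(toy_bag, state)
        assert a.prob_positive == b.prob_positive
        assert 0.0 <= a.prob_positive <= 1.0

    def test_training_with_full_sampling_equals_inference(self, toy_bag, tiny_protos):
        cfg = pm.ModelConfig(d1=6, d3=8, mlp_hidden=4, R=5, S=5, seed=0)
        state = pm.init_model_state(cfg, prototypes=tiny_protos)
        a = pm.forward(toy_bag, state, training=True, seed=123)
        b = pm.forward(toy_bag, state)
        assert np.array_equal(a.probs, b.probs)
        assert np.array_equal(a.used_indices, b.used_indices)

    def test_training_applies_dual_sampling(self, cohort8, protos8):
        bag = cohort8.bags[0]
        cfg = pm.ModelConfig(d1=8, d3=16, mlp_hidden=4, R=20, S=10, seed=0)
        state = pm.init_model_state(cfg, prototypes=protos8)
        res = pm.forward(bag, state, training=True, seed=5)
        assert res.measurement.n == 10
        assert len(res.used_indices) == 10

    def test_d1_mismatch_raises(self, toy_bag):
        state = identity_state(np.array([[1.0, 0.0]]))
        with pytest.raises(DimensionError):
            pm.forward(toy_bag, state)

    def test_fixed_vs_learnable_prototypes_under_training(self, cohort8):
        from protomil.training import Adam

        for mode, should_move in (("random_fixed", False), ("random_learnable", True)):
            cfg = pm.ModelConfig(d1=8, d3=16, mlp_hidden=4, prototype_mode=mode, seed=0)
            state = pm.init_model_state(cfg, n_prototypes=3)
            before = state.prototypes.data.copy()
            opt = Adam(state.trainable(), lr=1e-2)
            res = pm.forward(cohort8.bags[0], state, training=True, seed=1)
            loss = cross_entropy([res._probs_t[1]], [cohort8.bags[0].label])
            opt.zero_grad()
            loss.backward()
            opt.step()
            moved = not np.array_equal(before, state.prototypes.data)
            assert moved == should_move


class TestGradients:
    @pytest.mark.parametrize("head", ["mean", "attention", "transformer"])
    @pytest.mark.parametrize("mode", ["cluster", "random_learnable", "none"])
    def test_analytic_matches_finite_difference(self, toy_bag, tiny_protos, head, mode):
        """Loss gradients agree with central differences for every
        parameter group on a 5-instance toy bag."""
        cfg = pm.ModelConfig(
            d1=6, d3=8, mlp_hidden=4, head=head, prototype_mode=mode,
            n_heads=2 if mode != "none" else 1, R=5, S=5, seed=0,
        )
        state = pm.init_model_state(
            cfg,
            prototypes=tiny_protos if mode == "cluster" else None,
            n_prototypes=None if mode == "cluster" else 4,
        )

        def loss_value():
            res = pm.forward(toy_bag, state, training=True, seed=0)
            return cross_entropy([res._probs_t[1]], [1])

        loss = loss_value()
        loss.backward()
        rng = np.random.default_rng(0)
        groups = dict(state.params)
        if state.prototypes is not None and state.prototype_learnable:
            groups["prototypes"] = state.prototypes
        h = 1e-6
        for name, t in groups.items():
            analytic = t.grad if t.grad is not None else np.zeros_like(t.data)
            flat = t.data.reshape(-1)
            k = min(5, flat.size)
            for i in rng.choice(flat.size, size=k, replace=False):
                orig = flat[i]
                flat[i] = orig + h
                fp = float(loss_value().data)
                flat[i] = orig - h
                fm = float(loss_value().data)
                flat[i] = orig
                num = (fp - fm) / (2 * h)
                ana = analytic.reshape(-1)[i]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-7), (name, i)
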