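"""Network forward pass, loss heads, similarity penalty, serialization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtirank.models import (
    ModelSpec,
    ModelState,
    embed,
    forward_score,
    forward_scores,
    init_state,
    interact,
    listwise_loss,
    listwise_probs,
    load_state,
    pairwise_loss,
    pairwise_prob,
    pointwise_loss,
    predict_pointwise,
    save_state,
    similarity_penalty,
    total_loss,
)


def _random_state(seed, n=6, m=7, k=3, widths=(4,)):
    state = init_state(ModelSpec(k=k, hidden_widths=list(widths)), n, m, seed)
    rng = np.random.default_rng(seed + 100)
    for name, arr in state.param_items():
        state.set_param(name, np.asarray(arr, float) + rng.normal(0, 0.4, np.shape(arr)))
    return state


class TestInitState:
    def test_deterministic_under_seed(self):
        spec = ModelSpec(k=4, hidden_widths=[5, 3])
        a = init_state(spec, 8, 9, seed=1)
        b = init_state(spec, 8, 9, seed=1)
        for (na, pa), (_, pb) in zip(a.param_items(), b.param_items()):
            assert np.array_equal(pa, pb), na

    def test_different_seeds_differ(self):
        spec = ModelSpec(k=4)
        a = init_state(spec, 8, 9, seed=1)
        b = init_state(spec, 8, 9, seed=2)
        assert not np.array_equal(a.P, b.P)

    def test_shape_chaining(self):
        state = init_state(ModelSpec(k=16, hidden_widths=[8, 4]), 3, 3, seed=0)
        assert state.hidden[0][0].shape == (16, 8)
        assert state.hidden[1][0].shape == (8, 4)
        assert state.out_weight.shape == (4,)


class TestEmbedInteract:
    def test_embed_is_row_lookup(self):
        state = _random_state(0)
        state.P = np.eye(6, 3)
        p, _ = embed(state, 1, 0)
        assert np.array_equal(p, [0, 1, 0])

    def test_embed_out_of_range(self):
        state = _random_state(0)
        with pytest.raises(IndexError):
            embed(state, 99, 0)

    def test_interact_elementwise_product(self):
        assert np.array_equal(interact([1, 2], [3, 4]), [3, 8])
        p = np.array([0.3, -1.2])
        assert np.array_equal(interact(p, np.ones(2)), p)
        assert np.array_equal(interact(p, np.zeros(2)), np.zeros(2))

    def test_interact_length_mismatch(self):
        with pytest.raises(ValueError):
            interact([1, 2], [1, 2, 3])


class TestForwardScore:
    def test_zero_head_gives_zero(self):
        state = _random_state(1)
        state.out_weight = np.zeros_like(state.out_weight)
        state.out_bias = 0.0
        assert forward_score(state, 0, 0) == 0.0

    def test_zero_hidden_gives_out_bias(self):
        state = _random_state(2)
        state.hidden = [(np.zeros_like(W), np.zeros_like(b)) for W, b in state.hidden]
        state.out_bias = 0.7
        assert forward_score(state, 3, 4) == pytest.approx(0.7)

    def test_matches_straight_line_recomputation(self):
        # independent oracle: explicit matrix algebra for k=2, one hidden layer
        state = _random_state(3, k=2, widths=(3,))
        d, t = 2, 5
        h0 = state.P[d] * state.Q[t]
        W, b = state.hidden[0]
        h1 = np.maximum(W.T @ h0 + b, 0.0)
        expected = float(state.out_weight @ h1 + state.out_bias)
        assert forward_score(state, d, t) == pytest.approx(expected, abs=1e-10)

    def test_sigmoid_prediction_bounded_and_stable(self):
        state = _random_state(4)
        state.hidden = [(np.zeros_like(W), np.zeros_like(b)) for W, b in state.hidden]
        state.out_bias = -1000.0
        y = predict_pointwise(state, 0, 0)
        assert 0.0 < y <= 1e-300
        assert predict_pointwise(_zero_score_state(), 0, 0) == pytest.approx(0.5)


def _zero_score_state():
    state = _random_state(9)
    state.out_weight = np.zeros_like(state.out_weight)
    state.out_bias = 0.0
    return state


class TestPointwiseLoss:
    def test_half_predictions_all_positive_labels(self):
        state = _zero_score_state()  # every prediction is 0.5
        batch = (np.zeros(4, int), np.arange(4), np.ones(4))
        assert pointwise_loss(state, batch, lam=0.0) == pytest.approx(1.0)

    def test_matches_term_by_term_oracle(self):
        state = _random_state(5)
        d = np.array([0, 1, 2])
        t = np.array([3, 0, 6])
        y = np.array([1.0, 0.0, 1.0])
        lam = 0.1
        expected = sum(
            (yi - 1 / (1 + math.exp(-forward_score(state, di, ti)))) ** 2
            for di, ti, yi in zip(d, t, y)
        ) + lam * state.sq_norm()
        assert pointwise_loss(state, (d, t, y), lam) == pytest.approx(expected, abs=1e-10)

    def test_rejects_non_binary_labels(self):
        state = _random_state(6)
        with pytest.raises(ValueError):
            pointwise_loss(state, (np.array([0]), np.array([0]), np.array([0.5])), 0.0)


class TestPairwise:
    def test_equal_scores_give_half_and_ln2(self):
        state = _zero_score_state()
        assert pairwise_prob(state, 0, 1, 2) == pytest.approx(0.5)
        loss = pairwise_loss(state, (np.array([0]), np.array([1]), np.array([2])), 0.0)
        assert loss == pytest.approx(math.log(2), abs=1e-12)

    def test_swap_complements_probability(self):
        state = _random_state(7)
        p = pairwise_prob(state, 0, 1, 2)
        assert pairwise_prob(state, 0, 2, 1) == pytest.approx(1 - p, abs=1e-12)

    def test_same_target_rejected(self):
        state = _random_state(7)
        with pytest.raises(ValueError):
            pairwise_prob(state, 0, 1, 1)

    def test_matches_term_by_term_oracle(self):
        state = _random_state(8)
        rng = np.random.default_rng(0)
        d = rng.integers(0, 6, 5)
        t = rng.integers(0, 7, 5)
        i = (t + 1) % 7
        expected = sum(
            -math.log(1 / (1 + math.exp(-(forward_score(state, dd, tt) - forward_score(state, dd, ii)))))
            for dd, tt, ii in zip(d, t, i)
        ) + 0.05 * state.sq_norm()
        assert pairwise_loss(state, (d, t, i), 0.05) == pytest.approx(expected, abs=1e-8)

    def test_loss_strictly_decreasing_in_gap(self):
        # monotonicity of -ln sigmoid(gap), checked through the network by
        # scaling the score head
        state = _random_state(10)
        triple = (np.array([0]), np.array([1]), np.array([2]))
        base_gap = forward_score(state, 0, 1) - forward_score(state, 0, 2)
        losses = []
        for scale in [0.5, 1.0, 2.0]:
            s = state.copy()
            s.out_weight = state.out_weight * scale
            s.out_bias = state.out_bias * scale
            losses.append(pairwise_loss(s, triple, 0.0))
        if base_gap > 0:
            assert losses[0] > losses[1] > losses[2]
        else:
            assert losses[0] < losses[1] < losses[2]


class TestListwise:
    def test_uniform_probabilities(self):
        state = _zero_score_state()
        probs = listwise_probs(state, 0, [0, 1, 2, 3])
        assert np.allclose(probs, 0.25)

    def test_probs_sum_to_one_and_shift_invariant(self):
        state = _random_state(11)
        probs = listwise_probs(state, 2, [0, 3, 5])
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        shifted = state.copy()
        shifted.out_bias = state.out_bias + 37.0  # uniform score shift
        assert np.allclose(listwise_probs(shifted, 2, [0, 3, 5]), probs, atol=1e-9)

    def test_softmax_of_log_scores(self):
        # scores ln1..ln4 -> probabilities 0.1, 0.2, 0.3, 0.4
        z = np.log([1.0, 2.0, 3.0, 4.0])
        e = np.exp(z - z.max())
        assert np.allclose(e / e.sum(), [0.1, 0.2, 0.3, 0.4])

    def test_duplicate_targets_rejected(self):
        state = _random_state(11)
        with pytest.raises(ValueError):
            listwise_probs(state, 0, [1, 1, 2])

    def test_uniform_list_closed_form(self):
        state = _zero_score_state()
        loss = listwise_loss(state, (np.array([0]), np.array([[0, 1, 2, 3]])), 0.0)
        expected = -(math.log(0.25) + 3 * math.log(0.75))
        assert loss == pytest.approx(expected, abs=1e-9)

    def test_matches_term_by_term_oracle(self):
        state = _random_state(12)
        d = np.array([0, 1, 3, 5])
        T = np.array([[0, 1, 2], [3, 4, 5], [6, 0, 2], [1, 5, 6]])
        expected = 0.0
        for dd, row in zip(d, T):
            x = np.array([forward_score(state, dd, tt) for tt in row])
            p = np.exp(x - x.max())
            p /= p.sum()
            expected += -math.log(p[0]) - np.sum(np.log1p(-p[1:]))
        expected += 0.01 * state.sq_norm()
        assert listwise_loss(state, (d, T), 0.01) == pytest.approx(expected, abs=1e-8)


class TestSimilarityPenalty:
    def test_zero_residual(self):
        state = _random_state(13)
        S = state.P @ state.P.T
        assert similarity_penalty(state, S, None, 1.0, 0.0) == pytest.approx(0.0, abs=1e-18)

    def test_identity_vs_zero_embeddings(self):
        state = _random_state(14, n=3)
        state.P = np.zeros_like(state.P)
        assert similarity_penalty(state, np.eye(3), None, 1.0, 0.0) == pytest.approx(3.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        state = _random_state(15, n=4, m=5, k=2)
        Sd = rng.random((4, 4))
        Sd = (Sd + Sd.T) / 2
        G = state.P @ state.P.T
        expected = sum(
            (Sd[i, j] - G[i, j]) ** 2 for i in range(4) for j in range(4)
        )
        assert similarity_penalty(state, Sd, None, 1.0, 0.0) == pytest.approx(
            expected, abs=1e-10
        )

    def test_rotation_invariance_of_drug_term(self):
        state = _random_state(16)
        rng = np.random.default_rng(2)
        A = rng.normal(size=(3, 3))
        R, _ = np.linalg.qr(A)
        Sd = rng.random((6, 6))
        Sd = (Sd + Sd.T) / 2
        before = similarity_penalty(state, Sd, None, 1.0, 0.0)
        state.P = state.P @ R
        assert similarity_penalty(state, Sd, None, 1.0, 0.0) == pytest.approx(before)

    def test_dimension_mismatch(self):
        state = _random_state(17)
        with pytest.raises(ValueError):
            similarity_penalty(state, np.eye(3), None, 1.0, 0.0)


class TestTotalLoss:
    def test_additivity(self):
        state = _random_state(18)
        rng = np.random.default_rng(3)
        Sd = rng.random((6, 6))
        Sd = (Sd + Sd.T) / 2
        batch = (np.array([0, 1]), np.array([2, 3]), np.array([1.0, 0.0]))
        total = total_loss(state, batch, 0.01, 0.2, 0.0, Sd, None, variant="pointwise")
        parts = pointwise_loss(state, batch, 0.01) + similarity_penalty(
            state, Sd, None, 0.2, 0.0
        )
        assert total == pytest.approx(parts, abs=1e-10)

    def test_zero_sim_weights_equal_variant_loss(self):
        state = _random_state(19)
        batch = (np.array([0]), np.array([1]), np.array([2]))
        assert total_loss(state, batch, 0.0, variant="pairwise") == pytest.approx(
            pairwise_loss(state, batch, 0.0)
        )


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None)
def test_rank_order_preserved_by_sigmoid(seed):
    """predict_pointwise is a strictly monotone transform of forward_score,
    so score-based and probability-based rankings coincide."""
    state = _random_state(seed % 50)
    d = np.zeros(7, dtype=int)
    t = np.arange(7)
    x = forward_scores(state, d, t)
    y = 1 / (1 + np.exp(-x))
    assert np.array_equal(np.argsort(x), np.argsort(y))


def test_serialization_round_trip_bit_exact(tmp_path):
    state = _random_state(20, widths=(5, 2))
    path = tmp_path / "model.npz"
    save_state(path, state)
    again = load_state(path)
    assert again.spec.variant == state.spec.variant
    assert again.spec.hidden_widths == state.spec.hidden_widths
    for (na, pa), (_, pb) in zip(state.param_items(), again.param_items()):
        assert np.array_equal(np.asarray(pa), np.asarray(pb)), na
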