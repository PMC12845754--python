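"""Input assembly, conv stack, self-attention encoder and identity head."""

import numpy as np
import pytest

from aesmbe import nn
from aesmbe.backbone import rank_and_select
from aesmbe.cma import (
    CMANet,
    ConvStack,
    EncoderLayer,
    PersonIdentifier,
    assemble_input,
    classify,
    conv_stack_forward,
    encoder_forward,
)


class TestAssembleInput:
    def _ranking(self, scores):
        ranking, _ = rank_and_select(np.asarray(scores, float), len(scores))
        return ranking

    def test_ascending_reindex_rule(self):
        # ranking order by score: 7, 2, 9, 40 -> budget 4 stacks rows 2,7,9,40
        scores = np.zeros(64)
        scores[[7, 2, 9, 40]] = [4.0, 3.0, 2.0, 1.0]
        ranking = self._ranking(scores)
        assert ranking.order[:4] == (7, 2, 9, 40)
        data = np.arange(64 * 160, dtype=float).reshape(64, 160)
        out = assemble_input(data, ranking, 4)
        np.testing.assert_array_equal(out, data[[2, 7, 9, 40]])

    def test_full_budget_is_row_reordering(self):
        data = np.random.default_rng(0).standard_normal((6, 20))
        ranking = self._ranking([3, 1, 4, 1, 5, 9])
        out = assemble_input(data, ranking, 6)
        np.testing.assert_array_equal(out, data)  # ascending = original order

    def test_fixed_output_dimension_across_subjects(self):
        data = np.random.default_rng(1).standard_normal((16, 160))
        r_a = self._ranking(np.random.default_rng(2).random(16))
        r_b = self._ranking(np.random.default_rng(3).random(16))
        assert assemble_input(data, r_a, 4).shape == (4, 160)
        assert assemble_input(data, r_b, 4).shape == (4, 160)

    def test_missing_ranking_rejected(self):
        with pytest.raises(ValueError, match="not enrolled"):
            assemble_input(np.zeros((4, 10)), None, 2)


class TestConvStack:
    def test_default_stack_downsamples_160_to_20(self):
        stack = ConvStack(4, np.random.default_rng(0))
        out = conv_stack_forward(np.random.default_rng(1).standard_normal((4, 160)), stack)
        assert out.shape == (64, 20)

    def test_batch_axis_preserved(self):
        stack = ConvStack(3, np.random.default_rng(0), (8, 8), (5, 3), (2, 2))
        out = conv_stack_forward(np.zeros((7, 3, 32)), stack)
        assert out.shape == (7, 8, 8)

    def test_indivisible_length_rejected(self):
        stack = ConvStack(2, np.random.default_rng(0))
        with pytest.raises(ValueError, match="divisible"):
            conv_stack_forward(np.zeros((2, 150)), stack)

    def test_zero_weight_convs_propagate_zero(self):
        stack = ConvStack(2, np.random.default_rng(0), (4,), (3,), (1,))
        stack.conv0.weight.data[:] = 0
        stack.conv0.bias.data[:] = 0
        out = stack.conv0(nn.Tensor(np.random.standard_normal((1, 2, 16)))).data
        np.testing.assert_array_equal(out, 0.0)


class TestEncoder:
    def test_single_token_attention_is_identity_on_v(self):
        layer = EncoderLayer(4, 1, 8, np.random.default_rng(0))
        z = np.random.default_rng(1).standard_normal((1, 1, 4))
        layer._mhsa(nn.Tensor(z))
        np.testing.assert_allclose(layer.last_attention, 1.0)

    def test_attention_rows_are_distributions(self):
        layer = EncoderLayer(8, 2, 16, np.random.default_rng(0))
        z = np.random.default_rng(1).standard_normal((3, 12, 8))
        encoder_forward(z, [layer])
        att = layer.last_attention
        assert att.shape == (3, 2, 12, 12)
        np.testing.assert_allclose(att.sum(axis=-1), 1.0, atol=1e-6)
        assert (att >= 0).all()

    def test_two_token_hand_case(self):
        """Identity projections, d=1, tokens [1], [0]: scores row for the
        first token is [1, 0] and softmaxes to [e/(e+1), 1/(e+1)]."""
        layer = EncoderLayer(1, 1, 2, np.random.default_rng(0))
        for w in (layer.W_Q, layer.W_K, layer.W_V, layer.W_O):
            w.data = np.eye(1)
        z = np.array([[[1.0], [0.0]]])
        layer._mhsa(nn.Tensor(z))
        e = np.e
        np.testing.assert_allclose(
            layer.last_attention[0, 0],
            [[e / (e + 1), 1 / (e + 1)], [0.5, 0.5]],
            atol=1e-9,
        )
        np.testing.assert_allclose(
            layer.last_attention[0, 0, 0], [0.7311, 0.2689], atol=1e-4
        )

    def test_head_dim_mismatch_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            EncoderLayer(6, 4, 8, np.random.default_rng(0))


class TestClassify:
    def _head(self, k, c=4, zero=True):
        head = nn.Linear(c, k, np.random.default_rng(0))
        if zero:
            head.weight.data[:] = 0
            head.bias.data[:] = 0
        return head

    def test_uniform_posterior_for_zero_logits(self):
        pred = classify(np.random.default_rng(0).standard_normal((5, 4)), self._head(4))
        np.testing.assert_allclose(pred.probabilities, 0.25)
        assert pred.one_hot.tolist() == [1, 0, 0, 0]  # tie -> lowest index

    def test_one_hot_at_argmax(self):
        head = self._head(3, zero=True)
        head.bias.data = np.log(np.array([0.1, 0.7, 0.2]))
        pred = classify(np.zeros((2, 4)), head, classes=np.array(["a", "b", "c"]))
        np.testing.assert_allclose(pred.probabilities, [0.1, 0.7, 0.2], atol=1e-12)
        assert pred.one_hot.tolist() == [0, 1, 0]
        assert pred.predicted_id == "b"

    def test_logit_shift_invariance(self):
        head = self._head(3)
        head.bias.data = np.array([0.3, -1.2, 0.8])
        p1 = classify(np.zeros((1, 4)), head).probabilities
        head.bias.data = head.bias.data + 5.0
        p2 = classify(np.zeros((1, 4)), head).probabilities
        np.testing.assert_allclose(p1, p2, atol=1e-9)


class TestPersonIdentifier:
    def test_shape_contract_across_budgets(self):
        for budget in (4, 8, 16):
            net = CMANet(budget, 5, conv_channels=(8, 8, 8), seed=0)
            net.eval()
            x = np.random.default_rng(0).standard_normal((3, budget, 160))
            p = net(nn.Tensor(x)).softmax(axis=1).data
            assert p.shape == (3, 5)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_closed_set_and_determinism(self):
        rng = np.random.default_rng(0)
        t = np.arange(160) / 160
        X, y = [], []
        for i in range(30):
            subj = i % 3
            w = rng.standard_normal((2, 160))
            w[0] += 5 * np.sin(2 * np.pi * (8 + 2 * subj) * t + rng.uniform(0, 6))
            X.append(w / w.std(axis=1, keepdims=True))
            y.append(f"subject_{subj}")
        X, y = np.stack(X), np.array(y)
        hyper = dict(
            conv_channels=(8, 8), conv_kernels=(5, 3), conv_strides=(2, 2),
            n_layers=1, n_heads=2, ffn_dim=16,
            lr=0.02, batch_size=10, max_epochs=8, patience=8, seed=1,
        )
        est = PersonIdentifier(**hyper).fit(X, y)
        assert set(est.predict(X)) <= set(y)  # never outside the enrolled set
        assert est.net_.head.weight.data.shape[1] == 3  # one unit per identity
        est2 = PersonIdentifier(**hyper).fit(X, y)
        np.testing.assert_array_equal(
            est.net_.head.weight.data, est2.net_.head.weight.data
        )
        assert est.loss_history_[-1] < est.loss_history_[0]

    def test_single_identity_rejected(self):
        with pytest.raises(ValueError):
            PersonIdentifier().fit(np.zeros((4, 2, 160)), np.zeros(4))
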