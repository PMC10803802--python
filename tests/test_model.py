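"""Losses, last-token logits, prediction, adapters and the training loop."""

import math

import numpy as np
import pytest

from drgkit import (
    AdapterSpec,
    CcMccLabel,
    LinearBagBackbone,
    TinyAttentionBackbone,
    TrainConfig,
    apply_adapters,
    dissect,
    logits_last_token,
    predict_single,
    predict_two,
    single_label_loss,
    softmax,
    train,
    two_label_loss,
)
from drgkit.corpus import TokenSequence
from drgkit.model import cross_entropy, rank_logits


def oracle_ce(logits, target):
    """Independent scalar cross-entropy oracle: direct softmax evaluation."""
    e = [math.exp(v) for v in logits]
    return -math.log(e[target] / sum(e))


class TestLosses:
    def test_uniform_logits_give_log_c(self):
        for c in (3, 5, 738):
            assert single_label_loss(np.zeros(c), 0) == pytest.approx(math.log(c))

    def test_dominant_logit_example(self):
        # -log(e^10 / (e^10 + 2)) evaluated directly
        loss = single_label_loss(np.array([10.0, 0.0, 0.0]), 0)
        assert loss == pytest.approx(9.08e-5, rel=1e-2)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=20)
        a = single_label_loss(logits, 7)
        b = single_label_loss(logits + 123.4, 7)
        assert a == pytest.approx(b, rel=1e-9)

    def test_matches_oracle_on_100_random_cases(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(2, 40))
            logits = rng.normal(scale=3, size=n)
            t = int(rng.integers(n))
            assert single_label_loss(logits, t) == pytest.approx(
                oracle_ce(logits, t), rel=1e-6
            )

    def test_out_of_range_target_rejected(self):
        with pytest.raises(IndexError):
            single_label_loss(np.zeros(5), 5)

    def test_two_label_uniform(self):
        n_base = 340
        logits = np.zeros(n_base + 5)
        loss = two_label_loss(logits, 0, 0, n_base, lam=0.5)
        assert loss == pytest.approx(math.log(n_base) + 0.5 * math.log(5))

    def test_two_label_lambda_zero_is_base_only(self):
        rng = np.random.default_rng(2)
        logits = rng.normal(size=12 + 5)
        assert two_label_loss(logits, 3, 2, 12, lam=0.0) == pytest.approx(
            cross_entropy(logits[:12], 3)
        )

    def test_two_label_is_sum_of_component_oracles(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            nb = int(rng.integers(2, 30))
            logits = rng.normal(size=nb + 5)
            bt, ct = int(rng.integers(nb)), int(rng.integers(5))
            expect = oracle_ce(logits[:nb], bt) + 0.5 * oracle_ce(logits[nb:], ct)
            assert two_label_loss(logits, bt, ct, nb) == pytest.approx(expect, rel=1e-6)

    def test_softmax_sums_to_one_up_to_full_drg_dimension(self):
        rng = np.random.default_rng(4)
        for n in (2, 45, 738):
            p = softmax(rng.normal(scale=10, size=n))
            assert abs(p.sum() - 1.0) < 1e-9


class TestLogitsLastToken:
    def test_zero_head_gives_zero_logits(self):
        bb = TinyAttentionBackbone(n_labels=7, seed=0)
        bb.params["head_W"][:] = 0.0
        bb.params["head_b"][:] = 0.0
        out = logits_last_token(bb, TokenSequence((1, 2, 3)))
        assert np.allclose(out, 0.0)

    def test_single_token_collapses_to_head_of_embedding(self):
        bb = TinyAttentionBackbone(n_labels=4, seed=1)
        emb = bb.embed([5])
        out = logits_last_token(bb, TokenSequence((5,)))
        assert np.allclose(out, emb[0] @ bb.head_weight + bb.head_bias)

    def test_empty_sequence_rejected(self):
        bb = LinearBagBackbone(3, vocab_size=64)
        with pytest.raises(ValueError):
            logits_last_token(bb, TokenSequence(()))

    def test_matches_stepwise_forward_oracle(self):
        """Recompute the attention forward pass token by token, independently."""
        bb = TinyAttentionBackbone(n_labels=6, vocab_size=50, d=16, seed=7)
        ids = [3, 14, 1, 41, 9]
        p = bb.params
        X = np.array([p["E"][t] for t in ids]) + p["P"][: len(ids)]
        rows = []
        for i in range(len(ids)):  # causal: position i attends to 0..i
            q = X[i] @ p["Wq"]
            keys = X[: i + 1] @ p["Wk"]
            vals = X[: i + 1] @ p["Wv"]
            scores = keys @ q / np.sqrt(16)
            w = np.exp(scores - scores.max())
            w = w / w.sum()
            rows.append(X[i] + (w @ vals) @ p["Wo"])
        expect = rows[-1] @ p["head_W"] + p["head_b"]
        got = logits_last_token(bb, TokenSequence(tuple(ids)))
        assert np.allclose(got, expect, rtol=1e-6, atol=1e-9)

    def test_linear_bag_last_embedding_is_sequence_sum(self):
        bb = LinearBagBackbone(3, vocab_size=32)
        emb = bb.embed([1, 5, 1])
        counts = np.zeros(32)
        for t in (1, 5, 1):
            counts[t] += 1
        assert np.allclose(emb[-1], counts)


class TestPrediction:
    def test_dominant_logit_ranks_first(self):
        logits = np.array([0.0, 9.0, 1.0])
        pred = predict_single(logits, k=2)
        assert pred.indices[0] == 1

    def test_all_equal_logits_rank_by_index(self):
        pred = predict_single(np.zeros(6), k=6)
        assert pred.indices == (0, 1, 2, 3, 4, 5)

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(5)
        logits = rng.normal(size=40)
        pred = rank_logits(logits, k=10)
        oracle = sorted(range(40), key=lambda i: (-logits[i], i))[:10]
        assert list(pred.indices) == oracle
        probs = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(pred.probabilities, probs[oracle], rtol=1e-9)

    def test_predict_two_consistent_targets_round_trip(self, toy_catalog, toy_space):
        for c in toy_space.codes:
            _, b, cc = toy_space.targets_for(c.code)
            logits = np.full(toy_space.n_base + 5, -5.0)
            logits[b] = 5.0
            logits[toy_space.n_base + cc] = 5.0
            _, _, final = predict_two(logits, toy_catalog, toy_space)
            assert final.code == c.code

    def test_predict_two_applies_mapping_rule(self, toy_catalog, toy_space):
        b = toy_space.base_index("GAMMA REPAIR")  # two-way MCC vs rest
        logits = np.full(toy_space.n_base + 5, -5.0)
        logits[b] = 5.0
        logits[toy_space.n_base + int(CcMccLabel.WITH_CC)] = 5.0
        _, cc, final = predict_two(logits, toy_catalog, toy_space)
        assert cc is CcMccLabel.WITH_CC
        assert final.code == 7  # the WITHOUT MCC flavor


class TestAdapters:
    def test_identity_at_init_bit_for_bit(self):
        base = TinyAttentionBackbone(n_labels=5, seed=3)
        adapted = apply_adapters(base, AdapterSpec(r=4), seed=9)
        ids = TokenSequence((1, 8, 2, 2, 30))
        a = logits_last_token(base, ids)
        b = logits_last_token(adapted, ids)
        assert np.array_equal(a, b)  # B = 0 -> delta is exactly zero

    def test_random_factors_match_explicit_weight_oracle(self):
        spec = AdapterSpec(r=2, alpha=16)
        base = TinyAttentionBackbone(n_labels=5, d=24, seed=4)
        adapted = apply_adapters(base, spec, seed=1)
        rng = np.random.default_rng(11)
        for name in TinyAttentionBackbone.ATTENTION_WEIGHTS:
            B = rng.normal(size=(24, 2))
            A = rng.normal(size=(2, 24))
            adapted.lora[name] = (B, A, spec.scale)
        # explicit oracle: bake W0 + (alpha/r) B A into a plain backbone
        explicit = TinyAttentionBackbone(n_labels=5, d=24, seed=4)
        for name in TinyAttentionBackbone.ATTENTION_WEIGHTS:
            B, A, scale = adapted.lora[name]
            explicit.params[name] = base.params[name] + scale * (B @ A)
        ids = TokenSequence((7, 3, 19, 2))
        assert np.allclose(
            logits_last_token(adapted, ids),
            logits_last_token(explicit, ids),
            rtol=1e-6,
            atol=1e-12,
        )

    def test_full_rank_can_represent_any_delta(self):
        d = 8
        spec = AdapterSpec(r=d, alpha=d)  # scale 1
        base = TinyAttentionBackbone(n_labels=3, d=d, seed=5)
        adapted = apply_adapters(base, spec, seed=0)
        target_delta = np.random.default_rng(6).normal(size=(d, d))
        adapted.lora["Wq"] = (np.eye(d), target_delta, 1.0)
        assert np.allclose(adapted.effective_weight("Wq"), base.params["Wq"] + target_delta)

    def test_rank_larger_than_dimension_rejected(self):
        base = TinyAttentionBackbone(n_labels=3, d=8)
        with pytest.raises(ValueError):
            apply_adapters(base, AdapterSpec(r=16))

    def test_base_weights_shared_not_copied(self):
        base = TinyAttentionBackbone(n_labels=3, d=8)
        adapted = apply_adapters(base, AdapterSpec(r=2))
        assert adapted.params["Wq"] is base.params["Wq"]  # frozen, untouched


def _toy_texts():
    texts, labels = [], []
    for i, kw in enumerate(("alpha alpha", "beta beta", "gamma gamma")):
        for j in range(12):
            texts.append(f"{kw} common{j % 2}")
            labels.append(i)
    return texts, labels


class TestTrain:
    def test_separable_corpus_reaches_perfect_train_accuracy(self):
        texts, labels = _toy_texts()
        bb = LinearBagBackbone(3, vocab_size=256)
        cfg = TrainConfig(learning_rate=0.05, seed=0)
        fit = train(bb, texts, labels, cfg, mode="single")
        acc = (fit.score(texts).argmax(1) == np.array(labels)).mean()
        assert acc == 1.0
        assert fit.loss_trace[-1] < fit.loss_trace[0]

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        texts, labels = _toy_texts()
        bb = LinearBagBackbone(3, vocab_size=256, seed=1, init_scale=0.01)
        before = {k: v.copy() for k, v in bb.params.items()}
        train(bb, texts, labels, TrainConfig(learning_rate=0.0, seed=0), "single")
        for k in before:
            assert np.array_equal(bb.params[k], before[k])

    def test_deterministic_given_seed(self):
        texts, labels = _toy_texts()
        cfg = TrainConfig(learning_rate=0.05, seed=7)
        fits = []
        for _ in range(2):
            bb = LinearBagBackbone(3, vocab_size=256)
            fits.append(train(bb, texts, labels, cfg, "single"))
        assert np.array_equal(fits[0].backbone.params["head_W"], fits[1].backbone.params["head_W"])
        assert fits[0].loss_trace == fits[1].loss_trace

    def test_two_label_mode_trains_both_slices(self):
        texts, labels = _toy_texts()
        pairs = [(l, l % 5) for l in labels]  # base + cc targets
        bb = LinearBagBackbone(3 + 5, vocab_size=256)
        fit = train(
            bb, texts, pairs, TrainConfig(learning_rate=0.05, seed=0), "two", n_base=3
        )
        logits = fit.score(texts)
        assert (logits[:, :3].argmax(1) == np.array(labels)).mean() == 1.0
        assert (logits[:, 3:].argmax(1) == np.array([c for _, c in pairs])).mean() == 1.0

    def test_empty_training_set_rejected(self):
        bb = LinearBagBackbone(3, vocab_size=64)
        with pytest.raises(ValueError):
            train(bb, [], [], TrainConfig(), "single")

    def test_train_config_defaults(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 2e-5
        assert cfg.weight_decay == 0.01
        assert cfg.epochs == 3
        assert cfg.batch_size == 4
        assert cfg.lam == 0.5
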