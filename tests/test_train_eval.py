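"""Pairing, splits, metrics (with brute-force oracles), training behaviour."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from topoeeg import (Discriminator, Generator, RMSProp, TrainingConfig,
                     adversarial_train, auc_metric, average_precision,
                     classify_subjects, drifting_blob_sequences,
                     evaluate_prediction, identity_baseline_mae, mae,
                     make_pairs, map_metric, pretrain_generator,
                     split_subjects)
from topoeeg.pigat_gan import bce_grad_logits, bce_loss
from topoeeg.train_eval import PIPair


class TestMakePairs:
    def test_window_count_arithmetic(self, rng):
        seqs = {("s0", "Alpha"): rng.random((40, 4, 4))}
        assert len(make_pairs(seqs)) == 39

    def test_two_windows_one_pair(self, rng):
        seqs = {("s0", "Alpha"): rng.random((2, 4, 4))}
        pairs = make_pairs(seqs)
        assert len(pairs) == 1
        assert np.array_equal(pairs[0].y, seqs[("s0", "Alpha")][1])

    def test_pairs_never_cross_subjects(self, rng):
        seqs = {("a", "Alpha"): rng.random((5, 4, 4)),
                ("b", "Alpha"): rng.random((7, 4, 4))}
        pairs = make_pairs(seqs)
        assert len(pairs) == 4 + 6
        for p in pairs:
            src = seqs[(p.subject_id, p.band)]
            assert np.array_equal(p.x, src[p.t])
            assert np.array_equal(p.y, src[p.t + 1])

    def test_singleton_sequences_skipped(self, rng, caplog):
        seqs = {("solo", "Alpha"): rng.random((1, 4, 4))}
        with caplog.at_level("WARNING", logger="topoeeg"):
            assert make_pairs(seqs) == []
        assert "singleton" in caplog.text


class TestSplit:
    def test_disjoint_and_reproducible(self):
        ids = [f"s{i}" for i in range(20)]
        a = split_subjects(ids, seed=3)
        b = split_subjects(ids, seed=3)
        assert a == b
        train, val, test = a
        assert set(train) | set(val) | set(test) == set(ids)
        assert not (set(train) & set(val) or set(train) & set(test)
                    or set(val) & set(test))
        assert len(test) == 4  # 20% of 20
        assert len(val) == 2   # 10% of the training portion

    def test_different_seeds_differ(self):
        ids = [f"s{i}" for i in range(20)]
        assert split_subjects(ids, 0) != split_subjects(ids, 1)


class TestMetrics:
    def test_mae_examples(self):
        # sum |y_i - yhat_i| / n with n = 2 entries: (1 + 0) / 2
        assert mae([0.0, 0.5], [1.0, 0.5]) == pytest.approx(0.5)
        assert mae([0.3, 0.7], [0.3, 0.7]) == 0.0
        a, b = np.array([0.1, 0.9, 0.4]), np.array([0.2, 0.5, 0.9])
        perm = [2, 0, 1]
        assert mae(a, b) == pytest.approx(mae(a[perm], b[perm]))
        with pytest.raises(ValueError):
            mae(np.zeros(3), np.zeros(4))

    def test_ap_worked_example(self):
        assert average_precision([0.9, 0.8, 0.7], [1, 0, 1]) == \
            pytest.approx(5.0 / 6.0)

    def test_ap_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_ap_requires_positives(self):
        with pytest.raises(ValueError):
            average_precision([0.5, 0.2], [0, 0])

    def test_map_of_identical_queries_equals_single_ap(self):
        q = (np.array([0.9, 0.8, 0.7]), np.array([1, 0, 1]))
        assert map_metric([q, q, q]) == pytest.approx(5.0 / 6.0)

    def test_auc_examples(self):
        assert auc_metric([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auc_metric([0.4, 0.4, 0.4, 0.4], [1, 0, 1, 0]) == 0.5
        assert auc_metric([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == \
            pytest.approx(0.75)  # 3 of 4 pos/neg pairs correctly ordered
        with pytest.raises(ValueError):
            auc_metric([0.1, 0.2], [1, 1])

    def test_metrics_match_brute_force_and_sklearn(self):
        """Random instances <= 12 items against enumeration and sklearn."""
        for seed in range(25):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 13))
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # brute-force AUC: count correctly ordered pos/neg pairs
            pos, neg = scores[labels == 1], scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc_metric(scores, labels) == \
                pytest.approx(wins / (len(pos) * len(neg)))
            assert auc_metric(scores, labels) == \
                pytest.approx(roc_auc_score(labels, scores))
            # brute-force AP: precision at each positive hit in rank order
            order = np.argsort(-scores, kind="stable")
            hits, ap_terms = 0, []
            for rank, idx in enumerate(order, start=1):
                if labels[idx]:
                    hits += 1
                    ap_terms.append(hits / rank)
            assert average_precision(scores, labels) == \
                pytest.approx(np.mean(ap_terms))
            if len(np.unique(scores)) == len(scores):
                # sklearn groups tied scores into one threshold; the rank
                # formulation only coincides with it on untied inputs
                assert average_precision(scores, labels) == \
                    pytest.approx(average_precision_score(labels, scores))


def constant_target_pairs(rng, n=12, r=8):
    target = rng.random((r, r))
    return [PIPair("s0", "b", t, rng.random((r, r)), target.copy())
            for t in range(n)]


class TestPretraining:
    def test_constant_targets_are_learned(self, rng):
        pairs = constant_target_pairs(rng)
        cfg = TrainingConfig(resolution=8, epochs_pretrain=8, seed=0)
        gen = Generator(8, seed=0)
        curve = pretrain_generator(gen, pairs, cfg)
        assert curve[-1] < curve[0]

    def test_seeded_curves_identical(self, rng):
        pairs = constant_target_pairs(rng)
        cfg = TrainingConfig(resolution=8, epochs_pretrain=3, seed=5)
        c1 = pretrain_generator(Generator(8, seed=1), pairs, cfg)
        c2 = pretrain_generator(Generator(8, seed=1), pairs, cfg)
        assert c1 == c2

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            pretrain_generator(Generator(8, seed=0), [],
                               TrainingConfig(resolution=8))


class TestAdversarial:
    def test_seeded_curves_identical(self, rng):
        pairs = constant_target_pairs(rng)
        cfg = TrainingConfig(resolution=8, epochs_joint=3, seed=2)
        out1 = adversarial_train(Generator(8, seed=1), Discriminator(8, seed=1),
                                 pairs, cfg)
        out2 = adversarial_train(Generator(8, seed=1), Discriminator(8, seed=1),
                                 pairs, cfg)
        assert out1 == out2

    def test_discriminator_learns_real_vs_frozen_fake(self, rng):
        """On a frozen untrained generator, disc accuracy exceeds 0.9."""
        seqs = drifting_blob_sequences(4, 8, 8, seed=0)
        pairs = make_pairs(seqs)
        x = np.stack([p.x for p in pairs])
        y = np.stack([p.y for p in pairs])
        gen = Generator(8, seed=0)
        fake = gen.forward(x)
        disc = Discriminator(8, seed=0)
        opt = RMSProp(disc.params, lr=0.01)
        for _epoch in range(20):
            disc.zero_grads()
            pr = disc.forward(y)
            disc.backward(bce_grad_logits(pr, np.ones(len(y))))
            pf = disc.forward(fake)
            disc.backward(bce_grad_logits(pf, np.zeros(len(y))))
            opt.step(disc.params, disc.grads)
        acc = 0.5 * ((disc.forward(y) > 0.5).mean()
                     + (disc.forward(fake) <= 0.5).mean())
        assert acc > 0.9


class TestEvaluation:
    def test_oracle_generator_scores_perfectly(self, rng):
        class Identity:
            def forward(self, x, **kw):
                return np.asarray(x)

        imgs = rng.random((6, 8, 8))
        pairs = [PIPair("s", "b", t, imgs[t], imgs[t]) for t in range(6)]
        cfg = TrainingConfig(resolution=8)
        rep = evaluate_prediction(Identity(), pairs, cfg)
        assert rep.mae == 0.0
        assert rep.auc == 1.0
        assert rep.map == 1.0

    def test_constant_generator_is_uninformative(self, rng):
        class Half:
            def forward(self, x, **kw):
                return np.full_like(np.asarray(x), 0.5)

        imgs = rng.random((5, 8, 8))
        pairs = [PIPair("s", "b", t, imgs[t], imgs[t]) for t in range(5)]
        rep = evaluate_prediction(Half(), pairs, TrainingConfig(resolution=8))
        assert rep.auc == pytest.approx(0.5)
        assert rep.mae > 0.0

    def test_trained_model_beats_identity_baseline_on_drifting_blobs(self):
        """The forecaster must beat copying PI_t forward on drifting data."""
        seqs = drifting_blob_sequences(8, 8, 12, seed=3)
        ids = sorted({k[0] for k in seqs})
        train = make_pairs({k: v for k, v in seqs.items() if k[0] in ids[:6]})
        test = make_pairs({k: v for k, v in seqs.items() if k[0] in ids[6:]})
        cfg = TrainingConfig(resolution=12, epochs_pretrain=60,
                             gat_dropout=0.0, seed=3)
        gen = Generator(12, dropout=0.0, seed=3)
        pretrain_generator(gen, train, cfg)
        rep = evaluate_prediction(gen, test, cfg)
        assert rep.mae < identity_baseline_mae(test)


class TestClassification:
    def test_score_determinism_and_single_class_error(self, rng):
        imgs = rng.random((4, 8, 8))
        pairs = {"a": [PIPair("a", "b", 0, imgs[0], imgs[1])],
                 "c": [PIPair("c", "b", 0, imgs[2], imgs[3])]}
        gen = Generator(8, seed=0)
        cfg = TrainingConfig(resolution=8)
        labels = {"a": "patient", "c": "control"}
        s1, auc1 = classify_subjects(gen, pairs, labels, cfg)
        s2, auc2 = classify_subjects(gen, pairs, labels, cfg)
        assert s1 == s2 and auc1 == auc2
        with pytest.raises(ValueError):
            classify_subjects(gen, pairs, {"a": "patient", "c": "patient"}, cfg)

    def test_disc_mode_requires_discriminator(self, rng):
        imgs = rng.random((2, 8, 8))
        pairs = {"a": [PIPair("a", "b", 0, imgs[0], imgs[1])],
                 "c": [PIPair("c", "b", 0, imgs[0], imgs[1])]}
        labels = {"a": "patient", "c": "control"}
        with pytest.raises(ValueError):
            classify_subjects(Generator(8, seed=0), pairs, labels,
                              TrainingConfig(resolution=8), mode="disc")


def test_bce_matches_closed_form():
    p = np.array([0.8, 0.3])
    t = np.array([1.0, 0.0])
    expected = np.mean([-np.log(0.8), -np.log(0.7)])
    assert bce_loss(p, t) == pytest.approx(expected)
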