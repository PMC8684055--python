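"""CRF exactness (against brute-force enumeration), LSTM gradients,
training behavior and checkpointing."""

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp

import farmaner as f
from farmaner.tagger import (TagVocabulary, TaggerConfig, TaggerModel,
                             crf_log_likelihood, crf_log_partition,
                             crf_marginals, crf_path_score, viterbi_decode)


# ---------------------------------------------------------------------------
# Brute-force oracle: enumerate every tag path explicitly
# ---------------------------------------------------------------------------

def enumerate_paths(emissions, transitions, start, stop):
    n, T = emissions.shape
    scores = {}
    for path in itertools.product(range(T), repeat=n):
        s = transitions[start, path[0]] + emissions[0, path[0]]
        for t in range(1, n):
            s += transitions[path[t - 1], path[t]] + emissions[t, path[t]]
        s += transitions[path[-1], stop]
        scores[path] = s
    return scores


def random_instance(rng, n, T):
    em = rng.normal(size=(n, T))
    trans = rng.normal(size=(T + 2, T + 2))
    return em, trans, T, T + 1


class TestCrfAgainstBruteForce:
    @pytest.mark.parametrize("n,T", [(n, T) for n in range(1, 7)
                                     for T in range(2, 6)])
    def test_log_partition_equals_enumeration(self, n, T):
        rng = np.random.default_rng(100 * n + T)
        em, trans, start, stop = random_instance(rng, n, T)
        scores = enumerate_paths(em, trans, start, stop)
        brute = logsumexp(np.array(list(scores.values())))
        assert crf_log_partition(em, trans, start, stop) == \
            pytest.approx(brute, abs=1e-6)

    @pytest.mark.parametrize("n,T", [(n, T) for n in range(1, 7)
                                     for T in range(2, 6)])
    def test_viterbi_equals_enumeration(self, n, T):
        rng = np.random.default_rng(200 * n + T)
        em, trans, start, stop = random_instance(rng, n, T)
        scores = enumerate_paths(em, trans, start, stop)
        best = max(scores.values())
        path = viterbi_decode(em, trans, start, stop)
        assert crf_path_score(em, trans, path, start, stop) == \
            pytest.approx(best, abs=1e-9)

    def test_uniform_two_tokens_two_tags(self):
        em = np.zeros((2, 2))
        trans = np.zeros((4, 4))
        ll = crf_log_likelihood(em, trans, np.array([0, 1]), 2, 3)
        assert ll == pytest.approx(-np.log(4.0))

    def test_uniform_single_token(self):
        T = 5
        em = np.zeros((1, T))
        trans = np.zeros((T + 2, T + 2))
        ll = crf_log_likelihood(em, trans, np.array([3]), T, T + 1)
        assert ll == pytest.approx(-np.log(T))

    def test_log_likelihood_never_positive(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            em, trans, start, stop = random_instance(rng, 4, 3)
            gold = rng.integers(0, 3, size=4)
            assert crf_log_likelihood(em, trans, gold, start, stop) <= 1e-12

    def test_forbidden_transition_never_decoded(self):
        rng = np.random.default_rng(11)
        T = 3
        for _ in range(20):
            em = rng.normal(size=(5, T))
            trans = rng.normal(size=(T + 2, T + 2))
            trans[0, 1] = -np.inf  # forbid tag0 -> tag1
            path = viterbi_decode(em, trans, T, T + 1)
            for a, b in zip(path, path[1:]):
                assert not (a == 0 and b == 1)

    def test_marginals_sum_to_one(self):
        rng = np.random.default_rng(13)
        em, trans, start, stop = random_instance(rng, 5, 4)
        unary, _, _ = crf_marginals(em, trans, start, stop)
        assert np.allclose(unary.sum(axis=1), 1.0)

    def test_tag_outside_vocabulary_rejected(self):
        em = np.zeros((2, 3))
        trans = np.zeros((5, 5))
        with pytest.raises(ValueError):
            crf_log_likelihood(em, trans, np.array([0, 7]), 3, 4)


class TestEmissions:
    def _model(self, dropout=0.0):
        stack = f.build_stack([{"type": "hashed", "dim": 6, "seed": 1}])
        return TaggerModel(stack, TagVocabulary(),
                           TaggerConfig(hidden_size=5, seed=3,
                                        dropout=dropout))

    def test_shape_contract(self):
        m = self._model()
        E = np.zeros((4, 6))
        assert m.emission_scores(E).shape == (4, m.vocab.n_tags)

    def test_inference_deterministic(self):
        m = self._model(dropout=0.5)  # dropout must be off at inference
        E = np.random.default_rng(0).normal(size=(3, 6))
        assert np.array_equal(m.emission_scores(E), m.emission_scores(E))

    def test_width_mismatch_rejected(self):
        m = self._model()
        with pytest.raises(ValueError):
            m.emission_scores(np.zeros((3, 7)))

    def test_gradients_match_finite_differences(self):
        m = self._model()
        rng = np.random.default_rng(0)
        E = rng.normal(size=(3, 6))
        gold = np.array([0, 1, 2])
        _, grads = m._sentence_grads(E, gold, None)
        eps = 1e-6
        for key in ("Wo", "Wp", "fw_Wx", "bw_Wh", "trans"):
            p = m.params[key]
            idx = tuple(min(1, s - 1) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            up = m._sentence_grads(E, gold, None)[0]
            p[idx] = orig - eps
            dn = m._sentence_grads(E, gold, None)[0]
            p[idx] = orig
            assert grads[key][idx] == pytest.approx((up - dn) / (2 * eps),
                                                    rel=1e-4, abs=1e-7)


def _memorization_setup(seed=3):
    doc = f.AnnotatedDocument("d1", "El paciente tomo metoprida ayer.", [
        f.EntityMention("d1", "NORMALIZABLES", 17, 26, "metoprida")])
    stack = f.build_stack([{"type": "hashed", "dim": 16, "seed": 1}])
    cfg = TaggerConfig(hidden_size=12, max_epochs=200, batch_size=4,
                       seed=seed, dropout=0.0)
    return doc, stack, cfg


class TestTraining:
    def test_empty_corpus_rejected(self):
        stack = f.build_stack([{"type": "hashed", "dim": 4, "seed": 1}])
        with pytest.raises(ValueError):
            f.train_tagger([], stack)

    def test_memorizes_single_sentence(self):
        doc, stack, cfg = _memorization_setup()
        model = f.train_tagger([doc], stack, cfg)
        preds = f.predict(model, doc)
        assert [(m.label, m.start, m.end) for m in preds] == \
            [("NORMALIZABLES", 17, 26)]

    def test_identical_seed_identical_parameters(self):
        doc, stack, cfg = _memorization_setup()
        cfg.max_epochs = 5
        m1 = f.train_tagger([doc], stack, cfg)
        stack2 = f.build_stack([{"type": "hashed", "dim": 16, "seed": 1}])
        m2 = f.train_tagger([doc], stack2, cfg)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_loss_non_increasing_small_lr(self, caplog):
        """On a one-batch corpus with a small learning rate, training loss
        decreases monotonically."""
        doc, stack, _ = _memorization_setup()
        cfg = TaggerConfig(hidden_size=8, learning_rate=0.01,
                           max_epochs=15, batch_size=8, seed=1, dropout=0.0)
        import logging
        with caplog.at_level(logging.INFO, logger="farmaner.tagger"):
            f.train_tagger([doc], stack, cfg)
        losses = [float(rec.message.split("nll/sentence ")[1].split(",")[0])
                  for rec in caplog.records if "nll/sentence" in rec.message]
        assert len(losses) == 15
        assert all(a >= b - 1e-9 for a, b in zip(losses, losses[1:]))

    def test_save_load_predict_bit_identical(self, tmp_path):
        doc, stack, cfg = _memorization_setup()
        cfg.max_epochs = 30
        model = f.train_tagger([doc], stack, cfg)
        before = f.predict(model, doc)
        path = tmp_path / "model.npz"
        model.save(str(path))
        loaded = TaggerModel.load(str(path))
        for k in model.params:
            assert np.array_equal(model.params[k], loaded.params[k])
        assert f.predict(loaded, doc) == before

    def test_predict_empty_document(self):
        doc, stack, cfg = _memorization_setup()
        cfg.max_epochs = 1
        model = f.train_tagger([doc], stack, cfg)
        assert f.predict(model, "") == []
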