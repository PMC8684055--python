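"""BiLSTM-CRF sequence labeler for BIO-tagged entity recognition.

The architecture follows the classic neural sequence-labeling recipe: each
sentence is embedded token-by-token by a stacked embedding, a forward and a
backward LSTM read the sequence in both directions, a tanh projection maps
the concatenated states to per-tag confidence scores, and a linear-chain
CRF layer with learned transition scores decodes the best tag path jointly
(Viterbi) instead of tagging tokens independently.  Training minimizes the
negative CRF log-likelihood by mini-batch SGD.

Everything is plain numpy with hand-written backpropagation: forward-
backward marginals for the CRF gradient and BPTT through both LSTMs.  All
randomness (initialization, shuffling, dropout) flows through one seeded
generator, so identical seeds give bit-identical models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import logsumexp

from .corpus import (AnnotatedDocument, EntityMention, LABELS, decode_bio,
                     encode_bio, group_tokens_by_sentence, tokenize)
from .embeddings import StackedEmbedding, build_stack

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration and tag vocabulary
# ---------------------------------------------------------------------------

@dataclass
class TaggerConfig:
    """Hyperparameters of the tagger.

    The defaults are the published operating point: learning rate 0.1,
    dropout 0.5, at most 150 epochs, 300 hidden units per LSTM direction
    with a tanh projection, batches of 32 sentences.  SGD halves the
    learning rate when the monitored metric plateaus (patience 3) and
    clips gradients at global norm 5 — common practice for this
    architecture, exposed here as configuration.
    """

    hidden_size: int = 300
    learning_rate: float = 0.1
    dropout: float = 0.5
    max_epochs: int = 150
    batch_size: int = 32
    projection_activation: str = "tanh"
    seed: int = 1
    clip_norm: float = 5.0
    plateau_patience: int = 3
    early_stop_patience: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        for name in ("hidden_size", "max_epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.projection_activation not in ("tanh", "identity"):
            raise ValueError("projection_activation must be tanh or "
                             "identity")


class TagVocabulary:
    """Ordered BIO tag set plus START/STOP sentinels for the CRF."""

    def __init__(self, labels: tuple[str, ...] = LABELS):
        self.labels = tuple(labels)
        self.tags = ["O"]
        for lab in self.labels:
            self.tags.extend([f"B-{lab}", f"I-{lab}"])
        self.tag_to_idx = {t: i for i, t in enumerate(self.tags)}
        self.n_tags = len(self.tags)
        self.start = self.n_tags       # sentinel row/col indices
        self.stop = self.n_tags + 1

    def encode(self, tags: list[str]) -> np.ndarray:
        try:
            return np.array([self.tag_to_idx[t] for t in tags], dtype=int)
        except KeyError as exc:
            raise ValueError(f"tag outside vocabulary: {exc}") from exc

    def decode(self, indices) -> list[str]:
        return [self.tags[int(i)] for i in indices]


# ---------------------------------------------------------------------------
# CRF layer: scoring, partition, marginals, Viterbi
# ---------------------------------------------------------------------------

def crf_path_score(emissions: np.ndarray, transitions: np.ndarray,
                   tags: np.ndarray, start: int, stop: int) -> float:
    """Unnormalized score of one tag path."""
    score = transitions[start, tags[0]] + emissions[0, tags[0]]
    for t in range(1, len(tags)):
        score += transitions[tags[t - 1], tags[t]] + emissions[t, tags[t]]
    return float(score + transitions[tags[-1], stop])


def crf_log_partition(emissions: np.ndarray, transitions: np.ndarray,
                      start: int, stop: int) -> float:
    """Log of the sum of exponentiated scores over all tag paths (forward
    algorithm)."""
    n, T = emissions.shape
    alpha = transitions[start, :T] + emissions[0]
    for t in range(1, n):
        alpha = logsumexp(alpha[:, None] + transitions[:T, :T], axis=0) \
            + emissions[t]
    return float(logsumexp(alpha + transitions[:T, stop]))


def crf_log_likelihood(emissions: np.ndarray, transitions: np.ndarray,
                       tags: np.ndarray, start: int, stop: int) -> float:
    """score(gold path) - logZ; always <= 0."""
    n, T = emissions.shape
    if len(tags) != n:
        raise ValueError("emissions and gold tags disagree in length")
    if np.any((tags < 0) | (tags >= T)):
        raise ValueError("tag index outside vocabulary")
    return (crf_path_score(emissions, transitions, tags, start, stop)
            - crf_log_partition(emissions, transitions, start, stop))


def crf_marginals(emissions: np.ndarray, transitions: np.ndarray,
                  start: int, stop: int
                  ) -> tuple[np.ndarray, np.ndarray, float]:
    """Forward-backward pass.

    Returns (unary marginals (n, T), expected transition counts over the
    full (T+2, T+2) matrix, logZ).
    """
    n, T = emissions.shape
    alpha = np.zeros((n, T))
    alpha[0] = transitions[start, :T] + emissions[0]
    for t in range(1, n):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + transitions[:T, :T],
                             axis=0) + emissions[t]
    log_z = float(logsumexp(alpha[-1] + transitions[:T, stop]))
    beta = np.zeros((n, T))
    beta[-1] = transitions[:T, stop]
    for t in range(n - 2, -1, -1):
        beta[t] = logsumexp(transitions[:T, :T]
                            + (emissions[t + 1] + beta[t + 1])[None, :],
                            axis=1)
    unary = np.exp(alpha + beta - log_z)
    expected = np.zeros_like(transitions)
    for t in range(n - 1):
        pair = np.exp(alpha[t][:, None] + transitions[:T, :T]
                      + (emissions[t + 1] + beta[t + 1])[None, :] - log_z)
        expected[:T, :T] += pair
    expected[start, :T] += unary[0]
    expected[:T, stop] += unary[-1]
    return unary, expected, log_z


def viterbi_decode(emissions: np.ndarray, transitions: np.ndarray,
                   start: int, stop: int) -> np.ndarray:
    """The argmax-scoring tag path; ties resolve to the lowest tag index
    at each backtrack step, so decoding is deterministic."""
    n, T = emissions.shape
    if n == 0:
        raise ValueError("cannot decode an empty emission matrix")
    delta = transitions[start, :T] + emissions[0]
    psi = np.zeros((n, T), dtype=int)
    for t in range(1, n):
        scores = delta[:, None] + transitions[:T, :T]
        psi[t] = np.argmax(scores, axis=0)
        delta = scores[psi[t], np.arange(T)] + emissions[t]
    final = delta + transitions[:T, stop]
    path = np.zeros(n, dtype=int)
    path[-1] = int(np.argmax(final))
    for t in range(n - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path


# ---------------------------------------------------------------------------
# LSTM with backpropagation through time
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm_forward(X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray,
                 b: np.ndarray) -> tuple[np.ndarray, dict]:
    """Run an LSTM over ``X`` (n, D); returns hidden states (n, H) and the
    cache needed for BPTT.  Gate order in the fused weights: input, forget,
    cell, output."""
    n = X.shape[0]
    H = Wh.shape[0]
    h = np.zeros(H)
    c = np.zeros(H)
    hs = np.zeros((n, H))
    cache: dict = {"X": X, "gates": [], "c_prev": [], "h_prev": [],
                   "tanh_c": []}
    for t in range(n):
        a = X[t] @ Wx + h @ Wh + b
        i = _sigmoid(a[:H])
        f = _sigmoid(a[H:2 * H])
        g = np.tanh(a[2 * H:3 * H])
        o = _sigmoid(a[3 * H:])
        cache["c_prev"].append(c)
        cache["h_prev"].append(h)
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[t] = h
        cache["gates"].append((i, f, g, o))
        cache["tanh_c"].append(tc)
    return hs, cache


def lstm_backward(dH: np.ndarray, cache: dict, Wx: np.ndarray,
                  Wh: np.ndarray) -> dict:
    """BPTT given the gradient on every hidden state."""
    X = cache["X"]
    n = X.shape[0]
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dh_next = np.zeros(H)
    dc_next = np.zeros(H)
    for t in range(n - 1, -1, -1):
        i, f, g, o = cache["gates"][t]
        tc = cache["tanh_c"][t]
        dh = dH[t] + dh_next
        do = dh * tc
        dc = dh * o * (1 - tc * tc) + dc_next
        di = dc * g
        dg = dc * i
        df = dc * cache["c_prev"][t]
        dc_next = dc * f
        da = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                             dg * (1 - g * g), do * o * (1 - o)])
        dWx += np.outer(X[t], da)
        dWh += np.outer(cache["h_prev"][t], da)
        db += da
        dh_next = da @ Wh.T
    return {"Wx": dWx, "Wh": dWh, "b": db}


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class TaggerModel:
    """BiLSTM-CRF parameters bound to an embedding stack and a tag set."""

    PARAM_KEYS = ("fw_Wx", "fw_Wh", "fw_b", "bw_Wx", "bw_Wh", "bw_b",
                  "Wp", "bp", "Wo", "bo", "trans")

    def __init__(self, stack: StackedEmbedding, vocab: TagVocabulary,
                 config: TaggerConfig,
                 params: dict[str, np.ndarray] | None = None):
        self.stack = stack
        self.vocab = vocab
        self.config = config
        D = stack.total_dim
        H = config.hidden_size
        T = vocab.n_tags
        if params is None:
            rng = np.random.default_rng(config.seed)
            params = {}
            for prefix in ("fw", "bw"):
                params[f"{prefix}_Wx"] = rng.normal(
                    0, 1 / np.sqrt(D), (D, 4 * H))
                params[f"{prefix}_Wh"] = rng.normal(
                    0, 1 / np.sqrt(H), (H, 4 * H))
                b = np.zeros(4 * H)
                b[H:2 * H] = 1.0  # forget-gate bias
                params[f"{prefix}_b"] = b
            # tanh projection layer (H neurons) then linear map to tags
            params["Wp"] = rng.normal(0, 1 / np.sqrt(2 * H), (2 * H, H))
            params["bp"] = np.zeros(H)
            params["Wo"] = rng.normal(0, 1 / np.sqrt(H), (H, T))
            params["bo"] = np.zeros(T)
            params["trans"] = np.zeros((T + 2, T + 2))
        self.params = params

    # -- inference ---------------------------------------------------------

    def emission_scores(self, embedded: np.ndarray) -> np.ndarray:
        """Per-token confidence scores (n, |tags|) at inference (no
        dropout); deterministic given parameters and input."""
        em, _ = self._emissions_with_cache(embedded, dropout_rng=None)
        return em

    def _emissions_with_cache(self, E: np.ndarray, dropout_rng):
        p = self.params
        D = self.stack.total_dim
        if E.ndim != 2 or E.shape[1] != D:
            raise ValueError(f"embedded sentence has width "
                             f"{E.shape[1] if E.ndim == 2 else '?'}, "
                             f"model expects {D}")
        cache: dict = {}
        rate = self.config.dropout
        if dropout_rng is not None and rate > 0:
            mask_in = (dropout_rng.random(E.shape) >= rate) / (1 - rate)
            E = E * mask_in
            cache["mask_in"] = mask_in
        h_f, cache_f = lstm_forward(E, p["fw_Wx"], p["fw_Wh"], p["fw_b"])
        h_b_rev, cache_b = lstm_forward(E[::-1], p["bw_Wx"], p["bw_Wh"],
                                        p["bw_b"])
        H2 = np.hstack([h_f, h_b_rev[::-1]])
        if dropout_rng is not None and rate > 0:
            mask_out = (dropout_rng.random(H2.shape) >= rate) / (1 - rate)
            H2 = H2 * mask_out
            cache["mask_out"] = mask_out
        A = H2 @ p["Wp"] + p["bp"]
        Z = np.tanh(A) if self.config.projection_activation == "tanh" else A
        em = Z @ p["Wo"] + p["bo"]
        cache.update(E=E, cache_f=cache_f, cache_b=cache_b, H2=H2, Z=Z)
        return em, cache

    def _sentence_grads(self, E: np.ndarray, gold: np.ndarray,
                        dropout_rng) -> tuple[float, dict[str, np.ndarray]]:
        """Negative log-likelihood of one sentence and its parameter
        gradients."""
        p = self.params
        vocab = self.vocab
        em, cache = self._emissions_with_cache(E, dropout_rng)
        unary, expected, log_z = crf_marginals(
            em, p["trans"], vocab.start, vocab.stop)
        gold_score = crf_path_score(em, p["trans"], gold, vocab.start,
                                    vocab.stop)
        nll = log_z - gold_score
        # CRF gradients: expected counts minus observed gold counts
        d_trans = expected.copy()
        d_trans[vocab.start, gold[0]] -= 1
        for t in range(1, len(gold)):
            d_trans[gold[t - 1], gold[t]] -= 1
        d_trans[gold[-1], vocab.stop] -= 1
        dem = unary.copy()
        dem[np.arange(len(gold)), gold] -= 1
        Z = cache["Z"]
        dZ = dem @ p["Wo"].T
        if self.config.projection_activation == "tanh":
            dA = dZ * (1 - Z ** 2)
        else:
            dA = dZ
        H2 = cache["H2"]
        grads = {"Wo": Z.T @ dem, "bo": dem.sum(axis=0),
                 "Wp": H2.T @ dA, "bp": dA.sum(axis=0), "trans": d_trans}
        dH2 = dA @ p["Wp"].T
        if "mask_out" in cache:
            dH2 = dH2 * cache["mask_out"]
        H = self.config.hidden_size
        g_f = lstm_backward(dH2[:, :H], cache["cache_f"], p["fw_Wx"],
                            p["fw_Wh"])
        g_b = lstm_backward(dH2[::-1, H:], cache["cache_b"], p["bw_Wx"],
                            p["bw_Wh"])
        for k, v in g_f.items():
            grads[f"fw_{k}"] = v
        for k, v in g_b.items():
            grads[f"bw_{k}"] = v
        return nll, grads

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        """Single-archive checkpoint: parameters plus tag vocabulary,
        config, and the embedding-provider manifest."""
        meta = {"labels": list(self.vocab.labels),
                "config": asdict(self.config),
                "manifest": self.stack.manifest()}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode("utf-8"), dtype=np.uint8),
            **self.params)

    @classmethod
    def load(cls, path: str,
             stack: StackedEmbedding | None = None) -> "TaggerModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode("utf-8"))
            params = {k: data[k] for k in cls.PARAM_KEYS}
        config = TaggerConfig(**meta["config"])
        vocab = TagVocabulary(tuple(meta["labels"]))
        if stack is None:
            stack = _stack_from_manifest(meta["manifest"])
        return cls(stack, vocab, config, params=params)


def _stack_from_manifest(manifest: list[dict]) -> StackedEmbedding:
    spec = []
    for entry in manifest:
        kind = entry["type"]
        if kind == "StaticProvider":
            if entry.get("vocab_size", 0):
                raise ValueError(
                    "checkpoint used a file-backed static provider; pass "
                    "the reconstructed stack to TaggerModel.load")
            spec.append({"type": "hashed", "dim": entry["dim"],
                         "seed": entry.get("seed", 0),
                         "name": entry.get("name")})
        elif kind == "ContextualProvider":
            spec.append({"type": "contextual", "hidden": entry["hidden"],
                         "char_dim": entry["char_dim"],
                         "seed": entry.get("seed", 0),
                         "name": entry.get("name")})
        elif kind == "PooledContextualProvider":
            spec.append({"type": "pooled-contextual",
                         "hidden": entry["hidden"],
                         "char_dim": entry["char_dim"],
                         "pooling": entry.get("pooling", "mean"),
                         "seed": entry.get("seed", 0),
                         "name": entry.get("name")})
        else:
            raise ValueError(f"cannot rebuild provider {kind!r}")
    return build_stack(spec)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _prepare_sentences(docs: list[AnnotatedDocument],
                       stack: StackedEmbedding, vocab: TagVocabulary):
    """Tokenize, BIO-encode and embed every sentence once (the embedding
    providers are fixed during training, so their output is cacheable)."""
    prepared = []
    for doc in docs:
        stack.reset()
        tokens = tokenize(doc.text)
        groups = group_tokens_by_sentence(tokens)
        tags = encode_bio(doc, tokens)
        for sent_tokens, sent_tags in zip(groups, tags):
            if not sent_tokens:
                continue
            words = [t.surface(doc.text) for t in sent_tokens]
            E = stack.embed_sentence(words)
            prepared.append((E, vocab.encode(sent_tags)))
    return prepared


def train_tagger(train_docs: list[AnnotatedDocument],
                 stack: StackedEmbedding,
                 config: TaggerConfig | None = None,
                 dev_docs: list[AnnotatedDocument] | None = None,
                 ) -> TaggerModel:
    """Train a BiLSTM-CRF on annotated documents.

    Mini-batch SGD on the mean negative CRF log-likelihood, with gradient
    clipping and plateau-based learning-rate halving.  When ``dev_docs``
    is given, development micro-F1 drives early stopping and the best
    parameters are restored; otherwise training runs for
    ``config.max_epochs`` epochs.
    """
    from .evaluation import match_entities, micro_metrics  # cycle-free

    config = config or TaggerConfig()
    if not train_docs:
        raise ValueError("training corpus is empty")
    vocab = TagVocabulary()
    model = TaggerModel(stack, vocab, config)
    rng = np.random.default_rng(config.seed + 1)
    sentences = _prepare_sentences(train_docs, stack, vocab)
    if not sentences:
        raise ValueError("training corpus contains no tokenized sentences")
    lr = config.learning_rate
    best_metric = -np.inf
    best_params: dict[str, np.ndarray] | None = None
    stale = 0
    plateau = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(sentences))
        total_nll = 0.0
        for lo in range(0, len(order), config.batch_size):
            batch = order[lo:lo + config.batch_size]
            acc: dict[str, np.ndarray] = {
                k: np.zeros_like(v) for k, v in model.params.items()}
            for idx in batch:
                E, gold = sentences[idx]
                nll, grads = model._sentence_grads(E, gold, rng)
                if not np.isfinite(nll):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}")
                total_nll += nll
                for k, g in grads.items():
                    acc[k] += g
            scale = 1.0 / len(batch)
            gnorm = np.sqrt(sum(float(np.sum((g * scale) ** 2))
                                for g in acc.values()))
            clip = min(1.0, config.clip_norm / gnorm) if gnorm > 0 else 1.0
            for k in model.params:
                model.params[k] -= lr * scale * clip * acc[k]
        mean_nll = total_nll / len(sentences)
        if dev_docs is not None:
            preds = []
            golds = []
            for doc in dev_docs:
                preds.extend(predict(model, doc))
                golds.extend(doc.mentions)
            metric = micro_metrics(match_entities(golds, preds)).f1
        else:
            metric = -mean_nll
        logger.info("epoch %d: nll/sentence %.4f, metric %.4f, lr %.4g",
                    epoch, mean_nll, metric, lr)
        if metric > best_metric + 1e-12:
            best_metric = metric
            best_params = {k: v.copy() for k, v in model.params.items()}
            stale = 0
            plateau = 0
        else:
            stale += 1
            plateau += 1
        if plateau >= config.plateau_patience:
            lr *= 0.5
            plateau = 0
            logger.info("plateau: halving learning rate to %.4g", lr)
        if dev_docs is not None and (best_metric >= 1.0
                                     or stale >= config.early_stop_patience):
            break
    if best_params is not None:
        model.params = best_params
    return model


def predict(model: TaggerModel, document) -> list[EntityMention]:
    """Tag a document: tokenize, embed, score, Viterbi-decode, map the BIO
    runs back to character-offset mentions."""
    if isinstance(document, AnnotatedDocument):
        text, doc_id = document.text, document.doc_id
    else:
        text, doc_id = str(document), "doc"
    model.stack.reset()
    tokens = tokenize(text)
    groups = group_tokens_by_sentence(tokens)
    mentions: list[EntityMention] = []
    for sent_tokens in groups:
        if not sent_tokens:
            continue
        words = [t.surface(text) for t in sent_tokens]
        E = model.stack.embed_sentence(words)
        em = model.emission_scores(E)
        path = viterbi_decode(em, model.params["trans"], model.vocab.start,
                              model.vocab.stop)
        tags = model.vocab.decode(path)
        mentions.extend(decode_bio(sent_tokens, tags, text, doc_id))
    return mentions
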