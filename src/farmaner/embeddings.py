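"""Per-token vector providers and their concatenation.

Three provider families feed the tagger:

* static word vectors loaded from the standard text word-vector format
  (one provider instance for general-domain vectors, another for
  corpus-trained medical vectors — both are plain lookup tables here);
* a character-level contextual encoder: a seeded bidirectional recurrent
  net over the sentence's characters, so the same word gets different
  vectors in different contexts;
* the pooled variant of the contextual encoder, which concatenates each
  fresh occurrence vector with a running pool (mean/min/max) of the word's
  previously seen vectors.

A :class:`StackedEmbedding` concatenates any ordered subset of providers
into the tagger input; the row width is the sum of the provider dims.
"""

from __future__ import annotations

import gzip
import hashlib
import io
from dataclasses import dataclass

import numpy as np


class VectorFormatError(ValueError):
    """A word-vector file line that cannot be parsed."""


def _stable_word_seed(word: str, seed: int) -> np.random.Generator:
    digest = hashlib.blake2b(word.encode("utf-8"), digest_size=8).digest()
    h = int.from_bytes(digest, "big")
    return np.random.default_rng([seed & 0x7FFFFFFF, h & 0xFFFFFFFF,
                                  (h >> 32) & 0xFFFFFFFF])


def hashed_vector(word: str, dim: int, seed: int = 0) -> np.ndarray:
    """Deterministic unit-norm vector that is a pure function of
    (word, dim, seed) — the out-of-vocabulary fallback."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = _stable_word_seed(word, seed)
    v = rng.standard_normal(dim)
    norm = np.linalg.norm(v)
    while norm < 1e-12:  # vanishing draws are essentially impossible
        v = rng.standard_normal(dim)
        norm = np.linalg.norm(v)
    return v / norm


class Provider:
    """Interface: per-token vectors for a tokenized sentence."""

    name: str = "provider"
    dim: int

    def embed_sentence(self, words: list[str]) -> np.ndarray:
        raise NotImplementedError

    def reset(self) -> None:
        """Forget any cross-sentence state (no-op for static providers)."""


class StaticProvider(Provider):
    """Context-free lookup: one pre-computed vector per word form.

    Lookup order: verbatim, then lowercased, then the OOV policy
    (``zero`` or deterministic ``hashed`` vectors).
    """

    def __init__(self, vocabulary: dict[str, np.ndarray], dim: int,
                 oov_policy: str = "hashed", seed: int = 0,
                 name: str = "static"):
        if oov_policy not in ("zero", "hashed"):
            raise ValueError(f"unknown oov_policy {oov_policy!r}")
        for w, v in vocabulary.items():
            if len(v) != dim:
                raise VectorFormatError(
                    f"vector for {w!r} has length {len(v)}, expected {dim}")
        self.vocabulary = {w: np.asarray(v, dtype=np.float64)
                           for w, v in vocabulary.items()}
        self.dim = dim
        self.oov_policy = oov_policy
        self.seed = seed
        self.name = name

    def lookup(self, word: str) -> np.ndarray:
        v = self.vocabulary.get(word)
        if v is None:
            v = self.vocabulary.get(word.lower())
        if v is not None:
            return v
        if self.oov_policy == "zero":
            return np.zeros(self.dim)
        return hashed_vector(word, self.dim, self.seed)

    def embed_sentence(self, words: list[str]) -> np.ndarray:
        if not words:
            return np.zeros((0, self.dim))
        return np.stack([self.lookup(w) for w in words])


def load_static_vectors(source, expected_dim: int | None = None,
                        oov_policy: str = "hashed", seed: int = 0,
                        name: str = "static") -> StaticProvider:
    """Load a text word-vector file (``word v1 ... vd`` per line; an
    optional leading ``count dim`` header is auto-detected).  ``source`` may
    be a path (``.gz`` transparently decompressed) or a text stream."""
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        path = str(source)
        opener = gzip.open if path.endswith(".gz") else open
        stream = opener(path, "rt", encoding="utf-8")
    elif isinstance(source, io.TextIOBase) or hasattr(source, "read"):
        stream = source
    else:
        raise TypeError(f"cannot read vectors from {type(source)!r}")
    vocab: dict[str, np.ndarray] = {}
    dim: int | None = None
    with stream:
        for lineno, raw in enumerate(stream, start=1):
            parts = raw.rstrip("\n").split(" ")
            parts = [p for p in parts if p]
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:  # "count dim" header
                    int(parts[0]), int(parts[1])
                    continue
                except ValueError:
                    pass
            word, values = parts[0], parts[1:]
            try:
                vec = np.array([float(x) for x in values])
            except ValueError as exc:
                raise VectorFormatError(
                    f"line {lineno}: non-numeric vector component") from exc
            if dim is None:
                dim = len(vec)
            elif len(vec) != dim:
                raise VectorFormatError(
                    f"line {lineno}: expected {dim} components, "
                    f"got {len(vec)}")
            vocab[word] = vec
    if dim is None:
        raise VectorFormatError("empty word-vector file")
    if expected_dim is not None and dim != expected_dim:
        raise VectorFormatError(
            f"file has dimension {dim}, configuration expects {expected_dim}")
    return StaticProvider(vocab, dim, oov_policy=oov_policy, seed=seed,
                          name=name)


class ContextualProvider(Provider):
    """Character-level bidirectional recurrent encoder.

    The sentence is rendered as its characters (tokens joined by single
    spaces) and passed through a forward and a backward tanh recurrence
    over seeded character embeddings.  A token's vector is the forward
    state at its last character concatenated with the backward state at
    its first character, so ``dim = 2 * hidden``.  Weights are fixed after
    seeded initialization; the encoder is deterministic and produces
    context-dependent vectors for any character string.
    """

    def __init__(self, hidden: int = 32, char_dim: int = 16, seed: int = 0,
                 name: str = "contextual"):
        if hidden < 1 or char_dim < 1:
            raise ValueError("hidden and char_dim must be >= 1")
        rng = np.random.default_rng(seed)
        scale_x = 1.0 / np.sqrt(char_dim)
        scale_h = 1.0 / np.sqrt(hidden)
        self.W_fx = rng.normal(0, scale_x, (char_dim, hidden))
        self.W_fh = rng.normal(0, scale_h, (hidden, hidden))
        self.b_f = np.zeros(hidden)
        self.W_bx = rng.normal(0, scale_x, (char_dim, hidden))
        self.W_bh = rng.normal(0, scale_h, (hidden, hidden))
        self.b_b = np.zeros(hidden)
        self.hidden = hidden
        self.char_dim = char_dim
        self.seed = seed
        self.dim = 2 * hidden
        self.name = name
        self._char_cache: dict[str, np.ndarray] = {}

    def _char_vec(self, c: str) -> np.ndarray:
        v = self._char_cache.get(c)
        if v is None:
            v = hashed_vector(c, self.char_dim, self.seed + 7)
            self._char_cache[c] = v
        return v

    def embed_sentence(self, words: list[str]) -> np.ndarray:
        if not words:
            return np.zeros((0, self.dim))
        text = " ".join(words)
        # character offsets of each token within the joined string
        bounds = []
        pos = 0
        for w in words:
            bounds.append((pos, pos + max(len(w), 1) - 1))
            pos += len(w) + 1
        chars = [self._char_vec(c) for c in text]
        n = len(chars)
        fwd = np.zeros((n, self.hidden))
        h = np.zeros(self.hidden)
        for t in range(n):
            h = np.tanh(chars[t] @ self.W_fx + h @ self.W_fh + self.b_f)
            fwd[t] = h
        bwd = np.zeros((n, self.hidden))
        h = np.zeros(self.hidden)
        for t in range(n - 1, -1, -1):
            h = np.tanh(chars[t] @ self.W_bx + h @ self.W_bh + self.b_b)
            bwd[t] = h
        rows = [np.concatenate([fwd[last], bwd[first]])
                for first, last in bounds]
        return np.stack(rows)


@dataclass
class _Pool:
    total: np.ndarray
    count: int
    mn: np.ndarray
    mx: np.ndarray


class PooledContextualProvider(Provider):
    """Pooled contextual embeddings: each occurrence's fresh vector is
    concatenated with a running pool (``mean``/``min``/``max``) of the
    word's previous occurrence vectors.  The pool depends only on the
    occurrences seen so far and :meth:`reset` restores first-occurrence
    behavior exactly."""

    def __init__(self, base: ContextualProvider, pooling: str = "mean",
                 name: str = "pooled-contextual"):
        if pooling not in ("mean", "min", "max"):
            raise ValueError(f"unknown pooling op {pooling!r}")
        self.base = base
        self.pooling = pooling
        self.dim = 2 * base.dim
        self.name = name
        self._memory: dict[str, _Pool] = {}

    def reset(self) -> None:
        self._memory.clear()

    def pooled_lookup(self, word: str, fresh_vector: np.ndarray) -> np.ndarray:
        """Update the word's memory with this occurrence and return
        ``concat(fresh, pool)``; on the first occurrence the pool equals the
        fresh vector."""
        mem = self._memory.get(word)
        if mem is None:
            mem = _Pool(fresh_vector.copy(), 1, fresh_vector.copy(),
                        fresh_vector.copy())
            self._memory[word] = mem
        else:
            mem.total = mem.total + fresh_vector
            mem.count += 1
            mem.mn = np.minimum(mem.mn, fresh_vector)
            mem.mx = np.maximum(mem.mx, fresh_vector)
        if self.pooling == "mean":
            pool = mem.total / mem.count
        elif self.pooling == "min":
            pool = mem.mn
        else:
            pool = mem.mx
        return np.concatenate([fresh_vector, pool])

    def embed_sentence(self, words: list[str]) -> np.ndarray:
        fresh = self.base.embed_sentence(words)
        if not words:
            return np.zeros((0, self.dim))
        return np.stack([self.pooled_lookup(w, fresh[i])
                         for i, w in enumerate(words)])


class StackedEmbedding:
    """Ordered concatenation of providers into the tagger input."""

    def __init__(self, providers: list[Provider]):
        if not providers:
            raise ValueError("a stacked embedding needs at least one "
                             "provider")
        self.providers = list(providers)
        self.total_dim = sum(p.dim for p in providers)

    def reset(self) -> None:
        for p in self.providers:
            p.reset()

    def embed_sentence(self, words: list[str]) -> np.ndarray:
        parts = []
        for p in self.providers:
            try:
                parts.append(p.embed_sentence(words))
            except Exception as exc:
                raise RuntimeError(
                    f"embedding provider {p.name!r} failed") from exc
        if not words:
            return np.zeros((0, self.total_dim))
        return np.hstack(parts)

    def manifest(self) -> list[dict]:
        """Serializable description, for model checkpoints."""
        out = []
        for p in self.providers:
            entry: dict = {"name": p.name, "dim": p.dim,
                           "type": type(p).__name__}
            if isinstance(p, StaticProvider):
                entry.update(oov_policy=p.oov_policy, seed=p.seed,
                             vocab_size=len(p.vocabulary))
            elif isinstance(p, ContextualProvider):
                entry.update(hidden=p.hidden, char_dim=p.char_dim,
                             seed=p.seed)
            elif isinstance(p, PooledContextualProvider):
                entry.update(pooling=p.pooling, hidden=p.base.hidden,
                             char_dim=p.base.char_dim, seed=p.base.seed)
            out.append(entry)
        return out


def build_stack(spec: list[dict]) -> StackedEmbedding:
    """Build a stack from a configuration list.

    Each item needs a ``type``: ``static`` (with ``path`` or inline
    ``vocabulary``), ``hashed`` (pure OOV-hash provider with ``dim``),
    ``contextual`` or ``pooled-contextual`` (with ``hidden``, ``char_dim``,
    optional ``pooling``).  All accept ``seed`` and ``name``.
    """
    providers: list[Provider] = []
    for item in spec:
        kind = item.get("type")
        seed = int(item.get("seed", 0))
        name = item.get("name", kind)
        if kind == "static":
            if "path" in item:
                providers.append(load_static_vectors(
                    item["path"], expected_dim=item.get("dim"),
                    oov_policy=item.get("oov_policy", "hashed"), seed=seed,
                    name=name))
            else:
                vocab = {w: np.asarray(v)
                         for w, v in item.get("vocabulary", {}).items()}
                providers.append(StaticProvider(
                    vocab, int(item["dim"]),
                    oov_policy=item.get("oov_policy", "hashed"),
                    seed=seed, name=name))
        elif kind == "hashed":
            providers.append(StaticProvider(
                {}, int(item["dim"]), oov_policy="hashed", seed=seed,
                name=name))
        elif kind == "contextual":
            providers.append(ContextualProvider(
                hidden=int(item.get("hidden", 32)),
                char_dim=int(item.get("char_dim", 16)), seed=seed,
                name=name))
        elif kind == "pooled-contextual":
            base = ContextualProvider(
                hidden=int(item.get("hidden", 32)),
                char_dim=int(item.get("char_dim", 16)), seed=seed)
            providers.append(PooledContextualProvider(
                base, pooling=item.get("pooling", "mean"), name=name))
        else:
            raise ValueError(f"unknown provider type {kind!r}")
    return StackedEmbedding(providers)
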