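# Methods

## The recognition model

The tagger is a linear-chain BiLSTM-CRF.  A sentence of `n` tokens is
embedded row-wise into `X ∈ R^{n×D}` by the configured embedding stack.
A forward LSTM and a backward LSTM (each with `H` hidden units) produce
states `h_t = [h_t^→ ; h_t^←] ∈ R^{2H}`.  Emission scores are
`e_t = W_o tanh(W_p h_t + b_p) + b_o ∈ R^{T}` — a tanh layer of `H`
neurons predicting per-tag confidences through a final linear map, so the
scores are unbounded and the projection output width equals the tag-set
size.  A transition matrix over the `T` BIO tags plus START/STOP
sentinels scores tag bigrams; the score of a path is the sum of its
emissions and transitions, and training minimizes the negative
log-likelihood `log Z − score(gold)` where `log Z` is computed by the
forward algorithm.  Decoding is exact Viterbi with ties resolved to the
lowest tag index at every backtrack step.

Everything is plain numpy with hand-written gradients: CRF gradients are
expected-minus-observed sufficient statistics from the forward–backward
marginals, and both LSTMs are differentiated by backpropagation through
time.  The implementation is validated two ways: `log Z` and the Viterbi
path score are compared against brute-force enumeration of all `T^n`
paths for every `n ≤ 6`, `T ≤ 5`, and the full gradient is compared
against central finite differences.

**Default hyperparameters** are the published operating point: learning
rate 0.1, dropout 0.5 (applied to the embedding output and the BiLSTM
output), at most 150 epochs, 300 hidden units per direction with the tanh
projection, batch size 32 sentences.  Choices the source description
leaves open are config-exposed with conventional defaults: plain SGD with
learning-rate halving on plateau (patience 3), gradient clipping at
global norm 5, early stopping on development micro-F1 when a development
split is given.  "300 neurons" is read as *per direction*; CRF
transitions are learned unconstrained and invalid BIO output is repaired
during decoding (an orphan `I-X` starts a new mention) rather than masked
with −∞, keeping the probabilistic model simple.  All randomness —
initialization, shuffling, dropout — flows through one seeded generator,
so identical seeds give bit-identical models, and checkpoints reload
bit-compatibly.

## Embeddings

Three provider families can be stacked in any order; the tagger input
width is the sum of their dims.

* **Static providers** map each word form to one pre-computed vector
  (text word-vector format, optional `count dim` header, gzip
  transparent).  Lookup is verbatim first, lowercase second, then the
  out-of-vocabulary policy.  The general-domain (dim 100) and medical
  (dim 300) vector sets used at full scale are both static providers;
  training the medical vectors (skip-gram, lr 0.05, dim 300, 10 epochs,
  min count 5) happens with external tooling and is out of scope here —
  the files are simply loaded.
* **Hashed OOV vectors** are deterministic unit-norm vectors that are a
  pure function of (word, dim, seed).  They are the default OOV policy
  (rather than zeros) so synthetic experiments exercise distinct inputs
  per word type without any vector file.
* **Contextual provider**: a character-level bidirectional tanh
  recurrence over the sentence's characters; a token's vector is the
  forward state at its last character concatenated with the backward
  state at its first.  The same word therefore gets different vectors in
  different contexts.  Weights are fixed after seeded initialization:
  the encoder is a deterministic random feature map, which is sufficient
  for every behavioral contract tested here; joint fine-tuning with the
  tagger was considered and not implemented (it would triple the
  hand-written gradient surface for no tested benefit).
* **Pooled contextual**: each occurrence's fresh vector is concatenated
  with a running pool (mean by default; min/max available) of the word's
  previous occurrence vectors.  The pool depends only on occurrences
  seen so far, and resetting the memory restores first-occurrence
  behavior exactly.  Memory is reset per document.

## Concept indexing

All resources and queries are normalized identically and idempotently:
lowercase → accent stripping (NFD, combining marks removed) → lemmatizer
(identity by default; a rule-based Spanish plural stripper ships as an
optional plug-in) → punctuation replaced by spaces → stopword removal →
whitespace collapse.  The stopword list holds multi-letter function words
only ("de", "del", "la", …): single vowels are kept because they are
designators in terms like *proteína A amiloide* or *vitamina E*.  A term
consisting solely of stopwords keeps its words rather than vanishing.

The pipeline runs four stages in strict order and records which stage
fired, the matched description and the edit distance:

1. **supervised** — normalized surface found in the training code map
   (collisions resolve by majority vote, ties by lowest numeric code);
2. **exact** — the normalized entity, else any dictionary synonym, else
   any token permutation of entity or synonyms, equals a catalog
   description (distance 0; ties to the lowest code).  Permutations are
   capped at 6 tokens (720 orderings).  Exact matches outrank all fuzzy
   matches regardless of the entity-to-description distance — otherwise
   a synonym-mediated match like *GGT → gamma-glutamiltransferasa* could
   never beat a short near-miss description;
3. **fuzzy** — suggestion candidates ranked by Levenshtein distance
   between catalog description and the *normalized input entity* (a
   config flag switches to ranking against the generating candidate),
   ties by shorter description, then lower code;
4. **none** — empty catalog, or the best fuzzy distance exceeds the
   configured cap (no cap by default).

**The suggestion gate.**  The original system obtained fuzzy candidates
from a spell-suggester, which proposes entries resembling the query, and
only then ranked them by edit distance.  Replacing that step by a plain
nearest-description search changes the outcomes: raw edit distance favors
any short description over a related long one (for *beta hcg* the nearest
catalog description by raw distance is the unrelated *antiarina* at
distance 7, while the correct *gonadotrofina corionica humana* sits at
distance 26).  The matcher therefore emulates the suggester with a
character-trigram gate: only descriptions sharing at least one trigram
with some query form (entity, synonym, or permutation) are candidates,
falling back to the whole catalog when the gate matches nothing (e.g.
short acronyms like *antiRNA*, whose nearest description is then returned
— reproducing the documented failure on that mention).  The gate is a
config flag (`trigram_gate`); `suggest_candidates` itself remains a pure
k-nearest search.  Every tie-break in the pipeline is total (distance,
description length, numeric code), so output is deterministic.

Levenshtein distance is a two-row dynamic program written here (the
primitive is central to the method); tests verify it against an
independent full-matrix DP and against the `edlib` library on random
string pairs, and check symmetry, identity and the triangle inequality.

Per document, the assigned codes are deduplicated into a set of unique
concept identifiers; UNCLEAR mentions are skipped, matching the
evaluation protocol.

## Evaluation

A system mention is a true positive iff a gold mention with identical
(document, start, end, label) exists; matching is one-to-one by multiset
intersection, so duplicated spans cannot double-count.  Unmatched system
mentions are FP, unmatched gold mentions FN; UNCLEAR is excluded from
both sides.  Micro metrics pool TP/FP/FN over labels before computing
P/R/F1; zero denominators yield 0 with a logged warning rather than an
error.  Indexing is scored over per-document code sets with the same
machinery (a per-mention mode exists behind the audit output).  McNemar's
test uses the continuity-corrected statistic `(|b−c|−1)²/(b+c)` with a
chi-square (1 df) p-value, or the exact two-sided binomial tail for small
discordant counts; `b + c = 0` gives p = 1.

## Synthetic data

The generator emulates the shape of the target corpus, not its content:
documents of Poisson(25) sentences; mentions allocated to the four
categories by the published train-split counts (2304 / 24 / 1405 / 89)
using largest-remainder allocation, which hits the mix deterministically
even for the rare class where multinomial sampling would not; ~0.3
mentions per sentence; templated Spanish-like carrier sentences with slot
insertion so character offsets are exact by construction; a small rate
(5%) of injected nonsense tokens as carrier noise; synthetic gold codes
for the normalizable categories.  Entity gazetteers are label-disjoint
and disjoint from the carrier vocabulary, which makes the learning
benchmark well-posed, and every fourth entry is multi-word so span
decoding is exercised.  What the generator does **not** emulate: real
vocabulary statistics, annotation noise, overlapping or discontinuous
mentions, boundary ambiguity between gold and tokenizer.  Passing the
benchmark therefore demonstrates that the implementation can learn a
learnable corpus, not that it reaches the published corpus-scale scores,
which require the real corpus, licensed terminology, pretrained vectors
and GPU-scale training.

The **separable benchmark** (`farmaner.synth.separable_benchmark`) is the
scaled-down operating point chosen for a single CPU: 50 training / 10
development / 20 test documents, hashed static vectors (dim 48) stacked
with small pooled character-contextual embeddings (hidden 8), 32 LSTM
units per direction, SGD at 0.3 without dropout, at most 80 epochs with
early stopping on development F1 (patience 12).  Across seeds it reaches
held-out micro-F1 ≈ 0.97–0.99; the test suite requires ≥ 0.95 for each of
three seeds.  Dropout is disabled at this scale because the benchmark
measures memorization-plus-slight-generalization of a separable corpus,
where regularization noise only slows convergence.

## Corpus I/O conventions

Offsets are 0-based, half-open, in Unicode code points.  The BRAT reader
accepts entity (`T`) and note (`#… AnnotatorNotes`) lines; relation,
event and attribute lines are rejected, and discontinuous mentions are
unsupported.  A surface string disagreeing with `text[start:end]` is
flagged and the text substring wins.  Concept gold can also be supplied
as a TSV (`doc_id[\tmention_id]\tcode`).  The tokenizer splits on
whitespace and detaches punctuation as single-character tokens, keeping
punctuation flanked by digits (decimals, `15-3`) attached; it is lossless
by construction.  The sentence splitter terminates on `.`, `!`, `?` and
newline with a configurable abbreviation guard and digit-internal period
protection.  BIO encoding snaps mention boundaries outward to covering
tokens (never inward, so no gold characters are dropped) and resolves
overlapping gold mentions by keeping the longest (tie: earliest start) —
BIO cannot express overlaps and the choice is logged, not silent.

## Known limitations

* The contextual encoder is a fixed random character network, not a
  pretrained language model; its vectors carry form and context but no
  distributional semantics.
* No subword n-gram composition for OOV lookup of static vectors; the
  hashed fallback stands in.
* The indexer has no semantic-type filtering or contextual
  disambiguation beyond the stated ranking; acronyms absent from both
  the dictionary and the catalog resolve to their nearest description,
  which is sometimes wrong by design (see *antiRNA*).
* Corpus-scale scores on the real corpus are out of scope: they depend
  on resources (licensed terminology, pretrained embeddings, the
  original corpus) that this repository deliberately does not require.
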