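"""SNOMED-CT concept indexing for recognized chemical/drug mentions.

Each mention is assigned a single concept code by a hybrid pipeline:

1. **supervised** — look the normalized surface up in a code map harvested
   from coded training mentions;
2. **exact** — the normalized entity, any dictionary synonym of it, or any
   token permutation of those, equals a catalog description (distance 0);
3. **fuzzy** — rank suggestion candidates from the concept catalog by
   Levenshtein distance to the normalized entity and take the closest;
4. **none** — no code (empty catalog, or fuzzy disabled / over the distance
   cap).

The suggestion stage emulates a spell-suggester: only catalog descriptions
sharing at least one character trigram with some query form (entity, synonym
or permutation) are candidates; when the gate matches nothing the whole
catalog is searched.  This keeps wildly dissimilar short descriptions from
outranking a related long one on raw edit distance, while still always
returning the nearest description for unknown single-word acronyms.

All resources and queries are normalized identically: lowercase, accents
stripped, lemmatized (identity by default), punctuation removed, Spanish
stopwords removed.
"""

from __future__ import annotations

import itertools
import logging
import unicodedata
from collections.abc import Callable, Iterable
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

NONE_CODE = "NONE"

#: Connectives that disappear during normalization, so that e.g.
#: "isoenzimas de FA" and "isoenzimas FA" are the same term.  Single vowels
#: are deliberately absent: "a"/"e" are designators in terms like
#: "proteína A amiloide" or "vitamina E", not function words.
DEFAULT_STOPWORDS = (
    "de", "del", "la", "el", "los", "las", "lo", "y",
    "en", "con", "por", "para", "un", "una", "unos", "unas", "al",
)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationConfig:
    """How terms are standardized before any matching.

    ``lemmatizer`` is a per-token rewriter applied after accent stripping;
    the default is the identity.  Normalization must be idempotent, which
    holds for any lemmatizer that is itself idempotent.
    """

    lowercase: bool = True
    strip_accents: bool = True
    lemmatizer: Callable[[str], str] | None = None
    stopwords: tuple[str, ...] = DEFAULT_STOPWORDS


def strip_accents(text: str) -> str:
    """Remove combining marks (á → a, ü → u) via NFD decomposition."""
    decomposed = unicodedata.normalize("NFD", text)
    return unicodedata.normalize(
        "NFC", "".join(c for c in decomposed if not unicodedata.combining(c)))


def spanish_plural_stripper(token: str) -> str:
    """Optional rule-based lemmatizer: strip Spanish plural endings.

    Very small on purpose — it only rewrites ``-es``/``-s`` endings on
    tokens long enough for the ending to plausibly be a plural, with an
    exception list for common false friends.
    """
    exceptions = {"mes", "tres", "dos", "gas", "crisis", "dosis", "virus",
                  "pus", "lunes", "martes", "viernes", "analisis"}
    if token in exceptions or len(token) <= 3:
        return token
    if token.endswith("es") and len(token) > 4:
        return token[:-2]
    if token.endswith("s"):
        return token[:-1]
    return token


def normalize_term(text: str,
                   config: NormalizationConfig | None = None) -> str:
    """Standardize a term: lowercase, strip accents, lemmatize, drop
    punctuation and stopwords, collapse whitespace.  Idempotent."""
    config = config or NormalizationConfig()
    if config.lowercase:
        text = text.lower()
    if config.strip_accents:
        text = strip_accents(text)
    # punctuation (anything neither alphanumeric nor whitespace) -> space
    text = "".join(c if (c.isalnum() or c.isspace()) else " " for c in text)
    words = text.split()
    if config.lemmatizer is not None:
        words = [config.lemmatizer(w) for w in words]
    stop = set(config.stopwords)
    kept = [w for w in words if w not in stop]
    if not kept:  # an all-stopword term keeps its words rather than vanishing
        kept = words
    return " ".join(kept)


# ---------------------------------------------------------------------------
# Resources
# ---------------------------------------------------------------------------

class SynonymDictionary:
    """Equivalence classes of co-referring normalized terms.

    Groups from all sources are union-merged: if two groups share a member
    they become one class, so synonymy is symmetric and transitive.
    """

    def __init__(self) -> None:
        self._group_of: dict[str, int] = {}
        self._groups: list[set[str]] = []

    def add_group(self, terms: Iterable[str]) -> None:
        terms = [t for t in terms if t]
        if len(terms) < 2 and not any(t in self._group_of for t in terms):
            if not terms:
                return
        target: int | None = None
        for t in terms:
            if t in self._group_of:
                gid = self._group_of[t]
                if target is None:
                    target = gid
                elif gid != target:  # merge two existing classes
                    src = self._groups[gid]
                    self._groups[target] |= src
                    for member in src:
                        self._group_of[member] = target
                    src.clear()
        if target is None:
            target = len(self._groups)
            self._groups.append(set())
        for t in terms:
            self._groups[target].add(t)
            self._group_of[t] = target

    def group(self, term: str) -> set[str]:
        gid = self._group_of.get(term)
        return set(self._groups[gid]) if gid is not None else set()

    def synonyms(self, term: str) -> set[str]:
        """The term's synonym group minus itself; empty when unknown."""
        return self.group(term) - {term}

    def __len__(self) -> int:
        return sum(1 for g in self._groups if g)


def build_synonym_dictionary(sources: Iterable[Iterable[str]],
                             config: NormalizationConfig | None = None,
                             ) -> SynonymDictionary:
    """Build a dictionary from TSV sources (one synonym group per line,
    TAB-separated terms).  Terms are normalized; groups sharing members are
    merged across sources."""
    config = config or NormalizationConfig()
    d = SynonymDictionary()
    n_sources = 0
    for source in sources:
        n_sources += 1
        for line in source:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            terms = [normalize_term(t, config) for t in line.split("\t")]
            d.add_group(terms)
    if n_sources == 0:
        logger.warning("no synonym sources given; dictionary is empty")
    return d


@dataclass(frozen=True)
class CatalogEntry:
    code: str
    description: str  # normalized


class ConceptCatalog:
    """The terminology searched by the unsupervised matcher: rows of
    (numeric code, normalized description); one code may carry several
    descriptions."""

    def __init__(self, entries: Iterable[tuple[str, str]],
                 config: NormalizationConfig | None = None) -> None:
        config = config or NormalizationConfig()
        self.entries: list[CatalogEntry] = []
        self._by_description: dict[str, list[CatalogEntry]] = {}
        for code, description in entries:
            code = code.strip()
            if not code or not code.isdigit():
                raise ValueError(f"catalog code must be a digit string, "
                                 f"got {code!r}")
            entry = CatalogEntry(code, normalize_term(description, config))
            self.entries.append(entry)
            self._by_description.setdefault(entry.description, []).append(entry)

    @classmethod
    def from_tsv(cls, lines: Iterable[str],
                 config: NormalizationConfig | None = None) -> "ConceptCatalog":
        pairs = []
        for lineno, line in enumerate(lines, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"catalog TSV line {lineno}: expected "
                                 f"code<TAB>description")
            pairs.append((parts[0], parts[1]))
        return cls(pairs, config)

    def lookup_description(self, description: str) -> list[CatalogEntry]:
        """All entries whose description equals ``description`` exactly."""
        return list(self._by_description.get(description, []))

    def __len__(self) -> int:
        return len(self.entries)


class TrainingCodeMap:
    """Supervised surface → code map harvested from coded training mentions.

    Collisions resolve by majority vote, ties by the lowest numeric code.
    """

    def __init__(self, mapping: dict[str, str]):
        self._map = dict(mapping)

    def get(self, normalized_surface: str) -> str | None:
        return self._map.get(normalized_surface)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, term: str) -> bool:
        return term in self._map


def build_training_code_map(coded_mentions: Iterable[tuple[str, str]],
                            config: NormalizationConfig | None = None,
                            ) -> TrainingCodeMap:
    """Build the supervised map from (surface, code) pairs."""
    config = config or NormalizationConfig()
    votes: dict[str, dict[str, int]] = {}
    for surface, code in coded_mentions:
        if code is None:
            continue
        term = normalize_term(surface, config)
        votes.setdefault(term, {})
        votes[term][code] = votes[term].get(code, 0) + 1
    mapping = {}
    for term, counts in votes.items():
        best = sorted(counts.items(),
                      key=lambda kv: (-kv[1], _code_sort_key(kv[0])))[0][0]
        mapping[term] = best
    return TrainingCodeMap(mapping)


def _code_sort_key(code: str) -> tuple[int, str]:
    return (int(code), code) if code.isdigit() else (1 << 62, code)


# ---------------------------------------------------------------------------
# Matching primitives
# ---------------------------------------------------------------------------

def levenshtein(a: str, b: str) -> int:
    """Minimal number of single-character edits (insert, delete, substitute)
    transforming ``a`` into ``b``.  Two-row dynamic program."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) > len(b):
        a, b = b, a
    prev = list(range(len(a) + 1))
    for j, cb in enumerate(b, start=1):
        cur = [j] + [0] * len(a)
        for i, ca in enumerate(a, start=1):
            cur[i] = min(prev[i] + 1,          # delete from b
                         cur[i - 1] + 1,       # insert into b
                         prev[i - 1] + (ca != cb))
        prev = cur
    return prev[-1]


MAX_PERMUTATION_TOKENS = 6


def token_permutations(term: str) -> set[str]:
    """All orderings of the term's tokens (the paper's multi-word n-gram
    step): 'dimero d' can also appear as 'd dimero'.  Terms longer than
    ``MAX_PERMUTATION_TOKENS`` tokens return only themselves (720 orderings
    is the cost cap)."""
    tokens = term.split()
    if not tokens:
        return set()
    if len(tokens) > MAX_PERMUTATION_TOKENS:
        logger.warning("permutation cap: %r has %d tokens", term, len(tokens))
        return {term}
    return {" ".join(p) for p in itertools.permutations(tokens)}


def _char_trigrams(term: str) -> set[str]:
    return {term[i:i + 3] for i in range(len(term) - 2)}


def suggest_candidates(catalog: ConceptCatalog, term: str, k: int = 5,
                       ) -> list[tuple[str, str, int]]:
    """The ``k`` catalog entries nearest to ``term`` by Levenshtein distance.

    Ascending distance; ties broken by shorter description, then lower
    numeric code, so the ranking is total and deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    scored = sorted(
        catalog.entries,
        key=lambda e: (levenshtein(e.description, term), len(e.description),
                       _code_sort_key(e.code), e.description))
    return [(e.code, e.description, levenshtein(e.description, term))
            for e in scored[:k]]


# ---------------------------------------------------------------------------
# The hybrid pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndexerConfig:
    """Options of the hybrid matcher."""

    k_suggestions: int = 5
    max_distance: int | None = None     #: fuzzy matches above this -> none
    trigram_gate: bool = True           #: spell-suggester candidate gate
    rank_against_candidate: bool = False  #: rank by distance to the
    #: generating candidate instead of the normalized input entity
    normalization: NormalizationConfig = field(
        default_factory=NormalizationConfig)


@dataclass(frozen=True)
class IndexingResult:
    """Per-mention outcome of the pipeline."""

    surface: str
    normalized: str
    code: str
    matched_description: str
    distance: int
    stage: str  # supervised | exact-entity | exact-synonym |
    #           exact-permutation | fuzzy | none


def _best_exact(catalog: ConceptCatalog, terms: Iterable[str],
                ) -> CatalogEntry | None:
    hits = [e for t in sorted(set(terms))
            for e in catalog.lookup_description(t)]
    if not hits:
        return None
    return sorted(hits, key=lambda e: (_code_sort_key(e.code)))[0]


def index_mention(surface: str,
                  code_map: TrainingCodeMap,
                  dictionary: SynonymDictionary,
                  catalog: ConceptCatalog,
                  config: IndexerConfig | None = None) -> IndexingResult:
    """Assign a concept code to one mention surface.

    Stages run in strict order: supervised lookup, exact description match
    (entity, then synonyms, then permutations of both), fuzzy
    Levenshtein-ranked suggestion, none.
    """
    config = config or IndexerConfig()
    term = normalize_term(surface, config.normalization)

    # (1) supervised: codes seen on this surface in the training set
    code = code_map.get(term)
    if code is not None:
        return IndexingResult(surface, term, code, term, 0, "supervised")

    synonyms = sorted(dictionary.synonyms(term))

    # (2) exact description matches, in candidate-class order
    entry = _best_exact(catalog, [term])
    if entry is not None:
        return IndexingResult(surface, term, entry.code, entry.description,
                              0, "exact-entity")
    entry = _best_exact(catalog, synonyms)
    if entry is not None:
        return IndexingResult(surface, term, entry.code, entry.description,
                              0, "exact-synonym")
    permutations: set[str] = set()
    for t in [term] + synonyms:
        permutations |= token_permutations(t)
    permutations -= {term, *synonyms}
    entry = _best_exact(catalog, permutations)
    if entry is not None:
        return IndexingResult(surface, term, entry.code, entry.description,
                              0, "exact-permutation")

    # (3) fuzzy: suggestion candidates ranked by edit distance
    if len(catalog) == 0:
        return IndexingResult(surface, term, NONE_CODE, "", 0, "none")
    queries = [term, *synonyms, *sorted(permutations)]
    pool = catalog.entries
    if config.trigram_gate:
        grams: set[str] = set()
        for q in queries:
            grams |= _char_trigrams(q)
        gated = [e for e in pool if grams & _char_trigrams(e.description)]
        if gated:
            pool = gated
    ranked = []
    for e in pool:
        if config.rank_against_candidate:
            dist = min(levenshtein(e.description, q) for q in queries)
        else:
            dist = levenshtein(e.description, term)
        ranked.append((dist, len(e.description), _code_sort_key(e.code),
                       e.description, e))
    ranked.sort(key=lambda r: r[:4])
    dist, _len, _key, _desc, entry = ranked[0]
    if config.max_distance is not None and dist > config.max_distance:
        return IndexingResult(surface, term, NONE_CODE, "", 0, "none")
    return IndexingResult(surface, term, entry.code, entry.description,
                          dist, "fuzzy")


def index_document(mentions: Iterable,
                   code_map: TrainingCodeMap,
                   dictionary: SynonymDictionary,
                   catalog: ConceptCatalog,
                   config: IndexerConfig | None = None,
                   ) -> tuple[set[str], list[IndexingResult]]:
    """Index all mentions of one document.

    Returns the deduplicated set of assigned codes (the document's unique
    concept identifiers) plus the per-mention results.  UNCLEAR mentions are
    skipped, matching the evaluation protocol.
    """
    results: list[IndexingResult] = []
    codes: set[str] = set()
    for m in mentions:
        label = getattr(m, "label", None)
        surface = m.surface if hasattr(m, "surface") else str(m)
        if label == "UNCLEAR":
            continue
        r = index_mention(surface, code_map, dictionary, catalog, config)
        results.append(r)
        if r.code != NONE_CODE:
            codes.add(r.code)
    return codes, results


def results_to_audit_tsv(doc_id: str, mentions, results) -> str:
    """Per-mention audit rows: doc_id, start, end, surface, code, stage,
    distance, matched description."""
    rows = []
    for m, r in zip(mentions, results):
        rows.append("\t".join([
            doc_id, str(getattr(m, "start", "")), str(getattr(m, "end", "")),
            r.surface, r.code, r.stage, str(r.distance),
            r.matched_description]))
    return "\n".join(rows) + ("\n" if rows else "")
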