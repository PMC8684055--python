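"""Corpus I/O for Spanish clinical-case documents.

Documents are plain text paired with BRAT standoff annotations: typed
character-offset entity mentions (chemicals, drugs, proteins) optionally
carrying a SNOMED-CT concept code in an ``AnnotatorNotes`` line.  This module
reads and writes that format, tokenizes and sentence-splits the text, and
converts between offset mentions and per-token BIO tag sequences.

Offsets are 0-based, half-open, and count Unicode code points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

#: The four entity categories annotated in the corpus.  UNCLEAR mentions are
#: encoded and predicted like the others but excluded from evaluation.
LABELS = ("NORMALIZABLES", "NO_NORMALIZABLES", "PROTEINAS", "UNCLEAR")

#: Sentence-final period is suppressed after these tokens.
DEFAULT_ABBREVIATIONS = frozenset(
    {"Dr.", "Dra.", "Sr.", "Sra.", "Sta.", "etc.", "p.ej.", "Fig.", "fig.",
     "No.", "núm.", "vs.", "cols.", "et al."}
)


class BratParseError(ValueError):
    """A standoff line that does not follow the supported dialect."""


class OffsetRangeError(ValueError):
    """A mention whose offsets fall outside the document text."""


@dataclass(frozen=True)
class TokenSpan:
    """A token located by character offsets within a document."""

    start: int
    end: int
    sentence_index: int = 0

    def surface(self, text: str) -> str:
        return text[self.start:self.end]


@dataclass
class EntityMention:
    """A typed entity mention with character offsets and an optional code."""

    doc_id: str
    label: str
    start: int
    end: int
    surface: str
    code: str | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown entity label {self.label!r}")
        if not (0 <= self.start < self.end):
            raise OffsetRangeError(
                f"bad mention offsets [{self.start}, {self.end})")

    def key(self) -> tuple[str, int, int, str]:
        """Identity used for strict-span evaluation matching."""
        return (self.doc_id, self.start, self.end, self.label)


@dataclass
class AnnotatedDocument:
    """One clinical case: text plus its entity mentions."""

    doc_id: str
    text: str
    mentions: list[EntityMention] = field(default_factory=list)

    def validate(self) -> None:
        if self.mentions and not self.text:
            raise ValueError(f"{self.doc_id}: mentions on empty text")
        for m in self.mentions:
            if m.end > len(self.text):
                raise OffsetRangeError(
                    f"{self.doc_id}: mention [{m.start}, {m.end}) exceeds "
                    f"text length {len(self.text)}")
            if m.surface != self.text[m.start:m.end]:
                raise ValueError(
                    f"{self.doc_id}: surface {m.surface!r} does not match "
                    f"text[{m.start}:{m.end}] = {self.text[m.start:m.end]!r}")


# ---------------------------------------------------------------------------
# BRAT standoff reading and writing
# ---------------------------------------------------------------------------

def read_brat_document(text_content: str, ann_content: str,
                       doc_id: str = "doc") -> AnnotatedDocument:
    """Parse a ``.txt``/``.ann`` pair into an :class:`AnnotatedDocument`.

    Supported lines are entity lines ``T<k>\\t<LABEL> <start> <end>\\t<surface>``
    and concept-code notes ``#<k>\\tAnnotatorNotes T<j>\\t<code>``.  A surface
    string that disagrees with ``text[start:end]`` is flagged with a warning
    and replaced by the text substring, which is authoritative.
    """
    mentions_by_tid: dict[str, EntityMention] = {}
    order: list[str] = []
    notes: list[tuple[int, str, str]] = []
    for lineno, raw in enumerate(ann_content.splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line.strip():
            continue
        if line[0] == "T":
            parts = line.split("\t")
            if len(parts) < 3:
                raise BratParseError(
                    f"{doc_id} line {lineno}: expected 3 tab-separated "
                    f"fields, got {len(parts)}")
            tid, spec = parts[0], parts[1]
            surface = "\t".join(parts[2:])
            bits = spec.split(" ")
            if len(bits) != 3:
                raise BratParseError(
                    f"{doc_id} line {lineno}: expected 'LABEL start end', "
                    f"got {spec!r}")
            label = bits[0]
            try:
                start, end = int(bits[1]), int(bits[2])
            except ValueError as exc:
                raise BratParseError(
                    f"{doc_id} line {lineno}: non-integer offsets in "
                    f"{spec!r}") from exc
            if not (0 <= start < end <= len(text_content)):
                raise OffsetRangeError(
                    f"{doc_id} line {lineno}: offsets [{start}, {end}) out "
                    f"of range for text of length {len(text_content)}")
            actual = text_content[start:end]
            if surface != actual:
                logger.warning(
                    "%s line %d: surface %r disagrees with text %r; "
                    "using the text", doc_id, lineno, surface, actual)
            mentions_by_tid[tid] = EntityMention(
                doc_id=doc_id, label=label, start=start, end=end,
                surface=actual)
            order.append(tid)
        elif line[0] == "#":
            parts = line.split("\t")
            if len(parts) != 3 or not parts[1].startswith("AnnotatorNotes "):
                raise BratParseError(
                    f"{doc_id} line {lineno}: malformed note line")
            target = parts[1].split(" ", 1)[1]
            notes.append((lineno, target, parts[2].strip()))
        else:
            raise BratParseError(
                f"{doc_id} line {lineno}: unsupported standoff line type "
                f"{line[0]!r} (only T and # lines are handled)")
    for lineno, target, code in notes:
        mention = mentions_by_tid.get(target)
        if mention is None:
            raise BratParseError(
                f"{doc_id} line {lineno}: note refers to unknown entity "
                f"{target}")
        mention.code = code
    doc = AnnotatedDocument(doc_id=doc_id, text=text_content,
                            mentions=[mentions_by_tid[t] for t in order])
    doc.validate()
    return doc


def write_brat_document(doc: AnnotatedDocument) -> tuple[str, str]:
    """Serialize a document to its ``(.txt, .ann)`` contents (round-trip
    inverse of :func:`read_brat_document`)."""
    doc.validate()
    lines: list[str] = []
    note_lines: list[str] = []
    note_no = 0
    for i, m in enumerate(doc.mentions, start=1):
        lines.append(f"T{i}\t{m.label} {m.start} {m.end}\t{m.surface}")
        if m.code is not None:
            note_no += 1
            note_lines.append(f"#{note_no}\tAnnotatorNotes T{i}\t{m.code}")
    all_lines = lines + note_lines
    ann = "\n".join(all_lines) + ("\n" if all_lines else "")
    return doc.text, ann


def read_code_tsv(content: str) -> dict[str, set[str]]:
    """Parse a concept-gold TSV (``doc_id[<TAB>mention_id]<TAB>code``) into
    per-document code sets."""
    out: dict[str, set[str]] = {}
    for lineno, raw in enumerate(content.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"code TSV line {lineno}: expected at least "
                             f"doc_id and code")
        out.setdefault(parts[0], set()).add(parts[-1])
    return out


def write_code_tsv(codes: dict[str, set[str]]) -> str:
    rows = [f"{doc_id}\t{code}"
            for doc_id in sorted(codes)
            for code in sorted(codes[doc_id])]
    return "\n".join(rows) + ("\n" if rows else "")


# ---------------------------------------------------------------------------
# Tokenization and sentence splitting
# ---------------------------------------------------------------------------

def split_sentences(text: str,
                    abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS,
                    ) -> list[tuple[int, int]]:
    """Split ``text`` into sentence spans that partition it exactly.

    Terminators are ``.``, ``!``, ``?`` and the newline.  A period is not a
    terminator when it sits between two digits (decimal numbers) or when the
    token it closes is a known abbreviation.
    """
    if not text:
        return []
    splits: list[int] = []
    for i, c in enumerate(text):
        if c in "!?\n":
            splits.append(i + 1)
        elif c == ".":
            prev = text[i - 1] if i > 0 else ""
            nxt = text[i + 1] if i + 1 < len(text) else ""
            if prev.isdigit() and nxt.isdigit():
                continue
            # token ending at this period, for the abbreviation guard
            j = i
            while j > 0 and not text[j - 1].isspace():
                j -= 1
            if text[j:i + 1] in abbreviations:
                continue
            splits.append(i + 1)
    spans: list[tuple[int, int]] = []
    prev = 0
    for s in splits + [len(text)]:
        if s > prev:
            spans.append((prev, s))
            prev = s
    # merge whitespace-only spans into their predecessor so the partition
    # has no empty sentences
    merged: list[tuple[int, int]] = []
    for span in spans:
        if merged and not text[span[0]:span[1]].strip():
            merged[-1] = (merged[-1][0], span[1])
        else:
            merged.append(span)
    if merged and not text[merged[0][0]:merged[0][1]].strip():
        # leading whitespace-only span: attach forward
        if len(merged) > 1:
            merged[1] = (merged[0][0], merged[1][1])
            merged = merged[1:]
    return merged


def tokenize(text: str,
             sentences: list[tuple[int, int]] | None = None,
             ) -> list[TokenSpan]:
    """Tokenize ``text`` into :class:`TokenSpan` items.

    Splits on whitespace and detaches punctuation characters as
    single-character tokens, except punctuation flanked by digits on both
    sides (decimal separators, ranges like ``15-3``), which stays attached.
    Lossless: surfaces plus the original gaps reconstruct the input.
    """
    if sentences is None:
        sentences = split_sentences(text)
    tokens: list[TokenSpan] = []
    for sent_idx, (s, e) in enumerate(sentences):
        i = s
        while i < e:
            if text[i].isspace():
                i += 1
                continue
            j = i
            while j < e and not text[j].isspace():
                j += 1
            # split the chunk [i, j) on punctuation
            run = i
            k = i
            while k < j:
                c = text[k]
                if c.isalnum() or c == "_":
                    k += 1
                    continue
                attached = (k > i and k + 1 < j and text[k - 1].isdigit()
                            and text[k + 1].isdigit())
                if attached:
                    k += 1
                    continue
                if run < k:
                    tokens.append(TokenSpan(run, k, sent_idx))
                tokens.append(TokenSpan(k, k + 1, sent_idx))
                k += 1
                run = k
            if run < j:
                tokens.append(TokenSpan(run, j, sent_idx))
            i = j
    return tokens


def group_tokens_by_sentence(tokens: list[TokenSpan]) -> list[list[TokenSpan]]:
    """Group a token list into per-sentence lists (dense sentence indices)."""
    if not tokens:
        return []
    n_sent = max(t.sentence_index for t in tokens) + 1
    groups: list[list[TokenSpan]] = [[] for _ in range(n_sent)]
    for t in tokens:
        groups[t.sentence_index].append(t)
    return groups


# ---------------------------------------------------------------------------
# BIO encoding / decoding
# ---------------------------------------------------------------------------

def resolve_overlaps(mentions: list[EntityMention]) -> list[EntityMention]:
    """Drop overlapping mentions, keeping the longest (tie: earliest start).

    BIO tags cannot express overlapping spans, so a flat subset must be
    chosen; dropped mentions are logged.
    """
    ranked = sorted(mentions, key=lambda m: (-(m.end - m.start), m.start))
    kept: list[EntityMention] = []
    for m in ranked:
        if any(m.start < k.end and m.end > k.start for k in kept):
            logger.warning("%s: dropping mention %r [%d, %d) overlapping a "
                           "longer one", m.doc_id, m.surface, m.start, m.end)
            continue
        kept.append(m)
    kept.sort(key=lambda m: m.start)
    return kept


def encode_bio(doc: AnnotatedDocument,
               tokens: list[TokenSpan]) -> list[list[str]]:
    """Encode the document's mentions as per-sentence BIO tag sequences.

    Mention boundaries that do not align with token boundaries are snapped
    outward to the covering tokens (never inward, so no gold characters are
    dropped) and logged.
    """
    groups = group_tokens_by_sentence(tokens)
    tags = [["O"] * len(g) for g in groups]
    position = {(t.start, t.end): (t.sentence_index, i)
                for g in groups for i, t in enumerate(g)}
    for m in resolve_overlaps(doc.mentions):
        covering = [t for t in tokens if t.start < m.end and t.end > m.start]
        if not covering:
            logger.warning("%s: mention %r [%d, %d) covers no token",
                           m.doc_id, m.surface, m.start, m.end)
            continue
        if covering[0].start != m.start or covering[-1].end != m.end:
            logger.info("%s: snapped mention [%d, %d) outward to [%d, %d)",
                        m.doc_id, m.start, m.end,
                        covering[0].start, covering[-1].end)
        for i, t in enumerate(covering):
            sent, pos = position[(t.start, t.end)]
            tags[sent][pos] = ("B-" if i == 0 else "I-") + m.label
    return tags


def decode_bio(sent_tokens: list[TokenSpan], sent_tags: list[str],
               text: str, doc_id: str = "doc") -> list[EntityMention]:
    """Decode one sentence's BIO tags into offset mentions.

    Tagger output need not be valid BIO: an ``I-X`` without a preceding
    ``B-X``/``I-X`` of the same label is repaired to ``B-X``.
    """
    if len(sent_tokens) != len(sent_tags):
        raise ValueError("token/tag length mismatch: "
                         f"{len(sent_tokens)} vs {len(sent_tags)}")
    mentions: list[EntityMention] = []
    open_label: str | None = None
    open_start = 0
    open_end = 0

    def close() -> None:
        nonlocal open_label
        if open_label is not None:
            mentions.append(EntityMention(
                doc_id=doc_id, label=open_label, start=open_start,
                end=open_end, surface=text[open_start:open_end]))
            open_label = None

    for tok, tag in zip(sent_tokens, sent_tags):
        if tag == "O":
            close()
            continue
        prefix, label = tag.split("-", 1)
        if prefix == "B" or label != open_label:
            close()
            open_label = label
            open_start = tok.start
        open_end = tok.end
    close()
    return mentions


def decode_document(text: str, tokens: list[TokenSpan],
                    tags: list[list[str]],
                    doc_id: str = "doc") -> list[EntityMention]:
    """Decode all sentences of a document."""
    groups = group_tokens_by_sentence(tokens)
    out: list[EntityMention] = []
    for sent_tokens, sent_tags in zip(groups, tags):
        out.extend(decode_bio(sent_tokens, sent_tags, text, doc_id))
    return out
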