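"""Synthetic corpora and fixture resources.

The generator emulates the statistical shape of the Spanish clinical-case
corpus the system targets: documents of ~25 sentences, entity mentions of
four categories with the published train-split label mix (NORMALIZABLES
2304, NO_NORMALIZABLES 24, PROTEINAS 1405, UNCLEAR 89), and gold concept
codes for the normalizable categories.  Carrier sentences are templated
Spanish-like clinical text with slot insertion: realistic vocabulary
statistics are not the point, exact character offsets are.  Entity
gazetteers are synthetic, label-disjoint and disjoint from the carrier
vocabulary, so a tagger that learns the corpus is well-posed (the
separable-corpus benchmark).

``make_fixture_resources`` emits the toy synonym dictionary and concept
catalog holding the worked examples the indexing pipeline is validated
against (the GGT synonym group, the adriamycin/doxorubicin pair, the
chorionic-gonadotropin and anti-RNA catalog entries, and the remaining
published code/description pairs), so the whole pipeline is testable with
no external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import AnnotatedDocument, EntityMention
from .indexer import (ConceptCatalog, NormalizationConfig, SynonymDictionary,
                      TrainingCodeMap, build_synonym_dictionary,
                      build_training_code_map)

#: Train-split label counts of the published corpus; the default mix.
DEFAULT_LABEL_COUNTS = {
    "NORMALIZABLES": 2304,
    "NO_NORMALIZABLES": 24,
    "PROTEINAS": 1405,
    "UNCLEAR": 89,
}


@dataclass
class SynthConfig:
    """Shape of the generated corpus."""

    n_docs: int = 100                  #: training documents
    n_dev_docs: int | None = None      #: default: n_docs // 2
    n_test_docs: int | None = None     #: default: n_docs // 2
    sentences_per_doc: float = 25.0    #: Poisson mean
    label_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_COUNTS))
    entity_rate: float = 0.3           #: P(sentence carries a mention)
    gazetteer_sizes: dict[str, int] = field(
        default_factory=lambda: {"NORMALIZABLES": 30, "NO_NORMALIZABLES": 8,
                                 "PROTEINAS": 20, "UNCLEAR": 8})
    noise_rate: float = 0.05           #: P(extra nonsense token in sentence)
    seed: int = 0

    @property
    def label_mix(self) -> dict[str, float]:
        total = sum(self.label_counts.values())
        return {k: v / total for k, v in self.label_counts.items()}


# -- gazetteers -------------------------------------------------------------

_GAZ_PARTS = {
    "NORMALIZABLES": (["meto", "carbo", "fluo", "dexa", "amio", "cipro",
                       "lora", "keto", "predni", "oxa"],
                      ["prida", "zolida", "micina", "celina", "farina",
                       "dipina", "nazol", "cilina", "statina", "prazol"]),
    "NO_NORMALIZABLES": (["pira", "quino", "sulfo"],
                         ["lonas", "ridonas", "xamidas"]),
    "PROTEINAS": (["trans", "gluco", "hemo", "ferri", "cito", "inmuno",
                   "angio"],
                  ["globulina", "quinasa", "feratina", "peptina",
                   "albuminasa", "tropina"]),
    "UNCLEAR": (["fito", "herbo"], ["terapico", "vacunal", "tonico",
                                    "complejo"]),
}

_MODIFIERS = ["alfa", "beta", "gamma", "serica", "basal", "gm1", "cd44"]


def build_gazetteers(config: SynthConfig) -> dict[str, list[str]]:
    """Deterministic, label-disjoint entity surface lists; every fourth
    entry is multi-word so span decoding is exercised."""
    gaz: dict[str, list[str]] = {}
    for label, (prefixes, suffixes) in _GAZ_PARTS.items():
        size = config.gazetteer_sizes.get(label, 0)
        entries = []
        i = 0
        while len(entries) < size:
            name = prefixes[i % len(prefixes)] \
                + suffixes[(i // len(prefixes)) % len(suffixes)]
            if i % 4 == 3:
                name = name + " " + _MODIFIERS[i % len(_MODIFIERS)]
            if name not in entries:
                entries.append(name)
            i += 1
        gaz[label] = entries
    return gaz


def entity_code_map(gazetteers: dict[str, list[str]]) -> dict[str, str]:
    """Synthetic concept code per normalizable gazetteer entry."""
    codes: dict[str, str] = {}
    for base, label in ((100000, "NORMALIZABLES"), (200000, "PROTEINAS")):
        for i, surface in enumerate(gazetteers.get(label, [])):
            codes[surface] = str(base + i)
    return codes


# -- carrier text -----------------------------------------------------------

_SLOT_TEMPLATES = [
    "El paciente recibio tratamiento con {E} durante el ingreso",
    "Se determino {E} en la analitica de control",
    "Los niveles de {E} estaban claramente elevados",
    "Se suspendio {E} por sospecha de toxicidad",
    "La determinacion de {E} resulto dentro de la normalidad",
    "Tras iniciar {E} la evolucion fue favorable",
    "Destaca {E} en el estudio de laboratorio",
]

_PLAIN_TEMPLATES = [
    "El paciente ingreso por dolor abdominal difuso",
    "La exploracion fisica resulto anodina",
    "Se realizo una radiografia de torax sin hallazgos",
    "La evolucion clinica fue favorable tras el alta",
    "Se mantuvo estable durante toda la estancia",
    "El estudio de imagen no mostro alteraciones",
    "Refiere antecedentes familiares sin interes",
    "Acude a urgencias por fiebre de dos dias",
]


def _largest_remainder_allocation(total: int,
                                  mix: dict[str, float]) -> dict[str, int]:
    """Integer label counts matching the mix as closely as arithmetic
    allows (deterministic, unlike multinomial sampling, so rare labels hit
    their share too)."""
    raw = {k: total * p for k, p in mix.items()}
    counts = {k: int(v) for k, v in raw.items()}
    short = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: (counts[k] - raw[k], k))[:short]:
        counts[k] += 1
    return counts


def _generate_split(n_docs: int, prefix: str, config: SynthConfig,
                    gazetteers: dict[str, list[str]],
                    codes: dict[str, str],
                    rng: np.random.Generator,
                    ) -> tuple[list[AnnotatedDocument], dict[str, set[str]],
                               list[int]]:
    # plan sentence counts and slot flags first so label allocation can be
    # deterministic over the whole split
    plans = []
    total_slots = 0
    for d in range(n_docs):
        n_sent = max(1, int(rng.poisson(config.sentences_per_doc)))
        slots = rng.random(n_sent) < config.entity_rate
        total_slots += int(slots.sum())
        plans.append((n_sent, slots))
    label_counts = _largest_remainder_allocation(total_slots,
                                                 config.label_mix)
    label_pool = [lab for lab in sorted(label_counts)
                  for _ in range(label_counts[lab])]
    rng.shuffle(label_pool)
    docs: list[AnnotatedDocument] = []
    gold_codes: dict[str, set[str]] = {}
    sentence_counts: list[int] = []
    pool_pos = 0
    for d, (n_sent, slots) in enumerate(plans):
        doc_id = f"{prefix}-{d:04d}"
        pieces: list[str] = []
        mentions: list[EntityMention] = []
        offset = 0
        for s in range(n_sent):
            if slots[s] and pool_pos < len(label_pool):
                label = label_pool[pool_pos]
                pool_pos += 1
                template = _SLOT_TEMPLATES[
                    int(rng.integers(len(_SLOT_TEMPLATES)))]
                entries = gazetteers[label]
                surface = entries[int(rng.integers(len(entries)))]
                head, tail = template.split("{E}")
                sent = head + surface + tail
                start = offset + len(head)
                mentions.append(EntityMention(
                    doc_id=doc_id, label=label, start=start,
                    end=start + len(surface), surface=surface,
                    code=codes.get(surface)))
            else:
                sent = _PLAIN_TEMPLATES[
                    int(rng.integers(len(_PLAIN_TEMPLATES)))]
            if rng.random() < config.noise_rate:
                sent = sent + " zz" + str(int(rng.integers(100, 1000)))
            sent = sent + "."
            pieces.append(sent)
            offset += len(sent) + 1  # sentences joined by one space
        text = " ".join(pieces)
        doc = AnnotatedDocument(doc_id=doc_id, text=text, mentions=mentions)
        doc.validate()
        docs.append(doc)
        sentence_counts.append(n_sent)
        gold_codes[doc_id] = {m.code for m in doc.mentions
                              if m.code is not None}
    return docs, gold_codes, sentence_counts


@dataclass
class SynthCorpus:
    """A generated train/dev/test corpus plus its gold concept codes."""

    train: list[AnnotatedDocument]
    dev: list[AnnotatedDocument]
    test: list[AnnotatedDocument]
    gold_codes: dict[str, dict[str, set[str]]]
    gazetteers: dict[str, list[str]]
    codes: dict[str, str]
    sentence_counts: dict[str, list[int]]


def generate_corpus(config: SynthConfig | None = None) -> SynthCorpus:
    """Generate a deterministic synthetic corpus (same seed, same bytes)."""
    config = config or SynthConfig()
    gazetteers = build_gazetteers(config)
    for label, entries in gazetteers.items():
        if not entries:
            raise ValueError(f"empty gazetteer for label {label}")
    codes = entity_code_map(gazetteers)
    rng = np.random.default_rng(config.seed)
    n_dev = config.n_dev_docs if config.n_dev_docs is not None \
        else max(1, config.n_docs // 2)
    n_test = config.n_test_docs if config.n_test_docs is not None \
        else max(1, config.n_docs // 2)
    train, gc_train, sc_train = _generate_split(
        config.n_docs, "train", config, gazetteers, codes, rng)
    dev, gc_dev, sc_dev = _generate_split(
        n_dev, "dev", config, gazetteers, codes, rng)
    test, gc_test, sc_test = _generate_split(
        n_test, "test", config, gazetteers, codes, rng)
    return SynthCorpus(
        train=train, dev=dev, test=test,
        gold_codes={"train": gc_train, "dev": gc_dev, "test": gc_test},
        gazetteers=gazetteers, codes=codes,
        sentence_counts={"train": sc_train, "dev": sc_dev, "test": sc_test})


# ---------------------------------------------------------------------------
# Fixture resources: the published worked examples
# ---------------------------------------------------------------------------

#: Synonym groups, one per line of a TSV source.
FIXTURE_SYNONYM_GROUPS: list[list[str]] = [
    ["GGT", "gama glutamil transferasa", "GGTP",
     "gamma-glutamiltransferasa", "gamma GT"],
    ["Adriamicina", "doxorrubicina"],
    ["dímero D", "D dímero"],
]

#: Every published code/description pair used in the worked examples.
FIXTURE_CATALOG_ROWS: list[tuple[str, str]] = [
    ("60153001", "gamma-glutamiltransferasa"),
    ("372817009", "doxorrubicina"),
    ("412126005", "gonadotrofina corionica humana"),
    ("40940006", "gonadotrofina corionica humana subunidad beta"),
    ("47646004", "antiarina"),
    ("444236000", "anticuerpo anti-ácido ribonucleico"),
    ("314167003", "antígeno linfocitario CD31"),
    ("395835001", "proteína plasmática"),
    ("11353004", "anticuerpo antimembrana basal glomerular"),
    ("103092003", "antígeno cancerígeno 15-3"),
    ("40185008", "proteína amiloide sérica A"),
]

#: A few coded training mentions for the supervised map.
FIXTURE_CODED_MENTIONS: list[tuple[str, str]] = [
    ("glucosa", "67079006"),
    ("glucosa", "67079006"),
    ("creatinina", "70901006"),
]


@dataclass
class FixtureResources:
    dictionary: SynonymDictionary
    catalog: ConceptCatalog
    coded_mentions: list[tuple[str, str]]

    def training_code_map(self,
                          config: NormalizationConfig | None = None,
                          ) -> TrainingCodeMap:
        return build_training_code_map(self.coded_mentions, config)


def synonym_tsv() -> str:
    return "\n".join("\t".join(g) for g in FIXTURE_SYNONYM_GROUPS) + "\n"


def catalog_tsv() -> str:
    return "\n".join(f"{code}\t{desc}"
                     for code, desc in FIXTURE_CATALOG_ROWS) + "\n"


def separable_benchmark(seed: int) -> float:
    """Train the tagger on a 50-document separable synthetic corpus and
    return strict-span micro-F1 on a held-out 20-document test split.

    The corpus is separable by construction (label-disjoint gazetteers),
    so a correctly implemented tagger should recover the labeling nearly
    perfectly.  The model is a scaled-down operating point sized for a
    single CPU: hashed static vectors (dim 48) stacked with small pooled
    character-contextual embeddings, 32 hidden units per direction, SGD at
    0.3 with early stopping on a 10-document development split.
    """
    from .evaluation import match_entities, micro_metrics
    from .tagger import TaggerConfig, predict, train_tagger
    from .embeddings import build_stack

    corpus = generate_corpus(SynthConfig(
        n_docs=50, n_dev_docs=10, n_test_docs=20, seed=seed))
    stack = build_stack([
        {"type": "hashed", "dim": 48, "seed": seed},
        {"type": "pooled-contextual", "hidden": 8, "char_dim": 8,
         "seed": seed},
    ])
    cfg = TaggerConfig(hidden_size=32, learning_rate=0.3, dropout=0.0,
                       max_epochs=80, batch_size=32, seed=seed,
                       early_stop_patience=12)
    model = train_tagger(corpus.train, stack, cfg, dev_docs=corpus.dev)
    preds, golds = [], []
    for doc in corpus.test:
        preds.extend(predict(model, doc))
        golds.extend(doc.mentions)
    return micro_metrics(match_entities(golds, preds)).f1


def make_fixture_resources(config: NormalizationConfig | None = None,
                           ) -> FixtureResources:
    """Build the toy dictionary and catalog containing the published
    worked examples, normalized under ``config``."""
    config = config or NormalizationConfig()
    dictionary = build_synonym_dictionary(
        [synonym_tsv().splitlines()], config)
    catalog = ConceptCatalog(FIXTURE_CATALOG_ROWS, config)
    return FixtureResources(dictionary=dictionary, catalog=catalog,
                            coded_mentions=list(FIXTURE_CODED_MENTIONS))
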