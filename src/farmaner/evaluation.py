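"""Evaluation of recognition and indexing output.

NER is scored by exact-offset, exact-type matching: a system mention is a
true positive iff a gold mention with identical (document, start, end,
label) exists, matched one-to-one; unmatched system mentions are false
positives and unmatched gold mentions false negatives.  Metrics are
micro-averaged (counts pooled over labels before computing P/R/F1).
UNCLEAR mentions are excluded from both sides.

Concept indexing is scored over per-document code sets with the same micro
machinery.  Two systems are compared with McNemar's paired test on their
discordant per-item correctness counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EXCLUDED_LABELS = frozenset({"UNCLEAR"})


@dataclass
class EvalCounts:
    """Per-label and pooled TP/FP/FN counts."""

    per_label: dict[str, dict[str, int]] = field(default_factory=dict)

    def _row(self, label: str) -> dict[str, int]:
        return self.per_label.setdefault(label,
                                         {"tp": 0, "fp": 0, "fn": 0})

    def add(self, label: str, tp: int = 0, fp: int = 0, fn: int = 0) -> None:
        row = self._row(label)
        row["tp"] += tp
        row["fp"] += fp
        row["fn"] += fn

    @property
    def tp(self) -> int:
        return sum(r["tp"] for r in self.per_label.values())

    @property
    def fp(self) -> int:
        return sum(r["fp"] for r in self.per_label.values())

    @property
    def fn(self) -> int:
        return sum(r["fn"] for r in self.per_label.values())


@dataclass(frozen=True)
class MetricTriple:
    precision: float
    recall: float
    f1: float


def match_entities(gold, system) -> EvalCounts:
    """Count strict-span matches between gold and system mention lists.

    Mentions agree when document, start, end and label are all identical;
    duplicates are matched one-to-one by multiset intersection.
    """
    counts = EvalCounts()
    gold_keys = Counter(m.key() for m in gold
                        if m.label not in EXCLUDED_LABELS)
    sys_keys = Counter(m.key() for m in system
                       if m.label not in EXCLUDED_LABELS)
    labels = ({k[3] for k in gold_keys} | {k[3] for k in sys_keys})
    for label in sorted(labels):
        g = Counter({k: c for k, c in gold_keys.items() if k[3] == label})
        s = Counter({k: c for k, c in sys_keys.items() if k[3] == label})
        tp = sum((g & s).values())
        counts.add(label, tp=tp,
                   fp=sum(s.values()) - tp,
                   fn=sum(g.values()) - tp)
    return counts


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator computing %s; reporting 0", what)
        return 0.0
    return num / den


def micro_metrics(counts: EvalCounts) -> MetricTriple:
    """Micro-averaged precision, recall and balanced F1 from pooled counts."""
    p = _safe_div(counts.tp, counts.tp + counts.fp, "precision")
    r = _safe_div(counts.tp, counts.tp + counts.fn, "recall")
    f1 = _safe_div(2 * p * r, p + r, "F1")
    return MetricTriple(p, r, f1)


def label_metrics(counts: EvalCounts, label: str) -> MetricTriple:
    row = counts.per_label.get(label, {"tp": 0, "fp": 0, "fn": 0})
    p = _safe_div(row["tp"], row["tp"] + row["fp"], f"{label} precision")
    r = _safe_div(row["tp"], row["tp"] + row["fn"], f"{label} recall")
    f1 = _safe_div(2 * p * r, p + r, f"{label} F1")
    return MetricTriple(p, r, f1)


def fine_grained_table(counts: EvalCounts) -> pd.DataFrame:
    """Per-label error table: total gold mentions, TP, FP, FN.

    ``Total`` is TP + FN (every gold mention is either found or missed).
    """
    rows = []
    for label in sorted(counts.per_label):
        r = counts.per_label[label]
        rows.append({"label": label, "total": r["tp"] + r["fn"],
                     "tp": r["tp"], "fp": r["fp"], "fn": r["fn"]})
    return pd.DataFrame(rows, columns=["label", "total", "tp", "fp", "fn"])


def evaluate_indexing(gold_codes: dict[str, set[str]],
                      system_codes: dict[str, set[str]]) -> MetricTriple:
    """Micro P/R/F1 over (document, code) pairs with set semantics."""
    counts = EvalCounts()
    for doc_id in sorted(set(gold_codes) | set(system_codes)):
        g = set(gold_codes.get(doc_id, ()))
        s = set(system_codes.get(doc_id, ()))
        counts.add("codes", tp=len(g & s), fp=len(s - g), fn=len(g - s))
    return micro_metrics(counts)


def mcnemar_test(a_correct, b_correct,
                 exact: bool = False) -> tuple[float, float]:
    """McNemar's paired test on two systems' per-item correctness.

    ``b`` counts items A got right and B wrong; ``c`` the reverse.  The
    default statistic is the continuity-corrected (|b - c| - 1)^2 / (b + c)
    with a chi-square (1 df) p-value; ``exact=True`` uses the two-sided
    binomial tail instead (statistic reported as min(b, c)).
    """
    a_correct = list(a_correct)
    b_correct = list(b_correct)
    if len(a_correct) != len(b_correct):
        raise ValueError("paired correctness vectors differ in length")
    b = sum(1 for x, y in zip(a_correct, b_correct) if x and not y)
    c = sum(1 for x, y in zip(a_correct, b_correct) if y and not x)
    if b + c == 0:
        return 0.0, 1.0
    if exact:
        result = stats.binomtest(min(b, c), b + c, 0.5,
                                 alternative="two-sided")
        return float(min(b, c)), float(result.pvalue)
    statistic = (abs(b - c) - 1) ** 2 / (b + c)
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def report_text(counts: EvalCounts) -> str:
    """Human-readable evaluation report: per-label rows plus the micro line."""
    table = fine_grained_table(counts)
    lines = [table.to_string(index=False)]
    m = micro_metrics(counts)
    lines.append(f"micro  P={m.precision:.4f}  R={m.recall:.4f}  "
                 f"F1={m.f1:.4f}")
    return "\n".join(lines)
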