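"""Entity-level evaluation: IOB2 tag sequences -> entity spans -> exact-match
precision, recall and F-Measure.

An entity is a maximal ``B-T (I-T)*`` tag run; an ``I-T`` with no compatible
predecessor is repaired as if it were ``B-T`` (decoders can emit such runs
and evaluation must never crash).  Matching is exact: a predicted span counts
as a true positive only when its sentence, boundaries and type all equal a
gold span's.  Metrics are the standard

    P = TP / (TP + FP),   R = TP / (TP + FN),   F = 2 P R / (P + R)

reported as percentages; F is the harmonic mean of P and R, never the
arithmetic mean.  Degenerate zero denominators yield 0 with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus import Corpus

__all__ = [
    "EntitySpan",
    "EvalCounts",
    "Metrics",
    "spans_from_tags",
    "spans_from_corpus",
    "count_matches",
    "f_measure",
    "precision_recall_f",
    "evaluate_tags",
    "format_report",
]


@dataclass(frozen=True, order=True)
class EntitySpan:
    """Half-open token interval [start, end) of one entity mention."""

    sentence: int
    start: int
    end: int
    type: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass
class EvalCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "EvalCounts") -> "EvalCounts":
        return EvalCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class Metrics:
    """Precision/recall/F as percentages; ``degenerate`` marks any metric
    whose denominator was zero (reported as 0)."""

    precision: float
    recall: float
    f_measure: float
    degenerate: bool = False


def spans_from_tags(tags: Sequence[str], sentence: int = 0) -> set[EntitySpan]:
    """Decode one IOB2 tag sequence into entity spans.

    A stray ``I-T`` (at sentence start, after ``O``, or after a different
    type) starts a new span, as if it were ``B-T``.
    """
    spans: set[EntitySpan] = set()
    start = None
    cur_type = None
    for i, tag in enumerate(tags):
        if tag == "O":
            if start is not None:
                spans.add(EntitySpan(sentence, start, i, cur_type))
                start = None
            continue
        marker, _, etype = tag.partition("-")
        if marker == "B" or start is None or etype != cur_type:
            if start is not None:
                spans.add(EntitySpan(sentence, start, i, cur_type))
            start, cur_type = i, etype
    if start is not None:
        spans.add(EntitySpan(sentence, start, len(tags), cur_type))
    return spans


def spans_from_corpus(corpus: Corpus) -> set[EntitySpan]:
    spans: set[EntitySpan] = set()
    for si, sent in enumerate(corpus):
        spans |= spans_from_tags(sent.tags, si)
    return spans


def count_matches(gold: Iterable[EntitySpan], pred: Iterable[EntitySpan]) -> EvalCounts:
    """Exact-match counting: TP = |gold ∩ pred|, FP = |pred \\ gold|,
    FN = |gold \\ pred|."""
    g, p = set(gold), set(pred)
    return EvalCounts(tp=len(g & p), fp=len(p - g), fn=len(g - p))


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall, 2PR/(P+R) — not the arithmetic
    mean.  Input and output share the same scale (fractions or percent)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def precision_recall_f(counts: EvalCounts) -> Metrics:
    """Entity-level P, R and harmonic-mean F, in percent."""
    degenerate = False
    if counts.tp + counts.fp == 0:
        p, degenerate = 0.0, True
    else:
        p = 100.0 * counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        r, degenerate = 0.0, True
    else:
        r = 100.0 * counts.tp / (counts.tp + counts.fn)
    f = f_measure(p, r)
    if p + r == 0:
        degenerate = True
    return Metrics(p, r, f, degenerate)


def evaluate_tags(
    gold_tags: Sequence[Sequence[str]], pred_tags: Sequence[Sequence[str]]
) -> dict[str, dict]:
    """Score predicted tag sequences against gold, per entity type and
    overall.  Returns a machine-readable report dict."""
    if len(gold_tags) != len(pred_tags):
        raise ValueError("gold and predicted corpora have different sentence counts")
    gold: set[EntitySpan] = set()
    pred: set[EntitySpan] = set()
    for si, (g, p) in enumerate(zip(gold_tags, pred_tags)):
        if len(g) != len(p):
            raise ValueError(f"sentence {si}: gold and predicted lengths differ")
        gold |= spans_from_tags(g, si)
        pred |= spans_from_tags(p, si)

    report: dict[str, dict] = {}
    types = sorted({s.type for s in gold} | {s.type for s in pred})
    for etype in types + ["overall"]:
        if etype == "overall":
            g, p = gold, pred
        else:
            g = {s for s in gold if s.type == etype}
            p = {s for s in pred if s.type == etype}
        counts = count_matches(g, p)
        m = precision_recall_f(counts)
        report[etype] = {
            "tp": counts.tp,
            "fp": counts.fp,
            "fn": counts.fn,
            "precision": m.precision,
            "recall": m.recall,
            "f_measure": m.f_measure,
            "degenerate": m.degenerate,
        }
    return report


def format_report(report: dict[str, dict]) -> str:
    """Render an evaluation report as an aligned plain-text table
    (percentages to three decimals)."""
    lines = [f"{'type':<12}{'TP':>6}{'FP':>6}{'FN':>6}{'P%':>10}{'R%':>10}{'F%':>10}"]
    for etype, row in report.items():
        lines.append(
            f"{etype:<12}{row['tp']:>6}{row['fp']:>6}{row['fn']:>6}"
            f"{row['precision']:>10.3f}{row['recall']:>10.3f}{row['f_measure']:>10.3f}"
        )
    return "\n".join(lines)
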