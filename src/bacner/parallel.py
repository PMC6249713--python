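"""Chunked multi-worker batch prediction with an output-equivalence contract.

Decoding is a pure function of (model, sentence), so sharding a corpus across
worker processes can never change the result — only the wall time.  The
partition plan controls contiguous chunking; the central invariant, asserted
in the tests, is that every (n_workers, chunk_size) combination produces
bit-identical output, including the sequential n_workers = 1 path.

Workers receive the model read-only (joblib/loky pickles it once per worker);
nothing is mutated, and a failing chunk aborts the whole run with an error
naming the chunk — there is no partial silent output.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence, Union

from joblib import Parallel, delayed

from .corpus import Token
from .crf import CRFModel
from .errors import ConfigError, PipelineError

__all__ = ["PartitionPlan", "predict_corpus", "throughput_report", "report_to_tsv"]


@dataclass(frozen=True)
class PartitionPlan:
    """Contiguous chunking of a sentence collection over a worker pool.

    ``chunk_size=None`` means one chunk containing everything.
    """

    n_workers: int = 1
    chunk_size: Union[int, None] = None

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ConfigError("n_workers must be >= 1")
        if self.chunk_size is not None and self.chunk_size < 1:
            raise ConfigError("chunk_size must be >= 1")

    def chunks(self, n_sentences: int) -> list[tuple[int, int]]:
        """Non-overlapping [start, end) chunk bounds covering 0..n_sentences."""
        if n_sentences == 0:
            return []
        size = self.chunk_size or n_sentences
        return [(s, min(s + size, n_sentences)) for s in range(0, n_sentences, size)]


Sentences = Sequence[Sequence[Union[str, Token]]]


def _predict_chunk(model: CRFModel, chunk_id: int, sentences: Sentences) -> list[list[str]]:
    try:
        return [model.predict(s) for s in sentences]
    except Exception as exc:  # surfaced to the caller with the chunk named
        raise PipelineError(f"prediction failed in chunk {chunk_id}: {exc}") from exc


def predict_corpus(
    model: CRFModel, sentences: Sentences, plan: Union[PartitionPlan, None] = None
) -> list[list[str]]:
    """Predict IOB2 tags for every sentence, preserving input order.

    The output is identical for every partition plan; with ``n_workers == 1``
    everything runs in-process.
    """
    plan = plan or PartitionPlan()
    bounds = plan.chunks(len(sentences))
    if plan.n_workers == 1 or len(bounds) <= 1:
        chunk_results = [_predict_chunk(model, c, sentences[s:e]) for c, (s, e) in enumerate(bounds)]
    else:
        chunk_results = Parallel(n_jobs=plan.n_workers, backend="loky")(
            delayed(_predict_chunk)(model, c, list(sentences[s:e]))
            for c, (s, e) in enumerate(bounds)
        )
    out: list[list[str]] = []
    for r in chunk_results:
        out.extend(r)
    return out


def throughput_report(
    model: CRFModel,
    sentences: Sentences,
    plans: Sequence[PartitionPlan],
    repeats: int = 5,
) -> list[dict]:
    """Measure mean wall time per plan over repeated runs.

    Purely informational: timings depend on the host and are never asserted
    against fixed values.  Returns one row per plan with the mean seconds and
    derived sentences/second.
    """
    if not plans:
        raise ConfigError("at least one plan is required")
    rows = []
    for plan in plans:
        times = []
        for _ in range(repeats):
            t0 = time.perf_counter()
            predict_corpus(model, sentences, plan)
            times.append(time.perf_counter() - t0)
        mean = sum(times) / len(times)
        rows.append(
            {
                "n_workers": plan.n_workers,
                "chunk_size": plan.chunk_size or len(sentences),
                "n_sentences": len(sentences),
                "repeats": repeats,
                "mean_seconds": mean,
                "sentences_per_second": len(sentences) / mean if mean > 0 else float("inf"),
            }
        )
    return rows


def report_to_tsv(rows: Sequence[dict]) -> str:
    """Render a throughput report as a tab-separated table."""
    if not rows:
        return ""
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append(
            "\t".join(
                f"{row[c]:.4f}" if isinstance(row[c], float) else str(row[c]) for c in cols
            )
        )
    return "\n".join(lines)
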