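"""IOB2/CoNLL corpus reading and writing, plus rule-based tokenization of raw
abstract text.

The on-disk format is the two-column CoNLL convention: one token per line,
whitespace-separated columns with the token first and the IOB2 tag last,
blank lines separating sentences.  Middle columns, if present, are preserved
as opaque per-token annotations but are not written back (output is always
canonical two-column ``token<TAB>tag``).

Tokenization is deliberately rule-based and documented rather than learned:
sentence boundaries are sentence-final punctuation followed by whitespace and
a capital letter (single-capital abbreviations such as the "E." of "E. coli"
never end a sentence), and tokens are whitespace-delimited words with leading
and trailing punctuation detached as separate tokens.
"""

from __future__ import annotations

import io
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO, Union

from .errors import ParseError

__all__ = [
    "Token",
    "AnnotatedSentence",
    "Corpus",
    "read_iob2",
    "write_iob2",
    "tokenize",
    "detokenize",
]

#: grammar of a single IOB2 tag: O, or B-/I- followed by a type name
TAG_PATTERN = re.compile(r"^(O|[BI]-\S+)$")

_PUNCT = set(string.punctuation)
# one ASCII letter followed by a period, e.g. the genus initial "E."
_ABBREV = re.compile(r"^[A-Za-z]\.$")


@dataclass(frozen=True)
class Token:
    """A single surface token at a 0-based position within its sentence."""

    surface: str
    index: int

    def __post_init__(self) -> None:
        if not self.surface or any(c.isspace() for c in self.surface):
            raise ValueError(f"token surface must be non-empty, no whitespace: {self.surface!r}")
        if self.index < 0:
            raise ValueError("token index must be >= 0")


@dataclass
class AnnotatedSentence:
    """A token sequence with one IOB2 tag per token.

    ``extras`` holds any middle columns read from a CoNLL file (one tuple per
    token, possibly empty); they are carried along but never interpreted.
    """

    tokens: list[Token]
    tags: list[str]
    extras: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise ValueError("tokens and tags must have equal length")
        if not self.tokens:
            raise ValueError("sentence must contain at least one token")
        for t in self.tags:
            if not TAG_PATTERN.match(t):
                raise ValueError(f"not an IOB2 tag: {t!r}")
        if not self.extras:
            self.extras = [() for _ in self.tokens]

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]


@dataclass
class Corpus:
    """An ordered collection of annotated sentences."""

    sentences: list[AnnotatedSentence] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[AnnotatedSentence]:
        return iter(self.sentences)

    @property
    def tagset(self) -> set[str]:
        return {t for s in self.sentences for t in s.tags}

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)


Source = Union[str, Path, TextIO, Iterable[str]]


def _as_lines(source: Source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            yield from fh
    else:
        yield from source


def read_iob2(source: Source) -> Corpus:
    """Parse a two-or-more-column IOB2 stream into a :class:`Corpus`.

    ``source`` may be a path, an open text stream, or any iterable of lines.
    First column is the token, last column the tag; middle columns are kept
    as opaque extras.  Raises :class:`ParseError` naming the offending line
    for one-column lines or tags outside the IOB2 grammar.
    """
    sentences: list[AnnotatedSentence] = []
    toks: list[Token] = []
    tags: list[str] = []
    extras: list[tuple[str, ...]] = []

    def flush() -> None:
        nonlocal toks, tags, extras
        if toks:
            sentences.append(AnnotatedSentence(toks, tags, extras))
            toks, tags, extras = [], [], []

    for lineno, raw in enumerate(_as_lines(source), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            flush()
            continue
        cols = line.split()
        if len(cols) < 2:
            raise ParseError(f"line {lineno}: expected >= 2 columns, got {len(cols)}: {line!r}")
        tag = cols[-1]
        if not TAG_PATTERN.match(tag):
            raise ParseError(f"line {lineno}: not an IOB2 tag: {tag!r}")
        toks.append(Token(cols[0], len(toks)))
        tags.append(tag)
        extras.append(tuple(cols[1:-1]))
    flush()
    return Corpus(sentences)


def write_iob2(corpus: Corpus, dest: Union[str, Path, TextIO, None] = None) -> str:
    """Write ``corpus`` in canonical two-column form (``token<TAB>tag``, blank
    line after each sentence).  Returns the emitted text; ``dest`` may be a
    path or stream to also write to."""
    buf = io.StringIO()
    for sent in corpus:
        for tok, tag in zip(sent.tokens, sent.tags):
            buf.write(f"{tok.surface}\t{tag}\n")
        buf.write("\n")
    text = buf.getvalue()
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text, encoding="utf-8")
    elif dest is not None:
        dest.write(text)
    return text


# ---------------------------------------------------------------------------
# raw-text tokenization


def _sentence_segments(text: str) -> list[str]:
    """Split on [.!?] + whitespace + capital, except after a single-letter
    abbreviation like 'E.'."""
    bounds: list[int] = []
    for m in re.finditer(r"[.!?][\"')\]]*\s+(?=[A-Z])", text):
        p = m.start()  # position of the punctuation mark
        if text[p] == "." and p >= 1 and text[p - 1].isupper():
            # single capital letter before the period => abbreviation/initial
            if p == 1 or not text[p - 2].isalnum():
                continue
        bounds.append(m.end())
    segments = []
    prev = 0
    for b in bounds:
        segments.append(text[prev:b])
        prev = b
    segments.append(text[prev:])
    return [s for s in segments if s.strip()]


def _split_token(tok: str) -> list[str]:
    if all(c in _PUNCT for c in tok):
        return [tok]
    out_lead: list[str] = []
    out_trail: list[str] = []
    while tok and tok[0] in _PUNCT and not all(c in _PUNCT for c in tok):
        out_lead.append(tok[0])
        tok = tok[1:]
    while (
        tok
        and tok[-1] in _PUNCT
        and not all(c in _PUNCT for c in tok)
        and not _ABBREV.match(tok)
    ):
        out_trail.append(tok[-1])
        tok = tok[:-1]
    return out_lead + ([tok] if tok else []) + list(reversed(out_trail))


def tokenize(text: str) -> list[list[Token]]:
    """Deterministically split raw text into sentences of :class:`Token`.

    Whitespace-only input yields an empty list.  Internal periods of numbers
    ("7.0") and single-letter abbreviations ("E.") stay attached; other
    leading/trailing punctuation becomes separate tokens.
    """
    sentences: list[list[Token]] = []
    for seg in _sentence_segments(text):
        surfaces: list[str] = []
        for raw in seg.split():
            surfaces.extend(_split_token(raw))
        if surfaces:
            sentences.append([Token(s, i) for i, s in enumerate(surfaces)])
    return sentences


_NO_SPACE_BEFORE = {".", ",", ";", ":", "!", "?", ")", "]", "%"}
_NO_SPACE_AFTER = {"(", "["}


def detokenize(surfaces: Sequence[str]) -> str:
    """Join tokens back into running text with conventional punctuation
    spacing (inverse of :func:`tokenize` for well-behaved sentences)."""
    parts: list[str] = []
    for s in surfaces:
        if parts and (s in _NO_SPACE_BEFORE or parts[-1] in _NO_SPACE_AFTER):
            parts[-1] = parts[-1] + s
        else:
            parts.append(s)
    return " ".join(parts)
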