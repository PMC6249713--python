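"""Token attributes, CRF++-style feature templates, and the feature alphabet.

Each token is first mapped to a fixed set of named *attributes* (surface
word, lowercased word, prefixes/suffixes of length 1-4, word shapes,
orthographic flags, and a dictionary-membership flag).  *Templates* then
combine attributes at relative offsets into expanded feature strings, one set
per sentence position.  Feature strings are functions of the observation
sequence and position only — labels are conjoined at the model layer, where
each state feature string carries one weight per label and each transition
feature string one weight per label pair.

Template file syntax follows the CRF++ convention, with attribute names in
place of column numbers::

    U02:%x[0,word]
    U05:%x[-1,word]/%x[0,word]
    B

``U`` templates generate state (per-label) features, ``B`` templates generate
transition (label-bigram) features; a bare ``B`` line is the always-on
transition bias.  Offsets outside the sentence resolve to the sentinels
``_BOS_`` / ``_EOS_``; attributes undefined for a token (a length-3 prefix of
a one-letter token) resolve to ``_NONE_``.
"""

from __future__ import annotations

import re
import string
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .corpus import Corpus, Token
from .errors import ConfigError, ParseError

__all__ = [
    "ATTRIBUTE_NAMES",
    "DEFAULT_TEMPLATES",
    "Gazetteer",
    "token_attributes",
    "FeatureTemplate",
    "parse_templates",
    "expand_templates",
    "FeatureIndex",
    "build_feature_index",
]

_PUNCT = set(string.punctuation)

BOS = "_BOS_"
EOS = "_EOS_"
NONE = "_NONE_"


def _shape(s: str) -> str:
    return "".join(
        "X" if c.isupper() else "x" if c.islower() else "d" if c.isdigit() else c
        for c in s
    )


def _compress(s: str) -> str:
    out = []
    for c in s:
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


class Gazetteer:
    """A bacteria-name dictionary: plain text, one name per line.

    Membership is case-sensitive exact word membership — a token matches if
    it equals any whitespace-separated word of any entry ("coli" matches the
    entry "Escherichia coli").
    """

    def __init__(self, entries: Iterable[str] = ()):
        self.entries: tuple[str, ...] = tuple(e.strip() for e in entries if e.strip())
        self.words: frozenset[str] = frozenset(w for e in self.entries for w in e.split())

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "Gazetteer":
        return cls(Path(path).read_text(encoding="utf-8").splitlines())

    def __contains__(self, word: str) -> bool:
        return word in self.words

    def __len__(self) -> int:
        return len(self.entries)


#: the documented default attribute set (18 functions of the token surface)
ATTRIBUTE_NAMES = (
    "word",
    "lower",
    "prefix1",
    "prefix2",
    "prefix3",
    "prefix4",
    "suffix1",
    "suffix2",
    "suffix3",
    "suffix4",
    "shape",
    "shape2",
    "is_cap",
    "is_upper",
    "has_digit",
    "has_hyphen",
    "is_single",
    "is_punct",
    "in_dict",
)


def token_attributes(
    token: Union[Token, str], dictionary: Union[Gazetteer, Iterable[str], None] = None
) -> dict[str, Union[str, bool]]:
    """Compute the full default attribute map for one token surface.

    Prefixes/suffixes longer than the token are absent from the map.  Boolean
    flags stay booleans here; template expansion renders them as ``Y``/``N``.
    """
    s = token.surface if isinstance(token, Token) else token
    if dictionary is None:
        gaz = Gazetteer()
    elif isinstance(dictionary, Gazetteer):
        gaz = dictionary
    else:
        gaz = Gazetteer(dictionary)

    shape = _shape(s)
    attrs: dict[str, Union[str, bool]] = {
        "word": s,
        "lower": s.lower(),
        "shape": shape,
        "shape2": _compress(shape),
        "is_cap": s[0].isupper(),
        "is_upper": s.isupper(),
        "has_digit": any(c.isdigit() for c in s),
        "has_hyphen": "-" in s,
        "is_single": len(s) == 1,
        "is_punct": all(c in _PUNCT for c in s),
        "in_dict": s in gaz,
    }
    for k in (1, 2, 3, 4):
        if len(s) >= k:
            attrs[f"prefix{k}"] = s[:k]
            attrs[f"suffix{k}"] = s[-k:]
    return attrs


@dataclass(frozen=True)
class FeatureTemplate:
    """One template line: kind 'U' (state) or 'B' (transition), its name, and
    the (offset, attribute) references it expands."""

    kind: str  # 'U' or 'B'
    name: str  # full template id, e.g. 'U02' or 'B'
    refs: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if self.kind not in ("U", "B"):
            raise ConfigError(f"template kind must be U or B, got {self.kind!r}")
        for _, attr in self.refs:
            if attr not in ATTRIBUTE_NAMES:
                raise ConfigError(f"template {self.name}: unknown attribute {attr!r}")


_REF = re.compile(r"%x\[(-?\d+),([A-Za-z_][A-Za-z0-9_]*)\]")


def parse_templates(text: str) -> list[FeatureTemplate]:
    """Parse a template file (one template per line, '#' comments ignored)."""
    templates: list[FeatureTemplate] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        kind = line[0]
        if kind not in ("U", "B"):
            raise ParseError(f"template line {lineno}: must start with U or B: {line!r}")
        head, _, body = line.partition(":")
        refs = []
        if body:
            pos = 0
            for m in _REF.finditer(body):
                refs.append((int(m.group(1)), m.group(2)))
                pos = m.end()
            if not refs:
                raise ParseError(f"template line {lineno}: no %x[offset,attr] references: {line!r}")
        templates.append(FeatureTemplate(kind, head, tuple(refs)))
    if not templates:
        raise ParseError("template file contains no templates")
    names = [t.name + str(t.refs) for t in templates]
    if len(set(names)) != len(names):
        raise ParseError("duplicate template lines")
    return templates


#: default template set: context window -2..+2 over words, affix/shape/flag
#: unigrams, word-bigram conjunctions, dictionary flags, and the transition bias
DEFAULT_TEMPLATES = """\
U00:%x[-2,word]
U01:%x[-1,word]
U02:%x[0,word]
U03:%x[1,word]
U04:%x[2,word]
U05:%x[-1,word]/%x[0,word]
U06:%x[0,word]/%x[1,word]
U07:%x[0,lower]
U08:%x[0,prefix1]
U09:%x[0,prefix2]
U10:%x[0,prefix3]
U11:%x[0,prefix4]
U12:%x[0,suffix1]
U13:%x[0,suffix2]
U14:%x[0,suffix3]
U15:%x[0,suffix4]
U16:%x[0,shape]
U17:%x[-1,shape2]
U18:%x[0,shape2]
U19:%x[1,shape2]
U20:%x[0,is_cap]
U21:%x[0,is_upper]
U22:%x[0,has_digit]
U23:%x[0,has_hyphen]
U24:%x[0,is_single]
U25:%x[0,is_punct]
U26:%x[-1,in_dict]
U27:%x[0,in_dict]
U28:%x[1,in_dict]
U29:%x[0,in_dict]/%x[0,is_cap]
B
"""


def _render(value: Union[str, bool, None]) -> str:
    if value is None:
        return NONE
    if isinstance(value, bool):
        return "Y" if value else "N"
    return value


def expand_templates(
    sentence: Sequence[Union[Token, str]],
    attrs: Sequence[Mapping[str, Union[str, bool]]],
    templates: Sequence[FeatureTemplate],
) -> tuple[list[list[str]], list[list[str]]]:
    """Expand templates at every position of one sentence.

    Returns ``(state_features, transition_features)``, each a per-position
    list of feature strings.  Both depend only on the observation sequence —
    never on labels.  A string looks like ``U05:word[-1]|word[0]=the|coli``;
    the bare transition bias renders as ``B``.
    """
    n = len(sentence)
    if len(attrs) != n:
        raise ConfigError("attrs must be computed for every position")
    state: list[list[str]] = [[] for _ in range(n)]
    trans: list[list[str]] = [[] for _ in range(n)]
    for tpl in templates:
        sink = state if tpl.kind == "U" else trans
        if not tpl.refs:  # bare bias template
            for i in range(n):
                sink[i].append(tpl.name)
            continue
        key = "|".join(f"{attr}[{off}]" for off, attr in tpl.refs)
        for i in range(n):
            vals = []
            for off, attr in tpl.refs:
                j = i + off
                if j < 0:
                    vals.append(BOS)
                elif j >= n:
                    vals.append(EOS)
                else:
                    vals.append(_render(attrs[j].get(attr)))
            sink[i].append(f"{tpl.name}:{key}={'|'.join(vals)}")
    return state, trans


class FeatureIndex:
    """Dense bidirectional map from feature strings to integer ids.

    Ids are assigned 0..K-1 in lexicographic string order, so runs over the
    same corpus are reproducible.  Once frozen, unseen strings map to ``None``
    (they contribute zero score at prediction time) rather than new ids.
    """

    def __init__(self) -> None:
        self._counts: Counter[str] = Counter()
        self._ids: dict[str, int] = {}
        self._strings: list[str] = []
        self.frozen = False

    def observe(self, feature: str, count: int = 1) -> None:
        if self.frozen:
            raise ConfigError("cannot observe new features on a frozen index")
        self._counts[feature] += count

    def freeze(self, min_count: int = 1) -> None:
        if min_count < 1:
            raise ConfigError(f"min_count must be >= 1, got {min_count}")
        self._strings = sorted(s for s, c in self._counts.items() if c >= min_count)
        self._ids = {s: i for i, s in enumerate(self._strings)}
        self.frozen = True

    @classmethod
    def from_strings(cls, strings: Sequence[str]) -> "FeatureIndex":
        """Rebuild a frozen index from an id-ordered string list (model load)."""
        idx = cls()
        idx._strings = list(strings)
        idx._ids = {s: i for i, s in enumerate(strings)}
        idx.frozen = True
        return idx

    def get(self, feature: str) -> Union[int, None]:
        return self._ids.get(feature)

    def __getitem__(self, feature: str) -> int:
        return self._ids[feature]

    def string(self, fid: int) -> str:
        return self._strings[fid]

    @property
    def strings(self) -> tuple[str, ...]:
        return tuple(self._strings)

    def count(self, feature: str) -> int:
        return self._counts.get(feature, 0)

    def __contains__(self, feature: str) -> bool:
        return feature in self._ids

    def __len__(self) -> int:
        return len(self._strings)


def build_feature_index(
    corpus: Corpus,
    templates: Sequence[FeatureTemplate],
    dictionary: Union[Gazetteer, None] = None,
    min_count: int = 1,
) -> FeatureIndex:
    """Expand every sentence of ``corpus`` and index all feature strings
    occurring at least ``min_count`` times.  Returns a frozen index."""
    if min_count < 1:
        raise ConfigError(f"min_count must be >= 1, got {min_count}")
    if len(corpus) == 0:
        raise ConfigError("cannot build a feature index from an empty corpus")
    gaz = dictionary or Gazetteer()
    index = FeatureIndex()
    for sent in corpus:
        attrs = [token_attributes(t, gaz) for t in sent.tokens]
        state, trans = expand_templates(sent.tokens, attrs, templates)
        for feats in state:
            for f in feats:
                index.observe(f)
        # transition features attach to edges (i-1, i): position 0 has none
        for feats in trans[1:]:
            for f in feats:
                index.observe(f)
    index.freeze(min_count)
    return index
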