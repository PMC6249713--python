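"""Synthetic annotated corpora of bacteria mentions.

Real manually annotated bacteria-NER corpora are not redistributable, so this
module plants known entities into template sentences and returns the exact
gold spans alongside, giving every pipeline stage a ground truth.  It
emulates the surface phenomena that make bacteria mentions hard:

* multi-token Latin binomials ("Escherichia coli", "Bacillus subtilis");
* the same entity under different writings — a configurable fraction of
  mentions is abbreviated to genus initial + species ("E. coli");
* long names that contain shorter names as prefixes (strain and serovar
  designations such as "Escherichia coli O157" vs "Escherichia coli") — the
  surface side of nesting; IOB2 itself cannot encode overlapping gold spans,
  so only the longest planted span is annotated;
* out-of-dictionary mentions: plausible Latin-shaped names absent from the
  gazetteer, at a configurable rate;
* light noise: random case flips / character swaps on context tokens.

Two built-in sentence-template groups ("train" and "eval") share no context
vocabulary, so a model scored on eval-group text cannot lean on memorized
context words — only on the gazetteer and on token-internal evidence.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

from .corpus import AnnotatedSentence, Corpus, Token, detokenize
from .errors import ConfigError
from .evaluation import EntitySpan
from .features import Gazetteer

__all__ = [
    "BACTERIA_NAMES",
    "TRAIN_TEMPLATES",
    "EVAL_TEMPLATES",
    "SynthConfig",
    "generate_corpus",
    "generate_raw",
    "train_eval_configs",
]

#: ~50 real bacteria names, including pairs where one name is a prefix of a
#: longer one (the nesting phenomenon at surface level)
BACTERIA_NAMES: tuple[str, ...] = (
    "Escherichia coli",
    "Escherichia coli O157",
    "Bacillus subtilis",
    "Bacillus cereus",
    "Bacillus anthracis",
    "Staphylococcus aureus",
    "Staphylococcus epidermidis",
    "Streptococcus pneumoniae",
    "Streptococcus pyogenes",
    "Streptococcus mutans",
    "Salmonella enterica",
    "Salmonella enterica serovar Typhimurium",
    "Pseudomonas aeruginosa",
    "Pseudomonas putida",
    "Klebsiella pneumoniae",
    "Helicobacter pylori",
    "Mycobacterium tuberculosis",
    "Mycobacterium leprae",
    "Clostridium difficile",
    "Clostridium botulinum",
    "Clostridium perfringens",
    "Lactobacillus acidophilus",
    "Lactobacillus rhamnosus",
    "Lactobacillus plantarum",
    "Bifidobacterium longum",
    "Bifidobacterium bifidum",
    "Listeria monocytogenes",
    "Vibrio cholerae",
    "Vibrio parahaemolyticus",
    "Yersinia pestis",
    "Yersinia enterocolitica",
    "Haemophilus influenzae",
    "Neisseria meningitidis",
    "Neisseria gonorrhoeae",
    "Campylobacter jejuni",
    "Enterococcus faecalis",
    "Enterococcus faecium",
    "Acinetobacter baumannii",
    "Bacteroides fragilis",
    "Bacteroides thetaiotaomicron",
    "Proteus mirabilis",
    "Serratia marcescens",
    "Shigella flexneri",
    "Shigella dysenteriae",
    "Legionella pneumophila",
    "Borrelia burgdorferi",
    "Treponema pallidum",
    "Corynebacterium diphtheriae",
    "Moraxella catarrhalis",
    "Akkermansia muciniphila",
    "Faecalibacterium prausnitzii",
)

#: entity slots are written {ENT}; tokens are space-separated
TRAIN_TEMPLATES: tuple[str, ...] = (
    "{ENT} causes severe infection in hospitalized patients .",
    "We isolated {ENT} from contaminated soil samples .",
    "Cultures of {ENT} were grown overnight under anaerobic conditions .",
    "Treatment reduced colonization by {ENT} in the murine gut .",
    "{ENT} and {ENT} compete for scarce nutrients .",
    "Antibiotic resistance genes were detected in {ENT} strains .",
    "The genome of {ENT} encodes numerous virulence factors .",
)

#: no word of these templates occurs in TRAIN_TEMPLATES (punctuation aside)
EVAL_TEMPLATES: tuple[str, ...] = (
    "{ENT} produces a potent toxin during stationary phase .",
    "Colonies resembling {ENT} appeared on selective agar plates .",
    "Infants carrying {ENT} showed elevated inflammatory markers .",
    "Growth rates differed when {ENT} encountered oxidative stress .",
    "{ENT} adheres strongly to epithelial surfaces .",
    "Sequencing revealed that {ENT} harbors plasmid-borne determinants .",
)

TRAIN_FILLERS: tuple[str, ...] = ("this pathogen", "another microbe")
EVAL_FILLERS: tuple[str, ...] = ("one organism", "such species")

_OOV_GENUS_STEMS = ("Lacto", "Strepto", "Entero", "Pseudo", "Thermo", "Halo", "Micro", "Geo")
_OOV_GENUS_TAILS = ("vibrium", "sporum", "phagus", "nema", "toga", "cella")
_OOV_SPECIES = ("lentus", "parvus", "durans", "mirus", "albens", "rugosus", "tenax", "vorax")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    ``entity_rate`` is the probability that a template's entity slot receives
    an entity (rather than a plain noun phrase); ``abbrev_rate`` the
    probability a multi-token name is abbreviated; ``oov_rate`` the
    probability a planted entity is drawn from outside the dictionary;
    ``noise_rate`` the per-sentence probability of one casing/typo
    perturbation on a context token.  ``seed`` fixes all randomness.
    """

    n_sentences: int = 100
    names: tuple[str, ...] = BACTERIA_NAMES
    templates: tuple[str, ...] = TRAIN_TEMPLATES
    fillers: tuple[str, ...] = TRAIN_FILLERS
    entity_rate: float = 0.7
    abbrev_rate: float = 0.3
    oov_rate: float = 0.1
    noise_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sentences < 0:
            raise ConfigError("n_sentences must be >= 0")
        for name in ("entity_rate", "abbrev_rate", "oov_rate", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.entity_rate > 0 and not self.names and self.oov_rate < 1.0:
            raise ConfigError("entity_rate > 0 requires a non-empty name dictionary")
        if not self.templates:
            raise ConfigError("at least one sentence template is required")


def _oov_name(rng: random.Random, known: set[str]) -> str:
    for _ in range(100):
        genus = rng.choice(_OOV_GENUS_STEMS) + rng.choice(_OOV_GENUS_TAILS)
        name = f"{genus} {rng.choice(_OOV_SPECIES)}"
        if name not in known:
            return name
    raise ConfigError("could not draw an out-of-dictionary name")


def _abbreviate(name: str) -> str:
    words = name.split()
    return " ".join([words[0][0] + "."] + words[1:])


def _perturb(rng: random.Random, word: str) -> str:
    if len(word) >= 2 and rng.random() < 0.5:
        i = rng.randrange(len(word) - 1)
        return word[:i] + word[i + 1] + word[i] + word[i + 2 :]
    return word[0].swapcase() + word[1:] if word[0].isalpha() else word


def generate_corpus(config: SynthConfig) -> tuple[Corpus, set[EntitySpan]]:
    """Generate an annotated corpus and the exact set of planted gold spans.

    Reproducible: the same config (including seed) yields identical output.
    """
    rng = random.Random(config.seed)
    known = set(config.names)
    sentences: list[AnnotatedSentence] = []
    gold: set[EntitySpan] = set()

    for si in range(config.n_sentences):
        template = rng.choice(config.templates)
        surfaces: list[str] = []
        tags: list[str] = []
        spans: list[tuple[int, int]] = []
        for piece in template.split():
            if piece == "{ENT}":
                if rng.random() < config.entity_rate:
                    if config.oov_rate > 0 and rng.random() < config.oov_rate:
                        name = _oov_name(rng, known)
                    else:
                        name = rng.choice(config.names)
                    if len(name.split()) >= 2 and rng.random() < config.abbrev_rate:
                        name = _abbreviate(name)
                    words = name.split()
                    spans.append((len(surfaces), len(surfaces) + len(words)))
                    surfaces.extend(words)
                    tags.extend(["B-BAC"] + ["I-BAC"] * (len(words) - 1))
                else:
                    words = rng.choice(config.fillers).split()
                    surfaces.extend(words)
                    tags.extend(["O"] * len(words))
            else:
                surfaces.append(piece)
                tags.append("O")
        if config.noise_rate > 0 and rng.random() < config.noise_rate:
            o_positions = [i for i, t in enumerate(tags) if t == "O" and surfaces[i].isalpha()]
            if o_positions:
                i = rng.choice(o_positions)
                surfaces[i] = _perturb(rng, surfaces[i])
        # sentence-initial capitalization, as in real prose (entities already
        # start with a capitalized genus, so gold strings are unaffected)
        if tags[0] == "O" and surfaces[0][0].islower():
            surfaces[0] = surfaces[0][0].upper() + surfaces[0][1:]
        sentences.append(
            AnnotatedSentence([Token(s, i) for i, s in enumerate(surfaces)], tags)
        )
        for start, end in spans:
            gold.add(EntitySpan(si, start, end, "BAC"))

    return Corpus(sentences), gold


def generate_raw(
    config: SynthConfig, n_abstracts: int, sentences_per_abstract: int = 5
) -> tuple[list[str], Corpus, set[EntitySpan]]:
    """Generate untagged abstract texts plus the hidden gold annotation.

    Returns ``(texts, gold_corpus, gold_spans)``: one plain-text document per
    abstract (sentences detokenized and joined), and the token/tag ground
    truth for end-to-end scoring.  Sentence indices in the spans are global
    across abstracts, in reading order.
    """
    if n_abstracts < 0 or sentences_per_abstract < 1:
        raise ConfigError("n_abstracts must be >= 0 and sentences_per_abstract >= 1")
    total = n_abstracts * sentences_per_abstract
    corpus, gold = generate_corpus(replace(config, n_sentences=total))
    texts = []
    for a in range(n_abstracts):
        block = corpus.sentences[a * sentences_per_abstract : (a + 1) * sentences_per_abstract]
        texts.append(" ".join(detokenize(s.surfaces) for s in block))
    return texts, corpus, gold


def train_eval_configs(
    seed: int, n_train: int = 1000, n_eval: int = 300
) -> tuple[SynthConfig, SynthConfig]:
    """A matched pair of configs sharing the name dictionary but with
    disjoint context vocabulary, for held-out generalization experiments."""
    train_cfg = SynthConfig(n_sentences=n_train, seed=seed)
    eval_cfg = SynthConfig(
        n_sentences=n_eval,
        templates=EVAL_TEMPLATES,
        fillers=EVAL_FILLERS,
        seed=seed + 1,
    )
    return train_cfg, eval_cfg


def default_gazetteer() -> Gazetteer:
    """The built-in bacteria-name dictionary as a :class:`Gazetteer`."""
    return Gazetteer(BACTERIA_NAMES)
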