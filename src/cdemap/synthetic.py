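"""Seeded generator of class-structured synthetic CDE corpora.

Real caDSR data elements come in families: all members of one BRIDG
class share an object-class/property vocabulary, their long names are
concatenations of object class, property and representation term, and
their question texts are sentence-form paraphrases of the same content
words. The generator emulates exactly that structure with a synthetic
lexicon, so difficulty is controllable:

``overlap_fraction``
    share of each class's vocabulary drawn from a pool common to all
    classes (0 = pairwise disjoint class vocabularies, 1 = identical).
``typo_rate``
    per-word probability of one random single-character edit, which
    stresses the edit-distance word matching relative to the threshold.
``informative_attribute``
    when set (1..6), only that attribute draws from a tight per-class
    signature vocabulary; the other five carry striped "convention"
    phrases from a pool common to all classes — phrasing that recurs at
    the same member position across classes, the way representation-term
    conventions recur across real registries, and therefore carries no
    class signal. In this mode the informative attribute is the only one
    separating the classes, and weight learning should concentrate
    weight on it (a parameter-recovery scenario).

Content words double as the records' DEC concept identifiers, so the
concept-overlap statistic has an exact expected value under any
``overlap_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import CDECorpus, CDERecord
from .exceptions import ConfigurationError

_CONSONANTS = "bcdfghjklmnprstvz"
_VOWELS = "aeiou"
_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a generated corpus.

    Defaults mirror the scale of a realistic curated training set: 19
    classes of 60 members (~1140 records), a dozen content words per
    class vocabulary, moderate cross-class vocabulary sharing and a low
    typo rate.
    """

    n_classes: int = 19
    members_per_class: int | tuple[int, ...] = 60
    vocab_size_per_class: int = 12
    overlap_fraction: float = 0.3
    typo_rate: float = 0.05
    informative_attribute: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ConfigurationError(f"n_classes must be >= 1, got {self.n_classes}")
        sizes = self.class_sizes()
        if any(s < 2 for s in sizes):
            raise ConfigurationError(
                "members_per_class must be >= 2 everywhere (classes must "
                f"support within-class averages), got {sizes}"
            )
        if self.vocab_size_per_class < 2:
            raise ConfigurationError(
                f"vocab_size_per_class must be >= 2, got {self.vocab_size_per_class}"
            )
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ConfigurationError(
                f"overlap_fraction must lie in [0, 1], got {self.overlap_fraction}"
            )
        if not 0.0 <= self.typo_rate <= 1.0:
            raise ConfigurationError(f"typo_rate must lie in [0, 1], got {self.typo_rate}")
        if self.informative_attribute is not None and not 1 <= self.informative_attribute <= 6:
            raise ConfigurationError(
                f"informative_attribute must be 1..6 or None, got {self.informative_attribute}"
            )

    def class_sizes(self) -> tuple[int, ...]:
        if isinstance(self.members_per_class, int):
            return (self.members_per_class,) * self.n_classes
        sizes = tuple(int(s) for s in self.members_per_class)
        if len(sizes) != self.n_classes:
            raise ConfigurationError(
                f"members_per_class lists {len(sizes)} sizes for {self.n_classes} classes"
            )
        return sizes

    def to_dict(self) -> dict:
        return {
            "n_classes": self.n_classes,
            "members_per_class": (
                self.members_per_class
                if isinstance(self.members_per_class, int)
                else list(self.members_per_class)
            ),
            "vocab_size_per_class": self.vocab_size_per_class,
            "overlap_fraction": self.overlap_fraction,
            "typo_rate": self.typo_rate,
            "informative_attribute": self.informative_attribute,
            "seed": self.seed,
        }


def _make_word(rng: np.random.Generator) -> str:
    """A pronounceable CV-syllable word of length 4-10."""
    n_syllables = int(rng.integers(2, 6))
    return "".join(
        _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syllables)
    )


def _make_lexicon(rng: np.random.Generator, count: int) -> list[str]:
    """``count`` distinct synthetic words."""
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < count:
        w = _make_word(rng)
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def perturb_word(word: str, n_edits: int, rng: np.random.Generator) -> str:
    """Apply up to ``n_edits`` random single-character edits to a word.

    The result is non-empty and at edit distance at most ``n_edits``
    from the input (deletions are skipped on single-character words).
    """
    if not word:
        raise ConfigurationError("cannot perturb an empty word")
    out = word
    for _ in range(n_edits):
        ops = ["insert", "substitute"] + (["delete"] if len(out) > 1 else [])
        op = ops[rng.integers(len(ops))]
        if op == "insert":
            pos = int(rng.integers(len(out) + 1))
            out = out[:pos] + _ALPHABET[rng.integers(26)] + out[pos:]
        elif op == "delete":
            pos = int(rng.integers(len(out)))
            out = out[:pos] + out[pos + 1 :]
        else:
            pos = int(rng.integers(len(out)))
            out = out[:pos] + _ALPHABET[rng.integers(26)] + out[pos + 1 :]
    return out


def _maybe_typo(words: Sequence[str], typo_rate: float, rng: np.random.Generator) -> list[str]:
    return [
        perturb_word(w, 1, rng) if typo_rate > 0 and rng.random() < typo_rate else w
        for w in words
    ]


def _draw(vocab: Sequence[str], k: int, rng: np.random.Generator) -> list[str]:
    return [vocab[int(i)] for i in rng.integers(len(vocab), size=k)]


def generate_corpus(config: SyntheticConfig) -> CDECorpus:
    """Generate a labeled synthetic corpus per the configuration.

    In the default (templated) mode each record draws content words from
    its class vocabulary: object class (2 words), property (1), and
    representation term (2); the long name is their concatenation, the
    value domain long name extends the representation term, and the
    question text is the sentence "what was the <property> of the
    <object class>". With ``informative_attribute`` set, every attribute
    instead draws its words independently — the chosen attribute from
    the class vocabulary, the rest from a common pool — so that exactly
    one attribute separates the classes.

    Identical configs produce identical corpora (a single seeded
    generator drives every draw in a fixed order).
    """
    rng = np.random.default_rng(config.seed)
    sizes = config.class_sizes()
    V = config.vocab_size_per_class
    n_shared = int(round(config.overlap_fraction * V))
    n_specific = V - n_shared

    # one draw order, fixed: shared pool, common pool, then per-class words
    common_size = V
    lexicon = _make_lexicon(
        rng, n_shared + common_size + n_specific * config.n_classes
    )
    shared_pool = lexicon[:n_shared]
    common_pool = lexicon[n_shared : n_shared + common_size]
    class_vocabs: list[list[str]] = []
    signatures: list[list[str]] = []
    offset = n_shared + common_size
    for c in range(config.n_classes):
        specific = lexicon[offset : offset + n_specific]
        offset += n_specific
        class_vocabs.append(specific + shared_pool)
        # tight per-class signature for the informative-attribute mode:
        # few words (class-specific ones first), so the informative
        # attribute repeats within a class the way a real CDE family
        # repeats its object-class phrase
        signatures.append((specific + shared_pool)[: min(4, V)])

    records: list[CDERecord] = []
    idx = 0
    for c, size in enumerate(sizes):
        cls_name = f"SynClass{c + 1:02d}"
        vocab = class_vocabs[c]
        for member_idx in range(size):
            idx += 1
            if config.informative_attribute is None:
                oc = _draw(vocab, 2, rng)
                prop = _draw(vocab, 1, rng)
                rep = _draw(vocab, 2, rng)
                content = oc + prop + rep
                attrs = {
                    "object_class": oc,
                    "property_name": prop,
                    "representation_term": rep,
                    "long_name": oc + prop + rep,
                    "value_domain_long_name": rep + ["type"],
                    "question_text": ["what", "was", "the"] + prop + ["of", "the"] + oc,
                }
            else:
                # every attribute carries the same number of words here, and
                # there are no constant tokens: a shared sentence frame, a
                # "type" suffix, or a longer phrase would hand an attribute
                # a higher matched-word baseline and mask the informative one.
                # Non-informative attributes take striped "convention"
                # phrases from the common pool — phrasing that recurs at the
                # same position across classes (like representation-term
                # conventions in real registries) and so carries no class
                # signal at all.
                drawn = []
                for i in range(6):
                    if config.informative_attribute == i + 1:
                        drawn.append(_draw(signatures[c], 2, rng))
                    else:
                        pool_n = len(common_pool)
                        start = (2 * i + member_idx) % pool_n
                        drawn.append(
                            [common_pool[start], common_pool[(start + 1) % pool_n]]
                        )
                content = [w for words in drawn for w in words]
                attrs = dict(zip(
                    (
                        "long_name", "object_class", "property_name",
                        "value_domain_long_name", "representation_term",
                        "question_text",
                    ),
                    drawn,
                ))
            noisy = {
                name: " ".join(_maybe_typo(words, config.typo_rate, rng))
                for name, words in attrs.items()
            }
            records.append(
                CDERecord(
                    public_id=f"SYN{idx:05d}",
                    long_name=noisy["long_name"],
                    object_class=noisy["object_class"],
                    property_name=noisy["property_name"],
                    value_domain_long_name=noisy["value_domain_long_name"],
                    representation_term=noisy["representation_term"],
                    question_text=noisy["question_text"],
                    dec_concepts=frozenset(content),
                    mapped_class=cls_name,
                )
            )
    return CDECorpus(records)
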