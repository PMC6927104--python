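"""Lexical similarity between CDEs.

The similarity of two data elements is assembled bottom-up:

1. *word similarity* ``s_word = 1 - d/l`` where ``d`` is the Levenshtein
   edit distance between two words and ``l`` the length of the longer one;
2. a *greedy matrix reduction*: build the all-pairs word-similarity matrix
   between the two attribute phrases, repeatedly extract the current
   global maximum and delete its row and column, collecting the extracted
   values into a non-increasing word-similarity list;
3. *attribute similarity* ``s_i``: the fraction of list entries at or
   above a fixed word-similarity threshold;
4. *overall similarity* ``s = sum_i w_i s_i``: the weighted sum over the
   six attributes, with the weights ``w_1..w_6`` on the probability
   simplex. The weights are what training learns.

Edit distance itself is computed by edlib (banded Myers bit-vector
algorithm, unit costs), which agrees with the textbook dynamic program.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np

from .corpus import ATTRIBUTE_FIELDS, CDERecord
from .exceptions import ConfigurationError, ValidationError

_NON_ALNUM = re.compile(r"[^0-9a-z]+")

#: Human-readable labels for the six weights, in canonical order.
WEIGHT_LABELS: tuple[str, ...] = (
    "w1 (CDE Long Name)",
    "w2 (Object Class)",
    "w3 (Property)",
    "w4 (Value Domain Long Name)",
    "w5 (Representation Term)",
    "w6 (Question Text)",
)


def tokenize(text: str) -> tuple[str, ...]:
    """Split a phrase into lowercase words.

    Case is folded, every non-alphanumeric character becomes a separator,
    and runs of separators collapse; an empty phrase yields no tokens.
    """
    return tuple(t for t in _NON_ALNUM.split(text.lower()) if t)


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance between two words.

    Symmetric, zero exactly when the words are identical.
    """
    if not a or not b:
        return len(a) + len(b)
    return edlib.align(a, b)["editDistance"]


def word_similarity(a: str, b: str) -> float:
    """``1 - d/l``: edit distance scaled by the longer word's length.

    Case-insensitive; lies in [0, 1] and equals 1 exactly when the
    case-folded words coincide. Undefined (raises) when both words are
    empty.
    """
    a, b = a.casefold(), b.casefold()
    longer = max(len(a), len(b))
    if longer == 0:
        raise ValidationError("word similarity is undefined for two empty words")
    return 1.0 - edit_distance(a, b) / longer


def word_similarity_matrix(a: Sequence[str], b: Sequence[str]) -> np.ndarray:
    """|a| x |b| matrix of pairwise word similarities."""
    out = np.empty((len(a), len(b)))
    for i, wa in enumerate(a):
        for j, wb in enumerate(b):
            out[i, j] = word_similarity(wa, wb)
    return out


def greedy_reduce(matrix: np.ndarray) -> list[float]:
    """Greedy extraction of maxima from a similarity matrix.

    Repeatedly take the largest remaining entry (ties: smallest row, then
    smallest column), record it, and delete its row and column, until one
    dimension is exhausted. The result has length ``min(rows, cols)`` and
    is non-increasing.
    """
    m = np.array(matrix, dtype=float, copy=True)
    if m.size == 0:
        return []
    rows, cols = m.shape
    out: list[float] = []
    for _ in range(min(rows, cols)):
        flat = int(np.argmax(m))  # row-major argmax == smallest row, then col
        i, j = divmod(flat, cols)
        out.append(float(m[i, j]))
        m[i, :] = -np.inf
        m[:, j] = -np.inf
    return out


def greedy_similarity_list(a: Sequence[str], b: Sequence[str]) -> list[float]:
    """The word-similarity list for two token sequences.

    Either sequence empty yields the empty list.
    """
    if not a or not b:
        return []
    return greedy_reduce(word_similarity_matrix(a, b))


def _check_threshold(threshold: float) -> None:
    if not 0.0 < threshold <= 1.0:
        raise ConfigurationError(
            f"word similarity threshold must lie in (0, 1], got {threshold}"
        )


def attribute_similarity(a: str, b: str, threshold: float) -> float:
    """Fraction of greedily matched word pairs at or above ``threshold``.

    Both phrases are tokenized, the greedy word-similarity list is built,
    and a pair counts as matched when its similarity is >= the threshold
    (which is held fixed for the life of a model). If either phrase has
    no tokens the similarity is 0: absent text carries no evidence of a
    match.
    """
    _check_threshold(threshold)
    ta, tb = tokenize(a), tokenize(b)
    sims = greedy_similarity_list(ta, tb)
    if not sims:
        return 0.0
    matched = sum(1 for s in sims if s >= threshold)
    return matched / len(sims)


def attribute_vector(a: CDERecord, b: CDERecord, threshold: float) -> np.ndarray:
    """The six attribute similarities (s1..s6) between two records."""
    return np.array(
        [
            attribute_similarity(getattr(a, name), getattr(b, name), threshold)
            for name in ATTRIBUTE_FIELDS
        ]
    )


@dataclass(frozen=True)
class SimilarityWeights:
    """The six attribute weights, constrained to the probability simplex."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) != len(ATTRIBUTE_FIELDS):
            raise ConfigurationError(f"expected 6 weights, got {len(vals)}")
        if any(v < 0 for v in vals):
            raise ConfigurationError(f"weights must be non-negative, got {vals}")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ConfigurationError(f"weights must sum to 1 (tol 1e-9), got sum {sum(vals)!r}")

    @classmethod
    def uniform(cls) -> "SimilarityWeights":
        return cls((1 / 6,) * 6)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "SimilarityWeights":
        return cls(tuple(float(v) for v in arr))

    def as_array(self) -> np.ndarray:
        return np.array(self.values)

    def to_dict(self) -> dict[str, float]:
        return {f"w{i + 1}": v for i, v in enumerate(self.values)}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "SimilarityWeights":
        return cls(tuple(float(mapping[f"w{i + 1}"]) for i in range(6)))


def overall_similarity(vector: Sequence[float], weights: SimilarityWeights) -> float:
    """Weighted sum ``s = sum_i w_i s_i`` of the six attribute similarities."""
    return float(np.dot(np.asarray(vector, dtype=float), weights.as_array()))


class SimilarityCache:
    """Memoised attribute similarities at one fixed threshold.

    Attribute texts repeat heavily across a corpus (object classes,
    representation terms and question templates are shared by many
    records), so both the word-pair similarities and the phrase-pair
    attribute similarities are cached. Keys are symmetric.
    """

    def __init__(self, threshold: float):
        _check_threshold(threshold)
        self.threshold = threshold
        self._tokens: dict[str, tuple[str, ...]] = {}
        self._words: dict[tuple[str, str], float] = {}
        self._attrs: dict[tuple[str, str], float] = {}

    def _tokenize(self, text: str) -> tuple[str, ...]:
        try:
            return self._tokens[text]
        except KeyError:
            toks = tokenize(text)
            self._tokens[text] = toks
            return toks

    def _word_sim(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        try:
            return self._words[key]
        except KeyError:
            s = word_similarity(a, b)
            self._words[key] = s
            return s

    def attribute_similarity(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        try:
            return self._attrs[key]
        except KeyError:
            pass
        ta, tb = self._tokenize(a), self._tokenize(b)
        if not ta or not tb:
            result = 0.0
        else:
            m = np.empty((len(ta), len(tb)))
            for i, wa in enumerate(ta):
                for j, wb in enumerate(tb):
                    m[i, j] = self._word_sim(wa, wb)
            sims = greedy_reduce(m)
            result = sum(1 for s in sims if s >= self.threshold) / len(sims)
        self._attrs[key] = result
        return result

    def attribute_vector(self, a: CDERecord, b: CDERecord) -> np.ndarray:
        return np.array(
            [
                self.attribute_similarity(getattr(a, name), getattr(b, name))
                for name in ATTRIBUTE_FIELDS
            ]
        )

    def pairwise_matrix(self, records_a: Sequence[CDERecord], records_b: Sequence[CDERecord]) -> np.ndarray:
        """len(a) x len(b) x 6 array of attribute-similarity vectors."""
        out = np.empty((len(records_a), len(records_b), len(ATTRIBUTE_FIELDS)))
        for i, ra in enumerate(records_a):
            for j, rb in enumerate(records_b):
                out[i, j] = self.attribute_vector(ra, rb)
        return out
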