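"""Recommendation of candidate BRIDG classes and evaluation of a model.

A query CDE is scored against each stored class by averaging its overall
similarity to the class's stored members (mirroring the ``s_avg``
construction used in training); the top-k classes by score are returned
for a domain expert to review. The evaluation harness measures the
*match rate*: the percentage of labeled query CDEs whose known class
appears among the top-n recommendations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .corpus import CDECorpus, CDERecord, SplitConfig, cap_class_members, split_train_verify
from .exceptions import ConfigurationError, DegenerateInputError, ValidationError
from .similarity import SimilarityCache, SimilarityWeights, overall_similarity

if TYPE_CHECKING:  # pragma: no cover
    from .model import MapperResults, TrainingConfig


@dataclass(frozen=True)
class Recommendation:
    """Ranked candidate classes for one query CDE."""

    query_id: str
    candidates: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        scores = [s for _, s in self.candidates]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValidationError("candidate scores must be non-increasing")
        names = [c for c, _ in self.candidates]
        if len(set(names)) != len(names):
            raise ValidationError("candidate class names must be unique")

    def rank_of(self, class_name: str) -> int | None:
        """1-based rank of a class among the candidates, or None."""
        for rank, (name, _) in enumerate(self.candidates, start=1):
            if name == class_name:
                return rank
        return None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "query_id": self.query_id,
                "rank": range(1, len(self.candidates) + 1),
                "class": [c for c, _ in self.candidates],
                "score": [s for _, s in self.candidates],
            }
        )


@dataclass(frozen=True)
class EvaluationReport:
    """Top-n match rate over a labeled query set.

    ``per_query`` holds (query id, true class, rank of the true class in
    the full candidate ranking, or None when the class is unknown to the
    model).
    """

    n: int
    match_rate: float
    per_query: tuple[tuple[str, str, int | None], ...]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_query, columns=["query_id", "true_class", "rank"]
        )


def class_similarity(
    query: CDERecord,
    members: Sequence[CDERecord],
    w: SimilarityWeights,
    threshold: float,
    cache: SimilarityCache | None = None,
    aggregate: str = "mean",
) -> float:
    """Similarity of a query CDE to one class: mean (or max) over members.

    If the query itself is stored among the members it is excluded, so a
    training record does not trivially match its own class through
    self-similarity.
    """
    cache = cache or SimilarityCache(threshold)
    others = [m for m in members if m.public_id != query.public_id]
    if not others:
        raise DegenerateInputError(
            "class similarity undefined: no members to compare against"
        )
    sims = [
        overall_similarity(cache.attribute_vector(query, m), w) for m in others
    ]
    if aggregate == "mean":
        return float(np.mean(sims))
    if aggregate == "max":
        return float(np.max(sims))
    raise ConfigurationError(f"aggregate must be 'mean' or 'max', got {aggregate!r}")


def recommend(
    query: CDERecord,
    results: "MapperResults",
    k: int = 10,
    aggregate: str = "mean",
) -> Recommendation:
    """Top-k candidate classes for a query, scored with the fitted weights.

    Classes are ordered by descending score, ties broken by class name,
    and the list truncated to ``k`` (default 10, the length shown to
    domain experts).
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if not results.class_members:
        raise DegenerateInputError("model holds no classes")
    cache = getattr(results, "_cache")
    scored = [
        (
            cls,
            class_similarity(
                query,
                results.class_members[cls],
                results.weights,
                results.threshold,
                cache=cache,
                aggregate=aggregate,
            ),
        )
        for cls in sorted(results.class_members)
    ]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return Recommendation(query_id=query.public_id, candidates=tuple(scored[:k]))


def _ranks(
    queries: Iterable[CDERecord], results: "MapperResults", aggregate: str = "mean"
) -> list[tuple[str, str, int | None]]:
    n_classes = len(results.class_members)
    out = []
    for q in queries:
        if not q.mapped_class:
            raise ValidationError(f"query {q.public_id!r} carries no mapped_class")
        rec = recommend(q, results, k=n_classes, aggregate=aggregate)
        out.append((q.public_id, q.mapped_class, rec.rank_of(q.mapped_class)))
    return out


def match_rate(
    queries: CDECorpus | Iterable[CDERecord],
    results: "MapperResults",
    n: int,
    aggregate: str = "mean",
) -> EvaluationReport:
    """Top-n match rate: % of queries whose true class ranks within n."""
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    per_query = tuple(_ranks(queries, results, aggregate))
    if not per_query:
        raise DegenerateInputError("match rate undefined over zero queries")
    matched = sum(1 for _, _, rank in per_query if rank is not None and rank <= n)
    return EvaluationReport(
        n=n, match_rate=100.0 * matched / len(per_query), per_query=per_query
    )


def evaluation_table(
    queries: CDECorpus | Iterable[CDERecord],
    results: "MapperResults",
    n_values: Sequence[int] = tuple(range(1, 11)),
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Match rates for a range of n (default 1..10) from one ranking pass."""
    per_query = _ranks(queries, results, aggregate)
    if not per_query:
        raise DegenerateInputError("match rate undefined over zero queries")
    total = len(per_query)
    rows = []
    for n in n_values:
        matched = sum(1 for _, _, r in per_query if r is not None and r <= n)
        rows.append({"n": n, "match_rate_percent": round(100.0 * matched / total, 2),
                     "n_queries": total})
    return pd.DataFrame(rows)


def restrict_to_sufficient(
    queries: CDECorpus, results: "MapperResults", min_members: int
) -> list[CDERecord]:
    """Keep only queries whose true class has enough stored training data."""
    sufficient = {
        cls
        for cls, members in results.class_members.items()
        if len(members) >= min_members
    }
    return [q for q in queries if q.mapped_class in sufficient]


# ---------------------------------------------------------------------------
# parameter grid sweep


@dataclass(frozen=True)
class SweepPoint:
    """One grid point: a training config, a split config, a per-class cap
    on stored training members, and the n at which to score."""

    training: "TrainingConfig"
    split: SplitConfig
    per_class_cap: int | None
    n: int


def make_grid(
    train_fractions: Sequence[float],
    thresholds: Sequence[float],
    per_class_caps: Sequence[int | None],
    n_values: Sequence[int],
    seed: int = 0,
    **training_kwargs,
) -> list[SweepPoint]:
    """Cartesian product of the evaluation-grid axes."""
    from .model import TrainingConfig

    points = []
    for frac, thr, cap, n in itertools.product(
        train_fractions, thresholds, per_class_caps, n_values
    ):
        points.append(
            SweepPoint(
                training=TrainingConfig(
                    word_similarity_threshold=thr, seed=seed, **training_kwargs
                ),
                split=SplitConfig(train_fraction=frac, seed=seed),
                per_class_cap=cap,
                n=n,
            )
        )
    return points


def sweep_parameters(corpus: CDECorpus, grid: Iterable[SweepPoint]) -> pd.DataFrame:
    """Evaluate every grid point: split, filter, cap, train, score.

    Grid points sharing the same training/split/cap settings reuse one
    fitted model, so sweeping over n costs a single ranking pass. The
    output has one row per point: ratio, threshold, per_class_cap, n,
    match_rate_percent, n_queries.
    """
    from .corpus import filter_by_class_size
    from .model import CDEMapper

    grid = list(grid)
    if not grid:
        raise ConfigurationError("sweep grid is empty")
    fitted: dict[tuple, tuple] = {}
    rows = []
    for point in grid:
        key = (point.training, point.split, point.per_class_cap)
        if key not in fitted:
            train_c, verify_c = split_train_verify(corpus, point.split)
            train_c = filter_by_class_size(train_c, point.training.min_class_size)
            train_c = cap_class_members(
                train_c, point.per_class_cap, seed=point.split.seed
            )
            results = CDEMapper(train_c, point.training).fit()
            per_query = _ranks(verify_c, results)
            fitted[key] = (results, per_query)
        _, per_query = fitted[key]
        total = len(per_query)
        matched = sum(
            1 for _, _, r in per_query if r is not None and r <= point.n
        )
        rows.append(
            {
                "ratio": point.split.train_fraction,
                "threshold": point.training.word_similarity_threshold,
                "per_class_cap": point.per_class_cap,
                "n": point.n,
                "match_rate_percent": round(100.0 * matched / total, 2),
                "n_queries": total,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset statistics


def dec_concept_overlap(test: CDECorpus, train: CDECorpus) -> float:
    """Semantic similarity of a testing set to a training set, in percent.

    The share of distinct DEC concept identifiers in the test corpus that
    also occur in the training corpus (set semantics: duplicates within a
    record are irrelevant).
    """
    test_concepts: set[str] = set()
    for r in test:
        if r.dec_concepts:
            test_concepts.update(r.dec_concepts)
    if not test_concepts:
        raise DegenerateInputError(
            "DEC concept overlap undefined: test corpus carries no concepts"
        )
    train_concepts: set[str] = set()
    for r in train:
        if r.dec_concepts:
            train_concepts.update(r.dec_concepts)
    return 100.0 * len(test_concepts & train_concepts) / len(test_concepts)
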