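"""Weight learning: fit the six attribute weights to a labeled corpus.

The learner is a single-layer 6-to-1 network. Its input is the vector of
six attribute similarities between two CDEs and its output their overall
similarity ``s = sum_i w_i s_i``. Training adjusts the weights by
gradient descent so that, for an anchor CDE, the mean similarity to its
own BRIDG class (``s_avg``) dominates the mean similarity to all other
classes (``s_avg_other_cls``):

    E(w) = 1/2 * (s_max - s_avg)^2,       s_max = max(s_avg, s_avg_other_cls)
    dw_i = eta * (s_max - s_avg) * s_i,   then renormalise onto the simplex

An anchor that already satisfies ``s_avg >= s_avg_other_cls`` contributes
zero error and leaves the weights untouched. Classes are visited from
smallest to largest, for up to ``max_iterations`` full passes, stopping
early once the total per-pass error settles to within 1% of the previous
pass.

Usage follows the Model/Results convention::

    model = CDEMapper(train_corpus, TrainingConfig(word_similarity_threshold=0.8))
    results = model.fit()
    print(results.summary())
    results.recommend(query, k=10)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import CDECorpus, CDERecord, _record_to_row, _row_to_record
from .exceptions import ConfigurationError, DegenerateInputError, ValidationError
from .similarity import (
    ATTRIBUTE_FIELDS,
    WEIGHT_LABELS,
    SimilarityCache,
    SimilarityWeights,
    attribute_vector,
    overall_similarity,
)

#: Relative change in total per-pass error below which training stops.
EARLY_STOP_REL_TOL = 0.01


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the weight-learning run.

    eta
        Gradient-descent learning rate (default 0.05).
    max_iterations
        Cap on full passes over the classes (default 50; by then the
        error trace typically only fluctuates within about 1%).
    word_similarity_threshold
        Word-match cutoff used in every attribute similarity; fixed for
        the life of the model (default 0.8).
    min_class_size
        Classes with fewer members than this are excluded upstream
        (default 10); recorded here so a saved model documents it.
    anchor_mode
        ``"all"`` (default): every class member serves as anchor once per
        pass. ``"first"``: only the first stored member of each class.
    seed
        Seed recorded for provenance; training itself is deterministic.
    """

    eta: float = 0.05
    max_iterations: int = 50
    word_similarity_threshold: float = 0.8
    min_class_size: int = 10
    anchor_mode: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ConfigurationError(f"eta must be positive, got {self.eta}")
        if self.max_iterations < 1:
            raise ConfigurationError(f"max_iterations must be >= 1, got {self.max_iterations}")
        if not 0.0 < self.word_similarity_threshold <= 1.0:
            raise ConfigurationError(
                f"word_similarity_threshold must lie in (0, 1], got {self.word_similarity_threshold}"
            )
        if self.min_class_size < 1:
            raise ConfigurationError(f"min_class_size must be >= 1, got {self.min_class_size}")
        if self.anchor_mode not in ("first", "all"):
            raise ConfigurationError(f"anchor_mode must be 'first' or 'all', got {self.anchor_mode!r}")

    def to_dict(self) -> dict:
        return {
            "eta": self.eta,
            "max_iterations": self.max_iterations,
            "word_similarity_threshold": self.word_similarity_threshold,
            "min_class_size": self.min_class_size,
            "anchor_mode": self.anchor_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrainingConfig":
        return cls(**{k: d[k] for k in cls().to_dict() if k in d})


# ---------------------------------------------------------------------------
# the elementary training quantities


def _mean_similarity(
    anchor: CDERecord,
    others: Sequence[CDERecord],
    w: SimilarityWeights,
    threshold: float,
) -> float:
    sims = [
        overall_similarity(attribute_vector(anchor, m, threshold), w) for m in others
    ]
    return float(np.mean(sims))


def within_class_avg(
    anchor: CDERecord,
    members: Sequence[CDERecord],
    w: SimilarityWeights,
    threshold: float,
) -> float:
    """``s_avg``: mean overall similarity of an anchor to its class peers.

    The anchor itself is excluded (its self-similarity of 1 would inflate
    the average).
    """
    others = [m for m in members if m.public_id != anchor.public_id]
    if not others:
        raise DegenerateInputError(
            "within-class average undefined: the class has no member besides the anchor"
        )
    return _mean_similarity(anchor, others, w, threshold)


def other_class_avg(
    anchor: CDERecord,
    corpus: CDECorpus,
    own_class: str,
    w: SimilarityWeights,
    threshold: float,
) -> float:
    """``s_avg_other_cls``: mean overall similarity to all other classes' members."""
    others = [
        r for r in corpus if r.mapped_class is not None and r.mapped_class != own_class
    ]
    if not others:
        raise DegenerateInputError(
            "between-class average undefined: no records outside the anchor's class"
        )
    return _mean_similarity(anchor, others, w, threshold)


def training_error(s_avg: float, s_other: float) -> float:
    """``E = 1/2 (s_max - s_avg)^2`` — zero when the own class dominates."""
    s_max = max(s_avg, s_other)
    return 0.5 * (s_max - s_avg) ** 2


def update_weights(
    w: SimilarityWeights,
    s_avg: float,
    s_other: float,
    mean_attr: Sequence[float],
    eta: float,
) -> SimilarityWeights:
    """One delta-rule step, renormalised onto the simplex.

    No-op when ``s_avg >= s_other`` (zero error). Otherwise each weight
    gains ``eta * (s_max - s_avg) * mean_attr_i`` where ``mean_attr`` is
    the anchor's mean within-class attribute-similarity vector; dividing
    by the new total restores ``sum w_i = 1`` exactly while preserving
    the update's relative effect.
    """
    if s_avg >= s_other:
        return w
    arr = w.as_array() + eta * (s_other - s_avg) * np.asarray(mean_attr, dtype=float)
    return SimilarityWeights.from_array(arr / arr.sum())


@dataclass(frozen=True)
class TrainingState:
    """Snapshot of the quantities driving one anchor's update."""

    weights: SimilarityWeights
    s_avg: float
    s_avg_other_cls: float
    iteration: int

    @property
    def s_max(self) -> float:
        return max(self.s_avg, self.s_avg_other_cls)

    @property
    def error(self) -> float:
        return training_error(self.s_avg, self.s_avg_other_cls)


# ---------------------------------------------------------------------------
# Model / Results


class CDEMapper:
    """Weight-learning model over a labeled CDE corpus.

    Parameters
    ----------
    corpus
        Training corpus. Every record must carry ``mapped_class``, there
        must be at least two classes, and every class at least two
        members (apply :func:`cdemap.corpus.filter_by_class_size` first).
    config
        :class:`TrainingConfig`; keyword overrides may be passed instead
        of (or on top of) a config object.
    """

    def __init__(self, corpus: CDECorpus, config: TrainingConfig | None = None, **overrides):
        self.config = replace(config or TrainingConfig(), **overrides)
        unmapped = [r.public_id for r in corpus if not r.mapped_class]
        if unmapped:
            raise ValidationError(
                f"training corpus contains {len(unmapped)} unmapped record(s), "
                f"e.g. {unmapped[0]!r}"
            )
        sizes = corpus.class_sizes()
        if len(sizes) < 2:
            raise DegenerateInputError(
                f"training needs at least 2 classes, got {len(sizes)}"
            )
        small = [cls for cls, n in sizes.items() if n < 2]
        if small:
            raise ValidationError(
                "every class needs >= 2 members for within-class averages; "
                f"too small: {', '.join(sorted(small))}"
            )
        self.corpus = corpus
        # classes are trained from the smallest to the largest; ties break
        # lexicographically so the pass order is reproducible
        self.class_order: tuple[str, ...] = tuple(
            sorted(sizes, key=lambda cls: (sizes[cls], cls))
        )
        self._cache = SimilarityCache(self.config.word_similarity_threshold)
        self._pairwise: np.ndarray | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: TrainingConfig | None = None, **overrides) -> "CDEMapper":
        """Build a model from a DataFrame in the canonical column schema."""
        records = [_row_to_record(row) for row in df.to_dict(orient="records")]
        return cls(CDECorpus(records), config, **overrides)

    def _pairwise_attr(self) -> np.ndarray:
        """n x n x 6 attribute-similarity tensor over the training records.

        The attribute similarities do not depend on the weights, so they
        are computed once; every gradient pass then reduces to cheap
        dot products against this tensor.
        """
        if self._pairwise is None:
            records = self.corpus.records
            self._pairwise = self._cache.pairwise_matrix(records, records)
        return self._pairwise

    def fit(self) -> "MapperResults":
        """Run the gradient-descent training loop and return the results."""
        cfg = self.config
        records = self.corpus.records
        n = len(records)
        index_of = {r.public_id: i for i, r in enumerate(records)}
        class_indices = {
            cls: np.array([index_of[m.public_id] for m in members])
            for cls, members in self.corpus.class_index.items()
        }
        outside_mask = {
            cls: np.setdiff1d(np.arange(n), idx)
            for cls, idx in class_indices.items()
        }
        S = self._pairwise_attr()

        w = SimilarityWeights.uniform()
        error_trace: list[float] = []
        converged = False
        iterations_run = 0
        for _ in range(cfg.max_iterations):
            iterations_run += 1
            total_error = 0.0
            for cls in self.class_order:
                idx = class_indices[cls]
                anchors = idx[:1] if cfg.anchor_mode == "first" else idx
                out_idx = outside_mask[cls]
                for a in anchors:
                    in_idx = idx[idx != a]
                    sims = S[a] @ w.as_array()
                    s_avg = float(sims[in_idx].mean())
                    s_other = float(sims[out_idx].mean())
                    total_error += training_error(s_avg, s_other)
                    mean_attr = S[a, in_idx, :].mean(axis=0)
                    w = update_weights(w, s_avg, s_other, mean_attr, cfg.eta)
            error_trace.append(total_error)
            if len(error_trace) >= 2:
                prev, cur = error_trace[-2], error_trace[-1]
                if prev == 0.0:
                    if cur == 0.0:
                        converged = True
                        break
                elif abs(cur - prev) / prev < EARLY_STOP_REL_TOL:
                    converged = True
                    break
        return MapperResults(
            model=self,
            weights=w,
            threshold=cfg.word_similarity_threshold,
            class_members=dict(self.corpus.class_index),
            config=cfg,
            training_log=tuple(error_trace),
            n_iterations=iterations_run,
            converged=converged,
        )


@dataclass(frozen=True)
class MapperResults:
    """Fitted attribute weights plus everything needed to recommend.

    The persisted unit: :meth:`save` writes a JSON document with the six
    named weights, the word-similarity threshold, a config echo, the
    class membership (by public id, with the member records embedded so
    the file is self-contained), and the per-pass error trace;
    :meth:`load` re-validates the simplex constraint.
    """

    weights: SimilarityWeights
    threshold: float
    class_members: Mapping[str, tuple[CDERecord, ...]]
    config: TrainingConfig
    training_log: tuple[float, ...]
    n_iterations: int
    converged: bool
    model: CDEMapper | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "_cache", SimilarityCache(self.threshold))

    @property
    def params(self) -> np.ndarray:
        """The fitted weights as an array (statsmodels convention)."""
        return self.weights.as_array()

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(self.class_members))

    # -- recommendation / evaluation (delegates to cdemap.evaluate) ----------

    def recommend(self, query: CDERecord, k: int = 10, aggregate: str = "mean"):
        from .evaluate import recommend

        return recommend(query, self, k=k, aggregate=aggregate)

    def match_rate(self, queries: CDECorpus | Iterable[CDERecord], n: int = 10):
        from .evaluate import match_rate

        return match_rate(queries, self, n)

    # -- presentation ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable report of the fit, statsmodels style."""
        lines = [
            "CDE-to-BRIDG attribute-weight model",
            "=" * 55,
            f"classes:             {len(self.class_members)}",
            f"training records:    {sum(len(m) for m in self.class_members.values())}",
            f"threshold:           {self.threshold}",
            f"eta:                 {self.config.eta}",
            f"anchor mode:         {self.config.anchor_mode}",
            f"iterations run:      {self.n_iterations}"
            + (" (converged)" if self.converged else " (iteration cap reached)"),
            f"final total error:   {self.training_log[-1]:.6f}" if self.training_log else "",
            "-" * 55,
        ]
        for label, value in zip(WEIGHT_LABELS, self.weights.values):
            lines.append(f"{label:<30}{value:>12.9f}")
        lines.append("-" * 55)
        return "\n".join(lines)

    def weights_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"attribute": ATTRIBUTE_FIELDS, "weight": list(self.weights.values)}
        )

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        members: list[CDERecord] = []
        seen: set[str] = set()
        for cls in sorted(self.class_members):
            for record in self.class_members[cls]:
                if record.public_id not in seen:
                    seen.add(record.public_id)
                    members.append(record)
        doc = {
            "format": "cdemap-model",
            "version": 1,
            "weights": self.weights.to_dict(),
            "threshold": self.threshold,
            "config": self.config.to_dict(),
            "class_members": {
                cls: [m.public_id for m in self.class_members[cls]]
                for cls in sorted(self.class_members)
            },
            "records": [
                {**_record_to_row(r), "dec_concepts": sorted(r.dec_concepts or [])}
                for r in members
            ],
            "training_log": list(self.training_log),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "MapperResults":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        if doc.get("format") != "cdemap-model":
            raise ValidationError(f"{path} is not a cdemap model file")
        weights = SimilarityWeights.from_dict(doc["weights"])  # re-validates simplex
        by_id = {row["public_id"]: _row_to_record(row) for row in doc["records"]}
        class_members = {
            cls: tuple(by_id[pid] for pid in pids)
            for cls, pids in doc["class_members"].items()
        }
        return cls(
            weights=weights,
            threshold=float(doc["threshold"]),
            class_members=class_members,
            config=TrainingConfig.from_dict(doc["config"]),
            training_log=tuple(doc["training_log"]),
            n_iterations=int(doc["n_iterations"]),
            converged=bool(doc["converged"]),
            model=None,
        )


def train(corpus: CDECorpus, config: TrainingConfig | None = None) -> MapperResults:
    """Functional entry point: ``CDEMapper(corpus, config).fit()``."""
    return CDEMapper(corpus, config).fit()
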