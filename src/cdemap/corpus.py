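"""Common data element (CDE) records, corpora, and corpus-level operations.

An ISO 11179 CDE is represented by the six text attributes that carry its
semantics — CDE long name, object class, property, value domain long name,
representation term, and question text — plus an optional set of DEC
(data element concept) NCI Thesaurus concept identifiers and an optional
BRIDG class label recorded by a human mapping team.

The canonical on-disk interchange is a flat CSV or JSON schema (see
:func:`read_corpus`); a best-effort reader for caDSR CDE Browser XML
exports is also provided.
"""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter, OrderedDict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from lxml import etree

from .exceptions import (
    ConfigurationError,
    DuplicateIdError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: The six semantic attributes, in the fixed order used everywhere:
#: s1 = long name, s2 = object class, s3 = property, s4 = value domain
#: long name, s5 = representation term, s6 = question text.
ATTRIBUTE_FIELDS: tuple[str, ...] = (
    "long_name",
    "object_class",
    "property_name",
    "value_domain_long_name",
    "representation_term",
    "question_text",
)

#: Canonical CSV/JSON column order. ``property`` is the external name of the
#: ``property_name`` field (``property`` shadows a builtin in Python).
CSV_COLUMNS: tuple[str, ...] = (
    "public_id",
    "long_name",
    "object_class",
    "property",
    "value_domain_long_name",
    "representation_term",
    "question_text",
    "dec_concepts",
    "mapped_class",
)


@dataclass(frozen=True)
class CDERecord:
    """One common data element: six attribute texts plus optional metadata.

    Parameters
    ----------
    public_id
        Identifier, unique within a corpus (caDSR public ID for real data).
    long_name, object_class, property_name, value_domain_long_name, \
    representation_term, question_text
        The six semantic attributes. Always present; may be empty strings.
    dec_concepts
        Optional set of NCI Thesaurus concept identifiers annotating the
        record's data element concept.
    mapped_class
        Optional BRIDG class name assigned by a human mapper; records
        without it are recommendation queries, not training data.
    """

    public_id: str
    long_name: str = ""
    object_class: str = ""
    property_name: str = ""
    value_domain_long_name: str = ""
    representation_term: str = ""
    question_text: str = ""
    dec_concepts: frozenset[str] | None = None
    mapped_class: str | None = None

    def __post_init__(self) -> None:
        if not self.public_id:
            raise ValidationError("CDERecord requires a non-empty public_id")
        for name in ATTRIBUTE_FIELDS:
            if getattr(self, name) is None:
                raise ValidationError(f"attribute {name!r} must be text, not None")
        if self.dec_concepts is not None and not isinstance(self.dec_concepts, frozenset):
            object.__setattr__(self, "dec_concepts", frozenset(self.dec_concepts))

    def attributes(self) -> tuple[str, ...]:
        """The six attribute texts in canonical order."""
        return tuple(getattr(self, name) for name in ATTRIBUTE_FIELDS)


class CDECorpus:
    """An ordered collection of :class:`CDERecord` with a class index.

    The class index (BRIDG class name -> records carrying that label) is
    derived from the records at construction; records without a
    ``mapped_class`` belong to no class group.
    """

    def __init__(self, records: Iterable[CDERecord]):
        self._records: tuple[CDERecord, ...] = tuple(records)
        counts = Counter(r.public_id for r in self._records)
        dupes = [pid for pid, c in counts.items() if c > 1]
        if dupes:
            raise DuplicateIdError(dupes)
        index: "OrderedDict[str, list[CDERecord]]" = OrderedDict()
        for r in self._records:
            if r.mapped_class:
                index.setdefault(r.mapped_class, []).append(r)
        self._class_index: dict[str, tuple[CDERecord, ...]] = {
            cls: tuple(members) for cls, members in index.items()
        }
        self._by_id = {r.public_id: r for r in self._records}

    @property
    def records(self) -> tuple[CDERecord, ...]:
        return self._records

    @property
    def class_index(self) -> Mapping[str, tuple[CDERecord, ...]]:
        return self._class_index

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[CDERecord]:
        return iter(self._records)

    def __getitem__(self, public_id: str) -> CDERecord:
        return self._by_id[public_id]

    def __contains__(self, public_id: str) -> bool:
        return public_id in self._by_id

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CDECorpus) and self._records == other._records

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<CDECorpus: {len(self)} records, "
            f"{len(self._class_index)} mapped classes>"
        )

    def class_sizes(self) -> dict[str, int]:
        return {cls: len(members) for cls, members in self._class_index.items()}


@dataclass(frozen=True)
class SplitConfig:
    """Train/verification split parameters.

    ``train_fraction`` is the share of records placed in the training
    partition (strictly between 0 and 1). With ``stratified`` (the
    default) each mapped class contributes approximately that share of
    its members, with at least one member on each side.
    """

    train_fraction: float
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError(
                f"train_fraction must lie strictly between 0 and 1, got {self.train_fraction}"
            )


# ---------------------------------------------------------------------------
# readers / writers


def _record_to_row(record: CDERecord) -> dict[str, str]:
    concepts = ";".join(sorted(record.dec_concepts)) if record.dec_concepts else ""
    return {
        "public_id": record.public_id,
        "long_name": record.long_name,
        "object_class": record.object_class,
        "property": record.property_name,
        "value_domain_long_name": record.value_domain_long_name,
        "representation_term": record.representation_term,
        "question_text": record.question_text,
        "dec_concepts": concepts,
        "mapped_class": record.mapped_class or "",
    }


def _row_to_record(row: Mapping[str, str]) -> CDERecord:
    concepts_raw = row.get("dec_concepts") or ""
    if isinstance(concepts_raw, (list, tuple, set, frozenset)):
        concepts = frozenset(str(c).strip() for c in concepts_raw if str(c).strip())
    else:
        concepts = frozenset(c.strip() for c in concepts_raw.split(";") if c.strip())
    mapped = (row.get("mapped_class") or "").strip() or None
    return CDERecord(
        public_id=str(row["public_id"]).strip(),
        long_name=str(row["long_name"]).strip(),
        object_class=str(row["object_class"]).strip(),
        property_name=str(row["property"]).strip(),
        value_domain_long_name=str(row["value_domain_long_name"]).strip(),
        representation_term=str(row["representation_term"]).strip(),
        question_text=str(row["question_text"]).strip(),
        dec_concepts=concepts or None,
        mapped_class=mapped,
    )


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"csv", "json", "xml"}:
        return suffix
    raise SchemaError(f"cannot infer corpus format from path {path}; pass format=")


def read_corpus(path: str | Path, format: str | None = None) -> CDECorpus:
    """Read a corpus from canonical CSV/JSON or a caDSR XML export.

    For CSV and JSON, the columns/keys must match the canonical schema
    (:data:`CSV_COLUMNS`); a missing column raises :class:`SchemaError`
    naming it, a repeated public_id raises :class:`DuplicateIdError`.
    Fields are whitespace-trimmed. The XML reader is best-effort: records
    it cannot interpret are skipped with a logged warning.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in CSV_COLUMNS if c not in header]
            if missing:
                raise SchemaError(f"CSV is missing required column(s): {', '.join(missing)}")
            records = [_row_to_record(row) for row in reader]
        return CDECorpus(records)
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        if not isinstance(data, list):
            raise SchemaError("canonical JSON corpus must be an array of objects")
        records = []
        for obj in data:
            missing = [c for c in CSV_COLUMNS if c not in obj]
            if missing:
                raise SchemaError(f"JSON object is missing required key(s): {', '.join(missing)}")
            records.append(_row_to_record(obj))
        return CDECorpus(records)
    if fmt == "xml":
        return _read_cadsr_xml(path)
    raise SchemaError(f"unknown corpus format {fmt!r}")


def write_corpus(corpus: CDECorpus, path: str | Path, format: str | None = None) -> None:
    """Write a corpus in the canonical CSV or JSON schema.

    ``read_corpus(write_corpus(c)) == c`` for every valid corpus, and
    re-serialising the read-back corpus reproduces the file byte for byte
    (dec_concepts are emitted in sorted order to that end).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS, lineterminator="\n")
            writer.writeheader()
            for record in corpus:
                writer.writerow(_record_to_row(record))
        return
    if fmt == "json":
        rows = []
        for record in corpus:
            row = _record_to_row(record)
            row["dec_concepts"] = sorted(record.dec_concepts) if record.dec_concepts else []
            rows.append(row)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rows, fh, indent=2, ensure_ascii=False)
            fh.write("\n")
        return
    raise SchemaError(f"write_corpus supports csv and json, not {fmt!r}")


def _norm_tag(tag: str) -> str:
    return "".join(ch for ch in tag.lower() if ch.isalnum())


_XML_FIELD_TAGS: dict[str, tuple[str, ...]] = {
    "public_id": ("publicid", "cdeid", "id"),
    "long_name": ("longname", "cdelongname", "preferredname"),
    "object_class": ("objectclass", "objectclassname"),
    "property_name": ("property", "propertyname"),
    "value_domain_long_name": ("valuedomainlongname", "valuedomain", "vdlongname"),
    "representation_term": ("representationterm", "repterm"),
    "question_text": ("questiontext", "preferredquestiontext", "question"),
    "mapped_class": ("mappedclass", "bridgclass", "classname"),
}

_XML_RECORD_TAGS = {"dataelement", "cde", "record", "cderecord"}


def _read_cadsr_xml(path: Path) -> CDECorpus:
    """Best-effort reader for caDSR CDE Browser XML downloads.

    Element names are matched case-insensitively and ignoring
    punctuation, so ``<LONGNAME>``, ``<longName>`` and ``<Long_Name>``
    all map to the long-name attribute.
    """
    tree = etree.parse(str(path))
    records: list[CDERecord] = []
    skipped = 0
    for element in tree.iter():
        if not isinstance(element.tag, str):
            continue
        if _norm_tag(etree.QName(element).localname) not in _XML_RECORD_TAGS:
            continue
        texts: dict[str, str] = {}
        for child in element.iter():
            if child is element or not isinstance(child.tag, str):
                continue
            tag = _norm_tag(etree.QName(child).localname)
            for fieldname, candidates in _XML_FIELD_TAGS.items():
                if tag in candidates and fieldname not in texts and child.text:
                    texts[fieldname] = child.text.strip()
        if "public_id" not in texts:
            skipped += 1
            logger.warning("skipping XML element without a recognisable public id")
            continue
        try:
            records.append(
                CDERecord(
                    public_id=texts["public_id"],
                    long_name=texts.get("long_name", ""),
                    object_class=texts.get("object_class", ""),
                    property_name=texts.get("property_name", ""),
                    value_domain_long_name=texts.get("value_domain_long_name", ""),
                    representation_term=texts.get("representation_term", ""),
                    question_text=texts.get("question_text", ""),
                    mapped_class=texts.get("mapped_class"),
                )
            )
        except ValidationError as exc:
            skipped += 1
            logger.warning("skipping unparseable XML record: %s", exc)
    if skipped:
        logger.warning("XML reader skipped %d unparseable record(s)", skipped)
    return CDECorpus(records)


# ---------------------------------------------------------------------------
# corpus-level operations


def filter_by_class_size(corpus: CDECorpus, min_size: int) -> CDECorpus:
    """Drop unmapped records and classes with fewer than ``min_size`` members.

    Classes with too few members do not provide enough training examples
    and interfere with weight learning; the conventional cutoff is 10.
    Relative record order is preserved, and the operation is idempotent.
    """
    if min_size < 1:
        raise ConfigurationError(f"min_size must be >= 1, got {min_size}")
    sizes = corpus.class_sizes()
    keep = {cls for cls, n in sizes.items() if n >= min_size}
    return CDECorpus(r for r in corpus if r.mapped_class in keep)


def split_train_verify(
    corpus: CDECorpus, config: SplitConfig
) -> tuple[CDECorpus, CDECorpus]:
    """Partition a corpus into disjoint training and verification corpora.

    Records are selected randomly (never alphabetically, which would bias
    the partition). With ``config.stratified`` each class — and the pool
    of unmapped records, if any — is split separately so that roughly
    ``train_fraction`` of its members train, with at least one member on
    each side. The same seed always reproduces the same partition.
    """
    rng = np.random.default_rng(config.seed)
    n = len(corpus)
    if n < 2:
        raise ConfigurationError("cannot split a corpus with fewer than 2 records")
    train_idx: set[int] = set()
    if config.stratified:
        groups: "OrderedDict[str | None, list[int]]" = OrderedDict()
        for i, r in enumerate(corpus):
            groups.setdefault(r.mapped_class, []).append(i)
        for cls, indices in groups.items():
            if cls is not None and len(indices) < 2:
                raise ConfigurationError(
                    f"stratified split impossible: class {cls!r} has a single member"
                )
            train_idx.update(_split_group(indices, config.train_fraction, rng))
    else:
        train_idx.update(_split_group(list(range(n)), config.train_fraction, rng))
    train = CDECorpus(r for i, r in enumerate(corpus) if i in train_idx)
    verify = CDECorpus(r for i, r in enumerate(corpus) if i not in train_idx)
    return train, verify


def _split_group(indices: Sequence[int], fraction: float, rng: np.random.Generator) -> list[int]:
    size = len(indices)
    if size == 1:
        return list(indices)
    n_train = int(round(fraction * size))
    n_train = min(max(n_train, 1), size - 1)
    order = rng.permutation(size)
    return [indices[i] for i in order[:n_train]]


def cap_class_members(corpus: CDECorpus, cap: int | None, seed: int = 0) -> CDECorpus:
    """Subsample each class to at most ``cap`` members (seeded).

    Implements the "training CDEs per class" knob of the evaluation
    grid: a cap on how many stored examples represent each class, which
    bounds both training cost and the evidence available at
    recommendation time. ``cap=None`` is a no-op.
    """
    if cap is None:
        return corpus
    if cap < 1:
        raise ConfigurationError(f"per-class cap must be >= 1, got {cap}")
    rng = np.random.default_rng(seed)
    keep_ids: set[str] = set()
    for cls in sorted(corpus.class_index):
        members = corpus.class_index[cls]
        if len(members) <= cap:
            keep_ids.update(m.public_id for m in members)
        else:
            chosen = rng.choice(len(members), size=cap, replace=False)
            keep_ids.update(members[i].public_id for i in chosen)
    return CDECorpus(
        r for r in corpus if r.mapped_class is None or r.public_id in keep_ids
    )
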