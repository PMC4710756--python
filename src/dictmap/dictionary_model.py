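"""Data-dictionary parsing and the element-metadata store.

A *data dictionary* documents every data element (field/column) of a
dataset: its name, the table it lives in, short and long free-text
descriptions, and a value specification (an enumeration of codes, a
numeric range, or free text).  This module parses delimited or JSON
dictionaries into :class:`ElementMetadata` records held in a
:class:`MetadataStore`, and infers per-element value constraints from the
raw value-specification string.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

log = logging.getLogger(__name__)

#: value_kind tags
CODED = "coded"
NUMERIC_RANGE = "numeric_range"
FREE_TEXT = "free_text"
UNKNOWN = "unknown"

#: An element is addressed by (source_id, casefolded table, casefolded name).
ElementKey = tuple[str, str, str]


class DictionaryError(Exception):
    """Raised for unparseable dictionaries or invalid store operations."""


@dataclass(frozen=True)
class ElementMetadata:
    """One data element's dictionary entry.

    ``table_name`` may be empty when the dictionary does not group
    elements into tables.  ``allowed_values``/``cardinality`` are set only
    for coded elements, ``range_min``/``range_max`` only for numeric-range
    elements; otherwise they are ``None``.
    """

    source_id: str
    element_name: str
    table_name: str = ""
    short_description: str = ""
    long_description: str = ""
    value_kind: str = UNKNOWN
    allowed_values: frozenset[str] | None = None
    cardinality: int | None = None
    range_min: float | None = None
    range_max: float | None = None

    def __post_init__(self) -> None:
        if not self.element_name:
            raise DictionaryError("element_name must be non-empty")
        if self.value_kind == CODED:
            if not self.allowed_values:
                raise DictionaryError(
                    f"{self.element_name}: coded element needs allowed_values"
                )
            object.__setattr__(self, "cardinality", len(self.allowed_values))
        if self.value_kind == NUMERIC_RANGE:
            if self.range_min is None or self.range_max is None:
                raise DictionaryError(
                    f"{self.element_name}: numeric_range element needs min and max"
                )
            if self.range_min > self.range_max:
                raise DictionaryError(
                    f"{self.element_name}: range_min > range_max"
                )

    @property
    def key(self) -> ElementKey:
        return (self.source_id, self.table_name.casefold(), self.element_name.casefold())

    @property
    def description(self) -> str:
        """Short and long description concatenated — the text used downstream."""
        return " ".join(p for p in (self.short_description, self.long_description) if p).strip()


@dataclass(frozen=True)
class ValueConstraint:
    kind: str
    allowed_values: frozenset[str] | None = None
    cardinality: int | None = None
    range_min: float | None = None
    range_max: float | None = None


_NUM = r"[+-]?\d+(?:\.\d+)?"
_RANGE_RE = re.compile(rf"^\s*({_NUM})\s*(?:-|–|—|\bto\b)\s*({_NUM})\s*$", re.IGNORECASE)
_FREE_TEXT_RE = re.compile(
    r"^\s*(free\s*text|text|string|char(acter)?s?|varchar\w*|date|narrative)\s*$",
    re.IGNORECASE,
)


def infer_constraints(raw_value_spec: str | None) -> ValueConstraint:
    """Classify a raw value-specification string into a typed constraint.

    Grammar (deterministic, total — never raises):

    * ``"90-140"``, ``"90 – 140"``, ``"0 to 10"`` → numeric range;
    * comma/semicolon-separated tokens, optionally ``code=label``
      (labels are discarded here; callers may fold them into the
      description) → coded, cardinality = number of distinct codes;
    * ``"text"``, ``"string"``, ``"free text"`` … → free text;
    * anything else (including empty) → unknown, with a warning for
      non-empty unparseable specs.
    """
    if raw_value_spec is None:
        return ValueConstraint(UNKNOWN)
    spec = raw_value_spec.strip()
    if not spec:
        return ValueConstraint(UNKNOWN)
    m = _RANGE_RE.match(spec)
    if m:
        lo, hi = float(m.group(1)), float(m.group(2))
        if lo > hi:
            log.warning("value spec %r has min > max; treating as unknown", spec)
            return ValueConstraint(UNKNOWN)
        return ValueConstraint(NUMERIC_RANGE, range_min=lo, range_max=hi)
    if _FREE_TEXT_RE.match(spec):
        return ValueConstraint(FREE_TEXT)
    if "," in spec or ";" in spec or "=" in spec:
        tokens = [t.strip() for t in re.split(r"[,;]", spec)]
        codes = frozenset(t.split("=", 1)[0].strip() for t in tokens if t)
        codes = frozenset(c for c in codes if c)
        if codes:
            return ValueConstraint(CODED, allowed_values=codes, cardinality=len(codes))
    log.warning("unparseable value spec %r; falling back to unknown", spec)
    return ValueConstraint(UNKNOWN)


@dataclass
class Dialect:
    """Maps dictionary file columns onto :class:`ElementMetadata` fields.

    ``description_columns`` lists the columns concatenated (in order) into
    the short description first and the long description second; with one
    entry the long description is empty.
    """

    element_column: str = "element"
    table_column: str | None = "table"
    description_columns: tuple[str, ...] = ("short_description", "long_description")
    values_column: str | None = "values"
    delimiter: str = ","

    @classmethod
    def from_mapping(cls, m: Mapping) -> "Dialect":
        d = cls()
        if "element_column" not in m:
            raise DictionaryError("dialect is missing the element-name column")
        return replace(
            d,
            element_column=m["element_column"],
            table_column=m.get("table_column", d.table_column),
            description_columns=tuple(m.get("description_columns", d.description_columns)),
            values_column=m.get("values_column", d.values_column),
            delimiter=m.get("delimiter", d.delimiter),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "Dialect":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            return cls.from_mapping(yaml.safe_load(text))
        return cls.from_mapping(json.loads(text))


#: The canonical dialect used by :meth:`MetadataStore.to_csv`.
CANONICAL_DIALECT = Dialect()


class MetadataStore:
    """Collection of :class:`ElementMetadata` keyed by (source, table, name).

    Lookup of an unknown key is an error, never a silent empty result.
    """

    def __init__(self, elements: Iterable[ElementMetadata] = ()) -> None:
        self._elements: dict[ElementKey, ElementMetadata] = {}
        for e in elements:
            self.add(e)

    def add(self, element: ElementMetadata) -> None:
        if element.key in self._elements:
            raise DictionaryError(
                f"duplicate element key {element.key}: element names must be "
                "unique within (source, table)"
            )
        self._elements[element.key] = element

    def get(self, key: ElementKey) -> ElementMetadata:
        try:
            return self._elements[key]
        except KeyError:
            raise KeyError(f"no element with key {key} in store") from None

    def __contains__(self, key: ElementKey) -> bool:
        return key in self._elements

    def __len__(self) -> int:
        return len(self._elements)

    def __iter__(self) -> Iterator[ElementMetadata]:
        return iter(self._elements.values())

    def elements_of(self, source_id: str) -> list[ElementMetadata]:
        return [e for e in self._elements.values() if e.source_id == source_id]

    def sources(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self._elements.values():
            seen.setdefault(e.source_id, None)
        return list(seen)

    def tables_of(self, source_id: str) -> dict[str, list[ElementMetadata]]:
        """Elements of a source grouped by (casefolded) table name."""
        out: dict[str, list[ElementMetadata]] = {}
        for e in self.elements_of(source_id):
            out.setdefault(e.table_name.casefold(), []).append(e)
        return out

    def merge(self, other: "MetadataStore") -> "MetadataStore":
        merged = MetadataStore(self)
        for e in other:
            merged.add(e)
        return merged

    # ---- I/O ----------------------------------------------------------

    def to_csv(self, path: str | Path, source_id: str | None = None) -> None:
        """Dump (a source of) the store in the canonical dialect."""
        elements = self.elements_of(source_id) if source_id else list(self)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["table", "element", "short_description", "long_description", "values"]
            )
            for e in elements:
                w.writerow(
                    [
                        e.table_name,
                        e.element_name,
                        e.short_description,
                        e.long_description,
                        _format_value_spec(e),
                    ]
                )


def _format_value_spec(e: ElementMetadata) -> str:
    if e.value_kind == CODED:
        return ",".join(sorted(e.allowed_values or ()))
    if e.value_kind == NUMERIC_RANGE:
        return f"{_fmt_num(e.range_min)}-{_fmt_num(e.range_max)}"
    if e.value_kind == FREE_TEXT:
        return "text"
    return ""


def _fmt_num(x: float | None) -> str:
    assert x is not None
    return str(int(x)) if float(x).is_integer() else repr(x)


def _element_from_record(
    rec: Mapping[str, object], dialect: Dialect, source_id: str
) -> ElementMetadata:
    def col(name: str | None) -> str:
        if name is None:
            return ""
        v = rec.get(name, "")
        return "" if v is None else str(v).strip()

    name = col(dialect.element_column)
    if not name:
        raise DictionaryError("missing element name")
    descs = [col(c) for c in dialect.description_columns]
    short = descs[0] if descs else ""
    long_ = " ".join(d for d in descs[1:] if d)
    if not (short or long_):
        log.warning("element %r has empty descriptions", name)
    constraint = infer_constraints(col(dialect.values_column))
    return ElementMetadata(
        source_id=source_id,
        element_name=name,
        table_name=col(dialect.table_column),
        short_description=short,
        long_description=long_,
        value_kind=constraint.kind,
        allowed_values=constraint.allowed_values,
        cardinality=constraint.cardinality,
        range_min=constraint.range_min,
        range_max=constraint.range_max,
    )


def parse_dictionary(
    path: str | Path,
    source_id: str,
    dialect: Dialect | None = None,
) -> MetadataStore:
    """Parse one data dictionary into a store fragment.

    ``.json`` files are read as a record array (list of objects whose keys
    are the dialect's column names); anything else as delimited text with
    a header row.  Malformed rows are reported with their row numbers.
    """
    path = Path(path)
    dialect = dialect or CANONICAL_DIALECT
    if not path.exists():
        raise DictionaryError(f"dictionary file not found: {path}")

    if path.suffix == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise DictionaryError(f"{path}: JSON dictionary must be a record array")
        numbered = list(enumerate(records, start=1))
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter=dialect.delimiter)
            if reader.fieldnames is None:
                raise DictionaryError(f"{path}: empty dictionary file")
            if dialect.element_column not in reader.fieldnames:
                raise DictionaryError(
                    f"{path}: dialect element column {dialect.element_column!r} "
                    f"not among columns {reader.fieldnames}"
                )
            numbered = list(enumerate(reader, start=2))  # header is row 1

    if not numbered:
        raise DictionaryError(f"{path}: no data rows")

    store = MetadataStore()
    bad: list[str] = []
    for rownum, rec in numbered:
        try:
            store.add(_element_from_record(rec, dialect, source_id))
        except DictionaryError as exc:
            bad.append(f"row {rownum}: {exc}")
    if bad:
        raise DictionaryError(f"{path}: malformed rows — " + "; ".join(bad))
    return store
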