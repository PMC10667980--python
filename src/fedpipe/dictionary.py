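"""Harmonized data dictionary: variable schema, typed patient records, validation.

A :class:`DataDictionary` is the agreed schema that every contributing
source maps its export onto before any record enters the pipeline.  It is
shipped (and user-extended) as a human-editable YAML document, one document
per dictionary version.  Missing values are written with the explicit null
token ``NA`` — deliberately distinct from the empty string, so that a blank
cell (a formatting accident) and a declared missing value are different
things.
"""

from __future__ import annotations

import datetime as dt
import functools
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

__all__ = [
    "NULL_TOKEN",
    "FORMATS",
    "DictionaryError",
    "VariableSpec",
    "DataDictionary",
    "PatientRecord",
    "Violation",
    "load_dictionary",
    "default_dictionary",
    "write_dictionary",
    "validate_record",
    "coerce_record",
    "parse_value",
]

NULL_TOKEN = "NA"
FORMATS = ("date", "single_choice", "integer", "number", "text")


class DictionaryError(ValueError):
    """A dictionary document violates its structural invariants."""


@dataclass(frozen=True)
class VariableSpec:
    """Schema of one harmonized variable.

    Parameters
    ----------
    name : str
        Unique variable identifier (snake_case by convention).
    format : str
        One of ``date`` (ISO yyyy-mm-dd), ``single_choice``, ``integer``,
        ``number``, ``text``.
    choices : tuple of str, optional
        Allowed labels; required exactly when ``format == "single_choice"``.
    depends_on : tuple of str
        Names of other variables this variable's quality rules reference.
    """

    name: str
    format: str
    choices: tuple[str, ...] | None = None
    depends_on: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise DictionaryError(
                f"variable {self.name!r}: unknown format {self.format!r} "
                f"(expected one of {FORMATS})"
            )
        if (self.format == "single_choice") != bool(self.choices):
            raise DictionaryError(
                f"variable {self.name!r}: choices must be non-empty iff "
                f"format is single_choice"
            )


@dataclass(frozen=True)
class DataDictionary:
    """Ordered collection of :class:`VariableSpec`.

    The variable order is canonical: it defines the column order used by
    every downstream artifact (record CSVs, QC reports, bucket tables).
    """

    variables: tuple[VariableSpec, ...]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for spec in self.variables:
            if spec.name in seen:
                raise DictionaryError(f"duplicate variable name {spec.name!r}")
            seen.add(spec.name)
        for spec in self.variables:
            for dep in spec.depends_on:
                if dep not in seen:
                    raise DictionaryError(
                        f"variable {spec.name!r}: depends_on {dep!r} does not "
                        f"resolve to a dictionary variable"
                    )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.variables)

    @property
    def date_variables(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.variables if s.format == "date")

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def __getitem__(self, name: str) -> VariableSpec:
        for spec in self.variables:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def __iter__(self) -> Iterator[VariableSpec]:
        return iter(self.variables)


@dataclass(frozen=True)
class PatientRecord:
    """One patient row: ``source_id`` plus a variable-name → value mapping.

    Values are either typed (``datetime.date``, ``int``, ``float``, ``str``)
    or ``None`` for missing.  Raw (string) values are permitted transiently;
    :func:`coerce_record` produces the fully typed form.
    """

    source_id: str
    values: Mapping[str, Any]
    record_id: str | None = None

    def get(self, name: str, default: Any = None) -> Any:
        return self.values.get(name, default)

    def with_values(self, values: Mapping[str, Any]) -> "PatientRecord":
        return replace(self, values=dict(values))


@dataclass(frozen=True)
class Violation:
    """One dictionary-conformance problem found in a record (data, not an error)."""

    variable: str
    kind: str  # unknown_variable | parse | choice | type
    message: str


def parse_value(spec: VariableSpec, raw: Any) -> Any:
    """Coerce ``raw`` to the typed value for ``spec``.

    Accepts already-typed values (validated) or strings (parsed).  The null
    token and ``None`` give ``None``.  Raises ``ValueError`` on anything
    unparseable or out of the choice set.
    """
    if raw is None:
        return None
    if isinstance(raw, str):
        raw = raw.strip()
        if raw == NULL_TOKEN:
            return None
        if raw == "":
            raise ValueError("empty string is not a value (use the NA token for missing)")
    fmt = spec.format
    if fmt == "date":
        if isinstance(raw, dt.datetime):
            raise ValueError(f"expected a calendar date, got datetime {raw!r}")
        if isinstance(raw, dt.date):
            return raw
        try:
            return dt.date.fromisoformat(str(raw))
        except ValueError as exc:
            raise ValueError(f"not a valid yyyy-mm-dd date: {raw!r}") from exc
    if fmt == "single_choice":
        label = str(raw)
        assert spec.choices is not None
        if label not in spec.choices:
            raise ValueError(
                f"label {label!r} not in choices {list(spec.choices)}"
            )
        return label
    if fmt == "integer":
        if isinstance(raw, bool):
            raise ValueError(f"boolean is not an integer value: {raw!r}")
        if isinstance(raw, int):
            return raw
        if isinstance(raw, float) and raw.is_integer():
            return int(raw)
        try:
            return int(str(raw))
        except ValueError as exc:
            raise ValueError(f"not an integer: {raw!r}") from exc
    if fmt == "number":
        if isinstance(raw, bool):
            raise ValueError(f"boolean is not a number: {raw!r}")
        if isinstance(raw, (int, float)):
            return float(raw)
        try:
            return float(str(raw))
        except ValueError as exc:
            raise ValueError(f"not a number: {raw!r}") from exc
    # text
    return str(raw)


def validate_record(record: PatientRecord, dictionary: DataDictionary) -> list[Violation]:
    """Check ``record`` against ``dictionary``; return one violation per problem.

    Deterministic and independent of the key order in the record's value
    mapping (violations are reported in dictionary order, unknown variables
    last in sorted order).  An empty list means the record is
    dictionary-conformant.  Table-1-style logic is *not* applied here; that
    is the qc module's job.
    """
    violations: list[Violation] = []
    values = record.values
    for spec in dictionary.variables:
        if spec.name not in values:
            continue
        raw = values[spec.name]
        try:
            parse_value(spec, raw)
        except ValueError as exc:
            kind = "choice" if "not in choices" in str(exc) else "parse"
            violations.append(Violation(spec.name, kind, str(exc)))
    for name in sorted(values):
        if name not in dictionary:
            violations.append(
                Violation(name, "unknown_variable", f"variable {name!r} is not in the dictionary")
            )
    return violations


def coerce_record(
    record: PatientRecord, dictionary: DataDictionary
) -> tuple[PatientRecord, list[Violation]]:
    """Return the typed form of ``record`` plus any violations.

    Unparseable or out-of-choice values become missing (``None``); unknown
    variables are dropped from the typed record (and reported).
    """
    violations = validate_record(record, dictionary)
    bad = {v.variable for v in violations}
    typed: dict[str, Any] = {}
    for spec in dictionary.variables:
        if spec.name not in record.values:
            typed[spec.name] = None
        elif spec.name in bad:
            typed[spec.name] = None
        else:
            typed[spec.name] = parse_value(spec, record.values[spec.name])
    return record.with_values(typed), violations


def _spec_from_entry(entry: Mapping[str, Any]) -> VariableSpec:
    if not isinstance(entry, Mapping) or "name" not in entry:
        raise DictionaryError(f"malformed variable entry: {entry!r}")
    unknown = set(entry) - {"name", "format", "choices", "depends_on"}
    if unknown:
        raise DictionaryError(
            f"variable {entry.get('name')!r}: unknown keys {sorted(unknown)}"
        )
    choices = entry.get("choices")
    return VariableSpec(
        name=str(entry["name"]),
        format=str(entry.get("format", "text")),
        choices=tuple(str(c) for c in choices) if choices else None,
        depends_on=tuple(str(d) for d in entry.get("depends_on") or ()),
    )


def load_dictionary(source: str | Path | Mapping[str, Any]) -> DataDictionary:
    """Load a :class:`DataDictionary` from a YAML document.

    ``source`` may be a path, a YAML string, or an already-parsed mapping.
    Structural problems (duplicate names, unresolved depends_on, unknown
    format) raise :class:`DictionaryError` naming the offending entry.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists()):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "variables" not in doc:
        raise DictionaryError("dictionary document must be a mapping with a 'variables' list")
    specs = tuple(_spec_from_entry(e) for e in doc["variables"])
    return DataDictionary(variables=specs, version=str(doc.get("version", "unversioned")))


def write_dictionary(dictionary: DataDictionary, path: str | Path | None = None) -> str:
    """Serialize ``dictionary`` back to its YAML dialect (round-trip safe)."""
    doc: dict[str, Any] = {"version": dictionary.version, "variables": []}
    for spec in dictionary.variables:
        entry: dict[str, Any] = {"name": spec.name, "format": spec.format}
        if spec.choices:
            entry["choices"] = list(spec.choices)
        if spec.depends_on:
            entry["depends_on"] = list(spec.depends_on)
        doc["variables"].append(entry)
    text = yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


@functools.lru_cache(maxsize=1)
def default_dictionary() -> DataDictionary:
    """The shipped default dictionary (the printed core-data-set subset)."""
    text = resources.files("fedpipe.data").joinpath("core_dataset.yaml").read_text("utf-8")
    return load_dictionary(yaml.safe_load(text))
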