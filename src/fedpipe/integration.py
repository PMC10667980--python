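"""Contingency-bucket integration: binning, bucketize, aggregate, expand.

The federated sharing contract is built on one mathematical object: a
multivariate contingency table of patient counts.  Each analysis variable
``k`` gets a partition of its domain into bins (categories); a cleaned
record maps to a tuple of bin labels; a set of records maps to the table
``S`` of distinct tuples with their counts.  Tables from independent
sources aggregate by tuple-wise count addition, and the aggregate expands
back into a pseudo patient-level categorical table ``X`` (each tuple
repeated count-many times) for downstream modelling.

Only bin labels survive this representation — no exact age, date or score
is representable in a bucket table or an expanded table, which is the
privacy point of the federated stream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from .dictionary import PatientRecord

__all__ = [
    "EMPTY_LABEL",
    "IntegrationError",
    "BinSpec",
    "BinningScheme",
    "BucketTable",
    "ExpandedTable",
    "default_scheme",
    "categorize",
    "categorize_with_notes",
    "bucketize",
    "aggregate",
    "expand",
    "suppress_small_cells",
    "SEVERITY_OUTCOMES",
]

EMPTY_LABEL = "EMPTY"

SEVERITY_OUTCOMES = (
    "covid19_admission_hospital",
    "covid19_icu_admission",
    "covid19_ventilation",
    "covid19_death",
)


class IntegrationError(ValueError):
    """Scheme mismatch or malformed bucket data."""


@dataclass(frozen=True)
class BinSpec:
    """One category of one variable: a half-open/closed numeric interval or
    a set of choice labels.

    Exactly one of (``lo``/``hi``) or ``choices`` is used.  ``lo=None`` /
    ``hi=None`` mean unbounded on that side.
    """

    variable: str
    label: str
    lo: float | None = None
    hi: float | None = None
    lo_incl: bool = True
    hi_incl: bool = False
    choices: frozenset[str] | None = None

    def contains(self, value: Any) -> bool:
        if value is None:
            return False
        if self.choices is not None:
            return value in self.choices
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            return False
        if self.lo is not None:
            if value < self.lo or (value == self.lo and not self.lo_incl):
                return False
        if self.hi is not None:
            if value > self.hi or (value == self.hi and not self.hi_incl):
                return False
        return True


@dataclass(frozen=True)
class BinningScheme:
    """Per-variable ordered bin lists; the bin order is canonical.

    Every variable implicitly carries a terminal EMPTY bin that collects
    missing and out-of-domain values; it is not stored.
    """

    bins: tuple[tuple[str, tuple[BinSpec, ...]], ...]

    def __post_init__(self) -> None:
        for var, specs in self.bins:
            labels = [b.label for b in specs]
            if len(labels) != len(set(labels)):
                raise IntegrationError(f"variable {var!r}: duplicate bin labels")
            if EMPTY_LABEL in labels:
                raise IntegrationError(
                    f"variable {var!r}: {EMPTY_LABEL!r} is reserved for the implicit bin"
                )
            for b in specs:
                if b.variable != var:
                    raise IntegrationError(
                        f"bin {b.label!r} declares variable {b.variable!r} under {var!r}"
                    )

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(var for var, _ in self.bins)

    def labels(self, variable: str) -> tuple[str, ...]:
        for var, specs in self.bins:
            if var == variable:
                return tuple(b.label for b in specs)
        raise KeyError(variable)

    def bin_specs(self, variable: str) -> tuple[BinSpec, ...]:
        for var, specs in self.bins:
            if var == variable:
                return specs
        raise KeyError(variable)

    def sort_key(self, tup: Sequence[str]) -> tuple[int, ...]:
        """Canonical order of a category tuple (EMPTY sorts last per variable)."""
        key = []
        for (var, specs), label in zip(self.bins, tup):
            labels = [b.label for b in specs]
            key.append(labels.index(label) if label in labels else len(labels))
        return tuple(key)

    def check_tuple(self, tup: Sequence[str]) -> None:
        if len(tup) != len(self.bins):
            raise IntegrationError(
                f"category tuple has {len(tup)} labels, scheme has {len(self.bins)} variables"
            )
        for (var, specs), label in zip(self.bins, tup):
            if label != EMPTY_LABEL and label not in (b.label for b in specs):
                raise IntegrationError(f"label {label!r} is not a bin of {var!r}")


def _choice_bins(variable: str, labels: Sequence[str]) -> tuple[str, tuple[BinSpec, ...]]:
    return variable, tuple(
        BinSpec(variable=variable, label=lab, choices=frozenset({lab})) for lab in labels
    )


def default_scheme() -> BinningScheme:
    """The analysis binning: age 18-50/50-70/>70 (lower-inclusive, upper-open),
    sex, MS phenotype, EDSS dichotomized at 6, the 12 DMT categories, and the
    four severity outcomes as yes/no indicators."""
    dmt_labels = (
        "untreated",
        "alemtuzumab",
        "cladribine",
        "dimethyl_fumarate",
        "fingolimod",
        "glatiramer_acetate",
        "interferon",
        "natalizumab",
        "ocrelizumab",
        "rituximab",
        "teriflunomide",
        "other",
    )
    age = (
        "age_years",
        (
            BinSpec("age_years", "18-50", lo=18, hi=50),
            BinSpec("age_years", "50-70", lo=50, hi=70),
            BinSpec("age_years", ">70", lo=70, hi=None),
        ),
    )
    edss = (
        "edss_value",
        (
            BinSpec("edss_value", "0-6", lo=0, hi=6),
            BinSpec("edss_value", "6-10", lo=6, hi=10, hi_incl=True),
        ),
    )
    bins = (
        age,
        _choice_bins("sex", ("male", "female")),
        _choice_bins("ms_type", ("relapsing_remitting", "progressive")),
        edss,
        _choice_bins("type_dmt", dmt_labels),
    ) + tuple(_choice_bins(v, ("yes", "no")) for v in SEVERITY_OUTCOMES)
    return BinningScheme(bins=bins)


def categorize_with_notes(
    record: PatientRecord | Mapping[str, Any], scheme: BinningScheme
) -> tuple[tuple[str, ...], list[str]]:
    """Map a cleaned record to its category tuple, reporting out-of-domain values.

    Missing values take the EMPTY label silently; a non-missing value outside
    every bin (e.g. an age below the first analysis bin) also takes EMPTY but
    is noted."""
    values = record.values if isinstance(record, PatientRecord) else record
    labels: list[str] = []
    notes: list[str] = []
    for var, specs in scheme.bins:
        value = values.get(var)
        if value is None:
            labels.append(EMPTY_LABEL)
            continue
        for b in specs:
            if b.contains(value):
                labels.append(b.label)
                break
        else:
            labels.append(EMPTY_LABEL)
            notes.append(f"{var}={value!r} is outside every bin (out of domain)")
    return tuple(labels), notes


def categorize(
    record: PatientRecord | Mapping[str, Any], scheme: BinningScheme
) -> tuple[str, ...]:
    """Category tuple of one record (see :func:`categorize_with_notes`)."""
    return categorize_with_notes(record, scheme)[0]


@dataclass(eq=False)
class BucketTable:
    """Multivariate contingency table: category tuple -> positive count.

    ``by_source`` keeps the per-source breakdown as provenance so that
    expansion can emit a source label per row (the grouping factor of the
    downstream random-intercept model).  Equality and serialization use the
    summed view only: two tables are equal when scheme and tuple-wise counts
    match, whatever their provenance.
    """

    scheme: BinningScheme
    counts: dict[tuple[str, ...], int]
    source_id: str = "pooled"
    by_source: dict[str, dict[tuple[str, ...], int]] | None = None

    def __post_init__(self) -> None:
        for tup, c in self.counts.items():
            self.scheme.check_tuple(tup)
            if not isinstance(c, int) or isinstance(c, bool) or c <= 0:
                raise IntegrationError(
                    f"count for {tup} must be a positive integer, got {c!r}"
                )
        if self.by_source is None:
            self.by_source = {self.source_id: dict(self.counts)}

    @property
    def n(self) -> int:
        """Number of patients represented (sum of counts)."""
        return sum(self.counts.values())

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(sorted(self.by_source))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BucketTable):
            return NotImplemented
        return self.scheme == other.scheme and self.counts == other.counts

    def sorted_items(self) -> list[tuple[tuple[str, ...], int]]:
        return sorted(self.counts.items(), key=lambda kv: self.scheme.sort_key(kv[0]))

    def to_frame(self) -> pd.DataFrame:
        rows = [list(tup) + [c] for tup, c in self.sorted_items()]
        return pd.DataFrame(rows, columns=list(self.scheme.variables) + ["count"])


@dataclass(frozen=True)
class ExpandedTable:
    """Pseudo patient-level categorical table X: one category tuple per row,
    plus the source label each row came from."""

    scheme: BinningScheme
    rows: tuple[tuple[str, ...], ...]
    sources: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.sources):
            raise IntegrationError("rows and source labels differ in length")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def k(self) -> int:
        return len(self.scheme.variables)

    def to_dataframe(self, include_source: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(list(self.rows), columns=list(self.scheme.variables))
        if include_source:
            df.insert(0, "source", list(self.sources))
        return df

    def to_bucket_table(self) -> BucketTable:
        """Re-bucketize: tally the rows back into a BucketTable (inverse of
        :func:`expand`)."""
        by_source: dict[str, dict[tuple[str, ...], int]] = {}
        for tup, src in zip(self.rows, self.sources):
            by_source.setdefault(src, {})
            by_source[src][tup] = by_source[src].get(tup, 0) + 1
        total: Counter = Counter()
        for cnts in by_source.values():
            total.update(cnts)
        return BucketTable(
            scheme=self.scheme,
            counts=dict(total),
            source_id="+".join(sorted(by_source)) if by_source else "pooled",
            by_source=by_source or None,
        )


def bucketize(
    records: Iterable[PatientRecord | Mapping[str, Any]],
    scheme: BinningScheme,
    source_id: str = "pooled",
) -> BucketTable:
    """Tally records into the contingency table S for ``scheme``.

    Rows are exactly the distinct observed category tuples; the sum of
    counts equals the number of records (zero-count combinations are never
    materialized)."""
    counts: Counter = Counter()
    for rec in records:
        counts[categorize(rec, scheme)] += 1
    return BucketTable(scheme=scheme, counts=dict(counts), source_id=source_id)


def _first_scheme_difference(a: BinningScheme, b: BinningScheme) -> str:
    if a.variables != b.variables:
        for va, vb in zip(a.variables, b.variables):
            if va != vb:
                return f"variable {va!r} vs {vb!r}"
        return f"variable count {len(a.variables)} vs {len(b.variables)}"
    for var in a.variables:
        for ba, bb in zip(a.bin_specs(var), b.bin_specs(var)):
            if ba != bb:
                return f"bin {var!r}:{ba.label!r}"
        if len(a.bin_specs(var)) != len(b.bin_specs(var)):
            return f"bin count of {var!r}"
    return "unknown difference"


def aggregate(tables: Sequence[BucketTable]) -> BucketTable:
    """Tuple-wise sum of counts across sources sharing one scheme (by value).

    Provenance is the merged per-source breakdown; the summed view is what
    equality, serialization and conservation checks see."""
    if not tables:
        raise IntegrationError("nothing to aggregate")
    scheme = tables[0].scheme
    for t in tables[1:]:
        if t.scheme != scheme:
            raise IntegrationError(
                "scheme mismatch during aggregation: first difference at "
                + _first_scheme_difference(scheme, t.scheme)
            )
    total: Counter = Counter()
    by_source: dict[str, dict[tuple[str, ...], int]] = {}
    for t in tables:
        total.update(t.counts)
        for src, cnts in (t.by_source or {}).items():
            dest = by_source.setdefault(src, {})
            for tup, c in cnts.items():
                dest[tup] = dest.get(tup, 0) + c
    return BucketTable(
        scheme=scheme,
        counts=dict(total),
        source_id="+".join(sorted(by_source)),
        by_source=by_source,
    )


def expand(table: BucketTable) -> ExpandedTable:
    """Repeat each tuple count-many times: the analysis table X.

    Row order is deterministic — sources in sorted order, tuples in
    canonical scheme order within each source — so identical tables expand
    bit-identically."""
    rows: list[tuple[str, ...]] = []
    sources: list[str] = []
    for src in sorted(table.by_source or {}):
        items = sorted(
            table.by_source[src].items(), key=lambda kv: table.scheme.sort_key(kv[0])
        )
        for tup, c in items:
            rows.extend([tup] * c)
            sources.extend([src] * c)
    return ExpandedTable(scheme=table.scheme, rows=tuple(rows), sources=tuple(sources))


def suppress_small_cells(
    table: BucketTable, threshold: int
) -> tuple[BucketTable, int]:
    """Drop rows with count below ``threshold``; report the suppressed total.

    Threshold 0 (or 1) is the identity.  Suppression is applied to the
    summed view; provenance is filtered to the surviving tuples."""
    if threshold <= 1:
        return table, 0
    kept = {tup: c for tup, c in table.counts.items() if c >= threshold}
    suppressed = table.n - sum(kept.values())
    by_source = {
        src: {tup: c for tup, c in cnts.items() if tup in kept}
        for src, cnts in (table.by_source or {}).items()
    }
    by_source = {src: cnts for src, cnts in by_source.items() if cnts}
    return (
        BucketTable(
            scheme=table.scheme,
            counts=kept,
            source_id=table.source_id,
            by_source=by_source or {table.source_id: dict(kept)},
        ),
        suppressed,
    )
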