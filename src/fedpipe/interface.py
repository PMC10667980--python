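"""Stream I/O, acquisition summary, and pipeline orchestration.

Three data-sharing streams feed the pipeline:

* ``direct_entry`` — individual records submitted through a validated form,
  arriving as patient-level CSV;
* ``core`` — a registry's patient-level CSV mapped to the dictionary;
* ``federated`` — a registry that runs validation, QC and bucketization on
  its own side and shares only the bucket CSV (raw records never leave).

All artifacts are plain CSV.  Percentages in summaries are computed from
the stored integer counts at presentation time, rounded half-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

from .analysis import ModelSpec, SeverityModelResults, fit_severity_model, report
from .dictionary import (
    NULL_TOKEN,
    DataDictionary,
    PatientRecord,
    Violation,
    coerce_record,
    default_dictionary,
)
from .integration import (
    BinningScheme,
    BucketTable,
    EMPTY_LABEL,
    ExpandedTable,
    aggregate,
    bucketize,
    default_scheme,
    expand,
    suppress_small_cells,
)
from .qc import QCResult, RuleEngine, qc_summary

__all__ = [
    "STREAMS",
    "ManifestEntry",
    "StreamManifest",
    "AcquisitionSummary",
    "PipelineConfig",
    "PipelineResult",
    "PipelineError",
    "FormatError",
    "pct",
    "read_records_csv",
    "write_records_csv",
    "read_bucket_csv",
    "write_bucket_csv",
    "write_qc_report_csv",
    "acquisition_summary",
    "write_stream_artifacts",
    "local_node",
    "run_pipeline",
]

logger = logging.getLogger("fedpipe")

STREAMS = ("direct_entry", "core", "federated")


class FormatError(ValueError):
    """A stream file violates its format contract."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage and source for diagnosis."""

    def __init__(self, stage: str, source_id: str | None, cause: Exception) -> None:
        where = f"stage={stage}" + (f" source={source_id}" if source_id else "")
        super().__init__(f"{where}: {cause}")
        self.stage = stage
        self.source_id = source_id
        self.cause = cause


def pct(numerator: int, denominator: int, decimals: int = 2) -> float:
    """Percentage with half-up rounding, computed from exact integer counts."""
    if denominator == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    share = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(q, ROUND_HALF_UP)
    return float(share)


# -- record CSV --------------------------------------------------------------


def read_records_csv(
    path: str | Path,
    dictionary: DataDictionary | None = None,
    source_id: str | None = None,
) -> list[PatientRecord]:
    """Read a patient-level CSV into typed records.

    The header must name dictionary variables (any order); an optional
    ``record_id`` column is honoured.  Unknown columns are ignored with a
    logged violation; unparseable values are set missing with a logged
    warning.  The ``NA`` token means missing.
    """
    dictionary = dictionary or default_dictionary()
    path = Path(path)
    source_id = source_id or path.stem
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read record CSV {path}: {exc}") from exc
    if not any(c in dictionary for c in df.columns):
        raise FormatError(f"{path}: header shares no variable with the dictionary")
    records: list[PatientRecord] = []
    for i, row in enumerate(df.to_dict(orient="records")):
        rec_id = row.pop("record_id", None) or f"{source_id}-{i:05d}"
        raw = PatientRecord(source_id=source_id, values=row, record_id=rec_id)
        typed, violations = coerce_record(raw, dictionary)
        for v in violations:
            logger.warning(
                "record %s: %s (%s) -> value set missing", rec_id, v.message, v.kind
            )
        records.append(typed)
    return records


def write_records_csv(
    records: Sequence[PatientRecord],
    path: str | Path,
    dictionary: DataDictionary | None = None,
) -> None:
    """Write typed records in canonical dictionary column order (lossless)."""
    dictionary = dictionary or default_dictionary()
    rows = []
    for rec in records:
        row: dict[str, str] = {"record_id": rec.record_id or ""}
        for name in dictionary.names:
            value = rec.values.get(name)
            row[name] = NULL_TOKEN if value is None else str(value)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["record_id"] + list(dictionary.names))
    df.to_csv(path, index=False)


# -- bucket CSV --------------------------------------------------------------


def read_bucket_csv(
    path: str | Path, scheme: BinningScheme | None = None, source_id: str | None = None
) -> BucketTable:
    """Read a bucket CSV: columns = scheme variables + ``count``.

    Counts must be positive integers; labels must be scheme bins (or
    EMPTY).  Anything else raises :class:`FormatError`.
    """
    scheme = scheme or default_scheme()
    path = Path(path)
    source_id = source_id or path.stem
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = set(scheme.variables) | {"count"}
    if set(df.columns) != expected:
        raise FormatError(
            f"{path}: header {sorted(df.columns)} != scheme variables + 'count'"
        )
    counts: dict[tuple[str, ...], int] = {}
    for _, row in df.iterrows():
        try:
            c = int(row["count"])
        except ValueError as exc:
            raise FormatError(f"{path}: count {row['count']!r} is not an integer") from exc
        if c <= 0:
            raise FormatError(f"{path}: count {c} is not positive")
        tup = tuple(row[v] for v in scheme.variables)
        try:
            scheme.check_tuple(tup)
        except Exception as exc:
            raise FormatError(f"{path}: {exc}") from exc
        counts[tup] = counts.get(tup, 0) + c
    return BucketTable(scheme=scheme, counts=counts, source_id=source_id)


def write_bucket_csv(table: BucketTable, path: str | Path) -> None:
    """Write the summed bucket view in canonical row/column order."""
    table.to_frame().to_csv(path, index=False)


def write_qc_report_csv(results: Sequence[QCResult], path: str | Path) -> None:
    """Flat QC report: (record id, variable, flag, rule id that set it)."""
    rows = []
    for res in results:
        fired = {var: rule_id for rule_id, var in res.fired_rules}
        for var, flag in res.flags.items():
            rows.append(
                {
                    "record_id": res.cleaned.record_id or "",
                    "variable": var,
                    "flag": flag.value,
                    "rule_id": fired.get(var, ""),
                }
            )
    pd.DataFrame(rows, columns=["record_id", "variable", "flag", "rule_id"]).to_csv(
        path, index=False
    )


# -- manifest and acquisition summary ----------------------------------------


@dataclass(frozen=True)
class ManifestEntry:
    source_id: str
    stream: str
    path: str | Path
    country: str | None = None

    def __post_init__(self) -> None:
        if self.stream not in STREAMS:
            raise ValueError(f"unknown stream {self.stream!r}")


@dataclass(frozen=True)
class StreamManifest:
    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.source_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate source_id in manifest")

    def by_stream(self, stream: str) -> tuple[ManifestEntry, ...]:
        return tuple(e for e in self.entries if e.stream == stream)

    @classmethod
    def from_yaml(cls, source: str | Path | Mapping[str, Any]) -> "StreamManifest":
        import yaml

        if isinstance(source, Mapping):
            doc = source
        else:
            doc = yaml.safe_load(Path(source).read_text(encoding="utf-8"))
        entries = tuple(
            ManifestEntry(
                source_id=str(e["source_id"]),
                stream=str(e["stream"]),
                path=str(e["path"]),
                country=e.get("country"),
            )
            for e in doc["entries"]
        )
        return cls(entries=entries)

    def to_yaml(self, path: str | Path | None = None) -> str:
        import yaml

        doc = {
            "entries": [
                {
                    "source_id": e.source_id,
                    "stream": e.stream,
                    "path": str(e.path),
                    **({"country": e.country} if e.country else {}),
                }
                for e in self.entries
            ]
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


@dataclass
class AcquisitionSummary:
    """Record counts per stream and per country; shares derive from the counts."""

    stream_counts: dict[str, int]
    country_counts: dict[str, int]
    stream_sources: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.stream_counts.values())

    def stream_shares(self, decimals: int = 2) -> dict[str, float]:
        return {s: pct(c, self.total, decimals) for s, c in self.stream_counts.items()}

    def country_shares(self, decimals: int = 2) -> dict[str, float]:
        return {c: pct(n, self.total, decimals) for c, n in self.country_counts.items()}

    def registry_share(self, stream: str = "federated", decimals: int = 0) -> float:
        """Share of registries (core + federated sources) using ``stream``."""
        registries = self.stream_sources.get("core", 0) + self.stream_sources.get(
            "federated", 0
        )
        return pct(self.stream_sources.get(stream, 0), registries, decimals)

    def to_frame(self) -> pd.DataFrame:
        shares = self.stream_shares()
        rows = [
            {"stream": s, "records": c, "share_pct": shares[s],
             "sources": self.stream_sources.get(s, 0)}
            for s, c in self.stream_counts.items()
        ]
        return pd.DataFrame(rows, columns=["stream", "records", "share_pct", "sources"])


def acquisition_summary(
    manifest: StreamManifest,
    data: Mapping[str, Any],
) -> AcquisitionSummary:
    """Summarize acquisition per stream and country.

    ``data`` maps source_id to loaded content: a record list, a
    :class:`BucketTable` (contributing its count sum), or a plain integer
    count.  Sources without a country label are tallied as ``unknown``.
    """
    stream_counts = {s: 0 for s in STREAMS}
    stream_sources = {s: 0 for s in STREAMS}
    country_counts: dict[str, int] = {}
    for entry in manifest.entries:
        loaded = data.get(entry.source_id, 0)
        if isinstance(loaded, BucketTable):
            n = loaded.n
        elif isinstance(loaded, int):
            n = loaded
        else:
            n = len(loaded)
        stream_counts[entry.stream] += n
        stream_sources[entry.stream] += 1
        country = entry.country or "unknown"
        country_counts[country] = country_counts.get(country, 0) + n
    return AcquisitionSummary(
        stream_counts=stream_counts,
        country_counts=country_counts,
        stream_sources=stream_sources,
    )


# -- stream artifact emission (used by the synthetic generator) --------------


def write_stream_artifacts(
    sources: Sequence[tuple[str, Sequence[PatientRecord]]],
    assignment: Sequence[tuple[str, str]],
    outdir: str | Path,
    dictionary: DataDictionary | None = None,
    scheme: BinningScheme | None = None,
    engine: RuleEngine | None = None,
    countries: Mapping[str, str] | None = None,
) -> StreamManifest:
    """Materialize each source under its stream contract.

    Direct-entry and core sources are written as patient-level record CSVs.
    Federated sources run QC + bucketization locally and emit only the
    bucket CSV — no raw age, date or score appears in their artifact.
    """
    dictionary = dictionary or default_dictionary()
    scheme = scheme or default_scheme()
    engine = engine or RuleEngine(dictionary)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stream_of = dict(assignment)
    entries = []
    by_id = {sid: recs for sid, recs in sources}
    for source_id, stream in assignment:
        recs = by_id[source_id]
        if stream == "federated":
            path = outdir / f"{source_id}_buckets.csv"
            cleaned = [r.cleaned for r in engine.evaluate_records(list(recs))]
            write_bucket_csv(bucketize(cleaned, scheme, source_id), path)
        else:
            path = outdir / f"{source_id}_records.csv"
            write_records_csv(list(recs), path, dictionary)
        entries.append(
            ManifestEntry(
                source_id=source_id,
                stream=stream,
                path=str(path),
                country=(countries or {}).get(source_id),
            )
        )
    manifest = StreamManifest(entries=tuple(entries))
    manifest.to_yaml(outdir / "manifest.yaml")
    return manifest


def local_node(
    records_path: str | Path,
    outdir: str | Path,
    dictionary: DataDictionary | None = None,
    scheme: BinningScheme | None = None,
    strict_symptoms: bool = False,
    source_id: str | None = None,
) -> Path:
    """Registry-side run: validate + QC + bucketize only, emit the bucket CSV.

    This is the federated stream's local step — the only artifact that
    leaves the registry is the aggregated count table it returns the path
    of (plus a QC summary for local inspection)."""
    dictionary = dictionary or default_dictionary()
    scheme = scheme or default_scheme()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = read_records_csv(records_path, dictionary, source_id=source_id)
    sid = source_id or Path(records_path).stem
    engine = RuleEngine(dictionary, strict_symptoms=strict_symptoms)
    results = engine.evaluate_records(records)
    cleaned = [r.cleaned for r in results]
    bucket_path = outdir / f"{sid}_buckets.csv"
    write_bucket_csv(bucketize(cleaned, scheme, sid), bucket_path)
    qc_summary(results, dictionary).to_frame().to_csv(
        outdir / f"{sid}_qc_summary.csv", index=False
    )
    return bucket_path


# -- full pipeline -----------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end run configuration (validate -> qc -> bucketize -> aggregate
    -> expand -> analyze)."""

    manifest: StreamManifest
    dictionary: DataDictionary = field(default_factory=default_dictionary)
    scheme: BinningScheme = field(default_factory=default_scheme)
    outcomes: tuple[str, ...] = ("covid19_admission_hospital",)
    strict_symptoms: bool = False
    suppress_threshold: int = 0
    outdir: str | Path | None = None


@dataclass
class PipelineResult:
    tables: dict[str, BucketTable]
    aggregated: BucketTable
    expanded: ExpandedTable
    qc_results: dict[str, list[QCResult]]
    summary: AcquisitionSummary
    model_results: list[SeverityModelResults]
    suppressed_total: int = 0


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline over a stream manifest.

    Record streams (direct entry, core) are validated, QC-cleaned and
    bucketized centrally; federated sources enter at the aggregation step —
    their raw records are never read, and their QC is trusted to have run
    source-side.  Every stage failure raises :class:`PipelineError` naming
    the stage and source.
    """
    engine = RuleEngine(config.dictionary, strict_symptoms=config.strict_symptoms)
    tables: dict[str, BucketTable] = {}
    qc_results: dict[str, list[QCResult]] = {}
    loaded: dict[str, Any] = {}
    for entry in config.manifest.entries:
        if entry.stream == "federated":
            try:
                table = read_bucket_csv(entry.path, config.scheme, entry.source_id)
            except Exception as exc:
                raise PipelineError("read_buckets", entry.source_id, exc) from exc
            logger.info("stage=read_buckets source=%s n=%d", entry.source_id, table.n)
        else:
            try:
                records = read_records_csv(entry.path, config.dictionary, entry.source_id)
            except Exception as exc:
                raise PipelineError("read_records", entry.source_id, exc) from exc
            try:
                results = engine.evaluate_records(records)
            except Exception as exc:
                raise PipelineError("qc", entry.source_id, exc) from exc
            qc_results[entry.source_id] = results
            cleaned = [r.cleaned for r in results]
            n_fail = sum(
                1 for r in results for f in r.flags.values() if f.name == "FAIL"
            )
            logger.info(
                "stage=qc source=%s in=%d out=%d fail_flags=%d",
                entry.source_id, len(records), len(cleaned), n_fail,
            )
            try:
                table = bucketize(cleaned, config.scheme, entry.source_id)
            except Exception as exc:
                raise PipelineError("bucketize", entry.source_id, exc) from exc
            logger.info("stage=bucketize source=%s n=%d rows=%d",
                        entry.source_id, table.n, len(table.counts))
        tables[entry.source_id] = table
        loaded[entry.source_id] = table

    suppressed_total = 0
    if config.suppress_threshold > 1:
        for sid in list(tables):
            tables[sid], dropped = suppress_small_cells(
                tables[sid], config.suppress_threshold
            )
            suppressed_total += dropped
        logger.info("stage=suppress threshold=%d suppressed=%d",
                    config.suppress_threshold, suppressed_total)

    try:
        aggregated = aggregate(list(tables.values()))
    except Exception as exc:
        raise PipelineError("aggregate", None, exc) from exc
    expanded = expand(aggregated)
    logger.info("stage=aggregate sources=%d n=%d rows=%d",
                len(tables), aggregated.n, len(aggregated.counts))

    summary = acquisition_summary(config.manifest, loaded)

    model_results: list[SeverityModelResults] = []
    for outcome in config.outcomes:
        try:
            model_results.append(
                fit_severity_model(expanded, ModelSpec(outcome=outcome))
            )
        except Exception as exc:
            raise PipelineError("analyze", outcome, exc) from exc
        logger.info("stage=analyze outcome=%s n=%d", outcome, expanded.n)

    result = PipelineResult(
        tables=tables,
        aggregated=aggregated,
        expanded=expanded,
        qc_results=qc_results,
        summary=summary,
        model_results=model_results,
        suppressed_total=suppressed_total,
    )
    if config.outdir is not None:
        _write_pipeline_artifacts(config, result)
    return result


def _write_pipeline_artifacts(config: PipelineConfig, result: PipelineResult) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, table in result.tables.items():
        write_bucket_csv(table, outdir / f"buckets_{sid}.csv")
    write_bucket_csv(result.aggregated, outdir / "buckets_aggregated.csv")
    result.expanded.to_dataframe().to_csv(outdir / "expanded.csv", index=False)
    all_qc = [r for results in result.qc_results.values() for r in results]
    if all_qc:
        write_qc_report_csv(all_qc, outdir / "qc_report.csv")
        qc_summary(all_qc, config.dictionary).to_frame().to_csv(
            outdir / "qc_summary.csv", index=False
        )
    result.summary.to_frame().to_csv(outdir / "acquisition_summary.csv", index=False)
    report(result.model_results).to_csv(outdir / "results.csv", index=False)
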