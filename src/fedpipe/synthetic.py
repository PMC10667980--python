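"""Synthetic multi-registry generator with ground-truth effect ledger.

Emulates the statistical structure of the harmonized core data set so that
every pipeline stage is testable without any real registry export:

* covariates drawn from configurable category prevalences;
* per-source random intercepts (Normal, configurable SD) and severity
  outcomes from a logistic model with configurable DMT log-odds effects —
  the structure the downstream multilevel model assumes;
* realistic internally consistent dates (disease onset <= diagnosis <=
  suspected infection onset <= reporting date, all consistent with age), so
  clean-mode output passes every shipped temporal rule by construction;
* configurable per-variable missingness and injectable rule-violating
  errors, each recorded in a ground-truth ledger so detection can be
  asserted exactly.

The generator targets statistical structure, not clinical realism: default
prevalences are round numbers, not epidemiological estimates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np

from .dictionary import PatientRecord
from .qc import COMORBIDITY_VARIABLES, SYMPTOM_VARIABLES

__all__ = [
    "GeneratorConfig",
    "InjectedError",
    "GroundTruth",
    "ERROR_KINDS",
    "ERROR_FAIL_VARIABLE",
    "generate_sources",
    "assign_streams",
]

DMT_LABELS = (
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

OUTCOMES = (
    "covid19_admission_hospital",
    "covid19_icu_admission",
    "covid19_ventilation",
    "covid19_death",
)

ERROR_KINDS = (
    "future_date",
    "pre_birth_date",
    "onset_after_diagnosis",
    "symptom_contradiction",
    "age_out_of_range",
    "edss_out_of_range",
)

#: which variable each injected error kind makes FAIL under the shipped rules
ERROR_FAIL_VARIABLE = {
    "future_date": "ms_diagnosis_date",
    "pre_birth_date": "ms_onset_date",
    "onset_after_diagnosis": "ms_onset_date",
    "symptom_contradiction": "covid19_has_symptoms",  # strict mode only
    "age_out_of_range": "age_years",
    "edss_out_of_range": "edss_value",
}

_REPORTING_START = dt.date(2020, 3, 1)
_REPORTING_END = dt.date(2021, 6, 30)


def _default_prevalences() -> dict[str, dict[str, float]]:
    return {
        "age_years": {"18-50": 0.55, "50-70": 0.35, ">70": 0.10},
        "sex": {"female": 0.70, "male": 0.30},
        "ms_type": {"relapsing_remitting": 0.80, "progressive": 0.20},
        "edss_value": {"0-6": 0.75, "6-10": 0.25},
        "type_dmt": {
            "untreated": 0.15,
            "ocrelizumab": 0.12,
            "rituximab": 0.10,
            "fingolimod": 0.10,
            "dimethyl_fumarate": 0.10,
            "interferon": 0.10,
            "natalizumab": 0.08,
            "glatiramer_acetate": 0.08,
            "teriflunomide": 0.07,
            "cladribine": 0.04,
            "other": 0.04,
            "alemtuzumab": 0.02,
        },
        "covid19_has_symptoms": {"yes": 0.80, "no": 0.20},
        "covid19_confirmed_case": {"yes": 0.85, "no": 0.15},
    }


def _default_covariate_effects() -> dict[str, dict[tuple[str, str], float]]:
    # modest severity gradients over age, sex, phenotype and disability
    return {
        "covid19_admission_hospital": {
            ("age_years", "50-70"): 0.6, ("age_years", ">70"): 1.3,
            ("sex", "male"): 0.3, ("ms_type", "progressive"): 0.5,
            ("edss_value", "6-10"): 0.9,
        },
        "covid19_icu_admission": {
            ("age_years", "50-70"): 0.6, ("age_years", ">70"): 1.2,
            ("sex", "male"): 0.3, ("ms_type", "progressive"): 0.5,
            ("edss_value", "6-10"): 0.8,
        },
        "covid19_ventilation": {
            ("age_years", "50-70"): 0.7, ("age_years", ">70"): 1.4,
            ("sex", "male"): 0.3, ("ms_type", "progressive"): 0.5,
            ("edss_value", "6-10"): 1.0,
        },
        "covid19_death": {
            ("age_years", "50-70"): 1.2, ("age_years", ">70"): 2.3,
            ("sex", "male"): 0.3, ("ms_type", "progressive"): 0.5,
            ("edss_value", "6-10"): 1.5,
        },
    }


@dataclass
class GeneratorConfig:
    """Everything that determines a synthetic multi-registry draw.

    Parameters
    ----------
    n_per_source : tuple of int
        Record count per contributing source (default: 8 sources of 500).
    seed : int
        Fully determines the output (per-source substreams are derived).
    category_prevalences : mapping
        Per-variable probability vectors over the analysis categories.
    dmt_effects : mapping
        DMT label -> {outcome -> log-odds increment}.  The shipped default
        elevates rituximab (1.0) and ocrelizumab (0.55) on hospitalization
        so that recovery tests are directional; these are test fixtures,
        not clinical estimates.
    baseline_logits : mapping
        Outcome -> intercept on the log-odds scale.
    covariate_effects : mapping
        Outcome -> {(variable, category) -> log-odds increment}.
    source_intercept_sd : float
        SD of the per-source Normal random intercept (shared across
        outcomes).
    missingness_rates : mapping
        Per-variable probability of masking a clean value to missing.
    error_rates : mapping
        Per-error-kind injection probability (at most one error per
        record, so every injection stays independently detectable).
    """

    n_per_source: tuple[int, ...] = (500,) * 8
    seed: int = 0
    category_prevalences: dict[str, dict[str, float]] = field(default_factory=_default_prevalences)
    dmt_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "rituximab": {"covid19_admission_hospital": 1.0},
            "ocrelizumab": {"covid19_admission_hospital": 0.55},
        }
    )
    baseline_logits: dict[str, float] = field(
        default_factory=lambda: {
            "covid19_admission_hospital": -2.2,
            "covid19_icu_admission": -3.6,
            "covid19_ventilation": -4.2,
            "covid19_death": -4.4,
        }
    )
    covariate_effects: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=_default_covariate_effects
    )
    source_intercept_sd: float = 0.25
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: {
            "edss_value": 0.08,
            "ms_onset_date": 0.05,
            "ms_diagnosis_date": 0.05,
            "covid19_suspected_onset": 0.05,
            "has_comorbidities": 0.10,
        }
    )
    error_rates: dict[str, float] = field(default_factory=dict)
    source_countries: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_source):
            raise ValueError("n_per_source entries must be non-negative")
        for var, probs in self.category_prevalences.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"prevalences for {var!r} sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"negative prevalence for {var!r}")
        for name, rates in (("missingness_rates", self.missingness_rates),
                            ("error_rates", self.error_rates)):
            for key, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"{name}[{key!r}] = {r} outside [0, 1]")
        unknown = set(self.error_rates) - set(ERROR_KINDS)
        if unknown:
            raise ValueError(f"unknown error kinds: {sorted(unknown)}")
        if sum(self.error_rates.values()) > 1.0:
            raise ValueError("error rates sum above 1 (one error at most per record)")
        if self.source_intercept_sd < 0:
            raise ValueError("source_intercept_sd must be non-negative")


@dataclass(frozen=True)
class InjectedError:
    source_id: str
    record_id: str
    kind: str
    variable: str


@dataclass
class GroundTruth:
    """Everything true about a draw: injected errors, per-source intercepts,
    and the generating configuration."""

    config: GeneratorConfig
    source_intercepts: dict[str, float]
    errors: list[InjectedError]

    def error_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {k: 0 for k in ERROR_KINDS}
        for e in self.errors:
            counts[e.kind] += 1
        return {k: v for k, v in counts.items() if v}


def _draw_category(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> list[str]:
    labels = list(probs)
    p = np.asarray([probs[l] for l in labels], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(labels), size=n, p=p)
    return [labels[i] for i in idx]


def _age_from_bin(rng: np.random.Generator, label: str) -> int:
    lo, hi = {"18-50": (18, 49), "50-70": (50, 69), ">70": (70, 95)}[label]
    return int(rng.integers(lo, hi + 1))


def _edss_from_bin(rng: np.random.Generator, label: str) -> float:
    if label == "0-6":
        return float(rng.integers(0, 12)) / 2.0  # 0.0 .. 5.5
    return float(rng.integers(12, 20)) / 2.0  # 6.0 .. 9.5


def _generate_source(
    source_id: str,
    n: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    intercept: float,
) -> tuple[list[PatientRecord], list[InjectedError]]:
    prev = config.category_prevalences
    records: list[PatientRecord] = []
    errors: list[InjectedError] = []
    if n == 0:
        return records, errors

    age_bins = _draw_category(rng, prev["age_years"], n)
    sexes = _draw_category(rng, prev["sex"], n)
    ms_types = _draw_category(rng, prev["ms_type"], n)
    edss_bins = _draw_category(rng, prev["edss_value"], n)
    dmts = _draw_category(rng, prev["type_dmt"], n)
    sympt_flags = _draw_category(rng, prev["covid19_has_symptoms"], n)
    confirmed = _draw_category(rng, prev["covid19_confirmed_case"], n)
    reporting_offsets = rng.integers(0, (_REPORTING_END - _REPORTING_START).days + 1, size=n)

    # error-kind assignment: at most one kind per record, by one uniform draw
    kinds = [k for k in ERROR_KINDS if config.error_rates.get(k, 0) > 0]
    cum = np.cumsum([config.error_rates[k] for k in kinds]) if kinds else np.array([])
    u_err = rng.random(n)

    for i in range(n):
        v: dict[str, Any] = {}
        rec_id = f"{source_id}-{i:05d}"
        age = _age_from_bin(rng, age_bins[i])
        reporting = _REPORTING_START + dt.timedelta(days=int(reporting_offsets[i]))
        v["covid19_date_reporting"] = reporting
        v["age_years"] = age
        v["sex"] = sexes[i]
        v["ms_type"] = ms_types[i]
        v["edss_value"] = _edss_from_bin(rng, edss_bins[i])
        dmt = dmts[i]
        v["type_dmt"] = dmt
        v["current_dmt"] = "no" if dmt == "untreated" else "yes"
        v["type_dmt_other"] = None

        # dates, built backwards from the reporting anchor
        if age <= 18:
            onset = reporting - dt.timedelta(days=int(rng.integers(60, 365)))
        else:
            years_back = int(rng.integers(1, min(age - 18, 25) + 1))
            onset = reporting - dt.timedelta(days=years_back * 365 + int(rng.integers(0, 365)))
        gap = (reporting - onset).days
        diag = onset + dt.timedelta(days=int(rng.integers(0, max(1, min(gap - 30, 1095)))))
        susp = reporting - dt.timedelta(days=int(rng.integers(0, 22)))
        if susp < diag:
            susp = diag
        v["ms_onset_date"] = onset
        v["ms_diagnosis_date"] = diag
        v["covid19_suspected_onset"] = susp

        # symptoms
        has_sympt = sympt_flags[i]
        v["covid19_has_symptoms"] = has_sympt
        if has_sympt == "yes":
            draws = rng.random(len(SYMPTOM_VARIABLES)) < 0.35
            if not draws.any():
                draws[0] = True
            for s, flag in zip(SYMPTOM_VARIABLES, draws):
                v[s] = "yes" if flag else "no"
        else:
            for s in SYMPTOM_VARIABLES:
                v[s] = "no"

        # comorbidities
        com_draws = rng.random(len(COMORBIDITY_VARIABLES)) < 0.12
        for c, flag in zip(COMORBIDITY_VARIABLES, com_draws):
            v[c] = "yes" if flag else "no"
        v["has_comorbidities"] = "yes" if com_draws.any() else "no"

        # severity outcomes from the logistic model
        for outcome in OUTCOMES:
            lp = config.baseline_logits[outcome] + intercept
            eff = config.covariate_effects.get(outcome, {})
            lp += eff.get(("age_years", age_bins[i]), 0.0)
            lp += eff.get(("sex", sexes[i]), 0.0)
            lp += eff.get(("ms_type", ms_types[i]), 0.0)
            lp += eff.get(("edss_value", edss_bins[i]), 0.0)
            lp += config.dmt_effects.get(dmt, {}).get(outcome, 0.0)
            p = 1.0 / (1.0 + np.exp(-lp))
            v[outcome] = "yes" if rng.random() < p else "no"

        # a hospitalized case cannot be explicitly unconfirmed (rule-clean)
        v["covid19_confirmed_case"] = (
            "yes" if v["covid19_admission_hospital"] == "yes" else confirmed[i]
        )

        # missingness, then at most one injected error per record
        for var, rate in config.missingness_rates.items():
            if rate > 0 and rng.random() < rate:
                v[var] = None

        if kinds and u_err[i] < cum[-1]:
            kind = kinds[int(np.searchsorted(cum, u_err[i], side="right"))]
            if kind == "future_date":
                v["ms_diagnosis_date"] = reporting + dt.timedelta(days=int(rng.integers(30, 301)))
            elif kind == "pre_birth_date":
                birth_year = reporting.year - age
                v["ms_onset_date"] = dt.date(birth_year - int(rng.integers(1, 11)), 6, 15)
            elif kind == "onset_after_diagnosis":
                v["ms_diagnosis_date"] = diag
                v["ms_onset_date"] = diag + dt.timedelta(days=int(rng.integers(30, 301)))
            elif kind == "symptom_contradiction":
                v["covid19_has_symptoms"] = "no"
                v["covid19_sympt_fever"] = "yes"
            elif kind == "age_out_of_range":
                v["age_years"] = int(rng.integers(111, 151))
            elif kind == "edss_out_of_range":
                v["edss_value"] = float(rng.integers(21, 31)) / 2.0
            errors.append(InjectedError(source_id, rec_id, kind, ERROR_FAIL_VARIABLE[kind]))

        records.append(PatientRecord(source_id=source_id, values=v, record_id=rec_id))
    return records, errors


def generate_sources(
    config: GeneratorConfig,
) -> tuple[list[tuple[str, list[PatientRecord]]], GroundTruth]:
    """Draw the configured multi-registry record set plus its ground truth.

    The same seed always reproduces the same output; each source uses a
    substream derived from (seed, source index) so sources are independent
    of one another's sizes."""
    sources: list[tuple[str, list[PatientRecord]]] = []
    intercepts: dict[str, float] = {}
    all_errors: list[InjectedError] = []
    master = np.random.default_rng(config.seed)
    for idx, n in enumerate(config.n_per_source):
        source_id = f"source_{idx + 1:02d}"
        rng = np.random.default_rng([config.seed, idx])
        intercept = float(master.normal(0.0, config.source_intercept_sd))
        intercepts[source_id] = intercept
        records, errors = _generate_source(source_id, n, config, rng, intercept)
        sources.append((source_id, records))
        all_errors.extend(errors)
    return sources, GroundTruth(config=config, source_intercepts=intercepts, errors=all_errors)


def assign_streams(
    sources: Sequence[tuple[str, Sequence[PatientRecord]]],
    shares: tuple[float, float, float],
    outdir: str | None = None,
    **writer_kwargs: Any,
) -> list[tuple[str, str]]:
    """Label each source direct_entry / core / federated.

    ``shares`` are the target record-count fractions of the three streams
    in that order.  Sources are assigned greedily (largest first, to the
    stream with the largest remaining deficit), which reproduces exact
    stream totals whenever source sizes permit.  With ``outdir`` given the
    stream artifacts are also written: record CSVs for direct-entry and
    core sources, bucket CSVs only (raw records withheld) for federated
    sources.
    """
    if len(shares) != 3 or any(s < 0 for s in shares) or sum(shares) == 0:
        raise ValueError("shares must be three non-negative fractions, not all zero")
    total_share = float(sum(shares))
    streams = ("direct_entry", "core", "federated")
    n_total = sum(len(recs) for _, recs in sources)
    deficits = {s: n_total * (sh / total_share) for s, sh in zip(streams, shares)}
    assignment: dict[str, str] = {}
    for source_id, recs in sorted(sources, key=lambda sr: -len(sr[1])):
        best = max(streams, key=lambda s: deficits[s])
        assignment[source_id] = best
        deficits[best] -= len(recs)
    manifest = [(source_id, assignment[source_id]) for source_id, _ in sources]
    if outdir is not None:
        from .interface import write_stream_artifacts

        write_stream_artifacts(sources, manifest, outdir, **writer_kwargs)
    return manifest
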