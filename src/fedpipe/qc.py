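"""Data-quality rule engine: PASS/FAIL/EMPTY flags, temporal checks, derivations.

Every non-missing variable of a record is scrutinized against the
registered rules.  A failed variable is set to missing, flagged ``FAIL``,
and the patient row is always kept — quality assessment never drops
records.  Missing inputs are flagged ``EMPTY`` unless a derivation rule can
fill them (then ``PASS`` with the derivation recorded).

Rules are evaluated in a single pass in a fixed kind order::

    range -> temporal -> interdependency -> derivation

so derivations see post-FAIL missingness and later stages re-evaluate
against values already cleaned by earlier stages.  The shipped rules are
the printed core checks; additional checks are registered by the user in
the same declarative YAML dialect as the dictionary (see
:func:`load_rules`).
"""

from __future__ import annotations

import operator
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import yaml

from .dictionary import DataDictionary, PatientRecord, default_dictionary

__all__ = [
    "QCFlag",
    "QCRule",
    "QCResult",
    "QCSummary",
    "RuleEngine",
    "ConfigurationError",
    "default_rules",
    "load_rules",
    "qc_summary",
    "rule_reporting_date",
    "rule_no_future_dates",
    "rule_before_birth",
    "rule_covid_after_ms_baseline",
    "rule_hospitalization_consistency",
    "rule_dmt_consistency",
    "derive_has_symptoms",
    "derive_has_comorbidities",
    "SYMPTOM_VARIABLES",
    "COMORBIDITY_VARIABLES",
]

SYMPTOM_VARIABLES = (
    "covid19_sympt_fever",
    "covid19_sympt_dry_cough",
    "covid19_sympt_fatigue",
    "covid19_sympt_pain",
    "covid19_sympt_sore_throat",
    "covid19_sympt_shortness_breath",
    "covid19_sympt_nasal_congestion",
    "covid19_sympt_loss_smell_taste",
    "covid19_sympt_pneumonia",
)

COMORBIDITY_VARIABLES = (
    "com_hypertension",
    "com_diabetes",
    "com_cardiovascular_disease",
    "com_chronic_lung_disease",
    "com_obesity",
)

KIND_ORDER = ("range", "temporal", "interdependency", "derivation")


class QCFlag(str, Enum):
    PASS = "PASS"
    FAIL = "FAIL"
    EMPTY = "EMPTY"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ConfigurationError(ValueError):
    """A rule references a variable unknown to the dictionary (build-time)."""


@dataclass(frozen=True)
class RuleOutcome:
    """What one rule decided for one record."""

    fails: tuple[str, ...] = ()            # variables to flag FAIL (and blank)
    derived: tuple[tuple[str, Any], ...] = ()  # (variable, value) fills for EMPTY targets


@dataclass(frozen=True)
class QCRule:
    """One declarative quality rule.

    ``check`` inspects the record's current (partially cleaned) values and
    returns a :class:`RuleOutcome`.  ``references`` lists every variable the
    predicate touches, so the engine can verify them against the dictionary
    at build time rather than at evaluation time.
    """

    rule_id: str
    kind: str  # range | temporal | interdependency | derivation
    targets: tuple[str, ...]
    references: tuple[str, ...]
    check: Callable[[Mapping[str, Any]], RuleOutcome]

    def __post_init__(self) -> None:
        if self.kind not in KIND_ORDER:
            raise ConfigurationError(f"rule {self.rule_id!r}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class QCResult:
    """Cleaned record + per-variable flags + the rules that fired on it."""

    cleaned: PatientRecord
    flags: Mapping[str, QCFlag]
    fired_rules: tuple[tuple[str, str], ...]  # (rule_id, variable)

    @property
    def rule_ids(self) -> tuple[str, ...]:
        return tuple(r for r, _ in self.fired_rules)


def _values(record: PatientRecord | Mapping[str, Any]) -> Mapping[str, Any]:
    return record.values if isinstance(record, PatientRecord) else record


# ---------------------------------------------------------------------------
# Printed core rules.  Each helper returns the variables it would FAIL (or
# the derivations it would apply) given the record's current values; rules
# whose anchors are missing are skipped (undefined comparisons flag nothing).
# ---------------------------------------------------------------------------

def _check_reporting_date(v: Mapping[str, Any]) -> RuleOutcome:
    d = v.get("covid19_date_reporting")
    if d is not None and d.year < 2019:
        return RuleOutcome(fails=("covid19_date_reporting",))
    return RuleOutcome()


def _check_age_range(v: Mapping[str, Any]) -> RuleOutcome:
    a = v.get("age_years")
    if a is not None and (a < 0 or a > 110):
        return RuleOutcome(fails=("age_years",))
    return RuleOutcome()


def _check_edss_range(v: Mapping[str, Any]) -> RuleOutcome:
    e = v.get("edss_value")
    if e is not None and (e < 0 or e > 10):
        return RuleOutcome(fails=("edss_value",))
    return RuleOutcome()


def _check_no_future_dates(v: Mapping[str, Any], date_vars: Sequence[str]) -> RuleOutcome:
    rep = v.get("covid19_date_reporting")
    if rep is None:
        return RuleOutcome()
    fails = tuple(
        name
        for name in date_vars
        if name != "covid19_date_reporting"
        and v.get(name) is not None
        and v[name] > rep
    )
    return RuleOutcome(fails=fails)


def _check_before_birth(v: Mapping[str, Any], date_vars: Sequence[str]) -> RuleOutcome:
    rep = v.get("covid19_date_reporting")
    age = v.get("age_years")
    if rep is None or age is None:
        return RuleOutcome()
    birth_year = rep.year - age
    fails = tuple(
        name
        for name in date_vars
        if name != "covid19_date_reporting"
        and v.get(name) is not None
        and v[name].year < birth_year
    )
    return RuleOutcome(fails=fails)


def _check_ms_onset_order(v: Mapping[str, Any]) -> RuleOutcome:
    onset = v.get("ms_onset_date")
    if onset is None:
        return RuleOutcome()
    diag = v.get("ms_diagnosis_date")
    susp = v.get("covid19_suspected_onset")
    if (diag is not None and onset > diag) or (susp is not None and onset > susp):
        return RuleOutcome(fails=("ms_onset_date",))
    return RuleOutcome()


def _check_covid_after_baseline(v: Mapping[str, Any]) -> RuleOutcome:
    # COVID-19 dates must not precede the MS baseline dates.
    fails = []
    for covid_var in ("covid19_suspected_onset",):
        cd = v.get(covid_var)
        if cd is None:
            continue
        for base_var in ("ms_onset_date", "ms_diagnosis_date"):
            bd = v.get(base_var)
            if bd is not None and cd < bd:
                fails.append(covid_var)
                break
    return RuleOutcome(fails=tuple(fails))


def _check_hospitalization(v: Mapping[str, Any]) -> RuleOutcome:
    if v.get("covid19_admission_hospital") == "yes" and v.get("covid19_confirmed_case") == "no":
        return RuleOutcome(fails=("covid19_admission_hospital",))
    return RuleOutcome()


def _check_dmt(v: Mapping[str, Any]) -> RuleOutcome:
    # The printed rule fails a record claiming an ongoing therapy while
    # naming none; the non-missing inconsistent value is current_dmt.
    if v.get("type_dmt") is None and v.get("type_dmt_other") is None and v.get("current_dmt") == "yes":
        return RuleOutcome(fails=("current_dmt",))
    return RuleOutcome()


def _check_symptom_contradiction(v: Mapping[str, Any]) -> RuleOutcome:
    # strict mode only: explicit "no symptoms" contradicted by a named symptom
    if v.get("covid19_has_symptoms") == "no" and any(
        v.get(s) == "yes" for s in SYMPTOM_VARIABLES
    ):
        return RuleOutcome(fails=("covid19_has_symptoms",))
    return RuleOutcome()


def _derive_symptoms(v: Mapping[str, Any]) -> RuleOutcome:
    if v.get("covid19_has_symptoms") is not None:
        return RuleOutcome()
    vals = [v.get(s) for s in SYMPTOM_VARIABLES]
    if any(x == "yes" for x in vals):
        return RuleOutcome(derived=(("covid19_has_symptoms", "yes"),))
    if all(x == "no" for x in vals):
        return RuleOutcome(derived=(("covid19_has_symptoms", "no"),))
    return RuleOutcome()


def _derive_comorbidities(v: Mapping[str, Any]) -> RuleOutcome:
    # only the yes direction is defined for comorbidities
    if v.get("has_comorbidities") is None and any(
        v.get(c) == "yes" for c in COMORBIDITY_VARIABLES
    ):
        return RuleOutcome(derived=(("has_comorbidities", "yes"),))
    return RuleOutcome()


def default_rules(
    dictionary: DataDictionary | None = None, strict_symptoms: bool = False
) -> tuple[QCRule, ...]:
    """The shipped rule set, bound to ``dictionary``'s date variables."""
    dictionary = dictionary or default_dictionary()
    date_vars = dictionary.date_variables
    rules = [
        QCRule("reporting_date_pre_2019", "range", ("covid19_date_reporting",),
               ("covid19_date_reporting",), _check_reporting_date),
        QCRule("age_out_of_range", "range", ("age_years",), ("age_years",), _check_age_range),
        QCRule("edss_out_of_range", "range", ("edss_value",), ("edss_value",), _check_edss_range),
        QCRule("no_future_dates", "temporal", date_vars,
               date_vars + ("covid19_date_reporting",),
               lambda v, dv=date_vars: _check_no_future_dates(v, dv)),
        QCRule("date_before_birth", "temporal", date_vars,
               date_vars + ("covid19_date_reporting", "age_years"),
               lambda v, dv=date_vars: _check_before_birth(v, dv)),
        QCRule("ms_onset_order", "temporal", ("ms_onset_date",),
               ("ms_onset_date", "ms_diagnosis_date", "covid19_suspected_onset"),
               _check_ms_onset_order),
        QCRule("covid_before_ms_baseline", "temporal", ("covid19_suspected_onset",),
               ("covid19_suspected_onset", "ms_onset_date", "ms_diagnosis_date"),
               _check_covid_after_baseline),
        QCRule("hospitalization_without_confirmation", "interdependency",
               ("covid19_admission_hospital",),
               ("covid19_admission_hospital", "covid19_confirmed_case"),
               _check_hospitalization),
        QCRule("dmt_claimed_but_unnamed", "interdependency", ("current_dmt",),
               ("current_dmt", "type_dmt", "type_dmt_other"), _check_dmt),
    ]
    if strict_symptoms:
        rules.append(
            QCRule("symptom_contradiction_strict", "interdependency",
                   ("covid19_has_symptoms",),
                   ("covid19_has_symptoms",) + SYMPTOM_VARIABLES,
                   _check_symptom_contradiction)
        )
    rules += [
        QCRule("derive_has_symptoms", "derivation", ("covid19_has_symptoms",),
               ("covid19_has_symptoms",) + SYMPTOM_VARIABLES, _derive_symptoms),
        QCRule("derive_has_comorbidities", "derivation", ("has_comorbidities",),
               ("has_comorbidities",) + COMORBIDITY_VARIABLES, _derive_comorbidities),
    ]
    return tuple(rules)


# -- declarative user rules --------------------------------------------------

_OPS = {
    "eq": operator.eq,
    "ne": operator.ne,
    "lt": operator.lt,
    "le": operator.le,
    "gt": operator.gt,
    "ge": operator.ge,
}


def _eval_condition(cond: Mapping[str, Any], v: Mapping[str, Any]) -> bool | None:
    """Evaluate one declarative condition; None means undefined (skip)."""
    if "all" in cond:
        parts = [_eval_condition(c, v) for c in cond["all"]]
        return None if any(p is None for p in parts) else all(parts)
    if "any" in cond:
        parts = [_eval_condition(c, v) for c in cond["any"]]
        return None if any(p is None for p in parts) else any(parts)
    var = cond["var"]
    op = cond.get("op", "eq")
    left = v.get(var)
    if op == "is_null":
        return left is None
    if op == "not_null":
        return left is not None
    if left is None:
        return None
    right = v.get(cond["var2"]) if "var2" in cond else cond.get("value")
    if "var2" in cond and right is None:
        return None
    try:
        return bool(_OPS[op](left, right))
    except TypeError:
        return None


def _condition_vars(cond: Mapping[str, Any]) -> set[str]:
    if "all" in cond or "any" in cond:
        out: set[str] = set()
        for c in cond.get("all", cond.get("any", ())):
            out |= _condition_vars(c)
        return out
    out = {cond["var"]}
    if "var2" in cond:
        out.add(cond["var2"])
    return out


def load_rules(source: str | Path | Mapping[str, Any]) -> tuple[QCRule, ...]:
    """Load user-defined rules from the declarative YAML dialect.

    Each entry::

        - id: my_check
          kind: interdependency          # range|temporal|interdependency
          targets: [varA]
          fail_if: {all: [{var: varA, op: eq, value: "yes"},
                          {var: varB, op: lt, var2: varC}]}

    A condition with a missing operand is undefined and flags nothing.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        text = Path(source).read_text(encoding="utf-8") if (
            isinstance(source, Path) or (isinstance(source, str) and "\n" not in source and Path(source).exists())
        ) else str(source)
        doc = yaml.safe_load(text)
    rules = []
    for entry in doc.get("rules", []):
        cond = entry["fail_if"]
        targets = tuple(entry["targets"])

        def check(v: Mapping[str, Any], cond=cond, targets=targets) -> RuleOutcome:
            res = _eval_condition(cond, v)
            return RuleOutcome(fails=targets) if res else RuleOutcome()

        rules.append(
            QCRule(
                rule_id=str(entry["id"]),
                kind=str(entry.get("kind", "interdependency")),
                targets=targets,
                references=tuple(sorted(set(targets) | _condition_vars(cond))),
                check=check,
            )
        )
    return tuple(rules)


# -- engine ------------------------------------------------------------------


class RuleEngine:
    """Evaluates a rule set over dictionary-conformant records.

    Parameters
    ----------
    dictionary : DataDictionary, optional
        Defaults to the shipped core dictionary.
    rules : sequence of QCRule, optional
        Defaults to :func:`default_rules`.  Extra user rules are appended
        after the shipped ones (evaluation order within a kind is the
        registration order, which is fixed, so results do not depend on
        call-site ordering).
    strict_symptoms : bool
        Registers the strict symptom-contradiction check (default off:
        lenient mode derives but never fails).
    """

    def __init__(
        self,
        dictionary: DataDictionary | None = None,
        rules: Sequence[QCRule] | None = None,
        extra_rules: Sequence[QCRule] = (),
        strict_symptoms: bool = False,
    ) -> None:
        self.dictionary = dictionary or default_dictionary()
        base = tuple(rules) if rules is not None else default_rules(self.dictionary, strict_symptoms)
        self.rules = base + tuple(extra_rules)
        for rule in self.rules:
            for name in set(rule.references) | set(rule.targets):
                if name not in self.dictionary:
                    raise ConfigurationError(
                        f"rule {rule.rule_id!r} references unknown variable {name!r}"
                    )
        self._by_kind = {k: [r for r in self.rules if r.kind == k] for k in KIND_ORDER}

    def evaluate_record(self, record: PatientRecord) -> QCResult:
        values: dict[str, Any] = {name: record.values.get(name) for name in self.dictionary.names}
        flags: dict[str, QCFlag] = {
            name: (QCFlag.EMPTY if values[name] is None else QCFlag.PASS)
            for name in values
        }
        fired: list[tuple[str, str]] = []
        for kind in KIND_ORDER:
            for rule in self._by_kind[kind]:
                outcome = rule.check(values)
                for name in outcome.fails:
                    if values[name] is None:
                        continue  # only non-missing values can fail
                    values[name] = None
                    flags[name] = QCFlag.FAIL
                    fired.append((rule.rule_id, name))
                for name, filled in outcome.derived:
                    # derivations only fill inputs that were genuinely missing,
                    # never values blanked by a FAIL in this same pass
                    if values[name] is None and flags[name] is QCFlag.EMPTY:
                        values[name] = filled
                        flags[name] = QCFlag.PASS
                        fired.append((rule.rule_id, name))
        return QCResult(
            cleaned=record.with_values(values), flags=flags, fired_rules=tuple(fired)
        )

    def evaluate_records(self, records: Sequence[PatientRecord]) -> list[QCResult]:
        return [self.evaluate_record(r) for r in records]


# -- single-rule convenience wrappers (operate on one record) ---------------


def _flag_for(record: PatientRecord | Mapping[str, Any], variable: str,
              outcome: RuleOutcome) -> QCFlag:
    v = _values(record)
    if v.get(variable) is None:
        return QCFlag.EMPTY
    return QCFlag.FAIL if variable in outcome.fails else QCFlag.PASS


def rule_reporting_date(record: PatientRecord | Mapping[str, Any]) -> QCFlag:
    """Flag for covid19_date_reporting: FAIL iff its year precedes 2019."""
    return _flag_for(record, "covid19_date_reporting",
                     _check_reporting_date(_values(record)))


def rule_no_future_dates(
    record: PatientRecord | Mapping[str, Any],
    date_variables: Sequence[str] | None = None,
) -> dict[str, QCFlag]:
    """Flags for every date variable strictly later than the reporting date.

    If the reporting anchor is missing the rule is skipped and nothing is
    flagged (missing dates are EMPTY)."""
    v = _values(record)
    date_variables = tuple(date_variables or default_dictionary().date_variables)
    out = _check_no_future_dates(v, date_variables)
    return {
        name: (QCFlag.EMPTY if v.get(name) is None
               else QCFlag.FAIL if name in out.fails else QCFlag.PASS)
        for name in date_variables
        if name != "covid19_date_reporting"
    }


def rule_before_birth(
    record: PatientRecord | Mapping[str, Any],
    date_variables: Sequence[str] | None = None,
) -> dict[str, QCFlag]:
    """Flags for dates whose calendar year precedes reporting year minus age."""
    v = _values(record)
    date_variables = tuple(date_variables or default_dictionary().date_variables)
    out = _check_before_birth(v, date_variables)
    return {
        name: (QCFlag.EMPTY if v.get(name) is None
               else QCFlag.FAIL if name in out.fails else QCFlag.PASS)
        for name in date_variables
        if name != "covid19_date_reporting"
    }


def rule_covid_after_ms_baseline(
    record: PatientRecord | Mapping[str, Any],
) -> dict[str, QCFlag]:
    """MS onset must precede diagnosis and the suspected infection onset;
    COVID-19 dates must not precede the MS baseline dates."""
    v = _values(record)
    fails = set(_check_ms_onset_order(v).fails) | set(_check_covid_after_baseline(v).fails)
    return {
        name: (QCFlag.EMPTY if v.get(name) is None
               else QCFlag.FAIL if name in fails else QCFlag.PASS)
        for name in ("ms_onset_date", "covid19_suspected_onset")
    }


def rule_hospitalization_consistency(record: PatientRecord | Mapping[str, Any]) -> QCFlag:
    """FAIL iff hospital admission is 'yes' while the case is explicitly unconfirmed."""
    return _flag_for(record, "covid19_admission_hospital",
                     _check_hospitalization(_values(record)))


def rule_dmt_consistency(record: PatientRecord | Mapping[str, Any]) -> QCFlag:
    """FAIL iff an ongoing therapy is claimed while no therapy is named."""
    return _flag_for(record, "current_dmt", _check_dmt(_values(record)))


def derive_has_symptoms(
    record: PatientRecord | Mapping[str, Any], mode: str = "lenient"
) -> tuple[dict[str, Any], dict[str, QCFlag]]:
    """Fill an EMPTY covid19_has_symptoms from the nine symptom indicators.

    Returns ``(updates, flags)``; in strict mode an explicit 'no'
    contradicted by a named symptom is flagged FAIL instead.
    """
    v = dict(_values(record))
    flags: dict[str, QCFlag] = {}
    if mode == "strict":
        out = _check_symptom_contradiction(v)
        if out.fails:
            v["covid19_has_symptoms"] = None
            flags["covid19_has_symptoms"] = QCFlag.FAIL
            return {"covid19_has_symptoms": None}, flags
    out = _derive_symptoms(v)
    updates = dict(out.derived)
    for name in updates:
        flags[name] = QCFlag.PASS
    return updates, flags


def derive_has_comorbidities(record: PatientRecord | Mapping[str, Any]) -> dict[str, Any]:
    """Fill an EMPTY has_comorbidities with 'yes' when any comorbidity is 'yes'.

    Only the yes direction is defined; a null with no positive indicator
    stays EMPTY, and a non-missing value is never overwritten."""
    return dict(_derive_comorbidities(_values(record)).derived)


# -- summaries ---------------------------------------------------------------


@dataclass
class QCSummary:
    """Per-variable flag counts and per-rule fire counts over a batch."""

    n_records: int
    variable_counts: dict[str, dict[str, int]]
    rule_fires: dict[str, int]

    def to_frame(self):
        import pandas as pd

        rows = [
            {"variable": var, **counts} for var, counts in self.variable_counts.items()
        ]
        return pd.DataFrame(rows, columns=["variable", "PASS", "FAIL", "EMPTY"])


def qc_summary(results: Sequence[QCResult],
               dictionary: DataDictionary | None = None) -> QCSummary:
    """Tally PASS/FAIL/EMPTY per variable and fire counts per rule."""
    dictionary = dictionary or default_dictionary()
    counts: dict[str, Counter] = {name: Counter() for name in dictionary.names}
    fires: Counter = Counter()
    for res in results:
        for name, flag in res.flags.items():
            counts.setdefault(name, Counter())[flag.value] += 1
        for rule_id, _var in res.fired_rules:
            fires[rule_id] += 1
    return QCSummary(
        n_records=len(results),
        variable_counts={
            name: {"PASS": c.get("PASS", 0), "FAIL": c.get("FAIL", 0), "EMPTY": c.get("EMPTY", 0)}
            for name, c in counts.items()
        },
        rule_fires=dict(fires),
    )
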