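"""Quality-rule semantics: the printed core checks, derivations, invariants."""

import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from fedpipe.qc import (
    ConfigurationError,
    QCFlag,
    RuleEngine,
    derive_has_comorbidities,
    derive_has_symptoms,
    load_rules,
    qc_summary,
    rule_before_birth,
    rule_covid_after_ms_baseline,
    rule_dmt_consistency,
    rule_hospitalization_consistency,
    rule_no_future_dates,
    rule_reporting_date,
    SYMPTOM_VARIABLES,
)
from fedpipe.synthetic import GeneratorConfig, generate_sources

from conftest import BASELINE_VALUES, make_record


class TestPrintedRules:
    """Each shipped rule reproduces its stated outcome on the printed examples."""

    def test_age_above_110_fails_and_is_blanked(self, engine):
        res = engine.evaluate_record(make_record(age_years=120))
        assert res.flags["age_years"] is QCFlag.FAIL
        assert res.cleaned.values["age_years"] is None

    @pytest.mark.parametrize("age,flag", [(0, QCFlag.PASS), (110, QCFlag.PASS),
                                          (-1, QCFlag.FAIL), (111, QCFlag.FAIL)])
    def test_age_range_boundaries(self, engine, age, flag):
        res = engine.evaluate_record(make_record(age_years=age))
        assert res.flags["age_years"] is flag

    @pytest.mark.parametrize("edss,flag", [(4.5, QCFlag.PASS), (0.0, QCFlag.PASS),
                                           (10.0, QCFlag.PASS), (10.5, QCFlag.FAIL),
                                           (-0.5, QCFlag.FAIL)])
    def test_edss_range(self, engine, edss, flag):
        res = engine.evaluate_record(make_record(edss_value=edss))
        assert res.flags["edss_value"] is flag

    def test_reporting_date_before_2019_fails(self):
        assert rule_reporting_date(
            {"covid19_date_reporting": dt.date(2018, 12, 31)}) is QCFlag.FAIL
        assert rule_reporting_date(
            {"covid19_date_reporting": dt.date(2019, 1, 1)}) is QCFlag.PASS
        assert rule_reporting_date({"covid19_date_reporting": None}) is QCFlag.EMPTY

    def test_date_one_day_into_the_future_fails(self, engine):
        rep = BASELINE_VALUES["covid19_date_reporting"]
        res = engine.evaluate_record(
            make_record(ms_diagnosis_date=rep + dt.timedelta(days=1)))
        assert res.flags["ms_diagnosis_date"] is QCFlag.FAIL

    def test_dates_equal_to_reporting_date_pass(self, engine):
        rep = BASELINE_VALUES["covid19_date_reporting"]
        res = engine.evaluate_record(
            make_record(covid19_suspected_onset=rep, ms_diagnosis_date=rep))
        assert res.flags["covid19_suspected_onset"] is QCFlag.PASS
        assert res.flags["ms_diagnosis_date"] is QCFlag.PASS

    def test_future_rule_skipped_when_reporting_anchor_missing(self):
        flags = rule_no_future_dates(
            {"covid19_date_reporting": None,
             "ms_diagnosis_date": dt.date(2030, 1, 1)})
        assert flags["ms_diagnosis_date"] is QCFlag.PASS  # undefined -> no flag

    def test_date_before_birth_year_fails(self, engine):
        # reporting 2020, age 30 -> birth year 1990
        res = engine.evaluate_record(
            make_record(age_years=30, ms_onset_date=dt.date(1985, 5, 1),
                        ms_diagnosis_date=dt.date(2011, 6, 1)))
        assert res.flags["ms_onset_date"] is QCFlag.FAIL

    def test_birth_rule_uses_strict_year_comparison(self, engine):
        res = engine.evaluate_record(
            make_record(age_years=30, ms_onset_date=dt.date(1990, 1, 1),
                        ms_diagnosis_date=dt.date(2011, 6, 1)))
        assert res.flags["ms_onset_date"] is QCFlag.PASS

    def test_birth_rule_skipped_without_age(self):
        flags = rule_before_birth(
            {"covid19_date_reporting": dt.date(2020, 6, 1), "age_years": None,
             "ms_onset_date": dt.date(1900, 1, 1)})
        assert flags["ms_onset_date"] is QCFlag.PASS

    def test_onset_after_diagnosis_fails_onset(self, engine):
        res = engine.evaluate_record(
            make_record(ms_onset_date=dt.date(2015, 1, 1),
                        ms_diagnosis_date=dt.date(2010, 1, 1)))
        assert res.flags["ms_onset_date"] is QCFlag.FAIL
        assert res.cleaned.values["ms_onset_date"] is None
        assert res.flags["ms_diagnosis_date"] is QCFlag.PASS

    def test_consistent_onset_diagnosis_covid_ordering_passes(self, engine):
        res = engine.evaluate_record(make_record())
        assert res.flags["ms_onset_date"] is QCFlag.PASS
        assert res.flags["covid19_suspected_onset"] is QCFlag.PASS

    def test_covid_onset_before_ms_baseline_fails_covid_date(self):
        flags = rule_covid_after_ms_baseline(
            {"ms_onset_date": None, "ms_diagnosis_date": dt.date(2010, 1, 1),
             "covid19_suspected_onset": dt.date(2005, 1, 1)})
        assert flags["covid19_suspected_onset"] is QCFlag.FAIL

    @pytest.mark.parametrize(
        "hosp,confirmed,flag",
        [("yes", "no", QCFlag.FAIL), ("yes", "yes", QCFlag.PASS),
         ("no", "no", QCFlag.PASS)],
    )
    def test_hospitalization_requires_confirmation(self, hosp, confirmed, flag):
        assert rule_hospitalization_consistency(
            {"covid19_admission_hospital": hosp,
             "covid19_confirmed_case": confirmed}) is flag

    @pytest.mark.parametrize(
        "dmt,other,current,flag",
        [(None, None, "yes", QCFlag.FAIL), ("fingolimod", None, "yes", QCFlag.PASS),
         (None, None, "no", QCFlag.PASS), (None, "experimental", "yes", QCFlag.PASS)],
    )
    def test_claimed_therapy_must_be_named(self, dmt, other, current, flag):
        assert rule_dmt_consistency(
            {"type_dmt": dmt, "type_dmt_other": other, "current_dmt": current}) is flag


class TestDerivations:
    def test_empty_has_symptoms_with_positive_symptom_becomes_yes(self, engine):
        res = engine.evaluate_record(
            make_record(covid19_has_symptoms=None, covid19_sympt_fever="yes"))
        assert res.cleaned.values["covid19_has_symptoms"] == "yes"
        assert res.flags["covid19_has_symptoms"] is QCFlag.PASS
        assert ("derive_has_symptoms", "covid19_has_symptoms") in res.fired_rules

    def test_empty_has_symptoms_with_all_nine_negative_becomes_no(self, engine):
        overrides = {s: "no" for s in SYMPTOM_VARIABLES}
        res = engine.evaluate_record(
            make_record(covid19_has_symptoms=None, **overrides))
        assert res.cleaned.values["covid19_has_symptoms"] == "no"

    def test_partial_symptom_information_leaves_has_symptoms_empty(self, engine):
        overrides = {s: "no" for s in SYMPTOM_VARIABLES}
        overrides["covid19_sympt_pain"] = None
        res = engine.evaluate_record(
            make_record(covid19_has_symptoms=None, **overrides))
        assert res.cleaned.values["covid19_has_symptoms"] is None
        assert res.flags["covid19_has_symptoms"] is QCFlag.EMPTY

    def test_strict_mode_fails_contradicted_no(self, strict_engine):
        res = strict_engine.evaluate_record(
            make_record(covid19_has_symptoms="no", covid19_sympt_fatigue="yes"))
        assert res.flags["covid19_has_symptoms"] is QCFlag.FAIL
        assert res.cleaned.values["covid19_has_symptoms"] is None

    def test_lenient_mode_never_fails_the_contradiction(self, engine):
        res = engine.evaluate_record(
            make_record(covid19_has_symptoms="no", covid19_sympt_fatigue="yes"))
        assert res.flags["covid19_has_symptoms"] is QCFlag.PASS

    def test_derive_has_symptoms_wrapper_modes(self):
        updates, _ = derive_has_symptoms(
            {"covid19_has_symptoms": None, "covid19_sympt_fever": "yes"})
        assert updates == {"covid19_has_symptoms": "yes"}
        _, flags = derive_has_symptoms(
            {"covid19_has_symptoms": "no", "covid19_sympt_fever": "yes"},
            mode="strict")
        assert flags["covid19_has_symptoms"] is QCFlag.FAIL

    def test_comorbidity_yes_direction_only(self, engine):
        res = engine.evaluate_record(
            make_record(has_comorbidities=None, com_diabetes="yes"))
        assert res.cleaned.values["has_comorbidities"] == "yes"
        res = engine.evaluate_record(make_record(has_comorbidities=None))
        assert res.cleaned.values["has_comorbidities"] is None
        assert res.flags["has_comorbidities"] is QCFlag.EMPTY

    def test_derivation_never_overwrites_an_observed_value(self):
        assert derive_has_comorbidities(
            {"has_comorbidities": "no", "com_diabetes": "yes"}) == {}


class TestEngineInvariants:
    def test_all_missing_record_is_all_empty(self, engine, dictionary):
        rec = make_record(**{name: None for name in dictionary.names})
        res = engine.evaluate_record(rec)
        assert all(f is QCFlag.EMPTY for f in res.flags.values())
        assert dict(res.cleaned.values) == {n: None for n in dictionary.names}

    def test_rule_referencing_unknown_variable_fails_at_build_time(self, dictionary):
        rules = load_rules(
            {"rules": [{"id": "bad", "targets": ["age_years"],
                        "fail_if": {"var": "no_such_var", "op": "eq", "value": 1}}]}
        )
        with pytest.raises(ConfigurationError, match="no_such_var"):
            RuleEngine(dictionary, extra_rules=rules)

    def test_user_rule_in_declarative_dialect_fires(self, dictionary, engine):
        rules = load_rules(
            {"rules": [{"id": "edss_cap", "kind": "range", "targets": ["edss_value"],
                        "fail_if": {"all": [
                            {"var": "edss_value", "op": "gt", "value": 8.0},
                            {"var": "ms_type", "op": "eq",
                             "value": "relapsing_remitting"}]}}]}
        )
        custom = RuleEngine(dictionary, extra_rules=rules)
        res = custom.evaluate_record(make_record(edss_value=9.0))
        assert res.flags["edss_value"] is QCFlag.FAIL
        assert engine.evaluate_record(make_record(edss_value=9.0)).flags[
            "edss_value"] is QCFlag.PASS

    @given(
        age=st.one_of(st.none(), st.integers(-5, 130)),
        edss=st.one_of(st.none(), st.floats(-1, 12, allow_nan=False)),
        onset_year=st.one_of(st.none(), st.integers(1940, 2022)),
        diag_year=st.one_of(st.none(), st.integers(1940, 2022)),
        has_sympt=st.sampled_from([None, "yes", "no"]),
        fever=st.sampled_from([None, "yes", "no"]),
        hosp=st.sampled_from([None, "yes", "no"]),
        confirmed=st.sampled_from([None, "yes", "no"]),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_idempotence_and_fail_blanking(
        self, engine, age, edss, onset_year, diag_year, has_sympt, fever,
        hosp, confirmed,
    ):
        """A second evaluation of a cleaned record changes nothing and FAILed
        variables are always missing in the cleaned output."""
        rec = make_record(
            age_years=age,
            edss_value=edss,
            ms_onset_date=dt.date(onset_year, 3, 1) if onset_year else None,
            ms_diagnosis_date=dt.date(diag_year, 9, 1) if diag_year else None,
            covid19_has_symptoms=has_sympt,
            covid19_sympt_fever=fever,
            covid19_admission_hospital=hosp,
            covid19_confirmed_case=confirmed,
        )
        first = engine.evaluate_record(rec)
        for var, flag in first.flags.items():
            if flag is QCFlag.FAIL:
                assert first.cleaned.values[var] is None
        second = engine.evaluate_record(first.cleaned)
        assert dict(second.cleaned.values) == dict(first.cleaned.values)
        assert QCFlag.FAIL not in second.flags.values()

    def test_strict_mode_reevaluation_adds_no_new_fails(self, strict_engine):
        rec = make_record(covid19_has_symptoms="no", covid19_sympt_fever="yes")
        first = strict_engine.evaluate_record(rec)
        second = strict_engine.evaluate_record(first.cleaned)
        assert QCFlag.FAIL not in second.flags.values()

    def test_row_conservation_and_order_independence(self, engine, small_sources):
        sources, _ = small_sources
        records = [r for _, recs in sources for r in recs][:100]
        results = engine.evaluate_records(records)
        assert len(results) == len(records)
        reversed_results = engine.evaluate_records(records[::-1])
        for res, rev in zip(results, reversed_results[::-1]):
            assert dict(res.cleaned.values) == dict(rev.cleaned.values)
            assert res.flags == rev.flags


class TestSummary:
    def test_counts_tally_flags(self, engine, dictionary):
        results = engine.evaluate_records(
            [make_record(record_id="a"), make_record(record_id="b", age_years=120)]
        )
        summary = qc_summary(results, dictionary)
        assert summary.variable_counts["age_years"] == {"PASS": 1, "FAIL": 1, "EMPTY": 0}
        assert summary.rule_fires["age_out_of_range"] == 1

    def test_empty_input_gives_all_zeros(self, dictionary):
        summary = qc_summary([], dictionary)
        assert summary.n_records == 0
        assert all(
            counts == {"PASS": 0, "FAIL": 0, "EMPTY": 0}
            for counts in summary.variable_counts.values()
        )

    def test_injected_future_dates_are_all_detected(self, strict_engine):
        config = GeneratorConfig(
            n_per_source=(1000,), seed=42, error_rates={"future_date": 0.1}
        )
        sources, truth = generate_sources(config)
        n_injected = len(truth.errors)
        assert 60 <= n_injected <= 140  # binomial 99% interval around 100
        results = strict_engine.evaluate_records(sources[0][1])
        summary = qc_summary(results)
        assert summary.variable_counts["ms_diagnosis_date"]["FAIL"] == n_injected
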