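import datetime as dt

import pytest

from fedpipe.dictionary import PatientRecord, default_dictionary
from fedpipe.integration import default_scheme
from fedpipe.qc import RuleEngine
from fedpipe.synthetic import GeneratorConfig, generate_sources

#: an internally consistent record that passes every shipped rule
BASELINE_VALUES = {
    "covid19_date_reporting": dt.date(2020, 6, 15),
    "covid19_suspected_onset": dt.date(2020, 6, 5),
    "covid19_confirmed_case": "yes",
    "covid19_has_symptoms": "yes",
    "covid19_sympt_fever": "yes",
    "covid19_sympt_dry_cough": "no",
    "covid19_sympt_fatigue": "no",
    "covid19_sympt_pain": "no",
    "covid19_sympt_sore_throat": "no",
    "covid19_sympt_shortness_breath": "no",
    "covid19_sympt_nasal_congestion": "no",
    "covid19_sympt_loss_smell_taste": "no",
    "covid19_sympt_pneumonia": "no",
    "covid19_admission_hospital": "no",
    "covid19_icu_admission": "no",
    "covid19_ventilation": "no",
    "covid19_death": "no",
    "age_years": 40,
    "sex": "female",
    "ms_onset_date": dt.date(2010, 5, 1),
    "ms_diagnosis_date": dt.date(2011, 6, 1),
    "ms_type": "relapsing_remitting",
    "edss_value": 3.5,
    "current_dmt": "yes",
    "type_dmt": "fingolimod",
    "type_dmt_other": None,
    "has_comorbidities": "no",
    "com_hypertension": "no",
    "com_diabetes": "no",
    "com_cardiovascular_disease": "no",
    "com_chronic_lung_disease": "no",
    "com_obesity": "no",
}


def make_record(source_id="s1", record_id="r1", **overrides) -> PatientRecord:
    values = dict(BASELINE_VALUES)
    values.update(overrides)
    return PatientRecord(source_id=source_id, values=values, record_id=record_id)


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def engine(dictionary):
    return RuleEngine(dictionary)


@pytest.fixture(scope="session")
def strict_engine(dictionary):
    return RuleEngine(dictionary, strict_symptoms=True)


@pytest.fixture(scope="session")
def small_sources():
    """Three clean synthetic sources of 200 records each (fixed seed)."""
    config = GeneratorConfig(n_per_source=(200, 200, 200), seed=1)
    sources, truth = generate_sources(config)
    return sources, truth


@pytest.fixture(scope="session")
def cleaned_records(small_sources, engine):
    sources, _ = small_sources
    per_source = {
        sid: [res.cleaned for res in engine.evaluate_records(recs)]
        for sid, recs in sources
    }
    pooled = [rec for recs in per_source.values() for rec in recs]
    return per_source, pooled
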