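from datetime import date

import pandas as pd
import pytest

from ehrlink.codelib import (
    CodeEntry,
    Domain,
    DrugClass,
    SmokingTag,
    Specificity,
    SubtypeTag,
    Terminology,
    build_codelist,
)
from ehrlink.phenotype import CodedEvent, Source, StudyWindow


@pytest.fixture(scope="session")
def codelist():
    """Compact code list covering every branch the engine can take."""
    E = CodeEntry
    T, S, ST = Terminology, Specificity, SubtypeTag
    return build_codelist(
        [
            E(T.READ, "Eu02.", "Unspecified dementia", Domain.DEMENTIA, S.HIGH, ST.UNSPECIFIED),
            E(T.READ, "Eu00.", "Alzheimer's dementia", Domain.DEMENTIA, S.HIGH, ST.ALZHEIMERS_MIXED),
            E(T.READ, "Eu01.", "Vascular dementia", Domain.DEMENTIA, S.HIGH, ST.VASCULAR),
            E(T.SNOMED, "52448006", "Dementia", Domain.DEMENTIA, S.HIGH, ST.UNSPECIFIED),
            E(T.READ, "LOW1.", "Memory loss", Domain.DEMENTIA, S.LOW),
            E(T.READ, "LOW2.", "Delirium with dementia features", Domain.DEMENTIA, S.LOW),
            E(T.SNOMED, "111000", "Cognitive decline", Domain.DEMENTIA, S.LOW),
            E(T.ICD10, "F00", "Alzheimer's disease dementia", Domain.DEMENTIA, S.HIGH, ST.ALZHEIMERS_MIXED),
            E(T.ICD10, "F01", "Vascular dementia", Domain.DEMENTIA, S.HIGH, ST.VASCULAR),
            E(T.ICD10, "F03", "Unspecified dementia", Domain.DEMENTIA, S.HIGH, ST.UNSPECIFIED),
            E(T.READ, "CHF..", "Heart failure", Domain.COMORBIDITY, condition="chf", weight=2),
            E(T.READ, "CHF2.", "Heart failure follow-up", Domain.COMORBIDITY, condition="chf", weight=2),
            E(T.READ, "COPD.", "COPD", Domain.COMORBIDITY, condition="copd", weight=1),
            E(T.READ, "MET..", "Metastatic cancer", Domain.COMORBIDITY, condition="metastatic", weight=6),
            E(T.READ, "137R.", "Current smoker", Domain.SMOKING, smoking_tag=SmokingTag.CURRENT),
            E(T.READ, "137S.", "Ex-smoker", Domain.SMOKING, smoking_tag=SmokingTag.FORMER),
            E(T.READ, "1372.", "Never smoked", Domain.SMOKING, smoking_tag=SmokingTag.NEVER),
            E(T.SNOMED, "999000", "Donepezil", Domain.MEDICATION, drug_class=DrugClass.ACHEI),
        ],
        name="test-codelist",
        version="1",
    )


@pytest.fixture(scope="session")
def window():
    return StudyWindow()


def make_event(pid, source, terminology, code, d):
    return CodedEvent(
        patient_id=pid,
        source=Source(source),
        terminology=Terminology(terminology),
        code=code,
        event_date=d if isinstance(d, date) else date.fromisoformat(d),
    )


def events_frame(events):
    """CodedEvent list -> the events DataFrame schema build_cohort expects."""
    return pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in events],
            "source": [e.source.value for e in events],
            "terminology": [e.terminology.value for e in events],
            "code": [e.code for e in events],
            "event_date": [pd.Timestamp(e.event_date) for e in events],
        }
    )


@pytest.fixture()
def mk_event():
    return make_event
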