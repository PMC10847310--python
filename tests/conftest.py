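"""Shared fixtures: toy dictionaries, hand-built case tables, tmp FAERS files."""

import pandas as pd
import pytest
from hypothesis import settings

from pvkit import DrugDictionary, PartialDate, Vocabulary
from pvkit.cleaning import CASE_COLUMNS, CaseDrug

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def dictionary():
    return DrugDictionary(
        {
            "trastuzumab": ["HERCEPTIN"],
            "pertuzumab": ["PERJETA"],
            "TDM-1": ["KADCYLA", "ADO-TRASTUZUMAB EMTANSINE", "TRASTUZUMAB EMTANSINE"],
            "lapatinib": ["TYKERB"],
        }
    )


@pytest.fixture
def vocabulary():
    return Vocabulary(
        {
            "Cerebral haemorrhage": "Nervous system disorders",
            "Headache": "Nervous system disorders",
            "Gastrointestinal haemorrhage": "Gastrointestinal disorders",
            "Diarrhoea": "Gastrointestinal disorders",
            "Cardiac failure": "Cardiac disorders",
            "Thrombocytopenia": "Blood and lymphatic system disorders",
        }
    )


def make_case(
    primaryid,
    caseid=None,
    exposure=(),
    reactions=(),
    outcomes=(),
    age_years=None,
    sex="F",
    country="US",
    fda_dt=PartialDate(2020, 6, 1),
    event_dt=None,
    drugs=None,
):
    """One assembled-case row; drugs defaults to one PS record per exposure."""
    if drugs is None:
        drugs = tuple(
            CaseDrug(name, name, "PS" if i == 0 else "SS", None)
            for i, name in enumerate(sorted(exposure))
        )
    return {
        "primaryid": primaryid,
        "caseid": caseid if caseid is not None else primaryid,
        "fda_dt": fda_dt,
        "event_dt": event_dt,
        "age_years": age_years,
        "sex": sex,
        "country": country,
        "outcomes": frozenset(outcomes),
        "reactions": frozenset(reactions),
        "reactions_folded": frozenset(r.casefold() for r in reactions),
        "drugs": tuple(drugs),
        "exposure": frozenset(exposure),
    }


def make_cases(rows):
    return pd.DataFrame(rows, columns=CASE_COLUMNS)


@pytest.fixture
def toy_cases():
    """Six cases: the hand-countable drug-event toy set.

    Two TDM-1 cases with Cerebral haemorrhage, one without; one unexposed
    case with the event, two without -> (a, b, c, d) = (2, 1, 1, 2).
    """
    return make_cases(
        [
            make_case(1, exposure={"TDM-1"}, reactions={"Cerebral haemorrhage"}),
            make_case(2, exposure={"TDM-1"}, reactions={"Cerebral haemorrhage", "Nausea"}),
            make_case(3, exposure={"TDM-1"}, reactions={"Diarrhoea"}),
            make_case(4, exposure={"trastuzumab"}, reactions={"Cerebral haemorrhage"}),
            make_case(5, exposure={"trastuzumab"}, reactions={"Headache"}),
            make_case(6, exposure=set(), reactions={"Diarrhoea"}),
        ]
    )


DEMO_TEXT = "\n".join(
    [
        "primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$country",
        "1001$100$20200301$20200210$55$YR$F$US",
        "1000$100$20200101$$60$YR$F$US",
        "1010$101$20200401$202003$$$M$GB",
        "1020$102$20210115$20210101$660$MON$F$JP",
        "1030$103$20210601$$6.3$DEC$$CN",
    ]
)

DRUG_TEXT = "\n".join(
    [
        "primaryid$drug_seq$role_cod$drugname$prod_ai",
        "1001$1$PS$HERCEPTIN$",
        "1001$2$SS$PERJETA$PERTUZUMAB",
        "1001$3$C$PACLITAXEL$",
        "1010$1$PS$unknown tablet$ADO-TRASTUZUMAB EMTANSINE",
        "1020$1$PS$Herceptin$TRASTUZUMAB",
        "1020$2$SS$trastuzumab$",
        "1030$1$PS$TYKERB$",
    ]
)

REAC_TEXT = "\n".join(
    [
        "primaryid$pt",
        "1001$Cerebral haemorrhage",
        "1001$Diarrhoea",
        "1010$Thrombocytopenia",
        "1020$Cardiac failure",
        "1030$Diarrhoea",
        "9999$Headache",
    ]
)

OUTC_TEXT = "\n".join(
    [
        "primaryid$outc_cod",
        "1001$HO",
        "1010$DE",
        "1030$OT",
    ]
)

THER_TEXT = "\n".join(
    [
        "primaryid$dsg_drug_seq$start_dt$end_dt",
        "1001$1$20200101$",
        "1001$2$202002$",
        "1010$1$20200301$20200401",
        "1030$1$2021$",
    ]
)


@pytest.fixture
def faers_dir(tmp_path):
    """A miniature five-table FAERS extract with known quirks."""
    for name, text in [
        ("DEMO", DEMO_TEXT),
        ("DRUG", DRUG_TEXT),
        ("REAC", REAC_TEXT),
        ("OUTC", OUTC_TEXT),
        ("THER", THER_TEXT),
    ]:
        (tmp_path / f"{name}.txt").write_text(text + "\n")
    return tmp_path
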