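import numpy as np
import pandas as pd
import pytest

from settlescan.schema import derive_flags, expand_to_individuals
from settlescan.simulate import default_config, simulate


@pytest.fixture(scope="session")
def survey():
    """One default two-site synthetic survey, shared across tests."""
    return simulate(default_config(), seed=11)


@pytest.fixture(scope="session")
def analysis_rows(survey):
    return expand_to_individuals(survey.households, survey.individuals)


@pytest.fixture(scope="session")
def flags(survey):
    return derive_flags(survey.households)


def make_households(records):
    """Small literal household table with schema-conformant dtypes."""
    df = pd.DataFrame(records)
    for c in ["indoor_cooking", "water_constant_past_month",
              "head_secondary_education", "relatively_wealthy"]:
        if c in df.columns:
            df[c] = df[c].astype("boolean")
    return df


def household_record(i=0, site="s1", lon=-4.0, lat=5.3, **overrides):
    rec = dict(
        household_id=f"{site}-H{i:03d}", site_id=site, lon=lon, lat=lat,
        wall_material="finished_brick", roof_material="metal_sheet",
        floor_material="cement", n_rooms=2, n_members=3, indoor_cooking=True,
        water_source_code="piped_on_premises", sanitation_code="flush_to_septic",
        hygiene_code="handwashing_water_soap", water_constant_past_month=True,
        head_secondary_education=True, relatively_wealthy=False,
    )
    rec.update(overrides)
    return rec


def roster_for(households):
    """Minimal healthy roster matching each household's n_members."""
    rows = []
    for _, hh in households.iterrows():
        for j in range(int(hh["n_members"])):
            rows.append(dict(person_id=f"{hh['household_id']}-P{j}",
                             household_id=hh["household_id"],
                             under5=j == 0, female=j % 2 == 0, diarrhea_2wk=False))
    df = pd.DataFrame(rows)
    for c in ["under5", "female", "diarrhea_2wk"]:
        df[c] = df[c].astype("boolean")
    return df
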