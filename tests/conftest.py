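import pandas as pd
import pytest

import egsnet as eg


@pytest.fixture(scope="session")
def codes():
    return eg.default_codeset()


@pytest.fixture(scope="session")
def comorbidity():
    return eg.default_comorbidity_map()


@pytest.fixture(scope="session")
def small_world(codes, comorbidity):
    """A small simulated claims world shared across read-only tests."""
    cfg = eg.SimulationConfig(n_hospitals=40, n_patients=4000, seed=7)
    hospitals, encounters, truth = eg.simulate(cfg, codes, comorbidity)
    return cfg, hospitals, encounters, truth


@pytest.fixture(scope="session")
def small_world_linked(small_world, codes, comorbidity):
    cfg, hospitals, encounters, truth = small_world
    episodes = eg.build_episodes(encounters, codes)
    cohort = eg.filter_transfer_cohort(episodes)
    transfers = eg.transfers_frame(cohort)
    return cfg, hospitals, encounters, truth, episodes, cohort, transfers


def mk_encounter(
    patient_id="P1",
    hospital_id="A",
    setting="IP",
    admit="2016-03-01",
    discharge="2016-03-03",
    age=60,
    sex="M",
    dx=(),
    proc=(),
    died=False,
    state="NY",
):
    """Hand-build an Encounter from calendar dates."""
    return eg.Encounter(
        patient_id=patient_id,
        hospital_id=hospital_id,
        state=state,
        setting=setting,
        admit_day=pd.Timestamp(admit).toordinal(),
        discharge_day=pd.Timestamp(discharge).toordinal(),
        age=age,
        sex=sex,
        dx_codes=frozenset(dx),
        proc_codes=frozenset(proc),
        died=died,
    )
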