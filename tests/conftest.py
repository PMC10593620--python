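import datetime as dt

import numpy as np
import pytest

import cagerhythm as cr

# master seed for the simulated study cohort shared across tests
STUDY_SEED = 7


@pytest.fixture(scope="session")
def schedule():
    return cr.LightSchedule()


@pytest.fixture(scope="session")
def study_design():
    """The study calendar: 12+12 animals, 4 baseline + 12 dosing + 13 discontinuation days."""
    return cr.default_study_design()


@pytest.fixture(scope="session")
def group_params():
    return {g: cr.default_sim_params(g) for g in ("saline", "paroxetine")}


@pytest.fixture(scope="session")
def study_cohort(study_design, group_params):
    return cr.simulate_cohort(group_params, study_design, STUDY_SEED)


@pytest.fixture(scope="session")
def study_tables(study_cohort):
    """Per-day (uncollapsed) tidy tables for the simulated study cohort."""
    return cr.summarize_cohort(study_cohort, collapse=False)


@pytest.fixture
def tiny_design():
    """Two animals, 1 baseline + 1 dosing + 1 discontinuation day."""
    return cr.StudyDesign(
        groups={"a": "saline", "b": "saline"},
        baseline_days=1,
        dosing_days=1,
        discontinuation_days=1,
        start_date=dt.date(2021, 6, 1),
    )


def make_annotated(activity, schedule=None, design=None, animal_id="a", start=None):
    """Annotated trace starting at lights-on of the first baseline day."""
    schedule = schedule or cr.LightSchedule()
    if design is None:
        n_days = max(1, int(np.ceil(len(activity) / 8640)))
        design = cr.StudyDesign(
            groups={animal_id: "saline"},
            baseline_days=1,
            dosing_days=max(0, n_days - 1),
            discontinuation_days=0,
            start_date=dt.date(2021, 6, 1),
        )
    start = start or dt.datetime.combine(dt.date(2021, 6, 1), schedule.lights_on)
    trace = cr.PIRTrace(animal_id, start, np.asarray(activity, dtype=float))
    return cr.assign_zeitgeber(trace, schedule, design)
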