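import numpy as np
import pytest

import rollmetrics as rm
from rollmetrics.course import CourseSection


@pytest.fixture(scope="session")
def course():
    return rm.build_course()


@pytest.fixture(scope="session")
def mini_course():
    """Two-section 160 m course: keeps simulated runs short (~150 s) while
    still exercising both trigger pentads and the full stage chain."""
    return rm.build_course(
        [
            CourseSection(1, 0.0, 80.0, 1.0, 0.20, 0.0, 6.0, -18.0, 8.0),
            CourseSection(2, 80.0, 80.0, 1.2, 0.25, 2.0, 7.0, -20.0, 8.0),
        ]
    )


@pytest.fixture(scope="session")
def contrast_course():
    """Course identical everywhere except the section 1 vs 13 speed
    contrast (0.8 vs 1.81 m/s, SDs 0.23/0.64)."""
    lens = [47, 124, 99, 55, 39, 43, 74, 40, 50, 98, 30, 48, 42]
    rows, start = [], 0.0
    for i, ln in enumerate(lens):
        if i == 0:
            v, sd = 0.80, 0.23
        elif i == 12:
            v, sd = 1.81, 0.64
        else:
            v, sd = 1.20, 0.30
        rows.append(CourseSection(i + 1, start, float(ln), v, sd, 0.0, 6.0, -18.0, 8.0))
        start += ln
    return rm.build_course(rows)


@pytest.fixture(scope="session")
def noise_free_run():
    """Fully compliant participant, analytic noise-free limit."""
    return rm.simulate_run(
        profile=rm.ParticipantProfile("P1", compliance_lambda=1.0),
        seed=1,
        options=rm.SimulationOptions.noise_free(),
    )


@pytest.fixture(scope="session")
def noise_free_processed(noise_free_run):
    return rm.process_run(noise_free_run, rm.PipelineConfig(cop_smooth_m=0.0))


@pytest.fixture(scope="session")
def cohort_runs():
    """Seven realistic full-course runs (default profiles, one seed)."""
    return [rm.simulate_run(profile=p, seed=7) for p in rm.DEFAULT_PROFILES]


@pytest.fixture(scope="session")
def cohort_processed(cohort_runs):
    processed, cohort = rm.run_pipeline(cohort_runs)
    return processed, cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
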