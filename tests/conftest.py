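"""Shared fixtures.

Heavy simulation products (cohort run, high-count respiratory simulation)
are session-scoped so acceptance and unit tests share one computation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import mocospect.pipeline as pl
from mocospect.acquisition import AcquisitionSpec, acquire_listmode, expected_phase_projections
from mocospect.phantom import PhantomSpec, TumorSpec, dome_cohort, generate_phase_set

COHORT_SEED = 7


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(
        grid_shape=(32, 32, 32),
        spacing_mm=(6.0, 6.0, 6.0),
        tumors=[TumorSpec((-12.0, 0.0, -32.0), 15.0, 4.0)],
        motion_amplitude_mm=(0.0, 0.0, 12.0),
    )


@pytest.fixture(scope="session")
def resp_sim(small_spec):
    """High-count 8-phase simulation for respiratory-signal tests."""
    phantom = generate_phase_set(small_spec, 8)
    acq = AcquisitionSpec(n_projections=24)
    projector = acq.projector(phantom.grid)
    primary, scatter = expected_phase_projections(phantom, acq, projector)
    dwell = acq.time_per_projection_s / 8
    scale = 4.0e6 / ((primary.sum() + scatter.sum()) * dwell)
    lm = acquire_listmode(
        phantom, acq, seed=2, projector=projector,
        expected=(primary * scale, scatter * scale),
    )
    return {
        "phantom": phantom,
        "acq": acq,
        "projector": projector,
        "lm": lm,
        "expected": (primary * scale, scatter * scale),
    }


@pytest.fixture(scope="session")
def dome_report() -> pl.CohortReport:
    """Seeded 10-phantom dome-lesion cohort run through the full pipeline."""
    specs = dome_cohort(10, COHORT_SEED)
    cfg = pl.desk_config(n_patients=10, ct_phase=0)
    cfg.seed = COHORT_SEED
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pl.run_cohort(cfg, specs)


@pytest.fixture(scope="session")
def zero_motion_record() -> dict:
    spec = PhantomSpec(
        grid_shape=(32, 32, 32),
        spacing_mm=(6.0, 6.0, 6.0),
        tumors=[TumorSpec((-12.0, 0.0, -32.0), 15.0, 4.0)],
        motion_amplitude_mm=(0.0, 0.0, 0.0),
    )
    cfg = pl.desk_config(n_patients=1, ct_phase=0)
    cfg.seed = 11
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pl.run_patient(spec, cfg, 0)
    assert res.failure_stage is None, res.record.get("error")
    return res.record


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
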