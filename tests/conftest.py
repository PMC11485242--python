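"""Shared fixtures: small synthetic patients analysed once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chronolfp.clinical import day_labels
from chronolfp.ingest import bin_daily, condition_series, zscore_daily
from chronolfp.simulate import ArtifactSpec, PatientSimParams, simulate_patient

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


def _prepare(bundle, hemi="L"):
    conditioned, report = condition_series(bundle.series[hemi])
    matrix = zscore_daily(bin_daily(conditioned,
                                    bundle.trajectory.dbs_activation_date))
    states = day_labels(bundle.trajectory.intervals, matrix.days)
    states = states[states["state"] != "unlabeled"].reset_index(drop=True)
    return matrix, states, report


@pytest.fixture(scope="session")
def responder_bundle():
    params = PatientSimParams(patient_id="R001", responder=True)
    return simulate_patient(params, ArtifactSpec(), seed=1)


@pytest.fixture(scope="session")
def nonresponder_bundle():
    params = PatientSimParams(patient_id="N001", responder=False)
    return simulate_patient(params, ArtifactSpec(), seed=2)


@pytest.fixture(scope="session")
def responder_prepared(responder_bundle):
    return _prepare(responder_bundle)


@pytest.fixture(scope="session")
def nonresponder_prepared(nonresponder_bundle):
    return _prepare(nonresponder_bundle)


@pytest.fixture(scope="session")
def clean_patient_series():
    """Artifact-free, drift-free patient for exact-structure checks."""
    params = PatientSimParams(patient_id="C001", responder=True,
                              drift_per_day=0.0)
    return simulate_patient(params, ArtifactSpec.none(), seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
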