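"""Shared fixtures: one noiseless default synthetic run reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from silkmech.pipeline import analyze_record
from silkmech.simulate import EnvelopeModel, FiberModelParams, generate_test


@pytest.fixture(scope="session")
def default_params() -> FiberModelParams:
    return FiberModelParams()


@pytest.fixture(scope="session")
def default_envelope(default_params) -> EnvelopeModel:
    return EnvelopeModel(default_params)


@pytest.fixture(scope="session")
def default_run(default_params):
    """(record, ground truth, analysis result) of the noiseless default test."""
    record, truth = generate_test(default_params)
    result = analyze_record(record, default_params.geometry)
    return record, truth, result


def make_curve(strain, stress, **kw):
    from silkmech.kinematics import TrueCurve

    return TrueCurve(np.asarray(strain, dtype=float), np.asarray(stress, dtype=float), **kw)
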