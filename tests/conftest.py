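from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stygodiv as sg

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> sg.SimulationParams:
    return sg.SimulationParams(seed=7)


@pytest.fixture(scope="session")
def study(default_params) -> sg.StudyData:
    """One complete simulated study shared across test modules."""
    return sg.simulate_study(default_params)


@pytest.fixture(scope="session")
def corrected_study(study):
    corrected, thr, reports, controls = sg.decontaminate(study.table)
    return corrected, thr, reports, controls


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_records(rng: np.random.Generator, n: int, length: int = 60):
    """Random valid sequence records, species-labelled every other one."""
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = []
    for i in range(n):
        seq = alphabet[rng.integers(0, 4, size=length)].tobytes().decode()
        out.append(
            sg.SequenceRecord(
                id=f"seq{i}",
                sequence=seq,
                species=f"Species {i % 5}" if i % 2 == 0 else None,
            )
        )
    return out
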