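"""Shared fixtures.

The flow and FSI benchmarks are expensive (seconds to minutes); they
run once per session and every test that needs them reads from the
same result dict.
"""

from __future__ import annotations

import numpy as np
import pytest

from valvefsi.bench import (
    run_elastic_gate_benchmark,
    run_hydrostatic_benchmark,
    run_lv_conservation,
    run_poiseuille_benchmark,
    run_tube_valve_protocol,
)


@pytest.fixture(scope="session")
def hydrostatic_result():
    return run_hydrostatic_benchmark()


@pytest.fixture(scope="session")
def poiseuille_result():
    return run_poiseuille_benchmark()


@pytest.fixture(scope="session")
def gate_result():
    return run_elastic_gate_benchmark()


@pytest.fixture(scope="session")
def tube_valve_result():
    return run_tube_valve_protocol()


@pytest.fixture(scope="session")
def lv_result():
    return run_lv_conservation()


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
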