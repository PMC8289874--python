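"""Shared fixtures.

The expensive Langevin ensembles are session-scoped so the physics
acceptance checks and unit tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from ejectsim import SystemParams, predicted_exponents
from ejectsim.fixtures import tiny_md_configs
from ejectsim.simulator import run_ensemble


@pytest.fixture(scope="session")
def theory_2d():
    return predicted_exponents(2)


@pytest.fixture(scope="session")
def md_configs():
    return tiny_md_configs()


@pytest.fixture(scope="session")
def ens16_translocation():
    """N=16 translocation ensemble (D = inf), ~50 runs; the reference case
    where the whole process is a barrier crossing driven by chain entropy."""
    params = SystemParams(N=16, phi0=0.0)
    res = run_ensemble(params, n_runs=48, base_seed=2024,
                       equilibration=50.0, step_budget=20_000_000)
    assert len(res.completed) >= 40, "translocation ensemble mostly censored"
    return params, res


@pytest.fixture(scope="session")
def ens8_cavity():
    """Small confined ensemble (N=8, phi0=0.15) for end-to-end smoke tests."""
    params = SystemParams(N=8, phi0=0.15)
    res = run_ensemble(params, n_runs=6, base_seed=77, equilibration=30.0,
                       step_budget=20_000_000)
    assert len(res.completed) >= 4
    return params, res


@pytest.fixture(scope="session")
def equipartition_measurement():
    """<v^2> per component of a free thermostatted bead at kT = m = 1,
    measured over ~3M steps (expected 1.0; sampling SE ~0.6%)."""
    from ejectsim import _kernels as K

    pos = np.zeros((1, 3))
    vel = np.zeros((1, 3))
    ev = np.empty(0)
    evi = np.empty(0, dtype=np.int64)
    seeds = np.random.SeedSequence(7).generate_state(6000) % (2**31 - 1)
    acc = 0.0
    cnt = 0
    for k, s in enumerate(seeds):
        K.run_md(pos, vel, 1.0, 0.005, 1.0, 1.0, int(s), 500, 0,
                 1.0, 1.0, 600.0, 1.0, 3.0, 1.0,
                 -1e9, 1e9, 0.0, -1.0, 1e8, -1e8, 2e9, 1e9, 2e9,
                 False, 0.0, ev, evi, evi)
        if k >= 50:
            acc += float(np.sum(vel**2))
            cnt += 3
    return acc / cnt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
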