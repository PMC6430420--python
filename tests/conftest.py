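"""Shared fixtures.

The heavy network fixtures (multi-seed deprivation battery, threshold-
jitter sweep) are session-scoped: one development phase per seed is
shared across all deprivation paradigms.
"""
from __future__ import annotations

import numpy as np
import pytest

from odplast.params import Deprivation, ModelParams, Stage
from odplast.protocols import (
    develop_network,
    jitter_thresholds,
    run_deprivation,
    simplified_battery,
)

N_SEEDS = 50
KINDS = (Deprivation.MD_CL, Deprivation.MD_IL, Deprivation.BD, Deprivation.MI)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def simplified_double():
    """Shared-seed simplified battery, double-threshold rule."""
    from odplast.params import EEMode
    return simplified_battery(seed=1, ee_mode=EEMode.DOUBLE)


@pytest.fixture(scope="session")
def simplified_single():
    from odplast.params import EEMode
    return simplified_battery(seed=1, ee_mode=EEMode.SINGLE)


@pytest.fixture(scope="session")
def developed_cp(params):
    """One critical-period network developed for 50 s (seed 1)."""
    return develop_network(seed=1, params=params)


@pytest.fixture(scope="session")
def network_battery_results(params):
    """All four deprivations over N_SEEDS seeds, one development per seed."""
    out = {kind: [] for kind in KINDS}
    for seed in range(1, N_SEEDS + 1):
        dev = develop_network(seed=seed, params=params)
        for kind in KINDS:
            out[kind].append(run_deprivation(dev, kind))
    return out


@pytest.fixture(scope="session")
def jitter_sweep_results(params):
    """Population ODI shifts under 5% threshold jitter, 50 repeats."""
    return jitter_thresholds(seed=7, n_repeats=N_SEEDS, jitter_sd=0.05,
                             params=params)


@pytest.fixture(scope="session")
def mdcl_with_inh_trace(developed_cp):
    """MD-CL run with periodic inhibitory-response probes."""
    return run_deprivation(developed_cp, Deprivation.MD_CL, probe_every_ms=2000)


@pytest.fixture(scope="session")
def stage_results(params):
    """Pre-CP and adult MD-CL outcomes (seed 1)."""
    out = {}
    for stage in (Stage.PRE_CP, Stage.ADULT):
        dev = develop_network(seed=1, stage=stage, params=params)
        out[stage] = run_deprivation(dev, Deprivation.MD_CL)
    return out
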