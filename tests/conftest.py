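"""Shared fixtures: simulated patients and plausibility-filtered pools.

The expensive objects (ODE-simulated cohorts) are session-scoped and shared
across test modules; everything is generated programmatically from seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from bsabqsp import vpop
from bsabqsp.kinetics import PatientModel
from bsabqsp.params import InitialState, PatientParameters
from bsabqsp.regimens import two_step_priming


@pytest.fixture(scope="session")
def default_model() -> PatientModel:
    return PatientModel(PatientParameters(), InitialState())


@pytest.fixture(scope="session")
def primed_result(default_model):
    """Default patient under two-step priming + 76 mg QW, 6 cycles."""
    return default_model.simulate(two_step_priming(), horizon=168.0)


@pytest.fixture(scope="session")
def small_pool() -> vpop.PlausiblePool:
    """~120-patient plausible pool with the registrational regimen cached."""
    cand = vpop.sample_trial_patients(180, seed=7)
    return vpop.plausibility_filter(
        cand, regimen_ids=("two_step_priming_76qw",))


@pytest.fixture(scope="session")
def calibration_pool() -> vpop.PlausiblePool:
    """Reduced calibration-scale pool (shared by the acceptance checks)."""
    cand = vpop.sample_trial_patients(800, seed=11)
    return vpop.plausibility_filter(
        cand, regimen_ids=("two_step_priming_76qw",))


@pytest.fixture(scope="session")
def calibrated_vpop(calibration_pool):
    """One VPop of 120 selected against the registrational-cohort targets."""
    from bsabqsp import synthetic
    targets = synthetic.default_targets().subset(["two_step_priming_76qw"])
    return vpop.genetic_select(calibration_pool, targets, size=120, seed=0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
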