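import numpy as np
import pytest
from hypothesis import settings

import nanotoxkin as nk

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def medium_22c() -> nk.MediumState:
    return nk.MediumState.from_celsius(22.0)


@pytest.fixture(scope="session")
def condition_22c_5ug() -> nk.ExperimentCondition:
    return nk.ExperimentCondition.from_lab_units(22.0, 5.0)


@pytest.fixture(scope="session")
def pair_system(medium_22c) -> nk.PairDiffusionSystem:
    """Standard assay geometry: 5 um cell + 35 nm particle at 22 degC."""
    cell, particle = nk.CellSpec(), nk.ParticleSpec()
    return nk.PairDiffusionSystem.from_species(
        cell, particle, medium_22c, far_field_concentration=3.98e16
    )


@pytest.fixture(scope="session")
def oracle_solution(pair_system):
    """One shared finite-difference solve out to 10 R^2/D with a snapshot
    at R^2/D, reused by the profile and flux comparisons."""
    tau = pair_system.diffusion_time
    return nk.radial_diffusion_oracle(
        pair_system, horizon=10.0 * tau, snapshot_times=(tau,)
    )


@pytest.fixture(scope="session")
def noise_free_timecourse(medium_22c, condition_22c_5ug):
    """Eight-point noise-free series generated with P2 = 0.106 at 22 degC."""
    aod = nk.AodSurvivalModel(0.106)
    times = np.array([5.0, 10.0, 30.0, 60.0, 90.0, 120.0, 150.0, 210.0])
    frac = nk.predict_timecourse(times * 60.0, condition_22c_5ug, medium_22c, aod)
    return nk.DamageTimeCourse(
        time_min=times,
        fraction=frac,
        temperature=condition_22c_5ug.temperature,
        nanoparticle_density=condition_22c_5ug.nanoparticle_density,
        label="noise_free_p2_0.106",
    )
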