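import numpy as np
import pytest

from nodulemech import (
    CohortSpec,
    CrushCurveParams,
    MachineSpec,
    NoduleRecord,
    noise_free,
    simulate_cohort,
    simulate_crush_curve,
)


@pytest.fixture
def geometry():
    return NoduleRecord(nodule_id="fix1", a0_mm2=10.0, h0_mm=3.0)


@pytest.fixture
def plateau_params():
    """Noise-free ideal three-phase curve with a clean unit plateau."""
    return noise_free(
        CrushCurveParams(
            pattern="three_phase",
            elastic_modulus_mpa=10.0,
            yield_strain=0.1,
            plateau_stress_mpa=1.0,
            drop_rate=0.0,
        )
    )


@pytest.fixture
def gradual_params():
    return noise_free(
        CrushCurveParams(pattern="gradual", gradual_scale_mpa=4.0, gradual_power=2.0)
    )


@pytest.fixture
def plateau_recording(plateau_params, geometry):
    return simulate_crush_curve(plateau_params, geometry, seed=1)


@pytest.fixture
def gradual_recording(gradual_params, geometry):
    return simulate_crush_curve(gradual_params, geometry, seed=2)


#: Coarse machine spec for property tests over many curves (10x the default
#: sampling interval keeps each recording ~450 samples).
COARSE_MACHINE = MachineSpec(sampling_interval_ms=200.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-nodule cohort at default machine cadence (session-cached)."""
    return simulate_cohort(CohortSpec(n_nodules=40, seed=123))


@pytest.fixture(scope="session")
def property_cohort():
    """1000 random simulator curves at coarse cadence for invariant sweeps."""
    return simulate_cohort(
        CohortSpec(n_nodules=1000, machine=COARSE_MACHINE, seed=321)
    )


def rng_values(seed, n):
    return np.random.default_rng(seed).random(n)
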