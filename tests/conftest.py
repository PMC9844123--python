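import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from acoustosort.acoustics import AcousticField, FluidSpec
from acoustosort.gating import Gate
from acoustosort.sorter import ChannelGeometry, FlowConfig, SortPhysics

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def geometry():
    """The published device: 0.2 nl sorting region, 5 um bifurcation offset."""
    return ChannelGeometry(sorting_region_volume=0.2e-12)


@pytest.fixture
def flow():
    """0.01 ul/s sample + 0.07 ul/s sheath = 0.08 ul/s total (7:1)."""
    return FlowConfig(sample_flow=0.01e-9, sheath_flow=0.07e-9)


@pytest.fixture
def tsaw_physics():
    """A travelling-wave field strong enough to clear the 5 um offset."""
    field = AcousticField(mode="tsaw", frequency=135e6, energy_density=100.0,
                          pulse_duration=1e-3)
    return SortPhysics(field=field, fluid=FluidSpec())


@pytest.fixture
def small_bead_gate():
    return Gate(label="small", area_range=(115.0, 135.0), area_ratio_max=1.05)


@pytest.fixture
def wide_small_gate():
    """Captures essentially the whole small-bead population."""
    return Gate(label="small", area_range=(80.0, 148.0), area_ratio_max=1.05)


@pytest.fixture
def separable():
    """Two populations many SDs apart plus a gate that isolates the target.

    For closed-form coincidence oracles 'non-gated' must coincide with
    'the other population', so the overlap here is negligible (>4 sd on
    either side of the gate bounds).
    """
    from acoustosort.synthetic import Distribution, PopulationSpec

    def pop(label, mean):
        return PopulationSpec(
            label=label, n=0,
            size_dist=Distribution(mean, 0.10),
            deformation_dist=Distribution(0.05, 0.3, lower=0.0, upper=1.0),
            brightness_dist=Distribution(100.0, 0.03),
            area_ratio_dist=Distribution(1.01, 0.005, lower=1.0))

    populations = {"target": pop("target", 50.0), "other": pop("other", 200.0)}
    gate = Gate(label="target", area_range=(10.0, 120.0), area_ratio_max=1.08)
    return populations, gate
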