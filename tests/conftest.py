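import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nanodesi4d as nd
from nanodesi4d.pixelation import spot_sample
from nanodesi4d.simulate import (Phantom, default_species_panel,
                                 simulate_discrete_run)

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def discrete_schedule():
    return nd.AcquisitionSchedule.discrete_default()


@pytest.fixture(scope="session")
def species_panel():
    return default_species_panel()


@pytest.fixture(scope="session")
def uniform_panel(species_panel):
    """The default panel with every species at unit abundance everywhere."""
    return [dataclasses.replace(sp, abundance_map={0: 1.0})
            for sp in species_panel]


@pytest.fixture(scope="session")
def small_run(uniform_panel, discrete_schedule):
    """Noiseless 5x5 single-region discrete run plus its assembled image."""
    phantom = Phantom(5, 5, np.zeros((5, 5), dtype=int))
    scans, truth = simulate_discrete_run(phantom, uniform_panel,
                                         discrete_schedule, seed=11)
    image = spot_sample(scans, discrete_schedule, phantom.pixel_order())
    return phantom, scans, truth, image


@pytest.fixture(scope="session")
def segmentation_run(species_panel, discrete_schedule):
    """Noiseless run on the 420-pixel two-region phantom (coarse m/z grid)."""
    phantom = Phantom.two_region_default()
    scans, truth = simulate_discrete_run(phantom, species_panel,
                                         discrete_schedule, seed=5,
                                         grid_step_mz=1.0)
    image = spot_sample(scans, discrete_schedule, phantom.pixel_order())
    return phantom, scans, truth, image


def xic_target_for(species, tolerance=(60.0, "ppm")):
    return nd.XICTarget(species.name, species.mz_centers(), species.charges,
                        tolerance)
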