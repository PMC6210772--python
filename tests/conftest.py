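import numpy as np
import pytest

from voxcanopy.spectra import Spectrum
from voxcanopy.stand import StandParameters, generate_stand


def flat_spectrum(value: float, kind: str = "") -> Spectrum:
    return Spectrum(np.array([350.0, 2500.0]), np.array([value, value]), kind=kind)


def flat_materials(leaf_r=0.0, leaf_t=0.0, trunk_r=0.0, soil_r=0.25):
    return {
        "leaf_reflectance": flat_spectrum(leaf_r),
        "leaf_transmittance": flat_spectrum(leaf_t),
        "trunk_reflectance": flat_spectrum(trunk_r),
        "soil_reflectance": flat_spectrum(soil_r),
    }


@pytest.fixture(scope="session")
def small_stand():
    """A light stand (sparse foliage) for classification/scan fixtures."""
    params = StandParameters(
        plot_size=8.0, trees_per_ha=300.0, target_lai=0.4, rng_seed=7,
        crown_radius=3.2, min_spacing=3.0,
    )
    return generate_stand(params)


@pytest.fixture(scope="session")
def dense_stand_small_plot():
    """Study-density foliage on a small plot (LAI 2.32, 6 m core)."""
    params = StandParameters(plot_size=6.0, trees_per_ha=300.0, rng_seed=11,
                             crown_radius=2.5, min_spacing=2.0)
    return generate_stand(params)
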