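"""Shared fixtures: beams, phantoms and sources reused across the suite.

Everything here is generated programmatically (no stored data); expensive
objects (tuned spectra, the heel-effect truth source) are session-scoped.
"""
import numpy as np
import pytest

from kvbeam import phantom, spectra
from kvbeam import source_model as smod
from kvbeam.fixtures import make_heel_source

#: the four beam qualities of the modeled unit: kvp, added filtration,
#: measured central-axis HVL (mm Al)
BEAMS = {
    80: (spectra.FilterStack.of(("aluminum", 1.70)), 2.06),
    120: (spectra.FilterStack.of(("copper", 0.05), ("aluminum", 0.90)), 4.18),
    140: (spectra.FilterStack.of(("copper", 0.20), ("aluminum", 1.15)), 7.14),
    150: (spectra.FilterStack.of(("copper", 1.00), ("aluminum", 1.20)), 13.40),
}


@pytest.fixture(scope="session")
def spec120():
    """Nominal 120 kVp beam of the modeled unit (0.05 Cu + 0.90 Al)."""
    added, _ = BEAMS[120]
    return spectra.generate_spectrum(120, added=added)


@pytest.fixture(scope="session")
def tuned120():
    """120 kVp beam tuned to the measured 4.18 mm Al HVL."""
    added, hvl = BEAMS[120]
    _, spec = spectra.tune_inherent_filtration(120, added=added,
                                               target_hvl_mm_al=hvl)
    return spec


@pytest.fixture(scope="session")
def water_phantom():
    """Desk-scale water phantom: 0.4 cm transverse, 0.3 cm depth voxels."""
    return phantom.build_water_phantom(dims=(51, 51, 40),
                                       voxel_size=(0.4, 0.4, 0.3), ssd=15.0)


@pytest.fixture(scope="session")
def uniform_source(spec120):
    """5 cm applicator, SSD 15, flat fluence, single spectrum."""
    fm = smod.FluenceMap([-3, 0, 3], [1, 1, 1], [-3, 0, 3], [1, 1, 1])
    return smod.SourceModel(ssd=15.0, applicator_diameter=5.0,
                            fluence=fm, spectra=((0.0, spec120),))


@pytest.fixture(scope="session")
def heel_truth():
    """Ground-truth heel-effect source (15 cm applicator, SSD 25)."""
    return make_heel_source(kvp=140, hvl_center=7.0, hvl_gradient_per_cm=0.1,
                            aperture=15.0, ssd=25.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.Philox(20240915))
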