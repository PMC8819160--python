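import numpy as np
import pytest

from scarvt.anatomy import BivGeometry, generate_biv_labels, paint_scar
from scarvt.volumes import ScarSpec


@pytest.fixture(scope="session")
def biv_vol():
    """Default two-ventricle phantom at 1 mm."""
    return generate_biv_labels()


@pytest.fixture(scope="session")
def small_geom():
    """A lighter phantom geometry for expensive downstream stages."""
    return BivGeometry().scaled(0.7)


@pytest.fixture(scope="session")
def scarred_vol(biv_vol):
    """Phantom with a 3 mm conducting isthmus through the scar."""
    return paint_scar(biv_vol, ScarSpec(isthmus_width=3.0))


@pytest.fixture(scope="session")
def solid_scar_vol(biv_vol):
    """Phantom with a solid scar core (no isthmus)."""
    return paint_scar(biv_vol, ScarSpec(isthmus_width=0.0))
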