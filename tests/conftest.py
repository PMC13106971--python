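import numpy as np
import pytest

import lumiphasor as lp


@pytest.fixture(scope="session")
def window():
    return lp.DEFAULT_WINDOW


@pytest.fixture(scope="session")
def filters(window):
    # asymmetric bounds so bugs conflating the two filters are visible
    return lp.make_filters(window, f_min=0.15, f_max=0.85)


@pytest.fixture(scope="session")
def library():
    return lp.default_library()


@pytest.fixture(scope="session")
def refs(library):
    return lp.reference_phasors(library)


@pytest.fixture()
def ideal_camera():
    return lp.CameraModel.ideal()


@pytest.fixture()
def single_cell_scene():
    return lp.Scene(32, 32, [lp.CellSpec((16, 16), 8, "YeNL", 500.0)])
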