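import numpy as np
import pytest

from wholeheart.phantom import (BoxRegion, LESION_PRESETS, LesionSpec,
                                insert_lesion, make_slab_phantom,
                                make_concentric_sphere_phantom,
                                make_two_chamber_heart_phantom)
from wholeheart.conduction import build_visibility_graph, simulate_activation


@pytest.fixture(scope="session")
def slab():
    """60 x 10 x 10 mm myocardial slab, 5 mm lattice, corner source."""
    return make_slab_phantom((60.0, 10.0, 10.0), 5.0)


@pytest.fixture(scope="session")
def slab_graph(slab):
    return build_visibility_graph(slab)


@pytest.fixture(scope="session")
def slab_activation(slab, slab_graph):
    return simulate_activation(slab, graph=slab_graph)


@pytest.fixture(scope="session")
def scar_slab(slab):
    """Slab with a transmural 10 mm scar band between x=25 and x=35."""
    lesion = LesionSpec(BoxRegion((25.0, -1.0, -1.0), (35.0, 11.0, 11.0)),
                        LESION_PRESETS["scar"], id="scar")
    return insert_lesion(slab, lesion)


@pytest.fixture(scope="session")
def edema_slab(slab):
    """Slab with a full-cross-section 10 mm edema band between x=30 and x=40."""
    lesion = LesionSpec(BoxRegion((30.0, -1.0, -1.0), (40.0, 11.0, 11.0)),
                        LESION_PRESETS["edema"], id="edema")
    return insert_lesion(slab, lesion)


@pytest.fixture(scope="session")
def heart():
    """Default two-chamber heart phantom."""
    return make_two_chamber_heart_phantom()


@pytest.fixture(scope="session")
def heart_activation(heart):
    return simulate_activation(heart)


@pytest.fixture(scope="session")
def heart_torso_transfer(heart):
    """65-electrode BEM transfer matrix for the heart in a spherical torso."""
    from wholeheart.forward_inverse import (ConductorGeometry,
                                            build_transfer_matrix_bem,
                                            make_standard_electrodes)
    geom = ConductorGeometry.heart_in_torso(heart, torso_radius=60.0, level=2)
    electrodes = make_standard_electrodes(geom)
    return build_transfer_matrix_bem(geom, electrodes)


@pytest.fixture(scope="session")
def spheres_level1():
    """Concentric heart/body icospheres at subdivision level 1."""
    return make_concentric_sphere_phantom((50.0, 200.0), (None, 0.2), 1)
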