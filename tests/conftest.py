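import numpy as np
import pytest
import trimesh

import anteversion as av


@pytest.fixture(scope="session")
def femur30():
    """Default synthetic femur with 30 degrees of neck anteversion."""
    mesh, lm, truth = av.generate_femur(av.FemurSpec(nfa_deg=30.0))
    frame = av.build_femoral_frame(lm)
    return mesh, lm, frame, truth


@pytest.fixture(scope="session")
def symmetric_femur():
    """Fully mirror-symmetric femur: zero anteversion, symmetric bosses."""
    spec = av.FemurSpec(nfa_deg=0.0, lt_azimuth_deg=0.0, fossa_posterior_offset=0.0)
    mesh, lm, truth = av.generate_femur(spec)
    frame = av.build_femoral_frame(lm)
    return mesh, lm, frame, truth


@pytest.fixture(scope="session")
def sweep_femurs():
    """Anteversion sweep 0..60 degrees, one femur per step."""
    out = {}
    for nfa in range(0, 61, 10):
        mesh, lm, truth = av.generate_femur(av.FemurSpec(nfa_deg=float(nfa)))
        out[nfa] = (mesh, lm, av.build_femoral_frame(lm), truth)
    return out


def make_aligned_landmarks(**overrides):
    """A canonical right-side landmark set aligned with the global axes."""
    d = dict(
        head_center=[0.0, 0.0, 400.0],
        lesser_trochanter_apex=[-40.0, -5.0, 345.0],
        piriformis_fossa_center=[-50.0, 5.0, 368.0],
        trochanteric_fossa=[-52.0, -10.0, 365.0],
        post_condyle_medial=[24.5, -19.3, 0.0],
        post_condyle_lateral=[-24.5, -19.3, 0.0],
        epicondyle_medial=[35.0, 0.0, 0.0],
        epicondyle_lateral=[-35.0, 0.0, 0.0],
        side="right",
    )
    d.update(overrides)
    return av.LandmarkSet.from_dict(d)


@pytest.fixture
def aligned_landmarks():
    return make_aligned_landmarks()


@pytest.fixture(scope="session")
def vertical_cylinder():
    """Prism approximation of a vertical cylinder, radius 15, through z=345..365."""
    cyl = trimesh.creation.cylinder(radius=15.0, height=60.0, sections=256)
    cyl.apply_translation([0.0, 0.0, 355.0])
    return cyl


def rotation_about(axis, deg):
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(np.radians(deg) * np.asarray(axis) / np.linalg.norm(axis)).as_matrix()
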