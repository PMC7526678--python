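"""Shared fixtures: a small, fast phantom specimen used across modules.

The small geometry keeps the full C-shaped wedge anatomy (body, two
root attachments, radial taper) on a coarse grid so meshing, region
partition and strain tests run in well under a second each.
"""

import numpy as np
import pytest

import meniscus_strain as ms


@pytest.fixture(scope="session")
def small_geom() -> ms.PhantomGeometry:
    return ms.PhantomGeometry(
        inner_radius=15.0, outer_radius=30.0, angular_span=280.0,
        attachment_span=15.0, peripheral_height=8.0, inner_height=2.0,
        start_angle=40.0, z_base=2.0,
        grid_shape=(54, 54, 14), spacing=(1.5, 1.5, 1.0), origin=(-39.75, -39.75, 0.0),
    )


@pytest.fixture(scope="session")
def small_mask(small_geom):
    return ms.make_meniscus_mask(small_geom)


@pytest.fixture(scope="session")
def small_mesh(small_mask):
    return ms.mask_to_hexmesh(small_mask)


@pytest.fixture(scope="session")
def frame(small_geom) -> ms.CylindricalFrame:
    return ms.build_frame(np.asarray(small_geom.center))


@pytest.fixture(scope="session")
def sep_lines(small_geom):
    """Separation lines at the phantom's true body/attachment boundaries."""
    a = np.radians(small_geom.start_angle)
    p = np.radians(small_geom.start_angle + small_geom.angular_span)
    p = np.arctan2(np.sin(p), np.cos(p))  # wrap into (-pi, pi]
    return (ms.SeparationLine(angle=a, side="anterior"),
            ms.SeparationLine(angle=p, side="posterior"))


@pytest.fixture(scope="session")
def labeling(small_mesh, frame, sep_lines):
    return ms.label_regions(small_mesh, frame, *sep_lines)
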