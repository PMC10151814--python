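import numpy as np
import pytest

from cmrqc.contour_model import ContourPolygon, ContourStack, SliceAnnotation


def circle_ring(radius, cx=0.0, cy=0.0, n=256):
    """Regular n-gon approximating a circle, CCW, as an (n, 2) [x, y] array."""
    theta = 2 * np.pi * np.arange(n) / n
    return np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)])


def circle_contour(structure, radius, cx=0.0, cy=0.0, n=256):
    return ContourPolygon(structure, [circle_ring(radius, cx, cy, n)])


def single_structure_stack(indices, phase="ED", radius=20.0, cx=60.0, cy=60.0,
                           n_slices=10, reader_id="expert", spacing=(1.0, 1.0),
                           thickness=7.0, structure="lv_endo"):
    """Stack with one structure segmented on the given slice indices."""
    slices = []
    for i in range(n_slices):
        contours = (
            {structure: circle_contour(structure, radius, cx, cy)}
            if i in set(indices)
            else {}
        )
        slices.append(SliceAnnotation(i, phase, contours))
    return ContourStack(
        case_id="fixture",
        reader_id=reader_id,
        pixel_spacing_mm=spacing,
        slice_thickness_mm=thickness,
        slice_gap_mm=0.0,
        slices=slices,
    )


@pytest.fixture
def unit_square():
    return ContourPolygon("lv_endo", [[(0, 0), (1, 0), (1, 1), (0, 1)]])


@pytest.fixture
def rng():
    return np.random.default_rng(20230418)
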