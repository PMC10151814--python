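import numpy as np
import pytest

from cmrqc.contour_model import ContourPolygon, SliceAnnotation, build_region
from cmrqc.errors import DegenerateGeometryError
from cmrqc.geom_metrics import (
    StackMeta,
    compare_slice,
    dice,
    hausdorff,
    mean_surface_distance,
    slice_volume_difference,
)

from .conftest import circle_contour, circle_ring

META = StackMeta(pixel_spacing_mm=(1.0, 1.0), slice_thickness_mm=7.0)


def circle_region(radius, cx=0.0, cy=0.0, n=512, structure="lv_endo"):
    ann = SliceAnnotation(0, "ED", {structure: circle_contour(structure, radius, cx, cy, n)})
    return build_region(ann, structure)


def lens_area(r, d):
    """Intersection area of two radius-r circles with centres d apart."""
    return 2 * r**2 * np.arccos(d / (2 * r)) - (d / 2) * np.sqrt(4 * r**2 - d**2)


class TestDice:
    def test_identical_regions(self):
        a = circle_region(20.0, cx=50, cy=50)
        assert dice(a, a) == pytest.approx(100.0)

    def test_disjoint_regions(self):
        assert dice(circle_region(5.0), circle_region(5.0, cx=100)) == 0.0

    def test_offset_circles_match_lens_formula(self):
        r, d = 20.0, 5.0
        a = circle_region(r)
        b = circle_region(r, cx=d)
        expected = 100 * 2 * lens_area(r, d) / (2 * np.pi * r**2)
        assert dice(a, b) == pytest.approx(expected, abs=0.05)
        assert dice(a, b) == pytest.approx(84.1, abs=0.2)

    def test_symmetry(self):
        a, b = circle_region(20.0), circle_region(18.0, cx=4)
        assert dice(a, b) == dice(b, a)

    def test_monotone_in_radius_ratio(self):
        base = circle_region(20.0)
        ratios = [1.0, 0.95, 0.9, 0.8, 0.7]
        values = [dice(base, circle_region(20.0 * q)) for q in ratios]
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_zero_area_rejected(self):
        from shapely.geometry import Polygon

        from cmrqc.contour_model import RegionSpec

        empty = RegionSpec("lv_endo", Polygon(), (1.0, 1.0))
        with pytest.raises(DegenerateGeometryError):
            dice(circle_region(20.0), empty)

    def test_agrees_with_rasterization_oracle(self, rng):
        """Polygon-clipping Dice vs a 1024^2 rasterisation Dice, 20 random pairs."""
        from skimage.draw import polygon as draw_polygon

        for _ in range(20):
            r1, r2 = rng.uniform(10, 25, 2)
            d = rng.uniform(0, 10)
            a, b = circle_region(r1), circle_region(r2, cx=d)
            analytic = dice(a, b)

            # rasterise both onto a 1024^2 grid spanning the joint bbox
            minx, miny, maxx, maxy = (
                min(a.geometry.bounds[0], b.geometry.bounds[0]) - 1,
                min(a.geometry.bounds[1], b.geometry.bounds[1]) - 1,
                max(a.geometry.bounds[2], b.geometry.bounds[2]) + 1,
                max(a.geometry.bounds[3], b.geometry.bounds[3]) + 1,
            )
            n = 1024
            sx = (maxx - minx) / n
            sy = (maxy - miny) / n

            def raster(region):
                ring = np.asarray(region.geometry.exterior.coords)
                rr, cc = draw_polygon(
                    (ring[:, 1] - miny) / sy, (ring[:, 0] - minx) / sx, (n, n)
                )
                img = np.zeros((n, n), bool)
                img[rr, cc] = True
                return img

            ma, mb = raster(a), raster(b)
            raster_dice = 100 * 2 * (ma & mb).sum() / (ma.sum() + mb.sum())
            assert analytic == pytest.approx(raster_dice, abs=0.5)


class TestHausdorff:
    def test_identical_regions(self):
        a = circle_region(20.0, cx=50, cy=50)
        assert hausdorff(a, a) == 0.0

    def test_translated_circle(self):
        a = circle_region(20.0)
        b = circle_region(20.0, cx=5.0)
        assert hausdorff(a, b) == pytest.approx(5.0, abs=0.1)

    def test_nested_squares(self):
        def square_region(lo, hi):
            ring = [(lo, lo), (hi, lo), (hi, hi), (lo, hi)]
            ann = SliceAnnotation(0, "ED", {"lv_endo": ContourPolygon("lv_endo", [ring])})
            return build_region(ann, "lv_endo")

        a = square_region(0, 1)
        b = square_region(0, 2)
        assert hausdorff(a, b, max_step=0.05) == pytest.approx(np.sqrt(2), abs=0.1)

    def test_symmetry(self):
        a, b = circle_region(20.0), circle_region(15.0, cx=8)
        assert hausdorff(a, b) == hausdorff(b, a)

    def test_bounds_mean_surface_distance(self):
        a, b = circle_region(20.0), circle_region(16.0, cx=6)
        assert hausdorff(a, b) >= mean_surface_distance(a, b)

    def test_anisotropic_spacing_honoured(self):
        # same pixel geometry, doubled column spacing doubles an x-translation
        spacing = (1.0, 2.0)
        ann_a = SliceAnnotation(0, "ED", {"lv_endo": circle_contour("lv_endo", 20, 0, 0)})
        ann_b = SliceAnnotation(0, "ED", {"lv_endo": circle_contour("lv_endo", 20, 5, 0)})
        a = build_region(ann_a, "lv_endo", spacing)
        b = build_region(ann_b, "lv_endo", spacing)
        assert hausdorff(a, b) == pytest.approx(10.0, abs=0.2)

    def test_lvm_uses_both_rings(self):
        def annulus(endo_r):
            ann = SliceAnnotation(
                0,
                "ED",
                {
                    "lv_epi": circle_contour("lv_epi", 30.0, 50, 50),
                    "lv_endo": circle_contour("lv_endo", endo_r, 50, 50),
                },
            )
            return build_region(ann, "lvm")

        # only the endocardial (inner) ring differs: Hd must see it
        assert hausdorff(annulus(20.0), annulus(15.0)) == pytest.approx(5.0, abs=0.1)


class TestSliceVolumeDifference:
    def test_identical_slices(self):
        ann = SliceAnnotation(0, "ED", {"lv_endo": circle_contour("lv_endo", 20, 50, 50)})
        assert slice_volume_difference(ann, ann, "lv_endo", META) == (0.0, 0.0)

    def test_ring_difference_against_analytic(self):
        a = SliceAnnotation(0, "ED", {"lv_endo": circle_contour("lv_endo", 20.0, 50, 50, n=2048)})
        b = SliceAnnotation(0, "ED", {"lv_endo": circle_contour("lv_endo", 19.5, 50, 50, n=2048)})
        signed, absolute = slice_volume_difference(a, b, "lv_endo", META)
        expected = np.pi * (400 - 380.25) * 7 / 1000  # 0.434 ml
        assert absolute == pytest.approx(expected, rel=0.01)
        assert signed == pytest.approx(-expected, rel=0.01)

    def test_one_sided_region(self):
        b = SliceAnnotation(0, "ED", {"lv_endo": circle_contour("lv_endo", 20.0, 50, 50, n=2048)})
        signed, absolute = slice_volume_difference(None, b, "lv_endo", META)
        expected = np.pi * 400 * 7 / 1000  # 8.80 ml
        assert signed == pytest.approx(expected, rel=0.01)
        assert absolute == pytest.approx(expected, rel=0.01)


class TestCompareSlice:
    def test_neither_is_perfect_by_convention(self):
        rec = compare_slice(
            SliceAnnotation(0, "ED", {}), SliceAnnotation(0, "ED", {}), "lv_endo", META
        )
        assert rec.decision == "neither"
        assert rec.dice_pct == 100.0
        assert rec.hausdorff_mm is None

    def test_one_only_is_zero_by_convention(self):
        b = SliceAnnotation(0, "ED", {"lv_endo": circle_contour("lv_endo", 20, 50, 50)})
        rec = compare_slice(SliceAnnotation(0, "ED", {}), b, "lv_endo", META)
        assert rec.decision == "only_b"
        assert rec.dice_pct == 0.0
        assert rec.volume_diff_ml > 0

    def test_both_identical(self):
        ann = SliceAnnotation(0, "ED", {"lv_endo": circle_contour("lv_endo", 20, 50, 50)})
        rec = compare_slice(ann, ann, "lv_endo", META)
        assert rec.decision == "both"
        assert rec.dice_pct == pytest.approx(100.0)
        assert rec.hausdorff_mm == 0.0
        assert rec.abs_volume_diff_ml == 0.0
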