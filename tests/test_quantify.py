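"""Lesion quantification: subtraction, region growing, areas, axes, composition."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import pdist

from calciquant.grids import BinaryMask, ImageGrid
from calciquant.phantom import PhantomSpec, generate_phantom, generate_phantoms
from calciquant.quantify import (
    RegionGrowParams,
    ellipse_area,
    ellipsoid_volume,
    lesion_area,
    measure_axes,
    measurements_to_frame,
    quantify_image,
    region_grow,
    subtract_bone,
)

_EIGHT = np.ones((3, 3), int)


def brute_force_axes(mask: BinaryMask):
    """Independent O(n²) oracle: max pairwise distance + perpendicular extent."""
    pts = np.argwhere(mask.pixels).astype(float)
    if len(pts) < 2:
        return 0.0, 0.0
    d = pdist(pts)
    long_px = d.max()
    if long_px == 0:
        return 0.0, 0.0
    # recover the first maximal pair in pdist's (i, j) ordering
    k = int(np.argmax(d))
    n = len(pts)
    i = 0
    while k >= n - i - 1:
        k -= n - i - 1
        i += 1
    j = i + 1 + k
    v = pts[j] - pts[i]
    v /= np.linalg.norm(v)
    perp = np.array([-v[1], v[0]])
    proj = pts @ perp
    return long_px * mask.spacing, (proj.max() - proj.min()) * mask.spacing


class TestSubtractBone:
    def test_empty_mask_is_identity(self):
        s = generate_phantom(PhantomSpec(seed=0))
        empty = BinaryMask(np.zeros(s.image.shape, bool), s.image.spacing)
        out = subtract_bone(s.image, empty, dilation_px=1)
        assert np.array_equal(out.pixels, s.image.pixels)

    def test_full_mask_annihilates(self):
        s = generate_phantom(PhantomSpec(seed=0))
        full = BinaryMask(np.ones(s.image.shape, bool), s.image.spacing)
        out = subtract_bone(s.image, full, dilation_px=0)
        assert np.all(out.pixels == s.image.pixels.min())

    def test_lesions_untouched_bone_floored(self):
        s = generate_phantom(PhantomSpec(seed=4, n_lesions=2))
        out = subtract_bone(s.image, s.bone_mask, dilation_px=0)
        floor = s.image.pixels.min()
        assert np.all(out.pixels[s.bone_mask.pixels] == floor)
        for lm in s.lesion_masks:
            assert np.array_equal(out.pixels[lm.pixels], s.image.pixels[lm.pixels])

    def test_default_dilation_preserves_lesions(self):
        s = generate_phantom(PhantomSpec(seed=4, n_lesions=2))
        out = subtract_bone(s.image, s.bone_mask, dilation_px=1)
        for lm in s.lesion_masks:
            assert np.array_equal(out.pixels[lm.pixels], s.image.pixels[lm.pixels])

    def test_shape_mismatch_rejected(self):
        s = generate_phantom(PhantomSpec(seed=0))
        wrong = BinaryMask(np.zeros((32, 32), bool), s.image.spacing)
        with pytest.raises(ValueError):
            subtract_bone(s.image, wrong)


class TestRegionGrow:
    def _flat_with_blob(self):
        img = np.zeros((32, 32))
        img[10:15, 10:15] = 1000.0
        return ImageGrid(img, 1.0)

    def test_single_uniform_blob(self):
        masks = region_grow(self._flat_with_blob(), RegionGrowParams(intensity_threshold=500))
        assert len(masks) == 1
        assert masks[0].n_pixels == 25

    def test_all_below_threshold(self):
        img = ImageGrid(np.full((32, 32), 100.0), 1.0)
        assert region_grow(img, RegionGrowParams(intensity_threshold=500)) == []

    def test_two_blobs_match_component_oracle(self):
        img = np.zeros((32, 32))
        img[2:6, 2:6] = 900.0
        img[20:28, 20:26] = 950.0
        g = ImageGrid(img, 1.0)
        masks = region_grow(g, RegionGrowParams(intensity_threshold=500))
        _, n = ndimage.label(img >= 500, structure=_EIGHT)
        assert len(masks) == n == 2
        assert sorted(m.n_pixels for m in masks) == [16, 48]

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_infinite_tolerance_equals_component_labelling(self, connectivity):
        rng = np.random.default_rng(3)
        struct = _EIGHT if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
        for _ in range(150):
            img = rng.random((32, 32))
            g = ImageGrid(img, 1.0)
            params = RegionGrowParams(
                intensity_threshold=0.6,
                tolerance=np.inf,
                connectivity=connectivity,
                min_lesion_px=1,
            )
            masks = region_grow(g, params)
            labels, n = ndimage.label(img >= 0.6, structure=struct)
            assert len(masks) == n
            union = np.zeros((32, 32), bool)
            for m in masks:
                assert not (union & m.pixels).any()  # pairwise disjoint
                union |= m.pixels
            assert np.array_equal(union, img >= 0.6)

    def test_regions_connected_and_ordered(self):
        rng = np.random.default_rng(9)
        img = rng.random((48, 48)) * 1000
        g = ImageGrid(img, 1.0)
        masks = region_grow(g, RegionGrowParams(intensity_threshold=700, tolerance=400, min_lesion_px=1))
        sizes = [m.n_pixels for m in masks]
        assert sizes == sorted(sizes, reverse=True)
        for m in masks:
            _, n = ndimage.label(m.pixels, structure=_EIGHT)
            assert n == 1

    def test_min_lesion_px_filters_specks(self):
        img = np.zeros((32, 32))
        img[5, 5] = 1000.0  # 1-px speck
        img[20:25, 20:25] = 1000.0
        g = ImageGrid(img, 1.0)
        masks = region_grow(g, RegionGrowParams(intensity_threshold=500, min_lesion_px=3))
        assert len(masks) == 1 and masks[0].n_pixels == 25

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RegionGrowParams(tolerance=-1)
        with pytest.raises(ValueError):
            RegionGrowParams(connectivity=6)
        with pytest.raises(ValueError):
            RegionGrowParams(min_lesion_px=0)


class TestLesionArea:
    def test_area_definition(self):
        m = np.zeros((16, 16), bool)
        m[:10, :10] = True
        assert lesion_area(BinaryMask(m, 0.25)) == pytest.approx(6.25)

    def test_empty_mask_zero(self):
        assert lesion_area(BinaryMask(np.zeros((16, 16), bool), 1.0)) == 0.0

    def test_single_pixel_unit_spacing(self):
        m = np.zeros((16, 16), bool)
        m[3, 3] = True
        assert lesion_area(BinaryMask(m, 1.0)) == 1.0

    def test_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(1)
        a = rng.random((20, 20)) > 0.7
        b = rng.random((20, 20)) > 0.7
        b &= ~a
        union = a | b
        s = 0.3
        assert lesion_area(BinaryMask(union, s)) == pytest.approx(
            lesion_area(BinaryMask(a, s)) + lesion_area(BinaryMask(b, s))
        )


class TestMeasureAxes:
    def test_collinear_row(self):
        m = np.zeros((20, 20), bool)
        m[5, 3:14] = True  # 11 collinear pixels
        ax = measure_axes(BinaryMask(m, 1.0))
        assert ax.long_mm == 10.0 and ax.short_mm == 0.0 and ax.degenerate

    def test_single_pixel(self):
        m = np.zeros((20, 20), bool)
        m[5, 5] = True
        ax = measure_axes(BinaryMask(m, 1.0))
        assert ax.long_mm == 0.0 and ax.short_mm == 0.0 and ax.degenerate

    def test_rasterized_disk(self):
        rr, cc = np.mgrid[0:41, 0:41]
        disk = (rr - 20) ** 2 + (cc - 20) ** 2 <= 100
        ax = measure_axes(BinaryMask(disk, 1.0))
        assert 18.0 <= ax.long_mm <= 20.0
        assert abs(ax.long_mm - ax.short_mm) <= 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            measure_axes(BinaryMask(np.zeros((16, 16), bool), 1.0))

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            m = rng.random((24, 24)) > 0.8
            if not m.any():
                continue
            mask = BinaryMask(m, 0.5)
            ax = measure_axes(mask)
            long_o, short_o = brute_force_axes(mask)
            assert ax.long_mm == pytest.approx(long_o, abs=1e-9)
            assert ax.short_mm == pytest.approx(short_o, abs=1e-9)

    def test_matches_brute_force_on_generated_lesions(self):
        for s in generate_phantoms(10, base_seed=21):
            for lm in s.lesion_masks:
                ax = measure_axes(lm)
                long_o, short_o = brute_force_axes(lm)
                assert ax.long_mm == pytest.approx(long_o, abs=1e-9)
                assert ax.short_mm == pytest.approx(short_o, abs=1e-9)


class TestEllipseAndEllipsoid:
    def test_ellipse_area_formula(self):
        assert ellipse_area(10, 4) == pytest.approx(10 * np.pi)

    def test_circle_limit(self):
        r = 3.0
        assert ellipse_area(2 * r, 2 * r) == pytest.approx(np.pi * r * r)

    def test_degenerate_short_axis(self):
        assert ellipse_area(5.0, 0.0) == 0.0

    def test_invalid_axes_rejected(self):
        with pytest.raises(ValueError):
            ellipse_area(2.0, 3.0)
        with pytest.raises(ValueError):
            ellipse_area(2.0, -1.0)

    def test_ellipsoid_factor_is_0p52(self):
        factor = ellipsoid_volume(1.0, 1.0, 1.0)
        assert round(factor, 2) == 0.52

    def test_sphere_limit(self):
        r = 2.0
        assert ellipsoid_volume(2 * r, 2 * r, 2 * r) == pytest.approx(4 / 3 * np.pi * r**3)

    def test_zero_diameter(self):
        assert ellipsoid_volume(0.0, 3.0, 4.0) == 0.0

    def test_ellipse_estimate_close_to_pixel_area_for_ellipse_masks(self):
        """For genuinely elliptical lesions the two estimators nearly agree."""
        rr, cc = np.mgrid[0:64, 0:64]
        for (a, b) in [(14, 8), (20, 12), (10, 10), (18, 6)]:
            m = ((rr - 32) / a) ** 2 + ((cc - 32) / b) ** 2 <= 1.0
            mask = BinaryMask(m, 1.0)
            ax = measure_axes(mask)
            est = ellipse_area(ax.long_mm, ax.short_mm)
            assert abs(est - lesion_area(mask)) / lesion_area(mask) <= 0.15


class TestQuantifyImage:
    def test_truncated_phantom_gives_failure_marker(self):
        s = generate_phantom(PhantomSpec(seed=6, truncate_phalanges=True))
        res = quantify_image(s.image, s.bone_mask, RegionGrowParams())
        assert not res.complete and res.measurements is None

    def test_no_lesion_phantom_gives_empty_measurements(self):
        s = generate_phantom(PhantomSpec(seed=6, n_lesions=0))
        res = quantify_image(s.image, s.bone_mask, RegionGrowParams())
        assert res.complete and res.measurements == ()

    def test_recovers_known_areas(self):
        from conftest import match_lesion

        hits = 0
        for s in generate_phantoms(10, base_seed=33):
            res = quantify_image(s.image, s.bone_mask, RegionGrowParams())
            assert res.complete
            for lm, true_area in zip(s.lesion_masks, s.true_areas):
                if lm.n_pixels < 20:
                    continue
                c = np.argwhere(lm.pixels).mean(axis=0)
                m = match_lesion(res.measurements, c)
                assert abs(m.area_mm2 - true_area) / true_area <= 0.10
                hits += 1
        assert hits >= 10

    def test_measurement_invariants(self):
        s = generate_phantom(PhantomSpec(seed=12, n_lesions=2))
        res = quantify_image(s.image, s.bone_mask, RegionGrowParams())
        for m in res.measurements:
            assert m.area_mm2 == pytest.approx(m.pixel_count * s.image.spacing**2)
            assert m.long_axis_mm >= m.short_axis_mm >= 0
            assert m.ellipse_area_mm2 == pytest.approx(
                (m.long_axis_mm / 2) * (m.short_axis_mm / 2) * np.pi
            )

    def test_frame_export_columns(self):
        s_ok = generate_phantom(PhantomSpec(seed=12, n_lesions=2))
        s_bad = generate_phantom(PhantomSpec(seed=12, truncate_phalanges=True))
        frame = measurements_to_frame(
            {
                "ok": quantify_image(s_ok.image, s_ok.bone_mask, RegionGrowParams()),
                "bad": quantify_image(s_bad.image, s_bad.bone_mask, RegionGrowParams()),
            }
        )
        assert list(frame.columns) == [
            "image_id",
            "lesion_id",
            "pixel_count",
            "area_mm2",
            "long_axis_mm",
            "short_axis_mm",
            "ellipse_area_mm2",
            "degenerate",
            "visibility_complete",
        ]
        assert (~frame[frame.image_id == "bad"].visibility_complete).all()
        assert frame[frame.image_id == "ok"].visibility_complete.all()
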