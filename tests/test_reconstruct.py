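"""Segmentation, iso-surfacing, ripple filtering and surface metrics."""

import math

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st
from scipy.spatial import cKDTree

from thrombotrace.reconstruct import (
    SmoothingConfig,
    build_surface,
    convert_to_8bit,
    extract_contours,
    polygon_area,
    ripple_filter,
    segment_slice,
    segment_stack,
    surface_metrics,
)
from thrombotrace.types import (
    DegenerateInputError,
    MeshError,
    SliceImage,
    TriSurface,
    ZStack,
)
from .conftest import hemisphere_masks


def _img(data, bit_depth=12, ps=0.31, z=0.0, t=0.0):
    return SliceImage(data=np.asarray(data), z_um=z, t_s=t,
                      pixel_size_um=ps, bit_depth=bit_depth)


class TestConvertTo8Bit:
    @pytest.mark.parametrize("value,expected", [(4095, 255), (0, 0), (2048, 128)])
    def test_fixed_points(self, value, expected):
        """2048·255/4095 = 127.53 rounds half-up to 128; ends map to ends."""
        img = _img(np.full((4, 4), value, dtype=np.uint16))
        assert convert_to_8bit(img).data[0, 0] == expected

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=4094))
    def test_monotone(self, v):
        img = _img(np.array([[v, v + 1]], dtype=np.uint16))
        out = convert_to_8bit(img).data
        assert out[0, 0] <= out[0, 1]
        assert out.dtype == np.uint8


class TestSegmentation:
    def test_blank_image_empty_mask(self):
        img = _img(np.zeros((32, 32), dtype=np.uint8), bit_depth=8)
        assert not segment_slice(img, 100).any()

    def test_disk_area(self):
        """A 10 μm disk at intensity 200 segments to its analytic area."""
        ps = 0.31
        n = 128
        x = (np.arange(n) + 0.5) * ps - n * ps / 2
        X, Y = np.meshgrid(x, x)
        data = np.where(X**2 + Y**2 <= 10.0**2, 200, 0).astype(np.uint8)
        mask = segment_slice(_img(data, bit_depth=8, ps=ps), 100)
        from scipy import ndimage as ndi

        _, ncomp = ndi.label(mask)
        assert ncomp == 1
        assert mask.sum() * ps**2 == pytest.approx(math.pi * 100, rel=0.02)

    def test_threshold_zero_full_frame(self):
        img = _img(np.zeros((16, 16), dtype=np.uint8), bit_depth=8)
        assert segment_slice(img, 0, min_area_um2=0).all()

    def test_speck_removal_at_platelet_scale(self):
        """Components below the 2 μm-platelet disk area are discarded."""
        data = np.zeros((64, 64), dtype=np.uint8)
        data[2:4, 2:4] = 200            # ~0.38 μm² at 0.31 μm/px: a speck
        data[20:52, 20:52] = 200        # ~98 μm²: kept
        mask = segment_slice(_img(data, bit_depth=8), 100)
        assert not mask[2, 2]
        assert mask[30, 30]

    def test_blank_stack_auto_warns(self):
        imgs = [_img(np.zeros((8, 8), dtype=np.uint8), bit_depth=8, z=z)
                for z in (0.0, 0.5)]
        with pytest.warns(UserWarning, match="blank"):
            masks = segment_stack(ZStack(slices=imgs), "auto")
        assert not any(m.any() for m in masks)


class TestExtractContours:
    def test_empty_mask(self):
        cs = extract_contours(np.zeros((16, 16), bool), 0.31)
        assert cs.polygons == []

    def test_disk_polygon_area_matches_mask(self):
        ps = 0.31
        n = 128
        x = (np.arange(n) + 0.5) * ps - n * ps / 2
        X, Y = np.meshgrid(x, x)
        mask = X**2 + Y**2 <= 8.0**2
        cs = extract_contours(mask, ps)
        assert len(cs.polygons) == 1
        assert polygon_area(cs.polygons[0]) == pytest.approx(
            mask.sum() * ps**2, rel=0.02
        )

    def test_two_disks_two_labelled_polygons(self):
        mask = np.zeros((64, 64), bool)
        yy, xx = np.mgrid[:64, :64]
        mask |= (xx - 16) ** 2 + (yy - 16) ** 2 <= 64
        mask |= (xx - 48) ** 2 + (yy - 48) ** 2 <= 64
        cs = extract_contours(mask, 0.31)
        assert len(cs.polygons) == 2
        assert len(set(cs.labels)) == 2
        assert not any(cs.touches_border)

    def test_border_component_closed_and_flagged(self):
        mask = np.zeros((32, 32), bool)
        mask[:10, :10] = True
        cs = extract_contours(mask, 0.5)
        assert cs.touches_border == [True]
        poly = cs.polygons[0]
        # closed polygon: shoelace area positive and near 25 μm²
        assert polygon_area(poly) == pytest.approx(25.0, rel=0.1)


class TestBuildSurface:
    def test_hemisphere_volume(self):
        masks, zs, ps = hemisphere_masks(radius_um=15.0)
        surf = build_surface(masks, zs, ps, smoothing=SmoothingConfig(enabled=False))
        assert surf.is_watertight
        assert surf.volume_um3 == pytest.approx(2 / 3 * math.pi * 15**3, rel=0.02)

    def test_trapezoid_prism_volume_and_planarity(self):
        """Right trapezoidal prism: closed-form volume; faces stay planar
        (within one slice thickness) after ripple filtering."""
        # boundaries on pixel edges (all dimensions multiples of ps) so the
        # 0.5-level contour recovers the flat faces without alignment bias
        ps, dz, H = 0.25, 0.5, 20.0
        n = 160
        x = (np.arange(n) + 0.5) * ps - n * ps / 2
        X, Y = np.meshgrid(x, x)
        zs = np.arange(0.0, H + dz / 2, dz)
        Lx_bot, Lx_top, Ly = 30.0, 15.0, 14.0
        masks = []
        for z in zs:
            Lx = Lx_bot + (Lx_top - Lx_bot) * z / H
            masks.append((np.abs(Y) <= Ly / 2) & (X >= -Lx_bot / 2) & (X <= -Lx_bot / 2 + Lx))
        surf = build_surface(masks, zs, ps)
        expected = Ly * H * (Lx_bot + Lx_top) / 2.0
        assert surf.volume_um3 == pytest.approx(expected, rel=0.02)
        # planarity of the slanted face interior (away from the rounded
        # edges the smoothing legitimately softens): fits a plane to within
        # one slice thickness
        v = surf.vertices
        interior = (
            (v[:, 2] > 2.0)
            & (v[:, 2] < H - 2.0)
            & (np.abs(v[:, 1]) < Ly / 2 - 2.0)
        )
        slant = v[interior]
        x_face = -Lx_bot / 2 + Lx_bot + (Lx_top - Lx_bot) * slant[:, 2] / H
        slant = slant[np.abs(slant[:, 0] - x_face) < 1.0]
        A = np.column_stack([slant[:, 2], np.ones(len(slant))])
        coef, *_ = np.linalg.lstsq(A, slant[:, 0], rcond=None)
        resid = slant[:, 0] - A @ coef
        assert np.abs(resid).max() <= dz

    def test_single_slice_rejected(self):
        masks, zs, ps = hemisphere_masks(radius_um=3.0)
        with pytest.raises(DegenerateInputError):
            build_surface(masks[:1], zs[:1], ps)

    def test_resolution_monotonicity(self):
        """Halving slice thickness does not increase the volume error."""
        errs = []
        for dz in (1.0, 0.5):
            masks, zs, ps = hemisphere_masks(radius_um=15.0, dz_um=dz)
            surf = build_surface(masks, zs, ps,
                                 smoothing=SmoothingConfig(enabled=False))
            errs.append(abs(surf.volume_um3 / (2 / 3 * math.pi * 15**3) - 1))
        assert errs[1] <= errs[0] + 1e-6


class TestRippleFilter:
    def test_smooth_input_nearly_unchanged(self):
        """A smooth hemisphere stays within half a slice thickness of the
        analytic sphere (the filter must not distort smooth geometry)."""
        masks, zs, ps = hemisphere_masks(radius_um=15.0)
        surf = build_surface(masks, zs, ps, smoothing=SmoothingConfig(enabled=False))
        out = ripple_filter(surf)

        def radial_dev(ts):
            v = ts.vertices
            dome = v[v[:, 2] > 0.5]
            return np.abs(np.linalg.norm(dome, axis=1) - 15.0)

        assert radial_dev(out).max() <= 0.25
        # and it should sit no farther from the true surface than the input
        assert radial_dev(out).mean() <= radial_dev(surf).mean()

    def test_cylinder_ripple_attenuation(self):
        """Alternating 10/10.6 μm radii: radial spread cut ≥ 5×, mean kept."""
        ps, dz = 0.31, 0.5
        n = 96
        x = (np.arange(n) + 0.5) * ps - n * ps / 2
        X, Y = np.meshgrid(x, x)
        R = np.hypot(X, Y)
        zs = np.arange(0.0, 20.0 + dz / 2, dz)
        masks = [R <= (10.0 if k % 2 == 0 else 10.6) for k in range(len(zs))]
        raw = build_surface(masks, zs, ps, smoothing=SmoothingConfig(enabled=False))
        out = ripple_filter(raw)

        def radial_stats(ts):
            v = ts.vertices
            band = v[(v[:, 2] > 4.0) & (v[:, 2] < 16.0)]
            r = np.hypot(band[:, 0], band[:, 1])
            return r.mean(), r.std()

        m0, s0 = radial_stats(raw)
        m1, s1 = radial_stats(out)
        assert s0 / s1 >= 5.0
        assert m1 == pytest.approx(m0, rel=0.01)
        assert abs(out.volume_um3 / raw.volume_um3 - 1) <= 0.01

    def test_volume_preserved_and_watertight(self):
        masks, zs, ps = hemisphere_masks(radius_um=10.0)
        surf = build_surface(masks, zs, ps, smoothing=SmoothingConfig(enabled=False))
        out = ripple_filter(surf)
        assert out.is_watertight
        assert abs(out.volume_um3 / surf.volume_um3 - 1) <= 0.01


class TestSurfaceMetrics:
    def test_unit_cube(self):
        m = trimesh.creation.box(extents=(1, 1, 1))
        m.apply_translation([0.5, 0.5, 0.5])
        met = surface_metrics(TriSurface(mesh=m))
        assert met["volume_um3"] == pytest.approx(1.0)
        assert (met["length_um"], met["width_um"], met["height_um"]) == (1, 1, 1)

    def test_hemisphere(self):
        masks, zs, ps = hemisphere_masks(radius_um=15.0)
        surf = build_surface(masks, zs, ps)
        met = surface_metrics(surf)
        assert met["volume_um3"] == pytest.approx(2 / 3 * math.pi * 15**3, rel=0.02)
        assert met["height_um"] == pytest.approx(15.0, abs=0.5)

    def test_open_mesh_rejected(self):
        m = trimesh.creation.box(extents=(1, 1, 1))
        m.update_faces(np.arange(len(m.faces)) != 0)  # drop one face
        with pytest.raises(MeshError, match="watertight"):
            surface_metrics(TriSurface(mesh=m))
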