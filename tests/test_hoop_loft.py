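"""Hoop profiles, fitting, scaling, diamondization and lofting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dinomorph.hoop_loft import (DIAMOND_FACTOR, OCTAGON_ANGLES, Hoop,
                                 SegmentModel, add_cavity, diamondize,
                                 fit_hoop, loft_segment, scale_hoop)
from dinomorph.mesh_core import contains_points, mass_properties

U = np.array([0.0, 1.0, 0.0])
W = np.array([0.0, 0.0, 1.0])


def circular(station, center_x, radius):
    return Hoop(station, (center_x, 0, 0), U, W, "ellipse",
                np.array([radius, radius]))


def octagonal(station, center_x, radii):
    return Hoop(station, (center_x, 0, 0), U, W, "octagon", np.asarray(radii, float))


def shoelace(points):
    y, z = points[:, 0], points[:, 1]
    return 0.5 * abs(np.dot(y, np.roll(z, -1)) - np.dot(z, np.roll(y, -1)))


class TestLoftClosedForms:
    def test_cylinder_volume(self):
        mesh = loft_segment([circular(0, 0, 0.7), circular(3, 3, 0.7)])
        assert mass_properties(mesh).volume == pytest.approx(
            np.pi * 0.7 ** 2 * 3, rel=1e-12)

    def test_conical_frustum_volume(self):
        r1, r2, length = 1.0, 0.4, 2.5
        mesh = loft_segment([circular(0, 0, r1), circular(length, length, r2)])
        expected = np.pi * length * (r1 ** 2 + r1 * r2 + r2 ** 2) / 3
        assert mass_properties(mesh).volume == pytest.approx(expected, rel=1e-12)

    def test_octagonal_prism_volume_exact(self):
        r, length = 0.9, 2.0
        mesh = loft_segment([octagonal(0, 0, np.full(8, r)),
                             octagonal(length, length, np.full(8, r))])
        assert mass_properties(mesh).volume == pytest.approx(
            2 * np.sqrt(2) * r ** 2 * length, rel=1e-12)

    @pytest.mark.parametrize("ring_n", [8, 16, 64])
    def test_volume_exact_at_every_ring_resolution(self, ring_n):
        # area-preserving resampling: no volume error to refine away
        mesh = loft_segment([circular(0, 0, 0.5), circular(1, 1, 0.5)],
                            ring_n=ring_n)
        assert mass_properties(mesh).volume == pytest.approx(
            np.pi * 0.25, rel=1e-12)

    def test_shape_converges_quadratically_or_better(self):
        # inertia of a cylinder about its axis: m r^2 / 2
        errs = []
        for n in (8, 16, 32):
            mesh = loft_segment([circular(0, 0, 1.0), circular(2, 2, 1.0)],
                                ring_n=n)
            p = mass_properties(mesh, 1000.0)
            errs.append(abs(p.inertia[0, 0] - p.mass * 0.5))
        assert errs[0] / errs[1] >= 4.0
        assert errs[1] / errs[2] >= 4.0

    def test_loft_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            loft_segment([circular(0, 0, 1.0)])
        with pytest.raises(ValueError, match="increasing"):
            loft_segment([circular(1, 1, 1.0), circular(0, 0, 1.0)])

    def test_loft_watertight(self):
        mesh = loft_segment([octagonal(0, 0, np.arange(1, 9) / 4.0),
                             octagonal(1, 1, np.arange(1, 9) / 5.0)])
        mesh.validate()


class TestFitHoop:
    def test_extremes_at_radius_r_give_radius_r(self):
        pts = (0.8 * np.cos(OCTAGON_ANGLES)[:, None] * U
               + 0.8 * np.sin(OCTAGON_ANGLES)[:, None] * W)
        hoop = fit_hoop(0.0, pts, U, W, center=np.zeros(3), offset_fraction=0.0)
        assert hoop.radii == pytest.approx(np.full(8, 0.8), rel=1e-9)

    def test_offset_scales_all_radii(self):
        pts = (0.5 * np.cos(OCTAGON_ANGLES)[:, None] * U
               + 0.5 * np.sin(OCTAGON_ANGLES)[:, None] * W)
        tight = fit_hoop(0.0, pts, U, W, center=np.zeros(3), offset_fraction=0.0)
        loose = fit_hoop(0.0, pts, U, W, center=np.zeros(3), offset_fraction=0.2)
        assert loose.radii == pytest.approx(tight.radii * 1.2, rel=1e-9)

    def test_contains_all_section_points(self):
        """Vertebra + rib-like scatter must end up inside the fitted hoop."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            raw = rng.uniform(-1.0, 1.0, size=(12, 2))
            pts = raw[:, 0][:, None] * U + raw[:, 1][:, None] * W
            hoop = fit_hoop(0.0, pts, U, W, center=np.zeros(3))
            theta = np.arctan2(raw[:, 1], raw[:, 0])
            assert (np.hypot(*raw.T) <= hoop.radius_at(theta) * (1 + 1e-6)).all()

    def test_collinear_points_rejected(self):
        pts = np.array([[0, y, 0] for y in (0.1, 0.5, 0.9)], dtype=float)
        with pytest.raises(ValueError, match="non-collinear"):
            fit_hoop(0.0, pts, U, W, center=np.zeros(3))


class TestHoopTransforms:
    def test_scale_identity_and_area(self):
        hoop = octagonal(0, 0, np.full(8, 1.0))
        assert scale_hoop(hoop, 1.0).radii == pytest.approx(hoop.radii)
        assert scale_hoop(hoop, 1.2).area() == pytest.approx(1.44 * hoop.area())

    def test_scale_inverse_roundtrip(self):
        hoop = octagonal(0, 0, np.arange(1, 9) / 3.0)
        back = scale_hoop(scale_hoop(hoop, 0.8), 1 / 0.8)
        assert np.abs(back.radii - hoop.radii).max() < 1e-12

    def test_scale_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            scale_hoop(octagonal(0, 0, np.full(8, 1.0)), 0.0)

    def test_scale_preserves_station_and_center(self):
        hoop = octagonal(2.5, 2.5, np.full(8, 1.0))
        scaled = scale_hoop(hoop, 1.2)
        assert scaled.station == hoop.station
        assert scaled.center == pytest.approx(hoop.center)

    def test_diamondize_area_ratio_matches_shoelace_oracle(self):
        hoop = octagonal(0, 0, np.full(8, 1.0))
        diamond = diamondize(hoop)
        # oracle: shoelace area of the 8-vertex polygons, computed directly
        def poly(h):
            return np.column_stack([h.radii * np.cos(OCTAGON_ANGLES),
                                    h.radii * np.sin(OCTAGON_ANGLES)])
        ratio = shoelace(poly(diamond)) / shoelace(poly(hoop))
        assert diamond.area() / hoop.area() == pytest.approx(ratio, rel=1e-12)
        # alternating scaling: every edge has exactly one scaled endpoint
        assert ratio == pytest.approx(DIAMOND_FACTOR, rel=1e-12)

    def test_diamondize_monotone_and_identity(self):
        hoop = octagonal(0, 0, np.full(8, 0.7))
        assert diamondize(hoop).area() < hoop.area()
        assert diamondize(hoop, 1.0).radii == pytest.approx(hoop.radii)

    def test_diamondize_rejects_ellipse(self):
        with pytest.raises(ValueError, match="octagon"):
            diamondize(circular(0, 0, 1.0))

    @given(factor=st.floats(0.5, 1.5), diamond=st.floats(0.6, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_diamondize_and_scale_commute(self, factor, diamond):
        hoop = octagonal(0, 0, np.arange(1, 9) / 4.0)
        a = diamondize(scale_hoop(hoop, factor), diamond)
        b = scale_hoop(diamondize(hoop, diamond), factor)
        assert a.radii == pytest.approx(b.radii, rel=1e-12)

    def test_ellipse_to_octagon_preserves_control_radii(self):
        ell = Hoop(0, (0, 0, 0), U, W, "ellipse", np.array([1.0, 0.5]))
        octo = ell.to_octagon()
        assert octo.radii == pytest.approx(ell.radius_at(OCTAGON_ANGLES))


class TestSegmentModel:
    def _cube_segment(self, cavity_scale=None):
        # square "octagon" prism approximating a box
        radii = np.full(8, 1.0)
        hoops = [octagonal(0, 0, radii), octagonal(1, 1, radii)]
        seg = SegmentModel("body", hoops, density=1000.0)
        return seg

    def test_cavity_mass_arithmetic(self):
        seg = self._cube_segment()
        flesh_volume = mass_properties(seg.build_mesh()).volume
        cavity = [octagonal(0.25, 0.25, np.full(8, 0.3)),
                  octagonal(0.75, 0.75, np.full(8, 0.3))]
        add_cavity(seg, cavity)
        cav_volume = mass_properties(seg.build_cavity_meshes()[0]).volume
        props = seg.mass_properties()
        assert props.mass == pytest.approx(1000.0 * (flesh_volume - cav_volume))
        assert props.volume == pytest.approx(flesh_volume)  # external volume
        assert props.mass / props.volume < 1000.0

    def test_cavity_outside_flesh_warns(self):
        seg = self._cube_segment()
        escaped = [octagonal(0.25, 0.25, np.full(8, 0.3)),
                   octagonal(2.5, 2.5, np.full(8, 0.3))]  # pokes out the end
        with pytest.warns(UserWarning, match="cavity"):
            add_cavity(seg, escaped)

    def test_segment_needs_two_ordered_hoops(self):
        with pytest.raises(ValueError, match=">= 2 hoops"):
            SegmentModel("neck", [octagonal(0, 0, np.full(8, 1.0))])
        with pytest.raises(ValueError, match="increasing"):
            SegmentModel("neck", [octagonal(1, 1, np.full(8, 1.0)),
                                  octagonal(0, 0, np.full(8, 1.0))])

    def test_cavity_containment_samples_inside(self):
        seg = self._cube_segment()
        add_cavity(seg, [octagonal(0.3, 0.3, np.full(8, 0.2)),
                         octagonal(0.7, 0.7, np.full(8, 0.2))])
        assert seg.check_cavity_containment() == 1.0
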