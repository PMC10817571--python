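"""Mask morphometry: contour tracing, rotating calipers vs. brute force,
closed-form shapes and parameter recovery from phantom ground truth."""

import numpy as np
import pytest

from nervetrace import (generate_dataset, measure, min_area_rect,
                        principal_component_mask, trace_contour)
from nervetrace.errors import DegenerateMaskError, EmptyMaskError
from nervetrace.morphometry import convex_hull


def sweep_min_rect_area(points, step_deg=0.01):
    """Brute-force minimum rectangle area over a dense angle grid (oracle)."""
    pts = np.asarray(points, float)
    angles = np.deg2rad(np.arange(0.0, 90.0, step_deg))
    c, s = np.cos(angles), np.sin(angles)
    u = np.outer(pts[:, 0], c) + np.outer(pts[:, 1], s)
    v = -np.outer(pts[:, 0], s) + np.outer(pts[:, 1], c)
    areas = (u.max(0) - u.min(0)) * (v.max(0) - v.min(0))
    return float(areas.min())


def disc_mask(radius, size=None):
    size = size or (2 * radius + 9)
    yy, xx = np.indices((size, size))
    c = (size - 1) / 2
    return ((yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2).astype(np.uint8)


class TestPrincipalComponent:
    def test_single_component_unchanged(self):
        m = disc_mask(6)
        assert np.array_equal(principal_component_mask(m).pixels, m)

    def test_largest_of_two_discs_survives(self):
        m = np.zeros((60, 60), np.uint8)
        m[10:20, 10:20] = disc_mask(4, 10)
        m[35:55, 35:55] = disc_mask(9, 20)
        out = principal_component_mask(m)
        assert out.pixels[40:50, 40:50].any()
        assert not out.pixels[10:20, 10:20].any()

    def test_output_has_at_most_one_component(self, rng):
        from scipy import ndimage
        for _ in range(50):
            m = (rng.random((24, 24)) > 0.72).astype(np.uint8)
            out = principal_component_mask(m)
            _, n = ndimage.label(out.pixels, structure=np.ones((3, 3)))
            assert n <= 1

    def test_empty_mask_passes_through(self):
        out = principal_component_mask(np.zeros((5, 5), np.uint8))
        assert out.area() == 0


class TestTraceContour:
    def test_three_by_three_square_has_eight_vertices(self):
        m = np.zeros((5, 5), np.uint8)
        m[1:4, 1:4] = 1
        poly = trace_contour(m)
        assert len(poly) == 8
        assert len(np.unique(poly, axis=0)) == 8

    def test_flipped_mask_gives_flipped_contour(self):
        m = np.zeros((40, 40), np.uint8)
        m[8:20, 5:30] = 1
        m[20:26, 10:18] = 1
        a = set(map(tuple, trace_contour(m)))
        b = {(39 - r, c) for r, c in map(tuple, trace_contour(m[::-1]))}
        assert a == b

    def test_vertices_touch_background(self):
        m = disc_mask(9)
        padded = np.pad(m, 1)
        for r, c in trace_contour(m).astype(int):
            assert m[r, c] == 1
            neigh = padded[r:r + 3, c:c + 3]
            assert (neigh == 0).any()  # adjacent to background

    def test_steps_are_unit_or_diagonal(self):
        poly = trace_contour(disc_mask(7))
        closed = np.vstack([poly, poly[:1]])
        steps = np.hypot(*np.diff(closed, axis=0).T)
        assert set(np.round(steps, 6)) <= {1.0, round(np.sqrt(2), 6)}

    def test_empty_and_tiny_masks_signal(self):
        with pytest.raises(EmptyMaskError):
            trace_contour(np.zeros((5, 5), np.uint8))
        tiny = np.zeros((5, 5), np.uint8)
        tiny[2, 2] = 1
        with pytest.raises(DegenerateMaskError):
            trace_contour(tiny)


class TestMinAreaRect:
    def test_rotated_rectangle_corners(self):
        th = np.radians(30)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = np.array([[0, 0], [4, 0], [4, 2], [0, 2]], float) @ R.T
        w, h, ang = min_area_rect(pts)
        assert w == pytest.approx(4.0, abs=1e-9)
        assert h == pytest.approx(2.0, abs=1e-9)
        assert ang == pytest.approx(30.0, abs=1e-6)

    def test_matches_brute_force_sweep_on_random_convex_sets(self, rng):
        for _ in range(100):
            pts = rng.normal(0, 10, size=(rng.integers(4, 25), 2))
            hull = convex_hull(pts)
            w, h, _ = min_area_rect(pts)
            oracle = sweep_min_rect_area(hull)
            assert w * h <= oracle + 1e-9
            assert abs(w * h - oracle) <= 0.005 * max(oracle, 1e-12)


class TestMeasure:
    def test_axis_aligned_rectangle_closed_form(self):
        m = np.zeros((40, 40), np.uint8)
        m[5:15, 5:25] = 1  # 10 rows x 20 cols
        r = measure(m)
        assert r.mncsa == 200.0
        assert r.circumference == pytest.approx(56.0)
        assert r.d1 == pytest.approx(19.0)
        assert r.d2 == pytest.approx(9.0)

    def test_half_pixel_pad_restores_full_extent(self):
        m = np.zeros((40, 40), np.uint8)
        m[5:15, 5:25] = 1
        r = measure(m, pad_half_pixel=True)
        assert r.d1 == pytest.approx(20.0)
        assert r.d2 == pytest.approx(10.0)
        assert r.d1 * r.d2 >= r.mncsa  # rectangle bound holds when padded

    def test_disc_measures(self):
        r = measure(disc_mask(30))
        assert abs(r.mncsa - np.pi * 900) / (np.pi * 900) < 0.02
        assert abs(r.d1 - r.d2) / r.d1 < 0.03

    def test_mm_scaling(self):
        m = disc_mask(10)
        a = measure(m, mm_per_pixel=1.0)
        b = measure(m, mm_per_pixel=0.5)
        assert b.mncsa == pytest.approx(a.mncsa * 0.25)
        assert b.circumference == pytest.approx(a.circumference * 0.5)
        assert b.d1 == pytest.approx(a.d1 * 0.5)

    def test_flip_and_translation_invariance(self):
        m = np.zeros((50, 50), np.uint8)
        m[10:22, 8:36] = 1
        m[22:30, 15:25] = 1
        base = measure(m)
        shifted = np.roll(np.roll(m, 7, axis=0), -3, axis=1)
        for variant in (m[::-1], m[:, ::-1], shifted):
            r = measure(np.ascontiguousarray(variant))
            assert r.mncsa == base.mncsa
            assert r.circumference == pytest.approx(base.circumference)
            assert r.d1 == pytest.approx(base.d1, abs=1e-9)
            assert r.d2 == pytest.approx(base.d2, abs=1e-9)

    def test_isoperimetric_inequality(self, rng):
        data = generate_dataset(10, {"a": (8.0, 20.0), "b": (6.0, 12.0),
                                     "center_jitter": 3.0},
                                seed=4, frame_size=(64, 64), hard_fraction=0)
        for _, mask, _ in data:
            r = measure(mask)
            assert r.circumference ** 2 >= 4 * np.pi * r.mncsa * 0.95

    def test_phantom_parameter_recovery(self):
        """Ground-truth mask measures recover the generating ellipse.

        The rectangle sides are compared against the ellipse's exact
        support-function extent along the measured rectangle direction,
        2*sqrt(a^2 cos^2 t + b^2 sin^2 t): for low-eccentricity rotated
        ellipses the minimum-area rectangle of the discretised mask need
        not align with the ellipse axes, but its sides must still match
        the continuous extents in its own directions.
        """
        data = generate_dataset(20, {"a": (10.0, 24.0), "b": (7.0, 14.0),
                                     "center_jitter": 4.0},
                                seed=11, frame_size=(64, 64), hard_fraction=0)
        for _, mask, spec in data:
            a, b = spec.semi_axes
            r = measure(mask, pad_half_pixel=True)
            assert abs(r.mncsa - np.pi * a * b) / (np.pi * a * b) < 0.03

            def extent(angle_deg):
                t = np.radians(angle_deg - spec.rotation)
                return 2 * np.hypot(a * np.cos(t), b * np.sin(t))

            assert abs(r.d1 - extent(r.rect_angle)) <= 2.0
            assert abs(r.d2 - extent(r.rect_angle + 90)) <= 2.0

    def test_axis_aligned_phantom_recovers_axes(self):
        """Unrotated elongated ellipses: D1 ~ 2a and D2 ~ 2b directly."""
        data = generate_dataset(10, {"a": (16.0, 24.0), "b": (7.0, 10.0),
                                     "rotation": (0.0, 0.0),
                                     "center_jitter": 4.0},
                                seed=13, frame_size=(64, 64), hard_fraction=0)
        for _, mask, spec in data:
            a, b = spec.semi_axes
            r = measure(mask, pad_half_pixel=True)
            assert abs(r.d1 - 2 * a) <= 2.0
            assert abs(r.d2 - 2 * b) <= 2.0

    def test_dilation_never_shrinks_measures(self, rng):
        from scipy import ndimage
        m = disc_mask(12)
        for _ in range(3):
            grown = ndimage.binary_dilation(m).astype(np.uint8)
            r0, r1 = measure(m), measure(grown)
            assert r1.mncsa >= r0.mncsa
            assert max(r1.d1, r1.d2) >= max(r0.d1, r0.d2) - 1e-9
            assert min(r1.d1, r1.d2) >= min(r0.d1, r0.d2) - 1e-9
            m = grown

    def test_empty_mask_signals(self):
        with pytest.raises(EmptyMaskError):
            measure(np.zeros((8, 8), np.uint8))
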