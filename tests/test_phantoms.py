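"""Phantom generator: determinism, geometry, noise model, perturbation."""

import numpy as np
import pytest

from nervetrace import (NerveMask, PhantomSpec, generate_dataset,
                        generate_phantom, perturb_annotation)
from nervetrace.errors import ConfigurationError, PhantomSizingError
from nervetrace.phantoms import is_hard
from nervetrace.segmetrics import evaluate_pair


def ellipse_pixel_count(a, b, rotation=0.0, size=201):
    """Exhaustive pixel-center-in-ellipse enumeration (independent oracle)."""
    c = (size - 1) / 2
    th = np.radians(rotation)
    count = 0
    for r in range(size):
        for col in range(size):
            u = (col - c) * np.cos(th) + (r - c) * np.sin(th)
            v = -(col - c) * np.sin(th) + (r - c) * np.cos(th)
            if (u / a) ** 2 + (v / b) ** 2 <= 1.0:
                count += 1
    return count


class TestGeneratePhantom:
    def test_seeded_determinism_bit_identical(self):
        spec = PhantomSpec(semi_axes=(22, 12), blur_sigma=1.0, seed=7)
        f1, m1 = generate_phantom(spec)
        f2, m2 = generate_phantom(spec)
        assert np.array_equal(f1.pixels, f2.pixels)
        assert np.array_equal(m1.pixels, m2.pixels)

    def test_echo_structure_interior_darker_than_rim(self):
        spec = PhantomSpec(blur_sigma=0.0, speckle_shape=None)
        frame, mask = generate_phantom(spec)
        inside = mask.pixels.astype(bool)
        from nervetrace.phantoms import _ellipse_interior
        rim = _ellipse_interior(spec.frame_size, spec.center, spec.semi_axes,
                                spec.rotation, grow=spec.rim_thickness) & ~inside
        assert frame.pixels[inside].mean() < frame.pixels[rim].mean()

    def test_mask_area_matches_enumeration_oracle(self):
        spec = PhantomSpec(semi_axes=(20, 10), rotation=0.0)
        _, mask = generate_phantom(spec)
        oracle = ellipse_pixel_count(20, 10)
        assert mask.area() == oracle
        assert abs(mask.area() - np.pi * 200) / (np.pi * 200) < 0.02

    def test_threshold_recovers_interior_exactly_when_noise_off(self):
        spec = PhantomSpec(blur_sigma=0.0, speckle_shape=None)
        frame, mask = generate_phantom(spec)
        mid = 255 * (spec.interior_level + spec.background_level) / 2
        recovered = frame.pixels < mid
        assert np.array_equal(recovered, mask.pixels.astype(bool))

    def test_oversized_ellipse_rejected(self):
        spec = PhantomSpec(frame_size=(64, 64), center=(32, 32),
                           semi_axes=(40, 20))
        with pytest.raises(PhantomSizingError):
            generate_phantom(spec)

    @pytest.mark.parametrize("field, value", [
        ("interior_level", 0.9),   # violates interior < background
        ("blur_sigma", -1.0),
        ("semi_axes", (2, 10)),
        ("speckle_shape", -3.0),
    ])
    def test_invalid_spec_rejected(self, field, value):
        import dataclasses
        spec = dataclasses.replace(PhantomSpec(), **{field: value})
        with pytest.raises(ConfigurationError):
            generate_phantom(spec)

    def test_blur_monotonically_softens_rim_gradient(self):
        """Increasing blur_sigma decreases the mean rim gradient magnitude."""
        from nervetrace.phantoms import _ellipse_interior
        means = []
        for blur in (0.0, 1.0, 2.0, 3.0):
            vals = []
            for seed in range(20):
                spec = PhantomSpec(frame_size=(64, 64), center=(32, 32),
                                   semi_axes=(14, 9), blur_sigma=blur,
                                   seed=seed)
                frame, mask = generate_phantom(spec)
                rim = _ellipse_interior(spec.frame_size, spec.center,
                                        spec.semi_axes, spec.rotation,
                                        grow=spec.rim_thickness) \
                    & ~mask.pixels.astype(bool)
                gy, gx = np.gradient(frame.pixels.astype(float))
                vals.append(np.hypot(gy, gx)[rim].mean())
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestGenerateDataset:
    RANGES = {"a": (10.0, 20.0), "b": (7.0, 12.0), "center_jitter": 4.0}
    HARD = {"b": (6.0, 8.0), "aspect": (2.5, 3.0), "blur_sigma": (2.0, 3.0)}

    def test_sizes_and_determinism(self):
        d1 = generate_dataset(40, self.RANGES, seed=5, frame_size=(64, 64),
                              hard_ranges=self.HARD)
        d2 = generate_dataset(40, self.RANGES, seed=5, frame_size=(64, 64),
                              hard_ranges=self.HARD)
        assert len(d1) == 40
        assert all(f.pixels.shape == (64, 64) for f, _, _ in d1)
        for (f1, m1, s1), (f2, m2, s2) in zip(d1, d2):
            assert np.array_equal(f1.pixels, f2.pixels)
            assert s1 == s2

    def test_hard_stratum_fraction(self):
        data = generate_dataset(40, self.RANGES, seed=5, frame_size=(64, 64),
                                hard_fraction=0.25, hard_ranges=self.HARD)
        n_hard = sum(is_hard(s) for _, _, s in data)
        assert n_hard == round(0.25 * 40)

    def test_degenerate_point_ranges_hit_exactly(self):
        ranges = {"a": (15.0, 15.0), "b": (9.0, 9.0), "rotation": (30.0, 30.0),
                  "blur_sigma": (0.5, 0.5), "speckle_shape": (20.0, 20.0),
                  "rim_thickness": (3.0, 3.0), "interior_level": (0.2, 0.2),
                  "background_level": (0.45, 0.45), "rim_level": (0.7, 0.7),
                  "center_jitter": 0.0}
        (_, _, spec), = generate_dataset(1, ranges, seed=0,
                                         frame_size=(64, 64), hard_fraction=0)
        assert spec.semi_axes == (15.0, 9.0)
        assert spec.rotation == 30.0
        assert spec.blur_sigma == 0.5
        assert spec.center == (31.5, 31.5)

    def test_empty_range_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_dataset(5, {"a": (20.0, 10.0)}, frame_size=(64, 64))
        with pytest.raises(ConfigurationError):
            generate_dataset(0, self.RANGES)

    def test_true_area_recoverable_from_spec(self):
        """pi*a*b from the stored spec matches mask pixel count within 3%."""
        data = generate_dataset(10, self.RANGES, seed=9, frame_size=(64, 64),
                                hard_fraction=0)
        for _, mask, spec in data:
            a, b = spec.semi_axes
            assert abs(mask.area() - np.pi * a * b) / (np.pi * a * b) < 0.03


class TestPerturbAnnotation:
    @staticmethod
    def disc(radius=20, size=64):
        yy, xx = np.indices((size, size))
        c = (size - 1) / 2
        return NerveMask(((yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2
                          ).astype(np.uint8))

    def test_magnitude_zero_is_identity(self):
        mask = self.disc()
        out = perturb_annotation(mask, 0.0, seed=3)
        assert np.array_equal(out.pixels, mask.pixels)

    def test_moderate_perturbation_keeps_high_overlap(self):
        mask = self.disc(radius=20)
        ious = []
        for seed in range(1, 101):
            out = perturb_annotation(mask, 2.0, seed=seed)
            _, met = evaluate_pair(out, mask)
            ious.append(met.iou)
        assert min(ious) > 0.7

    def test_single_connected_component(self):
        from scipy import ndimage
        mask = self.disc(radius=15)
        for seed in (1, 2, 3, 4, 5):
            out = perturb_annotation(mask, 4.0, seed=seed)
            _, n = ndimage.label(out.pixels, structure=np.ones((3, 3)))
            assert n == 1
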