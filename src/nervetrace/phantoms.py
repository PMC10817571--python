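"""Synthetic ultrasound phantoms of a nerve cross-section.

Each phantom is a square B-mode-like frame containing one hypoechoic
(dark) elliptical nerve interior surrounded by a hyperechoic (bright)
epineurium rim on a mid-grey background.  The echogenicity map is blurred
with a Gaussian of configurable sigma (outline blur, the hard case for
segmentation), then multiplied by gamma-distributed speckle noise with
mean 1, clipped to [0, 1] and quantised to 8 bits.

Ground truth is geometric, not photometric: the mask marks exactly the
pixels whose centers lie inside the *unblurred* ellipse.  Blur and speckle
degrade the image only, mirroring a fixed anatomical truth seen through
imperfect imaging.

A dataset generator samples phantom parameters uniformly from configurable
ranges, reserving a stratum of elongated (aspect ratio >= 2.5), strongly
blurred (sigma >= 2) nerves -- the failure mode reported for encoder-decoder
segmentation of this anatomy.  An annotation perturber displaces mask
boundaries by a smooth random radial field to emulate imperfect manual
tracing for agreement analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, PhantomSizingError

__all__ = [
    "PhantomSpec",
    "UltrasoundFrame",
    "NerveMask",
    "DEFAULT_RANGES",
    "HARD_RANGES",
    "is_hard",
    "generate_phantom",
    "generate_dataset",
    "perturb_annotation",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Generating parameters of one phantom frame.

    Echogenicity levels are mean reflectivities in [0, 1] and must satisfy
    ``interior_level < background_level < rim_level`` (hypoechoic nerve
    interior, hyperechoic rim).  ``speckle_shape`` is the gamma shape
    parameter of the multiplicative noise (mean 1, variance 1/shape);
    ``None`` or ``inf`` switches the noise off.
    """

    frame_size: tuple[int, int] = (300, 300)
    center: tuple[float, float] = (150.0, 150.0)  # (row, col)
    semi_axes: tuple[float, float] = (25.0, 15.0)  # (a, b) px
    rotation: float = 0.0  # degrees, a-axis vs. image horizontal
    rim_thickness: float = 3.0
    interior_level: float = 0.18
    rim_level: float = 0.75
    background_level: float = 0.45
    blur_sigma: float = 0.0
    speckle_shape: float | None = 30.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.frame_size
        a, b = self.semi_axes
        if not (self.interior_level < self.background_level < self.rim_level):
            raise ConfigurationError(
                "echogenicity must satisfy interior < background < rim")
        if min(a, b) < 3:
            raise ConfigurationError("semi-axes must both be >= 3 px")
        if self.blur_sigma < 0:
            raise ConfigurationError("blur_sigma must be >= 0")
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise ConfigurationError("speckle_shape must be positive")
        r = max(a, b) + self.rim_thickness
        cr, cc = self.center
        if cr - r < 0 or cc - r < 0 or cr + r > h - 1 or cc + r > w - 1:
            raise PhantomSizingError(
                f"ellipse with rim (radius {r:.1f} at {self.center}) does not "
                f"fit inside a {h}x{w} frame")

    @property
    def aspect_ratio(self) -> float:
        a, b = self.semi_axes
        return max(a, b) / min(a, b)


@dataclass
class UltrasoundFrame:
    """8-bit grayscale frame with optional physical calibration."""

    pixels: np.ndarray
    mm_per_pixel: float = 1.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or 0 in self.pixels.shape:
            raise ConfigurationError("frame must be a non-empty 2-D grid")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ConfigurationError("intensities must lie in [0, 255]")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class NerveMask:
    """Binary {0,1} mask aligned 1:1 with its frame."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        vals = np.unique(self.pixels)
        if not np.isin(vals, (0, 1)).all():
            raise ConfigurationError("mask must be exactly binary {0,1}")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self):
        return self.pixels.shape

    def area(self) -> int:
        return int(self.pixels.sum())


def _ellipse_interior(shape, center, semi_axes, rotation_deg, grow=0.0):
    """Boolean grid of pixel centers inside the (optionally grown) ellipse."""
    rr, cc = np.indices(shape, dtype=float)
    cr, ccol = center
    th = math.radians(rotation_deg)
    # u along the a-axis (horizontal at rotation 0), v along the b-axis
    u = (cc - ccol) * math.cos(th) + (rr - cr) * math.sin(th)
    v = -(cc - ccol) * math.sin(th) + (rr - cr) * math.cos(th)
    a, b = semi_axes[0] + grow, semi_axes[1] + grow
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[UltrasoundFrame, NerveMask]:
    """Render one frame and its ground-truth mask, reproducibly from the seed."""
    spec.validate()
    inside = _ellipse_interior(spec.frame_size, spec.center, spec.semi_axes,
                               spec.rotation)
    rim = _ellipse_interior(spec.frame_size, spec.center, spec.semi_axes,
                            spec.rotation, grow=spec.rim_thickness) & ~inside

    echo = np.full(spec.frame_size, spec.background_level)
    echo[rim] = spec.rim_level
    echo[inside] = spec.interior_level
    if spec.blur_sigma > 0:
        echo = ndimage.gaussian_filter(echo, spec.blur_sigma)
    if spec.speckle_shape is not None and np.isfinite(spec.speckle_shape):
        rng = np.random.default_rng(spec.seed)
        k = spec.speckle_shape
        echo = echo * rng.gamma(k, 1.0 / k, size=spec.frame_size)
    img = np.rint(np.clip(echo, 0.0, 1.0) * 255.0).astype(np.uint8)
    return UltrasoundFrame(img), NerveMask(inside.astype(np.uint8))


# Covariate ranges for a 300x300 frame: the nerve occupies a few percent of
# the frame, its rim is 2-4 px, speckle is moderate.  Calibrated once,
# qualitatively, against published example frames.
DEFAULT_RANGES: dict = {
    "a": (18.0, 34.0),
    "b": (10.0, 20.0),
    "rotation": (0.0, 180.0),
    "blur_sigma": (0.0, 1.5),
    "speckle_shape": (15.0, 50.0),
    "rim_thickness": (2.0, 4.0),
    "interior_level": (0.12, 0.25),
    "background_level": (0.38, 0.52),
    "rim_level": (0.65, 0.85),
    "center_jitter": 20.0,
}

# Elongated + blurred stratum: aspect ratio >= 2.5 and blur_sigma >= 2.
HARD_RANGES: dict = {
    "b": (8.0, 12.0),
    "aspect": (2.5, 3.5),
    "blur_sigma": (2.0, 3.5),
}


def is_hard(spec: PhantomSpec) -> bool:
    """Does the spec fall in the elongated + blurred stratum?"""
    return spec.aspect_ratio >= 2.5 and spec.blur_sigma >= 2.0


def _check_range(name, rng_pair):
    lo, hi = rng_pair
    if hi < lo:
        raise ConfigurationError(f"empty range for {name!r}: ({lo}, {hi})")
    return float(lo), float(hi)


def _sample_spec(rng: np.random.Generator, ranges: dict, hard_ranges: dict,
                 frame_size: tuple[int, int], hard: bool, seed: int) -> PhantomSpec:
    def u(name, table=ranges):
        lo, hi = _check_range(name, table[name])
        return lo if lo == hi else rng.uniform(lo, hi)

    if hard:
        b = u("b", hard_ranges)
        a = b * u("aspect", hard_ranges)
        blur = u("blur_sigma", hard_ranges)
    else:
        a, b = u("a"), u("b")
        if a < b:
            a, b = b, a
        blur = u("blur_sigma")
    rim = u("rim_thickness")
    h, w = frame_size
    slack = min(h, w) / 2 - (max(a, b) + rim + 2.0)
    jit = min(float(ranges.get("center_jitter", 0.0)), max(slack, 0.0))
    center = ((h - 1) / 2 + rng.uniform(-jit, jit),
              (w - 1) / 2 + rng.uniform(-jit, jit))
    return PhantomSpec(
        frame_size=frame_size,
        center=center,
        semi_axes=(a, b),
        rotation=u("rotation"),
        rim_thickness=rim,
        interior_level=u("interior_level"),
        rim_level=u("rim_level"),
        background_level=u("background_level"),
        blur_sigma=blur,
        speckle_shape=u("speckle_shape"),
        seed=seed,
    )


def generate_dataset(n: int, covariate_ranges: dict | None = None, seed: int = 0,
                     frame_size: tuple[int, int] = (300, 300),
                     hard_fraction: float = 0.25,
                     hard_ranges: dict | None = None,
                     ) -> list[tuple[UltrasoundFrame, NerveMask, PhantomSpec]]:
    """Sample ``n`` phantoms with parameters drawn uniformly from the ranges.

    ``round(hard_fraction * n)`` of them come from the elongated + blurred
    stratum; which positions are hard is itself a seeded draw.  Each phantom
    gets a child seed derived from ``seed``, and its spec is returned so the
    true morphometry (e.g. area pi*a*b) is recoverable.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    ranges = dict(DEFAULT_RANGES)
    ranges.update(covariate_ranges or {})
    hranges = dict(HARD_RANGES)
    hranges.update(hard_ranges or {})
    for key, val in ranges.items():
        if key != "center_jitter":
            _check_range(key, val)

    rng = np.random.default_rng(seed)
    n_hard = int(round(hard_fraction * n))
    hard_flags = np.zeros(n, dtype=bool)
    hard_flags[rng.permutation(n)[:n_hard]] = True
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=n)

    out = []
    for i in range(n):
        spec = _sample_spec(rng, ranges, hranges, tuple(frame_size),
                            bool(hard_flags[i]), int(child_seeds[i]))
        frame, mask = generate_phantom(spec)
        out.append((frame, mask, spec))
    return out


def perturb_annotation(mask: NerveMask | np.ndarray, magnitude: float,
                       seed: int = 0, n_harmonics: int = 4) -> NerveMask:
    """Displace the mask boundary by a smooth random radial field.

    The boundary moves by ``delta(theta)``, a zero-mean sum of the first
    ``n_harmonics`` Fourier harmonics of the polar angle about the mask
    centroid, scaled so its root-mean-square equals ``magnitude`` pixels.
    Emulates the variability of manual tracing.  Magnitude 0 is the
    identity; the result is kept a single filled connected component.
    """
    pix = np.asarray(getattr(mask, "pixels", mask)).astype(bool)
    if magnitude < 0:
        raise ConfigurationError("magnitude must be >= 0")
    if magnitude == 0 or not pix.any():
        return NerveMask(pix.astype(np.uint8))

    rng = np.random.default_rng(seed)
    coeffs = rng.standard_normal(2 * n_harmonics)
    # RMS over theta of sum_k (a_k cos k t + b_k sin k t) = sqrt(sum c^2 / 2)
    coeffs *= magnitude / math.sqrt((coeffs ** 2).sum() / 2.0)

    rr, cc = np.indices(pix.shape, dtype=float)
    crow, ccol = ndimage.center_of_mass(pix)
    theta = np.arctan2(rr - crow, cc - ccol)
    delta = np.zeros_like(theta)
    for k in range(1, n_harmonics + 1):
        delta += (coeffs[2 * k - 2] * np.cos(k * theta)
                  + coeffs[2 * k - 1] * np.sin(k * theta))

    # signed distance: negative inside, positive outside (pixel units)
    sd = (ndimage.distance_transform_edt(~pix)
          - ndimage.distance_transform_edt(pix))
    new = sd <= delta
    labels, nlab = ndimage.label(new, structure=np.ones((3, 3), dtype=int))
    if nlab > 1:
        sizes = ndimage.sum_labels(new, labels, index=range(1, nlab + 1))
        new = labels == (1 + int(np.argmax(sizes)))
    new = ndimage.binary_fill_holes(new)
    return NerveMask(new.astype(np.uint8))


def with_seed(spec: PhantomSpec, seed: int) -> PhantomSpec:
    """Convenience: the same geometry with a different noise seed."""
    return replace(spec, seed=seed)
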