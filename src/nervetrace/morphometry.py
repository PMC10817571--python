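"""Morphometry of a binary nerve mask.

Measures mirror how sonographic nerve morphology is quantified: the
cross-sectional area (pixel count), the circumference (perimeter of the
traced boundary polygon), and the two longest diameters D1 (radial-ulnar,
within 45 degrees of the image horizontal) and D2 (dorsal-palmar), taken
as the sides of the minimum-area bounding rectangle of the traced outline.

Conventions
-----------
Coordinates are pixel centers, so an axis-aligned W-column by H-row filled
rectangle measures (W-1) x (H-1) across; the optional ``pad_half_pixel``
mode adds one pixel per dimension for area-consistent sizing.  Components
and boundaries use 8-connectivity (Moore neighbourhood).  The minimum-area
rectangle is found over the convex hull of the boundary pixel centers by
edge enumeration (rotating calipers): the optimal rectangle has one side
collinear with a hull edge, so the enumeration is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateMaskError, EmptyMaskError
from .phantoms import NerveMask

__all__ = [
    "MorphMeasures",
    "principal_component_mask",
    "trace_contour",
    "convex_hull",
    "min_area_rect",
    "measure",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class MorphMeasures:
    """Nerve cross-section measures; units follow ``mm_per_pixel``."""

    mncsa: float          # cross-sectional area (px^2 or mm^2)
    circumference: float  # traced-outline perimeter (px or mm)
    d1: float             # radial-ulnar (horizontal-ish) rectangle side
    d2: float             # dorsal-palmar (vertical-ish) rectangle side
    rect_angle: float     # degrees of the D1 side vs. image horizontal

    def as_dict(self) -> dict:
        return {"mncsa": self.mncsa, "circumference": self.circumference,
                "d1": self.d1, "d2": self.d2, "rect_angle": self.rect_angle}


def principal_component_mask(mask: NerveMask | np.ndarray) -> NerveMask:
    """Keep only the largest 8-connected foreground component.

    Model outputs may contain stray blobs; measurements are of one nerve.
    An empty mask passes through unchanged.
    """
    pix = np.asarray(getattr(mask, "pixels", mask)).astype(bool)
    labels, nlab = ndimage.label(pix, structure=_EIGHT)
    if nlab <= 1:
        return NerveMask(pix.astype(np.uint8))
    sizes = ndimage.sum_labels(pix, labels, index=range(1, nlab + 1))
    keep = 1 + int(np.argmax(sizes))
    return NerveMask((labels == keep).astype(np.uint8))


# Moore neighbourhood in clockwise order starting due west, as
# (drow, dcol) offsets.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_contour(mask: NerveMask | np.ndarray) -> np.ndarray:
    """Trace the outer boundary as an ordered closed polygon of pixel centers.

    Moore-neighbour tracing with Jacob's stopping criterion, started from
    the topmost-leftmost foreground pixel.  Vertices are (row, col) pixel
    centers of boundary pixels; consecutive vertices are 8-neighbours (step
    lengths 1 or sqrt 2).  The polygon is returned counter-clockwise in
    standard x=col, y=-row orientation and is implicitly closed (the first
    vertex is not repeated).
    """
    pix = np.asarray(getattr(mask, "pixels", mask)).astype(bool)
    area = int(pix.sum())
    if area == 0:
        raise EmptyMaskError("cannot trace an empty mask")
    if area < 4:
        raise DegenerateMaskError(f"mask area {area} < 4 px is too small to trace")

    padded = np.pad(pix, 1)
    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    b0 = (start[0], start[1] - 1)         # entered from the west (background)

    contour = [start]
    p, b = start, b0
    max_steps = 4 * area + 8
    for _ in range(max_steps):
        # scan the Moore neighbourhood of p clockwise, starting just past b
        off = (b[0] - p[0], b[1] - p[1])
        i0 = _MOORE.index(off)
        nxt = None
        prev = b
        for k in range(1, 9):
            d = _MOORE[(i0 + k) % 8]
            q = (p[0] + d[0], p[1] + d[1])
            if padded[q]:
                nxt = q
                break
            prev = q
        if nxt is None:  # isolated pixel; cannot happen for area >= 4
            break
        p, b = nxt, prev
        if p == start and b == b0:  # Jacob's stopping criterion
            break
        contour.append(p)

    poly = np.array(contour, dtype=float) - 1.0  # undo padding offset
    # enforce counter-clockwise orientation in x=col, y=-row coordinates
    x, y = poly[:, 1], -poly[:, 0]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    if area2 < 0:
        poly = poly[::-1]
    return poly


def _perimeter(poly: np.ndarray) -> float:
    d = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull (Andrew's monotone chain) of (x, y) points, CCW order."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) <= 2:
        return pts
    pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return np.array(lower[:-1] + upper[:-1])


def min_area_rect(points: np.ndarray) -> tuple[float, float, float]:
    """Minimum-area bounding rectangle of (x, y) points.

    Returns ``(width, height, angle_deg)`` where ``width >= height`` is the
    extent along the rectangle direction ``angle_deg`` (in (-90, 90],
    measured from the +x axis) and ``height`` the perpendicular extent.
    Exact by edge enumeration over the convex hull.
    """
    hull = convex_hull(points)
    if len(hull) == 1:
        return 0.0, 0.0, 0.0
    if len(hull) == 2:
        d = hull[1] - hull[0]
        ang = math.degrees(math.atan2(d[1], d[0]))
        return float(np.hypot(*d)), 0.0, _norm_angle(ang)

    best = None
    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    for ex, ey in edges:
        norm = math.hypot(ex, ey)
        if norm == 0:
            continue
        c, s = ex / norm, ey / norm
        u = hull[:, 0] * c + hull[:, 1] * s
        v = -hull[:, 0] * s + hull[:, 1] * c
        w = u.max() - u.min()
        h = v.max() - v.min()
        if best is None or w * h < best[0] - 1e-12:
            best = (w * h, w, h, math.degrees(math.atan2(s, c)))
    _, w, h, ang = best
    if h > w:  # canonical form: longer side first, with its direction
        w, h, ang = h, w, ang + 90.0
    return float(w), float(h), _norm_angle(ang)


def _norm_angle(ang: float) -> float:
    """Fold an angle into (-90, 90] degrees (rectangle directions)."""
    while ang > 90.0:
        ang -= 180.0
    while ang <= -90.0:
        ang += 180.0
    return ang


def _assign_diameters(w: float, h: float, angle: float) -> tuple[float, float, float]:
    """Split rectangle sides into D1 (radial-ulnar, within +/-45 deg of the
    horizontal) and D2 (dorsal-palmar).  At exactly 45 deg, D1 is the longer
    side."""
    a_w = abs(angle)            # direction of the w side vs. horizontal
    a_h = abs(_norm_angle(angle + 90.0))
    if math.isclose(a_w, 45.0, abs_tol=1e-9) and math.isclose(a_h, 45.0,
                                                              abs_tol=1e-9):
        d1, d2 = max(w, h), min(w, h)
        ang1 = angle if w >= h else _norm_angle(angle + 90.0)
    elif a_w <= a_h:
        d1, d2, ang1 = w, h, angle
    else:
        d1, d2, ang1 = h, w, _norm_angle(angle + 90.0)
    return d1, d2, ang1


def measure(mask: NerveMask | np.ndarray, mm_per_pixel: float = 1.0,
            pad_half_pixel: bool = False) -> MorphMeasures:
    """Measure area, circumference and bounding-rectangle diameters.

    The mask should be a single component (apply
    :func:`principal_component_mask` first for model outputs).  Raises
    :class:`EmptyMaskError` / :class:`DegenerateMaskError` on empty or
    sub-4-pixel masks.
    """
    pix = np.asarray(getattr(mask, "pixels", mask)).astype(bool)
    area_px = int(pix.sum())
    poly = trace_contour(pix)  # raises on empty/degenerate
    perim = _perimeter(poly)
    # hull in x=col, y=row coordinates
    xy = poly[:, ::-1].copy()
    w, h, angle = min_area_rect(xy)
    if pad_half_pixel:
        w, h = w + 1.0, h + 1.0
    d1, d2, ang1 = _assign_diameters(w, h, angle)
    s = mm_per_pixel
    return MorphMeasures(mncsa=area_px * s * s, circumference=perim * s,
                         d1=d1 * s, d2=d2 * s, rect_angle=ang1)
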