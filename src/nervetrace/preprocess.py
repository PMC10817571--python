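"""Dataset preparation: cropping, resizing, splitting and flip augmentation.

The study protocol this mirrors: square frames are cropped free of any UI
border, resized to the network input size (bilinear for images, nearest-
neighbour for masks so they stay binary), randomly partitioned into
train/validation/test at proportions 3/4 : 1/12 : 1/6 (600 images give
450/50/100), and the training set is doubled by adding one randomly
flipped copy of every image (vertical, horizontal, or both).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import ConfigurationError, GeometryError
from .phantoms import NerveMask, UltrasoundFrame

__all__ = [
    "DatasetSplit",
    "crop_and_resize",
    "split_dataset",
    "augment_flips",
    "FLIPS",
]

PROPORTIONS = (3 / 4, 1 / 12, 1 / 6)


@dataclass
class DatasetSplit:
    """Disjoint, exhaustive partition of image identifiers."""

    train: list
    validation: list
    test: list
    seed: int
    proportions: tuple = PROPORTIONS

    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))

    def partition_of(self) -> dict:
        out = {}
        for name in ("train", "validation", "test"):
            for i in getattr(self, name):
                out[i] = name
        return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(ids: list, seed: int = 0) -> DatasetSplit:
    """Randomly partition ``ids`` at proportions 3/4 : 1/12 : 1/6.

    Sizes are fixed before shuffling: train = round(3n/4), validation =
    round(n/12), test = the remainder, in that order (half-up rounding).
    """
    ids = list(ids)
    n = len(ids)
    if n < 12:
        raise ConfigurationError(f"need at least 12 ids to split, got {n}")
    n_train = _round_half_up(3 * n / 4)
    n_val = _round_half_up(n / 12)
    perm = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in perm]
    return DatasetSplit(
        train=shuffled[:n_train],
        validation=shuffled[n_train:n_train + n_val],
        test=shuffled[n_train + n_val:],
        seed=seed,
    )


def _resize_frame(pix: np.ndarray, target: int) -> np.ndarray:
    out = _sk_resize(pix.astype(float), (target, target), order=1,
                     preserve_range=True, anti_aliasing=False)
    return np.rint(np.clip(out, 0, 255)).astype(np.uint8)


def _resize_mask(pix: np.ndarray, target: int) -> np.ndarray:
    out = _sk_resize(pix, (target, target), order=0, preserve_range=True,
                     anti_aliasing=False)
    return (out > 0.5).astype(np.uint8)


def crop_and_resize(frame: UltrasoundFrame | np.ndarray, crop_box=None,
                    target: int = 256, mask: NerveMask | np.ndarray | None = None):
    """Crop ``crop_box`` = (row0, col0, height, width) and resize to target.

    Frames are interpolated bilinearly; a paired mask, if given, undergoes
    the identical geometry with nearest-neighbour interpolation and stays
    binary.  Returns the frame, or a (frame, mask) pair.
    """
    pix = np.asarray(getattr(frame, "pixels", frame))
    mmpp = getattr(frame, "mm_per_pixel", 1.0)
    H, W = pix.shape
    if crop_box is None:
        crop_box = (0, 0, H, W)
    r0, c0, h, w = crop_box
    if r0 < 0 or c0 < 0 or h <= 0 or w <= 0 or r0 + h > H or c0 + w > W:
        raise GeometryError(f"crop box {crop_box} exceeds frame bounds {(H, W)}")
    cropped = pix[r0:r0 + h, c0:c0 + w]
    out_frame = UltrasoundFrame(_resize_frame(cropped, target),
                                mm_per_pixel=mmpp * w / target)
    if mask is None:
        return out_frame
    mpix = np.asarray(getattr(mask, "pixels", mask))
    if mpix.shape != (H, W):
        raise GeometryError("mask shape does not match frame shape")
    out_mask = NerveMask(_resize_mask(mpix[r0:r0 + h, c0:c0 + w], target))
    return out_frame, out_mask


#: flip codes: axes of np.flip on a 2-D image
FLIPS = {"vertical": (0,), "horizontal": (1,), "both": (0, 1)}


def _flip_pair(frame, mask, axes):
    fpix = np.flip(np.asarray(getattr(frame, "pixels", frame)), axis=axes)
    mpix = np.flip(np.asarray(getattr(mask, "pixels", mask)), axis=axes)
    return (UltrasoundFrame(fpix.copy(),
                            getattr(frame, "mm_per_pixel", 1.0)),
            NerveMask(mpix.copy()))


def augment_flips(train_pairs: list, seed: int = 0) -> list:
    """Append one randomly flipped copy of every (frame, mask) pair.

    Each image's flip direction (vertical, horizontal or both) is an
    independent seeded draw; frame and mask flip together.  Output length
    is exactly twice the input length, originals first.
    """
    if not train_pairs:
        raise ConfigurationError("augment_flips needs a non-empty input")
    rng = np.random.default_rng(seed)
    names = list(FLIPS)
    choices = rng.integers(0, len(names), size=len(train_pairs))
    flipped = [_flip_pair(f, m, FLIPS[names[c]])
               for (f, m), c in zip(train_pairs, choices)]
    return list(train_pairs) + flipped
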