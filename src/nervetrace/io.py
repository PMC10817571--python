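"""Reading and writing frames, masks and phantom spec tables.

Frames are 8-bit grayscale TIFF or PNG; masks are PNG with values 0/255;
phantom specs serialize to one CSV row per image.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import ConfigurationError
from .phantoms import NerveMask, PhantomSpec, UltrasoundFrame

__all__ = [
    "save_frame", "load_frame", "save_mask", "load_mask",
    "specs_to_csv", "specs_from_csv",
]


def save_frame(frame: UltrasoundFrame, path) -> None:
    path = Path(path)
    pix = np.asarray(frame.pixels, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pix)
    else:
        Image.fromarray(pix, mode="L").save(path)


def load_frame(path, mm_per_pixel: float = 1.0) -> UltrasoundFrame:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pix = tifffile.imread(path)
    else:
        pix = np.asarray(Image.open(path).convert("L"))
    return UltrasoundFrame(pix.astype(np.uint8), mm_per_pixel=mm_per_pixel)


def save_mask(mask: NerveMask, path) -> None:
    pix = (np.asarray(mask.pixels, dtype=np.uint8) * 255)
    Image.fromarray(pix, mode="L").save(Path(path))


def load_mask(path) -> NerveMask:
    arr = np.asarray(Image.open(Path(path)).convert("L"))
    vals = np.unique(arr)
    if not np.isin(vals, (0, 255)).all():
        raise ConfigurationError(f"mask file {path} is not binary 0/255")
    return NerveMask((arr > 0).astype(np.uint8))


_SPEC_COLS = ["image_id", "frame_h", "frame_w", "center_row", "center_col",
              "a", "b", "rotation", "rim_thickness", "interior_level",
              "rim_level", "background_level", "blur_sigma", "speckle_shape",
              "seed"]


def specs_to_csv(specs: list[PhantomSpec], path, ids=None) -> pd.DataFrame:
    ids = ids if ids is not None else list(range(len(specs)))
    rows = []
    for i, s in zip(ids, specs):
        rows.append({
            "image_id": i, "frame_h": s.frame_size[0], "frame_w": s.frame_size[1],
            "center_row": s.center[0], "center_col": s.center[1],
            "a": s.semi_axes[0], "b": s.semi_axes[1], "rotation": s.rotation,
            "rim_thickness": s.rim_thickness, "interior_level": s.interior_level,
            "rim_level": s.rim_level, "background_level": s.background_level,
            "blur_sigma": s.blur_sigma,
            "speckle_shape": np.nan if s.speckle_shape is None else s.speckle_shape,
            "seed": s.seed,
        })
    df = pd.DataFrame(rows, columns=_SPEC_COLS)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def specs_from_csv(path) -> list[tuple[object, PhantomSpec]]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        spec = PhantomSpec(
            frame_size=(int(r.frame_h), int(r.frame_w)),
            center=(float(r.center_row), float(r.center_col)),
            semi_axes=(float(r.a), float(r.b)),
            rotation=float(r.rotation),
            rim_thickness=float(r.rim_thickness),
            interior_level=float(r.interior_level),
            rim_level=float(r.rim_level),
            background_level=float(r.background_level),
            blur_sigma=float(r.blur_sigma),
            speckle_shape=None if pd.isna(r.speckle_shape)
            else float(r.speckle_shape),
            seed=int(r.seed),
        )
        out.append((r.image_id, spec))
    return out
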