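"""Mask-stack I/O, contrast normalization, and area-signal extraction.

The segmentation stage upstream of this package (an aorta tracker fed with
seed prompts) emits one binary lumen mask per axial slice.  The only
quantity the downstream detectors need is the per-slice segmented pixel
count — a proxy for aortic cross-sectional area.  This module reads mask
stacks (multi-page TIFF or a directory of per-slice TIFF/PNG files),
binarizes them, counts pixels, and round-trips the resulting 1D signal
through a two-column CSV table.

Grayscale source images are normalized to 8-bit with linear contrast
stretching to the range [10, 245] before any segmentation model sees them;
:func:`contrast_stretch` implements that map.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .types import AreaSignal, MaskStack

__all__ = [
    "contrast_stretch",
    "load_mask_stack",
    "extract_area_signal",
    "read_signal_table",
    "write_signal_table",
]

_MASK_EXTENSIONS = {".tif", ".tiff", ".png"}


def contrast_stretch(image, lo: int = 10, hi: int = 245) -> np.ndarray:
    """Linearly stretch an image so its observed range maps onto [lo, hi].

    The observed minimum maps to ``lo``, the maximum to ``hi``, intermediate
    values linearly with round-half-up to the nearest integer.  A constant
    image maps everywhere to ``lo``.  Returns an 8-bit image.
    """
    if not (0 <= lo < hi <= 255):
        raise ValueError(f"need 0 <= lo < hi <= 255, got lo={lo}, hi={hi}")
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("cannot stretch an empty image")
    if np.any(image < 0):
        raise ValueError("image values must be nonnegative")
    imin, imax = image.min(), image.max()
    if imax == imin:
        return np.full(image.shape, lo, dtype=np.uint8)
    scaled = lo + (image - imin) * (hi - lo) / (imax - imin)
    return np.floor(scaled + 0.5).astype(np.uint8)  # round half up


def _read_one_slice(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB(A) mask replicas to one channel
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D mask, got shape {arr.shape}")
    return arr


def load_mask_stack(path: str | os.PathLike, patient_id: str | None = None) -> MaskStack:
    """Load a mask stack from a multi-page TIFF or a directory of slices.

    Directory entries are ordered lexicographically by filename; multi-page
    TIFF pages keep their page order.  Any nonzero pixel is binarized to 1.
    """
    path = Path(path)
    if patient_id is None:
        patient_id = path.stem if path.is_file() else path.name
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _MASK_EXTENSIONS
        )
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG slices found in {path}")
        slices = [_read_one_slice(p) for p in files]
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise ValueError(
                f"inconsistent slice dimensions in {path}: {sorted(shapes)}"
            )
        stack = np.stack(slices)
    elif path.is_file():
        stack = tifffile.imread(path)
        stack = np.asarray(stack)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim == 4:  # pages with a trailing channel axis
            stack = stack[..., 0]
        if stack.ndim != 3:
            raise ValueError(
                f"{path}: expected a (pages, h, w) TIFF, got shape {stack.shape}"
            )
    else:
        raise FileNotFoundError(f"no such file or directory: {path}")
    return MaskStack(patient_id=patient_id, slices=stack)


def extract_area_signal(stack: MaskStack) -> AreaSignal:
    """Count segmented (value-1) pixels per slice."""
    counts = stack.slices.reshape(stack.n, -1).sum(axis=1, dtype=np.int64)
    return AreaSignal(patient_id=stack.patient_id, counts=counts)


def write_signal_table(signal: AreaSignal, path: str | os.PathLike) -> None:
    """Write the signal as a two-column CSV ``slice_index,pixel_count``."""
    df = pd.DataFrame(
        {"slice_index": np.arange(signal.n), "pixel_count": signal.counts}
    )
    df.to_csv(path, index=False)


def read_signal_table(path: str | os.PathLike, patient_id: str | None = None) -> AreaSignal:
    """Read a ``slice_index,pixel_count`` CSV back into an :class:`AreaSignal`.

    Slice indices must be consecutive from 0 and counts nonnegative.
    """
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["slice_index", "pixel_count"]
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {expected}, got {list(df.columns)}"
        )
    idx = df["slice_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(idx))):
        raise ValueError(f"{path}: slice_index must run consecutively from 0")
    counts = df["pixel_count"].to_numpy()
    if np.any(counts < 0):
        raise ValueError(f"{path}: negative pixel counts")
    if patient_id is None:
        patient_id = path.stem
    return AreaSignal(patient_id=patient_id, counts=counts)
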