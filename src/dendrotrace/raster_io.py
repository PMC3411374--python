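"""Raster image input/output and basic geometry.

Images are plain numpy arrays with a fixed convention used throughout the
package:

* ``RasterImage`` — ``uint8`` array of shape ``(height, width, 3)`` (RGB);
* ``GrayImage``   — ``uint8`` array of shape ``(height, width)``;
* ``BinaryImage`` — ``bool`` array of shape ``(height, width)``, ``True`` is
  foreground (black ink), ``False`` is background (white paper).

Coordinates are ``(row, col)``, 0-based, origin at the top-left corner.
Supported file formats are PNG, JPEG and GIF; an alpha channel is composited
onto white on load because tree figures are assumed to sit on a light
background.
"""

from __future__ import annotations

import os
from typing import NamedTuple

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import BoundsError, FormatError

__all__ = ["Rect", "load_image", "save_image", "to_grayscale", "crop"]

_SUPPORTED = {"PNG", "JPEG", "GIF"}
_EXT_FORMAT = {
    ".png": "PNG",
    ".jpg": "JPEG",
    ".jpeg": "JPEG",
    ".gif": "GIF",
}

# ITU-R BT.601 luminance weights.
_LUMA = np.array([0.299, 0.587, 0.114])


class Rect(NamedTuple):
    """Axis-aligned crop rectangle in (row, col) coordinates."""

    top: int
    left: int
    height: int
    width: int

    def check_inside(self, shape: tuple[int, ...]) -> None:
        h, w = shape[0], shape[1]
        if self.height < 1 or self.width < 1:
            raise BoundsError(f"rectangle {self} has empty extent")
        if self.top < 0 or self.left < 0 or self.top + self.height > h or self.left + self.width > w:
            raise BoundsError(f"rectangle {self} does not fit inside a {h}x{w} image")


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG/GIF file into an RGB ``RasterImage``.

    Alpha (or GIF transparency) is composited onto a white background.
    Anything else — including PDF — is rejected with :class:`FormatError`.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".pdf":
        raise FormatError(
            "PDF is not supported; extract the figure to PNG/JPEG/GIF first"
        )
    try:
        with Image.open(path) as im:
            fmt = im.format
            if fmt not in _SUPPORTED:
                raise FormatError(f"unsupported image format {fmt!r} (need PNG, JPEG or GIF)")
            rgba = im.convert("RGBA")
    except UnidentifiedImageError as exc:
        raise FormatError(f"cannot identify image file {path!r}") from exc
    arr = np.asarray(rgba, dtype=np.float64)
    alpha = arr[..., 3:4] / 255.0
    rgb = arr[..., :3] * alpha + 255.0 * (1.0 - alpha)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def save_image(img: np.ndarray, path: str | os.PathLike, format: str | None = None) -> None:
    """Write an image array (raster, gray or binary) to PNG/JPEG/GIF.

    Binary arrays are written as black-on-white. PNG and GIF round-trip
    pixel-exactly through :func:`load_image`.
    """
    path = os.fspath(path)
    if format is None:
        try:
            format = _EXT_FORMAT[os.path.splitext(path)[1].lower()]
        except KeyError:
            raise FormatError(f"cannot infer format from path {path!r}")
    format = format.upper()
    if format == "JPG":
        format = "JPEG"
    if format not in _SUPPORTED:
        raise FormatError(f"unsupported output format {format!r}")
    arr = np.asarray(img)
    if arr.dtype == bool:
        arr = np.where(arr, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        mode = "L"
    elif arr.ndim == 3 and arr.shape[2] == 3:
        mode = "RGB"
    else:
        raise FormatError(f"cannot save array of shape {arr.shape}")
    try:
        Image.fromarray(arr.astype(np.uint8), mode=mode).save(path, format=format)
    except OSError as exc:
        raise OSError(f"cannot write image to {path!r}: {exc}") from exc


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB raster to a ``GrayImage`` by BT.601 luminance.

    Pixels that are already gray (equal channels) are returned unchanged,
    so the conversion is idempotent on gray content.
    """
    arr = np.asarray(img)
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    gray = np.rint(arr.astype(np.float64) @ _LUMA)
    return np.clip(gray, 0, 255).astype(np.uint8)


def crop(img: np.ndarray, region: Rect) -> np.ndarray:
    """Return the sub-image covered by ``region`` (copy)."""
    arr = np.asarray(img)
    region.check_inside(arr.shape)
    return arr[region.top : region.top + region.height, region.left : region.left + region.width].copy()
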