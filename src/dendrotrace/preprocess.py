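"""Preprocessing toolbox: turn any supported image into a clean line drawing.

Everything downstream of this module works on a ``BinaryImage`` (bool array,
``True`` = foreground ink). The tools here mirror what a user of an
interactive figure editor would do by hand — thresholding, gray-level
filtering, pencil/rubber/line/fill strokes, and a "white halo" that detaches
lettering from nearby tree lines — but are deterministic functions so an
entire correction session can be replayed from an edit script.

Conventions
-----------
* Binarization: a pixel is foreground iff its intensity is *strictly below*
  the threshold (dark ink on light paper; use the ``invert`` filter first for
  light-on-dark figures).
* The AUTO global threshold maximizes Otsu's between-class variance by
  exhaustive scan over all 256 cut points, computed in exact integer
  arithmetic (first maximum wins on ties).
* Local thresholding is mean-minus-offset over an odd window with edge
  replication, again in exact integer arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi

from .errors import BoundsError, ParameterError
from .raster_io import Rect

__all__ = [
    "AUTO",
    "EditStroke",
    "threshold_global",
    "threshold_local",
    "otsu_threshold",
    "apply_filter",
    "draw_edit",
    "white_halo",
]

AUTO = "auto"

_S8 = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


@dataclass(frozen=True)
class EditStroke:
    """One drawing gesture: pencil, rubber, line or fill.

    ``points`` is an ordered polyline in (row, col); ``radius`` widens pencil
    and rubber strokes to a square brush of side ``2*radius + 1`` (chessboard
    ball). ``fill`` takes a single seed point and flips the 4-connected
    region of the seed's state.
    """

    kind: Literal["pencil", "rubber", "line", "fill"]
    points: Sequence[tuple[int, int]] = field(default_factory=list)
    radius: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("pencil", "rubber", "line", "fill"):
            raise ParameterError(f"unknown stroke kind {self.kind!r}")
        if not self.points:
            raise ParameterError("stroke needs at least one point")
        if self.kind == "fill" and len(self.points) != 1:
            raise ParameterError("fill takes exactly one seed point")
        if self.radius < 0:
            raise ParameterError("stroke radius must be >= 0")


def otsu_threshold(img: np.ndarray) -> int:
    """Otsu's threshold by exhaustive between-class variance maximization.

    Returns the cut point ``t`` such that foreground = intensity < ``t``.
    The between-class variance ``w0*w1*(mu0-mu1)^2`` is compared as exact
    integer cross-products, so the result is free of floating-point ties.
    """
    arr = np.asarray(img)
    hist = np.bincount(arr.ravel().astype(np.int64), minlength=256)
    counts = [int(c) for c in hist]
    total = sum(counts)
    total_sum = sum(v * c for v, c in enumerate(counts))
    best_t, best_num, best_den = 0, 0, 1
    w0 = 0
    s0 = 0
    for t in range(1, 256):
        w0 += counts[t - 1]
        s0 += (t - 1) * counts[t - 1]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        # w0*w1*(mu0-mu1)^2 == (s0*w1 - (S-s0)*w0)^2 / (w0*w1)
        num = (s0 * w1 - (total_sum - s0) * w0) ** 2
        den = w0 * w1
        if num * best_den > best_num * den:
            best_t, best_num, best_den = t, num, den
    if best_num == 0:
        # constant (or empty-class) image: no cut separates anything
        return int(arr.min()) if arr.size else 0
    return best_t


def threshold_global(img: np.ndarray, t: int | str = AUTO) -> np.ndarray:
    """Binarize: foreground iff intensity < ``t``; ``t=AUTO`` uses Otsu."""
    arr = np.asarray(img)
    if t == AUTO:
        t = otsu_threshold(arr)
    return arr < int(t)


def threshold_local(img: np.ndarray, window: int, offset: int = 0) -> np.ndarray:
    """Adaptive mean threshold: foreground iff v < mean(window) - offset.

    The window mean is edge-replicated and the comparison is carried out on
    integer window sums, so boundary cases (constant images, offset 0) behave
    exactly as stated: a pixel equal to its neighborhood mean is background.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    arr = np.asarray(img).astype(np.int64)
    r = window // 2
    padded = np.pad(arr, r, mode="edge")
    # exact sliding-window sum via 2D cumulative sums
    cs = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1), dtype=np.int64)
    cs[1:, 1:] = padded.cumsum(0).cumsum(1)
    h, w = arr.shape
    win_sum = (
        cs[window : window + h, window : window + w]
        - cs[:h, window : window + w]
        - cs[window : window + h, :w]
        + cs[:h, :w]
    )
    n = window * window
    # v < sum/n - offset  <=>  v*n < sum - offset*n   (exact in integers)
    return arr * n < win_sum - int(offset) * n


_FILTERS = (
    "median",
    "minimum",
    "blur",
    "sharpen",
    "lighten",
    "darken",
    "invert",
    "histogram_stretch",
)


def apply_filter(img: np.ndarray, kind: str, param: int | None = None) -> np.ndarray:
    """Apply one gray-level filter and return a new ``GrayImage``.

    ``param`` is the odd window size for median/minimum/blur/sharpen and the
    additive amount for lighten/darken; invert and histogram_stretch take no
    parameter.
    """
    arr = np.asarray(img).astype(np.uint8)
    if kind not in _FILTERS:
        raise ParameterError(f"unknown filter kind {kind!r}; choose one of {_FILTERS}")
    if kind in ("median", "minimum", "blur", "sharpen"):
        window = 3 if param is None else int(param)
        if window < 1 or window % 2 == 0:
            raise ParameterError(f"{kind} window must be odd, got {window}")
    if kind == "median":
        return ndi.median_filter(arr, size=window, mode="nearest")
    if kind == "minimum":
        return ndi.minimum_filter(arr, size=window, mode="nearest")
    if kind == "blur":
        out = ndi.uniform_filter(arr.astype(np.float64), size=window, mode="nearest")
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if kind == "sharpen":
        blur = ndi.uniform_filter(arr.astype(np.float64), size=window, mode="nearest")
        out = 2.0 * arr - blur  # unsharp mask, unit amount
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if kind == "lighten":
        amount = 16 if param is None else int(param)
        return np.clip(arr.astype(np.int64) + amount, 0, 255).astype(np.uint8)
    if kind == "darken":
        amount = 16 if param is None else int(param)
        return np.clip(arr.astype(np.int64) - amount, 0, 255).astype(np.uint8)
    if kind == "invert":
        return (255 - arr.astype(np.int64)).astype(np.uint8)
    # histogram_stretch
    lo, hi = int(arr.min()), int(arr.max())
    if lo == hi:
        return arr.copy()
    out = (arr.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _bresenham(p0: tuple[int, int], p1: tuple[int, int]) -> list[tuple[int, int]]:
    """Integer line rasterization between two (row, col) points, inclusive."""
    r0, c0 = p0
    r1, c1 = p1
    dr = abs(r1 - r0)
    dc = abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dc - dr
    out = []
    r, c = r0, c0
    while True:
        out.append((r, c))
        if (r, c) == (r1, c1):
            break
        e2 = 2 * err
        if e2 > -dr:
            err -= dr
            c += sc
        if e2 < dc:
            err += dc
            r += sr
    return out


def draw_edit(img: np.ndarray, stroke: EditStroke) -> np.ndarray:
    """Apply one stroke to a ``BinaryImage`` and return the edited copy."""
    mask = np.asarray(img).astype(bool).copy()
    h, w = mask.shape
    for r, c in stroke.points:
        if not (0 <= r < h and 0 <= c < w):
            raise BoundsError(f"stroke point ({r},{c}) outside {h}x{w} image")
    if stroke.kind == "fill":
        seed = tuple(stroke.points[0])
        state = mask[seed]
        lbl, _ = ndi.label(mask == state)  # 4-connected regions of seed's state
        mask[lbl == lbl[seed]] = not state
        return mask
    value = stroke.kind in ("pencil", "line")
    pts = list(stroke.points)
    pixels: list[tuple[int, int]] = []
    if len(pts) == 1:
        pixels = [tuple(pts[0])]
    else:
        for a, b in zip(pts, pts[1:]):
            pixels.extend(_bresenham(tuple(a), tuple(b)))
    rad = stroke.radius
    for r, c in pixels:
        r0, r1 = max(0, r - rad), min(h, r + rad + 1)
        c0, c1 = max(0, c - rad), min(w, c + rad + 1)
        mask[r0:r1, c0:c1] = value
    return mask


def white_halo(img: np.ndarray, region: Rect, thickness: int = 1) -> np.ndarray:
    """Surround drawings inside ``region`` with a white border.

    Every 8-connected foreground component lying *entirely inside* the region
    keeps its own pixels, but everything else within chessboard distance
    ``thickness`` of it (and inside the region) is forced to background.
    This detaches text glyphs from tree lines that pass close by. Components
    that cross the region boundary produce no halo and their pixels outside
    any halo are untouched.
    """
    if thickness < 1:
        raise ParameterError("halo thickness must be >= 1")
    mask = np.asarray(img).astype(bool).copy()
    region.check_inside(mask.shape)
    r0, c0 = region.top, region.left
    r1, c1 = r0 + region.height, c0 + region.width
    labels, n = ndi.label(mask, structure=_S8)
    if n == 0:
        return mask
    inside_box = np.zeros_like(mask)
    inside_box[r0:r1, c0:c1] = True
    outside_labels = np.unique(labels[~inside_box & (labels > 0)])
    inner = np.zeros_like(mask)
    for lbl in np.unique(labels[inside_box & (labels > 0)]):
        if lbl in outside_labels:
            continue  # crosses the region boundary: no halo
        inner |= labels == lbl
    if not inner.any():
        return mask
    footprint = np.ones((2 * thickness + 1, 2 * thickness + 1), dtype=bool)
    halo = ndi.binary_dilation(inner, structure=footprint) & ~inner & inside_box
    mask[halo] = False
    return mask
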