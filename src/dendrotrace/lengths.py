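"""Measure branch lengths in pixels and calibrate them to user units.

Two measurement modes mirror the two figure styles:

* **freeform** — the drawn length of the branch carries the signal, so the
  length is the geometric length of the whole pixel path (axial steps count
  1, diagonal steps sqrt(2));
* **rectangular** — only horizontal extent encodes branch length; vertical
  connectors are layout. The path is segmented into maximal straight runs
  and only runs whose angle to the horizontal is within a slope tolerance
  contribute their geometric length.

Run segmentation uses the 8-way step direction, smoothed by a majority vote
over a 5-step window so that the staircase aliasing of slightly rotated
scans does not shatter a branch into many tiny runs. The default slope
tolerance of 10 degrees keeps the horizontal portions of mildly rotated
figures (a few degrees of scanner skew) while excluding diagonal edges.

A scale bar of known length converts pixels into substitution units; user
overrides replace computed values verbatim and are flagged as manual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

from .errors import ParameterError
from .trace import Branch, TreeGraph

__all__ = [
    "TreeTypeChoice",
    "ScaleBar",
    "BranchLength",
    "path_length_freeform",
    "path_length_rectangular",
    "calibrate",
]

_SQRT2 = math.sqrt(2.0)
_SMOOTH_WINDOW = 5  # steps, for the majority vote on direction codes


@dataclass(frozen=True)
class TreeTypeChoice:
    """Figure style; must be chosen before branches are measured."""

    kind: Literal["freeform", "rectangular"]
    slope_tolerance: float = 10.0  # degrees, rectangular mode only

    def __post_init__(self) -> None:
        if self.kind not in ("freeform", "rectangular"):
            raise ParameterError(f"unknown tree type {self.kind!r}")
        if self.slope_tolerance < 0:
            raise ParameterError("slope tolerance must be >= 0")


@dataclass(frozen=True)
class ScaleBar:
    """A line of known length in the image, e.g. a printed scale bar."""

    pixel_length: float
    unit_length: float

    def __post_init__(self) -> None:
        if not (self.pixel_length > 0 and self.unit_length > 0):
            raise ParameterError("scale bar lengths must be positive")

    @property
    def units_per_pixel(self) -> float:
        return self.unit_length / self.pixel_length


@dataclass(frozen=True)
class BranchLength:
    value: float
    provenance: Literal["computed", "scaled", "manual"]


def _step_lengths(path) -> list[float]:
    out = []
    for (r0, c0), (r1, c1) in zip(path, path[1:]):
        out.append(1.0 if r0 == r1 or c0 == c1 else _SQRT2)
    return out


def path_length_freeform(b: Branch) -> float:
    """Geometric length of the whole pixel path (pixels)."""
    if not b.path:
        if b.manual_length is None:
            raise ParameterError("branch has neither a pixel path nor a manual length")
        return b.manual_length
    return sum(_step_lengths(b.path))


def _direction_codes(path) -> list[int]:
    codes = []
    for (r0, c0), (r1, c1) in zip(path, path[1:]):
        codes.append((r1 - r0 + 1) * 3 + (c1 - c0 + 1))  # 0..8, 4 impossible
    return codes


def _smooth_majority(codes: list[int], window: int = _SMOOTH_WINDOW) -> list[int]:
    half = window // 2
    out = []
    for i, code in enumerate(codes):
        lo, hi = max(0, i - half), min(len(codes), i + half + 1)
        seg = codes[lo:hi]
        counts: dict[int, int] = {}
        for x in seg:
            counts[x] = counts.get(x, 0) + 1
        best = max(counts.values())
        if counts[code] == best:
            out.append(code)  # keep own direction on ties
        else:
            out.append(min(c for c, n in counts.items() if n == best))
    return out


def path_length_rectangular(b: Branch, tol: float = 10.0) -> float:
    """Sum of the geometric lengths of the near-horizontal runs (pixels).

    The path is split where the (majority-smoothed) step direction changes;
    a run contributes iff the angle between its endpoints and the horizontal
    is at most ``tol`` degrees.
    """
    if not b.path:
        if b.manual_length is None:
            raise ParameterError("branch has neither a pixel path nor a manual length")
        return b.manual_length
    if len(b.path) < 2:
        return 0.0
    steps = _step_lengths(b.path)
    codes = _smooth_majority(_direction_codes(b.path))
    total = 0.0
    run_start = 0
    for i in range(1, len(codes) + 1):
        if i == len(codes) or codes[i] != codes[run_start]:
            # angle from the run interior: the first and last pixel of a run
            # sit on the elbow (or a junction snapped off the line) and would
            # bias short runs, so trim one pixel per side when possible
            if i - run_start >= 3:
                p0, p1 = b.path[run_start + 1], b.path[i - 1]
            else:
                p0, p1 = b.path[run_start], b.path[i]
            dr, dc = abs(p1[0] - p0[0]), abs(p1[1] - p0[1])
            angle = math.degrees(math.atan2(dr, dc))
            if angle <= tol:
                total += sum(steps[run_start:i])
            run_start = i
    return total


def measure_branch(b: Branch, choice: TreeTypeChoice) -> float:
    if choice.kind == "freeform":
        return path_length_freeform(b)
    return path_length_rectangular(b, tol=choice.slope_tolerance)


def calibrate(
    g: TreeGraph,
    choice: TreeTypeChoice,
    bar: ScaleBar | None = None,
    overrides: Mapping[tuple[int, int], float] | None = None,
) -> dict[tuple[int, int], BranchLength]:
    """Per-branch lengths in units (or raw pixels without a scale bar).

    ``overrides`` maps branch keys (sorted endpoint id pairs) to lengths that
    are already in final units and replace the computed value verbatim.
    """
    overrides = {tuple(sorted(k)): v for k, v in (overrides or {}).items()}
    for key, v in overrides.items():
        if not v > 0:
            raise ParameterError(f"override for branch {key} must be positive, got {v}")
    factor = bar.units_per_pixel if bar is not None else 1.0
    out: dict[tuple[int, int], BranchLength] = {}
    for b in g.branches:
        key = b.key
        if key in overrides:
            out[key] = BranchLength(value=float(overrides[key]), provenance="manual")
            continue
        px = measure_branch(b, choice)
        prov = "manual" if (not b.path and b.manual_length is not None) else (
            "scaled" if bar is not None else "computed"
        )
        out[key] = BranchLength(value=px * factor, provenance=prov)
    return out
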