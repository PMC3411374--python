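"""Select the connected foreground component that constitutes the tree.

After thinning, the image may still contain lettering fragments, scale bars
or border decorations. The recognition pipeline operates only on the flooded
component: everything 8-connected to a seed pixel chosen on the tree. In
headless runs without a seed the largest foreground component is taken —
in practice the tree is the biggest structure in a figure — and a warning
records the assumption.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import SeedError
from .skeleton import Skeleton

__all__ = ["ComponentMask", "flood", "largest_component"]

logger = logging.getLogger(__name__)

_S8 = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class ComponentMask:
    """Boolean membership grid of one 8-connected skeleton component."""

    member: np.ndarray  # bool (H, W)
    seed: tuple[int, int]

    @property
    def count(self) -> int:
        return int(self.member.sum())


def flood(skel: Skeleton, seed: tuple[int, int]) -> ComponentMask:
    """All skeleton foreground 8-connected to ``seed``.

    Raises :class:`SeedError` if the seed is on background — pick a pixel
    that lies on the tree.
    """
    mask = skel.pixels
    r, c = seed
    h, w = mask.shape
    if not (0 <= r < h and 0 <= c < w) or not mask[r, c]:
        raise SeedError(
            f"seed ({r},{c}) is not on the skeleton foreground; "
            "choose a pixel on the tree"
        )
    labels, _ = ndi.label(mask, structure=_S8)
    return ComponentMask(member=labels == labels[r, c], seed=(r, c))


def largest_component(
    skel: Skeleton, include_fragments: bool = True, fragment_fraction: float = 0.05
) -> ComponentMask:
    """Headless default: flood the largest foreground component.

    A broken tree (gaps where lettering was erased, scanning dropouts)
    splits into several large fragments; silently recognizing only the
    biggest would return a plausible-looking subtree. With
    ``include_fragments`` (the default) every component whose size is at
    least ``fragment_fraction`` of the largest is kept in the mask, so the
    break surfaces as a disconnection diagnostic downstream instead of
    being ignored. Tiny components (specks, detached glyphs) are still
    dropped. Pass a seed to :func:`flood` for strict single-component
    selection.
    """
    labels, n = ndi.label(skel.pixels, structure=_S8)
    if n == 0:
        raise SeedError("image has no foreground; nothing to flood")
    sizes = ndi.sum_labels(skel.pixels, labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    coords = np.argwhere(labels == best)
    seed = tuple(int(x) for x in coords[0])
    member = labels == best
    kept = 1
    if include_fragments and n > 1:
        floor = fragment_fraction * float(sizes[best - 1])
        for lbl in range(1, n + 1):
            if lbl != best and sizes[lbl - 1] >= floor:
                member |= labels == lbl
                kept += 1
    if n > 1:
        logger.warning(
            "no flood seed given; treating %d of %d components as the tree "
            "(largest %d px, seed %s)", kept, n, int(sizes[best - 1]), seed,
        )
    return ComponentMask(member=member, seed=seed)
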