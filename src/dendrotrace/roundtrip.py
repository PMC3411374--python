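"""Render -> recognize -> compare: the package's end-to-end check.

A source Newick tree is drawn by the fixture renderer, optionally perturbed,
pushed through the full recognition pipeline, and the recovered tree is
compared with the source: Robinson–Foulds distance for the topology, and
per-branch pixel-length errors (matched by bipartition) for the metric part.
Tips are identified by position — each ground-truth tip coordinate names the
nearest detected tip — mirroring how a user reads labels off the figure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .metrics import bipartition_lengths, rf_distance
from .pipeline import PipelineConfig, PipelineResult, run_pipeline
from .render import GroundTruth, RenderSpec, perturb, render_tree

__all__ = ["RoundTripResult", "roundtrip", "run_on_render"]


@dataclass
class RoundTripResult:
    rf: int | None  # None if the pipeline failed validation
    newick: str | None
    result: PipelineResult
    truth: GroundTruth
    branch_errors: dict[frozenset, float] = field(default_factory=dict)  # |measured - true| px
    true_lengths: dict[frozenset, float] = field(default_factory=dict)
    unmatched: int = 0  # recovered edges with no ground-truth partner

    @property
    def ok(self) -> bool:
        return self.rf == 0

    @property
    def max_branch_error(self) -> float:
        return max(self.branch_errors.values(), default=math.nan)


def run_on_render(
    image: np.ndarray, truth: GroundTruth, **pipeline_kwargs
) -> tuple[PipelineResult, list[dict]]:
    """Run the pipeline on a rendered image, naming tips from ground truth."""
    anchors = [{"pos": list(pos), "name": name} for name, pos in truth.tip_positions.items()]
    cfg = PipelineConfig(image=image, tip_names=anchors, **pipeline_kwargs)
    return run_pipeline(cfg), anchors


def roundtrip(
    newick: str,
    spec: RenderSpec,
    tree_type: str = "rectangular",
    slope_tolerance: float = 10.0,
    edit_script=None,
) -> RoundTripResult:
    """Full render-and-recognize cycle for one source tree."""
    image, truth = render_tree(newick, spec)
    if spec.rotation or spec.gaps or spec.label_overlap or spec.noise:
        image, truth = perturb(image, spec, truth)
    result, _ = run_on_render(
        image,
        truth,
        tree_type=tree_type,
        slope_tolerance=slope_tolerance,
        edit_script=edit_script,
    )
    if not result.ok:
        return RoundTripResult(rf=None, newick=None, result=result, truth=truth)

    rf = rf_distance(truth.newick, result.newick)
    true_px = {
        b.clade: b.length_px_horizontal if tree_type == "rectangular" else b.length_px_total
        for b in truth.branches
    }
    # canonicalize clades the same way bipartition_lengths does
    all_taxa = frozenset(truth.tip_positions)
    anchor = min(all_taxa)
    canon: dict[frozenset, float] = {}
    for clade, px in true_px.items():
        if len(clade) == len(all_taxa):
            continue
        key = clade if anchor not in clade else all_taxa - clade
        canon[key] = canon.get(key, 0.0) + px
    measured = bipartition_lengths(result.newick)
    errors: dict[frozenset, float] = {}
    unmatched = 0
    for key, m in measured.items():
        if key in canon:
            errors[key] = abs(m - canon[key])
        else:
            unmatched += 1
    return RoundTripResult(
        rf=rf,
        newick=result.newick,
        result=result,
        truth=truth,
        branch_errors=errors,
        true_lengths=canon,
        unmatched=unmatched,
    )
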