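"""Headless orchestration of the full image-to-Newick workflow.

The recognition procedure is a fixed succession of stages — load, grayscale,
preprocess, binarize, skeletonize, flood, detect nodes, trace branches,
measure, calibrate, name, root, serialize — in which an interactive user
would inspect intermediate results and correct them. Here the corrections
are supplied up front as an *edit script*: an ordered list of operations
(gray-level filters, threshold choice, pencil/rubber/line/fill strokes,
white halo, node edits, manual branches, length overrides). Each operation
is applied at its natural stage, preserving script order within a stage, so
a whole correction session replays deterministically.

If the traced graph fails validation the pipeline does not crash: it returns
the diagnostics so the caller can extend the edit script and re-run —
the usual correct-and-repeat loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from . import newick as newick_mod
from . import preprocess, raster_io
from .component import ComponentMask, flood, largest_component
from .errors import ConfigError
from .lengths import BranchLength, ScaleBar, TreeTypeChoice, calibrate
from .nodes import NodeEdit, NodeSet, detect_nodes, edit_nodes
from .skeleton import Skeleton, skeletonize
from .trace import TreeGraph, add_manual_branch, trace_branches, validate

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_edit_script"]

logger = logging.getLogger(__name__)

_GRAY_OPS = {"filter"}
_THRESHOLD_OPS = {"threshold_global", "threshold_local"}
_BINARY_OPS = {"pencil", "rubber", "line", "fill", "white_halo"}
_NODE_OPS = {"add_node", "move_node", "remove_node"}
_BRANCH_OPS = {"add_branch"}
_LENGTH_OPS = {"set_length"}
_ALL_OPS = _GRAY_OPS | _THRESHOLD_OPS | _BINARY_OPS | _NODE_OPS | _BRANCH_OPS | _LENGTH_OPS


@dataclass
class PipelineConfig:
    """Everything needed for one headless conversion run."""

    input_path: str | None = None
    image: np.ndarray | None = None  # alternative to input_path
    edit_script: Sequence[Mapping[str, Any]] | str | None = None
    tree_type: str = "rectangular"
    slope_tolerance: float = 10.0
    seed_point: tuple[int, int] | None = None
    threshold: int | str = preprocess.AUTO
    scale_bar: ScaleBar | None = None
    tip_names: Any = newick_mod.AUTO  # AUTO | {tip_id: name} | [{"pos": [r,c], "name": ...}]
    root: int | str = newick_mod.AUTO
    with_lengths: bool = True
    precision: int = 6

    def validate(self) -> None:
        if (self.input_path is None) == (self.image is None):
            raise ConfigError("provide exactly one of input_path or image")
        if self.tree_type not in ("freeform", "rectangular"):
            raise ConfigError(f"tree type must be freeform or rectangular, not {self.tree_type!r}")


@dataclass
class PipelineResult:
    newick: str | None
    diagnostics: list
    graph: TreeGraph | None = None
    names: dict[int, str] = field(default_factory=dict)
    branch_lengths: dict[tuple[int, int], BranchLength] = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)
    snapshots: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.newick is not None

    def report_rows(self) -> list[tuple[str, str, str]]:
        """Per-branch (endpoints, length, provenance) for a TSV report."""
        return [
            (f"{a}-{b}", f"{bl.value:.6g}", bl.provenance)
            for (a, b), bl in sorted(self.branch_lengths.items())
        ]


def load_edit_script(source) -> list[dict[str, Any]]:
    """Read an edit script: a YAML/JSON list of {op: ..., params} mappings."""
    if source is None:
        return []
    if isinstance(source, (list, tuple)):
        ops = list(source)
    else:
        with open(source) as fh:
            ops = yaml.safe_load(fh) or []
    if not isinstance(ops, list):
        raise ConfigError("edit script must be a list of operations")
    for op in ops:
        if not isinstance(op, dict) or "op" not in op:
            raise ConfigError(f"malformed edit-script entry: {op!r}")
        if op["op"] not in _ALL_OPS:
            raise ConfigError(f"unknown edit-script op {op['op']!r}")
    return ops


def _as_points(raw) -> list[tuple[int, int]]:
    return [(int(r), int(c)) for r, c in raw]


def run_pipeline(cfg: PipelineConfig, snapshot: bool = False) -> PipelineResult:
    """Run the whole workflow; returns diagnostics instead of raising on an
    invalid traced graph."""
    cfg.validate()
    script = load_edit_script(cfg.edit_script)
    stages: list[str] = []
    snaps: dict[str, np.ndarray] = {}

    def log(stage: str, msg: str, image: np.ndarray | None = None) -> None:
        stages.append(f"{stage}: {msg}")
        logger.info("%s: %s", stage, msg)
        if snapshot and image is not None:
            snaps[stage] = image.copy()

    if cfg.image is not None:
        raster = np.asarray(cfg.image)
    else:
        raster = raster_io.load_image(cfg.input_path)
    log("load", f"{raster.shape[0]}x{raster.shape[1]} image", raster)

    gray = raster_io.to_grayscale(raster)
    for op in script:
        if op["op"] == "filter":
            gray = preprocess.apply_filter(gray, op["kind"], op.get("param"))
            log("preprocess", f"filter {op['kind']}", gray)

    threshold_ops = [op for op in script if op["op"] in _THRESHOLD_OPS]
    if threshold_ops:
        op = threshold_ops[-1]
        if op["op"] == "threshold_global":
            binary = preprocess.threshold_global(gray, op.get("t", preprocess.AUTO))
        else:
            binary = preprocess.threshold_local(gray, int(op["window"]), int(op.get("offset", 0)))
    else:
        binary = preprocess.threshold_global(gray, cfg.threshold)
    log("binarize", f"{int(binary.sum())} foreground px", binary)

    for op in script:
        name = op["op"]
        if name in ("pencil", "rubber", "line", "fill"):
            stroke = preprocess.EditStroke(
                kind=name, points=_as_points(op["points"]), radius=int(op.get("radius", 0))
            )
            binary = preprocess.draw_edit(binary, stroke)
            log("edit", f"{name} stroke ({len(stroke.points)} pts)", binary)
        elif name == "white_halo":
            region = raster_io.Rect(
                int(op["top"]), int(op["left"]), int(op["height"]), int(op["width"])
            )
            binary = preprocess.white_halo(binary, region, int(op.get("thickness", 1)))
            log("edit", f"white halo {region}", binary)

    skel: Skeleton = skeletonize(binary)
    log("skeletonize", f"{int(skel.pixels.sum())} skeleton px", skel.pixels)

    if cfg.seed_point is not None:
        mask: ComponentMask = flood(skel, tuple(cfg.seed_point))
    else:
        mask = largest_component(skel)
    log("flood", f"component of {mask.count} px from seed {mask.seed}", mask.member)

    ns: NodeSet = detect_nodes(skel, mask)
    node_edits = []
    for op in script:
        if op["op"] == "add_node":
            node_edits.append(NodeEdit("add", pos=tuple(_as_points([op["pos"]])[0]), kind=op["kind"]))
        elif op["op"] == "move_node":
            node_edits.append(NodeEdit("move", node_id=int(op["id"]), pos=tuple(_as_points([op["pos"]])[0])))
        elif op["op"] == "remove_node":
            node_edits.append(NodeEdit("remove", node_id=int(op["id"])))
    if node_edits:
        ns = edit_nodes(ns, node_edits, mask)
    log("nodes", f"{len(ns.tips)} tips, {len(ns.inner)} inner nodes")

    graph = trace_branches(skel, mask, ns)
    for op in script:
        if op["op"] == "add_branch":
            graph = add_manual_branch(graph, int(op["a"]), int(op["b"]), float(op["length"]))
    log("trace", f"{len(graph.branches)} branches")

    diagnostics = validate(graph)
    if diagnostics:
        log("validate", f"{len(diagnostics)} problem(s); fix the image or edit script and re-run")
        return PipelineResult(
            newick=None, diagnostics=diagnostics, graph=graph, stages=stages, snapshots=snaps
        )
    log("validate", "tree graph is valid")

    choice = TreeTypeChoice(kind=cfg.tree_type, slope_tolerance=cfg.slope_tolerance)
    overrides = {
        (int(op["a"]), int(op["b"])): float(op["value"])
        for op in script
        if op["op"] == "set_length"
    }
    blens = calibrate(graph, choice, bar=cfg.scale_bar, overrides=overrides)
    log("measure", f"{len(blens)} branch lengths ({cfg.tree_type} mode)")

    names = _resolve_names(graph, cfg.tip_names)
    phylo = newick_mod.root_tree(
        graph,
        root=cfg.root,
        names=names,
        branch_lengths={k: v.value for k, v in blens.items()},
    )
    out = newick_mod.to_newick(phylo, with_lengths=cfg.with_lengths, precision=cfg.precision)
    log("newick", f"root node {phylo.root}, {len(names)} named tips")
    return PipelineResult(
        newick=out,
        diagnostics=[],
        graph=graph,
        names=names,
        branch_lengths=blens,
        stages=stages,
        snapshots=snaps,
    )


def _resolve_names(graph: TreeGraph, tip_names) -> dict[int, str]:
    """Turn the configured naming into an id->name map for assign_names."""
    if tip_names == newick_mod.AUTO or tip_names is None:
        return newick_mod.assign_names(graph, newick_mod.AUTO)
    if isinstance(tip_names, Mapping):
        return newick_mod.assign_names(graph, {int(k): v for k, v in tip_names.items()})
    # position-anchored names: list of {"pos": (row, col), "name": str};
    # each anchor names the nearest detected tip
    tips = graph.nodes.tips
    mapping: dict[int, str] = {}
    for entry in tip_names:
        r, c = entry["pos"]
        nearest = min(tips, key=lambda t: (t.pos[0] - r) ** 2 + (t.pos[1] - c) ** 2)
        mapping[nearest.id] = str(entry["name"])
    return newick_mod.assign_names(graph, mapping)
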