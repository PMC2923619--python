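"""Rectangular-phylogram layout.

x is cumulative branch length times a pixel scale, y is leaf rank; branches
are drawn as right-angle elbows (a horizontal segment per non-root node plus
one vertical connector per internal node).  Coordinates use the SVG
convention: origin top-left, y grows downward, first leaf at the top.  Node x
is relative to the left edge of the branch area (the root of a tree without a
root edge sits at x = 0); the renderer adds the canvas margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .tree import Tree, cumulative_depths, leaves_in_order


class LayoutError(ValueError):
    """Canvas/geometry validation failure."""


@dataclass(frozen=True)
class Canvas:
    """Drawing surface budget, in px.

    ``margin`` applies to all four sides.  ``label_gutter`` is reserved right
    of the branch area (rect) or outside the tree radius (circular) for leaf
    labels; ``chart_gutter`` is reserved beyond the labels for chart tracks.
    """

    width: float = 800.0
    height: float = 600.0
    margin: float = 10.0
    label_gutter: float = 120.0
    chart_gutter: float = 0.0

    @property
    def branch_area_width(self) -> float:
        return self.width - 2 * self.margin - self.label_gutter - self.chart_gutter

    @property
    def drawable_height(self) -> float:
        return self.height - 2 * self.margin

    def validate(self) -> None:
        if self.branch_area_width <= 0 or self.drawable_height <= 0:
            raise LayoutError(
                f"canvas {self.width}x{self.height} leaves no drawable branch "
                f"area after margins/gutters"
            )


@dataclass
class HSeg:
    """Horizontal branch segment for ``node_id`` (the edge leading to it)."""

    x0: float
    x1: float
    y: float
    node_id: int


@dataclass
class VSeg:
    """Vertical connector under internal node ``node_id``."""

    x: float
    y0: float
    y1: float
    node_id: int


@dataclass
class RectLayout:
    positions: Dict[int, Tuple[float, float]]  # node_id -> (x, y)
    h_segments: List[HSeg]
    v_segments: List[VSeg]
    scale: float  # px per branch-length unit
    scale_bar: Optional[Tuple[float, float]]  # (units, px) or None
    canvas: Canvas
    leaf_ids: List[int]  # leaves in display order
    branch_area_width: float
    max_depth: float

    @property
    def leaf_spacing(self) -> float:
        return self.canvas.drawable_height / len(self.leaf_ids)


def pick_scale_bar(max_depth: float) -> Tuple[float, float]:
    """Round length (1/2/5 x 10^k units) nearest to 10% of the tree depth.

    Nearness is measured on a log scale so e.g. 0.2 beats 0.5 for a target
    of 0.3.  Returns (units, fraction-of-depth); the caller multiplies by the
    px/unit scale.
    """
    target = 0.1 * max_depth
    k = math.floor(math.log10(target))
    best = None
    for kk in (k - 1, k, k + 1):
        for m in (1.0, 2.0, 5.0):
            cand = m * 10.0 ** kk
            score = abs(math.log10(cand / target))
            if best is None or score < best[0]:
                best = (score, cand)
    return best[1], best[1] / max_depth


def layout_rectangular(tree: Tree, canvas: Canvas = Canvas()) -> RectLayout:
    """Place every node and build the elbow branch geometry.

    scale = branch-area width / max cumulative leaf depth.  Leaf i of n gets
    y = margin + (i + 0.5) * drawable_height / n; an internal node's y is the
    arithmetic mean of its children's.  The branch path to child c is the
    horizontal segment (x(parent), y(c)) -- (x(c), y(c)); siblings share a
    vertical connector at x(parent).
    """
    canvas.validate()
    depths, max_depth = cumulative_depths(tree)
    bw = canvas.branch_area_width
    scale = bw / max_depth if max_depth > 0 else 0.0

    leaves = leaves_in_order(tree)
    n = len(leaves)
    spacing = canvas.drawable_height / n
    positions: Dict[int, Tuple[float, float]] = {}
    leaf_rank = {leaf.node_id: i for i, leaf in enumerate(leaves)}

    def place_all(node) -> float:
        x = depths[node.node_id] * scale
        if node.is_leaf:
            y = canvas.margin + (leaf_rank[node.node_id] + 0.5) * spacing
        else:
            child_ys = [place_all(c) for c in node.children]
            y = sum(child_ys) / len(child_ys)
        positions[node.node_id] = (x, y)
        return y

    place_all(tree.root)

    h_segments: List[HSeg] = []
    v_segments: List[VSeg] = []
    root = tree.root
    root_x, root_y = positions[root.node_id]
    if root_x > 0 or tree.n_nodes == 1:
        h_segments.append(HSeg(x0=0.0, x1=root_x, y=root_y, node_id=root.node_id))
    for node in root.preorder():
        if node.children:
            px, _ = positions[node.node_id]
            child_ys = [positions[c.node_id][1] for c in node.children]
            v_segments.append(
                VSeg(x=px, y0=min(child_ys), y1=max(child_ys), node_id=node.node_id)
            )
            for child in node.children:
                cx, cy = positions[child.node_id]
                h_segments.append(HSeg(x0=px, x1=cx, y=cy, node_id=child.node_id))

    scale_bar = None
    if max_depth > 0 and not tree.unit_lengths:
        units, frac = pick_scale_bar(max_depth)
        scale_bar = (units, units * scale)

    return RectLayout(
        positions=positions,
        h_segments=h_segments,
        v_segments=v_segments,
        scale=scale,
        scale_bar=scale_bar,
        canvas=canvas,
        leaf_ids=[leaf.node_id for leaf in leaves],
        branch_area_width=bw,
        max_depth=max_depth,
    )
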