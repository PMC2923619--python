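"""Circular-phylogram layout.

Radius encodes cumulative branch length, angle encodes leaf rank.  Angles are
degrees throughout the public types, measured from 12 o'clock, clockwise
positive; leaf i of n sits at start_angle + (i + 0.5) * usable_arc / n and an
internal node at the mean of its children's angles.  Branches are a radial
segment per non-root node plus a true circular arc (not a chord) per internal
node at its own radius.  Cartesian conversion: x = cx + r sin(theta),
y = cy - r cos(theta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

from .layout_rect import Canvas, LayoutError
from .tree import Tree, cumulative_depths, leaves_in_order


@dataclass(frozen=True)
class CircularParams:
    """Angular configuration of the circular view.

    total_arc: degrees of circle used, in (0, 360]; default full circle.
    start_angle: degrees at which the first leaf slot begins (0 = 12 o'clock).
    inner_radius: px radius at which the root sits.
    gap: degrees of unused arc (a small gap keeps the first and last leaf
    labels from colliding on a full circle).
    """

    total_arc: float = 360.0
    start_angle: float = 0.0
    inner_radius: float = 0.0
    gap: float = 0.0

    def validate(self) -> None:
        if not 0.0 < self.total_arc <= 360.0:
            raise LayoutError(f"total_arc {self.total_arc} not in (0, 360]")
        if self.gap < 0 or self.total_arc - self.gap <= 0:
            raise LayoutError("gap leaves no usable arc")
        if self.inner_radius < 0:
            raise LayoutError("inner_radius must be >= 0")

    @property
    def usable_arc(self) -> float:
        return self.total_arc - self.gap


@dataclass
class RadialSeg:
    """Radial branch segment for ``node_id`` at angle theta (degrees)."""

    r0: float
    r1: float
    theta: float
    node_id: int


@dataclass
class ArcSeg:
    """Arc connector under internal node ``node_id`` at its own radius."""

    r: float
    theta0: float
    theta1: float
    node_id: int


@dataclass
class CircularLayout:
    polar: Dict[int, Tuple[float, float]]  # node_id -> (r, theta degrees)
    radial_segments: List[RadialSeg]
    arc_segments: List[ArcSeg]
    center: Tuple[float, float]
    scale: float  # px per branch-length unit
    canvas: Canvas
    params: CircularParams
    leaf_ids: List[int]
    outer_radius: float
    max_depth: float

    def leaf_slot(self, rank: int) -> Tuple[float, float]:
        """Angular slot [theta_start, theta_end] of leaf at display rank."""
        n = len(self.leaf_ids)
        slot = self.params.usable_arc / n
        start = self.params.start_angle + rank * slot
        return start, start + slot

    def to_xy(self, r: float, theta_deg: float) -> Tuple[float, float]:
        rad = math.radians(theta_deg)
        cx, cy = self.center
        return cx + r * math.sin(rad), cy - r * math.cos(rad)


def layout_circular(
    tree: Tree,
    canvas: Canvas = Canvas(),
    params: CircularParams = CircularParams(),
) -> CircularLayout:
    """Place every node in polar coordinates and build the branch geometry.

    The outer tree radius is min(width, height)/2 minus margin and the label
    and chart gutters, so labels and chart rings fit inside the canvas;
    scale = (outer_radius - inner_radius) / max cumulative leaf depth.
    """
    params.validate()
    if canvas.drawable_height <= 0:
        raise LayoutError("canvas has no drawable area")
    outer_radius = (
        min(canvas.width, canvas.height) / 2.0
        - canvas.margin
        - canvas.label_gutter
        - canvas.chart_gutter
    )
    if outer_radius <= params.inner_radius:
        raise LayoutError(
            f"outer tree radius {outer_radius:.1f} px does not exceed "
            f"inner_radius {params.inner_radius:.1f} px"
        )

    depths, max_depth = cumulative_depths(tree)
    scale = (outer_radius - params.inner_radius) / max_depth if max_depth > 0 else 0.0

    leaves = leaves_in_order(tree)
    n = len(leaves)
    slot = params.usable_arc / n
    leaf_rank = {leaf.node_id: i for i, leaf in enumerate(leaves)}
    polar: Dict[int, Tuple[float, float]] = {}

    def place(node) -> float:
        r = params.inner_radius + depths[node.node_id] * scale
        if node.is_leaf:
            theta = params.start_angle + (leaf_rank[node.node_id] + 0.5) * slot
        else:
            child_thetas = [place(c) for c in node.children]
            theta = sum(child_thetas) / len(child_thetas)
        polar[node.node_id] = (r, theta)
        return theta

    place(tree.root)

    radial_segments: List[RadialSeg] = []
    arc_segments: List[ArcSeg] = []
    root = tree.root
    root_r, root_theta = polar[root.node_id]
    if root_r > params.inner_radius or tree.n_nodes == 1:
        radial_segments.append(
            RadialSeg(r0=params.inner_radius, r1=root_r, theta=root_theta,
                      node_id=root.node_id)
        )
    for node in root.preorder():
        if node.children:
            pr, _ = polar[node.node_id]
            child_thetas = [polar[c.node_id][1] for c in node.children]
            arc_segments.append(
                ArcSeg(r=pr, theta0=min(child_thetas), theta1=max(child_thetas),
                       node_id=node.node_id)
            )
            for child in node.children:
                cr, ct = polar[child.node_id]
                radial_segments.append(
                    RadialSeg(r0=pr, r1=cr, theta=ct, node_id=child.node_id)
                )

    center = (canvas.width / 2.0, canvas.height / 2.0)
    return CircularLayout(
        polar=polar,
        radial_segments=radial_segments,
        arc_segments=arc_segments,
        center=center,
        scale=scale,
        canvas=canvas,
        params=params,
        leaf_ids=[leaf.node_id for leaf in leaves],
        outer_radius=outer_radius,
        max_depth=max_depth,
    )
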