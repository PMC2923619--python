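"""Deterministic SVG serialization of layouts, chart tracks, labels and
styles.

The output is a standalone SVG 1.1 document.  Element order is fixed —
background, branches, confidence labels, scale bar, leaf labels, tracks — and
every numeric attribute is printed at fixed 3-decimal precision with "-0.000"
normalized to "0.000", so identical inputs produce byte-identical files.
Interactivity is static: a node with a ``url`` wraps its label in an anchor,
a node or cell description becomes a child ``<title>`` (the native browser
tooltip), and stable element ids (``node-<id>``, ``track-<k>-cell-<i>``) let
downstream pages attach their own scripts.
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

from .charts import RectCell, SectorCell, TrackGeometry
from .layout_circular import CircularLayout
from .layout_rect import RectLayout
from .tree import Tree, leaves_in_order

logger = logging.getLogger(__name__)

SVG_NS = "http://www.w3.org/2000/svg"

#: heuristic px-per-character width at font size 1 (SVG offers no font
#: metrics at generation time); used only for gutter budgeting advice
CHAR_WIDTH_FACTOR = 0.6


@dataclass
class StyleSpec:
    """Merged stylistic parameters.

    A total spec (every field set) is obtained with :func:`merge_styles`,
    which applies defaults <- XML-embedded <- programmatic/CLI in increasing
    precedence.  ``overrides`` maps a node label or track name to a partial
    style dict (e.g. ``{"TaxonA": {"label_color": "#c00"}}``).
    """

    font_family: str = "sans-serif"
    font_size: float = 10.0  # pt
    branch_stroke_width: float = 1.5  # px
    branch_color: str = "#333333"
    label_color: str = "#000000"
    background: str = "#ffffff"
    show_confidence: bool = True
    show_scale_bar: bool = True
    confidence_font_size: float = 7.0
    confidence_font_floor: float = 5.0  # suppress confidence text below this
    track_fill: str = "#4477aa"
    overrides: Dict[str, Dict[str, str]] = field(default_factory=dict)


_STYLE_FIELDS = {f.name: f.type for f in dc_fields(StyleSpec)}
_BOOL_FIELDS = {"show_confidence", "show_scale_bar"}
_FLOAT_FIELDS = {
    "font_size",
    "branch_stroke_width",
    "confidence_font_size",
    "confidence_font_floor",
}


class StyleError(ValueError):
    pass


def _coerce(key: str, value):
    if key in _BOOL_FIELDS:
        if isinstance(value, bool):
            return value
        return str(value).strip().lower() in ("1", "true", "yes", "on")
    if key in _FLOAT_FIELDS:
        return float(value)
    return value


def merge_styles(
    defaults: Optional[StyleSpec] = None,
    xml_style: Optional[Mapping] = None,
    cli_style: Optional[Mapping] = None,
) -> Tuple[StyleSpec, Dict[str, str]]:
    """Field-wise merge with precedence cli > xml > defaults.

    ``xml_style`` and ``cli_style`` are partial mappings (field name ->
    value).  Returns the total spec plus a provenance map recording which
    layer supplied each field.  Unknown keys are warned about and ignored.
    """
    spec = StyleSpec() if defaults is None else defaults
    merged = StyleSpec(**{f.name: getattr(spec, f.name) for f in dc_fields(StyleSpec)})
    provenance = {f.name: "default" for f in dc_fields(StyleSpec)}
    for layer_name, layer in (("xml", xml_style), ("cli", cli_style)):
        if not layer:
            continue
        for key, value in layer.items():
            if key == "overrides":
                ov = dict(merged.overrides)
                for target, sub in value.items():
                    ov[target] = {**ov.get(target, {}), **sub}
                merged.overrides = ov
                provenance["overrides"] = layer_name
                continue
            if key not in _STYLE_FIELDS:
                logger.warning("unknown style key %r ignored", key)
                continue
            setattr(merged, key, _coerce(key, value))
            provenance[key] = layer_name
    return merged, provenance


def fmt(value: float) -> str:
    """Fixed-point 3-decimal formatting; "-0.000" normalized to "0.000"."""
    out = f"{value:.3f}"
    return "0.000" if out == "-0.000" else out


def _conf_text(value: float) -> str:
    return f"{value:.10g}"


def _polar_xy(center: Tuple[float, float], r: float, theta_deg: float) -> Tuple[float, float]:
    rad = math.radians(theta_deg)
    return center[0] + r * math.sin(rad), center[1] - r * math.cos(rad)


def _arc_path(center, r, theta0, theta1) -> str:
    """Circular arc from theta0 to theta1 (degrees, clockwise on screen)."""
    x0, y0 = _polar_xy(center, r, theta0)
    x1, y1 = _polar_xy(center, r, theta1)
    large = 1 if (theta1 - theta0) > 180.0 else 0
    return (
        f"M {fmt(x0)} {fmt(y0)} "
        f"A {fmt(r)} {fmt(r)} 0 {large} 1 {fmt(x1)} {fmt(y1)}"
    )


def _sector_path(center, r_in, r_out, theta0, theta1) -> str:
    """Closed annular-sector path (two arcs + two radial edges)."""
    large = 1 if (theta1 - theta0) > 180.0 else 0
    ox0, oy0 = _polar_xy(center, r_out, theta0)
    ox1, oy1 = _polar_xy(center, r_out, theta1)
    ix0, iy0 = _polar_xy(center, r_in, theta0)
    ix1, iy1 = _polar_xy(center, r_in, theta1)
    return (
        f"M {fmt(ox0)} {fmt(oy0)} "
        f"A {fmt(r_out)} {fmt(r_out)} 0 {large} 1 {fmt(ox1)} {fmt(oy1)} "
        f"L {fmt(ix1)} {fmt(iy1)} "
        f"A {fmt(r_in)} {fmt(r_in)} 0 {large} 0 {fmt(ix0)} {fmt(iy0)} Z"
    )


def _label_style(style: StyleSpec, label: Optional[str]) -> Tuple[str, float]:
    color, size = style.label_color, style.font_size
    if label and label in style.overrides:
        ov = style.overrides[label]
        color = ov.get("label_color", color)
        size = float(ov.get("font_size", size))
    return color, size


def _track_fill(style: StyleSpec, track) -> str:
    fill = track.style.get("fill", style.track_fill)
    if track.name in style.overrides:
        fill = style.overrides[track.name].get("fill", fill)
    return fill


def _binary_groups(track) -> Dict[str, str]:
    """Parse the 'groups' style key: comma-separated label=color pairs."""
    raw = track.style.get("groups", "")
    out: Dict[str, str] = {}
    for part in raw.split(","):
        if "=" in part:
            label, color = part.split("=", 1)
            out[label.strip()] = color.strip()
    return out


def render(
    base: Union[RectLayout, CircularLayout],
    tracks: Sequence[TrackGeometry],
    tree: Tree,
    style: Optional[StyleSpec] = None,
) -> str:
    """Serialize one finished layout (plus tracks) to SVG text."""
    if style is None:
        style = StyleSpec()
    canvas = base.canvas
    nodes = {n.node_id: n for n in tree.root.preorder()}
    leaves = leaves_in_order(tree)

    svg = ET.Element(
        "svg",
        {
            "xmlns": SVG_NS,
            "width": fmt(canvas.width),
            "height": fmt(canvas.height),
            "viewBox": f"0 0 {fmt(canvas.width)} {fmt(canvas.height)}",
            "version": "1.1",
        },
    )
    ET.SubElement(
        svg,
        "rect",
        {
            "id": "background",
            "x": "0.000",
            "y": "0.000",
            "width": fmt(canvas.width),
            "height": fmt(canvas.height),
            "fill": style.background,
        },
    )

    branches = ET.SubElement(svg, "g", {
        "id": "branches",
        "stroke": style.branch_color,
        "stroke-width": fmt(style.branch_stroke_width),
        "fill": "none",
        "stroke-linecap": "square",
    })
    conf_group = ET.SubElement(svg, "g", {
        "id": "confidence-labels",
        "font-family": style.font_family,
        "font-size": fmt(style.confidence_font_size),
        "fill": style.label_color,
    })

    if isinstance(base, RectLayout):
        _render_rect(svg, branches, conf_group, base, tracks, tree, style, nodes, leaves)
    elif isinstance(base, CircularLayout):
        _render_circular(svg, branches, conf_group, base, tracks, tree, style, nodes, leaves)
    else:
        raise TypeError(f"unsupported layout type {type(base).__name__}")

    body = ET.tostring(svg, encoding="unicode")
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + body + "\n"


def _leaf_text_element(parent, node, x, y, extra_attrs, style):
    """<text> for a leaf label, wrapped in <a> when a url is present."""
    container = parent
    if node.url:
        container = ET.SubElement(parent, "a", {"href": node.url})
    color, size = _label_style(style, node.label)
    attrs = {
        "id": f"label-{node.node_id}",
        "x": fmt(x),
        "y": fmt(y),
        "font-family": style.font_family,
        "font-size": fmt(size),
        "fill": color,
    }
    attrs.update(extra_attrs)
    text = ET.SubElement(container, "text", attrs)
    if node.description:
        title = ET.SubElement(text, "title")
        title.text = node.description
        tspan = ET.SubElement(text, "tspan")
        tspan.text = node.label or ""
    else:
        text.text = node.label or ""
    return text


def _cell_tooltip(cell_el, leaf, geom) -> None:
    title = ET.SubElement(cell_el, "title")
    label = leaf.label or f"leaf {leaf.node_id}"
    title.text = f"{label} · {geom.track.name}: {cell_value_text(geom, leaf)}"


def cell_value_text(geom: TrackGeometry, leaf) -> str:
    for cell in geom.cells:
        if cell.leaf_id == leaf.node_id:
            return f"{cell.value:.10g}"
    return "?"


def _render_tracks(svg, base, tracks, tree, style, leaves, shape) -> None:
    leaf_by_id = {leaf.node_id: leaf for leaf in leaves}
    for k, geom in enumerate(tracks):
        group = ET.SubElement(svg, "g", {"id": f"track-{k}"})
        fill = _track_fill(style, geom.track)
        groups = _binary_groups(geom.track)
        for i, cell in enumerate(geom.cells):
            leaf = leaf_by_id[cell.leaf_id]
            cell_fill = fill
            if groups and leaf.label in groups:
                cell_fill = groups[leaf.label]
            if shape == "rect":
                attrs = {
                    "id": f"track-{k}-cell-{i}",
                    "x": fmt(base.canvas.margin + cell.x),
                    "y": fmt(cell.y),
                    "width": fmt(cell.width),
                    "height": fmt(cell.height),
                }
                if cell.filled:
                    attrs["fill"] = cell_fill
                else:
                    attrs["fill"] = "none"
                    attrs["stroke"] = "#cccccc"
                    attrs["stroke-width"] = "0.500"
                el = ET.SubElement(group, "rect", attrs)
            else:
                attrs = {
                    "id": f"track-{k}-cell-{i}",
                    "d": _sector_path(
                        base.center, cell.r_in, cell.r_out,
                        cell.theta_start, cell.theta_end,
                    ),
                }
                if cell.filled:
                    attrs["fill"] = cell_fill
                else:
                    attrs["fill"] = "none"
                    attrs["stroke"] = "#cccccc"
                    attrs["stroke-width"] = "0.500"
                el = ET.SubElement(group, "path", attrs)
            _cell_tooltip(el, leaf, geom)


def _render_rect(svg, branches, conf_group, base: RectLayout, tracks, tree,
                 style: StyleSpec, nodes, leaves) -> None:
    ox = base.canvas.margin  # branch-area x origin

    for seg in base.h_segments:
        ET.SubElement(branches, "path", {
            "id": f"node-{seg.node_id}",
            "d": f"M {fmt(ox + seg.x0)} {fmt(seg.y)} H {fmt(ox + seg.x1)}",
        })
    for seg in base.v_segments:
        ET.SubElement(branches, "path", {
            "id": f"node-{seg.node_id}-connector",
            "d": f"M {fmt(ox + seg.x)} {fmt(seg.y0)} V {fmt(seg.y1)}",
        })

    if style.show_confidence and style.confidence_font_size >= style.confidence_font_floor:
        for seg in base.h_segments:
            node = nodes[seg.node_id]
            if node.confidence is None or node.is_leaf:
                continue
            el = ET.SubElement(conf_group, "text", {
                "id": f"confidence-{node.node_id}",
                "x": fmt(ox + seg.x0 + 2.0),
                "y": fmt(seg.y - 2.0),
            })
            el.text = _conf_text(node.confidence)

    if style.show_scale_bar and base.scale_bar is not None:
        units, px = base.scale_bar
        bar = ET.SubElement(svg, "g", {
            "id": "scale-bar",
            "stroke": style.branch_color,
            "stroke-width": fmt(style.branch_stroke_width),
        })
        y = base.canvas.height - base.canvas.margin / 2.0
        ET.SubElement(bar, "path", {
            "d": f"M {fmt(ox)} {fmt(y)} H {fmt(ox + px)}",
        })
        label = ET.SubElement(bar, "text", {
            "x": fmt(ox + px + 4.0),
            "y": fmt(y),
            "font-family": style.font_family,
            "font-size": fmt(style.confidence_font_size),
            "fill": style.label_color,
            "stroke": "none",
        })
        label.text = f"{units:.10g}"

    labels = ET.SubElement(svg, "g", {"id": "leaf-labels"})
    for leaf in leaves:
        x, y = base.positions[leaf.node_id]
        _leaf_text_element(
            labels, leaf,
            ox + x + 4.0,
            y + style.font_size * 0.35,  # approximate vertical centering
            {}, style,
        )

    _render_tracks(svg, base, tracks, tree, style, leaves, "rect")


def _render_circular(svg, branches, conf_group, base: CircularLayout, tracks,
                     tree, style: StyleSpec, nodes, leaves) -> None:
    center = base.center

    for seg in base.radial_segments:
        x0, y0 = _polar_xy(center, seg.r0, seg.theta)
        x1, y1 = _polar_xy(center, seg.r1, seg.theta)
        ET.SubElement(branches, "path", {
            "id": f"node-{seg.node_id}",
            "d": f"M {fmt(x0)} {fmt(y0)} L {fmt(x1)} {fmt(y1)}",
        })
    for seg in base.arc_segments:
        if seg.theta1 - seg.theta0 <= 0:
            continue  # single-child arc degenerates to a point
        ET.SubElement(branches, "path", {
            "id": f"node-{seg.node_id}-connector",
            "d": _arc_path(center, seg.r, seg.theta0, seg.theta1),
        })

    if style.show_confidence and style.confidence_font_size >= style.confidence_font_floor:
        for seg in base.radial_segments:
            node = nodes[seg.node_id]
            if node.confidence is None or node.is_leaf:
                continue
            mx, my = _polar_xy(center, (seg.r0 + seg.r1) / 2.0, seg.theta)
            el = ET.SubElement(conf_group, "text", {
                "id": f"confidence-{node.node_id}",
                "x": fmt(mx),
                "y": fmt(my - 2.0),
                "text-anchor": "middle",
            })
            el.text = _conf_text(node.confidence)

    labels = ET.SubElement(svg, "g", {"id": "leaf-labels"})
    pad = 4.0
    for leaf in leaves:
        r, theta = base.polar[leaf.node_id]
        lx, ly = _polar_xy(center, base.outer_radius + pad, theta)
        t = theta % 360.0
        if 90.0 < t < 270.0:
            # flip so text is never upside down; anchor at the far end
            rot = t + 90.0
            anchor = "end"
        else:
            rot = t - 90.0
            anchor = "start"
        _leaf_text_element(
            labels, leaf, lx, ly,
            {
                "text-anchor": anchor,
                "dominant-baseline": "middle",
                "transform": f"rotate({fmt(rot)} {fmt(lx)} {fmt(ly)})",
            },
            style,
        )

    _render_tracks(svg, base, tracks, tree, style, leaves, "circular")


def estimate_label_gutter(tree: Tree, font_size: float) -> float:
    """Suggested label gutter: longest label times the width heuristic."""
    longest = max((len(l.label or "") for l in leaves_in_order(tree)), default=0)
    return longest * font_size * CHAR_WIDTH_FACTOR
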